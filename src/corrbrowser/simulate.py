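"""Synthetic cohorts with planted hub–responder correlation structure.

The generator emulates the study design the browser assumes: a discovery
cohort of 105 postmenopausal blood samples quantified on ~17k array features
plus a PCR miRNA layer, and a larger replication cohort (n = 1204) sharing
the same structure.

Generative model (single latent factor per hub):

* each hub h draws a latent factor z_h ~ N(0, 1) per sample and is observed
  as z_h itself;
* each of its responders is lam * z_h + sqrt(1 - lam^2) * noise_sd * eps with
  eps ~ N(0, 1), so at noise_sd = 1 every feature has unit population
  variance and the planted hub–responder correlation is exactly lam (and
  lam^2 between co-responders);
* background features are independent N(0, 1);
* each miRNA couples with negative loading beta to a designated target's
  observed value and is expressed on a Ct-like scale (affine map of the
  unit-normal value into [18, 36]), with cells dropped at random to mimic
  failed amplification.

All randomness flows from one spec-level seed through named SeedSequence
streams (cohort, replication, annotation, mirna), so each sub-simulation is
independently reproducible.
"""

from __future__ import annotations

import json
from dataclasses import dataclass, field, asdict

import numpy as np
import pandas as pd

from .expression import ARRAY, PCR, ExpressionMatrix

__all__ = [
    "HubSpec",
    "PcrBlockSpec",
    "ReplicationSpec",
    "SimulationSpec",
    "GroundTruth",
    "simulate_cohort",
    "simulate_replication",
    "simulate_annotation",
    "simulate_mirna_layer",
    "build_annotation_frame",
    "mini_spec",
    "full_scale_spec",
    "write_cohort_files",
]

_STREAMS = {"cohort": 0, "replication": 1, "annotation": 2, "mirna": 3}


def _rng(seed: int, stream: str) -> np.random.Generator:
    root = np.random.SeedSequence(seed)
    return np.random.default_rng(root.spawn(len(_STREAMS))[_STREAMS[stream]])


@dataclass(frozen=True)
class HubSpec:
    hub_id: str
    n_responders: int
    loading: float  # planted hub-responder correlation, in (0, 1)


@dataclass(frozen=True)
class PcrBlockSpec:
    n_mirna: int = 10
    coupling: float = -0.6  # planted miRNA-target correlation, <= 0
    ct_dropout_rate: float = 0.05


@dataclass(frozen=True)
class ReplicationSpec:
    n_samples: int = 1204
    feature_dropout_rate: float = 0.07


@dataclass(frozen=True)
class SimulationSpec:
    """Cohort design: sample/feature counts, planted hubs, noise and rates."""

    n_samples: int = 105
    n_features: int = 2000
    hubs: tuple[HubSpec, ...] = (HubSpec("HUB01", 200, 0.8),)
    noise_sd: float = 1.0
    background_annotation_rate: float = 0.483
    enriched_annotation_rate: float = 0.91
    pcr_block: PcrBlockSpec | None = PcrBlockSpec()
    replication: ReplicationSpec = ReplicationSpec()
    rng_seed: int = 0

    def __post_init__(self) -> None:
        for hub in self.hubs:
            if not (0 <= hub.loading < 1):
                raise ValueError("hub loading must lie in [0, 1)")
        total = len(self.hubs) + sum(h.n_responders for h in self.hubs)
        if total > self.n_features:
            raise ValueError("hubs + responders exceed n_features")
        for rate in (self.background_annotation_rate, self.enriched_annotation_rate):
            if not (0 <= rate <= 1):
                raise ValueError("annotation rates must lie in [0, 1]")
        if self.pcr_block is not None and self.pcr_block.coupling > 0:
            raise ValueError("miRNA coupling must be <= 0")


@dataclass
class GroundTruth:
    """Planted structure of a simulated cohort.

    ``roles`` partitions feature IDs into hub / responder:<hub> / background /
    mirna; ``planted_pairs`` lists every (hub, responder) and (mirna, target)
    pair whose population correlation is non-zero by construction.
    """

    spec: SimulationSpec
    roles: dict[str, str]
    responders: dict[str, list[str]]
    mirna_targets: dict[str, str] = field(default_factory=dict)

    @property
    def planted_pairs(self) -> list[tuple[str, str]]:
        pairs = [(h, r) for h, rs in self.responders.items() for r in rs]
        pairs += list(self.mirna_targets.items())
        return pairs

    def array_features(self) -> list[str]:
        return [f for f, role in self.roles.items() if role != "mirna"]


def _feature_layout(spec: SimulationSpec):
    """Deterministic feature IDs and roles: hubs, responders, background."""
    ids: list[str] = []
    roles: dict[str, str] = {}
    responders: dict[str, list[str]] = {}
    for hub in spec.hubs:
        ids.append(hub.hub_id)
        roles[hub.hub_id] = "hub"
        rs = [f"{hub.hub_id}_R{i:04d}" for i in range(1, hub.n_responders + 1)]
        responders[hub.hub_id] = rs
        ids.extend(rs)
        for r in rs:
            roles[r] = f"responder:{hub.hub_id}"
    n_bg = spec.n_features - len(ids)
    for i in range(1, n_bg + 1):
        fid = f"BG{i:05d}"
        ids.append(fid)
        roles[fid] = "background"
    return ids, roles, responders


def simulate_cohort(spec: SimulationSpec) -> tuple[ExpressionMatrix, GroundTruth]:
    """Array-platform cohort with planted hub-responder correlations.

    Deterministic given ``spec.rng_seed``.  The PCR miRNA layer is appended
    separately by :func:`simulate_mirna_layer`.
    """
    rng = _rng(spec.rng_seed, "cohort")
    ids, roles, responders = _feature_layout(spec)
    values = np.empty((len(ids), spec.n_samples))
    pos = {f: i for i, f in enumerate(ids)}

    for hub in spec.hubs:
        z = rng.standard_normal(spec.n_samples)
        values[pos[hub.hub_id]] = z
        lam = hub.loading
        eps = rng.standard_normal((hub.n_responders, spec.n_samples))
        values[[pos[r] for r in responders[hub.hub_id]]] = (
            lam * z + np.sqrt(1.0 - lam * lam) * spec.noise_sd * eps
        )
    bg = [f for f in ids if roles[f] == "background"]
    values[[pos[f] for f in bg]] = rng.standard_normal((len(bg), spec.n_samples))

    matrix = ExpressionMatrix(
        feature_ids=ids,
        sample_ids=[f"S{i:04d}" for i in range(1, spec.n_samples + 1)],
        values=values,
        platform=np.array([ARRAY] * len(ids), dtype=object),
    )
    return matrix, GroundTruth(spec=spec, roles=roles, responders=responders)


def simulate_replication(spec: SimulationSpec, truth: GroundTruth) -> ExpressionMatrix:
    """Replication cohort: fresh samples from the same planted structure.

    Array features only (mirroring an array-based replication platform); a
    ``feature_dropout_rate`` fraction of features is removed at random,
    simulating transcripts undetected on the replication platform.  Hub
    features are exempt from dropout: the replication analysis conditions on
    the seed transcript being measured in both cohorts.
    """
    rep = spec.replication
    if rep.feature_dropout_rate >= 1:
        raise ValueError("feature_dropout_rate must be < 1")
    rng = _rng(spec.rng_seed, "replication")
    ids, roles, responders = _feature_layout(spec)
    values = np.empty((len(ids), rep.n_samples))
    pos = {f: i for i, f in enumerate(ids)}
    for hub in spec.hubs:
        z = rng.standard_normal(rep.n_samples)
        values[pos[hub.hub_id]] = z
        lam = hub.loading
        eps = rng.standard_normal((hub.n_responders, rep.n_samples))
        values[[pos[r] for r in responders[hub.hub_id]]] = (
            lam * z + np.sqrt(1.0 - lam * lam) * spec.noise_sd * eps
        )
    bg = [f for f in ids if roles[f] == "background"]
    values[[pos[f] for f in bg]] = rng.standard_normal((len(bg), rep.n_samples))

    keep = rng.random(len(ids)) >= rep.feature_dropout_rate
    keep |= np.array([roles[f] == "hub" for f in ids])
    kept = [f for f, k in zip(ids, keep) if k]
    return ExpressionMatrix(
        feature_ids=kept,
        sample_ids=[f"F{i:05d}" for i in range(1, rep.n_samples + 1)],
        values=values[keep],
        platform=np.array([ARRAY] * len(kept), dtype=object),
    )


def simulate_annotation(
    truth: GroundTruth,
    enriched_rate: float | None = None,
    background_rate: float | None = None,
    rng_seed: int | None = None,
) -> set[str]:
    """Binding-site-style gene labels: responders enriched over background.

    Every responder gene is annotated with probability ``enriched_rate`` and
    every other gene with ``background_rate`` (defaults from the spec).
    Returns the annotated gene-ID set (gene IDs here are feature IDs mapped
    through :func:`build_annotation_frame` symbols).
    """
    spec = truth.spec
    enriched = spec.enriched_annotation_rate if enriched_rate is None else enriched_rate
    background = spec.background_annotation_rate if background_rate is None else background_rate
    for rate in (enriched, background):
        if not (0 <= rate <= 1):
            raise ValueError("rates must lie in [0, 1]")
    rng = _rng(spec.rng_seed if rng_seed is None else rng_seed, "annotation")
    annotated: set[str] = set()
    for fid, role in truth.roles.items():
        if role == "mirna":
            continue
        rate = enriched if role.startswith("responder:") else background
        if rng.random() < rate:
            annotated.add(fid)
    return annotated


def simulate_mirna_layer(
    spec: SimulationSpec,
    truth: GroundTruth,
    matrix: ExpressionMatrix,
) -> ExpressionMatrix:
    """Append PCR miRNA features anti-correlated with designated targets.

    miRNA i couples with loading beta <= 0 to the observed value of its
    target (the i-th responder of the first hub, falling back to background
    features).  Values are mapped onto a Ct-like scale, ct = 27 - 3 * value,
    spanning [18, 36] over +/-3 SD, and individual cells are set missing at
    ``ct_dropout_rate`` to mimic failed amplification.  Updates
    ``truth.roles`` and ``truth.mirna_targets`` in place.
    """
    block = spec.pcr_block
    if block is None or block.n_mirna == 0:
        return matrix
    rng = _rng(spec.rng_seed, "mirna")
    beta = block.coupling

    candidates = [f for f in matrix.feature_ids if truth.roles.get(f) != "mirna"]
    targets = candidates[1:block.n_mirna + 1] if len(candidates) > block.n_mirna else candidates
    n = matrix.n_samples
    rows = []
    ids = []
    for i, target in enumerate(targets, start=1):
        mid = f"mir{i:04d}"
        u = matrix.values[matrix.index_of(target)]
        u = (u - u.mean()) / u.std()
        latent = beta * u + np.sqrt(1.0 - beta * beta) * rng.standard_normal(n)
        ct = np.clip(27.0 - 3.0 * latent, 18.0, 36.0)
        drop = rng.random(n) < block.ct_dropout_rate
        inv_ct = -ct
        inv_ct[drop] = np.nan
        rows.append(inv_ct)
        ids.append(mid)
        truth.roles[mid] = "mirna"
        truth.mirna_targets[mid] = target

    return ExpressionMatrix(
        feature_ids=list(matrix.feature_ids) + ids,
        sample_ids=list(matrix.sample_ids),
        values=np.vstack([matrix.values, np.array(rows)]),
        platform=np.concatenate([matrix.platform, np.array([PCR] * len(ids), dtype=object)]),
    )


def build_annotation_frame(truth: GroundTruth) -> pd.DataFrame:
    """Annotation table for a simulated cohort (one probe set per feature).

    Hubs get "transcription factor" titles (so the TF filter finds them);
    responders alternate between two GO terms for keyword-filter tests.
    """
    rows = []
    entrez = 1000
    acc = 100000
    for fid, role in truth.roles.items():
        entrez += 1
        acc += 1
        if role == "hub":
            title = f"transcription factor {fid}"
            go = "regulation of transcription; DNA binding"
            symbol = fid
        elif role.startswith("responder:"):
            hub = role.split(":", 1)[1]
            title = f"{hub} responsive transcript {fid}"
            go = "signal transduction" if entrez % 2 else "immune response"
            symbol = fid
        elif role == "mirna":
            title = f"microRNA {fid}"
            go = "gene silencing by miRNA"
            symbol = f"hsa-{fid}"
        else:
            title = f"uncharacterized locus {fid}"
            go = ""
            symbol = fid
        rows.append({
            "probe_set_id": fid,
            "entrez_id": str(entrez),
            "gene_symbol": symbol,
            "accessions": f"NM_{acc:06d}",
            "gene_title": title,
            "go_terms": go,
        })
    return pd.DataFrame(rows)


def mini_spec(rng_seed: int = 0, **overrides) -> SimulationSpec:
    """Default test-scale preset: 105 samples x 2,000 features, one hub."""
    return SimulationSpec(rng_seed=rng_seed, **overrides)


def full_scale_spec(rng_seed: int = 0) -> SimulationSpec:
    """Full-scale preset: 105 samples x 17,328 features (slow to build)."""
    return SimulationSpec(
        n_samples=105,
        n_features=17328,
        hubs=(HubSpec("HUB01", 200, 0.8),),
        pcr_block=PcrBlockSpec(n_mirna=341),
        rng_seed=rng_seed,
    )


def write_cohort_files(outdir, spec: SimulationSpec) -> dict[str, str]:
    """Generate a cohort and write every browser input format to ``outdir``.

    Emits the expression TSV (with PCR layer), annotation TSV, the annotated
    gene set and universe files, discovery/miRNA pair lists, and a
    ground-truth JSON.  Returns a name -> path map.
    """
    from pathlib import Path
    from .expression import write_expression

    outdir = Path(outdir)
    outdir.mkdir(parents=True, exist_ok=True)
    matrix, truth = simulate_cohort(spec)
    matrix = simulate_mirna_layer(spec, truth, matrix)
    annotated = simulate_annotation(truth)

    paths = {name: str(outdir / fname) for name, fname in [
        ("expression", "expression.tsv"),
        ("annotation", "annotation.tsv"),
        ("gene_set", "annotated_genes.txt"),
        ("universe", "universe.txt"),
        ("discovery_pairs", "discovery_pairs.tsv"),
        ("mirna_pairs", "mirna_pairs.tsv"),
        ("truth", "truth.json"),
    ]}
    write_expression(matrix, paths["expression"])
    build_annotation_frame(truth).to_csv(paths["annotation"], sep="\t", index=False)
    with open(paths["gene_set"], "w") as fh:
        fh.write("# annotated (binding-site) genes\n")
        fh.writelines(f"{g}\n" for g in sorted(annotated))
    with open(paths["universe"], "w") as fh:
        fh.writelines(f"{g}\n" for g in sorted(truth.array_features()))
    with open(paths["discovery_pairs"], "w") as fh:
        fh.write("id_a\tid_b\n")
        for hub, rs in truth.responders.items():
            fh.writelines(f"{hub}\t{r}\n" for r in rs)
    with open(paths["mirna_pairs"], "w") as fh:
        fh.write("id_a\tid_b\n")
        fh.writelines(f"{m}\t{t}\n" for m, t in truth.mirna_targets.items())
    with open(paths["truth"], "w") as fh:
        json.dump({
            "spec": asdict(spec),
            "roles": truth.roles,
            "responders": truth.responders,
            "mirna_targets": truth.mirna_targets,
        }, fh, indent=1)
    return paths
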