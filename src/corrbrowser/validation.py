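"""The three evaluation procedures run against a built correlation store.

1. Binding-site enrichment: the fraction of a seed's top-k correlated genes
   carrying a transcription-factor binding annotation, against a baseline of
   repeated random draws of k genes from the cohort universe (mean, SD, and a
   resampling empirical p with the +1 correction).
2. Discovery -> replication accounting: carry a pair list into a second
   cohort, recompute Pearson r, Bonferroni-correct over the carried-forward
   family, and tally significant / non-significant / undetected.
3. miRNA-target recall: the share of externally curated miRNA-mRNA pairs
   that reach nominal (uncorrected) significance in the store, with the
   anti-correlated subset reported separately.
"""

from __future__ import annotations

from dataclasses import dataclass, field

import numpy as np
import pandas as pd

from .annotate import AnnotationTable
from .expression import ExpressionMatrix
from .stats import DEFAULT_MIN_N, DegenerateFeatureError, bonferroni, pearson_r
from .store import GLOBAL, CorrelationStore

__all__ = [
    "EnrichmentResult",
    "ReplicationResult",
    "RecallReport",
    "TargetPairSet",
    "topk_binding_enrichment",
    "replicate_associations",
    "mirna_target_recall",
    "read_gene_set",
    "read_pairs",
]


@dataclass(frozen=True)
class EnrichmentResult:
    """Top-k annotated fraction vs. a random-gene resampling baseline."""

    seed: str
    k: int
    n_topk_annotated: int
    fraction_annotated: float
    baseline_mean: float
    baseline_sd: float
    n_resamples: int
    empirical_p: float


@dataclass
class ReplicationResult:
    """Significance accounting of discovery pairs in a replication cohort.

    Invariant (asserted): n_discovery = n_undetected + n_significant +
    n_nonsignificant.
    """

    n_discovery: int
    n_undetected: int
    n_significant: int
    n_nonsignificant: int
    alpha: float
    family_size: int
    table: pd.DataFrame = field(repr=False)

    def __post_init__(self) -> None:
        assert self.n_discovery == (
            self.n_undetected + self.n_significant + self.n_nonsignificant
        ), "replication counts must partition the discovery list"


@dataclass(frozen=True)
class TargetPairSet:
    """Curated (miRNA, target mRNA) pairs from an external interaction source."""

    pairs: tuple[tuple[str, str], ...]
    source: str = ""

    def __post_init__(self) -> None:
        if len(set(self.pairs)) != len(self.pairs):
            raise ValueError("duplicate pairs in target set")

    def __len__(self) -> int:
        return len(self.pairs)


@dataclass(frozen=True)
class RecallReport:
    """Nominal-significance recall of curated pairs in the store."""

    n_pairs_input: int
    n_detected: int
    n_nominal: int
    fraction_nominal: float  # NaN when n_detected == 0
    n_nominal_negative: int
    fraction_nominal_negative: float
    alpha: float


def topk_binding_enrichment(
    store: CorrelationStore,
    seed: str,
    k: int,
    annotated_set: set[str],
    universe: set[str],
    n_resamples: int = 1000,
    rng_seed: int = 0,
    annotation: AnnotationTable | None = None,
) -> EnrichmentResult:
    """Observed top-k annotated fraction vs. random k-gene draws.

    Top-k partners are mapped to gene level through ``annotation`` (a gene
    counts once) before intersecting with ``annotated_set``.  The baseline is
    ``n_resamples`` independent draws of k genes without replacement from
    ``universe`` minus the seed gene; empirical_p applies the +1 correction,
    (1 + #{draws with fraction >= observed}) / (n_resamples + 1), so it is
    never zero.
    """
    if k < 1:
        raise ValueError("k must be >= 1")
    if n_resamples < 1:
        raise ValueError("n_resamples must be >= 1")
    gene_of = annotation.gene_of if annotation is not None else (lambda f: f)

    records = store.top_neighbors(seed, k, family=GLOBAL)
    seed_gene = gene_of(seed)
    genes: list[str] = []
    seen: set[str] = set()
    for rec in records:
        g = gene_of(store.partner_of(rec, seed))
        if g not in seen:
            seen.add(g)
            genes.append(g)
    n_hit = sum(1 for g in genes if g in annotated_set)
    observed = n_hit / k

    pool = np.array(sorted(universe - {seed_gene}))
    if k > pool.size:
        raise ValueError(f"k={k} exceeds universe size {pool.size}")
    annotated_in_pool = np.isin(pool, sorted(annotated_set & set(pool)))
    rng = np.random.default_rng(rng_seed)
    fracs = np.empty(n_resamples)
    for b in range(n_resamples):
        draw = rng.choice(pool.size, size=k, replace=False)
        fracs[b] = annotated_in_pool[draw].mean()
    emp_p = (1 + int((fracs >= observed).sum())) / (n_resamples + 1)
    return EnrichmentResult(
        seed=seed,
        k=k,
        n_topk_annotated=n_hit,
        fraction_annotated=observed,
        baseline_mean=float(fracs.mean()),
        baseline_sd=float(fracs.std(ddof=1)) if n_resamples > 1 else 0.0,
        n_resamples=n_resamples,
        empirical_p=emp_p,
    )


def replicate_associations(
    discovery_pairs,
    replication_matrix: ExpressionMatrix,
    alpha: float = 0.05,
    family_size: int | None = None,
    min_n: int = DEFAULT_MIN_N,
) -> ReplicationResult:
    """Test each discovery pair for Bonferroni significance in a new cohort.

    ``discovery_pairs`` is a list of (seed, partner) or (seed, partner,
    discovery_r) tuples.  A pair with either member absent from the
    replication matrix — or with too few complete observations — is counted
    undetected; the rest are correlated, Bonferroni-corrected over
    ``family_size`` (default: the number of carried-forward pairs) and
    compared to ``alpha``.
    """
    pairs = [tuple(p) for p in discovery_pairs]
    if not pairs:
        raise ValueError("empty discovery pair list")
    if not (0 < alpha < 1):
        raise ValueError("alpha must lie in (0, 1)")
    m = len(pairs) if family_size is None else family_size
    if m < len(pairs):
        raise ValueError("family_size must cover the tested pairs")

    present = set(replication_matrix.feature_ids)
    rows = []
    counts = {"undetected": 0, "significant": 0, "nonsignificant": 0}
    for pair in pairs:
        a, b = pair[0], pair[1]
        r_disc = float(pair[2]) if len(pair) > 2 else np.nan
        if a not in present or b not in present:
            status, r_rep, p_corr = "undetected", np.nan, np.nan
        else:
            try:
                stat = pearson_r(
                    replication_matrix.values[replication_matrix.index_of(a)],
                    replication_matrix.values[replication_matrix.index_of(b)],
                    min_n=min_n,
                )
            except DegenerateFeatureError:
                stat = None
            if stat is None or stat.undetected:
                status, r_rep, p_corr = "undetected", np.nan, np.nan
            else:
                r_rep = stat.r
                p_corr = bonferroni(stat.p_raw, m)
                status = "significant" if p_corr < alpha else "nonsignificant"
        counts[status] += 1
        rows.append({"id_a": a, "id_b": b, "discovery_r": r_disc,
                     "replication_r": r_rep, "replication_p_bonferroni": p_corr,
                     "status": status})
    return ReplicationResult(
        n_discovery=len(pairs),
        n_undetected=counts["undetected"],
        n_significant=counts["significant"],
        n_nonsignificant=counts["nonsignificant"],
        alpha=alpha,
        family_size=m,
        table=pd.DataFrame(rows),
    )


def mirna_target_recall(
    store: CorrelationStore,
    pairs: TargetPairSet,
    alpha: float = 0.05,
) -> RecallReport:
    """Share of curated miRNA-target pairs nominally significant in the store.

    A pair is detected when both members are retained in the store and the
    pair itself has enough complete observations; "nominal" means raw
    (uncorrected) p below ``alpha``.  The anti-correlated (r < 0) subset is
    reported separately since miRNA action predicts negative correlation.
    """
    if len(pairs) == 0:
        raise ValueError("empty pair set")
    if not (0 < alpha < 1):
        raise ValueError("alpha must lie in (0, 1)")
    n_detected = n_nominal = n_neg = 0
    for a, b in pairs.pairs:
        if a not in store or b not in store:
            continue
        rec = store.lookup_pair(a, b)
        if rec.undetected:
            continue
        n_detected += 1
        if rec.p_raw < alpha:
            n_nominal += 1
            if rec.r < 0:
                n_neg += 1
    return RecallReport(
        n_pairs_input=len(pairs),
        n_detected=n_detected,
        n_nominal=n_nominal,
        fraction_nominal=n_nominal / n_detected if n_detected else np.nan,
        n_nominal_negative=n_neg,
        fraction_nominal_negative=n_neg / n_detected if n_detected else np.nan,
        alpha=alpha,
    )


def read_gene_set(path) -> set[str]:
    """One gene ID per line; '#' comments and blank lines ignored."""
    out = set()
    with open(path) as fh:
        for line in fh:
            line = line.split("#", 1)[0].strip()
            if line:
                out.add(line)
    return out


def read_pairs(path, source: str = "") -> TargetPairSet:
    """Two-column TSV of (id_a, id_b); an optional header row is skipped."""
    pairs = []
    with open(path) as fh:
        for ln, line in enumerate(fh):
            line = line.rstrip("\n")
            if not line or line.startswith("#"):
                continue
            cells = line.split("\t")
            if len(cells) < 2:
                raise ValueError(f"{path}:{ln + 1}: expected two tab-separated columns")
            if ln == 0 and cells[0].lower() in ("id_a", "mirna_id", "seed", "feature_a"):
                continue
            pairs.append((cells[0], cells[1]))
    return TargetPairSet(pairs=tuple(pairs), source=source)
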