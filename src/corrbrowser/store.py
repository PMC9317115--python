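"""All-pairs correlation matrix: blockwise build, HDF5 persistence, queries.

The store keeps one payload per unordered feature pair in condensed
upper-triangle order (the scipy ``squareform`` convention): for features
indexed ``0..F-1`` the pair ``(i, j)`` with ``i < j`` lives at

    k = F*i - i*(i+1)//2 + (j - i - 1).

Only ``(r, n_obs)`` are stored — r as float32, n_obs as uint16.  Raw and
adjusted p-values are recomputed at query time from these and the chosen
family size, which halves storage for the 150-million-pair full cohort and
lets the multiplicity family vary per query without a rebuild.

HDF5 layout (documented for cross-language readers)::

    /pairs/r               float32[P]   condensed Pearson r (NaN = undetected)
    /pairs/n_obs           uint16[P]    pairwise-complete sample counts
    /index/feature_ids     bytes[F]     retained feature IDs, store order
    /index/platform        bytes[F]     "array" | "pcr" per feature
    /meta  (attributes)    n_features, n_samples, min_n, build JSON, sha256

Datasets are written with ``track_times=False`` so identical inputs yield
byte-identical files.
"""

from __future__ import annotations

import hashlib
import json
import logging
from dataclasses import dataclass

import h5py
import numpy as np

from .expression import ARRAY, ExpressionMatrix
from .stats import DEFAULT_MIN_N, bh_fdr, bonferroni, correlation_pvalue

__all__ = [
    "CorrelationRecord",
    "CorrelationStore",
    "FeatureNotFoundError",
    "build_store",
    "compute_all_pairs",
    "condensed_index",
    "pair_count",
]

log = logging.getLogger(__name__)

GLOBAL = "global"
PER_SEED = "per_seed"


class FeatureNotFoundError(KeyError):
    """Feature unknown to the store; distinguishes never-present from dropped."""

    def __init__(self, feature_id: str, dropped_at_detection: bool = False):
        self.feature_id = feature_id
        self.dropped_at_detection = dropped_at_detection
        why = "removed at detection" if dropped_at_detection else "never present"
        super().__init__(f"feature {feature_id!r} not in store ({why})")


@dataclass(frozen=True)
class CorrelationRecord:
    """One unordered feature pair with correlation and significance fields.

    ``feature_a`` precedes ``feature_b`` lexicographically (canonical order).
    Undetected pairs carry NaN in r and all p/q fields.
    """

    feature_a: str
    feature_b: str
    r: float
    n_obs: int
    p_raw: float
    p_bonferroni: float
    q_bh: float
    undetected: bool = False


def pair_count(n_features: int) -> int:
    """Number of unordered pairs F(F-1)/2 — exact integer arithmetic."""
    return n_features * (n_features - 1) // 2


def condensed_index(i, j, n_features: int):
    """Condensed position of pair (i, j), i != j, vectorised; order-free."""
    i = np.asarray(i, dtype=np.int64)
    j = np.asarray(j, dtype=np.int64)
    lo = np.minimum(i, j)
    hi = np.maximum(i, j)
    return n_features * lo - lo * (lo + 1) // 2 + (hi - lo - 1)


def _pairwise_complete_vs_all(xi: np.ndarray, X: np.ndarray, min_n: int):
    """Pearson r of one (possibly gappy) row against every row of X.

    Returns (r, n) arrays of length X.shape[0]; r is NaN where the pair has
    fewer than min_n complete observations or is degenerate on its subset.
    """
    vi = np.isfinite(xi)
    V = np.isfinite(X) & vi  # F x S validity per pair
    n = V.sum(axis=1)
    xiz = np.where(np.isfinite(xi), xi, 0.0)
    Xz = np.where(np.isfinite(X), X, 0.0)
    sx = V @ xiz
    sy = (V * Xz).sum(axis=1)
    sxx = V @ (xiz * xiz)
    syy = (V * Xz * Xz).sum(axis=1)
    sxy = (Xz * xiz).sum(axis=1) if V.all() else (V * Xz * xiz).sum(axis=1)
    with np.errstate(invalid="ignore", divide="ignore"):
        cov = n * sxy - sx * sy
        varx = n * sxx - sx * sx
        vary = n * syy - sy * sy
        r = cov / np.sqrt(varx * vary)
    r = np.clip(r, -1.0, 1.0)
    r[(n < min_n) | (varx <= 0) | (vary <= 0)] = np.nan
    return r, n.astype(np.int64)


def compute_all_pairs(matrix: ExpressionMatrix, block_size: int = 512,
                      min_n: int = DEFAULT_MIN_N):
    """All-pairs condensed (r, n_obs) for the retained features, in float64.

    Complete rows are standardised once and correlated by block outer
    products; any pair touching a row with missing cells falls back to the
    pairwise-complete path.  :func:`build_store` casts r to float32 only at
    persistence time.
    """
    X = matrix.values
    F, S = X.shape
    P = pair_count(F)
    r_out = np.full(P, np.nan, dtype=np.float64)
    n_out = np.zeros(P, dtype=np.int64)

    complete = np.isfinite(X).all(axis=1)
    comp_idx = np.flatnonzero(complete)
    gap_idx = np.flatnonzero(~complete)

    # complete x complete via standardised block products
    if comp_idx.size >= 2:
        Z = X[comp_idx] - X[comp_idx].mean(axis=1, keepdims=True)
        norms = np.linalg.norm(Z, axis=1)
        Z = Z / norms[:, None]
        C = comp_idx.size
        for a0 in range(0, C, block_size):
            a1 = min(a0 + block_size, C)
            R = Z[a0:a1] @ Z.T  # (a1-a0) x C
            for ai in range(a0, a1):
                js = np.arange(ai + 1, C)
                if js.size == 0:
                    continue
                k = condensed_index(comp_idx[ai], comp_idx[js], F)
                r_out[k] = np.clip(R[ai - a0, js], -1.0, 1.0)
                n_out[k] = S
    elif comp_idx.size == 1 and gap_idx.size == 0:
        pass  # single feature, no pairs

    # pairs touching a gappy row: one vectorised sweep per gappy feature
    for t, gi in enumerate(gap_idx):
        others = np.concatenate([comp_idx, gap_idx[t + 1:]])
        if others.size == 0:
            continue
        r, n = _pairwise_complete_vs_all(X[gi], X[others], min_n)
        k = condensed_index(gi, others, F)
        r_out[k] = r
        n_out[k] = np.minimum(n, np.iinfo(np.uint16).max)
    return r_out, n_out


def build_store(
    matrix: ExpressionMatrix,
    out_path,
    block_size: int = 512,
    min_n: int = DEFAULT_MIN_N,
) -> "CorrelationStore":
    """Compute every unordered pair correlation and persist the store.

    Zero-variance features are excluded up front with a logged warning so no
    undefined records enter the store.  Requires >= 2 retained features.
    """
    if block_size < 1:
        raise ValueError("block_size must be >= 1")
    with np.errstate(invalid="ignore"):
        variances = np.nanvar(matrix.values, axis=1)
    degenerate = [
        matrix.feature_ids[i]
        for i in range(matrix.n_features)
        if not np.isfinite(variances[i]) or variances[i] == 0.0
    ]
    if degenerate:
        log.warning("excluding %d zero-variance feature(s): %s",
                    len(degenerate), ", ".join(degenerate[:10]))
        matrix = matrix.subset([f for f in matrix.feature_ids if f not in set(degenerate)])
    if matrix.n_features < 2:
        raise ValueError("need at least 2 retained features to build a store")
    if matrix.n_samples < min_n:
        raise ValueError(f"need at least min_n={min_n} samples")

    r64, n64 = compute_all_pairs(matrix, block_size, min_n)
    r = r64.astype(np.float32)
    n_obs = n64.astype(np.uint16)

    payload_hash = hashlib.sha256(r.tobytes() + n_obs.tobytes()).hexdigest()
    meta = {
        "n_features": matrix.n_features,
        "n_samples": matrix.n_samples,
        "n_pairs": int(r.size),
        "min_n": int(min_n),
        "block_size": int(block_size),
        "excluded_degenerate": degenerate,
        "payload_sha256": payload_hash,
    }
    ids = np.array([f.encode() for f in matrix.feature_ids])
    plat = np.array([str(p).encode() for p in matrix.platform])
    with h5py.File(out_path, "w", track_order=False) as h5:
        g = h5.create_group("pairs")
        g.create_dataset("r", data=r, track_times=False)
        g.create_dataset("n_obs", data=n_obs, track_times=False)
        gi = h5.create_group("index")
        gi.create_dataset("feature_ids", data=ids, track_times=False)
        gi.create_dataset("platform", data=plat, track_times=False)
        h5.create_group("meta").attrs["json"] = json.dumps(meta, sort_keys=True)
    return CorrelationStore(out_path)


class CorrelationStore:
    """Read-side view of a persisted store: symmetric lookup + neighbor scans.

    The condensed payload is loaded into memory on open (8 bytes per pair —
    comfortable for cohorts up to a few thousand features; the 17k-feature
    full cohort needs ~1.2 GB and is typically queried on a large-memory
    host).
    """

    def __init__(self, path):
        self.path = str(path)
        with h5py.File(path, "r") as h5:
            self.r = h5["pairs/r"][:]
            self.n_obs = h5["pairs/n_obs"][:].astype(np.int64)
            self.feature_ids = [b.decode() for b in h5["index/feature_ids"][:]]
            self.platform = np.array([b.decode() for b in h5["index/platform"][:]],
                                     dtype=object)
            self.meta = json.loads(h5["meta"].attrs["json"])
        self._pos = {f: i for i, f in enumerate(self.feature_ids)}
        self._dropped = set(self.meta.get("excluded_degenerate", []))

    @property
    def n_features(self) -> int:
        return len(self.feature_ids)

    @property
    def n_pairs(self) -> int:
        return int(self.r.size)

    @property
    def m_global(self) -> int:
        return self.n_pairs

    def _index(self, feature_id: str) -> int:
        try:
            return self._pos[feature_id]
        except KeyError:
            raise FeatureNotFoundError(
                feature_id, dropped_at_detection=feature_id in self._dropped
            ) from None

    def __contains__(self, feature_id: str) -> bool:
        return feature_id in self._pos

    def _family_size(self, family: str) -> int:
        if family == GLOBAL:
            return self.m_global
        if family == PER_SEED:
            return self.n_features - 1
        raise ValueError(f"family must be '{GLOBAL}' or '{PER_SEED}'")

    def _record(self, i: int, j: int, m: int, q_bh: float = np.nan) -> CorrelationRecord:
        k = int(condensed_index(i, j, self.n_features))
        r = float(self.r[k])
        n = int(self.n_obs[k])
        a, b = self.feature_ids[i], self.feature_ids[j]
        if a > b:
            a, b = b, a
        if not np.isfinite(r):
            return CorrelationRecord(a, b, np.nan, n, np.nan, np.nan, np.nan,
                                     undetected=True)
        p = correlation_pvalue(r, n)
        return CorrelationRecord(a, b, r, n, p, bonferroni(p, m), float(q_bh))

    def lookup_pair(self, id_a: str, id_b: str, family: str = GLOBAL) -> CorrelationRecord:
        """Record for one pair; symmetric in its arguments.

        The Bonferroni family defaults to the whole matrix (m = F(F-1)/2).
        BH q is computed over the neighbor family of the canonically first
        (lexicographically smaller) feature, so the result is symmetric in
        its arguments.
        """
        i, j = self._index(id_a), self._index(id_b)
        if i == j:
            raise ValueError("a feature has no pair with itself")
        m = self._family_size(family)
        if self.feature_ids[j] < self.feature_ids[i]:
            i, j = j, i
        _, p_all, order_idx = self._neighbor_pvalues(i)
        q_all = bh_fdr(p_all)
        pos = np.flatnonzero(order_idx == j)
        q = float(q_all[pos[0]]) if pos.size else np.nan
        return self._record(i, j, m, q_bh=q)

    def _neighbor_pvalues(self, i: int):
        """(neighbor indices, raw p, defined-subset indices) for feature i."""
        F = self.n_features
        others = np.concatenate([np.arange(0, i), np.arange(i + 1, F)])
        k = condensed_index(i, others, F)
        r = self.r[k].astype(float)
        n = self.n_obs[k]
        defined = np.isfinite(r)
        p = correlation_pvalue(r[defined], np.maximum(n[defined], 3))
        return others, p, others[defined]

    def neighbors(self, feature_id: str):
        """All neighbor payloads of a feature: (partner ids, r, n_obs)."""
        i = self._index(feature_id)
        F = self.n_features
        others = np.concatenate([np.arange(0, i), np.arange(i + 1, F)])
        k = condensed_index(i, others, F)
        partners = [self.feature_ids[j] for j in others]
        return partners, self.r[k].astype(float), self.n_obs[k]

    def top_neighbors(
        self,
        seed_feature: str,
        k: int,
        family: str = GLOBAL,
        record_filter=None,
    ) -> list[CorrelationRecord]:
        """The k most significantly correlated partners of a seed feature.

        Ranking is by raw p ascending with ties broken by larger \\|r\\| and
        then lexicographic partner ID.  BH q is computed over the seed's full
        neighbor family (its detected neighbors) before truncation to k;
        ``record_filter`` (record -> bool) is applied before truncation too.
        Undetected pairs never appear.
        """
        if k < 0:
            raise ValueError("k must be >= 0")
        i = self._index(seed_feature)
        m = self._family_size(family)
        others, p, defined_idx = self._neighbor_pvalues(i)
        if defined_idx.size == 0 or k == 0:
            return []
        q = bh_fdr(p)
        kk = condensed_index(i, defined_idx, self.n_features)
        r = self.r[kk].astype(float)
        n = self.n_obs[kk]

        order = np.lexsort((
            [self.feature_ids[j] for j in defined_idx],
            -np.abs(r),
            p,
        ))
        records = []
        for t in order:
            j = int(defined_idx[t])
            a, b = seed_feature, self.feature_ids[j]
            if a > b:
                a, b = b, a
            rec = CorrelationRecord(a, b, float(r[t]), int(n[t]), float(p[t]),
                                    bonferroni(float(p[t]), m), float(q[t]))
            if record_filter is not None and not record_filter(rec):
                continue
            records.append(rec)
            if len(records) == k:
                break
        return records

    def partner_of(self, record: CorrelationRecord, seed_feature: str) -> str:
        """The non-seed member of a canonical-order record."""
        return record.feature_b if record.feature_a == seed_feature else record.feature_a
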