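"""Pearson correlation, its two-sided p-value, and multiple-testing corrections.

This is the numerical heart of the correlation browser.  Every stored pair
carries only ``(r, n_obs)``; raw p-values, Bonferroni-adjusted p-values and
Benjamini–Hochberg q-values are recomputed from these on demand, so the
functions here must be exact and cheap.

The p-value for a Pearson product-moment correlation uses the classical
Student-t transform

    t = r * sqrt((n - 2) / (1 - r^2)),   df = n - 2,

referred two-sided to the t distribution.  Correlations that are numerically
at +/-1 are reported with p = 0 rather than letting the transform overflow.
"""

from __future__ import annotations

from dataclasses import dataclass

import numpy as np
from scipy import stats as _sps
from statsmodels.stats.multitest import multipletests

__all__ = [
    "PairStat",
    "CorrectedP",
    "DegenerateFeatureError",
    "UndefinedPValueError",
    "InvalidFamilyError",
    "pearson_r",
    "correlation_pvalue",
    "bonferroni",
    "bh_fdr",
]

#: |r| at or above this is treated as exactly +/-1 (p = 0).
R_CLAMP = 1.0 - 1e-15

#: Default minimum pairwise-complete observations for a pair to be "detected".
DEFAULT_MIN_N = 20


class DegenerateFeatureError(ValueError):
    """A feature has zero variance over the pairwise-complete positions."""


class UndefinedPValueError(ValueError):
    """The t-transform p-value needs at least 3 observations (df >= 1)."""


class InvalidFamilyError(ValueError):
    """Multiple-testing family size must be a positive integer."""


@dataclass(frozen=True)
class PairStat:
    """Correlation of one feature pair over its pairwise-complete samples.

    ``undetected`` is set when fewer than ``min_n`` complete observations
    exist; ``r`` and ``p_raw`` are NaN in that case.
    """

    r: float
    n_obs: int
    p_raw: float
    undetected: bool = False


@dataclass(frozen=True)
class CorrectedP:
    """Bonferroni- and BH-adjusted values for one raw p in a family of m tests."""

    p_bonferroni: float
    q_bh: float
    m: int


def pearson_r(x, y, min_n: int = DEFAULT_MIN_N) -> PairStat:
    """Pearson r over pairwise-complete positions of two equal-length vectors.

    Missing entries (NaN) are allowed in either vector; only positions where
    both are observed contribute.  If fewer than ``min_n`` such positions
    exist the pair is flagged undetected (r and p undefined).  A constant
    vector over the complete positions raises :class:`DegenerateFeatureError`.
    """
    x = np.asarray(x, dtype=float)
    y = np.asarray(y, dtype=float)
    if x.shape != y.shape or x.ndim != 1:
        raise ValueError("x and y must be 1-D vectors of equal length")
    if min_n < 3:
        raise ValueError("min_n must be >= 3 (t-test needs df >= 1)")

    mask = np.isfinite(x) & np.isfinite(y)
    n_obs = int(mask.sum())
    if n_obs < min_n:
        return PairStat(r=np.nan, n_obs=n_obs, p_raw=np.nan, undetected=True)

    xc = x[mask] - x[mask].mean()
    yc = y[mask] - y[mask].mean()
    sxx = float(xc @ xc)
    syy = float(yc @ yc)
    if sxx == 0.0 or syy == 0.0:
        raise DegenerateFeatureError(
            f"zero variance over {n_obs} pairwise-complete observations"
        )
    r = float(xc @ yc) / np.sqrt(sxx * syy)
    r = float(np.clip(r, -1.0, 1.0))
    return PairStat(r=r, n_obs=n_obs, p_raw=correlation_pvalue(r, n_obs))


def correlation_pvalue(r, n_obs):
    """Two-sided p-value for Pearson r via the Student-t transform.

    Accepts scalars or arrays (broadcast together).  ``n_obs`` must be >= 3
    everywhere; values of |r| numerically at 1 give p = 0 exactly.
    """
    r_arr = np.asarray(r, dtype=float)
    n_arr = np.asarray(n_obs)
    scalar = r_arr.ndim == 0 and n_arr.ndim == 0
    if np.any(n_arr < 3):
        raise UndefinedPValueError("p-value undefined for n_obs < 3")
    if np.any(np.abs(r_arr) > 1.0 + 1e-12):
        raise ValueError("|r| must be <= 1")

    r_arr = np.clip(r_arr, -1.0, 1.0)
    saturated = np.abs(r_arr) >= R_CLAMP
    df = np.asarray(n_arr, dtype=float) - 2.0
    with np.errstate(divide="ignore", invalid="ignore"):
        t = r_arr * np.sqrt(df / (1.0 - r_arr * r_arr))
    p = np.where(saturated, 0.0, 2.0 * _sps.t.sf(np.abs(np.where(saturated, 0.0, t)), df))
    p = np.minimum(p, 1.0)
    return float(p) if scalar else p


def bonferroni(p_raw, m: int):
    """Bonferroni adjustment min(1, p * m) for a family of m tests."""
    if m < 1:
        raise InvalidFamilyError(f"family size must be >= 1, got {m}")
    return np.minimum(1.0, np.asarray(p_raw, dtype=float) * m) if np.ndim(p_raw) else min(
        1.0, float(p_raw) * m
    )


def bh_fdr(p_values) -> np.ndarray:
    """Benjamini–Hochberg step-up adjusted q-values, in input order.

    Rejecting ``q <= alpha`` reproduces the BH step-up rejection set exactly.
    An empty input yields an empty output.
    """
    p = np.asarray(p_values, dtype=float)
    if p.ndim != 1:
        raise ValueError("p_values must be 1-D")
    if p.size == 0:
        return np.empty(0, dtype=float)
    if np.any((p < 0) | (p > 1) | ~np.isfinite(p)):
        raise ValueError("p-values must lie in [0, 1]")
    return multipletests(p, alpha=0.05, method="fdr_bh")[1]
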