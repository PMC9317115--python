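"""Expression-matrix container and TSV ingestion.

The cohort matrix holds features in rows and samples in columns.  Two
platforms coexist: microarray features (log2 RMA-normalised signals, never
missing) and PCR features (cycle-threshold values, possibly missing where a
transcript failed to amplify).  Ct values are orientation-reversed at load
time — stored as ``-Ct`` — so that for every feature a larger value means a
more abundant transcript and correlations share one sign convention.
"""

from __future__ import annotations

import logging
from dataclasses import dataclass, field

import numpy as np
import pandas as pd

__all__ = [
    "ExpressionMatrix",
    "ExpressionParseError",
    "DetectionReport",
    "load_expression",
    "detect_features",
    "write_expression",
]

log = logging.getLogger(__name__)

ARRAY = "array"
PCR = "pcr"

#: Ct above this counts as "not detected" in a sample (configurable per call).
DEFAULT_CT_MAX = 35.0
#: A PCR feature must be detected in at least this fraction of samples.
DEFAULT_MIN_DETECTED_FRACTION = 0.5

#: Cell tokens read as missing, besides the empty field.
NA_TOKENS = ("NA", "NaN", "nan", "Undetermined", "undetermined")


class ExpressionParseError(ValueError):
    """Malformed expression TSV (duplicates, ragged rows, non-numeric cells)."""


@dataclass
class ExpressionMatrix:
    """Features x samples value grid with per-feature platform tags.

    ``values`` uses NaN for missing cells; PCR rows are already on the
    inverse-Ct scale (negated Ct).  Array rows must be complete.
    """

    feature_ids: list[str]
    sample_ids: list[str]
    values: np.ndarray
    platform: np.ndarray  # dtype object/str, one of {"array", "pcr"} per feature

    def __post_init__(self) -> None:
        self.values = np.asarray(self.values, dtype=float)
        self.platform = np.asarray(self.platform, dtype=object)
        if len(set(self.feature_ids)) != len(self.feature_ids):
            raise ExpressionParseError("duplicate feature IDs")
        if len(set(self.sample_ids)) != len(self.sample_ids):
            raise ExpressionParseError("duplicate sample IDs")
        if self.values.shape != (len(self.feature_ids), len(self.sample_ids)):
            raise ValueError("values shape does not match id lists")
        if self.platform.shape != (len(self.feature_ids),):
            raise ValueError("platform tag required per feature")
        bad = set(self.platform) - {ARRAY, PCR}
        if bad:
            raise ValueError(f"unknown platform tags: {sorted(bad)}")
        arr_rows = self.platform == ARRAY
        if np.any(~np.isfinite(self.values[arr_rows])):
            raise ExpressionParseError("array-platform rows must have no missing cells")

    @property
    def n_features(self) -> int:
        return len(self.feature_ids)

    @property
    def n_samples(self) -> int:
        return len(self.sample_ids)

    def index_of(self, feature_id: str) -> int:
        try:
            return self.feature_ids.index(feature_id)
        except ValueError:
            raise KeyError(feature_id) from None

    def subset(self, keep: list[str]) -> "ExpressionMatrix":
        idx = [self.index_of(f) for f in keep]
        return ExpressionMatrix(
            feature_ids=[self.feature_ids[i] for i in idx],
            sample_ids=list(self.sample_ids),
            values=self.values[idx],
            platform=self.platform[idx],
        )


@dataclass
class DetectionReport:
    """Per-feature outcome of the PCR detection screen."""

    retained: list[str]
    dropped: list[str]
    detected_fraction: dict[str, float] = field(default_factory=dict)


def load_expression(
    path,
    platform_column: str = "platform",
    ct_sentinel: str | None = None,
    apply_detection: bool = True,
    ct_max: float = DEFAULT_CT_MAX,
    min_detected_fraction: float = DEFAULT_MIN_DETECTED_FRACTION,
) -> ExpressionMatrix:
    """Read an expression TSV into an :class:`ExpressionMatrix`.

    Layout: header row of sample IDs, first column the feature ID, and an
    optional ``platform`` column ("array"/"pcr"); without it every feature is
    treated as array.  Missing cells are empty fields, "NA"/"NaN",
    "Undetermined", or the configured ``ct_sentinel``.  PCR rows are read as
    Ct and transformed to inverse-Ct (negated); when ``apply_detection`` is
    true, PCR features failing the detection screen are dropped (logged).
    """
    na_values = list(NA_TOKENS) + ([ct_sentinel] if ct_sentinel else [])
    try:
        df = pd.read_csv(path, sep="\t", dtype={0: str}, na_values=na_values,
                         keep_default_na=True)
    except pd.errors.ParserError as exc:  # ragged rows carry a line number
        raise ExpressionParseError(f"{path}: {exc}") from exc
    if df.shape[1] < 2:
        raise ExpressionParseError(f"{path}: need a feature-ID column and >= 1 sample")

    feat_col = df.columns[0]
    features = df[feat_col].astype(str).tolist()
    dup = df[feat_col][df[feat_col].duplicated()]
    if not dup.empty:
        first = dup.iloc[0]
        line = int(dup.index[0]) + 2  # header is line 1
        raise ExpressionParseError(f"{path}:{line}: duplicate feature ID {first!r}")

    if platform_column in df.columns:
        platform = df[platform_column].astype(str).str.lower().to_numpy(dtype=object)
        data = df.drop(columns=[feat_col, platform_column])
    else:
        platform = np.array([ARRAY] * len(df), dtype=object)
        data = df.drop(columns=[feat_col])

    try:
        values = data.apply(pd.to_numeric, errors="raise").to_numpy(dtype=float)
    except (ValueError, TypeError) as exc:
        # locate the first offending cell for the error message
        for j, col in enumerate(data.columns):
            coerced = pd.to_numeric(data[col], errors="coerce")
            bad = coerced.isna() & data[col].notna()
            if bad.any():
                line = int(bad.idxmax()) + 2
                raise ExpressionParseError(
                    f"{path}:{line}: non-numeric cell {data[col][bad.idxmax()]!r} "
                    f"in sample column {col!r}"
                ) from exc
        raise ExpressionParseError(f"{path}: non-numeric cell") from exc

    pcr_rows = platform == PCR
    values[pcr_rows] = -values[pcr_rows]  # Ct -> inverse-Ct

    matrix = ExpressionMatrix(
        feature_ids=features,
        sample_ids=[str(c) for c in data.columns],
        values=values,
        platform=platform,
    )
    if apply_detection:
        report = detect_features(matrix, min_detected_fraction, ct_max)
        if report.dropped:
            log.warning(
                "dropped %d PCR feature(s) below detection level: %s",
                len(report.dropped), ", ".join(report.dropped[:10]),
            )
            matrix = matrix.subset(report.retained)
    return matrix


def detect_features(
    matrix: ExpressionMatrix,
    min_detected_fraction: float = DEFAULT_MIN_DETECTED_FRACTION,
    ct_max: float = DEFAULT_CT_MAX,
) -> DetectionReport:
    """Screen PCR features for detection level; array features always pass.

    A PCR feature is retained iff its Ct is below ``ct_max`` (i.e. inverse-Ct
    above ``-ct_max``) in at least ``min_detected_fraction`` of samples.
    """
    if not (0 < min_detected_fraction <= 1):
        raise ValueError("min_detected_fraction must be in (0, 1]")
    retained: list[str] = []
    dropped: list[str] = []
    fractions: dict[str, float] = {}
    n = matrix.n_samples
    for i, fid in enumerate(matrix.feature_ids):
        if matrix.platform[i] == ARRAY:
            retained.append(fid)
            continue
        row = matrix.values[i]
        detected = np.isfinite(row) & (row > -ct_max)
        frac = float(detected.sum()) / n
        fractions[fid] = frac
        (retained if frac >= min_detected_fraction else dropped).append(fid)
    return DetectionReport(retained=retained, dropped=dropped, detected_fraction=fractions)


def write_expression(matrix: ExpressionMatrix, path, float_format: str = "%.6g") -> None:
    """Write the matrix back to TSV (PCR rows re-expressed as raw Ct)."""
    values = matrix.values.copy()
    pcr_rows = matrix.platform == PCR
    values[pcr_rows] = -values[pcr_rows]
    df = pd.DataFrame(values, columns=matrix.sample_ids)
    df.insert(0, "feature_id", matrix.feature_ids)
    df.insert(1, "platform", matrix.platform)
    df.to_csv(path, sep="\t", index=False, float_format=float_format, na_rep="NA")
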