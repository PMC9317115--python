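"""Identifier resolution and annotation-based output filters.

Users address transcripts by any of four identifier kinds — probe-set ID,
Entrez Gene ID, accession number, or gene symbol — all matched exactly but
case-insensitively.  Resolution walks a fixed precedence (probe set, Entrez,
accession, symbol) and returns every probe set matching at the first tier
that yields anything, so an Entrez ID that happens to collide with a probe
set ID never silently merges two transcripts.

Output filters mirror the browser's options: a GO keyword (substring over a
partner's GO terms), a transcription-factor restriction ("transcription"
appearing in the gene title), and a correlation-sign restriction.
"""

from __future__ import annotations

import re
from dataclasses import dataclass

import pandas as pd

from .store import CorrelationRecord

__all__ = [
    "AnnotationTable",
    "AnnotationSchemaError",
    "QuerySpec",
    "load_annotation",
    "resolve_identifier",
    "apply_filters",
]

REQUIRED_COLUMN = "probe_set_id"
OPTIONAL_COLUMNS = ("entrez_id", "gene_symbol", "accessions", "gene_title", "go_terms")
_LIST_SPLIT = re.compile(r"[;,|/]+")


class AnnotationSchemaError(ValueError):
    """Annotation TSV missing required columns or violating key uniqueness."""


@dataclass
class QuerySpec:
    """One browser query: seed, optional partner, and output restrictions."""

    seed_query: str
    partner_query: str | None = None
    go_keyword: str | None = None
    tf_only: bool = False
    sign: str = "both"  # positive | negative | both
    max_results: int = 200
    family: str = "global"

    def __post_init__(self) -> None:
        if self.sign not in ("positive", "negative", "both"):
            raise ValueError("sign must be 'positive', 'negative' or 'both'")
        if self.max_results < 0:
            raise ValueError("max_results must be >= 0")


class AnnotationTable:
    """Feature annotations keyed by probe set, with case-folded lookup maps."""

    def __init__(self, df: pd.DataFrame):
        if REQUIRED_COLUMN not in df.columns:
            raise AnnotationSchemaError(f"missing required column {REQUIRED_COLUMN!r}")
        df = df.copy()
        df[REQUIRED_COLUMN] = df[REQUIRED_COLUMN].astype(str)
        if df[REQUIRED_COLUMN].duplicated().any():
            dup = df[REQUIRED_COLUMN][df[REQUIRED_COLUMN].duplicated()].iloc[0]
            raise AnnotationSchemaError(f"duplicate probe_set_id {dup!r}")
        for col in OPTIONAL_COLUMNS:
            if col not in df.columns:
                df[col] = ""
            df[col] = df[col].fillna("").astype(str)
        self.df = df.set_index(REQUIRED_COLUMN, drop=False)

        self._by_probe: dict[str, list[str]] = {}
        self._by_entrez: dict[str, list[str]] = {}
        self._by_accession: dict[str, list[str]] = {}
        self._by_symbol: dict[str, list[str]] = {}
        for probe, row in self.df.iterrows():
            self._by_probe.setdefault(probe.casefold(), []).append(probe)
            if row["entrez_id"]:
                self._by_entrez.setdefault(row["entrez_id"].casefold(), []).append(probe)
            for acc in _LIST_SPLIT.split(row["accessions"]):
                acc = acc.strip()
                if acc:
                    self._by_accession.setdefault(acc.casefold(), []).append(probe)
            if row["gene_symbol"]:
                self._by_symbol.setdefault(row["gene_symbol"].casefold(), []).append(probe)

    def __len__(self) -> int:
        return len(self.df)

    def __contains__(self, probe_set_id: str) -> bool:
        return probe_set_id in self.df.index

    def gene_symbol(self, probe_set_id: str) -> str:
        return self.df.at[probe_set_id, "gene_symbol"] if probe_set_id in self.df.index else ""

    def gene_of(self, probe_set_id: str) -> str:
        """Gene-level identity of a probe set: its symbol, else the probe ID."""
        sym = self.gene_symbol(probe_set_id)
        return sym if sym else probe_set_id

    def gene_title(self, probe_set_id: str) -> str:
        return self.df.at[probe_set_id, "gene_title"] if probe_set_id in self.df.index else ""

    def go_terms(self, probe_set_id: str) -> list[str]:
        if probe_set_id not in self.df.index:
            return []
        raw = self.df.at[probe_set_id, "go_terms"]
        return [t.strip() for t in _LIST_SPLIT.split(raw) if t.strip()]

    def entrez_id(self, probe_set_id: str) -> str:
        return self.df.at[probe_set_id, "entrez_id"] if probe_set_id in self.df.index else ""


def load_annotation(path) -> AnnotationTable:
    """Read the annotation TSV (probe_set_id required; other columns optional)."""
    df = pd.read_csv(path, sep="\t", dtype=str)
    return AnnotationTable(df)


def resolve_identifier(table: AnnotationTable, query: str) -> list[str]:
    """Probe sets matching a user identifier, by tiered exact match.

    Precedence: probe set ID, then Entrez ID, then accession, then gene
    symbol; matching is exact after case-folding.  Returns all probe sets at
    the first non-empty tier, or an empty list when nothing matches.
    """
    if not query or not query.strip():
        raise ValueError("empty identifier query")
    key = query.strip().casefold()
    for tier in (table._by_probe, table._by_entrez, table._by_accession, table._by_symbol):
        hits = tier.get(key)
        if hits:
            return sorted(hits)
    return []


def _passes(record: CorrelationRecord, partner: str, table: AnnotationTable,
            spec: QuerySpec) -> bool:
    if spec.sign == "positive" and not (record.r > 0):
        return False
    if spec.sign == "negative" and not (record.r < 0):
        return False
    if spec.tf_only and "transcription" not in table.gene_title(partner).casefold():
        return False
    if spec.go_keyword is not None:
        kw = spec.go_keyword.casefold()
        if not any(kw in term.casefold() for term in table.go_terms(partner)):
            return False
    return True


def apply_filters(
    records: list[CorrelationRecord],
    table: AnnotationTable,
    spec: QuerySpec,
    seed_feature: str | None = None,
) -> list[CorrelationRecord]:
    """Keep records whose *partner* satisfies the spec's restrictions.

    The partner is the non-seed member when ``seed_feature`` is given,
    otherwise ``feature_b``.  Order is preserved; r = 0 exactly is excluded
    by both sign filters (it carries no sign).
    """
    out = []
    for rec in records:
        if seed_feature is not None and rec.feature_a != seed_feature:
            partner = rec.feature_a
        else:
            partner = rec.feature_b
        if _passes(rec, partner, table, spec):
            out.append(rec)
    return out


def make_record_filter(table: AnnotationTable, spec: QuerySpec, seed_feature: str):
    """Predicate form of :func:`apply_filters` for streaming top-k queries."""
    def _filter(rec: CorrelationRecord) -> bool:
        partner = rec.feature_a if rec.feature_a != seed_feature else rec.feature_b
        return _passes(rec, partner, table, spec)
    return _filter
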