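"""Multi-tool read-annotation merging and abundance-matrix construction.

Metagenome reads are annotated by several tools in parallel (a k-mer
classifier, a translated aligner, a pathway profiler).  Each tool reports, per
read pair, a taxonomic and/or functional label together with the length of the
mapping that supports it.  To avoid counting a read pair twice when two tools
both annotate it, the longest mapping wins; exact length ties default to the
``diamond`` dialect.  The surviving assignments are tabulated into
sample x feature count matrices and into per-sample species-function
read-pair counts (the edge weights of the downstream graphs).
"""

from __future__ import annotations

import re
from dataclasses import dataclass, field
from pathlib import Path

import numpy as np
import pandas as pd

__all__ = [
    "SOURCE_PRECEDENCE",
    "AbundanceMatrix",
    "merge_assignments",
    "build_matrix",
    "build_pair_counts",
    "read_assignment_table",
    "write_assignment_table",
]

#: Tie-break order on equal mapped length: earliest wins.  The translated
#: aligner is the documented default; the remaining order is fixed so that a
#: tie between any two dialects is deterministic.
SOURCE_PRECEDENCE = ("diamond", "kraken2", "humann3")

ASSIGNMENT_COLUMNS = ["read_id", "sample_id", "source", "kind", "label", "mapped_length"]

_KNUM_RE = re.compile(r"^K\d+$")


def is_k_number(label: str) -> bool:
    """True when *label* is a KEGG orthologue identifier (``K`` + digits)."""
    return bool(_KNUM_RE.match(str(label)))


@dataclass
class AbundanceMatrix:
    """Sample x feature count matrix (species or KEGG orthologues).

    ``data`` holds samples as rows and features as columns.  ``normalisation``
    tracks whether the values are raw integer counts, rarefied counts, or
    counts-per-million against one of two per-sample totals.
    """

    data: pd.DataFrame
    feature_kind: str  # "taxon" | "function"
    normalisation: str = "raw"  # raw | rarefied | cpm_total | cpm_mapped

    def __post_init__(self) -> None:
        if self.feature_kind not in ("taxon", "function"):
            raise ValueError(f"feature_kind must be 'taxon' or 'function', got {self.feature_kind!r}")
        if self.normalisation not in ("raw", "rarefied", "cpm_total", "cpm_mapped"):
            raise ValueError(f"unknown normalisation {self.normalisation!r}")
        if self.data.index.duplicated().any():
            dupes = self.data.index[self.data.index.duplicated()].tolist()
            raise ValueError(f"duplicate sample ids: {dupes}")
        if self.data.columns.duplicated().any():
            dupes = self.data.columns[self.data.columns.duplicated()].tolist()
            raise ValueError(f"duplicate feature ids: {dupes}")
        if (self.data.to_numpy() < 0).any():
            raise ValueError("counts must be non-negative")
        if self.normalisation in ("raw", "rarefied"):
            vals = self.data.to_numpy()
            if vals.size and not np.allclose(vals, np.round(vals)):
                raise ValueError(f"{self.normalisation} counts must be integers")

    @property
    def sample_ids(self) -> list[str]:
        return list(self.data.index)

    @property
    def feature_ids(self) -> list[str]:
        return list(self.data.columns)

    def to_csv(self, path: str | Path) -> None:
        out = self.data.copy()
        out.index.name = "sample_id"
        out.to_csv(path)

    @classmethod
    def from_csv(cls, path: str | Path, feature_kind: str, normalisation: str = "raw") -> "AbundanceMatrix":
        data = pd.read_csv(path, index_col="sample_id")
        return cls(data=data, feature_kind=feature_kind, normalisation=normalisation)


def _validate_assignments(records: pd.DataFrame) -> pd.DataFrame:
    missing = [c for c in ASSIGNMENT_COLUMNS if c not in records.columns]
    if missing:
        raise ValueError(f"assignment table missing columns: {missing}")
    records = records[ASSIGNMENT_COLUMNS].copy()
    bad_source = set(records["source"]) - set(SOURCE_PRECEDENCE)
    if bad_source:
        raise ValueError(f"unknown source dialects: {sorted(bad_source)}")
    bad_kind = set(records["kind"]) - {"taxon", "function"}
    if bad_kind:
        raise ValueError(f"unknown kinds: {sorted(bad_kind)}")
    if (records["mapped_length"] <= 0).any():
        raise ValueError("mapped_length must be positive")
    func = records.loc[records["kind"] == "function", "label"]
    bad = func[~func.map(is_k_number)]
    if len(bad):
        raise ValueError(f"function labels must be K-numbers; offending labels: {sorted(set(bad))[:5]}")
    dup = records.duplicated(subset=["read_id", "sample_id", "kind", "source"], keep=False)
    if dup.any():
        offending = records.loc[dup, "read_id"].iloc[0]
        raise ValueError(
            f"duplicate (read, sample, kind, source) group, e.g. read {offending!r}: "
            "each source may appear at most once per read and kind"
        )
    return records


def merge_assignments(records: pd.DataFrame) -> pd.DataFrame:
    """Resolve multi-tool annotation claims to one winner per read and kind.

    Within each ``(read_id, sample_id, kind)`` group the record with the
    largest ``mapped_length`` is kept; on an exact tie the dialect earliest in
    :data:`SOURCE_PRECEDENCE` wins.  Taxon and function claims are merged
    independently, so a read may carry one of each.  Empty input yields an
    empty table.  Output order is canonical (sample, read, kind) so the result
    is independent of input row order.
    """
    if len(records) == 0:
        return pd.DataFrame(columns=ASSIGNMENT_COLUMNS)
    records = _validate_assignments(records)
    prio = {s: i for i, s in enumerate(SOURCE_PRECEDENCE)}
    work = records.assign(_prio=records["source"].map(prio))
    work = work.sort_values(
        ["sample_id", "read_id", "kind", "mapped_length", "_prio"],
        ascending=[True, True, True, False, True],
        kind="mergesort",
    )
    merged = work.drop_duplicates(subset=["sample_id", "read_id", "kind"], keep="first")
    merged = merged.drop(columns="_prio").reset_index(drop=True)
    return merged


def build_matrix(
    merged: pd.DataFrame,
    kind: str,
    sample_ids: list[str] | None = None,
    feature_ids: list[str] | None = None,
) -> AbundanceMatrix:
    """Tabulate merged records of one *kind* into a raw count matrix.

    Rows are samples, columns features, both in lexicographic order unless an
    explicit ordering is supplied (in which case absent rows/columns are
    zero-filled — useful for round trips against a known universe).
    """
    if kind not in ("taxon", "function"):
        raise ValueError(f"kind must be 'taxon' or 'function', got {kind!r}")
    sub = merged[merged["kind"] == kind] if len(merged) else merged
    if len(sub) == 0:
        index = pd.Index(sorted(sample_ids) if sample_ids is not None else [], name="sample_id")
        cols = pd.Index(sorted(feature_ids) if feature_ids is not None else [])
        data = pd.DataFrame(0, index=index, columns=cols, dtype=np.int64)
    else:
        data = pd.crosstab(sub["sample_id"], sub["label"]).astype(np.int64)
        data = data.sort_index(axis=0).sort_index(axis=1)
        data.index.name = "sample_id"
        data.columns.name = None
    if sample_ids is not None:
        data = data.reindex(index=list(sample_ids), fill_value=0)
        data.index.name = "sample_id"
    if feature_ids is not None:
        data = data.reindex(columns=list(feature_ids), fill_value=0)
    return AbundanceMatrix(data=data, feature_kind=kind, normalisation="raw")


def build_pair_counts(merged: pd.DataFrame) -> pd.DataFrame:
    """Count reads whose merged taxon and function winners coexist.

    Returns a table with columns ``sample_id, species, function, count`` —
    one row per (sample, species, K-number) pair with a positive read-pair
    count.  Reads lacking either annotation contribute nothing.  Winners are
    paired regardless of which source dialect produced each.
    """
    if len(merged) == 0:
        return pd.DataFrame(columns=["sample_id", "species", "function", "count"])
    taxa = merged[merged["kind"] == "taxon"][["sample_id", "read_id", "label"]]
    funcs = merged[merged["kind"] == "function"][["sample_id", "read_id", "label"]]
    both = taxa.merge(funcs, on=["sample_id", "read_id"], suffixes=("_taxon", "_function"))
    if len(both) == 0:
        return pd.DataFrame(columns=["sample_id", "species", "function", "count"])
    pairs = (
        both.groupby(["sample_id", "label_taxon", "label_function"], sort=True)
        .size()
        .reset_index(name="count")
        .rename(columns={"label_taxon": "species", "label_function": "function"})
    )
    return pairs


def write_assignment_table(records: pd.DataFrame, path: str | Path) -> None:
    records[ASSIGNMENT_COLUMNS].to_csv(path, sep="\t", index=False)


def read_assignment_table(path: str | Path) -> pd.DataFrame:
    records = pd.read_csv(path, sep="\t", dtype={"read_id": str, "sample_id": str, "label": str})
    return _validate_assignments(records)
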