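"""Abundance tables and sample metadata: reading, validation, alignment.

The analysis consumes two feature-by-sample count tables (genus-level taxa
and function-subrole level) plus a per-sample metadata sheet describing the
mother--infant-pair cohort design.  Counts are raw sequence counts; relative
abundances are derived on demand.  Tables are tab-separated text with feature
identifiers in the first column and sample identifiers in the header row.
"""

from __future__ import annotations

import json
import logging
from dataclasses import dataclass, field

import numpy as np
import pandas as pd

logger = logging.getLogger(__name__)

#: Canonical sampling occasions: infant weeks 1, 4, 13, 30, 52 and the
#: maternal samples just before delivery (MA) and one year after (MB).
TIMEPOINTS = ("I1", "I2", "I3", "I4", "I5", "MA", "MB")
INFANT_TIMEPOINTS = ("I1", "I2", "I3", "I4", "I5")
MATERNAL_TIMEPOINTS = ("MA", "MB")

#: Week-scale numeric codes used when regressing diversity against age.
TIMEPOINT_WEEKS = {"I1": 1.0, "I2": 4.0, "I3": 13.0, "I4": 30.0, "I5": 52.0}

DELIVERY_MODES = ("vaginal", "c_section", "na")
FEEDING_MODES = ("breast", "mixed", "formula", "solid", "na")


class FormatError(ValueError):
    """Raised when an input file violates the expected table format."""


def _check_unique(ids, kind: str) -> None:
    seen = set()
    for x in ids:
        if x in seen:
            raise FormatError(f"duplicate {kind} ID: {x!r}")
        seen.add(x)


@dataclass
class AbundanceTable:
    """Feature-by-sample table of nonnegative integer counts.

    Parameters
    ----------
    counts
        DataFrame with feature IDs as the index and sample IDs as columns.
        Entries must be nonnegative integers and every sample must contain
        at least one nonzero count.
    """

    counts: pd.DataFrame

    def __post_init__(self) -> None:
        df = self.counts
        _check_unique(df.index, "feature")
        _check_unique(df.columns, "sample")
        arr = df.to_numpy()
        if arr.size == 0:
            raise FormatError("empty abundance table")
        if not np.issubdtype(arr.dtype, np.number):
            raise FormatError("non-numeric entries in abundance table")
        if np.any(arr < 0):
            i, j = np.argwhere(arr < 0)[0]
            raise FormatError(
                f"negative count at feature {df.index[i]!r}, sample {df.columns[j]!r}"
            )
        if np.any(arr != np.round(arr)):
            i, j = np.argwhere(arr != np.round(arr))[0]
            raise FormatError(
                f"non-integer count at feature {df.index[i]!r}, sample {df.columns[j]!r}"
            )
        zero = arr.sum(axis=0) == 0
        if zero.any():
            bad = df.columns[zero][0]
            raise FormatError(f"sample {bad!r} has zero total count")
        self.counts = df.astype(np.int64)

    # -- basic accessors -------------------------------------------------
    @property
    def feature_ids(self) -> list[str]:
        return list(self.counts.index)

    @property
    def sample_ids(self) -> list[str]:
        return list(self.counts.columns)

    @property
    def shape(self) -> tuple[int, int]:
        return self.counts.shape

    def sample_totals(self) -> pd.Series:
        return self.counts.sum(axis=0)

    def detected(self) -> pd.DataFrame:
        """Boolean detection mask: a feature is present iff its raw count >= 1."""
        return self.counts >= 1

    def detected_set(self, sample_id: str) -> frozenset[str]:
        col = self.counts[sample_id]
        return frozenset(col.index[col >= 1])

    def subset_samples(self, sample_ids) -> "AbundanceTable":
        return AbundanceTable(self.counts.loc[:, list(sample_ids)].copy())

    def drop_empty_features(self) -> "AbundanceTable":
        keep = self.counts.sum(axis=1) > 0
        return AbundanceTable(self.counts.loc[keep].copy())

    def __eq__(self, other) -> bool:  # type: ignore[override]
        return isinstance(other, AbundanceTable) and self.counts.equals(other.counts)


@dataclass
class RelativeAbundanceTable:
    """Feature-by-sample table of proportions; each column sums to one."""

    proportions: pd.DataFrame

    def __post_init__(self) -> None:
        df = self.proportions
        _check_unique(df.index, "feature")
        _check_unique(df.columns, "sample")
        arr = df.to_numpy(dtype=float)
        if np.any(arr < 0) or np.any(arr > 1):
            raise FormatError("relative abundances outside [0, 1]")
        sums = arr.sum(axis=0)
        if np.any(np.abs(sums - 1.0) > 1e-9):
            bad = df.columns[np.argmax(np.abs(sums - 1.0))]
            raise FormatError(f"sample {bad!r} proportions do not sum to 1")

    @property
    def feature_ids(self) -> list[str]:
        return list(self.proportions.index)

    @property
    def sample_ids(self) -> list[str]:
        return list(self.proportions.columns)


@dataclass
class SampleMetadata:
    """Per-sample cohort metadata.

    Indexed by sample ID with columns ``pair_id``, ``timepoint``,
    ``delivery``, ``peripartum_antibiotics`` and ``feeding``.  Each
    ``(pair_id, timepoint)`` combination occurs at most once.
    """

    records: pd.DataFrame

    REQUIRED = ("pair_id", "timepoint", "delivery", "peripartum_antibiotics", "feeding")

    def __post_init__(self) -> None:
        df = self.records
        missing = [c for c in self.REQUIRED if c not in df.columns]
        if missing:
            raise FormatError(f"metadata missing columns: {missing}")
        _check_unique(df.index, "sample")
        bad_tp = set(df["timepoint"]) - set(TIMEPOINTS)
        if bad_tp:
            raise FormatError(f"unknown timepoints: {sorted(bad_tp)}")
        dup = df.duplicated(subset=["pair_id", "timepoint"])
        if dup.any():
            pair, tp = df.loc[dup, ["pair_id", "timepoint"]].iloc[0]
            raise FormatError(f"duplicate (pair, timepoint): ({pair}, {tp})")

    @property
    def sample_ids(self) -> list[str]:
        return list(self.records.index)

    def timepoint_of(self, sample_id: str) -> str:
        return self.records.loc[sample_id, "timepoint"]

    def samples_at(self, timepoint: str) -> list[str]:
        df = self.records
        return list(df.index[df["timepoint"] == timepoint])

    def pairs(self) -> list[str]:
        return sorted(self.records["pair_id"].unique())

    def sample_for(self, pair_id: str, timepoint: str) -> str | None:
        df = self.records
        hit = df.index[(df["pair_id"] == pair_id) & (df["timepoint"] == timepoint)]
        return hit[0] if len(hit) else None

    def subset(self, sample_ids) -> "SampleMetadata":
        return SampleMetadata(self.records.loc[list(sample_ids)].copy())

    def groups(self, sample_ids=None) -> list[str]:
        """Timepoint label per sample, in the order of ``sample_ids``."""
        ids = self.sample_ids if sample_ids is None else list(sample_ids)
        return [self.records.loc[s, "timepoint"] for s in ids]


# ---------------------------------------------------------------------------
# Readers / writers
# ---------------------------------------------------------------------------

def read_abundance_table(path, format: str = "tsv") -> AbundanceTable:
    """Read a feature-by-sample count table.

    ``tsv``: tab-separated, UTF-8, feature IDs in column 1, samples in the
    header row.  ``biom``: minimal dense BIOM-style JSON with ``rows``,
    ``columns`` and ``data`` keys.
    """
    if format == "tsv":
        try:
            df = pd.read_csv(path, sep="\t", index_col=0, dtype=object)
        except Exception as exc:  # pragma: no cover - pandas message passthrough
            raise FormatError(f"cannot parse {path}: {exc}") from exc
        df.index = df.index.astype(str)
        df.columns = df.columns.astype(str)
        _check_unique(df.index, "feature")
        _check_unique(df.columns, "sample")
        numeric = df.apply(pd.to_numeric, errors="coerce")
        bad = numeric.isna() & df.notna()
        if bad.to_numpy().any():
            i, j = np.argwhere(bad.to_numpy())[0]
            raise FormatError(
                f"non-numeric cell at row {df.index[i]!r}, column {df.columns[j]!r}"
            )
        return AbundanceTable(numeric.fillna(0))
    if format == "biom":
        with open(path) as fh:
            doc = json.load(fh)
        rows = [r["id"] if isinstance(r, dict) else r for r in doc["rows"]]
        cols = [c["id"] if isinstance(c, dict) else c for c in doc["columns"]]
        df = pd.DataFrame(np.asarray(doc["data"]), index=rows, columns=cols)
        return AbundanceTable(df)
    raise ValueError(f"unknown format: {format!r}")


def write_abundance_table(table: AbundanceTable, path) -> None:
    table.counts.to_csv(path, sep="\t", index_label="feature_id")


def read_metadata(path) -> SampleMetadata:
    df = pd.read_csv(path, dtype=str).set_index("sample_id")
    if "peripartum_antibiotics" in df.columns:
        df["peripartum_antibiotics"] = df["peripartum_antibiotics"].map(
            lambda v: {"True": True, "False": False, "true": True, "false": False}.get(v, v)
        )
    return SampleMetadata(df)


def write_metadata(metadata: SampleMetadata, path) -> None:
    metadata.records.to_csv(path, index_label="sample_id")


# ---------------------------------------------------------------------------
# Transformations
# ---------------------------------------------------------------------------

def to_relative(table: AbundanceTable | RelativeAbundanceTable) -> RelativeAbundanceTable:
    """Convert counts to per-sample proportions (idempotent)."""
    if isinstance(table, RelativeAbundanceTable):
        df = table.proportions
    else:
        df = table.counts
    totals = df.sum(axis=0)
    zero = totals == 0
    if zero.any():
        raise FormatError(f"sample {df.columns[zero.argmax()]!r} has zero total")
    return RelativeAbundanceTable(df.astype(float) / totals)


def align(tables, metadata: SampleMetadata):
    """Intersect and co-order samples across tables and metadata.

    Returns ``(aligned_tables, aligned_metadata)``.  Samples missing from any
    input are dropped with a warning; an empty intersection is an error.
    """
    tables = list(tables)
    if not tables:
        raise ValueError("no tables to align")
    common = [s for s in tables[0].sample_ids if all(s in t.counts.columns for t in tables)]
    common = [s for s in common if s in metadata.records.index]
    if not common:
        raise ValueError("no samples shared by all inputs")
    all_ids = set(metadata.sample_ids) | {s for t in tables for s in t.sample_ids}
    dropped = sorted(all_ids - set(common))
    if dropped:
        logger.warning("align: dropping %d sample(s): %s", len(dropped), ", ".join(dropped))
    out_tables = [t.subset_samples(common) for t in tables]
    return out_tables, metadata.subset(common)
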