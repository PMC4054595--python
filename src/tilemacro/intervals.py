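"""Genomic interval algebra shared by every pipeline stage.

Interval collections are plain :class:`pandas.DataFrame` objects with at
least ``chrom`` (str), ``start`` and ``end`` (int) columns.  Coordinates are
0-based half-open throughout the package, i.e. an interval covers the
nucleotides ``start .. end-1`` and has length ``end - start``.

Two semantic choices are fixed here and relied on downstream:

* ``merge_intervals`` joins intervals that share at least one nucleotide;
  *bookended* intervals (``a.end == b.start``) stay separate.  This matches
  the window-overlap semantics of the segmentation stage.
* Strand is carried through unchanged but ignored by all tiling-stage
  operations (tiling-array signal is unstranded); only the proximal-pair
  rules in :mod:`tilemacro.validation` honor it.
"""

from __future__ import annotations

import dataclasses
from typing import Iterable, Mapping

import numpy as np
import pandas as pd

CORE_COLS = ["chrom", "start", "end"]
BED6_COLS = ["chrom", "start", "end", "name", "score", "strand"]

#: Fixed vocabulary of annotation feature classes.
FEATURE_CLASSES = frozenset(
    {
        "gene_body",
        "coding_exon",
        "noncoding_exon",
        "pseudogene_exon",
        "lncrna_exon",
        "intron",
        "repeat",
        "gap",
        "tss",
        "terminus",
    }
)


class IntervalError(ValueError):
    """Malformed interval record (e.g. end <= start)."""


@dataclasses.dataclass(frozen=True)
class GenomicInterval:
    """A single genomic interval, 0-based half-open."""

    chrom: str
    start: int
    end: int
    strand: str = "."

    def __post_init__(self) -> None:
        if self.start < 0 or self.end <= self.start:
            raise IntervalError(
                f"malformed interval {self.chrom}:{self.start}-{self.end}"
            )

    @property
    def length(self) -> int:
        return self.end - self.start


def intervals(records: Iterable[tuple] | None = None, **extra) -> pd.DataFrame:
    """Build an interval frame from ``(chrom, start, end[, ...])`` tuples."""
    records = list(records or [])
    if not records:
        return empty_intervals()
    width = len(records[0])
    cols = (CORE_COLS + BED6_COLS[3:])[:width]
    df = pd.DataFrame(records, columns=cols)
    return df.astype({"start": np.int64, "end": np.int64})


def empty_intervals() -> pd.DataFrame:
    return pd.DataFrame(
        {"chrom": pd.Series(dtype=str),
         "start": pd.Series(dtype=np.int64),
         "end": pd.Series(dtype=np.int64)}
    )


def validate_intervals(df: pd.DataFrame, name: str = "intervals") -> pd.DataFrame:
    """Validate an interval frame, raising :class:`IntervalError` naming the record."""
    missing = [c for c in CORE_COLS if c not in df.columns]
    if missing:
        raise IntervalError(f"{name}: missing columns {missing}")
    if len(df) == 0:
        return df
    starts = df["start"].to_numpy()
    ends = df["end"].to_numpy()
    bad = np.flatnonzero((ends <= starts) | (starts < 0))
    if bad.size:
        row = df.iloc[bad[0]]
        raise IntervalError(
            f"{name}: malformed interval {row['chrom']}:{row['start']}-{row['end']}"
            f" (record {bad[0]})"
        )
    return df


def sort_intervals(df: pd.DataFrame) -> pd.DataFrame:
    return df.sort_values(["chrom", "start", "end"], kind="mergesort").reset_index(
        drop=True
    )


def total_length(df: pd.DataFrame) -> int:
    """Summed lengths; call on merged input for unique-nucleotide counts."""
    if len(df) == 0:
        return 0
    return int((df["end"] - df["start"]).sum())


def merge_intervals(df: pd.DataFrame, name: str = "intervals") -> pd.DataFrame:
    """Merge intervals overlapping by >= 1 nt; bookended intervals stay apart.

    Output is disjoint, sorted, and covers exactly the input's nucleotide union.
    """
    validate_intervals(df, name)
    if len(df) == 0:
        return empty_intervals()
    df = sort_intervals(df[CORE_COLS])
    out_frames = []
    for chrom, g in df.groupby("chrom", sort=True):
        s = g["start"].to_numpy()
        e = g["end"].to_numpy()
        run_max = np.maximum.accumulate(e)
        new_grp = np.ones(len(s), dtype=bool)
        new_grp[1:] = s[1:] >= run_max[:-1]  # >= : bookended starts a new group
        grp_start_idx = np.flatnonzero(new_grp)
        merged_start = s[grp_start_idx]
        merged_end = np.maximum.reduceat(e, grp_start_idx)
        out_frames.append(
            pd.DataFrame({"chrom": chrom, "start": merged_start, "end": merged_end})
        )
    return pd.concat(out_frames, ignore_index=True)


def subtract_intervals(a: pd.DataFrame, b: pd.DataFrame) -> pd.DataFrame:
    """Nucleotides of ``a`` not covered by ``b``, as maximal intervals."""
    a_m = merge_intervals(a, "a")
    if len(a_m) == 0:
        return empty_intervals()
    b_m = merge_intervals(b, "b")
    if len(b_m) == 0:
        return a_m
    b_by_chrom = {c: (g["start"].to_numpy(), g["end"].to_numpy())
                  for c, g in b_m.groupby("chrom", sort=False)}
    chroms, starts, ends = [], [], []
    for row in a_m.itertuples(index=False):
        if row.chrom not in b_by_chrom:
            chroms.append(row.chrom)
            starts.append(row.start)
            ends.append(row.end)
            continue
        bs, be = b_by_chrom[row.chrom]
        lo = int(np.searchsorted(be, row.start, side="right"))
        hi = int(np.searchsorted(bs, row.end, side="left"))
        cursor = row.start
        for j in range(lo, hi):
            if bs[j] > cursor:
                chroms.append(row.chrom)
                starts.append(cursor)
                ends.append(int(bs[j]))
            cursor = max(cursor, int(be[j]))
        if cursor < row.end:
            chroms.append(row.chrom)
            starts.append(cursor)
            ends.append(row.end)
    if not chroms:
        return empty_intervals()
    return pd.DataFrame(
        {"chrom": chroms,
         "start": np.asarray(starts, dtype=np.int64),
         "end": np.asarray(ends, dtype=np.int64)}
    )


def intersect_intervals(a: pd.DataFrame, b: pd.DataFrame) -> pd.DataFrame:
    """Nucleotides covered by both collections, as maximal intervals."""
    a_m = merge_intervals(a, "a")
    return subtract_intervals(a_m, subtract_intervals(a_m, b))


def overlap_nucleotides(a: pd.DataFrame, b: pd.DataFrame) -> int:
    """Number of nucleotides covered by both ``a`` and ``b``.

    Both sides are merged internally, so no nucleotide is double counted:
    |A ∩ B| = |A| + |B| − |A ∪ B|.
    """
    a_m = merge_intervals(a, "a")
    b_m = merge_intervals(b, "b")
    if len(a_m) == 0 or len(b_m) == 0:
        return 0
    union = merge_intervals(pd.concat([a_m, b_m], ignore_index=True))
    return total_length(a_m) + total_length(b_m) - total_length(union)


def complement_intervals(
    df: pd.DataFrame, chrom_sizes: Mapping[str, int]
) -> pd.DataFrame:
    """Per-chromosome complement of ``df`` within ``chrom_sizes``."""
    space = pd.DataFrame(
        {"chrom": list(chrom_sizes),
         "start": np.zeros(len(chrom_sizes), dtype=np.int64),
         "end": np.asarray(list(chrom_sizes.values()), dtype=np.int64)}
    )
    return subtract_intervals(space, df)


class CoverageIndex:
    """Fast per-query nucleotide-coverage lookups against a fixed interval set."""

    def __init__(self, df: pd.DataFrame):
        m = merge_intervals(df)
        self._by_chrom: dict[str, tuple[np.ndarray, np.ndarray, np.ndarray]] = {}
        for chrom, g in m.groupby("chrom", sort=False):
            s = g["start"].to_numpy()
            e = g["end"].to_numpy()
            cum = np.concatenate([[0], np.cumsum(e - s)])
            self._by_chrom[str(chrom)] = (s, e, cum)
        self.total = total_length(m)

    def overlap(self, chrom: str, start: int, end: int) -> int:
        return int(self.overlap_many(np.array([chrom]),
                                     np.array([start]), np.array([end]))[0])

    def overlap_many(
        self, chroms: np.ndarray, starts: np.ndarray, ends: np.ndarray
    ) -> np.ndarray:
        out = np.zeros(len(starts), dtype=np.int64)
        chroms = np.asarray(chroms)
        for chrom in np.unique(chroms):
            if chrom not in self._by_chrom:
                continue
            s, e, cum = self._by_chrom[chrom]
            sel = np.flatnonzero(chroms == chrom)
            q0 = np.asarray(starts)[sel]
            q1 = np.asarray(ends)[sel]
            i = np.searchsorted(e, q0, side="right")
            j = np.searchsorted(s, q1, side="left")
            cov = cum[j] - cum[i]
            has = j > i
            first_clip = np.where(has, np.maximum(0, q0 - s[np.minimum(i, len(s) - 1)]), 0)
            last_clip = np.where(has, np.maximum(0, e[np.maximum(j - 1, 0)] - q1), 0)
            out[sel] = np.maximum(cov - first_clip - last_clip, 0)
        return out


@dataclasses.dataclass
class AnnotationSet:
    """A named collection of annotation interval sets, keyed by feature class.

    Feature classes are drawn from :data:`FEATURE_CLASSES`; intervals are kept
    sorted per chromosome.
    """

    name: str
    features: dict[str, pd.DataFrame] = dataclasses.field(default_factory=dict)

    def __post_init__(self) -> None:
        clean = {}
        for klass, df in self.features.items():
            if klass not in FEATURE_CLASSES:
                raise ValueError(
                    f"unknown feature class {klass!r}; expected one of "
                    f"{sorted(FEATURE_CLASSES)}"
                )
            validate_intervals(df, f"{self.name}/{klass}")
            clean[klass] = sort_intervals(df)
        self.features = clean

    def get(self, klass: str) -> pd.DataFrame:
        if klass not in FEATURE_CLASSES:
            raise ValueError(f"unknown feature class {klass!r}")
        df = self.features.get(klass)
        return df if df is not None else empty_intervals()
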