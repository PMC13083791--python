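"""Peak-file I/O and interval algebra.

All coordinates are 0-based half-open (BED convention). Strand is ignored:
accessibility and binding peaks are unstranded. narrowPeak q-values are
stored as -log10(q) per the ENCODE format.
"""

from __future__ import annotations

import os
from dataclasses import dataclass, field
from typing import Iterable, Mapping, Optional, Sequence

import numpy as np

from .errors import ConfigurationError, PeakParseError, UsageError

__all__ = [
    "GenomicInterval",
    "SampleKey",
    "PeakSet",
    "UnionIntervalSet",
    "read_peaks",
    "write_bed",
    "write_narrowpeak",
    "write_union_bed4",
    "merge_intervals",
    "build_union",
    "overlap_any",
    "overlap_bases",
    "subtract_peaks",
]


@dataclass(frozen=True)
class GenomicInterval:
    """A half-open genomic interval [start, end) on a named chromosome."""

    chrom: str
    start: int
    end: int
    name: Optional[str] = None
    score: Optional[float] = None

    def __post_init__(self) -> None:
        if not self.chrom or any(ch.isspace() for ch in self.chrom):
            raise ValueError(f"invalid chromosome name: {self.chrom!r}")
        if not isinstance(self.start, (int, np.integer)) or not isinstance(
            self.end, (int, np.integer)
        ):
            raise ValueError(
                f"coordinates must be integers: {self.start!r}, {self.end!r}"
            )
        if self.start < 0 or self.start >= self.end:
            raise ValueError(
                f"require 0 <= start < end, got [{self.start}, {self.end})"
            )
        if self.score is not None and self.score < 0:
            raise ValueError(f"score must be non-negative, got {self.score}")

    @property
    def length(self) -> int:
        return self.end - self.start

    @property
    def midpoint(self) -> int:
        return (self.start + self.end) // 2

    @property
    def sort_key(self) -> tuple:
        return (self.chrom, self.start, self.end)

    def overlaps(self, other: "GenomicInterval") -> bool:
        return (
            self.chrom == other.chrom
            and self.start < other.end
            and other.start < self.end
        )


@dataclass(frozen=True)
class SampleKey:
    """Identifies one sequenced sample: a condition at one timepoint."""

    condition: str
    timepoint: str

    def __str__(self) -> str:  # used in file names and error messages
        return f"{self.condition}:{self.timepoint}"


def _sorted_tuple(intervals: Iterable[GenomicInterval]) -> tuple:
    return tuple(sorted(intervals, key=lambda iv: iv.sort_key))


@dataclass(frozen=True)
class PeakSet:
    """Called peaks for one sample, kept sorted by (chrom, start, end)."""

    intervals: tuple = ()
    sample: Optional[SampleKey] = None

    def __post_init__(self) -> None:
        object.__setattr__(self, "intervals", _sorted_tuple(self.intervals))

    def __len__(self) -> int:
        return len(self.intervals)

    def __iter__(self):
        return iter(self.intervals)


@dataclass(frozen=True)
class UnionIntervalSet:
    """Disjoint, sorted atlas of intervals merged from several peak sets."""

    intervals: tuple
    n_sources: int

    def __post_init__(self) -> None:
        ivs = _sorted_tuple(self.intervals)
        for a, b in zip(ivs, ivs[1:]):
            if a.chrom == b.chrom and b.start <= a.end:
                raise ValueError(
                    f"union intervals must be disjoint and non-bookended: "
                    f"{a} / {b}"
                )
        object.__setattr__(self, "intervals", ivs)

    def __len__(self) -> int:
        return len(self.intervals)

    def __iter__(self):
        return iter(self.intervals)

    @property
    def lengths(self) -> np.ndarray:
        return np.array([iv.length for iv in self.intervals], dtype=np.int64)


# ---------------------------------------------------------------------------
# interval algebra
# ---------------------------------------------------------------------------


def merge_intervals(
    intervals: Iterable[GenomicInterval], merge_bookended: bool = True
) -> list:
    """Merge overlapping (and optionally bookended) intervals.

    Returns a sorted list of disjoint intervals. Names and scores are not
    propagated: a merged interval is a new anonymous region.
    """
    out: list = []
    cur_chrom = None
    cur_start = cur_end = 0
    for iv in sorted(intervals, key=lambda x: x.sort_key):
        joins = (
            cur_chrom == iv.chrom
            and (iv.start < cur_end or (merge_bookended and iv.start == cur_end))
        )
        if joins:
            cur_end = max(cur_end, iv.end)
        else:
            if cur_chrom is not None:
                out.append(GenomicInterval(cur_chrom, cur_start, cur_end))
            cur_chrom, cur_start, cur_end = iv.chrom, iv.start, iv.end
    if cur_chrom is not None:
        out.append(GenomicInterval(cur_chrom, cur_start, cur_end))
    return out


def build_union(peak_sets: Sequence[PeakSet]) -> UnionIntervalSet:
    """Merge all peaks across samples into one disjoint union atlas."""
    if not peak_sets:
        raise UsageError("build_union requires at least one peak set")
    all_ivs = [iv for ps in peak_sets for iv in ps.intervals]
    if not all_ivs:
        raise UsageError("all input peak sets are empty; nothing to classify")
    merged = merge_intervals(all_ivs, merge_bookended=True)
    return UnionIntervalSet(intervals=tuple(merged), n_sources=len(peak_sets))


def _merged_arrays(subject: Iterable[GenomicInterval]) -> dict:
    """Per-chromosome (starts, ends, cumulative-length) arrays of the merged subject."""
    arrays: dict = {}
    for iv in merge_intervals(subject, merge_bookended=True):
        arrays.setdefault(iv.chrom, ([], []))
        arrays[iv.chrom][0].append(iv.start)
        arrays[iv.chrom][1].append(iv.end)
    out = {}
    for chrom, (ss, ee) in arrays.items():
        ms = np.asarray(ss, dtype=np.int64)
        me = np.asarray(ee, dtype=np.int64)
        cum = np.concatenate([[0], np.cumsum(me - ms)])
        out[chrom] = (ms, me, cum)
    return out


def overlap_bases(
    query: Sequence[GenomicInterval], subject: Iterable[GenomicInterval]
) -> np.ndarray:
    """Number of bases of each query interval covered by the subject set."""
    query = list(query)
    out = np.zeros(len(query), dtype=np.int64)
    arrays = _merged_arrays(subject)
    by_chrom: dict = {}
    for i, iv in enumerate(query):
        by_chrom.setdefault(iv.chrom, []).append(i)
    for chrom, idx in by_chrom.items():
        if chrom not in arrays:
            continue
        ms, me, cum = arrays[chrom]
        qi = np.asarray(idx, dtype=np.int64)
        qs = np.array([query[i].start for i in idx], dtype=np.int64)
        qe = np.array([query[i].end for i in idx], dtype=np.int64)
        i0 = np.searchsorted(me, qs, side="right")
        i1 = np.searchsorted(ms, qe, side="left")
        hit = i1 > i0
        if hit.any():
            a, b = i0[hit], i1[hit]
            total = cum[b] - cum[a]
            left = np.maximum(qs[hit] - ms[a], 0)
            right = np.maximum(me[b - 1] - qe[hit], 0)
            out[qi[hit]] = total - left - right
    return out


def overlap_any(
    query: Sequence[GenomicInterval], subject: Iterable[GenomicInterval]
) -> np.ndarray:
    """Boolean vector: does each query interval share >=1 base with the subject?"""
    return overlap_bases(query, subject) > 0


def subtract_peaks(peaks: PeakSet, control: PeakSet) -> PeakSet:
    """Drop every peak that overlaps any control peak (whole-peak removal)."""
    if not len(control):
        return peaks
    keep = ~overlap_any(peaks.intervals, control.intervals)
    return PeakSet(
        intervals=tuple(iv for iv, k in zip(peaks.intervals, keep) if k),
        sample=peaks.sample,
    )


# ---------------------------------------------------------------------------
# file I/O
# ---------------------------------------------------------------------------

NARROWPEAK_COLUMNS = 10
_NARROWPEAK_QVALUE_COL = 8  # 0-based index of the -log10(q) column


def read_peaks(
    path: "str | os.PathLike",
    format: str = "narrowpeak",
    q_max: Optional[float] = None,
    sample: Optional[SampleKey] = None,
) -> PeakSet:
    """Read a BED3 or ENCODE narrowPeak file into a sorted PeakSet.

    With ``format="narrowpeak"`` and ``q_max`` set, rows whose -log10(q)
    column falls below -log10(q_max) are dropped (i.e. only peaks with
    q < q_max survive, matching a caller-side FDR threshold).
    """
    fmt = format.lower()
    if fmt not in ("bed3", "narrowpeak"):
        raise UsageError(f"unknown peak format: {format!r} (use bed3|narrowpeak)")
    if not os.path.exists(path):
        raise FileNotFoundError(f"peak file not found: {path}")
    q_floor = None if q_max is None else -np.log10(q_max)
    intervals = []
    with open(path) as fh:
        for lineno, line in enumerate(fh, start=1):
            line = line.rstrip("\n")
            if not line or line.startswith(("#", "track", "browser")):
                continue
            fields = line.split("\t")
            if fmt == "narrowpeak" and len(fields) < NARROWPEAK_COLUMNS:
                raise PeakParseError(
                    f"{path}:{lineno}: narrowPeak rows need >= "
                    f"{NARROWPEAK_COLUMNS} columns, got {len(fields)}"
                )
            if len(fields) < 3:
                raise PeakParseError(
                    f"{path}:{lineno}: expected >= 3 tab-separated columns"
                )
            try:
                start, end = int(fields[1]), int(fields[2])
            except ValueError as exc:
                raise PeakParseError(
                    f"{path}:{lineno}: non-integer coordinates "
                    f"{fields[1]!r}, {fields[2]!r}"
                ) from exc
            name = None
            score = None
            if fmt == "narrowpeak":
                name = fields[3] if fields[3] not in (".", "") else None
                try:
                    signal = float(fields[6])
                    qvalue = float(fields[_NARROWPEAK_QVALUE_COL])
                except ValueError as exc:
                    raise PeakParseError(
                        f"{path}:{lineno}: malformed narrowPeak numeric column"
                    ) from exc
                score = signal
                if q_floor is not None and qvalue < q_floor:
                    continue
            try:
                intervals.append(
                    GenomicInterval(fields[0], start, end, name=name, score=score)
                )
            except ValueError as exc:
                raise PeakParseError(f"{path}:{lineno}: {exc}") from exc
    return PeakSet(intervals=tuple(intervals), sample=sample)


def write_bed(intervals: Iterable[GenomicInterval], path) -> None:
    with open(path, "w") as fh:
        for iv in sorted(intervals, key=lambda x: x.sort_key):
            fh.write(f"{iv.chrom}\t{iv.start}\t{iv.end}\n")


def write_narrowpeak(
    peaks: "PeakSet | Iterable[GenomicInterval]", path, neg_log10_q: float = -1.0
) -> None:
    """Write intervals as 10-column narrowPeak.

    ``neg_log10_q`` fills the qValue column for every row (-1 = unset, the
    narrowPeak convention); pass a real value when downstream readers will
    apply a q threshold.
    """
    intervals = peaks.intervals if isinstance(peaks, PeakSet) else peaks
    with open(path, "w") as fh:
        for i, iv in enumerate(sorted(intervals, key=lambda x: x.sort_key), 1):
            name = iv.name or f"peak_{i}"
            signal = iv.score if iv.score is not None else 0.0
            fh.write(
                f"{iv.chrom}\t{iv.start}\t{iv.end}\t{name}\t0\t.\t"
                f"{signal:g}\t-1\t{neg_log10_q:g}\t-1\n"
            )


def write_union_bed4(union: UnionIntervalSet, path) -> None:
    """Write a union set as BED4 with sequential IDs U000001, U000002, ..."""
    with open(path, "w") as fh:
        for i, iv in enumerate(union.intervals, 1):
            fh.write(f"{iv.chrom}\t{iv.start}\t{iv.end}\tU{i:06d}\n")
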