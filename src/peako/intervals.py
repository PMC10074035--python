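"""Genomic interval model, BED / narrowPeak I/O, and overlap set algebra.

All coordinates are 0-based half-open (BED convention).  "Overlap" always
means sharing at least one base under half-open arithmetic, so book-ended
intervals (end of one == start of the next) do NOT overlap for
:func:`subtract_all` and :func:`intersect_keep_a`, but ARE fused by
:func:`merge_intervals`, which merges regions at distance 0.  This mirrors
the default semantics of the BEDTools operations ``subtract -A``,
``intersect -wa`` and ``merge`` that the ranking metric is defined over.
"""

from __future__ import annotations

import logging
from dataclasses import dataclass, replace
from pathlib import Path
from typing import Iterable, Iterator, Mapping

import numpy as np

log = logging.getLogger(__name__)

STRANDS = frozenset({"+", "-", "."})

__all__ = [
    "GenomicInterval",
    "NarrowPeakRecord",
    "PeakSet",
    "ParseError",
    "read_bed",
    "write_bed",
    "read_narrowpeak",
    "write_narrowpeak",
    "read_chrom_sizes",
    "extend_to_uniform",
    "subtract_all",
    "intersect_keep_a",
    "merge_intervals",
]


class ParseError(ValueError):
    """Raised on malformed BED/narrowPeak/chrom-sizes input."""


@dataclass(frozen=True)
class GenomicInterval:
    """A half-open genomic region ``chrom:[start, end)``.

    Empty intervals are rejected: every stored interval covers at least
    one base.
    """

    chrom: str
    start: int
    end: int
    name: str = ""
    score: float | None = None
    strand: str = "."

    def __post_init__(self) -> None:
        if self.start < 0:
            raise ValueError(f"negative start in {self.chrom}:{self.start}-{self.end}")
        if self.end <= self.start:
            raise ValueError(
                f"empty or inverted interval {self.chrom}:{self.start}-{self.end}"
            )
        if self.strand not in STRANDS:
            raise ValueError(f"invalid strand {self.strand!r}")

    @property
    def key(self) -> tuple[str, int, int]:
        return (self.chrom, self.start, self.end)

    def __len__(self) -> int:
        return self.end - self.start

    def overlaps(self, other: "GenomicInterval") -> bool:
        """True when the two intervals share >= 1 base."""
        return (
            self.chrom == other.chrom
            and self.start < other.end
            and other.start < self.end
        )


@dataclass(frozen=True)
class NarrowPeakRecord:
    """One ENCODE narrowPeak line: an interval plus summit and signal stats.

    ``summit_offset`` is relative to ``interval.start``; the sentinel ``-1``
    marks an unknown summit.
    """

    interval: GenomicInterval
    summit_offset: int
    signal: float = 0.0
    p_score: float = -1.0
    q_score: float = -1.0

    def __post_init__(self) -> None:
        if self.summit_offset != -1:
            if self.summit_offset < 0:
                raise ValueError(f"negative summit offset {self.summit_offset}")
            if self.interval.start + self.summit_offset >= self.interval.end:
                raise ValueError(
                    f"summit offset {self.summit_offset} outside peak "
                    f"{self.interval.chrom}:{self.interval.start}-{self.interval.end}"
                )

    @property
    def center(self) -> int:
        """Summit position, falling back to the interval midpoint."""
        if self.summit_offset == -1:
            return (self.interval.start + self.interval.end) // 2
        return self.interval.start + self.summit_offset


class PeakSet:
    """An ordered multiset of :class:`GenomicInterval`, sorted by
    (chrom, start, end).

    Duplicates are permitted — ``intersect_keep_a`` deliberately emits one
    copy of an A interval per overlapping B interval — and are only
    collapsed by :func:`merge_intervals` (or :meth:`deduplicated`).
    """

    __slots__ = ("intervals", "label")

    def __init__(
        self,
        intervals: Iterable[GenomicInterval] = (),
        label: str = "derived",
        *,
        presorted: bool = False,
    ) -> None:
        ivs = list(intervals)
        if presorted:
            for prev, cur in zip(ivs, ivs[1:]):
                if cur.key < prev.key:
                    raise ValueError("intervals claimed presorted but are not")
        else:
            ivs.sort(key=lambda iv: iv.key)
        self.intervals = ivs
        self.label = label

    def __len__(self) -> int:
        return len(self.intervals)

    def __iter__(self) -> Iterator[GenomicInterval]:
        return iter(self.intervals)

    def __getitem__(self, i):
        return self.intervals[i]

    def __eq__(self, other) -> bool:
        if not isinstance(other, PeakSet):
            return NotImplemented
        return self.intervals == other.intervals

    def __repr__(self) -> str:
        return f"PeakSet(n={len(self)}, label={self.label!r})"

    def coordinates(self) -> list[tuple[str, int, int]]:
        return [iv.key for iv in self.intervals]

    def deduplicated(self) -> "PeakSet":
        """Collapse intervals with identical (chrom, start, end)."""
        out: list[GenomicInterval] = []
        seen: set[tuple[str, int, int]] = set()
        for iv in self.intervals:
            if iv.key not in seen:
                seen.add(iv.key)
                out.append(iv)
        return PeakSet(out, label=self.label, presorted=True)


# ---------------------------------------------------------------------------
# I/O
# ---------------------------------------------------------------------------

_SKIP_PREFIXES = ("#", "track", "browser")


def _data_lines(path: Path) -> Iterator[tuple[int, str]]:
    with open(path) as fh:
        for lineno, raw in enumerate(fh, start=1):
            line = raw.rstrip("\n").rstrip("\r")
            if not line.strip() or line.startswith(_SKIP_PREFIXES):
                continue
            yield lineno, line


def _parse_coords(cols: list[str], path, lineno: int) -> tuple[str, int, int]:
    try:
        start, end = int(cols[1]), int(cols[2])
    except ValueError as exc:
        raise ParseError(f"{path}: line {lineno}: non-integer coordinate") from exc
    if start < 0 or start >= end:
        raise ParseError(
            f"{path}: line {lineno}: invalid interval [{start}, {end})"
        )
    return cols[0], start, end


def read_bed(path, label: str = "derived") -> PeakSet:
    """Read a BED3+ file into a sorted :class:`PeakSet`.

    Comment, ``track`` and ``browser`` lines are skipped.  Malformed lines
    raise :class:`ParseError` naming the offending line number.
    """
    out: list[GenomicInterval] = []
    for lineno, line in _data_lines(Path(path)):
        cols = line.split("\t")
        if len(cols) == 1:  # tolerate space-separated BED
            cols = line.split()
        if len(cols) < 3:
            raise ParseError(f"{path}: line {lineno}: expected >= 3 columns")
        chrom, start, end = _parse_coords(cols, path, lineno)
        name = cols[3] if len(cols) > 3 else ""
        score: float | None = None
        if len(cols) > 4 and cols[4] not in (".", ""):
            try:
                score = float(cols[4])
            except ValueError as exc:
                raise ParseError(f"{path}: line {lineno}: bad score {cols[4]!r}") from exc
        strand = cols[5] if len(cols) > 5 else "."
        if strand not in STRANDS:
            raise ParseError(f"{path}: line {lineno}: bad strand {strand!r}")
        out.append(GenomicInterval(chrom, start, end, name, score, strand))
    return PeakSet(out, label=label)


def write_bed(peaks: PeakSet, path) -> None:
    """Write a :class:`PeakSet` as BED6; round-trips the coordinate multiset."""
    with open(path, "w") as fh:
        for iv in peaks:
            score = "0" if iv.score is None else format(iv.score, "g")
            fh.write(
                f"{iv.chrom}\t{iv.start}\t{iv.end}\t{iv.name or '.'}\t{score}\t{iv.strand}\n"
            )


def read_narrowpeak(path) -> list[NarrowPeakRecord]:
    """Read a 10-column ENCODE narrowPeak file.

    Column 10 is the summit offset relative to the peak start; ``-1`` is
    preserved as the unknown-summit sentinel.  Any other column count, or a
    summit outside the peak, is a :class:`ParseError`.
    """
    out: list[NarrowPeakRecord] = []
    for lineno, line in _data_lines(Path(path)):
        cols = line.split("\t")
        if len(cols) != 10:
            raise ParseError(
                f"{path}: line {lineno}: narrowPeak requires 10 columns, got {len(cols)}"
            )
        chrom, start, end = _parse_coords(cols, path, lineno)
        strand = cols[5] if cols[5] in STRANDS else "."
        try:
            score = float(cols[4])
            signal, p_score, q_score = (float(c) for c in cols[6:9])
            summit = int(cols[9])
        except ValueError as exc:
            raise ParseError(f"{path}: line {lineno}: bad numeric field") from exc
        if summit != -1 and summit >= end - start:
            raise ParseError(
                f"{path}: line {lineno}: summit offset {summit} outside peak of "
                f"length {end - start}"
            )
        iv = GenomicInterval(chrom, start, end, cols[3], score, strand)
        out.append(NarrowPeakRecord(iv, summit, signal, p_score, q_score))
    out.sort(key=lambda r: r.interval.key)
    return out


def write_narrowpeak(records: Iterable[NarrowPeakRecord], path) -> None:
    with open(path, "w") as fh:
        for rec in records:
            iv = rec.interval
            score = 0 if iv.score is None else iv.score
            fh.write(
                f"{iv.chrom}\t{iv.start}\t{iv.end}\t{iv.name or '.'}\t"
                f"{format(score, 'g')}\t{iv.strand}\t{format(rec.signal, 'g')}\t"
                f"{format(rec.p_score, 'g')}\t{format(rec.q_score, 'g')}\t{rec.summit_offset}\n"
            )


def read_chrom_sizes(path) -> dict[str, int]:
    """Read two-column ``<chrom>\\t<length>`` text."""
    sizes: dict[str, int] = {}
    for lineno, line in _data_lines(Path(path)):
        cols = line.split()
        if len(cols) < 2:
            raise ParseError(f"{path}: line {lineno}: expected 2 columns")
        try:
            sizes[cols[0]] = int(cols[1])
        except ValueError as exc:
            raise ParseError(f"{path}: line {lineno}: bad length {cols[1]!r}") from exc
    return sizes


# ---------------------------------------------------------------------------
# Summit-centered uniform extension
# ---------------------------------------------------------------------------


def extend_to_uniform(
    records: Iterable[NarrowPeakRecord],
    width: int,
    chrom_sizes: Mapping[str, int],
    *,
    clip: bool = False,
    label: str = "derived",
) -> PeakSet:
    """Re-center each peak on its summit and extend to a uniform ``width``.

    Peaks with an unknown summit (sentinel -1) are centered on the interval
    midpoint.  By default, peaks whose centered window would cross a
    chromosome boundary are dropped (and the drop count logged) so that
    every surviving peak has length exactly ``width``; pass ``clip=True``
    for slop-style truncation at the boundary instead.
    """
    if width <= 0:
        raise ValueError(f"width must be positive, got {width}")
    half = width // 2
    out: list[GenomicInterval] = []
    dropped = 0
    for rec in records:
        chrom = rec.interval.chrom
        if chrom not in chrom_sizes:
            raise KeyError(f"chromosome {chrom!r} missing from chrom_sizes")
        clen = chrom_sizes[chrom]
        start = rec.center - half
        end = start + width
        if start < 0 or end > clen:
            if clip:
                start, end = max(0, start), min(clen, end)
                if end <= start:
                    dropped += 1
                    continue
            else:
                dropped += 1
                continue
        out.append(
            replace(rec.interval, start=start, end=end)
        )
    if dropped:
        log.info(
            "extend_to_uniform: dropped %d peak(s) crossing chromosome boundaries",
            dropped,
        )
    return PeakSet(out, label=label)


# ---------------------------------------------------------------------------
# Set algebra
# ---------------------------------------------------------------------------


def _chrom_index(peaks: PeakSet) -> dict[str, tuple[np.ndarray, np.ndarray, np.ndarray]]:
    """Per-chromosome (starts, running-max ends, sorted ends) arrays."""
    grouped: dict[str, list[GenomicInterval]] = {}
    for iv in peaks:
        grouped.setdefault(iv.chrom, []).append(iv)
    index = {}
    for chrom, ivs in grouped.items():
        starts = np.array([iv.start for iv in ivs])  # sorted: PeakSet order
        ends = np.array([iv.end for iv in ivs])
        index[chrom] = (starts, np.maximum.accumulate(ends), np.sort(ends))
    return index


def subtract_all(a: PeakSet, b: PeakSet) -> PeakSet:
    """Whole-interval subtraction: keep A intervals with zero overlapping
    bases against every B interval (BEDTools ``subtract -A``).

    Intervals are never truncated; the output is a sub-multiset of ``a``.
    """
    idx = _chrom_index(b)
    out: list[GenomicInterval] = []
    for iv in a:
        hit = False
        if iv.chrom in idx:
            starts, maxend, _ = idx[iv.chrom]
            j = int(np.searchsorted(starts, iv.end, side="left"))
            hit = j > 0 and maxend[j - 1] > iv.start
        if not hit:
            out.append(iv)
    return PeakSet(out, label=a.label, presorted=True)


def intersect_keep_a(a: PeakSet, b: PeakSet) -> PeakSet:
    """For every (a_i, b_j) pair sharing >= 1 base, emit one copy of a_i
    with its original coordinates (BEDTools ``intersect -wa``).

    Duplicates are retained by design; apply :func:`merge_intervals` to
    collapse them.
    """
    idx = _chrom_index(b)
    out: list[GenomicInterval] = []
    for iv in a:
        if iv.chrom not in idx:
            continue
        starts, _, ends_sorted = idx[iv.chrom]
        n_before = int(np.searchsorted(starts, iv.end, side="left"))
        n_ended = int(np.searchsorted(ends_sorted, iv.start, side="right"))
        out.extend([iv] * (n_before - n_ended))
    return PeakSet(out, label=a.label, presorted=True)


def merge_intervals(p: PeakSet) -> PeakSet:
    """Fuse overlapping and book-ended intervals per chromosome
    (BEDTools ``merge`` with default distance 0).

    The output covers exactly the same bases as the input with pairwise
    disjoint, non-book-ended intervals; names/scores/strands are dropped.
    """
    out: list[GenomicInterval] = []
    cur: tuple[str, int, int] | None = None
    for iv in p:  # already sorted by (chrom, start, end)
        if cur is not None and iv.chrom == cur[0] and iv.start <= cur[2]:
            cur = (cur[0], cur[1], max(cur[2], iv.end))
        else:
            if cur is not None:
                out.append(GenomicInterval(*cur))
            cur = (iv.chrom, iv.start, iv.end)
    if cur is not None:
        out.append(GenomicInterval(*cur))
    return PeakSet(out, label="derived", presorted=True)
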