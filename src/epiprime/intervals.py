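"""Genomic intervals, peak sets, BED I/O and interval set algebra.

Coordinates are 0-based half-open throughout (native BED convention), so an
interval [start, end) has length ``end - start`` and two intervals that merely
touch ([0,10) and [10,20)) do not overlap.
"""
from __future__ import annotations

from dataclasses import dataclass, field, replace
from typing import Iterable, Iterator, Sequence

__all__ = [
    "GenomicInterval",
    "PeakSet",
    "read_bed",
    "write_bed",
    "overlap_pairs",
    "overlap_length",
    "stage_unique_sets",
    "BedParseError",
]


class BedParseError(ValueError):
    """Raised for malformed BED records; carries the offending line number."""


@dataclass(frozen=True, order=True)
class GenomicInterval:
    """A half-open genomic interval [start, end) on ``chrom``.

    ``strand`` is '+', '-' or '.' (unstranded). ``name`` is optional and does
    not participate in equality-based de-duplication of peak sets, which is by
    (chrom, start, end).
    """

    chrom: str
    start: int
    end: int
    name: str = field(default="", compare=False)
    strand: str = field(default=".", compare=False)

    def __post_init__(self) -> None:
        if not self.chrom:
            raise ValueError("chrom must be non-empty")
        if not (0 <= self.start < self.end):
            raise ValueError(
                f"require 0 <= start < end, got [{self.start}, {self.end})"
            )
        if self.strand not in ("+", "-", "."):
            raise ValueError(f"invalid strand {self.strand!r}")

    @property
    def length(self) -> int:
        return self.end - self.start

    @property
    def midpoint(self) -> int:
        """Deterministic single-point location: floor((start+end)/2)."""
        return (self.start + self.end) // 2


def overlap_length(a: GenomicInterval, b: GenomicInterval) -> int:
    """Number of bases shared by two intervals (0 if different chromosomes)."""
    if a.chrom != b.chrom:
        return 0
    return max(0, min(a.end, b.end) - max(a.start, b.start))


class PeakSet:
    """An ordered, de-duplicated collection of intervals for one condition.

    Intervals are kept sorted by (chrom, start, end); duplicates by
    (chrom, start, end) are dropped on construction (first occurrence wins, so
    names survive de-duplication).
    """

    def __init__(self, intervals: Iterable[GenomicInterval], label: str = ""):
        seen: dict[tuple[str, int, int], GenomicInterval] = {}
        for iv in intervals:
            key = (iv.chrom, iv.start, iv.end)
            if key not in seen:
                seen[key] = iv
        self.intervals: list[GenomicInterval] = sorted(seen.values())
        self.label = label

    def __len__(self) -> int:
        return len(self.intervals)

    def __iter__(self) -> Iterator[GenomicInterval]:
        return iter(self.intervals)

    def __getitem__(self, i: int) -> GenomicInterval:
        return self.intervals[i]

    def __eq__(self, other: object) -> bool:
        if not isinstance(other, PeakSet):
            return NotImplemented
        return self.intervals == other.intervals

    def __repr__(self) -> str:
        return f"PeakSet({self.label!r}, n={len(self)})"

    def by_chrom(self) -> dict[str, list[GenomicInterval]]:
        out: dict[str, list[GenomicInterval]] = {}
        for iv in self.intervals:
            out.setdefault(iv.chrom, []).append(iv)
        return out

    def region_ids(self) -> list[str]:
        """Stable identifiers: the interval name, or chrom:start-end."""
        return [
            iv.name if iv.name else f"{iv.chrom}:{iv.start}-{iv.end}"
            for iv in self.intervals
        ]

    def relabel(self, label: str) -> "PeakSet":
        ps = PeakSet([], label)
        ps.intervals = list(self.intervals)
        return ps


def read_bed(path, label: str = "") -> PeakSet:
    """Read a BED3/BED6 file into a PeakSet.

    Lines starting with '#', 'track' or 'browser' are skipped. Coordinates are
    taken as 0-based half-open (native BED). Malformed lines raise
    :class:`BedParseError` naming the 1-based line number.
    """
    intervals = []
    with open(path) as fh:
        for lineno, raw in enumerate(fh, start=1):
            line = raw.rstrip("\n")
            if not line or line.startswith(("#", "track", "browser")):
                continue
            fields = line.split("\t")
            if len(fields) < 3:
                raise BedParseError(f"{path}:{lineno}: fewer than 3 columns")
            chrom = fields[0]
            try:
                start, end = int(fields[1]), int(fields[2])
            except ValueError as exc:
                raise BedParseError(
                    f"{path}:{lineno}: non-integer coordinates"
                ) from exc
            name = fields[3] if len(fields) > 3 else ""
            strand = fields[5] if len(fields) > 5 and fields[5] in "+-" else "."
            try:
                intervals.append(
                    GenomicInterval(chrom, start, end, name=name, strand=strand)
                )
            except ValueError as exc:
                raise BedParseError(f"{path}:{lineno}: {exc}") from exc
    return PeakSet(intervals, label=label)


def write_bed(peaks: PeakSet, path) -> None:
    """Write a PeakSet as BED6 (score column 0)."""
    with open(path, "w") as fh:
        for iv in peaks:
            fh.write(
                f"{iv.chrom}\t{iv.start}\t{iv.end}\t{iv.name or '.'}\t0\t{iv.strand}\n"
            )


def overlap_pairs(
    a: PeakSet | Sequence[GenomicInterval],
    b: PeakSet | Sequence[GenomicInterval],
    min_bp: int = 1,
) -> list[tuple[GenomicInterval, GenomicInterval]]:
    """All pairs (x in a, y in b) overlapping by at least ``min_bp`` bases.

    Sorted two-pointer sweep per chromosome; output ordered by (x, y).
    Swapping the arguments transposes the pairs.
    """
    if min_bp < 1:
        raise ValueError(f"min_bp must be >= 1, got {min_bp}")
    a_by = _group_sorted(a)
    b_by = _group_sorted(b)
    pairs: list[tuple[GenomicInterval, GenomicInterval]] = []
    for chrom in sorted(set(a_by) & set(b_by)):
        xs, ys = a_by[chrom], b_by[chrom]
        start_j = 0
        for x in xs:
            # advance past b-intervals that end before x could overlap them
            while start_j < len(ys) and ys[start_j].end <= x.start:
                start_j += 1
            j = start_j
            while j < len(ys) and ys[j].start < x.end:
                if min(x.end, ys[j].end) - max(x.start, ys[j].start) >= min_bp:
                    pairs.append((x, ys[j]))
                j += 1
    return pairs


def _group_sorted(ivs: Iterable[GenomicInterval]) -> dict[str, list[GenomicInterval]]:
    out: dict[str, list[GenomicInterval]] = {}
    for iv in sorted(ivs):
        out.setdefault(iv.chrom, []).append(iv)
    return out


def stage_unique_sets(
    stage_sets: dict[str, PeakSet], min_bp: int = 1
) -> dict[str, dict[str, PeakSet]]:
    """Partition each stage's peaks into stage-unique and shared subsets.

    A peak is unique to stage ``s`` iff it overlaps (>= min_bp) no peak of any
    other stage; otherwise it is shared. The partition is exhaustive and
    disjoint within each stage, and invariant to the order of stages.
    """
    if len(stage_sets) < 2:
        raise ValueError("need at least 2 stages")
    result: dict[str, dict[str, PeakSet]] = {}
    for stage, peaks in stage_sets.items():
        overlapping: set[tuple[str, int, int]] = set()
        for other, other_peaks in stage_sets.items():
            if other == stage:
                continue
            for x, _ in overlap_pairs(peaks, other_peaks, min_bp=min_bp):
                overlapping.add((x.chrom, x.start, x.end))
        unique, shared = [], []
        for iv in peaks:
            (shared if (iv.chrom, iv.start, iv.end) in overlapping else unique).append(iv)
        result[stage] = {
            "unique": PeakSet(unique, label=f"{peaks.label}/unique"),
            "shared": PeakSet(shared, label=f"{peaks.label}/shared"),
        }
    return result
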