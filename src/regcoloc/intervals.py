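"""Genomic interval data model, BED I/O, and the windowed-overlap kernel.

Coordinates follow the BED convention: 0-based, half-open ``[start, end)``.
All downstream distance computations are between single positions (peak
centers, TSSs), so the convention affects a peak center by at most 1 bp.
"""

from __future__ import annotations

from collections import defaultdict
from dataclasses import dataclass, field, replace
from pathlib import Path
from typing import Iterable, Iterator, Mapping, Sequence

from intervaltree import IntervalTree

__all__ = [
    "GenomicInterval",
    "IntervalSet",
    "read_intervals",
    "write_intervals",
    "read_genome",
    "write_genome",
    "window_hits",
    "merge_overlapping",
    "subtract_intervals",
]


@dataclass(frozen=True, order=True)
class GenomicInterval:
    """A half-open genomic interval ``[start, end)`` on ``chrom``.

    ``strand`` is "+", "-" or "." (unstranded).  ``score`` is carried through
    BED6 round-trips and is used by the consensus module to store replicate
    support.
    """

    chrom: str
    start: int
    end: int
    name: str | None = None
    score: float | None = None
    strand: str = "."

    def __post_init__(self) -> None:
        if not self.chrom:
            raise ValueError("chrom must be non-empty")
        if not (0 <= self.start < self.end):
            raise ValueError(
                f"invalid interval {self.chrom}:{self.start}-{self.end}: "
                "need 0 <= start < end"
            )
        if self.strand not in ("+", "-", "."):
            raise ValueError(f"invalid strand {self.strand!r}")

    @property
    def length(self) -> int:
        return self.end - self.start

    @property
    def center(self) -> int:
        """Midpoint, rounded down: ``floor((start + end) / 2)``."""
        return (self.start + self.end) // 2

    def expanded(self, window_bp: int) -> "GenomicInterval":
        """Interval widened by ``window_bp`` on both sides (clipped at 0)."""
        if window_bp < 0:
            raise ValueError("window_bp must be non-negative")
        return replace(self, start=max(0, self.start - window_bp), end=self.end + window_bp)

    def overlaps(self, other: "GenomicInterval") -> bool:
        """True iff the two intervals share >= 1 bp (same chromosome)."""
        return (
            self.chrom == other.chrom
            and self.start < other.end
            and other.start < self.end
        )


class IntervalSet:
    """A collection of :class:`GenomicInterval` with an optional genome table.

    Preserves input order; builds per-chromosome interval trees lazily so
    chromosome-restricted queries are O(log n + k).
    """

    def __init__(
        self,
        intervals: Iterable[GenomicInterval] = (),
        genome: Mapping[str, int] | None = None,
    ) -> None:
        self.intervals: list[GenomicInterval] = list(intervals)
        self.genome: dict[str, int] | None = dict(genome) if genome is not None else None
        self._trees: dict[str, IntervalTree] | None = None
        if self.genome is not None:
            bad = [
                iv
                for iv in self.intervals
                if iv.chrom in self.genome and iv.end > self.genome[iv.chrom]
            ]
            if bad:
                iv = bad[0]
                raise ValueError(
                    f"interval {iv.chrom}:{iv.start}-{iv.end} extends past "
                    f"chromosome length {self.genome[iv.chrom]}"
                )

    def __len__(self) -> int:
        return len(self.intervals)

    def __iter__(self) -> Iterator[GenomicInterval]:
        return iter(self.intervals)

    def __repr__(self) -> str:
        return f"IntervalSet({len(self)} intervals)"

    @property
    def chromosomes(self) -> list[str]:
        seen: dict[str, None] = {}
        for iv in self.intervals:
            seen.setdefault(iv.chrom, None)
        return list(seen)

    def validate_chromosomes(self) -> list[str]:
        """Chromosome names absent from the genome table (exact-string match).

        Silent "chr1" vs "1" mismatches are the classic interval-analysis bug;
        callers are expected to surface a non-empty return value.
        """
        if self.genome is None:
            return []
        return [c for c in self.chromosomes if c not in self.genome]

    def _tree(self, chrom: str) -> IntervalTree:
        if self._trees is None:
            trees: dict[str, IntervalTree] = defaultdict(IntervalTree)
            for idx, iv in enumerate(self.intervals):
                trees[iv.chrom].addi(iv.start, iv.end, idx)
            self._trees = dict(trees)
        return self._trees.get(chrom, IntervalTree())

    def overlapping(self, chrom: str, start: int, end: int) -> list[GenomicInterval]:
        """All member intervals sharing >= 1 bp with ``[start, end)``."""
        return [self.intervals[hit.data] for hit in sorted(self._tree(chrom).overlap(start, end))]

    def total_bp(self) -> int:
        """Total covered bp after merging overlaps."""
        return sum(iv.length for iv in merge_overlapping(self))


def _parse_bed_line(line: str, lineno: int, fmt: str) -> GenomicInterval:
    fields = line.rstrip("\n").split("\t")
    min_cols = 3 if fmt == "BED3" else 6
    if len(fields) < min_cols:
        raise ValueError(f"line {lineno}: expected >= {min_cols} columns, got {len(fields)}")
    try:
        start, end = int(fields[1]), int(fields[2])
    except ValueError as exc:
        raise ValueError(f"line {lineno}: non-integer coordinates") from exc
    if start >= end:
        raise ValueError(f"line {lineno}: start >= end ({start} >= {end})")
    name = score = None
    strand = "."
    if fmt == "BED6":
        name = fields[3] if fields[3] != "." else None
        score = None if fields[4] == "." else float(fields[4])
        strand = fields[5]
    try:
        return GenomicInterval(fields[0], start, end, name=name, score=score, strand=strand)
    except ValueError as exc:
        raise ValueError(f"line {lineno}: {exc}") from exc


def read_intervals(
    path: str | Path,
    format: str = "BED6",
    genome: Mapping[str, int] | None = None,
) -> IntervalSet:
    """Read a BED3 or BED6 file (tab-separated, no header) into an IntervalSet.

    Input order is preserved.  Malformed lines raise ``ValueError`` naming the
    line number.  With ``format="BED6"`` a 3-column file is rejected.
    """
    if format not in ("BED3", "BED6"):
        raise ValueError(f"unsupported format {format!r}")
    intervals = []
    with open(path) as fh:
        for lineno, line in enumerate(fh, start=1):
            if not line.strip():
                continue
            intervals.append(_parse_bed_line(line, lineno, format))
    return IntervalSet(intervals, genome=genome)


def write_intervals(iset: IntervalSet, path: str | Path, format: str = "BED6") -> None:
    """Write BED3/BED6.  Missing name/score are written as ".", "0"."""
    with open(path, "w") as fh:
        for iv in iset:
            if format == "BED3":
                fh.write(f"{iv.chrom}\t{iv.start}\t{iv.end}\n")
            elif format == "BED6":
                score = "0" if iv.score is None else f"{iv.score:g}"
                fh.write(
                    f"{iv.chrom}\t{iv.start}\t{iv.end}\t{iv.name or '.'}\t{score}\t{iv.strand}\n"
                )
            else:
                raise ValueError(f"unsupported format {format!r}")


def read_genome(path: str | Path) -> dict[str, int]:
    """Read a bedtools-style genome file: two tab-separated columns (chrom, length)."""
    genome: dict[str, int] = {}
    with open(path) as fh:
        for lineno, line in enumerate(fh, start=1):
            if not line.strip():
                continue
            fields = line.split("\t")
            if len(fields) < 2:
                raise ValueError(f"line {lineno}: expected 2 columns")
            genome[fields[0]] = int(fields[1])
    return genome


def write_genome(genome: Mapping[str, int], path: str | Path) -> None:
    with open(path, "w") as fh:
        for chrom, length in genome.items():
            fh.write(f"{chrom}\t{length}\n")


def window_hits(
    query: IntervalSet,
    subject: IntervalSet,
    window_bp: int = 0,
) -> set[tuple[GenomicInterval, GenomicInterval]]:
    """All (query, subject) pairs within ``window_bp`` of each other.

    Semantics copy ``bedtools window -w``: the query interval is expanded by
    ``window_bp`` on both sides and a pair is reported iff the expanded query
    shares >= 1 bp with the subject (half-open arithmetic, same chromosome).
    Swapping query and subject yields the transposed pair set.
    """
    if window_bp < 0:
        raise ValueError("window_bp must be non-negative")
    hits: set[tuple[GenomicInterval, GenomicInterval]] = set()
    for q in query:
        expanded = q.expanded(window_bp)
        for s in subject.overlapping(q.chrom, expanded.start, expanded.end):
            hits.add((q, s))
    return hits


def merge_overlapping(iset: IntervalSet) -> IntervalSet:
    """Merge the transitive closure of >= 1 bp overlaps into union spans.

    Output is sorted by (chrom, start) and non-overlapping; names/scores are
    dropped.  Idempotent.
    """
    merged: list[GenomicInterval] = []
    for iv in sorted(iset, key=lambda x: (x.chrom, x.start, x.end)):
        if merged and merged[-1].chrom == iv.chrom and iv.start < merged[-1].end:
            if iv.end > merged[-1].end:
                merged[-1] = replace(merged[-1], end=iv.end)
        else:
            merged.append(GenomicInterval(iv.chrom, iv.start, iv.end))
    return IntervalSet(merged, genome=iset.genome)


def subtract_intervals(iset: IntervalSet, control: IntervalSet) -> IntervalSet:
    """Remove every interval sharing >= 1 bp with any control interval.

    Whole-interval subtraction (the interval is dropped, not trimmed), which
    is how control/artifact peaks are removed from ChIP peak lists.  Survivor
    order and attributes are unchanged; idempotent.
    """
    kept = [
        iv for iv in iset if not control.overlapping(iv.chrom, iv.start, iv.end)
    ]
    return IntervalSet(kept, genome=iset.genome)
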