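"""Genomic intervals and per-chromosome interval indexing.

All internal coordinates are 0-based half-open. VCF/GTF 1-based conventions
are converted at the I/O boundary (see :mod:`asedit.io_formats`).
"""

from __future__ import annotations

from dataclasses import dataclass, field
from typing import Dict, Iterable, List, Sequence, Tuple

from intervaltree import IntervalTree

STRANDS = ("+", "-", ".")


@dataclass(frozen=True)
class GenomicInterval:
    """Half-open genomic interval on a named chromosome."""

    chrom: str
    start: int
    end: int
    strand: str = "."

    def __post_init__(self) -> None:
        if not self.chrom:
            raise ValueError("chrom must be non-empty")
        if not (0 <= self.start < self.end):
            raise ValueError(
                f"invalid interval {self.chrom}:{self.start}-{self.end} "
                "(need 0 <= start < end)"
            )
        if self.strand not in STRANDS:
            raise ValueError(f"invalid strand {self.strand!r}")

    def __len__(self) -> int:
        return self.end - self.start

    def contains(self, chrom: str, pos: int) -> bool:
        return chrom == self.chrom and self.start <= pos < self.end

    def expanded(self, flank: int) -> "GenomicInterval":
        """Interval widened by *flank* on both sides (clipped at 0)."""
        return GenomicInterval(
            self.chrom, max(0, self.start - flank), self.end + flank, self.strand
        )

    def gap_to(self, other: "GenomicInterval") -> int | None:
        """Edge-to-edge distance; 0 when overlapping; None across chromosomes."""
        if self.chrom != other.chrom:
            return None
        if self.start < other.end and other.start < self.end:
            return 0
        return max(self.start, other.start) - min(self.end, other.end)


def merge_intervals(intervals: Iterable[GenomicInterval]) -> List[GenomicInterval]:
    """Merge overlapping or touching intervals per chromosome.

    Strand is dropped ('.') on merged output: masks are strand-blind.
    """
    by_chrom: Dict[str, List[GenomicInterval]] = {}
    for iv in intervals:
        by_chrom.setdefault(iv.chrom, []).append(iv)
    out: List[GenomicInterval] = []
    for chrom in sorted(by_chrom):
        ivs = sorted(by_chrom[chrom], key=lambda i: (i.start, i.end))
        cur_s, cur_e = ivs[0].start, ivs[0].end
        for iv in ivs[1:]:
            if iv.start <= cur_e:
                cur_e = max(cur_e, iv.end)
            else:
                out.append(GenomicInterval(chrom, cur_s, cur_e))
                cur_s, cur_e = iv.start, iv.end
        out.append(GenomicInterval(chrom, cur_s, cur_e))
    return out


@dataclass
class IntervalIndex:
    """Per-chromosome interval tree supporting point and range queries."""

    trees: Dict[str, IntervalTree] = field(default_factory=dict)

    @classmethod
    def build(cls, intervals: Iterable[GenomicInterval]) -> "IntervalIndex":
        idx = cls()
        for iv in intervals:
            idx.add(iv)
        return idx

    def add(self, iv: GenomicInterval) -> None:
        self.trees.setdefault(iv.chrom, IntervalTree()).addi(iv.start, iv.end, iv)

    def at(self, chrom: str, pos: int) -> List[GenomicInterval]:
        tree = self.trees.get(chrom)
        if tree is None:
            return []
        return [hit.data for hit in tree.at(pos)]

    def overlapping(self, chrom: str, start: int, end: int) -> List[GenomicInterval]:
        tree = self.trees.get(chrom)
        if tree is None:
            return []
        return [hit.data for hit in tree.overlap(start, end)]

    def covers(self, chrom: str, pos: int) -> bool:
        return bool(self.at(chrom, pos))


def intersect_stranded(
    plus: Sequence[GenomicInterval], minus: Sequence[GenomicInterval]
) -> List[GenomicInterval]:
    """Pairwise intersection of two merged interval sets (same chromosome key).

    Used to derive bidirectional-gene regions: bases covered by gene bodies
    on both strands.
    """
    out: List[GenomicInterval] = []
    minus_by_chrom: Dict[str, List[GenomicInterval]] = {}
    for iv in minus:
        minus_by_chrom.setdefault(iv.chrom, []).append(iv)
    for p in plus:
        for m in minus_by_chrom.get(p.chrom, []):
            s, e = max(p.start, m.start), min(p.end, m.end)
            if s < e:
                out.append(GenomicInterval(p.chrom, s, e))
    return merge_intervals(out)


def point_in_any(
    intervals: Sequence[GenomicInterval], chrom: str, pos: int
) -> bool:
    """Linear-scan membership; the brute-force mirror of IntervalIndex.covers."""
    return any(iv.contains(chrom, pos) for iv in intervals)


Pair = Tuple[int, int]
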