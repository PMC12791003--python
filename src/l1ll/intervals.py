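"""Genomic interval primitives and overlap queries.

All coordinates in this package are 0-based, half-open (BED convention):
``[start, end)``. File readers convert on the way in (GTF is 1-based,
closed), writers convert on the way out. Strand is one of ``+``, ``-`` or
``.`` (unstranded).
"""

from __future__ import annotations

from dataclasses import dataclass, replace
from typing import Iterable, Sequence

from intervaltree import IntervalTree

VALID_STRANDS = ("+", "-", ".")


@dataclass(frozen=True, order=True)
class GenomicInterval:
    """A half-open genomic interval ``[start, end)`` on one chromosome."""

    chrom: str
    start: int
    end: int
    strand: str = "."

    def __post_init__(self) -> None:
        if not self.chrom:
            raise ValueError("chrom must be a non-empty string")
        if self.start < 0:
            raise ValueError(f"start must be >= 0, got {self.start}")
        if self.end <= self.start:
            raise ValueError(
                f"end must be greater than start, got [{self.start}, {self.end})"
            )
        if self.strand not in VALID_STRANDS:
            raise ValueError(f"strand must be one of {VALID_STRANDS}, got {self.strand!r}")

    @property
    def length(self) -> int:
        return self.end - self.start

    def overlaps(self, other: "GenomicInterval") -> bool:
        return overlap_length(self, other) > 0


def overlap_length(a: GenomicInterval, b: GenomicInterval) -> int:
    """Number of bases shared by two intervals (0 if different chromosomes)."""
    if a.chrom != b.chrom:
        return 0
    return max(0, min(a.end, b.end) - max(a.start, b.start))


def expand_interval(x: GenomicInterval, flank: int = 100) -> GenomicInterval:
    """Add ``flank`` bp on both sides, clipping at the chromosome origin."""
    if flank < 0:
        raise ValueError(f"flank must be >= 0, got {flank}")
    if flank == 0:
        return x
    return replace(x, start=max(0, x.start - flank), end=x.end + flank)


def intersect_sets(
    a: Sequence[GenomicInterval],
    b: Sequence[GenomicInterval],
    min_overlap: int = 1,
    match_strand: bool = False,
) -> list[tuple[int, int]]:
    """All index pairs ``(i, j)`` where ``a[i]`` and ``b[j]`` overlap.

    Overlap must cover at least ``min_overlap`` bases on the same
    chromosome; strand is ignored unless ``match_strand`` is set. Pairs are
    returned ordered by index in ``a``, then index in ``b``.
    """
    if min_overlap < 1:
        raise ValueError("min_overlap must be >= 1")
    trees: dict[str, IntervalTree] = {}
    for j, iv in enumerate(b):
        trees.setdefault(iv.chrom, IntervalTree()).addi(iv.start, iv.end, j)
    pairs: list[tuple[int, int]] = []
    for i, iv in enumerate(a):
        tree = trees.get(iv.chrom)
        if tree is None:
            continue
        hits = []
        for hit in tree.overlap(iv.start, iv.end):
            j = hit.data
            if min(iv.end, hit.end) - max(iv.start, hit.begin) < min_overlap:
                continue
            if match_strand and iv.strand != b[j].strand:
                continue
            hits.append(j)
        pairs.extend((i, j) for j in sorted(hits))
    return pairs


def merge_intervals(intervals: Iterable[GenomicInterval]) -> list[GenomicInterval]:
    """Union of intervals per chromosome, strand discarded, sorted."""
    by_chrom: dict[str, list[GenomicInterval]] = {}
    for iv in intervals:
        by_chrom.setdefault(iv.chrom, []).append(iv)
    merged: list[GenomicInterval] = []
    for chrom in sorted(by_chrom):
        ivs = sorted(by_chrom[chrom], key=lambda x: (x.start, x.end))
        cur_start, cur_end = ivs[0].start, ivs[0].end
        for iv in ivs[1:]:
            if iv.start <= cur_end:
                cur_end = max(cur_end, iv.end)
            else:
                merged.append(GenomicInterval(chrom, cur_start, cur_end))
                cur_start, cur_end = iv.start, iv.end
        merged.append(GenomicInterval(chrom, cur_start, cur_end))
    return merged
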