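"""Genomic-interval arithmetic and the base-overlap F-score.

All coordinates are 0-based half-open internally; conversion from other
conventions (1-based inclusive variant tables) happens at file boundaries.
"""

from __future__ import annotations

from dataclasses import dataclass
from typing import ClassVar, Iterable, Sequence

__all__ = [
    "GenomicInterval",
    "OverlapScore",
    "fscore",
    "merge_intervals",
    "max_fscore_against_set",
    "read_bed",
    "write_bed",
]


@dataclass(frozen=True, order=True)
class GenomicInterval:
    """A chromosome-anchored half-open span ``[start, end)``.

    Parameters
    ----------
    chrom
        Chromosome identifier, e.g. ``"chr1"``.
    start
        0-based inclusive start.
    end
        0-based exclusive end; must satisfy ``end > start``.
    """

    chrom: str
    start: int
    end: int

    def __post_init__(self) -> None:
        if self.end <= self.start:
            raise ValueError(
                f"invalid interval {self.chrom}:[{self.start},{self.end}): "
                "end must be greater than start"
            )
        if self.start < 0:
            raise ValueError(f"negative start {self.start} for {self.chrom}")

    @property
    def length(self) -> int:
        return self.end - self.start

    def contains(self, other: "GenomicInterval") -> bool:
        """True if *other* lies fully within this interval (same chromosome)."""
        return (
            self.chrom == other.chrom
            and self.start <= other.start
            and other.end <= self.end
        )

    def intersection_length(self, other: "GenomicInterval") -> int:
        if self.chrom != other.chrom:
            return 0
        return max(0, min(self.end, other.end) - max(self.start, other.start))

    def __str__(self) -> str:  # pragma: no cover - cosmetic
        return f"{self.chrom}:[{self.start},{self.end})"


@dataclass(frozen=True)
class OverlapScore:
    """Precision/recall/F of the base-level overlap of a test span vs a reference."""

    precision: float
    recall: float
    fscore: float

    ZERO: ClassVar["OverlapScore"]


OverlapScore.ZERO = OverlapScore(0.0, 0.0, 0.0)


def fscore(reference: GenomicInterval, test: GenomicInterval) -> OverlapScore:
    """Score the base-level overlap of *test* against *reference*.

    Precision is the fraction of the test span covered by the reference,
    recall the fraction of the reference span covered by the test, and the
    F-score their harmonic mean, ``2PR/(P+R)``.  Disjoint spans (including
    spans on different chromosomes) score 0 on all three components.

    The F-score is symmetric: ``F(A, B) == F(B, A) == 2|A∩B|/(|A|+|B|)``.
    """
    inter = reference.intersection_length(test)
    if inter == 0:
        return OverlapScore.ZERO
    precision = inter / test.length
    recall = inter / reference.length
    return OverlapScore(
        precision=precision,
        recall=recall,
        fscore=2.0 * precision * recall / (precision + recall),
    )


def merge_intervals(intervals: Iterable[GenomicInterval]) -> list[GenomicInterval]:
    """Collapse intervals into sorted, non-overlapping maximal spans.

    Overlapping and abutting (``end == start``) intervals merge; the output
    covers exactly the union of the input base sets, ordered by
    (chrom, start).
    """
    pool = sorted(intervals)
    merged: list[GenomicInterval] = []
    for iv in pool:
        if merged and merged[-1].chrom == iv.chrom and iv.start <= merged[-1].end:
            last = merged[-1]
            if iv.end > last.end:
                merged[-1] = GenomicInterval(last.chrom, last.start, iv.end)
        else:
            merged.append(iv)
    return merged


def max_fscore_against_set(
    reference: GenomicInterval, regions: Sequence[GenomicInterval]
) -> OverlapScore:
    """Best single-region OverlapScore of *reference* against *regions*.

    Regions are expected to be pre-merged (non-overlapping).  Returns the
    zero score when *regions* is empty or nothing overlaps.  When several
    regions overlap the reference, the score of the one with the maximal
    F decides (max-of-singles, not F against the union).
    """
    best = OverlapScore.ZERO
    for region in regions:
        score = fscore(reference, region)
        if score.fscore > best.fscore:
            best = score
    return best


def read_bed(path) -> list[GenomicInterval]:
    """Read intervals from a BED file (0-based half-open; first 3 columns)."""
    out: list[GenomicInterval] = []
    with open(path) as fh:
        for line in fh:
            line = line.strip()
            if not line or line.startswith(("#", "track", "browser")):
                continue
            chrom, start, end = line.split("\t")[:3]
            out.append(GenomicInterval(chrom, int(start), int(end)))
    return out


def write_bed(intervals: Iterable[GenomicInterval], path) -> None:
    """Write intervals as 3-column BED (0-based half-open)."""
    with open(path, "w") as fh:
        for iv in intervals:
            fh.write(f"{iv.chrom}\t{iv.start}\t{iv.end}\n")
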