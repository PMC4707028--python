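"""1-based inclusive genomic intervals and the interval arithmetic used throughout.

In memory every interval is 1-based and inclusive at both ends; the on-disk BED
representation (0-based, half-open) lives in :mod:`autozyg.io`.  Interval length
follows the ``end - start`` convention, so chr6:25,500,000-35,000,000 spans
9.5 Mb.
"""
from __future__ import annotations

from dataclasses import dataclass
from typing import Iterable, Sequence


@dataclass(frozen=True, order=True)
class GenomicInterval:
    """A 1-based, inclusive interval on one chromosome."""

    chrom: str
    start: int
    end: int

    def __post_init__(self) -> None:
        if self.start < 1:
            raise ValueError(f"start must be >= 1, got {self.start}")
        if self.start > self.end:
            raise ValueError(f"start {self.start} > end {self.end}")

    @property
    def length_bp(self) -> int:
        return self.end - self.start

    def contains(self, chrom: str, pos: int) -> bool:
        return chrom == self.chrom and self.start <= pos <= self.end

    def overlaps(self, other: "GenomicInterval") -> bool:
        return (
            self.chrom == other.chrom
            and self.start <= other.end
            and other.start <= self.end
        )

    def intersect(self, other: "GenomicInterval") -> "GenomicInterval | None":
        if not self.overlaps(other):
            return None
        return GenomicInterval(
            self.chrom, max(self.start, other.start), min(self.end, other.end)
        )


def _by_chrom(intervals: Iterable[GenomicInterval]) -> dict[str, list[GenomicInterval]]:
    out: dict[str, list[GenomicInterval]] = {}
    for iv in intervals:
        out.setdefault(iv.chrom, []).append(iv)
    for lst in out.values():
        lst.sort()
    return out


def merge_intervals(intervals: Iterable[GenomicInterval]) -> list[GenomicInterval]:
    """Union of intervals as a sorted, non-overlapping list.

    Bookended intervals (end + 1 == next start) are merged, since positions are
    integers and the pair covers a contiguous range.
    """
    merged: list[GenomicInterval] = []
    for chrom in sorted(_by_chrom(intervals)):
        run: GenomicInterval | None = None
        for iv in _by_chrom(intervals)[chrom]:
            if run is None:
                run = iv
            elif iv.start <= run.end + 1:
                if iv.end > run.end:
                    run = GenomicInterval(chrom, run.start, iv.end)
            else:
                merged.append(run)
                run = iv
        if run is not None:
            merged.append(run)
    return merged


def intersect_two(
    a: Sequence[GenomicInterval], b: Sequence[GenomicInterval]
) -> list[GenomicInterval]:
    """Intersection of two interval covers (each treated as a union)."""
    a_m, b_m = merge_intervals(a), merge_intervals(b)
    out: list[GenomicInterval] = []
    for iv in a_m:
        for jv in b_m:
            got = iv.intersect(jv)
            if got is not None:
                out.append(got)
    return merge_intervals(out)


def intersect_many(covers: Sequence[Sequence[GenomicInterval]]) -> list[GenomicInterval]:
    if not covers:
        raise ValueError("need at least one interval cover")
    acc = merge_intervals(covers[0])
    for cover in covers[1:]:
        acc = intersect_two(acc, cover)
        if not acc:
            break
    return acc


def subtract(
    cover: Sequence[GenomicInterval], minus: Sequence[GenomicInterval]
) -> list[GenomicInterval]:
    """Remove every region of ``minus`` from ``cover`` (1-based inclusive)."""
    result: list[GenomicInterval] = []
    minus_by_chrom = _by_chrom(merge_intervals(minus))
    for iv in merge_intervals(cover):
        pieces = [iv]
        for sub in minus_by_chrom.get(iv.chrom, []):
            next_pieces: list[GenomicInterval] = []
            for piece in pieces:
                if not piece.overlaps(sub):
                    next_pieces.append(piece)
                    continue
                if sub.start > piece.start:
                    next_pieces.append(
                        GenomicInterval(piece.chrom, piece.start, sub.start - 1)
                    )
                if sub.end < piece.end:
                    next_pieces.append(
                        GenomicInterval(piece.chrom, sub.end + 1, piece.end)
                    )
            pieces = next_pieces
        result.extend(pieces)
    return merge_intervals(result)


def covered_by(pos_chrom: str, pos: int, cover: Iterable[GenomicInterval]) -> bool:
    return any(iv.contains(pos_chrom, pos) for iv in cover)
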