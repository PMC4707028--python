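"""Absence-of-heterozygosity (AOH) mapping from read-level variant calls.

Exome variant calls are transformed into per-site zygosity calls (a site is
heterozygous when the minor-allele read fraction reaches ``het_fraction``, and
no call is made below ``min_depth`` reads), each sample's genome is segmented
into runs of homozygous calls uninterrupted by a heterozygous call, and the
candidate autozygous interval for a recessive trait is the intersection of the
affected individuals' AOH segments minus anything covered by a healthy
parent's AOH.
"""
from __future__ import annotations

import enum
from dataclasses import dataclass
from typing import Mapping, Sequence

import numpy as np
import pandas as pd

from .intervals import GenomicInterval, intersect_many, merge_intervals, subtract

DEFAULT_MIN_DEPTH = 5
DEFAULT_HET_FRACTION = 0.25
DEFAULT_MIN_MARKERS = 25
DEFAULT_MIN_SPAN_BP = 1_000_000


class Zygosity(str, enum.Enum):
    HOM_REF = "hom_ref"
    HET = "het"
    HOM_ALT = "hom_alt"
    NO_CALL = "no_call"


@dataclass(frozen=True)
class SiteCall:
    sample: str
    chrom: str
    pos: int
    ref_reads: int
    alt_reads: int
    zygosity: Zygosity


@dataclass(frozen=True)
class AOHSegment:
    sample: str
    interval: GenomicInterval
    n_markers: int


def call_zygosity(
    ref_reads: int,
    alt_reads: int,
    min_depth: int = DEFAULT_MIN_DEPTH,
    het_fraction: float = DEFAULT_HET_FRACTION,
) -> Zygosity:
    """Zygosity from allele read counts.

    NO_CALL below ``min_depth`` total reads; HET when the minor-allele read
    fraction is at least ``het_fraction``; otherwise homozygous for the
    majority allele.
    """
    if ref_reads < 0 or alt_reads < 0:
        raise ValueError("read counts must be non-negative")
    depth = ref_reads + alt_reads
    if depth < min_depth:
        return Zygosity.NO_CALL
    if min(ref_reads, alt_reads) / depth >= het_fraction:
        return Zygosity.HET
    return Zygosity.HOM_ALT if alt_reads > ref_reads else Zygosity.HOM_REF


def zygosity_codes(
    ref_reads: np.ndarray,
    alt_reads: np.ndarray,
    min_depth: int = DEFAULT_MIN_DEPTH,
    het_fraction: float = DEFAULT_HET_FRACTION,
) -> np.ndarray:
    """Vectorised :func:`call_zygosity`; codes 0=hom_ref, 1=het, 2=hom_alt, 3=no_call."""
    ref = np.asarray(ref_reads, dtype=np.int64)
    alt = np.asarray(alt_reads, dtype=np.int64)
    depth = ref + alt
    with np.errstate(divide="ignore", invalid="ignore"):
        minor_frac = np.where(depth > 0, np.minimum(ref, alt) / np.maximum(depth, 1), 0.0)
    codes = np.where(alt > ref, 2, 0)
    codes = np.where(minor_frac >= het_fraction, 1, codes)
    codes = np.where(depth < min_depth, 3, codes)
    return codes.astype(np.int8)


_CODE_TO_ZYG = {0: Zygosity.HOM_REF, 1: Zygosity.HET, 2: Zygosity.HOM_ALT, 3: Zygosity.NO_CALL}


def add_zygosity(
    calls: pd.DataFrame,
    min_depth: int = DEFAULT_MIN_DEPTH,
    het_fraction: float = DEFAULT_HET_FRACTION,
) -> pd.DataFrame:
    """Add a ``zygosity`` column to a (sample, chrom, pos, ref_reads, alt_reads) table."""
    codes = zygosity_codes(
        calls["ref_reads"].to_numpy(), calls["alt_reads"].to_numpy(), min_depth, het_fraction
    )
    out = calls.copy()
    out["zygosity"] = [_CODE_TO_ZYG[c] for c in codes]
    return out


def segment_aoh(
    calls: pd.DataFrame,
    min_markers: int = DEFAULT_MIN_MARKERS,
    min_span_bp: int = DEFAULT_MIN_SPAN_BP,
    sample: str | None = None,
) -> list[AOHSegment]:
    """Segment one sample's zygosity calls into AOH runs.

    ``calls`` holds one sample with columns chrom, pos, zygosity (NO_CALL sites
    are ignored; they neither support nor interrupt a run).  A run is a maximal
    stretch of consecutive homozygous calls uninterrupted by a HET call; it is
    reported when it has at least ``min_markers`` supporting homozygous calls
    and spans at least ``min_span_bp``, bounded by the outermost homozygous
    markers of the run.
    """
    if sample is None:
        samples = calls["sample"].unique() if "sample" in calls else ["?"]
        if len(samples) != 1:
            raise ValueError("calls must contain exactly one sample; pass sample=")
        sample = str(samples[0])
    segments: list[AOHSegment] = []
    for chrom, sub in calls.groupby("chrom", sort=True):
        pos = sub["pos"].to_numpy()
        if np.any(np.diff(pos) < 0):
            raise ValueError(f"calls on {chrom} are not sorted by position")
        # normalise to plain strings: numpy scalar conversion of a str-Enum
        # compares via str(), which is not the member value
        zyg = np.array([Zygosity(z).value for z in sub["zygosity"]])
        keep = zyg != Zygosity.NO_CALL.value
        pos, zyg = pos[keep], zyg[keep]
        is_hom = (zyg == Zygosity.HOM_REF.value) | (zyg == Zygosity.HOM_ALT.value)
        # run boundaries: split wherever a HET call occurs
        idx = 0
        n = len(pos)
        while idx < n:
            if not is_hom[idx]:
                idx += 1
                continue
            j = idx
            while j < n and is_hom[j]:
                j += 1
            n_markers = j - idx
            span = int(pos[j - 1] - pos[idx])
            if n_markers >= min_markers and span >= min_span_bp:
                segments.append(
                    AOHSegment(
                        sample=sample,
                        interval=GenomicInterval(str(chrom), int(pos[idx]), int(pos[j - 1])),
                        n_markers=n_markers,
                    )
                )
            idx = j
    return segments


def map_shared_autozygosity(
    affected_segments: Mapping[str, Sequence[AOHSegment]] | Sequence[Sequence[AOHSegment]],
    parent_segments: Mapping[str, Sequence[AOHSegment]] | Sequence[Sequence[AOHSegment]],
) -> list[GenomicInterval]:
    """Candidate autozygous interval(s) for a recessive trait.

    Intersection of every affected sample's AOH cover, minus any region covered
    by an AOH segment of any listed parent; sorted and non-overlapping.
    """
    aff = list(affected_segments.values()) if isinstance(affected_segments, Mapping) else list(affected_segments)
    par = list(parent_segments.values()) if isinstance(parent_segments, Mapping) else list(parent_segments)
    if not aff:
        raise ValueError("need at least one affected sample")
    covers = [[seg.interval for seg in segs] for segs in aff]
    shared = intersect_many(covers)
    parent_cover = merge_intervals(
        [seg.interval for segs in par for seg in segs]
    )
    return subtract(shared, parent_cover)
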