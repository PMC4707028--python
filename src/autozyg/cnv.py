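"""Exome read-depth CNV analysis: RPKM transformation and the five-criterion
homozygous/hemizygous deletion caller.

Per-exon read depth is normalised to RPKM (reads per kilobase of target per
million mapped reads).  Candidate homozygous deletions are exons with
RPKM < 0.5; common deletions (carrier frequency >= 0.5% among the rest of the
cohort at that exon) and low-quality exons (>= 99% of samples without
RPKM > 1) are removed; calls must overlap an autozygosity (AOH) segment longer
than 0.5 Mb of the same sample; calls at consecutive exons of one gene are
merged; and samples left with more than 10 merged calls are dropped as
low-quality.
"""
from __future__ import annotations

from dataclasses import dataclass, field
from typing import Mapping, Sequence

import numpy as np

from .aoh import AOHSegment
from .intervals import GenomicInterval

RPKM_DELETION_THRESHOLD = 0.5
MAX_COHORT_FREQ = 0.005
EXON_QUALITY_FRACTION = 0.99
EXON_QUALITY_RPKM = 1.0
MIN_AOH_SPAN_BP = 500_000
MAX_CALLS_PER_SAMPLE = 10


class DataError(ValueError):
    """Sample mismatch between the RPKM matrix and the AOH input."""


@dataclass(frozen=True)
class ExonDef:
    gene: str
    exon_index: int
    interval: GenomicInterval
    length_bp: int | None = None

    def __post_init__(self) -> None:
        if self.length_bp is None:
            object.__setattr__(self, "length_bp", self.interval.length_bp)


@dataclass
class RpkmMatrix:
    """Exon x sample matrix of RPKM values."""

    exons: list[ExonDef]
    samples: list[str]
    values: np.ndarray
    total_reads: dict[str, int] | None = None

    def __post_init__(self) -> None:
        self.values = np.asarray(self.values, dtype=float)
        if self.values.shape != (len(self.exons), len(self.samples)):
            raise ValueError(
                f"values shape {self.values.shape} != "
                f"({len(self.exons)}, {len(self.samples)})"
            )
        if np.any(self.values < 0):
            raise ValueError("RPKM values must be non-negative")

    @classmethod
    def from_read_counts(
        cls,
        counts: np.ndarray,
        exons: Sequence[ExonDef],
        samples: Sequence[str],
        total_reads: Mapping[str, int],
    ) -> "RpkmMatrix":
        counts = np.asarray(counts, dtype=float)
        lengths = np.array([e.length_bp for e in exons], dtype=float)
        totals = np.array([total_reads[s] for s in samples], dtype=float)
        if np.any(lengths <= 0) or np.any(totals <= 0):
            raise ValueError("exon lengths and total read counts must be positive")
        values = counts / (lengths[:, None] / 1e3) / (totals[None, :] / 1e6)
        return cls(list(exons), list(samples), values, dict(total_reads))


@dataclass(frozen=True)
class DeletionCall:
    sample: str
    interval: GenomicInterval
    n_exons: int
    cohort_freq: float
    gene: str = ""
    exon_indices: tuple[int, ...] = field(default=())


def compute_rpkm(read_count: int, exon_length_bp: int, total_reads: int) -> float:
    """RPKM = reads / (exon kb) / (total reads in millions)."""
    if exon_length_bp <= 0:
        raise ValueError("exon length must be positive")
    if total_reads <= 0:
        raise ValueError("total read count must be positive")
    if read_count < 0:
        raise ValueError("read count must be non-negative")
    return read_count / (exon_length_bp / 1e3) / (total_reads / 1e6)


def call_homozygous_deletions(
    m: RpkmMatrix,
    aoh: Mapping[str, Sequence[AOHSegment | GenomicInterval]],
    rpkm_threshold: float = RPKM_DELETION_THRESHOLD,
    max_cohort_freq: float = MAX_COHORT_FREQ,
    exon_quality_fraction: float = EXON_QUALITY_FRACTION,
    exon_quality_rpkm: float = EXON_QUALITY_RPKM,
    min_aoh_span_bp: int = MIN_AOH_SPAN_BP,
    max_calls_per_sample: int = MAX_CALLS_PER_SAMPLE,
) -> list[DeletionCall]:
    """Apply the five deletion-calling criteria, strictly in order.

    (1) candidate entries have RPKM < ``rpkm_threshold``; (2) exon-level
    carrier frequency among the *other* cohort samples must stay below
    ``max_cohort_freq`` and the exon must be callable (< ``exon_quality_fraction``
    of samples at RPKM <= ``exon_quality_rpkm``); (3) the exon must overlap an
    AOH segment of the same sample whose own span exceeds ``min_aoh_span_bp``;
    (4) candidate calls at consecutive exons of one gene are merged; (5)
    samples with more than ``max_calls_per_sample`` merged calls are dropped.
    """
    missing = [s for s in m.samples if s not in aoh]
    if missing:
        raise DataError(f"samples missing from AOH input: {missing}")

    n_exons, n_samples = m.values.shape
    cand = m.values < rpkm_threshold  # criterion 1

    # criterion 2: common deletions (leave-one-out carrier frequency) ...
    carriers_per_exon = cand.sum(axis=1)
    if n_samples > 1:
        other_freq = (carriers_per_exon[:, None] - cand) / (n_samples - 1)
    else:
        other_freq = np.zeros_like(cand, dtype=float)
    cand &= ~(other_freq >= max_cohort_freq)
    # ... and low-quality exons
    low_quality_exon = (m.values <= exon_quality_rpkm).mean(axis=1) >= exon_quality_fraction
    cand[low_quality_exon, :] = False

    # criterion 3: must overlap a sufficiently long AOH segment of the sample
    aoh_intervals: dict[str, list[GenomicInterval]] = {}
    for s in m.samples:
        ivs = []
        for seg in aoh[s]:
            iv = seg.interval if isinstance(seg, AOHSegment) else seg
            if iv.length_bp > min_aoh_span_bp:
                ivs.append(iv)
        aoh_intervals[s] = ivs
    for e, exon in enumerate(m.exons):
        for s_idx, s in enumerate(m.samples):
            if cand[e, s_idx] and not any(
                exon.interval.overlaps(iv) for iv in aoh_intervals[s]
            ):
                cand[e, s_idx] = False

    # cohort frequency recorded per exon: fraction of all samples below threshold
    exon_cohort_freq = (m.values < rpkm_threshold).mean(axis=1)

    # criterion 4: merge consecutive exons of the same gene, per sample
    order = sorted(
        range(n_exons),
        key=lambda e: (m.exons[e].interval.chrom, m.exons[e].interval.start),
    )
    calls: list[DeletionCall] = []
    for s_idx, s in enumerate(m.samples):
        run: list[int] = []
        for e in order + [None]:  # sentinel flushes the last run
            exon = m.exons[e] if e is not None else None
            extend = (
                e is not None
                and cand[e, s_idx]
                and run
                and exon.gene == m.exons[run[-1]].gene
                and exon.exon_index == m.exons[run[-1]].exon_index + 1
            )
            if extend:
                run.append(e)
                continue
            if run:
                calls.append(
                    DeletionCall(
                        sample=s,
                        interval=GenomicInterval(
                            m.exons[run[0]].interval.chrom,
                            m.exons[run[0]].interval.start,
                            m.exons[run[-1]].interval.end,
                        ),
                        n_exons=len(run),
                        cohort_freq=float(max(exon_cohort_freq[e2] for e2 in run)),
                        gene=m.exons[run[0]].gene,
                        exon_indices=tuple(m.exons[e2].exon_index for e2 in run),
                    )
                )
                run = []
            if e is not None and cand[e, s_idx]:
                run = [e]

    # criterion 5: drop low-quality samples (applied to post-merge call counts)
    per_sample: dict[str, int] = {}
    for call in calls:
        per_sample[call.sample] = per_sample.get(call.sample, 0) + 1
    bad = {s for s, n in per_sample.items() if n > max_calls_per_sample}
    return [c for c in calls if c.sample not in bad]
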