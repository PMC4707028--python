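"""SNP-based fine mapping of a linked region using informative recombinants.

Within a linked region all affected individuals are homozygous for the shared
haplotype; an unaffected homozygote with an informative recombination is
heterozygous for a subset of SNPs, which bounds the locus: the *minimum*
interval spans the discordant (heterozygous) SNPs and the *maximum* interval
extends to the nearest flanking SNPs at which the discordant sample is
homozygous-concordant with the affecteds (or to the region boundary if none).
"""
from __future__ import annotations

from dataclasses import dataclass
from typing import Sequence

import numpy as np
import pandas as pd

from .intervals import GenomicInterval

HOM_A, HET, HOM_B, MISSING = 0, 1, 2, -1


class NoRefinementError(ValueError):
    """The discordant sample is not heterozygous at any SNP in the matrix."""


@dataclass
class SnpGenotypeMatrix:
    """SNP x sample genotype matrix on one chromosome.

    Genotypes are coded 0 (HOM_A), 1 (HET), 2 (HOM_B) and -1 (MISSING); SNPs
    are sorted by position.
    """

    chrom: str
    snp_ids: list[str]
    positions: np.ndarray
    samples: list[str]
    genotypes: np.ndarray  # shape (n_snps, n_samples)

    def __post_init__(self) -> None:
        self.positions = np.asarray(self.positions, dtype=np.int64)
        self.genotypes = np.asarray(self.genotypes, dtype=np.int8)
        if self.genotypes.shape != (len(self.snp_ids), len(self.samples)):
            raise ValueError("genotype matrix shape mismatch")
        if np.any(np.diff(self.positions) < 0):
            raise ValueError("SNPs must be sorted by position")

    def column(self, sample: str) -> np.ndarray:
        return self.genotypes[:, self.samples.index(sample)]

    def to_frame(self) -> pd.DataFrame:
        df = pd.DataFrame(self.genotypes, columns=self.samples)
        df.insert(0, "snp", self.snp_ids)
        df.insert(1, "chrom", self.chrom)
        df.insert(2, "pos", self.positions)
        return df


@dataclass(frozen=True)
class RefinedLocus:
    minimum: GenomicInterval
    maximum: GenomicInterval

    def __post_init__(self) -> None:
        if not (
            self.maximum.chrom == self.minimum.chrom
            and self.maximum.start <= self.minimum.start
            and self.minimum.end <= self.maximum.end
        ):
            raise ValueError("minimum interval must be contained in maximum")


def select_informative_snps(
    m: SnpGenotypeMatrix,
    obligate_carriers: Sequence[str],
    region: GenomicInterval,
) -> list[str]:
    """SNP ids inside ``region`` that can distinguish the shared haplotype.

    A SNP is informative when it is heterozygous in at least one obligate
    carrier and both alleles are observed somewhere in the cohort.
    """
    selected = []
    carrier_idx = [m.samples.index(s) for s in obligate_carriers]
    for i, snp in enumerate(m.snp_ids):
        if not region.contains(m.chrom, int(m.positions[i])):
            continue
        row = m.genotypes[i]
        if not any(row[c] == HET for c in carrier_idx):
            continue
        called = row[row != MISSING]
        has_a = np.any((called == HOM_A) | (called == HET))
        has_b = np.any((called == HOM_B) | (called == HET))
        if has_a and has_b:
            selected.append(snp)
    return selected


def refine_interval(
    m: SnpGenotypeMatrix,
    affecteds: Sequence[str],
    discordant: str,
    region: GenomicInterval | None = None,
) -> RefinedLocus:
    """Minimum and maximum candidate intervals from one informative recombinant.

    Every affected must be homozygous (for the same allele) at every typed SNP;
    the minimum interval spans the discordant sample's heterozygous SNPs and
    the maximum extends to the nearest flanking homozygous-concordant SNPs,
    falling back to the region boundary (default: the SNP span) when no such
    flanking SNP exists.  MISSING genotypes are skipped when searching for
    flanking concordant SNPs.
    """
    aff_idx = [m.samples.index(s) for s in affecteds]
    aff_geno = m.genotypes[:, aff_idx]
    shared: list[int] = []
    for i in range(len(m.snp_ids)):
        called = aff_geno[i][aff_geno[i] != MISSING]
        uniq = set(int(g) for g in called)
        if HET in uniq or len(uniq) > 1:
            raise ValueError(
                f"affecteds are not homozygous-concordant at SNP {m.snp_ids[i]}"
            )
        shared.append(uniq.pop() if uniq else MISSING)

    disc = m.column(discordant)
    het_pos = m.positions[disc == HET]
    if het_pos.size == 0:
        raise NoRefinementError(
            f"sample {discordant!r} is not heterozygous at any SNP"
        )
    minimum = GenomicInterval(m.chrom, int(het_pos.min()), int(het_pos.max()))

    if region is None:
        region = GenomicInterval(m.chrom, int(m.positions.min()), int(m.positions.max()))
    left_idx = np.where(m.positions < minimum.start)[0]
    right_idx = np.where(m.positions > minimum.end)[0]

    def concordant(i: int) -> bool:
        return disc[i] != MISSING and disc[i] != HET and int(disc[i]) == shared[i]

    left = max((i for i in left_idx if concordant(i)), default=None)
    right = min((i for i in right_idx if concordant(i)), default=None)
    max_start = int(m.positions[left]) if left is not None else region.start
    max_end = int(m.positions[right]) if right is not None else region.end
    maximum = GenomicInterval(m.chrom, max_start, max_end)
    return RefinedLocus(minimum=minimum, maximum=maximum)


def locate_gene_in_interval(position: GenomicInterval, locus: RefinedLocus) -> str:
    """Classify a gene/variant point position against a refined locus.

    Returns ``"inside_minimum"``, ``"inside_maximum_only"`` or ``"outside"``;
    containment is inclusive at both endpoints.
    """
    if position.chrom != locus.minimum.chrom:
        raise ValueError(
            f"chromosome mismatch: {position.chrom} vs {locus.minimum.chrom}"
        )
    pos = position.start
    if locus.minimum.start <= pos <= locus.minimum.end:
        return "inside_minimum"
    if locus.maximum.start <= pos <= locus.maximum.end:
        return "inside_maximum_only"
    return "outside"
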