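"""Fine mapping: informative-SNP selection and recombinant-based refinement."""
import numpy as np
import pytest

from autozyg.finemap import (
    HET,
    HOM_A,
    HOM_B,
    MISSING,
    NoRefinementError,
    SnpGenotypeMatrix,
    locate_gene_in_interval,
    refine_interval,
    select_informative_snps,
)
from autozyg.intervals import GenomicInterval

POSITIONS = [32_557_483, 33_384_473, 33_756_856, 33_851_052, 35_479_574]


def five_snp_matrix(discordant_genotypes):
    """Three affecteds homozygous-B everywhere plus one discordant sample."""
    samples = ["A1", "A2", "A3", "D"]
    geno = np.full((5, 4), HOM_B, dtype=np.int8)
    geno[:, 3] = discordant_genotypes
    return SnpGenotypeMatrix(
        chrom="6",
        snp_ids=[f"snp{i}" for i in range(5)],
        positions=np.array(POSITIONS),
        samples=samples,
        genotypes=geno,
    )


def test_worked_example_minimum_and_maximum_intervals():
    m = five_snp_matrix([HOM_B, HET, HET, HET, HOM_B])
    locus = refine_interval(m, ["A1", "A2", "A3"], "D")
    assert (locus.minimum.start, locus.minimum.end) == (33_384_473, 33_851_052)
    assert (locus.maximum.start, locus.maximum.end) == (32_557_483, 35_479_574)


def test_gene_containment_classification():
    m = five_snp_matrix([HOM_B, HET, HET, HET, HOM_B])
    locus = refine_interval(m, ["A1", "A2", "A3"], "D")
    point = lambda p: GenomicInterval("6", p, p)
    assert locate_gene_in_interval(point(33_756_856), locus) == "inside_minimum"
    assert locate_gene_in_interval(point(30_954_617), locus) == "outside"
    assert locate_gene_in_interval(point(32_557_483), locus) == "inside_maximum_only"
    with pytest.raises(ValueError, match="chromosome"):
        locate_gene_in_interval(GenomicInterval("7", 1, 1), locus)


def test_het_everywhere_minimum_equals_maximum_equals_span():
    m = five_snp_matrix([HET] * 5)
    locus = refine_interval(m, ["A1", "A2", "A3"], "D")
    assert locus.minimum == locus.maximum
    assert (locus.minimum.start, locus.minimum.end) == (POSITIONS[0], POSITIONS[-1])


def test_single_het_gives_point_minimum():
    m = five_snp_matrix([HOM_B, HOM_B, HET, HOM_B, HOM_B])
    locus = refine_interval(m, ["A1", "A2", "A3"], "D")
    assert locus.minimum.start == locus.minimum.end == 33_756_856


def test_missing_genotypes_skipped_for_flanks():
    m = five_snp_matrix([HOM_B, MISSING, HET, HET, HOM_B])
    locus = refine_interval(m, ["A1", "A2", "A3"], "D")
    # snp1 is missing, so the left flank falls back to snp0
    assert locus.maximum.start == POSITIONS[0]


def test_discordant_hom_for_other_allele_is_not_concordant():
    m = five_snp_matrix([HOM_A, HET, HET, HET, HOM_B])
    locus = refine_interval(m, ["A1", "A2", "A3"], "D", region=GenomicInterval("6", 32_000_000, 36_000_000))
    assert locus.maximum.start == 32_000_000  # falls back to the region boundary


def test_no_het_raises_no_refinement():
    m = five_snp_matrix([HOM_B] * 5)
    with pytest.raises(NoRefinementError):
        refine_interval(m, ["A1", "A2", "A3"], "D")


def test_non_homozygous_affecteds_rejected():
    m = five_snp_matrix([HOM_B, HET, HET, HET, HOM_B])
    m.genotypes[2, 0] = HET
    with pytest.raises(ValueError, match="homozygous"):
        refine_interval(m, ["A1", "A2", "A3"], "D")


def test_minimum_always_within_maximum_within_region(rng):
    region = GenomicInterval("6", 1, 1_000_000)
    for _ in range(50):
        pos = np.sort(rng.choice(np.arange(1, 1_000_000), 8, replace=False))
        disc = rng.choice([HOM_B, HET], size=8)
        if not (disc == HET).any():
            disc[3] = HET
        m = SnpGenotypeMatrix(
            chrom="6",
            snp_ids=[f"s{i}" for i in range(8)],
            positions=pos,
            samples=["A1", "D"],
            genotypes=np.column_stack([np.full(8, HOM_B, dtype=np.int8), disc]),
        )
        locus = refine_interval(m, ["A1"], "D", region=region)
        assert locus.maximum.start <= locus.minimum.start <= locus.minimum.end <= locus.maximum.end
        assert region.start <= locus.maximum.start and locus.maximum.end <= region.end


def test_select_informative_snps():
    region = GenomicInterval("6", 33_000_000, 36_000_000)
    samples = ["C1", "C2", "X1"]
    geno = np.array(
        [
            [HET, HOM_A, HOM_B],   # het in carrier but outside the region -> excluded
            [HOM_A, HOM_A, HOM_A], # monomorphic -> excluded
            [HOM_B, HET, HOM_A],   # het in carrier C2, both alleles seen -> selected
            [HOM_A, HOM_A, HET],   # het only in a non-carrier -> excluded
            [HET, HET, HOM_B],     # selected
        ],
        dtype=np.int8,
    )
    m = SnpGenotypeMatrix(
        chrom="6",
        snp_ids=[f"s{i}" for i in range(5)],
        positions=np.array(POSITIONS),
        samples=samples,
        genotypes=geno,
    )
    got = select_informative_snps(m, ["C1", "C2"], region)
    assert got == ["s2", "s4"]


def test_selected_snps_distinguish_linked_haplotype(study):
    """On gene-dropped data every informative SNP separates the disease
    haplotype from at least one other founder haplotype in the cohort."""
    truth = study.truth
    samples = study.ped.ids
    geno = np.vstack([truth.marker_genotypes[s] for s in samples]).T
    m = SnpGenotypeMatrix(
        chrom="6",
        snp_ids=[f"m{i}" for i in range(truth.marker_positions.size)],
        positions=truth.marker_positions,
        samples=list(samples),
        genotypes=geno.astype(np.int8),
    )
    carriers = list(study.design.parents)
    region = GenomicInterval("6", 1, study.cfg.chrom_length_bp)
    selected = select_informative_snps(m, carriers, region)
    assert selected  # a consanguineous drop always leaves informative sites
    target = truth.disease_hap_label
    idx = {f"m{i}": i for i in range(truth.marker_positions.size)}
    for snp in selected:
        i = idx[snp]
        target_allele = truth.founder_hap_alleles[target, i]
        others = np.delete(truth.founder_hap_alleles[:, i], target)
        assert np.any(others != target_allele)
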