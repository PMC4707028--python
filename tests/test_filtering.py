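"""Variant filter funnel: class/rarity predicates, stage 1/2, compound hets."""
import pytest

from autozyg.aoh import Zygosity
from autozyg.filtering import (
    DataError,
    FamilyDesign,
    VariantRecord,
    apply_basic_filters,
    compound_het_scan,
    is_deleterious_class,
    is_rare,
    stage1_shared_homozygous,
    stage2_region_union,
)
from autozyg.intervals import GenomicInterval
from autozyg.pedigree import Individual, Pedigree
from autozyg.sim import SimConfig, simulate_variant_table

HOM, HET, REF, NC = Zygosity.HOM_ALT, Zygosity.HET, Zygosity.HOM_REF, Zygosity.NO_CALL


def var(pos=100, consequence="missense", freqs=None, in_db=False, zyg=None,
        gene="G1", splice=None, quality=True):
    return VariantRecord(
        chrom="6", pos=pos, ref="A", alt="G", gene=gene,
        consequence=consequence,
        panel_freqs=freqs or {},
        in_disease_db=in_db,
        quality_pass=quality,
        splice_distance_bp=splice,
        zygosity_by_sample=zyg or {},
    )


@pytest.mark.parametrize(
    "consequence,splice,expected",
    [
        ("missense", None, True),
        ("nonsense", None, True),
        ("stop_loss", None, True),
        ("indel", None, True),
        ("splice_region", 5, True),
        ("splice_region", 6, False),  # outside the +/-5 bp window
        ("other", None, False),
    ],
)
def test_is_deleterious_class(consequence, splice, expected):
    assert is_deleterious_class(var(consequence=consequence, splice=splice)) is expected


@pytest.mark.parametrize(
    "freqs,in_db,expected",
    [
        ({"ESP": 0.004, "KGP": 0.009, "ARIC": 0.0}, False, True),
        ({"ESP": 0.01}, False, False),  # strict < 1%
        ({"ESP": 0.04}, True, True),  # known disease-db variant, < 5%
        ({"ESP": 0.05}, True, False),
        ({}, False, True),  # absent panels count as 0
    ],
)
def test_is_rare(freqs, in_db, expected):
    assert is_rare(var(freqs=freqs, in_db=in_db)) is expected


DESIGN = FamilyDesign(affected_groups=(("A1", "A2"), ("A3",)), parents=("P1", "P2"))


def test_design_rejects_overlap():
    with pytest.raises(ValueError):
        FamilyDesign(affected_groups=(("A1",),), parents=("A1",))


def test_stage1_keeps_shared_hom_not_in_parents():
    good = var(zyg={"A1": HOM, "A2": HOM, "A3": HOM, "P1": HET, "P2": REF})
    in_parent = var(zyg={"A1": HOM, "A2": HOM, "A3": HOM, "P1": HOM, "P2": REF})
    het_affected = var(zyg={"A1": HOM, "A2": HET, "A3": HOM, "P1": HET, "P2": REF})
    got = stage1_shared_homozygous([good, in_parent, het_affected], DESIGN)
    assert got == [good]


def test_stage1_missing_sample_is_data_error():
    with pytest.raises(DataError):
        stage1_shared_homozygous([var(zyg={"A1": HOM})], DESIGN)


REGION = GenomicInterval("6", 50, 150)


def test_stage2_group_union_inside_region():
    only_arm2 = var(pos=100, zyg={"A1": NC, "A2": REF, "A3": HOM})
    outside = var(pos=500, zyg={"A1": NC, "A2": REF, "A3": HOM})
    dropout_arm1 = var(pos=120, zyg={"A1": NC, "A2": NC, "A3": HOM})
    got = stage2_region_union([only_arm2, outside, dropout_arm1], DESIGN, REGION)
    assert got == [only_arm2, dropout_arm1]


def test_funnel_monotone_and_stage1_within_stage2(study):
    basic = apply_basic_filters(study.variants)
    assert len(basic) <= len(study.variants)
    s1 = stage1_shared_homozygous(basic, study.design)
    assert set(id(v) for v in s1) <= set(id(v) for v in basic)
    region = GenomicInterval("6", 1, study.cfg.chrom_length_bp)
    s2 = stage2_region_union(basic, study.design, region)
    assert set(id(v) for v in s1) <= set(id(v) for v in s2)


def test_synthetic_funnel_recovers_exactly_the_causal_variant(study):
    basic = apply_basic_filters(study.variants)
    s1 = stage1_shared_homozygous(basic, study.design)
    assert [v.gene for v in s1] == ["G_causal"]


def test_common_background_variant_never_survives_rarity(study):
    for v in study.variants:
        if max(v.panel_freqs.values(), default=0) >= 0.05 and not v.in_disease_db:
            assert not is_rare(v)


def test_zero_background_gives_single_variant(study):
    variants = simulate_variant_table(
        study.ped, study.truth, study.cfg, n_background=0
    )
    assert len(variants) == 1 and variants[0].gene == "G_causal"


# -- compound heterozygotes -------------------------------------------------

TRIO = Pedigree(
    [
        Individual("P1", sex="male", affected=False),
        Individual("P2", sex="female", affected=False),
        Individual("A1", "P1", "P2", affected=True),
    ]
)
TRIO_DESIGN = FamilyDesign(affected_groups=(("A1",),), parents=("P1", "P2"))


def test_compound_het_opposite_origins_reported():
    v1 = var(pos=10, gene="G9", zyg={"A1": HET, "P1": HET, "P2": REF})
    v2 = var(pos=20, gene="G9", zyg={"A1": HET, "P1": REF, "P2": HET})
    got = compound_het_scan([v1, v2], TRIO_DESIGN, TRIO)
    assert len(got) == 1 and got[0][0] == "G9"


def test_compound_het_same_parent_not_reported():
    v1 = var(pos=10, gene="G9", zyg={"A1": HET, "P1": HET, "P2": REF})
    v2 = var(pos=20, gene="G9", zyg={"A1": HET, "P1": HET, "P2": REF})
    assert compound_het_scan([v1, v2], TRIO_DESIGN, TRIO) == []


def test_ambiguous_origin_excluded():
    v1 = var(pos=10, gene="G9", zyg={"A1": HET, "P1": HET, "P2": HET})
    v2 = var(pos=20, gene="G9", zyg={"A1": HET, "P1": REF, "P2": HET})
    assert compound_het_scan([v1, v2], TRIO_DESIGN, TRIO) == []


def test_recessive_autozygous_study_has_no_compound_hets(study):
    assert compound_het_scan(study.variants, study.design, study.ped) == []
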