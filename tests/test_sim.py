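"""Synthetic-data generator: Mendelian consistency, IBD bookkeeping,
closed-form inbreeding, read-count moments and determinism."""
import numpy as np
import pytest

from autozyg.cnv import ExonDef
from autozyg.intervals import GenomicInterval
from autozyg.sim import (
    ConfigError,
    SimConfig,
    first_cousin_pedigree,
    gene_drop,
    simulate_read_counts,
    simulate_rpkm_matrix,
    simulate_study,
)

CFG = SimConfig(seed=5, n_markers=400)


def test_zero_markers_is_config_error(cousin_ped):
    with pytest.raises(ConfigError):
        gene_drop(cousin_ped, SimConfig(seed=1, n_markers=0))


def test_causal_position_outside_chromosome_rejected():
    with pytest.raises(ConfigError):
        SimConfig(causal_position_bp=200_000_000, chrom_length_bp=150_000_000)


def test_same_seed_identical_output(cousin_ped):
    g1, t1 = gene_drop(cousin_ped, CFG)
    g2, t2 = gene_drop(cousin_ped, CFG)
    for iid in g1:
        assert np.array_equal(g1[iid], g2[iid])
    assert np.array_equal(t1.marker_positions, t2.marker_positions)
    for iid in t1.ibd_labels:
        assert np.array_equal(t1.ibd_labels[iid], t2.ibd_labels[iid])


def test_no_recombination_transmits_intact_haplotypes(cousin_ped):
    cfg = SimConfig(seed=3, n_markers=200, cm_per_mb=0.0)
    _, truth = gene_drop(cousin_ped, cfg)
    for ind in cousin_ped.nonfounders:
        labels = truth.ibd_labels[ind.iid]
        # each transmitted haplotype carries a single founder label throughout
        assert len(set(labels[0])) == 1
        assert len(set(labels[1])) == 1


def _mendel_ok(gc, gf, gm):
    """Exhaustive rule: child dosage must be one transmissible pair."""
    paternal = {0: {0}, 1: {0, 1}, 2: {1}}[gf]
    maternal = {0: {0}, 1: {0, 1}, 2: {1}}[gm]
    return any(gc == p + m for p in paternal for m in maternal)


def test_mendelian_consistency_exhaustive(cousin_ped):
    genotypes, _ = gene_drop(cousin_ped, CFG)
    for ind in cousin_ped.nonfounders:
        gc, gf, gm = (
            genotypes[ind.iid],
            genotypes[ind.father],
            genotypes[ind.mother],
        )
        for j in range(len(gc)):
            assert _mendel_ok(int(gc[j]), int(gf[j]), int(gm[j]))


def test_ibd_segments_tile_the_marker_span(cousin_ped):
    _, truth = gene_drop(cousin_ped, CFG)
    labels = truth.ibd_labels["K"]
    auto = labels[0] == labels[1]
    # segments recorded in truth match the autozygosity mask exactly
    mask = np.zeros(len(auto), dtype=bool)
    for seg in truth.true_autozygous_segments["K"]:
        inside = (truth.site_positions >= seg.start) & (truth.site_positions <= seg.end)
        assert not np.any(mask & inside)  # no overlap
        mask |= inside
    assert np.array_equal(mask, auto)


def test_affecteds_autozygous_for_one_founder_haplotype(study):
    truth = study.truth
    c = truth.causal_site_index
    for s in study.design.all_affected:
        lab = truth.ibd_labels[s]
        assert lab[0][c] == lab[1][c] == truth.disease_hap_label
        assert truth.causal_genotype[s] == 2
    for p in study.design.parents:
        assert truth.causal_genotype[p] == 1


def test_first_cousin_offspring_autozygosity_near_one_sixteenth():
    # closed form: inbreeding coefficient F = 1/16 for first-cousin offspring
    cfg = SimConfig(seed=17, n_markers=120)
    ped = first_cousin_pedigree()
    rng = np.random.default_rng(17)
    fractions = np.empty(10_000)
    for i in range(10_000):
        _, truth = gene_drop(ped, cfg, rng=rng)
        lab = truth.ibd_labels["K"]
        fractions[i] = np.mean(lab[0] == lab[1])
    se = fractions.std(ddof=1) / np.sqrt(fractions.size)
    assert abs(fractions.mean() - 1 / 16) <= 3 * se


def test_read_counts_moments():
    rng = np.random.default_rng(9)
    cfg = SimConfig(seed=9, mean_depth=30.0, n_markers=10_000)
    pos = np.arange(1, 10_001) * 1000
    hom = {"S": np.zeros(10_000, dtype=np.int8)}
    het = {"S": np.ones(10_000, dtype=np.int8)}
    df_hom = simulate_read_counts(hom, pos, cfg, rng=rng)
    depth = (df_hom.ref_reads + df_hom.alt_reads).to_numpy()
    assert abs(depth.mean() - 30.0) / 30.0 < 0.01
    cfg0 = SimConfig(seed=9, base_error_rate=0.0, mean_depth=40)
    df0 = simulate_read_counts(hom, pos, cfg0, rng=rng)
    assert (df0.alt_reads == 0).all()
    df_het = simulate_read_counts(het, pos, SimConfig(seed=9, mean_depth=40), rng=rng)
    called = df_het[(df_het.ref_reads + df_het.alt_reads) > 0]
    frac = (called.alt_reads / (called.ref_reads + called.alt_reads)).to_numpy()
    se = frac.std(ddof=1) / np.sqrt(frac.size)
    assert abs(frac.mean() - 0.5) <= 3 * se


def _exons(n=8, gene="G"):
    return [
        ExonDef(gene, i + 1, GenomicInterval("1", 1000 + 10_000 * i, 1200 + 10_000 * i))
        for i in range(n)
    ]


def test_rpkm_matrix_deletions_and_noise():
    cfg = SimConfig(seed=2)
    m = simulate_rpkm_matrix(_exons(), ["s1", "s2"], [("s2", (4, 6))], cfg)
    assert m.values.shape == (8, 2)
    assert (m.values[4:7, 1] < 0.5).all()
    # noise SD 0: non-deleted entries equal the per-exon baseline exactly
    cfg0 = SimConfig(seed=2, rpkm_noise_sd_log=0.0)
    m0 = simulate_rpkm_matrix(_exons(), ["s1", "s2"], [], cfg0)
    assert np.allclose(m0.values[:, 0], m0.values[:, 1])
    m0b = simulate_rpkm_matrix(_exons(), ["s1", "s2"], [], cfg0)
    assert np.array_equal(m0.values, m0b.values)


def test_rpkm_matrix_requires_exons():
    with pytest.raises(ConfigError):
        simulate_rpkm_matrix([], ["s1"], [], SimConfig(seed=1))


def test_study_determinism():
    a = simulate_study(SimConfig(seed=21))
    b = simulate_study(SimConfig(seed=21))
    assert a.calls.equals(b.calls)
    assert np.array_equal(a.rpkm.values, b.rpkm.values)
    assert [
        (v.pos, v.gene, tuple(sorted((k, z.value) for k, z in v.zygosity_by_sample.items())))
        for v in a.variants
    ] == [
        (v.pos, v.gene, tuple(sorted((k, z.value) for k, z in v.zygosity_by_sample.items())))
        for v in b.variants
    ]
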