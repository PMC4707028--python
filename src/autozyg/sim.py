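"""Synthetic consanguineous-pedigree study generator.

Gene dropping propagates founder haplotypes through a pedigree under a
Haldane (no-interference) recombination map derived from physical distance at
a configurable cM/Mb rate.  Each meiosis is a two-state Markov switching
process along the chromosome, simulated outward from the causal locus so that
the drop can be conditioned on the disease-locus inheritance pattern: in
pedigrees with affected members the founder-mutation scenario is enforced
(every affected is autozygous for one target founder haplotype carrying the
disease allele, and nobody marked unaffected is homozygous for the disease
allele).  Identity-by-descent labels trace every transmitted allele to a
founder haplotype, which yields exact true autozygous segments for recovery
tests.

Read-level calls use a Poisson depth / binomial allele-sampling model, the
variant table embeds one causal rare homozygous deleterious variant among
background variants drawn at Hardy-Weinberg genotype frequencies, and RPKM
matrices carry log-normal noise with embedded near-zero homozygous deletions.
All randomness flows from one explicit seed.
"""
from __future__ import annotations

from dataclasses import dataclass, field, replace
from typing import Mapping, Sequence

import numpy as np
import pandas as pd

from .aoh import Zygosity
from .cnv import ExonDef, RpkmMatrix
from .filtering import FamilyDesign, VariantRecord
from .intervals import GenomicInterval
from .pedigree import Individual, Pedigree

PANELS = ("ESP", "KGP", "ARIC")


class ConfigError(ValueError):
    """Invalid simulation configuration."""


@dataclass(frozen=True)
class SimConfig:
    seed: int = 0
    n_markers: int = 2000
    chrom: str = "6"
    chrom_length_bp: int = 150_000_000
    marker_maf: float = 0.3
    causal_position_bp: int = 60_000_000
    disease_allele_freq_founders: float = 0.02
    mean_depth: float = 40.0
    base_error_rate: float = 0.005
    rpkm_noise_sd_log: float = 0.2
    cm_per_mb: float = 1.0
    n_background_variants: int = 500
    zero_recomb_window: tuple[int, int] | None = None

    def __post_init__(self) -> None:
        if not 0.0 < self.marker_maf <= 0.5:
            raise ConfigError("marker_maf must be in (0, 0.5]")
        for name in ("disease_allele_freq_founders", "base_error_rate"):
            v = getattr(self, name)
            if not 0.0 <= v <= 1.0:
                raise ConfigError(f"{name} must be in [0, 1]")
        if self.mean_depth <= 0:
            raise ConfigError("mean_depth must be positive")
        if self.rpkm_noise_sd_log < 0:
            raise ConfigError("rpkm_noise_sd_log must be non-negative")
        if self.cm_per_mb < 0:
            raise ConfigError("cM/Mb rate must be non-negative")
        if not 1 <= self.causal_position_bp <= self.chrom_length_bp:
            raise ConfigError("causal position outside the chromosome")


@dataclass
class TrueState:
    """Ground truth of one gene drop, for recovery tests."""

    chrom: str
    marker_positions: np.ndarray
    site_positions: np.ndarray  # markers plus the causal locus
    causal_site_index: int
    founder_hap_alleles: np.ndarray  # (2F, n_markers) indicator of the rarer allele
    hap_disease: np.ndarray  # (2F,) disease-allele indicator per founder haplotype
    hap_owner: dict[str, tuple[int, int]]  # founder id -> haplotype labels
    disease_hap_label: int | None
    ibd_labels: dict[str, np.ndarray]  # iid -> (2, n_sites) founder-haplotype labels
    marker_genotypes: dict[str, np.ndarray]  # iid -> rarer-allele counts
    causal_genotype: dict[str, int]
    true_autozygous_segments: dict[str, list[GenomicInterval]]
    true_deletions: list[tuple[str, tuple[int, int]]] = field(default_factory=list)


def _draw_marker_positions(rng: np.random.Generator, cfg: SimConfig) -> np.ndarray:
    pos: np.ndarray = np.array([], dtype=np.int64)
    while pos.size < cfg.n_markers:
        extra = rng.integers(1, cfg.chrom_length_bp + 1, size=2 * cfg.n_markers)
        pos = np.unique(np.concatenate([pos, extra]))
        pos = pos[pos != cfg.causal_position_bp]
    return np.sort(rng.choice(pos, size=cfg.n_markers, replace=False))


def _meiosis_list(ped: Pedigree) -> list[tuple[str, str]]:
    return [(ind.iid, side) for ind in ped.nonfounders for side in ("p", "m")]


def _labels_at_causal(
    ped: Pedigree, hap_owner: Mapping[str, tuple[int, int]], bits: np.ndarray,
    meiosis_index: Mapping[tuple[str, str], int],
) -> dict[str, tuple[int, int]]:
    lab: dict[str, tuple[int, int]] = {}
    for ind in ped:
        if ind.is_founder:
            lab[ind.iid] = hap_owner[ind.iid]
        else:
            f, m = lab[ind.father], lab[ind.mother]
            lab[ind.iid] = (
                f[bits[meiosis_index[(ind.iid, "p")]]],
                m[bits[meiosis_index[(ind.iid, "m")]]],
            )
    return lab


def gene_drop(
    ped: Pedigree,
    cfg: SimConfig,
    rng: np.random.Generator | None = None,
    condition_on_affection: bool | None = None,
    max_attempts: int = 500_000,
) -> tuple[dict[str, np.ndarray], TrueState]:
    """Drop founder haplotypes through the pedigree.

    Returns marker genotypes (counts of the rarer allele per individual) and
    the :class:`TrueState` ground truth.  When the pedigree contains affected
    members (or ``condition_on_affection=True``), the drop is conditioned by
    rejection sampling of the disease-locus inheritance vector so that every
    affected is autozygous for one disease-carrying target founder haplotype
    and no individual marked unaffected is homozygous for the disease allele;
    marker transmission is then simulated outward from the causal locus,
    conditional on that inheritance vector, which leaves the Haldane map
    intact.
    """
    if cfg.n_markers <= 0:
        raise ConfigError("need at least one marker")
    if rng is None:
        rng = np.random.default_rng(cfg.seed)
    if condition_on_affection is None:
        condition_on_affection = any(i.affected is True for i in ped)

    founders = ped.founders
    n_f = len(founders)
    hap_owner = {f.iid: (2 * k, 2 * k + 1) for k, f in enumerate(founders)}
    meioses = _meiosis_list(ped)
    meiosis_index = {m: j for j, m in enumerate(meioses)}
    n_m = len(meioses)

    positions = _draw_marker_positions(rng, cfg)
    founder_alleles = (rng.random((2 * n_f, cfg.n_markers)) < cfg.marker_maf).astype(np.int8)

    # --- disease-locus inheritance vector --------------------------------
    # Rejection sampling, vectorised over attempts: propagate the founder
    # haplotype labels at the causal locus for a whole batch of candidate
    # inheritance vectors at once and keep the first phenotype-consistent one.
    target: int | None = None
    if condition_on_affection:
        batch = 4096
        attempts = 0
        found = False
        while attempts < max_attempts and not found:
            attempts += batch
            targets = rng.integers(0, 2 * n_f, size=batch)
            hap_dis = rng.random((batch, 2 * n_f)) < cfg.disease_allele_freq_founders
            rows = np.arange(batch)
            hap_dis[rows, targets] = True
            bits_b = rng.integers(0, 2, size=(batch, n_m), dtype=np.int8)
            lab_pb: dict[str, np.ndarray] = {}
            lab_mb: dict[str, np.ndarray] = {}
            ok = np.ones(batch, dtype=bool)
            for ind in ped:
                if ind.is_founder:
                    a, b = hap_owner[ind.iid]
                    lp = np.full(batch, a)
                    lm = np.full(batch, b)
                else:
                    bp = bits_b[:, meiosis_index[(ind.iid, "p")]]
                    bm = bits_b[:, meiosis_index[(ind.iid, "m")]]
                    lp = np.where(bp == 0, lab_pb[ind.father], lab_mb[ind.father])
                    lm = np.where(bm == 0, lab_pb[ind.mother], lab_mb[ind.mother])
                lab_pb[ind.iid], lab_mb[ind.iid] = lp, lm
                if ind.affected is True:
                    ok &= (lp == lm) & (lp == targets)
                elif ind.affected is False:
                    ok &= ~(hap_dis[rows, lp] & hap_dis[rows, lm])
            hits = np.nonzero(ok)[0]
            if hits.size:
                k = int(hits[0])
                target = int(targets[k])
                hap_disease = hap_dis[k]
                bits_causal = bits_b[k]
                found = True
        if not found:
            raise ConfigError(
                "could not condition the gene drop on the affection pattern; "
                "check that the pedigree can make every affected autozygous"
            )
    else:
        hap_disease = rng.random(2 * n_f) < cfg.disease_allele_freq_founders
        bits_causal = rng.integers(0, 2, size=n_m)

    # --- marker transmission, outward from the causal locus ---------------
    c = int(np.searchsorted(positions, cfg.causal_position_bp))
    sites = np.concatenate([positions[:c], [cfg.causal_position_bp], positions[c:]])
    marker_idx = np.concatenate([np.arange(c), np.arange(c + 1, sites.size)])
    gaps = np.diff(sites).astype(float)
    if cfg.zero_recomb_window is not None:
        ws, we = cfg.zero_recomb_window
        overlap = np.clip(
            np.minimum(sites[1:], we) - np.maximum(sites[:-1], ws), 0, None
        )
        gaps = gaps - overlap
    morgans = gaps * cfg.cm_per_mb * 1e-8
    r = 0.5 * (1.0 - np.exp(-2.0 * morgans))  # Haldane map function

    bits = np.empty((n_m, sites.size), dtype=np.int8)
    switches = rng.random((n_m, r.size)) < r
    for j in range(n_m):
        par = np.zeros(sites.size, dtype=np.int64)
        par[c + 1 :] = np.cumsum(switches[j, c:])
        if c > 0:
            par[:c] = np.cumsum(switches[j, :c][::-1])[::-1]
        bits[j] = (int(bits_causal[j]) + par) % 2

    # --- propagate haplotypes ---------------------------------------------
    lab_p: dict[str, np.ndarray] = {}
    lab_m: dict[str, np.ndarray] = {}
    al_p: dict[str, np.ndarray] = {}
    al_m: dict[str, np.ndarray] = {}
    for ind in ped:
        if ind.is_founder:
            a, b = hap_owner[ind.iid]
            lab_p[ind.iid] = np.full(sites.size, a, dtype=np.int32)
            lab_m[ind.iid] = np.full(sites.size, b, dtype=np.int32)
            al_p[ind.iid] = founder_alleles[a]
            al_m[ind.iid] = founder_alleles[b]
        else:
            bp = bits[meiosis_index[(ind.iid, "p")]]
            bm = bits[meiosis_index[(ind.iid, "m")]]
            lab_p[ind.iid] = np.where(bp == 0, lab_p[ind.father], lab_m[ind.father])
            lab_m[ind.iid] = np.where(bm == 0, lab_p[ind.mother], lab_m[ind.mother])
            bpm, bmm = bp[marker_idx], bm[marker_idx]
            al_p[ind.iid] = np.where(bpm == 0, al_p[ind.father], al_m[ind.father])
            al_m[ind.iid] = np.where(bmm == 0, al_p[ind.mother], al_m[ind.mother])

    genotypes = {iid: (al_p[iid] + al_m[iid]).astype(np.int8) for iid in ped.ids}
    causal_genotype = {
        iid: int(hap_disease[lab_p[iid][c]]) + int(hap_disease[lab_m[iid][c]])
        for iid in ped.ids
    }

    segments: dict[str, list[GenomicInterval]] = {}
    for iid in ped.ids:
        auto = lab_p[iid] == lab_m[iid]
        segs: list[GenomicInterval] = []
        i = 0
        while i < auto.size:
            if not auto[i]:
                i += 1
                continue
            j = i
            while j < auto.size and auto[j]:
                j += 1
            segs.append(GenomicInterval(cfg.chrom, int(sites[i]), int(sites[j - 1])))
            i = j
        segments[iid] = segs

    truth = TrueState(
        chrom=cfg.chrom,
        marker_positions=positions,
        site_positions=sites,
        causal_site_index=c,
        founder_hap_alleles=founder_alleles,
        hap_disease=np.asarray(hap_disease, dtype=bool),
        hap_owner=hap_owner,
        disease_hap_label=target,
        ibd_labels={iid: np.vstack([lab_p[iid], lab_m[iid]]) for iid in ped.ids},
        marker_genotypes=genotypes,
        causal_genotype=causal_genotype,
        true_autozygous_segments=segments,
    )
    return genotypes, truth


def simulate_read_counts(
    genotypes: Mapping[str, np.ndarray],
    positions: np.ndarray,
    cfg: SimConfig,
    rng: np.random.Generator | None = None,
) -> pd.DataFrame:
    """Read-level calls: Poisson depth, binomial allele sampling.

    Heterozygous sites draw alternate reads at 0.5, homozygous sites at the
    base error rate (or its complement).  Returns a long table with columns
    sample, chrom, pos, ref_reads, alt_reads.
    """
    if cfg.mean_depth <= 0:
        raise ConfigError("mean_depth must be positive")
    if rng is None:
        rng = np.random.default_rng(cfg.seed + 1)
    p_alt = np.array([cfg.base_error_rate, 0.5, 1.0 - cfg.base_error_rate])
    frames = []
    for sample in genotypes:
        g = np.asarray(genotypes[sample])
        depth = rng.poisson(cfg.mean_depth, size=g.size)
        alt = rng.binomial(depth, p_alt[g])
        frames.append(
            pd.DataFrame(
                {
                    "sample": sample,
                    "chrom": cfg.chrom,
                    "pos": positions,
                    "ref_reads": depth - alt,
                    "alt_reads": alt,
                }
            )
        )
    return pd.concat(frames, ignore_index=True)


_ZYG_FROM_COUNT = {0: Zygosity.HOM_REF, 1: Zygosity.HET, 2: Zygosity.HOM_ALT}

_CONSEQUENCES = ("other", "missense", "splice_region", "indel", "nonsense", "stop_loss")
_CONSEQUENCE_P = (0.50, 0.30, 0.08, 0.08, 0.03, 0.01)


def simulate_variant_table(
    ped: Pedigree,
    truth: TrueState,
    cfg: SimConfig,
    rng: np.random.Generator | None = None,
    n_background: int | None = None,
    dropout_samples: Sequence[str] = (),
) -> list[VariantRecord]:
    """Variant annotation/zygosity table with one embedded causal variant.

    The causal variant sits at the causal position, is rare (<1% in every
    panel), of a deleterious class, and carries each individual's true
    disease genotype; ``dropout_samples`` lose their causal call (NO_CALL),
    emulating a capture-platform dropout.  Background variants draw positions
    uniformly, panel frequencies from a common/rare mixture, and per-sample
    genotypes at Hardy-Weinberg proportions.
    """
    if rng is None:
        rng = np.random.default_rng(cfg.seed + 2)
    samples = ped.ids
    causal_zyg = {
        iid: (Zygosity.NO_CALL if iid in dropout_samples else _ZYG_FROM_COUNT[truth.causal_genotype[iid]])
        for iid in samples
    }
    causal = VariantRecord(
        chrom=cfg.chrom,
        pos=cfg.causal_position_bp,
        ref="C",
        alt="T",
        gene="G_causal",
        consequence="missense",
        panel_freqs={p: float(rng.uniform(0.0, 0.005)) for p in PANELS},
        in_disease_db=False,
        quality_pass=True,
        zygosity_by_sample=causal_zyg,
    )
    variants = [causal]
    n_bg = cfg.n_background_variants if n_background is None else n_background
    if n_bg:
        pos = rng.integers(1, cfg.chrom_length_bp + 1, size=n_bg)
        pos = pos[pos != cfg.causal_position_bp]
        for k, p in enumerate(sorted(int(x) for x in pos)):
            common = rng.random() < 0.6
            af = float(rng.uniform(0.05, 0.5)) if common else float(rng.uniform(0.0, 0.007))
            cons = str(rng.choice(_CONSEQUENCES, p=_CONSEQUENCE_P))
            g = rng.binomial(2, af, size=len(samples))
            nocall = rng.random(len(samples)) < 0.01
            zyg = {
                s: (Zygosity.NO_CALL if nocall[i] else _ZYG_FROM_COUNT[int(g[i])])
                for i, s in enumerate(samples)
            }
            variants.append(
                VariantRecord(
                    chrom=cfg.chrom,
                    pos=p,
                    ref="A",
                    alt="G",
                    gene=f"G{k:04d}",
                    consequence=cons,
                    splice_distance_bp=int(rng.integers(1, 11)) if cons == "splice_region" else None,
                    panel_freqs={
                        pl: float(np.clip(af * rng.uniform(0.7, 1.3), 0.0, 0.9))
                        for pl in PANELS
                    },
                    in_disease_db=bool(rng.random() < 0.02),
                    quality_pass=bool(rng.random() < 0.97),
                    zygosity_by_sample=zyg,
                )
            )
    variants.sort(key=lambda v: v.pos)
    return variants


def simulate_rpkm_matrix(
    exons: Sequence[ExonDef],
    samples: Sequence[str],
    true_deletions: Sequence[tuple[str, tuple[int, int]]],
    cfg: SimConfig,
    rng: np.random.Generator | None = None,
) -> RpkmMatrix:
    """Exon x sample RPKM matrix with log-normal noise and embedded deletions.

    ``true_deletions`` are (sample, (first_exon, last_exon)) index ranges,
    inclusive, into ``exons``; deleted entries are drawn near zero (< 0.5).
    """
    if not exons:
        raise ConfigError("need at least one exon")
    if rng is None:
        rng = np.random.default_rng(cfg.seed + 3)
    baselines = rng.uniform(20.0, 60.0, size=len(exons))
    noise = rng.normal(0.0, cfg.rpkm_noise_sd_log, size=(len(exons), len(samples)))
    values = baselines[:, None] * np.exp(noise)
    sample_idx = {s: i for i, s in enumerate(samples)}
    for sample, (e0, e1) in true_deletions:
        values[e0 : e1 + 1, sample_idx[sample]] = rng.uniform(0.0, 0.3, size=e1 - e0 + 1)
    return RpkmMatrix(list(exons), list(samples), values)


# ---------------------------------------------------------------------------
# the default study: two consanguineous family arms sharing a founder mutation
# ---------------------------------------------------------------------------


def consanguineous_study_pedigree() -> Pedigree:
    """Two related family arms, each producing affected offspring of
    first-cousin unions, descending from one ancestral couple.

    GF x GM found the kindred; their children A1, A2 marry unrelated founders;
    three first-cousin unions (B1xB3, B2xB4, B5xB6) each produce one affected
    child (C1..C3).  Six healthy parents, three affecteds in two arms.
    """
    def ind(iid, father=None, mother=None, sex="unknown", affected=False):
        return Individual(iid, father, mother, sex, affected)

    members = [
        ind("GF", sex="male"), ind("GM", sex="female"),
        ind("S1", sex="female"), ind("S2", sex="male"),
        ind("A1", "GF", "GM", "male"), ind("A2", "GF", "GM", "female"),
        ind("B1", "A1", "S1", "male"), ind("B2", "A1", "S1", "male"),
        ind("B5", "A1", "S1", "male"),
        ind("B3", "A2", "S2", "female"), ind("B4", "A2", "S2", "female"),
        ind("B6", "A2", "S2", "female"),
        ind("C1", "B1", "B3", "male", True),
        ind("C2", "B2", "B4", "female", True),
        ind("C3", "B5", "B6", "male", True),
    ]
    return Pedigree(members)


def default_design() -> FamilyDesign:
    """Two-arm filtering design: affecteds C1+C2 vs C3, six healthy parents."""
    return FamilyDesign(
        affected_groups=(("C1", "C2"), ("C3",)),
        parents=("B1", "B3", "B2", "B4", "B5", "B6"),
    )


def first_cousin_pedigree(child_affected: bool | None = None) -> Pedigree:
    """First-cousin union with one child (inbreeding coefficient F = 1/16)."""
    def ind(iid, father=None, mother=None, sex="unknown", affected=None):
        return Individual(iid, father, mother, sex, affected)

    return Pedigree(
        [
            ind("GF", sex="male"), ind("GM", sex="female"),
            ind("SA", sex="female"), ind("SB", sex="male"),
            ind("P1", "GF", "GM", "male"), ind("P2", "GF", "GM", "female"),
            ind("Q1", "P1", "SA", "male"), ind("Q2", "P2", "SB", "female"),
            ind("K", "Q1", "Q2", affected=child_affected),
        ]
    )


@dataclass
class SimulatedStudy:
    cfg: SimConfig
    ped: Pedigree
    design: FamilyDesign
    truth: TrueState
    genotypes: dict[str, np.ndarray]
    calls: pd.DataFrame
    variants: list[VariantRecord]
    causal_variant: VariantRecord
    exons: list[ExonDef]
    rpkm: RpkmMatrix


def _study_exons(cfg: SimConfig) -> list[ExonDef]:
    """A small exome slab: two genes near the causal locus, two far away."""
    exons: list[ExonDef] = []
    layout = [
        ("GENE_NEAR1", cfg.causal_position_bp - 200_000, 10),
        ("GENE_NEAR2", cfg.causal_position_bp + 150_000, 10),
        ("GENE_FAR1", max(1, cfg.causal_position_bp - 40_000_000), 10),
        ("GENE_FAR2", min(cfg.chrom_length_bp - 200_000, cfg.causal_position_bp + 40_000_000), 10),
    ]
    for gene, start, n in layout:
        for i in range(n):
            s = start + i * 5_000
            exons.append(
                ExonDef(gene, i + 1, GenomicInterval(cfg.chrom, s, s + 200))
            )
    return exons


def simulate_study(
    cfg: SimConfig,
    ped: Pedigree | None = None,
    design: FamilyDesign | None = None,
    dropout_samples: Sequence[str] = (),
    rng: np.random.Generator | None = None,
) -> SimulatedStudy:
    """Generate a complete synthetic study with ground truth.

    One private 3-exon homozygous deletion is embedded near the causal locus
    in the first affected sample (inside its autozygous segment), so the
    affecteds share no deletion, matching the recessive-CNV null expectation.
    """
    if ped is None:
        ped = consanguineous_study_pedigree()
    if design is None:
        design = default_design()
    if rng is None:
        rng = np.random.default_rng(cfg.seed)
    if not ped.affecteds:
        raise ConfigError("study pedigree has no affected individuals")
    genotypes, truth = gene_drop(ped, cfg, rng=rng)
    calls = simulate_read_counts(genotypes, truth.marker_positions, cfg, rng=rng)
    variants = simulate_variant_table(
        ped, truth, cfg, rng=rng, dropout_samples=dropout_samples
    )
    causal = next(v for v in variants if v.gene == "G_causal")
    exons = _study_exons(cfg)
    # private deletion: exons 3-5 of GENE_NEAR1 in the first affected sample
    first_affected = design.all_affected[0]
    e0 = next(i for i, e in enumerate(exons) if e.gene == "GENE_NEAR1" and e.exon_index == 3)
    deletions = [(first_affected, (e0, e0 + 2))]
    rpkm = simulate_rpkm_matrix(exons, ped.ids, deletions, cfg, rng=rng)
    truth.true_deletions = list(deletions)
    return SimulatedStudy(
        cfg=cfg,
        ped=ped,
        design=design,
        truth=truth,
        genotypes=genotypes,
        calls=calls,
        variants=variants,
        causal_variant=causal,
        exons=exons,
        rpkm=rpkm,
    )
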