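"""End-to-end orchestration: simulate -> AOH -> filter -> LOD -> CNV ->
finemap -> annotate, with schema-validated configuration and reproducible
seeding.

Every stage writes its intermediate output to the run directory and
contributes record counts to the run report, so the whole candidate-variant
funnel is machine-checkable.  A rerun with the same configuration produces
byte-identical outputs.
"""
from __future__ import annotations

import logging
from dataclasses import dataclass, field
from pathlib import Path
from typing import Sequence

import numpy as np
import yaml
from pydantic import BaseModel, ConfigDict

from . import io as azio
from .annotation import interval_length_mb
from .aoh import AOHSegment, Zygosity, add_zygosity, map_shared_autozygosity, segment_aoh
from .cnv import call_homozygous_deletions
from .filtering import (
    FamilyDesign,
    apply_basic_filters,
    compound_het_scan,
    stage1_shared_homozygous,
    stage2_region_union,
)
from .finemap import (
    HET,
    NoRefinementError,
    SnpGenotypeMatrix,
    locate_gene_in_interval,
    refine_interval,
    select_informative_snps,
)
from .intervals import GenomicInterval
from .linkage import DEFAULT_THETA_GRID, DiseaseModel, two_point_lod
from .pedigree import Pedigree
from .sim import ConfigError, SimConfig, SimulatedStudy, simulate_study

logger = logging.getLogger("autozyg")


class _Params(BaseModel):
    model_config = ConfigDict(extra="forbid")


class SimParams(_Params):
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
    dropout_samples: list[str] = []


class AohParams(_Params):
    min_depth: int = 5
    het_fraction: float = 0.25
    min_markers: int = 25
    min_span_bp: int = 1_000_000


class LodParams(_Params):
    disease_allele_freq: float = 0.05
    marker_allele_freq: float | None = None  # default: estimated from founders
    theta_grid: list[float] = list(DEFAULT_THETA_GRID)


class CnvParams(_Params):
    rpkm_threshold: float = 0.5
    max_cohort_freq: float = 0.005
    exon_quality_fraction: float = 0.99
    min_aoh_span_bp: int = 500_000
    max_calls_per_sample: int = 10


class RunConfig(_Params):
    seed: int = 0
    outdir: str = "autozyg_run"
    pedigree_file: str | None = None
    sim: SimParams = SimParams()
    aoh: AohParams = AohParams()
    lod: LodParams = LodParams()
    cnv: CnvParams = CnvParams()
    log_level: str = "INFO"

    @classmethod
    def from_yaml(cls, path: str | Path) -> "RunConfig":
        return cls.model_validate(yaml.safe_load(Path(path).read_text()) or {})


@dataclass
class RunReport:
    seed: int
    counts: dict = field(default_factory=dict)
    headline: dict = field(default_factory=dict)

    def to_dict(self) -> dict:
        return {"format": azio.FORMAT_VERSION, "seed": self.seed,
                "counts": self.counts, "headline": self.headline}


class StageFailure(RuntimeError):
    def __init__(self, stage: str, cause: Exception):
        super().__init__(f"stage {stage!r} failed: {cause}")
        self.stage = stage
        self.cause = cause


def _interval_str(iv: GenomicInterval) -> str:
    return f"{iv.chrom}:{iv.start}-{iv.end}"


def _estimate_marker_freq(study: SimulatedStudy, zygosity_by_sample) -> float:
    counts = {Zygosity.HOM_REF: 0, Zygosity.HET: 1, Zygosity.HOM_ALT: 2}
    total = n = 0
    for ind in study.ped.founders:
        z = zygosity_by_sample.get(ind.iid)
        if z in counts:
            total += counts[z]
            n += 2
    if n == 0:
        return 0.05
    return float(min(max(total / n, 0.01), 0.99))


def run_pipeline(cfg: RunConfig) -> RunReport:
    """Execute all stages in order, writing intermediates to ``cfg.outdir``."""
    logging.basicConfig(level=cfg.log_level)
    outdir = Path(cfg.outdir)
    outdir.mkdir(parents=True, exist_ok=True)
    report = RunReport(seed=cfg.seed)

    # -- validation before any stage runs ---------------------------------
    ped = design = None
    if cfg.pedigree_file is not None:
        ped = azio.read_ped(cfg.pedigree_file)
        if not ped.affecteds:
            raise ConfigError("pedigree has no affected individuals")
        design = FamilyDesign(
            affected_groups=(tuple(ped.affecteds),),
            parents=tuple(ped.obligate_carriers),
        )

    stage = "simulate"
    try:
        sim_kwargs = cfg.sim.model_dump()
        dropout = sim_kwargs.pop("dropout_samples")
        sim_cfg = SimConfig(seed=cfg.seed, **sim_kwargs)
        study = simulate_study(sim_cfg, ped=ped, design=design, dropout_samples=dropout)
        azio.write_ped(study.ped, outdir / "study.ped")
        azio.write_calls_vcf(study.calls, outdir / "calls.vcf",
                             cfg.aoh.min_depth, cfg.aoh.het_fraction)
        azio.write_variants_tsv(study.variants, outdir / "variants.tsv")
        azio.write_rpkm_tsv(study.rpkm, outdir / "rpkm.tsv")
        azio.write_bed(
            [iv for segs in study.truth.true_autozygous_segments.values() for iv in segs],
            outdir / "true_segments.bed",
        )
        report.counts["simulate"] = {
            "individuals": len(study.ped),
            "markers": int(study.truth.marker_positions.size),
            "variants": len(study.variants),
            "exons": len(study.exons),
        }
        logger.info("simulate: %s", report.counts["simulate"])

        stage = "aoh"
        calls = add_zygosity(study.calls, cfg.aoh.min_depth, cfg.aoh.het_fraction)
        segments: dict[str, list[AOHSegment]] = {}
        for sample, sub in calls.groupby("sample"):
            segments[str(sample)] = segment_aoh(
                sub.sort_values(["chrom", "pos"]),
                cfg.aoh.min_markers,
                cfg.aoh.min_span_bp,
                sample=str(sample),
            )
        shared = map_shared_autozygosity(
            {s: segments[s] for s in study.design.all_affected},
            {s: segments[s] for s in study.design.parents},
        )
        azio.write_bed([s for segs in segments.values() for s in segs], outdir / "aoh_segments.bed")
        azio.write_bed(shared, outdir / "shared_intervals.bed")
        report.counts["aoh"] = {
            "segments": sum(len(s) for s in segments.values()),
            "shared_intervals": len(shared),
        }
        if not shared:
            raise ValueError("no shared autozygous interval found")
        region = max(shared, key=lambda iv: iv.length_bp)
        report.headline["shared_interval"] = _interval_str(region)
        report.headline["shared_interval_mb"] = interval_length_mb(region)

        stage = "filter"
        basic = apply_basic_filters(study.variants)
        stage1 = stage1_shared_homozygous(basic, study.design)
        stage2 = stage2_region_union(basic, study.design, region)
        comphet = compound_het_scan(study.variants, study.design, study.ped)
        azio.write_variants_tsv(stage1, outdir / "stage1_variants.tsv")
        azio.write_variants_tsv(stage2, outdir / "stage2_variants.tsv")
        report.counts["filter"] = {
            "input": len(study.variants),
            "after_basic": len(basic),
            "stage1": len(stage1),
            "stage2": len(stage2),
            "compound_het_pairs": len(comphet),
        }
        candidates = stage1 if stage1 else stage2
        if not candidates:
            raise ValueError("no candidate variant survived filtering")
        candidate = candidates[0]
        report.headline["candidate_variant"] = f"{candidate.gene}@{candidate.chrom}:{candidate.pos}"

        stage = "lod"
        marker_geno = {
            iid: z for iid, z in candidate.zygosity_by_sample.items()
            if z != Zygosity.NO_CALL
        }
        model = DiseaseModel(disease_allele_freq=cfg.lod.disease_allele_freq)
        marker_freq = (
            cfg.lod.marker_allele_freq
            if cfg.lod.marker_allele_freq is not None
            else _estimate_marker_freq(study, candidate.zygosity_by_sample)
        )
        curve = two_point_lod(study.ped, marker_geno, model, marker_freq, cfg.lod.theta_grid)
        azio.write_lod_tsv(curve, outdir / "lod.tsv")
        report.headline["max_lod"] = round(curve.max_lod, 4)
        report.headline["argmax_theta"] = curve.argmax_theta

        stage = "cnv"
        del_calls = call_homozygous_deletions(
            study.rpkm,
            {s: segments.get(s, []) for s in study.rpkm.samples},
            rpkm_threshold=cfg.cnv.rpkm_threshold,
            max_cohort_freq=cfg.cnv.max_cohort_freq,
            exon_quality_fraction=cfg.cnv.exon_quality_fraction,
            min_aoh_span_bp=cfg.cnv.min_aoh_span_bp,
            max_calls_per_sample=cfg.cnv.max_calls_per_sample,
        )
        azio.write_deletion_calls_tsv(del_calls, outdir / "cnv_calls.tsv")
        by_affected = [
            {c.interval for c in del_calls if c.sample == s}
            for s in study.design.all_affected
        ]
        shared_deletions = set.intersection(*by_affected) if by_affected else set()
        report.counts["cnv"] = {
            "calls": len(del_calls),
            "shared_by_affecteds": len(shared_deletions),
        }

        stage = "finemap"
        snp_matrix = _snp_matrix_from_truth(study, region)
        azio.write_snp_matrix_tsv(snp_matrix, outdir / "snp_matrix.tsv")
        informative = select_informative_snps(
            snp_matrix, list(study.design.parents), region
        )
        refined = None
        keep = [i for i, s in enumerate(snp_matrix.snp_ids) if s in informative]
        sub = SnpGenotypeMatrix(
            chrom=snp_matrix.chrom,
            snp_ids=[snp_matrix.snp_ids[i] for i in keep],
            positions=snp_matrix.positions[keep],
            samples=snp_matrix.samples,
            genotypes=snp_matrix.genotypes[keep],
        )
        discordant = _pick_discordant(study, sub)
        if discordant is not None:
            try:
                refined = refine_interval(
                    sub, list(study.design.all_affected), discordant, region
                )
            except NoRefinementError:
                refined = None
        report.counts["finemap"] = {
            "snps": len(snp_matrix.snp_ids),
            "informative": len(informative),
        }
        if refined is not None:
            report.headline["refined_minimum"] = _interval_str(refined.minimum)
            report.headline["refined_maximum"] = _interval_str(refined.maximum)
            report.headline["refined_minimum_mb"] = interval_length_mb(refined.minimum)
            report.headline["refined_maximum_mb"] = interval_length_mb(refined.maximum)
            report.headline["candidate_in_refined"] = locate_gene_in_interval(
                GenomicInterval(candidate.chrom, candidate.pos, candidate.pos), refined
            )
    except Exception as exc:
        (outdir / "FAILED").write_text(f"stage={stage}\nerror={exc}\n")
        if isinstance(exc, (ConfigError,)):
            raise
        raise StageFailure(stage, exc) from exc

    azio.write_json_report(report.to_dict(), outdir / "report.json")
    return report


def _snp_matrix_from_truth(study: SimulatedStudy, region: GenomicInterval) -> SnpGenotypeMatrix:
    """Genotyping-panel emulation: true genotypes of markers inside the region
    at which all affecteds are homozygous for the same allele."""
    truth = study.truth
    pos = truth.marker_positions
    inside = (pos >= region.start) & (pos <= region.end)
    samples = study.ped.ids
    geno = np.vstack([truth.marker_genotypes[s] for s in samples]).T  # snp x sample
    aff_idx = [samples.index(s) for s in study.design.all_affected]
    aff = geno[:, aff_idx]
    hom_shared = inside & np.all(aff != 1, axis=1) & (aff.max(axis=1) == aff.min(axis=1))
    keep = np.where(hom_shared)[0]
    return SnpGenotypeMatrix(
        chrom=truth.chrom,
        snp_ids=[f"snp{pos[i]}" for i in keep],
        positions=pos[keep],
        samples=list(samples),
        genotypes=geno[keep],
    )


def _pick_discordant(study: SimulatedStudy, m: SnpGenotypeMatrix) -> str | None:
    """The unaffected individual with the fewest (but >=1) heterozygous SNPs:
    the most informative recombinant."""
    best: tuple[int, str] | None = None
    affected = set(study.design.all_affected)
    for s in m.samples:
        if s in affected:
            continue
        n_het = int((m.column(s) == HET).sum())
        if n_het >= 1 and (best is None or (n_het, s) < best):
            best = (n_het, s)
    return best[1] if best else None
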