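"""Readers and writers for the text formats the pipeline exchanges.

PED is the 6-column linkage dialect (FID IID PAT MAT SEX PHENO).  VCF is a
minimal single-chromosome dialect with GT:AD:DP sample fields; reading goes
through cyvcf2.  Intervals are 1-based inclusive in memory and 0-based
half-open in BED files on disk.  All writers emit a format-version comment
where the format allows one.
"""
from __future__ import annotations

import json
from pathlib import Path
from typing import Mapping, Sequence

import numpy as np
import pandas as pd
from cyvcf2 import VCF

from .aoh import AOHSegment, Zygosity, call_zygosity
from .cnv import DeletionCall, ExonDef, RpkmMatrix
from .filtering import VariantRecord
from .finemap import SnpGenotypeMatrix
from .intervals import GenomicInterval
from .linkage import LodCurve
from .pedigree import Individual, Pedigree

FORMAT_VERSION = "autozyg-v1"

_SEX_TO_PED = {"male": "1", "female": "2", "unknown": "0"}
_PED_TO_SEX = {"1": "male", "2": "female"}
_AFF_TO_PED = {True: "2", False: "1", None: "0"}
_PED_TO_AFF = {"2": True, "1": False}


def write_ped(ped: Pedigree, path: str | Path, family_id: str = "FAM1") -> None:
    lines = []
    for ind in ped:
        lines.append(
            "\t".join(
                [
                    family_id,
                    ind.iid,
                    ind.father or "0",
                    ind.mother or "0",
                    _SEX_TO_PED.get(ind.sex, "0"),
                    _AFF_TO_PED[ind.affected],
                ]
            )
        )
    Path(path).write_text("\n".join(lines) + "\n")


def read_ped(path: str | Path) -> Pedigree:
    members = []
    for line in Path(path).read_text().splitlines():
        line = line.strip()
        if not line or line.startswith("#"):
            continue
        _fid, iid, pat, mat, sex, pheno = line.split()[:6]
        members.append(
            Individual(
                iid=iid,
                father=None if pat == "0" else pat,
                mother=None if mat == "0" else mat,
                sex=_PED_TO_SEX.get(sex, "unknown"),
                affected=_PED_TO_AFF.get(pheno),
            )
        )
    return Pedigree(members)


# ---------------------------------------------------------------------------
# VCF (GT:AD:DP)
# ---------------------------------------------------------------------------


def write_calls_vcf(
    calls: pd.DataFrame,
    path: str | Path,
    min_depth: int = 5,
    het_fraction: float = 0.25,
) -> None:
    """Write a (sample, chrom, pos, ref_reads, alt_reads) table as minimal VCF."""
    samples = sorted(calls["sample"].unique())
    wide_ref = calls.pivot_table(index=["chrom", "pos"], columns="sample", values="ref_reads")
    wide_alt = calls.pivot_table(index=["chrom", "pos"], columns="sample", values="alt_reads")
    gt_for = {
        Zygosity.HOM_REF: "0/0",
        Zygosity.HET: "0/1",
        Zygosity.HOM_ALT: "1/1",
        Zygosity.NO_CALL: "./.",
    }
    with open(path, "w") as fh:
        fh.write("##fileformat=VCFv4.2\n")
        fh.write(f"##source={FORMAT_VERSION}\n")
        for chrom in sorted({c for c, _ in wide_ref.index}):
            fh.write(f"##contig=<ID={chrom}>\n")
        fh.write('##FORMAT=<ID=GT,Number=1,Type=String,Description="Genotype">\n')
        fh.write('##FORMAT=<ID=AD,Number=R,Type=Integer,Description="Allele read depths">\n')
        fh.write('##FORMAT=<ID=DP,Number=1,Type=Integer,Description="Read depth">\n')
        fh.write("#CHROM\tPOS\tID\tREF\tALT\tQUAL\tFILTER\tINFO\tFORMAT\t" + "\t".join(samples) + "\n")
        for chrom, pos in wide_ref.index:
            fields = [str(chrom), str(pos), ".", "A", "G", ".", "PASS", ".", "GT:AD:DP"]
            for s in samples:
                ref = int(wide_ref.loc[(chrom, pos), s])
                alt = int(wide_alt.loc[(chrom, pos), s])
                gt = gt_for[call_zygosity(ref, alt, min_depth, het_fraction)]
                fields.append(f"{gt}:{ref},{alt}:{ref + alt}")
            fh.write("\t".join(fields) + "\n")


def read_calls_vcf(path: str | Path) -> pd.DataFrame:
    """Read a GT:AD:DP VCF into a long (sample, chrom, pos, ref, alt reads) table."""
    vcf = VCF(str(path))
    samples = list(vcf.samples)
    rows: dict[str, list] = {k: [] for k in ("sample", "chrom", "pos", "ref_reads", "alt_reads")}
    for variant in vcf:
        ad = variant.format("AD")
        for i, s in enumerate(samples):
            rows["sample"].append(s)
            rows["chrom"].append(variant.CHROM)
            rows["pos"].append(variant.POS)
            rows["ref_reads"].append(int(ad[i][0]))
            rows["alt_reads"].append(int(ad[i][1]))
    vcf.close()
    return pd.DataFrame(rows).sort_values(["sample", "chrom", "pos"]).reset_index(drop=True)


# ---------------------------------------------------------------------------
# BED (0-based half-open on disk)
# ---------------------------------------------------------------------------


def write_bed(
    intervals: Sequence[GenomicInterval] | Sequence[AOHSegment],
    path: str | Path,
) -> None:
    lines = [f"# {FORMAT_VERSION}"]
    for item in intervals:
        if isinstance(item, AOHSegment):
            iv, name = item.interval, f"{item.sample};n_markers={item.n_markers}"
        else:
            iv, name = item, "."
        lines.append(f"{iv.chrom}\t{iv.start - 1}\t{iv.end}\t{name}")
    Path(path).write_text("\n".join(lines) + "\n")


def read_bed(path: str | Path) -> list[GenomicInterval]:
    out = []
    for line in Path(path).read_text().splitlines():
        if not line.strip() or line.startswith(("#", "track")):
            continue
        chrom, start, end = line.split("\t")[:3]
        out.append(GenomicInterval(chrom, int(start) + 1, int(end)))
    return out


def read_aoh_bed(path: str | Path) -> dict[str, list[AOHSegment]]:
    """Read AOH segments written by :func:`write_bed` back into per-sample lists."""
    out: dict[str, list[AOHSegment]] = {}
    for line in Path(path).read_text().splitlines():
        if not line.strip() or line.startswith(("#", "track")):
            continue
        chrom, start, end, name = line.split("\t")[:4]
        sample, _, rest = name.partition(";")
        n_markers = int(rest.partition("=")[2]) if rest else 0
        out.setdefault(sample, []).append(
            AOHSegment(sample, GenomicInterval(chrom, int(start) + 1, int(end)), n_markers)
        )
    return out


# ---------------------------------------------------------------------------
# TSV tables
# ---------------------------------------------------------------------------


def variants_to_frame(variants: Sequence[VariantRecord]) -> pd.DataFrame:
    samples = sorted({s for v in variants for s in v.zygosity_by_sample})
    panels = sorted({p for v in variants for p in v.panel_freqs})
    rows = []
    for v in variants:
        row = {
            "chrom": v.chrom,
            "pos": v.pos,
            "ref": v.ref,
            "alt": v.alt,
            "gene": v.gene,
            "consequence": v.consequence,
            "splice_distance_bp": v.splice_distance_bp,
            "in_disease_db": v.in_disease_db,
            "quality_pass": v.quality_pass,
        }
        for p in panels:
            row[f"freq_{p}"] = v.panel_freqs.get(p, 0.0)
        for s in samples:
            row[f"zyg_{s}"] = v.zygosity_by_sample.get(s, Zygosity.NO_CALL).value
        rows.append(row)
    return pd.DataFrame(rows)


def write_variants_tsv(variants: Sequence[VariantRecord], path: str | Path) -> None:
    with open(path, "w") as fh:
        fh.write(f"# {FORMAT_VERSION}\n")
        variants_to_frame(variants).to_csv(fh, sep="\t", index=False)


def read_variants_tsv(path: str | Path) -> list[VariantRecord]:
    df = pd.read_csv(path, sep="\t", comment="#")
    freq_cols = [c for c in df.columns if c.startswith("freq_")]
    zyg_cols = [c for c in df.columns if c.startswith("zyg_")]
    out = []
    for _, row in df.iterrows():
        out.append(
            VariantRecord(
                chrom=str(row["chrom"]),
                pos=int(row["pos"]),
                ref=str(row["ref"]),
                alt=str(row["alt"]),
                gene=str(row["gene"]),
                consequence=str(row["consequence"]),
                splice_distance_bp=None if pd.isna(row["splice_distance_bp"]) else int(row["splice_distance_bp"]),
                in_disease_db=bool(row["in_disease_db"]),
                quality_pass=bool(row["quality_pass"]),
                panel_freqs={c[5:]: float(row[c]) for c in freq_cols},
                zygosity_by_sample={c[4:]: Zygosity(row[c]) for c in zyg_cols},
            )
        )
    return out


def write_rpkm_tsv(m: RpkmMatrix, path: str | Path) -> None:
    with open(path, "w") as fh:
        fh.write(f"# {FORMAT_VERSION}\n")
        df = pd.DataFrame(m.values, columns=m.samples)
        meta = pd.DataFrame(
            {
                "gene": [e.gene for e in m.exons],
                "exon_index": [e.exon_index for e in m.exons],
                "chrom": [e.interval.chrom for e in m.exons],
                "start": [e.interval.start for e in m.exons],
                "end": [e.interval.end for e in m.exons],
            }
        )
        pd.concat([meta, df], axis=1).to_csv(fh, sep="\t", index=False, float_format="%.6g")


def read_rpkm_tsv(path: str | Path) -> RpkmMatrix:
    df = pd.read_csv(path, sep="\t", comment="#")
    meta_cols = ["gene", "exon_index", "chrom", "start", "end"]
    samples = [c for c in df.columns if c not in meta_cols]
    exons = [
        ExonDef(
            str(r.gene), int(r.exon_index), GenomicInterval(str(r.chrom), int(r.start), int(r.end))
        )
        for r in df.itertuples()
    ]
    return RpkmMatrix(exons, samples, df[samples].to_numpy(dtype=float))


def write_deletion_calls_tsv(calls: Sequence[DeletionCall], path: str | Path) -> None:
    with open(path, "w") as fh:
        fh.write(f"# {FORMAT_VERSION}\n")
        pd.DataFrame(
            {
                "sample": [c.sample for c in calls],
                "chrom": [c.interval.chrom for c in calls],
                "start": [c.interval.start for c in calls],
                "end": [c.interval.end for c in calls],
                "gene": [c.gene for c in calls],
                "n_exons": [c.n_exons for c in calls],
                "cohort_freq": [c.cohort_freq for c in calls],
            }
        ).to_csv(fh, sep="\t", index=False, float_format="%.6g")


def write_lod_tsv(curve: LodCurve, path: str | Path) -> None:
    with open(path, "w") as fh:
        fh.write(f"# {FORMAT_VERSION}\n")
        fh.write("theta\tlod\n")
        for t, l in zip(curve.theta_grid, curve.lod):
            fh.write(f"{t}\t{l:.6g}\n")


def write_snp_matrix_tsv(m: SnpGenotypeMatrix, path: str | Path) -> None:
    with open(path, "w") as fh:
        fh.write(f"# {FORMAT_VERSION}\n")
        m.to_frame().to_csv(fh, sep="\t", index=False)


def read_snp_matrix_tsv(path: str | Path) -> SnpGenotypeMatrix:
    df = pd.read_csv(path, sep="\t", comment="#")
    samples = [c for c in df.columns if c not in ("snp", "chrom", "pos")]
    chroms = df["chrom"].unique()
    if len(chroms) != 1:
        raise ValueError("SNP genotype matrix must cover one chromosome")
    return SnpGenotypeMatrix(
        chrom=str(chroms[0]),
        snp_ids=[str(s) for s in df["snp"]],
        positions=df["pos"].to_numpy(),
        samples=samples,
        genotypes=df[samples].to_numpy(dtype=np.int8),
    )


def write_json_report(obj: Mapping, path: str | Path) -> None:
    Path(path).write_text(json.dumps(obj, indent=2, sort_keys=True) + "\n")
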