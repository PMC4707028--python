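"""Two-stage rare homozygous variant filtering for recessive traits.

The funnel keeps variants that are high quality, of a potentially deleterious
consequence class, and rare (stricter frequency bound when the variant is a
known disease-database entry); stage 1 then retains variants homozygous in
every affected individual and not homozygous in any healthy parent, and
stage 2 rescues capture-platform dropouts by retaining variants inside the
linked region homozygous in at least one complete affected group.  A
compound-heterozygote scan covers the alternative recessive architecture.
"""
from __future__ import annotations

from dataclasses import dataclass, field
from typing import Iterable, Sequence

from .aoh import Zygosity
from .intervals import GenomicInterval
from .pedigree import Pedigree

DELETERIOUS_CLASSES = {"missense", "nonsense", "stop_loss", "indel", "splice_region"}
SPLICE_WINDOW_BP = 5
RARE_FREQ = 0.01
RARE_FREQ_IN_DB = 0.05


class DataError(ValueError):
    """A sample referenced by the design is missing from the variant data."""


@dataclass
class VariantRecord:
    chrom: str
    pos: int
    ref: str
    alt: str
    gene: str
    consequence: str  # missense, nonsense, stop_loss, indel, splice_region, other
    panel_freqs: dict[str, float] = field(default_factory=dict)
    in_disease_db: bool = False
    quality_pass: bool = True
    splice_distance_bp: int | None = None
    zygosity_by_sample: dict[str, Zygosity] = field(default_factory=dict)

    def __post_init__(self) -> None:
        for panel, freq in self.panel_freqs.items():
            if not 0.0 <= freq <= 1.0:
                raise ValueError(f"panel {panel} frequency {freq} outside [0, 1]")

    def zygosity(self, sample: str) -> Zygosity:
        try:
            return self.zygosity_by_sample[sample]
        except KeyError as exc:
            raise DataError(
                f"sample {sample!r} missing from variant {self.chrom}:{self.pos}"
            ) from exc


@dataclass(frozen=True)
class FamilyDesign:
    """Affected sample groups (one per family arm) and the healthy parents."""

    affected_groups: tuple[tuple[str, ...], ...]
    parents: tuple[str, ...]

    def __post_init__(self) -> None:
        flat = [s for grp in self.affected_groups for s in grp]
        if set(flat) & set(self.parents):
            raise ValueError("affected groups and parents must be disjoint")

    @property
    def all_affected(self) -> tuple[str, ...]:
        return tuple(s for grp in self.affected_groups for s in grp)


def is_deleterious_class(v: VariantRecord) -> bool:
    """Potentially deleterious consequence: missense, nonsense, stop loss,
    indel, or a splice-region variant within +/-5 bp of an exon."""
    if v.consequence not in DELETERIOUS_CLASSES:
        return False
    if v.consequence == "splice_region":
        return v.splice_distance_bp is not None and abs(v.splice_distance_bp) <= SPLICE_WINDOW_BP
    return True


def is_rare(v: VariantRecord) -> bool:
    """Rarity rule: max panel frequency < 1% if not a known disease-database
    variant, < 5% if it is (absent panels count as frequency 0)."""
    max_freq = max(v.panel_freqs.values(), default=0.0)
    limit = RARE_FREQ_IN_DB if v.in_disease_db else RARE_FREQ
    return max_freq < limit


def passes_basic_filters(v: VariantRecord) -> bool:
    return v.quality_pass and is_deleterious_class(v) and is_rare(v)


def apply_basic_filters(variants: Iterable[VariantRecord]) -> list[VariantRecord]:
    return [v for v in variants if passes_basic_filters(v)]


def stage1_shared_homozygous(
    variants: Iterable[VariantRecord], design: FamilyDesign
) -> list[VariantRecord]:
    """Variants homozygous-alt in every affected (all groups) and not
    homozygous-alt in any healthy parent."""
    out = []
    for v in variants:
        if all(v.zygosity(s) == Zygosity.HOM_ALT for s in design.all_affected) and not any(
            v.zygosity(p) == Zygosity.HOM_ALT for p in design.parents
        ):
            out.append(v)
    return out


def stage2_region_union(
    variants: Iterable[VariantRecord],
    design: FamilyDesign,
    region: GenomicInterval,
) -> list[VariantRecord]:
    """Variants inside the linked region homozygous-alt in every member of at
    least one affected group (rescues platform dropouts in the other arm)."""
    if not design.affected_groups or not all(design.affected_groups):
        raise ValueError("design needs at least one non-empty affected group")
    out = []
    for v in variants:
        if not region.contains(v.chrom, v.pos):
            continue
        if any(
            all(v.zygosity(s) == Zygosity.HOM_ALT for s in grp)
            for grp in design.affected_groups
        ):
            out.append(v)
    return out


def _parental_origin(
    v: VariantRecord, child: str, ped: Pedigree
) -> str | None:
    """Which parent transmitted a heterozygous variant to ``child``.

    Trio inference: the transmitting parent must carry the allele and the
    other parent must be homozygous reference; anything else is ambiguous.
    """
    ind = ped[child]
    if ind.is_founder:
        return None
    carrier = {Zygosity.HET, Zygosity.HOM_ALT}
    f = v.zygosity_by_sample.get(ind.father, Zygosity.NO_CALL)
    m = v.zygosity_by_sample.get(ind.mother, Zygosity.NO_CALL)
    if f in carrier and m == Zygosity.HOM_REF:
        return "paternal"
    if m in carrier and f == Zygosity.HOM_REF:
        return "maternal"
    return None


def compound_het_scan(
    variants: Iterable[VariantRecord],
    design: FamilyDesign,
    ped: Pedigree,
) -> list[tuple[str, VariantRecord, VariantRecord]]:
    """Candidate compound-heterozygote pairs.

    Pairs of rare, deleterious, quality-passing variants in the same gene that
    are heterozygous in every affected individual, with trio-inferred parental
    origins that are opposite in every affected.  Pairs with an ambiguous
    origin in any affected are excluded (conservative).
    """
    affected = design.all_affected
    candidates = [
        v
        for v in apply_basic_filters(variants)
        if all(v.zygosity(s) == Zygosity.HET for s in affected)
    ]
    by_gene: dict[str, list[VariantRecord]] = {}
    for v in candidates:
        by_gene.setdefault(v.gene, []).append(v)
    pairs: list[tuple[str, VariantRecord, VariantRecord]] = []
    for gene, vs in sorted(by_gene.items()):
        for i in range(len(vs)):
            for j in range(i + 1, len(vs)):
                ok = True
                for child in affected:
                    o1 = _parental_origin(vs[i], child, ped)
                    o2 = _parental_origin(vs[j], child, ped)
                    if o1 is None or o2 is None or o1 == o2:
                        ok = False
                        break
                if ok:
                    pairs.append((gene, vs[i], vs[j]))
    return pairs
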