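"""Deterministic annotation arithmetic: HGVS coding coordinates, frameshift
nomenclature, Hardy-Weinberg homozygote frequency and locus-size reporting.

Coding (c.) positions count from the first base of the start codon, so codon
number is ``ceil(pos / 3)``; a frameshift descriptor ``fs*N`` appends ``N - 1``
non-native residues before the premature stop; and under Hardy-Weinberg
equilibrium a recessive genotype with allele frequency q occurs at q^2,
i.e. roughly "1 in 1/q^2" births.
"""
from __future__ import annotations

import math
import re
from dataclasses import dataclass

from .intervals import GenomicInterval


@dataclass(frozen=True)
class HgvsCoding:
    """A coding-sequence change: substitution or single-base deletion."""

    cdna_pos: int
    edit: str  # "sub" or "del"
    ref: str | None = None
    alt: str | None = None

    def __post_init__(self) -> None:
        if self.cdna_pos < 1:
            raise ValueError("cDNA position must be >= 1")


@dataclass(frozen=True)
class HgvsProteinFs:
    """Frameshift protein descriptor p.Xxx<pos>Yyyfs*<ter>."""

    first_changed_residue: int
    ter_position_in_new_frame: int

    def __post_init__(self) -> None:
        if self.ter_position_in_new_frame < 2:
            raise ValueError("fs* termination position must be >= 2")


def cdna_to_codon(cdna_pos: int) -> int:
    """Codon (amino-acid) number containing a coding position: ceil(pos/3)."""
    if cdna_pos < 1:
        raise ValueError("cDNA position must be >= 1")
    return math.ceil(cdna_pos / 3)


def frameshift_tail_length(p: HgvsProteinFs) -> int:
    """Number of aberrant residues added before the new-frame stop (ter - 1)."""
    return p.ter_position_in_new_frame - 1


def hw_homozygote_freq(q: float) -> tuple[float, int | None]:
    """Hardy-Weinberg homozygote frequency q^2 and the "1 in N million" figure.

    Returns ``(q**2, round(1 / q**2 / 1e6))``; the reciprocal is ``None`` for
    q = 0.  The rounding of the reciprocal is to the nearest million.
    """
    if not 0.0 <= q <= 1.0:
        raise ValueError("allele frequency must be in [0, 1]")
    q2 = q * q
    if q == 0.0:
        return 0.0, None
    return q2, round(1.0 / q2 / 1e6)


def sum_allele_frequencies(freqs: list[float]) -> float:
    """Total allele frequency of a set of variants (sum, clipped at 1)."""
    for f in freqs:
        if not 0.0 <= f <= 1.0:
            raise ValueError("allele frequencies must be in [0, 1]")
    return min(1.0, float(sum(freqs)))


def interval_length_mb(interval: GenomicInterval) -> float:
    """Interval length in Mb, half-up rounded to one decimal (end - start)."""
    mb10 = interval.length_bp / 1e5
    return math.floor(mb10 + 0.5) / 10.0


_C_SUB = re.compile(r"^c\.(?:([ACGT])(\d+)([ACGT])|(\d+)([ACGT])>([ACGT]))$")
_C_DEL = re.compile(r"^c\.(\d+)del([ACGT]?)$")
_P_FS = re.compile(r"^p\.[A-Z][a-z]{2}(\d+)[A-Z][a-z]{2}fs\*(\d+)$")


def parse_hgvs(text: str) -> HgvsCoding | HgvsProteinFs:
    """Parse the small HGVS-like dialect used in reports.

    Accepts substitutions as ``c.T38G`` or ``c.38T>G``, single-base deletions
    as ``c.665delC``, and frameshift protein descriptors like
    ``p.Ala222Valfs*221``.
    """
    m = _C_SUB.match(text)
    if m:
        if m.group(2) is not None:
            return HgvsCoding(int(m.group(2)), "sub", ref=m.group(1), alt=m.group(3))
        return HgvsCoding(int(m.group(4)), "sub", ref=m.group(5), alt=m.group(6))
    m = _C_DEL.match(text)
    if m:
        return HgvsCoding(int(m.group(1)), "del", ref=m.group(2) or None)
    m = _P_FS.match(text)
    if m:
        return HgvsProteinFs(int(m.group(1)), int(m.group(2)))
    raise ValueError(f"unrecognised HGVS-like descriptor: {text!r}")


def describe(text: str) -> dict:
    """Annotation report for one descriptor (used by the CLI)."""
    parsed = parse_hgvs(text)
    if isinstance(parsed, HgvsCoding):
        return {
            "input": text,
            "kind": "coding",
            "cdna_pos": parsed.cdna_pos,
            "edit": parsed.edit,
            "codon": cdna_to_codon(parsed.cdna_pos),
        }
    return {
        "input": text,
        "kind": "protein_frameshift",
        "first_changed_residue": parsed.first_changed_residue,
        "ter_position_in_new_frame": parsed.ter_position_in_new_frame,
        "aberrant_residues": frameshift_tail_length(parsed),
    }
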