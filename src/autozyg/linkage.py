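"""Two-point LOD scores on consanguineous pedigrees under a fully penetrant
recessive model.

The likelihood of marker genotypes and affection phenotypes is computed by
Elston-Stewart peeling: a sum-product elimination over each individual's
two-locus genotype (disease locus x marker, with phase carried by ordered
haplotype pairs), with founder genotypes at Hardy-Weinberg/linkage-equilibrium
priors and transmission mixing haplotypes at recombination fraction theta.
Consanguineous loops are broken by duplicating one individual per loop and
summing over the genotype shared by the duplicate copies.  All bookkeeping is
scaled, so deep pedigrees do not underflow.

The two-point LOD at theta is log10 L(theta) - log10 L(0.5).
"""
from __future__ import annotations

import math
from dataclasses import dataclass, field
from typing import Mapping, Sequence

import numpy as np

from .aoh import Zygosity
from .pedigree import Pedigree, break_loops

N_HAP = 4  # haplotype = (disease bit, marker bit); index = 2*d + m
N_GENO = 16  # ordered pair (paternal haplotype, maternal haplotype)

_HP = np.arange(N_GENO) // N_HAP
_HM = np.arange(N_GENO) % N_HAP
_D_COUNT = (_HP // 2) + (_HM // 2)  # copies of the disease allele
_MARKER_SUM = (_HP % 2) + (_HM % 2)  # 0='11', 1='12', 2='22'

DEFAULT_THETA_GRID = (0.0, 0.01, 0.05, 0.1, 0.2, 0.3, 0.4, 0.5)

_MARKER_CODE = {"11": 0, "12": 1, "21": 1, "22": 2, 0: 0, 1: 1, 2: 2}


@dataclass(frozen=True)
class DiseaseModel:
    """Penetrances P(affected | AA, Aa, aa) and the disease allele frequency.

    The fully penetrant recessive, no-phenocopy model is (0, 0, 1).
    """

    penetrances: tuple[float, float, float] = (0.0, 0.0, 1.0)
    disease_allele_freq: float = 0.05

    def __post_init__(self) -> None:
        if not all(0.0 <= p <= 1.0 for p in self.penetrances):
            raise ValueError("penetrances must be in [0, 1]")
        if not 0.0 < self.disease_allele_freq < 1.0:
            raise ValueError("disease allele frequency must be in (0, 1)")


@dataclass
class LodCurve:
    theta_grid: list[float]
    lod: list[float]
    max_lod: float = field(init=False)
    argmax_theta: float = field(init=False)

    def __post_init__(self) -> None:
        finite = [(l, t) for t, l in zip(self.theta_grid, self.lod) if math.isfinite(l)]
        if not finite:
            self.max_lod, self.argmax_theta = float("-inf"), 0.5
        else:
            self.max_lod, self.argmax_theta = max(finite)


def _gamete_probs(theta: float) -> np.ndarray:
    """(16, 4) matrix: P(gamete haplotype | parent ordered genotype, theta)."""
    g = np.zeros((N_GENO, N_HAP))
    for geno in range(N_GENO):
        hp, hm = geno // N_HAP, geno % N_HAP
        dp, mp = hp // 2, hp % 2
        dm, mm = hm // 2, hm % 2
        for d_src, m_src, prob in (
            (dp, mp, 0.5 * (1 - theta)),
            (dp, mm, 0.5 * theta),
            (dm, mm, 0.5 * (1 - theta)),
            (dm, mp, 0.5 * theta),
        ):
            g[geno, 2 * d_src + m_src] += prob
    return g


def _transmission(theta: float) -> np.ndarray:
    """T[g_father, g_mother, g_child] transmission probabilities."""
    g = _gamete_probs(theta)
    # child ordered genotype = (hap from father, hap from mother)
    t = g[:, _HP][:, None, :] * g[:, _HM][None, :, :]
    return t


def _founder_prior(model: DiseaseModel, marker_allele_freq: float) -> np.ndarray:
    if not 0.0 < marker_allele_freq < 1.0:
        raise ValueError("marker allele frequency must be in (0, 1)")
    fd = np.array([1 - model.disease_allele_freq, model.disease_allele_freq])
    fm = np.array([1 - marker_allele_freq, marker_allele_freq])
    hap = np.array([fd[h // 2] * fm[h % 2] for h in range(N_HAP)])
    return hap[_HP] * hap[_HM]


def _data_factor(
    affected: bool | None, marker_geno, model: DiseaseModel
) -> np.ndarray:
    pen = np.array(model.penetrances)[_D_COUNT]
    if affected is True:
        vec = pen.copy()
    elif affected is False:
        vec = 1.0 - pen
    else:
        vec = np.ones(N_GENO)
    if marker_geno is not None:
        code = _MARKER_CODE[marker_geno]
        vec = vec * (_MARKER_SUM == code)
    return vec


# ---------------------------------------------------------------------------
# sum-product elimination engine (scaled, log10 bookkeeping)
# ---------------------------------------------------------------------------


class _Factor:
    __slots__ = ("vars", "arr")

    def __init__(self, vars: tuple[str, ...], arr: np.ndarray):
        self.vars = vars
        self.arr = arr


def _product(f1: _Factor, f2: _Factor) -> _Factor:
    union = list(f1.vars) + [v for v in f2.vars if v not in f1.vars]

    def expand(f: _Factor) -> np.ndarray:
        shape = [N_GENO if v in f.vars else 1 for v in union]
        perm = [f.vars.index(v) for v in union if v in f.vars]
        return np.transpose(f.arr, perm).reshape(shape)

    return _Factor(tuple(union), expand(f1) * expand(f2))


def _eliminate_all(factors: list[_Factor]) -> float:
    """Sum out every variable; returns log10 of the total, -inf if zero."""
    log10_scale = 0.0
    factors = list(factors)
    variables = sorted({v for f in factors for v in f.vars})
    while variables:
        # greedy min-fill-ish: eliminate the variable with the smallest
        # resulting clique
        best_var, best_size = None, None
        for v in variables:
            touching = [f for f in factors if v in f.vars]
            size = len({u for f in touching for u in f.vars})
            if best_size is None or size < best_size or (size == best_size and v < best_var):
                best_var, best_size = v, size
        touching = [f for f in factors if best_var in f.vars]
        rest = [f for f in factors if best_var not in f.vars]
        combined = touching[0]
        for f in touching[1:]:
            combined = _product(combined, f)
        axis = combined.vars.index(best_var)
        arr = combined.arr.sum(axis=axis)
        new_vars = tuple(v for v in combined.vars if v != best_var)
        mx = float(arr.max()) if arr.size else 0.0
        if mx <= 0.0:
            return float("-inf")
        arr = arr / mx
        log10_scale += math.log10(mx)
        rest.append(_Factor(new_vars, arr))
        factors = rest
        variables.remove(best_var)
    total = 1.0
    for f in factors:
        total *= float(f.arr)
    if total <= 0.0:
        return float("-inf")
    return math.log10(total) + log10_scale


def _log10_sum(values: Sequence[float]) -> float:
    finite = [v for v in values if v != float("-inf")]
    if not finite:
        return float("-inf")
    m = max(finite)
    return m + math.log10(sum(10 ** (v - m) for v in finite))


def _normalise_marker_genotypes(marker_genotypes: Mapping) -> dict:
    geno = {}
    for iid, g in marker_genotypes.items():
        if g is None:
            continue
        if isinstance(g, Zygosity):
            if g == Zygosity.NO_CALL:
                continue
            g = {Zygosity.HOM_REF: 0, Zygosity.HET: 1, Zygosity.HOM_ALT: 2}[g]
        geno[iid] = _MARKER_CODE[g]
    return geno


def pedigree_likelihood(
    ped: Pedigree,
    marker_genotypes: Mapping,
    model: DiseaseModel,
    marker_allele_freq: float,
    theta: float,
) -> float:
    """log10 likelihood of phenotypes and marker genotypes at recombination
    fraction ``theta``.

    Marker genotypes map individual id -> '11' | '12' | '22' (or 0/1/2 counts
    of the rarer allele, or a :class:`Zygosity`); untyped individuals are
    summed over.  Monozygotic twin pairs are collapsed to a single individual
    and consanguineous loops broken before peeling.  Data impossible under the
    model yield ``-inf`` (not an exception).
    """
    if not 0.0 <= theta <= 0.5:
        raise ValueError("theta must be in [0, 0.5]")
    ped = ped.collapse_mz_twins()
    geno = _normalise_marker_genotypes(marker_genotypes)
    broken, bindings = break_loops(ped)

    trans = _transmission(theta)
    prior = _founder_prior(model, marker_allele_freq)
    duplicates = {dup for _, dup in bindings}

    base_factors: list[_Factor] = []
    data: dict[str, np.ndarray] = {}
    for ind in broken:
        data[ind.iid] = _data_factor(ind.affected, geno.get(ind.iid), model)
        if ind.is_founder:
            if ind.iid not in duplicates:
                base_factors.append(_Factor((ind.iid,), prior.copy()))
        else:
            base_factors.append(
                _Factor((ind.father, ind.mother, ind.iid), trans.copy())
            )
        if ind.iid not in duplicates:
            base_factors.append(_Factor((ind.iid,), data[ind.iid]))

    if not bindings:
        return _eliminate_all(base_factors)

    # sum over the genotype shared by each (original, duplicate) pair;
    # restrict to genotypes compatible with the original's own data
    allowed = [np.nonzero(data[orig] > 0)[0] for orig, _ in bindings]
    combos: list[list[int]] = [[]]
    for opts in allowed:
        combos = [c + [int(o)] for c in combos for o in opts]
    parts = []
    for combo in combos:
        clamped = list(base_factors)
        for (orig, dup), state in zip(bindings, combo):
            ind = np.zeros(N_GENO)
            ind[state] = 1.0
            clamped.append(_Factor((orig,), ind))
            clamped.append(_Factor((dup,), ind.copy()))
        parts.append(_eliminate_all(clamped))
    return _log10_sum(parts)


def two_point_lod(
    ped: Pedigree,
    marker_genotypes: Mapping,
    model: DiseaseModel,
    marker_allele_freq: float,
    theta_grid: Sequence[float] = DEFAULT_THETA_GRID,
) -> LodCurve:
    """Two-point LOD curve: lod(theta) = log10 L(theta) - log10 L(0.5)."""
    grid = list(theta_grid)
    if 0.5 not in grid:
        raise ValueError("theta grid must include 0.5 (the no-linkage reference)")
    loglik = {
        t: pedigree_likelihood(ped, marker_genotypes, model, marker_allele_freq, t)
        for t in grid
    }
    ref = loglik[0.5]
    if ref == float("-inf"):
        raise ValueError("data impossible even without linkage; check genotypes")
    lod = [loglik[t] - ref if loglik[t] != float("-inf") else float("-inf") for t in grid]
    return LodCurve(theta_grid=grid, lod=lod)


# ---------------------------------------------------------------------------
# cosegregation
# ---------------------------------------------------------------------------


@dataclass
class CosegregationResult:
    """Per-class genotype/phenotype consistency under a recessive model."""

    n_affected: int
    n_affected_hom: int
    n_carriers: int
    n_carriers_het: int
    n_others: int
    n_others_ok: int
    inconsistencies: list[tuple[str, str]]

    @property
    def n_inconsistent(self) -> int:
        return len(self.inconsistencies)

    def summary(self) -> str:
        return (
            f"homozygous in {self.n_affected_hom} of {self.n_affected} affected; "
            f"heterozygous in {self.n_carriers_het} of {self.n_carriers} obligate carriers; "
            f"heterozygous or absent in {self.n_others_ok} of {self.n_others} others"
        )


def cosegregation_check(
    ped: Pedigree, zygosity_by_sample: Mapping[str, Zygosity]
) -> CosegregationResult:
    """Classify every genotyped individual and flag recessive-model violations.

    Affected individuals must be homozygous for the variant, obligate carriers
    (unaffected parents of an affected) heterozygous, and all remaining family
    members heterozygous or homozygous reference.  Monozygotic twin pairs are
    collapsed first so a pair counts as one individual.
    """
    ped = ped.collapse_mz_twins()
    carriers = set(ped.obligate_carriers)
    res = CosegregationResult(0, 0, 0, 0, 0, 0, [])
    for ind in ped:
        z = zygosity_by_sample.get(ind.iid)
        if z is None or z == Zygosity.NO_CALL:
            continue
        if ind.affected is True:
            res.n_affected += 1
            if z == Zygosity.HOM_ALT:
                res.n_affected_hom += 1
            else:
                res.inconsistencies.append((ind.iid, "affected not homozygous"))
        elif ind.iid in carriers:
            res.n_carriers += 1
            if z == Zygosity.HET:
                res.n_carriers_het += 1
            else:
                res.inconsistencies.append((ind.iid, "obligate carrier not heterozygous"))
        else:
            res.n_others += 1
            if z in (Zygosity.HET, Zygosity.HOM_REF):
                res.n_others_ok += 1
            else:
                res.inconsistencies.append((ind.iid, "unaffected homozygote"))
    return res
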