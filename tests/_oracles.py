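"""Independent oracles used by the test suite.

The likelihood oracle enumerates every two-locus genotype assignment over the
pedigree by depth-first search (no peeling, no loop breaking), so it is valid
on looped pedigrees directly and serves as the ground truth for the peeling
engine.  Interval oracles work on explicit position bitmaps.
"""
from __future__ import annotations

import math

import numpy as np

from autozyg.pedigree import Individual, Pedigree

# haplotype index = 2*d + m with d = disease allele present, m = rarer marker allele
_HAPS = [(d, m) for d in (0, 1) for m in (0, 1)]


def _gamete_table(theta: float) -> list[dict[int, float]]:
    """For each ordered parent genotype (hp, hm): P(gamete haplotype).

    Enumerates the four meiosis outcomes explicitly: the disease allele and
    the marker allele each come from one parental haplotype; same haplotype
    with probability (1 - theta)/2 each, recombinant with theta/2 each.
    """
    out = []
    for hp in range(4):
        for hm in range(4):
            probs: dict[int, float] = {}
            for (d_src, m_src, p) in (
                (hp, hp, 0.5 * (1 - theta)),
                (hp, hm, 0.5 * theta),
                (hm, hm, 0.5 * (1 - theta)),
                (hm, hp, 0.5 * theta),
            ):
                g = 2 * (d_src // 2) + (m_src % 2)
                probs[g] = probs.get(g, 0.0) + p
            out.append(probs)
    return out


def brute_force_loglik10(
    ped: Pedigree,
    marker_genotypes: dict,
    penetrances: tuple[float, float, float],
    disease_freq: float,
    marker_freq: float,
    theta: float,
) -> float:
    """log10 likelihood by exhaustive enumeration (DFS with zero pruning)."""
    code = {"11": 0, "12": 1, "21": 1, "22": 2, 0: 0, 1: 1, 2: 2}
    geno = {k: code[v] for k, v in marker_genotypes.items() if v is not None}
    hapf = [
        (disease_freq if d else 1 - disease_freq) * (marker_freq if m else 1 - marker_freq)
        for d, m in _HAPS
    ]
    gam = _gamete_table(theta)

    members = list(ped)
    order = [i.iid for i in members]
    data = {}
    for ind in members:
        vec = []
        for g in range(16):
            hp, hm = g // 4, g % 4
            nd = hp // 2 + hm // 2
            p = 1.0
            if ind.affected is True:
                p *= penetrances[nd]
            elif ind.affected is False:
                p *= 1 - penetrances[nd]
            if ind.iid in geno and (hp % 2 + hm % 2) != geno[ind.iid]:
                p = 0.0
            vec.append(p)
        data[ind.iid] = vec

    assigned: dict[str, int] = {}
    total = 0.0

    def dfs(k: int, prob: float) -> None:
        nonlocal total
        if k == len(order):
            total += prob
            return
        iid = order[k]
        ind = ped[iid]
        for g in range(16):
            p = data[iid][g]
            if p == 0.0:
                continue
            if ind.is_founder:
                p *= hapf[g // 4] * hapf[g % 4]
            else:
                gf, gm = assigned[ind.father], assigned[ind.mother]
                p *= gam[gf].get(g // 4, 0.0) * gam[gm].get(g % 4, 0.0)
            if p == 0.0:
                continue
            assigned[iid] = g
            dfs(k + 1, prob * p)
        assigned.pop(iid, None)

    dfs(0, 1.0)
    return math.log10(total) if total > 0 else float("-inf")


def random_pedigree_with_data(
    rng: np.random.Generator,
    max_members: int = 8,
    loop_prob: float = 0.35,
) -> tuple[Pedigree, dict]:
    """Random small pedigree plus consistent marker/phenotype data.

    Structure: a founder couple with 2-3 children; children may marry in a
    founder and have children, or (with probability ``loop_prob``) two sibs
    mate, closing a consanguineous loop.  Alleles are dropped directly; the
    phenotype is the fully penetrant recessive one; most individuals are
    marker-typed.
    """
    while True:
        members = [
            Individual("F0", sex="male"),
            Individual("M0", sex="female"),
        ]
        n_kids = int(rng.integers(2, 4))
        kids = []
        for k in range(n_kids):
            iid = f"K{k}"
            members.append(Individual(iid, "F0", "M0"))
            kids.append(iid)
        if rng.random() < loop_prob and len(kids) >= 2:
            members.append(Individual("L0", kids[0], kids[1]))
            if len(members) < max_members and rng.random() < 0.5:
                members.append(Individual("L1", kids[0], kids[1]))
        else:
            members.append(Individual("S0", sex="female"))
            members.append(Individual("G0", kids[0], "S0"))
            if len(members) < max_members and rng.random() < 0.6:
                members.append(Individual("G1", kids[0], "S0"))
        if len(members) <= max_members:
            break

    # drop alleles: haplotype = (disease, marker)
    theta_gen = 0.2
    haps: dict[str, tuple[tuple[int, int], tuple[int, int]]] = {}
    by_id = {m.iid: m for m in members}
    for m in members:
        if m.father is None:
            haps[m.iid] = (
                (int(rng.random() < 0.25), int(rng.random() < 0.4)),
                (int(rng.random() < 0.25), int(rng.random() < 0.4)),
            )

    def gamete(iid: str) -> tuple[int, int]:
        h1, h2 = haps[iid]
        first = int(rng.random() < 0.5)
        d_src = (h1, h2)[first]
        m_src = d_src if rng.random() >= theta_gen else (h1, h2)[1 - first]
        return (d_src[0], m_src[1])

    for m in members:
        if m.father is not None and m.iid not in haps:
            haps[m.iid] = (gamete(m.father), gamete(m.mother))

    final = []
    genotypes = {}
    for m in members:
        h1, h2 = haps[m.iid]
        affected = h1[0] + h2[0] == 2
        final.append(
            Individual(m.iid, m.father, m.mother, m.sex, affected)
        )
        if rng.random() < 0.8:
            genotypes[m.iid] = {0: "11", 1: "12", 2: "22"}[h1[1] + h2[1]]
    return Pedigree(final), genotypes


def bitmap_interval_ops(
    universe: int,
    covers: list[list[tuple[int, int]]],
    minus: list[tuple[int, int]],
) -> list[tuple[int, int]]:
    """Interval intersection-minus-subtraction via an explicit position bitmap."""
    masks = []
    for cover in covers:
        mask = np.zeros(universe + 2, dtype=bool)
        for s, e in cover:
            mask[s : e + 1] = True
        masks.append(mask)
    acc = np.logical_and.reduce(masks) if masks else np.zeros(universe + 2, bool)
    for s, e in minus:
        acc[s : e + 1] = False
    out = []
    i = 1
    while i <= universe:
        if acc[i]:
            j = i
            while j <= universe and acc[j]:
                j += 1
            out.append((i, j - 1))
            i = j
        else:
            i += 1
    return out
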