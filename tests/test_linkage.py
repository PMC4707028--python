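"""Pedigree likelihood and two-point LOD: oracle agreement, closed forms,
factorisation at theta = 0.5 and cosegregation classification."""
import math

import numpy as np
import pytest

from _oracles import brute_force_loglik10, random_pedigree_with_data
from autozyg.aoh import Zygosity
from autozyg.linkage import (
    DiseaseModel,
    cosegregation_check,
    pedigree_likelihood,
    two_point_lod,
)
from autozyg.pedigree import Individual, Pedigree

MODEL = DiseaseModel(penetrances=(0.0, 0.0, 1.0), disease_allele_freq=0.1)


def phase_known_family(m_children: int, n_recombinant: int = 0):
    """Affected aa/11 parent x phase-known doubly heterozygous parent.

    The heterozygous parent's phase is fixed by its own parents (affected
    aa/22 x unaffected 11), so each affected child is one phase-known meiosis:
    marker '12' = non-recombinant, '11' = recombinant.
    """
    members = [
        Individual("gp1", sex="male", affected=True),
        Individual("gp2", sex="female", affected=False),
        Individual("B", "gp1", "gp2", affected=False),
        Individual("A", sex="male", affected=True),
    ]
    geno = {"gp1": "22", "gp2": "11", "B": "12", "A": "11"}
    for k in range(m_children):
        members.append(Individual(f"k{k}", "A", "B", affected=True))
        geno[f"k{k}"] = "11" if k < n_recombinant else "12"
    return Pedigree(members), geno


def test_peeling_matches_enumeration_oracle_on_random_pedigrees():
    rng = np.random.default_rng(2024)
    n_looped = 0
    for _ in range(40):
        ped, geno = random_pedigree_with_data(rng)
        n_looped += ped.n_loops > 0
        theta = float(rng.uniform(0.01, 0.5))
        freq = float(rng.uniform(0.1, 0.6))
        got = pedigree_likelihood(ped, geno, MODEL, freq, theta)
        want = brute_force_loglik10(
            ped, geno, MODEL.penetrances, MODEL.disease_allele_freq, freq, theta
        )
        assert got == pytest.approx(want, abs=1e-9)
    assert n_looped >= 5  # the loop-broken path is genuinely exercised


@pytest.mark.parametrize("m", range(1, 11))
def test_closed_form_lod_m_nonrecombinant_meioses(m):
    ped, geno = phase_known_family(m)
    curve = two_point_lod(ped, geno, DiseaseModel(), 0.1)
    assert curve.lod[0] == pytest.approx(m * math.log10(2), abs=1e-9)


def test_lod_is_zero_at_half_and_minus_inf_with_obligate_recombinant():
    ped, geno = phase_known_family(4, n_recombinant=1)
    curve = two_point_lod(ped, geno, DiseaseModel(), 0.1)
    assert curve.lod[-1] == 0.0
    assert curve.lod[0] == float("-inf")
    # continuous (finite) away from theta = 0
    assert all(math.isfinite(l) for l in curve.lod[1:])


def test_likelihood_independent_of_theta_when_marker_untyped(trio):
    vals = [pedigree_likelihood(trio, {}, MODEL, 0.3, t) for t in (0.0, 0.2, 0.5)]
    assert vals[0] == pytest.approx(vals[1], abs=1e-12)
    assert vals[0] == pytest.approx(vals[2], abs=1e-12)


def test_likelihood_factorises_at_theta_half():
    ped, geno = phase_known_family(3)
    joint = pedigree_likelihood(ped, geno, MODEL, 0.2, 0.5)
    marker_only = pedigree_likelihood(
        Pedigree([Individual(i.iid, i.father, i.mother, i.sex, None) for i in ped]),
        geno, MODEL, 0.2, 0.5,
    )
    disease_only = pedigree_likelihood(ped, {}, MODEL, 0.2, 0.5)
    assert joint == pytest.approx(marker_only + disease_only, abs=1e-9)


def test_impossible_data_gives_minus_inf_not_exception(trio):
    # affected child of typed 11 x 11 parents: under full penetrance and a
    # marker-independent disease this is fine, but an affected child whose
    # parents are typed hom for *different* marker alleles while the child is
    # also hom is Mendelian-impossible
    geno = {"F": "11", "M": "11", "K": "22"}
    val = pedigree_likelihood(trio, geno, MODEL, 0.3, 0.1)
    assert val == float("-inf")


def test_lod_nonincreasing_in_marker_frequency():
    # cosegregating rare marker on a fixed pedigree; one untyped parent makes
    # the marker frequency informative
    members = [
        Individual("A", sex="male", affected=True),
        Individual("B", sex="female", affected=False),
    ]
    geno = {"A": "11"}
    for k in range(3):
        members.append(Individual(f"k{k}", "A", "B", affected=True))
        geno[f"k{k}"] = "12"
    ped = Pedigree(members)
    lods = []
    for freq in (0.01, 0.05, 0.1, 0.2, 0.3, 0.4):
        lods.append(two_point_lod(ped, geno, DiseaseModel(), freq).lod[0])
    assert all(a >= b - 1e-12 for a, b in zip(lods, lods[1:]))


def test_mz_twins_counted_once():
    ped, geno = phase_known_family(2)
    twin_members = list(ped) + [Individual("k1b", "A", "B", affected=True)]
    twin_ped = Pedigree(twin_members, mz_twin_pairs=[("k1", "k1b")])
    geno_twins = dict(geno, k1b=geno["k1"])
    collapsed = two_point_lod(twin_ped, geno_twins, DiseaseModel(), 0.1)
    assert collapsed.lod[0] == pytest.approx(2 * math.log10(2), abs=1e-9)


# -- cosegregation ----------------------------------------------------------


def _coseg_pedigree(n_affected=17, n_couples=11, n_others=45):
    """Nuclear families: n_couples carrier couples, 17 affected children
    distributed among them, plus unaffected relatives."""
    members = []
    zyg = {}
    aff_left = n_affected
    for c in range(n_couples):
        f, m = f"F{c}", f"M{c}"
        members += [
            Individual(f, sex="male", affected=False),
            Individual(m, sex="female", affected=False),
        ]
        zyg[f] = zyg[m] = Zygosity.HET
        take = min(2 if aff_left > n_couples - c else 1, aff_left)
        for k in range(take):
            iid = f"A{c}_{k}"
            members.append(Individual(iid, f, m, affected=True))
            zyg[iid] = Zygosity.HOM_ALT
        aff_left -= take
    for k in range(n_others):
        iid = f"U{k}"
        members.append(Individual(iid, "F0", "M0", affected=False))
        zyg[iid] = Zygosity.HET if k % 2 else Zygosity.HOM_REF
    return Pedigree(members), zyg


def test_cosegregation_17_22_45_table_is_consistent():
    ped, zyg = _coseg_pedigree()
    res = cosegregation_check(ped, zyg)
    assert (res.n_affected, res.n_carriers, res.n_others) == (17, 22, 45)
    assert res.n_inconsistent == 0
    assert "17 of 17" in res.summary() and "22 of 22" in res.summary()


def test_one_unaffected_homozygote_flagged():
    ped, zyg = _coseg_pedigree()
    zyg["U3"] = Zygosity.HOM_ALT  # healthy homozygote pattern
    res = cosegregation_check(ped, zyg)
    assert res.n_inconsistent == 1
    assert res.inconsistencies[0][0] == "U3"


def test_affected_het_flagged():
    ped, zyg = _coseg_pedigree()
    zyg["A0_0"] = Zygosity.HET
    res = cosegregation_check(ped, zyg)
    assert ("A0_0", "affected not homozygous") in res.inconsistencies
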