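"""Pedigree graphs with consanguineous loops, twins and loop breaking.

A pedigree is a directed family graph: founders have no parents, every
non-founder has both parents present, and consanguineous unions close cycles
("loops") in the marriage graph.  Monozygotic twin pairs can be annotated and
collapsed to a single individual (as done when counting births in
cosegregation analyses), and loops can be broken for likelihood peeling by
duplicating one individual per loop; the duplicate is genotype-bound to its
original during likelihood summation.
"""
from __future__ import annotations

from dataclasses import dataclass, replace
from typing import Iterable, Sequence

import networkx as nx

MALE = "male"
FEMALE = "female"


class PedigreeError(ValueError):
    """Structural or reference error in a pedigree definition."""


@dataclass(frozen=True)
class Individual:
    iid: str
    father: str | None = None
    mother: str | None = None
    sex: str = "unknown"
    affected: bool | None = None

    def __post_init__(self) -> None:
        if (self.father is None) != (self.mother is None):
            raise PedigreeError(
                f"{self.iid}: a non-founder needs both parents, got "
                f"father={self.father!r} mother={self.mother!r}"
            )

    @property
    def is_founder(self) -> bool:
        return self.father is None


@dataclass(frozen=True)
class PedigreeSpec:
    """Declarative pedigree description consumed by :func:`build_pedigree`."""

    individuals: tuple[Individual, ...]
    mz_twin_pairs: tuple[tuple[str, str], ...] = ()


class Pedigree:
    """Validated family graph, stored in topological (parents-first) order."""

    def __init__(
        self,
        individuals: Iterable[Individual],
        mz_twin_pairs: Sequence[tuple[str, str]] = (),
    ) -> None:
        members = list(individuals)
        by_id: dict[str, Individual] = {}
        for ind in members:
            if ind.iid in by_id:
                raise PedigreeError(f"duplicate individual id {ind.iid!r}")
            by_id[ind.iid] = ind
        for ind in members:
            for parent in (ind.father, ind.mother):
                if parent is not None and parent not in by_id:
                    raise PedigreeError(
                        f"{ind.iid}: unknown parent id {parent!r}"
                    )
        graph = nx.DiGraph()
        graph.add_nodes_from(by_id)
        for ind in members:
            if not ind.is_founder:
                graph.add_edge(ind.father, ind.iid)
                graph.add_edge(ind.mother, ind.iid)
        try:
            order = list(nx.topological_sort(graph))
        except nx.NetworkXUnfeasible as exc:
            raise PedigreeError("cycle in ancestry graph") from exc
        # deterministic order: stable topological generations, then id
        depth = {iid: 0 for iid in by_id}
        for iid in order:
            ind = by_id[iid]
            if not ind.is_founder:
                depth[iid] = 1 + max(depth[ind.father], depth[ind.mother])
        self._members = {
            iid: by_id[iid] for iid in sorted(by_id, key=lambda i: (depth[i], i))
        }
        self._depth = depth
        self.mz_twin_pairs = tuple(tuple(p) for p in mz_twin_pairs)
        for a, b in self.mz_twin_pairs:
            ia, ib = self[a], self[b]
            if (ia.father, ia.mother) != (ib.father, ib.mother):
                raise PedigreeError(f"MZ twins {a}/{b} have different parents")

    # -- basic access -----------------------------------------------------
    def __getitem__(self, iid: str) -> Individual:
        try:
            return self._members[iid]
        except KeyError as exc:
            raise PedigreeError(f"unknown individual id {iid!r}") from exc

    def __contains__(self, iid: str) -> bool:
        return iid in self._members

    def __iter__(self):
        return iter(self._members.values())

    def __len__(self) -> int:
        return len(self._members)

    @property
    def ids(self) -> list[str]:
        return list(self._members)

    @property
    def founders(self) -> list[Individual]:
        return [i for i in self if i.is_founder]

    @property
    def nonfounders(self) -> list[Individual]:
        return [i for i in self if not i.is_founder]

    @property
    def affecteds(self) -> list[str]:
        return [i.iid for i in self if i.affected is True]

    def depth(self, iid: str) -> int:
        return self._depth[iid]

    def children_of(self, iid: str) -> list[str]:
        return [i.iid for i in self if iid in (i.father, i.mother)]

    @property
    def obligate_carriers(self) -> list[str]:
        """Unaffected parents of affected individuals (recessive model)."""
        out: list[str] = []
        for ind in self:
            if ind.affected is True and not ind.is_founder:
                for parent in (ind.father, ind.mother):
                    if self[parent].affected is not True and parent not in out:
                        out.append(parent)
        return sorted(out)

    # -- marriage graph and loops -----------------------------------------
    def marriage_graph(self) -> nx.Graph:
        """Bipartite graph of individual nodes and union (mating) nodes."""
        g = nx.Graph()
        for ind in self:
            g.add_node(("i", ind.iid))
        for ind in self.nonfounders:
            union = ("u", (ind.father, ind.mother))
            g.add_edge(("i", ind.father), union)
            g.add_edge(("i", ind.mother), union)
            g.add_edge(union, ("i", ind.iid))
        return g

    @property
    def n_loops(self) -> int:
        """Number of independent cycles (consanguineous loops) in the marriage graph."""
        g = self.marriage_graph()
        return len(nx.cycle_basis(g))

    # -- transforms --------------------------------------------------------
    def collapse_mz_twins(self) -> "Pedigree":
        """Collapse each MZ twin pair to a single individual.

        The first twin of each pair is kept; children of the dropped twin are
        re-attached to the kept one, so one monozygotic pair counts as a
        single birth/individual.
        """
        if not self.mz_twin_pairs:
            return self
        keep_for = {}
        for a, b in self.mz_twin_pairs:
            keep_for[b] = a
        members = []
        for ind in self:
            if ind.iid in keep_for:
                continue
            father = keep_for.get(ind.father, ind.father)
            mother = keep_for.get(ind.mother, ind.mother)
            members.append(replace(ind, father=father, mother=mother))
        return Pedigree(members)


def build_pedigree(spec: PedigreeSpec) -> Pedigree:
    """Validate a :class:`PedigreeSpec` and return the pedigree graph.

    The input order is irrelevant: members are topologically sorted, ancestry
    cycles raise a structural :class:`PedigreeError` and dangling parent ids a
    reference error.
    """
    return Pedigree(spec.individuals, spec.mz_twin_pairs)


def break_loops(ped: Pedigree) -> tuple[Pedigree, list[tuple[str, str]]]:
    """Break consanguineous loops by duplicating one individual per loop.

    Returns the loop-free pedigree and ``(original, duplicate)`` bindings.
    The duplicated copy takes over the original's spouse/children roles and
    becomes parentless; during likelihood evaluation both copies must be
    constrained to the same genotype.  The split individual is the youngest
    (deepest) splittable member of the loop, ties broken by id.
    """
    members = {i.iid: i for i in ped}
    bindings: list[tuple[str, str]] = []

    def current() -> Pedigree:
        return Pedigree(members.values())

    for _ in range(100):
        ped_now = current()
        cycles = nx.cycle_basis(ped_now.marriage_graph())
        if not cycles:
            break
        cycle_ids = [n[1] for n in cycles[0] if n[0] == "i"]
        candidates = [
            iid
            for iid in cycle_ids
            if not members[iid].is_founder and ped_now.children_of(iid)
        ]
        candidates.sort(key=lambda iid: (-ped_now.depth(iid), iid))
        done = False
        for orig in candidates:
            dup = f"{orig}*"
            trial = dict(members)
            trial[dup] = replace(
                members[orig], iid=dup, father=None, mother=None, affected=None
            )
            for iid, ind in list(trial.items()):
                if iid == dup:
                    continue
                father = dup if ind.father == orig else ind.father
                mother = dup if ind.mother == orig else ind.mother
                if (father, mother) != (ind.father, ind.mother):
                    trial[iid] = replace(ind, father=father, mother=mother)
            n_after = len(nx.cycle_basis(Pedigree(trial.values()).marriage_graph()))
            if n_after < len(cycles):
                members = trial
                bindings.append((orig, dup))
                done = True
                break
        if not done:  # pragma: no cover - guarded by pedigree validation
            raise PedigreeError("could not break a consanguineous loop")
    else:  # pragma: no cover
        raise PedigreeError("loop breaking did not terminate")
    return current(), bindings
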