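"""Core data model for weighted mutually exclusive maximum set cover instances.

An instance is a universe of opaque element IDs, an ordered family of
weighted sets over that universe, and the intersection graph induced by
nonempty pairwise overlaps.  Solutions are pairwise-disjoint subfamilies
ranked first by number of covered elements (more is better) and then by
total weight (less is better).
"""

from __future__ import annotations

from dataclasses import dataclass, field
from typing import Dict, FrozenSet, Iterable, List, Mapping, Sequence, Tuple

__all__ = [
    "ValidationError",
    "WeightedSet",
    "CoverInstance",
    "IntersectionGraph",
    "CoverSolution",
    "SearchStats",
    "normalize_instance",
    "build_intersection_graph",
    "connected_components",
    "neighbor_closed",
    "is_better",
    "solution_weight",
    "make_solution",
]


class ValidationError(ValueError):
    """An instance, solution, or serialized artifact failed validation."""


@dataclass(frozen=True)
class WeightedSet:
    """One candidate set: an identifier, its elements, and a real weight."""

    set_id: str
    elements: FrozenSet[str]
    weight: float

    @staticmethod
    def of(set_id: str, elements: Iterable[str], weight: float = 0.0) -> "WeightedSet":
        return WeightedSet(str(set_id), frozenset(str(e) for e in elements), float(weight))


@dataclass(frozen=True)
class CoverInstance:
    """Universe plus an ordered family of weighted sets.

    The family order after :func:`normalize_instance` (lexicographic by
    ``set_id``) is the deterministic tie-break order used everywhere.
    """

    universe: FrozenSet[str]
    family: Tuple[WeightedSet, ...]

    @property
    def m(self) -> int:
        return len(self.family)

    @property
    def n(self) -> int:
        return len(self.universe)

    def weight_map(self) -> Dict[str, float]:
        return {ws.set_id: ws.weight for ws in self.family}

    def set_map(self) -> Dict[str, WeightedSet]:
        return {ws.set_id: ws for ws in self.family}

    @staticmethod
    def of(
        sets: Iterable[WeightedSet],
        universe: Iterable[str] | None = None,
    ) -> "CoverInstance":
        fam = tuple(sets)
        union: set = set()
        for ws in fam:
            union |= ws.elements
        if universe is not None:
            uni = frozenset(str(e) for e in universe) | frozenset(union)
        else:
            uni = frozenset(union)
        return CoverInstance(uni, fam)


@dataclass(frozen=True)
class IntersectionGraph:
    """Graph on set_ids with an edge iff two sets share >= 1 element."""

    adjacency: Mapping[str, FrozenSet[str]]

    @property
    def nodes(self) -> Tuple[str, ...]:
        return tuple(sorted(self.adjacency))

    def degree(self, node: str) -> int:
        return len(self.adjacency[node])

    def max_degree(self) -> int:
        if not self.adjacency:
            return 0
        return max(len(v) for v in self.adjacency.values())


@dataclass(frozen=True)
class CoverSolution:
    """A pairwise-disjoint chosen subfamily with its coverage and weight."""

    chosen: FrozenSet[str]
    coverage: int
    weight: float

    def sorted_chosen(self) -> Tuple[str, ...]:
        return tuple(sorted(self.chosen))


@dataclass
class SearchStats:
    """Instrumentation of the branch-and-bound search tree.

    ``branch_leaves`` counts terminals of the include/exclude recursion:
    subinstances resolved without branching (empty, all-isolated, or handed
    to the polynomial degree-<=2 solver).  Component splits contribute
    additively.  ``cover2_internal_leaves`` counts leaves of the degree-<=2
    recursion separately.
    """

    branch_leaves: int = 0
    branch_nodes: int = 0
    max_depth: int = 0
    cover2_internal_leaves: int = 0

    def as_dict(self) -> Dict[str, int]:
        return {
            "branch_leaves": self.branch_leaves,
            "branch_nodes": self.branch_nodes,
            "max_depth": self.max_depth,
            "cover2_internal_leaves": self.cover2_internal_leaves,
        }


def normalize_instance(instance: CoverInstance) -> CoverInstance:
    """Validate and canonicalize an instance.

    Removes empty sets, rejects duplicate set_ids and out-of-universe
    elements, and sorts the family lexicographically by set_id.
    """
    seen: set = set()
    for ws in instance.family:
        if ws.set_id in seen:
            raise ValidationError(f"duplicate set_id: {ws.set_id!r}")
        seen.add(ws.set_id)
        extra = ws.elements - instance.universe
        if extra:
            raise ValidationError(
                f"set {ws.set_id!r} contains elements outside the universe: "
                f"{sorted(extra)[:5]}"
            )
    fam = tuple(
        sorted((ws for ws in instance.family if ws.elements), key=lambda w: w.set_id)
    )
    return CoverInstance(frozenset(instance.universe), fam)


def build_intersection_graph(instance: CoverInstance) -> IntersectionGraph:
    """One node per family member; edge iff the two sets intersect."""
    fam = instance.family
    adj: Dict[str, set] = {ws.set_id: set() for ws in fam}
    for i in range(len(fam)):
        si = fam[i]
        for j in range(i + 1, len(fam)):
            sj = fam[j]
            if si.elements & sj.elements:
                adj[si.set_id].add(sj.set_id)
                adj[sj.set_id].add(si.set_id)
    return IntersectionGraph({k: frozenset(v) for k, v in adj.items()})


def connected_components(graph: IntersectionGraph) -> List[FrozenSet[str]]:
    """Maximal connected node-sets, sorted by smallest member id."""
    adj = graph.adjacency
    unvisited = set(adj)
    comps: List[FrozenSet[str]] = []
    while unvisited:
        start = min(unvisited)
        stack = [start]
        comp = {start}
        unvisited.discard(start)
        while stack:
            node = stack.pop()
            for nb in adj[node]:
                if nb in unvisited:
                    unvisited.discard(nb)
                    comp.add(nb)
                    stack.append(nb)
        comps.append(frozenset(comp))
    comps.sort(key=min)
    return comps


def neighbor_closed(graph: IntersectionGraph, s: str) -> FrozenSet[str]:
    """The closed neighborhood {s} | adjacency(s)."""
    if s not in graph.adjacency:
        raise ValidationError(f"unknown node: {s!r}")
    return frozenset({s}) | graph.adjacency[s]


def is_better(a: CoverSolution, b: CoverSolution) -> int:
    """Return 1 if ``a`` is better, -1 if ``b`` is better, 0 on a tie.

    Better means more coverage, or equal coverage and strictly smaller
    weight.  Equal coverage and weight is a tie; downstream code breaks
    ties by the lexicographically smallest sorted chosen-id tuple.
    """
    if a.coverage != b.coverage:
        return 1 if a.coverage > b.coverage else -1
    if a.weight != b.weight:
        return 1 if a.weight < b.weight else -1
    return 0


def solution_weight(chosen: Iterable[str], weight_map: Mapping[str, float]) -> float:
    # summation in sorted set_id order keeps float ties reproducible
    return float(sum(weight_map[i] for i in sorted(chosen)))


def make_solution(instance: CoverInstance, chosen: Iterable[str]) -> CoverSolution:
    """Build and validate a solution for ``instance`` from chosen ids."""
    ids = frozenset(chosen)
    smap = instance.set_map()
    covered: set = set()
    total = 0
    for sid in sorted(ids):
        if sid not in smap:
            raise ValidationError(f"chosen id {sid!r} not in instance")
        elems = smap[sid].elements
        if covered & elems:
            raise ValidationError("chosen sets are not pairwise disjoint")
        covered |= elems
        total += len(elems)
    return CoverSolution(ids, len(covered), solution_weight(ids, instance.weight_map()))
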