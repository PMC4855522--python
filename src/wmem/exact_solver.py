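"""Exact branch-and-bound solver for mutually exclusive maximum set cover.

The solver maximizes the number of covered elements first and minimizes the
total weight of the chosen sets second.  Isolated sets (no overlap with any
other set) are included directly; the remaining sets are decomposed into
connected components of the intersection graph and each component is solved
independently.  Within a component the branch node depends on the maximum
degree: degree >= 4 branches on a maximum-degree node; degree exactly 3
branches on a degree-3 node reached by walking from a minimum-degree node;
degree <= 2 components (paths and rings) are solved by a quadratic
middle-node recursion with no further high-degree branching.
"""

from __future__ import annotations

from dataclasses import dataclass
from typing import Dict, FrozenSet, List, Mapping, Sequence, Tuple

from .instance_model import (
    CoverInstance,
    CoverSolution,
    IntersectionGraph,
    SearchStats,
    ValidationError,
    WeightedSet,
    build_intersection_graph,
    connected_components,
    normalize_instance,
    solution_weight,
)

__all__ = [
    "solve",
    "solve_component_deg2",
    "solve_component_deg3",
    "find_branch_node_deg3",
    "brute_force_solve",
]

# a partial solution inside the recursion: (chosen ids, covered elements)
_Partial = Tuple[FrozenSet[str], FrozenSet[str]]

_EMPTY: _Partial = (frozenset(), frozenset())


def _adjacency(sets: Sequence[WeightedSet]) -> Dict[str, FrozenSet[str]]:
    adj: Dict[str, set] = {ws.set_id: set() for ws in sets}
    for i in range(len(sets)):
        si = sets[i]
        for j in range(i + 1, len(sets)):
            sj = sets[j]
            if si.elements & sj.elements:
                adj[si.set_id].add(sj.set_id)
                adj[sj.set_id].add(si.set_id)
    return {k: frozenset(v) for k, v in adj.items()}


def _components(adj: Mapping[str, FrozenSet[str]]) -> List[FrozenSet[str]]:
    return connected_components(IntersectionGraph(adj))


def _prefer(a: _Partial, b: _Partial, wmap: Mapping[str, float]) -> _Partial:
    """Pick the better partial: coverage desc, weight asc, sorted-id tuple asc."""
    ka = (-len(a[1]), solution_weight(a[0], wmap), tuple(sorted(a[0])))
    kb = (-len(b[1]), solution_weight(b[0], wmap), tuple(sorted(b[0])))
    return a if ka <= kb else b


def _merge(a: _Partial, b: _Partial) -> _Partial:
    return (a[0] | b[0], a[1] | b[1])


def solve(instance: CoverInstance) -> Tuple[CoverSolution, SearchStats]:
    """Return the optimal mutually exclusive cover and search statistics."""
    inst = normalize_instance(instance)
    wmap = inst.weight_map()
    stats = SearchStats()
    chosen, covered = _solve(list(inst.family), 0, stats, wmap)
    sol = CoverSolution(chosen, len(covered), solution_weight(chosen, wmap))
    return sol, stats


def _solve(
    sets: Sequence[WeightedSet],
    depth: int,
    stats: SearchStats,
    wmap: Mapping[str, float],
) -> _Partial:
    if depth > stats.max_depth:
        stats.max_depth = depth
    if not sets:
        stats.branch_leaves += 1
        return _EMPTY

    adj = _adjacency(sets)
    by_id = {ws.set_id: ws for ws in sets}

    # isolated sets never conflict: include them directly
    result: _Partial = _EMPTY
    remaining: List[WeightedSet] = []
    for ws in sets:
        if adj[ws.set_id]:
            remaining.append(ws)
        else:
            result = _merge(result, (frozenset({ws.set_id}), ws.elements))

    if not remaining:
        stats.branch_leaves += 1
        return result

    sub_adj = {ws.set_id: adj[ws.set_id] for ws in remaining}
    for comp in _components(sub_adj):
        comp_sets = [ws for ws in remaining if ws.set_id in comp]
        max_deg = max(len(sub_adj[i]) for i in comp)
        if max_deg <= 2:
            stats.branch_leaves += 1
            part = _cover2_connected(comp_sets, sub_adj, stats, wmap)
        else:
            if max_deg == 3:
                x_id = _deg3_branch_node({i: sub_adj[i] for i in comp})
            else:
                x_id = min(i for i in comp if len(sub_adj[i]) == max_deg)
            part = _branch(comp_sets, sub_adj, x_id, depth, stats, wmap)
        result = _merge(result, part)
    return result


def _branch(
    comp_sets: Sequence[WeightedSet],
    adj: Mapping[str, FrozenSet[str]],
    x_id: str,
    depth: int,
    stats: SearchStats,
    wmap: Mapping[str, float],
) -> _Partial:
    """Include/exclude branching on node x; recurse through the full solver."""
    stats.branch_nodes += 1
    x = next(ws for ws in comp_sets if ws.set_id == x_id)
    closed = frozenset({x_id}) | adj[x_id]

    include = _solve(
        [ws for ws in comp_sets if ws.set_id not in closed], depth + 1, stats, wmap
    )
    include = _merge(include, (frozenset({x_id}), x.elements))

    exclude = _solve(
        [ws for ws in comp_sets if ws.set_id != x_id], depth + 1, stats, wmap
    )
    return _prefer(include, exclude, wmap)


# ---------------------------------------------------------------------------
# degree <= 2 components: paths and rings, solved in O(m^2)
# ---------------------------------------------------------------------------


def solve_component_deg2(instance: CoverInstance) -> Tuple[CoverSolution, SearchStats]:
    """Solve a connected instance whose intersection graph has degree <= 2."""
    inst = normalize_instance(instance)
    wmap = inst.weight_map()
    stats = SearchStats()
    sets = list(inst.family)
    adj = _adjacency(sets)
    if adj and max(len(v) for v in adj.values()) > 2:
        raise ValidationError("solve_component_deg2 requires maximum degree <= 2")
    if sets and len(_components(adj)) != 1:
        raise ValidationError("solve_component_deg2 requires a connected instance")
    if not sets:
        stats.branch_leaves += 1
        return CoverSolution(frozenset(), 0, 0.0), stats
    stats.branch_leaves += 1
    chosen, covered = _cover2_connected(sets, adj, stats, wmap)
    return CoverSolution(chosen, len(covered), solution_weight(chosen, wmap)), stats


def _cover2_multi(
    sets: Sequence[WeightedSet],
    stats: SearchStats,
    wmap: Mapping[str, float],
) -> _Partial:
    if not sets:
        stats.cover2_internal_leaves += 1
        return _EMPTY
    adj = _adjacency(sets)
    result: _Partial = _EMPTY
    for comp in _components(adj):
        comp_sets = [ws for ws in sets if ws.set_id in comp]
        result = _merge(result, _cover2_connected(comp_sets, adj, stats, wmap))
    return result


def _cover2_connected(
    comp_sets: Sequence[WeightedSet],
    adj: Mapping[str, FrozenSet[str]],
    stats: SearchStats,
    wmap: Mapping[str, float],
) -> _Partial:
    if len(comp_sets) == 1:
        ws = comp_sets[0]
        stats.cover2_internal_leaves += 1
        return (frozenset({ws.set_id}), ws.elements)

    ids = {ws.set_id for ws in comp_sets}
    degs = {i: len(adj[i] & ids) for i in ids}
    endpoints = sorted(i for i, d in degs.items() if d <= 1)
    if endpoints:
        # simple path: branch on the middle node, walking from the
        # smallest-id endpoint (even length -> lower-indexed middle node)
        order = [endpoints[0]]
        prev = None
        while len(order) < len(comp_sets):
            cur = order[-1]
            nxt = sorted(n for n in adj[cur] & ids if n != prev)
            prev = cur
            order.append(nxt[0])
        x_id = order[(len(order) - 1) // 2]
    else:
        # simple ring: branch on the deterministic first node
        x_id = min(ids)

    x = next(ws for ws in comp_sets if ws.set_id == x_id)
    closed = (adj[x_id] & ids) | {x_id}

    include = _cover2_multi(
        [ws for ws in comp_sets if ws.set_id not in closed], stats, wmap
    )
    include = _merge(include, (frozenset({x_id}), x.elements))
    exclude = _cover2_multi(
        [ws for ws in comp_sets if ws.set_id != x_id], stats, wmap
    )
    return _prefer(include, exclude, wmap)


# ---------------------------------------------------------------------------
# degree == 3 components
# ---------------------------------------------------------------------------


def find_branch_node_deg3(graph: IntersectionGraph) -> str:
    """Branch node for a connected component with maximum degree exactly 3.

    From the smallest-id minimum-degree node, walk along degree-<=2 nodes
    (smallest-id successor first) until the first degree-3 node.  If the
    graph is 3-regular, return the smallest-id node.
    """
    adj = graph.adjacency
    if not adj or max(len(v) for v in adj.values()) != 3:
        raise ValidationError("find_branch_node_deg3 requires maximum degree exactly 3")
    return _deg3_branch_node(adj)


def _deg3_branch_node(adj: Mapping[str, FrozenSet[str]]) -> str:
    degs = {v: len(adj[v]) for v in adj}
    min_deg = min(degs.values())
    if min_deg == 3:
        return min(adj)
    cur = min(v for v, d in degs.items() if d == min_deg)
    prev = None
    visited = {cur}
    while degs[cur] < 3:
        nxt = sorted(n for n in adj[cur] if n != prev)[0]
        prev, cur = cur, nxt
        if cur in visited:  # pragma: no cover - impossible on valid input
            raise ValidationError("walk revisited a node; graph is not valid")
        visited.add(cur)
    return cur


def solve_component_deg3(instance: CoverInstance) -> Tuple[CoverSolution, SearchStats]:
    """Solve a connected instance whose intersection graph has max degree 3."""
    inst = normalize_instance(instance)
    wmap = inst.weight_map()
    sets = list(inst.family)
    adj = _adjacency(sets)
    if not adj or max(len(v) for v in adj.values()) != 3:
        raise ValidationError("solve_component_deg3 requires maximum degree exactly 3")
    if len(_components(adj)) != 1:
        raise ValidationError("solve_component_deg3 requires a connected instance")
    stats = SearchStats()
    x_id = _deg3_branch_node(adj)
    chosen, covered = _branch(sets, adj, x_id, 0, stats, wmap)
    return CoverSolution(chosen, len(covered), solution_weight(chosen, wmap)), stats


# ---------------------------------------------------------------------------
# brute-force oracle
# ---------------------------------------------------------------------------


def brute_force_solve(instance: CoverInstance, max_m: int = 20) -> CoverSolution:
    """Exhaustively enumerate disjoint subfamilies; same contract as solve().

    Refuses instances with more than ``max_m`` sets.
    """
    inst = normalize_instance(instance)
    if inst.m > max_m:
        raise ValidationError(f"brute force refused: m={inst.m} > max_m={max_m}")
    fam = inst.family
    wmap = inst.weight_map()

    elems = sorted(set().union(*(ws.elements for ws in fam)) if fam else set())
    bit = {e: 1 << i for i, e in enumerate(elems)}
    masks = [sum(bit[e] for e in ws.elements) for ws in fam]

    best_key = (0, 0.0, ())
    best_ids: Tuple[str, ...] = ()

    def rec(i: int, mask: int, chosen: List[str]) -> None:
        nonlocal best_key, best_ids
        if i == len(fam):
            key = (
                -mask.bit_count(),
                solution_weight(chosen, wmap),
                tuple(sorted(chosen)),
            )
            if key < best_key:
                best_key = key
                best_ids = key[2]
            return
        rec(i + 1, mask, chosen)  # exclude
        if not mask & masks[i]:  # include if disjoint
            chosen.append(fam[i].set_id)
            rec(i + 1, mask | masks[i], chosen)
            chosen.pop()

    rec(0, 0, [])
    return CoverSolution(
        frozenset(best_ids), -best_key[0], solution_weight(best_ids, wmap)
    )
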