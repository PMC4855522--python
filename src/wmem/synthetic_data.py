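"""Seeded generators for solver instances and full synthetic cohorts.

Solver-side generators produce random instances, instances realizing an
exact intersection graph, and planted-solution benchmarks.  The cohort
generator emulates the structural assumptions of the pipeline: a set of
mutually exclusive driver genes, each signal-perturbed tumor carrying
exactly one driver event (mutation or a GISTIC +/-2 call with a concordant
expression shift), signature genes strongly dysregulated in perturbed
tumors and normal-like elsewhere, and passenger events as noise.

All generators are pure functions of their parameters and a required seed.
"""

from __future__ import annotations

from dataclasses import dataclass, field
from typing import Dict, FrozenSet, Iterable, List, Mapping, Optional, Sequence, Tuple

import networkx as nx
import numpy as np
import pandas as pd

from .instance_model import (
    CoverInstance,
    ValidationError,
    WeightedSet,
    build_intersection_graph,
    normalize_instance,
)
from .sga_preprocess import CohortData

__all__ = [
    "PlantedTruth",
    "random_instance",
    "instance_from_graph",
    "planted_instance",
    "random_max_degree_graph",
    "synthetic_cohort",
]

# relative spread of baseline expression on the log scale; present even in
# "noiseless" cohorts so that CNV z-score backgrounds have nonzero variance
_BASE_JITTER = 0.05


@dataclass(frozen=True)
class PlantedTruth:
    """Ground truth recorded by a generator."""

    seed: int
    params: Mapping[str, object]
    planted_sets: Tuple[str, ...] = ()
    drivers: Tuple[str, ...] = ()
    driver_assignment: Mapping[str, str] = field(default_factory=dict)
    perturbed: FrozenSet[str] = frozenset()
    signature_genes: Tuple[str, ...] = ()


def random_instance(
    m: int,
    n: int,
    density: float,
    weight_range: Tuple[float, float] = (-1.0, 1.0),
    seed: int = 0,
) -> CoverInstance:
    """``m`` random sets over ``n`` elements with expected size density*n."""
    if m < 0:
        raise ValidationError("m must be >= 0")
    if n < 1:
        raise ValidationError("n must be >= 1")
    if not (0.0 < density <= 1.0):
        raise ValidationError("density must be in (0, 1]")
    lo, hi = weight_range
    if lo > hi:
        raise ValidationError("weight_range must be (lo, hi) with lo <= hi")
    rng = np.random.default_rng(seed)
    universe = [f"e{i:04d}" for i in range(n)]
    sets = []
    width = max(3, len(str(max(m - 1, 0))))
    for i in range(m):
        size = max(1, int(rng.binomial(n, density)))
        elems = rng.choice(n, size=size, replace=False)
        weight = float(rng.uniform(lo, hi))
        sets.append(WeightedSet(f"S{i:0{width}d}", frozenset(universe[j] for j in elems), weight))
    return normalize_instance(CoverInstance.of(sets, universe=universe))


def instance_from_graph(
    graph_spec: nx.Graph,
    private_elements_per_node: int = 1,
    seed: int = 0,
    weight_range: Tuple[float, float] = (0.0, 0.0),
) -> CoverInstance:
    """Realize an exact intersection graph as a set family.

    Each edge contributes one unique element shared by its two endpoints;
    each node additionally receives ``private_elements_per_node`` unique
    elements, so the rebuilt intersection graph is isomorphic (indeed
    identical up to node naming) to ``graph_spec``.
    """
    if private_elements_per_node < 1:
        raise ValidationError("private_elements_per_node must be >= 1")
    if graph_spec.is_multigraph():
        raise ValidationError("multigraphs are not supported")
    if any(u == v for u, v in graph_spec.edges()):
        raise ValidationError("self-loops are not supported")
    rng = np.random.default_rng(seed)
    lo, hi = weight_range
    if lo > hi:
        raise ValidationError("weight_range must be (lo, hi) with lo <= hi")

    nodes = sorted(graph_spec.nodes(), key=str)
    members: Dict[str, set] = {str(v): set() for v in nodes}
    for idx, (u, v) in enumerate(sorted((tuple(sorted((str(a), str(b))))) for a, b in graph_spec.edges())):
        elem = f"shared{idx:05d}"
        members[u].add(elem)
        members[v].add(elem)
    for v in nodes:
        for j in range(private_elements_per_node):
            members[str(v)].add(f"priv_{v}_{j}")

    sets = [
        WeightedSet(str(v), frozenset(members[str(v)]), float(rng.uniform(lo, hi)))
        for v in nodes
    ]
    inst = normalize_instance(CoverInstance.of(sets))
    rebuilt = build_intersection_graph(inst)
    want = {str(v): frozenset(str(u) for u in graph_spec.neighbors(v)) for v in nodes}
    if dict(rebuilt.adjacency) != want:  # pragma: no cover - construction guarantee
        raise ValidationError("rebuilt intersection graph does not match the spec")
    return inst


def random_max_degree_graph(n_nodes: int, max_degree: int, seed: int = 0, target_edges: Optional[int] = None) -> nx.Graph:
    """Random simple graph on ``n_nodes`` nodes with degree <= ``max_degree``
    and maximum degree exactly ``max_degree`` when feasible."""
    if n_nodes < max_degree + 1:
        raise ValidationError("need at least max_degree + 1 nodes")
    rng = np.random.default_rng(seed)
    labels = [f"v{i:03d}" for i in range(n_nodes)]
    g = nx.Graph()
    g.add_nodes_from(labels)
    if target_edges is None:
        target_edges = int(n_nodes * max_degree // 2 * 0.8)
    attempts = 0
    while g.number_of_edges() < target_edges and attempts < 50 * target_edges:
        attempts += 1
        i, j = rng.choice(n_nodes, size=2, replace=False)
        u, v = labels[i], labels[j]
        if g.has_edge(u, v) or g.degree(u) >= max_degree or g.degree(v) >= max_degree:
            continue
        g.add_edge(u, v)
    # top up so the maximum degree is actually reached
    if max(dict(g.degree()).values(), default=0) < max_degree:
        for u in labels:
            while g.degree(u) < max_degree:
                others = [v for v in labels if v != u and not g.has_edge(u, v) and g.degree(v) < max_degree]
                if not others:
                    break
                g.add_edge(u, others[int(rng.integers(len(others)))])
            if g.degree(u) == max_degree:
                break
    return g


def planted_instance(
    k: int,
    set_size: int,
    n_decoys: int,
    overlap_rate: float,
    seed: int = 0,
) -> Tuple[CoverInstance, PlantedTruth]:
    """``k`` disjoint near-zero-weight planted sets exactly covering the
    universe, plus heavier decoys overlapping them."""
    if k < 1 or set_size < 1:
        raise ValidationError("k and set_size must be >= 1")
    if n_decoys < 0:
        raise ValidationError("n_decoys must be >= 0")
    if not (0.0 <= overlap_rate <= 1.0):
        raise ValidationError("overlap_rate must be in [0, 1]")
    rng = np.random.default_rng(seed)
    n = k * set_size
    universe = [f"e{i:04d}" for i in range(n)]
    order = rng.permutation(n)
    sets: List[WeightedSet] = []
    planted_ids = []
    for i in range(k):
        sid = f"P{i:02d}"
        planted_ids.append(sid)
        elems = frozenset(universe[j] for j in order[i * set_size : (i + 1) * set_size])
        sets.append(WeightedSet(sid, elems, float(rng.uniform(0.0, 1e-3))))
    planted_elems = {s.set_id: s.elements for s in sets}
    for i in range(n_decoys):
        # bias part of the decoy into one planted set, rest anywhere
        anchor = planted_ids[int(rng.integers(k))]
        n_anchor = min(set_size, max(1, int(round(overlap_rate * set_size))))
        pool = sorted(planted_elems[anchor])
        picked = set(rng.choice(pool, size=min(n_anchor, len(pool)), replace=False))
        rest = [e for e in universe if e not in picked]
        extra = set_size - len(picked)
        if extra > 0 and rest:
            picked |= set(rng.choice(rest, size=min(extra, len(rest)), replace=False))
        sets.append(WeightedSet(f"D{i:02d}", frozenset(picked), float(rng.uniform(0.5, 1.0))))
    inst = normalize_instance(CoverInstance.of(sets, universe=universe))
    truth = PlantedTruth(
        seed=seed,
        params={"k": k, "set_size": set_size, "n_decoys": n_decoys, "overlap_rate": overlap_rate},
        planted_sets=tuple(planted_ids),
    )
    return inst, truth


def synthetic_cohort(
    n_tumors: int = 200,
    n_normals: int = 20,
    n_genes: int = 300,
    signature_size: int = 10,
    n_drivers: int = 4,
    passenger_rate: float = 0.05,
    fold_effect: float = 3.0,
    noise_sd: float = 0.0,
    seed: int = 0,
    perturbed_fraction: float = 0.5,
) -> Tuple[CohortData, List[Tuple[str, str, List[str]]], PlantedTruth]:
    """Generate a cohort with planted mutually exclusive driver SGAs.

    Returns (cohort, signatures, truth) where signatures is a list of GMT
    records (id, description, genes).  Each perturbed tumor carries exactly
    one driver event; signature genes are >= fold_effect-fold up-regulated
    in perturbed tumors and within twofold of the normal median elsewhere.
    """
    if n_tumors < 1 or n_normals < 1:
        raise ValidationError("need at least one tumor and one normal")
    if fold_effect < 1.0:
        raise ValidationError("fold_effect must be >= 1")
    if not (0.0 < perturbed_fraction <= 1.0):
        raise ValidationError("perturbed_fraction must be in (0, 1]")
    if signature_size < 1 or signature_size >= 50:
        raise ValidationError("signature_size must be in [1, 49]")
    if n_genes < n_drivers + signature_size + 1:
        raise ValidationError("n_genes too small for drivers + signature")
    if not (0.0 <= passenger_rate <= 1.0):
        raise ValidationError("passenger_rate must be in [0, 1]")

    rng = np.random.default_rng(seed)
    tumors = [f"T{i:04d}" for i in range(n_tumors)]
    normals = [f"N{i:03d}" for i in range(n_normals)]
    drivers = [f"DRV{i:02d}" for i in range(n_drivers)]
    sig_genes = [f"SIG{i:02d}" for i in range(signature_size)]
    n_bg = n_genes - n_drivers - signature_size
    bg_genes = [f"BG{i:04d}" for i in range(n_bg)]
    genes = drivers + sig_genes + bg_genes
    samples = tumors + normals

    n_pert = int(round(perturbed_fraction * n_tumors))
    perturbed = sorted(rng.choice(tumors, size=n_pert, replace=False))

    # exactly one driver event per perturbed tumor, balanced round-robin
    shuffled = list(perturbed)
    rng.shuffle(shuffled)
    assignment = {t: drivers[i % n_drivers] for i, t in enumerate(shuffled)}

    mutation = pd.DataFrame(0, index=genes, columns=tumors, dtype=int)
    gistic = pd.DataFrame(0, index=genes, columns=tumors, dtype=int)

    jitter = _BASE_JITTER + noise_sd
    base = rng.uniform(80.0, 120.0, size=len(genes))
    expr = pd.DataFrame(
        base[:, None] * np.exp(rng.normal(0.0, jitter, size=(len(genes), len(samples)))),
        index=genes,
        columns=samples,
    )

    # signature genes: strong up-regulation in perturbed tumors, with margin
    # so folds stay >= fold_effect under the pseudocount and jitter
    for g in sig_genes:
        ref = float(np.median(expr.loc[g, normals]))
        expr.loc[g, perturbed] = (ref + 1.0) * fold_effect * 1.5 * np.exp(
            rng.normal(0.0, jitter, size=len(perturbed))
        )

    event_kinds = ["mut", "amp", "del"]
    cnv_events: List[Tuple[str, str, int]] = []  # (gene, tumor, +-2)
    for t in perturbed:
        g = assignment[t]
        kind = event_kinds[int(rng.integers(3))]
        if kind == "mut":
            mutation.loc[g, t] = 1
        elif kind == "amp":
            gistic.loc[g, t] = 2
            cnv_events.append((g, t, 2))
        else:
            gistic.loc[g, t] = -2
            cnv_events.append((g, t, -2))

    # passenger events on background genes, across all tumors
    if passenger_rate > 0 and bg_genes:
        hits = rng.random((len(bg_genes), n_tumors)) < passenger_rate
        for gi, g in enumerate(bg_genes):
            for ti in np.nonzero(hits[gi])[0]:
                t = tumors[ti]
                r = rng.random()
                if r < 0.7:
                    mutation.loc[g, t] = 1
                elif r < 0.85:
                    gistic.loc[g, t] = 2
                    cnv_events.append((g, t, 2))
                else:
                    gistic.loc[g, t] = -2
                    cnv_events.append((g, t, -2))
        # a sprinkle of GISTIC +-1 calls, which the pipeline must ignore
        low = rng.random((len(bg_genes), n_tumors)) < passenger_rate / 2
        for gi, g in enumerate(bg_genes):
            for ti in np.nonzero(low[gi])[0]:
                if gistic.iloc[genes.index(g), ti] == 0:
                    gistic.loc[g, tumors[ti]] = int(rng.choice([-1, 1]))

    # concordant expression for CNV events: +-3 background SDs clears the
    # 1.64 z threshold deterministically (same ddof as the caller)
    by_gene: Dict[str, List[Tuple[str, int]]] = {}
    for g, t, sign in cnv_events:
        by_gene.setdefault(g, []).append((t, sign))
    for g, events in by_gene.items():
        bg_cols = [t for t in tumors if gistic.loc[g, t] == 0]
        vals = expr.loc[g, bg_cols]
        mean, sd = float(vals.mean()), float(vals.std(ddof=1))
        for t, sign in events:
            expr.loc[g, t] = max(0.0, mean + sign * 3.0 * sd)

    sample_type = pd.Series(
        ["tumor"] * len(tumors) + ["normal"] * len(normals), index=samples
    )
    cohort = CohortData(mutation=mutation, gistic=gistic, expression=expr, sample_type=sample_type)
    signatures = [("SIG_MAIN", "synthetic co-regulated signature", list(sig_genes))]
    truth = PlantedTruth(
        seed=seed,
        params={
            "n_tumors": n_tumors,
            "n_normals": n_normals,
            "n_genes": n_genes,
            "signature_size": signature_size,
            "n_drivers": n_drivers,
            "passenger_rate": passenger_rate,
            "fold_effect": fold_effect,
            "noise_sd": noise_sd,
            "perturbed_fraction": perturbed_fraction,
        },
        drivers=tuple(drivers),
        driver_assignment=dict(assignment),
        perturbed=frozenset(perturbed),
        signature_genes=tuple(sig_genes),
    )
    return cohort, signatures, truth
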