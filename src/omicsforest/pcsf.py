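"""Prize-Collecting Steiner Forest (PCSF) optimization on a confidence-weighted interactome.

The integration step represents differential proteins and inferred
transcription factors as prized nodes on a physical-interaction network
and searches for a forest F(V_F, E_F) maximizing

    f(F) = beta * sum_{v in V_F} p(v) - sum_{e in E_F} c'(e) - omega * kappa

where p(v) >= 0 are node prizes, c'(e) are degree-regularized edge costs,
and kappa is the number of trees. The per-tree term is equivalent to a
rooted construction in which a virtual root v0 is connected to every node
by an edge of cost omega: each tree of the forest attaches to v0 through
exactly one such edge. The omega term is implemented as a penalty by
default (``omega_sign="penalty"``); a bonus form (``"bonus"``) is kept as
a comparison switch (see the methods note for why the penalty form is the
meaningful one).

Hub bias is controlled by regularizing the cost of an edge between nodes
a and b with degrees da, db in an interactome of N nodes:

    c'(e) = c(e) + alpha * (da * db) / ((N - da - 1) * (N - db - 1) + da * db)

The penalty term lies in [0, alpha] and increases monotonically with each
degree, so edges between hubs are discouraged.
"""

from __future__ import annotations

import itertools
import math
from dataclasses import dataclass, field
from typing import Iterable, Mapping, Sequence

import networkx as nx
import numpy as np

__all__ = [
    "COST_FLOOR",
    "Interactome",
    "PrizeMap",
    "Hyperparameters",
    "ForestSolution",
    "RobustnessSummary",
    "edge_cost",
    "regularized_edge_cost",
    "forest_objective",
    "brute_force_pcsf",
    "solve_pcsf",
    "force_include",
    "assign_prizes",
    "robustness_ensemble",
    "specificity_ensemble",
    "select_parameters",
]

COST_FLOOR = 1e-6


class Interactome:
    """Undirected confidence-weighted protein-interaction network.

    Each edge carries a confidence s in (0, 1] and a base cost
    c(e) = 1 - s (floored at :data:`COST_FLOOR` so perfectly confident
    edges are still not free).
    """

    def __init__(self, edges: Iterable[tuple[str, str, float]]):
        g = nx.Graph()
        for u, v, s in edges:
            if u == v:
                raise ValueError(f"self-loop on node {u!r}")
            if g.has_edge(u, v):
                raise ValueError(f"duplicate edge {u!r}-{v!r}")
            g.add_edge(u, v, confidence=float(s), cost=edge_cost(float(s)))
        self.graph = g

    @property
    def n_nodes(self) -> int:
        return self.graph.number_of_nodes()

    @property
    def n_edges(self) -> int:
        return self.graph.number_of_edges()

    @property
    def nodes(self) -> list[str]:
        return sorted(self.graph.nodes)

    def degree(self, node: str) -> int:
        return self.graph.degree[node]

    def edges(self) -> list[tuple[str, str, float]]:
        """Sorted (u, v, confidence) triples with u < v."""
        out = []
        for u, v, data in self.graph.edges(data=True):
            a, b = sorted((u, v))
            out.append((a, b, data["confidence"]))
        return sorted(out)

    def regularized_costs(self, alpha: float) -> dict[tuple[str, str], float]:
        """c'(e) for every edge, keyed by sorted node pair."""
        n = self.n_nodes
        deg = dict(self.graph.degree)
        out = {}
        for u, v, data in self.graph.edges(data=True):
            a, b = sorted((u, v))
            if alpha == 0:
                out[(a, b)] = data["cost"]
            else:
                out[(a, b)] = regularized_edge_cost(
                    data["cost"], deg[u], deg[v], n, alpha
                )
        return out


@dataclass
class PrizeMap:
    """Nonnegative node prizes with per-node provenance.

    Provenance distinguishes where each prize came from: ``protein``
    (differential proteomics), ``TF`` (motif-enrichment inference),
    ``forced`` (manually pinned, e.g. the disease gene itself), or
    ``none``.
    """

    prizes: dict[str, float]
    provenance: dict[str, str] = field(default_factory=dict)

    def __post_init__(self) -> None:
        for node, p in self.prizes.items():
            if p < 0:
                raise ValueError(f"negative prize for {node!r}")
        for node in self.prizes:
            self.provenance.setdefault(node, "none")

    def get(self, node: str) -> float:
        return self.prizes.get(node, 0.0)

    def prized_nodes(self) -> set[str]:
        return {v for v, p in self.prizes.items() if p > 0}

    def missing_from(self, interactome: Interactome) -> set[str]:
        """Prized ids absent from the interactome (reported, not dropped)."""
        return self.prized_nodes() - set(interactome.graph.nodes)


@dataclass
class Hyperparameters:
    """Scalars of the objective plus ensemble settings.

    beta scales prizes, omega is the per-tree opening cost, alpha scales
    the hub penalty. noise_sd is the log-normal sd used to perturb edge
    costs in the robustness ensemble; reps and top_k parametrize the
    ensembles; n_restarts controls the local-search restarts of the
    heuristic solver.
    """

    beta: float = 1.0
    omega: float = 0.1
    alpha: float = 0.0
    noise_sd: float = 0.3
    reps: int = 100
    top_k: int = 400
    omega_sign: str = "penalty"
    n_restarts: int = 4

    def __post_init__(self) -> None:
        if self.beta < 0 or self.omega < 0 or self.alpha < 0:
            raise ValueError("beta, omega and alpha must be nonnegative")
        if self.reps < 1:
            raise ValueError("reps must be >= 1")
        if self.omega_sign not in ("penalty", "bonus"):
            raise ValueError("omega_sign must be 'penalty' or 'bonus'")


@dataclass
class ForestSolution:
    """A feasible forest with its objective value and node provenance."""

    nodes: tuple[str, ...]
    edges: tuple[tuple[str, str], ...]
    n_trees: int
    objective: float
    provenance: dict[str, str]

    def node_set(self) -> set[str]:
        return set(self.nodes)

    def steiner_nodes(self) -> set[str]:
        return {v for v, kind in self.provenance.items() if kind == "steiner"}


@dataclass
class RobustnessSummary:
    """Per-node ensemble frequencies and the robustness-selected node set."""

    inclusion_frequency: dict[str, float]
    selected: tuple[str, ...]
    specificity_frequency: dict[str, float] | None = None


def edge_cost(confidence: float) -> float:
    """Base edge cost c(e) = 1 - s, floored, for confidence s in (0, 1]."""
    if not (0.0 < confidence <= 1.0):
        raise ValueError(f"confidence must lie in (0, 1], got {confidence}")
    return max(1.0 - confidence, COST_FLOOR)


def regularized_edge_cost(
    c: float, d_a: int, d_b: int, n_nodes: int, alpha: float
) -> float:
    """Degree-regularized edge cost c'(e); penalty term lies in [0, alpha]."""
    if n_nodes < 3:
        raise ValueError("need at least three nodes for the degree penalty")
    if not (1 <= d_a <= n_nodes - 1) or not (1 <= d_b <= n_nodes - 1):
        raise ValueError(
            f"degrees ({d_a}, {d_b}) inconsistent with N={n_nodes}"
        )
    num = d_a * d_b
    denom = (n_nodes - d_a - 1) * (n_nodes - d_b - 1) + num
    return c + alpha * num / denom


class _UnionFind:
    __slots__ = ("parent",)

    def __init__(self, items: Iterable[str]):
        self.parent = {x: x for x in items}

    def find(self, x: str) -> str:
        p = self.parent
        root = x
        while p[root] != root:
            root = p[root]
        while p[x] != root:
            p[x], x = root, p[x]
        return root

    def union(self, a: str, b: str) -> bool:
        ra, rb = self.find(a), self.find(b)
        if ra == rb:
            return False
        self.parent[rb] = ra
        return True


def _best_forest_on_subset(
    subset: set[str],
    adjacency: Mapping[str, list[tuple[str, float]]],
    prizes: PrizeMap,
    params: Hyperparameters,
) -> tuple[float, list[tuple[str, str]], int]:
    """Optimal edge choice for a fixed node subset.

    Starting from all-singleton trees, merging two components through an
    edge of cost c changes the objective by (omega - c) in the penalty
    form, so a Kruskal sweep that only accepts merges with c < omega
    yields the optimal forest on the subset (greedy on the graphic
    matroid). In the bonus form merges never pay and the forest stays
    edgeless.
    """
    induced = []
    for u in subset:
        for v, c in adjacency[u]:
            if u < v and v in subset:
                induced.append((c, u, v))
    chosen: list[tuple[str, str]] = []
    edge_total = 0.0
    kappa = len(subset)
    if params.omega_sign == "penalty" and induced:
        induced.sort()
        uf = _UnionFind(subset)
        for c, u, v in induced:
            if c < params.omega and uf.union(u, v):
                chosen.append((u, v))
                edge_total += c
                kappa -= 1
    prize_total = sum(prizes.get(v) for v in subset)
    omega_term = params.omega * kappa
    if params.omega_sign == "penalty":
        objective = params.beta * prize_total - edge_total - omega_term
    else:
        objective = params.beta * prize_total - edge_total + omega_term
    return objective, chosen, kappa


def _adjacency(
    interactome: Interactome, costs: Mapping[tuple[str, str], float]
) -> dict[str, list[tuple[str, float]]]:
    adj: dict[str, list[tuple[str, float]]] = {v: [] for v in interactome.graph.nodes}
    for (u, v), c in costs.items():
        adj[u].append((v, c))
        adj[v].append((u, c))
    return adj


def _make_solution(
    subset: set[str],
    adjacency: Mapping[str, list[tuple[str, float]]],
    prizes: PrizeMap,
    params: Hyperparameters,
) -> ForestSolution:
    objective, edges, kappa = _best_forest_on_subset(
        subset, adjacency, prizes, params
    )
    provenance = {
        v: ("prize" if prizes.get(v) > 0 else "steiner") for v in subset
    }
    return ForestSolution(
        nodes=tuple(sorted(subset)),
        edges=tuple(sorted(tuple(sorted(e)) for e in edges)),
        n_trees=kappa,
        objective=objective,
        provenance=provenance,
    )


def forest_objective(
    forest: ForestSolution,
    prizes: PrizeMap,
    params: Hyperparameters,
    interactome: Interactome,
) -> float:
    """Evaluate f(F) for an explicit forest; validates forest structure."""
    nodes = set(forest.nodes)
    costs = interactome.regularized_costs(params.alpha)
    g = nx.Graph()
    g.add_nodes_from(nodes)
    edge_total = 0.0
    for u, v in forest.edges:
        key = tuple(sorted((u, v)))
        if key not in costs:
            raise ValueError(f"edge {key} not in interactome")
        if u not in nodes or v not in nodes:
            raise ValueError(f"edge {key} leaves the node set")
        g.add_edge(u, v)
        edge_total += costs[key]
    if g.number_of_edges() != len(forest.edges):
        raise ValueError("duplicate edges in forest")
    if g.number_of_nodes() and not nx.is_forest(g):
        raise ValueError("edge set contains a cycle")
    kappa = nx.number_connected_components(g) if nodes else 0
    prize_total = sum(prizes.get(v) for v in nodes)
    omega_term = params.omega * kappa
    if params.omega_sign == "penalty":
        return params.beta * prize_total - edge_total - omega_term
    return params.beta * prize_total - edge_total + omega_term


def brute_force_pcsf(
    interactome: Interactome,
    prizes: PrizeMap,
    params: Hyperparameters,
    max_nodes: int = 14,
) -> ForestSolution:
    """Exact PCSF by exhaustive subset enumeration (small instances only).

    For each node subset the optimal forest is the thresholded minimum
    spanning forest of :func:`_best_forest_on_subset`; ties in objective
    are broken toward the lexicographically smallest sorted node tuple.
    """
    nodes = interactome.nodes
    if len(nodes) > max_nodes:
        raise ValueError(
            f"instance has {len(nodes)} nodes; brute force capped at {max_nodes}"
        )
    costs = interactome.regularized_costs(params.alpha)
    adjacency = _adjacency(interactome, costs)
    best_obj = 0.0
    best_subset: tuple[str, ...] = ()
    for r in range(len(nodes) + 1):
        for combo in itertools.combinations(nodes, r):
            obj, _, _ = _best_forest_on_subset(
                set(combo), adjacency, prizes, params
            )
            if obj > best_obj + 1e-12 or (
                abs(obj - best_obj) <= 1e-12 and combo < best_subset
            ):
                best_obj = obj
                best_subset = combo
    return _make_solution(set(best_subset), adjacency, prizes, params)


def _local_search(
    start: set[str],
    adjacency: Mapping[str, list[tuple[str, float]]],
    prizes: PrizeMap,
    params: Hyperparameters,
    candidate_pool: set[str],
    small: bool,
) -> tuple[float, set[str]]:
    """Hill-climb over node subsets with single toggles plus pair moves."""
    subset = set(start)
    obj, _, _ = _best_forest_on_subset(subset, adjacency, prizes, params)

    def candidates() -> set[str]:
        cand = set(candidate_pool)
        for u in subset:
            cand.update(v for v, _ in adjacency[u])
        cand.update(subset)
        return cand

    improved = True
    while improved:
        improved = False
        # single-node toggles, best-improvement
        best_delta, best_node = 1e-12, None
        for v in candidates():
            trial = subset ^ {v}
            t_obj, _, _ = _best_forest_on_subset(trial, adjacency, prizes, params)
            if t_obj - obj > best_delta:
                best_delta, best_node = t_obj - obj, v
        if best_node is not None:
            subset ^= {best_node}
            obj += best_delta
            improved = True
            continue
        # pair toggles rescue two-step structures (e.g. Steiner chains)
        if small:
            pool = sorted(candidates())
            pairs = itertools.combinations(pool, 2)
        else:
            outside = [
                v for v in candidates() if v not in subset
            ]
            pairs = (
                (u, w)
                for u in outside
                for w, _ in adjacency[u]
                if w not in subset and w > u
            )
        for u, w in pairs:
            trial = subset ^ {u, w}
            t_obj, _, _ = _best_forest_on_subset(trial, adjacency, prizes, params)
            if t_obj - obj > 1e-12:
                subset, obj = trial, t_obj
                improved = True
                break
    return obj, subset


def solve_pcsf(
    interactome: Interactome,
    prizes: PrizeMap,
    params: Hyperparameters,
    seed: int | None = None,
) -> ForestSolution:
    """Heuristic PCSF solver: multi-start local search over node subsets.

    The rooted transformation (virtual root v0 joined to every node by an
    omega-cost edge) reduces edge selection within any fixed node subset
    to a thresholded minimum spanning forest, so the search only has to
    explore subsets. Deterministic starts (empty, all prized nodes) are
    complemented by seeded random subsets of the prized nodes; each start
    is improved by best-improvement single toggles plus pair toggles
    until locally optimal. Ties across starts break toward the
    lexicographically smallest node tuple.
    """
    costs = interactome.regularized_costs(params.alpha)
    adjacency = _adjacency(interactome, costs)
    prized = sorted(prizes.prized_nodes() & set(interactome.graph.nodes))
    small = interactome.n_nodes <= 24
    starts: list[set[str]] = [set(), set(prized)]
    rng = np.random.default_rng(seed)
    for _ in range(params.n_restarts):
        if prized:
            mask = rng.random(len(prized)) < 0.5
            starts.append({v for v, keep in zip(prized, mask) if keep})
    best_obj = 0.0
    best_subset: tuple[str, ...] = ()
    for start in starts:
        obj, subset = _local_search(
            start, adjacency, prizes, params, set(prized), small
        )
        key = tuple(sorted(subset))
        if obj > best_obj + 1e-12 or (
            abs(obj - best_obj) <= 1e-12 and key < best_subset
        ):
            best_obj, best_subset = obj, key
    # enforce forest invariant: no isolated zero-prize (Steiner) nodes
    subset = set(best_subset)
    _, edges, _ = _best_forest_on_subset(subset, adjacency, prizes, params)
    touched = {v for e in edges for v in e}
    subset = {v for v in subset if v in touched or prizes.get(v) > 0}
    return _make_solution(subset, adjacency, prizes, params)


def force_include(prizes: PrizeMap, node_id: str, interactome: Interactome) -> PrizeMap:
    """Pin a node into the solution by assigning it 10x the current max prize.

    Used for the disease gene when it is not detected in the proteomics.
    Calling twice multiplies again relative to the new maximum.
    """
    if node_id not in interactome.graph:
        raise ValueError(f"node {node_id!r} not in interactome")
    current_max = max(prizes.prizes.values(), default=0.0)
    new = dict(prizes.prizes)
    new[node_id] = 10.0 * max(current_max, 1e-9)
    prov = dict(prizes.provenance)
    prov[node_id] = "forced"
    return PrizeMap(prizes=new, provenance=prov)


def assign_prizes(
    protein_table, tf_table=None, fdr: float = 0.1
) -> PrizeMap:
    """Map differential tables to node prizes.

    Protein prize = |log2FC| of proteins significant at the given FDR;
    TF prize = min(1, -log10(enrichment FDR) / 10). Both mappings are
    simple monotone encodings of evidence strength and can be replaced by
    the caller.
    """
    prizes: dict[str, float] = {}
    provenance: dict[str, str] = {}
    for _, row in protein_table.iterrows():
        if row["fdr"] < fdr:
            prizes[row["id"]] = abs(float(row["log2fc"]))
            provenance[row["id"]] = "protein"
    if tf_table is not None:
        for _, row in tf_table.iterrows():
            val = min(1.0, -math.log10(max(float(row["fdr"]), 1e-300)) / 10.0)
            if val > prizes.get(row["id"], 0.0):
                prizes[row["id"]] = val
                provenance[row["id"]] = "TF"
    return PrizeMap(prizes=prizes, provenance=provenance)


def _solve_with_costs(
    interactome: Interactome,
    adjacency: Mapping[str, list[tuple[str, float]]],
    prizes: PrizeMap,
    params: Hyperparameters,
    rng: np.random.Generator,
) -> set[str]:
    prized = sorted(prizes.prized_nodes() & set(interactome.graph.nodes))
    small = interactome.n_nodes <= 24
    starts: list[set[str]] = [set(prized)]
    for _ in range(max(0, params.n_restarts - 1)):
        if prized:
            mask = rng.random(len(prized)) < 0.5
            starts.append({v for v, keep in zip(prized, mask) if keep})
    best_obj, best_subset = 0.0, set()
    for start in starts:
        obj, subset = _local_search(
            start, adjacency, prizes, params, set(prized), small
        )
        if obj > best_obj + 1e-12:
            best_obj, best_subset = obj, subset
    _, edges, _ = _best_forest_on_subset(best_subset, adjacency, prizes, params)
    touched = {v for e in edges for v in e}
    return {v for v in best_subset if v in touched or prizes.get(v) > 0}


def robustness_ensemble(
    interactome: Interactome,
    prizes: PrizeMap,
    params: Hyperparameters,
    seed: int | None = None,
) -> RobustnessSummary:
    """Noise-perturbed re-solves: per-node inclusion frequency and top-k set.

    Each replicate multiplies every base edge cost by exp(Normal(0,
    noise_sd)) (the hub penalty is recomputed on top), re-solves, and
    records the solution nodes. The top_k most frequent nodes are kept
    (ties broken by higher prize, then lexicographically) and nodes with
    no interactome edge to another selected node are dropped.
    """
    rng = np.random.default_rng(seed)
    base_costs = interactome.regularized_costs(0.0)
    penalty = {
        e: c - base_costs[e]
        for e, c in interactome.regularized_costs(params.alpha).items()
    }
    edge_keys = sorted(base_costs)
    counts: dict[str, int] = {}
    for _ in range(params.reps):
        noise = np.exp(rng.normal(0.0, params.noise_sd, size=len(edge_keys)))
        noisy = {
            e: base_costs[e] * f + penalty[e] for e, f in zip(edge_keys, noise)
        }
        adjacency = _adjacency(interactome, noisy)
        nodes = _solve_with_costs(interactome, adjacency, prizes, params, rng)
        for v in nodes:
            counts[v] = counts.get(v, 0) + 1
    freq = {v: counts.get(v, 0) / params.reps for v in interactome.graph.nodes}
    ranked = sorted(
        (v for v in freq if freq[v] > 0),
        key=lambda v: (-freq[v], -prizes.get(v), v),
    )
    selected = ranked[: params.top_k]
    keep = set(selected)
    connected = {
        v
        for v in keep
        if any(nbr in keep for nbr in interactome.graph.neighbors(v))
    }
    return RobustnessSummary(
        inclusion_frequency=freq, selected=tuple(sorted(connected))
    )


def specificity_ensemble(
    interactome: Interactome,
    prizes: PrizeMap,
    params: Hyperparameters,
    seed: int | None = None,
) -> dict[str, float]:
    """Random-prize re-solves: frequency each node appears regardless of input.

    The multiset of prize values is placed on uniformly random nodes each
    replicate; a node that keeps appearing is structurally favored (for
    example a hub) rather than driven by the actual data, so high
    frequency means low specificity.
    """
    rng = np.random.default_rng(seed)
    costs = interactome.regularized_costs(params.alpha)
    adjacency = _adjacency(interactome, costs)
    all_nodes = interactome.nodes
    values = sorted(prizes.prizes.values(), reverse=True)
    counts: dict[str, int] = {}
    for _ in range(params.reps):
        targets = rng.choice(len(all_nodes), size=len(values), replace=False)
        rand_prizes = PrizeMap(
            prizes={all_nodes[i]: val for i, val in zip(targets, values)}
        )
        nodes = _solve_with_costs(
            interactome, adjacency, rand_prizes, params, rng
        )
        for v in nodes:
            counts[v] = counts.get(v, 0) + 1
    return {v: counts.get(v, 0) / params.reps for v in all_nodes}


def select_parameters(
    grid: Sequence[Hyperparameters],
    interactome: Interactome,
    prizes: PrizeMap,
    spec_threshold: float = 0.3,
    deg_threshold: float = 0.2,
    seed: int | None = None,
) -> dict:
    """Pick hyperparameters by the three published criteria.

    A setting passes when its solution (1) performs feature selection
    (retains < 100% of prized nodes), (2) is specific (mean random-prize
    frequency of its nodes <= spec_threshold), and (3) has a node degree
    distribution close to that of the prized nodes (two-sample KS
    distance <= deg_threshold). Among passing settings the one retaining
    the largest prize fraction wins; ties keep grid order. If nothing
    passes, ``chosen`` is None and the diagnostics say which criterion
    failed where.
    """
    from scipy import stats as sps

    if not grid:
        raise ValueError("parameter grid must be non-empty")
    prized = prizes.prized_nodes() & set(interactome.graph.nodes)
    prize_degrees = np.array([interactome.degree(v) for v in sorted(prized)])
    diagnostics = []
    best = None
    for i, params in enumerate(grid):
        solution = solve_pcsf(interactome, prizes, params, seed=seed)
        sol_nodes = solution.node_set()
        retained = len(sol_nodes & prized) / len(prized) if prized else 0.0
        spec = specificity_ensemble(interactome, prizes, params, seed=seed)
        mean_spec = (
            float(np.mean([spec[v] for v in sorted(sol_nodes)]))
            if sol_nodes
            else 0.0
        )
        sol_degrees = np.array(
            [interactome.degree(v) for v in sorted(sol_nodes)]
        )
        if sol_degrees.size and prize_degrees.size:
            deg_dist = float(sps.ks_2samp(sol_degrees, prize_degrees).statistic)
        else:
            deg_dist = 1.0
        row = {
            "index": i,
            "params": params,
            "retained_fraction": retained,
            "feature_selection": retained < 1.0,
            "mean_specificity": mean_spec,
            "specific": mean_spec <= spec_threshold,
            "degree_distance": deg_dist,
            "degree_matched": deg_dist <= deg_threshold,
        }
        row["passes"] = (
            row["feature_selection"] and row["specific"] and row["degree_matched"]
        )
        diagnostics.append(row)
        if row["passes"] and (
            best is None or retained > diagnostics[best]["retained_fraction"]
        ):
            best = i
    return {
        "chosen": None if best is None else grid[best],
        "chosen_index": best,
        "diagnostics": diagnostics,
    }
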