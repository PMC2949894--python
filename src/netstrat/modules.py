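"""Module extraction and the modular compatibility score Cp.

Three community-extraction algorithms are provided:

* k-clique percolation (density-based, overlapping): communities are the
  connected components of the k-clique adjacency structure, two k-cliques
  being adjacent when they share k-1 nodes;
* simulated-annealing maximization of the modularity score
  M = sum_s [ l_s/L - (k_s/2L)^2 ], where L is the network's edge count,
  l_s a module's internal edge count and k_s the sum of its node degrees;
* iterative removal of the highest-edge-betweenness edge until a chosen
  fraction of edges is gone, the residue's connected components (singletons
  dropped) being the modules.

Two module sets are compared with the modular compatibility score Cp: each
module is matched to the module of the other set sharing the most nodes,
the match being admissible only when the shared nodes cover at least 50% of
the focal module; the per-module overlap terms C/(T+P-C) are averaged within
each matching direction and the two directions are averaged.  Unmatched
modules contribute 0.  Under this normalization Cp lies in [0, 1] and
Cp(S, S) = 1.
"""

from __future__ import annotations

import itertools
import math
import random
from dataclasses import dataclass, field
from typing import Callable, Sequence

import networkx as nx
import numpy as np
import pandas as pd
from scipy import stats

from netstrat.graph_core import Network

Module = frozenset[str]


@dataclass
class ModuleSet:
    """Modules extracted from one network by one algorithm run."""

    network: str
    algorithm: str
    params: dict
    modules: list[Module]
    overlapping: bool = False

    def __post_init__(self) -> None:
        # canonical order: larger modules first, then lexicographic content
        self.modules = sorted(
            (frozenset(m) for m in self.modules),
            key=lambda m: (-len(m), tuple(sorted(m))),
        )

    def __len__(self) -> int:
        return len(self.modules)

    def nodes(self) -> set[str]:
        out: set[str] = set()
        for m in self.modules:
            out |= m
        return out

    def filtered(self, min_size: int) -> "ModuleSet":
        """Copy keeping only modules with at least ``min_size`` nodes."""
        return ModuleSet(
            network=self.network,
            algorithm=self.algorithm,
            params=dict(self.params, min_size=min_size),
            modules=[m for m in self.modules if len(m) >= min_size],
            overlapping=self.overlapping,
        )


# ---------------------------------------------------------------------------
# clique percolation


def clique_percolation(net: Network, k: int = 4) -> ModuleSet:
    """Overlapping communities by k-clique percolation.

    Uses the standard equivalence with maximal cliques: maximal cliques of
    size >= k are chained whenever they share at least k-1 nodes, and each
    community is the union of the chained cliques' nodes.  A k larger than
    the maximum clique yields an empty module set.
    """
    if k < 3:
        raise ValueError(f"k must be >= 3, got {k}")
    g = net.to_networkx()
    cliques = [frozenset(c) for c in nx.find_cliques(g) if len(c) >= k]
    cliques.sort(key=lambda c: tuple(sorted(c)))
    # index cliques by their (k-1)-subsets to find percolation adjacency
    perc = nx.Graph()
    perc.add_nodes_from(range(len(cliques)))
    membership: dict[frozenset, list[int]] = {}
    for i, c in enumerate(cliques):
        for sub in itertools.combinations(sorted(c), k - 1):
            membership.setdefault(frozenset(sub), []).append(i)
    for idxs in membership.values():
        for i, j in itertools.combinations(idxs, 2):
            perc.add_edge(i, j)
    communities = []
    for comp in nx.connected_components(perc):
        nodes: set[str] = set()
        for i in comp:
            nodes |= cliques[i]
        communities.append(frozenset(nodes))
    return ModuleSet(
        network=net.name,
        algorithm="cpm",
        params={"k": k},
        modules=communities,
        overlapping=True,
    )


# ---------------------------------------------------------------------------
# modularity and its simulated-annealing maximization


def modularity(net: Network, partition: Sequence[set[str]]) -> float | None:
    """Modularity M of a disjoint partition covering all nodes.

    M = sum_s [ l_s/L - (k_s/2L)^2 ].  Returns None for an edgeless network.
    """
    L = net.n_edges
    if L == 0:
        return None
    seen: set[str] = set()
    for part in partition:
        if seen & set(part):
            raise ValueError("partition modules overlap")
        seen |= set(part)
    if seen != net.nodes:
        raise ValueError("partition does not cover the node set exactly")
    g = net.to_networkx()
    degree = dict(g.degree())
    m = 0.0
    for part in partition:
        ls = sum(1 for a, b in net.edges if a in part and b in part)
        ks = sum(degree[v] for v in part)
        m += ls / L - (ks / (2 * L)) ** 2
    return m


@dataclass
class SASchedule:
    """Annealing schedule: geometric cooling from t0 down to t_min.

    Per temperature, ``node_moves`` single-node reassignments and
    ``merge_split_moves`` merge/split proposals are attempted.  Defaults
    (|V|^2 node moves, |V| merge/split moves, t0 = 1, cooling 0.95,
    t_min = 1e-3) follow the classical annealing lineage for modularity and
    may be reduced for large networks.
    """

    t0: float = 1.0
    cooling: float = 0.95
    t_min: float = 1e-3
    node_moves: int | None = None  # default |V|^2
    merge_split_moves: int | None = None  # default |V|


class _SAState:
    """Incremental partition state for modularity annealing."""

    def __init__(self, net: Network) -> None:
        g = net.to_networkx()
        self.L = net.n_edges
        self.adj = {v: sorted(g.neighbors(v)) for v in net.sorted_nodes()}
        self.degree = {v: len(nbrs) for v, nbrs in self.adj.items()}
        self.nodes = net.sorted_nodes()
        # start from singletons
        self.comm_of = {v: i for i, v in enumerate(self.nodes)}
        self.members: dict[int, set[str]] = {i: {v} for i, v in enumerate(self.nodes)}
        self.l_s = {i: 0 for i in self.members}
        self.k_s = {i: self.degree[v] for i, v in enumerate(self.nodes)}
        self.next_label = len(self.nodes)
        self.m = sum(
            -((k / (2 * self.L)) ** 2) for k in self.k_s.values()
        )

    def links_to(self, v: str, comm: int) -> int:
        members = self.members[comm]
        return sum(1 for u in self.adj[v] if u in members and u != v)

    def delta_move(self, v: str, target: int) -> float:
        src = self.comm_of[v]
        if src == target:
            return 0.0
        L, kv = self.L, self.degree[v]
        l_out = self.links_to(v, src)
        l_in = self.links_to(v, target)
        d = (l_in - l_out) / L
        d -= ((self.k_s[target] + kv) ** 2 - self.k_s[target] ** 2) / (4 * L * L)
        d -= ((self.k_s[src] - kv) ** 2 - self.k_s[src] ** 2) / (4 * L * L)
        return d

    def apply_move(self, v: str, target: int, delta: float) -> None:
        src = self.comm_of[v]
        kv = self.degree[v]
        self.l_s[src] -= self.links_to(v, src)
        self.k_s[src] -= kv
        self.members[src].discard(v)
        if not self.members[src]:
            del self.members[src], self.l_s[src], self.k_s[src]
        self.l_s[target] += self.links_to(v, target)
        self.k_s[target] += kv
        self.members[target].add(v)
        self.comm_of[v] = target
        self.m += delta

    def new_community(self) -> int:
        label = self.next_label
        self.next_label += 1
        self.members[label] = set()
        self.l_s[label] = 0
        self.k_s[label] = 0
        return label

    def edges_between(self, c1: int, c2: int) -> int:
        a, b = self.members[c1], self.members[c2]
        if len(a) > len(b):
            a, b = b, a
        return sum(1 for v in a for u in self.adj[v] if u in b)

    def delta_merge(self, c1: int, c2: int) -> float:
        e = self.edges_between(c1, c2)
        return e / self.L - 2 * self.k_s[c1] * self.k_s[c2] / (4 * self.L * self.L)

    def apply_merge(self, c1: int, c2: int, delta: float) -> None:
        e = self.edges_between(c1, c2)
        for v in self.members[c2]:
            self.comm_of[v] = c1
        self.members[c1] |= self.members[c2]
        self.l_s[c1] += self.l_s[c2] + e
        self.k_s[c1] += self.k_s[c2]
        del self.members[c2], self.l_s[c2], self.k_s[c2]
        self.m += delta

    def partition(self) -> list[frozenset[str]]:
        return [frozenset(m) for m in self.members.values()]


def sa_modularity(
    net: Network,
    schedule: SASchedule | None = None,
    seed: int = 0,
) -> ModuleSet:
    """Partition by simulated-annealing maximization of modularity M.

    Moves are single-node reassignments (to a neighboring community or a
    fresh one) plus community merge and random-bipartition split proposals,
    accepted by the Metropolis rule on the modularity gain.  The best
    partition seen is returned; the run is fully reproducible under ``seed``.
    """
    schedule = schedule or SASchedule()
    rng = random.Random(seed)
    if net.n_edges == 0:
        return ModuleSet(net.name, "sa", {"seed": seed}, [frozenset({v}) for v in net.nodes])
    state = _SAState(net)
    n = len(state.nodes)
    node_moves = schedule.node_moves if schedule.node_moves is not None else n * n
    ms_moves = (
        schedule.merge_split_moves if schedule.merge_split_moves is not None else n
    )
    best_m = state.m
    best_partition = state.partition()
    t = schedule.t0
    while t > schedule.t_min:
        for _ in range(node_moves):
            v = rng.choice(state.nodes)
            neigh_comms = sorted({state.comm_of[u] for u in state.adj[v]} - {state.comm_of[v]})
            if neigh_comms and rng.random() < 0.9:
                target = rng.choice(neigh_comms)
            else:
                target = state.new_community()
            delta = state.delta_move(v, target)
            if delta >= 0 or rng.random() < math.exp(delta / t):
                state.apply_move(v, target, delta)
            elif not state.members[target]:
                del state.members[target], state.l_s[target], state.k_s[target]
        for _ in range(ms_moves):
            labels = sorted(state.members)
            if rng.random() < 0.5 and len(labels) >= 2:
                c1, c2 = rng.sample(labels, 2)
                delta = state.delta_merge(c1, c2)
                if delta >= 0 or rng.random() < math.exp(delta / t):
                    state.apply_merge(c1, c2, delta)
            else:
                c = rng.choice(labels)
                members = sorted(state.members[c])
                if len(members) < 2:
                    continue
                half = rng.sample(members, len(members) // 2)
                target = state.new_community()
                deltas = 0.0
                moved: list[str] = []
                for v in half:
                    d = state.delta_move(v, target)
                    state.apply_move(v, target, d)
                    deltas += d
                    moved.append(v)
                if deltas < 0 and rng.random() >= math.exp(deltas / t):
                    for v in moved:  # revert
                        d = state.delta_move(v, c)
                        state.apply_move(v, c, d)
        if state.m > best_m:
            best_m = state.m
            best_partition = state.partition()
        t *= schedule.cooling
    return ModuleSet(
        network=net.name,
        algorithm="sa",
        params={
            "seed": seed,
            "t0": schedule.t0,
            "cooling": schedule.cooling,
            "t_min": schedule.t_min,
            "node_moves": node_moves,
            "merge_split_moves": ms_moves,
        },
        modules=best_partition,
    )


# ---------------------------------------------------------------------------
# edge-betweenness partitioning


def girvan_newman(net: Network, removal_fraction: float = 0.4) -> ModuleSet:
    """Partition by iterative removal of the highest-edge-betweenness edge.

    round(removal_fraction * L) edges are removed, recomputing edge
    betweenness after each removal (ties broken by sorted edge ID); the
    modules are the connected components of the residue, singleton
    components dropped.
    """
    if not 0 <= removal_fraction < 1:
        raise ValueError(f"removal_fraction must be in [0, 1), got {removal_fraction}")
    g = net.to_networkx().copy()
    n_remove = round(removal_fraction * net.n_edges)
    for _ in range(n_remove):
        eb = nx.edge_betweenness_centrality(g, normalized=False)
        best = min(
            eb, key=lambda e: (-eb[e], tuple(sorted(e)))
        )
        g.remove_edge(*best)
    comps = [frozenset(c) for c in nx.connected_components(g) if len(c) >= 2]
    return ModuleSet(
        network=net.name,
        algorithm="gn",
        params={"removal_fraction": removal_fraction},
        modules=comps,
    )


# ---------------------------------------------------------------------------
# modular compatibility


@dataclass
class MatchRecord:
    """Best-match bookkeeping for one focal module (one direction)."""

    focal_index: int
    focal_size: int  # T
    match_index: int | None
    match_size: int | None  # P
    shared: int  # C
    term: float  # C / (T + P - C), 0 when unmatched


@dataclass
class CpResult:
    pair: tuple[str, str]
    cp: float
    direction_1: float
    direction_2: float
    matches_1: list[MatchRecord] = field(default_factory=list)
    matches_2: list[MatchRecord] = field(default_factory=list)
    metadata: dict[str, str] = field(
        default_factory=lambda: {
            "matching": "most shared nodes; admissible if shared >= 50% of the focal module",
            "normalization": "per-direction mean of module terms, directions averaged",
            "tie_break": "larger Jaccard with focal module, then lexicographic module content",
        }
    )


def _best_match(focal: Module, candidates: list[Module]) -> MatchRecord:
    best: tuple[int, float, tuple[str, ...]] | None = None
    best_idx: int | None = None
    for j, cand in enumerate(candidates):
        shared = len(focal & cand)
        if shared == 0:
            continue
        jac = shared / len(focal | cand)
        key = (shared, jac, tuple(sorted(cand)))
        if best is None or (key[0], key[1]) > (best[0], best[1]) or (
            (key[0], key[1]) == (best[0], best[1]) and key[2] < best[2]
        ):
            best = key
            best_idx = j
    t = len(focal)
    if best is None or best[0] < 0.5 * t:
        return MatchRecord(-1, t, None, None, best[0] if best else 0, 0.0)
    c = best[0]
    p = len(candidates[best_idx])
    return MatchRecord(-1, t, best_idx, p, c, c / (t + p - c))


def modular_compatibility(s1: ModuleSet, s2: ModuleSet) -> CpResult:
    """Modular compatibility score Cp between two module sets.

    Each direction matches every module against the other set (most shared
    nodes, 50% coverage rule), averages the per-module terms C/(T+P-C) over
    the direction's module count, and Cp is the mean of the two directions.
    """
    if not s1.modules or not s2.modules:
        raise ValueError("modular compatibility of an empty module set is undefined")
    matches_1 = []
    for i, m in enumerate(s1.modules):
        rec = _best_match(m, s2.modules)
        rec.focal_index = i
        matches_1.append(rec)
    matches_2 = []
    for j, m in enumerate(s2.modules):
        rec = _best_match(m, s1.modules)
        rec.focal_index = j
        matches_2.append(rec)
    d1 = sum(r.term for r in matches_1) / len(matches_1)
    d2 = sum(r.term for r in matches_2) / len(matches_2)
    return CpResult(
        pair=(s1.network, s2.network),
        cp=0.5 * (d1 + d2),
        direction_1=d1,
        direction_2=d2,
        matches_1=matches_1,
        matches_2=matches_2,
    )


# ---------------------------------------------------------------------------
# the Cp comparison protocol

_ALGORITHMS: dict[str, Callable[..., ModuleSet]] = {
    "cpm": clique_percolation,
    "sa": sa_modularity,
    "gn": girvan_newman,
}

# k = 3 clique percolation is excluded from the default grid: on dense
# conglomerate-scale networks it notoriously percolates into one giant
# community, which measures the percolation transition rather than module
# structure
DEFAULT_GRIDS: dict[str, list[dict]] = {
    "cpm": [{"k": 4}, {"k": 5}],
    "sa": [{"seed": 11}, {"seed": 23}, {"seed": 47}],
    "gn": [{"removal_fraction": 0.3}, {"removal_fraction": 0.4}, {"removal_fraction": 0.5}],
}


def cp_comparison_protocol(
    family,
    algorithm: str = "cpm",
    param_grid: list[dict] | None = None,
    min_module_size: int = 3,
    levels: tuple[int, ...] = (3,),
    sa_schedule: "SASchedule | None" = None,
) -> dict:
    """Compare total-vs-subnetwork Cp with within-network Cp across parameters.

    Group (i): Cp between the total network's modules and each stratified
    subnetwork's modules at matched clustering parameters.  Group (ii): Cp
    between module sets of the same network obtained with different
    parameter settings.  The two groups are compared with a two-sided
    Mann-Whitney U test.
    """
    if algorithm not in _ALGORITHMS:
        raise ValueError(f"unknown algorithm {algorithm!r}")
    grid = param_grid if param_grid is not None else DEFAULT_GRIDS[algorithm]
    if len(grid) < 2:
        raise ValueError("param_grid needs at least two parameter settings")
    extract = _ALGORITHMS[algorithm]
    networks = [family.total] + [
        n for lvl in levels for n in family.at_level(lvl) if n.name != family.total.name
    ]
    modsets: dict[tuple[str, int], ModuleSet] = {}
    for net in networks:
        for gi, params in enumerate(grid):
            kwargs = dict(params)
            if algorithm == "sa" and sa_schedule is not None:
                kwargs["schedule"] = sa_schedule
            modsets[(net.name, gi)] = extract(net, **kwargs).filtered(min_module_size)

    rows: list[dict] = []
    between: list[float] = []
    within: list[float] = []
    total_name = family.total.name
    for gi in range(len(grid)):
        for net in networks[1:]:
            s1, s2 = modsets[(total_name, gi)], modsets[(net.name, gi)]
            if not s1.modules or not s2.modules:
                continue
            cp = modular_compatibility(s1, s2).cp
            between.append(cp)
            rows.append({"group": "total_vs_subnetwork", "a": total_name, "b": net.name,
                         "params": repr(grid[gi]), "cp": cp})
    for net in networks:
        for gi, gj in itertools.combinations(range(len(grid)), 2):
            s1, s2 = modsets[(net.name, gi)], modsets[(net.name, gj)]
            if not s1.modules or not s2.modules:
                continue
            cp = modular_compatibility(s1, s2).cp
            within.append(cp)
            rows.append({"group": "within_network", "a": net.name, "b": net.name,
                         "params": f"{grid[gi]!r} vs {grid[gj]!r}", "cp": cp})
    report: dict = {
        "algorithm": algorithm,
        "table": pd.DataFrame(rows),
        "mean_cp_between": float(np.mean(between)) if between else float("nan"),
        "mean_cp_within": float(np.mean(within)) if within else float("nan"),
        "median_cp_between": float(np.median(between)) if between else float("nan"),
        "median_cp_within": float(np.median(within)) if within else float("nan"),
        "n_between": len(between),
        "n_within": len(within),
    }
    if len(between) >= 1 and len(within) >= 1:
        u = stats.mannwhitneyu(between, within, alternative="two-sided")
        report["mannwhitney_u"] = float(u.statistic)
        report["mannwhitney_p"] = float(u.pvalue)
    return report
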