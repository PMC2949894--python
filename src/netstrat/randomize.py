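"""Perturbation protocols: node-sampling nulls and false-interaction replacement.

Two protocols are implemented.  Node-sampling randomization mimics a
stratified subnetwork by overlaying a uniform random protein sample of the
source list's size onto the total network and keeping the induced
interactions, accepting a replicate only when its total degree (twice the
edge count) falls within a tolerance (default 10%) of the mimicked
subnetwork's.  Edge replacement emulates false interactions by removing a
fraction of edges uniformly and adding the same number of node pairs absent
from the original network, preserving node and edge counts exactly.
"""

from __future__ import annotations

from dataclasses import dataclass
from typing import Sequence

import numpy as np
import pandas as pd

from netstrat.graph_core import Network, canonical_edge, induce_subnetwork, node_stats
from netstrat.stratify import stratify_all
from netstrat.topology import identify_roles, status_change


def random_subnetwork(
    total: Network,
    n_proteins: int,
    tolerance: float = 0.10,
    seed: int | np.random.Generator = 0,
    max_retries: int = 200,
    reference_degree: int | None = None,
    universe: set[str] | None = None,
) -> Network:
    """One node-sampling randomized subnetwork of the total network.

    Samples ``n_proteins`` proteins uniformly from ``universe`` (the total
    protein list when given, otherwise the network's nodes) — matching the
    protein-list size, not the realized subnetwork size — overlays them onto
    the network by induction, and, when ``reference_degree`` is given,
    rejection-resamples until the replicate's total degree is within
    ``tolerance`` of it.
    """
    pool = sorted(universe) if universe is not None else total.sorted_nodes()
    if n_proteins > len(pool):
        raise ValueError(f"n_proteins {n_proteins} exceeds sampling universe size {len(pool)}")
    if tolerance <= 0:
        raise ValueError("tolerance must be positive")
    rng = np.random.default_rng(seed) if not isinstance(seed, np.random.Generator) else seed
    node_arr = np.array(pool)
    achieved: list[int] = []
    for attempt in range(max_retries):
        sample = set(rng.choice(node_arr, size=n_proteins, replace=False))
        net = induce_subnetwork(total, sample, name=f"{total.name}|rand{attempt}")
        if reference_degree is None:
            return net
        achieved.append(net.total_degree)
        if abs(net.total_degree - reference_degree) <= tolerance * reference_degree:
            return net
    raise RuntimeError(
        f"no replicate within {tolerance:.0%} of total degree {reference_degree} after "
        f"{max_retries} tries (achieved range {min(achieved)}-{max(achieved)})"
    )


def replace_interactions(
    net: Network,
    fraction: float,
    seed: int | np.random.Generator = 0,
    universe: Network | None = None,
) -> Network:
    """Replace a fraction of edges with pairs absent from the original network.

    round(fraction * L) uniformly chosen edges are removed and the same
    number of uniformly chosen absent node pairs (between existing nodes,
    and absent from ``universe`` too when given) are added, so |V| and |E|
    are conserved exactly.
    """
    if not 0 <= fraction < 1:
        raise ValueError(f"fraction must be in [0, 1), got {fraction}")
    rng = np.random.default_rng(seed) if not isinstance(seed, np.random.Generator) else seed
    n_replace = round(fraction * net.n_edges)
    if n_replace == 0:
        return Network(name=net.name, nodes=set(net.nodes), edges=set(net.edges),
                       edge_provenance=dict(net.edge_provenance) if net.edge_provenance else None)
    nodes = net.sorted_nodes()
    n = len(nodes)
    forbidden = set(net.edges)
    if universe is not None:
        forbidden |= universe.edges
    max_pairs = n * (n - 1) // 2
    if max_pairs - len(net.edges) < n_replace:
        raise ValueError("not enough absent node pairs to draw replacements from")
    edges = net.sorted_edges()
    drop_idx = rng.choice(len(edges), size=n_replace, replace=False)
    kept = set(edges) - {edges[i] for i in drop_idx}
    new_edges: set[tuple[str, str]] = set()
    guard = 0
    while len(new_edges) < n_replace:
        guard += 1
        if guard > 1000 * n_replace:
            raise RuntimeError("could not sample enough absent pairs")
        i, j = rng.integers(0, n, size=2)
        if i == j:
            continue
        e = canonical_edge(nodes[int(i)], nodes[int(j)])
        if e in forbidden or e in new_edges:
            continue
        new_edges.add(e)
    return Network(
        name=f"{net.name}|replaced{fraction:g}",
        nodes=set(net.nodes),
        edges=kept | new_edges,
    )


@dataclass
class StatusChangeNull:
    """Observed role status-change percentage vs its node-sampling null."""

    subnetwork: str
    kind: str
    observed_pct: float
    null_pcts: np.ndarray
    t_statistic: float
    p_value: float

    @property
    def null_mean(self) -> float:
        return float(self.null_pcts.mean())


def status_change_randomization(
    total: Network,
    total_stats,
    reference_sub: Network,
    list_size: int,
    universe: set[str],
    kind: str = "degree",
    pct: float = 20.0,
    n_rep: int = 20,
    tolerance: float = 0.10,
    seed: int | np.random.Generator = 0,
    max_retries: int = 200,
) -> StatusChangeNull:
    """Compare one subnetwork's role->non-role percentage with a null of
    node-sampling randomized subnetworks of matched protein-list size.

    Each of the ``n_rep`` replicates draws ``list_size`` proteins from the
    total protein list, induces the subnetwork, and must land within
    ``tolerance`` of the real subnetwork's total degree.  Observed and null
    percentages are compared by a one-sample two-sided Student's t-test.
    """
    from scipy import stats as sps

    rng = np.random.default_rng(seed) if not isinstance(seed, np.random.Generator) else seed
    needed = (kind,)
    ref_roles = identify_roles(total_stats, kind, pct)
    observed = status_change(
        ref_roles, identify_roles(node_stats(reference_sub, needed), kind, pct)
    ).pct_role_to_nonrole
    null = np.empty(n_rep)
    for i in range(n_rep):
        rand = random_subnetwork(
            total,
            list_size,
            tolerance=tolerance,
            seed=rng,
            max_retries=max_retries,
            reference_degree=reference_sub.total_degree,
            universe=universe,
        )
        null[i] = status_change(
            ref_roles, identify_roles(node_stats(rand, needed), kind, pct)
        ).pct_role_to_nonrole
    if np.allclose(null.std(ddof=1), 0.0):
        t, p = float("inf"), 0.0 if not np.isclose(observed, null.mean()) else 1.0
    else:
        res = sps.ttest_1samp(null, observed)
        t, p = float(res.statistic), float(res.pvalue)
    return StatusChangeNull(
        subnetwork=reference_sub.name,
        kind=kind,
        observed_pct=observed,
        null_pcts=null,
        t_statistic=t,
        p_value=p,
    )


@dataclass
class RobustnessReport:
    """Deltas of hub/bottleneck status-change percentages and network
    statistics between perturbed and unperturbed runs."""

    table: pd.DataFrame
    baseline: pd.DataFrame


def robustness_protocol(
    conglomerate: Network,
    hierarchy,
    fractions: Sequence[float] = (0.1, 0.2, 0.3, 0.4),
    seeds: Sequence[int] = (0,),
    kind: str = "degree",
    pct: float = 20.0,
    compare_level: int = 3,
) -> RobustnessReport:
    """False-interaction robustness of the status-change analysis.

    For each replacement fraction and seed, the conglomerate is rebuilt with
    replaced interactions, re-stratified against the same hierarchy, and the
    total-vs-subnetwork role status-change percentages and network-average
    statistics are recomputed; the report gives their deltas against the
    unperturbed run.
    """

    needed = ("degree", "clustering") if kind == "degree" else ("degree", "betweenness", "clustering")

    def run(con: Network) -> pd.DataFrame:
        family = stratify_all(con, hierarchy)
        total_stats = node_stats(family.total, needed)
        ref = identify_roles(total_stats, kind, pct)
        rows = []
        for sub in family.at_level(compare_level):
            if sub.n_nodes == 0:
                continue
            sub_stats = node_stats(sub, needed)
            rep = status_change(ref, identify_roles(sub_stats, kind, pct))
            rows.append(
                {
                    "subnetwork": sub.name,
                    "pct_role_to_nonrole": rep.pct_role_to_nonrole,
                    "pct_nonrole_to_role": rep.pct_nonrole_to_role,
                    "avg_degree": sub_stats.summary["avg_degree"],
                    "avg_clustering": sub_stats.summary["avg_clustering"],
                }
            )
        return pd.DataFrame(rows).set_index("subnetwork")

    baseline = run(conglomerate)
    rows = []
    for fraction in fractions:
        for seed in seeds:
            perturbed = replace_interactions(conglomerate, fraction, seed=seed)
            perturbed.name = conglomerate.name
            result = run(perturbed)
            joined = result.reindex(baseline.index)
            for sub in baseline.index:
                for col in baseline.columns:
                    rows.append(
                        {
                            "fraction": fraction,
                            "seed": seed,
                            "subnetwork": sub,
                            "metric": col,
                            "baseline": baseline.loc[sub, col],
                            "perturbed": joined.loc[sub, col],
                            "delta": joined.loc[sub, col] - baseline.loc[sub, col],
                        }
                    )
    return RobustnessReport(table=pd.DataFrame(rows), baseline=baseline)
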