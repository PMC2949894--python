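"""Network data model, file I/O, conglomerate assembly and per-node statistics.

Networks here are undirected simple graphs over opaque protein identifiers.
Edges are canonicalized as lexicographically sorted ID pairs; self-loops are
dropped at construction and duplicate edges across source datasets are merged
with their provenance unioned.  All iteration is over sorted IDs so that every
downstream tie-break is reproducible.
"""

from __future__ import annotations

import sys
from dataclasses import dataclass, field
from pathlib import Path
from typing import Iterable, Sequence

import networkx as nx
import pandas as pd

Edge = tuple[str, str]


def canonical_edge(a: str, b: str) -> Edge:
    """Canonical unordered pair: lexicographically sorted 2-tuple."""
    return (a, b) if a <= b else (b, a)


@dataclass
class Network:
    """An undirected simple graph of protein IDs.

    Parameters
    ----------
    name:
        Label for the network (dataset or context name).
    nodes:
        Set of protein IDs.  May contain isolated nodes only when they are
        explicitly retained (e.g. the raw conglomerate); stratified
        subnetworks never do.
    edges:
        Set of canonical unordered ID pairs; every endpoint must be in
        ``nodes``.
    edge_provenance:
        Optional map edge -> set of source-dataset labels.
    """

    name: str
    nodes: set[str] = field(default_factory=set)
    edges: set[Edge] = field(default_factory=set)
    edge_provenance: dict[Edge, frozenset[str]] | None = None

    def __post_init__(self) -> None:
        self.edges = {canonical_edge(a, b) for a, b in self.edges if a != b}
        missing = {v for e in self.edges for v in e} - self.nodes
        if missing:
            self.nodes |= missing
        self._nx: nx.Graph | None = None

    # -- basic accessors ---------------------------------------------------
    @property
    def n_nodes(self) -> int:
        return len(self.nodes)

    @property
    def n_edges(self) -> int:
        return len(self.edges)

    @property
    def total_degree(self) -> int:
        """Sum of node degrees, i.e. 2|E|."""
        return 2 * len(self.edges)

    def sorted_nodes(self) -> list[str]:
        return sorted(self.nodes)

    def sorted_edges(self) -> list[Edge]:
        return sorted(self.edges)

    def to_networkx(self) -> nx.Graph:
        """Deterministically ordered networkx view (cached)."""
        if self._nx is None:
            g = nx.Graph()
            g.add_nodes_from(self.sorted_nodes())
            g.add_edges_from(self.sorted_edges())
            self._nx = g
        return self._nx

    def __contains__(self, node: str) -> bool:
        return node in self.nodes

    def __repr__(self) -> str:  # pragma: no cover - cosmetic
        return f"Network({self.name!r}, n={self.n_nodes}, e={self.n_edges})"


@dataclass
class NodeStatsTable:
    """Per-node topological statistics plus network-level summaries.

    ``per_node`` is indexed by protein ID with columns ``degree``,
    ``betweenness`` (raw pair-dependency counts, endpoints excluded),
    ``clustering`` (local clustering coefficient, 0 for degree < 2) and
    ``eccentricity`` (within the node's connected component).
    """

    network: str
    per_node: pd.DataFrame
    summary: dict[str, float]

    def values(self, statistic: str) -> pd.Series:
        if statistic not in self.per_node.columns:
            raise KeyError(f"unknown statistic {statistic!r}")
        return self.per_node[statistic]


def assemble_conglomerate(
    edge_lists: Sequence[tuple[str, Iterable[tuple[str, str]]]],
    name: str = "conglomerate",
) -> Network:
    """Union several PPI edge datasets into one conglomerate network.

    Duplicate edges across sources are merged and their provenance labels
    unioned; self-loops are dropped; the node set is the union of all edge
    endpoints.
    """
    if not edge_lists:
        raise ValueError("no datasets")
    provenance: dict[Edge, set[str]] = {}
    nodes: set[str] = set()
    for label, pairs in edge_lists:
        for i, pair in enumerate(pairs):
            try:
                a, b = pair
            except (TypeError, ValueError) as exc:
                raise ValueError(f"dataset {label!r}: malformed pair at position {i}: {pair!r}") from exc
            if not a or not b:
                raise ValueError(f"dataset {label!r}: empty ID in pair at position {i}: {pair!r}")
            nodes.add(a)
            nodes.add(b)
            if a == b:
                continue  # self-loop
            provenance.setdefault(canonical_edge(a, b), set()).add(label)
    return Network(
        name=name,
        nodes=nodes,
        edges=set(provenance),
        edge_provenance={e: frozenset(s) for e, s in provenance.items()},
    )


def induce_subnetwork(net: Network, proteins: set[str], name: str | None = None) -> Network:
    """Subnetwork induced on a protein list: edges with both endpoints listed.

    Listed proteins without a surviving interaction are not members of the
    subnetwork (the stratified content is its interacting proteins); IDs
    absent from ``net`` are silently ignored.
    """
    listed = proteins & net.nodes
    edges = {e for e in net.edges if e[0] in listed and e[1] in listed}
    nodes = {v for e in edges for v in e}
    prov = None
    if net.edge_provenance is not None:
        prov = {e: net.edge_provenance[e] for e in edges if e in net.edge_provenance}
    return Network(name=name or f"{net.name}|induced", nodes=nodes, edges=edges, edge_provenance=prov)


ALL_STATISTICS = ("degree", "betweenness", "clustering", "eccentricity")


def node_stats(
    net: Network, statistics: Sequence[str] = ALL_STATISTICS
) -> NodeStatsTable:
    """Per-node topological statistics with network-level summaries.

    Betweenness is the unnormalized count of shortest paths through a node
    with fractional credit for ties (pair-dependency accumulation), endpoints
    excluded.  Eccentricity is computed within each node's connected
    component; the network average eccentricity averages over all nodes.
    ``statistics`` restricts the computed columns (betweenness and
    eccentricity cost all-pairs shortest paths).
    """
    if net.n_nodes == 0:
        raise ValueError(f"network {net.name!r} is empty")
    unknown = set(statistics) - set(ALL_STATISTICS)
    if unknown:
        raise ValueError(f"unknown statistics: {sorted(unknown)}")
    g = net.to_networkx()
    order = net.sorted_nodes()
    columns: dict[str, list] = {}
    if "degree" in statistics:
        degree = dict(g.degree())
        columns["degree"] = [degree[v] for v in order]
    if "betweenness" in statistics:
        betweenness = nx.betweenness_centrality(g, normalized=False)
        columns["betweenness"] = [betweenness[v] for v in order]
    if "clustering" in statistics:
        clustering = nx.clustering(g)
        columns["clustering"] = [clustering[v] for v in order]
    if "eccentricity" in statistics:
        eccentricity: dict[str, int] = {}
        for comp in nx.connected_components(g):
            eccentricity.update(nx.eccentricity(g.subgraph(comp)))
        columns["eccentricity"] = [eccentricity[v] for v in order]
    per_node = pd.DataFrame(columns, index=pd.Index(order, name="protein"))
    summary = {"n_nodes": float(net.n_nodes), "n_edges": float(net.n_edges)}
    for col in per_node.columns:
        summary[f"avg_{col}"] = float(per_node[col].mean())
        summary[f"max_{col}"] = float(per_node[col].max())
    return NodeStatsTable(network=net.name, per_node=per_node, summary=summary)


# -- file I/O ---------------------------------------------------------------

def read_network(path: str | Path, name: str | None = None) -> Network:
    """Read a two-column TSV edge list (optional third provenance column).

    Lines starting with ``#`` and blank lines are skipped; whitespace-separated
    columns are accepted.  Duplicate lines and reversed duplicates collapse to
    a single canonical edge.
    """
    path = Path(path)
    provenance: dict[Edge, set[str]] = {}
    edges: set[Edge] = set()
    nodes: set[str] = set()
    with path.open() as fh:
        for lineno, line in enumerate(fh, 1):
            line = line.strip()
            if not line or line.startswith("#"):
                continue
            cols = line.split()
            if len(cols) < 2:
                raise ValueError(f"{path}:{lineno}: expected at least two columns, got {line!r}")
            a, b = cols[0], cols[1]
            nodes.add(a)
            nodes.add(b)
            if a == b:
                continue
            e = canonical_edge(a, b)
            edges.add(e)
            if len(cols) >= 3:
                provenance.setdefault(e, set()).update(cols[2].split(","))
    prov = {e: frozenset(s) for e, s in provenance.items()} if provenance else None
    return Network(name=name or path.stem, nodes=nodes, edges=edges, edge_provenance=prov)


def write_network(net: Network, path: str | Path) -> None:
    """Write a network as a TSV edge list with a commented header."""
    path = Path(path)
    with path.open("w") as fh:
        fh.write(f"# network: {net.name}\tnodes: {net.n_nodes}\tedges: {net.n_edges}\n")
        for a, b in net.sorted_edges():
            if net.edge_provenance and (a, b) in net.edge_provenance:
                src = ",".join(sorted(net.edge_provenance[(a, b)]))
                fh.write(f"{a}\t{b}\t{src}\n")
            else:
                fh.write(f"{a}\t{b}\n")


def read_protein_list(path: str | Path) -> set[str]:
    """Read a protein list file, one ID per line ('#' comments allowed)."""
    out: set[str] = set()
    with Path(path).open() as fh:
        for line in fh:
            line = line.strip()
            if line and not line.startswith("#"):
                out.add(line.split()[0])
    return out


def log(msg: str) -> None:
    print(msg, file=sys.stderr)
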