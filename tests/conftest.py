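import itertools

import networkx as nx
import pytest

from netstrat.graph_core import Network, canonical_edge
from netstrat.synthdata import demo_fixture
from netstrat.stratify import stratify_all


def make_network(name: str, edges) -> Network:
    return Network(name=name, edges={canonical_edge(a, b) for a, b in edges})


def gnp_network(n: int, p: float, seed: int, name: str | None = None) -> Network:
    """Seeded Erdos-Renyi fixture with string node IDs."""
    g = nx.gnp_random_graph(n, p, seed=seed)
    edges = {canonical_edge(f"n{a:02d}", f"n{b:02d}") for a, b in g.edges()}
    nodes = {f"n{i:02d}" for i in range(n)}
    return Network(name=name or f"gnp{n}", nodes=nodes, edges=edges)


@pytest.fixture(scope="session")
def two_triangles_bridge() -> Network:
    """Two triangles {a,b,c} and {d,e,f} joined by the bridge c-d (L=7)."""
    return make_network(
        "tri_bridge",
        [("a", "b"), ("b", "c"), ("a", "c"), ("c", "d"), ("d", "e"), ("e", "f"), ("d", "f")],
    )


@pytest.fixture(scope="session")
def path3() -> Network:
    return make_network("path3", [("a", "b"), ("b", "c")])


@pytest.fixture(scope="session")
def triangle() -> Network:
    return make_network("triangle", [("a", "b"), ("b", "c"), ("a", "c")])


@pytest.fixture(scope="session")
def small_fixtures(two_triangles_bridge) -> list[Network]:
    """Connected and disconnected fixtures of <= 40 nodes for oracle tests."""
    karate = nx.karate_club_graph()
    knet = Network(
        name="karate",
        nodes={f"k{v:02d}" for v in karate.nodes()},
        edges={canonical_edge(f"k{a:02d}", f"k{b:02d}") for a, b in karate.edges()},
    )
    return [
        two_triangles_bridge,
        gnp_network(12, 0.30, seed=3),
        gnp_network(25, 0.15, seed=7),
        gnp_network(40, 0.08, seed=11),
        knet,
    ]


@pytest.fixture(scope="session")
def tiny_fixtures() -> list[Network]:
    """<= 8-node fixtures used for exhaustive-partition comparisons."""
    two_tri = make_network(
        "two_triangles",
        [("a", "b"), ("b", "c"), ("a", "c"), ("d", "e"), ("e", "f"), ("d", "f")],
    )
    tri_bridge = make_network(
        "tri_bridge",
        [("a", "b"), ("b", "c"), ("a", "c"), ("c", "d"), ("d", "e"), ("e", "f"), ("d", "f")],
    )
    barbell = make_network(
        "barbell44",
        list(itertools.combinations("abcd", 2))
        + list(itertools.combinations("efgh", 2))
        + [("d", "e")],
    )
    cycle6 = make_network("cycle6", list(zip("abcdef", "bcdefa")))
    path8 = make_network("path8", list(zip("abcdefg", "bcdefgh")))
    single_edge = make_network("single_edge", [("a", "b")])
    return [two_tri, tri_bridge, barbell, cycle6, path8, single_edge]


@pytest.fixture(scope="session")
def demo_bundle():
    return demo_fixture(seed=0)


@pytest.fixture(scope="session")
def demo_family(demo_bundle):
    return stratify_all(demo_bundle.conglomerate, demo_bundle.hierarchy)
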