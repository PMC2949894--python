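import math

import networkx as nx
import pytest

from netstrat.graph_core import Network
from netstrat.modules import (
    ModuleSet,
    SASchedule,
    clique_percolation,
    cp_comparison_protocol,
    girvan_newman,
    modular_compatibility,
    modularity,
    sa_modularity,
)
from tests.conftest import gnp_network, make_network
from tests.oracles import (
    brute_edge_betweenness,
    brute_kclique_communities,
    brute_modularity,
)


def modset(*mods, name="x", algorithm="manual"):
    return ModuleSet(network=name, algorithm=algorithm, params={}, modules=[frozenset(m) for m in mods])


# ---------------------------------------------------------------------------
# clique percolation


def test_cpm_worked_examples(triangle, path3):
    assert clique_percolation(triangle, 3).modules == [frozenset("abc")]
    two_tri_shared = make_network(
        "shared", [("a", "b"), ("b", "c"), ("a", "c"), ("b", "d"), ("c", "d")]
    )
    assert clique_percolation(two_tri_shared, 3).modules == [frozenset("abcd")]
    assert clique_percolation(path3, 3).modules == []
    with pytest.raises(ValueError, match="k must be"):
        clique_percolation(triangle, 2)


def test_cpm_matches_brute_oracle(small_fixtures):
    for net in small_fixtures:
        for k in (3, 4):
            got = {frozenset(m) for m in clique_percolation(net, k).modules}
            want = brute_kclique_communities(net.sorted_nodes(), net.edges, k)
            assert got == want, (net.name, k)


def test_cpm_structural_properties(small_fixtures):
    for net in small_fixtures:
        ms = clique_percolation(net, 4)
        g = net.to_networkx()
        cliques = [frozenset(c) for c in nx.find_cliques(g) if len(c) >= 4]
        for m in ms.modules:
            # every community contains at least one k-clique
            assert any(c <= m for c in cliques)
        # every maximal k-clique lands inside exactly one community
        for c in cliques:
            assert sum(1 for m in ms.modules if c <= m) == 1


# ---------------------------------------------------------------------------
# modularity


def test_modularity_worked_values(two_triangles_bridge, triangle):
    m = modularity(two_triangles_bridge, [set("abc"), set("def")])
    assert math.isclose(m, 5 / 14, abs_tol=1e-12)
    assert f"{m:.6f}" == "0.357143"  # 0.357142857...
    assert modularity(triangle, [set("abc")]) == 0.0
    assert modularity(Network(name="e", nodes={"a", "b"}), [{"a"}, {"b"}]) is None


def test_modularity_errors(triangle):
    with pytest.raises(ValueError, match="overlap"):
        modularity(triangle, [{"a", "b"}, {"b", "c"}])
    with pytest.raises(ValueError, match="cover"):
        modularity(triangle, [{"a", "b"}])


def test_modularity_matches_formula_oracle(small_fixtures):
    for net in small_fixtures:
        nodes = net.sorted_nodes()
        half = set(nodes[: len(nodes) // 2])
        part = [half, set(nodes) - half]
        assert math.isclose(
            modularity(net, part), brute_modularity(net.edges, part), abs_tol=1e-12
        )


# ---------------------------------------------------------------------------
# simulated annealing


def test_sa_two_triangles():
    net = make_network(
        "two_tri", [("a", "b"), ("b", "c"), ("a", "c"), ("d", "e"), ("e", "f"), ("d", "f")]
    )
    ms = sa_modularity(net, seed=1)
    assert set(ms.modules) == {frozenset("abc"), frozenset("def")}


def test_sa_edgeless_and_determinism(triangle):
    empty = Network(name="iso", nodes={"a", "b"})
    assert set(sa_modularity(empty, seed=0).modules) == {frozenset("a"), frozenset("b")}
    net = gnp_network(15, 0.3, seed=6)
    sched = SASchedule(t0=0.5, cooling=0.8, node_moves=60, merge_split_moves=10)
    a = sa_modularity(net, sched, seed=3)
    b = sa_modularity(net, sched, seed=3)
    assert a.modules == b.modules


def test_sa_partition_is_valid_and_scored(two_triangles_bridge):
    ms = sa_modularity(two_triangles_bridge, seed=5)
    # result is a disjoint cover, so modularity() accepts it
    m = modularity(two_triangles_bridge, [set(x) for x in ms.modules])
    assert m is not None and m >= 5 / 14 - 1e-12


# ---------------------------------------------------------------------------
# edge-betweenness partitioning


def test_gn_worked_example(two_triangles_bridge):
    ms = girvan_newman(two_triangles_bridge, 1 / 7)
    assert set(ms.modules) == {frozenset("abc"), frozenset("def")}


def test_gn_fraction_zero_and_validation(two_triangles_bridge):
    ms = girvan_newman(two_triangles_bridge, 0.0)
    assert set(ms.modules) == {frozenset("abcdef")}
    with pytest.raises(ValueError, match="removal_fraction"):
        girvan_newman(two_triangles_bridge, 1.0)


def test_gn_first_removal_attains_brute_maximum(small_fixtures):
    for net in small_fixtures:
        if net.n_edges == 0:
            continue
        eb = brute_edge_betweenness(net.sorted_nodes(), net.edges)
        best = min(eb, key=lambda e: (-eb[e], e))
        g = net.to_networkx().copy()
        got = nx.edge_betweenness_centrality(g, normalized=False)
        top = min(got, key=lambda e: (-got[e], tuple(sorted(e))))
        top = tuple(sorted(top))
        assert math.isclose(got[top] if top in got else got[(top[1], top[0])], eb[best], abs_tol=1e-10)
        assert top == best


def test_edge_betweenness_oracle(small_fixtures):
    for net in small_fixtures:
        got = nx.edge_betweenness_centrality(net.to_networkx(), normalized=False)
        want = brute_edge_betweenness(net.sorted_nodes(), net.edges)
        for e, v in want.items():
            g = got.get(e, got.get((e[1], e[0])))
            assert math.isclose(g, v, abs_tol=1e-10)


# ---------------------------------------------------------------------------
# modular compatibility


def test_cp_identical_and_disjoint():
    s = modset({"a", "b", "c"}, {"d", "e", "f"})
    assert modular_compatibility(s, s).cp == 1.0
    t = modset({"x", "y", "z"})
    assert modular_compatibility(s, t).cp == 0.0


def test_cp_worked_example():
    s1 = modset({"a", "b", "c", "d"}, name="S1")
    s2 = modset({"a", "b", "c"}, {"d", "e", "f"}, name="S2")
    res = modular_compatibility(s1, s2)
    assert math.isclose(res.direction_1, 0.75)
    assert math.isclose(res.direction_2, 0.375)
    assert math.isclose(res.cp, 0.5625)
    # the second S2 module shares only one node (< 50% of 3): unmatched
    unmatched = [r for r in res.matches_2 if r.match_index is None]
    assert len(unmatched) == 1 and unmatched[0].term == 0.0


def test_cp_symmetry_and_bounds():
    s1 = modset({"a", "b", "c"}, {"d", "e"}, {"f", "g", "h"})
    s2 = modset({"a", "b", "x"}, {"f", "g", "h", "i"})
    r12 = modular_compatibility(s1, s2)
    r21 = modular_compatibility(s2, s1)
    assert math.isclose(r12.cp, r21.cp)
    assert 0.0 <= r12.cp <= 1.0


def test_cp_empty_set_errors():
    s = modset({"a", "b"})
    empty = ModuleSet(network="e", algorithm="manual", params={}, modules=[])
    with pytest.raises(ValueError, match="empty module set"):
        modular_compatibility(s, empty)


def test_module_set_ordering_and_filter():
    ms = modset({"z", "y"}, {"a", "b", "c"}, {"m"})
    assert [len(m) for m in ms.modules] == [3, 2, 1]
    assert [len(m) for m in ms.filtered(2).modules] == [3, 2]


# ---------------------------------------------------------------------------
# the comparison protocol


def test_cp_protocol_identical_family_p_near_one():
    class Fam:
        pass

    import itertools

    # three disjoint 4-cliques: CPM at k=3 and k=4 both recover exactly them
    edges = [
        e
        for block in ("abcd", "efgh", "ijkl")
        for e in itertools.combinations(block, 2)
    ]
    from tests.conftest import make_network

    net = make_network("total", edges)
    fam = Fam()
    fam.total = net
    clones = [Network(name=f"c{i}", nodes=net.nodes, edges=net.edges) for i in range(3)]
    fam.at_level = lambda lvl: clones
    rep = cp_comparison_protocol(fam, algorithm="cpm", param_grid=[{"k": 3}, {"k": 4}])
    # every subnetwork equals the total: between and within groups coincide
    assert math.isclose(rep["mean_cp_between"], rep["mean_cp_within"], abs_tol=1e-12)
    assert rep["mannwhitney_p"] > 0.5


def test_cp_protocol_validation(demo_family):
    with pytest.raises(ValueError, match="unknown algorithm"):
        cp_comparison_protocol(demo_family, algorithm="louvain")
    with pytest.raises(ValueError, match="at least two"):
        cp_comparison_protocol(demo_family, param_grid=[{"k": 4}])


def test_cp_protocol_on_demo_fixture(demo_family):
    rep = cp_comparison_protocol(demo_family, algorithm="cpm")
    assert rep["n_between"] > 0 and rep["n_within"] > 0
    assert rep["mean_cp_between"] < rep["mean_cp_within"]
    assert set(rep["table"]["group"]) == {"total_vs_subnetwork", "within_network"}
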