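import math

import numpy as np
import pandas as pd
import pytest
from scipy import stats as sps

from netstrat.graph_core import Network, NodeStatsTable, node_stats
from netstrat.topology import (
    assign_classes,
    class_changes,
    compare_stat_distributions,
    identify_roles,
    powerlaw_slope,
    status_change,
    status_change_table,
)
from tests.conftest import gnp_network, make_network
from tests.oracles import brute_mannwhitney_u, brute_welch


def degree_table(name: str, degrees: dict[str, float]) -> NodeStatsTable:
    df = pd.DataFrame({"degree": pd.Series(degrees, dtype=float)})
    df.index.name = "protein"
    return NodeStatsTable(network=name, per_node=df, summary={})


def test_identify_roles_worked_example():
    # degrees 4,3,2,2,1 at pct=20: rank ceil(0.2*5)=1 -> threshold 4, one hub
    tbl = degree_table("x", {"a": 4, "b": 3, "c": 2, "d": 2, "e": 1})
    ra = identify_roles(tbl, "degree", 20)
    assert ra.threshold == 4 and ra.roles == {"a"}
    assert ra.role_name == "hub"


def test_identify_roles_ties_are_inclusive():
    # a 5-cycle is degree-regular: the threshold ties every node into the role
    cyc = make_network("c5", list(zip("abcde", "bcdea")))
    ra = identify_roles(node_stats(cyc, ("degree",)), "degree", 20)
    assert ra.roles == {"a", "b", "c", "d", "e"}


def test_identify_roles_rank_oracle():
    for seed in (1, 2, 3):
        net = gnp_network(30, 0.2, seed=seed)
        tbl = node_stats(net, ("degree", "betweenness"))
        for kind, pct in (("degree", 20), ("betweenness", 10)):
            ra = identify_roles(tbl, kind, pct)
            vals = tbl.values(kind)
            thr = sorted(vals, reverse=True)[math.ceil(pct / 100 * len(vals)) - 1]
            assert ra.threshold == thr
            assert ra.roles == set(vals.index[vals >= thr])
            assert ra.n_roles >= math.ceil(pct / 100 * len(vals))


def test_identify_roles_errors():
    tbl = degree_table("x", {"a": 1})
    with pytest.raises(ValueError, match="kind"):
        identify_roles(tbl, "clustering", 20)
    with pytest.raises(ValueError, match="pct"):
        identify_roles(tbl, "degree", 0)
    with pytest.raises(ValueError, match="pct"):
        identify_roles(tbl, "degree", 100)


def test_status_change_worked_example():
    ref = identify_roles(degree_table("ref", {"a": 5, "b": 4, "c": 1, "d": 1, "e": 1}), "degree", 40)
    cmp_ = identify_roles(degree_table("cmp", {"a": 1, "c": 3, "d": 2, "e": 1}), "degree", 40)
    assert ref.roles == {"a", "b"}
    rep = status_change(ref, cmp_)
    assert rep.role_to_nonrole == 1  # a became a non-hub
    assert rep.role_to_absent == 1  # b is missing from cmp
    assert rep.role_to_role == 0
    assert rep.pct_role_to_nonrole == 50.0


def test_status_change_partition_identity():
    for seed in (4, 5, 6):
        ref_net = gnp_network(40, 0.15, seed=seed)
        sub_nodes = set(ref_net.sorted_nodes()[: 30])
        cmp_net = Network(
            name="sub",
            edges={e for e in ref_net.edges if e[0] in sub_nodes and e[1] in sub_nodes},
        )
        ref = identify_roles(node_stats(ref_net, ("degree",)), "degree", 20)
        cmp_ = identify_roles(node_stats(cmp_net, ("degree",)), "degree", 20)
        rep = status_change(ref, cmp_)
        assert rep.role_to_role + rep.role_to_nonrole + rep.role_to_absent == rep.ref_roles


def test_status_change_kind_mismatch():
    tbl = node_stats(gnp_network(10, 0.4, seed=1))
    with pytest.raises(ValueError, match="kind mismatch"):
        status_change(identify_roles(tbl, "degree", 20), identify_roles(tbl, "betweenness", 20))


def test_assign_classes_band_sizes():
    # 20 distinct degrees, cutoffs 5/10/20/50 -> bands of 1, 1, 2, 6, 10
    tbl = degree_table("x", {f"p{i:02d}": 20 - i for i in range(20)})
    ca = assign_classes(tbl, "degree", (5, 10, 20, 50))
    assert ca.band_sizes() == [1, 1, 2, 6, 10]
    assert ca.n_classes == 5
    # every node gets exactly one class
    assert set(ca.classes) <= set(range(1, 6)) and len(ca.classes) == 20


def test_assign_classes_alternate_cutoffs_and_errors():
    tbl = degree_table("x", {f"p{i:02d}": 20 - i for i in range(20)})
    ca = assign_classes(tbl, "degree", (10, 20, 50))
    assert ca.band_sizes() == [2, 2, 6, 10]
    with pytest.raises(ValueError, match="strictly increasing"):
        assign_classes(tbl, "degree", (20, 10))
    with pytest.raises(ValueError, match="in \\(0, 100\\)"):
        assign_classes(tbl, "degree", (5, 100))


def test_class_changes_leap():
    a = assign_classes(degree_table("a", {f"p{i:02d}": 20 - i for i in range(20)}))
    # reverse the ranking: the top node falls to the bottom band
    b = assign_classes(degree_table("b", {f"p{i:02d}": i + 1 for i in range(20)}))
    df = class_changes(a, b)
    assert df.loc["p00", "class_a"] == 1 and df.loc["p00", "class_b"] == 5
    assert bool(df.loc["p00", "leap"])
    assert not bool(df.loc["p09", "leap"]) or abs(df.loc["p09", "delta"]) >= 2


def test_compare_stat_distributions_identical():
    tbl = node_stats(gnp_network(25, 0.2, seed=9), ("degree",))
    for test in ("welch", "student", "mannwhitney"):
        _, p = compare_stat_distributions(tbl, tbl, "degree", test)
        assert p > 0.99


def test_compare_stat_distributions_oracles():
    a = node_stats(gnp_network(20, 0.3, seed=2), ("degree",))
    b = node_stats(gnp_network(25, 0.1, seed=3), ("degree",))
    x = list(a.values("degree"))
    y = list(b.values("degree"))
    t, p = compare_stat_distributions(a, b, "degree", "welch")
    t0, df0 = brute_welch(x, y)
    assert math.isclose(t, t0, abs_tol=1e-10)
    assert math.isclose(p, 2 * sps.t.sf(abs(t0), df0), abs_tol=1e-10)
    u, _ = compare_stat_distributions(a, b, "degree", "mannwhitney")
    assert math.isclose(u, brute_mannwhitney_u(x, y), abs_tol=1e-10)
    with pytest.raises(ValueError, match="unknown test"):
        compare_stat_distributions(a, b, "degree", "ks")


def test_powerlaw_slope_recovers_k_minus_2():
    # counts exactly proportional to k^-2 over k=1..6 (3600 / k^2)
    degrees: dict[str, float] = {}
    i = 0
    for k in range(1, 7):
        for _ in range(3600 // k**2):
            degrees[f"p{i:04d}"] = k
            i += 1
    slope, r2 = powerlaw_slope(degree_table("pl", degrees))
    assert abs(slope - (-2.0)) < 0.01
    assert r2 > 0.999


def test_powerlaw_slope_degenerate():
    assert powerlaw_slope(degree_table("flat", {f"p{i}": 3 for i in range(10)})) is None


def test_status_change_table_summaries():
    ref_net = gnp_network(30, 0.2, seed=12)
    ref = identify_roles(node_stats(ref_net, ("degree",)), "degree", 20)
    reports = []
    for seed in (1, 2):
        sub_nodes = set(gnp_network(30, 0.2, seed=12).sorted_nodes()[: 20 + seed])
        cmp_net = Network(
            name=f"s{seed}",
            edges={e for e in ref_net.edges if e[0] in sub_nodes and e[1] in sub_nodes},
        )
        reports.append(
            status_change(ref, identify_roles(node_stats(cmp_net, ("degree",)), "degree", 20))
        )
    df = status_change_table(reports)
    assert len(df) == 2
    pooled = 100.0 * df.role_to_nonrole.sum() / df.ref_roles.sum()
    assert math.isclose(df.attrs["pooled_pct_role_to_nonrole"], pooled)
    assert math.isclose(
        df.attrs["mean_pct_role_to_nonrole"], float(np.mean(df.pct_role_to_nonrole))
    )
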