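import numpy as np
import pytest

from netstrat.modules import sa_modularity
from netstrat.netcompat import jaccard
from netstrat.stratify import ContextHierarchy, stratify_all
from netstrat.synthdata import (
    FixtureBundle,
    SynthConfig,
    generate,
    internal_density,
    demo_fixture,
    write_bundle,
)

SMALL = dict(
    n_proteins=300,
    modules_per_context=2,
    module_size_range=(6, 9),
    artifact_modules=1,
    housekeeping_terms=18,
    housekeeping_coverage=0.22,
)


def test_generate_is_deterministic():
    a_net, a_h, a_annot, a_truth = generate(SynthConfig(seed=5, **SMALL))
    b_net, b_h, b_annot, b_truth = generate(SynthConfig(seed=5, **SMALL))
    assert a_net.edges == b_net.edges
    assert {n: c.proteins for n, c in a_h.contexts.items()} == {
        n: c.proteins for n, c in b_h.contexts.items()
    }
    assert a_annot.annotations == b_annot.annotations
    assert a_truth.planted_modules == b_truth.planted_modules
    c_net, *_ = generate(SynthConfig(seed=6, **SMALL))
    assert c_net.edges != a_net.edges


def test_config_validation():
    with pytest.raises(ValueError, match="4-tuple"):
        SynthConfig(n_contexts=(2, 5)).validate()
    with pytest.raises(ValueError, match="base contexts"):
        SynthConfig(n_contexts=(1, 2, 3, 2)).validate()
    with pytest.raises(ValueError, match="jaccard_target"):
        SynthConfig(jaccard_band=(0.4, 0.6), jaccard_target=0.7).validate()
    with pytest.raises(ValueError, match="list_fraction"):
        SynthConfig(list_fraction=0.0).validate()
    with pytest.raises(ValueError, match="core_size"):
        SynthConfig(module_core_size=8, module_size_range=(8, 12)).validate()


def test_hierarchy_shape_and_validity(demo_bundle):
    h = demo_bundle.hierarchy
    assert [len(h.at_level(lv)) for lv in (1, 2, 3, 4)] == [1, 2, 5, 4]
    h.validate()


def test_conglomerate_is_union_of_stratified_layers(demo_bundle, demo_family):
    # every conglomerate edge reappears in some coarse- or base-level
    # subnetwork, and vice versa: stratification loses nothing
    union: set = set()
    for lvl in (2, 3):
        for ctx in demo_bundle.hierarchy.at_level(lvl):
            union |= demo_family.networks[ctx.name].edges
    assert union == demo_family.total.edges == demo_bundle.conglomerate.edges


def test_list_jaccard_inside_band():
    for seed in (0, 1, 2):
        _, h, _, _ = generate(SynthConfig(seed=seed, **SMALL))
        base = h.at_level(3)
        lo, hi = SynthConfig().jaccard_band
        js = [
            jaccard(a.proteins, b.proteins)
            for i, a in enumerate(base)
            for b in base[i + 1:]
        ]
        assert all(lo <= j <= hi for j in js), (seed, js)


def test_artifact_density_contrast(demo_bundle, demo_family):
    cfg = demo_bundle.config
    for art in demo_bundle.truth.artifacts:
        assert internal_density(demo_bundle.conglomerate, art.nodes) >= cfg.density_hi
        for ctx in demo_bundle.hierarchy.at_level(3):
            sub = demo_family.networks[ctx.name]
            remnant_nodes = art.nodes & sub.nodes
            assert internal_density(sub, art.nodes) <= cfg.density_lo, (
                art.term,
                ctx.name,
                len(remnant_nodes),
            )


def test_artifact_truth_consistency(demo_bundle):
    h = demo_bundle.hierarchy
    for art in demo_bundle.truth.artifacts:
        assert len(art.parts) == 4
        assert frozenset().union(*art.parts) == art.nodes
        assert len(art.sentinels) == 4
        # parts 0 and 2 are never co-listed in any context
        for ctx in h.at_level(3):
            assert not (art.parts[0] <= ctx.proteins and art.parts[2] <= ctx.proteins)
        # decoy carriers are listed in every base context
        for ctx in h.at_level(3):
            assert demo_bundle.truth.artifact_decoys <= ctx.proteins


def test_planted_modules_dense_in_their_context(demo_bundle, demo_family):
    cfg = demo_bundle.config
    for ctx_name, modules in demo_bundle.truth.planted_modules.items():
        sub = demo_family.networks[ctx_name]
        for module in modules:
            assert internal_density(sub, module) >= cfg.p_in - 0.25


def test_module_cores_listed_everywhere(demo_bundle):
    for ctx in demo_bundle.hierarchy.at_level(3):
        for core in demo_bundle.truth.module_cores:
            assert core <= ctx.proteins


def test_internal_density_values(triangle):
    assert internal_density(triangle, {"a", "b", "c"}) == 1.0
    assert internal_density(triangle, {"a", "b", "z", "w"}) == 1 / 6
    assert internal_density(triangle, {"a"}) == 0.0


def test_write_bundle_round_trip(tmp_path, demo_bundle):
    import json

    from netstrat.graph_core import read_network

    write_bundle(
        demo_bundle.conglomerate,
        demo_bundle.hierarchy,
        demo_bundle.annotations,
        demo_bundle.truth,
        tmp_path,
    )
    net = read_network(tmp_path / "conglomerate.edges.tsv")
    assert net.edges == demo_bundle.conglomerate.edges
    back = ContextHierarchy.from_config(tmp_path / "hierarchy.yaml")
    for name, ctx in demo_bundle.hierarchy.contexts.items():
        assert back.contexts[name].proteins == ctx.proteins
    truth = json.loads((tmp_path / "truth.json").read_text())
    assert set(truth["planted_modules"]) == set(demo_bundle.truth.planted_modules)
    assert len(truth["artifacts"]) == len(demo_bundle.truth.artifacts)


def test_demo_fixture_is_stable(demo_bundle):
    again = demo_fixture(seed=0)
    assert isinstance(again, FixtureBundle)
    assert again.conglomerate.edges == demo_bundle.conglomerate.edges


def test_sa_recovers_planted_modules_at_default_densities():
    # sparse-backbone recovery fixture: default planted-module density
    # (p_in) against a minimal preferential-attachment background, so the
    # planted modules are the dominant communities of their context network
    cfg_kwargs = dict(
        n_proteins=240,
        ba_m=1,
        modules_per_context=2,
        module_size_range=(10, 14),
        module_core_size=4,
        artifact_modules=0,
    )
    scores = []
    for seed in range(10):
        con, h, _, truth = generate(SynthConfig(seed=seed, **cfg_kwargs))
        family = stratify_all(con, h)
        ctx = h.at_level(3)[0].name
        found = sa_modularity(family.networks[ctx], seed=seed).modules
        for planted in truth.planted_modules[ctx]:
            scores.append(max(jaccard(set(planted), set(m)) for m in found))
    assert float(np.mean(scores)) >= 0.8
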