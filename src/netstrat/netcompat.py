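"""Node/edge Jaccard compatibility between networks and its randomized null.

Compatibility between two networks is the Jaccard index of their node sets
(J_v) and of their canonical unordered edge sets (J_e).  Significance is
assessed against a null of randomized subnetworks: each replicate induces a
subnetwork of the total network on a uniform node sample of matched size, and
the two replicate streams are paired index-by-index (replicate i of the
size-A stream against replicate i of the size-B stream, 500 pairs by
default).  The observed value is compared with the null replicate
distribution by a one-sample Student's t-test.
"""

from __future__ import annotations

from dataclasses import dataclass, field

import numpy as np
from scipy import stats

from netstrat.graph_core import Network, induce_subnetwork, log


@dataclass
class CompatibilityResult:
    """Jaccard compatibility of one network pair, optionally with its null."""

    pair: tuple[str, str]
    j_nodes: float
    j_edges: float
    null_replicates: int = 0
    null_mean_nodes: float | None = None
    null_sd_nodes: float | None = None
    p_nodes: float | None = None
    null_mean_edges: float | None = None
    null_sd_edges: float | None = None
    p_edges: float | None = None
    metadata: dict[str, str] = field(default_factory=dict)


def jaccard(set_a: set, set_b: set) -> float:
    """|A ∩ B| / |A ∪ B|; defined as 0 for two empty sets (with a warning)."""
    union = set_a | set_b
    if not union:
        log("warning: Jaccard of two empty sets, returning 0")
        return 0.0
    return len(set_a & set_b) / len(union)


def network_compatibility(a: Network, b: Network) -> CompatibilityResult:
    """Node and edge Jaccard agreement between two networks (symmetric)."""
    return CompatibilityResult(
        pair=(a.name, b.name),
        j_nodes=jaccard(a.nodes, b.nodes),
        j_edges=jaccard(a.edges, b.edges),
    )


def compatibility_null(
    total: Network,
    size_a: int,
    size_b: int,
    n_rep: int = 500,
    seed: int | np.random.Generator = 0,
    observed: CompatibilityResult | None = None,
) -> CompatibilityResult | tuple[np.ndarray, np.ndarray]:
    """Randomized-network compatibility null for one pair of subnetwork sizes.

    Each replicate draws a uniform node sample of the stated size from the
    total network and induces the subnetwork on it; Jaccard indices are
    computed between independently drawn replicate pairs.  When ``observed``
    is given, the observed J values are tested against the null replicate
    distribution (one-sample two-sided Student's t) and a filled-in
    :class:`CompatibilityResult` is returned; otherwise the raw null arrays
    (J_v, J_e) are returned.
    """
    if size_a > total.n_nodes or size_b > total.n_nodes:
        raise ValueError(
            f"sample sizes ({size_a}, {size_b}) exceed total network size {total.n_nodes}"
        )
    rng = np.random.default_rng(seed) if not isinstance(seed, np.random.Generator) else seed
    node_arr = np.array(total.sorted_nodes())
    jv = np.empty(n_rep)
    je = np.empty(n_rep)
    for i in range(n_rep):
        sample_a = set(rng.choice(node_arr, size=size_a, replace=False))
        sample_b = set(rng.choice(node_arr, size=size_b, replace=False))
        net_a = induce_subnetwork(total, sample_a, name=f"rand_a_{i}")
        net_b = induce_subnetwork(total, sample_b, name=f"rand_b_{i}")
        jv[i] = jaccard(net_a.nodes, net_b.nodes)
        je[i] = jaccard(net_a.edges, net_b.edges)
    if observed is None:
        return jv, je
    p_nodes = _one_sample_p(jv, observed.j_nodes)
    p_edges = _one_sample_p(je, observed.j_edges)
    return CompatibilityResult(
        pair=observed.pair,
        j_nodes=observed.j_nodes,
        j_edges=observed.j_edges,
        null_replicates=n_rep,
        null_mean_nodes=float(jv.mean()),
        null_sd_nodes=float(jv.std(ddof=1)),
        p_nodes=p_nodes,
        null_mean_edges=float(je.mean()),
        null_sd_edges=float(je.std(ddof=1)),
        p_edges=p_edges,
        metadata={
            "null": "induced subnetworks on uniform node samples of matched sizes",
            "pairing": "replicate i of stream A vs replicate i of stream B (independent)",
            "test": "one-sample two-sided Student's t of observed vs null replicates",
        },
    )


def _one_sample_p(null: np.ndarray, observed: float) -> float:
    if np.allclose(null.std(ddof=1), 0.0):
        return 1.0 if np.isclose(observed, null.mean()) else 0.0
    return float(stats.ttest_1samp(null, observed).pvalue)
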