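"""Hub/bottleneck identification, status change, class assignment, and
distributional comparisons of network statistics.

Hubs are the nodes in the top percentile band of degree (default top 20%,
"equal or higher" at the threshold); bottlenecks the same for betweenness.
Status-change accounting compares a node's role between a reference network
(typically the total network) and a comparison network (a stratified
subnetwork); nodes absent from the comparison network are reported in a
separate column rather than folded into demotions.  Class assignment bins
nodes into percentile bands (default cutoffs 5/10/20/50 giving five classes);
a shift of two or more classes between networks is a "leap" change.
"""

from __future__ import annotations

import math
from dataclasses import dataclass

import numpy as np
import pandas as pd
from scipy import stats

from netstrat.graph_core import NodeStatsTable

ROLE_KINDS = {"degree": "hub", "betweenness": "bottleneck"}


@dataclass
class RoleAssignment:
    """Per-node role flags for one network at one percentile cutoff.

    ``threshold`` is the statistic of the node at descending rank
    ceil(pct/100 * N); every node with statistic >= threshold is a role node,
    so ties at the threshold can push the role count above pct percent.
    """

    network: str
    kind: str  # "degree" (hub) or "betweenness" (bottleneck)
    pct: float
    threshold: float
    roles: set[str]
    nodes: set[str]

    @property
    def role_name(self) -> str:
        return ROLE_KINDS[self.kind]

    @property
    def n_roles(self) -> int:
        return len(self.roles)


@dataclass
class StatusChangeReport:
    """Role status change between a reference and a comparison network.

    Counts are over nodes present in both networks; reference role nodes
    missing from the comparison network are counted in ``role_to_absent``.
    Identity: role_to_nonrole + role_to_role + role_to_absent = reference
    role count.  The demotion percentage divides by the reference network's
    role count; the promotion percentage divides by the comparison network's
    role count.
    """

    reference: str
    comparison: str
    kind: str
    ref_roles: int
    cmp_roles: int
    role_to_role: int
    role_to_nonrole: int
    role_to_absent: int
    nonrole_to_role: int
    pct_role_to_nonrole: float
    pct_nonrole_to_role: float

    def as_dict(self) -> dict[str, object]:
        return dict(self.__dict__)


def identify_roles(stats_table: NodeStatsTable, kind: str, pct: float) -> RoleAssignment:
    """Flag the top ``pct`` percent of nodes by degree or betweenness.

    The threshold is the statistic value at descending rank ceil(pct/100*N)
    and thresholding is inclusive, so all ties at the threshold become roles.
    """
    if kind not in ROLE_KINDS:
        raise ValueError(f"kind must be one of {sorted(ROLE_KINDS)}, got {kind!r}")
    if not 0 < pct < 100:
        raise ValueError(f"pct must be in (0, 100), got {pct}")
    values = stats_table.values(kind)
    n = len(values)
    if n == 0:
        raise ValueError("empty statistics table")
    rank = math.ceil(pct / 100.0 * n)
    threshold = float(np.sort(values.to_numpy())[::-1][rank - 1])
    roles = set(values.index[values >= threshold])
    return RoleAssignment(
        network=stats_table.network,
        kind=kind,
        pct=pct,
        threshold=threshold,
        roles=roles,
        nodes=set(values.index),
    )


def status_change(ref: RoleAssignment, cmp: RoleAssignment) -> StatusChangeReport:
    """Count role gains/losses between two role assignments of the same kind."""
    if ref.kind != cmp.kind:
        raise ValueError(f"kind mismatch: {ref.kind!r} vs {cmp.kind!r}")
    shared = ref.nodes & cmp.nodes
    role_to_role = len(ref.roles & cmp.roles & shared)
    role_to_nonrole = len((ref.roles & shared) - cmp.roles)
    role_to_absent = len(ref.roles - cmp.nodes)
    nonrole_to_role = len((cmp.roles & shared) - ref.roles)
    return StatusChangeReport(
        reference=ref.network,
        comparison=cmp.network,
        kind=ref.kind,
        ref_roles=ref.n_roles,
        cmp_roles=cmp.n_roles,
        role_to_role=role_to_role,
        role_to_nonrole=role_to_nonrole,
        role_to_absent=role_to_absent,
        nonrole_to_role=nonrole_to_role,
        pct_role_to_nonrole=100.0 * role_to_nonrole / ref.n_roles if ref.n_roles else 0.0,
        pct_nonrole_to_role=100.0 * nonrole_to_role / cmp.n_roles if cmp.n_roles else 0.0,
    )


@dataclass
class ClassAssignment:
    """Percentile-band class per node (class 1 = top band)."""

    network: str
    kind: str
    cutoffs: tuple[float, ...]
    thresholds: tuple[float, ...]
    classes: pd.Series  # node -> class index in 1..len(cutoffs)+1

    @property
    def n_classes(self) -> int:
        return len(self.cutoffs) + 1

    def band_sizes(self) -> list[int]:
        counts = self.classes.value_counts()
        return [int(counts.get(k, 0)) for k in range(1, self.n_classes + 1)]


def assign_classes(
    stats_table: NodeStatsTable,
    kind: str = "degree",
    cutoffs: tuple[float, ...] = (5, 10, 20, 50),
) -> ClassAssignment:
    """Partition nodes into percentile bands by degree or betweenness.

    Each cutoff defines an inclusive threshold exactly as in
    :func:`identify_roles`; a node's class is the first band whose threshold
    it reaches, class ``len(cutoffs)+1`` otherwise.  Alternate schemes such
    as (10, 20, 50) or (5, 15, 25, 60) are accepted.
    """
    cutoffs = tuple(float(c) for c in cutoffs)
    if any(b <= a for a, b in zip(cutoffs, cutoffs[1:])) or not cutoffs:
        raise ValueError(f"cutoffs must be strictly increasing and non-empty, got {cutoffs}")
    if cutoffs[-1] >= 100 or cutoffs[0] <= 0:
        raise ValueError(f"cutoffs must lie in (0, 100), got {cutoffs}")
    values = stats_table.values(kind)
    n = len(values)
    desc = np.sort(values.to_numpy())[::-1]
    thresholds = tuple(float(desc[math.ceil(c / 100.0 * n) - 1]) for c in cutoffs)
    arr = values.to_numpy()
    cls = np.full(n, len(cutoffs) + 1, dtype=int)
    for k in range(len(cutoffs) - 1, -1, -1):
        cls[arr >= thresholds[k]] = k + 1
    return ClassAssignment(
        network=stats_table.network,
        kind=kind,
        cutoffs=cutoffs,
        thresholds=thresholds,
        classes=pd.Series(cls, index=values.index, name="class"),
    )


def class_changes(a: ClassAssignment, b: ClassAssignment) -> pd.DataFrame:
    """Per-shared-node class delta between two networks with leap flags.

    Returns a DataFrame indexed by protein with columns ``class_a``,
    ``class_b``, ``delta`` (b minus a) and ``leap`` (|delta| >= 2).
    """
    if a.kind != b.kind:
        raise ValueError(f"kind mismatch: {a.kind!r} vs {b.kind!r}")
    shared = a.classes.index.intersection(b.classes.index)
    ca = a.classes.loc[shared]
    cb = b.classes.loc[shared]
    delta = cb - ca
    return pd.DataFrame(
        {"class_a": ca, "class_b": cb, "delta": delta, "leap": delta.abs() >= 2},
        index=shared,
    )


def compare_stat_distributions(
    table_a: NodeStatsTable,
    table_b: NodeStatsTable,
    statistic: str = "degree",
    test: str = "welch",
) -> tuple[float, float]:
    """Two-sided comparison of one statistic's distribution between networks.

    ``test`` selects Welch's t (unequal variances), Student's t, or the
    Mann-Whitney U test.  Returns (test statistic, two-sided p-value).
    """
    x = table_a.values(statistic).to_numpy(dtype=float)
    y = table_b.values(statistic).to_numpy(dtype=float)
    if len(x) < 2 or len(y) < 2:
        raise ValueError("need at least two observations per side")
    if test == "welch":
        res = stats.ttest_ind(x, y, equal_var=False)
    elif test == "student":
        res = stats.ttest_ind(x, y, equal_var=True)
    elif test == "mannwhitney":
        res = stats.mannwhitneyu(x, y, alternative="two-sided")
    else:
        raise ValueError(f"unknown test {test!r}")
    return float(res.statistic), float(res.pvalue)


def powerlaw_slope(stats_table: NodeStatsTable) -> tuple[float, float] | None:
    """Least-squares slope of log frequency vs log degree (descriptive).

    Zero-degree nodes and empty histogram bins are dropped.  Returns
    (slope, r^2), or None when fewer than five distinct positive degree
    values exist.
    """
    degrees = stats_table.values("degree").to_numpy()
    degrees = degrees[degrees > 0]
    ks, counts = np.unique(degrees, return_counts=True)
    if len(ks) < 5:
        return None
    x = np.log(ks.astype(float))
    y = np.log(counts.astype(float))
    res = stats.linregress(x, y)
    return float(res.slope), float(res.rvalue**2)


def status_change_table(reports: list[StatusChangeReport]) -> pd.DataFrame:
    """Tabulate status-change reports; appends pooled and averaged summaries.

    Because "on average" can mean the mean of per-pair percentages or the
    pooled count ratio, both are emitted.
    """
    df = pd.DataFrame([r.as_dict() for r in reports])
    if df.empty:
        return df
    pooled_demote = 100.0 * df.role_to_nonrole.sum() / df.ref_roles.sum()
    pooled_promote = 100.0 * df.nonrole_to_role.sum() / df.cmp_roles.sum()
    df.attrs["mean_pct_role_to_nonrole"] = float(df.pct_role_to_nonrole.mean())
    df.attrs["mean_pct_nonrole_to_role"] = float(df.pct_nonrole_to_role.mean())
    df.attrs["pooled_pct_role_to_nonrole"] = float(pooled_demote)
    df.attrs["pooled_pct_nonrole_to_role"] = float(pooled_promote)
    return df
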