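"""Context-dependent stratification of a conglomerate network.

Stratification overlays a context-specific protein list onto the conglomerate
network and keeps the interactions whose two partners both occur in that
context.  Context lists are organized in a leveled hierarchy (level 1 = the
total list of proteins seen in any context; deeper levels are finer strata);
one induced subnetwork is produced per context.  The level-1 "total network"
is itself the induced subnetwork of the conglomerate on the total list; the
raw conglomerate is kept separately for assembly and edge replacement only.
"""

from __future__ import annotations

from dataclasses import dataclass, field
from pathlib import Path
from typing import Iterator

import yaml

from netstrat.graph_core import Network, induce_subnetwork, log, read_protein_list


@dataclass
class Context:
    name: str
    level: int
    parent: str | None
    proteins: set[str]


@dataclass
class ContextHierarchy:
    """A leveled tree of named protein lists driving stratification.

    Exactly one level-1 context (the total list); every non-root context has
    a parent at a strictly lower level.  Child lists need not be subsets of
    their parent's; :meth:`validate` reports violations without enforcing.
    """

    contexts: dict[str, Context] = field(default_factory=dict)

    def add(self, name: str, level: int, parent: str | None, proteins: set[str]) -> None:
        if name in self.contexts:
            raise ValueError(f"duplicate context {name!r}")
        self.contexts[name] = Context(name, level, parent, set(proteins))

    @property
    def root(self) -> Context:
        roots = [c for c in self.contexts.values() if c.level == 1]
        if len(roots) != 1:
            raise ValueError(f"expected exactly one level-1 context, found {len(roots)}")
        return roots[0]

    def at_level(self, level: int) -> list[Context]:
        return sorted((c for c in self.contexts.values() if c.level == level), key=lambda c: c.name)

    def levels(self) -> list[int]:
        return sorted({c.level for c in self.contexts.values()})

    def __iter__(self) -> Iterator[Context]:
        return iter(sorted(self.contexts.values(), key=lambda c: (c.level, c.name)))

    def validate(self) -> list[str]:
        """Structural check; returns a list of human-readable problems.

        Raises on fatal defects (root count, dangling or non-ancestral
        parents); non-subset child lists are reported, not enforced.
        """
        problems: list[str] = []
        _ = self.root  # raises if not exactly one level-1 context
        for c in self.contexts.values():
            if c.level < 1:
                raise ValueError(f"context {c.name!r}: level must be >= 1")
            if c.level == 1:
                if c.parent is not None:
                    raise ValueError(f"root context {c.name!r} must not have a parent")
                continue
            if c.parent is None or c.parent not in self.contexts:
                raise ValueError(f"context {c.name!r}: missing parent {c.parent!r}")
            p = self.contexts[c.parent]
            if p.level >= c.level:
                raise ValueError(
                    f"context {c.name!r} (level {c.level}) has parent {p.name!r} at level {p.level}"
                )
            extra = len(c.proteins - p.proteins)
            if extra:
                problems.append(
                    f"context {c.name!r}: {extra} proteins not in parent {p.name!r} list"
                )
        return problems

    @classmethod
    def from_config(cls, path: str | Path) -> "ContextHierarchy":
        """Load a hierarchy from YAML/JSON: list of {name, level, parent, list_file}."""
        path = Path(path)
        with path.open() as fh:
            cfg = yaml.safe_load(fh)
        entries = cfg["contexts"] if isinstance(cfg, dict) else cfg
        h = cls()
        for entry in entries:
            proteins = read_protein_list(path.parent / entry["list_file"])
            h.add(entry["name"], int(entry["level"]), entry.get("parent"), proteins)
        h.validate()
        return h


@dataclass
class StratifiedFamily:
    """The family of context-dependent subnetworks of one conglomerate.

    ``coverage`` maps each context to the fraction of its source protein list
    that survives as interacting proteins in its subnetwork.
    """

    hierarchy: ContextHierarchy
    networks: dict[str, Network]
    coverage: dict[str, float]

    @property
    def total(self) -> Network:
        return self.networks[self.hierarchy.root.name]

    def at_level(self, level: int) -> list[Network]:
        return [self.networks[c.name] for c in self.hierarchy.at_level(level)]


def stratify_all(conglomerate: Network, hierarchy: ContextHierarchy) -> StratifiedFamily:
    """Induce one subnetwork per context of the hierarchy.

    Every stratified network is (by construction) a subgraph of the level-1
    total network, which is the conglomerate induced on the total list.
    """
    hierarchy.validate()
    root = hierarchy.root
    total = induce_subnetwork(conglomerate, root.proteins, name=root.name)
    networks: dict[str, Network] = {}
    coverage: dict[str, float] = {}
    for ctx in hierarchy:
        if ctx.name == root.name:
            net = total
        else:
            net = induce_subnetwork(total, ctx.proteins, name=ctx.name)
        if net.n_nodes == 0:
            log(f"warning: context {ctx.name!r} has no overlap with the conglomerate")
        networks[ctx.name] = net
        coverage[ctx.name] = net.n_nodes / len(ctx.proteins) if ctx.proteins else 0.0
    return StratifiedFamily(hierarchy=hierarchy, networks=networks, coverage=coverage)


def level_pairs(
    family: StratifiedFamily, level_a: int, level_b: int
) -> list[tuple[Network, Network]]:
    """Cross product of level-A and level-B networks for pairwise comparison.

    Pairs involving the total network come first; identical-context pairs are
    skipped when the two levels coincide.
    """
    ctx_a = family.hierarchy.at_level(level_a)
    ctx_b = family.hierarchy.at_level(level_b)
    if not ctx_a:
        raise ValueError(f"no contexts at level {level_a}")
    if not ctx_b:
        raise ValueError(f"no contexts at level {level_b}")
    root = family.hierarchy.root.name

    def key(pair: tuple[str, str]) -> tuple[int, str, str]:
        return (0 if root in pair else 1, pair[0], pair[1])

    names = sorted(
        ((a.name, b.name) for a in ctx_a for b in ctx_b if a.name != b.name), key=key
    )
    return [(family.networks[a], family.networks[b]) for a, b in names]


def write_family(family: StratifiedFamily, outdir: str | Path) -> None:
    """Write one edge-list TSV per context plus a coverage TSV."""
    from netstrat.graph_core import write_network

    outdir = Path(outdir)
    outdir.mkdir(parents=True, exist_ok=True)
    for name, net in sorted(family.networks.items()):
        write_network(net, outdir / f"{name}.edges.tsv")
    with (outdir / "coverage.tsv").open("w") as fh:
        fh.write("context\tlevel\tn_nodes\tn_edges\tlist_size\tcoverage\n")
        for ctx in family.hierarchy:
            net = family.networks[ctx.name]
            fh.write(
                f"{ctx.name}\t{ctx.level}\t{net.n_nodes}\t{net.n_edges}"
                f"\t{len(ctx.proteins)}\t{family.coverage[ctx.name]:.4f}\n"
            )
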