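"""Synthetic conglomerate networks with planted ground truth.

The generator emulates the study conditions of a conglomerate PPI network
pooled from several overlapping biological contexts:

* five (by default) base contexts, each with a protein list made of a
  common core plus an independent sample of the shared pool, calibrated so
  the expected pairwise list Jaccard hits a configurable target inside the
  accepted band (default 0.39-0.65) while the lists stay well above chance
  overlap for their size; contexts are arranged in a 4-level hierarchy
  (total / coarse / base / fine);
* a single scale-free interactome backbone (preferential attachment) over a
  sub-unity "PPI coverage" of the protein universe; each context layer keeps
  the backbone interactions among its listed proteins and adds a modest set
  of context-specific random interactions, so that listed-but-uncovered
  proteins drop out of every stratified subnetwork and real subnetworks stay
  comparable in total degree to random protein samples of the same list size;
* planted dense module *families*: each family owns a small core listed in
  every context plus a context-exclusive periphery per context, all edges
  dense within each context's core+periphery variant.  Stratified
  subnetworks thus carry clean context-specific modules, while in the
  conglomerate union the five variants of a family merge through the shared
  core into one chimeric community — so total-network modules match
  context-network modules poorly, as modules pooled across contexts do.
  Each context variant is tagged by a context-specific annotation term;
* planted *artifact* modules: node sets that are dense only in the
  conglomerate union.  Each artifact set is split into four parts; five of
  the six part-pairs are assigned to five distinct base contexts, and each
  context's layer carries the complete graph on its two parts.  No single
  context ever lists more than two parts, so every single-context remnant
  stays sparse relative to the whole set while the union is dense.  One
  part-pair is never co-listed anywhere; two sentinel proteins in each of
  those two parts carry the artifact's annotation term, so all four
  sentinels co-occur in one dense module only when the conglomerate union
  assembles — the signature of an assembly artifact.  Three ubiquitous
  decoy proteins also carry every artifact term; they are listed in every
  context, so each term keeps a visible background count well above the
  two sentinels any single-context remnant can gather;
* housekeeping annotation terms spread uniformly over the whole universe
  plus a small random annotation noise.
"""

from __future__ import annotations

import json
from dataclasses import dataclass
from pathlib import Path

import networkx as nx
import numpy as np

from netstrat.enrichment import AnnotationMap, CATEGORIES
from netstrat.graph_core import Network, assemble_conglomerate, canonical_edge
from netstrat.stratify import ContextHierarchy

# part-pairs of the artifact construction; parts 0 and 2 never co-occur and
# carry the sentinel annotations
_ARTIFACT_BLOCKS = ((0, 1), (0, 3), (1, 2), (1, 3), (2, 3))
_N_PARTS = 4


@dataclass
class SynthConfig:
    """Generator parameters; defaults are the package's study conditions."""

    n_proteins: int = 1000
    n_contexts: tuple[int, ...] = (1, 2, 5, 4)  # contexts per hierarchy level
    jaccard_band: tuple[float, float] = (0.39, 0.65)
    jaccard_target: float = 0.43  # expected pairwise list Jaccard aimed for
    list_fraction: float = 0.56  # context-list size as a fraction of the shared pool
    modules_per_context: int = 3
    module_size_range: tuple[int, int] = (8, 12)
    module_core_size: int = 4  # shared core of each planted-module family
    p_in: float = 0.9  # intra-edge probability of planted modules
    ba_m: int = 4  # preferential-attachment edges per new backbone node
    ctx_edge_rate: float = 0.15  # context-specific random edges per member
    ppi_coverage: float = 0.55  # interactome-covered fraction of the universe
    artifact_modules: int = 2
    artifact_part_size: int = 3
    housekeeping_terms: int = 24
    housekeeping_coverage: float = 0.18  # universe fraction per housekeeping term
    annotation_noise: float = 0.05
    level2_fraction: float = 0.88  # coarse-list fraction of the shared pool
    level4_fraction: float = 0.80  # fine-list fraction of the parent list
    level4_perturbation: float = 0.02  # swapped-in proteins outside the parent
    density_hi: float = 0.6  # artifact density demanded in the union
    density_lo: float = 0.3  # artifact density allowed in any single context
    seed: int = 0

    def validate(self) -> None:
        if len(self.n_contexts) != 4 or self.n_contexts[0] != 1:
            raise ValueError("n_contexts must be a 4-tuple starting with 1")
        if self.artifact_modules > 0 and self.n_contexts[2] < len(_ARTIFACT_BLOCKS):
            raise ValueError(
                f"artifact planting needs >= {len(_ARTIFACT_BLOCKS)} base contexts, "
                f"got {self.n_contexts[2]}"
            )
        if self.artifact_modules > 0 and self.artifact_part_size < 2:
            raise ValueError("artifact_part_size must be >= 2 (two sentinel carriers per part)")
        if not 0 <= self.jaccard_band[0] < self.jaccard_band[1] <= 1:
            raise ValueError("jaccard_band must satisfy 0 <= lo < hi <= 1")
        if not self.jaccard_band[0] <= self.jaccard_target <= self.jaccard_band[1]:
            raise ValueError("jaccard_target must lie inside jaccard_band")
        if not 0 < self.list_fraction <= 1:
            raise ValueError("list_fraction must lie in (0, 1]")
        for prob in (self.p_in, self.ppi_coverage, self.housekeeping_coverage,
                     self.annotation_noise, self.level2_fraction, self.level4_fraction):
            if not 0 <= prob <= 1:
                raise ValueError("probabilities must lie in [0, 1]")
        if self.module_size_range[0] < 3 or self.module_size_range[0] > self.module_size_range[1]:
            raise ValueError("module_size_range must be (lo, hi) with 3 <= lo <= hi")
        if self.module_core_size >= self.module_size_range[0]:
            raise ValueError("module_core_size must be smaller than the minimum module size")


@dataclass
class ArtifactModule:
    nodes: frozenset[str]
    parts: list[frozenset[str]]
    block_contexts: dict[tuple[int, int], str]
    sentinels: tuple[str, ...]
    term: str


@dataclass
class PlantedTruth:
    """Ground truth planted by the generator."""

    planted_modules: dict[str, list[frozenset[str]]]
    module_cores: list[frozenset[str]]  # shared core of each module family
    module_terms: dict[str, tuple[str, int]]  # term -> (context, module index)
    artifacts: list[ArtifactModule]
    artifact_decoys: frozenset[str]  # ubiquitous co-carriers of artifact terms
    housekeeping: set[str]

    def artifact_terms(self) -> set[str]:
        return {a.term for a in self.artifacts}


def internal_density(net: Network, nodes: set[str] | frozenset[str]) -> float:
    """Edges of ``net`` inside a node set over all its potential pairs.

    Absent nodes contribute no edges but stay in the denominator, so this
    measures how much of the putative module is realized in the network.
    """
    n = len(nodes)
    if n < 2:
        return 0.0
    inside = sum(1 for a, b in net.edges if a in nodes and b in nodes)
    return inside / (n * (n - 1) / 2)


def _expected_jaccard(c: float, pool: int, size: float, shared: float, exclusives: float) -> float:
    """Expected pairwise list Jaccard for core-plus-rest lists.

    Each list holds a common core (fraction ``c`` of the pool), an
    independent sample of the remaining pool filling the list up to
    ``size``, plus ``shared`` proteins common to all lists and
    ``exclusives`` private ones.
    """
    rest = size - c * pool - shared - exclusives
    if rest < 0 or pool * (1 - c) <= 0:
        return 1.0
    f_r = min(rest / (pool * (1 - c)), 1.0)
    inter = c * pool + f_r * f_r * (1 - c) * pool + shared
    union = 2 * size - inter
    return inter / union if union else 0.0


def _solve_core_fraction(
    pool: int, size: float, shared: float, exclusives: float, target: float
) -> tuple[float, float]:
    """Core fraction and rest-sampling rate whose expected pairwise list
    Jaccard hits ``target`` at the requested list size.

    Expected Jaccard increases with the core fraction at fixed list size, so
    a bisection suffices; errors with the feasible range when the target
    is unreachable at this size.
    """
    c_max = max((size - shared - exclusives) / pool, 0.0)
    j_min = _expected_jaccard(0.0, pool, size, shared, exclusives)
    j_max = _expected_jaccard(c_max, pool, size, shared, exclusives)
    if not j_min <= target <= j_max:
        raise ValueError(
            f"overlap target {target} infeasible at list size {size:.0f}; "
            f"feasible expected-Jaccard range is [{j_min:.3f}, {j_max:.3f}]"
        )
    lo_c, hi_c = 0.0, c_max
    for _ in range(60):
        mid = 0.5 * (lo_c + hi_c)
        if _expected_jaccard(mid, pool, size, shared, exclusives) < target:
            lo_c = mid
        else:
            hi_c = mid
    c = 0.5 * (lo_c + hi_c)
    f_r = (size - c * pool - shared - exclusives) / (pool * (1 - c))
    return c, min(max(f_r, 0.0), 1.0)


def _ba_layer(members: list[str], m: int, rng: np.random.Generator) -> set[tuple[str, str]]:
    """Preferential-attachment background over a shuffled member list."""
    if len(members) < 2:
        return set()
    order = list(members)
    rng.shuffle(order)
    m_eff = min(m, len(order) - 1)
    g = nx.barabasi_albert_graph(len(order), m_eff, seed=int(rng.integers(2**31)))
    return {canonical_edge(order[a], order[b]) for a, b in g.edges()}


def _random_pairs(members: list[str], n: int, rng: np.random.Generator) -> set[tuple[str, str]]:
    """``n`` distinct random pairs among ``members`` (uniform, no self-pairs)."""
    out: set[tuple[str, str]] = set()
    if len(members) < 2:
        return out
    n = min(n, len(members) * (len(members) - 1) // 2)
    while len(out) < n:
        i, j = rng.integers(0, len(members), size=2)
        if i != j:
            out.add(canonical_edge(members[int(i)], members[int(j)]))
    return out


def generate(
    config: SynthConfig | None = None,
) -> tuple[Network, ContextHierarchy, AnnotationMap, PlantedTruth]:
    """Generate a synthetic conglomerate, hierarchy, annotations and truth.

    Deterministic under ``config.seed``; the conglomerate's edge set is
    exactly the union of the base-context layers.
    """
    cfg = config or SynthConfig()
    cfg.validate()
    rng = np.random.default_rng(cfg.seed)
    n3 = cfg.n_contexts[2]
    base_names = [f"tissue_{i + 1}" for i in range(n3)]

    width = len(str(cfg.n_proteins))
    universe = [f"P{i:0{width}d}" for i in range(cfg.n_proteins)]
    free = list(universe)

    def take(k: int) -> list[str]:
        if k > len(free):
            raise ValueError("n_proteins too small for the requested planted structure")
        out = [free.pop() for _ in range(k)]
        return out

    # ---- reserve artifact parts and planted-module exclusives ------------
    artifacts: list[ArtifactModule] = []
    artifact_parts_by_ctx: dict[str, list[frozenset[str]]] = {name: [] for name in base_names}
    for a in range(cfg.artifact_modules):
        parts = [frozenset(take(cfg.artifact_part_size)) for _ in range(_N_PARTS)]
        ctx_choice = list(rng.choice(n3, size=len(_ARTIFACT_BLOCKS), replace=False))
        block_contexts = {
            block: base_names[int(c)] for block, c in zip(_ARTIFACT_BLOCKS, ctx_choice)
        }
        nodes = frozenset().union(*parts)
        # two sentinel carriers in each of the two never-co-listed parts:
        # all four co-occur in one dense module only in the conglomerate
        # union, while any single-context remnant holds at most two
        sentinels = tuple(sorted(parts[0])[:2] + sorted(parts[2])[:2])
        artifacts.append(
            ArtifactModule(nodes, parts, block_contexts, sentinels, f"ART_{a + 1:02d}")
        )
        for (i, j), ctx in block_contexts.items():
            artifact_parts_by_ctx[ctx].append(parts[i] | parts[j])
    # three ubiquitous decoy carriers shared by all artifact terms; listed
    # in every base context and wired through the backbone, they keep each
    # term's visible background count above the two sentinels a remnant can
    # gather, so remnants stay below enrichment significance
    decoys: frozenset[str] = frozenset(take(3)) if artifacts else frozenset()

    # module families: a shared core listed everywhere plus per-context
    # exclusive peripheries.  The core is at least max clique size - 1 large
    # by default so clique percolation chains the variants together in the
    # union at any clique size up to core+1.
    cores = [frozenset(take(cfg.module_core_size)) for _ in range(cfg.modules_per_context)]
    planted: dict[str, list[frozenset[str]]] = {}
    for name in base_names:
        mods = []
        for core in cores:
            size = int(rng.integers(cfg.module_size_range[0], cfg.module_size_range[1] + 1))
            mods.append(core | frozenset(take(size - len(core))))
        planted[name] = mods

    # ---- context lists ---------------------------------------------------
    shared = np.array(sorted(free))
    pool = shared[
        rng.choice(len(shared), size=round(cfg.level2_fraction * len(shared)), replace=False)
    ]
    ubiquitous: set[str] = (set().union(*cores) if cores else set()) | decoys
    exclusives: dict[str, set[str]] = {
        name: set().union(set(), *planted[name], *artifact_parts_by_ctx[name]) - ubiquitous
        for name in base_names
    }
    mean_excl = float(np.mean([len(exclusives[n]) for n in base_names]))
    size = cfg.list_fraction * len(pool)
    c, f_r = _solve_core_fraction(len(pool), size, len(ubiquitous), mean_excl, cfg.jaccard_target)
    core_sample = set(
        str(p) for p in pool[rng.choice(len(pool), size=round(c * len(pool)), replace=False)]
    )
    rest = np.array(sorted(set(str(p) for p in pool) - core_sample))
    n_rest = round(f_r * len(rest))
    base_lists: dict[str, set[str]] = {}
    for name in base_names:
        sampled = core_sample | set(
            str(p) for p in rest[rng.choice(len(rest), size=n_rest, replace=False)]
        )
        base_lists[name] = sampled | exclusives[name] | ubiquitous

    hierarchy = ContextHierarchy()
    coarse_names = [f"coarse_{i + 1}" for i in range(cfg.n_contexts[1])]
    organs = coarse_names[0]
    organs_list = set(pool) | ubiquitous | set().union(*(exclusives[n] for n in base_names))
    coarse_lists: dict[str, set[str]] = {organs: organs_list}
    for name in coarse_names[1:]:
        size = round(cfg.level2_fraction * len(shared))
        coarse_lists[name] = set(shared[rng.choice(len(shared), size=size, replace=False)])

    total_list = set().union(*coarse_lists.values(), *base_lists.values())

    # ---- per-context interaction layers ----------------------------------
    # interactome coverage is a global property of a protein (either the PPI
    # sources know interactions for it or they do not), so the covered subset
    # is drawn once; listed-but-uncovered proteins stay isolated and drop out
    # of every stratified subnetwork, emulating sub-unity list coverage
    all_exclusive = set().union(ubiquitous, *(exclusives[n] for n in base_names))
    uncommitted = sorted(total_list - all_exclusive)
    n_covered = round(cfg.ppi_coverage * len(uncommitted))
    covered = set(
        np.array(uncommitted)[rng.choice(len(uncommitted), size=n_covered, replace=False)]
    ) | all_exclusive
    # a single scale-free interactome backbone spans the covered universe;
    # each context observes the backbone interactions among its own listed
    # proteins plus a modest layer of context-specific interactions, planted
    # modules and artifact blocks.  The broad coarse contexts contribute
    # backbone-only layers, so nearly the whole backbone reaches the
    # conglomerate regardless of how the narrow base lists overlap — like
    # interaction databases assembled independently of any context list.
    # This keeps real context subnetworks comparable in total degree to
    # node-sampling randomized subnetworks of the same list size, as the
    # study conditions require.
    backbone = _ba_layer(sorted(covered), cfg.ba_m, rng)

    fine_lists: dict[str, tuple[str, set[str]]] = {}
    for i in range(cfg.n_contexts[3]):
        parent = base_names[i % n3]
        parent_list = sorted(base_lists[parent])
        f_size = round(cfg.level4_fraction * len(parent_list))
        sub = set(np.array(parent_list)[rng.choice(len(parent_list), size=f_size, replace=False)])
        outside = sorted(organs_list - base_lists[parent])
        n_pert = round(cfg.level4_perturbation * f_size)
        if outside and n_pert:
            sub |= set(np.array(outside)[rng.choice(len(outside), size=min(n_pert, len(outside)),
                                                    replace=False)])
        fine_lists[f"fine_{i + 1}"] = (parent, sub)

    hierarchy.add("total", 1, None, total_list)
    for name in coarse_names:
        hierarchy.add(name, 2, "total", coarse_lists[name])
    for name in base_names:
        hierarchy.add(name, 3, organs, base_lists[name])
    for name, (parent, sub) in fine_lists.items():
        hierarchy.add(name, 4, parent, sub)

    layers: list[tuple[str, set[tuple[str, str]]]] = []
    for name, members_list in coarse_lists.items():
        coarse_members = members_list & covered
        layers.append(
            (name, {e for e in backbone if e[0] in coarse_members and e[1] in coarse_members})
        )
    for name in base_names:
        members = sorted(base_lists[name] & covered)
        member_set = set(members)
        edges = {e for e in backbone if e[0] in member_set and e[1] in member_set}
        edges |= _random_pairs(members, round(cfg.ctx_edge_rate * len(members)), rng)
        for module in planted[name]:
            members = sorted(module)
            for i in range(len(members)):
                for j in range(i + 1, len(members)):
                    if rng.random() < cfg.p_in:
                        edges.add(canonical_edge(members[i], members[j]))
        for union_nodes in artifact_parts_by_ctx[name]:
            members = sorted(union_nodes)
            for i in range(len(members)):
                for j in range(i + 1, len(members)):
                    edges.add(canonical_edge(members[i], members[j]))
        layers.append((name, edges))
    conglomerate = assemble_conglomerate(layers, name="conglomerate")

    # ---- annotations -----------------------------------------------------
    annot = AnnotationMap()
    housekeeping: set[str] = set()
    uni = np.array(universe)
    for h in range(cfg.housekeeping_terms):
        term = f"HK_{h + 1:02d}"
        housekeeping.add(term)
        carriers = uni[rng.choice(len(uni), size=round(cfg.housekeeping_coverage * len(uni)),
                                  replace=False)]
        category = CATEGORIES[0] if h % 3 != 2 else CATEGORIES[h % len(CATEGORIES)]
        # two of three housekeeping terms are biological_process so that the
        # default enrichment category keeps near-complete universe coverage
        for p in carriers:
            annot.add(str(p), "biological_process", term)
            if category != "biological_process":
                annot.add(str(p), category, term)
    module_terms: dict[str, tuple[str, int]] = {}
    context_terms: list[str] = []
    n_planted_assignments = 0
    for name in base_names:
        for mi, module in enumerate(planted[name]):
            term = f"CTX_{name}_{mi + 1}"
            module_terms[term] = (name, mi)
            context_terms.append(term)
            for p in sorted(module):
                annot.add(p, "biological_process", term)
            n_planted_assignments += len(module)
    n_noise = round(cfg.annotation_noise * n_planted_assignments)
    for _ in range(n_noise):
        term = context_terms[int(rng.integers(len(context_terms)))]
        annot.add(str(uni[int(rng.integers(len(uni)))]), "biological_process", term)
    for art in artifacts:
        for s in (*art.sentinels, *sorted(decoys)):
            annot.add(s, "biological_process", art.term)

    truth = PlantedTruth(
        planted_modules=planted,
        module_cores=cores,
        module_terms=module_terms,
        artifacts=artifacts,
        artifact_decoys=decoys,
        housekeeping=housekeeping,
    )
    return conglomerate, hierarchy, annot, truth


@dataclass
class FixtureBundle:
    conglomerate: Network
    hierarchy: ContextHierarchy
    annotations: AnnotationMap
    truth: PlantedTruth
    config: SynthConfig


def demo_fixture(seed: int = 0) -> FixtureBundle:
    """A small fixed bundle (~300 proteins, 5 base contexts) for docs and
    integration tests; regenerated deterministically from the seed."""
    cfg = SynthConfig(
        n_proteins=300,
        modules_per_context=2,
        module_size_range=(6, 9),
        artifact_modules=1,
        housekeeping_terms=18,
        housekeeping_coverage=0.22,
        seed=seed,
    )
    con, hier, annot, truth = generate(cfg)
    return FixtureBundle(con, hier, annot, truth, cfg)


def write_bundle(
    conglomerate: Network,
    hierarchy: ContextHierarchy,
    annot: AnnotationMap,
    truth: PlantedTruth,
    outdir: str | Path,
) -> None:
    """Write edge list, per-context list files, hierarchy config, annotation
    TSV and a truth JSON into a directory."""
    from netstrat.graph_core import write_network

    outdir = Path(outdir)
    outdir.mkdir(parents=True, exist_ok=True)
    write_network(conglomerate, outdir / "conglomerate.edges.tsv")
    entries = []
    for ctx in hierarchy:
        list_file = f"{ctx.name}.list.txt"
        with (outdir / list_file).open("w") as fh:
            for p in sorted(ctx.proteins):
                fh.write(p + "\n")
        entries.append(
            {"name": ctx.name, "level": ctx.level, "parent": ctx.parent, "list_file": list_file}
        )
    with (outdir / "hierarchy.yaml").open("w") as fh:
        import yaml

        yaml.safe_dump({"contexts": entries}, fh, sort_keys=False)
    annot.to_tsv(outdir / "annotations.tsv")
    truth_json = {
        "planted_modules": {
            ctx: [sorted(m) for m in mods] for ctx, mods in truth.planted_modules.items()
        },
        "module_cores": [sorted(c) for c in truth.module_cores],
        "artifact_decoys": sorted(truth.artifact_decoys),
        "module_terms": {t: list(v) for t, v in truth.module_terms.items()},
        "housekeeping": sorted(truth.housekeeping),
        "artifacts": [
            {
                "term": a.term,
                "nodes": sorted(a.nodes),
                "parts": [sorted(p) for p in a.parts],
                "sentinels": list(a.sentinels),
                "block_contexts": {f"{i}-{j}": c for (i, j), c in a.block_contexts.items()},
            }
            for a in truth.artifacts
        ],
    }
    with (outdir / "truth.json").open("w") as fh:
        json.dump(truth_json, fh, indent=1)
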