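# Methods

This document states the models and formulas implemented by `netstrat`, the
meaning of every generator parameter, the scope of what the synthetic
generator emulates, the numerical conventions, and the known limitations.
Nothing here claims empirical results beyond what the package computes.

## Networks and stratification

A network is an undirected simple graph over string protein IDs. Edges are
stored canonically as sorted pairs `(a, b)` with `a < b`; self-loops are
dropped at construction (the endpoint is kept as a node). A conglomerate is
assembled as the union of several edge datasets; each edge remembers the set
of datasets that reported it (provenance).

Context lists are organized in a leveled hierarchy: exactly one level-1
context (the *total list*), and every deeper context has a parent at a
strictly lower level. Child lists are not forced to be subsets of their
parents; violations are reported by `validate()` but not rejected.

Stratification induces one subnetwork per context: the interactions of the
total network whose two partners both occur in the context's list. Listed
proteins without any surviving interaction are dropped, so a subnetwork's
nodes are its *interacting* proteins; the ratio of interacting proteins to
list size is the context's coverage. By construction every stratified
subnetwork is a subgraph of the total network (the conglomerate induced on
the total list).

## Topology

Per-node statistics (degree, clustering coefficient, betweenness,
eccentricity) are computed with networkx. Betweenness is unnormalized
shortest-path betweenness with fractional credit for tied shortest paths and
endpoints excluded; eccentricity is taken within each connected component.

**Roles.** Hubs are the top `pct` percent of nodes by degree (default 20),
bottlenecks the same for betweenness. The threshold is the statistic value at
descending rank `ceil(pct/100 · N)` and thresholding is inclusive, so ties at
the threshold all become role nodes.

**Status change** between a reference network and a comparison network
partitions the reference's role nodes into kept (`role_to_role`), demoted
(`role_to_nonrole`, shared nodes only), and absent (`role_to_absent`), with
the identity `kept + demoted + absent = reference role count`. Demotion
percentages divide by the reference role count; promotion percentages by the
comparison role count.

**Classes.** Nodes are binned into percentile bands (default cutoffs
5/10/20/50, giving five classes, class 1 the top band) using the same
inclusive-threshold rule; a change of two or more classes between networks is
a *leap*.

**Distribution tests.** Degree (or other statistic) distributions of two
networks are compared two-sided with Welch's t (default), Student's t, or
Mann-Whitney U. The power-law slope is the least-squares slope of log
frequency vs log degree over nonzero degrees, a descriptive quantity only
(no maximum-likelihood tail fitting); it returns nothing when fewer than five
distinct positive degree values exist.

## Network compatibility

Compatibility of two networks is the Jaccard index of their node sets and of
their edge sets. The null model induces subnetworks of the total network on
uniform node samples of matched sizes, pairing replicate *i* of the size-A
stream with replicate *i* of the size-B stream (500 pairs by default). The
observed Jaccard is compared to the null replicate distribution with a
one-sample two-sided Student's t-test. When the null has zero variance the
p-value degenerates to 1 if the observed value equals the null mean and 0
otherwise.

## Modules

Three extraction algorithms:

* **k-clique percolation** (overlapping): maximal cliques of size ≥ k are
  chained whenever they share ≥ k−1 nodes; a community is the node union of a
  chain. Equivalent to percolating all k-cliques. The default comparison grid
  uses k = 4 and k = 5; k = 3 percolates into one giant community on dense
  conglomerate-scale networks and is excluded by default.
* **Simulated-annealing modularity maximization**: modularity of a disjoint
  partition is `M = Σ_s [ l_s/L − (k_s/2L)² ]` with `L` the edge count,
  `l_s` a module's internal edges and `k_s` its degree sum. Annealing starts
  from singletons; moves are single-node reassignments (to a neighboring or
  fresh community) plus community merges and random bipartition splits,
  accepted by the Metropolis rule; geometric cooling (t₀ = 1, factor 0.95,
  floor 1e-3; |V|² node moves and |V| merge/split moves per temperature).
  The best partition seen is returned; fully reproducible under the seed.
* **Edge-betweenness partitioning**: repeatedly remove the edge of maximum
  edge betweenness (recomputed after each removal; ties broken by sorted edge
  ID) until `round(fraction · L)` edges are gone; modules are the connected
  components of the residue with singletons dropped.

**Modular compatibility Cp.** For each module A of one set, its best match in
the other set is the module sharing the most nodes, admissible only when the
shared count covers at least 50% of A. The per-module term is `C/(T+P−C)`
(shared, focal size, match size); unmatched modules contribute 0. Terms are
averaged within each matching direction (dividing by that direction's module
count) and the two directions are averaged, so Cp ∈ [0, 1] and Cp(S, S) = 1.
Worked value: S1 = {{a,b,c,d}}, S2 = {{a,b,c},{d,e,f}} gives directions 0.75
and (0.75+0)/2 = 0.375, Cp = 0.5625.

**Cp comparison protocol.** Group (i): Cp between total-network modules and
each subnetwork's modules at matched clustering parameters. Group (ii): Cp
between module sets of the same network across parameter settings. Groups
are compared with a two-sided Mann-Whitney U test. Modules smaller than
`min_module_size` (default 3) are dropped first; pairs with an empty module
set are skipped.

## Enrichment

Annotation terms are opaque pre-mapped labels in three categories
(biological_process, molecular_function, cellular_component; default
category biological_process). The universe is restricted to annotated
proteins of the background; the foreground is additionally intersected with
the background.

Per-term significance is the one-sided over-representation p-value
`P(X ≥ k)` for `X ~ Hypergeometric(N, K, n)` — identical to the one-sided
Fisher exact test of the 2×2 table — at significance cutoff α = 5e-4 with no
multiple-testing correction by default (an optional flag adds
Benjamini-Hochberg q-values). Pair enrichment counts interacting pairs whose
two partners share a term, against the background network's pairs.

χ² comparisons treat one count vector as observed and rescale the other to
its total as expected, pooling cells with expected count < 1.

Module-level summaries test every module (≥ `min_module_size`) against its
network's protein background. Terms enriched in at least one module of every
network are *universal*; terms enriched in exactly one network's modules are
*exclusive* to it; terms exclusive to the total network are flagged as
candidate artifacts of conglomerate assembly.

## Randomization and robustness

**Node-sampling null.** A randomized counterpart of a stratified subnetwork
draws a protein list of the same size uniformly from the total list, induces
the subnetwork, and accepts the replicate only when its total degree is
within a tolerance (default 10%) of the real subnetwork's; the run fails
after `max_retries` rejections (the null is then not comparable). The
observed demotion percentage is tested against 20 such replicates by a
one-sample two-sided Student's t-test.

**False-interaction replacement** removes `round(fraction · L)` uniformly
chosen edges and adds the same number of uniformly chosen node pairs absent
from the original network (and from an optional larger universe network),
conserving |V| and |E| exactly. The robustness protocol re-runs the
status-change analysis on the perturbed conglomerate and reports per-metric
deltas against the unperturbed run.

## Synthetic generator

`SynthConfig` parameters and their meaning:

| parameter | default | meaning |
|---|---|---|
| `n_proteins` | 1000 | size of the protein universe |
| `n_contexts` | (1, 2, 5, 4) | contexts per hierarchy level (total / coarse / base / fine) |
| `jaccard_band` | (0.39, 0.65) | accepted band for pairwise base-list Jaccard |
| `jaccard_target` | 0.43 | expected pairwise list Jaccard aimed for (must lie in the band) |
| `list_fraction` | 0.56 | base-list size as a fraction of the shared pool |
| `modules_per_context` | 3 | planted module families |
| `module_size_range` | (8, 12) | per-context size of a family's variant |
| `module_core_size` | 4 | shared core of each family, listed in every context |
| `p_in` | 0.9 | intra-edge probability of planted modules |
| `ba_m` | 4 | preferential-attachment edges per new backbone node |
| `ctx_edge_rate` | 0.15 | context-specific random edges per listed member |
| `ppi_coverage` | 0.55 | interactome-covered fraction of the universe |
| `artifact_modules` | 2 | planted conglomerate-only artifact modules |
| `artifact_part_size` | 3 | proteins per artifact part (4 parts per artifact) |
| `housekeeping_terms` | 24 | broad annotation terms |
| `housekeeping_coverage` | 0.18 | universe fraction carrying each housekeeping term |
| `annotation_noise` | 0.05 | random extra context-term assignments (fraction of planted ones) |
| `level2_fraction` | 0.88 | coarse-list fraction of the shared pool |
| `level4_fraction` | 0.80 | fine-list fraction of the parent list |
| `level4_perturbation` | 0.02 | fine-list swap-ins from outside the parent |
| `density_hi` | 0.6 | artifact density demanded in the conglomerate union |
| `density_lo` | 0.3 | artifact density allowed in any single context |
| `seed` | 0 | master seed; the run is fully deterministic under it |

Construction, in order: artifact parts and planted-module families are
reserved from the universe; each base-context list is a common core plus an
independent sample of the remaining pool — the core fraction is solved by
bisection so the *expected* pairwise list Jaccard equals `jaccard_target` —
plus its exclusive planted proteins and the ubiquitous set (module cores and
artifact decoys). A single preferential-attachment backbone spans a
`ppi_coverage` subset of the listed universe; coarse contexts contribute
backbone-only layers (so nearly the whole backbone reaches the
conglomerate), base contexts add context-specific random pairs, their
planted-module variants (edges with probability `p_in`) and their assigned
artifact blocks (complete graphs on two parts). The conglomerate is exactly
the union of the context layers.

Artifacts: each artifact's four parts define six part-pairs; five of them are
assigned to five distinct base contexts, which carry the complete graph on
the pair. Parts 0 and 2 are never co-listed, so every single-context remnant
stays sparse (≤ `density_lo`) while the union is dense (≥ `density_hi`).
Two sentinel proteins in each of parts 0 and 2 carry the artifact's
annotation term; three ubiquitous decoy proteins also carry every artifact
term, keeping single-context remnant enrichment below the α = 5e-4 cutoff
while the assembled union module is strongly enriched — the conglomerate-only
signature.

**Emulation scope.** The generator reproduces the *structure* of the study
conditions — overlapping context lists with calibrated Jaccard, sub-unity
interactome coverage, context-specific interactions, chimeric merged modules,
conglomerate-only artifact modules, broad and context-specific annotations —
at roughly desk scale (~600 interacting proteins). It does not emulate
literature-curation biases, experimental error models, protein abundance, or
any particular organism's interactome; absolute sizes, densities and
coverage differ from any real dataset.

## Numerical conventions

* All randomness flows from explicit integer seeds through
  `numpy.random.default_rng` (library, generator) or `random.Random`
  (annealing); derived seeds are drawn below 2³¹.
* Jaccard of two empty sets is defined as 0 (with a warning).
* Modularity of an edgeless network is undefined (`None`).
* Zero-variance nulls degenerate to p = 1 (observed equals the null mean) or
  p = 0 (it does not) instead of dividing by zero.
* Hypergeometric tail probabilities are computed by `scipy.stats.hypergeom.sf`
  and clipped to [0, 1].
* Exact worked identities asserted in the test suite: Jaccard({a,b,c},{b,c,d})
  = 0.5; modularity of two triangles joined by a bridge under the triangle
  partition = 5/14 ≈ 0.357143; modularity of the one-module partition = 0;
  the Cp worked example above = 0.5625; the all-in-foreground Fisher table on
  a 20-protein universe with a 5-protein term = 1/C(20,5).

## Limitations

* Simulated annealing is a stochastic heuristic; it is verified against the
  exhaustive-partition optimum only on ≤ 8-node fixtures and against planted
  modules on sparse-backbone synthetic fixtures. On dense backbones it may
  legitimately absorb boundary nodes into planted modules.
* Edge-betweenness partitioning recomputes betweenness after every removal
  (O(removals · V·E)); it is impractical beyond a few thousand edges.
* The compatibility and status-change nulls assume uniform node sampling;
  degree-stratified sampling is not implemented. When no degree-matched
  replicate exists within the retry budget the null is reported as not
  comparable rather than silently relaxed.
* Enrichment p-values are uncorrected by default (matching the α = 5e-4
  convention); the Benjamini-Hochberg option controls FDR per table, not
  across networks or modules.
* The power-law slope is a least-squares log-log fit, adequate for the
  descriptive comparisons here but not a rigorous tail estimator.
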