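# Methods

## The model and what it assumes

The package operates on a simple undirected graph G = (V, E) whose nodes
are gene/protein identifiers and whose edges are experimentally supported
interactions, together with one or more *label classes* (e.g. "locus
heterogeneity", "Mendelian"), each a collection of disorder → gene sets.
Three modelling assumptions run through everything:

- interactions are binary and context-free (no weights, tissues, or
  directions); self-loops and parallel edges carry no information and are
  removed on ingestion;
- disease annotation is a property of nodes, not edges, so a null model
  may re-assign labels while leaving the interactome fixed;
- genes of one heterogeneous disorder participate in shared complexes or
  pathways, which should surface as (a) excess labeled–labeled adjacency
  and (b) dense modules enriched for single disorders.

## Interconnectivity statistic and its null

For a labeled set L ⊆ V the statistic is

  s(L) = |{v ∈ L : N(v) ∩ L ≠ ∅}| / |L|,

the proportion of labeled nodes with at least one labeled neighbor. The
null re-draws |L| distinct nodes and recomputes s, by default uniformly
over V ("uniform" mode). Because curated disease genes are better studied
and tend to sit on higher-degree nodes, a "degree_stratified" mode
re-draws within degree-decile strata matching the observed labels; both
modes ship because either reading of "equally many random nodes" is
defensible, and on heavy-tailed networks they genuinely differ.

The p-value is the add-one estimator p = (r + 1)/(n + 1) with r the
number of null samples ≥ the observed value; ties count as exceedances
(conservative) and the raw exceedance fraction r/n is reported alongside
so "p < 1/n" statements can be made exactly. One root seed spawns an
independent RNG substream per permutation (`numpy.random.SeedSequence`),
so results are bitwise reproducible and independent of evaluation order.
For |V| ≤ ~20 the null can be enumerated exactly over all C(|V|, |L|)
placements (`exact_null`), which is the oracle the Monte Carlo path is
tested against; the two must agree within Monte Carlo error by
construction, not by shared code.

The statistic is discrete (multiples of 1/|L|), so null p-values are
uniform only up to the statistic's point masses; the calibration test
uses 150 labels on the 2000-node default background, enough support that
the discreteness is far below the resolution of a 200-run KS test.

## Topology parameters

Per network (and separately for its largest connected component, LCC):
node/edge counts, average degree 2m/n, isolated nodes (degree 0) as count
and percentage, mean clustering coefficient, and degree centralization.
Centralization defaults to the NetworkAnalyzer-style formula
(n/(n−2))·(k_max/(n−1) − density) with Freeman's classical
Σ(k_max − k_i)/((n−1)(n−2)) behind a flag; both are 1 on stars and 0 on
regular graphs. Local clustering of degree < 2 nodes is defined as 0 and
*included* in the network mean — the convention that keeps one number
well-defined for disease subnetworks where a third or more of nodes are
isolated; a flag restricts the mean to degree ≥ 2 nodes for comparison
with tools that exclude them. Percentages print to one decimal place.
LCC size ties break toward the component containing the lexicographically
smallest identifier, so outputs are deterministic.

## MCODE and the cross-check

Stage 1 weights each node v by k_max · density(H) where H is the highest
k-core of the closed neighborhood N[v]; isolated nodes weigh 0. Stage 2
takes seeds in decreasing weight order (ties by identifier) and grows a
complex breadth-first, admitting unvisited neighbors whose weight is
strictly greater than seed_weight · (1 − VWP); a node joins at most one
complex. Stage 3 discards complexes without a 2-core; haircut (on by
default) retains exactly the complex's 2-core, which provably keeps the
complex connected and leaves every member with ≥ 2 intra-module links;
fluff (off by default, semantics vary across published implementations)
adds boundary neighbors whose closed-neighborhood density exceeds a
threshold. Defaults VWP = 0.2, haircut on, fluff off are the algorithm's
published defaults. Score = density × size; downstream filtering keeps
score **strictly** greater than 3.

MCODE recovers dense *cores*: a planted community whose internal edge
probability is well below 1 is typically returned as a high-weight
subset, not in full, and two cliques joined by an edge merge whenever the
smaller clique's weights clear the larger seed's threshold (e.g. K7 into
K8 at VWP 0.2). The planted-clique benchmark therefore plants mutually
non-adjacent cliques — that separation *is* the planted structure whose
exact recovery is being claimed.

The cross-check runs Louvain modularity maximization (seeded) and reports,
per module, the fraction of member pairs co-assigned to one community; a
module validates at ≥ 0.8. The threshold is a design choice: any
module whose members end in a single community validates at 1.0, while a
scatter of k ≥ 5 random nodes across a sparse graph has near-zero
co-assignment. One independent algorithm suffices for the agreement
check; external partitions can be scored the same way.

Per-disorder module enrichment is the hypergeometric upper tail on
(module size, disorder genes on the network, network size), corrected by
Benjamini–Hochberg across all module × disorder pairs.

## Candidate nomination and its calibration

An unlabeled module member is a candidate for a disorder when it has
≥ min_links (default 2) neighbors among that disorder's genes *within the
module* (network-wide counting is a flag; it can only add candidates).
One-link genes are deliberately reported via `min_links=1` rather than
dropped, but never mixed into the default list. Ranking: labeled-link
count, then fraction of the disorder's on-network genes contacted, then
identifier. Leave-one-out recovery unlabels each disorder gene in turn
and asks whether the rule re-nominates it; module detection never reads
labels, so modules are reused across holdouts unchanged. On planted
modules with within-disorder edge probability q and g genes, per-gene
recovery is approximately the binomial tail P(Bin(g−1, q) ≥ min_links)
(≈ 0.994 at g = 12, q = 0.5, min_links = 2), which the recovery test
checks at a 0.9 floor.

## Synthetic data: what it emulates and what it does not

`GeneratorConfig` defaults define the standing study conditions: a
2000-node preferential-attachment background with 3 edges per new node
(mean degree ≈ 6, heavy-tailed degrees as in curated interactomes), 5
disorders × 12 genes planted on non-hub nodes (below the 90th degree
percentile, so planted signal is not an artifact of hubness), and
within-disorder edge probability 0.4 — strong but imperfect
interconnection. An Erdős–Rényi background, disorder overlap genes, and
random edge deletion (interactome incompleteness) are available switches.
The generator does **not** emulate evidence heterogeneity (Y2H vs co-IP),
false-positive edge structure, ascertainment bias of curation, or
correlated study coverage; passing tests show the machinery is correct
under the planted model, not that real disease gene sets will behave like
planted ones. Every generated study carries a truth record (memberships,
added edges) from which the observed statistic is recomputed as a
self-check, and identical seeds yield byte-identical files.

## Numerical and procedural choices

- All tie-breaks (seed order, member iteration, module ordering, LCC
  ties, candidate ranking) resolve by smallest identifier; reruns are
  byte-identical, which the pipeline test asserts on whole output files.
- Exact-null enumeration refuses past 10⁶ combinations.
- χ² homogeneity drops zero-total categories with a warning, rejects
  zero row margins, and allows the Yates correction only for 2×2 tables
  (off by default; the disease-category tables here are 2 × 20).
- BH adjustment is the standard step-up q_(i) = min_{j ≥ i} m·p_(j)/j,
  capped at 1, returned in input order.
- Centralization of networks with fewer than 3 nodes is reported as 0 in
  summaries (the formula is undefined; such inputs are degenerate
  fixtures) and raises when requested directly.
- Identifier mapping is many-to-one; merged nodes union their edges and
  merge-induced self-loops are dropped. Label genes that cannot be placed
  on the mapped network are removed from the analysis label set and
  reported (both pre- and post-merge label counts appear in the report,
  since redundancy and mapping failure are distinct attrition causes).

## Problem sizes in the test and acceptance runs

Simulation-backed checks run at the generator defaults (n = 2000) for
calibration/power and at n = 300–500 for properties that need many seeds
(planted-clique recovery, monotonicity grids, pipeline determinism);
permutation counts are 10,000 where the protocol itself is under test and
200–1,000 where only reproducibility or ordering matters. These sizes
were chosen so the full suite exercises every code path at the standing
study conditions while remaining comfortable to run locally.

## Known limitations

- MCODE module *identity* on diffuse planted communities is
  core-biased (see above); coverage-style claims should use the planted
  truth, as the recovery analyses here do.
- The degree-stratified null uses decile strata; for highly tied degree
  distributions strata collapse and the mode raises rather than guessing.
- Fluff post-processing is approximate and off by default.
- No ontology/pathway evidence is integrated; enrichment is purely
  hypergeometric on the supplied label sets.
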