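# Methods

## Data model

A release snapshot is a simple undirected graph over opaque string
identifiers. Edges are stored canonically (lexicographically ordered
pairs), so duplicate rows and reversed orientations of the same pair merge
their evidence (union of publication identifiers and source labels);
multiplicity is never incremented — curated PPI networks are simple graphs.
Self-interactions (homodimers) are retained and flagged but excluded by
default from degree, clustering-coefficient and path computations; with
loops included, a loop contributes 2 to its endpoint's degree (handshake
convention). Identifiers are case-sensitive and unvalidated, so synthetic
identifiers behave exactly like accession numbers. The filtering mode of a
snapshot (`unfiltered` / `standard` / `cross_checked`) is metadata only;
the interaction-reliability scoring that distinguishes the modes is outside
this package's scope. Column layouts of edge-table exports vary between
resources, so the reader takes a column-mapping dialect instead of
hard-coding one.

## Synthetic release series

The generator's defaults encode the statistical regime of a mature curated
human interactome and are not meant to be tuned per run:

* **Base release** (`n0 = 1000` nodes for the reference analyses, 4 planted
  blocks): nodes are assigned to blocks and inserted in random order; each
  node draws Poisson(`base_mean_degree`/2 = 4) stubs and attaches each stub
  preferentially (weight = degree + 1) within its own block with
  probability `intra_block_preference = 0.95`, across blocks otherwise.
  This yields a heavy-tailed degree sequence (log–log OLS slope magnitude
  ≈ 1.3–1.5 at n = 1000–2000) and leaves a few isolated nodes and small
  components, as observed in early releases of real resources.
* **Release steps**: growth is strictly monotone — no node or edge is ever
  retracted (real reference proteomes drift by <1% between releases, which
  we deliberately ignore and surface as warnings when real inputs violate
  it). Nodes grow by `node_growth_rate = 6%` per release (compounding to
  ≈ 40% over six releases, matching the reported decade-scale expansion of
  curated human interactomes). The *relative* edge growth per release is
  `edge_to_node_ratio = 4` times the relative node growth. We emphasise
  that this is a ratio of growth rates, not of added counts: at
  interactome-like mean degree, a 4× rate ratio corresponds to tens of
  added edges per added node, and it is what makes the density
  `2|E| / (|V|(|V|−1))` non-decreasing across releases — a count ratio of
  4:1 would instead dilute density at any realistic mean degree.
* **Arrival degrees**: each new node draws its degree from a discrete
  distribution pinned to two cumulative anchors — P(deg ≤ 4) = 0.80 and
  P(deg ≤ 12) = 0.95 — with geometric decay inside each segment and a
  geometric tail above the last anchor (truncated at 100). Only the two
  quantiles are empirically grounded; the within-segment shape is a
  modelling choice. New nodes attach to existing nodes only
  (preferentially, block-biased as above); the remaining edge budget of a
  release is spent between existing nodes, so hubs keep accreting.
* **Literature evidence**: each release is overlaid with simulated studies.
  The number of publications defaults to `|E| / 4.8` (target interactions
  per publication) and study sizes follow a zeta distribution truncated at
  `|E|`, with the exponent found by bisection so the expected total
  edge–publication incidence equals `|E|·(1 + ln(1/f))`, which makes the
  expected single-publication fraction equal the target `f = 0.79`. Because
  the zeta tail gives the realized total a very large variance, study sizes
  are then nudged by ±1 at randomly chosen studies until the total matches
  its expectation exactly; this preserves the study count and the shape of
  the size distribution while keeping the realized single-publication
  fraction within a point of target (observed 0.788 ± 0.003 over 10 seeds).
  Every edge receives exactly one "discovery" assignment; surplus study
  capacity re-validates uniformly drawn edges (resampling when a study
  already covers the drawn edge). The heavy tail produces a realistic count
  of >100- and >1000-interaction studies. In full-series simulations the
  per-release targets ramp linearly (interactions/publication 2.8 → 4.8,
  single-publication fraction 0.84 → 0.79), reproducing the drift toward
  high-throughput evidence.
* **Reference proteome**: the network's nodes plus `extra_no_ppi` fresh
  identifiers, with PE levels drawn from proportions
  (PE1…PE5) = (0.76, 0.13, 0.06, 0.03, 0.02) and 80% of the uncertain
  (PE5) labels forced onto the no-interaction identifiers.
* **Determinism**: all randomness in one call flows from a single
  `numpy.random.Generator`; a fixed seed reproduces the series exactly.

What the generator does **not** emulate: duplication–divergence mechanisms,
isoform-level interactions, identifier renames between releases, detection
method biases, and any correlation between a protein's PE level and its
degree. Passing tests on synthetic series therefore demonstrate the
correctness and stability of the *analytics*, not biological fidelity of
the inputs.

## Topology metrics

Conventions follow the Cytoscape NetworkAnalyzer ones common in this
literature: the global clustering coefficient is the unweighted mean of
local coefficients with degree-<2 nodes contributing 0; characteristic path
length and diameter are computed over connected pairs of the largest
component only (the full graphs have many components). Exact path metrics
run BFS from every node; above a configurable size a sampled mode (BFS from
k random sources) is used and records its seed and sample size. The
power-law fit is OLS of log₁₀ count on log₁₀ degree over the raw
(degree, count) histogram restricted to positive counts — the convention
that reproduces R² values in the 80–90% range on networks of this type;
logarithmic binning is available but off by default, and the minimum degree
of the fit window is exposed because neither choice is canonical.
Degenerate distributions (fewer than 3 distinct degrees is an error;
zero-variance axes) report slope 0 and R² 0 with a warning rather than
aborting a pipeline run. k-core numbers follow the standard peeling
definition; the "k-core" of a release means the maximum-k (main) core, and
the full core-number map is exposed alongside it.

## Clustering

**Random-walk communities.** Walktrap measures vertex similarity through
t-step random-walk transition probabilities and agglomerates greedily,
cutting the merge sequence at maximum modularity; we run it with t = 4
steps through igraph's implementation, per connected component, with labels
made globally unique (components without edges become singletons). The
computation uses exact transition probabilities, so results are
deterministic and invariant to node relabelling.

**Node embedding.** From every non-isolated node we run 10 uniform random
walks of length 80 (node2vec with p = q = 1, i.e. DeepWalk; the bias
parameters are exposed nowhere because uniform walks are the documented
setting), collect skip-gram (centre, context) pairs within a window of 10,
and train 128-dimensional embeddings by skip-gram with 5 negative samples
(unigram^0.75 noise), 2 epochs, linearly decaying learning rate from
0.025. The SGD kernel is numba-compiled and uses an explicit xorshift64
state, so a given seed reproduces the embedding bit-for-bit. A
deterministic alternative backend factorises the shifted-PMI co-occurrence
matrix by SVD (the closed-form counterpart of negative sampling) and is
used where optimizer stochasticity is undesirable. Isolated nodes are
embedded at the origin, flagged, and excluded from clustering with a
warning.

**Dynamic tree cut.** Average-linkage hierarchical clustering on Euclidean
distances, split top-down and per branch: within each subtree the sorted
merge heights are scanned (upper half of the height range) for gaps of at
least `rel_gap = 0.1` of the subtree height; a candidate cut is accepted
only if it separates at least two branches of `min_cluster_size/2` or more
leaves — single outliers peeling off at a noise gap are not structure —
and accepted children are examined recursively. Unsplit subtrees become
clusters if they have ≥ `min_cluster_size = 20` members; smaller leftovers
stay unassigned. The 0.1 default sits between the merge-height noise of
homogeneous point clouds (relative gaps ≤ ~0.06) and the separation of
genuinely distinct neighbourhoods in embedding space (≥ ~0.15 on block
benchmarks). This is the basic "tree" flavour of dynamic cutting; the
hybrid variant with PAM-style reassignment of leftovers is out of scope.

**Consensus.** The two partitions are compared over each method's top-15
clusters by size: intersection counts and Jaccard indices, with
intersections ranked by member count (ties broken lexicographically by
label pair) and member lists emitted for enrichment. On planted-community
benchmarks (4-block SBM, n = 400, p_in = 0.2, p_out = 0.005) both routes
reach adjusted Rand index 1.0 (5-seed mean ≥ 0.9 asserted), and the four
top intersections each coincide with one planted block. A practical
boundary worth knowing: on the preferential-attachment generator at
default density, the embedding + dynamic-cut route requires ≥ ~98%
within-block edge placement to recover blocks, because low-degree nodes
with one cross-block edge blur the dendrogram's height gaps; random-walk
clustering is robust down to 95%.

## Enrichment

Over-representation of a node set against annotation terms uses the exact
hypergeometric upper tail P(X ≥ k) for an overlap of k between a query of
size N and a term of size n in a background of size M, with
Benjamini–Hochberg adjustment across the emitted (overlap ≥ 1) terms. The
background defaults to the reference proteome when one is supplied, else
the network node set. This is a transparent substitute for web-service
functional annotation tools, which add proprietary term-clustering
heuristics on top of essentially the same test; no attempt is made to mimic
those heuristics.

## Pipeline and problem sizes

`run_pipeline` executes simulate/ingest → per-release metrics →
cross-release comparison → dual clustering of the final release →
enrichment of the top intersections → report, with a provenance block
(package version, seed, full configuration) and a summary JSON that is
byte-identical under a fixed seed. Conservation identities are asserted on
every run: Venn region counts sum to the edge total and coverage counts sum
to the proteome size. The reference analyses use n0 = 1000 with 5 releases
for the growth/evidence/core statistics and n = 400 SBM benchmarks for
clustering recovery — sizes at which exact path metrics and all-pairs
oracles remain cheap while degree distributions and core structure are
already well developed; all sizes scale up through configuration.

## Known limitations

* Monotone growth only; retractions in real data are tolerated with
  warnings but not modelled.
* The power-law fit is a descriptive OLS convention, not a maximum-
  likelihood tail estimate; R² on raw counts of small synthetic networks
  runs ~0.75–0.85, below the ~0.9 typical of 10⁴-node interactomes.
* Embedding-based clustering is sensitive to block mixing (see above) and,
  unlike the random-walk route, depends on a seed.
* GMT enrichment is term-by-term; no ontology topology is used.
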