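# ppievo — analysis of evolving protein–protein interaction networks

`ppievo` is a toolkit for asking how complete a reconstructed interactome
is, by following it across successive releases of a curated PPI resource.
It is aimed at systems biologists who track a human (or other organism)
protein-interaction network through time: each release is an
evidence-annotated graph (proteins as nodes, experimentally supported
binary interactions as edges, each edge carrying its supporting
publications, source databases and detection-method class), and the
question is whether the network's *structure* has stabilised even while
edges keep accumulating.

## What it computes

For a series of release snapshots `G_1 ⊆ G_2 ⊆ … ⊆ G_T`:

* **Growth and evidence accounting** — node/edge/publication counts with
  percent changes (consecutive and versus baseline), interactions per
  publication `|E| / #publications`, the fraction of interactions supported
  by a single publication, and counts of high-throughput studies (>100,
  >1000 interactions per publication).
* **Topology metrics** per release — degree distribution with hub flagging
  (degree > 300), an OLS power-law fit on log₁₀–log₁₀ axes
  (`log₁₀ n(k) = α + β·log₁₀ k`, reporting β and R²), Watts–Strogatz mean
  clustering coefficient, characteristic path length and diameter on the
  largest component, and k-core decomposition. The *main core* (maximum-k
  core) is the densest neighbourhood of the graph; its overlap across
  releases (intersection counts, Jaccard) is a stability signal.
* **New-node degree profiles** — degrees of proteins added between
  releases, with the cumulative anchors P(deg ≤ 4) and P(deg ≤ 12); a
  structurally settled network accretes mostly low-degree nodes.
* **Reference-proteome coverage** — which fraction of a reference protein
  set (identifier → protein-existence level PE1…PE5) has any interaction,
  and the PE composition of the proteins still without interactions.
* **Consensus clustering** — two independent views of neighbourhood
  structure: (1) random-walk (Walktrap) community detection with t = 4
  steps, cut at maximum modularity; (2) a DeepWalk/node2vec-style node
  embedding (D = 128, 10 uniform walks of length 80 per node, window 10)
  trained by skip-gram with negative sampling, followed by average-linkage
  hierarchical clustering on Euclidean distances split by a dynamic tree
  cut (minimum cluster size 20). The ranked intersections of the two
  partitions pick out the most robustly connected protein neighbourhoods.
* **Over-representation analysis** — exact hypergeometric upper-tail tests
  of any node set (e.g. a consensus intersection) against GMT annotation
  sets, with Benjamini–Hochberg adjustment.

A seeded synthetic-release generator produces series with the statistical
signature of a real curated interactome (scale-free degrees with planted
communities, edge growth four-fold the node growth per release, ~80% of
arrivals with degree ≤ 4, heavy-tailed study sizes with ~79% of
interactions supported by one publication, PE labels with uncertain
proteins concentrated outside the network), so the entire pipeline is
testable without downloading anything.

## Worked example

```bash
ppievo run --seed 7 --outdir out/
cat out/report.txt
```

```
Releases:
  r1: 400 nodes, 1447 edges
  ...
  r4: 476 nodes, 2750 edges

Growth versus first release (%):
  nodes 19.0  edges 90.0  publications 10.8
  PPIs per publication: 2.80 -> 4.80
  single-publication fraction: 0.795
  new nodes r1->r2: n=24 P(deg<=4)=0.79 P(deg<=12)=1.00
  ...
RW cluster sizes: [121, 119, 119, 116, 1]
N2V-HC cluster sizes: [120, 120, 118, 117]
Intersection RW0/HC1 (n=120): BLOCK1
```

Reading this: across four simulated releases the node count grew 19% while
edges grew 90% (the ~4:1 growth-rate ratio of a densifying interactome);
the mean number of interactions per publication rose from 2.8 to 4.8 while
79.5% of interactions still rest on a single publication — the signature of
high-throughput studies driving recent growth. Arrivals are predominantly
low-degree. Both clustering algorithms recover four large neighbourhoods,
and their top intersections coincide with the planted communities
(`BLOCK*`), each significantly enriched in its own annotation term.

The same stages run on real release exports: `ppievo metrics`,
`ppievo compare`, `ppievo cluster` and `ppievo enrich` accept tab-delimited
edge tables (configurable columns: `id_a`, `id_b`, `pmids`, `sources`,
`method_class`), a two-column proteome TSV and GMT annotation files; GraphML
export is provided for Cytoscape.

## Layout

```
src/ppievo/
  graph_model.py   snapshot/proteome/annotation types, TSV/GraphML/GMT I/O
  synthetic.py     seeded evolving-network generator with planted truth
  metrics.py       degree/power-law/connectivity/k-core metrics
  compare.py       cross-release growth, profiles, core overlap, coverage, Venn
  clustering.py    Walktrap, node embedding, dynamic tree cut, intersections
  enrichment.py    hypergeometric ORA + Benjamini-Hochberg
  pipeline.py      end-to-end orchestration with provenance
  cli.py           `ppievo` command-line interface
docs/methods.md    model, parameter and design notes
```
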