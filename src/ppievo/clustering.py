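"""Dual-algorithm consensus clustering of an interactome snapshot.

Two complementary views of the network neighbourhood structure:

* ``rw_cluster`` — random-walk community detection (Walktrap): vertex
  distances derived from t-step random-walk transition probabilities,
  agglomerated greedily, dendrogram cut at maximum modularity.  The number
  of steps defaults to 4.
* ``n2v_embed`` + ``hc_dynamic_cut`` — a DeepWalk/node2vec-style embedding
  (uniform random walks, skip-gram pairs within a window, negative-sampling
  SGD; a deterministic shifted-PMI SVD backend is available), followed by
  average-linkage hierarchical clustering on Euclidean distances split by a
  dynamic tree cut with a minimum cluster size.

The consensus step, ``cluster_intersections``, ranks the pairwise overlaps
between the largest clusters of the two methods; densely connected
neighbourhoods show up as large intersections.
"""

from __future__ import annotations

import warnings
from dataclasses import dataclass, field

import igraph as ig
import numpy as np
import pandas as pd
from numba import njit
from scipy.cluster.hierarchy import linkage, to_tree
from scipy.sparse import csr_matrix

from ppievo.graph_model import ReleaseSnapshot


@dataclass
class RWParams:
    """Random-walk community detection parameters."""

    t: int = 4  # walk length in steps

    def __post_init__(self) -> None:
        if self.t < 1:
            raise ValueError("t must be >= 1")


@dataclass
class N2VParams:
    """Embedding + hierarchical clustering parameters.

    Defaults follow common practice for interactome-scale embeddings:
    dimension 128, 10 walks of length 80 per node, window 10, minimum
    cluster size 20.
    """

    d: int = 128
    walk_length: int = 80
    num_walks: int = 10
    window: int = 10
    min_cluster_size: int = 20
    seed: int = 0
    epochs: int = 2
    learning_rate: float = 0.025
    negative: int = 5
    backend: str = "sgd"  # or "svd" (deterministic shifted-PMI SVD)
    rel_gap: float = 0.1  # relative height gap required to split a branch
    max_pairs: int = 20_000_000

    def __post_init__(self) -> None:
        if self.d < 2:
            raise ValueError("embedding dimension must be >= 2")
        for name in ("walk_length", "num_walks", "window", "min_cluster_size"):
            if getattr(self, name) < 1:
                raise ValueError(f"{name} must be >= 1")


@dataclass
class Clustering:
    """A node -> cluster-label partition with method provenance.

    ``None`` labels mark unassigned nodes (below-minimum leftovers of the
    dynamic tree cut, or isolated nodes).
    """

    method: str
    labels: dict[str, int | None] = field(default_factory=dict)

    def partition(self) -> dict[int, set[str]]:
        out: dict[int, set[str]] = {}
        for node, lab in self.labels.items():
            if lab is not None:
                out.setdefault(lab, set()).add(node)
        return out

    def sizes(self) -> list[tuple[int, int]]:
        """(label, size) pairs, largest first; ties by label."""
        part = self.partition()
        return [
            (lab, len(members))
            for lab, members in sorted(
                part.items(), key=lambda kv: (-len(kv[1]), kv[0])
            )
        ]

    def sizes_list(self) -> list[int]:
        return [size for _, size in self.sizes()]

    def n_clusters(self) -> int:
        return len(self.partition())

    def relabel_by_size(self) -> "Clustering":
        """Renumber labels 0..k-1 in decreasing size order."""
        mapping = {lab: i for i, (lab, _) in enumerate(self.sizes())}
        return Clustering(
            self.method,
            {n: (mapping[l] if l is not None else None) for n, l in self.labels.items()},
        )


@dataclass
class EmbeddingTable:
    """Node embedding; isolated nodes sit at the origin and are flagged."""

    nodes: list[str]
    vectors: np.ndarray  # len(nodes) x D
    isolated: set[str] = field(default_factory=set)

    def active(self) -> tuple[list[str], np.ndarray]:
        keep = [i for i, n in enumerate(self.nodes) if n not in self.isolated]
        return [self.nodes[i] for i in keep], self.vectors[keep]


# ---------------------------------------------------------------------------
# Random-walk (Walktrap) communities


def rw_cluster(snapshot: ReleaseSnapshot, params: RWParams | None = None) -> Clustering:
    """Walktrap community detection, cut at maximum modularity.

    Each connected component is clustered independently and the labels are
    made globally unique; isolated nodes become singletons.  The
    implementation uses exact t-step transition probabilities (the igraph
    Walktrap agglomeration), so results are fully deterministic.
    """
    params = params or RWParams()
    g = snapshot.to_networkx(include_self_loops=False)
    labels: dict[str, int | None] = {}
    next_label = 0
    import networkx as nx

    for comp in sorted(nx.connected_components(g), key=lambda c: (-len(c), min(c))):
        comp_nodes = sorted(comp)
        sub = g.subgraph(comp_nodes)
        if sub.number_of_edges() == 0:
            for n in comp_nodes:
                labels[n] = next_label
                next_label += 1
            continue
        index = {n: i for i, n in enumerate(comp_nodes)}
        edges = [(index[a], index[b]) for a, b in sub.edges()]
        graph = ig.Graph(n=len(comp_nodes), edges=edges)
        dendro = graph.community_walktrap(steps=params.t)
        membership = dendro.as_clustering().membership
        for n, m in zip(comp_nodes, membership):
            labels[n] = next_label + m
        next_label += max(membership) + 1
    return Clustering(method="RW", labels=labels).relabel_by_size()


# ---------------------------------------------------------------------------
# Random-walk node embedding


def _simulate_walks(
    indptr: np.ndarray,
    indices: np.ndarray,
    n_nodes: int,
    num_walks: int,
    walk_length: int,
    rng: np.random.Generator,
) -> np.ndarray:
    """Uniform random walks from every non-isolated node, vectorized."""
    deg = np.diff(indptr)
    starts = np.repeat(np.flatnonzero(deg > 0), num_walks)
    rng.shuffle(starts)
    walks = np.empty((len(starts), walk_length), dtype=np.int64)
    walks[:, 0] = starts
    cur = starts.copy()
    for step in range(1, walk_length):
        offs = rng.integers(0, deg[cur])
        cur = indices[indptr[cur] + offs]
        walks[:, step] = cur
    return walks


def _skipgram_pairs(walks: np.ndarray, window: int) -> np.ndarray:
    """All (center, context) pairs within the window, both directions."""
    chunks = []
    for d in range(1, window + 1):
        if walks.shape[1] <= d:
            break
        left = walks[:, :-d].ravel()
        right = walks[:, d:].ravel()
        chunks.append(np.stack([left, right], axis=1))
        chunks.append(np.stack([right, left], axis=1))
    return np.concatenate(chunks, axis=0)


@njit(cache=True, fastmath=True)
def _sgns_kernel(
    pairs: np.ndarray,
    W: np.ndarray,
    C: np.ndarray,
    cdf: np.ndarray,
    epochs: int,
    lr0: float,
    negative: int,
    seed: int,
) -> None:  # pragma: no cover - exercised through n2v_embed
    """Sequential skip-gram negative-sampling SGD (word2vec-style updates).

    Randomness comes from an explicit xorshift64* state, so a given seed
    reproduces the embedding bit-for-bit regardless of the platform RNG.
    """
    n_pairs = pairs.shape[0]
    d = W.shape[1]
    state = np.uint64(seed * 2862933555777941757 + 3037000493)
    total = float(epochs * n_pairs)
    done = 0.0
    idx = np.arange(n_pairs)
    buf = np.empty(d)
    for _ in range(epochs):
        for i in range(n_pairs - 1, 0, -1):  # Fisher-Yates shuffle
            state ^= state << np.uint64(13)
            state ^= state >> np.uint64(7)
            state ^= state << np.uint64(17)
            j = int(state % np.uint64(i + 1))
            idx[i], idx[j] = idx[j], idx[i]
        for ii in range(n_pairs):
            p = idx[ii]
            c = pairs[p, 0]
            lr = lr0 * (1.0 - done / total)
            if lr < lr0 * 1e-4:
                lr = lr0 * 1e-4
            for dd in range(d):
                buf[dd] = 0.0
            for kk in range(negative + 1):
                if kk == 0:
                    t = pairs[p, 1]
                    label = 1.0
                else:
                    state ^= state << np.uint64(13)
                    state ^= state >> np.uint64(7)
                    state ^= state << np.uint64(17)
                    u = float(state >> np.uint64(11)) / 9007199254740992.0
                    t = np.searchsorted(cdf, u)
                    label = 0.0
                dot = 0.0
                for dd in range(d):
                    dot += W[c, dd] * C[t, dd]
                if dot > 30.0:
                    s = 1.0
                elif dot < -30.0:
                    s = 0.0
                else:
                    s = 1.0 / (1.0 + np.exp(-dot))
                g = lr * (label - s)
                for dd in range(d):
                    buf[dd] += g * C[t, dd]
                    C[t, dd] += g * W[c, dd]
            for dd in range(d):
                W[c, dd] += buf[dd]
            done += 1.0


def _train_sgns(
    pairs: np.ndarray,
    n_nodes: int,
    params: N2VParams,
    rng: np.random.Generator,
) -> np.ndarray:
    """Skip-gram with negative sampling over the walk co-occurrence pairs."""
    d = params.d
    W = (rng.random((n_nodes, d)) - 0.5) / d
    C = np.zeros((n_nodes, d))
    counts = np.bincount(pairs[:, 1], minlength=n_nodes).astype(float)
    noise = counts**0.75
    cdf = np.cumsum(noise / noise.sum())
    cdf[-1] = 1.0
    _sgns_kernel(
        np.ascontiguousarray(pairs, dtype=np.int64),
        W,
        C,
        cdf,
        params.epochs,
        params.learning_rate,
        params.negative,
        int(rng.integers(0, 2**31)),
    )
    return W


def _spmi_svd(pairs: np.ndarray, n_nodes: int, params: N2VParams) -> np.ndarray:
    """Deterministic embedding: SVD of the shifted-PMI co-occurrence matrix.

    Factorizing max(0, PMI - log k) is the closed-form counterpart of
    skip-gram with k negative samples.
    """
    counts = csr_matrix(
        (np.ones(len(pairs)), (pairs[:, 0], pairs[:, 1])),
        shape=(n_nodes, n_nodes),
    ).toarray()
    total = counts.sum()
    row = counts.sum(axis=1, keepdims=True)
    col = counts.sum(axis=0, keepdims=True)
    with np.errstate(divide="ignore", invalid="ignore"):
        pmi = np.log(counts * total / (row @ col))
    pmi[~np.isfinite(pmi)] = -np.inf
    spmi = np.maximum(pmi - np.log(params.negative), 0.0)
    u, s, _ = np.linalg.svd(spmi, full_matrices=False)
    k = min(params.d, len(s))
    emb = u[:, :k] * np.sqrt(s[:k])
    if k < params.d:
        emb = np.pad(emb, ((0, 0), (0, params.d - k)))
    return emb


def n2v_embed(
    snapshot: ReleaseSnapshot, params: N2VParams | None = None
) -> EmbeddingTable:
    """Random-walk node embedding of dimension D << N.

    Runs ``num_walks`` uniform random walks of ``walk_length`` from every
    non-isolated node, collects skip-gram (center, context) pairs within
    the window, and trains the embedding by negative-sampling SGD
    (``backend='sgd'``, default) or by a deterministic shifted-PMI SVD
    (``backend='svd'``).  Isolated nodes are placed at the origin and
    excluded from downstream clustering with a warning.
    """
    params = params or N2VParams()
    g = snapshot.to_networkx(include_self_loops=False)
    nodes = sorted(g.nodes)
    n = len(nodes)
    if n < 2:
        raise ValueError("need at least 2 nodes with edges to embed")
    if params.d >= n:
        raise ValueError(f"embedding dimension {params.d} must be < n nodes {n}")
    index = {node: i for i, node in enumerate(nodes)}
    rows, cols = [], []
    for a, b in g.edges():
        rows += [index[a], index[b]]
        cols += [index[b], index[a]]
    adj = csr_matrix((np.ones(len(rows)), (rows, cols)), shape=(n, n))
    adj.sum_duplicates()
    isolated = {nodes[i] for i in np.flatnonzero(np.diff(adj.indptr) == 0)}
    if isolated:
        warnings.warn(
            f"{len(isolated)} isolated node(s) embedded at the origin and "
            "excluded from clustering",
            stacklevel=2,
        )
    rng = np.random.default_rng(params.seed)
    walks = _simulate_walks(
        adj.indptr, adj.indices, n, params.num_walks, params.walk_length, rng
    )
    pairs = _skipgram_pairs(walks, params.window)
    if len(pairs) > params.max_pairs:
        keep = rng.choice(len(pairs), size=params.max_pairs, replace=False)
        pairs = pairs[keep]
    if params.backend == "sgd":
        vectors = _train_sgns(pairs, n, params, rng)
    elif params.backend == "svd":
        vectors = _spmi_svd(pairs, n, params)
    else:
        raise ValueError(f"unknown backend {params.backend!r}")
    vectors = np.asarray(vectors, dtype=float)
    for node in isolated:
        vectors[index[node]] = 0.0
    return EmbeddingTable(nodes=nodes, vectors=vectors, isolated=isolated)


# ---------------------------------------------------------------------------
# Hierarchical clustering with dynamic tree cut


def _leaf_ids(node) -> list[int]:
    """Leaf indices of a dendrogram subtree, iteratively (deep trees)."""
    out: list[int] = []
    stack = [node]
    while stack:
        cur = stack.pop()
        if cur.is_leaf():
            out.append(cur.id)
        else:
            stack.extend((cur.left, cur.right))
    return out


def _subtree_merge_heights(node) -> list[float]:
    heights: list[float] = []
    stack = [node]
    while stack:
        cur = stack.pop()
        if not cur.is_leaf():
            heights.append(cur.dist)
            stack.extend((cur.left, cur.right))
    return sorted(heights)


def _branch_cut_height(node, rel_gap: float, size_floor: int) -> float | None:
    """Cut height for one branch, or None when it should stay whole.

    Candidate cuts sit in the largest gaps between consecutive merge
    heights in the subtree's upper height range (a gap of at least
    ``rel_gap`` x subtree height separates tight sub-branches from the
    looser joins above them).  A cut is only accepted when it yields at
    least two branches of ``size_floor`` leaves or more — single points
    peeling off at a spurious height gap do not constitute structure.
    """
    if node.is_leaf():
        return None
    heights = _subtree_merge_heights(node)
    top = heights[-1]
    if top <= 0:
        return None
    candidates = []
    for lo, hi in zip(heights, heights[1:]):
        if hi < 0.5 * top:
            continue
        gap = (hi - lo) / top
        if gap >= rel_gap:
            candidates.append((gap, 0.5 * (lo + hi)))
    for _, cut in sorted(candidates, reverse=True):
        sizes = sorted(
            (len(_leaf_ids(ch)) for ch in _cut_children(node, cut)), reverse=True
        )
        if len(sizes) >= 2 and sizes[1] >= size_floor:
            return cut
    return None


def _cut_children(node, tau: float) -> list:
    """Maximal subtrees whose top merge lies below the cut height."""
    out = []
    stack = [node]
    while stack:
        cur = stack.pop()
        if cur.is_leaf() or cur.dist < tau:
            out.append(cur)
        else:
            stack.extend((cur.left, cur.right))
    return out


def hc_dynamic_cut(
    embedding: EmbeddingTable, params: N2VParams | None = None
) -> Clustering:
    """Average-linkage clustering on Euclidean distances, dynamically cut.

    The dendrogram is split per branch, adaptively: within each subtree the
    merge heights are scanned for the largest gap between consecutive
    heights in the subtree's upper height range; when that gap exceeds
    ``rel_gap`` of the subtree height, the subtree is cut there (possibly
    into several children at once) and each child is examined recursively.
    Subtrees that never split become clusters when they have at least
    ``min_cluster_size`` members; smaller leftovers stay unassigned.
    """
    params = params or N2VParams()
    names, X = embedding.active()
    labels: dict[str, int | None] = {n: None for n in embedding.nodes}
    if len(names) == 0:
        raise ValueError("no active points to cluster")
    if len(names) < params.min_cluster_size:
        warnings.warn(
            f"only {len(names)} points (< min_cluster_size="
            f"{params.min_cluster_size}); returning a single cluster",
            stacklevel=2,
        )
        for n in names:
            labels[n] = 0
        return Clustering(method="N2V-HC", labels=labels)
    Z = linkage(X, method="average", metric="euclidean")
    root = to_tree(Z)

    size_floor = max(2, params.min_cluster_size // 2)
    groups: list[list[int]] = []
    pending = [root]
    while pending:
        node = pending.pop()
        cut = _branch_cut_height(node, params.rel_gap, size_floor)
        if cut is None:
            groups.append(_leaf_ids(node))
        else:
            pending.extend(_cut_children(node, cut))
    kept = sorted(
        (g for g in groups if len(g) >= params.min_cluster_size),
        key=lambda g: (-len(g), min(g)),
    )
    for lab, group in enumerate(kept):
        for i in group:
            labels[names[i]] = lab
    return Clustering(method="N2V-HC", labels=labels)


def n2v_hc_cluster(
    snapshot: ReleaseSnapshot, params: N2VParams | None = None
) -> Clustering:
    """Convenience wrapper: embed then cut."""
    params = params or N2VParams()
    return hc_dynamic_cut(n2v_embed(snapshot, params), params)


# ---------------------------------------------------------------------------
# Consensus: cluster intersections


@dataclass
class IntersectionReport:
    """Overlap structure between the top clusters of two methods."""

    method_a: str
    method_b: str
    top_a: list[int]
    top_b: list[int]
    intersection_counts: pd.DataFrame
    jaccard: pd.DataFrame
    ranked: pd.DataFrame  # label_a, label_b, size, jaccard
    members: dict[tuple[int, int], set[str]] = field(default_factory=dict)


def cluster_intersections(
    a: Clustering, b: Clustering, top_k: int = 15
) -> IntersectionReport:
    """Overlap matrix over the ``top_k`` largest clusters of each method.

    Intersections are ranked by member count, ties broken lexicographically
    by the (label_a, label_b) pair; member identifier sets are emitted for
    downstream enrichment.
    """
    part_a, part_b = a.partition(), b.partition()
    if not part_a or not part_b:
        raise ValueError("cannot intersect an empty clustering")
    top_a = [lab for lab, _ in a.sizes()[:top_k]]
    top_b = [lab for lab, _ in b.sizes()[:top_k]]
    counts = np.zeros((len(top_a), len(top_b)), dtype=int)
    jac = np.zeros((len(top_a), len(top_b)))
    members: dict[tuple[int, int], set[str]] = {}
    rows = []
    for i, la in enumerate(top_a):
        for j, lb in enumerate(top_b):
            inter = part_a[la] & part_b[lb]
            counts[i, j] = len(inter)
            union = len(part_a[la] | part_b[lb])
            jac[i, j] = len(inter) / union if union else 0.0
            if inter:
                members[(la, lb)] = inter
            rows.append(
                {
                    "label_a": la,
                    "label_b": lb,
                    "size": len(inter),
                    "jaccard": jac[i, j],
                }
            )
    ranked = (
        pd.DataFrame(rows)
        .sort_values(
            ["size", "label_a", "label_b"],
            ascending=[False, True, True],
            ignore_index=True,
        )
    )
    return IntersectionReport(
        method_a=a.method,
        method_b=b.method,
        top_a=top_a,
        top_b=top_b,
        intersection_counts=pd.DataFrame(counts, index=top_a, columns=top_b),
        jaccard=pd.DataFrame(jac, index=top_a, columns=top_b),
        ranked=ranked,
        members=members,
    )
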