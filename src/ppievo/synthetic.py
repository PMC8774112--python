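"""Seeded generator of evolving interactome snapshots with planted structure.

The generator emulates the statistical signature of a curated PPI
meta-database followed across releases:

* a heavy-tailed (preferential-attachment) degree distribution with planted
  communities ("blocks") in the base release;
* strictly monotone growth, with the relative edge-addition rate four-fold
  the relative node-addition rate, new nodes attaching with low degrees
  (P(deg <= 4) ~ 0.80, P(deg <= 12) ~ 0.95) and extra edges landing
  preferentially on existing high-degree nodes, so hubs persist;
* literature evidence drawn from a heavy-tailed studies-size distribution
  (truncated zeta), calibrated so that a target fraction of interactions is
  supported by a single publication (~0.79 by default) at a target mean of
  interactions per publication;
* a reference proteome around the network with protein-existence levels
  PE1..PE5, the uncertain PE5 class concentrated among proteins without
  interactions.

All randomness flows from one integer seed through one
``numpy.random.Generator`` per call, so identical parameters reproduce the
series exactly.
"""

from __future__ import annotations

import math
import warnings
from dataclasses import dataclass, field

import numpy as np

from ppievo.graph_model import (
    AnnotationCollection,
    Edge,
    EdgeEvidence,
    ReferenceProteome,
    ReleaseSnapshot,
    canonical_edge,
)

DEFAULT_NEWNODE_CDF: tuple[tuple[int, float], ...] = ((4, 0.80), (12, 0.95))
DEFAULT_PE_MIX: tuple[float, ...] = (0.76, 0.13, 0.06, 0.03, 0.02)


@dataclass
class EvolutionParams:
    """Parameters of the structural evolution of the synthetic series.

    ``edge_to_node_ratio`` is the target ratio of the *relative* growth
    rates: the percent increase in edges per release is this multiple of
    the percent increase in nodes.  (At interactome-like mean degrees this
    means many more added edges than added nodes in absolute count, which
    is what drives densification.)  ``newnode_degree_cdf`` gives cumulative
    anchor points (degree, P(deg <= degree)) for the arrival-degree
    distribution; between and beyond the anchors the distribution decays
    geometrically.  ``node_growth_rate`` is the fractional node increase per
    release (default 6%, compounding to roughly 40% over six releases).
    """

    n0: int = 1000
    releases: int = 5
    edge_to_node_ratio: float = 4.0
    node_growth_rate: float = 0.06
    newnode_degree_cdf: tuple[tuple[int, float], ...] = DEFAULT_NEWNODE_CDF
    blocks: int = 4
    block_sizes: tuple[int, ...] | None = None
    intra_block_preference: float = 0.95
    base_mean_degree: float = 8.0
    seed: int = 0

    def __post_init__(self) -> None:
        if self.edge_to_node_ratio <= 0:
            raise ValueError("edge_to_node_ratio must be positive")
        prev = 0.0
        for d, p in self.newnode_degree_cdf:
            if not (0.0 <= p <= 1.0) or p < prev:
                raise ValueError("newnode_degree_cdf must be a CDF in [0, 1]")
            prev = p
        if not (0.0 <= self.intra_block_preference <= 1.0):
            raise ValueError("intra_block_preference must be in [0, 1]")


@dataclass
class EvidenceParams:
    """Parameters of the literature-evidence overlay.

    ``pubs`` fixes the number of simulated studies; when ``None`` it is
    derived from ``target_ppis_per_publication``.  The study-size
    distribution is a zeta distribution truncated at the edge count, its
    exponent chosen by bisection so the expected total edge-publication
    incidence hits ``target_single_pub_fraction``.
    """

    pubs: int | None = None
    target_single_pub_fraction: float = 0.79
    target_ppis_per_publication: float = 4.8
    seed: int = 0

    def __post_init__(self) -> None:
        if self.pubs is not None and self.pubs < 1:
            raise ValueError("pubs must be >= 1")
        if not (0.0 < self.target_single_pub_fraction <= 1.0):
            raise ValueError("target_single_pub_fraction must be in (0, 1]")


@dataclass
class PlantedTruth:
    """Ground truth recorded by the generator for downstream tests."""

    block_of: dict[str, int] = field(default_factory=dict)
    added_nodes: dict[str, list[str]] = field(default_factory=dict)
    added_edges: dict[str, list[Edge]] = field(default_factory=dict)
    arrival_degree: dict[str, int] = field(default_factory=dict)

    def blocks(self) -> dict[int, set[str]]:
        out: dict[int, set[str]] = {}
        for node, b in self.block_of.items():
            out.setdefault(b, set()).add(node)
        return out


def _node_id(i: int) -> str:
    return f"P{i:05d}"


def _new_node_degree_pmf(
    cdf_anchors: tuple[tuple[int, float], ...], d_max: int = 100
) -> tuple[np.ndarray, np.ndarray]:
    """Discrete arrival-degree pmf hitting the CDF anchors exactly.

    Within each segment the pmf decays geometrically; beyond the last anchor
    a geometric tail carries the residual mass up to ``d_max``.
    """
    anchors = sorted(cdf_anchors)
    degrees = np.arange(1, d_max + 1)
    pmf = np.zeros(d_max, dtype=float)
    lo = 1
    prev_cum = 0.0
    ratios = 0.6
    for d_anchor, cum in anchors:
        seg = np.arange(lo, min(d_anchor, d_max) + 1)
        if len(seg) == 0:
            continue
        w = ratios ** (seg - seg[0])
        pmf[seg - 1] = w / w.sum() * (cum - prev_cum)
        lo = d_anchor + 1
        prev_cum = cum
    if prev_cum < 1.0 and lo <= d_max:
        seg = np.arange(lo, d_max + 1)
        w = 0.8 ** (seg - seg[0])
        pmf[seg - 1] = w / w.sum() * (1.0 - prev_cum)
    pmf = pmf / pmf.sum()
    return degrees, pmf


def _pick_preferential(
    rng: np.random.Generator, candidates: np.ndarray, degree: np.ndarray, k: int = 1
) -> np.ndarray:
    """Sample k distinct candidates with probability proportional to degree+1."""
    w = degree[candidates] + 1.0
    w = w / w.sum()
    k = min(k, len(candidates))
    return rng.choice(candidates, size=k, replace=False, p=w)


def generate_base_network(
    params: EvolutionParams,
) -> tuple[ReleaseSnapshot, PlantedTruth]:
    """Base release: preferential attachment with planted blocks.

    Nodes are assigned to blocks, then inserted sequentially; each node
    draws a Poisson number of stub edges and attaches them preferentially
    (degree + 1 weighting) within its own block with probability
    ``intra_block_preference``, across blocks otherwise.  Nodes whose
    Poisson draw is zero may stay isolated, so connectivity of the base
    release is not guaranteed — mirroring the small isolated components of
    early interactome releases.
    """
    if params.n0 < 2 * params.blocks:
        raise ValueError(
            f"n0={params.n0} too small for {params.blocks} blocks "
            f"(need >= {2 * params.blocks})"
        )
    rng = np.random.default_rng(params.seed)
    n0 = params.n0
    if params.block_sizes is not None:
        if sum(params.block_sizes) != n0:
            raise ValueError("block_sizes must sum to n0")
        sizes = list(params.block_sizes)
    else:
        base = n0 // params.blocks
        sizes = [base] * params.blocks
        for i in range(n0 - base * params.blocks):
            sizes[i] += 1
    block_of_idx = np.repeat(np.arange(params.blocks), sizes)
    rng.shuffle(block_of_idx)

    degree = np.zeros(n0, dtype=float)
    snap = ReleaseSnapshot(release_id="r1")
    truth = PlantedTruth()
    order = rng.permutation(n0)
    members_by_block: list[list[int]] = [[] for _ in range(params.blocks)]
    seen: list[int] = []
    m_per_node = params.base_mean_degree / 2.0
    for idx in order:
        node = _node_id(idx)
        blk = int(block_of_idx[idx])
        snap.add_node(node)
        truth.block_of[node] = blk
        n_stubs = int(rng.poisson(m_per_node))
        for _ in range(n_stubs):
            if not seen:
                break
            same = members_by_block[blk]
            other = [j for j in seen if block_of_idx[j] != blk]
            want_intra = rng.random() < params.intra_block_preference
            pool = same if want_intra else other
            if not pool:
                # fall back across the boundary only when mixing is allowed
                if want_intra and params.intra_block_preference >= 1.0:
                    continue
                if not want_intra and params.intra_block_preference <= 0.0:
                    continue
                pool = other if want_intra else same
                if not pool:
                    continue
            target = int(
                _pick_preferential(rng, np.asarray(pool, dtype=int), degree, 1)[0]
            )
            if target == idx or snap.has_edge(node, _node_id(target)):
                continue
            snap.add_edge(node, _node_id(target))
            degree[idx] += 1
            degree[target] += 1
        seen.append(int(idx))
        members_by_block[blk].append(int(idx))
    truth.added_nodes["r1"] = sorted(snap.nodes)
    truth.added_edges["r1"] = sorted(snap.edges)
    return snap, truth


def evolve_release(
    prev: ReleaseSnapshot,
    truth: PlantedTruth,
    params: EvolutionParams,
    release_id: str | None = None,
) -> tuple[ReleaseSnapshot, PlantedTruth]:
    """Grow one release step; the result is a strict superset of ``prev``.

    New nodes arrive with degrees drawn from the configured arrival-degree
    distribution and attach preferentially; the balance of the edge budget
    (the percent edge growth being ``edge_to_node_ratio`` times the percent
    node growth) is spent on new edges between existing nodes, again
    preferentially, so hubs keep accreting and the network densifies.
    """
    rng = np.random.default_rng(
        params.seed + 100_003 * (len(truth.added_nodes) + 1)
    )
    snap = prev.copy()
    rel = release_id or f"r{len(truth.added_nodes) + 1}"
    snap.release_id = rel

    n_existing = prev.n_nodes
    n_new = max(1, round(params.node_growth_rate * n_existing))
    # edge growth rate = ratio x realized node growth rate
    target_edges = round(
        params.edge_to_node_ratio * (n_new / n_existing) * prev.n_edges
    )
    if target_edges < n_new:
        raise ValueError(
            f"edge budget {target_edges} cannot give each of {n_new} new "
            f"nodes one edge; feasible edge_to_node_ratio >= "
            f"{n_existing / max(prev.n_edges, 1):.3f}"
        )

    index_of = {node: i for i, node in enumerate(sorted(snap.nodes))}
    next_index = max(
        (int(n[1:]) for n in snap.nodes if n[1:].isdigit()), default=-1
    ) + 1
    all_nodes = sorted(snap.nodes)
    degree_map = snap.degrees()
    degree = np.array([degree_map[n] for n in all_nodes], dtype=float)
    blocks_arr = np.array([truth.block_of[n] for n in all_nodes], dtype=int)
    n_blocks = int(blocks_arr.max()) + 1

    dvals, pmf = _new_node_degree_pmf(params.newnode_degree_cdf)
    added_nodes: list[str] = []
    added_edges: list[Edge] = []

    def add_edge_tracked(a: str, b: str) -> bool:
        key = canonical_edge(a, b)
        if a == b or key in snap.edges:
            return False
        snap.add_edge(a, b)
        added_edges.append(key)
        return True

    # --- arrivals -------------------------------------------------------
    block_sizes = np.bincount(blocks_arr, minlength=n_blocks).astype(float)
    for _ in range(n_new):
        node = _node_id(next_index)
        next_index += 1
        blk = int(rng.choice(n_blocks, p=block_sizes / block_sizes.sum()))
        d = int(rng.choice(dvals, p=pmf))
        d = min(d, len(all_nodes))
        truth.block_of[node] = blk
        truth.arrival_degree[node] = d
        snap.add_node(node)
        added_nodes.append(node)
        same = np.flatnonzero(blocks_arr == blk)
        other = np.flatnonzero(blocks_arr != blk)
        n_intra = int(rng.binomial(d, params.intra_block_preference))
        n_intra = min(n_intra, len(same))
        n_cross = min(d - n_intra, len(other))
        targets: list[int] = []
        if n_intra:
            targets.extend(_pick_preferential(rng, same, degree, n_intra).tolist())
        if n_cross:
            targets.extend(_pick_preferential(rng, other, degree, n_cross).tolist())
        for t in targets:
            if add_edge_tracked(node, all_nodes[t]):
                degree[t] += 1
        block_sizes[blk] += 1

    # --- densification among existing nodes -----------------------------
    extra = target_edges - len(added_edges)
    attempts = 0
    while extra > 0 and attempts < 50 * target_edges:
        attempts += 1
        a = int(_pick_preferential(rng, np.arange(len(all_nodes)), degree, 1)[0])
        blk = int(blocks_arr[a])
        if rng.random() < params.intra_block_preference:
            pool = np.flatnonzero(blocks_arr == blk)
        else:
            pool = np.flatnonzero(blocks_arr != blk)
        if len(pool) == 0:
            continue
        b = int(_pick_preferential(rng, pool, degree, 1)[0])
        if add_edge_tracked(all_nodes[a], all_nodes[b]):
            degree[a] += 1
            degree[b] += 1
            extra -= 1
    if extra > 0:
        warnings.warn(
            f"{rel}: edge budget not exhausted ({extra} edges short)", stacklevel=2
        )
    truth.added_nodes[rel] = added_nodes
    truth.added_edges[rel] = added_edges
    return snap, truth


# ---------------------------------------------------------------------------
# Literature evidence


def _truncated_zeta_pmf(exponent: float, cap: int) -> np.ndarray:
    k = np.arange(1, cap + 1, dtype=float)
    w = k ** (-exponent)
    return w / w.sum()


def _truncated_zeta_mean(exponent: float, cap: int) -> float:
    k = np.arange(1, cap + 1, dtype=float)
    w = k ** (-exponent)
    return float((k * w).sum() / w.sum())


def _solve_zeta_exponent(target_mean: float, cap: int) -> float:
    """Bisect the truncated-zeta exponent so the mean study size matches."""
    lo, hi = 1.0001, 12.0
    if target_mean >= _truncated_zeta_mean(lo, cap):
        return lo
    if target_mean <= _truncated_zeta_mean(hi, cap):
        return hi
    for _ in range(80):
        mid = 0.5 * (lo + hi)
        if _truncated_zeta_mean(mid, cap) > target_mean:
            lo = mid
        else:
            hi = mid
    return 0.5 * (lo + hi)


def assign_evidence(
    snapshot: ReleaseSnapshot, params: EvidenceParams
) -> ReleaseSnapshot:
    """Overlay publication evidence on every edge of a snapshot.

    Each simulated study covers a zeta-distributed number of interactions.
    Every edge receives exactly one "discovery" assignment; the surplus
    study capacity re-validates uniformly chosen edges, which fixes the
    expected single-publication fraction at
    ``exp(-(T - E)/E)`` for total incidence T over E edges.  The zeta
    exponent is bisected so T matches the configured target fraction.
    """
    E = snapshot.n_edges
    if E == 0:
        raise ValueError("snapshot has no edges")
    rng = np.random.default_rng(params.seed)
    n_pubs = params.pubs
    if n_pubs is None:
        n_pubs = max(1, round(E / params.target_ppis_per_publication))
    # total incidence needed so that P(edge never re-sampled) = target
    t_total = round(E * (1.0 + math.log(1.0 / params.target_single_pub_fraction)))
    cap = min(E, 20_000)
    exponent = _solve_zeta_exponent(t_total / n_pubs, cap)
    sizes = rng.choice(
        np.arange(1, cap + 1), size=n_pubs, p=_truncated_zeta_pmf(exponent, cap)
    )
    # the heavy tail makes the realized total very variable; nudge sizes by
    # +/-1 interactions at random studies until the total matches exactly,
    # keeping the study count and the size distribution shape
    delta = int(t_total - sizes.sum())
    while delta > 0:
        chunk = rng.integers(0, n_pubs, size=delta)
        np.add.at(sizes, chunk, 1)
        over = np.maximum(sizes - cap, 0)
        sizes -= over
        delta = int(over.sum())
    while delta < 0:
        candidates = np.flatnonzero(sizes > 1)
        if len(candidates) == 0:
            break
        chunk = rng.choice(candidates, size=min(-delta, len(candidates)), replace=False)
        sizes[chunk] -= 1
        delta = int(t_total - sizes.sum())

    snap = snapshot.copy()
    edges = sorted(snap.edges)
    for ev in snap.edges.values():
        ev.pmids = set()

    slots = np.repeat(np.arange(n_pubs), sizes)
    rng.shuffle(slots)
    perm = rng.permutation(E)
    pmid = [f"PMID{params.seed % 1000:03d}{i:06d}" for i in range(n_pubs + E)]
    n_disc = min(E, len(slots))
    for i in range(n_disc):
        snap.edges[edges[int(perm[i])]].pmids.add(pmid[int(slots[i])])
    next_patch = n_pubs
    for i in range(n_disc, E):  # studies too small to cover all edges
        snap.edges[edges[int(perm[i])]].pmids.add(pmid[next_patch])
        next_patch += 1
    if next_patch > n_pubs:
        warnings.warn(
            f"added {next_patch - n_pubs} single-edge studies to cover all edges",
            stacklevel=2,
        )
    # source-database labels: three overlapping pseudo-databases, so the
    # Venn accounting downstream has non-trivial regions
    source_p = {"DB_A": 0.65, "DB_B": 0.45, "DB_C": 0.2}
    for edge in edges:
        ev = snap.edges[edge]
        ev.sources = {db for db, p in source_p.items() if rng.random() < p}
        if not ev.sources:
            ev.sources = {"DB_A"}

    extra_slots = slots[E:] if len(slots) > E else np.empty(0, dtype=int)
    revalidated = rng.integers(0, E, size=len(extra_slots))
    for slot, edge_idx in zip(extra_slots, revalidated):
        study = pmid[int(slot)]
        target = snap.edges[edges[int(edge_idx)]]
        # resample when the study already covers this edge, otherwise the
        # assignment is a no-op and the single-publication fraction drifts up
        for _ in range(8):
            if study not in target.pmids:
                break
            target = snap.edges[edges[int(rng.integers(0, E))]]
        target.pmids.add(study)
    return snap


# ---------------------------------------------------------------------------
# Reference proteome and block annotations


def generate_reference_proteome(
    snapshot: ReleaseSnapshot,
    pe_mix: tuple[float, ...] = DEFAULT_PE_MIX,
    extra_no_ppi: int = 0,
    pe5_no_ppi_fraction: float = 0.8,
    seed: int = 0,
) -> ReferenceProteome:
    """Reference proteome = network nodes plus ``extra_no_ppi`` fresh ids.

    PE levels are drawn from ``pe_mix`` (PE1..PE5 proportions); a fraction
    ``pe5_no_ppi_fraction`` of the uncertain PE5 labels is forced onto the
    no-interaction identifiers, emulating the concentration of uncertain
    proteins outside the network.
    """
    if abs(sum(pe_mix) - 1.0) > 1e-9 or len(pe_mix) != 5:
        raise ValueError("pe_mix must be 5 proportions summing to 1")
    rng = np.random.default_rng(seed)
    with_ppi = sorted(snapshot.nodes)
    no_ppi = [f"NP{i:05d}" for i in range(extra_no_ppi)]
    total = len(with_ppi) + len(no_ppi)
    counts = np.floor(np.asarray(pe_mix) * total).astype(int)
    counts[0] += total - counts.sum()

    entries: dict[str, str] = {}
    pe5_to_no_ppi = min(round(counts[4] * pe5_no_ppi_fraction), len(no_ppi))
    no_ppi_shuffled = list(no_ppi)
    rng.shuffle(no_ppi_shuffled)
    for ident in no_ppi_shuffled[:pe5_to_no_ppi]:
        entries[ident] = "PE5"
    remaining = with_ppi + no_ppi_shuffled[pe5_to_no_ppi:]
    rng.shuffle(remaining)
    labels = (
        ["PE1"] * counts[0]
        + ["PE2"] * counts[1]
        + ["PE3"] * counts[2]
        + ["PE4"] * counts[3]
        + ["PE5"] * (counts[4] - pe5_to_no_ppi)
    )
    rng.shuffle(labels)
    for ident, pe in zip(remaining, labels):
        entries[ident] = pe
    return ReferenceProteome(entries=entries, version="synthetic")


def block_annotations(truth: PlantedTruth, prefix: str = "BLOCK") -> AnnotationCollection:
    """GMT-style annotation terms derived from the planted blocks."""
    coll = AnnotationCollection()
    for blk, members in sorted(truth.blocks().items()):
        coll.terms[f"{prefix}{blk}"] = (
            f"planted community {blk}",
            set(members),
        )
    return coll


# ---------------------------------------------------------------------------
# Full series


def simulate_series(
    evo: EvolutionParams,
    evidence: EvidenceParams | None = None,
    ppp_range: tuple[float, float] | None = None,
    single_pub_range: tuple[float, float] | None = None,
) -> tuple[list[ReleaseSnapshot], PlantedTruth]:
    """Generate the whole release series with evidence overlays.

    When ``ppp_range`` / ``single_pub_range`` are given, the per-release
    evidence targets are interpolated linearly from the first to the last
    release (e.g. mean interactions per publication ramping from 2.8 to 4.8
    while the single-publication fraction eases from 0.84 to 0.79),
    reproducing the drift towards high-throughput studies.
    """
    base, truth = generate_base_network(evo)
    releases = [base]
    for _ in range(evo.releases - 1):
        nxt, truth = evolve_release(releases[-1], truth, evo)
        releases.append(nxt)
    ev = evidence or EvidenceParams(seed=evo.seed)
    out: list[ReleaseSnapshot] = []
    k = len(releases)
    for i, snap in enumerate(releases):
        frac = i / max(1, k - 1)
        ppp = ev.target_ppis_per_publication
        spf = ev.target_single_pub_fraction
        if ppp_range is not None:
            ppp = ppp_range[0] + frac * (ppp_range[1] - ppp_range[0])
        if single_pub_range is not None:
            spf = single_pub_range[0] + frac * (single_pub_range[1] - single_pub_range[0])
        step = EvidenceParams(
            pubs=ev.pubs,
            target_single_pub_fraction=spf,
            target_ppis_per_publication=ppp,
            seed=ev.seed + i,
        )
        out.append(assign_evidence(snap, step))
    return out, truth
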