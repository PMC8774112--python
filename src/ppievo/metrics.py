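"""Topology metrics for one interactome snapshot.

Implements the per-release network characterisation used throughout the
pipeline: degree tables with hub flagging, an ordinary-least-squares
power-law fit of the degree distribution on log-log axes, global
connectivity metrics (Watts-Strogatz mean clustering coefficient,
characteristic path length and diameter on the largest component), and
k-core decomposition with the main (maximum-k) core.

Conventions follow the Cytoscape NetworkAnalyzer ones common in the
interactome literature: the clustering coefficient is the mean of local
coefficients with degree-<2 nodes contributing zero, and path metrics are
restricted to connected pairs of the largest connected component.
"""

from __future__ import annotations

import warnings
from dataclasses import dataclass, field

import networkx as nx
import numpy as np
import pandas as pd
from scipy import stats

from ppievo.graph_model import ReleaseSnapshot

#: Degree above which a node is considered a hub (interactome convention:
#: more than 300 interactions).
HUB_THRESHOLD = 300


@dataclass
class NetworkMetrics:
    n_nodes: int
    n_edges: int
    clustering_coefficient: float
    characteristic_path_length: float
    diameter: float
    n_components: int
    component_sizes: list[int] = field(default_factory=list)
    path_mode: str = "exact"
    path_sample_size: int | None = None
    path_seed: int | None = None


@dataclass
class PowerLawFit:
    slope: float
    intercept: float
    r_squared: float
    min_degree: int = 1
    binning: str = "raw"
    n_points: int = 0


@dataclass
class CoreAssignment:
    core_numbers: dict[str, int]
    k_max: int
    main_core: set[str]


def degree_table(
    snapshot: ReleaseSnapshot, hub_threshold: int = HUB_THRESHOLD
) -> tuple[pd.DataFrame, pd.DataFrame]:
    """Per-node degrees and the degree histogram.

    Returns ``(node_table, dist_table)``: the first has columns
    ``node, degree, is_hub``; the second ``degree, count`` with counts
    summing to the number of nodes.  Self-loops are excluded from degree.
    """
    deg = snapshot.degrees()
    node_table = pd.DataFrame(
        {"node": list(deg.keys()), "degree": list(deg.values())}
    ).sort_values(["degree", "node"], ascending=[False, True], ignore_index=True)
    node_table["is_hub"] = node_table["degree"] > hub_threshold
    dist = (
        node_table.groupby("degree").size().rename("count").reset_index()
    ).sort_values("degree", ignore_index=True)
    return node_table, dist


def power_law_fit(
    degree_counts: pd.DataFrame,
    min_degree: int = 1,
    binning: str = "raw",
) -> PowerLawFit:
    """OLS fit of log10(count) against log10(degree).

    ``degree_counts`` is a frame with ``degree`` and ``count`` columns
    (zero-count degrees absent).  ``binning='log'`` first aggregates counts
    into logarithmic degree bins; the default fits the raw histogram.
    Degenerate inputs (zero variance in either axis) report slope 0 and
    R-squared 0 with a warning instead of failing.
    """
    sub = degree_counts[
        (degree_counts["degree"] >= max(min_degree, 1))
        & (degree_counts["count"] > 0)
    ]
    if binning == "log":
        edges = np.geomspace(
            sub["degree"].min(), sub["degree"].max() + 1, num=min(len(sub), 16) + 1
        )
        idx = np.clip(np.digitize(sub["degree"], edges) - 1, 0, len(edges) - 2)
        grouped = pd.DataFrame(
            {
                "degree": sub.groupby(idx)["degree"].mean(),
                "count": sub.groupby(idx)["count"].mean(),
            }
        )
        sub = grouped
    elif binning != "raw":
        raise ValueError(f"unknown binning {binning!r} (use 'raw' or 'log')")
    if len(sub) < 3:
        raise ValueError(
            "need at least 3 distinct degrees to fit; lower min_degree or "
            "use raw binning"
        )
    x = np.log10(sub["degree"].to_numpy(dtype=float))
    y = np.log10(sub["count"].to_numpy(dtype=float))
    if np.ptp(x) == 0 or np.ptp(y) == 0:
        warnings.warn(
            "degenerate degree distribution: slope and R^2 reported as 0",
            stacklevel=2,
        )
        return PowerLawFit(0.0, float(y.mean()), 0.0, min_degree, binning, len(sub))
    res = stats.linregress(x, y)
    return PowerLawFit(
        slope=float(res.slope),
        intercept=float(res.intercept),
        r_squared=float(res.rvalue) ** 2,
        min_degree=min_degree,
        binning=binning,
        n_points=len(sub),
    )


def _path_metrics_exact(g: nx.Graph) -> tuple[float, float]:
    """Mean shortest-path length over connected pairs, and the diameter."""
    total = 0
    pairs = 0
    diameter = 0
    for source in g.nodes:
        lengths = nx.single_source_shortest_path_length(g, source)
        for target, d in lengths.items():
            if target == source:
                continue
            total += d
            pairs += 1
            if d > diameter:
                diameter = d
    if pairs == 0:
        return float("nan"), 0.0
    return total / pairs, float(diameter)


def _path_metrics_sampled(
    g: nx.Graph, k: int, seed: int
) -> tuple[float, float, int]:
    rng = np.random.default_rng(seed)
    nodes = sorted(g.nodes)
    k = min(k, len(nodes))
    sources = rng.choice(len(nodes), size=k, replace=False)
    total = 0
    pairs = 0
    diameter = 0
    for i in sources:
        lengths = nx.single_source_shortest_path_length(g, nodes[int(i)])
        for target, d in lengths.items():
            if target == nodes[int(i)]:
                continue
            total += d
            pairs += 1
            if d > diameter:
                diameter = d
    return (total / pairs if pairs else float("nan")), float(diameter), k


def global_metrics(
    snapshot: ReleaseSnapshot,
    path_mode: str = "exact",
    sample_size: int = 200,
    seed: int = 0,
) -> NetworkMetrics:
    """Global connectivity metrics of a snapshot.

    Path metrics (characteristic path length and diameter) are computed on
    the largest connected component only.  ``path_mode='sampled'`` runs BFS
    from ``sample_size`` random sources instead of every node, for large
    graphs; the sample size and seed used are recorded in the result.
    """
    g = snapshot.to_networkx(include_self_loops=False)
    if g.number_of_nodes() == 0:
        raise ValueError("empty graph")
    components = sorted(nx.connected_components(g), key=len, reverse=True)
    sizes = [len(c) for c in components]
    # mean of local clustering coefficients; degree-<2 nodes contribute 0
    cc = float(np.mean(list(nx.clustering(g).values())))
    lcc = g.subgraph(components[0])
    sample_used: int | None = None
    if lcc.number_of_edges() == 0:
        cpl, diam = float("nan"), 0.0
    elif path_mode == "exact":
        cpl, diam = _path_metrics_exact(lcc)
    elif path_mode == "sampled":
        cpl, diam, sample_used = _path_metrics_sampled(lcc, sample_size, seed)
    else:
        raise ValueError(f"unknown path_mode {path_mode!r}")
    return NetworkMetrics(
        n_nodes=g.number_of_nodes(),
        n_edges=g.number_of_edges(),
        clustering_coefficient=cc,
        characteristic_path_length=cpl,
        diameter=diam,
        n_components=len(components),
        component_sizes=sizes,
        path_mode=path_mode,
        path_sample_size=sample_used,
        path_seed=seed if path_mode == "sampled" else None,
    )


def core_decomposition(snapshot: ReleaseSnapshot) -> CoreAssignment:
    """k-core decomposition; the main core is the maximum-k core.

    Core numbers follow the standard peeling definition: the core number of
    a node is the largest k such that the node belongs to a subgraph of
    minimum degree k.  Self-loops are ignored.
    """
    g = snapshot.to_networkx(include_self_loops=False)
    if g.number_of_nodes() == 0:
        return CoreAssignment({}, 0, set())
    core = nx.core_number(g)
    k_max = max(core.values(), default=0)
    main = {n for n, k in core.items() if k == k_max}
    return CoreAssignment(core_numbers=dict(core), k_max=k_max, main_core=main)
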