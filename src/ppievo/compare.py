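"""Cross-release analytics: growth, evidence, new nodes, cores, coverage.

Given an ordered series of release snapshots this module computes the
release-over-release summaries used to argue about interactome
completeness: node/edge/publication growth with percent changes, the
interactions-per-publication and single-publication statistics, degree
profiles of newly added proteins, overlap of the main k-cores across
releases, coverage of a reference proteome by protein-existence level, and
source-database Venn counts.
"""

from __future__ import annotations

import warnings
from dataclasses import dataclass, field
from itertools import combinations

import numpy as np
import pandas as pd

from ppievo.graph_model import PE_LEVELS, ReferenceProteome, ReleaseSnapshot
from ppievo.metrics import HUB_THRESHOLD, core_decomposition

#: Interactions-per-study thresholds defining "high-throughput" studies.
HT_THRESHOLDS = (100, 1000)


def _evidence_stats(snapshot: ReleaseSnapshot) -> dict[str, float | int | None]:
    pubs_per_edge = [len(ev.pmids) for ev in snapshot.edges.values()]
    if snapshot.n_edges == 0 or all(n == 0 for n in pubs_per_edge):
        return {
            "n_publications": None,
            "ppis_per_publication": None,
            "single_publication_fraction": None,
            f"studies_gt_{HT_THRESHOLDS[0]}": None,
            f"studies_gt_{HT_THRESHOLDS[1]}": None,
        }
    per_study: dict[str, int] = {}
    for ev in snapshot.edges.values():
        for pmid in ev.pmids:
            per_study[pmid] = per_study.get(pmid, 0) + 1
    n_pubs = len(per_study)
    counts = np.fromiter(per_study.values(), dtype=int)
    return {
        "n_publications": n_pubs,
        "ppis_per_publication": snapshot.n_edges / n_pubs,
        "single_publication_fraction": float(
            np.mean([n == 1 for n in pubs_per_edge])
        ),
        f"studies_gt_{HT_THRESHOLDS[0]}": int((counts > HT_THRESHOLDS[0]).sum()),
        f"studies_gt_{HT_THRESHOLDS[1]}": int((counts > HT_THRESHOLDS[1]).sum()),
    }


def growth_series(releases: list[ReleaseSnapshot]) -> pd.DataFrame:
    """Per-release growth and evidence table.

    One row per release with node/edge/publication counts, interactions per
    publication, single-publication fraction and high-throughput study
    counts, plus percent changes both against the previous release
    (``pct_*_prev``) and against the first release (``pct_*_base``);
    percent change = 100 * (new - old) / old.
    """
    if not releases:
        raise ValueError("empty release list")
    rows = []
    for snap in releases:
        row: dict[str, object] = {
            "release": snap.release_id,
            "n_nodes": snap.n_nodes,
            "n_edges": snap.n_edges,
        }
        stats = _evidence_stats(snap)
        if stats["n_publications"] is None and snap.n_edges > 0:
            warnings.warn(
                f"{snap.release_id}: no publication evidence; "
                "publication statistics are null",
                stacklevel=2,
            )
        row.update(stats)
        rows.append(row)
    df = pd.DataFrame(rows)

    def pct(new: pd.Series, old: pd.Series) -> pd.Series:
        return 100.0 * (new - old) / old

    for col in ("n_nodes", "n_edges", "n_publications"):
        series = df[col].astype(float)
        df[f"pct_{col}_prev"] = pct(series, series.shift(1))
        df[f"pct_{col}_base"] = pct(series, series.iloc[0])
    return df


@dataclass
class NewNodeProfile:
    """Degree profile of nodes added between two releases."""

    pair_label: str
    nodes: pd.DataFrame  # columns: node, degree
    histogram: pd.DataFrame  # columns: degree, count, cum_fraction
    frac_le_4: float
    frac_le_12: float
    n_new_hubs: int


def new_node_profile(
    older: ReleaseSnapshot,
    newer: ReleaseSnapshot,
    hub_threshold: int = HUB_THRESHOLD,
) -> NewNodeProfile:
    """Degrees (in the newer release) of nodes absent from the older one."""
    missing = older.nodes - newer.nodes
    if missing:
        warnings.warn(
            f"{len(missing)} node(s) of {older.release_id} absent from "
            f"{newer.release_id}: {sorted(missing)[:5]}...",
            stacklevel=2,
        )
    new_nodes = sorted(newer.nodes - older.nodes)
    deg = newer.degrees()
    table = pd.DataFrame({"node": new_nodes, "degree": [deg[n] for n in new_nodes]})
    if len(table):
        hist = table.groupby("degree").size().rename("count").reset_index()
        hist["cum_fraction"] = hist["count"].cumsum() / len(table)
        frac4 = float((table["degree"] <= 4).mean())
        frac12 = float((table["degree"] <= 12).mean())
        hubs = int((table["degree"] > hub_threshold).sum())
    else:
        hist = pd.DataFrame(columns=["degree", "count", "cum_fraction"])
        frac4 = frac12 = float("nan")
        hubs = 0
    return NewNodeProfile(
        pair_label=f"{older.release_id}->{newer.release_id}",
        nodes=table,
        histogram=hist,
        frac_le_4=frac4,
        frac_le_12=frac12,
        n_new_hubs=hubs,
    )


@dataclass
class CoreOverlapReport:
    """Pairwise overlap of the main k-cores across releases."""

    release_ids: list[str]
    main_cores: dict[str, set[str]]
    k_max: dict[str, int]
    intersection_counts: pd.DataFrame
    jaccard: pd.DataFrame
    overlap_coefficient: pd.DataFrame
    universal_intersection: set[str] = field(default_factory=set)


def core_overlap(releases: list[ReleaseSnapshot]) -> CoreOverlapReport:
    """Main-core overlap across releases.

    The measure behind a core "correlation matrix" is ambiguous, so three
    are emitted: raw intersection counts, Jaccard index and overlap
    coefficient (intersection over the smaller core).
    """
    if len(releases) < 2:
        raise ValueError("need at least two releases")
    ids = [s.release_id for s in releases]
    cores: dict[str, set[str]] = {}
    kmax: dict[str, int] = {}
    for snap in releases:
        if snap.n_edges == 0:
            raise ValueError(f"{snap.release_id}: empty graph has no core")
        ca = core_decomposition(snap)
        cores[snap.release_id] = ca.main_core
        kmax[snap.release_id] = ca.k_max
    n = len(ids)
    counts = np.zeros((n, n), dtype=int)
    jac = np.zeros((n, n))
    ovl = np.zeros((n, n))
    for i in range(n):
        for j in range(n):
            a, b = cores[ids[i]], cores[ids[j]]
            inter = len(a & b)
            counts[i, j] = inter
            union = len(a | b)
            jac[i, j] = inter / union if union else 0.0
            smaller = min(len(a), len(b))
            ovl[i, j] = inter / smaller if smaller else 0.0
    universal = set.intersection(*(cores[r] for r in ids))
    return CoreOverlapReport(
        release_ids=ids,
        main_cores=cores,
        k_max=kmax,
        intersection_counts=pd.DataFrame(counts, index=ids, columns=ids),
        jaccard=pd.DataFrame(jac, index=ids, columns=ids),
        overlap_coefficient=pd.DataFrame(ovl, index=ids, columns=ids),
        universal_intersection=universal,
    )


@dataclass
class CoverageTable:
    """Reference-proteome coverage of one release."""

    release_id: str
    proteome_size: int
    n_with_ppi: int
    n_without_ppi: int
    coverage_pct: float
    without_ppi_by_pe: dict[str, int]
    network_pe_composition: dict[str, int]
    network_nodes_not_in_proteome: int


def proteome_coverage(
    release: ReleaseSnapshot, proteome: ReferenceProteome
) -> CoverageTable:
    """Which part of the reference proteome has interactions, by PE level."""
    if len(proteome) == 0:
        raise ValueError("empty reference proteome")
    in_network = {n for n in proteome.entries if n in release.nodes}
    outside = set(proteome.entries) - in_network
    stray = release.nodes - set(proteome.entries)
    if stray:
        warnings.warn(
            f"{len(stray)} network node(s) absent from the reference proteome",
            stacklevel=2,
        )
    without_by_pe = {pe: 0 for pe in PE_LEVELS}
    for ident in outside:
        without_by_pe[proteome.entries[ident]] += 1
    net_pe = {pe: 0 for pe in PE_LEVELS}
    for ident in in_network:
        net_pe[proteome.entries[ident]] += 1
    return CoverageTable(
        release_id=release.release_id,
        proteome_size=len(proteome),
        n_with_ppi=len(in_network),
        n_without_ppi=len(outside),
        coverage_pct=100.0 * len(in_network) / len(proteome),
        without_ppi_by_pe=without_by_pe,
        network_pe_composition=net_pe,
        network_nodes_not_in_proteome=len(stray),
    )


def source_overlap(snapshot: ReleaseSnapshot) -> dict[frozenset[str], int]:
    """Venn region counts over the edge source-database labels.

    For k distinct source labels every non-empty label subset is a region;
    an edge is counted in the region matching its exact label set.  Edges
    without any source label fall into the ``{'unlabelled'}`` region with a
    warning.  Region counts always sum to the edge total.
    """
    regions: dict[frozenset[str], int] = {}
    unlabelled = 0
    for ev in snapshot.edges.values():
        key = frozenset(ev.sources) if ev.sources else frozenset({"unlabelled"})
        if not ev.sources:
            unlabelled += 1
        regions[key] = regions.get(key, 0) + 1
    if unlabelled:
        warnings.warn(
            f"{unlabelled} edge(s) without source labels counted as 'unlabelled'",
            stacklevel=2,
        )
    assert sum(regions.values()) == snapshot.n_edges
    # make every region of the label powerset explicit (zero where empty)
    labels = sorted({lab for key in regions for lab in key})
    for r in range(1, len(labels) + 1):
        for combo in combinations(labels, r):
            regions.setdefault(frozenset(combo), 0)
    return regions
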