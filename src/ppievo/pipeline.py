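"""End-to-end orchestration: simulate/ingest -> metrics -> compare ->
cluster -> enrich -> report.

``run_pipeline`` takes a configuration mapping (or a YAML file path),
executes the stages in the order of a release-series study, and writes one
output directory containing per-stage files, a machine-readable
``summary.json`` (byte-identical under a fixed seed) and a human-readable
``report.txt``, with a full provenance block of seeds and parameters.
"""

from __future__ import annotations

import dataclasses
import json
import warnings
from pathlib import Path
from typing import Any, Mapping

import numpy as np
import yaml

from ppievo import __version__
from ppievo.clustering import (
    N2VParams,
    RWParams,
    cluster_intersections,
    hc_dynamic_cut,
    n2v_embed,
    rw_cluster,
)
from ppievo.compare import (
    core_overlap,
    growth_series,
    new_node_profile,
    proteome_coverage,
    source_overlap,
)
from ppievo.enrichment import ora
from ppievo.graph_model import (
    AnnotationCollection,
    ReferenceProteome,
    read_edge_table,
    read_gmt,
    read_proteome_table,
    write_graph,
    write_proteome_table,
)
from ppievo.metrics import degree_table, global_metrics, power_law_fit
from ppievo.synthetic import (
    EvidenceParams,
    EvolutionParams,
    block_annotations,
    generate_reference_proteome,
    simulate_series,
)


class PipelineError(RuntimeError):
    """A stage failed; partial outputs are retained in the output directory."""

    def __init__(self, stage: str, cause: BaseException):
        super().__init__(f"stage {stage!r} failed: {cause}")
        self.stage = stage
        self.cause = cause


def _jsonable(obj: Any) -> Any:
    if dataclasses.is_dataclass(obj) and not isinstance(obj, type):
        return _jsonable(dataclasses.asdict(obj))
    if isinstance(obj, Mapping):
        return {str(k): _jsonable(v) for k, v in obj.items()}
    if isinstance(obj, (set, frozenset)):
        return sorted(str(x) for x in obj)
    if isinstance(obj, (list, tuple)):
        return [_jsonable(x) for x in obj]
    if isinstance(obj, (np.integer,)):
        return int(obj)
    if isinstance(obj, (np.floating,)):
        return float(obj)
    if isinstance(obj, float) and not np.isfinite(obj):
        return None
    if hasattr(obj, "to_dict") and not isinstance(obj, (str, bytes)):
        return _jsonable(obj.to_dict())
    return obj


DEFAULT_CONFIG: dict[str, Any] = {
    "seed": 0,
    "simulate": {
        "n0": 400,
        "releases": 4,
        "blocks": 4,
        "edge_to_node_ratio": 4.0,
        "node_growth_rate": 0.06,
        "intra_block_preference": 0.95,
        "base_mean_degree": 8.0,
        "extra_no_ppi": 100,
        "ppp_range": [2.8, 4.8],
        "single_pub_range": [0.84, 0.79],
    },
    "metrics": {"path_mode": "exact", "sample_size": 200, "sampled_above": 3000},
    "cluster": {"enabled": True, "rw": {}, "n2v": {}, "top_k": 15},
    "enrich": {"enabled": True, "max_intersections": 4},
}


def _merged_config(config: Mapping[str, Any] | str | Path | None) -> dict[str, Any]:
    if isinstance(config, (str, Path)):
        with open(config) as fh:
            config = yaml.safe_load(fh) or {}
    cfg = json.loads(json.dumps(DEFAULT_CONFIG))
    for key, val in (config or {}).items():
        if isinstance(val, Mapping) and isinstance(cfg.get(key), dict):
            cfg[key].update(val)
        else:
            cfg[key] = val
    return cfg


def run_pipeline(
    config: Mapping[str, Any] | str | Path | None,
    outdir: str | Path,
) -> dict[str, Any]:
    """Run the full analysis and write the report bundle to ``outdir``.

    The configuration either names input files (``inputs`` with ordered
    release edge tables and an optional proteome/GMT) or simulation
    parameters (``simulate``).  Returns the summary dictionary that is also
    written to ``summary.json``.
    """
    cfg = _merged_config(config)
    outdir = Path(outdir)
    outdir.mkdir(parents=True, exist_ok=True)
    seed = int(cfg.get("seed", 0))
    summary: dict[str, Any] = {
        "provenance": {
            "package": "ppievo",
            "version": __version__,
            "seed": seed,
            "config": _jsonable(cfg),
        }
    }
    stage = "setup"
    try:
        # -- stage: inputs / simulation ---------------------------------
        stage = "inputs"
        truth = None
        annotations: AnnotationCollection | None = None
        proteome: ReferenceProteome | None = None
        if "inputs" in cfg:
            inp = cfg["inputs"]
            releases = [read_edge_table(p) for p in inp["releases"]]
            if inp.get("proteome"):
                proteome = read_proteome_table(inp["proteome"])
            if inp.get("annotations"):
                annotations = read_gmt(inp["annotations"])
        else:
            sim = cfg["simulate"]
            evo = EvolutionParams(
                n0=int(sim["n0"]),
                releases=int(sim["releases"]),
                blocks=int(sim["blocks"]),
                edge_to_node_ratio=float(sim["edge_to_node_ratio"]),
                node_growth_rate=float(sim["node_growth_rate"]),
                intra_block_preference=float(sim["intra_block_preference"]),
                base_mean_degree=float(sim["base_mean_degree"]),
                seed=seed,
            )
            releases, truth = simulate_series(
                evo,
                EvidenceParams(seed=seed),
                ppp_range=tuple(sim["ppp_range"]),
                single_pub_range=tuple(sim["single_pub_range"]),
            )
            proteome = generate_reference_proteome(
                releases[-1],
                extra_no_ppi=int(sim["extra_no_ppi"]),
                seed=seed,
            )
            annotations = block_annotations(truth)
            for snap in releases:
                write_graph(snap, outdir / f"release_{snap.release_id}.tsv", "tsv")
            write_proteome_table(proteome, outdir / "proteome.tsv")
        summary["releases"] = [
            {"release": s.release_id, "n_nodes": s.n_nodes, "n_edges": s.n_edges}
            for s in releases
        ]

        # -- stage: per-release metrics ----------------------------------
        stage = "metrics"
        mcfg = cfg["metrics"]
        per_release = []
        for snap in releases:
            mode = (
                "sampled"
                if snap.n_nodes > int(mcfg["sampled_above"])
                else mcfg["path_mode"]
            )
            nm = global_metrics(
                snap, path_mode=mode, sample_size=int(mcfg["sample_size"]), seed=seed
            )
            _, dist = degree_table(snap)
            try:
                fit = power_law_fit(dist)
                fit_info = {
                    "slope": fit.slope,
                    "r_squared": fit.r_squared,
                    "n_points": fit.n_points,
                }
            except ValueError:
                fit_info = None
            per_release.append(
                {
                    "release": snap.release_id,
                    "metrics": _jsonable(nm),
                    "power_law": fit_info,
                }
            )
        summary["network_metrics"] = per_release

        # -- stage: cross-release comparison ------------------------------
        stage = "compare"
        if len(releases) >= 2:
            growth = growth_series(releases)
            growth.to_csv(outdir / "growth_table.tsv", sep="\t", index=False)
            summary["growth"] = _jsonable(
                growth.round(6).to_dict(orient="records")
            )
            profiles = [
                new_node_profile(releases[i], releases[i + 1])
                for i in range(len(releases) - 1)
            ]
            summary["new_node_profiles"] = [
                {
                    "pair": p.pair_label,
                    "n_new": int(len(p.nodes)),
                    "frac_le_4": p.frac_le_4,
                    "frac_le_12": p.frac_le_12,
                    "n_new_hubs": p.n_new_hubs,
                }
                for p in profiles
            ]
            cores = core_overlap(releases)
            summary["core_overlap"] = {
                "k_max": cores.k_max,
                "core_sizes": {r: len(c) for r, c in cores.main_cores.items()},
                "intersection_counts": _jsonable(
                    cores.intersection_counts.to_dict()
                ),
                "jaccard": _jsonable(cores.jaccard.round(6).to_dict()),
                "universal_intersection": sorted(cores.universal_intersection),
            }
        else:
            summary["growth"] = None
            summary["comparison_note"] = (
                "single release: cross-release comparison skipped"
            )
        if proteome is not None:
            cov = proteome_coverage(releases[-1], proteome)
            assert cov.n_with_ppi + cov.n_without_ppi == cov.proteome_size
            summary["proteome_coverage"] = _jsonable(cov)
        venn = source_overlap(releases[-1])
        assert sum(venn.values()) == releases[-1].n_edges
        summary["source_overlap"] = {
            "&".join(sorted(k)): v for k, v in sorted(venn.items(), key=lambda kv: sorted(kv[0]))
        }

        # -- stage: consensus clustering ----------------------------------
        stage = "cluster"
        intersections = None
        if cfg["cluster"].get("enabled", True):
            final = releases[-1]
            rw = rw_cluster(final, RWParams(**cfg["cluster"].get("rw", {})))
            n2v_kwargs = dict(cfg["cluster"].get("n2v", {}))
            n2v_kwargs.setdefault("seed", seed)
            n2v_params = N2VParams(**n2v_kwargs)
            emb = n2v_embed(final, n2v_params)
            hc = hc_dynamic_cut(emb, n2v_params)
            report = cluster_intersections(
                rw, hc, top_k=int(cfg["cluster"].get("top_k", 15))
            )
            assignments = []
            for node in sorted(final.nodes):
                assignments.append(
                    {
                        "node": node,
                        "rw": rw.labels.get(node),
                        "n2v_hc": hc.labels.get(node),
                    }
                )
            with open(outdir / "cluster_assignments.tsv", "w") as fh:
                fh.write("node\trw\tn2v_hc\n")
                for row in assignments:
                    fh.write(
                        f"{row['node']}\t{row['rw']}\t"
                        f"{'' if row['n2v_hc'] is None else row['n2v_hc']}\n"
                    )
            intersections = report
            summary["clustering"] = {
                "rw_cluster_sizes": [s for _, s in rw.sizes()],
                "n2v_hc_cluster_sizes": [s for _, s in hc.sizes()],
                "n2v_unassigned": sum(
                    1 for v in hc.labels.values() if v is None
                ),
                "top_intersections": _jsonable(
                    report.ranked.head(10).to_dict(orient="records")
                ),
            }

        # -- stage: enrichment --------------------------------------------
        stage = "enrich"
        if (
            cfg["enrich"].get("enabled", True)
            and annotations is not None
            and intersections is not None
        ):
            background = (
                set(proteome.entries) if proteome is not None else set(releases[-1].nodes)
            )
            enriched = []
            n_top = int(cfg["enrich"].get("max_intersections", 4))
            for _, row in intersections.ranked.head(n_top).iterrows():
                key = (int(row["label_a"]), int(row["label_b"]))
                members = intersections.members.get(key, set())
                if not members:
                    continue
                table = ora(members, annotations, background)
                enriched.append(
                    {
                        "intersection": {
                            "rw": key[0],
                            "n2v_hc": key[1],
                            "size": int(row["size"]),
                        },
                        "top_terms": _jsonable(
                            table.head(5)
                            .drop(columns=["members"])
                            .round(12)
                            .to_dict(orient="records")
                        ),
                    }
                )
            summary["enrichment"] = enriched

        # -- stage: report ------------------------------------------------
        stage = "report"
        with open(outdir / "summary.json", "w") as fh:
            json.dump(_jsonable(summary), fh, indent=2, sort_keys=True)
            fh.write("\n")
        _write_text_report(summary, outdir / "report.txt")
    except PipelineError:
        raise
    except Exception as exc:  # noqa: BLE001 - rewrapped with stage context
        raise PipelineError(stage, exc) from exc
    return summary


def _write_text_report(summary: Mapping[str, Any], path: Path) -> None:
    lines = [
        "Interactome release-series report",
        "=" * 34,
        f"package ppievo {summary['provenance']['version']}, "
        f"seed {summary['provenance']['seed']}",
        "",
        "Releases:",
    ]
    for rel in summary.get("releases", []):
        lines.append(
            f"  {rel['release']}: {rel['n_nodes']} nodes, {rel['n_edges']} edges"
        )
    growth = summary.get("growth")
    if growth:
        last = growth[-1]
        lines += [
            "",
            "Growth versus first release (%):",
            f"  nodes {last['pct_n_nodes_base']:.1f}  edges "
            f"{last['pct_n_edges_base']:.1f}  publications "
            f"{last['pct_n_publications_base']:.1f}",
            f"  PPIs per publication: {growth[0]['ppis_per_publication']:.2f}"
            f" -> {last['ppis_per_publication']:.2f}",
            f"  single-publication fraction: "
            f"{last['single_publication_fraction']:.3f}",
        ]
    for prof in summary.get("new_node_profiles", []):
        lines.append(
            f"  new nodes {prof['pair']}: n={prof['n_new']} "
            f"P(deg<=4)={prof['frac_le_4']:.2f} P(deg<=12)={prof['frac_le_12']:.2f}"
        )
    core = summary.get("core_overlap")
    if core:
        lines += ["", "Main k-core sizes: " + str(core["core_sizes"])]
        lines.append(
            "Universal core intersection: "
            + (",".join(core["universal_intersection"][:10]) or "(empty)")
        )
    clu = summary.get("clustering")
    if clu:
        lines += [
            "",
            f"RW cluster sizes: {clu['rw_cluster_sizes'][:8]}",
            f"N2V-HC cluster sizes: {clu['n2v_hc_cluster_sizes'][:8]}",
        ]
    for block in summary.get("enrichment", []) or []:
        inter = block["intersection"]
        terms = ", ".join(t["term"] for t in block["top_terms"][:3])
        lines.append(
            f"Intersection RW{inter['rw']}/HC{inter['n2v_hc']} "
            f"(n={inter['size']}): {terms}"
        )
    path.write_text("\n".join(lines) + "\n")
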