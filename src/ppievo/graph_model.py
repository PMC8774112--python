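"""Data model for evidence-annotated interactome snapshots and file I/O.

A release snapshot is a simple undirected graph over opaque protein
identifiers.  Every edge carries its literature evidence: the set of
supporting publication identifiers, the set of source databases that report
it, and an optional detection-method class.  Self-interactions (homodimers)
are retained and flagged; by default they are excluded from degree and
topology computations.

Snapshots are read from tab-delimited edge tables whose column layout is
described by a :class:`ColumnDialect`, so database exports and synthetic
fixtures parse through the same code path.
"""

from __future__ import annotations

import csv
import warnings
from dataclasses import dataclass, field, replace
from pathlib import Path
from typing import Iterable, Mapping

import networkx as nx
import pandas as pd

PE_LEVELS = ("PE1", "PE2", "PE3", "PE4", "PE5")
FILTERING_MODES = ("unfiltered", "standard", "cross_checked")

Edge = tuple[str, str]


def canonical_edge(a: str, b: str) -> Edge:
    """Return the unordered pair (a, b) in canonical (lexicographic) order."""
    return (a, b) if a <= b else (b, a)


@dataclass
class EdgeEvidence:
    """Literature evidence attached to one interaction."""

    pmids: set[str] = field(default_factory=set)
    sources: set[str] = field(default_factory=set)
    method_class: str | None = None

    def merge(self, other: "EdgeEvidence") -> None:
        self.pmids |= other.pmids
        self.sources |= other.sources
        if self.method_class is None:
            self.method_class = other.method_class

    def copy(self) -> "EdgeEvidence":
        return EdgeEvidence(set(self.pmids), set(self.sources), self.method_class)


@dataclass
class ReleaseSnapshot:
    """One release of an interaction network.

    ``edges`` maps canonical unordered identifier pairs to their evidence.
    Self-loops are stored with both endpoints equal.  ``filtering_mode`` is
    carried as metadata only; the reliability scoring that produces the three
    modes is outside the scope of this package.
    """

    release_id: str = ""
    nodes: set[str] = field(default_factory=set)
    edges: dict[Edge, EdgeEvidence] = field(default_factory=dict)
    filtering_mode: str = "cross_checked"

    def __post_init__(self) -> None:
        if self.filtering_mode not in FILTERING_MODES:
            raise ValueError(
                f"filtering_mode must be one of {FILTERING_MODES}, "
                f"got {self.filtering_mode!r}"
            )

    # -- construction -----------------------------------------------------

    def add_node(self, node: str) -> None:
        if not node:
            raise ValueError("empty identifier")
        self.nodes.add(node)

    def add_edge(
        self, a: str, b: str, evidence: EdgeEvidence | None = None
    ) -> Edge:
        """Insert an edge, canonicalizing the pair and merging evidence."""
        if not a or not b:
            raise ValueError("empty identifier in edge")
        key = canonical_edge(a, b)
        self.nodes.add(a)
        self.nodes.add(b)
        ev = evidence if evidence is not None else EdgeEvidence()
        if key in self.edges:
            self.edges[key].merge(ev)
        else:
            self.edges[key] = ev.copy()
        return key

    # -- basic queries ----------------------------------------------------

    @property
    def n_nodes(self) -> int:
        return len(self.nodes)

    @property
    def n_edges(self) -> int:
        return len(self.edges)

    @property
    def self_loops(self) -> set[Edge]:
        return {e for e in self.edges if e[0] == e[1]}

    def has_edge(self, a: str, b: str) -> bool:
        return canonical_edge(a, b) in self.edges

    def publications(self) -> set[str]:
        """Distinct publication identifiers across all edges."""
        out: set[str] = set()
        for ev in self.edges.values():
            out |= ev.pmids
        return out

    def degrees(self, include_self_loops: bool = False) -> dict[str, int]:
        """Node degree map.

        Self-loops are excluded by default; when included each loop
        contributes 2 to its endpoint, the usual handshake convention.
        """
        deg = dict.fromkeys(self.nodes, 0)
        for a, b in self.edges:
            if a == b:
                if include_self_loops:
                    deg[a] += 2
            else:
                deg[a] += 1
                deg[b] += 1
        return deg

    def to_networkx(self, include_self_loops: bool = False) -> nx.Graph:
        g = nx.Graph()
        g.add_nodes_from(self.nodes)
        for (a, b), ev in self.edges.items():
            if a == b and not include_self_loops:
                continue
            g.add_edge(
                a,
                b,
                pmids=";".join(sorted(ev.pmids)),
                sources=";".join(sorted(ev.sources)),
                method_class=ev.method_class or "",
                is_self_loop=(a == b),
            )
        g.graph["release_id"] = self.release_id
        g.graph["filtering_mode"] = self.filtering_mode
        return g

    def copy(self) -> "ReleaseSnapshot":
        return ReleaseSnapshot(
            release_id=self.release_id,
            nodes=set(self.nodes),
            edges={e: ev.copy() for e, ev in self.edges.items()},
            filtering_mode=self.filtering_mode,
        )

    def validate(self) -> None:
        """Check the structural invariants; raise ValueError on violation."""
        for a, b in self.edges:
            if (a, b) != canonical_edge(a, b):
                raise ValueError(f"edge {(a, b)} is not stored canonically")
            if a not in self.nodes or b not in self.nodes:
                raise ValueError(f"edge {(a, b)} has an endpoint outside nodes")


@dataclass
class ReferenceProteome:
    """Reference protein set: identifier -> protein-existence level PE1..PE5.

    Serves as the denominator for interactome coverage; PE5 marks proteins
    whose existence is uncertain.
    """

    entries: dict[str, str] = field(default_factory=dict)
    version: str = ""

    def __post_init__(self) -> None:
        bad = {pe for pe in self.entries.values() if pe not in PE_LEVELS}
        if bad:
            raise ValueError(f"invalid PE levels: {sorted(bad)}")

    def __len__(self) -> int:
        return len(self.entries)

    def __contains__(self, identifier: str) -> bool:
        return identifier in self.entries

    def by_level(self) -> dict[str, set[str]]:
        out: dict[str, set[str]] = {pe: set() for pe in PE_LEVELS}
        for ident, pe in self.entries.items():
            out[pe].add(ident)
        return out


@dataclass
class AnnotationCollection:
    """GO-style annotation term sets: term id -> (description, member set)."""

    terms: dict[str, tuple[str, set[str]]] = field(default_factory=dict)

    def __len__(self) -> int:
        return len(self.terms)

    def members(self, term_id: str) -> set[str]:
        return self.terms[term_id][1]

    def validate(self) -> None:
        empty = [t for t, (_, m) in self.terms.items() if not m]
        if empty:
            raise ValueError(f"terms with no members: {empty[:5]}")


# ---------------------------------------------------------------------------
# Edge-table I/O


@dataclass(frozen=True)
class ColumnDialect:
    """Column mapping for tab-delimited edge tables.

    ``pmids`` and ``sources`` columns, when present, hold
    ``list_sep``-separated values.  Only the endpoint columns are mandatory.
    """

    id_a: str = "id_a"
    id_b: str = "id_b"
    pmids: str | None = "pmids"
    sources: str | None = "sources"
    method_class: str | None = "method_class"
    list_sep: str = ";"


DEFAULT_DIALECT = ColumnDialect()


def _split_list(value: object, sep: str) -> set[str]:
    if value is None or (isinstance(value, float) and pd.isna(value)):
        return set()
    text = str(value).strip()
    if not text:
        return set()
    return {tok for tok in (t.strip() for t in text.split(sep)) if tok}


def read_edge_table(
    path: str | Path,
    dialect: ColumnDialect = DEFAULT_DIALECT,
    release_id: str | None = None,
    filtering_mode: str = "cross_checked",
) -> ReleaseSnapshot:
    """Read a tab-delimited edge table into a canonical snapshot.

    Duplicate rows for the same unordered pair merge their evidence (union of
    publication ids and sources).  Rows with an empty endpoint identifier are
    skipped with a warning.  A missing endpoint column is a hard error.
    """
    path = Path(path)
    df = pd.read_csv(path, sep="\t", dtype=str, comment="#", keep_default_na=False)
    for col in (dialect.id_a, dialect.id_b):
        if col not in df.columns:
            raise ValueError(
                f"{path.name}: required endpoint column {col!r} not found "
                f"(columns: {list(df.columns)})"
            )
    snap = ReleaseSnapshot(
        release_id=release_id if release_id is not None else path.stem,
        filtering_mode=filtering_mode,
    )
    skipped = 0
    for row in df.itertuples(index=False):
        rec = row._asdict() if hasattr(row, "_asdict") else dict(zip(df.columns, row))
        a = str(rec.get(dialect.id_a, "")).strip()
        b = str(rec.get(dialect.id_b, "")).strip()
        if not a or not b:
            skipped += 1
            continue
        ev = EdgeEvidence()
        if dialect.pmids and dialect.pmids in df.columns:
            ev.pmids = _split_list(rec.get(dialect.pmids), dialect.list_sep)
        if dialect.sources and dialect.sources in df.columns:
            ev.sources = _split_list(rec.get(dialect.sources), dialect.list_sep)
        if dialect.method_class and dialect.method_class in df.columns:
            mc = str(rec.get(dialect.method_class, "")).strip()
            ev.method_class = mc or None
        snap.add_edge(a, b, ev)
    if skipped:
        warnings.warn(
            f"{path.name}: skipped {skipped} row(s) with empty identifiers",
            stacklevel=2,
        )
    # isolated nodes may be listed on comment lines written by write_graph
    for node in _read_isolated_nodes(path):
        snap.add_node(node)
    return snap


def _read_isolated_nodes(path: Path) -> list[str]:
    out: list[str] = []
    with open(path) as fh:
        for line in fh:
            if not line.startswith("#"):
                continue
            body = line[1:].strip()
            if body.startswith("isolated_nodes:"):
                payload = body.split(":", 1)[1].strip()
                if payload:
                    out.extend(payload.split(","))
    return out


def write_graph(
    snapshot: ReleaseSnapshot, path: str | Path, format: str = "tsv"
) -> Path:
    """Write a snapshot to ``tsv`` (edge table) or ``graphml``.

    Both formats round-trip through :func:`read_graph`: node set, edge set
    and per-edge publication/source sets are reproduced exactly.  Isolated
    nodes in the TSV format are kept on a ``# isolated_nodes:`` comment line.
    """
    path = Path(path)
    if format == "graphml":
        g = snapshot.to_networkx(include_self_loops=True)
        # GraphML attributes must be scalars; evidence sets are ';'-joined.
        nx.write_graphml(g, path)
    elif format == "tsv":
        with open(path, "w", newline="") as fh:
            fh.write(f"# release_id: {snapshot.release_id}\n")
            fh.write(f"# filtering_mode: {snapshot.filtering_mode}\n")
            isolated = sorted(
                snapshot.nodes
                - {n for e in snapshot.edges for n in e}
            )
            if isolated:
                fh.write("# isolated_nodes: " + ",".join(isolated) + "\n")
            w = csv.writer(fh, delimiter="\t", lineterminator="\n")
            w.writerow(["id_a", "id_b", "pmids", "sources", "method_class"])
            for (a, b) in sorted(snapshot.edges):
                ev = snapshot.edges[(a, b)]
                w.writerow(
                    [
                        a,
                        b,
                        ";".join(sorted(ev.pmids)),
                        ";".join(sorted(ev.sources)),
                        ev.method_class or "",
                    ]
                )
    else:
        raise ValueError(f"unknown graph format {format!r} (use 'tsv' or 'graphml')")
    return path


def read_graph(path: str | Path, format: str = "tsv") -> ReleaseSnapshot:
    """Inverse of :func:`write_graph` for both supported formats."""
    path = Path(path)
    if format == "tsv":
        snap = read_edge_table(path)
        meta = _read_tsv_metadata(path)
        if "release_id" in meta:
            snap.release_id = meta["release_id"]
        if "filtering_mode" in meta:
            snap = replace(snap, filtering_mode=meta["filtering_mode"])
        return snap
    if format == "graphml":
        g = nx.read_graphml(path)
        snap = ReleaseSnapshot(
            release_id=str(g.graph.get("release_id", path.stem)),
            filtering_mode=str(g.graph.get("filtering_mode", "cross_checked")),
        )
        for n in g.nodes:
            snap.add_node(str(n))
        for a, b, data in g.edges(data=True):
            ev = EdgeEvidence(
                pmids=_split_list(data.get("pmids", ""), ";"),
                sources=_split_list(data.get("sources", ""), ";"),
                method_class=str(data.get("method_class", "")) or None,
            )
            snap.add_edge(str(a), str(b), ev)
        return snap
    raise ValueError(f"unknown graph format {format!r} (use 'tsv' or 'graphml')")


def _read_tsv_metadata(path: Path) -> dict[str, str]:
    meta: dict[str, str] = {}
    with open(path) as fh:
        for line in fh:
            if not line.startswith("#"):
                break
            body = line[1:].strip()
            if ":" in body:
                key, val = body.split(":", 1)
                meta[key.strip()] = val.strip()
    return meta


# ---------------------------------------------------------------------------
# GMT and proteome tables


def read_gmt(path: str | Path) -> AnnotationCollection:
    """Read a GMT file: one term per line, tab-separated, >=3 fields.

    Duplicate members within a line are deduplicated; malformed lines
    (fewer than three fields) are skipped with a warning.
    """
    path = Path(path)
    coll = AnnotationCollection()
    skipped = 0
    with open(path) as fh:
        for line in fh:
            line = line.rstrip("\n")
            if not line.strip():
                continue
            fields = line.split("\t")
            if len(fields) < 3:
                skipped += 1
                continue
            term, desc = fields[0], fields[1]
            members = {m.strip() for m in fields[2:] if m.strip()}
            if members:
                coll.terms[term] = (desc, members)
    if skipped:
        warnings.warn(
            f"{path.name}: skipped {skipped} malformed GMT line(s)", stacklevel=2
        )
    return coll


def write_gmt(annotations: AnnotationCollection, path: str | Path) -> Path:
    path = Path(path)
    with open(path, "w") as fh:
        for term in sorted(annotations.terms):
            desc, members = annotations.terms[term]
            fh.write("\t".join([term, desc, *sorted(members)]) + "\n")
    return path


def read_proteome_table(path: str | Path, version: str = "") -> ReferenceProteome:
    """Read a two-column TSV (identifier, PE level) reference proteome."""
    df = pd.read_csv(Path(path), sep="\t", dtype=str, comment="#")
    if df.shape[1] < 2:
        raise ValueError("proteome table needs two columns: identifier, PE level")
    id_col, pe_col = df.columns[0], df.columns[1]
    entries = dict(zip(df[id_col].astype(str), df[pe_col].astype(str)))
    return ReferenceProteome(entries=entries, version=version or Path(path).stem)


def write_proteome_table(proteome: ReferenceProteome, path: str | Path) -> Path:
    path = Path(path)
    with open(path, "w", newline="") as fh:
        w = csv.writer(fh, delimiter="\t", lineterminator="\n")
        w.writerow(["identifier", "pe_level"])
        for ident in sorted(proteome.entries):
            w.writerow([ident, proteome.entries[ident]])
    return path


def snapshot_from_edges(
    edges: Iterable[tuple[str, str]],
    release_id: str = "",
    pmids: Mapping[tuple[str, str], Iterable[str]] | None = None,
) -> ReleaseSnapshot:
    """Convenience constructor used widely in tests and simulations."""
    snap = ReleaseSnapshot(release_id=release_id)
    for a, b in edges:
        ev = EdgeEvidence()
        if pmids is not None:
            key = canonical_edge(a, b)
            for source_key in (key, (a, b)):
                if source_key in pmids:
                    ev.pmids = set(pmids[source_key])
                    break
        snap.add_edge(a, b, ev)
    return snap
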