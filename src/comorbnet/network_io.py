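"""Readers, writers and graph construction for scored interaction tables.

Input formats are deliberately minimal and database-agnostic:

* interactions — delimited text (tab or comma, auto-detected) with a header
  naming two protein columns and a confidence column, HIPPIE-export style;
* disease annotations — delimited text mapping protein identifiers to
  disease labels, DisGeNET-export style;
* pathway gene sets — GMT (set name, description, members, tab-separated);
* comorbid diseases — plain text, one label per line.

Identifiers are opaque, case-sensitive strings; no accession mapping is
attempted. The constructed interaction graph is a simple undirected
:class:`networkx.Graph` whose every edge carries a ``confidence`` attribute
at or above the configured threshold and whose every node has degree >= 1.
"""

from __future__ import annotations

import dataclasses
import io
import warnings
from pathlib import Path
from typing import Iterable, Mapping, Sequence, TextIO, Union

import networkx as nx
import pandas as pd

Source = Union[str, Path, TextIO]

__all__ = [
    "FormatError",
    "EmptyNetworkError",
    "ScoredInteraction",
    "DiseaseAnnotation",
    "PathwaySet",
    "NetworkBuildReport",
    "read_interactions",
    "build_network",
    "read_disease_annotations",
    "read_gene_sets",
    "read_comorbid_list",
    "write_results",
]


class FormatError(ValueError):
    """An input table does not conform to the expected layout."""


class EmptyNetworkError(ValueError):
    """No interaction survived filtering; downstream stages are meaningless."""


@dataclasses.dataclass(frozen=True)
class ScoredInteraction:
    """One undirected weighted edge candidate from an interaction table."""

    protein_a: str
    protein_b: str
    confidence: float

    def __post_init__(self) -> None:
        if not self.protein_a or not self.protein_b:
            raise ValueError("protein identifiers must be nonempty")
        if not 0.0 <= self.confidence <= 1.0:
            raise ValueError(f"confidence {self.confidence!r} outside [0, 1]")


@dataclasses.dataclass(frozen=True)
class NetworkBuildReport:
    """Bookkeeping emitted alongside the filtered graph."""

    n_input_records: int
    n_input_proteins: int
    n_retained_proteins: int
    n_retained_edges: int
    excluded_proteins: frozenset


class DiseaseAnnotation:
    """Protein -> disease-label mapping with a consistent inverse."""

    def __init__(self, pairs: Iterable[tuple]) -> None:
        forward: dict = {}
        reverse: dict = {}
        for protein, disease in pairs:
            forward.setdefault(protein, set()).add(disease)
            reverse.setdefault(disease, set()).add(protein)
        self._forward = {p: frozenset(d) for p, d in forward.items()}
        self._reverse = {d: frozenset(p) for d, p in reverse.items()}

    @property
    def proteins(self) -> frozenset:
        return frozenset(self._forward)

    @property
    def diseases(self) -> frozenset:
        return frozenset(self._reverse)

    def diseases_for(self, protein: str) -> frozenset:
        return self._forward.get(protein, frozenset())

    def proteins_for(self, disease: str) -> frozenset:
        return self._reverse.get(disease, frozenset())

    def items(self):
        """Iterate (protein, disease) pairs in sorted order."""
        for protein in sorted(self._forward):
            for disease in sorted(self._forward[protein]):
                yield protein, disease

    def __len__(self) -> int:
        return sum(len(v) for v in self._forward.values())


class PathwaySet:
    """Named gene sets with optional per-set descriptions."""

    def __init__(self, sets: Mapping[str, Iterable[str]],
                 descriptions: Mapping[str, str] | None = None) -> None:
        self._sets = {}
        for name, members in sets.items():
            members = frozenset(members)
            if not members:
                raise ValueError(f"pathway {name!r} has no members")
            self._sets[name] = members
        self._descriptions = dict(descriptions or {})

    @property
    def names(self) -> list:
        return sorted(self._sets)

    def members(self, name: str) -> frozenset:
        return self._sets[name]

    def description(self, name: str) -> str:
        return self._descriptions.get(name, "")

    def items(self):
        for name in self.names:
            yield name, self._sets[name]

    def __len__(self) -> int:
        return len(self._sets)

    def __contains__(self, name: str) -> bool:
        return name in self._sets


# ---------------------------------------------------------------------------
# readers
# ---------------------------------------------------------------------------

def _read_text(source: Source) -> str:
    if hasattr(source, "read"):
        return source.read()
    return Path(source).read_text()


def _sniff_table(text: str) -> pd.DataFrame:
    """Parse delimited text with a header, auto-detecting tab vs comma."""
    first_line = text.split("\n", 1)[0]
    sep = "\t" if "\t" in first_line else ","
    return pd.read_csv(io.StringIO(text), sep=sep, dtype=str)


def _require_columns(df: pd.DataFrame, needed: Sequence[str], what: str) -> None:
    missing = [c for c in needed if c not in df.columns]
    if missing:
        raise FormatError(
            f"{what}: missing column(s) {', '.join(repr(c) for c in missing)}; "
            f"found {list(df.columns)}"
        )


DEFAULT_INTERACTION_COLUMNS = {
    "protein_a": "protein_a",
    "protein_b": "protein_b",
    "confidence": "confidence",
}

DEFAULT_ANNOTATION_COLUMNS = {"protein": "protein", "disease": "disease"}


def read_interactions(source: Source,
                      columns: Mapping[str, str] | None = None
                      ) -> list:
    """Read scored interactions from delimited text.

    ``columns`` maps the roles ``protein_a``, ``protein_b`` and
    ``confidence`` to the actual header names. Rows whose confidence cannot
    be parsed as a real number in [0, 1], or whose identifiers are empty
    after trimming, are reported via a warning and excluded — never silently
    dropped. Self-interactions are returned as-is; filtering is the job of
    :func:`build_network`.
    """
    colmap = dict(DEFAULT_INTERACTION_COLUMNS)
    colmap.update(columns or {})
    text = _read_text(source)
    try:
        df = _sniff_table(text)
    except pd.errors.EmptyDataError:
        warnings.warn("interaction table is empty", stacklevel=2)
        return []
    _require_columns(df, [colmap["protein_a"], colmap["protein_b"],
                          colmap["confidence"]], "interaction table")
    records: list = []
    bad_rows: list = []
    for i, row in enumerate(df.itertuples(index=False)):
        a = str(getattr(row, colmap["protein_a"]) or "").strip()
        b = str(getattr(row, colmap["protein_b"]) or "").strip()
        raw = getattr(row, colmap["confidence"])
        try:
            conf = float(raw)
        except (TypeError, ValueError):
            bad_rows.append((i + 2, f"unparseable confidence {raw!r}"))
            continue
        if not 0.0 <= conf <= 1.0:
            bad_rows.append((i + 2, f"confidence {conf} outside [0, 1]"))
            continue
        if not a or not b or a.lower() == "nan" or b.lower() == "nan":
            bad_rows.append((i + 2, "empty protein identifier"))
            continue
        records.append(ScoredInteraction(a, b, conf))
    if bad_rows:
        detail = "; ".join(f"line {ln}: {why}" for ln, why in bad_rows[:10])
        warnings.warn(
            f"interaction table: skipped {len(bad_rows)} malformed row(s) "
            f"({detail})", stacklevel=2)
    if not records and not bad_rows:
        warnings.warn("interaction table has a header but no data rows",
                      stacklevel=2)
    return records


def build_network(interactions: Iterable[ScoredInteraction],
                  min_confidence: float = 0.73
                  ) -> tuple:
    """Construct the confidence-filtered simple interaction graph.

    Edges with confidence below ``min_confidence`` are removed (the
    comparison is inclusive: an edge exactly at the threshold is kept).
    Self-loops are dropped. Duplicate pairs, in either orientation, collapse
    to a single edge keeping the maximum confidence. Proteins left with no
    qualifying partner are excluded from the graph entirely.

    Returns ``(graph, report)``; raises :class:`EmptyNetworkError` if
    nothing survives.
    """
    if not 0.0 <= min_confidence <= 1.0:
        raise ValueError("min_confidence must lie in [0, 1]")
    interactions = list(interactions)
    input_proteins = set()
    best: dict = {}
    for rec in interactions:
        input_proteins.add(rec.protein_a)
        input_proteins.add(rec.protein_b)
        if rec.protein_a == rec.protein_b:
            continue
        key = (rec.protein_a, rec.protein_b)
        if rec.protein_b < rec.protein_a:
            key = (rec.protein_b, rec.protein_a)
        if rec.confidence > best.get(key, -1.0):
            best[key] = rec.confidence
    graph = nx.Graph()
    for (a, b), conf in sorted(best.items()):
        if conf >= min_confidence:
            graph.add_edge(a, b, confidence=conf)
    if graph.number_of_edges() == 0:
        raise EmptyNetworkError(
            f"no interaction met the confidence threshold {min_confidence}")
    report = NetworkBuildReport(
        n_input_records=len(interactions),
        n_input_proteins=len(input_proteins),
        n_retained_proteins=graph.number_of_nodes(),
        n_retained_edges=graph.number_of_edges(),
        excluded_proteins=frozenset(input_proteins - set(graph.nodes)),
    )
    return graph, report


def read_disease_annotations(source: Source,
                             columns: Mapping[str, str] | None = None
                             ) -> DiseaseAnnotation:
    """Read a protein -> disease annotation table (duplicates collapse)."""
    colmap = dict(DEFAULT_ANNOTATION_COLUMNS)
    colmap.update(columns or {})
    text = _read_text(source)
    try:
        df = _sniff_table(text)
    except pd.errors.EmptyDataError:
        warnings.warn("annotation table is empty", stacklevel=2)
        return DiseaseAnnotation([])
    _require_columns(df, [colmap["protein"], colmap["disease"]],
                     "annotation table")
    pairs = []
    for row in df.itertuples(index=False):
        protein = str(getattr(row, colmap["protein"]) or "").strip()
        disease = str(getattr(row, colmap["disease"]) or "").strip()
        if protein and disease:
            pairs.append((protein, disease))
    return DiseaseAnnotation(pairs)


def read_gene_sets(source: Source) -> PathwaySet:
    """Read pathway gene sets in GMT format.

    Each nonempty line must carry at least three tab-separated fields:
    name, description, then one or more member identifiers.
    """
    text = _read_text(source)
    sets: dict = {}
    descriptions: dict = {}
    for lineno, line in enumerate(text.splitlines(), start=1):
        if not line.strip():
            warnings.warn(f"GMT line {lineno}: empty line skipped",
                          stacklevel=2)
            continue
        fields = line.rstrip("\n").split("\t")
        if len(fields) < 3:
            raise FormatError(
                f"GMT line {lineno}: expected >= 3 tab-separated fields, "
                f"got {len(fields)}")
        name, description = fields[0].strip(), fields[1].strip()
        members = {m.strip() for m in fields[2:] if m.strip()}
        if not members:
            raise FormatError(f"GMT line {lineno}: set {name!r} has no members")
        sets[name] = members
        descriptions[name] = description
    return PathwaySet(sets, descriptions)


def read_comorbid_list(source: Source) -> list:
    """Read a plain-text comorbid-disease list (one label per line)."""
    text = _read_text(source)
    labels = []
    for line in text.splitlines():
        label = line.strip()
        if label and not label.startswith("#"):
            labels.append(label)
    return labels


# ---------------------------------------------------------------------------
# writers
# ---------------------------------------------------------------------------

def _members_str(members: Iterable[str]) -> str:
    return ";".join(sorted(members))


def write_results(out_dir, network, clusters, disease_results,
                  pathway_results) -> dict:
    """Write all result artifacts into ``out_dir``.

    Produces the cluster membership table, the disease-enrichment table,
    the pathway-enrichment table, and the filtered graph as GraphML with
    per-node cluster id and shared-protein status, so the network can be
    loaded straight into Cytoscape or networkx.

    Returns a dict of logical name -> written path.
    """
    out_dir = Path(out_dir)
    out_dir.mkdir(parents=True, exist_ok=True)

    cluster_rows = [{
        "cluster_id": c.rank,
        "rank": c.rank,
        "score": f"{c.score:.3f}",
        "n_nodes": len(c.members),
        "n_edges": c.n_edges,
        "seed": c.seed,
        "members": _members_str(c.members),
    } for c in clusters]
    clusters_path = out_dir / "clusters.tsv"
    pd.DataFrame(cluster_rows, columns=[
        "cluster_id", "rank", "score", "n_nodes", "n_edges", "seed",
        "members"]).to_csv(clusters_path, sep="\t", index=False)

    disease_rows = [{
        "cluster_id": r.cluster_id,
        "disease": r.disease,
        "a": r.table.a, "b": r.table.b, "c": r.table.c, "d": r.table.d,
        "p_value": f"{r.p_value:.6g}",
        "significant": r.significant,
        "comorbid": r.comorbid,
        "shared_proteins": _members_str(r.shared_proteins),
    } for r in disease_results]
    disease_path = out_dir / "disease_enrichment.tsv"
    pd.DataFrame(disease_rows, columns=[
        "cluster_id", "disease", "a", "b", "c", "d", "p_value",
        "significant", "comorbid", "shared_proteins",
    ]).to_csv(disease_path, sep="\t", index=False)

    pathway_rows = [{
        "cluster_id": r.cluster_id,
        "pathway": r.pathway,
        "overlap": r.overlap_count,
        "cluster_size": r.cluster_size,
        "pathway_size": r.pathway_size,
        "universe": r.universe_size,
        "raw_p": f"{r.raw_p:.6g}",
        "adjusted_p_holm": f"{r.adjusted_p:.6g}",
        "significant": r.significant,
        "shared": r.shared,
        "overlap_proteins": _members_str(r.overlap_proteins),
    } for r in pathway_results]
    pathway_path = out_dir / "pathway_enrichment.tsv"
    pd.DataFrame(pathway_rows, columns=[
        "cluster_id", "pathway", "overlap", "cluster_size", "pathway_size",
        "universe", "raw_p", "adjusted_p_holm", "significant", "shared",
        "overlap_proteins"]).to_csv(pathway_path, sep="\t", index=False)

    node_cluster = {}
    for c in clusters:
        for node in c.members:
            node_cluster.setdefault(node, c.rank)
    shared_nodes = set()
    for r in disease_results:
        if r.significant and r.comorbid:
            shared_nodes.update(r.shared_proteins)
    export = nx.Graph()
    for node in sorted(network.nodes):
        export.add_node(node,
                        cluster_id=int(node_cluster.get(node, 0)),
                        shared_protein=int(node in shared_nodes))
    for a, b in sorted(map(tuple, map(sorted, network.edges))):
        export.add_edge(a, b, confidence=float(network[a][b]["confidence"]))
    graph_path = out_dir / "network.graphml"
    nx.write_graphml(export, graph_path)

    return {
        "clusters": clusters_path,
        "disease_enrichment": disease_path,
        "pathway_enrichment": pathway_path,
        "network": graph_path,
    }
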