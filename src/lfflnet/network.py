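"""Typed TF/miRNA/lncRNA regulatory network and feed-forward-loop motif enumeration.

The central object of study is the lncRNA-mediated feed-forward loop (L-FFL):
a transcription factor (TF) transcriptionally regulates a miRNA, and both the
TF and the miRNA regulate a common target lncRNA.  The three directed
interaction layers (TF->miRNA, TF->lncRNA, miRNA->lncRNA) are read from
two-column edge lists, merged into one typed directed network, and every
complete (TF, miRNA, lncRNA) triangle is enumerated as a motif.

Node classes are inferred purely from the position a transcript occupies in
its edges, never from id syntax; an id implied to belong to two classes is a
hard error because a silent misclassification would corrupt motif
enumeration downstream.  Edge direction is structural only — activation vs
repression is not modelled, since all downstream scores use absolute
correlation differences.
"""

from __future__ import annotations

import logging
from dataclasses import dataclass
from enum import Enum
from pathlib import Path
from typing import Iterable, Mapping

import networkx as nx

from .errors import ClassConflictError, DataError, ParseError

log = logging.getLogger(__name__)

__all__ = [
    "EdgeClass",
    "NodeClass",
    "RegulatoryEdge",
    "LFFLMotif",
    "LFFLNetwork",
    "read_interaction_table",
    "build_network",
    "enumerate_motifs",
    "annotate_nodes",
    "export_network",
    "read_graphml",
    "write_motif_table",
    "read_motif_table",
]


class EdgeClass(str, Enum):
    """The three regulatory interaction layers."""

    TF_MIRNA = "TF_MIRNA"
    TF_LNCRNA = "TF_LNCRNA"
    MIRNA_LNCRNA = "MIRNA_LNCRNA"


class NodeClass(str, Enum):
    TF = "TF"
    MIRNA = "MIRNA"
    LNCRNA = "LNCRNA"


#: node classes implied for (source, target) by each edge class
ENDPOINT_CLASSES: dict[EdgeClass, tuple[NodeClass, NodeClass]] = {
    EdgeClass.TF_MIRNA: (NodeClass.TF, NodeClass.MIRNA),
    EdgeClass.TF_LNCRNA: (NodeClass.TF, NodeClass.LNCRNA),
    EdgeClass.MIRNA_LNCRNA: (NodeClass.MIRNA, NodeClass.LNCRNA),
}


@dataclass(frozen=True, order=True)
class RegulatoryEdge:
    """One directed regulator->target interaction of a given layer."""

    source_id: str
    target_id: str
    edge_class: EdgeClass

    def __post_init__(self) -> None:
        if not self.source_id or not self.target_id:
            raise ValueError("edge endpoints must be non-empty identifiers")
        if self.source_id == self.target_id:
            raise ValueError(f"self-edge not allowed: {self.source_id!r}")
        object.__setattr__(self, "edge_class", EdgeClass(self.edge_class))


@dataclass(frozen=True, order=True)
class LFFLMotif:
    """One (TF, miRNA, lncRNA) feed-forward-loop triangle.

    A motif is identified by the ordered triple; the three ids are distinct.
    """

    tf_id: str
    mirna_id: str
    lncrna_id: str

    def __post_init__(self) -> None:
        ids = (self.tf_id, self.mirna_id, self.lncrna_id)
        if len(set(ids)) != 3:
            raise ValueError(f"motif ids must be pairwise distinct, got {ids}")

    @property
    def transcripts(self) -> tuple[str, str, str]:
        return (self.tf_id, self.mirna_id, self.lncrna_id)

    def as_tuple(self) -> tuple[str, str, str]:
        return self.transcripts


class LFFLNetwork:
    """A typed directed network over TF, miRNA and lncRNA nodes.

    Thin wrapper around :class:`networkx.DiGraph`; every node carries a
    ``node_class`` attribute and every edge an ``edge_class`` attribute.
    Extra node attributes are free-form annotations (e.g. disease links).
    """

    def __init__(self, graph: nx.DiGraph | None = None) -> None:
        self.graph: nx.DiGraph = graph if graph is not None else nx.DiGraph()

    # -- basic introspection -------------------------------------------------
    @property
    def n_nodes(self) -> int:
        return self.graph.number_of_nodes()

    @property
    def n_edges(self) -> int:
        return self.graph.number_of_edges()

    def node_class(self, node_id: str) -> NodeClass:
        return NodeClass(self.graph.nodes[node_id]["node_class"])

    def nodes_of_class(self, node_class: NodeClass | str) -> list[str]:
        wanted = NodeClass(node_class).value
        return sorted(
            n for n, d in self.graph.nodes(data=True) if d["node_class"] == wanted
        )

    def annotations(self, node_id: str) -> dict[str, str]:
        data = dict(self.graph.nodes[node_id])
        data.pop("node_class", None)
        return data

    def edges(self) -> list[RegulatoryEdge]:
        return sorted(
            RegulatoryEdge(u, v, EdgeClass(d["edge_class"]))
            for u, v, d in self.graph.edges(data=True)
        )

    def __eq__(self, other: object) -> bool:
        if not isinstance(other, LFFLNetwork):
            return NotImplemented
        mine = {n: dict(d) for n, d in self.graph.nodes(data=True)}
        theirs = {n: dict(d) for n, d in other.graph.nodes(data=True)}
        return mine == theirs and set(self.edges()) == set(other.edges())

    def __repr__(self) -> str:  # pragma: no cover - cosmetic
        return f"<LFFLNetwork: {self.n_nodes} nodes, {self.n_edges} edges>"


def read_interaction_table(
    path: str | Path,
    edge_class: EdgeClass | str,
    *,
    header: bool = False,
) -> list[RegulatoryEdge]:
    """Read a two-column regulator/target TSV into deduplicated edges.

    Dialect: tab-separated, ``#``-prefixed comment lines and blank lines are
    skipped, an optional single header row is dropped when ``header=True``.
    Column 1 is the regulator, column 2 the target; extra columns are ignored.
    Whitespace around ids is trimmed.  Duplicate rows are collapsed (count
    logged); self-edges are rejected rows (logged, not fatal).

    Raises
    ------
    ParseError
        If a data row has fewer than two usable fields; the message names the
        1-based line number.
    """
    edge_class = EdgeClass(edge_class)
    path = Path(path)
    rows: list[tuple[int, str]] = []
    with open(path, encoding="utf-8") as fh:
        for lineno, line in enumerate(fh, start=1):
            stripped = line.rstrip("\n")
            if not stripped.strip() or stripped.lstrip().startswith("#"):
                continue
            rows.append((lineno, stripped))
    if header and rows:
        rows = rows[1:]
    if not rows:
        log.warning("%s: no data rows, returning empty edge list", path)
        return []

    edges: list[RegulatoryEdge] = []
    seen: set[tuple[str, str]] = set()
    n_dup = 0
    n_self = 0
    for lineno, line in rows:
        fields = [f.strip() for f in line.split("\t")]
        if len(fields) < 2 or not fields[0] or not fields[1]:
            raise ParseError(
                f"{path}: line {lineno}: expected 2 tab-separated fields, got {line!r}"
            )
        source, target = fields[0], fields[1]
        if source == target:
            n_self += 1
            log.warning("%s: line %d: self-edge %r rejected", path, lineno, source)
            continue
        key = (source, target)
        if key in seen:
            n_dup += 1
            continue
        seen.add(key)
        edges.append(RegulatoryEdge(source, target, edge_class))
    if n_dup:
        log.info("%s: collapsed %d duplicate row(s)", path, n_dup)
    if n_self:
        log.info("%s: rejected %d self-edge row(s)", path, n_self)
    return edges


def build_network(edges: Iterable[RegulatoryEdge]) -> LFFLNetwork:
    """Merge edges from the three layers into one typed network.

    Node classes are inferred from the edge class of every incident edge.

    Raises
    ------
    ClassConflictError
        If one id is implied to belong to two different node classes; the
        message names the id and both classes.
    """
    edges = list(edges)
    classes: dict[str, NodeClass] = {}
    for e in edges:
        src_cls, tgt_cls = ENDPOINT_CLASSES[e.edge_class]
        for nid, ncls in ((e.source_id, src_cls), (e.target_id, tgt_cls)):
            prev = classes.get(nid)
            if prev is not None and prev != ncls:
                raise ClassConflictError(
                    f"node {nid!r} implied as both {prev.value} and {ncls.value}"
                )
            classes[nid] = ncls
    g = nx.DiGraph()
    for nid in sorted(classes):
        g.add_node(nid, node_class=classes[nid].value)
    for e in sorted(set(edges)):
        g.add_edge(e.source_id, e.target_id, edge_class=e.edge_class.value)
    return LFFLNetwork(g)


def enumerate_motifs(net: LFFLNetwork) -> list[LFFLMotif]:
    """Enumerate every complete (TF, miRNA, lncRNA) feed-forward triangle.

    A triple (t, m, l) is a motif iff edges t->m (TF_MIRNA), t->l (TF_LNCRNA)
    and m->l (MIRNA_LNCRNA) all exist.  The result is sorted lexicographically
    by (tf, mirna, lncrna) so downstream ranks are reproducible.
    """
    g = net.graph
    # miRNA -> set of lncRNA targets, built once
    mirna_targets: dict[str, set[str]] = {}
    motifs: list[LFFLMotif] = []
    for t in net.nodes_of_class(NodeClass.TF):
        tf_mirnas: list[str] = []
        tf_lncrnas: set[str] = set()
        for _, v, d in g.out_edges(t, data=True):
            if d["edge_class"] == EdgeClass.TF_MIRNA.value:
                tf_mirnas.append(v)
            elif d["edge_class"] == EdgeClass.TF_LNCRNA.value:
                tf_lncrnas.add(v)
        for m in tf_mirnas:
            if m not in mirna_targets:
                mirna_targets[m] = {
                    v
                    for _, v, d in g.out_edges(m, data=True)
                    if d["edge_class"] == EdgeClass.MIRNA_LNCRNA.value
                }
            for l in tf_lncrnas & mirna_targets[m]:
                motifs.append(LFFLMotif(t, m, l))
    motifs.sort()
    return motifs


def annotate_nodes(
    net: LFFLNetwork, table: Mapping[str, Mapping[str, str] | str]
) -> LFFLNetwork:
    """Attach annotations to matching nodes; unmatched keys are logged only.

    A plain-string value is stored under the key ``"annotation"``; a mapping
    value is stored key-by-key as node attributes.  Returns a new network.
    """
    g = net.graph.copy()
    unmatched = 0
    for nid, ann in table.items():
        if nid not in g:
            unmatched += 1
            continue
        if isinstance(ann, Mapping):
            for k, v in ann.items():
                g.nodes[nid][str(k)] = str(v)
        else:
            g.nodes[nid]["annotation"] = str(ann)
    if unmatched:
        log.info("annotate_nodes: %d annotation key(s) not in network", unmatched)
    return LFFLNetwork(g)


def export_network(net: LFFLNetwork, fmt: str, path: str | Path) -> None:
    """Write the network as GraphML or SIF.

    GraphML carries ``node_class`` and annotations as node attributes and
    ``edge_class`` as the edge attribute; a GraphML round trip is lossless.
    SIF uses the edge class as the interaction token
    (``source<TAB>edge_class<TAB>target``).
    """
    fmt = fmt.lower()
    path = Path(path)
    if fmt == "graphml":
        nx.write_graphml(net.graph, path)
    elif fmt == "sif":
        with open(path, "w", encoding="utf-8") as fh:
            for e in net.edges():
                fh.write(f"{e.source_id}\t{e.edge_class.value}\t{e.target_id}\n")
    else:
        raise ValueError(f"unknown export format {fmt!r}; use 'graphml' or 'sif'")


def read_graphml(path: str | Path) -> LFFLNetwork:
    """Read a network previously written by :func:`export_network` (GraphML)."""
    g = nx.read_graphml(path)
    out = nx.DiGraph()
    for n in sorted(g.nodes):
        data = {str(k): str(v) for k, v in g.nodes[n].items()}
        if "node_class" not in data:
            raise DataError(f"GraphML node {n!r} lacks a node_class attribute")
        out.add_node(n, **data)
    for u, v, d in g.edges(data=True):
        out.add_edge(u, v, edge_class=str(d["edge_class"]))
    return LFFLNetwork(out)


def write_motif_table(motifs: Iterable[LFFLMotif], path: str | Path) -> None:
    with open(path, "w", encoding="utf-8") as fh:
        fh.write("tf\tmirna\tlncrna\n")
        for m in motifs:
            fh.write(f"{m.tf_id}\t{m.mirna_id}\t{m.lncrna_id}\n")


def read_motif_table(path: str | Path) -> list[LFFLMotif]:
    motifs: list[LFFLMotif] = []
    with open(path, encoding="utf-8") as fh:
        for lineno, line in enumerate(fh, start=1):
            line = line.rstrip("\n")
            if not line.strip() or line.startswith("#"):
                continue
            if lineno == 1 and line.split("\t")[:3] == ["tf", "mirna", "lncrna"]:
                continue
            fields = [f.strip() for f in line.split("\t")]
            if len(fields) < 3:
                raise ParseError(f"{path}: line {lineno}: expected 3 fields")
            motifs.append(LFFLMotif(fields[0], fields[1], fields[2]))
    return motifs
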