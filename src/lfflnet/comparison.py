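"""Cross-cancer comparison of dysregulated motif sets and motif cross-talk.

A motif dysregulated in at least two cancer types is *common*; one
dysregulated in exactly one cancer type is *specific*.  The union of all
dysregulated motifs forms a pan-cancer sub-network whose nodes carry their
degree and the number of cancers they participate in.

Cross-talk with other motif families is purely structural: an L-FFL and an
mRNA-mediated FFL (M-FFL) form an L-M-FFL pair when they share both the TF
and the miRNA; an L-FFL and a ceRNA triple (mRNA and lncRNA competing for a
miRNA) form a pair when they share both the miRNA and the lncRNA.  ceRNA
triples are consumed as a provided table, not re-derived.
"""

from __future__ import annotations

import logging
from dataclasses import dataclass
from pathlib import Path
from typing import Iterable, Mapping

import pandas as pd

from .errors import DataError, ParseError
from .network import EdgeClass, LFFLMotif, LFFLNetwork, RegulatoryEdge, build_network

log = logging.getLogger(__name__)

__all__ = [
    "MFFLMotif",
    "CeRNATriple",
    "MotifCancerMatrix",
    "classify_common_specific",
    "union_subnetwork",
    "find_lmffl_crosstalk",
    "find_cerna_crosstalk",
    "read_mffl_table",
    "read_cerna_table",
]


@dataclass(frozen=True, order=True)
class MFFLMotif:
    """mRNA-mediated feed-forward loop: TF -> miRNA, both -> a common mRNA."""

    tf_id: str
    mirna_id: str
    mrna_id: str

    def __post_init__(self) -> None:
        if len({self.tf_id, self.mirna_id, self.mrna_id}) != 3:
            raise ValueError("M-FFL ids must be pairwise distinct")


@dataclass(frozen=True, order=True)
class CeRNATriple:
    """Competing-endogenous-RNA triple: mRNA and lncRNA sharing a miRNA."""

    mrna_id: str
    lncrna_id: str
    mirna_id: str

    def __post_init__(self) -> None:
        if len({self.mrna_id, self.lncrna_id, self.mirna_id}) != 3:
            raise ValueError("ceRNA ids must be pairwise distinct")


class MotifCancerMatrix:
    """Boolean motif x cancer dysregulation matrix.

    Rows are motifs (MultiIndex tf/mirna/lncrna), columns cancer labels.
    Rows are ordered by descending cancer count, then lexicographically.
    """

    def __init__(self, table: pd.DataFrame) -> None:
        table = table.astype(bool)
        counts = table.sum(axis=1)
        order = sorted(
            range(len(table)), key=lambda i: (-counts.iloc[i], table.index[i])
        )
        self.table = table.iloc[order]

    @classmethod
    def from_dysregulated(
        cls, per_cancer: Mapping[str, Iterable[LFFLMotif]]
    ) -> "MotifCancerMatrix":
        per_cancer = {label: set(ms) for label, ms in per_cancer.items()}
        all_motifs = sorted(set().union(*per_cancer.values())) if per_cancer else []
        index = pd.MultiIndex.from_tuples(
            [m.as_tuple() for m in all_motifs], names=["tf", "mirna", "lncrna"]
        )
        data = {
            label: [m in per_cancer[label] for m in all_motifs]
            for label in sorted(per_cancer)
        }
        return cls(pd.DataFrame(data, index=index))

    @property
    def cancer_labels(self) -> list[str]:
        return list(self.table.columns)

    @property
    def cancer_count(self) -> pd.Series:
        return self.table.sum(axis=1)

    def motifs(self) -> list[LFFLMotif]:
        return [LFFLMotif(*t) for t in self.table.index]

    def to_tsv(self, path) -> None:
        out = self.table.astype(int).reset_index()
        out.to_csv(path, sep="\t", index=False)


def classify_common_specific(matrix: MotifCancerMatrix) -> pd.Series:
    """Label each motif ``common`` (>=2 cancers) or ``specific`` (exactly 1).

    Motifs dysregulated in no cancer are excluded from the result.
    """
    if not matrix.cancer_labels:
        raise DataError("motif-cancer matrix has no cancer columns")
    counts = matrix.cancer_count
    counts = counts[counts >= 1]
    return counts.map(lambda c: "common" if c >= 2 else "specific").rename("label")


def union_subnetwork(matrix: MotifCancerMatrix) -> LFFLNetwork:
    """Network induced by the union of all dysregulated motifs.

    Every motif contributes its three edges; node attributes: ``degree``
    (total degree in the union network) and ``n_cancers`` (number of cancers
    in which the node participates via at least one flagged motif).
    """
    counts = matrix.cancer_count
    flagged = [LFFLMotif(*t) for t, c in counts.items() if c >= 1]
    if not flagged:
        raise DataError("no dysregulated motif to build a union sub-network from")
    edges: set[RegulatoryEdge] = set()
    node_cancers: dict[str, set[str]] = {}
    for motif in flagged:
        edges.add(RegulatoryEdge(motif.tf_id, motif.mirna_id, EdgeClass.TF_MIRNA))
        edges.add(RegulatoryEdge(motif.tf_id, motif.lncrna_id, EdgeClass.TF_LNCRNA))
        edges.add(RegulatoryEdge(motif.mirna_id, motif.lncrna_id, EdgeClass.MIRNA_LNCRNA))
        row = matrix.table.loc[motif.as_tuple()]
        cancers = {label for label in matrix.cancer_labels if bool(row[label])}
        for node in motif.transcripts:
            node_cancers.setdefault(node, set()).update(cancers)
    net = build_network(sorted(edges))
    for node in net.graph.nodes:
        net.graph.nodes[node]["degree"] = int(net.graph.degree(node))
        net.graph.nodes[node]["n_cancers"] = len(node_cancers[node])
    return net


def find_lmffl_crosstalk(
    lffl: Iterable[LFFLMotif], mffl: Iterable[MFFLMotif]
) -> list[tuple[LFFLMotif, MFFLMotif]]:
    """All (L-FFL, M-FFL) pairs sharing both the TF and the miRNA."""
    by_key: dict[tuple[str, str], list[MFFLMotif]] = {}
    for m in mffl:
        by_key.setdefault((m.tf_id, m.mirna_id), []).append(m)
    pairs = []
    for l in lffl:
        for m in by_key.get((l.tf_id, l.mirna_id), []):
            pairs.append((l, m))
    pairs.sort()
    return pairs


def find_cerna_crosstalk(
    lffl: Iterable[LFFLMotif], cerna: Iterable[CeRNATriple]
) -> list[tuple[LFFLMotif, CeRNATriple]]:
    """All (L-FFL, ceRNA) pairs sharing both the miRNA and the lncRNA."""
    by_key: dict[tuple[str, str], list[CeRNATriple]] = {}
    for c in cerna:
        by_key.setdefault((c.mirna_id, c.lncrna_id), []).append(c)
    pairs = []
    for l in lffl:
        for c in by_key.get((l.mirna_id, l.lncrna_id), []):
            pairs.append((l, c))
    pairs.sort()
    return pairs


def _read_triple_table(path, names, cls, header=False):
    rows = []
    with open(Path(path), encoding="utf-8") as fh:
        data_rows = [
            (i, line.rstrip("\n"))
            for i, line in enumerate(fh, start=1)
            if line.strip() and not line.lstrip().startswith("#")
        ]
    if header and data_rows:
        data_rows = data_rows[1:]
    for lineno, line in data_rows:
        fields = [f.strip() for f in line.split("\t")]
        if len(fields) < 3 or not all(fields[:3]):
            raise ParseError(f"{path}: line {lineno}: expected 3 tab-separated fields")
        rows.append(cls(*fields[:3]))
    return sorted(set(rows))


def read_mffl_table(path, header: bool = False) -> list[MFFLMotif]:
    """Read an M-FFL table (columns tf, mirna, mrna)."""
    return _read_triple_table(path, ("tf", "mirna", "mrna"), MFFLMotif, header)


def read_cerna_table(path, header: bool = False) -> list[CeRNATriple]:
    """Read a ceRNA table (columns mrna, lncrna, mirna)."""
    return _read_triple_table(path, ("mrna", "lncrna", "mirna"), CeRNATriple, header)
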