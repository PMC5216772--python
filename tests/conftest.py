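"""Shared fixtures and independent brute-force oracles."""

from __future__ import annotations

import numpy as np
import pandas as pd
import pytest

from lfflnet import (
    EdgeClass,
    ExpressionCohort,
    LFFLMotif,
    NodeClass,
    RegulatoryEdge,
    build_network,
)


# ---------------------------------------------------------------------------
# independent oracles (deliberately naive; never share code with the package)
# ---------------------------------------------------------------------------
def brute_force_motifs(net):
    """Exhaustive triple loop over all (TF, miRNA, lncRNA) combinations."""
    g = net.graph

    def has(u, v, cls):
        return g.has_edge(u, v) and g[u][v]["edge_class"] == cls.value

    out = []
    for t in net.nodes_of_class(NodeClass.TF):
        for m in net.nodes_of_class(NodeClass.MIRNA):
            for l in net.nodes_of_class(NodeClass.LNCRNA):
                if (
                    has(t, m, EdgeClass.TF_MIRNA)
                    and has(t, l, EdgeClass.TF_LNCRNA)
                    and has(m, l, EdgeClass.MIRNA_LNCRNA)
                ):
                    out.append(LFFLMotif(t, m, l))
    return sorted(out)


def random_tripartite_edges(rng, n_tf=5, n_mirna=8, n_lncrna=8, density=0.2):
    """Random edges in all three layers at the given density."""
    tfs = [f"T{i}" for i in range(n_tf)]
    mirnas = [f"M{i}" for i in range(n_mirna)]
    lncrnas = [f"L{i}" for i in range(n_lncrna)]
    edges = []
    for regs, tgts, cls in (
        (tfs, mirnas, EdgeClass.TF_MIRNA),
        (tfs, lncrnas, EdgeClass.TF_LNCRNA),
        (mirnas, lncrnas, EdgeClass.MIRNA_LNCRNA),
    ):
        for r in regs:
            for t in tgts:
                if rng.random() < density:
                    edges.append(RegulatoryEdge(r, t, cls))
    return edges


def make_cohort(
    rng,
    tf_ids=("T0", "T1"),
    mirna_ids=("M0", "M1"),
    lncrna_ids=("L0", "L1"),
    n_tumor=10,
    n_normal=10,
    label="TEST",
):
    """Cohort of independent lognormal-ish background expression."""
    n = n_tumor + n_normal
    samples = pd.DataFrame(
        {
            "condition": ["tumor"] * n_tumor + ["normal"] * n_normal,
            "patient_id": [f"P{i}" for i in range(n_tumor)]
            + [f"P{i}" for i in range(n_normal)],
        },
        index=pd.Index([f"S{i}" for i in range(n)], name="sample_id"),
    )

    def mat(ids):
        vals = np.maximum(np.exp2(rng.normal(5, 1, size=(len(ids), n))) - 1, 0)
        return pd.DataFrame(vals, index=list(ids), columns=samples.index)

    return ExpressionCohort(
        tf=mat(tf_ids), mirna=mat(mirna_ids), lncrna=mat(lncrna_ids),
        samples=samples, cancer_label=label,
    )


# ---------------------------------------------------------------------------
# fixtures
# ---------------------------------------------------------------------------
@pytest.fixture
def rng():
    return np.random.default_rng(42)


@pytest.fixture
def triangle_edges():
    """The single-triangle example network."""
    return [
        RegulatoryEdge("E2F1", "hsa-miR-15b", EdgeClass.TF_MIRNA),
        RegulatoryEdge("E2F1", "IQCH-AS1", EdgeClass.TF_LNCRNA),
        RegulatoryEdge("hsa-miR-15b", "IQCH-AS1", EdgeClass.MIRNA_LNCRNA),
    ]


@pytest.fixture
def triangle_network(triangle_edges):
    return build_network(triangle_edges)
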