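"""Topology diagnostics of the regulatory network.

Four classical per-node/per-degree diagnostics, all computed on the
undirected projection of the typed network (the convention of Cytoscape's
NetworkAnalyzer, for which these metrics are defined):

* degree ``k`` and the degree->count distribution;
* clustering coefficient ``2 e_n / (k_n (k_n - 1))`` where ``e_n`` counts
  edges among the neighbours of ``n`` (undefined for ``k < 2``);
* topological coefficient: for node ``n`` with neighbours ``N(n)``, the mean
  over all nodes ``m`` sharing at least one neighbour with ``n`` of
  ``(|N(n) ∩ N(m)| + [n~m]) / k_n`` — a shared-neighbour tendency used as a
  modularity/scale-freeness diagnostic;
* neighbourhood connectivity: for each degree ``k``, the mean over nodes of
  degree ``k`` of the mean degree of their neighbours.

A straight line on the log10(count) vs log10(degree) plot with negative
slope is the usual operational signature of a scale-free-like degree
distribution; :func:`degree_distribution_fit` returns that OLS fit.
"""

from __future__ import annotations

import math
from dataclasses import dataclass

import networkx as nx
import numpy as np
import pandas as pd

from .errors import DataError
from .network import LFFLNetwork

__all__ = [
    "TopologyProfile",
    "compute_topology_profile",
    "degree_distribution_fit",
    "plot_degree_distribution",
]


@dataclass
class TopologyProfile:
    """Per-node metric table plus the two degree-binned distributions."""

    nodes: pd.DataFrame  # node_id, node_class, degree, clustering_coefficient, topological_coefficient
    degree_counts: pd.DataFrame  # degree, count
    neighborhood_connectivity: pd.DataFrame  # degree, mean_neighbor_degree

    def to_tsv(self, nodes_path, degree_path, connectivity_path) -> None:
        self.nodes.to_csv(nodes_path, sep="\t", index=False)
        self.degree_counts.to_csv(degree_path, sep="\t", index=False)
        self.neighborhood_connectivity.to_csv(connectivity_path, sep="\t", index=False)


def _topological_coefficient(g: nx.Graph, n) -> float:
    kn = g.degree(n)
    if kn < 2:
        return math.nan
    nbrs = set(g[n])
    partners: set = set()
    for w in nbrs:
        partners.update(g[w])
    partners.discard(n)
    if not partners:
        return math.nan
    total = 0.0
    for m in partners:
        shared = len(nbrs & set(g[m]))
        total += (shared + (1 if g.has_edge(n, m) else 0)) / kn
    return total / len(partners)


def compute_topology_profile(net: LFFLNetwork) -> TopologyProfile:
    """Compute all four diagnostics on the undirected projection of ``net``."""
    if net.n_nodes == 0:
        raise DataError("cannot profile an empty network")
    g = net.graph.to_undirected()
    clustering = nx.clustering(g)
    avg_nbr_deg = nx.average_neighbor_degree(g)

    rows = []
    for n in sorted(g.nodes):
        k = g.degree(n)
        rows.append(
            {
                "node_id": n,
                "node_class": g.nodes[n]["node_class"],
                "degree": k,
                "clustering_coefficient": clustering[n] if k >= 2 else math.nan,
                "topological_coefficient": _topological_coefficient(g, n),
            }
        )
    nodes = pd.DataFrame(rows)

    degree_counts = (
        nodes["degree"].value_counts().sort_index().rename_axis("degree").reset_index(name="count")
    )

    # mean over nodes of degree k of the mean degree of their neighbours
    conn_rows = []
    by_degree: dict[int, list[float]] = {}
    for n in g.nodes:
        k = g.degree(n)
        if k == 0:
            continue
        by_degree.setdefault(k, []).append(avg_nbr_deg[n])
    for k in sorted(by_degree):
        conn_rows.append({"degree": k, "mean_neighbor_degree": float(np.mean(by_degree[k]))})
    neighborhood_connectivity = pd.DataFrame(
        conn_rows, columns=["degree", "mean_neighbor_degree"]
    )

    return TopologyProfile(nodes, degree_counts, neighborhood_connectivity)


def degree_distribution_fit(profile: TopologyProfile) -> tuple[float, float, float]:
    """OLS fit of log10(count) vs log10(degree) over nonzero bins.

    Returns ``(slope, intercept, r_squared)``; a clearly negative slope is
    the scale-free-like signature.  Degree-0 bins are excluded (log of 0).

    Raises
    ------
    DataError
        If fewer than 3 distinct positive degrees have nonzero counts.
    """
    dc = profile.degree_counts
    dc = dc[(dc["degree"] > 0) & (dc["count"] > 0)]
    if len(dc) < 3:
        raise DataError(
            f"degree distribution fit needs >=3 distinct degrees, got {len(dc)}"
        )
    x = np.log10(dc["degree"].to_numpy(dtype=float))
    y = np.log10(dc["count"].to_numpy(dtype=float))
    slope, intercept = np.polyfit(x, y, 1)
    resid = y - (slope * x + intercept)
    ss_res = float(np.sum(resid**2))
    ss_tot = float(np.sum((y - y.mean()) ** 2))
    r_squared = 1.0 if ss_tot == 0 else 1.0 - ss_res / ss_tot
    return float(slope), float(intercept), float(r_squared)


def plot_degree_distribution(profile: TopologyProfile, path) -> None:
    """Log-log degree-distribution scatter with the OLS fit line (PNG)."""
    import matplotlib

    matplotlib.use("Agg")
    import matplotlib.pyplot as plt

    dc = profile.degree_counts
    dc = dc[(dc["degree"] > 0) & (dc["count"] > 0)]
    fig, ax = plt.subplots(figsize=(4.5, 3.5))
    ax.loglog(dc["degree"], dc["count"], "o", ms=5, mfc="none")
    try:
        slope, intercept, r2 = degree_distribution_fit(profile)
        xs = np.linspace(np.log10(dc["degree"].min()), np.log10(dc["degree"].max()), 50)
        ax.plot(10**xs, 10 ** (slope * xs + intercept), "-", lw=1,
                label=f"slope={slope:.2f}, $r^2$={r2:.2f}")
        ax.legend(frameon=False, fontsize=8)
    except DataError:
        pass
    ax.set_xlabel("degree k")
    ax.set_ylabel("node count")
    fig.tight_layout()
    fig.savefig(path, dpi=150)
    plt.close(fig)
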