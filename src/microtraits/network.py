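"""Co-occurrence networks from OTU tables and their topology metrics.

Nodes are the most abundant OTUs; edges are strong, multiple-testing-robust
rank correlations between their relative-abundance profiles across samples.
Topology summaries (mean degree, clustering, path length, diameter,
modularity) characterize how community organization changes along the
restoration gradient.
"""

from __future__ import annotations

from dataclasses import dataclass, asdict

import networkx as nx
import numpy as np
import pandas as pd
from scipy import stats
from statsmodels.stats.multitest import multipletests

from .community import OtuTable

__all__ = ["NetworkParams", "NetworkStats", "build_network", "network_stats"]


class DegenerateNetworkError(ValueError):
    """Raised when fewer than two OTUs survive candidate selection."""


@dataclass(frozen=True)
class NetworkParams:
    """Candidate selection and edge-filtering thresholds.

    Defaults: the 500 most abundant OTUs, Spearman |r| > 0.75, and
    Benjamini–Hochberg false discovery rate < 0.05 across all pairs.
    """

    top_n_otus: int = 500
    r_threshold: float = 0.75
    fdr_threshold: float = 0.05
    correlation: str = "spearman"

    def __post_init__(self) -> None:
        if not (0 < self.r_threshold < 1):
            raise ValueError("r_threshold must lie in (0, 1)")
        if not (0 < self.fdr_threshold < 1):
            raise ValueError("fdr_threshold must lie in (0, 1)")
        if self.correlation != "spearman":
            raise ValueError("only the spearman estimator is implemented")


@dataclass
class NetworkStats:
    n_nodes: int
    n_edges: int
    n_components: int
    positive_edge_fraction: float | None
    avg_degree: float
    avg_clustering: float
    average_path_length: float | None
    diameter: float | None
    modularity: float | None

    def to_dict(self) -> dict:
        return asdict(self)


def select_top_otus(table: OtuTable, top_n: int) -> list[str]:
    """The ``top_n`` OTUs by total relative abundance, ties broken by id."""
    rel = table.relative_abundance().fillna(0.0)
    totals = rel.sum(axis=1)
    order = sorted(totals.index, key=lambda o: (-totals[o], o))
    return order[:top_n]


def build_network(table: OtuTable, params: NetworkParams | None = None) -> nx.Graph:
    """Spearman co-occurrence network over the most abundant OTUs.

    Correlations are computed on relative abundances (hence invariant to
    per-sample sequencing depth); p-values for all candidate pairs are
    adjusted with Benjamini–Hochberg, and an edge is kept when |r| exceeds
    the threshold AND the adjusted p (q) is below the FDR threshold.  Edge
    attributes: r, q, sign.
    """
    params = params or NetworkParams()
    if table.counts.shape[1] < 4:
        raise ValueError("need at least 4 samples for rank correlations")
    otus = select_top_otus(table, params.top_n_otus)
    if len(otus) < 2:
        raise DegenerateNetworkError("fewer than two candidate OTUs")
    rel = table.relative_abundance().fillna(0.0).loc[otus]
    data = rel.to_numpy().T  # samples x otus
    with np.errstate(invalid="ignore"):
        rho, pval = stats.spearmanr(data)
    rho = np.atleast_2d(rho)
    pval = np.atleast_2d(pval)
    iu = np.triu_indices(len(otus), k=1)
    r_flat = rho[iu]
    p_flat = pval[iu]
    ok = np.isfinite(r_flat) & np.isfinite(p_flat)
    q_flat = np.full_like(p_flat, np.nan)
    if ok.any():
        q_flat[ok] = multipletests(p_flat[ok], method="fdr_bh")[1]
    graph = nx.Graph()
    graph.add_nodes_from(otus)
    # scalar attributes only, so the graph stays GraphML-serializable
    graph.graph.update(asdict(params))
    graph.graph["modularity_algorithm"] = "greedy_modularity_communities"
    for i, j, r, q in zip(iu[0], iu[1], r_flat, q_flat):
        if np.isfinite(r) and np.isfinite(q) and abs(r) > params.r_threshold and q < params.fdr_threshold:
            graph.add_edge(
                otus[i], otus[j], r=float(r), q=float(q),
                sign="+" if r > 0 else "-",
            )
    return graph


def network_stats(graph: nx.Graph) -> NetworkStats:
    """Topology metrics of a co-occurrence network.

    Mean degree is 2E/N; the clustering coefficient averages local clustering
    with degree-<2 nodes contributing 0; path length and diameter are
    computed unweighted on the largest connected component; modularity comes
    from greedy agglomerative community detection on the unsigned graph.
    Path metrics are None for edgeless networks.
    """
    if graph.number_of_nodes() == 0:
        raise ValueError("network has no nodes")
    n, e = graph.number_of_nodes(), graph.number_of_edges()
    components = list(nx.connected_components(graph))
    signs = [d["sign"] for _, _, d in graph.edges(data=True)]
    pos_frac = signs.count("+") / len(signs) if signs else None
    avg_cc = float(np.mean(list(nx.clustering(graph).values())))
    apl = diam = modularity = None
    if e > 0:
        largest = graph.subgraph(max(components, key=len))
        if largest.number_of_nodes() > 1:
            apl = float(nx.average_shortest_path_length(largest))
            diam = float(nx.diameter(largest))
        communities = nx.community.greedy_modularity_communities(graph)
        modularity = float(nx.community.modularity(graph, communities))
    return NetworkStats(
        n_nodes=n,
        n_edges=e,
        n_components=len(components),
        positive_edge_fraction=pos_frac,
        avg_degree=2 * e / n,
        avg_clustering=avg_cc,
        average_path_length=apl,
        diameter=diam,
        modularity=modularity,
    )


def edge_table(graph: nx.Graph) -> pd.DataFrame:
    """Edge list as a DataFrame (source, target, r, q, sign)."""
    rows = [
        {"source": u, "target": v, "r": d["r"], "q": d["q"], "sign": d["sign"]}
        for u, v, d in sorted(graph.edges(data=True))
    ]
    return pd.DataFrame(rows, columns=["source", "target", "r", "q", "sign"])
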