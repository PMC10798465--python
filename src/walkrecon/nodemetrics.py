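"""Node-level structural metrics and matched-node correlation.

Six metrics characterize each node of a connected, undirected, unweighted
graph: degree, local clustering coefficient, closeness, (shortest-path)
betweenness, eccentricity and coreness (k-core index).  Recovery is scored
by correlating a metric measured on the reconstructed graph with the same
metric measured on the original graph, over exactly the nodes present in
the reconstruction — each node paired with itself.

Shortest-path-heavy metrics (closeness, betweenness, eccentricity) are
evaluated through igraph's C routines; they are exact, not approximations.
Normalization constants are chosen for interpretability only: Pearson is
affine-invariant and Spearman monotone-invariant, so they do not affect
the scores.
"""

from __future__ import annotations

import math
from dataclasses import dataclass

import igraph as ig
import networkx as nx
import numpy as np
from scipy import stats

METRICS = (
    "degree",
    "clustering",
    "closeness",
    "betweenness",
    "eccentricity",
    "coreness",
)


@dataclass(frozen=True)
class CorrelationResult:
    """Pearson and Spearman coefficients over matched nodes.

    ``defined`` is False when either vector is constant or fewer than three
    nodes are matched; such results carry NaN coefficients and are excluded
    from aggregates.
    """

    pearson: float
    spearman: float
    n_matched: int

    @property
    def defined(self) -> bool:
        return not (math.isnan(self.pearson) or math.isnan(self.spearman))


def _to_igraph(net: nx.Graph) -> tuple[ig.Graph, list]:
    nodes = list(net.nodes())
    index = {v: i for i, v in enumerate(nodes)}
    edges = [(index[u], index[v]) for u, v in net.edges()]
    return ig.Graph(n=len(nodes), edges=edges), nodes


def compute_property(net: nx.Graph, metric: str) -> dict:
    """Map node -> value for one of the six supported metrics.

    The graph must be connected (closeness and eccentricity are otherwise
    ill-defined); callers pass the largest component or a walk trace, both
    of which are connected.
    """
    if metric not in METRICS:
        raise ValueError(f"unknown metric {metric!r}; expected one of {METRICS}")
    if net.number_of_nodes() == 0:
        raise ValueError("empty network")
    if not nx.is_connected(net):
        raise ValueError("metrics require a connected network")

    if metric == "degree":
        return {v: float(d) for v, d in net.degree()}
    if metric == "clustering":
        return {v: float(c) for v, c in nx.clustering(net).items()}
    if metric == "coreness":
        return {v: float(c) for v, c in nx.core_number(net).items()}

    g, nodes = _to_igraph(net)
    n = len(nodes)
    if metric == "closeness":
        vals = [1.0] * n if n == 1 else g.closeness()
    elif metric == "eccentricity":
        vals = g.eccentricity()
    else:  # betweenness, normalized by the number of ordered-out pairs
        norm = (n - 1) * (n - 2) / 2.0
        raw = g.betweenness()
        vals = [b / norm for b in raw] if norm > 0 else [0.0] * n
    return {v: float(x) for v, x in zip(nodes, vals)}


def matched_correlation(
    orig: dict, recon: dict, nodes=None
) -> CorrelationResult:
    """Correlate a metric between original and reconstructed graphs.

    ``orig`` and ``recon`` map node -> value; the comparison runs over the
    reconstruction's nodes (or an explicit ``nodes`` subset), each paired
    with itself in the original.  Spearman uses average ranks for ties.
    """
    node_list = list(recon.keys() if nodes is None else nodes)
    missing = [v for v in node_list if v not in orig]
    if missing:
        raise ValueError(f"{len(missing)} reconstructed node(s) absent from the original")
    x = np.array([orig[v] for v in node_list], dtype=float)
    y = np.array([recon[v] for v in node_list], dtype=float)
    n = len(node_list)
    if n < 3 or np.ptp(x) == 0 or np.ptp(y) == 0:
        return CorrelationResult(float("nan"), float("nan"), n)
    pearson = float(stats.pearsonr(x, y).statistic)
    spearman = float(stats.spearmanr(x, y).statistic)
    return CorrelationResult(pearson, spearman, n)
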