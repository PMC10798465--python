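"""Community detection and partition-agreement scoring.

Communities are detected with the Leiden algorithm optimizing modularity
(resolution 1.0).  Agreement between a reference partition — planted for
the modular benchmark, or Leiden on the original network otherwise — and
the partition of a reconstruction is scored by normalized mutual
information (arithmetic-mean normalization, in [0, 1]) and the adjusted
Rand index (chance-corrected, in [-1, 1]); both are invariant to label
permutations and are evaluated on the discovered-node subset only, since
the reconstruction carries no labels for unseen nodes.
"""

from __future__ import annotations

import igraph as ig
import leidenalg
import networkx as nx
from sklearn.metrics import adjusted_rand_score, normalized_mutual_info_score

from walkrecon.nodemetrics import _to_igraph


def detect_leiden(net: nx.Graph, seed: int | None = None, resolution: float = 1.0) -> dict:
    """Leiden partition (modularity objective); returns node -> community label."""
    if net.number_of_nodes() == 0:
        raise ValueError("cannot partition an empty network")
    g, nodes = _to_igraph(net)
    part = leidenalg.find_partition(
        g,
        leidenalg.RBConfigurationVertexPartition,
        resolution_parameter=resolution,
        seed=seed,
    )
    return {v: int(c) for v, c in zip(nodes, part.membership)}


def partition_agreement(p_orig: dict, p_recon: dict, nodes) -> tuple[float, float]:
    """(NMI, ARI) between two partitions restricted to a matched node set."""
    node_list = list(nodes)
    if len(node_list) < 2:
        raise ValueError("need at least two matched nodes to compare partitions")
    labels_orig = [p_orig[v] for v in node_list]
    labels_recon = [p_recon[v] for v in node_list]
    nmi = float(
        normalized_mutual_info_score(labels_orig, labels_recon, average_method="arithmetic")
    )
    ari = float(adjusted_rand_score(labels_orig, labels_recon))
    return nmi, ari


def save_partition(partition: dict, path) -> None:
    """Two-column CSV: node,community."""
    with open(path, "w") as fh:
        fh.write("node,community\n")
        for v in sorted(partition):
            fh.write(f"{v},{partition[v]}\n")


def load_partition(path) -> dict:
    """Inverse of :func:`save_partition`."""
    partition = {}
    with open(path) as fh:
        header = fh.readline()
        if header.strip() and header.strip() != "node,community":
            u, c = header.strip().split(",")
            partition[_coerce(u)] = int(c)
        for line in fh:
            if not line.strip():
                continue
            u, c = line.strip().split(",")
            partition[_coerce(u)] = int(c)
    return partition


def _coerce(token: str):
    try:
        return int(token)
    except ValueError:
        return token
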