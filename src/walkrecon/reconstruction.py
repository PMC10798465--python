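"""Co-occurrence reconstruction of the perceived network.

The walk's node sequence is the only information available: two nodes are
linked in the reconstruction whenever they appear consecutively in the
sequence.  The result is an unweighted simple subgraph of the walked
network (repeat adjacencies collapse), and it is connected by construction
because it is the trace of a walk.
"""

from __future__ import annotations

import json
from dataclasses import dataclass

import networkx as nx
import numpy as np

from walkrecon.netmodels import write_edgelist
from walkrecon.walkers import WalkSequence


@dataclass
class ReconstructedNetwork:
    """The perceived subgraph together with the sequence it came from."""

    graph: nx.Graph
    source: WalkSequence

    @property
    def discovered_nodes(self) -> set:
        return set(self.graph.nodes())

    @property
    def discovered_edges(self) -> set:
        return {frozenset(e) for e in self.graph.edges()}


def reconstruct(seq: WalkSequence) -> ReconstructedNetwork:
    """Build the co-occurrence graph of a walk sequence.

    One node per distinct symbol; one edge per distinct unordered pair of
    consecutive symbols.  The first symbol contributes a node but no edge.
    """
    nodes = seq.nodes
    if len(nodes) == 0:
        raise ValueError("cannot reconstruct from an empty sequence")
    g = nx.Graph()
    g.add_nodes_from(nodes)
    g.add_edges_from(
        (u, v) for u, v in zip(nodes[:-1], nodes[1:]) if u != v
    )
    return ReconstructedNetwork(graph=g, source=seq)


def knowledge_fraction(seq: WalkSequence, n_original: int) -> float:
    """Fraction of the original network's nodes discovered by the walk."""
    if n_original <= 0:
        raise ValueError("n_original must be positive")
    n_unique = len(set(seq.nodes))
    if n_unique > n_original:
        raise ValueError(
            f"sequence contains {n_unique} distinct nodes but the original has {n_original}"
        )
    return n_unique / n_original

def unique_counts(seq: WalkSequence) -> np.ndarray:
    """Cumulative number of distinct nodes after each sequence position.

    ``unique_counts(seq)[w - 1]`` is the number of nodes discovered by the
    length-``w`` prefix, so coverage curves over nested prefixes come from
    a single pass.
    """
    seen: set = set()
    out = np.empty(len(seq.nodes), dtype=np.intp)
    count = 0
    for k, v in enumerate(seq.nodes):
        if v not in seen:
            seen.add(v)
            count += 1
        out[k] = count
    return out


def save_reconstruction(recon: ReconstructedNetwork, path, network_id: str | None = None) -> None:
    """Edge list plus a ``<path>.json`` provenance sidecar."""
    write_edgelist(recon.graph, path)
    meta = {
        "dynamics": recon.source.dynamics,
        "lambda": recon.source.lam,
        "w": len(recon.source),
        "seed": recon.source.seed,
        "source_network": network_id,
        "n_nodes": recon.graph.number_of_nodes(),
        "n_edges": recon.graph.number_of_edges(),
    }
    with open(f"{path}.json", "w") as fh:
        json.dump(meta, fh, indent=2)
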