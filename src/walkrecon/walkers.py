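"""Single-agent walk dynamics producing node sequences.

Five dynamics are supported; at each step the agent sits on node ``i`` and
chooses the next node ``j`` among the neighbors ``Γ_i`` with probability
proportional to a dynamics-specific weight:

========== =====================================================
``rw``        1 (uniform over neighbors)
``rwd``       ``k_j`` (degree-biased, prefers hubs)
``rwid``      ``1 / k_j`` (inverse-degree, avoids hubs)
``tsaw-node`` ``exp(-λ f_j)`` with ``f_j`` = times ``j`` was visited
``tsaw-edge`` ``exp(-λ f_ij)`` with ``f_ij`` = times edge ``{i,j}``
              was traversed (either direction)
========== =====================================================

The true self-avoiding (TSAW) variants only *discourage* revisits, so the
walk can never get stuck; the default avoidance strength is ``λ = ln 2``,
i.e. every past visit halves a candidate's weight.  A walk of length ``w``
is the sequence of ``w`` visited nodes (``w - 1`` transitions); the start
node counts as visited before the first transition.
"""

from __future__ import annotations

import json
import math
from collections import Counter
from dataclasses import dataclass, field

import networkx as nx
import numpy as np

DYNAMICS = ("rw", "rwd", "rwid", "tsaw-node", "tsaw-edge")

#: default self-avoidance strength: each previous visit halves the weight
DEFAULT_LAMBDA = math.log(2.0)


class WalkError(RuntimeError):
    """The walk reached a state it cannot move from (isolated node)."""


def _edge_key(u, v):
    return (u, v) if u <= v else (v, u)


@dataclass
class WalkState:
    """Mutable walk history: current node, visit counts, traversal counts."""

    current: object
    node_visits: Counter = field(default_factory=Counter)
    edge_visits: Counter = field(default_factory=Counter)
    rng: np.random.Generator | None = None

    @classmethod
    def fresh(cls, start, seed: int | None = None) -> "WalkState":
        """State at the beginning of a walk: the start node already visited once."""
        state = cls(current=start, rng=np.random.default_rng(seed))
        state.node_visits[start] = 1
        return state


@dataclass
class WalkSequence:
    """Ordered list of visited nodes plus the provenance of the walk."""

    nodes: list
    dynamics: str
    lam: float = DEFAULT_LAMBDA
    seed: int | None = None

    def __len__(self) -> int:
        return len(self.nodes)

    @property
    def w(self) -> int:
        return len(self.nodes)

    def unique_nodes(self) -> set:
        return set(self.nodes)

    def prefix(self, w: int) -> "WalkSequence":
        """The first ``w`` visited nodes as a walk in its own right."""
        if not 1 <= w <= len(self.nodes):
            raise ValueError(f"prefix length must be in [1, {len(self.nodes)}]")
        return WalkSequence(self.nodes[:w], self.dynamics, self.lam, self.seed)


def neighbor_distribution(
    net: nx.Graph, state: WalkState, dynamics: str, lam: float = DEFAULT_LAMBDA
) -> tuple[list, np.ndarray]:
    """Transition distribution over the neighbors of the current node.

    Returns the neighbor list and the matching probability vector (sums
    to 1).  Raises :class:`WalkError` on an isolated current node, which
    cannot occur on connected inputs.
    """
    if dynamics not in DYNAMICS:
        raise ValueError(f"unknown dynamics {dynamics!r}; expected one of {DYNAMICS}")
    i = state.current
    nbrs = list(net.neighbors(i))
    if not nbrs:
        raise WalkError(f"node {i!r} has no neighbors")
    if dynamics == "rw":
        weights = np.ones(len(nbrs))
    elif dynamics == "rwd":
        weights = np.array([net.degree(j) for j in nbrs], dtype=float)
    elif dynamics == "rwid":
        weights = 1.0 / np.array([net.degree(j) for j in nbrs], dtype=float)
    elif dynamics == "tsaw-node":
        weights = np.exp(-lam * np.array([state.node_visits[j] for j in nbrs], dtype=float))
    else:  # tsaw-edge
        weights = np.exp(
            -lam * np.array([state.edge_visits[_edge_key(i, j)] for j in nbrs], dtype=float)
        )
    return nbrs, weights / weights.sum()


def _engine_run(
    net: nx.Graph,
    dynamics: str,
    lam: float,
    rng: np.random.Generator,
    start,
    max_len: int,
    target_unique: int | None,
) -> list:
    """Core sampling loop on an index-mapped adjacency structure.

    Emits up to ``max_len`` nodes, stopping early once ``target_unique``
    distinct nodes have been seen (when given).  Weight bookkeeping follows
    :func:`neighbor_distribution` exactly; cumulative-sum inverse sampling
    keeps the per-step cost at O(k) for degree k.
    """
    nodes = list(net.nodes())
    index = {v: k for k, v in enumerate(nodes)}
    nbr = [
        np.fromiter((index[u] for u in net.neighbors(v)), dtype=np.intp)
        for v in nodes
    ]
    deg = np.array([a.size for a in nbr], dtype=float)
    cum = None
    if dynamics == "rwd":
        cum = [np.cumsum(deg[a]) for a in nbr]
    elif dynamics == "rwid":
        cum = [np.cumsum(1.0 / deg[a]) for a in nbr]

    visits = np.zeros(len(nodes))
    edge_counts: dict[tuple[int, int], int] | None = (
        {} if dynamics == "tsaw-edge" else None
    )
    cur = index[start]
    visits[cur] = 1.0
    unique = 1
    out = np.empty(max_len, dtype=np.intp)
    out[0] = cur
    emitted = 1
    while emitted < max_len and (target_unique is None or unique < target_unique):
        a = nbr[cur]
        if a.size == 0:
            raise WalkError(f"node {nodes[cur]!r} has no neighbors")
        if dynamics == "rw":
            nxt = int(a[rng.integers(a.size)])
        elif cum is not None:
            c = cum[cur]
            nxt = int(a[np.searchsorted(c, rng.random() * c[-1], side="right")])
        elif dynamics == "tsaw-node":
            c = np.cumsum(np.exp(-lam * visits[a]))
            nxt = int(a[np.searchsorted(c, rng.random() * c[-1], side="right")])
        else:  # tsaw-edge
            f = np.array(
                [edge_counts.get((cur, j) if cur < j else (j, cur), 0) for j in a],
                dtype=float,
            )
            c = np.cumsum(np.exp(-lam * f))
            nxt = int(a[np.searchsorted(c, rng.random() * c[-1], side="right")])
        if edge_counts is not None:
            key = (cur, nxt) if cur < nxt else (nxt, cur)
            edge_counts[key] = edge_counts.get(key, 0) + 1
        cur = nxt
        if visits[cur] == 0:
            unique += 1
        visits[cur] += 1.0
        out[emitted] = cur
        emitted += 1
    return [nodes[i] for i in out[:emitted]]


def _prepare(net: nx.Graph, dynamics: str, w: int, seed, start):
    if dynamics not in DYNAMICS:
        raise ValueError(f"unknown dynamics {dynamics!r}; expected one of {DYNAMICS}")
    if w < 1:
        raise ValueError("walk length must be >= 1")
    if net.number_of_nodes() == 0:
        raise ValueError("cannot walk on an empty network")
    if not nx.is_connected(net):
        raise ValueError("walks require a connected network; extract the largest component")
    rng = np.random.default_rng(seed)
    if isinstance(start, str) and start == "uniform":
        all_nodes = list(net.nodes())
        start = all_nodes[int(rng.integers(len(all_nodes)))]
    elif start not in net:
        raise ValueError(f"start node {start!r} not in network")
    return rng, start


def run_walk(
    net: nx.Graph,
    dynamics: str,
    w: int,
    seed: int | None = None,
    start="uniform",
    lam: float = DEFAULT_LAMBDA,
) -> WalkSequence:
    """Simulate a walk of exactly ``w`` visited nodes on a connected network."""
    rng, start = _prepare(net, dynamics, w, seed, start)
    visited = _engine_run(net, dynamics, lam, rng, start, w, target_unique=None)
    return WalkSequence(visited, dynamics, lam, seed)


def walk_until_unique(
    net: nx.Graph,
    dynamics: str,
    target_unique: int,
    seed: int | None = None,
    max_steps: int | None = None,
    start="uniform",
    lam: float = DEFAULT_LAMBDA,
) -> tuple[WalkSequence, bool]:
    """Walk until ``target_unique`` distinct nodes have been visited.

    Returns the sequence truncated at the first crossing and a flag that is
    False when the cap ``max_steps`` (default ``400 * n``) was hit first.
    """
    if target_unique < 1 or target_unique > net.number_of_nodes():
        raise ValueError("target_unique must be in [1, n]")
    cap = max_steps if max_steps is not None else 400 * net.number_of_nodes()
    rng, start = _prepare(net, dynamics, 1, seed, start)
    visited = _engine_run(net, dynamics, lam, rng, start, cap, target_unique)
    seq = WalkSequence(visited, dynamics, lam, seed)
    return seq, len(set(visited)) >= target_unique


def save_sequence(seq: WalkSequence, path) -> None:
    """One node id per line, plus a ``<path>.json`` sidecar with the metadata."""
    with open(path, "w") as fh:
        for v in seq.nodes:
            fh.write(f"{v}\n")
    meta = {"dynamics": seq.dynamics, "lambda": seq.lam, "w": len(seq), "seed": seq.seed}
    with open(f"{path}.json", "w") as fh:
        json.dump(meta, fh, indent=2)


def load_sequence(path) -> WalkSequence:
    """Inverse of :func:`save_sequence`; the sidecar is optional."""
    with open(path) as fh:
        nodes = [_coerce(line.strip()) for line in fh if line.strip()]
    meta = {}
    try:
        with open(f"{path}.json") as fh:
            meta = json.load(fh)
    except FileNotFoundError:
        pass
    return WalkSequence(
        nodes,
        dynamics=meta.get("dynamics", "rw"),
        lam=meta.get("lambda", DEFAULT_LAMBDA),
        seed=meta.get("seed"),
    )


def _coerce(token: str):
    try:
        return int(token)
    except ValueError:
        return token
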