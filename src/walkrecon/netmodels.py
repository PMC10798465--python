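"""Network generators and edge-list I/O.

Four topology families are provided, all undirected and simple:

* Erdős–Rényi random graphs (constant linking probability),
* Barabási–Albert scale-free graphs (preferential attachment),
* Waxman geometric graphs (linking probability decaying exponentially with
  Euclidean distance in the unit square), and
* LFR-style modular graphs with a planted community partition, a power-law
  degree sequence and a tunable mixing parameter ``mu`` (the expected
  fraction of each node's edges that leave its community).

External networks can be read from whitespace-separated edge lists or GML.
Walk simulations require a connected graph, so helpers are provided to
extract the largest connected component and relabel nodes to ``0..n-1``.
"""

from __future__ import annotations

import logging
import math
from dataclasses import dataclass

import networkx as nx
import numpy as np
from scipy.optimize import brentq
from scipy.spatial.distance import pdist

logger = logging.getLogger(__name__)

#: diagonal of the unit square — the maximum possible node distance
UNIT_SQUARE_DIAGONAL = math.sqrt(2.0)


class GenerationError(RuntimeError):
    """A generator could not realize the requested configuration."""


class EdgeListParseError(ValueError):
    """An edge-list file contains a malformed line."""


@dataclass(frozen=True)
class LFRParams:
    """Parameters of the modular (LFR-style) benchmark generator.

    Attributes
    ----------
    n_communities : number of planted communities.
    degree_exponent : exponent of the power-law degree distribution
        (``p(k) ~ k**-degree_exponent``).
    community_size_exponent : exponent of the community-size distribution;
        0 denotes the degenerate (uniform) case of near-equal sizes.
    mu : mixing parameter in [0, 1] — expected fraction of each node's
        stubs wired outside its own community.  Small ``mu`` means
        well-separated communities.
    n_nodes : number of nodes before largest-component extraction.
    avg_degree : target mean degree of the drawn degree sequence.
    """

    n_communities: int = 5
    degree_exponent: float = 3.0
    community_size_exponent: float = 0.0
    mu: float = 0.05
    n_nodes: int = 5000
    avg_degree: float = 4.0

    def __post_init__(self) -> None:
        if not 0.0 <= self.mu <= 1.0:
            raise ValueError(f"mu must be in [0, 1], got {self.mu}")
        if self.n_communities < 1:
            raise ValueError("n_communities must be >= 1")
        if self.n_communities > self.n_nodes:
            raise ValueError("more communities than nodes")
        if self.degree_exponent <= 2.0:
            raise ValueError("degree_exponent must exceed 2 for a finite mean")
        if self.avg_degree <= 0:
            raise ValueError("avg_degree must be positive")


# ---------------------------------------------------------------------------
# generators


def generate_er(n: int, avg_degree: float, seed: int | None = None) -> nx.Graph:
    """Erdős–Rényi graph with linking probability ``avg_degree / (n - 1)``.

    Every pair of nodes is linked independently with the same probability,
    chosen so the expected mean degree equals ``avg_degree``.
    """
    if n < 2:
        raise ValueError("n must be >= 2")
    if not 0 <= avg_degree <= n - 1:
        raise ValueError(f"avg_degree must be in [0, {n - 1}], got {avg_degree}")
    p = avg_degree / (n - 1)
    return nx.fast_gnp_random_graph(n, p, seed=seed)


def generate_ba(n: int, m: int, seed: int | None = None) -> nx.Graph:
    """Barabási–Albert preferential-attachment graph.

    Each new node attaches ``m`` edges to existing nodes with probability
    proportional to their current degree, giving a power-law degree tail
    with exponent ~3 and mean degree approaching ``2 m``.
    """
    if m < 1 or m >= n:
        raise ValueError(f"require 1 <= m < n, got m={m}, n={n}")
    return nx.barabasi_albert_graph(n, m, seed=seed)


def waxman_link_probability(
    distance: float | np.ndarray,
    beta: float,
    alpha: float,
    l_max: float = UNIT_SQUARE_DIAGONAL,
):
    """Linking probability ``beta * exp(-d / (alpha * l_max))`` of the Waxman model."""
    return beta * np.exp(-np.asarray(distance, dtype=float) / (alpha * l_max))


def generate_waxman(
    n: int,
    avg_degree: float,
    seed: int | None = None,
    *,
    alpha: float = 0.1,
    max_iter: int = 12,
    tol: float = 0.05,
) -> nx.Graph:
    """Waxman geometric graph calibrated to a target mean degree.

    Nodes are placed uniformly in the unit square and each pair is linked
    with probability ``beta * exp(-d_ij / (alpha * l_max))``.  ``alpha``
    fixes the interaction range as a fraction of the domain diagonal;
    ``beta`` is calibrated iteratively so that the mean degree of the
    returned largest connected component lands within ``tol`` (relative)
    of ``avg_degree``.  Nodes are relabeled to ``0..n_lcc-1``.
    """
    if n < 2:
        raise ValueError("n must be >= 2")
    rng = np.random.default_rng(seed)
    pos = rng.random((n, 2))
    decay = np.exp(-pdist(pos) / (alpha * UNIT_SQUARE_DIAGONAL))
    iu, ju = np.triu_indices(n, k=1)
    target_m = n * avg_degree / 2.0
    beta = min(1.0, target_m / decay.sum())
    for _ in range(max_iter):
        mask = rng.random(decay.size) < beta * decay
        g = nx.Graph()
        g.add_nodes_from(range(n))
        g.add_edges_from(zip(iu[mask].tolist(), ju[mask].tolist()))
        lcc = largest_component(g)
        realized = 2.0 * lcc.number_of_edges() / lcc.number_of_nodes()
        if realized > 0 and abs(realized - avg_degree) <= tol * avg_degree:
            relabeled, _ = relabel_to_range(lcc)
            return relabeled
        # multiplicative correction toward the target; beta stays a probability
        scale = avg_degree / realized if realized > 0 else 2.0
        beta = min(1.0, beta * scale)
    raise GenerationError(
        f"Waxman calibration failed after {max_iter} iterations "
        f"(n={n}, avg_degree={avg_degree}, alpha={alpha})"
    )


def _rounded_pareto_mean(x_min: float, exponent: float, k_max: int = 1_000_000) -> float:
    """Mean of round(X) for X ~ continuous power law p(x) ~ x**-exponent, x >= x_min."""
    a = exponent - 1.0  # survival S(x) = (x_min / x) ** a
    k0 = max(1, int(math.floor(x_min)))
    ks = np.arange(k0, k_max + 1, dtype=float)
    lo = np.maximum(ks - 0.5, x_min)
    hi = ks + 0.5
    surv = lambda x: (x_min / x) ** a  # noqa: E731
    probs = surv(lo) - surv(hi)
    probs[probs < 0] = 0.0
    return float(np.sum(ks * probs))


def _community_sizes(params: LFRParams, rng: np.random.Generator) -> np.ndarray:
    """Community sizes: near-equal when the size exponent is 0, power law otherwise."""
    n, nc, t2 = params.n_nodes, params.n_communities, params.community_size_exponent
    if t2 == 0:
        base, rem = divmod(n, nc)
        return np.array([base + (1 if c < rem else 0) for c in range(nc)])
    if t2 <= 1:
        raise ValueError("community_size_exponent must be 0 (uniform) or > 1")
    raw = rng.pareto(t2 - 1.0, size=nc) + 1.0
    sizes = np.maximum(1, np.round(raw / raw.sum() * n)).astype(int)
    # fix rounding drift so sizes sum exactly to n
    drift = n - int(sizes.sum())
    order = np.argsort(sizes)[::-1]
    for i in range(abs(drift)):
        sizes[order[i % nc]] += int(math.copysign(1, drift))
    if sizes.min() < 1:
        raise GenerationError("infeasible community-size configuration")
    return sizes


def _pair_stubs(
    stubs: np.ndarray,
    rng: np.random.Generator,
    edges: set,
    community_of: np.ndarray | None = None,
    rounds: int = 5,
) -> None:
    """Pair stubs into simple edges (in place into ``edges``); unresolvable stubs drop.

    When ``community_of`` is given, pairs falling inside one community are
    rejected and re-shuffled (used for the inter-community stub pool).
    """
    pool = stubs
    for _ in range(rounds):
        if pool.size < 2:
            break
        pool = rng.permutation(pool)
        if pool.size % 2:
            pool = pool[:-1]
        left, right = pool[0::2], pool[1::2]
        rejected: list[int] = []
        for u, v in zip(left.tolist(), right.tolist()):
            if u == v:
                rejected += [u, v]
                continue
            if community_of is not None and community_of[u] == community_of[v]:
                rejected += [u, v]
                continue
            key = (u, v) if u < v else (v, u)
            if key in edges:
                rejected += [u, v]
                continue
            edges.add(key)
        if len(rejected) == pool.size:
            break  # no progress; give up on the remainder
        pool = np.array(rejected, dtype=np.intp)


def generate_lfr(
    params: LFRParams, seed: int | None = None
) -> tuple[nx.Graph, dict[int, int]]:
    """Modular benchmark graph with a planted partition.

    Degrees are drawn from a rounded continuous power law with exponent
    ``degree_exponent`` whose lower cutoff is solved numerically so the
    expected mean degree equals ``avg_degree``.  Each stub of node ``i`` is
    declared inter-community independently with probability ``mu``;
    intra-community stubs are matched within the node's community and
    inter-community stubs across communities, both by randomized stub
    matching with self-loops, multi-edges and (for the external pool)
    same-community pairs rejected.  The largest connected component is
    returned, relabeled to ``0..n_lcc-1``, together with the planted
    partition restricted to it.
    """
    rng = np.random.default_rng(seed)
    n, nc = params.n_nodes, params.n_communities
    sizes = _community_sizes(params, rng)
    community_of = np.repeat(np.arange(nc), sizes)

    # lower cutoff of the degree power law: solve E[round(X)] = avg_degree
    try:
        x_min = brentq(
            lambda x: _rounded_pareto_mean(x, params.degree_exponent) - params.avg_degree,
            0.6,
            params.avg_degree,
            xtol=1e-6,
        )
    except ValueError as exc:  # pragma: no cover - defensive
        raise GenerationError(f"cannot calibrate degree cutoff: {exc}") from exc
    a = params.degree_exponent - 1.0
    degrees = np.rint(x_min * (1.0 - rng.random(n)) ** (-1.0 / a)).astype(np.intp)
    degrees = np.clip(degrees, 1, n - 1)

    external = rng.binomial(degrees, params.mu).astype(np.intp)
    internal = degrees - external
    # a node cannot have more intra-community partners than community size - 1
    cap = sizes[community_of] - 1
    overflow = np.maximum(internal - cap, 0)
    internal -= overflow
    external += overflow

    edges: set[tuple[int, int]] = set()
    node_ids = np.arange(n, dtype=np.intp)
    for c in range(nc):
        members = node_ids[community_of == c]
        _pair_stubs(np.repeat(members, internal[members]), rng, edges)
    _pair_stubs(np.repeat(node_ids, external), rng, edges, community_of=community_of)

    g = nx.Graph()
    g.add_nodes_from(range(n))
    g.add_edges_from(edges)
    lcc = largest_component(g)
    relabeled, mapping = relabel_to_range(lcc)
    partition = {new: int(community_of[old]) for old, new in mapping.items()}
    return relabeled, partition


# ---------------------------------------------------------------------------
# normalization and I/O


def largest_component(net: nx.Graph) -> nx.Graph:
    """Induced subgraph on the largest connected component (labels preserved).

    Ties in component size are broken toward the component containing the
    smallest node id, so the result is deterministic.
    """
    if net.number_of_nodes() == 0:
        raise ValueError("empty network has no components")
    comp = max(nx.connected_components(net), key=lambda c: (len(c), -min(c)))
    return net.subgraph(comp).copy()


def relabel_to_range(net: nx.Graph) -> tuple[nx.Graph, dict]:
    """Relabel nodes to ``0..n-1`` (sorted original order); returns (graph, old->new)."""
    mapping = {v: i for i, v in enumerate(sorted(net.nodes()))}
    return nx.relabel_nodes(net, mapping, copy=True), mapping


def load_edgelist(path) -> nx.Graph:
    """Read an undirected simple graph from a whitespace-separated edge list.

    Lines starting with ``#`` and blank lines are skipped.  Tokens are
    interpreted as integers when possible.  Self-loops and duplicate edges
    are dropped with a logged count; a line without exactly two tokens
    raises :class:`EdgeListParseError` naming the line number.
    """
    g = nx.Graph()
    n_loops = n_dups = 0
    with open(path) as fh:
        for lineno, line in enumerate(fh, start=1):
            stripped = line.strip()
            if not stripped or stripped.startswith("#"):
                continue
            tokens = stripped.split()
            if len(tokens) != 2:
                raise EdgeListParseError(
                    f"{path}: line {lineno}: expected two tokens, got {len(tokens)}"
                )
            u, v = (_coerce_node(t) for t in tokens)
            if u == v:
                g.add_node(u)
                n_loops += 1
                continue
            if g.has_edge(u, v):
                n_dups += 1
                continue
            g.add_edge(u, v)
    if n_loops or n_dups:
        logger.warning(
            "%s: dropped %d self-loop(s) and %d duplicate edge(s)", path, n_loops, n_dups
        )
    return g


def _coerce_node(token: str):
    try:
        return int(token)
    except ValueError:
        return token


def write_edgelist(net: nx.Graph, path) -> None:
    """Write the canonicalized edge set, one ``u v`` pair per line, sorted."""
    pairs = sorted(tuple(sorted(e, key=_sort_key)) for e in net.edges())
    with open(path, "w") as fh:
        for u, v in pairs:
            fh.write(f"{u} {v}\n")


def _sort_key(x):
    return (0, x) if isinstance(x, int) else (1, str(x))


def load_gml(path) -> nx.Graph:
    """Read a GML file as an undirected simple graph (self-loops dropped)."""
    g = nx.Graph(nx.read_gml(path, label="id"))
    g.remove_edges_from(nx.selfloop_edges(g))
    return g
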