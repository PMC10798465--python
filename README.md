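# walkrecon

How well does an observer who only sees a *sequence* of visited nodes
perceive the network that generated it?  Many systems — click-streams, word
co-occurrences, navigation traces — expose a networked space only through
the trajectory of an agent walking on it.  `walkrecon` simulates that
situation end to end: it generates (or loads) an undirected network, walks
it with one of five single-agent dynamics, rebuilds the "perceived" network
from the node sequence alone, and quantifies how faithfully node-level
structure and community structure survive the process.

It is aimed at network scientists studying sampling bias: which walk
dynamics, at which sequence lengths, let you trust the degree, centrality
or community structure measured on a co-occurrence reconstruction.

## The model

An agent sits on node *i* of a connected, undirected, unweighted graph and
steps to neighbor *j ∈ Γᵢ* with probability proportional to a weight
*wᵢⱼ* that defines the dynamics:

| dynamics    | weight *wᵢⱼ*      | behavior                     |
|-------------|-------------------|------------------------------|
| `rw`        | 1                 | uniform neighbor choice      |
| `rwd`       | *kⱼ*              | prefers hubs                 |
| `rwid`      | *kⱼ*⁻¹            | avoids hubs                  |
| `tsaw-node` | e^(−λ·*fⱼ*)       | avoids visited nodes         |
| `tsaw-edge` | e^(−λ·*fᵢⱼ*)      | avoids traversed edges       |

where *kⱼ* is the degree of *j*, *fⱼ* counts previous visits to *j*,
*fᵢⱼ* counts previous traversals of edge {*i,j*} in either direction, and
λ = ln 2 by default (each revisit halves a candidate's weight; the "true"
self-avoiding walks discourage but never forbid revisits, so they cannot
get stuck).

The walk emits the sequence of *w* visited nodes.  The **reconstruction**
links two nodes whenever they are adjacent in the sequence — the standard
co-occurrence rule — yielding a connected, simple subgraph of the original.
Recovery is then scored by:

* **Pearson (C_p) and Spearman (C_s) correlations** of a node metric
  (degree, clustering coefficient, closeness, betweenness, eccentricity,
  coreness) between reconstruction and original, over exactly the
  discovered nodes, each paired with itself;
* **NMI and ARI** between the Leiden partition of the reconstruction and a
  reference partition (planted for the modular benchmark, Leiden on the
  original otherwise);
* the **knowledge fraction** — the share of the original's nodes
  discovered — which turns length-dependence into coverage-dependence.

Built-in generators cover Erdős–Rényi, Barabási–Albert, Waxman geometric
and LFR-style modular networks (default scale: N = 5000 nodes, mean degree
⟨k⟩ = 4; modular benchmark with 5 planted communities, degree exponent 3,
near-equal community sizes and mixing parameter μ).

## Worked example

```python
import walkrecon as wr

net, planted = wr.generate_lfr(wr.LFRParams(mu=0.05, n_nodes=5000), seed=7)
deg = wr.compute_property(net, "degree")

for dynamics in ("rwd", "rwid"):
    seq = wr.run_walk(net, dynamics, w=5000, seed=1)      # 5000 visited nodes
    recon = wr.reconstruct(seq)
    res = wr.matched_correlation(deg, wr.compute_property(recon.graph, "degree"))
    kf = wr.knowledge_fraction(seq, net.number_of_nodes())
    print(f"{dynamics}: C_p={res.pearson:.2f}  C_s={res.spearman:.2f}  "
          f"coverage={kf:.2f}  ({res.n_matched} nodes)")
```

```
rwd: C_p=0.93  C_s=0.63  coverage=0.26  (1305 nodes)
rwid: C_p=0.25  C_s=0.42  coverage=0.34  (1687 nodes)
```

The hub-preferring walk (`rwd`) keeps revisiting the same high-degree
nodes, so it discovers only 26% of the network — but the degrees of the
nodes it does see are almost correctly perceived (C_p = 0.93).  The
hub-avoiding walk (`rwid`) covers more nodes yet badly distorts their
perceived degrees (C_p = 0.25), because hubs are reached through only a
few of their many edges.

The same experiment over a whole grid, from the shell:

```bash
walkrecon sweep --model lfr --mu 0.05 --dynamics rwd --dynamics rwid \
    --walk-lengths 100,1000,5000,50000 --reps 20 --seed 1 --out results/
```

writes one tidy CSV per network (per-repetition rows plus mean/sd
aggregates) and a JSON manifest.  `walkrecon coverage-sweep` evaluates
nested prefixes of one long walk per repetition, pairing each correlation
with the knowledge fraction reached.  `walkrecon generate`, `walk` and
`reconstruct` expose the individual stages on edge-list files.

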