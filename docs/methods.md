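# Methods

This note records the modeling choices behind `walkrecon`: what each stage
assumes, which parameters matter, how the generators are constructed, and
where the design was genuinely open.

## Walk dynamics

All five dynamics are single-agent Markov (or history-dependent) walks on a
connected, undirected, unweighted, simple graph.  From node *i* the next
node is drawn from the neighbors *Γᵢ* with probability proportional to:

* `rw` — 1 (uniform);
* `rwd` — *kⱼ* (degree-biased);
* `rwid` — *kⱼ*⁻¹ (inverse-degree-biased);
* `tsaw-node` — exp(−λ·*fⱼ*), where *fⱼ* is the number of times *j* has
  been visited so far;
* `tsaw-edge` — exp(−λ·*fᵢⱼ*), where *fᵢⱼ* counts traversals of the
  undirected edge {*i,j*} in either direction.

Conventions that the definitions leave open, fixed here once:

* **Walk length** *w* counts *visited nodes* (sequence length), so a walk
  of length *w* makes *w − 1* transitions.
* **Start node**: drawn uniformly at random per repetition (no natural
  distribution is implied by the problem; uniform is the neutral choice),
  and its visit count is incremented *before* the first transition — the
  agent has been there.
* **λ = ln 2** by default: each past visit (or traversal) halves a
  candidate's weight.  λ = 0 reduces both TSAW variants exactly to the
  uniform walk, which is tested.  The avoidance is "true" self-avoidance:
  weights decay but never vanish, so the walk cannot trap itself and
  visit/traversal counts accumulate over the whole walk.
* On a *k*-regular graph with no history, `rw`, `rwd` and `rwid` are
  step-for-step identical (uniform); also tested.

The sampling loop uses cumulative-sum inversion over the (at most *k*)
neighbor weights, giving O(k) per step; a 50 000-step walk on the
5000-node benchmarks runs in well under a second.  One independent
`numpy` generator is created per walk from its own seed, so repetitions
are reproducible and order-independent.

## Reconstruction and knowledge

The perceived network links two nodes whenever they are adjacent in the
sequence (co-occurrence with window 1).  The first symbol contributes a
node and no edge; repeated adjacencies collapse — the reconstruction is
unweighted because all downstream metrics are defined for unweighted
graphs.  A walk trace is connected by construction, so every
reconstruction is a valid input for the metric stage.  The *knowledge
fraction* is the number of distinct visited nodes divided by the node
count of the (largest-component) original.

## Networks

All generated networks are reduced to their largest connected component
and relabeled to 0..n−1 before walking (a walk cannot leave a component),
with the original-label map retained for external edge lists.  Defaults:
N = 5000 nodes, target mean degree ⟨k⟩ = 4.

* **Erdős–Rényi**: constant linking probability π = ⟨k⟩/(N−1).
* **Barabási–Albert**: preferential attachment with m = 2 edges per new
  node, giving ⟨k⟩ → 4; attachment probability proportional to the
  *existing* node's degree.
* **Waxman**: nodes uniform in the unit square; pair {i,j} linked with
  probability β·exp(−dᵢⱼ/(α·L)), L = √2 the domain diagonal.  α = 0.1
  fixes the interaction range (only ⟨k⟩ is externally constrained); β is
  calibrated — analytic first guess β = M_target/Σᵢⱼ exp(−dᵢⱼ/(αL)),
  then multiplicative correction on the realized largest-component mean
  degree — until ⟨k⟩ lands within 5% of target (bounded iterations,
  error on failure).
* **LFR-style modular benchmark**: n_C = 5 communities, degree exponent
  t₁ = 3, community-size exponent t₂ = 0 interpreted as the degenerate
  (uniform) size distribution — near-equal sizes N/n_C with the remainder
  spread; t₂ > 1 falls back to a normalized power-law size draw.  Degrees
  are a rounded continuous power law whose lower cutoff is solved
  numerically (Brent) so the expected rounded mean equals ⟨k⟩ — for
  t₁ = 3, ⟨k⟩ = 4 this gives a minimum degree of 2.  Each stub is
  declared inter-community independently with probability μ (so the
  expected cross-community edge fraction is μ, verified against counts);
  intra-community stubs are matched within communities and
  inter-community stubs across communities by randomized stub matching
  with rejection of self-loops, multi-edges and (externally)
  same-community pairs, re-shuffling rejects for up to five rounds.
  Unresolvable stubs drop, costing ~2–3% of edges; the realized mean
  degree stays within 5% of target.  The planted partition is returned
  restricted to the largest component.

## Metrics and scoring

Degree, clustering (2·triangles/k(k−1), 0 for k < 2) and coreness come
from networkx; closeness, eccentricity and exact Brandes betweenness from
igraph's C implementations (exact, not sampled; betweenness on a
5000-node, ⟨k⟩=4 graph takes ~2 s).  Normalizations (betweenness by the
pair count, closeness by n−1) are cosmetic: Pearson is affine-invariant
and Spearman monotone-invariant, which the tests assert.

`matched_correlation` pairs each reconstructed node with itself in the
original — metrics are computed *on* the reconstruction for one vector
and *on* the original for the other — and reports Pearson and Spearman
together.  A correlation is *undefined* when fewer than 3 nodes are
matched or either vector is constant (e.g. clustering in a tree-like
sample); undefined cells carry NaN, are logged, and are excluded from
aggregates rather than imputed (imputing 0 would bias means arbitrarily).

Communities: Leiden optimizing modularity (RBConfiguration at resolution
1.0), seeded, library-default iteration budget.  The reference partition
is the planted one for the modular benchmark and Leiden on the original
otherwise, computed once per network.  NMI uses arithmetic-mean
normalization (the most common default; recorded in output metadata) and
ARI is chance-corrected; both are label-permutation invariant and are
evaluated on the discovered-node subset only, since the reconstruction
has no labels for unseen nodes.

## Experiment designs

* *Recovery vs walk length*: independent walks per (network, dynamics,
  w ∈ {100, 200, 400, 500, 600, 800, 1000, 2000, 5000, 20000, 50000},
  repetition), 20 repetitions by default.
* *Recovery vs knowledge*: one long walk per (network, dynamics,
  repetition) evaluated at nested prefixes of the same grid — each prefix
  supplies both the correlation and the knowledge fraction; a
  `fresh_walks` flag switches to independent walks per length.  Both
  per-repetition values and aggregate means are emitted, so either
  averaging order (coverage first or correlation first) can be read from
  the table.
* *Coverage stopping*: `run_until_coverage` extends a walk to the first
  crossing of a target knowledge fraction, with a step cap (default
  400·N) that flags, rather than hides, unreached targets.

Every cell's seed is `crc32(global_seed | network | dynamics | w | rep)`
(< 2³¹), so any record is re-runnable in isolation and a repeated run of
the same configuration writes byte-identical CSVs.

## What the synthetic benchmarks do and do not show

The generators reproduce the *scale* (N = 5000, ⟨k⟩ = 4), heavy-tailed
degrees (BA, LFR), geometry (Waxman) and mesoscale structure (LFR with
μ ∈ {0.05, 0.2, 0.8}) of the study conditions.  They do not reproduce
degree–degree correlations, clustering levels, or the noise and
measurement artifacts of real co-occurrence data; conclusions about which
dynamics best recover a property transfer to real networks only insofar
as those networks resemble the models (heavy-tailed social networks
behave like BA; geographical infrastructure like Waxman).

Two quantitative caveats at this sparsity:

* At ⟨k⟩ = 4 the modularity landscape is fragile: Leiden splits the five
  1000-node planted communities into ~20–40 modules (the resolution
  limit), capping Leiden-vs-planted NMI at ≈0.42–0.45 on the μ = 0.2
  benchmark even for a perfect reconstruction, and randomly deleting 15%
  of edges drops it to ≈0.32.  Community-recovery scores for sparsifying
  dynamics (RWID, TSAW-node) are therefore ceiling-limited by the
  benchmark itself, not only by the walk.  The same ceiling appears with
  networkx's canonical LFR implementation, so it is a property of the
  regime, not of this generator variant.
* Degree-recovery correlations for short walks depend on the minimum
  degree of the drawn sequence (here 2); benchmarks with a different
  cutoff shift the low-coverage end of the curves.

## Numerical choices and degenerate inputs

* Component tie-break: the largest component is chosen by (size, smallest
  node id), so extraction is deterministic.
* Correlations guard zero-variance vectors before calling scipy
  (`pearsonr` would warn and return NaN anyway); Spearman uses
  average-rank ties.
* Walks on a 1-node graph, length-1 walks, empty sequences, empty graphs
  and disconnected inputs raise explicit errors at the boundary they
  violate rather than propagating NaNs.
* Edge-list parsing drops self-loops and duplicate edges with a logged
  count and reports malformed lines by number.

## Problem sizes in the shipped benchmarks

The acceptance script and the full-scale tests use the study conditions
directly: N = 5000 networks, 20 repetitions for the degree-recovery
statistics (w = 5000 and w = 50 000), 5 dynamics × 10 repetitions for
community recovery, and 10 half-coverage repetitions for the betweenness
comparison — about half a minute end to end on one CPU, dominated by the
w = 50 000 walks and the exact betweenness of the BA network.  Unit tests
use graphs of 10–2000 nodes with exhaustive-enumeration oracles
(all-shortest-path betweenness, flood-fill components, walk enumeration
on K₁₀) that are only feasible at that scale.

## Known limitations

* Undirected, unweighted, single-agent only; no teleportation, Lévy
  flights or interacting walkers.
* Reconstruction uses adjacency (window 1) only — no wider co-occurrence
  windows, no edge weights from repeat counts.
* The LFR variant targets the degenerate uniform community-size case;
  sizes from a power law are supported but lightly exercised.
* Coreness, like all metrics, is computed on every network type; the
  sweep configuration can exclude metrics per network where they are not
  of interest.
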