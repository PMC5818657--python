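# Methods

This note records the model, the numerical choices, and the limits of what
the test suite demonstrates.

## Quality function and optimizer

The multiresolution quality function is the resolution-parameterized
modularity `Q(g, γ) = Σ_ij (A_ij − γP_ij) δ(g_i, g_j)`, summed over ordered
node pairs *including* `i = j`. The diagonal adds a partition-independent
constant whenever self-loops are absent, so optimization is unaffected; we
keep it in reported values so that `Q` of the single-cluster partition under
the configuration null at γ = 1 is exactly 0. For networks the null is
`P_ij = k_i k_j / 2m`, held in rank-one form and never materialized during
optimization; for consensus matrices the null is an explicit dense matrix
and γ is fixed to 1.

The optimizer is a two-phase Louvain with *weighted random moves*: each
sweep visits nodes in a freshly drawn random order, and a node moves to a
community sampled among the strictly improving candidates with probability
proportional to the gain. Candidate targets are all nonempty communities
plus one empty community in the dense case, and the communities adjacent to
the node plus one empty community in the sparse case (a move to a
non-adjacent nonempty community is always dominated by the move to an empty
one, so the restriction prunes only near-zero-probability candidates).
Phase 2 aggregates communities into supernodes; phases repeat until no
improvement, and the whole algorithm is restarted from its own output until
the quality stops increasing. A move or restart counts as improving only if
the gain exceeds `1e-10` of the total interaction weight. One explicit seed
drives each top-level call; ensemble members and recursion branches receive
independently derived seeds, making every pipeline a pure function of its
seed. The sweep kernels are compiled with numba; local optimality of the
returned partitions under single-node moves is asserted directly in the
tests, and on 8-node instances the optimizer reaches the exhaustively
enumerated global optimum in ≥ 95 of 100 seeds.

## Resolution range and event sampling

`γ_max = max_{i≠j} A_ij/P_ij` is exact. `γ_min` is estimated iteratively:
partitions are sampled at γ = 1 (10 per iteration by default); since `Q` is
linear in γ for fixed `g`, each non-trivial partition yields the smallest γ
at which it beats the single cluster, the minimum over the sample updates
the estimate, and sampling moves to `γ_min(1 − ε)` with relative
`ε = 1e-3` until only the trivial partition appears. Two boundary cases are
handled explicitly: if the initial sample is already all-trivial the search
first moves geometrically toward `γ_max` (a single clique reports
`γ_min = γ_max`), and a disconnected network reports `γ_min = 0` because its
component partition beats the trivial one at every positive γ.

Event sampling tabulates the distinct critical ratios `A_ij/P_ij` (all
non-adjacent pairs collapse into one event at 0, duplicate ratios into one
event), with prefix sums of `A` and `P` masses over the sorted events. β is
then piecewise smooth, continuous and nondecreasing on `[0, γ_max]`, and its
inverse is evaluated by binary search over event β values followed by the
per-interval closed form. The β grid includes both endpoints
`β(γ_min)` and 1.

## Ensemble null models and consensus

Per-partition co-classification probabilities are the permutation model
`p(t) = Σ_c (s_c/n)((s_c−1)/(n−1))` (pair-independent) and the local
permutation model `p_ij(t) = (s_{g_i(t)}−1)/(n−1)` (depends on `i` only;
the default, because the global model splits off spurious singletons).
Null mean and variance follow from the independent-Bernoulli form. The
significance matrix is the lower α-quantile of the null co-classification
distribution, symmetrized as `min(q_ij, q_ji)` so that the larger of the two
pair CDFs equals α. The default tail is the normal approximation
(`q = μ + σ z_α`, clipped to [0, 1]; a degenerate σ = 0 pair gets `q = μ`);
a Monte-Carlo tail simulates the Bernoulli scheme and takes the largest
support value whose empirical CDF is ≤ α — conservative, since a discrete
CDF generically never equals α exactly.

The iterative consensus step regenerates an ensemble of the *same* size by
optimizing `Q_C` (so the null granularity `1/|g|` is stable across
iterations), recomputes C and the null from the working ensemble, and stops
when all partitions are identical. C is never thresholded. The recursion
restricts the *original* input ensemble to each cluster's nodes, with labels
re-canonicalized and null probabilities recomputed at the reduced n; an
α-level consensus that returns a single cluster terminates the branch.

## Hierarchy, strengths, and cuts

Every tree vertex carries ⟨C⟩, the mean of the original ensemble's
co-classification matrix over its distinct member pairs (diagonal excluded;
a singleton has ⟨C⟩ = 1 by convention). The strength at which a split was
created is the minimum of its children's strengths. A cut at threshold `t`
performs exactly the splits created at strength above `t`, with the root's
split always performed: threshold 1 gives the coarsest partition below the
root, threshold 0 the leaf partition, and cuts are nested in `t`. Strengths
need not decrease monotonically along a branch, so no ultrametric repair is
attempted — the enumerated cuts simply follow the split-creation rule. Trees
serialize to JSON (canonical) and annotated Newick, with vertex strengths as
labels and `1 − ⟨C⟩` branch heights.

## Hierarchical benchmark

The generator plants a two-level hierarchy: each split draws its child count
from Poisson(4) resampled until ≥ 2, child proportions from a symmetric
Dirichlet(1.5), and assigns nodes multinomially (an accidentally empty child
is dropped). The conditional-Poisson child-count mean is
`(λ − λe^{−λ})/(1 − e^{−λ} − λe^{−λ}) ≈ 4.32` at λ = 4 and is verified
against simulation. Degrees are drawn from a discrete power law with
exponent 2 on [5, 70] by inverse CDF. `m = round(Σk/2)` edges are assigned
categories with probabilities `(p₀, p₁, p₂)` — global, within-level-1,
within-level-2 — and endpoints are drawn degree-proportionally, the second
endpoint within the first's block for constrained categories. Self-loops
and duplicates are rejected and redrawn (100 attempts, then the edge is
dropped and counted as a deficit), so realizations are always simple graphs.
Stub sampling approximates the degree sequence rather than reproducing it
exactly; the planted partitions, not the exact degrees, are what the
evaluation uses.

What the generator does *not* emulate: degree–community correlations,
weighted or directed edges, overlapping or deeper-than-two hierarchies, and
the LFR benchmark family. Passing the recovery tests therefore shows the
pipeline recovers clean planted block hierarchies at realistic degree
heterogeneity, not that it handles every real-data pathology.

## Problem sizes in the tests

The end-to-end studies run at n = 1000 with 250-partition ensembles and 10
benchmark seeds (hierarchy recovery), 20 seeds of ER(100, 0.05) with
250-partition ensembles (random-network behavior), and a 1000-node ER check
at fixed γ = 1. Enumeration oracles use 8–10 node instances; Monte-Carlo
oracles use 10⁴–10⁵ replicates with 3-standard-error bands.

## Known limitations and observed behavior

* **Significance is relative to the independence null.** The
  Poisson–Binomial null treats ensemble members as independent random
  labelings with fixed cluster sizes. Any structure that an optimizer finds
  *reproducibly* is therefore significant once the ensemble is large
  enough — detection kicks in roughly when `|g| ≳ z_α²(1−p)/p` for
  within-cluster null probability `p`. This reproduces the
  minimum-ensemble-size resolution limit (a chain of twenty 5-cliques is
  invisible to 10-partition ensembles and resolved by 250), but it also
  means *small* random graphs are split: ER(100, 0.05) has density pockets
  that independent optimizer runs rediscover (pairwise AMI ≈ 0.4–0.5 between
  runs, for this package's optimizer and for networkx's Louvain alike), and
  those splits pass the test at α = 0.05. At n = 1000 the degeneracy of the
  modularity landscape takes over (pairwise AMI ≈ 0.05–0.2) and the
  procedure correctly returns a single cluster on random graphs. The
  random-graph safety property is thus a large-n property, not a guarantee
  at every size.
* On fixtures whose clusters are large relative to n (two 5-cliques,
  n = 10), even 10 partitions suffice to split significantly — the
  small-ensemble protection only exists when clusters are small relative to
  the network.
* The hierarchy tends to be conservative and may interpose spurious
  intermediate levels between the planted ones; tests compare against the
  best dendrogram cut rather than asserting level counts.
* Dense O(n²) co-classification storage limits practical network size to
  roughly 10⁴ nodes; the `C = GGᵀ/|g|` factorization is available via the
  ensemble's label matrix but is not exploited by the clustering step.
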