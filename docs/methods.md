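# Methods

This note documents the model, the numerical and design choices, and the
benchmark conditions that back the package's acceptance suite
(`tests/test_acceptance.py`) and reporting script (`scripts/acceptance.py`).

## 1. Succinct adjacency

### Edge encoding

An edge *(a, b)* of a graph with |V| nodes is encoded as the single integer
φ<sub>k</sub>(a, b) = a·2<sup>k</sup> + b with k = max(1, ⌈log₂ |V|⌉). The
codes of all edges out of node *a* fill the contiguous range
[φ<sub>k</sub>(a, 0), φ<sub>k</sub>(a + 1, 0)), so on the sorted code set:

- `degree(a)` = `rank(φ_k(a+1, 0))` − `rank(φ_k(a, 0))`, and
- the *i*-th neighbor of *a* is `select(rank(φ_k(a, 0)) + i) mod 2^k`.

Codes are kept in a single 64-bit word, which caps |V| at 2<sup>32</sup>;
the constructor rejects larger graphs explicitly rather than silently
spilling into multi-word arithmetic.

### Elias–Fano layout

For n sorted values in a universe of size u, each value is split into
ℓ = ⌊log₂(u/n)⌋ low bits (stored verbatim in a packed array) and a high
part whose successive gaps are stored in inverted-unary code — equivalently,
a bit vector with a one at position h<sub>i</sub> + i. Total payload is at
most 2n + n⌈log₂(u/n)⌉ bits; `tests/test_eliasfano.py` and the acceptance
sweep verify the bound on hundreds of random sets (worst observed ratio
0.999).

Conventions: `rank(m)` counts elements **strictly below** m, and `select(i)`
is **0-based**. `rank` is answered by locating the high-part bucket with a
select-zero and scanning its low bits; `select(i)` reads the (i+1)-th one of
the high bits and the i-th packed low field.

### Position indexes

`select` scans the high bit vector from the nearest *quantized index*
entry: the positions of every 1024th one and every 1024th zero are stored
as 32-bit integers. That costs 32/1024 = 3.125 % of the indexed bits and
bounds the expected scan to 1024 bits / 64-bit words / 2 ≈ 16 words (uniform
query positions land half a quantum from the previous entry on average).
Both constants are recomputed, not hard-coded, in
`efgraph.experiments.analytic_constants`.

## 2. Second-order walks

### Bias decomposition

The node2vec transition mass from v to a neighbor x, given previous node t,
is classically written in terms of the BFS distance d(t, x):
α = 1/p at distance 0, 1 at distance 1, 1/q at distance 2. The package never
computes distances; it uses the algebraically identical factorization

π<sub>vx</sub> = β<sub>q</sub>(t, x) · γ<sub>p</sub>(t, x) · w<sub>vx</sub>

with β = 1 if x ∈ N(t) ∪ {t} and 1/q otherwise (a sorted-set membership
probe), and γ = 1/p iff x = t (a binary search). Equivalence with an
independent BFS-distance oracle is asserted exactly (error 0.0) over random
graphs and a (p, q) grid in the acceptance suite, for all eight dispatch
specializations {p = 1, p ≠ 1} × {q = 1, q ≠ 1} × {unweighted, weighted}.

### Sampling

Steps are drawn from the running cumulative sum of unnormalized masses:
one uniform draw, then the index is found by linear scan when the candidate
list is shorter than 128 and by binary search otherwise. 128 is the point
where a branch-free sequential scan stops beating binary search on typical
cache lines; the two strategies are asserted to give identical indices.

### SUSS approximation

For a node of degree d > d_T, the neighbor index range [0, d) is divided
into d_T contiguous buckets of ⌊d/d_T⌋ positions (the last absorbs the
remainder) and one uniform position is drawn per bucket — a sorted, unique
sample in Θ(d_T), obtained before any weight or bias is touched. The default
study threshold is d_T = 10.

Two properties are verified: (i) with a single bucket the draw is uniform
over the range — 10⁶ draws over [0, 10000] pass a chi-square test
(p ≈ 0.5); (ii) downstream parity — the full link-prediction pipeline run
with exact walks and with d_T = 10 on the same 2×60-block SBM is
statistically indistinguishable across 10 holdouts (Wilcoxon rank-sum
p > 0.05 on AUROC, AUPRC, accuracy, and F1).

*Caveat:* SUSS draws are not independent — at most one candidate per bucket,
so consecutive neighbor positions are anti-correlated and can never be
co-sampled from the same bucket. On neighbor lists with strong positional
structure (e.g. IDs assigned by community) this is a real bias; the parity
experiment shows it is immaterial for embedding training on the graphs
studied here.

### Random-number streams

Each walk gets an independent generator derived from
`SeedSequence((seed, iteration, source))` (numpy PCG64). The documented
intent — one splittable, seedable stream per walk so batches are
reproducible and embarrassingly parallel — is kept, while a vetted generator
replaces a hand-rolled xorshift variant.

## 3. Embedding

SkipGram and CBOW are trained with negative sampling in vectorized
mini-batches (default 512). Gradients are computed against a stale snapshot
of the weights and scatter-added (`np.add.at`) without locking; with one
worker and a fixed seed training is bitwise reproducible, and the
synchronization-free contract matches asynchronous SGD semantics. Input
weights start uniform in ±0.5/dim, output weights at zero; the learning rate
(0.025) decays linearly to 10⁻⁴ of its start. Negatives are drawn
degree-proportionally by decoding the source endpoint of a uniform edge
position (one `select` on the succinct backend); a negative colliding with
the center is resampled once, then masked out. Divergence (NaN/inf weights)
raises rather than returning garbage.

Defaults (32 dimensions, window 3, 3 epochs, 5 negatives) are word2vec-scale
settings that converge within seconds on the desk-scale benchmarks while
leaving clear headroom.

## 4. Evaluation

### Connected Monte Carlo holdouts

A uniformly shuffled Kruskal pass builds a random spanning forest, which is
pinned to the training side; test positives are drawn only from non-forest
edges. Consequently the training graph keeps exactly the component structure
of the full graph and every node remains embeddable. The acceptance suite
confirms zero component violations and zero train/test leaks across 30
holdouts over three generator families.

### Negative edges

Test negatives are sampled (uniform or degree-proportional endpoints,
self-pairs excluded, undirected pairs canonicalized) and by default are
**not** checked against the edge set — on sparse genome-scale graphs the
false-negative rate of unchecked sampling is negligible. That premise fails
on small dense benchmarks: at ~40 % density, ~40 % of "negatives" are true
edges, which corrupts both training signal and test labels. The splitter and
pipeline therefore expose `exclude_existing_negatives`, which the benchmark
conditions below enable; the library default remains unchecked.

### Metrics and baseline

AUROC/AUPRC (undefined, reported as `None`, when only one class is present)
plus accuracy, balanced accuracy, F1, precision, recall, miss rate,
markedness, diagnostic odds ratio (with an explicit infinity flag), and MCC,
thresholded at 0.5. The baseline classifier is a single-layer logistic
scorer trained with the Nadam (Nesterov-accelerated Adam) update rule; tests
check it against scikit-learn's logistic regression on separable data.

## 5. Benchmark conditions and the attainable-AUROC analysis

Problem sizes are the package's own choice, set once so the whole acceptance
run finishes in about a minute on one core: oracle sweeps use 1000 random
sets / 30 random graphs, uniformity uses 10⁶ draws, and the evaluation
experiments use two-block SBMs of 120–200 nodes with 3–10 holdouts.

The **recovery benchmark** uses a 2×100 SBM with p_in = 0.8,
p_out = 0.002. The regime is chosen from a feasibility argument, not tuned:
in an SBM, edge indicators are conditionally independent given block
memberships, so even a predictor with perfect knowledge of the blocks (and
of the training edges) faces test positives and negatives whose block
configuration distributions overlap. On a *sparse* balanced 2-block SBM
(e.g. p_in = 0.2) roughly half of sampled negatives are within-block pairs,
and the resulting overlap caps AUROC at ~0.72–0.83 — no implementation can
beat the generator there. At p_in = 0.8 with near-zero cross-block wiring,
and with true edges excluded from the negatives, the optimal block-aware
predictor reaches AUROC ≈ 0.92; the pipeline lands essentially on that
ceiling (measured 0.914–0.918), which is the strongest statement the
generator admits.

The **parity benchmark** (exact vs d_T = 10) deliberately uses a sparser
2×60 SBM (p_in = 0.2, p_out = 0.02, median degree ≈ 13) so a meaningful
fraction of nodes actually exceeds the threshold and the approximation is
exercised, while holdout metrics retain enough variance for a rank-sum test
to be informative.

### What the generators emulate — and don't

SBMs stand in for modular interactomes, preferential attachment for
heavy-tailed degree laws, hub graphs for the extreme-degree nodes that
motivate SUSS. They do *not* reproduce degree-correlated communities,
overlapping modules, or edge-weight structure of real biological networks;
absolute metric values here calibrate the machinery, they do not forecast
performance on real data.

## 6. Limitations

- Single-word edge codes cap graphs at 2³² nodes.
- Walk generation is pure Python/numpy per step; throughput is desk-scale
  (the design favors auditability over raw speed).
- SUSS positional anti-correlation (see above).
- The Nadam perceptron is linear in the edge features; with Hadamard
  features it cannot represent non-monotone interactions, which is part of
  why the sparse-SBM ceiling discussed in §5 binds.
- CBOW is provided and tested for convergence but the evaluation pipeline
  uses SkipGram only.
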