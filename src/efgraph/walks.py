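"""First- and second-order (node2vec-style) random walks.

The second-order transition mass from ``v`` to a neighbor ``x``, given the
previous node ``t``, is ``pi_vx = beta_q(t, x) * gamma_p(t, x) * w_vx`` where
the in-out bias ``beta_q`` is ``1`` when ``x`` is adjacent to ``t`` (``t``
itself included) and ``1/q`` otherwise, and the return bias ``gamma_p`` is
``1/p`` when ``x == t`` and ``1`` otherwise.  This factorization is equivalent
to the classic distance-based search bias (``1/p`` at distance 0, ``1`` at
distance 1, ``1/q`` at distance 2) but needs only a sorted set difference
``N(v) \\ N(t)`` and a membership probe instead of BFS distances.

Sampling is done on the fly: unnormalized masses, cumulative sum, one uniform
draw, then index identification by linear scan for short candidate lists and
binary search for long ones.  No alias tables are ever built.

Nodes whose degree exceeds an optional threshold ``d_T`` are handled by the
approximated walker: SUSS (sorted unique sub-sampling) draws one neighbor
position per contiguous bucket of the neighbor range, yielding ``d_T`` sorted
unique candidates in Theta(d_T) before any bias or weight is computed.
"""

from __future__ import annotations

from dataclasses import dataclass, field

import numpy as np

from .graph import EncodedGraph

__all__ = [
    "WalkParams",
    "TransitionDistribution",
    "WalkBatch",
    "sorted_set_difference",
    "second_order_masses",
    "approximated_second_order_masses",
    "sample_from_cumsum",
    "first_order_walk",
    "second_order_walk",
    "dispatch_specialization",
    "suss_sample",
    "generate_walks",
    "walk_rng",
    "write_walks",
]

#: below this many candidates a linear scan beats binary search
LINEAR_SCAN_THRESHOLD = 128


@dataclass
class WalkParams:
    """Parameters of a (possibly approximated) biased random walk.

    ``p`` is the return parameter (small p pulls the walk back), ``q`` the
    in-out parameter (small q pushes it outward, DFS-like); ``degree_threshold``
    enables the approximated walker for nodes of larger degree.
    """

    p: float = 1.0
    q: float = 1.0
    walk_length: int = 80
    iterations: int = 10
    degree_threshold: int | None = None
    seed: int = 0
    linear_scan_threshold: int = LINEAR_SCAN_THRESHOLD

    def __post_init__(self):
        if not (np.isfinite(self.p) and self.p > 0):
            raise ValueError("p must be finite and positive")
        if not (np.isfinite(self.q) and self.q > 0):
            raise ValueError("q must be finite and positive")
        if self.walk_length < 1:
            raise ValueError("walk_length must be >= 1")
        if self.iterations < 1:
            raise ValueError("iterations must be >= 1")
        if self.degree_threshold is not None and self.degree_threshold < 2:
            raise ValueError("degree_threshold must be >= 2 when enabled")


@dataclass
class TransitionDistribution:
    """Unnormalized step distribution over sorted candidate destinations."""

    candidates: np.ndarray
    masses: np.ndarray
    cumulative: np.ndarray = field(init=False)

    def __post_init__(self):
        self.cumulative = np.cumsum(self.masses)

    @property
    def total(self) -> float:
        return float(self.cumulative[-1]) if len(self.cumulative) else 0.0

    def normalized(self) -> np.ndarray:
        return self.masses / self.masses.sum()


@dataclass
class WalkBatch:
    """One walk per (iteration, source): ragged rows of node IDs."""

    walks: list[np.ndarray]
    sources: np.ndarray
    iterations: int

    def __len__(self) -> int:
        return len(self.walks)


def walk_rng(seed: int, iteration: int, source: int) -> np.random.Generator:
    """Independent RNG stream for one walk.

    Streams are split with :class:`numpy.random.SeedSequence` keyed by
    ``(seed, iteration, source)``, so every walk is reproducible in isolation
    and walks can be generated in parallel with no shared state.
    """
    return np.random.default_rng(
        np.random.SeedSequence((int(seed), int(iteration), int(source))))


def sorted_set_difference(a: np.ndarray, b: np.ndarray) -> np.ndarray:
    """A \\ B for strictly increasing integer arrays, single merge pass."""
    a = np.asarray(a)
    b = np.asarray(b)
    if a.size and np.any(a[1:] <= a[:-1]):
        raise ValueError("first input is not strictly increasing")
    if b.size and np.any(b[1:] <= b[:-1]):
        raise ValueError("second input is not strictly increasing")
    if not b.size:
        return a.copy()
    idx = np.searchsorted(b, a)
    idx[idx == b.size] = b.size - 1
    return a[b[idx] != a]


def _member_sorted(values: np.ndarray, sorted_set: np.ndarray) -> np.ndarray:
    """Boolean membership of ``values`` in a sorted array."""
    if not sorted_set.size:
        return np.zeros(values.shape, dtype=bool)
    idx = np.searchsorted(sorted_set, values)
    idx[idx == sorted_set.size] = sorted_set.size - 1
    return sorted_set[idx] == values


def dispatch_specialization(params: WalkParams, weighted: bool) -> str:
    """Tag of the specialized sampler for (p, q, weightedness).

    Eight variants cover the cross product {p=1, p!=1} x {q=1, q!=1} x
    {unweighted, weighted}; each skips the biases that vanish.
    """
    return "-".join([
        "p1" if params.p == 1.0 else "p",
        "q1" if params.q == 1.0 else "q",
        "weighted" if weighted else "unweighted",
    ])


def _masses_for(graph: EncodedGraph, t: int, v: int,
                candidates: np.ndarray, weights: np.ndarray | None,
                params: WalkParams) -> np.ndarray:
    """Specialized mass computation on an explicit candidate list."""
    base = (weights.astype(np.float64).copy() if weights is not None
            else np.ones(len(candidates)))
    if params.q != 1.0:
        # in-out bias: 1/q on X_beta = N(v) \ N(t), with t in its own
        # neighborhood by convention
        nt = graph.neighbors(t)
        outside = ~_member_sorted(candidates, nt)
        outside &= candidates != t
        base[outside] /= params.q
    if params.p != 1.0:
        # return bias: binary-search t among the sorted candidates
        j = int(np.searchsorted(candidates, t))
        if j < len(candidates) and candidates[j] == t:
            base[j] /= params.p
    return base


def second_order_masses(graph: EncodedGraph, t: int, v: int,
                        params: WalkParams) -> TransitionDistribution:
    """Exact unnormalized second-order step distribution out of ``v``.

    Requires that ``(t, v)`` is an edge of the graph.
    """
    if not graph.has_edge(t, v):
        raise ValueError(f"({t}, {v}) is not an edge")
    candidates = graph.neighbors(v)
    masses = _masses_for(graph, t, v, candidates,
                         graph.neighbor_weights(v), params)
    return TransitionDistribution(candidates, masses)


def suss_sample(n: int, k: int,
                rng: np.random.Generator | int) -> np.ndarray:
    """Sorted unique sub-sampling of ``k`` integers from ``[0, n)``.

    The range is split into ``k`` contiguous buckets of length ``n // k``
    (the last bucket absorbs the remainder) and one value is drawn uniformly
    from each, so the output is inherently sorted and unique, in Theta(k).
    """
    if k < 1:
        raise ValueError("k must be >= 1")
    if k > n:
        raise ValueError(f"cannot draw {k} unique values from range of {n}")
    if isinstance(rng, (int, np.integer)):
        rng = np.random.default_rng(rng)
    width = n // k
    starts = np.arange(k, dtype=np.int64) * width
    lengths = np.full(k, width, dtype=np.int64)
    lengths[-1] = n - starts[-1]
    return starts + rng.integers(0, lengths)


def approximated_second_order_masses(
        graph: EncodedGraph, t: int, v: int, params: WalkParams,
        rng: np.random.Generator) -> TransitionDistribution:
    """Second-order masses on a SUSS-sub-sampled neighborhood of ``v``.

    Falls back to the exact distribution when ``degree(v)`` does not exceed
    the threshold; otherwise biases and weights are computed only for the
    ``d_T`` sub-sampled candidates.
    """
    if params.degree_threshold is None:
        raise ValueError("degree_threshold is not enabled")
    if not graph.has_edge(t, v):
        raise ValueError(f"({t}, {v}) is not an edge")
    deg = graph.degree(v)
    if deg <= params.degree_threshold:
        return second_order_masses(graph, t, v, params)
    pos = suss_sample(deg, params.degree_threshold, rng)
    candidates = graph.neighbors(v)[pos]
    w = graph.neighbor_weights(v)
    masses = _masses_for(graph, t, v, candidates,
                         w[pos] if w is not None else None, params)
    return TransitionDistribution(candidates, masses)


def sample_from_cumsum(cumulative: np.ndarray, draw: float,
                       linear_scan_threshold: int = LINEAR_SCAN_THRESHOLD
                       ) -> int:
    """Smallest index i with ``cumulative[i] > draw``.

    Uses a linear scan below the threshold length (better cache behavior,
    no branching penalty) and binary search above it.
    """
    cumulative = np.asarray(cumulative)
    total = float(cumulative[-1]) if cumulative.size else 0.0
    if total <= 0:
        raise ValueError("total mass is zero (dead end)")
    if len(cumulative) < linear_scan_threshold:
        return int(np.argmax(cumulative > draw))
    return int(np.searchsorted(cumulative, draw, side="right"))


def _first_order_step(graph: EncodedGraph, v: int, params: WalkParams,
                      rng: np.random.Generator) -> int | None:
    nbrs = graph.neighbors(v)
    if not nbrs.size:
        return None
    w = graph.neighbor_weights(v)
    if w is None:
        return int(nbrs[rng.integers(0, nbrs.size)])
    cum = np.cumsum(w)
    draw = rng.uniform(0.0, cum[-1])
    return int(nbrs[sample_from_cumsum(cum, draw,
                                       params.linear_scan_threshold)])


def first_order_walk(graph: EncodedGraph, source: int, params: WalkParams,
                     rng: np.random.Generator | None = None) -> np.ndarray:
    """Uniform (or weight-proportional) walk of ``walk_length`` nodes.

    The walk truncates early at a sink node.
    """
    graph._check_node(source)
    if rng is None:
        rng = walk_rng(params.seed, 0, source)
    walk = [source]
    v = source
    for _ in range(params.walk_length - 1):
        nxt = _first_order_step(graph, v, params, rng)
        if nxt is None:
            break
        walk.append(nxt)
        v = nxt
    return np.array(walk, dtype=np.int64)


def second_order_walk(graph: EncodedGraph, source: int, params: WalkParams,
                      rng: np.random.Generator | None = None) -> np.ndarray:
    """Biased second-order walk; first step is first-order.

    With ``degree_threshold`` set, steps out of high-degree nodes use the
    SUSS-approximated distribution.
    """
    graph._check_node(source)
    if rng is None:
        rng = walk_rng(params.seed, 0, source)
    walk = [source]
    nxt = _first_order_step(graph, source, params, rng)
    if nxt is None:
        return np.array(walk, dtype=np.int64)
    walk.append(nxt)
    t, v = source, nxt
    d_T = params.degree_threshold
    for _ in range(params.walk_length - 2):
        if d_T is not None and graph.degree(v) > d_T:
            dist = approximated_second_order_masses(graph, t, v, params, rng)
        else:
            dist = second_order_masses(graph, t, v, params)
        if dist.total <= 0:
            break
        draw = rng.uniform(0.0, dist.total)
        idx = sample_from_cumsum(dist.cumulative, draw,
                                 params.linear_scan_threshold)
        t, v = v, int(dist.candidates[idx])
        walk.append(v)
    return np.array(walk, dtype=np.int64)


def generate_walks(graph: EncodedGraph, params: WalkParams, *,
                   order: int = 2) -> WalkBatch:
    """``iterations`` walks from every node, independent RNG streams.

    Each walk is fully determined by ``(seed, iteration, source)``, so the
    batch is reproducible and embarrassingly parallel over sources.
    """
    if graph.num_nodes == 0:
        raise ValueError("graph is empty")
    walker = second_order_walk if order == 2 else first_order_walk
    walks = []
    sources = []
    for it in range(params.iterations):
        for src in range(graph.num_nodes):
            rng = walk_rng(params.seed, it, src)
            walks.append(walker(graph, src, params, rng))
            sources.append(src)
    return WalkBatch(walks, np.array(sources, dtype=np.int64),
                     params.iterations)


def write_walks(batch: WalkBatch, path, node_names: list[str]) -> None:
    """Write one walk per line, space-separated names (word2vec corpus)."""
    with open(path, "w") as fh:
        for walk in batch.walks:
            fh.write(" ".join(node_names[i] for i in walk) + "\n")
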