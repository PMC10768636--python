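"""Seeded synthetic graph generators.

Each family targets a structural property one of the algorithms assumes:
stochastic block models give community structure for embedding-recovery
experiments, preferential attachment gives heavy-tailed degree sequences,
hub graphs exercise the approximated (SUSS) walker, and Erdos-Renyi graphs
provide unstructured baselines.  All generators return an
:class:`~efgraph.graph.EncodedGraph` carrying ground-truth metadata (block
memberships, hub IDs, attachment counts) and are reproducible from their
seed.
"""

from __future__ import annotations

from dataclasses import dataclass, field

import numpy as np

from .graph import EncodedGraph

__all__ = [
    "GeneratorSpec",
    "generate",
    "erdos_renyi",
    "stochastic_block_model",
    "scale_free",
    "hub_graph",
    "path_graph",
    "star_graph",
    "clique_pair",
    "worked_fixtures",
]


@dataclass
class GeneratorSpec:
    """Declarative description of one synthetic graph."""

    family: str
    params: dict = field(default_factory=dict)
    seed: int = 0


def _undirected(num_nodes: int, a: np.ndarray, b: np.ndarray,
                **kw) -> EncodedGraph:
    src = np.concatenate([a, b])
    dst = np.concatenate([b, a])
    return EncodedGraph(num_nodes, src, dst, directed=False, **kw)


def erdos_renyi(n: int, p: float, seed: int = 0) -> EncodedGraph:
    """G(n, p): each unordered pair is an edge independently with prob p."""
    if n < 1:
        raise ValueError("parameter n must be >= 1")
    if not 0 <= p <= 1:
        raise ValueError("parameter p must be in [0, 1]")
    rng = np.random.default_rng(seed)
    iu, ju = np.triu_indices(n, k=1)
    keep = rng.random(iu.size) < p
    return _undirected(n, iu[keep], ju[keep],
                       metadata={"family": "erdos_renyi", "n": n, "p": p})


def stochastic_block_model(block_sizes, p_in: float, p_out: float,
                           seed: int = 0) -> EncodedGraph:
    """SBM with dense within-block and sparse between-block wiring."""
    block_sizes = list(block_sizes)
    if any(s < 1 for s in block_sizes):
        raise ValueError("parameter block_sizes must be positive")
    if not (0 <= p_in <= 1 and 0 <= p_out <= 1):
        raise ValueError("parameter p_in/p_out must be in [0, 1]")
    n = sum(block_sizes)
    labels = np.repeat(np.arange(len(block_sizes)), block_sizes)
    rng = np.random.default_rng(seed)
    iu, ju = np.triu_indices(n, k=1)
    prob = np.where(labels[iu] == labels[ju], p_in, p_out)
    keep = rng.random(iu.size) < prob
    return _undirected(
        n, iu[keep], ju[keep],
        metadata={"family": "sbm", "blocks": labels,
                  "p_in": p_in, "p_out": p_out})


def scale_free(n: int, attachment: int, seed: int = 0) -> EncodedGraph:
    """Preferential attachment: each new node links to ``attachment`` targets
    drawn proportionally to current degree (Barabasi-Albert style)."""
    if attachment < 1:
        raise ValueError("parameter attachment must be >= 1")
    if n <= attachment:
        raise ValueError("parameter n must exceed attachment")
    rng = np.random.default_rng(seed)
    # degree-proportional sampling via the repeated-endpoints list
    repeated: list[int] = []
    a_list: list[int] = []
    b_list: list[int] = []
    targets = list(range(attachment))
    for new in range(attachment, n):
        for t in targets:
            a_list.append(new)
            b_list.append(t)
            repeated.extend((new, t))
        # next targets: sample distinct endpoints from the repeated list
        chosen: set[int] = set()
        while len(chosen) < attachment:
            chosen.add(repeated[rng.integers(0, len(repeated))])
        targets = sorted(chosen)
    a = np.array(a_list)
    b = np.array(b_list)
    return _undirected(n, a, b,
                       metadata={"family": "scale_free", "n": n,
                                 "attachment": attachment})


def hub_graph(num_leaves: int, extra_ring: bool = True,
              seed: int = 0) -> EncodedGraph:
    """One hub connected to every leaf; optionally leaves form a ring.

    The ring keeps leaf degrees at 3 so second-order walks out of leaves
    remain non-trivial while the hub dominates with degree ``num_leaves``.
    """
    if num_leaves < 2:
        raise ValueError("parameter num_leaves must be >= 2")
    hub = 0
    leaves = np.arange(1, num_leaves + 1)
    a = [np.full(num_leaves, hub)]
    b = [leaves]
    if extra_ring:
        a.append(leaves)
        b.append(np.roll(leaves, -1))
    return _undirected(num_leaves + 1, np.concatenate(a), np.concatenate(b),
                       metadata={"family": "hub", "hub": hub,
                                 "hub_degree": num_leaves})


def path_graph(n: int) -> EncodedGraph:
    if n < 2:
        raise ValueError("parameter n must be >= 2")
    idx = np.arange(n - 1)
    return _undirected(n, idx, idx + 1, metadata={"family": "path"})


def star_graph(num_leaves: int) -> EncodedGraph:
    if num_leaves < 1:
        raise ValueError("parameter num_leaves must be >= 1")
    leaves = np.arange(1, num_leaves + 1)
    return _undirected(num_leaves + 1, np.zeros(num_leaves, dtype=np.int64),
                       leaves, metadata={"family": "star", "hub": 0})


def clique_pair(clique_size: int, bridges: int = 1,
                seed: int = 0) -> EncodedGraph:
    """Two cliques joined by ``bridges`` random cross edges."""
    if clique_size < 2:
        raise ValueError("parameter clique_size must be >= 2")
    n = 2 * clique_size
    rng = np.random.default_rng(seed)
    a_l, b_l = [], []
    for off in (0, clique_size):
        iu, ju = np.triu_indices(clique_size, k=1)
        a_l.append(iu + off)
        b_l.append(ju + off)
    ba = rng.integers(0, clique_size, size=bridges)
    bb = rng.integers(clique_size, n, size=bridges)
    a = np.concatenate(a_l + [ba])
    b = np.concatenate(b_l + [bb])
    labels = np.repeat([0, 1], clique_size)
    return _undirected(n, a, b,
                       metadata={"family": "clique_pair", "blocks": labels})


_FAMILIES = {
    "erdos_renyi": lambda p, s: erdos_renyi(seed=s, **p),
    "sbm": lambda p, s: stochastic_block_model(seed=s, **p),
    "scale_free": lambda p, s: scale_free(seed=s, **p),
    "hub": lambda p, s: hub_graph(seed=s, **p),
    "path": lambda p, s: path_graph(**p),
    "star": lambda p, s: star_graph(**p),
    "clique_pair": lambda p, s: clique_pair(seed=s, **p),
}


def generate(spec: GeneratorSpec) -> EncodedGraph:
    """Build the graph described by ``spec`` (seed-reproducible)."""
    if spec.family not in _FAMILIES:
        raise ValueError(f"unknown generator family {spec.family!r}")
    return _FAMILIES[spec.family](dict(spec.params), spec.seed)


def worked_fixtures() -> dict[str, EncodedGraph]:
    """Small hand-enumerable graphs used throughout the documentation.

    ``bias_fixture`` is the 4-node graph with N(0) = {1, 2} and
    N(1) = {0, 2, 3} on which the second-order bias arithmetic can be done
    by hand; ``fig3_hub`` has a source node with exactly 15 neighbors for
    walking through the sub-sampled (d_T = 5) step.
    """
    triangle = _undirected(3, np.array([0, 0, 1]), np.array([1, 2, 2]),
                           metadata={"family": "triangle"})
    path4 = path_graph(4)
    star10 = star_graph(10)
    bias = _undirected(4, np.array([0, 0, 1, 1]), np.array([1, 2, 2, 3]),
                       metadata={"family": "bias_fixture"})
    # source 0 with 15 neighbors; neighbors chained so distance-2 sets
    # are non-trivial
    leaves = np.arange(1, 16)
    fig3 = _undirected(
        16,
        np.concatenate([np.zeros(15, dtype=np.int64), leaves[:-1]]),
        np.concatenate([leaves, leaves[1:]]),
        metadata={"family": "fig3_hub", "source": 0, "source_degree": 15})
    return {"triangle": triangle, "path4": path4, "star10": star10,
            "bias_fixture": bias, "fig3_hub": fig3}
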