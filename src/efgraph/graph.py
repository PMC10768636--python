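"""Graph container with succinct (Elias-Fano) and CSR adjacency backends.

Nodes get dense numeric IDs in order of first appearance.  Each directed edge
``(a, b)`` is encoded as the single integer ``phi_k(a, b) = a * 2**k + b`` with
``k = max(1, ceil(log2 |V|))``, i.e. the concatenation of the two fixed-width
endpoint IDs.  The sorted set of edge codes is stored both in an
:class:`~efgraph.eliasfano.EliasFanoSet` and as CSR arrays; both backends
answer degree and neighbor queries identically.  All codes with source ``a``
fall in ``[phi_k(a, 0), phi_k(a+1, 0))``, so on the succinct backend

``degree(a) = rank(Gamma, phi_k(a+1, 0)) - rank(Gamma, phi_k(a, 0))``

and the neighbors are the selected codes in that range masked with ``2**k - 1``.
"""

from __future__ import annotations

import warnings
from dataclasses import dataclass, field

import numpy as np
from scipy.sparse import csr_matrix
from scipy.sparse.csgraph import connected_components as _cc

from .eliasfano import EliasFanoSet

__all__ = [
    "CSRAdjacency",
    "EncodedGraph",
    "encode_edge",
    "decode_edge",
    "load_edge_list",
    "write_edge_list",
    "connected_components",
    "random_spanning_forest",
    "graph_report",
    "MAX_SINGLE_WORD_K",
]

# 2k <= 64-bit machine word => k <= 32 => at most 2**32 nodes per word
MAX_SINGLE_WORD_K = 32


def encode_edge(a: int, b: int, k: int) -> int:
    """Encode the edge (a, b) as the integer ``a * 2**k + b``."""
    if k < 1:
        raise ValueError("bit width k must be >= 1")
    if not (0 <= a < (1 << k)) or not (0 <= b < (1 << k)):
        raise ValueError(f"endpoints ({a}, {b}) do not fit in {k} bits")
    return (a << k) | b


def decode_edge(code: int, k: int) -> tuple[int, int]:
    """Invert :func:`encode_edge`."""
    if not (0 <= code < (1 << (2 * k))):
        raise ValueError(f"code {code} out of range for k={k}")
    return code >> k, code & ((1 << k) - 1)


@dataclass
class CSRAdjacency:
    """Compressed-sparse-row adjacency: per-row sorted neighbor slices."""

    offsets: np.ndarray          # length |V|+1, non-decreasing
    columns: np.ndarray          # sorted within each row
    weights: np.ndarray | None = None

    def neighbors(self, a: int) -> np.ndarray:
        return self.columns[self.offsets[a]:self.offsets[a + 1]]

    def degree(self, a: int) -> int:
        return int(self.offsets[a + 1] - self.offsets[a])


class EncodedGraph:
    """Immutable graph over dense node IDs with dual adjacency backends.

    Undirected graphs store both orientations of every edge so the
    contiguous-code-range trick answers undirected adjacency directly.
    """

    def __init__(self, num_nodes: int, sources: np.ndarray,
                 destinations: np.ndarray, *, directed: bool = False,
                 weights: np.ndarray | None = None,
                 node_names: list[str] | None = None,
                 node_types: list[str] | None = None,
                 edge_types: np.ndarray | None = None,
                 metadata: dict | None = None):
        num_nodes = int(num_nodes)
        k = max(1, (num_nodes - 1).bit_length()) if num_nodes > 1 else 1
        if k > MAX_SINGLE_WORD_K:
            raise ValueError(
                f"{num_nodes} nodes exceed single-word encoding capacity "
                f"(2**{MAX_SINGLE_WORD_K})")
        self.num_nodes = num_nodes
        self.directed = bool(directed)
        self.k = k
        src = np.asarray(sources, dtype=np.uint64)
        dst = np.asarray(destinations, dtype=np.uint64)
        if src.size and (int(src.max()) >= num_nodes
                         or int(dst.max()) >= num_nodes):
            raise ValueError("edge endpoint out of node range")
        codes = (src << np.uint64(k)) | dst
        order = np.argsort(codes, kind="stable")
        codes = codes[order]
        if weights is not None:
            weights = np.asarray(weights, dtype=np.float64)[order]
        if edge_types is not None:
            edge_types = np.asarray(edge_types)[order]
        # collapse duplicates, first weight wins
        if codes.size:
            keep = np.concatenate(([True], codes[1:] != codes[:-1]))
            if not keep.all():
                warnings.warn(
                    f"collapsed {int((~keep).sum())} duplicate edge(s); "
                    "first weight wins", stacklevel=2)
                codes = codes[keep]
                if weights is not None:
                    weights = weights[keep]
                if edge_types is not None:
                    edge_types = edge_types[keep]
        self.edge_codes = codes
        self.weights = weights
        self.edge_types = edge_types
        self.node_names = (list(node_names) if node_names is not None
                           else [str(i) for i in range(num_nodes)])
        self.name_to_id = {nm: i for i, nm in enumerate(self.node_names)}
        self.node_types = node_types
        self.metadata = metadata or {}

        self.ef = EliasFanoSet(codes, u=1 << (2 * k))
        s = (codes >> np.uint64(k)).astype(np.int64)
        d = (codes & np.uint64((1 << k) - 1)).astype(np.int64)
        offsets = np.zeros(num_nodes + 1, dtype=np.int64)
        np.add.at(offsets, s + 1, 1)
        np.cumsum(offsets, out=offsets)
        self.csr = CSRAdjacency(offsets, d, weights)
        self._sources = s

    # -- basic queries ----------------------------------------------------

    @property
    def num_edges(self) -> int:
        """Number of stored (directed) edge codes |Gamma|."""
        return int(self.edge_codes.size)

    @property
    def is_weighted(self) -> bool:
        return self.weights is not None

    def _check_node(self, a: int) -> None:
        if not 0 <= a < self.num_nodes:
            raise ValueError(f"node {a} out of range [0, {self.num_nodes})")

    def degree(self, a: int, backend: str = "csr") -> int:
        self._check_node(a)
        if backend == "csr":
            return self.csr.degree(a)
        if backend == "eliasfano":
            lo = self.ef.rank(encode_edge(a, 0, self.k))
            hi = (self.ef.rank((a + 1) << self.k)
                  if a + 1 < (1 << self.k) else self.ef.n)
            return hi - lo
        raise ValueError(f"unknown backend {backend!r}")

    def neighbors(self, a: int, backend: str = "csr") -> np.ndarray:
        """Sorted destination IDs of edges leaving ``a``."""
        self._check_node(a)
        if backend == "csr":
            return self.csr.neighbors(a)
        if backend == "eliasfano":
            lo = self.ef.rank(encode_edge(a, 0, self.k))
            hi = (self.ef.rank((a + 1) << self.k)
                  if a + 1 < (1 << self.k) else self.ef.n)
            mask = (1 << self.k) - 1
            return np.array([self.ef.select(i) & mask for i in range(lo, hi)],
                            dtype=np.int64)
        raise ValueError(f"unknown backend {backend!r}")

    def neighbor_weights(self, a: int) -> np.ndarray | None:
        if self.weights is None:
            return None
        return self.weights[self.csr.offsets[a]:self.csr.offsets[a + 1]]

    def edge_source(self, i: int) -> int:
        """Source endpoint of the i-th smallest edge code (via select)."""
        return self.ef.select(i) >> self.k

    def edge_array(self) -> tuple[np.ndarray, np.ndarray]:
        """(sources, destinations) decoded from the sorted code list."""
        return (self._sources.copy(),
                self.csr.columns.copy())

    def canonical_edges(self) -> np.ndarray:
        """Undirected edge list with each edge once, min endpoint first.

        For directed graphs simply returns all (src, dst) pairs.
        """
        s, d = self._sources, self.csr.columns
        if self.directed:
            return np.column_stack([s, d])
        keep = s <= d
        return np.column_stack([s[keep], d[keep]])

    def has_edge(self, a: int, b: int) -> bool:
        return encode_edge(a, b, self.k) in self.ef

    def to_csr_matrix(self) -> csr_matrix:
        data = (self.weights if self.weights is not None
                else np.ones(self.num_edges))
        return csr_matrix((data, self.csr.columns, self.csr.offsets),
                          shape=(self.num_nodes, self.num_nodes))

    def subgraph_without_edges(self, removed: np.ndarray) -> "EncodedGraph":
        """Copy of the graph with the given canonical edges removed."""
        removed = np.asarray(removed, dtype=np.int64).reshape(-1, 2)
        drop = set()
        for a, b in removed:
            drop.add(encode_edge(int(a), int(b), self.k))
            if not self.directed:
                drop.add(encode_edge(int(b), int(a), self.k))
        keep = np.array([int(c) not in drop for c in self.edge_codes])
        s = self._sources[keep]
        d = self.csr.columns[keep]
        w = self.weights[keep] if self.weights is not None else None
        return EncodedGraph(self.num_nodes, s, d, directed=self.directed,
                            weights=w, node_names=self.node_names,
                            node_types=self.node_types,
                            metadata=dict(self.metadata))

    def __repr__(self) -> str:  # pragma: no cover
        kind = "directed" if self.directed else "undirected"
        return (f"EncodedGraph({kind}, |V|={self.num_nodes}, "
                f"|Gamma|={self.num_edges})")


# -- TSV I/O ---------------------------------------------------------------

_HEADER_WORDS = {"src", "source", "from", "subject", "dst", "destination",
                 "to", "object", "weight", "edge_type", "type", "node_name",
                 "node_type"}


def _looks_like_header(fields: list[str]) -> bool:
    return any(f.strip().lower() in _HEADER_WORDS for f in fields[:2])


def load_edge_list(path, *, directed: bool = False, weighted: bool = False,
                   node_list: str | None = None) -> EncodedGraph:
    """Read a TSV edge list (src, dst[, weight[, edge_type]]) into a graph.

    '#'-prefixed comment lines are skipped and a header row is auto-detected.
    Dense node IDs are assigned in order of first appearance.  Undirected
    input is symmetrized; duplicate edges collapse with a warning (first
    weight wins).  Malformed rows and non-positive weights are rejected with
    their 1-based row number.
    """
    names: list[str] = []
    ids: dict[str, int] = {}
    node_types = None

    def nid(name: str) -> int:
        if name not in ids:
            ids[name] = len(names)
            names.append(name)
        return ids[name]

    if node_list is not None:
        node_types = {}
        with open(node_list) as fh:
            for lineno, line in enumerate(fh, 1):
                line = line.rstrip("\n")
                if not line or line.startswith("#"):
                    continue
                fields = line.split("\t")
                if lineno == 1 and _looks_like_header(fields):
                    continue
                node_types[nid(fields[0])] = (
                    fields[1].split("|") if len(fields) > 1 else [])

    srcs: list[int] = []
    dsts: list[int] = []
    wts: list[float] = []
    etypes: list[str] = []
    header_seen = False
    with open(path) as fh:
        for lineno, line in enumerate(fh, 1):
            line = line.rstrip("\n")
            if not line or line.startswith("#"):
                continue
            fields = line.split("\t")
            if not header_seen:
                header_seen = True
                if _looks_like_header(fields):
                    continue
            if len(fields) < 2:
                raise ValueError(f"malformed row {lineno}: "
                                 f"expected at least 2 columns, got {line!r}")
            a, b = nid(fields[0]), nid(fields[1])
            srcs.append(a)
            dsts.append(b)
            if weighted:
                if len(fields) < 3:
                    raise ValueError(f"malformed row {lineno}: "
                                     "missing weight column")
                try:
                    w = float(fields[2])
                except ValueError:
                    raise ValueError(
                        f"malformed row {lineno}: bad weight {fields[2]!r}")
                if not np.isfinite(w) or w <= 0:
                    raise ValueError(
                        f"row {lineno}: weight must be finite and > 0, "
                        f"got {w}")
                wts.append(w)
            tcol = 3 if weighted else 2
            if len(fields) > tcol:
                etypes.append(fields[tcol])

    src = np.array(srcs, dtype=np.int64)
    dst = np.array(dsts, dtype=np.int64)
    w = np.array(wts) if weighted else None
    et = np.array(etypes) if etypes and len(etypes) == len(srcs) else None
    if not directed:
        loop = src == dst
        src, dst = (np.concatenate([src, dst[~loop]]),
                    np.concatenate([dst, src[~loop]]))
        if w is not None:
            w = np.concatenate([w, w[~loop]])
        if et is not None:
            et = np.concatenate([et, et[~loop]])
    ntypes = None
    if node_types is not None:
        ntypes = [node_types.get(i, []) for i in range(len(names))]
    return EncodedGraph(len(names), src, dst, directed=directed, weights=w,
                        node_names=names, node_types=ntypes, edge_types=et)


def write_edge_list(graph: EncodedGraph, path) -> None:
    """Write the graph back to TSV (canonical edges, names, weights)."""
    edges = graph.canonical_edges()
    with open(path, "w") as fh:
        for row_i, (a, b) in enumerate(edges):
            cols = [graph.node_names[a], graph.node_names[b]]
            if graph.weights is not None:
                w = graph.weights[graph.ef.rank(
                    encode_edge(int(a), int(b), graph.k))]
                cols.append(repr(float(w)))
            fh.write("\t".join(cols) + "\n")


# -- whole-graph utilities -------------------------------------------------

def connected_components(graph: EncodedGraph) -> np.ndarray:
    """Component label per node (edges treated as undirected)."""
    if graph.num_nodes == 0:
        return np.zeros(0, dtype=np.int64)
    n_comp, labels = _cc(graph.to_csr_matrix(), directed=False)
    return labels.astype(np.int64)


def random_spanning_forest(graph: EncodedGraph, seed: int) -> np.ndarray:
    """Uniformly shuffled Kruskal: a seed-reproducible random spanning forest.

    Returns canonical (a, b) pairs; per component the edge count is the
    component size minus one.
    """
    edges = graph.canonical_edges()
    edges = edges[edges[:, 0] != edges[:, 1]]  # self-loops never span
    rng = np.random.default_rng(seed)
    order = rng.permutation(len(edges))
    parent = np.arange(graph.num_nodes)

    def find(x: int) -> int:
        root = x
        while parent[root] != root:
            root = parent[root]
        while parent[x] != root:
            parent[x], x = root, parent[x]
        return root

    chosen = []
    for idx in order:
        a, b = int(edges[idx, 0]), int(edges[idx, 1])
        ra, rb = find(a), find(b)
        if ra != rb:
            parent[ra] = rb
            chosen.append((a, b))
    return np.array(sorted(chosen), dtype=np.int64).reshape(-1, 2)


def graph_report(graph: EncodedGraph) -> str:
    """Plain-text summary: sizes, density, degree stats, components."""
    n, m = graph.num_nodes, graph.num_edges
    lines = [f"nodes: {n}", f"stored edge codes: {m}",
             f"directed: {graph.directed}"]
    if n:
        degs = np.diff(graph.csr.offsets)
        possible = n * (n - 1) if n > 1 else 1
        lines += [
            f"density: {m / possible:.6f}" if n > 1 else "density: n/a",
            f"degree min/median/max: {degs.min()}/"
            f"{np.median(degs):g}/{degs.max()}",
            f"connected components: "
            f"{len(np.unique(connected_components(graph)))}",
        ]
    else:
        lines.append("connected components: 0")
    return "\n".join(lines)
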