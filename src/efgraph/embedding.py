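"""Shallow node-embedding models trained on random-walk windows.

SkipGram predicts the nodes of a sliding window from its central node; CBOW
predicts the central node from the average of the window.  Both are trained
with negative sampling: for each observed (center, context) pair the
log-sigmoid score of the true pair is ascended and the scores of
``negatives_per_positive`` sampled negatives are descended.  Negatives are
drawn scale-free, i.e. with probability proportional to node degree, by
picking a uniform position in the sorted edge-code set and decoding its
source endpoint (the succinct backend answers this with a single select).

Updates are applied without any coordination: mini-batch gradients are
computed against a stale snapshot of the weights and scatter-added, and
whatever interleaving results is accepted as-is.  With a single worker and a
fixed seed training is bitwise reproducible.
"""

from __future__ import annotations

from dataclasses import dataclass, field

import numpy as np

from .graph import EncodedGraph
from .walks import WalkBatch

__all__ = [
    "TrainingConfig",
    "EmbeddingMatrix",
    "extract_windows",
    "extract_context_windows",
    "ScaleFreeNegativeSampler",
    "scale_free_negative_sampler",
    "train_skipgram",
    "train_cbow",
    "edge_embedding",
    "edge_features",
    "EDGE_OPERATORS",
    "save_embedding_tsv",
    "save_embedding_word2vec",
]


@dataclass
class TrainingConfig:
    """Hyper-parameters of the shallow models."""

    dimension: int = 32
    window_size: int = 3
    epochs: int = 3
    negatives_per_positive: int = 5
    learning_rate: float = 0.025
    final_lr_fraction: float = 1e-4   # linear decay target, fraction of lr
    batch_size: int = 512
    ns_exponent: float = 1.0          # degree exponent of the neg. sampler
    seed: int = 0

    def __post_init__(self):
        if self.dimension < 2:
            raise ValueError("dimension must be >= 2")
        if self.window_size < 1:
            raise ValueError("window_size must be >= 1")
        if self.negatives_per_positive < 1:
            raise ValueError("negatives_per_positive must be >= 1")


@dataclass
class EmbeddingMatrix:
    """Input- and output-layer weights of a trained shallow model.

    The input layer (``vectors``) is the published node embedding; rows are
    ordered by node ID.
    """

    vectors: np.ndarray
    output: np.ndarray
    loss_history: list = field(default_factory=list)

    def __getitem__(self, node: int) -> np.ndarray:
        return self.vectors[node]


def extract_windows(batch: WalkBatch, window_size: int
                    ) -> tuple[np.ndarray, np.ndarray]:
    """All (center, context) pairs within ``window_size`` along each walk."""
    if window_size < 1:
        raise ValueError("window_size must be >= 1")
    centers, contexts = [], []
    for walk in batch.walks:
        L = len(walk)
        for d in range(1, window_size + 1):
            if d >= L:
                break
            centers.append(walk[:-d])
            contexts.append(walk[d:])
            centers.append(walk[d:])
            contexts.append(walk[:-d])
    if not centers:
        empty = np.zeros(0, dtype=np.int64)
        return empty, empty
    return np.concatenate(centers), np.concatenate(contexts)


def extract_context_windows(batch: WalkBatch, window_size: int
                            ) -> tuple[np.ndarray, np.ndarray, np.ndarray]:
    """Per-position windows for CBOW: (centers, padded contexts, mask)."""
    centers, ctxs = [], []
    for walk in batch.walks:
        L = len(walk)
        for i in range(L):
            ctx = np.concatenate([walk[max(0, i - window_size):i],
                                  walk[i + 1:i + 1 + window_size]])
            if ctx.size:
                centers.append(walk[i])
                ctxs.append(ctx)
    if not centers:
        return (np.zeros(0, dtype=np.int64),
                np.zeros((0, 0), dtype=np.int64),
                np.zeros((0, 0), dtype=bool))
    width = max(len(c) for c in ctxs)
    padded = np.zeros((len(ctxs), width), dtype=np.int64)
    mask = np.zeros((len(ctxs), width), dtype=bool)
    for r, c in enumerate(ctxs):
        padded[r, :len(c)] = c
        mask[r, :len(c)] = True
    return np.array(centers, dtype=np.int64), padded, mask


class ScaleFreeNegativeSampler:
    """Degree-proportional node sampler backed by the sorted edge set.

    With the default exponent of 1 a uniform edge position is drawn and its
    source endpoint decoded, which is exactly degree-proportional sampling;
    other exponents fall back to an explicit cumulative table over
    ``degree**exponent``.
    """

    def __init__(self, graph: EncodedGraph, exponent: float = 1.0):
        if graph.num_edges == 0:
            raise ValueError("graph has no edges")
        self.graph = graph
        self.exponent = exponent
        if exponent == 1.0:
            self._sources = graph.edge_array()[0]
            self._cum = None
        else:
            degs = np.diff(graph.csr.offsets).astype(np.float64)
            self._cum = np.cumsum(degs ** exponent)
            self._sources = None

    def sample(self, count: int, rng: np.random.Generator) -> np.ndarray:
        if self._cum is None:
            idx = rng.integers(0, self.graph.num_edges, size=count)
            return self._sources[idx]
        draws = rng.uniform(0, self._cum[-1], size=count)
        return np.searchsorted(self._cum, draws, side="right")


def scale_free_negative_sampler(graph: EncodedGraph, count: int,
                                seed: int) -> np.ndarray:
    """Draw ``count`` nodes with probability proportional to degree."""
    rng = np.random.default_rng(seed)
    return ScaleFreeNegativeSampler(graph).sample(count, rng)


def _sigmoid(x: np.ndarray) -> np.ndarray:
    out = np.empty_like(x)
    pos = x >= 0
    out[pos] = 1.0 / (1.0 + np.exp(-x[pos]))
    e = np.exp(x[~pos])
    out[~pos] = e / (1.0 + e)
    return out


def _init_layers(num_nodes: int, cfg: TrainingConfig
                 ) -> tuple[np.ndarray, np.ndarray, np.random.Generator]:
    rng = np.random.default_rng(cfg.seed)
    span = 0.5 / cfg.dimension
    w_in = rng.uniform(-span, span, size=(num_nodes, cfg.dimension))
    w_out = np.zeros((num_nodes, cfg.dimension))
    return w_in, w_out, rng


def _lr_schedule(cfg: TrainingConfig, step: int, total_steps: int) -> float:
    lo = cfg.learning_rate * cfg.final_lr_fraction
    frac = step / max(1, total_steps)
    return max(lo, cfg.learning_rate * (1.0 - frac))


def _check_finite(w_in: np.ndarray) -> None:
    if not np.all(np.isfinite(w_in)):
        raise FloatingPointError(
            "NaN/inf in embedding weights; lower the learning rate")


def train_skipgram(pairs: tuple[np.ndarray, np.ndarray],
                   graph: EncodedGraph, cfg: TrainingConfig
                   ) -> EmbeddingMatrix:
    """Negative-sampling SkipGram over (center, context) pairs."""
    centers, contexts = pairs
    if centers.size == 0:
        raise ValueError("empty pair stream")
    w_in, w_out, rng = _init_layers(graph.num_nodes, cfg)
    sampler = ScaleFreeNegativeSampler(graph, cfg.ns_exponent)
    emb = EmbeddingMatrix(w_in, w_out)
    n = centers.size
    B = cfg.batch_size
    batches_per_epoch = (n + B - 1) // B
    total_steps = cfg.epochs * batches_per_epoch
    step = 0
    neg = cfg.negatives_per_positive
    for _ in range(cfg.epochs):
        order = rng.permutation(n)
        epoch_loss = 0.0
        for b0 in range(0, n, B):
            sel = order[b0:b0 + B]
            c = centers[sel]
            targets = np.empty((sel.size, 1 + neg), dtype=np.int64)
            targets[:, 0] = contexts[sel]
            negs = sampler.sample(sel.size * neg, rng).reshape(sel.size, neg)
            # negatives colliding with the center: resample once, then skip
            hit = negs == c[:, None]
            if hit.any():
                negs[hit] = sampler.sample(int(hit.sum()), rng)
            targets[:, 1:] = negs
            live = np.ones_like(targets, dtype=bool)
            live[:, 1:] = negs != c[:, None]

            lr = _lr_schedule(cfg, step, total_steps)
            C = w_in[c]                       # (B, d) stale snapshot
            O = w_out[targets]                # (B, 1+neg, d)
            scores = np.einsum("bd,bkd->bk", C, O)
            probs = _sigmoid(scores)
            labels = np.zeros_like(probs)
            labels[:, 0] = 1.0
            g = (probs - labels) * live       # (B, 1+neg)
            eps = 1e-12
            epoch_loss += float(
                -np.log(probs[:, 0] + eps).sum()
                - np.log1p(-probs[:, 1:] * live[:, 1:] + eps).sum())
            grad_in = np.einsum("bk,bkd->bd", g, O)
            grad_out = g[:, :, None] * C[:, None, :]
            np.add.at(w_in, c, -lr * grad_in)
            np.add.at(w_out, targets.ravel(),
                      -lr * grad_out.reshape(-1, cfg.dimension))
            step += 1
        _check_finite(w_in)
        emb.loss_history.append(epoch_loss / n)
    return emb


def train_cbow(windows: tuple[np.ndarray, np.ndarray, np.ndarray],
               graph: EncodedGraph, cfg: TrainingConfig) -> EmbeddingMatrix:
    """Negative-sampling CBOW: averaged context predicts the center.

    With a single context node per window the update coincides with the
    SkipGram update with the roles of center and context swapped.
    """
    centers, ctx, mask = windows
    if centers.size == 0:
        raise ValueError("empty window stream")
    w_in, w_out, rng = _init_layers(graph.num_nodes, cfg)
    sampler = ScaleFreeNegativeSampler(graph, cfg.ns_exponent)
    emb = EmbeddingMatrix(w_in, w_out)
    n = centers.size
    B = cfg.batch_size
    total_steps = cfg.epochs * ((n + B - 1) // B)
    step = 0
    neg = cfg.negatives_per_positive
    for _ in range(cfg.epochs):
        order = rng.permutation(n)
        epoch_loss = 0.0
        for b0 in range(0, n, B):
            sel = order[b0:b0 + B]
            c = centers[sel]
            cx = ctx[sel]
            mk = mask[sel]
            counts = mk.sum(axis=1, keepdims=True)
            H = (w_in[cx] * mk[:, :, None]).sum(axis=1) / counts  # (B, d)
            targets = np.empty((sel.size, 1 + neg), dtype=np.int64)
            targets[:, 0] = c
            negs = sampler.sample(sel.size * neg, rng).reshape(sel.size, neg)
            hit = negs == c[:, None]
            if hit.any():
                negs[hit] = sampler.sample(int(hit.sum()), rng)
            targets[:, 1:] = negs
            live = np.ones_like(targets, dtype=bool)
            live[:, 1:] = negs != c[:, None]

            lr = _lr_schedule(cfg, step, total_steps)
            O = w_out[targets]
            scores = np.einsum("bd,bkd->bk", H, O)
            probs = _sigmoid(scores)
            labels = np.zeros_like(probs)
            labels[:, 0] = 1.0
            g = (probs - labels) * live
            eps = 1e-12
            epoch_loss += float(
                -np.log(probs[:, 0] + eps).sum()
                - np.log1p(-probs[:, 1:] * live[:, 1:] + eps).sum())
            grad_h = np.einsum("bk,bkd->bd", g, O)        # dL/dH
            grad_out = g[:, :, None] * H[:, None, :]
            # gradient to each contributing context vector is grad_h / count
            per_ctx = (grad_h[:, None, :] / counts[:, :, None]) \
                * mk[:, :, None]
            np.add.at(w_in, cx.ravel(),
                      -lr * per_ctx.reshape(-1, cfg.dimension))
            np.add.at(w_out, targets.ravel(),
                      -lr * grad_out.reshape(-1, cfg.dimension))
            step += 1
        _check_finite(w_in)
        emb.loss_history.append(epoch_loss / n)
    return emb


# -- edge embeddings -------------------------------------------------------

def _cosine(u: np.ndarray, v: np.ndarray) -> np.ndarray:
    nu = np.linalg.norm(u, axis=-1)
    nv = np.linalg.norm(v, axis=-1)
    denom = np.where(nu * nv == 0, 1.0, nu * nv)
    return np.atleast_1d((u * v).sum(axis=-1) / denom)


EDGE_OPERATORS = {
    "hadamard": lambda u, v: u * v,
    "average": lambda u, v: (u + v) / 2.0,
    "l1": lambda u, v: np.abs(u - v),
    "l2": lambda u, v: (u - v) ** 2,
    "concat": lambda u, v: np.concatenate([u, v], axis=-1),
    "cosine": _cosine,
}


def edge_embedding(u_vec: np.ndarray, v_vec: np.ndarray,
                   op: str = "hadamard") -> np.ndarray:
    """Combine two node vectors into one edge feature vector."""
    u_vec = np.asarray(u_vec, dtype=np.float64)
    v_vec = np.asarray(v_vec, dtype=np.float64)
    if u_vec.shape != v_vec.shape:
        raise ValueError("node vectors must share a dimension")
    key = op.lower()
    if key not in EDGE_OPERATORS:
        raise ValueError(f"unknown edge operator {op!r}; "
                         f"choose from {sorted(EDGE_OPERATORS)}")
    return EDGE_OPERATORS[key](u_vec, v_vec)


def edge_features(embedding: EmbeddingMatrix, pairs: np.ndarray,
                  op: str = "hadamard", chunk_size: int = 8192):
    """Lazily yield edge-feature chunks for a (possibly huge) pair list."""
    pairs = np.asarray(pairs, dtype=np.int64).reshape(-1, 2)
    for lo in range(0, len(pairs), chunk_size):
        block = pairs[lo:lo + chunk_size]
        yield edge_embedding(embedding.vectors[block[:, 0]],
                             embedding.vectors[block[:, 1]], op)


def save_embedding_tsv(embedding: EmbeddingMatrix, node_names: list[str],
                       path) -> None:
    with open(path, "w") as fh:
        for name, row in zip(node_names, embedding.vectors):
            fh.write(name + "\t" + "\t".join(f"{x:.8g}" for x in row) + "\n")


def save_embedding_word2vec(embedding: EmbeddingMatrix,
                            node_names: list[str], path) -> None:
    """word2vec text format: a 'count dim' header, then name + vector."""
    vecs = embedding.vectors
    with open(path, "w") as fh:
        fh.write(f"{len(node_names)} {vecs.shape[1]}\n")
        for name, row in zip(node_names, vecs):
            fh.write(name + " " + " ".join(f"{x:.8g}" for x in row) + "\n")
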