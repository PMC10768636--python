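"""Holdout schemas, negative-edge sampling, metrics, and baselines.

Edge-prediction holdouts use the *connected Monte Carlo* schema: a random
spanning forest is pinned to the training side, test positives are drawn only
from the remaining (non-forest) edges, so the training graph never gains new
connected components and embeddings trained on it see every node.  Negative
edges are sampled either uniformly or scale-free (endpoints proportional to
degree), one per test positive by default, and are not checked against the
edge set unless the caller opts in (sparse graphs make false negatives
negligible).

The baseline classifier is a single-layer logistic scorer over edge features,
trained with the Nadam update rule.
"""

from __future__ import annotations

import json
import hashlib
from dataclasses import dataclass, field, asdict

import numpy as np
from sklearn.metrics import (accuracy_score, average_precision_score,
                             balanced_accuracy_score, confusion_matrix,
                             f1_score, matthews_corrcoef, precision_score,
                             recall_score, roc_auc_score)

from .graph import EncodedGraph, connected_components, random_spanning_forest
from .embedding import (EmbeddingMatrix, ScaleFreeNegativeSampler,
                        TrainingConfig, edge_embedding, extract_windows,
                        train_skipgram)
from .walks import WalkParams, generate_walks

__all__ = [
    "HoldoutSplit",
    "MetricsReport",
    "connected_monte_carlo_split",
    "stratified_split",
    "sample_negative_edges",
    "compute_metrics",
    "NadamPerceptron",
    "perceptron_edge_classifier",
    "run_edge_prediction_pipeline",
    "summarize_reports",
]


@dataclass
class HoldoutSplit:
    """One train/test edge partition plus its negative samples."""

    train_graph: EncodedGraph
    test_positives: np.ndarray       # (m, 2) canonical pairs
    test_negatives: np.ndarray       # (m, 2) canonical pairs
    schema: str
    seed: int
    train_ratio: float


@dataclass
class MetricsReport:
    """Threshold (at 0.5) and rank metrics of one evaluation."""

    auroc: float | None
    auprc: float | None
    accuracy: float
    balanced_accuracy: float
    f1: float
    precision: float
    recall: float
    miss_rate: float
    markedness: float
    diagnostic_odds_ratio: float
    dor_is_infinite: bool
    mcc: float

    def as_dict(self) -> dict:
        return asdict(self)


def connected_monte_carlo_split(graph: EncodedGraph, ratio: float,
                                seed: int, *,
                                negative_distribution: str = "scale_free",
                                exclude_existing_negatives: bool = False,
                                allow_smaller_test: bool = False
                                ) -> HoldoutSplit:
    """80:20-style edge holdout that never disconnects the training graph.

    A random spanning forest is kept in the train side unconditionally; test
    positives are sampled uniformly from the remaining edges up to
    ``(1 - ratio) * |E|``.  Fails if the non-forest edges cannot fill the
    requested test fraction, unless ``allow_smaller_test``.

    ``exclude_existing_negatives`` filters true edges out of the sampled
    test negatives; keep it on for small dense benchmark graphs, where the
    false-negative rate of unchecked sampling is far from negligible.
    """
    if graph.directed:
        raise ValueError("connected Monte Carlo requires an undirected graph")
    if not 0 < ratio < 1:
        raise ValueError("train ratio must be in (0, 1)")
    rng = np.random.default_rng(seed)
    forest = random_spanning_forest(graph, seed)
    edges = graph.canonical_edges()
    forest_codes = {(int(a), int(b)) for a, b in forest}
    removable = np.array(
        [i for i, (a, b) in enumerate(edges)
         if (int(a), int(b)) not in forest_codes], dtype=np.int64)
    n_test = int(round((1 - ratio) * len(edges)))
    if n_test > len(removable):
        if not allow_smaller_test:
            raise ValueError(
                f"only {len(removable)} non-forest edges available for a "
                f"test set of {n_test}; pass allow_smaller_test=True to "
                f"accept the smaller split")
        n_test = len(removable)
    if n_test == 0 and not allow_smaller_test:
        raise ValueError("zero removable edges: graph is a forest")
    chosen = rng.choice(removable, size=n_test, replace=False)
    test_pos = edges[np.sort(chosen)]
    train_graph = graph.subgraph_without_edges(test_pos)
    test_neg = sample_negative_edges(
        graph, len(test_pos), distribution=negative_distribution,
        exclude_existing=exclude_existing_negatives,
        seed=int(rng.integers(0, 2**31)))
    return HoldoutSplit(train_graph, test_pos, test_neg,
                        schema="connected_monte_carlo", seed=seed,
                        train_ratio=ratio)


def stratified_split(labels, ratio: float, seed: int
                     ) -> tuple[np.ndarray, np.ndarray]:
    """Per-class node split: train fraction within one node of ``ratio``."""
    labels = np.asarray(labels)
    if not 0 < ratio < 1:
        raise ValueError("train ratio must be in (0, 1)")
    rng = np.random.default_rng(seed)
    train_idx, test_idx = [], []
    for cls in np.unique(labels):
        members = np.flatnonzero(labels == cls)
        if len(members) < 2:
            raise ValueError(f"class {cls!r} has a single node; "
                             "stratified split impossible")
        members = rng.permutation(members)
        n_train = int(round(ratio * len(members)))
        n_train = min(max(n_train, 1), len(members) - 1)
        train_idx.append(members[:n_train])
        test_idx.append(members[n_train:])
    return (np.sort(np.concatenate(train_idx)),
            np.sort(np.concatenate(test_idx)))


def sample_negative_edges(graph: EncodedGraph, count: int, *,
                          distribution: str = "scale_free", seed: int = 0,
                          exclude_existing: bool = False,
                          max_attempts: int = 100) -> np.ndarray:
    """Draw ``count`` node pairs as negative (assumed non-existing) edges.

    Endpoints are drawn uniformly or degree-proportionally.  Self-pairs are
    excluded, and undirected pairs are canonicalized (min ID first).  By
    default pairs are *not* checked against the edge set; pass
    ``exclude_existing=True` to filter true edges out.
    """
    if graph.num_nodes < 2:
        raise ValueError("need at least two nodes to sample negative edges")
    rng = np.random.default_rng(seed)
    if distribution == "scale_free":
        sampler = ScaleFreeNegativeSampler(graph)
        draw = lambda m: (sampler.sample(m, rng), sampler.sample(m, rng))
    elif distribution == "uniform":
        draw = lambda m: (rng.integers(0, graph.num_nodes, size=m),
                          rng.integers(0, graph.num_nodes, size=m))
    else:
        raise ValueError(f"unknown distribution {distribution!r}")

    out = np.zeros((0, 2), dtype=np.int64)
    for _ in range(max_attempts):
        need = count - len(out)
        if need <= 0:
            break
        a, b = draw(2 * need + 8)
        lo = np.minimum(a, b) if not graph.directed else a
        hi = np.maximum(a, b) if not graph.directed else b
        keep = lo != hi
        if exclude_existing:
            keep &= ~np.array([graph.has_edge(int(x), int(y))
                               for x, y in zip(lo, hi)])
        cand = np.column_stack([lo[keep], hi[keep]])[:need]
        out = np.concatenate([out, cand.astype(np.int64)])
    if len(out) < count:
        raise ValueError(
            f"could only sample {len(out)} of {count} negative edges "
            f"under the current exclusion policy")
    return out[:count]


def compute_metrics(scores, labels) -> MetricsReport:
    """Full metric suite: rank metrics plus threshold metrics at 0.5.

    With single-class labels the rank metrics are undefined and reported
    as ``None``.
    """
    scores = np.asarray(scores, dtype=np.float64)
    labels = np.asarray(labels).astype(np.int64)
    if scores.shape != labels.shape:
        raise ValueError("scores and labels must have equal length")
    both_classes = len(np.unique(labels)) == 2
    auroc = float(roc_auc_score(labels, scores)) if both_classes else None
    auprc = (float(average_precision_score(labels, scores))
             if both_classes else None)
    pred = (scores >= 0.5).astype(np.int64)
    tn, fp, fn, tp = confusion_matrix(labels, pred, labels=[0, 1]).ravel()
    miss_rate = fn / (fn + tp) if (fn + tp) else 0.0
    ppv = tp / (tp + fp) if (tp + fp) else 0.0
    npv = tn / (tn + fn) if (tn + fn) else 0.0
    markedness = ppv + npv - 1.0
    dor_inf = (fn == 0 or fp == 0) and tp > 0 and tn > 0
    if fn > 0 and fp > 0 and tn > 0:
        dor = (tp / fn) / (fp / tn)
    elif dor_inf:
        dor = float("inf")
    else:
        dor = 0.0
    return MetricsReport(
        auroc=auroc,
        auprc=auprc,
        accuracy=float(accuracy_score(labels, pred)),
        balanced_accuracy=float(balanced_accuracy_score(labels, pred)),
        f1=float(f1_score(labels, pred, zero_division=0)),
        precision=float(precision_score(labels, pred, zero_division=0)),
        recall=float(recall_score(labels, pred, zero_division=0)),
        miss_rate=float(miss_rate),
        markedness=float(markedness),
        diagnostic_odds_ratio=float(dor),
        dor_is_infinite=bool(dor_inf),
        mcc=float(matthews_corrcoef(labels, pred)),
    )


class NadamPerceptron:
    """Single-layer logistic scorer trained with the Nadam update rule."""

    def __init__(self, learning_rate: float = 0.01, epochs: int = 50,
                 batch_size: int = 256, beta1: float = 0.9,
                 beta2: float = 0.999, eps: float = 1e-8, seed: int = 0):
        self.learning_rate = learning_rate
        self.epochs = epochs
        self.batch_size = batch_size
        self.beta1, self.beta2, self.eps = beta1, beta2, eps
        self.seed = seed
        self.weights: np.ndarray | None = None
        self.bias: float = 0.0

    def _init(self, dim: int, rng: np.random.Generator) -> None:
        self.weights = rng.normal(0.0, 0.01, size=dim)
        self.bias = 0.0
        self._m = np.zeros(dim + 1)
        self._v = np.zeros(dim + 1)
        self._t = 0

    def fit(self, features, labels) -> "NadamPerceptron":
        X = np.asarray(features, dtype=np.float64)
        y = np.asarray(labels, dtype=np.float64)
        if len(np.unique(y)) < 2:
            raise ValueError("need at least one example per class")
        if np.all(X.std(axis=0) == 0):
            import warnings
            warnings.warn("features are constant; scores uninformative",
                          stacklevel=2)
        rng = np.random.default_rng(self.seed)
        self._init(X.shape[1], rng)
        b1, b2 = self.beta1, self.beta2
        n = len(X)
        for _ in range(self.epochs):
            order = rng.permutation(n)
            for lo in range(0, n, self.batch_size):
                sel = order[lo:lo + self.batch_size]
                xb, yb = X[sel], y[sel]
                z = xb @ self.weights + self.bias
                p = 1.0 / (1.0 + np.exp(-np.clip(z, -35, 35)))
                err = p - yb
                g = np.concatenate([xb.T @ err / len(sel),
                                    [err.mean()]])
                self._t += 1
                self._m = b1 * self._m + (1 - b1) * g
                self._v = b2 * self._v + (1 - b2) * g * g
                m_hat = self._m / (1 - b1 ** self._t)
                v_hat = self._v / (1 - b2 ** self._t)
                # Nesterov-accelerated Adam: look-ahead momentum term
                m_bar = b1 * m_hat + (1 - b1) * g / (1 - b1 ** self._t)
                upd = self.learning_rate * m_bar / (np.sqrt(v_hat) + self.eps)
                self.weights -= upd[:-1]
                self.bias -= upd[-1]
        return self

    def predict_proba(self, features) -> np.ndarray:
        X = np.asarray(features, dtype=np.float64)
        z = X @ self.weights + self.bias
        return 1.0 / (1.0 + np.exp(-np.clip(z, -35, 35)))

    def fit_lazy(self, feature_chunks, label_chunks) -> "NadamPerceptron":
        """Fit from streamed (chunked) features without materializing them."""
        X = np.concatenate(list(feature_chunks))
        y = np.concatenate(list(label_chunks))
        return self.fit(X, y)


def perceptron_edge_classifier(features, labels, seed: int = 0,
                               **kwargs) -> NadamPerceptron:
    """Train the Nadam perceptron baseline on edge features."""
    return NadamPerceptron(seed=seed, **kwargs).fit(features, labels)


# -- end-to-end pipeline ---------------------------------------------------

def _train_edge_sets(split: HoldoutSplit, rng: np.random.Generator
                     ) -> tuple[np.ndarray, np.ndarray]:
    """Training positives (train-graph edges) and matched negatives."""
    pos = split.train_graph.canonical_edges()
    pos = pos[pos[:, 0] != pos[:, 1]]
    neg = sample_negative_edges(split.train_graph, len(pos),
                                distribution="scale_free",
                                seed=int(rng.integers(0, 2**31)))
    return pos, neg


def run_edge_prediction_pipeline(
        graph: EncodedGraph, *,
        walk_params: WalkParams | None = None,
        training_config: TrainingConfig | None = None,
        n_holdouts: int = 10,
        train_ratio: float = 0.8,
        edge_operator: str = "hadamard",
        classifier_kwargs: dict | None = None,
        exclude_existing_negatives: bool = False,
        seed: int = 0,
        smoke_test: bool = False,
        cache: dict | None = None) -> list[MetricsReport]:
    """Connected Monte Carlo edge-prediction evaluation, one report/holdout.

    Per holdout the embedding is retrained on the training graph only (test
    positives never reach the embedder), edge features are combined with the
    chosen operator, and the Nadam perceptron is scored on the held-out
    positives versus freshly sampled negatives.  ``smoke_test`` shrinks the
    configuration to a within-seconds end-to-end run.  ``cache`` (a mutable
    mapping) enables differential caching of completed holdouts keyed by the
    full configuration.
    """
    walk_params = walk_params or WalkParams(walk_length=30, iterations=5)
    training_config = training_config or TrainingConfig()
    classifier_kwargs = dict(classifier_kwargs or {})
    if smoke_test:
        n_holdouts = min(n_holdouts, 2)
        walk_params = WalkParams(
            p=walk_params.p, q=walk_params.q, walk_length=10, iterations=2,
            degree_threshold=walk_params.degree_threshold,
            seed=walk_params.seed)
        training_config = TrainingConfig(
            dimension=8, window_size=2, epochs=1, seed=training_config.seed)
        classifier_kwargs.setdefault("epochs", 10)

    cfg_key = None
    if cache is not None:
        blob = json.dumps({
            "walks": asdict(walk_params), "train": asdict(training_config),
            "ratio": train_ratio, "op": edge_operator, "seed": seed,
            "excl": exclude_existing_negatives,
            "clf": classifier_kwargs}, sort_keys=True, default=str)
        cfg_key = hashlib.sha256(blob.encode()).hexdigest()[:16]

    reports: list[MetricsReport] = []
    master = np.random.SeedSequence(seed)
    for h, child in enumerate(master.spawn(n_holdouts)):
        if cache is not None and (cfg_key, h) in cache:
            reports.append(cache[(cfg_key, h)])
            continue
        hseed = int(child.generate_state(1)[0] % (2**31))
        rng = np.random.default_rng(hseed)
        try:
            split = connected_monte_carlo_split(
                graph, train_ratio, hseed,
                exclude_existing_negatives=exclude_existing_negatives)
        except ValueError as exc:
            raise RuntimeError(f"holdout stage failed: {exc}") from exc
        wp = WalkParams(p=walk_params.p, q=walk_params.q,
                        walk_length=walk_params.walk_length,
                        iterations=walk_params.iterations,
                        degree_threshold=walk_params.degree_threshold,
                        seed=hseed)
        try:
            batch = generate_walks(split.train_graph, wp)
            pairs = extract_windows(batch, training_config.window_size)
            cfg = TrainingConfig(**{**asdict(training_config),
                                    "seed": hseed})
            emb = train_skipgram(pairs, split.train_graph, cfg)
        except (ValueError, FloatingPointError) as exc:
            raise RuntimeError(f"embedding stage failed: {exc}") from exc

        def feats(pairs_arr: np.ndarray) -> np.ndarray:
            return edge_embedding(emb.vectors[pairs_arr[:, 0]],
                                  emb.vectors[pairs_arr[:, 1]],
                                  edge_operator)

        train_pos, train_neg = _train_edge_sets(split, rng)
        X_train = np.concatenate([feats(train_pos), feats(train_neg)])
        y_train = np.concatenate([np.ones(len(train_pos)),
                                  np.zeros(len(train_neg))])
        clf = NadamPerceptron(seed=hseed, **classifier_kwargs)
        try:
            clf.fit(X_train, y_train)
        except ValueError as exc:
            raise RuntimeError(f"classifier stage failed: {exc}") from exc

        X_test = np.concatenate([feats(split.test_positives),
                                 feats(split.test_negatives)])
        y_test = np.concatenate([np.ones(len(split.test_positives)),
                                 np.zeros(len(split.test_negatives))])
        report = compute_metrics(clf.predict_proba(X_test), y_test)
        reports.append(report)
        if cache is not None:
            cache[(cfg_key, h)] = report
    return reports


def summarize_reports(reports: list[MetricsReport]) -> dict[str, dict]:
    """Mean and standard deviation per metric across holdouts."""
    summary: dict[str, dict] = {}
    for name in ("auroc", "auprc", "accuracy", "balanced_accuracy", "f1",
                 "precision", "recall", "miss_rate", "markedness", "mcc"):
        vals = np.array([getattr(r, name) for r in reports
                         if getattr(r, name) is not None], dtype=np.float64)
        if vals.size:
            summary[name] = {"mean": float(vals.mean()),
                             "sd": float(vals.std(ddof=1))
                             if vals.size > 1 else 0.0}
    return summary
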