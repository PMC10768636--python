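"""Holdout schemas, negative sampling, metrics, Nadam baseline, pipeline."""

import numpy as np
import pytest
from sklearn.linear_model import LogisticRegression

from efgraph import synthetic
from efgraph.evaluation import (NadamPerceptron, compute_metrics,
                                connected_monte_carlo_split,
                                perceptron_edge_classifier,
                                run_edge_prediction_pipeline,
                                sample_negative_edges, stratified_split,
                                summarize_reports)
from efgraph.graph import connected_components
from efgraph.walks import WalkParams


class TestConnectedMonteCarlo:
    def test_train_graph_stays_connected(self, small_sbm):
        for seed in range(5):
            split = connected_monte_carlo_split(small_sbm, 0.8, seed)
            labels = connected_components(split.train_graph)
            assert len(np.unique(labels)) == 1

    def test_component_count_preserved_on_disconnected_graph(self):
        g = synthetic.clique_pair(8, bridges=0)
        n_before = len(np.unique(connected_components(g)))
        split = connected_monte_carlo_split(g, 0.8, seed=1)
        n_after = len(np.unique(connected_components(split.train_graph)))
        assert n_after == n_before == 2

    def test_test_positives_absent_from_train(self, small_sbm):
        split = connected_monte_carlo_split(small_sbm, 0.8, seed=3)
        for a, b in split.test_positives:
            assert not split.train_graph.has_edge(int(a), int(b))
            assert small_sbm.has_edge(int(a), int(b))

    def test_split_sizes(self, small_sbm):
        split = connected_monte_carlo_split(small_sbm, 0.8, seed=4)
        n_edges = len(small_sbm.canonical_edges())
        assert len(split.test_positives) == round(0.2 * n_edges)
        assert len(split.test_negatives) == len(split.test_positives)

    def test_forest_graph_has_no_removable_edges(self):
        g = synthetic.path_graph(10)
        with pytest.raises(ValueError, match="forest"):
            connected_monte_carlo_split(g, 0.8, seed=0)
        split = connected_monte_carlo_split(g, 0.8, seed=0,
                                            allow_smaller_test=True)
        assert len(split.test_positives) == 0

    def test_infeasible_ratio_suggests_flag(self):
        # path + one chord: only 1 removable edge but 20% of 11 edges ~ 2
        g = synthetic.clique_pair(3, bridges=1)
        with pytest.raises(ValueError, match="allow_smaller_test"):
            connected_monte_carlo_split(g, 0.1, seed=0)

    def test_seed_reproducible(self, small_sbm):
        s1 = connected_monte_carlo_split(small_sbm, 0.8, seed=9)
        s2 = connected_monte_carlo_split(small_sbm, 0.8, seed=9)
        assert np.array_equal(s1.test_positives, s2.test_positives)
        assert np.array_equal(s1.test_negatives, s2.test_negatives)

    def test_exclude_existing_filters_true_edges(self):
        g = synthetic.stochastic_block_model([40, 40], 0.6, 0.01, seed=2)
        split = connected_monte_carlo_split(
            g, 0.8, seed=2, exclude_existing_negatives=True)
        for a, b in split.test_negatives:
            assert not g.has_edge(int(a), int(b))

    def test_rejects_directed(self):
        from efgraph.graph import EncodedGraph
        g = EncodedGraph(3, [0, 1], [1, 2], directed=True)
        with pytest.raises(ValueError, match="undirected"):
            connected_monte_carlo_split(g, 0.8, seed=0)


class TestStratifiedSplit:
    def test_per_class_fraction_within_one_node(self):
        labels = np.repeat([0, 1, 2], [10, 25, 7])
        train, test = stratified_split(labels, 0.8, seed=0)
        assert len(np.intersect1d(train, test)) == 0
        assert len(train) + len(test) == len(labels)
        for cls, size in zip([0, 1, 2], [10, 25, 7]):
            got = int(np.sum(labels[train] == cls))
            assert abs(got - 0.8 * size) <= 1.0

    def test_singleton_class_raises(self):
        with pytest.raises(ValueError, match="single node"):
            stratified_split([0, 0, 1], 0.8, seed=0)

    def test_every_class_in_both_sides(self):
        labels = np.repeat([0, 1], [2, 2])
        train, test = stratified_split(labels, 0.9, seed=1)
        assert set(labels[train]) == set(labels[test]) == {0, 1}


class TestNegativeSampling:
    def test_no_self_pairs_and_canonical(self, small_sbm):
        neg = sample_negative_edges(small_sbm, 500, seed=0)
        assert np.all(neg[:, 0] != neg[:, 1])
        assert np.all(neg[:, 0] < neg[:, 1])

    def test_uniform_distribution_option(self, small_sbm):
        neg = sample_negative_edges(small_sbm, 200, distribution="uniform",
                                    seed=1)
        assert len(neg) == 200

    def test_unknown_distribution(self, small_sbm):
        with pytest.raises(ValueError, match="unknown distribution"):
            sample_negative_edges(small_sbm, 10, distribution="alias")

    def test_exclude_existing(self, small_sbm):
        neg = sample_negative_edges(small_sbm, 300, seed=2,
                                    exclude_existing=True)
        for a, b in neg:
            assert not small_sbm.has_edge(int(a), int(b))

    def test_infeasible_exclusion_raises(self):
        from efgraph.graph import EncodedGraph
        # complete 3-node graph: no non-edges exist to sample
        full = EncodedGraph(3, [0, 0, 1, 1, 2, 2], [1, 2, 0, 2, 0, 1])
        with pytest.raises(ValueError, match="could only sample"):
            sample_negative_edges(full, 5, seed=0, exclude_existing=True)

    def test_scale_free_prefers_hubs(self):
        g = synthetic.hub_graph(100, extra_ring=True)
        neg = sample_negative_edges(g, 5000, seed=3)
        hub_rate = float(np.mean(np.any(neg == 0, axis=1)))
        unif = sample_negative_edges(g, 5000, distribution="uniform", seed=3)
        unif_rate = float(np.mean(np.any(unif == 0, axis=1)))
        assert hub_rate > 3 * unif_rate


class TestMetrics:
    def test_perfect_scores(self):
        r = compute_metrics([0.9, 0.8, 0.1, 0.2], [1, 1, 0, 0])
        assert r.auroc == 1.0 and r.auprc == 1.0
        assert r.accuracy == 1.0 and r.miss_rate == 0.0
        assert r.dor_is_infinite and r.diagnostic_odds_ratio == float("inf")
        assert r.markedness == 1.0 and r.mcc == 1.0

    def test_random_scores_near_half(self):
        rng = np.random.default_rng(0)
        labels = rng.integers(0, 2, size=4000)
        scores = rng.random(4000)
        r = compute_metrics(scores, labels)
        assert abs(r.auroc - 0.5) < 0.03
        assert abs(r.accuracy - 0.5) < 0.03

    def test_hand_confusion_matrix(self):
        # scores -> pred [1, 1, 0, 0, 1]; labels [1, 0, 0, 1, 1]
        # tp=2 fp=1 tn=1 fn=1
        r = compute_metrics([0.9, 0.7, 0.2, 0.3, 0.6], [1, 0, 0, 1, 1])
        assert r.precision == pytest.approx(2 / 3)
        assert r.recall == pytest.approx(2 / 3)
        assert r.miss_rate == pytest.approx(1 / 3)
        assert r.diagnostic_odds_ratio == pytest.approx((2 / 1) / (1 / 1))
        assert r.markedness == pytest.approx(2 / 3 + 1 / 2 - 1)
        assert not r.dor_is_infinite

    def test_single_class_rank_metrics_none(self):
        r = compute_metrics([0.9, 0.3], [1, 1])
        assert r.auroc is None and r.auprc is None

    def test_length_mismatch(self):
        with pytest.raises(ValueError):
            compute_metrics([0.5], [1, 0])

    def test_matches_sklearn_rank_metrics(self, rng):
        from sklearn.metrics import roc_auc_score
        labels = rng.integers(0, 2, size=500)
        labels[0], labels[1] = 0, 1
        scores = rng.random(500) * 0.5 + labels * 0.3
        r = compute_metrics(scores, labels)
        assert r.auroc == pytest.approx(roc_auc_score(labels, scores))


class TestNadamPerceptron:
    def _blobs(self, n=400, seed=0):
        rng = np.random.default_rng(seed)
        X = np.concatenate([rng.normal(-1.0, 0.6, size=(n // 2, 4)),
                            rng.normal(1.0, 0.6, size=(n // 2, 4))])
        y = np.repeat([0, 1], n // 2)
        return X, y

    def test_separable_blobs(self):
        X, y = self._blobs()
        clf = NadamPerceptron(seed=0).fit(X, y)
        acc = float(np.mean((clf.predict_proba(X) >= 0.5) == y))
        assert acc > 0.95

    def test_close_to_sklearn_logistic(self):
        X, y = self._blobs(seed=1)
        ours = NadamPerceptron(seed=0, epochs=100).fit(X, y)
        ref = LogisticRegression().fit(X, y)
        ours_acc = float(np.mean((ours.predict_proba(X) >= 0.5) == y))
        ref_acc = ref.score(X, y)
        assert ours_acc >= ref_acc - 0.02

    def test_single_class_rejected(self):
        X = np.zeros((5, 2))
        with pytest.raises(ValueError, match="per class"):
            NadamPerceptron().fit(X, np.ones(5))

    def test_constant_features_warn(self):
        X = np.ones((10, 2))
        y = np.tile([0, 1], 5)
        with pytest.warns(UserWarning, match="constant"):
            NadamPerceptron(epochs=1).fit(X, y)

    def test_seed_reproducible(self):
        X, y = self._blobs(seed=2)
        w1 = NadamPerceptron(seed=5, epochs=5).fit(X, y).weights
        w2 = NadamPerceptron(seed=5, epochs=5).fit(X, y).weights
        assert np.array_equal(w1, w2)

    def test_fit_lazy_matches_fit(self):
        X, y = self._blobs(seed=3)
        a = NadamPerceptron(seed=1, epochs=5).fit(X, y)
        b = NadamPerceptron(seed=1, epochs=5).fit_lazy(
            (X[i:i + 100] for i in range(0, len(X), 100)),
            (y[i:i + 100] for i in range(0, len(y), 100)))
        assert np.array_equal(a.weights, b.weights)

    def test_helper(self):
        X, y = self._blobs(seed=4)
        clf = perceptron_edge_classifier(X, y, seed=0, epochs=5)
        assert clf.weights is not None


class TestPipeline:
    def test_smoke_run_produces_reports(self, small_sbm):
        cache = {}
        reports = run_edge_prediction_pipeline(
            small_sbm, n_holdouts=2, seed=0, smoke_test=True, cache=cache)
        assert len(reports) == 2
        for r in reports:
            assert r.auroc is not None and 0.0 <= r.auroc <= 1.0
        assert len(cache) == 2

    def test_cache_short_circuits(self, small_sbm):
        cache = {}
        r1 = run_edge_prediction_pipeline(
            small_sbm, n_holdouts=2, seed=0, smoke_test=True, cache=cache)
        r2 = run_edge_prediction_pipeline(
            small_sbm, n_holdouts=2, seed=0, smoke_test=True, cache=cache)
        assert [a.as_dict() for a in r1] == [b.as_dict() for b in r2]
        assert len(cache) == 2  # nothing recomputed under a new key

    def test_stage_error_names_stage(self):
        g = synthetic.path_graph(6)  # a forest: holdout stage must fail
        with pytest.raises(RuntimeError, match="holdout stage"):
            run_edge_prediction_pipeline(g, n_holdouts=1, seed=0,
                                         smoke_test=True)

    def test_summary_shape(self, small_sbm):
        reports = run_edge_prediction_pipeline(
            small_sbm, n_holdouts=2, seed=1, smoke_test=True)
        summary = summarize_reports(reports)
        assert "auroc" in summary and "mean" in summary["auroc"]
        assert summary["accuracy"]["sd"] >= 0.0
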