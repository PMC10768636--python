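"""Second-order bias decomposition, SUSS, cumsum sampling, walk generation."""

import numpy as np
import pytest
from scipy import stats

from efgraph import synthetic
from efgraph.experiments import reference_search_bias_masses
from efgraph.walks import (LINEAR_SCAN_THRESHOLD, WalkParams,
                           approximated_second_order_masses,
                           dispatch_specialization, first_order_walk,
                           generate_walks, sample_from_cumsum,
                           second_order_masses, second_order_walk,
                           sorted_set_difference, suss_sample, walk_rng,
                           write_walks)


class TestParams:
    def test_defaults(self):
        p = WalkParams()
        assert p.p == 1.0 and p.q == 1.0
        assert p.linear_scan_threshold == LINEAR_SCAN_THRESHOLD == 128

    @pytest.mark.parametrize("kw", [
        dict(p=0.0), dict(q=-1.0), dict(p=float("inf")),
        dict(walk_length=0), dict(iterations=0), dict(degree_threshold=1),
    ])
    def test_validation(self, kw):
        with pytest.raises(ValueError):
            WalkParams(**kw)


class TestSortedSetDifference:
    def test_basic(self):
        out = sorted_set_difference(np.array([1, 3, 5, 7]),
                                    np.array([3, 4, 7]))
        assert out.tolist() == [1, 5]

    def test_empty_b(self):
        assert sorted_set_difference(np.array([1, 2]),
                                     np.array([], dtype=np.int64)).tolist() \
            == [1, 2]

    def test_rejects_unsorted(self):
        with pytest.raises(ValueError):
            sorted_set_difference(np.array([2, 1]), np.array([1]))

    def test_matches_python_sets(self, rng):
        for _ in range(50):
            a = np.unique(rng.integers(0, 100, size=rng.integers(0, 30)))
            b = np.unique(rng.integers(0, 100, size=rng.integers(0, 30)))
            expect = sorted(set(a.tolist()) - set(b.tolist()))
            assert sorted_set_difference(a, b).tolist() == expect


class TestBiasDecomposition:
    def test_hand_worked_fixture(self, bias_fixture):
        # walk at v=1 coming from t=0, p=2, q=4.
        # N(1) = {0, 2, 3}: 0 is the return node (1/p), 2 is adjacent to
        # t (bias 1), 3 is outside N(t) u {t} (1/q) -> masses 1/2, 1, 1/4,
        # normalized (2/7, 4/7, 1/7).
        dist = second_order_masses(bias_fixture, 0, 1,
                                   WalkParams(p=2.0, q=4.0))
        assert dist.candidates.tolist() == [0, 2, 3]
        np.testing.assert_allclose(dist.normalized(),
                                   [2 / 7, 4 / 7, 1 / 7])

    def test_requires_edge(self, bias_fixture):
        with pytest.raises(ValueError, match="not an edge"):
            second_order_masses(bias_fixture, 0, 3, WalkParams())

    def test_p1_q1_is_uniform(self, bias_fixture):
        dist = second_order_masses(bias_fixture, 0, 1, WalkParams())
        np.testing.assert_allclose(dist.masses, 1.0)

    def test_matches_distance_oracle_on_random_graphs(self):
        params_grid = [(0.25, 1.0), (1.0, 4.0), (0.5, 2.0), (4.0, 0.25)]
        for gseed in range(5):
            g = synthetic.erdos_renyi(30, 0.2, seed=gseed)
            s, d = g.edge_array()
            for p, q in params_grid:
                wp = WalkParams(p=p, q=q)
                for e in range(0, len(s), 17):
                    t, v = int(s[e]), int(d[e])
                    dist = second_order_masses(g, t, v, wp)
                    ref = reference_search_bias_masses(g, t, v, p, q)
                    np.testing.assert_allclose(dist.masses, ref, atol=1e-12)

    def test_weighted_masses_scale_with_weight(self):
        from efgraph.graph import EncodedGraph
        gw = EncodedGraph(4, [0, 1, 1, 2, 2, 3], [1, 0, 2, 1, 3, 2],
                          directed=True,
                          weights=[1.0, 1.0, 5.0, 5.0, 1.0, 1.0])
        dist = second_order_masses(gw, 0, 1, WalkParams())
        assert dist.candidates.tolist() == [0, 2]
        np.testing.assert_allclose(dist.masses, [1.0, 5.0])

    def test_all_eight_specializations_tagged(self):
        tags = {dispatch_specialization(WalkParams(p=p, q=q), w)
                for p in (1.0, 2.0) for q in (1.0, 2.0)
                for w in (False, True)}
        assert len(tags) == 8


class TestSuss:
    def test_output_sorted_unique(self, rng):
        for _ in range(100):
            n = int(rng.integers(5, 500))
            k = int(rng.integers(1, n + 1))
            out = suss_sample(n, k, rng)
            assert len(out) == k
            assert np.all(np.diff(out) > 0)
            assert out[0] >= 0 and out[-1] < n

    def test_k_equals_n_returns_everything(self):
        out = suss_sample(7, 7, np.random.default_rng(0))
        assert out.tolist() == list(range(7))

    def test_rejects_k_above_n(self):
        with pytest.raises(ValueError):
            suss_sample(3, 4, np.random.default_rng(0))

    def test_bucket_containment(self, rng):
        n, k = 100, 10
        for _ in range(20):
            out = suss_sample(n, k, rng)
            for j in range(k - 1):
                assert 10 * j <= out[j] < 10 * (j + 1)
            assert 90 <= out[-1] < 100

    def test_k1_is_uniform_chi_square(self):
        # with k=1 every value of [0, n) must be equally likely
        rng = np.random.default_rng(7)
        n, draws = 101, 50_000
        counts = np.bincount(
            np.concatenate([suss_sample(n, 1, rng) for _ in range(draws)]),
            minlength=n)
        p = stats.chisquare(counts).pvalue
        assert p > 1e-4


class TestCumsumSampling:
    def test_linear_and_binary_agree(self, rng):
        for size in (3, 50, 127, 128, 129, 500):
            masses = rng.random(size) + 0.01
            cum = np.cumsum(masses)
            for _ in range(50):
                draw = rng.uniform(0, cum[-1])
                lin = sample_from_cumsum(cum, draw, 10**9)
                binr = sample_from_cumsum(cum, draw, 0)
                assert lin == binr

    def test_zero_mass_raises(self):
        with pytest.raises(ValueError, match="dead end"):
            sample_from_cumsum(np.array([0.0, 0.0]), 0.0)

    def test_empirical_frequencies(self):
        rng = np.random.default_rng(3)
        masses = np.array([1.0, 2.0, 7.0])
        cum = np.cumsum(masses)
        draws = rng.uniform(0, cum[-1], size=30_000)
        idx = np.array([sample_from_cumsum(cum, d) for d in draws])
        freq = np.bincount(idx, minlength=3) / len(idx)
        np.testing.assert_allclose(freq, masses / masses.sum(), atol=0.02)


class TestWalks:
    def test_first_order_length_and_adjacency(self, small_sbm):
        wp = WalkParams(walk_length=20, seed=1)
        walk = first_order_walk(small_sbm, 0, wp)
        assert len(walk) == 20
        for a, b in zip(walk[:-1], walk[1:]):
            assert small_sbm.has_edge(int(a), int(b))

    def test_second_order_adjacency(self, small_sbm):
        wp = WalkParams(p=0.5, q=2.0, walk_length=30, seed=2)
        walk = second_order_walk(small_sbm, 5, wp)
        assert len(walk) == 30
        for a, b in zip(walk[:-1], walk[1:]):
            assert small_sbm.has_edge(int(a), int(b))

    def test_sink_truncation(self):
        from efgraph.graph import EncodedGraph
        g = EncodedGraph(3, [0], [1], directed=True)
        walk = second_order_walk(g, 0, WalkParams(walk_length=10, seed=0))
        assert walk.tolist() == [0, 1]
        assert first_order_walk(g, 2, WalkParams(walk_length=5)).tolist() \
            == [2]

    def test_reproducible_streams(self, small_sbm):
        wp = WalkParams(p=2.0, q=0.5, walk_length=15, seed=42)
        w1 = second_order_walk(small_sbm, 3, wp, walk_rng(42, 0, 3))
        w2 = second_order_walk(small_sbm, 3, wp, walk_rng(42, 0, 3))
        w3 = second_order_walk(small_sbm, 3, wp, walk_rng(43, 0, 3))
        assert np.array_equal(w1, w2)
        assert not np.array_equal(w1, w3)  # overwhelmingly likely

    def test_generate_walks_shape(self, small_sbm):
        wp = WalkParams(walk_length=5, iterations=2, seed=0)
        batch = generate_walks(small_sbm, wp)
        assert len(batch) == 2 * small_sbm.num_nodes
        assert batch.iterations == 2

    def test_approximated_walker_on_hub(self):
        g = synthetic.hub_graph(200)
        wp = WalkParams(p=2.0, q=0.5, walk_length=25, seed=0,
                        degree_threshold=10)
        walk = second_order_walk(g, 0, wp)
        assert len(walk) == 25
        for a, b in zip(walk[:-1], walk[1:]):
            assert g.has_edge(int(a), int(b))

    def test_approximated_candidate_count(self):
        g = synthetic.hub_graph(200)
        wp = WalkParams(degree_threshold=10)
        rng = np.random.default_rng(0)
        dist = approximated_second_order_masses(g, 1, 0, wp, rng)
        assert len(dist.candidates) == 10
        assert np.all(np.diff(dist.candidates) > 0)

    def test_approximated_falls_back_below_threshold(self, bias_fixture):
        wp = WalkParams(p=2.0, q=4.0, degree_threshold=10)
        rng = np.random.default_rng(0)
        dist = approximated_second_order_masses(bias_fixture, 0, 1, wp, rng)
        np.testing.assert_allclose(dist.normalized(), [2 / 7, 4 / 7, 1 / 7])

    def test_write_walks(self, tmp_path, triangle):
        wp = WalkParams(walk_length=4, iterations=1, seed=0)
        batch = generate_walks(triangle, wp)
        out = tmp_path / "walks.txt"
        write_walks(batch, out, [str(i) for i in range(3)])
        lines = out.read_text().splitlines()
        assert len(lines) == 3
        assert all(len(line.split()) == 4 for line in lines)


def test_return_parameter_controls_backtracking(small_sbm):
    """Small p must produce more immediate returns than large p."""
    def backtrack_rate(p):
        wp = WalkParams(p=p, q=1.0, walk_length=40, seed=7)
        back = total = 0
        for src in range(0, small_sbm.num_nodes, 4):
            w = second_order_walk(small_sbm, src, wp, walk_rng(7, 0, src))
            back += int(np.sum(w[2:] == w[:-2]))
            total += max(len(w) - 2, 0)
        return back / total

    assert backtrack_rate(0.1) > backtrack_rate(10.0) + 0.1
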