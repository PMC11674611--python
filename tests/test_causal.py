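"""Pairwise Granger causality: detrending, order selection, the F statistic
and the batched all-pairs causal matrix."""

import numpy as np
import pytest

from hbnet.causal import causal_matrix, detrend_window, granger_pair, select_order
from hbnet.containers import WindowSample
from hbnet.errors import NumericalError
from hbnet.synthetic import simulate_var_sources


def _window(data):
    return WindowSample(data=data, t_start=0.0)


def _brute_force_gc(a, b, p):
    """Independent oracle: explicit normal-equations OLS for both models."""
    r = len(a)
    y = a[p:]
    Za = np.column_stack([a[p - k : r - k] for k in range(1, p + 1)])
    Zb = np.column_stack([b[p - k : r - k] for k in range(1, p + 1)])
    Z = np.hstack([Za, Zb])
    beta_r = np.linalg.solve(Za.T @ Za, Za.T @ y)
    beta_f = np.linalg.solve(Z.T @ Z, Z.T @ y)
    rss_r = np.sum((y - Za @ beta_r) ** 2)
    rss_f = np.sum((y - Z @ beta_f) ** 2)
    return np.log(rss_r / rss_f)


class TestDetrendWindow:
    def test_exact_line_becomes_zero(self):
        t = np.arange(100.0)
        w = _window(np.column_stack([2.0 + 0.3 * t, -1.0 + 5.0 * t]))
        out = detrend_window(w)
        assert np.allclose(out.data, 0.0, atol=1e-9)

    def test_output_mean_is_zero(self, rng):
        w = _window(rng.normal(size=(200, 3)))
        out = detrend_window(w)
        assert np.abs(out.data.mean(axis=0)).max() < 1e-10

    def test_equals_input_minus_polyfit_prediction(self, rng):
        x = rng.normal(size=300).cumsum()
        w = _window(x[:, None])
        out = detrend_window(w)
        t = np.arange(300.0)
        coeffs = np.polyfit(t, x, 1)
        assert np.allclose(out.data[:, 0], x - np.polyval(coeffs, t), atol=1e-8)


class TestGrangerPair:
    def test_independent_series_give_small_f(self, rng):
        r, p = 600, 2
        fs = []
        for _ in range(100):
            a = rng.normal(size=r)
            b = rng.normal(size=r)
            fs.append(granger_pair(a, b, p))
        # under the null E[F] ~ p / N_eff
        assert np.mean(fs) < 0.02

    def test_strong_coupling_gives_large_f(self, rng):
        n = 600
        b = rng.normal(size=n + 1)
        a = 0.9 * b[:-1] + 0.01 * rng.normal(size=n)
        assert granger_pair(a, b[1:], 1) > 1.0

    def test_matches_brute_force_ols(self, rng):
        A = np.array([[0.5, 0.2], [0.3, 0.4]])
        S = simulate_var_sources(A, 1, 600, 200.0, 1.0, seed=4)
        a, b = S.data[0], S.data[1]
        for p in (1, 2, 3):
            assert granger_pair(a, b, p) == pytest.approx(
                max(_brute_force_gc(a, b, p), 0.0), abs=1e-10
            )

    def test_matches_statsmodels_granger_statistic(self, rng):
        # statsmodels fits with an intercept, so compare on zero-mean data
        # with a loose tolerance; it is an independent implementation.
        from statsmodels.tsa.stattools import grangercausalitytests

        A = np.array([[0.4, 0.0], [0.5, 0.4]])
        S = simulate_var_sources(A, 1, 2000, 200.0, 1.0, seed=8)
        a, b = S.data[1] - S.data[1].mean(), S.data[0] - S.data[0].mean()
        p = 1
        res = grangercausalitytests(np.column_stack([a, b]), maxlag=[p])
        restricted, full = res[p][1][0], res[p][1][1]
        expected = np.log(restricted.ssr / full.ssr)
        assert granger_pair(a, b, p) == pytest.approx(expected, rel=0.02)

    def test_nonnegative_for_random_series(self, rng):
        for _ in range(20):
            a, b = rng.normal(size=100), rng.normal(size=100)
            assert granger_pair(a, b, 3) >= 0.0

    def test_scale_invariance(self, rng):
        a, b = rng.normal(size=300), rng.normal(size=300)
        f1 = granger_pair(a, b, 2)
        f2 = granger_pair(1e4 * a, 1e4 * b, 2)
        assert f1 == pytest.approx(f2, abs=1e-10)

    def test_constant_series_rejected(self, rng):
        with pytest.raises(NumericalError):
            granger_pair(np.ones(100), rng.normal(size=100), 2)


class TestSelectOrder:
    def test_var2_order_recovered(self):
        hits = 0
        for seed in range(50):
            A = np.array(
                [
                    [[0.5, 0.0], [0.2, 0.5]],
                    [[0.3, 0.0], [0.15, 0.3]],
                ]
            )
            S = simulate_var_sources(A, 2, 2000, 200.0, 1.0, seed=seed)
            w = detrend_window(_window(S.data.T))
            hits += select_order(w, p_max=5) == 2
        assert hits >= 45

    def test_white_noise_selects_smallest_order(self, rng):
        votes = []
        for _ in range(20):
            w = _window(rng.normal(size=(1500, 2)))
            votes.append(select_order(w, p_max=5))
        assert np.mean(np.asarray(votes) == 1) > 0.5

    def test_pmax_one_returns_one(self, rng):
        w = _window(rng.normal(size=(200, 2)))
        assert select_order(w, p_max=1) == 1

    def test_pmax_below_one_rejected(self, rng):
        with pytest.raises(ValueError):
            select_order(_window(rng.normal(size=(200, 2))), p_max=0)


class TestCausalMatrix:
    def test_two_nodes_compose_from_pairwise_values(self, rng):
        w = detrend_window(_window(rng.normal(size=(400, 2)).cumsum(axis=0) * 0.01
                                   + rng.normal(size=(400, 2))))
        cm = causal_matrix(w, 2)
        a, b = w.data[:, 0], w.data[:, 1]
        assert cm.g[0, 1] == pytest.approx(granger_pair(b, a, 2), abs=1e-10)
        assert cm.g[1, 0] == pytest.approx(granger_pair(a, b, 2), abs=1e-10)
        assert cm.g[0, 0] == cm.g[1, 1] == 0.0

    def test_independent_sources_have_small_entries(self, rng):
        maxima = []
        for _ in range(100):
            w = _window(rng.normal(size=(600, 3)))
            maxima.append(causal_matrix(w, 2).g.max())
        assert np.mean(maxima) < 0.05

    def test_chain_edges_dominate_reverse_and_skip(self):
        A = np.zeros((3, 3))
        A[0, 0] = A[1, 1] = A[2, 2] = 0.3
        A[1, 0] = A[2, 1] = 0.5  # 1 -> 2 -> 3
        gs = []
        for seed in range(10):
            S = simulate_var_sources(A, 1, 600, 200.0, 1.0, seed=seed)
            w = detrend_window(_window(S.data.T))
            gs.append(causal_matrix(w, 1).g)
        g = np.mean(gs, axis=0)
        for fwd in (g[0, 1], g[1, 2]):
            assert fwd > g[1, 0] and fwd > g[2, 1] and fwd > g[0, 2]

    def test_matches_granger_pair_for_all_ordered_pairs(self, chain_adjacency, rng):
        A, _ = chain_adjacency
        S = simulate_var_sources(A, 2, 600, 200.0, 1.0, seed=3)
        w = detrend_window(_window(S.data.T))
        cm = causal_matrix(w, 2)
        c = A.shape[0]
        for i in range(c):
            for j in range(c):
                if i == j:
                    continue
                expected = granger_pair(w.data[:, j], w.data[:, i], 2)
                assert cm.g[i, j] == pytest.approx(expected, abs=1e-10)
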