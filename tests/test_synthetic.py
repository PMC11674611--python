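"""Ground-truth simulator: VAR dynamics, scalp projection, fNIRS forward model."""

import numpy as np
import pytest
from scipy import linalg as sla

from hbnet.config import SimConfig
from hbnet.containers import SourceSignals
from hbnet.coupling import hrf_kernel, predict_fnirs, stft_power, timevarying_power
from hbnet.errors import StabilityError
from hbnet.synthetic import (
    _lag_matrices,
    _perturb_class_templates,
    _random_base_templates,
    companion_spectral_radius,
    modulate_sources,
    project_to_scalp,
    simulate_dataset,
    simulate_fnirs,
    simulate_var_sources,
)


class TestSimulateVarSources:
    def test_zero_adjacency_gives_independent_white_noise(self):
        c, n = 3, 4000
        S = simulate_var_sources(np.zeros((c, c)), 1, n, 200.0, 1.0, seed=1)
        x = S.data
        for i in range(c):
            for j in range(c):
                if i == j:
                    continue
                r = np.corrcoef(x[i, :-1], x[j, 1:])[0, 1]
                assert abs(r) < 3 / np.sqrt(n)

    def test_same_seed_is_bit_identical(self, chain_adjacency):
        A, _ = chain_adjacency
        a = simulate_var_sources(A, 2, 1000, 200.0, 1.0, seed=5)
        b = simulate_var_sources(A, 2, 1000, 200.0, 1.0, seed=5)
        assert np.array_equal(a.data, b.data)

    def test_lag1_cross_covariance_matches_yule_walker(self):
        # 2-node chain x1 -> x2, gain 0.5, VAR(1): the stationary covariance
        # solves the discrete Lyapunov equation G0 = A G0 A' + I, and the
        # lag-1 cross-covariance is (A G0)[1, 0].
        A = np.array([[0.5, 0.0], [0.5, 0.5]])
        n = 5000
        S = simulate_var_sources(A, 1, n, 200.0, 1.0, seed=2)
        G0 = sla.solve_discrete_lyapunov(A, np.eye(2))
        expected = (A @ G0)[1, 0]
        x = S.data
        sample = np.mean((x[0, :-1] - x[0].mean()) * (x[1, 1:] - x[1].mean()))
        assert sample == pytest.approx(expected, rel=0.05)

    def test_unstable_var_raises(self):
        A = np.array([[1.1, 0.0], [0.0, 0.5]])
        with pytest.raises(StabilityError):
            simulate_var_sources(A, 1, 1000, 200.0, 1.0, seed=0)

    def test_nonpositive_noise_sd_rejected(self):
        with pytest.raises(ValueError):
            simulate_var_sources(np.zeros((2, 2)), 1, 1000, 200.0, 0.0, seed=0)


class TestProjectToScalp:
    def test_identity_lead_field_reproduces_sources(self, var_sources):
        c = var_sources.n_regions
        X = project_to_scalp(var_sources, np.eye(c), np.arange(1, c + 1), 0.0, seed=0)
        assert np.allclose(X, var_sources.data)

    def test_zero_sources_give_pure_noise(self):
        S = SourceSignals(np.zeros((3, 20000)), ["a", "b", "c"], 200.0)
        X = project_to_scalp(S, np.eye(3), np.array([1, 2, 3]), 1.0, seed=3)
        assert abs(X.std() - 1.0) < 0.1

    def test_residual_sd_matches_sensor_noise(self, rng):
        c, u, v, n = 4, 8, 20, 10000
        S = SourceSignals(rng.normal(size=(c, n)), [f"r{i}" for i in range(c)], 200.0)
        L = rng.normal(size=(u, v))
        membership = 1 + np.arange(v) % c
        X = project_to_scalp(S, L, membership, 0.7, seed=9)
        resid = X - L @ S.data[membership - 1]
        assert resid.std() == pytest.approx(0.7, rel=0.05)

    def test_membership_outside_sources_raises(self, var_sources):
        with pytest.raises(IndexError):
            project_to_scalp(
                var_sources, np.eye(9, 9), np.arange(1, 10), 0.0, seed=0
            )


class TestSimulateFnirs:
    def test_zero_weights_zero_noise_is_zero(self, var_sources):
        y = simulate_fnirs(var_sources, np.zeros((8, 3)), 11.0, 0.0, seed=0)
        assert np.allclose(y, 0.0)

    def test_single_source_equals_predict_fnirs(self, var_sources):
        S1 = SourceSignals(var_sources.data[:1], ["r1"], 200.0)
        y = simulate_fnirs(S1, np.ones((1, 1)), 200.0, 0.0, seed=0)
        P, freqs, times = stft_power(S1.data[0], 200.0)
        p = timevarying_power(P, freqs, times, n_out=S1.n_samples, fs_out=200.0)
        expected = predict_fnirs(p, hrf_kernel(200.0))
        assert np.allclose(y[0], expected)

    def test_linear_in_coupling_weights(self, var_sources):
        S2 = SourceSignals(var_sources.data[:2], ["r1", "r2"], 200.0)
        y1 = simulate_fnirs(S2, np.array([[1.0], [0.0]]), 200.0, 0.0, seed=0)
        y2 = simulate_fnirs(S2, np.array([[0.0], [1.0]]), 200.0, 0.0, seed=0)
        y12 = simulate_fnirs(S2, np.array([[1.0], [2.0]]), 200.0, 0.0, seed=0)
        assert np.allclose(y12, y1 + 2 * y2, rtol=1e-10, atol=1e-12)

    def test_shape_mismatch_raises(self, var_sources):
        with pytest.raises(ValueError):
            simulate_fnirs(var_sources, np.zeros((5, 2)), 11.0, 0.0, seed=0)


class TestModulateSources:
    def test_zero_depth_is_noop(self, var_sources):
        out = modulate_sources(var_sources, 0.0, seed=1)
        assert np.array_equal(out.data, var_sources.data)

    def test_class_profiles_shared_across_trials(self, var_sources):
        a = modulate_sources(var_sources, 0.5, seed=1, class_seed=9, class_frac=1.0)
        b = modulate_sources(var_sources, 0.5, seed=2, class_seed=9, class_frac=1.0)
        assert np.allclose(a.data, b.data)

    def test_depth_out_of_range_rejected(self, var_sources):
        with pytest.raises(ValueError):
            modulate_sources(var_sources, 1.5, seed=0)


@pytest.fixture(scope="module")
def small_cfg():
    return SimConfig(
        c=4, d=2, u=6, v=8, n_classes=4, trials_per_class=10,
        trial_s=5.0, n_edges=3, seed=3,
    )


class TestSimulateDataset:
    def test_balanced_labels(self, small_cfg):
        ds = simulate_dataset(small_cfg)
        assert len(ds.trials) == 40
        labels = [t[2] for t in ds.trials]
        assert np.bincount(labels).tolist() == [10, 10, 10, 10]

    def test_zero_effect_size_gives_identical_templates(self, small_cfg):
        cfg = small_cfg.model_copy(update={"effect_size": 0.0})
        ds = simulate_dataset(cfg)
        gt = ds.ground_truth
        for k in range(cfg.n_classes):
            assert np.allclose(gt.class_adjacency[k], gt.adjacency)
            assert np.allclose(gt.class_coupling[k], gt.coupling_weights)

    def test_fixed_seed_reproduces_everything(self, small_cfg):
        a = simulate_dataset(small_cfg)
        b = simulate_dataset(small_cfg)
        assert np.array_equal(a.ground_truth.adjacency, b.ground_truth.adjacency)
        assert np.array_equal(a.ground_truth.labels, b.ground_truth.labels)
        for (ea, fa, la), (eb, fb, lb) in zip(a.trials, b.trials):
            assert np.array_equal(ea, eb) and np.array_equal(fa, fb) and la == lb

    def test_every_region_has_a_dipole(self, small_cfg):
        ds = simulate_dataset(small_cfg)
        assert set(ds.membership) == set(range(1, small_cfg.c + 1))

    def test_all_class_templates_stable_over_many_configs(self):
        # stability must hold before any trial is emitted, whatever the draw
        for i in range(100):
            cfg = SimConfig(
                c=int(3 + i % 6), d=2, u=6, v=12, n_edges=int(2 + i % 7),
                effect_size=0.2 + (i % 5) * 0.2, var_order=1 + i % 3, seed=i,
            )
            rng = np.random.default_rng(cfg.seed)
            A, W = _random_base_templates(cfg, rng)
            class_A, _ = _perturb_class_templates(cfg, A, W, rng)
            for k in range(cfg.n_classes):
                rho = companion_spectral_radius(_lag_matrices(class_A[k], cfg.var_order))
                assert rho < 1.0
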