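"""Neurovascular coupling: STFT power, HRF, convolution, GLM, trial pipeline."""

import math

import numpy as np
import pytest

from hbnet.containers import SourceSignals, TimeVaryingPower
from hbnet.coupling import (
    coupling_matrix,
    glm_fit,
    hrf_kernel,
    predict_fnirs,
    stft_power,
    timevarying_power,
    trial_coupling,
)
from hbnet.errors import NumericalError
from hbnet.preprocess import segment
from hbnet.synthetic import simulate_fnirs, simulate_var_sources


class TestStftPower:
    def test_zero_signal_zero_spectrogram(self):
        P, _, _ = stft_power(np.zeros(1000), 200.0)
        assert np.allclose(P, 0.0)

    def test_peak_at_tone_frequency(self):
        t = np.arange(2000) / 200.0
        P, freqs, _ = stft_power(np.sin(2 * np.pi * 10.0 * t), 200.0)
        assert freqs[np.argmax(P.mean(axis=0))] == pytest.approx(10.0, abs=1.0)

    def test_matches_brute_force_windowed_dft(self, rng):
        s = rng.normal(size=256)
        fs, win_s, hop_s = 64.0, 0.5, 0.25
        P, freqs, times = stft_power(s, fs, win_s, hop_s)
        m, hop = 32, 16
        h = 0.5 - 0.5 * np.cos(2 * np.pi * np.arange(m) / m)  # periodic Hann
        for fi, frame_start in enumerate(range(0, 256 - m + 1, hop)):
            seg = s[frame_start : frame_start + m] * h
            for ki in range(m // 2 + 1):
                dft = sum(
                    seg[n_] * np.exp(-2j * np.pi * ki * n_ / m) for n_ in range(m)
                )
                assert P[fi, ki] == pytest.approx(abs(dft) ** 2, abs=1e-8)

    def test_window_longer_than_signal_rejected(self, rng):
        with pytest.raises(ValueError):
            stft_power(rng.normal(size=50), 200.0, win_s=1.0)


class TestTimevaryingPower:
    def test_steady_tone_gives_flat_envelope(self):
        t = np.arange(4000) / 200.0
        P, freqs, times = stft_power(np.sin(2 * np.pi * 10.0 * t), 200.0)
        tvp = timevarying_power(P, freqs, times)
        assert tvp.p.max() - tvp.p.min() < 0.2 or np.allclose(tvp.p, 0.0)

    def test_burst_raises_second_half(self, rng):
        n = 4000
        t = np.arange(n) / 200.0
        s = np.sin(2 * np.pi * 10.0 * t)
        s[n // 2 :] *= 3.0
        P, freqs, times = stft_power(s, 200.0)
        tvp = timevarying_power(P, freqs, times, n_out=n, fs_out=200.0)
        assert tvp.p[n // 2 :].mean() > tvp.p[: n // 2].mean()

    def test_zero_signal_maps_to_zeros(self):
        P, freqs, times = stft_power(np.zeros(1000), 200.0)
        tvp = timevarying_power(P, freqs, times, n_out=1000, fs_out=200.0)
        assert np.allclose(tvp.p, 0.0)

    def test_empty_band_rejected(self):
        P, freqs, times = stft_power(np.zeros(1000), 200.0)
        with pytest.raises(ValueError):
            timevarying_power(P, freqs, times, f_min=300.0, f_max=400.0)


class TestHrfKernel:
    def test_zero_at_origin(self):
        assert hrf_kernel(200.0).samples[0] == 0.0

    def test_peak_between_4p5_and_5p5_seconds(self):
        k = hrf_kernel(200.0)
        t_peak = np.argmax(k.samples) * k.dt
        assert 4.5 < t_peak < 5.5

    def test_undershoot_negative_at_15_seconds(self):
        k = hrf_kernel(200.0)
        assert k.samples[int(15.0 / k.dt)] < 0.0

    def test_matches_direct_gamma_formula(self):
        k = hrf_kernel(10.0)
        for idx in (7, 40, 100, 250):
            t = idx * k.dt
            expected = (
                t**5 * math.exp(-t) / math.gamma(6)
                - t**15 * math.exp(-t) / math.gamma(16) / 16.0
            )
            assert k.samples[idx] == pytest.approx(expected, rel=1e-12)

    def test_single_sign_change_after_peak(self):
        k = hrf_kernel(50.0)
        after_peak = k.samples[np.argmax(k.samples) :]
        signs = np.sign(after_peak[np.abs(after_peak) > 1e-12])
        assert np.count_nonzero(np.diff(signs)) == 1


class TestPredictFnirs:
    def test_impulse_reproduces_kernel(self):
        k = hrf_kernel(20.0, duration_s=10.0)
        n = 150
        p = np.zeros(n)
        p[0] = 1.0
        y = predict_fnirs(TimeVaryingPower(p, 20.0), k)
        assert np.allclose(y, k.samples[:n] * k.dt)

    def test_zero_power_zero_prediction(self):
        k = hrf_kernel(20.0)
        y = predict_fnirs(TimeVaryingPower(np.zeros(100), 20.0), k)
        assert np.allclose(y, 0.0)

    def test_matches_direct_convolution_sum(self, rng):
        n = 500
        p = rng.random(n)
        k = hrf_kernel(25.0, duration_s=8.0)
        y = predict_fnirs(TimeVaryingPower(p, 25.0), k)
        m = len(k.samples)
        expected = np.array(
            [sum(p[t - j] * k.samples[j] for j in range(min(t + 1, m))) for t in range(n)]
        ) * k.dt
        assert np.allclose(y, expected, atol=1e-10)


class TestGlmFit:
    def test_noiseless_recovery_is_exact(self, rng):
        D = rng.normal(size=(100, 5))
        beta = rng.normal(size=(5, 3))
        assert np.allclose(glm_fit(D, D @ beta), beta, atol=1e-8)

    def test_orthonormal_design_closed_form(self, rng):
        D, _ = np.linalg.qr(rng.normal(size=(60, 4)))
        Y = rng.normal(size=(60, 2))
        assert np.allclose(glm_fit(D, Y), D.T @ Y, atol=1e-10)

    def test_matches_normal_equations_on_conditioned_fixture(self, rng):
        D = rng.normal(size=(600, 8))
        Y = rng.normal(size=(600, 3))
        expected = np.linalg.solve(D.T @ D, D.T @ Y)
        assert np.allclose(glm_fit(D, Y), expected, atol=1e-8)

    def test_matches_statsmodels_ols(self, rng):
        import statsmodels.api as sm

        D = rng.normal(size=(200, 4))
        y = rng.normal(size=200)
        expected = sm.OLS(y, D).fit().params
        assert np.allclose(glm_fit(D, y), expected, atol=1e-10)

    def test_zero_columns_dropped_with_warning(self, rng):
        D = rng.normal(size=(50, 3))
        D[:, 1] = 0.0
        Y = rng.normal(size=(50, 2))
        with pytest.warns(UserWarning, match="all-zero"):
            beta = glm_fit(D, Y)
        assert np.allclose(beta[1], 0.0)

    def test_all_zero_design_rejected(self, rng):
        with pytest.raises(NumericalError):
            glm_fit(np.zeros((50, 3)), rng.normal(size=(50, 1)))

    def test_stabilised_modes_match_plain_fit_when_model_exact(self, rng):
        D = rng.normal(size=(120, 5))
        beta = rng.normal(size=(5, 2))
        Y = D @ beta
        assert np.allclose(glm_fit(D, Y, kappa=3.0), beta, atol=1e-8)
        assert np.allclose(glm_fit(D, Y, sv_rel=0.01), beta, atol=1e-8)


class TestCouplingMatrix:
    def test_absolute_value(self):
        cm = coupling_matrix(np.array([[-1.0, 2.0]]))
        assert np.array_equal(cm.cs, [[1.0, 2.0]])

    def test_nonnegative_and_idempotent(self, rng):
        beta = rng.normal(size=(4, 3))
        once = coupling_matrix(beta).cs
        twice = coupling_matrix(once).cs
        assert np.all(once >= 0)
        assert np.array_equal(once, twice)


@pytest.fixture(scope="module")
def sources():
    A = np.eye(3) * 0.4
    A[1, 0] = 0.3
    return simulate_var_sources(A, 2, 6000, 200.0, 1.0, seed=21)


class TestTrialCoupling:
    def test_window_count_matches_segment(self, sources):
        W = np.ones((3, 2))
        y = simulate_fnirs(sources, W, 200.0, 0.0, seed=0)
        cms = trial_coupling(sources, y)
        assert len(cms) == len(segment(sources.data, 200.0))

    def test_scalar_noiseless_recovers_weight(self):
        S1 = simulate_var_sources(np.array([[0.4]]), 1, 6000, 200.0, 1.0, seed=5)
        y = simulate_fnirs(S1, np.array([[2.0]]), 200.0, 0.0, seed=0)
        for cm in trial_coupling(S1, y):
            assert cm.cs[0, 0] == pytest.approx(2.0, rel=0.05)

    def test_noiseless_window_average_recovers_weights(self, sources, rng):
        W = rng.uniform(0.3, 1.0, size=(3, 2))
        y = simulate_fnirs(sources, W, 200.0, 0.0, seed=0)
        cs = np.mean([m.cs for m in trial_coupling(sources, y)], axis=0)
        r = np.corrcoef(cs.ravel(), np.abs(W).ravel())[0, 1]
        assert r > 0.95

    def test_length_mismatch_rejected(self, sources, rng):
        from hbnet.errors import AlignmentError

        with pytest.raises(AlignmentError):
            trial_coupling(sources, rng.normal(size=(2, 5000)))
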