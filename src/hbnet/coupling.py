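"""Neurovascular coupling networks between EEG sources and fNIRS.

Emotion-evoking stimuli (minute-long videos) cannot be modelled as the
boxcar regressors of event paradigms: their intensity fluctuates
continuously and the cortical response differs by region. Each region's
stimulus model is therefore its own normalised time-varying power
envelope P_i(t):

1. squared-magnitude STFT spectrogram of the source series (Hann
   window; defaults 1 s window, 0.1 s hop),
2. power summed over the EEG band (0.5-45 Hz) per frame, min-max
   normalised to [0, 1] over the trial, interpolated back onto the
   full-rate sample grid,
3. convolved with the canonical double-gamma haemodynamic response
   HRF(t) = g(t, 6) - g(t, 16)/16, g(t, d) = t^{d-1} e^{-t} / Gamma(d),
   truncated to the first n samples -> predicted fNIRS series.

Stacking the c predicted series as the design matrix D of a general
linear model Y = D beta + eps against the d measured HbO channels of
the same 3 s window yields beta in R^{c x d}; the coupling strength is
|beta_ij|, the weight of source i in explaining fNIRS channel j.

No intercept or drift regressors are added: measured fNIRS is
band-passed (0.01-0.2 Hz) and baseline-corrected upstream, which
removes the DC component.
"""

from __future__ import annotations

import warnings

import numpy as np
from scipy import fft as _fft
from scipy import signal as _sig
from scipy.special import gammaln

from .containers import (
    CouplingMatrix,
    HrfKernel,
    SourceSignals,
    TimeVaryingPower,
    WindowRef,
)
from .errors import AlignmentError, NumericalError
from .preprocess import segment

__all__ = [
    "stft_power",
    "timevarying_power",
    "hrf_kernel",
    "predict_fnirs",
    "glm_fit",
    "coupling_matrix",
    "predicted_fnirs_matrix",
    "trial_coupling",
]


def stft_power(
    s: np.ndarray, fs: float, win_s: float = 1.0, hop_s: float = 0.1
) -> tuple[np.ndarray, np.ndarray, np.ndarray]:
    """Squared-magnitude short-time Fourier spectrogram of one series.

    Frames of ``round(win_s * fs)`` samples start at multiples of the
    hop and lie fully inside the signal (no zero padding), each tapered
    by a Hann window before the real FFT.

    Returns
    -------
    P : frames x freqs nonnegative power matrix
    freqs : frequency bin centres in Hz (0..fs/2)
    times : frame-centre times in seconds
    """
    s = np.asarray(s, dtype=float).ravel()
    m = int(round(win_s * fs))
    hop = max(int(round(hop_s * fs)), 1)
    if m < 8:
        raise ValueError(f"STFT window of {m} samples too short (need >= 8)")
    if m > s.shape[0]:
        raise ValueError(f"STFT window ({m}) longer than signal ({s.shape[0]})")
    n_frames = (s.shape[0] - m) // hop + 1
    starts = np.arange(n_frames) * hop
    frames = np.lib.stride_tricks.sliding_window_view(s, m)[starts]
    h = _sig.windows.hann(m, sym=False)
    spec = _fft.rfft(frames * h, axis=1)
    P = np.abs(spec) ** 2
    freqs = _fft.rfftfreq(m, d=1.0 / fs)
    times = (starts + (m - 1) / 2.0) / fs
    return P, freqs, times


def timevarying_power(
    P: np.ndarray,
    freqs: np.ndarray,
    times: np.ndarray,
    f_min: float = 0.5,
    f_max: float = 45.0,
    n_out: int | None = None,
    fs_out: float | None = None,
) -> TimeVaryingPower:
    """Band-summed, min-max normalised power envelope on the sample grid.

    Power is summed over bins with f_min <= f <= f_max per frame,
    normalised to [0, 1] over the whole trial (a constant envelope maps
    to zeros so degenerate sources never produce NaN), and linearly
    interpolated from frame centres onto ``n_out`` samples at ``fs_out``.
    When ``n_out``/``fs_out`` are omitted the frame-rate envelope is
    returned unchanged.
    """
    band = (freqs >= f_min) & (freqs <= f_max)
    if not band.any():
        raise ValueError(f"band [{f_min}, {f_max}] Hz contains no frequency bin")
    env = P[:, band].sum(axis=1)
    lo, hi = float(env.min()), float(env.max())
    # a numerically constant envelope maps to zeros, never 0/0
    if hi - lo <= 1e-12 * max(abs(hi), abs(lo), 1e-300):
        env = np.zeros_like(env)
    else:
        env = (env - lo) / (hi - lo)
    if n_out is None:
        fs_frame = 1.0 / float(np.median(np.diff(times))) if len(times) > 1 else 1.0
        return TimeVaryingPower(p=env, fs=fs_frame)
    if fs_out is None:
        raise ValueError("fs_out required when n_out is given")
    t_grid = np.arange(n_out) / fs_out
    p = np.interp(t_grid, times, env)
    return TimeVaryingPower(p=p, fs=fs_out)


def _gamma_pdf(t: np.ndarray, d: float) -> np.ndarray:
    """Unit-scale gamma density t^{d-1} e^{-t} / Gamma(d), zero for t <= 0."""
    out = np.zeros_like(t, dtype=float)
    pos = t > 0
    tp = t[pos]
    out[pos] = np.exp((d - 1) * np.log(tp) - tp - gammaln(d))
    return out


def hrf_kernel(fs: float, duration_s: float = 32.0) -> HrfKernel:
    """Canonical double-gamma haemodynamic response sampled at ``fs``.

    HRF(t) = g(t, 6) - g(t, 16) / 16: a positive lobe peaking near 5 s
    followed by an undershoot; zero at t = 0 and effectively zero beyond
    ~30 s, hence the 32 s default support.
    """
    if fs <= 0:
        raise ValueError("sampling rate must be positive")
    dt = 1.0 / fs
    t = np.arange(0.0, duration_s, dt)
    samples = _gamma_pdf(t, 6.0) - _gamma_pdf(t, 16.0) / 16.0
    return HrfKernel(samples=samples, dt=dt)


def predict_fnirs(p: TimeVaryingPower, k: HrfKernel) -> np.ndarray:
    """Predicted fNIRS series: dt-scaled convolution, first n samples kept.

    The dt factor makes the discrete sum approximate the continuous
    convolution integral, so predictions are invariant to the sampling
    rate of the common grid.
    """
    if abs(p.fs * k.dt - 1.0) > 1e-9:
        raise AlignmentError(
            f"power envelope at {p.fs} Hz but kernel sampled at {1.0 / k.dt} Hz"
        )
    n = p.p.shape[0]
    return np.convolve(p.p, k.samples)[:n] * k.dt


def glm_fit(
    D: np.ndarray,
    Y: np.ndarray,
    kappa: float | None = None,
    sv_rel: float = 0.0,
) -> np.ndarray:
    """Least-squares coefficients of the window GLM Y = D beta + eps.

    D : r x c design (predicted fNIRS series in columns)
    Y : r x d measured fNIRS window
    kappa : optional significance cutoff for SVD coordinates (see below);
        ``None`` (default) is the plain least-squares solution.
    sv_rel : relative singular-value floor; coordinates with
        sigma_k < sv_rel * sigma_1 are treated as null space.

    All-zero design columns (degenerate power envelopes) are dropped
    from the fit with a warning and their coefficients set to zero; a
    fully zero design is an error. A rank-deficient design is resolved
    by the minimum-norm solution, with a warning.

    Windowed HRF-convolved regressors are severely ill-conditioned (a
    3 s window of signals band-limited below ~0.3 Hz has an effective
    dimension of 2-4, whatever c is), so the plain solution amplifies
    any noise or design mismatch along the small singular directions by
    the condition number. Two stabilisations are available, both exact
    no-ops when the model explains the data perfectly and the design is
    well conditioned: with ``kappa`` set, the fit is computed in the SVD
    basis D = U S V^T and coordinate k is kept only when its data
    projection is significant against the full fit's own residual noise,
    |u_k^T y| > kappa * s with s^2 = RSS/(r - rank) per channel; with
    ``sv_rel`` > 0, coordinates whose singular value falls below
    ``sv_rel * sigma_1`` are dropped regardless — the stable-subspace
    policy the feature-extraction pipeline uses, because coefficients
    along those directions cannot be estimated from band-limited
    physiological data at any realistic noise level.
    """
    D = np.atleast_2d(np.asarray(D, dtype=float))
    Y = np.asarray(Y, dtype=float)
    squeeze = Y.ndim == 1
    if squeeze:
        Y = Y[:, None]
    if D.shape[0] != Y.shape[0]:
        raise AlignmentError(f"design has {D.shape[0]} rows but Y has {Y.shape[0]}")
    norms = np.linalg.norm(D, axis=0)
    live = norms > 0
    if not live.any():
        raise NumericalError("design matrix is identically zero")
    if not live.all():
        warnings.warn(
            f"dropping {int((~live).sum())} all-zero design column(s) from GLM",
            stacklevel=2,
        )
    beta = np.zeros((D.shape[1], Y.shape[1]))
    if kappa is None and sv_rel <= 0:
        sol, _, rank, _ = np.linalg.lstsq(D[:, live], Y, rcond=None)
        if rank < int(live.sum()):
            warnings.warn(
                f"rank-deficient design (rank {rank} < {int(live.sum())}); minimum-norm solution",
                stacklevel=2,
            )
    else:
        U, sv, Vt = np.linalg.svd(D[:, live], full_matrices=False)
        UtY = U.T @ Y
        floor = max(sv_rel, np.finfo(float).eps * max(D.shape))
        keep = np.broadcast_to((sv >= sv[0] * floor)[:, None], UtY.shape).copy()
        if kappa is not None:
            rss = np.maximum((Y**2).sum(axis=0) - (UtY**2).sum(axis=0), 0.0)
            dof = max(D.shape[0] - sv.size, 1)
            s = np.sqrt(rss / dof)
            keep &= np.abs(UtY) > kappa * s[None, :]
        coef = np.where(keep, UtY / sv[:, None], 0.0)
        sol = Vt.T @ coef
    beta[live] = sol
    return beta[:, 0] if squeeze else beta


def coupling_matrix(beta: np.ndarray, window: WindowRef | None = None) -> CouplingMatrix:
    """Coupling strengths |beta| as a nonnegative c x d matrix."""
    beta = np.asarray(beta, dtype=float)
    return CouplingMatrix(cs=np.abs(beta), window=window or WindowRef(0, 0.0))


def predicted_fnirs_matrix(
    S: SourceSignals,
    f_min: float = 0.5,
    f_max: float = 45.0,
    stft_win_s: float = 1.0,
    stft_hop_s: float = 0.1,
    hrf_duration_s: float = 32.0,
    fs_out: float | None = None,
    n_out: int | None = None,
) -> np.ndarray:
    """Predicted fNIRS series for every source, as a c x n matrix.

    Shared by the analysis path (design-matrix construction) and the
    synthetic forward model, so simulation and recovery use the exact
    same envelope/convolution definitions. ``fs_out``/``n_out`` let the
    forward model sample the prediction on a slower fNIRS grid; they
    default to the source grid.
    """
    fs_out = fs_out or S.fs
    n_out = n_out or int(round(S.n_samples * fs_out / S.fs))
    k = hrf_kernel(fs_out, hrf_duration_s)
    out = np.empty((S.n_regions, n_out))
    for i in range(S.n_regions):
        P, freqs, times = stft_power(S.data[i], S.fs, stft_win_s, stft_hop_s)
        p = timevarying_power(P, freqs, times, f_min, f_max, n_out=n_out, fs_out=fs_out)
        out[i] = predict_fnirs(p, k)
    return out


def trial_coupling(
    S: SourceSignals,
    Y_measured: np.ndarray,
    window_s: float = 3.0,
    step_s: float = 1.5,
    f_min: float = 0.5,
    f_max: float = 45.0,
    stft_win_s: float = 1.0,
    stft_hop_s: float = 0.1,
    hrf_duration_s: float = 32.0,
    glm_kappa: float | None = 3.0,
    glm_sv_rel: float = 0.0,
    trial_id: int = 0,
) -> list[CouplingMatrix]:
    """Per-window coupling matrices for one trial.

    The c predicted series are computed on the full trial, then the
    predicted and measured streams are segmented identically (default
    3 s / 1.5 s) and one GLM is fit per window. ``Y_measured`` must be
    d x n on the same grid as ``S`` (i.e. already upsampled to the
    common rate).
    """
    Y_measured = np.atleast_2d(np.asarray(Y_measured, dtype=float))
    if Y_measured.shape[1] != S.n_samples:
        raise AlignmentError(
            f"measured fNIRS has {Y_measured.shape[1]} samples but sources have {S.n_samples}"
        )
    Yhat = predicted_fnirs_matrix(
        S, f_min, f_max, stft_win_s, stft_hop_s, hrf_duration_s
    )
    win_pred = segment(Yhat, S.fs, window_s, step_s, trial_id=trial_id)
    win_meas = segment(Y_measured, S.fs, window_s, step_s, trial_id=trial_id)
    out = []
    for wp, wm in zip(win_pred, win_meas):
        beta = glm_fit(wp.data, wm.data, kappa=glm_kappa, sv_rel=glm_sv_rel)
        out.append(coupling_matrix(beta, window=wp.ref))
    return out
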