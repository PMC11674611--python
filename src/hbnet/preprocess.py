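"""Signal conditioning shared by both network stages.

EEG is band-pass filtered (default 0.5-45 Hz) and resampled to a common
200 Hz grid; fNIRS optical density is baseline corrected, band-passed
(0.01-0.2 Hz), converted to HbO concentration changes via the modified
Beer-Lambert law and upsampled to the same grid. Both streams are then
cut into identical 3 s windows sliding by 1.5 s, so that every causal
matrix, coupling matrix and measured-fNIRS window refers to the same
stretch of time.

Filters are zero-phase (forward-backward 4th-order Butterworth): the
band edges are the only published parameters, and zero-phase filtering
avoids introducing phase lags that would bias the lagged regressions of
the causal stage.
"""

from __future__ import annotations

import warnings
from fractions import Fraction

import numpy as np
from scipy import signal

from .containers import RawFNIRS, WindowSample
from .errors import DataError, NumericalError

__all__ = [
    "bandpass",
    "resample",
    "baseline_correct",
    "mbll",
    "segment",
    "DEFAULT_EXTINCTION",
]


def bandpass(x: np.ndarray, fs: float, low: float, high: float, order: int = 4) -> np.ndarray:
    """Zero-phase Butterworth band-pass along the last axis.

    Parameters
    ----------
    x : array, series x time (or 1-D)
    fs : sampling rate in Hz
    low, high : band edges in Hz, 0 < low < high < fs/2
    """
    x = np.asarray(x, dtype=float)
    if not 0 < low < high:
        raise ValueError(f"need 0 < low < high, got ({low}, {high})")
    if high >= fs / 2:
        raise ValueError(f"high edge {high} Hz is at or above Nyquist ({fs / 2} Hz)")
    sos = signal.butter(order, [low, high], btype="bandpass", fs=fs, output="sos")
    return signal.sosfiltfilt(sos, x, axis=-1)


def resample(x: np.ndarray, fs_in: float, fs_out: float) -> np.ndarray:
    """Band-limited resampling along the last axis.

    Polyphase filtering handles both directions: the low-pass stage acts
    as anti-alias filter when downsampling and as interpolation filter
    when upsampling. Output length is round(n * fs_out / fs_in).
    """
    x = np.asarray(x, dtype=float)
    if x.shape[-1] == 0:
        raise ValueError("cannot resample an empty signal")
    if fs_in <= 0 or fs_out <= 0:
        raise ValueError("sampling rates must be positive")
    if fs_in == fs_out:
        return x.copy()
    frac = Fraction(fs_out / fs_in).limit_denominator(10000)
    y = signal.resample_poly(x, frac.numerator, frac.denominator, axis=-1)
    n_out = int(round(x.shape[-1] * fs_out / fs_in))
    if y.shape[-1] > n_out:
        y = y[..., :n_out]
    elif y.shape[-1] < n_out:
        pad = np.repeat(y[..., -1:], n_out - y.shape[-1], axis=-1)
        y = np.concatenate([y, pad], axis=-1)
    return y


def baseline_correct(x: np.ndarray, fs: float, baseline_window: tuple[float, float] | None = None) -> np.ndarray:
    """Subtract the per-series mean over ``baseline_window`` (seconds).

    ``None`` uses the whole signal as baseline.
    """
    x = np.atleast_2d(np.asarray(x, dtype=float))
    n = x.shape[-1]
    if baseline_window is None:
        i0, i1 = 0, n
    else:
        t0, t1 = baseline_window
        i0, i1 = int(round(t0 * fs)), int(round(t1 * fs))
        if not (0 <= i0 < i1 <= n):
            raise ValueError(f"baseline window ({t0}, {t1}) s outside signal extent")
    if i1 - i0 < 1:
        raise ValueError("baseline window is empty")
    return x - x[..., i0:i1].mean(axis=-1, keepdims=True)


# Molar extinction coefficients in 1/(cm * M), {wavelength nm: (HbO, HbR)}.
# Tabulated compilation commonly used for CW-NIRS; override via `extinction`.
DEFAULT_EXTINCTION: dict[float, tuple[float, float]] = {
    760.0: (1486.5865, 3843.707),
    850.0: (2526.391, 1798.643),
}


def mbll(
    od: RawFNIRS,
    wavelengths: tuple[float, float] = (760.0, 850.0),
    dpf: float = 6.0,
    distance_cm: float = 3.0,
    extinction: dict[float, tuple[float, float]] | None = None,
) -> tuple[RawFNIRS, RawFNIRS]:
    """Modified Beer-Lambert conversion from optical density to (HbO, HbR).

    ``od.data`` stacks the two wavelength blocks row-wise: rows
    ``0..d-1`` are channel OD changes at ``wavelengths[0]`` and rows
    ``d..2d-1`` the same channels at ``wavelengths[1]``. For each channel
    the 2x2 extinction system

        dOD(lambda) = [eps_HbO(lambda), eps_HbR(lambda)] . [dHbO, dHbR] * L * DPF

    is inverted (L = source-detector distance). Only HbO feeds the
    coupling stage; HbR is returned for completeness.
    """
    if od.signal_kind != "optical_density":
        raise DataError("mbll expects optical-density input")
    if od.data.shape[0] % 2 != 0:
        raise DataError("optical-density data must stack two equal wavelength blocks")
    ext = extinction or DEFAULT_EXTINCTION
    try:
        e = np.array([ext[float(w)] for w in wavelengths], dtype=float)  # 2x2
    except KeyError as exc:
        raise ValueError(f"no extinction coefficients for wavelength {exc}") from exc
    if abs(np.linalg.det(e)) < 1e-12 * np.abs(e).max() ** 2:
        raise NumericalError("extinction matrix is singular: wavelengths not distinct enough")
    d = od.data.shape[0] // 2
    path = distance_cm * dpf
    # dOD is (2, d, n); solve per channel: conc = e^{-1} dOD / path
    dod = od.data.reshape(2, d, -1)
    conc = np.linalg.solve(e, dod.reshape(2, -1)).reshape(2, d, -1) / path
    names = list(od.channel_names[:d])
    hbo = RawFNIRS(conc[0], od.fs, names, signal_kind="hbo")
    hbr = RawFNIRS(conc[1], od.fs, names, signal_kind="hbr")
    return hbo, hbr


def mbll_forward(
    hbo: np.ndarray,
    hbr: np.ndarray,
    wavelengths: tuple[float, float] = (760.0, 850.0),
    dpf: float = 6.0,
    distance_cm: float = 3.0,
    extinction: dict[float, tuple[float, float]] | None = None,
) -> np.ndarray:
    """Forward Beer-Lambert model: concentrations -> stacked dOD blocks.

    Inverse of :func:`mbll`; used to synthesise optical-density fixtures.
    """
    ext = extinction or DEFAULT_EXTINCTION
    e = np.array([ext[float(w)] for w in wavelengths], dtype=float)
    conc = np.stack([np.atleast_2d(hbo), np.atleast_2d(hbr)])  # (2, d, n)
    path = distance_cm * dpf
    dod = np.einsum("wk,kdn->wdn", e, conc) * path
    return dod.reshape(-1, conc.shape[-1])


def segment(
    x: np.ndarray,
    fs: float,
    window_s: float = 3.0,
    step_s: float = 1.5,
    trial_id: int = 0,
    label: int | None = None,
    t_offset: float = 0.0,
) -> list[WindowSample]:
    """Cut a series x time matrix into overlapping windows.

    Windows start at ``k * step_s`` seconds, k = 0, 1, ...; the count is
    ``floor((n - r) / step) + 1`` with r the window length in samples.
    Each :class:`WindowSample` is time-major (r x m), the orientation the
    regression stages consume. A signal shorter than one window yields an
    empty list and a warning, not an error.
    """
    x = np.atleast_2d(np.asarray(x, dtype=float))
    n = x.shape[-1]
    r = int(round(window_s * fs))
    step = int(round(step_s * fs))
    if r < 1 or step < 1:
        raise ValueError("window and step must be at least one sample")
    if n < r:
        warnings.warn(
            f"signal of {n} samples shorter than one {r}-sample window; no output",
            stacklevel=2,
        )
        return []
    count = (n - r) // step + 1
    out = []
    for k in range(count):
        i0 = k * step
        out.append(
            WindowSample(
                data=x[:, i0 : i0 + r].T.copy(),
                t_start=t_offset + i0 / fs,
                trial_id=trial_id,
                label=label,
            )
        )
    return out
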