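"""Synthetic concurrent EEG/fNIRS sessions with known ground truth.

The generator emulates the structure the analysis assumes, end to end:

* cortical sources follow a stable VAR process with a known directed
  coupling matrix (column j drives row i), so the causal stage has a
  ground-truth edge set to recover;
* scalp EEG is the linear lead-field projection of the dipole series
  (each dipole carrying its region's source signal) plus white sensor
  noise — the forward model the minimum-norm inverse undoes;
* fNIRS is generated by the same neurovascular forward model the
  coupling stage fits: each source's normalised time-varying power is
  convolved with the canonical HRF and mixed into channels by a known
  nonnegative weight matrix, plus noise at a configurable SNR;
* trials belong to one of K classes whose VAR and coupling templates
  are class-specific perturbations of a common base, so every network
  type carries class information.

Everything is deterministic given the config seed.
"""

from __future__ import annotations

import numpy as np

from .config import SimConfig
from .containers import GroundTruth, SourceSignals, SyntheticDataset
from .coupling import predicted_fnirs_matrix
from .errors import StabilityError
from .preprocess import resample

__all__ = [
    "companion_spectral_radius",
    "simulate_var_sources",
    "modulate_sources",
    "project_to_scalp",
    "simulate_fnirs",
    "simulate_dataset",
]

BURN_IN = 500  # samples discarded so emitted series are (weakly) stationary


def _lag_matrices(adjacency: np.ndarray, var_order: int) -> np.ndarray:
    """Expand a c x c adjacency into VAR lag matrices (p, c, c).

    A (p, c, c) input is used verbatim. A single c x c matrix is spread
    over lags with geometrically decaying weights w_k ~ 0.5^(k-1)
    normalised to sum to one, so the total lagged gain equals the
    adjacency entry whatever the order.
    """
    adjacency = np.asarray(adjacency, dtype=float)
    if adjacency.ndim == 3:
        if adjacency.shape[0] != var_order:
            raise ValueError(
                f"got {adjacency.shape[0]} lag matrices for var_order={var_order}"
            )
        return adjacency
    if adjacency.ndim != 2 or adjacency.shape[0] != adjacency.shape[1]:
        raise ValueError(f"adjacency must be square, got {adjacency.shape}")
    w = 0.5 ** np.arange(var_order)
    w /= w.sum()
    return w[:, None, None] * adjacency[None, :, :]


def companion_spectral_radius(A: np.ndarray) -> float:
    """Spectral radius of the companion matrix of VAR lag matrices (p, c, c)."""
    A = np.asarray(A, dtype=float)
    p, c, _ = A.shape
    comp = np.zeros((c * p, c * p))
    comp[:c, :] = np.concatenate(list(A), axis=1)
    if p > 1:
        comp[c:, : c * (p - 1)] = np.eye(c * (p - 1))
    return float(np.abs(np.linalg.eigvals(comp)).max())


def simulate_var_sources(
    adjacency: np.ndarray,
    var_order: int,
    n: int,
    fs: float,
    noise_sd: float,
    seed: int,
    region_names: list[str] | None = None,
) -> SourceSignals:
    """Simulate c stationary source series from a VAR process.

    Parameters
    ----------
    adjacency : c x c directed gains (column drives row; diagonal =
        self-regression), or explicit (var_order, c, c) lag matrices
    var_order : VAR order p
    n : emitted samples (after a 500-sample burn-in is discarded)
    noise_sd : innovation standard deviation (> 0)

    Raises
    ------
    StabilityError
        if the companion-matrix spectral radius is >= 1.
    """
    if noise_sd <= 0:
        raise ValueError("noise_sd must be positive")
    if not np.all(np.isfinite(np.asarray(adjacency, dtype=float))):
        raise ValueError("adjacency must be finite")
    A = _lag_matrices(adjacency, var_order)
    p, c, _ = A.shape
    if n <= 10 * var_order:
        raise ValueError(f"n={n} too short for order {var_order} (need > {10 * var_order})")
    rho = companion_spectral_radius(A)
    if rho >= 1.0:
        raise StabilityError(f"VAR is unstable: companion spectral radius {rho:.4f} >= 1")
    rng = np.random.default_rng(seed)
    total = n + BURN_IN
    x = np.zeros((total, c))
    eps = rng.normal(0.0, noise_sd, size=(total, c))
    x[:p] = eps[:p]
    for t in range(p, total):
        acc = eps[t].copy()
        for k in range(p):
            acc += A[k] @ x[t - 1 - k]
        x[t] = acc
    names = region_names or [f"region_{i:02d}" for i in range(1, c + 1)]
    return SourceSignals(data=x[BURN_IN:].T.copy(), region_names=names, fs=fs)


def _sinusoid_profile(
    rng: np.random.Generator, t: np.ndarray, f_lo: float, f_hi: float, n_components: int
) -> np.ndarray:
    f = rng.uniform(f_lo, f_hi, n_components)
    phase = rng.uniform(0, 2 * np.pi, n_components)
    amp = rng.uniform(0.5, 1.0, n_components)
    return (amp[:, None] * np.sin(2 * np.pi * f[:, None] * t + phase[:, None])).sum(axis=0)


def modulate_sources(
    S: SourceSignals,
    depth: float,
    seed: int,
    class_seed: int | None = None,
    class_frac: float = 0.0,
    f_lo: float = 0.04,
    f_hi: float = 0.25,
    n_components: int = 4,
) -> SourceSignals:
    """Slow, source-specific amplitude modulation of stationary sources.

    Emotion-evoking video stimuli fluctuate in intensity over tens of
    seconds and drive cortical regions differentially; the neurovascular
    forward model is only informative if band power actually varies in
    time, and different emotion categories differ in exactly these
    temporal intensity profiles. Each source is multiplied by
    1 + depth * m_i(t) where m_i is a unit-peak random sum of
    ``n_components`` sinusoids in [f_lo, f_hi] Hz. With ``class_seed``
    set, m_i blends a class-level profile (shared by all trials of a
    class, drawn from ``class_seed``) with a trial-level profile (drawn
    from ``seed``) in proportion ``class_frac`` : 1 - class_frac,
    modelling same-emotion stimuli that share temporal structure while
    differing from video to video. depth = 0 is a no-op.
    """
    if not 0 <= depth < 1:
        raise ValueError("modulation depth must lie in [0, 1)")
    if not 0 <= class_frac <= 1:
        raise ValueError("class_frac must lie in [0, 1]")
    if depth == 0:
        return S
    rng = np.random.default_rng(seed)
    crng = np.random.default_rng(class_seed) if class_seed is not None else None
    t = np.arange(S.n_samples) / S.fs
    data = S.data.copy()
    for i in range(S.n_regions):
        m = (1.0 - class_frac) * _sinusoid_profile(rng, t, f_lo, f_hi, n_components)
        if crng is not None and class_frac > 0:
            m += class_frac * _sinusoid_profile(crng, t, f_lo, f_hi, n_components)
        m /= np.abs(m).max()
        data[i] *= 1.0 + depth * m
    return SourceSignals(data=data, region_names=S.region_names, fs=S.fs)


def project_to_scalp(
    S: SourceSignals,
    lead_field: np.ndarray,
    membership: np.ndarray,
    sensor_noise_sd: float,
    seed: int,
) -> np.ndarray:
    """Scalp EEG X = L J + noise, each dipole carrying its region's series."""
    L = np.asarray(lead_field, dtype=float)
    membership = np.asarray(membership, dtype=int)
    if not np.all(np.isfinite(L)):
        raise ValueError("lead field must be finite")
    if L.shape[1] != membership.shape[0]:
        raise ValueError(
            f"lead field has {L.shape[1]} dipole columns but membership lists {membership.shape[0]}"
        )
    if membership.min() < 1 or membership.max() > S.n_regions:
        raise IndexError(
            f"membership ids must lie in 1..{S.n_regions}, got range "
            f"[{membership.min()}, {membership.max()}]"
        )
    J = S.data[membership - 1]  # v x n
    rng = np.random.default_rng(seed)
    X = L @ J
    if sensor_noise_sd > 0:
        X = X + rng.normal(0.0, sensor_noise_sd, size=X.shape)
    return X


def simulate_fnirs(
    S: SourceSignals,
    coupling_weights: np.ndarray,
    fs: float,
    noise_sd: float,
    seed: int,
    f_min: float = 0.5,
    f_max: float = 45.0,
) -> np.ndarray:
    """fNIRS channels from the neurovascular forward model.

    y_j(t) = sum_i w_ij (P_i * HRF)(t) + noise, with P_i the normalised
    time-varying power of source i computed by the exact routine the
    coupling stage uses for its design matrix. The haemodynamic mix is
    evaluated on the source grid (where P_i lives) and then sampled at
    the fNIRS acquisition rate ``fs`` — the mixed signal is band-limited
    well below any realistic fNIRS rate, so this models a slow optical
    recording of the fast neural process. Returns a
    d x round(n * fs / fs_eeg) matrix.
    """
    W = np.asarray(coupling_weights, dtype=float)
    if not np.all(np.isfinite(W)):
        raise ValueError("coupling weights must be finite")
    if W.ndim != 2 or W.shape[0] != S.n_regions:
        raise ValueError(
            f"coupling weights must be c x d with c={S.n_regions}, got {W.shape}"
        )
    Yhat = predicted_fnirs_matrix(S, f_min=f_min, f_max=f_max)  # c x n at S.fs
    y = W.T @ Yhat
    if abs(fs - S.fs) > 1e-9:
        y = resample(y, S.fs, fs)
    if noise_sd > 0:
        rng = np.random.default_rng(seed)
        y = y + rng.normal(0.0, noise_sd, size=y.shape)
    return y


def _random_base_templates(cfg: SimConfig, rng: np.random.Generator):
    """Base adjacency (with self terms) and nonnegative coupling weights."""
    c, d = cfg.c, cfg.d
    A = np.eye(c) * cfg.self_gain
    off = [(i, j) for i in range(c) for j in range(c) if i != j]
    picks = rng.choice(len(off), size=min(cfg.n_edges, len(off)), replace=False)
    for k in picks:
        i, j = off[k]
        A[i, j] = cfg.edge_gain * rng.uniform(0.8, 1.2)
    A = _stabilise(A, cfg.var_order)
    W = rng.uniform(0.3, 1.0, size=(c, d)) * (rng.random((c, d)) < 0.6)
    for j in range(d):  # every channel must be driven by at least one source
        if not W[:, j].any():
            W[rng.integers(c), j] = rng.uniform(0.5, 1.0)
    return A, W


def _stabilise(A: np.ndarray, var_order: int, margin: float = 0.97) -> np.ndarray:
    """Shrink off-diagonal gains until the implied VAR is stable."""
    A = A.copy()
    for _ in range(200):
        if companion_spectral_radius(_lag_matrices(A, var_order)) < margin:
            return A
        off = ~np.eye(A.shape[0], dtype=bool)
        A[off] *= 0.9
    raise StabilityError("could not stabilise adjacency template")


def _perturb_class_templates(cfg: SimConfig, A: np.ndarray, W: np.ndarray, rng):
    """Class templates: rectified Gaussian perturbation of the base gains.

    Existing edges (and coupling weights) are scaled by (1 + effect_size * z),
    z ~ N(0, 1), clipped to stay nonnegative; effect_size = 0 reproduces
    the base exactly for every class (a null dataset).
    """
    K = cfg.n_classes
    class_A = np.empty((K, *A.shape))
    class_W = np.empty((K, *W.shape))
    off = ~np.eye(A.shape[0], dtype=bool)
    for k in range(K):
        zA = rng.normal(0.0, 1.0, size=A.shape)
        zW = rng.normal(0.0, 1.0, size=W.shape)
        Ak = A.copy()
        Ak[off] = np.clip(A[off] * (1.0 + cfg.effect_size * zA[off]), 0.0, None)
        class_A[k] = _stabilise(Ak, cfg.var_order)
        class_W[k] = np.clip(W * (1.0 + cfg.effect_size * zW), 0.0, None)
    return class_A, class_W


def simulate_dataset(cfg: SimConfig) -> SyntheticDataset:
    """Generate a labelled concurrent EEG/fNIRS session.

    Trials of all classes are generated and then shuffled into a random
    acquisition order; the ground-truth sidecar retains the base and
    per-class templates, the label sequence, and the seed.
    """
    if cfg.effect_size < 0:
        raise ValueError("effect size must be nonnegative")
    rng = np.random.default_rng(cfg.seed)
    A_base, W_base = _random_base_templates(cfg, rng)
    class_A, class_W = _perturb_class_templates(cfg, A_base, W_base, rng)

    # Lead field: random electrode sensitivities, unit-norm dipole columns.
    L = rng.normal(size=(cfg.u, cfg.v))
    L /= np.linalg.norm(L, axis=0, keepdims=True)
    membership = 1 + np.arange(cfg.v) % cfg.c

    n = int(round(cfg.trial_s * cfg.fs_eeg))
    region_names = [f"region_{i:02d}" for i in range(1, cfg.c + 1)]
    labels = np.repeat(np.arange(cfg.n_classes), cfg.trials_per_class)
    rng.shuffle(labels)

    class_mod_seeds = [int(rng.integers(2**31)) for _ in range(cfg.n_classes)]
    trials = []
    for label in labels:
        s_seed = int(rng.integers(2**31))
        m_seed = int(rng.integers(2**31))
        e_seed = int(rng.integers(2**31))
        f_seed = int(rng.integers(2**31))
        S = simulate_var_sources(
            class_A[label], cfg.var_order, n, cfg.fs_eeg, cfg.source_noise_sd,
            seed=s_seed, region_names=region_names,
        )
        S = modulate_sources(
            S, cfg.modulation_depth, seed=m_seed,
            class_seed=class_mod_seeds[label],
            class_frac=cfg.modulation_class_frac if cfg.effect_size > 0 else 0.0,
        )
        eeg = project_to_scalp(S, L, membership, cfg.eeg_noise_sd, seed=e_seed)
        y_clean = simulate_fnirs(S, class_W[label], cfg.fs_fnirs, 0.0, seed=f_seed)
        if cfg.fnirs_snr_db is None:
            fnirs = y_clean
        else:
            sd = float(y_clean.std()) * 10.0 ** (-cfg.fnirs_snr_db / 20.0)
            fnirs = y_clean + np.random.default_rng(f_seed).normal(0.0, sd, size=y_clean.shape)
        trials.append((eeg, fnirs, int(label)))

    gt = GroundTruth(
        adjacency=A_base,
        coupling_weights=W_base,
        labels=np.asarray(labels, dtype=int),
        seed=cfg.seed,
        var_order=cfg.var_order,
        fs=cfg.fs_eeg,
        class_adjacency=class_A,
        class_coupling=class_W,
    )
    return SyntheticDataset(
        trials=trials,
        lead_field=L,
        membership=membership,
        region_names=region_names,
        ground_truth=gt,
        fs_eeg=cfg.fs_eeg,
        fs_fnirs=cfg.fs_fnirs,
        eeg_channel_names=[f"EEG{i:03d}" for i in range(1, cfg.u + 1)],
        fnirs_channel_names=[f"CH{i}" for i in range(1, cfg.d + 1)],
    )
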