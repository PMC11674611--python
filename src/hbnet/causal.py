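"""Directed causal networks from windowed source signals.

For every ordered pair of source series (s_i, s_j) within a 3 s window,
two nested autoregressions of the target s_j are fit by ordinary least
squares on the same r - p target points:

    restricted:  s_j(t) = sum_k a_k s_j(t-k) + xi(t)
    full:        s_j(t) = sum_k b_k s_j(t-k) + sum_k c_k s_i(t-k) + eta(t)

The Granger causality of i onto j is the log residual-variance ratio
F_{i->j} = ln(var(xi) / var(eta)), which is nonnegative in-sample
because the models are nested and both variances divide by the same
effective sample size. Collecting all c(c-1) ordered pairs gives the
causal matrix G (diagonal fixed at 0 by convention: self-causality is
undefined under this contrast).

The lag order p is shared by all pairs of a window and chosen once by
BIC over pooled bivariate VAR fits. Windows are linearly detrended
first; Granger analysis assumes weak stationarity and the short-window
trend is the dominant violation.

``granger_pair`` is the readable reference implementation on explicit
design matrices; ``causal_matrix`` computes identical statistics from a
single per-window Gram matrix with batched small solves, which is what
makes 62-region networks tractable.
"""

from __future__ import annotations

import numpy as np
from scipy import signal as _sig

from .containers import CausalMatrix, WindowSample
from .errors import NumericalError

__all__ = ["detrend_window", "select_order", "granger_pair", "causal_matrix"]

_RSS_FLOOR = 1e-300


def detrend_window(w: WindowSample) -> WindowSample:
    """Remove the per-series least-squares linear trend (and hence the mean)."""
    if w.n_times < 3:
        raise ValueError("need at least 3 time points to detrend")
    data = _sig.detrend(w.data, axis=0, type="linear")
    return WindowSample(data=data, t_start=w.t_start, trial_id=w.trial_id, label=w.label)


def _lag_embed(x: np.ndarray, p: int) -> tuple[np.ndarray, np.ndarray]:
    """Targets Y (N x m) and lag design Z (N x m*p) for t = p..r-1.

    Z columns are grouped per series: series j occupies columns
    j*p..(j+1)*p-1 holding lags 1..p.
    """
    r, m = x.shape
    n = r - p
    Y = x[p:, :]
    Z = np.empty((n, m * p))
    for j in range(m):
        for k in range(1, p + 1):
            Z[:, j * p + k - 1] = x[p - k : r - k, j]
    return Y, Z


def granger_pair(a: np.ndarray, b: np.ndarray, p: int) -> float:
    """Granger causality F_{b->a}: does b's past help predict a?

    Reference implementation on explicit design matrices (lstsq). The
    series should already be detrended; length must exceed 2p + 1.
    """
    a = np.asarray(a, dtype=float).ravel()
    b = np.asarray(b, dtype=float).ravel()
    if p < 1:
        raise ValueError("lag order must be at least 1")
    r = a.shape[0]
    if b.shape[0] != r:
        raise ValueError("series lengths differ")
    if r <= 2 * p + 1:
        raise ValueError(f"series length {r} too short for order {p}")
    if a.std() < 1e-14 or b.std() < 1e-14:
        raise NumericalError("constant series: Granger statistic undefined")
    x = np.column_stack([a, b])
    Y, Z = _lag_embed(x, p)
    y = Y[:, 0]
    Za = Z[:, :p]  # own lags of a
    coef_r, *_ = np.linalg.lstsq(Za, y, rcond=None)
    rss_r = float(np.sum((y - Za @ coef_r) ** 2))
    coef_f, *_ = np.linalg.lstsq(Z, y, rcond=None)
    rss_f = float(np.sum((y - Z @ coef_f) ** 2))
    if rss_f <= _RSS_FLOOR:
        raise NumericalError("full-model residual is zero: series are collinear")
    return max(float(np.log(rss_r / rss_f)), 0.0)


def _solve_gram(A: np.ndarray, b: np.ndarray) -> np.ndarray:
    """Solve normal equations, batched; pinv fallback on singularity."""
    try:
        return np.linalg.solve(A, b)
    except np.linalg.LinAlgError:
        return np.linalg.pinv(A) @ b


def select_order(w: WindowSample, p_max: int = 10) -> int:
    """BIC-selected shared lag order for one window.

    For each candidate p in 1..p_max a bivariate VAR(p) is fit to every
    unordered series pair on the common sample t = p_max..r-1 and scored
    by BIC = ln det(Sigma_hat) + k ln(N)/N with k = 4p parameters per
    pair; scores are pooled (averaged) over pairs and the smallest p
    wins ties. With a single series the fits are univariate AR models.
    """
    if p_max < 1:
        raise ValueError("p_max must be at least 1")
    x = w.data
    r, c = x.shape
    if r <= 10 * p_max:
        raise ValueError(f"window of {r} points too short for p_max={p_max} (need > {10 * p_max})")
    Y, Z = _lag_embed(x, p_max)
    n = Y.shape[0]
    G = Z.T @ Z
    C = Z.T @ Y
    YY = Y.T @ Y
    pairs = [(i, j) for i in range(c) for j in range(i + 1, c)] if c > 1 else [(0, 0)]
    bics = np.empty(p_max)
    for p in range(1, p_max + 1):
        scores = []
        for i, j in pairs:
            if i == j:  # univariate fallback
                idx = np.arange(i * p_max, i * p_max + p)
                tgt = [i]
                k = p
            else:
                idx = np.r_[
                    np.arange(i * p_max, i * p_max + p),
                    np.arange(j * p_max, j * p_max + p),
                ]
                tgt = [i, j]
                k = 4 * p
            Gs = G[np.ix_(idx, idx)]
            Cs = C[np.ix_(idx, tgt)]
            B = _solve_gram(Gs, Cs)
            ee = YY[np.ix_(tgt, tgt)] - Cs.T @ B
            sigma = ee / n
            sign, logdet = np.linalg.slogdet(sigma)
            if sign <= 0:
                logdet = -np.inf  # perfect fit; BIC then driven by penalty
            scores.append(logdet + k * np.log(n) / n)
        bics[p - 1] = float(np.mean(scores))
    return int(np.argmin(bics)) + 1


def causal_matrix(w: WindowSample, p: int) -> CausalMatrix:
    """All-pairs Granger causal matrix of one (detrended) window.

    g[i, j] = F_{i->j}; computed from one lag-Gram matrix per window
    with batched 2p x 2p solves, numerically equal to calling
    :func:`granger_pair` per ordered pair.
    """
    x = w.data
    r, c = x.shape
    if p < 1:
        raise ValueError("lag order must be at least 1")
    if r <= 2 * p + 1:
        raise ValueError(f"window of {r} points too short for order {p}")
    stds = x.std(axis=0)
    if np.any(stds < 1e-14):
        bad = int(np.argmin(stds))
        raise NumericalError(f"series {bad} is constant: Granger statistic undefined")
    Y, Z = _lag_embed(x, p)
    G = Z.T @ Z
    C = Z.T @ Y
    ysq = np.einsum("ti,ti->i", Y, Y)

    # Restricted models: target j on its own lags only; c solves of size p.
    own = np.arange(c)[:, None] * p + np.arange(p)[None, :]
    G_r = G[own[:, :, None], own[:, None, :]]  # (c, p, p)
    C_r = C[own, np.arange(c)[:, None]][:, :, None]  # (c, p, 1)
    b_r = _solve_gram(G_r, C_r)
    rss_r = ysq - np.einsum("cpi,cpi->c", C_r, b_r)

    # Full models: target j on lags of j then i; c(c-1) solves of size 2p.
    drivers, targets = np.where(~np.eye(c, dtype=bool))
    idx = np.concatenate([own[targets], own[drivers]], axis=1)  # (n_pairs, 2p)
    G_f = G[idx[:, :, None], idx[:, None, :]]
    C_f = C[idx, targets[:, None]][:, :, None]
    b_f = _solve_gram(G_f, C_f)
    rss_f = ysq[targets] - np.einsum("kpi,kpi->k", C_f, b_f)

    if np.any(rss_f <= _RSS_FLOOR):
        k = int(np.argmax(rss_f <= _RSS_FLOOR))
        raise NumericalError(
            f"zero full-model residual for pair ({drivers[k]}, {targets[k]}): collinear series"
        )
    f = np.log(rss_r[targets] / rss_f)
    g = np.zeros((c, c))
    g[drivers, targets] = np.maximum(f, 0.0)
    return CausalMatrix(g=g, order=p, window=w.ref)
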