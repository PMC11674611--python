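"""In-memory containers shared across the pipeline.

Conventions
-----------
Continuous multichannel signals are stored rows = series (channels or
regions), columns = time. Window samples are stored the other way round
(rows = time points), which is the orientation the regression steps
consume; the transpose happens exactly once, inside ``segment``.

Region membership vectors are 1-based: dipole ``k`` belongs to region
``membership[k]`` in ``1..c``. The order of ``region_names`` fixes the
row/column order of every source-space matrix downstream.
"""

from __future__ import annotations

from dataclasses import dataclass, field

import numpy as np

from .errors import DataError


def _check_finite(a: np.ndarray, what: str) -> None:
    if not np.all(np.isfinite(a)):
        raise DataError(f"{what} contains NaN or inf")


@dataclass
class RawEEG:
    """Multichannel scalp EEG, rows = channels."""

    data: np.ndarray
    fs: float
    channel_names: list[str]

    def __post_init__(self) -> None:
        self.data = np.asarray(self.data, dtype=float)
        if self.data.ndim != 2 or self.data.shape[0] < 1:
            raise DataError("EEG data must be a 2-D channels x time matrix")
        if self.fs <= 0:
            raise DataError("EEG sampling rate must be positive")
        _check_finite(self.data, "EEG data")
        if len(self.channel_names) != self.data.shape[0]:
            raise DataError("channel_names length must match channel count")

    @property
    def n_channels(self) -> int:
        return self.data.shape[0]

    @property
    def n_samples(self) -> int:
        return self.data.shape[1]


@dataclass
class RawFNIRS:
    """Multichannel fNIRS, rows = channels.

    ``signal_kind`` records whether the rows are optical-density changes
    or oxygenated-haemoglobin concentration changes; it is propagated by
    every transform so the coupling stage can insist on HbO input.
    """

    data: np.ndarray
    fs: float
    channel_names: list[str]
    signal_kind: str = "hbo"  # "optical_density" | "hbo"

    def __post_init__(self) -> None:
        self.data = np.asarray(self.data, dtype=float)
        if self.data.ndim != 2 or self.data.shape[0] < 1:
            raise DataError("fNIRS data must be a 2-D channels x time matrix")
        if self.fs <= 0:
            raise DataError("fNIRS sampling rate must be positive")
        if self.signal_kind not in ("optical_density", "hbo", "hbr"):
            raise DataError(f"unknown signal_kind {self.signal_kind!r}")
        _check_finite(self.data, "fNIRS data")
        if len(self.channel_names) != self.data.shape[0]:
            raise DataError("channel_names length must match channel count")

    @property
    def n_channels(self) -> int:
        return self.data.shape[0]


@dataclass
class SourceSignals:
    """Region-level cortical time series, rows = atlas regions."""

    data: np.ndarray
    region_names: list[str]
    fs: float

    def __post_init__(self) -> None:
        self.data = np.asarray(self.data, dtype=float)
        if self.data.ndim != 2:
            raise DataError("source signals must be a 2-D regions x time matrix")
        _check_finite(self.data, "source signals")
        if len(self.region_names) != self.data.shape[0]:
            raise DataError("region_names length must match region count")

    @property
    def n_regions(self) -> int:
        return self.data.shape[0]

    @property
    def n_samples(self) -> int:
        return self.data.shape[1]


@dataclass(frozen=True)
class WindowRef:
    """Identifies one analysis window within one trial."""

    trial_id: int
    t_start: float


@dataclass
class WindowSample:
    """One sliding-window sample: rows = time points, columns = series."""

    data: np.ndarray
    t_start: float
    trial_id: int = 0
    label: int | None = None

    def __post_init__(self) -> None:
        self.data = np.asarray(self.data, dtype=float)
        if self.data.ndim != 2:
            raise DataError("window data must be 2-D (time x series)")

    @property
    def ref(self) -> WindowRef:
        return WindowRef(self.trial_id, self.t_start)

    @property
    def n_times(self) -> int:
        return self.data.shape[0]

    @property
    def n_series(self) -> int:
        return self.data.shape[1]


@dataclass
class CausalMatrix:
    """Directed Granger-causality adjacency for one window.

    ``g[i, j]`` is the causality of source i onto source j (log residual
    variance ratio of the restricted vs. the full regression), so the
    matrix is generally asymmetric. The diagonal is fixed at zero:
    self-causality is undefined under the nested-model contrast.
    """

    g: np.ndarray
    order: int
    window: WindowRef

    def __post_init__(self) -> None:
        self.g = np.asarray(self.g, dtype=float)
        if self.g.ndim != 2 or self.g.shape[0] != self.g.shape[1]:
            raise DataError("causal matrix must be square")
        _check_finite(self.g, "causal matrix")
        if np.any(self.g < 0):
            raise DataError("causal matrix entries must be nonnegative")


@dataclass
class TimeVaryingPower:
    """Band-summed, min-max normalised power envelope of one source.

    Values lie in [0, 1]; a constant (degenerate) envelope maps to all
    zeros rather than dividing by zero.
    """

    p: np.ndarray
    fs: float

    def __post_init__(self) -> None:
        self.p = np.asarray(self.p, dtype=float)
        _check_finite(self.p, "time-varying power")
        if np.any(self.p < -1e-12):
            raise DataError("time-varying power must be nonnegative")


@dataclass
class HrfKernel:
    """Canonical haemodynamic response sampled on a uniform grid."""

    samples: np.ndarray
    dt: float

    def __post_init__(self) -> None:
        self.samples = np.asarray(self.samples, dtype=float)
        _check_finite(self.samples, "HRF kernel")


@dataclass
class CouplingMatrix:
    """EEG-source -> fNIRS-channel coupling strengths for one window.

    ``cs[i, j] = |beta_ij|`` from the window's GLM fit: the absolute
    regression coefficient of predicted-fNIRS regressor i for measured
    channel j.
    """

    cs: np.ndarray
    window: WindowRef

    def __post_init__(self) -> None:
        self.cs = np.asarray(self.cs, dtype=float)
        _check_finite(self.cs, "coupling matrix")
        if np.any(self.cs < 0):
            raise DataError("coupling strengths must be nonnegative")


@dataclass
class HybridNetwork:
    """Column-wise concatenation of a causal and a coupling matrix, c x (c+d)."""

    h: np.ndarray
    window: WindowRef
    label: int | None = None

    def __post_init__(self) -> None:
        self.h = np.asarray(self.h, dtype=float)
        _check_finite(self.h, "hybrid network")


FEATURE_KINDS = ("EG", "SG", "EC", "SC", "EG_EC", "SG_SC")


@dataclass
class FeatureSet:
    """Vectorised network features ready for classification."""

    matrix: np.ndarray
    labels: np.ndarray
    feature_kind: str
    subject: str = "sub-01"

    def __post_init__(self) -> None:
        self.matrix = np.asarray(self.matrix, dtype=float)
        self.labels = np.asarray(self.labels, dtype=int)
        if self.feature_kind not in FEATURE_KINDS:
            raise DataError(f"unknown feature kind {self.feature_kind!r}")
        if self.matrix.ndim != 2 or self.matrix.shape[0] != self.labels.shape[0]:
            raise DataError("feature matrix and labels disagree on sample count")
        _check_finite(self.matrix, "feature matrix")


@dataclass
class GroundTruth:
    """True generative parameters of a synthetic dataset.

    ``adjacency[i, j]`` is the VAR gain of source j driving source i
    (column drives row); the diagonal holds self-regression gains and is
    excluded from edge-recovery scoring. ``class_adjacency`` /
    ``class_coupling`` hold the per-class templates actually used to
    generate trials (they equal the base templates when the class effect
    size is zero).
    """

    adjacency: np.ndarray
    coupling_weights: np.ndarray
    labels: np.ndarray
    seed: int
    var_order: int
    fs: float
    class_adjacency: np.ndarray | None = None
    class_coupling: np.ndarray | None = None


@dataclass
class SyntheticDataset:
    """A full synthetic multimodal recording session."""

    trials: list  # of (eeg: u x n, fnirs: d x n_f, label)
    lead_field: np.ndarray
    membership: np.ndarray
    region_names: list[str]
    ground_truth: GroundTruth
    fs_eeg: float
    fs_fnirs: float
    eeg_channel_names: list[str] = field(default_factory=list)
    fnirs_channel_names: list[str] = field(default_factory=list)
    fnirs_signal_kind: str = "hbo"
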