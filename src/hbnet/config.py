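"""Validated configuration for the pipeline and the simulator.

All models reject unknown keys so that a typo in a YAML file fails loudly
before any compute starts.
"""

from __future__ import annotations

import json
from pathlib import Path

import yaml
from pydantic import BaseModel, ConfigDict, Field, ValidationError, model_validator

from .errors import ConfigError

__all__ = [
    "SimConfig",
    "PreprocessConfig",
    "InverseSettings",
    "GrangerConfig",
    "CouplingConfig",
    "EvalConfig",
    "PipelineConfig",
    "load_config",
]


class _Strict(BaseModel):
    model_config = ConfigDict(extra="forbid")


class SimConfig(_Strict):
    """Study-design parameters of the synthetic concurrent EEG/fNIRS session.

    Defaults mirror a desk-scale version of a 4-emotion video paradigm:
    four balanced classes of 15 trials each (60 trials), 30 s trials,
    EEG at 200 Hz through a 16-electrode montage over 16 dipoles in 8
    cortical regions, and 4 fNIRS channels at 11 Hz driven by the
    sources through known nonnegative coupling weights.
    """

    c: int = Field(8, ge=2, description="number of cortical regions")
    d: int = Field(4, ge=1, description="number of fNIRS channels")
    u: int = Field(16, ge=2, description="number of EEG electrodes")
    v: int = Field(16, ge=2, description="number of dipoles")
    n_classes: int = Field(4, ge=2)
    trials_per_class: int = Field(15, ge=1)
    trial_s: float = Field(30.0, gt=0)
    fs_eeg: float = Field(200.0, gt=0)
    fs_fnirs: float = Field(11.0, gt=0)
    var_order: int = Field(2, ge=1)
    n_edges: int = Field(6, ge=0, description="directed cross-couplings in the base VAR")
    self_gain: float = Field(0.4, description="diagonal VAR gain of every source")
    edge_gain: float = Field(0.35, gt=0, description="mean gain of a cross-coupling edge")
    effect_size: float = Field(
        0.5, ge=0, description="relative sd of the class-template perturbation"
    )
    source_noise_sd: float = Field(1.0, gt=0)
    modulation_depth: float = Field(
        0.6, ge=0, lt=1,
        description="peak relative amplitude of the slow stimulus-intensity modulation",
    )
    modulation_class_frac: float = Field(
        0.8, ge=0, le=1,
        description="share of the intensity modulation common to all trials of a class "
        "(same-emotion stimuli share temporal structure); disabled when effect_size = 0",
    )
    eeg_noise_sd: float = Field(0.5, ge=0)
    fnirs_snr_db: float | None = Field(10.0, description="None = noiseless fNIRS")
    seed: int = 0

    @model_validator(mode="after")
    def _dims(self) -> "SimConfig":
        if self.v < self.c:
            raise ValueError(f"need at least one dipole per region (v={self.v} < c={self.c})")
        return self


class MbllConfig(_Strict):
    wavelengths: tuple[float, float] = (760.0, 850.0)
    dpf: float = Field(6.0, gt=0)
    distance_cm: float = Field(3.0, gt=0)


class PreprocessConfig(_Strict):
    eeg_band: tuple[float, float] = (0.5, 45.0)
    fnirs_band: tuple[float, float] = (0.01, 0.2)
    target_fs: float = Field(200.0, gt=0)
    window_s: float = Field(3.0, gt=0)
    step_s: float = Field(1.5, gt=0)
    rereference: bool = False  # optional common-average re-reference of EEG
    mbll: MbllConfig = MbllConfig()


class InverseSettings(_Strict):
    alpha: float | None = Field(None, gt=0, description="None = data-scale default")
    snr: float = Field(3.0, gt=0)


class GrangerConfig(_Strict):
    p_max: int = Field(10, ge=1)
    fixed_p: int | None = Field(None, ge=1, description="skip BIC selection when set")


class CouplingConfig(_Strict):
    stft_win_s: float = Field(1.0, gt=0)
    stft_hop_s: float = Field(0.1, gt=0)
    f_min: float = Field(0.5, gt=0)
    f_max: float = Field(45.0, gt=0)
    hrf_duration_s: float = Field(32.0, gt=0)
    glm_kappa: float | None = Field(
        3.0, gt=0,
        description="significance cutoff for SVD coordinates of the window GLM; "
        "None = plain least squares",
    )
    glm_sv_rel: float = Field(
        0.1, ge=0,
        description="relative singular-value floor of the window GLM used for "
        "feature extraction (stable-subspace policy)",
    )


class EvalConfig(_Strict):
    classifiers: list[str] = ["svm_linear", "knn10"]
    feature_kinds: list[str] = ["SG", "SC", "SG_SC"]
    k_folds: int = Field(5, ge=2)
    repeats: int = Field(5, ge=1)
    fold_unit: str = Field(
        "sample",
        pattern="^(sample|trial)$",
        description="'sample' replicates the reference protocol; 'trial' avoids "
        "leakage through overlapping windows of one trial",
    )


class PipelineConfig(_Strict):
    seed: int = 0
    subject: str = "sub-01"
    sim: SimConfig = SimConfig()
    preprocess: PreprocessConfig = PreprocessConfig()
    inverse: InverseSettings = InverseSettings()
    granger: GrangerConfig = GrangerConfig()
    coupling: CouplingConfig = CouplingConfig()
    evaluate: EvalConfig = EvalConfig()
    include_sensor_space: bool = Field(
        False, description="also build sensor-space (EG/EC) networks"
    )


def load_config(path: str | Path | None = None, overrides: dict | None = None) -> PipelineConfig:
    """Load and validate a pipeline config from YAML or JSON.

    ``overrides`` (e.g. a CLI --seed) are applied on top of the file.
    Unknown keys anywhere raise :class:`ConfigError` naming the key.
    """
    payload: dict = {}
    if path is not None:
        text = Path(path).read_text()
        payload = yaml.safe_load(text) if str(path).endswith((".yml", ".yaml")) else json.loads(text)
        if payload is None:
            payload = {}
        if not isinstance(payload, dict):
            raise ConfigError(f"config root must be a mapping, got {type(payload).__name__}")
    if overrides:
        payload = _deep_merge(payload, overrides)
    try:
        return PipelineConfig.model_validate(payload)
    except ValidationError as exc:
        raise ConfigError(str(exc)) from exc


def _deep_merge(base: dict, extra: dict) -> dict:
    out = dict(base)
    for k, v in extra.items():
        if isinstance(v, dict) and isinstance(out.get(k), dict):
            out[k] = _deep_merge(out[k], v)
        else:
            out[k] = v
    return out
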