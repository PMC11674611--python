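"""Staged orchestration: simulate -> preprocess -> source -> networks ->
features -> evaluate.

Each stage persists its outputs (compressed array archives plus JSON
manifests recording the config hash, seed and package version) under its
own directory and skips work whose outputs already exist under the same
config hash, so reruns are cheap and interrupted runs resume. The causal
stage is the slow one — c(c-1) lagged regressions per window — which is
why per-trial caching pays off.
"""

from __future__ import annotations

import hashlib
import json
import logging
import time
import warnings
from pathlib import Path

import numpy as np

from . import __version__
from .causal import causal_matrix, detrend_window, select_order
from .config import PipelineConfig
from .containers import RawFNIRS, SourceSignals
from .coupling import trial_coupling
from .errors import CapabilityError, DataError
from .features import EvalResult, build_feature_set, evaluate
from .io_formats import load_dataset, read_leadfield, write_dataset, write_delimited
from .preprocess import bandpass, baseline_correct, mbll, resample, segment
from .source_space import InverseConfig, mne_inverse, parcellate
from .synthetic import simulate_dataset

log = logging.getLogger("hbnet")

__all__ = [
    "run_simulate",
    "run_preprocess",
    "run_source",
    "run_networks",
    "run_features",
    "run_evaluate",
    "run_all",
    "config_hash",
]


def config_hash(cfg: PipelineConfig) -> str:
    return hashlib.sha256(cfg.model_dump_json().encode()).hexdigest()[:16]


def _write_manifest(out: Path, cfg: PipelineConfig, stage: str, extra: dict | None = None) -> None:
    payload = {
        "stage": stage,
        "config_hash": config_hash(cfg),
        "seed": cfg.seed,
        "version": __version__,
    }
    if extra:
        payload.update(extra)
    (out / "manifest.json").write_text(json.dumps(payload, sort_keys=True))


def _manifest_matches(out: Path, cfg: PipelineConfig) -> bool:
    mf = out / "manifest.json"
    if not mf.exists():
        return False
    try:
        return json.loads(mf.read_text()).get("config_hash") == config_hash(cfg)
    except (json.JSONDecodeError, OSError):
        return False


def run_simulate(cfg: PipelineConfig, out_dir: str | Path) -> Path:
    """Generate the synthetic dataset and write it in the on-disk layout."""
    out = Path(out_dir)
    out.mkdir(parents=True, exist_ok=True)
    t0 = time.perf_counter()
    sim_cfg = cfg.sim.model_copy(update={"seed": cfg.seed})
    ds = simulate_dataset(sim_cfg)
    write_dataset(ds, out, subject=cfg.subject)
    _write_manifest(out, cfg, "simulate", {"n_trials": len(ds.trials)})
    log.info("simulate: %d trials in %.1fs", len(ds.trials), time.perf_counter() - t0)
    return out


def run_preprocess(cfg: PipelineConfig, dataset_dir: str | Path, out_dir: str | Path) -> Path:
    """Filter/convert/resample both modalities onto the common grid."""
    out = Path(out_dir)
    out.mkdir(parents=True, exist_ok=True)
    t0 = time.perf_counter()
    ds = load_dataset(dataset_dir, subject=cfg.subject)
    p = cfg.preprocess
    n_warn = 0
    for idx, (eeg, fnirs, label) in enumerate(ds.trials, start=1):
        path = out / f"trial_{idx:03d}.npz"
        if path.exists() and _manifest_matches(out, cfg):
            continue
        x = np.asarray(eeg, dtype=float)
        if p.rereference:
            x = x - x.mean(axis=0, keepdims=True)
        x = bandpass(x, ds.fs_eeg, *p.eeg_band)
        x = resample(x, ds.fs_eeg, p.target_fs)
        payload = {"eeg": x, "label": label}
        if fnirs is not None:
            y = baseline_correct(np.asarray(fnirs, dtype=float), ds.fs_fnirs)
            y = bandpass(y, ds.fs_fnirs, *p.fnirs_band)
            if ds.fnirs_signal_kind == "optical_density":
                hbo, _ = mbll(
                    RawFNIRS(y, ds.fs_fnirs, ds.fnirs_channel_names, "optical_density"),
                    wavelengths=p.mbll.wavelengths,
                    dpf=p.mbll.dpf,
                    distance_cm=p.mbll.distance_cm,
                )
                y = hbo.data
            y = resample(y, ds.fs_fnirs, p.target_fs)
            payload["fnirs"] = y
        np.savez_compressed(path, **payload)
    _write_manifest(out, cfg, "preprocess", {"n_trials": len(ds.trials), "warnings": n_warn})
    log.info("preprocess: %d trials in %.1fs", len(ds.trials), time.perf_counter() - t0)
    return out


def run_source(
    cfg: PipelineConfig, dataset_dir: str | Path, preproc_dir: str | Path, out_dir: str | Path
) -> Path:
    """Minimum-norm inversion and parcellation of every trial."""
    out = Path(out_dir)
    out.mkdir(parents=True, exist_ok=True)
    t0 = time.perf_counter()
    L, membership, region_names = read_leadfield(
        Path(dataset_dir) / cfg.subject / "leadfield.json"
    )
    inv = InverseConfig(alpha=cfg.inverse.alpha, snr=cfg.inverse.snr)
    files = sorted(Path(preproc_dir).glob("trial_*.npz"))
    for path in files:
        opath = out / path.name
        if opath.exists() and _manifest_matches(out, cfg):
            continue
        with np.load(path) as z:
            X, label = z["eeg"], int(z["label"])
        J = mne_inverse(X, L, inv)
        S = parcellate(J, membership, region_names, fs=cfg.preprocess.target_fs)
        np.savez_compressed(opath, sources=S.data, label=label)
    _write_manifest(out, cfg, "source", {"n_trials": len(files)})
    log.info("source: %d trials in %.1fs", len(files), time.perf_counter() - t0)
    return out


def _trial_networks(cfg: PipelineConfig, series: np.ndarray, fnirs: np.ndarray | None, trial_id: int):
    """Per-window causal (and coupling) matrices for one set of series."""
    p_cfg = cfg.preprocess
    windows = segment(series, p_cfg.target_fs, p_cfg.window_s, p_cfg.step_s, trial_id=trial_id)
    gs, orders, t_starts = [], [], []
    for w in windows:
        wd = detrend_window(w)
        p = cfg.granger.fixed_p or select_order(wd, cfg.granger.p_max)
        gs.append(causal_matrix(wd, p).g)
        orders.append(p)
        t_starts.append(w.t_start)
    cs = None
    if fnirs is not None:
        S = SourceSignals(
            data=series,
            region_names=[f"s{i}" for i in range(series.shape[0])],
            fs=p_cfg.target_fs,
        )
        cc = cfg.coupling
        cms = trial_coupling(
            S,
            fnirs,
            window_s=p_cfg.window_s,
            step_s=p_cfg.step_s,
            f_min=cc.f_min,
            f_max=cc.f_max,
            stft_win_s=cc.stft_win_s,
            stft_hop_s=cc.stft_hop_s,
            hrf_duration_s=cc.hrf_duration_s,
            glm_kappa=cc.glm_kappa,
            glm_sv_rel=cc.glm_sv_rel,
            trial_id=trial_id,
        )
        if len(cms) != len(windows):
            raise DataError(
                f"trial {trial_id}: {len(cms)} coupling vs {len(windows)} causal windows"
            )
        cs = np.stack([m.cs for m in cms])
    return np.stack(gs), cs, np.asarray(orders), np.asarray(t_starts)


def run_networks(
    cfg: PipelineConfig, preproc_dir: str | Path, source_dir: str | Path, out_dir: str | Path
) -> Path:
    """Per-trial, per-window causal and coupling matrices (resumable)."""
    out = Path(out_dir)
    out.mkdir(parents=True, exist_ok=True)
    t0 = time.perf_counter()
    files = sorted(Path(source_dir).glob("trial_*.npz"))
    n_skipped = 0
    for path in files:
        opath = out / path.name
        if opath.exists() and _manifest_matches(out, cfg):
            continue
        try:
            with np.load(path) as z:
                S, label = z["sources"], int(z["label"])
            fnirs = None
            ppath = Path(preproc_dir) / path.name
            with np.load(ppath) as z:
                if "fnirs" in z:
                    fnirs = z["fnirs"]
                eeg = z["eeg"] if cfg.include_sensor_space else None
        except (OSError, ValueError, KeyError, json.JSONDecodeError) as exc:
            warnings.warn(f"skipping unreadable trial {path.name}: {exc}", stacklevel=2)
            n_skipped += 1
            continue
        trial_id = int(path.stem.split("_")[1])
        gs, cs, orders, t_starts = _trial_networks(cfg, S, fnirs, trial_id)
        payload = {"gs": gs, "orders": orders, "t_starts": t_starts, "label": label}
        if cs is not None:
            payload["cs"] = cs
        if eeg is not None:
            eg, ec, *_ = _trial_networks(cfg, eeg, fnirs, trial_id)
            payload["eg"] = eg
            if ec is not None:
                payload["ec"] = ec
        np.savez_compressed(opath, **payload)
    _write_manifest(out, cfg, "networks", {"n_trials": len(files), "skipped": n_skipped})
    log.info(
        "networks: %d trials (%d skipped) in %.1fs",
        len(files), n_skipped, time.perf_counter() - t0,
    )
    return out


_KIND_BLOCKS = {
    "SG": ("gs",),
    "SC": ("cs",),
    "SG_SC": ("gs", "cs"),
    "EG": ("eg",),
    "EC": ("ec",),
    "EG_EC": ("eg", "ec"),
}


def run_features(cfg: PipelineConfig, networks_dir: str | Path, out_dir: str | Path) -> Path:
    """Assemble per-window feature matrices for every requested kind."""
    out = Path(out_dir)
    out.mkdir(parents=True, exist_ok=True)
    files = sorted(Path(networks_dir).glob("trial_*.npz"))
    if not files:
        raise DataError(f"no network files under {networks_dir}")
    for kind in cfg.evaluate.feature_kinds:
        blocks = _KIND_BLOCKS.get(kind)
        if blocks is None:
            raise ValueError(f"unknown feature kind {kind!r}")
        rows, labels, groups = [], [], []
        for path in files:
            with np.load(path) as z:
                missing = [b for b in blocks if b not in z]
                if missing:
                    raise CapabilityError(
                        f"feature kind {kind} needs network block(s) {missing} absent from "
                        f"{path.name} (EEG-only data cannot support coupling features)"
                    )
                mats = [z[b] for b in blocks]
                label = int(z["label"])
            trial_id = int(path.stem.split("_")[1])
            n_w = mats[0].shape[0]
            for wi in range(n_w):
                rows.append(np.concatenate([m[wi].reshape(-1) for m in mats]))
                labels.append(label)
                groups.append(trial_id)
        X = np.stack(rows)
        write_delimited(
            out / f"features_{kind}.csv",
            X,
            fs=0.0,
            channel_names=[f"f{i}" for i in range(X.shape[1])],
            extra_meta={
                "feature_kind": kind,
                "labels": labels,
                "groups": groups,
                "subject": cfg.subject,
            },
        )
    _write_manifest(out, cfg, "features", {"kinds": cfg.evaluate.feature_kinds})
    return out


def load_feature_set(features_dir: str | Path, kind: str):
    path = Path(features_dir) / f"features_{kind}.csv"
    if not path.exists():
        raise CapabilityError(f"no feature file for kind {kind} under {features_dir}")
    meta = json.loads(Path(str(path) + ".json").read_text())
    X = np.loadtxt(path, delimiter=",", skiprows=1, ndmin=2)
    return build_feature_set(
        [row for row in X],  # rows are already vectors
        meta["labels"],
        kind,
        subject=meta.get("subject", "sub-01"),
        groups=meta.get("groups"),
    )


def run_evaluate(cfg: PipelineConfig, features_dir: str | Path, out_dir: str | Path) -> dict:
    """Cross-validated accuracies for every (feature kind x classifier) cell."""
    out = Path(out_dir)
    out.mkdir(parents=True, exist_ok=True)
    ev = cfg.evaluate
    report: dict = {"seed": cfg.seed, "config_hash": config_hash(cfg), "cells": {}}
    for kind in ev.feature_kinds:
        fs = load_feature_set(features_dir, kind)
        for clf in ev.classifiers:
            res: EvalResult = evaluate(
                fs, clf, k_folds=ev.k_folds, repeats=ev.repeats,
                seed=cfg.seed, fold_unit=ev.fold_unit,
            )
            report["cells"][f"{kind}/{clf}"] = res.to_dict()
    (out / "report.json").write_text(json.dumps(report, indent=2))
    lines = [
        "# Evaluation report",
        "",
        f"seed: {cfg.seed}, config: {report['config_hash']}",
        "",
        "| feature | classifier | accuracy | sd |",
        "|---|---|---|---|",
    ]
    for cell, r in report["cells"].items():
        kind, clf = cell.split("/")
        lines.append(
            f"| {kind} | {clf} | {100 * r['accuracy_mean']:.1f}% | {100 * r['accuracy_sd']:.2f} |"
        )
    (out / "report.md").write_text("\n".join(lines) + "\n")
    return report


def run_all(cfg: PipelineConfig, workdir: str | Path) -> dict:
    """Run the full chain under one working directory."""
    workdir = Path(workdir)
    ds = run_simulate(cfg, workdir / "dataset")
    pp = run_preprocess(cfg, ds, workdir / "preproc")
    src = run_source(cfg, ds, pp, workdir / "source")
    net = run_networks(cfg, pp, src, workdir / "networks")
    feat = run_features(cfg, net, workdir / "features")
    return run_evaluate(cfg, feat, workdir / "report")
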