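"""Readers and writers for every format the pipeline touches.

The canonical interchange format is a delimited text matrix (rows =
channels, one header line of channel names) with a small JSON sidecar
(``<file>.json``) holding the sampling rate and, for fNIRS, the signal
kind. EDF (via mne), SNIRF (via h5py) and MAT v5 (via scipy) are
supported for interoperability; MAT trial files additionally accept a
user-supplied variable-name mapping because vendor exports do not agree
on naming.

Datasets live in one directory per subject with ``EEG/`` and ``FNIRS/``
subdirectories holding one file per trial, plus ``leadfield.json`` and a
``ground_truth.json`` sidecar when the data are synthetic.

All readers reject NaN/inf payloads and silently truncated files.
"""

from __future__ import annotations

import json
import warnings
from pathlib import Path

import h5py
import numpy as np
from scipy import io as sio

from .containers import GroundTruth, RawEEG, RawFNIRS, SyntheticDataset
from .errors import ConsistencyError, DataError, FormatError, MetadataError

__all__ = [
    "read_eeg",
    "read_fnirs",
    "read_leadfield",
    "write_leadfield",
    "write_delimited",
    "write_edf",
    "write_snirf",
    "write_mat",
    "write_dataset",
    "load_dataset",
]


# ---------------------------------------------------------------- delimited

def write_delimited(
    path: str | Path,
    data: np.ndarray,
    fs: float,
    channel_names: list[str],
    signal_kind: str | None = None,
    extra_meta: dict | None = None,
) -> None:
    """Write rows-as-channels delimited matrix plus JSON metadata sidecar."""
    path = Path(path)
    data = np.atleast_2d(np.asarray(data, dtype=float))
    header = ",".join(channel_names)
    np.savetxt(path, data, delimiter=",", header=header, comments="")
    meta = {"fs": fs, "channel_names": list(channel_names)}
    if signal_kind is not None:
        meta["signal_kind"] = signal_kind
    if extra_meta:
        meta.update(extra_meta)
    Path(str(path) + ".json").write_text(json.dumps(meta))


def _read_delimited(path: Path, fs: float | None):
    lines = path.read_text().splitlines()
    if not lines:
        raise DataError(f"{path} is empty")
    names = [s.strip() for s in lines[0].split(",")]
    try:
        data = np.loadtxt(lines[1:], delimiter=",", ndmin=2)
    except ValueError as exc:
        raise DataError(f"{path} is malformed or truncated: {exc}") from exc
    if data.shape[0] != len(names):
        raise DataError(
            f"{path}: header names {len(names)} channels but file has {data.shape[0]} rows"
        )
    meta = {}
    sidecar = Path(str(path) + ".json")
    if sidecar.exists():
        meta = json.loads(sidecar.read_text())
    if fs is None:
        fs = meta.get("fs")
    if fs is None:
        raise MetadataError(f"sampling rate for {path} not in sidecar and not supplied")
    return data, float(fs), names, meta


# ---------------------------------------------------------------------- EDF

def write_edf(path: str | Path, data: np.ndarray, fs: float, channel_names: list[str]) -> None:
    """Minimal EDF+ -compatible writer (16-bit, 1 s data records).

    Physical ranges are stored as integers so the 8-character header
    fields parse exactly; amplitudes are quantised to 16 bits, so the
    round trip preserves the sampling rate exactly and the samples to
    ~1e-4 relative. Requires an integer sampling rate; signals whose
    length is not a whole number of seconds are zero-padded to the next
    record boundary (lengths are restored from the sidecar-free EDF
    header only up to that boundary).
    """
    path = Path(path)
    data = np.atleast_2d(np.asarray(data, dtype=float))
    if abs(fs - round(fs)) > 1e-9:
        raise ValueError("EDF writer requires an integer sampling rate")
    spr = int(round(fs))  # samples per 1 s record
    nch, n = data.shape
    n_rec = -(-n // spr)
    padded = np.zeros((nch, n_rec * spr))
    padded[:, :n] = data

    pmin = np.floor(padded.min(axis=1)).astype(int)
    pmax = np.ceil(padded.max(axis=1)).astype(int)
    same = pmax <= pmin
    pmax[same] = pmin[same] + 1
    if (np.abs(pmin) > 9_999_999).any() or (np.abs(pmax) > 9_999_999).any():
        raise DataError("amplitudes too large for EDF physical-range fields; rescale first")

    def field(text: str, width: int) -> bytes:
        b = str(text).encode("ascii")
        if len(b) > width:
            raise ValueError(f"EDF field {text!r} exceeds {width} chars")
        return b.ljust(width)

    hdr = b"".join(
        [
            field("0", 8),
            field("X X X X", 80),
            field("Startdate 01-JAN-2000 X X X", 80),
            field("01.01.00", 8),
            field("00.00.00", 8),
            field(str(256 * (nch + 1)), 8),
            field("", 44),
            field(str(n_rec), 8),
            field("1", 8),
            field(str(nch), 4),
        ]
    )
    per = [
        b"".join(field(nm, 16) for nm in channel_names),
        b"".join(field("", 80) for _ in channel_names),
        b"".join(field("uV", 8) for _ in channel_names),
        b"".join(field(str(v), 8) for v in pmin),
        b"".join(field(str(v), 8) for v in pmax),
        b"".join(field("-32768", 8) for _ in channel_names),
        b"".join(field("32767", 8) for _ in channel_names),
        b"".join(field("", 80) for _ in channel_names),
        b"".join(field(str(spr), 8) for _ in channel_names),
        b"".join(field("", 32) for _ in channel_names),
    ]
    gain = (pmax - pmin) / 65535.0
    dig = np.round((padded - pmin[:, None]) / gain[:, None]) - 32768
    dig = np.clip(dig, -32768, 32767).astype("<i2")
    records = dig.reshape(nch, n_rec, spr).transpose(1, 0, 2)  # record-major
    with open(path, "wb") as fh:
        fh.write(hdr)
        fh.writelines(per)
        fh.write(records.tobytes())


def _read_edf(path: Path):
    import mne

    with warnings.catch_warnings():
        warnings.simplefilter("ignore")
        raw = mne.io.read_raw_edf(path, preload=True, verbose="error")
    # mne scales channels labelled uV to volts; undo to return file units
    data = raw.get_data() * 1e6
    return data, float(raw.info["sfreq"]), list(raw.ch_names)


# -------------------------------------------------------------------- SNIRF

def write_snirf(
    path: str | Path,
    data: np.ndarray,
    fs: float,
    channel_names: list[str],
    signal_kind: str = "hbo",
    wavelengths: tuple[float, float] = (760.0, 850.0),
) -> None:
    """Write the minimal SNIRF v1.0 structure the reader needs.

    Processed haemoglobin series use dataType 99999 with dataTypeLabel
    'HbO'; optical density uses dataType 1 (CW amplitude).
    """
    path = Path(path)
    data = np.atleast_2d(np.asarray(data, dtype=float))
    n = data.shape[1]
    with h5py.File(path, "w") as f:
        f.create_dataset("formatVersion", data="1.0")
        nirs = f.create_group("nirs")
        d1 = nirs.create_group("data1")
        d1.create_dataset("dataTimeSeries", data=data.T)  # time x channels
        d1.create_dataset("time", data=np.arange(n) / fs)
        for k in range(data.shape[0]):
            ml = d1.create_group(f"measurementList{k + 1}")
            ml.create_dataset("sourceIndex", data=k + 1)
            ml.create_dataset("detectorIndex", data=k + 1)
            ml.create_dataset("wavelengthIndex", data=1)
            if signal_kind == "optical_density":
                ml.create_dataset("dataType", data=1)
            else:
                ml.create_dataset("dataType", data=99999)
                ml.create_dataset("dataTypeLabel", data="HbO")
        probe = nirs.create_group("probe")
        probe.create_dataset("wavelengths", data=np.asarray(wavelengths))
        nirs.create_dataset(
            "channelNames", data=np.array(channel_names, dtype=h5py.string_dtype())
        )


def _read_snirf(path: Path):
    with h5py.File(path, "r") as f:
        if "nirs/data1/dataTimeSeries" not in f:
            raise FormatError(f"{path} lacks /nirs/data1/dataTimeSeries; not a SNIRF file?")
        data = np.asarray(f["nirs/data1/dataTimeSeries"]).T  # channels x time
        if "nirs/data1/time" not in f:
            raise MetadataError(f"{path} lacks the SNIRF time dataset (sampling rate unknown)")
        t = np.asarray(f["nirs/data1/time"]).ravel()
        if t.size == 2 and data.shape[1] > 2:
            fs = 1.0 / float(t[1])  # [start, dt] form
        elif t.size >= 2:
            fs = 1.0 / float(np.median(np.diff(t)))
        else:
            raise MetadataError(f"{path}: time dataset too short to infer sampling rate")
        kind = "optical_density"
        ml1 = f.get("nirs/data1/measurementList1")
        if ml1 is not None:
            label = ml1.get("dataTypeLabel")
            if label is not None:
                val = label[()]
                text = val.decode() if isinstance(val, bytes) else str(val)
                if text.lower().startswith("hbo"):
                    kind = "hbo"
                elif text.lower().startswith("hbr"):
                    kind = "hbr"
        if "nirs/channelNames" in f:
            names = [
                s.decode() if isinstance(s, bytes) else str(s)
                for s in np.asarray(f["nirs/channelNames"]).ravel()
            ]
        else:
            names = [f"CH{i + 1}" for i in range(data.shape[0])]
    return data, fs, names, kind


# --------------------------------------------------------------------- MAT

def write_mat(
    path: str | Path, data: np.ndarray, fs: float, channel_names: list[str], var: str = "data"
) -> None:
    sio.savemat(
        str(path),
        {var: np.asarray(data, dtype=float), "fs": float(fs), "channel_names": channel_names},
    )


def _read_mat(path: Path, fs: float | None, var_map: dict | None):
    var_map = var_map or {}
    contents = sio.loadmat(str(path))
    data_var = var_map.get("data")
    if data_var is None:
        # best effort: the largest 2-D numeric array in the file
        cands = {
            k: v
            for k, v in contents.items()
            if not k.startswith("__") and isinstance(v, np.ndarray) and v.ndim == 2 and v.size > 1
        }
        if not cands:
            raise FormatError(f"{path}: no 2-D numeric array found; supply var_map={{'data': name}}")
        data_var = max(cands, key=lambda k: cands[k].size)
    if data_var not in contents:
        raise FormatError(f"{path}: variable {data_var!r} not present")
    data = np.asarray(contents[data_var], dtype=float)
    fs_var = var_map.get("fs", "fs")
    if fs is None:
        if fs_var in contents:
            fs = float(np.asarray(contents[fs_var]).ravel()[0])
        else:
            raise MetadataError(f"{path}: sampling rate variable {fs_var!r} missing and fs not supplied")
    names_var = var_map.get("channel_names", "channel_names")
    if names_var in contents:
        names = [str(s).strip() for s in np.asarray(contents[names_var]).ravel()]
    else:
        names = [f"ch{i + 1}" for i in range(data.shape[0])]
    return data, float(fs), names


# ------------------------------------------------------------ entry points

def read_eeg(
    path: str | Path,
    format: str = "delimited",
    fs: float | None = None,
    var_map: dict | None = None,
) -> RawEEG:
    """Load multichannel EEG from ``delimited``, ``edf`` or ``mat``."""
    path = Path(path)
    if not path.exists():
        raise FileNotFoundError(path)
    if format == "delimited":
        data, fs, names, _ = _read_delimited(path, fs)
    elif format == "edf":
        data, fs, names = _read_edf(path)
    elif format == "mat":
        data, fs, names = _read_mat(path, fs, var_map)
    else:
        raise FormatError(f"unknown EEG format {format!r} (use delimited/edf/mat)")
    return RawEEG(data=data, fs=fs, channel_names=names)


def read_fnirs(
    path: str | Path,
    format: str = "delimited",
    fs: float | None = None,
    signal_kind: str | None = None,
    var_map: dict | None = None,
) -> RawFNIRS:
    """Load multichannel fNIRS from ``delimited``, ``snirf`` or ``mat``.

    ``signal_kind`` overrides metadata; delimited files carry it in the
    sidecar, SNIRF in dataTypeLabel, MAT files need the flag.
    """
    path = Path(path)
    if not path.exists():
        raise FileNotFoundError(path)
    if format == "delimited":
        data, fs, names, meta = _read_delimited(path, fs)
        kind = signal_kind or meta.get("signal_kind")
        if kind is None:
            raise MetadataError(f"{path}: signal_kind not in sidecar and not supplied")
    elif format == "snirf":
        data, fs_file, names, kind = _read_snirf(path)
        fs = fs if fs is not None else fs_file
        kind = signal_kind or kind
    elif format == "mat":
        data, fs, names = _read_mat(path, fs, var_map)
        kind = signal_kind or "hbo"
    else:
        raise FormatError(f"unknown fNIRS format {format!r} (use delimited/snirf/mat)")
    return RawFNIRS(data=data, fs=fs, channel_names=names, signal_kind=kind)


# --------------------------------------------------------------- lead field

def write_leadfield(
    path: str | Path,
    lead_field: np.ndarray,
    membership: np.ndarray,
    region_names: list[str],
) -> None:
    payload = {
        "lead_field": np.asarray(lead_field, dtype=float).tolist(),
        "membership": np.asarray(membership, dtype=int).tolist(),
        "region_names": list(region_names),
    }
    Path(path).write_text(json.dumps(payload))


def read_leadfield(path: str | Path) -> tuple[np.ndarray, np.ndarray, list[str]]:
    """Load a lead field with its dipole->region membership map.

    The order of ``region_names`` defines the row/column order of every
    source-space matrix downstream. Membership ids must lie in 1..c.
    """
    payload = json.loads(Path(path).read_text())
    for key in ("lead_field", "membership", "region_names"):
        if key not in payload:
            raise FormatError(f"{path} lacks required key {key!r}")
    L = np.asarray(payload["lead_field"], dtype=float)
    membership = np.asarray(payload["membership"], dtype=int)
    names = [str(s) for s in payload["region_names"]]
    if L.ndim != 2:
        raise ConsistencyError("lead field must be 2-D")
    if membership.shape[0] != L.shape[1]:
        raise ConsistencyError(
            f"membership lists {membership.shape[0]} dipoles but lead field has {L.shape[1]} columns"
        )
    c = len(names)
    if membership.min() < 1 or membership.max() > c:
        raise ConsistencyError(
            f"membership ids must lie in 1..{c}, found range "
            f"[{membership.min()}, {membership.max()}]"
        )
    if not np.all(np.isfinite(L)):
        raise DataError("lead field contains NaN or inf")
    return L, membership, names


# ------------------------------------------------------------ dataset layout

def write_dataset(ds: SyntheticDataset, root: str | Path, subject: str = "sub-01") -> Path:
    """Persist a dataset as one directory per subject with EEG/ and FNIRS/."""
    sub = Path(root) / subject
    (sub / "EEG").mkdir(parents=True, exist_ok=True)
    (sub / "FNIRS").mkdir(parents=True, exist_ok=True)
    for idx, (eeg, fnirs, label) in enumerate(ds.trials, start=1):
        meta = {"label": int(label), "trial": idx}
        write_delimited(
            sub / "EEG" / f"trial_{idx:03d}.csv",
            eeg,
            ds.fs_eeg,
            ds.eeg_channel_names or [f"EEG{i:03d}" for i in range(1, eeg.shape[0] + 1)],
            extra_meta=meta,
        )
        if fnirs is not None:
            write_delimited(
                sub / "FNIRS" / f"trial_{idx:03d}.csv",
                fnirs,
                ds.fs_fnirs,
                ds.fnirs_channel_names or [f"CH{i}" for i in range(1, fnirs.shape[0] + 1)],
                signal_kind=ds.fnirs_signal_kind,
                extra_meta=meta,
            )
    write_leadfield(sub / "leadfield.json", ds.lead_field, ds.membership, ds.region_names)
    gt = ds.ground_truth
    if gt is not None:
        payload = {
            "adjacency": gt.adjacency.tolist(),
            "coupling_weights": gt.coupling_weights.tolist(),
            "labels": gt.labels.tolist(),
            "seed": gt.seed,
            "var_order": gt.var_order,
            "fs": gt.fs,
        }
        if gt.class_adjacency is not None:
            payload["class_adjacency"] = gt.class_adjacency.tolist()
        if gt.class_coupling is not None:
            payload["class_coupling"] = gt.class_coupling.tolist()
        (sub / "ground_truth.json").write_text(json.dumps(payload))
    return sub


def load_dataset(root: str | Path, subject: str | None = None) -> SyntheticDataset:
    """Load a dataset written by :func:`write_dataset`."""
    root = Path(root)
    if subject is None:
        subs = sorted(p.name for p in root.iterdir() if (p / "EEG").is_dir())
        if len(subs) != 1:
            raise FormatError(f"{root} holds {len(subs)} subjects; pass subject explicitly")
        subject = subs[0]
    sub = root / subject
    L, membership, region_names = read_leadfield(sub / "leadfield.json")
    eeg_files = sorted((sub / "EEG").glob("trial_*.csv"))
    fnirs_files = sorted((sub / "FNIRS").glob("trial_*.csv")) if (sub / "FNIRS").is_dir() else []
    if not eeg_files:
        raise ConsistencyError(f"{sub}: no EEG trial files")
    if fnirs_files and len(eeg_files) != len(fnirs_files):
        raise ConsistencyError(
            f"{sub}: {len(eeg_files)} EEG vs {len(fnirs_files)} fNIRS trial files"
        )
    trials = []
    fs_eeg = fs_fnirs = None
    eeg_names: list[str] = []
    fnirs_names: list[str] = []
    fnirs_kind = "hbo"
    for i, ef in enumerate(eeg_files):
        eeg = read_eeg(ef, "delimited")
        meta = json.loads(Path(str(ef) + ".json").read_text())
        fs_eeg = eeg.fs
        eeg_names = eeg.channel_names
        fnirs_data = None
        if fnirs_files:
            fnirs = read_fnirs(fnirs_files[i], "delimited")
            fnirs_data = fnirs.data
            fs_fnirs = fnirs.fs
            fnirs_names = fnirs.channel_names
            fnirs_kind = fnirs.signal_kind
        trials.append((eeg.data, fnirs_data, int(meta.get("label", -1))))
    gt = None
    gt_path = sub / "ground_truth.json"
    if gt_path.exists():
        payload = json.loads(gt_path.read_text())
        gt = GroundTruth(
            adjacency=np.asarray(payload["adjacency"], dtype=float),
            coupling_weights=np.asarray(payload["coupling_weights"], dtype=float),
            labels=np.asarray(payload["labels"], dtype=int),
            seed=int(payload["seed"]),
            var_order=int(payload["var_order"]),
            fs=float(payload["fs"]),
            class_adjacency=(
                np.asarray(payload["class_adjacency"], dtype=float)
                if "class_adjacency" in payload
                else None
            ),
            class_coupling=(
                np.asarray(payload["class_coupling"], dtype=float)
                if "class_coupling" in payload
                else None
            ),
        )
    return SyntheticDataset(
        trials=trials,
        lead_field=L,
        membership=membership,
        region_names=region_names,
        ground_truth=gt,
        fs_eeg=fs_eeg,
        fs_fnirs=fs_fnirs,
        eeg_channel_names=eeg_names,
        fnirs_channel_names=fnirs_names,
        fnirs_signal_kind=fnirs_kind,
    )
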