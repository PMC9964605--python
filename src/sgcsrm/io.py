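"""Configuration, file formats, reports, and run manifests.

Readers cover the per-subject MAT layout common to EEG emotion corpora
(MAT v7 via scipy, v7.3/HDF5 via h5py), with configurable key patterns,
plus an HDF5 feature store written by this package.  Writers emit plain
JSON/CSV reports that round-trip exactly.
"""

from __future__ import annotations

import hashlib
import json
import re
import time
from dataclasses import asdict, dataclass, field, fields
from pathlib import Path

import h5py
import numpy as np
import pandas as pd
import scipy.io
import yaml

from . import __version__
from .features import BandFeatureTensor, CLASS_NAMES, DEFAULT_BANDS, RawRecording
from .training import FoldResult, RunSummary

__all__ = [
    "RunConfig",
    "load_config",
    "RunManifest",
    "load_seed_mat",
    "save_feature_tensor",
    "load_feature_tensor",
    "write_manifest",
    "write_report",
    "read_report",
    "save_checkpoint",
    "load_checkpoint",
]

#: SEED convention: trial labels -1/0/1 meaning negative/neutral/positive.
_SEED_LABEL_TO_CLASS = {-1: 0, 0: 1, 1: 2}


@dataclass(frozen=True)
class RunConfig:
    """All tunable run settings with their defaults.

    Unknown keys in a config file are rejected rather than ignored, so typos
    cannot silently fall back to defaults.
    """

    a: float = 0.01  # L1 regularization strength on the band adjacencies
    lr0: float = 0.001
    decay: float = 0.96
    epochs: int = 50
    batch_size: int = 64
    delta: float = 5.0  # inverse-square-law scale of the initial adjacency
    channels: str = "all"  # "all" | "seed12"
    bands: str = "all"  # "all" | "four"
    feature_kind: str = "DE"  # "DE" | "PSD"
    window_s: float = 1.0
    target_windows: int = 265
    mode: str = "fusion"  # "fusion" | "direct"
    use_srm: bool = True
    use_global: bool = True
    freeze_adjacency: bool = False
    h1: int = 128
    metric_window: int = 10
    seed: int = 0


def load_config(path) -> RunConfig:
    """Load a YAML config; empty file means all defaults; unknown keys error."""
    text = Path(path).read_text()
    raw = yaml.safe_load(text) or {}
    if not isinstance(raw, dict):
        raise ValueError("config file must contain a mapping")
    known = {f.name for f in fields(RunConfig)}
    unknown = sorted(set(raw) - known)
    if unknown:
        raise ValueError(f"unknown config keys: {unknown}")
    return RunConfig(**raw)


@dataclass
class RunManifest:
    """Everything needed to re-run a result bit-identically."""

    config: dict
    seed: int
    package_version: str = __version__
    input_digests: dict = field(default_factory=dict)
    created_unix: float = field(default_factory=time.time)

    @staticmethod
    def digest(path) -> str:
        h = hashlib.sha256()
        h.update(Path(path).read_bytes())
        return h.hexdigest()


def write_manifest(manifest: RunManifest, path) -> None:
    Path(path).write_text(json.dumps(asdict(manifest), indent=2, sort_keys=True))


# ---------------------------------------------------------------------------
# MAT reading (SEED layout)
# ---------------------------------------------------------------------------


def _load_mat_any(path) -> dict[str, np.ndarray]:
    """Read MAT v7 (scipy) or v7.3 (HDF5) into a flat dict of arrays."""
    path = Path(path)
    try:
        raw = scipy.io.loadmat(path)
        return {k: np.asarray(v) for k, v in raw.items() if not k.startswith("__")}
    except NotImplementedError:
        # v7.3 files are HDF5; scipy defers them
        try:
            out: dict[str, np.ndarray] = {}
            with h5py.File(path, "r") as f:
                def visit(name, obj):
                    if isinstance(obj, h5py.Dataset):
                        # MATLAB v7.3 stores arrays transposed
                        out[name.split("/")[-1]] = np.asarray(obj).T
                f.visititems(visit)
            return out
        except OSError as exc:
            raise ValueError(f"cannot read MAT file {path}: {exc}") from exc
    except Exception as exc:  # scipy surfaces corrupt files in several ways
        raise ValueError(f"cannot read MAT file {path}: {exc}") from exc


def load_seed_mat(
    directory,
    key_pattern: str = r".*eeg(\d+)$",
    label_file: str = "label.mat",
    label_key: str = "label",
    fs: float = 200.0,
    channel_names: tuple[str, ...] | None = None,
    kind: str = "raw",
    band_names: tuple[str, ...] | None = None,
):
    """Read a directory of per-subject MAT files in the SEED layout.

    Each subject file holds one array per trial under keys matching
    ``key_pattern`` (one capture group: the 1-based trial number); a separate
    label file maps trials to {-1, 0, 1} = negative/neutral/positive.

    ``kind='raw'`` expects (channels x time) arrays and returns a list of
    :class:`RawRecording`; ``kind='de'`` expects precomputed
    (channels x windows x bands) tensors and returns a
    :class:`BandFeatureTensor` (trials zero-padded to the longest).
    """
    directory = Path(directory)
    label_path = directory / label_file
    if not label_path.exists():
        raise FileNotFoundError(f"missing label file {label_path}")
    labels_raw = np.asarray(_load_mat_any(label_path)[label_key]).ravel().astype(int)
    pattern = re.compile(key_pattern)

    subject_files = sorted(
        p for p in directory.iterdir() if p.suffix == ".mat" and p.name != label_file
    )
    if not subject_files:
        raise FileNotFoundError(f"no subject MAT files in {directory}")

    records: list[tuple[str, int, np.ndarray]] = []  # (subject, trial number, array)
    for path in subject_files:
        subject = path.stem.split("_")[0]
        data = _load_mat_any(path)
        for key, arr in data.items():
            match = pattern.match(key)
            if match is None:
                continue
            trial_no = int(match.group(1))
            if trial_no < 1 or trial_no > len(labels_raw):
                raise ValueError(
                    f"trial key {key!r} in {path.name} outside the label table "
                    f"(1..{len(labels_raw)})"
                )
            records.append((subject, trial_no, np.asarray(arr, dtype=float)))
    if not records:
        raise ValueError(f"no keys matching {key_pattern!r} found in {directory}")

    if kind == "raw":
        recordings = []
        for subject, trial_no, arr in records:
            if arr.ndim != 2:
                raise ValueError(
                    f"raw trial arrays must be (channels x time); found shape {arr.shape}"
                )
            names = channel_names or tuple(f"ch{i}" for i in range(arr.shape[0]))
            recordings.append(
                RawRecording(
                    samples=arr,
                    fs=fs,
                    channel_names=names,
                    subject_id=subject,
                    trial_id=f"{subject}_t{trial_no:02d}",
                    label=CLASS_NAMES[_SEED_LABEL_TO_CLASS[int(labels_raw[trial_no - 1])]],
                )
            )
        return recordings

    if kind != "de":
        raise ValueError("kind must be 'raw' or 'de'")
    arrays = [arr for _, _, arr in records]
    for arr in arrays:
        if arr.ndim != 3:
            raise ValueError(
                f"DE trial arrays must be (channels x windows x bands); found shape {arr.shape}"
            )
    c = arrays[0].shape[0]
    b = arrays[0].shape[2]
    d_max = max(arr.shape[1] for arr in arrays)
    values = np.zeros((len(arrays), c, b, d_max))
    for i, arr in enumerate(arrays):
        values[i, :, :, : arr.shape[1]] = arr.transpose(0, 2, 1)
    names = channel_names or tuple(f"ch{i}" for i in range(c))
    bands = band_names or tuple(band.name for band in DEFAULT_BANDS[:b])
    return BandFeatureTensor(
        values=values,
        channel_names=names,
        band_names=bands,
        subject_ids=np.array([s for s, _, _ in records]),
        labels=np.array(
            [_SEED_LABEL_TO_CLASS[int(labels_raw[t - 1])] for _, t, _ in records]
        ),
        feature_kind="DE",
        trial_ids=np.array([f"{s}_t{t:02d}" for s, t, _ in records]),
        n_windows=np.array([arr.shape[1] for arr in arrays]),
    )


# ---------------------------------------------------------------------------
# HDF5 feature store
# ---------------------------------------------------------------------------


def save_feature_tensor(tensor: BandFeatureTensor, path, manifest_csv=None) -> None:
    """Write a feature tensor to HDF5 with axis-name attributes.

    Optionally also writes a CSV manifest (trial, subject, label, n_windows).
    """
    with h5py.File(path, "w") as f:
        f.create_dataset("values", data=tensor.values)
        f.attrs["feature_kind"] = tensor.feature_kind
        f.attrs["axes"] = "trial,channel,band,window"
        str_dt = h5py.string_dtype()
        f.create_dataset("channel_names", data=np.array(tensor.channel_names, dtype=object), dtype=str_dt)
        f.create_dataset("band_names", data=np.array(tensor.band_names, dtype=object), dtype=str_dt)
        f.create_dataset("subject_ids", data=tensor.subject_ids.astype(object), dtype=str_dt)
        f.create_dataset("labels", data=tensor.labels.astype(int))
        if tensor.trial_ids is not None:
            f.create_dataset("trial_ids", data=tensor.trial_ids.astype(object), dtype=str_dt)
        if tensor.n_windows is not None:
            f.create_dataset("n_windows", data=tensor.n_windows.astype(int))
    if manifest_csv is not None:
        n = tensor.values.shape[0]
        pd.DataFrame(
            {
                "trial": tensor.trial_ids if tensor.trial_ids is not None else np.arange(n),
                "subject": tensor.subject_ids,
                "label": [CLASS_NAMES[int(l)] for l in tensor.labels],
                "n_windows": tensor.n_windows
                if tensor.n_windows is not None
                else np.full(n, tensor.values.shape[3]),
            }
        ).to_csv(manifest_csv, index=False)


def load_feature_tensor(path) -> BandFeatureTensor:
    with h5py.File(path, "r") as f:
        def strs(name):
            return tuple(x.decode() if isinstance(x, bytes) else str(x) for x in f[name][()])
        return BandFeatureTensor(
            values=f["values"][()],
            channel_names=strs("channel_names"),
            band_names=strs("band_names"),
            subject_ids=np.array(strs("subject_ids")),
            labels=f["labels"][()],
            feature_kind=f.attrs["feature_kind"],
            trial_ids=np.array(strs("trial_ids")) if "trial_ids" in f else None,
            n_windows=f["n_windows"][()] if "n_windows" in f else None,
        )


# ---------------------------------------------------------------------------
# Reports
# ---------------------------------------------------------------------------


def write_report(summary: RunSummary, directory, manifest: RunManifest | None = None) -> dict:
    """Write summary.json, folds.csv, confusion.csv (and manifest.json).

    Returns the paths written.  Re-reading ``summary.json`` reproduces the
    summary exactly (:func:`read_report`).
    """
    directory = Path(directory)
    directory.mkdir(parents=True, exist_ok=True)
    paths = {
        "summary": directory / "summary.json",
        "folds": directory / "folds.csv",
        "confusion": directory / "confusion.csv",
    }
    paths["summary"].write_text(json.dumps(summary.as_dict(), indent=2))
    pd.DataFrame(
        {
            "held_out_subject": [f.held_out_subject for f in summary.fold_results],
            "fold_accuracy": [f.fold_accuracy for f in summary.fold_results],
        }
    ).to_csv(paths["folds"], index=False)
    pd.DataFrame(
        summary.confusion_percent, index=list(CLASS_NAMES), columns=list(CLASS_NAMES)
    ).to_csv(paths["confusion"])
    if manifest is not None:
        paths["manifest"] = directory / "manifest.json"
        write_manifest(manifest, paths["manifest"])
    return paths


def read_report(directory) -> RunSummary:
    """Rebuild a :class:`RunSummary` from a written report directory."""
    raw = json.loads((Path(directory) / "summary.json").read_text())
    folds = [
        FoldResult(
            held_out_subject=f["held_out_subject"],
            per_epoch_test_accuracy=f["per_epoch_test_accuracy"],
            fold_accuracy=f["fold_accuracy"],
            confusion_counts=np.asarray(f["confusion_counts"], dtype=int),
        )
        for f in raw["folds"]
    ]
    return RunSummary(
        acc_mean=raw["acc_mean"],
        acc_std=raw["acc_std"],
        fold_results=folds,
        confusion_percent=np.asarray(raw["confusion_percent"]),
    )


# ---------------------------------------------------------------------------
# Checkpoints
# ---------------------------------------------------------------------------


def save_checkpoint(model, path, sidecar_json=None) -> None:
    """Single-file NPZ of all weights/adjacencies plus a JSON config sidecar."""
    state = model.state_arrays()
    config = asdict(model.config) if not isinstance(model.config, dict) else model.config
    np.savez(path, __config__=json.dumps(config, default=str), **state)
    if sidecar_json is not None:
        Path(sidecar_json).write_text(
            json.dumps(
                {"parameter_count": model.parameter_count(), "config": config},
                indent=2,
                default=str,
            )
        )


def load_checkpoint(path, layout):
    """Rebuild a model from a checkpoint written by :func:`save_checkpoint`."""
    from .model import ConvStackConfig, ModelConfig, SgcSrmModel

    with np.load(path, allow_pickle=False) as data:
        config_raw = json.loads(str(data["__config__"]))
        state = {k: data[k] for k in data.files if k != "__config__"}
    if config_raw.get("conv") is not None:
        config_raw["conv"] = ConvStackConfig(**config_raw["conv"])
    config_raw["bands"] = tuple(config_raw["bands"])
    model = SgcSrmModel(ModelConfig(**config_raw), layout)
    model.load_state_arrays(state)
    return model
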