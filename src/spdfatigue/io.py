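"""Readers and writers: trial containers, EDF ingestion, tables and checkpoints.

The plain trial container is one ``.npy`` float array (channels x samples)
per trial plus a JSON sidecar holding the sampling rate and channel names.  A
dataset directory holds a ``trials/`` folder of containers and a
``trials.csv`` table (trial_id, subject_id, local_RT, global_RT, class,
label).  Model checkpoints are a ``.npz`` of named arrays plus a JSON
manifest recording the architecture, the vech ordering and the feature
layout, so a reloaded model reproduces identical predictions.
"""

from __future__ import annotations

import dataclasses
import json
from pathlib import Path

import numpy as np
import pandas as pd

from . import fusion, spd, temporal as tb
from .fusion import FusionModel, TrainConfig
from .synthetic import TrialSet

__all__ = [
    "save_trial",
    "load_trial",
    "save_dataset",
    "load_dataset",
    "read_edf",
    "save_checkpoint",
    "load_checkpoint",
]


def save_trial(stem, signal: np.ndarray, fs: float, channel_names=None) -> None:
    """Write one trial container: ``<stem>.npy`` plus ``<stem>.json`` sidecar."""
    stem = Path(stem)
    signal = np.asarray(signal, dtype=float)
    np.save(stem.with_suffix(".npy"), signal)
    names = (
        list(channel_names)
        if channel_names is not None
        else [f"ch{i:02d}" for i in range(signal.shape[0])]
    )
    meta = {"fs": float(fs), "channel_names": names, "shape": list(signal.shape)}
    stem.with_suffix(".json").write_text(json.dumps(meta, indent=1))


def load_trial(stem):
    """Read one trial container; returns ``(signal, meta)`` and checks the shape."""
    stem = Path(stem)
    signal = np.load(stem.with_suffix(".npy"))
    meta = json.loads(stem.with_suffix(".json").read_text())
    if list(signal.shape) != meta["shape"]:
        raise ValueError(
            f"{stem}: header shape {meta['shape']} but array shape {list(signal.shape)}"
        )
    return signal, meta


def save_dataset(path, dataset: TrialSet) -> None:
    """Write a generated dataset: per-trial containers plus the trial table."""
    path = Path(path)
    (path / "trials").mkdir(parents=True, exist_ok=True)
    for t in dataset.trials:
        if t.signal is not None:
            save_trial(path / "trials" / f"trial_{t.trial_id:05d}", t.signal,
                       fs=dataset.config.fs)
    dataset.to_frame().to_csv(path / "trials.csv", index=False)
    cfg = dataclasses.asdict(dataset.config)
    cfg["trials_per_subject"] = list(cfg["trials_per_subject"])
    (path / "gen_config.json").write_text(json.dumps(cfg, indent=1))


def load_dataset(path):
    """Read a dataset directory back as ``(signals, table)``.

    Signals are stacked in trial-table order; trials without a stored
    container (e.g. excluded ones written without signals) raise.
    """
    path = Path(path)
    table = pd.read_csv(path / "trials.csv")
    signals = []
    for tid in table["trial_id"]:
        stem = path / "trials" / f"trial_{int(tid):05d}"
        if not stem.with_suffix(".npy").exists():
            raise FileNotFoundError(f"missing trial container {stem}.npy")
        sig, _ = load_trial(stem)
        signals.append(sig)
    return np.stack(signals), table


def read_edf(path, drop_channels=()):
    """Read an EDF recording via MNE; returns ``(data, fs, channel_names)``.

    ``drop_channels`` removes e.g. reference electrodes before analysis.
    """
    import mne

    raw = mne.io.read_raw_edf(str(path), preload=True, verbose="error")
    drop = [ch for ch in drop_channels if ch in raw.ch_names]
    if drop:
        raw.drop_channels(drop)
    return raw.get_data(), float(raw.info["sfreq"]), list(raw.ch_names)


# ---------------------------------------------------------------------------
# checkpoints
# ---------------------------------------------------------------------------


def _config_to_dict(cfg: TrainConfig) -> dict:
    return dataclasses.asdict(cfg)


def save_checkpoint(path, model: FusionModel) -> None:
    """Serialize a fused model: named arrays (.npz) plus a JSON manifest."""
    path = Path(path)
    arrays = {"fc_w": model.fc_w, "fc_b": model.fc_b}
    for i, layer in enumerate(model.lstm.layers):
        arrays[f"lstm{i}_wx"] = layer.wx
        arrays[f"lstm{i}_wh"] = layer.wh
        arrays[f"lstm{i}_b"] = layer.b
    if model.spdnet is not None:
        arrays["spd_w1"] = model.spdnet.w1
        arrays["spd_w2"] = model.spdnet.w2
    if model.centers is not None:
        arrays["center_vigilant"] = model.centers.vigilant.matrix
        arrays["center_drowsy"] = model.centers.drowsy.matrix
    if model.lstm_mean is not None:
        arrays["lstm_mean"] = model.lstm_mean
        arrays["lstm_std"] = model.lstm_std
    np.savez(path.with_suffix(".npz"), **arrays)
    manifest = {
        "config": _config_to_dict(model.config),
        "layout": [list(b) for b in model.layout.blocks],
        "n_lstm_layers": len(model.lstm.layers),
        "vech_ordering": "row-major lower triangle (diagonal included)",
        "layer_order": ["BiMap", "ReEig", "BiMap", "LogEig"],
        "centers": None
        if model.centers is None
        else {
            "vigilant": {"iterations": model.centers.vigilant.iterations,
                         "residual": model.centers.vigilant.residual},
            "drowsy": {"iterations": model.centers.drowsy.iterations,
                       "residual": model.centers.drowsy.residual},
        },
    }
    path.with_suffix(".json").write_text(json.dumps(manifest, indent=1))


def load_checkpoint(path) -> FusionModel:
    """Reload a checkpoint; the result reproduces identical predictions."""
    path = Path(path)
    arrays = np.load(path.with_suffix(".npz"))
    manifest = json.loads(path.with_suffix(".json").read_text())
    cfg = TrainConfig(**manifest["config"])
    from .spdnet import SPDNetParams
    from .temporal import LSTMLayerParams, LSTMParams

    layers = [
        LSTMLayerParams(arrays[f"lstm{i}_wx"], arrays[f"lstm{i}_wh"], arrays[f"lstm{i}_b"])
        for i in range(manifest["n_lstm_layers"])
    ]
    spdp = None
    if "spd_w1" in arrays:
        spdp = SPDNetParams(arrays["spd_w1"], arrays["spd_w2"],
                            eps_rect=cfg.eps_rect, stiefel=cfg.stiefel)
    centers = None
    if "center_vigilant" in arrays:
        m = manifest["centers"]
        centers = spd.CenterPair(
            vigilant=spd.CenterResult(arrays["center_vigilant"],
                                      m["vigilant"]["iterations"],
                                      m["vigilant"]["residual"], True),
            drowsy=spd.CenterResult(arrays["center_drowsy"],
                                    m["drowsy"]["iterations"],
                                    m["drowsy"]["residual"], True),
        )
    layout = fusion.FeatureLayout(tuple((n, int(l)) for n, l in manifest["layout"]))
    return FusionModel(
        layout=layout,
        lstm=LSTMParams(layers),
        fc_w=arrays["fc_w"],
        fc_b=arrays["fc_b"],
        config=cfg,
        spdnet=spdp,
        centers=centers,
        lstm_mean=arrays["lstm_mean"] if "lstm_mean" in arrays else None,
        lstm_std=arrays["lstm_std"] if "lstm_std" in arrays else None,
    )
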