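"""Feature fusion, alternating spatial-temporal training, and LOSO evaluation.

Per trial, three feature blocks are available:

* ``X_L`` — final hidden state of the 2-layer LSTM over the 7-step covariance
  sequence (temporal-relation features);
* ``X_S`` — half-vectorized output of the SPD network applied to the
  whole-trial covariance (spatial-relation features);
* ``X_D`` — the two Stein-divergence distances to the vigilant and drowsy
  class centers, computed from training trials only.

The blocks are concatenated in the order (X_L, X_S, X_D) and classified by a
fully connected layer with softmax.  Training alternates: odd iterations take
a gradient step on the LSTM, even iterations on the SPD network, and the
fully connected head moves every iteration; the loss is the cross-entropy of
the softmax output, optimized full-batch with plain gradient steps.  Early
stopping monitors a held-out split of the training fold.

Ablation variants restrict the fused feature layout: ``TRDC`` uses X_L only,
``SDTR`` uses (X_L, X_D), ``SNTR`` uses (X_L, X_S), ``full`` uses all three.

Evaluation is leave-one-subject-out: one fold per subject, drowsy as the
positive class, and accuracy / sensitivity / specificity / F1 reported per
fold with mean and variance aggregates.
"""

from __future__ import annotations

import warnings
from dataclasses import dataclass, field, replace

import numpy as np
import pandas as pd

from . import spd, spdnet as sn, temporal as tb

__all__ = [
    "TrainConfig",
    "FeatureLayout",
    "FusionModel",
    "Metrics",
    "VARIANTS",
    "fuse",
    "predict",
    "prepare_features",
    "train_alternating",
    "model_probabilities",
    "evaluate_loso",
    "ablation_variants",
    "metrics_from_confusion",
]

VARIANTS = {
    "full": ("XL", "XS", "XD"),
    "TRDC": ("XL",),
    "SDTR": ("XL", "XD"),
    "SNTR": ("XL", "XS"),
}


@dataclass(frozen=True)
class TrainConfig:
    """Hyperparameters of the fused classifier and its optimizer."""

    # spatial branch
    d1: int = 24
    d2: int = 16
    eps_rect: float = 1e-4
    stiefel: bool = True
    # temporal branch
    hidden_size: int = 64
    n_layers: int = 2
    standardize_lstm: bool = True
    # covariance estimation / centers
    eps_cov: float = 1e-8
    center_thre: float = 1e-9
    center_max_iter: int = 50
    # optimizer (plain alternating gradient steps)
    lr_lstm: float = 3e-2
    lr_spd: float = 1e-2
    lr_fc: float = 0.25
    maxite: int = 50
    early_stopping: bool = True
    val_frac: float = 0.1
    patience: int = 10
    # trial geometry
    win: float = 3.0
    step: float = 1.0
    fs: float = 250.0
    n_channels: int = 30
    variant: str = "full"
    seed: int = 0

    def __post_init__(self):
        if self.variant not in VARIANTS:
            raise ValueError(
                f"unknown variant {self.variant!r}; valid names: {sorted(VARIANTS)}"
            )


@dataclass(frozen=True)
class FeatureLayout:
    """Named spans of the fused feature vector."""

    blocks: tuple  # ordered tuple of (name, length)

    @property
    def total(self) -> int:
        return sum(n for _, n in self.blocks)

    def slices(self) -> dict:
        out, start = {}, 0
        for name, length in self.blocks:
            out[name] = slice(start, start + length)
            start += length
        return out

    def split(self, fused: np.ndarray) -> dict:
        return {name: fused[..., sl] for name, sl in self.slices().items()}


def layout_for(config: TrainConfig) -> FeatureLayout:
    sizes = {
        "XL": config.hidden_size,
        "XS": tb.vech_length(config.d2),
        "XD": 2,
    }
    return FeatureLayout(tuple((b, sizes[b]) for b in VARIANTS[config.variant]))


@dataclass
class FusionModel:
    """Parameter bundle of the fused classifier."""

    layout: FeatureLayout
    lstm: tb.LSTMParams
    fc_w: np.ndarray
    fc_b: np.ndarray
    config: TrainConfig
    spdnet: sn.SPDNetParams | None = None
    centers: spd.CenterPair | None = None
    lstm_mean: np.ndarray | None = None
    lstm_std: np.ndarray | None = None

    def copy_params(self) -> dict:
        return {
            "lstm": self.lstm.copy(),
            "spdnet": self.spdnet.copy() if self.spdnet is not None else None,
            "fc_w": self.fc_w.copy(),
            "fc_b": self.fc_b.copy(),
        }

    def restore_params(self, saved: dict) -> None:
        self.lstm = saved["lstm"]
        self.spdnet = saved["spdnet"]
        self.fc_w = saved["fc_w"]
        self.fc_b = saved["fc_b"]


def fuse(xl, xs, xd, layout: FeatureLayout) -> np.ndarray:
    """Concatenate the feature blocks the layout requests, in (X_L, X_S, X_D) order."""
    blocks = {"XL": xl, "XS": xs, "XD": xd}
    parts = []
    for name, length in layout.blocks:
        arr = np.asarray(blocks[name], dtype=float)
        if arr.shape[-1] != length:
            raise ValueError(
                f"block {name} has length {arr.shape[-1]}, layout expects {length}"
            )
        parts.append(arr)
    return np.concatenate(parts, axis=-1)


def _softmax(z: np.ndarray) -> np.ndarray:
    z = z - z.max(axis=-1, keepdims=True)
    e = np.exp(z)
    return e / e.sum(axis=-1, keepdims=True)


def predict(fused: np.ndarray, fc_w: np.ndarray, fc_b: np.ndarray) -> np.ndarray:
    """Class probability pairs (vigilant, drowsy) from fused features."""
    logits = np.asarray(fused, dtype=float) @ fc_w + fc_b
    return _softmax(logits)


def prepare_features(signals, config: TrainConfig):
    """Per-trial whole-trial covariances and 7x465 covariance sequences."""
    covs, seqs = [], []
    for x in signals:
        covs.append(spd.covariance(x, eps=config.eps_cov))
        seqs.append(
            tb.trial_to_sequence(x, win=config.win, step=config.step, fs=config.fs,
                                 eps=config.eps_cov)
        )
    return np.stack(covs), np.stack(seqs)


def _forward(model: FusionModel, covs, seqs_std, xd, with_cache=False):
    uses = dict(model.layout.blocks)
    caches = {}
    if "XL" in uses:
        out = tb.lstm_forward(seqs_std, model.lstm, return_cache=with_cache)
        xl, caches["XL"] = out if with_cache else (out, None)
    else:  # pragma: no cover - every variant uses XL
        xl = np.zeros((len(seqs_std), 0))
    if "XS" in uses:
        out = sn.spdnet_forward(covs, model.spdnet, return_cache=with_cache)
        xs, caches["XS"] = out if with_cache else (out, None)
    else:
        xs = None
    fused = fuse(xl, xs, xd, model.layout)
    probs = predict(fused, model.fc_w, model.fc_b)
    return fused, probs, caches


def _cross_entropy(probs: np.ndarray, y: np.ndarray) -> float:
    p = np.clip(probs[np.arange(len(y)), y], 1e-300, None)
    return float(-np.mean(np.log(p)))


def _standardizer(seqs: np.ndarray):
    flat = seqs.reshape(-1, seqs.shape[-1])
    mean = flat.mean(axis=0)
    std = flat.std(axis=0)
    std = np.where(std < 1e-12, 1.0, std)
    return mean, std


def train_alternating(
    covs: np.ndarray,
    seqs: np.ndarray,
    y: np.ndarray,
    config: TrainConfig,
    history: dict | None = None,
) -> FusionModel:
    """Fit the fused classifier with the alternating spatial-temporal schedule.

    Odd iterations step the LSTM, even iterations step the SPD network, and
    the fully connected layer steps every iteration.  Class centers and
    feature standardization statistics come from the training data passed in
    (callers are responsible for fold hygiene).  ``history``, if given, is
    filled with per-iteration losses and the branch iteration counters.
    """
    y = np.asarray(y, dtype=int)
    if len(np.unique(y)) < 2:
        raise ValueError("training data must contain both classes")
    rng = np.random.default_rng(config.seed)
    layout = layout_for(config)
    uses = dict(layout.blocks)

    centers = None
    xd = np.zeros((len(y), 2))
    if "XD" in uses:
        centers = spd.class_centers(
            covs, y, thre=config.center_thre, max_iter=config.center_max_iter
        )
        xd = np.stack([spd.distance_features(C, centers) for C in covs])

    mean = std = None
    seqs_std = seqs
    if config.standardize_lstm:
        mean, std = _standardizer(seqs)
        seqs_std = (seqs - mean) / std

    lstm = tb.init_lstm(
        input_size=seqs.shape[-1], hidden_size=config.hidden_size,
        n_layers=config.n_layers, rng=rng,
    )
    spdp = None
    if "XS" in uses:
        spdp = sn.init_spdnet(
            d0=covs.shape[-1], d1=config.d1, d2=config.d2,
            eps_rect=config.eps_rect, stiefel=config.stiefel, rng=rng,
        )
    k = 1.0 / np.sqrt(layout.total)
    fc_w = rng.uniform(-k, k, size=(layout.total, 2))
    fc_b = np.zeros(2)
    model = FusionModel(
        layout=layout, lstm=lstm, fc_w=fc_w, fc_b=fc_b, config=config,
        spdnet=spdp, centers=centers, lstm_mean=mean, lstm_std=std,
    )

    # held-out split of the training data for early stopping
    val_idx = np.array([], dtype=int)
    if config.early_stopping and config.val_frac > 0:
        parts = []
        for cls in (0, 1):
            idx = np.flatnonzero(y == cls)
            idx = rng.permutation(idx)
            n_val = int(np.floor(config.val_frac * len(idx)))
            parts.append(idx[:n_val])
        val_idx = np.concatenate(parts)
    train_idx = np.setdiff1d(np.arange(len(y)), val_idx)
    if len(np.unique(y[train_idx])) < 2:
        train_idx = np.arange(len(y))
        val_idx = np.array([], dtype=int)

    hist = history if history is not None else {}
    hist.update({"loss": [], "val_loss": [], "t_l": 0, "t_s": 0, "stopped_at": None})
    best = None
    best_val = np.inf
    bad = 0
    yt = y[train_idx]
    onehot = np.eye(2)[yt]
    for t in range(1, config.maxite + 1):
        fused, probs, caches = _forward(
            model, covs[train_idx], seqs_std[train_idx], xd[train_idx],
            with_cache=True,
        )
        loss = _cross_entropy(probs, yt)
        if not np.isfinite(loss):
            raise FloatingPointError(f"loss diverged at iteration {t}")
        hist["loss"].append(loss)
        dlogits = (probs - onehot) / len(yt)
        d_fused = dlogits @ model.fc_w.T
        split = model.layout.split(d_fused)
        if t % 2 == 1:
            grads = tb.lstm_backward(caches["XL"], split["XL"])
            tb.lstm_apply_grads(model.lstm, grads, config.lr_lstm)
            hist["t_l"] += 1
        elif "XS" in dict(model.layout.blocks):
            g = sn.spdnet_backward(caches["XS"], split["XS"])
            sn.spdnet_apply_grads(model.spdnet, g, config.lr_spd)
            hist["t_s"] += 1
        model.fc_w = model.fc_w - config.lr_fc * (fused.T @ dlogits)
        model.fc_b = model.fc_b - config.lr_fc * dlogits.sum(axis=0)

        if len(val_idx):
            _, vprobs, _ = _forward(model, covs[val_idx], seqs_std[val_idx], xd[val_idx])
            vloss = _cross_entropy(vprobs, y[val_idx])
            hist["val_loss"].append(vloss)
            if vloss < best_val - 1e-12:
                best_val = vloss
                best = model.copy_params()
                bad = 0
            else:
                bad += 1
                if bad >= config.patience:
                    hist["stopped_at"] = t
                    break
    if best is not None:
        model.restore_params(best)
    return model


def model_probabilities(model: FusionModel, covs, seqs) -> np.ndarray:
    """Class probabilities for new trials using the trained model's statistics."""
    uses = dict(model.layout.blocks)
    xd = np.zeros((len(covs), 2))
    if "XD" in uses:
        xd = np.stack([spd.distance_features(C, model.centers) for C in covs])
    seqs_std = seqs
    if model.lstm_mean is not None:
        seqs_std = (seqs - model.lstm_mean) / model.lstm_std
    _, probs, _ = _forward(model, covs, seqs_std, xd)
    return probs


def metrics_from_confusion(tp: int, fn: int, tn: int, fp: int) -> dict:
    """Percent accuracy/sensitivity/specificity/F1 with drowsy as positive class."""

    def _ratio(num, den):
        return 100.0 * num / den if den > 0 else np.nan

    total = tp + fn + tn + fp
    acc = _ratio(tp + tn, total)
    sens = _ratio(tp, tp + fn)
    spec = _ratio(tn, tn + fp)
    prec = _ratio(tp, tp + fp)
    if np.isnan(prec) or np.isnan(sens) or (prec + sens) == 0:
        f1 = np.nan
    else:
        f1 = 2.0 * prec * sens / (prec + sens)
    return {
        "accuracy": acc, "sensitivity": sens, "specificity": spec, "f1": f1,
        "tp": tp, "fn": fn, "tn": tn, "fp": fp,
    }


@dataclass
class Metrics:
    """Per-fold and aggregate leave-one-subject-out metrics."""

    per_fold: pd.DataFrame

    _COLS = ("accuracy", "sensitivity", "specificity", "f1")

    @property
    def mean(self) -> pd.Series:
        return self.per_fold[list(self._COLS)].mean()

    @property
    def variance(self) -> pd.Series:
        return self.per_fold[list(self._COLS)].var(ddof=1)

    def to_dict(self) -> dict:
        return {
            "mean": {k: float(v) for k, v in self.mean.items()},
            "variance": {k: float(v) for k, v in self.variance.items()},
            "n_folds": int(len(self.per_fold)),
        }

    def summary(self) -> str:
        lines = ["Leave-one-subject-out metrics (drowsy = positive class)"]
        lines.append(f"{'metric':<14}{'mean (%)':>10}{'variance':>12}")
        for k in self._COLS:
            lines.append(f"{k:<14}{self.mean[k]:>10.3f}{self.variance[k]:>12.3f}")
        return "\n".join(lines)


def _fold_seed(base: int, k: int) -> int:
    return int((base * 9973 + 7919 * (k + 1)) % (2**31 - 1))


def evaluate_loso(signals, y, subjects, config: TrainConfig,
                  features=None) -> Metrics:
    """Leave-one-subject-out evaluation: one fold per subject.

    ``features`` may carry precomputed ``(covs, seqs)`` to share across calls.
    """
    y = np.asarray(y, dtype=int)
    subjects = np.asarray(subjects)
    uniq = [s for s in pd.unique(subjects)]
    if len(uniq) < 2:
        raise ValueError("leave-one-subject-out needs at least 2 subjects")
    covs, seqs = features if features is not None else prepare_features(signals, config)
    rows = []
    for k, subj in enumerate(uniq):
        test = subjects == subj
        if not test.any():  # pragma: no cover - defensive
            warnings.warn(f"subject {subj} has no trials; skipping fold")
            continue
        train = ~test
        fold_cfg = replace(config, seed=_fold_seed(config.seed, k))
        model = train_alternating(covs[train], seqs[train], y[train], fold_cfg)
        probs = model_probabilities(model, covs[test], seqs[test])
        pred = probs.argmax(axis=1)
        yt = y[test]
        row = metrics_from_confusion(
            tp=int(np.sum((pred == 1) & (yt == 1))),
            fn=int(np.sum((pred == 0) & (yt == 1))),
            tn=int(np.sum((pred == 0) & (yt == 0))),
            fp=int(np.sum((pred == 1) & (yt == 0))),
        )
        row["subject"] = subj
        row["n_test"] = int(test.sum())
        rows.append(row)
    return Metrics(per_fold=pd.DataFrame(rows))


def ablation_variants(config: TrainConfig, names=None) -> dict:
    """Configurations of the requested ablation variants (all four by default)."""
    names = tuple(VARIANTS) if names is None else tuple(names)
    bad = [n for n in names if n not in VARIANTS]
    if bad:
        raise ValueError(f"unknown variant(s) {bad}; valid names: {sorted(VARIANTS)}")
    return {name: replace(config, variant=name) for name in names}
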