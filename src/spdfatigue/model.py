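"""Statsmodels-style front end: a model object fitted to trial data.

``FatigueFusionModel`` bundles the trials, labels and subject grouping with a
:class:`~spdfatigue.fusion.TrainConfig`; ``fit()`` runs the alternating
spatial-temporal optimizer and returns a :class:`FatigueFusionResults` that
carries the fitted parameter bundle, the loss trajectory, training diagnostics
and a ``summary()`` table, and can predict on new trials or run the
leave-one-subject-out evaluation.
"""

from __future__ import annotations

from dataclasses import replace

import numpy as np
import pandas as pd

from . import fusion
from .fusion import Metrics, TrainConfig
from .synthetic import TrialSet

__all__ = ["FatigueFusionModel", "FatigueFusionResults"]


class FatigueFusionModel:
    """Spatial-temporal fusion classifier over EEG covariance structure.

    Parameters
    ----------
    signals : (n_trials, channels, samples) array of preprocessed trials.
    labels : 0 = vigilant, 1 = drowsy.
    subjects : optional per-trial subject ids; required for LOSO evaluation.
    config : TrainConfig, or keyword overrides of its defaults.
    """

    def __init__(self, signals, labels, subjects=None, config: TrainConfig | None = None,
                 **config_overrides):
        self.signals = np.asarray(signals, dtype=float)
        self.labels = np.asarray(labels, dtype=int)
        if self.signals.ndim != 3 or len(self.signals) != len(self.labels):
            raise ValueError("signals must be (n_trials, channels, samples) matching labels")
        self.subjects = None if subjects is None else np.asarray(subjects)
        base = config if config is not None else TrainConfig()
        self.config = replace(base, **config_overrides) if config_overrides else base
        self._features = None

    @classmethod
    def from_trialset(cls, dataset: TrialSet, config: TrainConfig | None = None,
                      **config_overrides) -> "FatigueFusionModel":
        """Build from a generated dataset, keeping only RT-labeled trials."""
        X, y, subj = dataset.labeled_arrays()
        return cls(X, y, subjects=subj, config=config, **config_overrides)

    @property
    def features(self):
        """Cached (whole-trial covariances, covariance sequences)."""
        if self._features is None:
            self._features = fusion.prepare_features(self.signals, self.config)
        return self._features

    def fit(self) -> "FatigueFusionResults":
        """Train on all trials with the alternating optimizer."""
        covs, seqs = self.features
        history: dict = {}
        params = fusion.train_alternating(covs, seqs, self.labels, self.config,
                                          history=history)
        return FatigueFusionResults(self, params, history)

    def evaluate_loso(self, config: TrainConfig | None = None) -> Metrics:
        """Leave-one-subject-out cross-validation with per-fold metrics."""
        if self.subjects is None:
            raise ValueError("subject ids are required for LOSO evaluation")
        cfg = config if config is not None else self.config
        return fusion.evaluate_loso(self.signals, self.labels, self.subjects, cfg,
                                    features=self.features if cfg is self.config else None)


class FatigueFusionResults:
    """Fitted parameters, diagnostics and prediction interface."""

    def __init__(self, model: FatigueFusionModel, params: fusion.FusionModel,
                 history: dict):
        self.model = model
        self.params = params
        self.history = history

    @property
    def loss_history(self) -> np.ndarray:
        return np.asarray(self.history.get("loss", []))

    def predict_proba(self, signals=None) -> np.ndarray:
        """(vigilant, drowsy) probability pairs; training trials by default."""
        if signals is None:
            covs, seqs = self.model.features
        else:
            covs, seqs = fusion.prepare_features(np.asarray(signals, dtype=float),
                                                 self.model.config)
        return fusion.model_probabilities(self.params, covs, seqs)

    def predict(self, signals=None) -> np.ndarray:
        return self.predict_proba(signals).argmax(axis=1)

    @property
    def train_accuracy(self) -> float:
        return float(np.mean(self.predict() == self.model.labels))

    def summary(self) -> str:
        cfg = self.model.config
        lay = ", ".join(f"{n}[{l}]" for n, l in self.params.layout.blocks)
        lines = [
            "Spatial-temporal fusion of EEG covariance features",
            "=" * 52,
            f"variant:            {cfg.variant} ({lay})",
            f"trials / classes:   {len(self.model.labels)} "
            f"({int(np.sum(self.model.labels == 0))} vigilant, "
            f"{int(np.sum(self.model.labels == 1))} drowsy)",
            f"SPDNet layers:      {cfg.n_channels}->{cfg.d1}->{cfg.d2} "
            f"(eps_rect={cfg.eps_rect:g}, stiefel={cfg.stiefel})",
            f"LSTM:               {cfg.n_layers} layers, hidden={cfg.hidden_size}",
            f"iterations run:     {len(self.loss_history)} of {cfg.maxite} "
            f"(t_l={self.history.get('t_l')}, t_s={self.history.get('t_s')})",
        ]
        if len(self.loss_history):
            lines.append(f"final train loss:   {self.loss_history[-1]:.4f}")
        lines.append(f"train accuracy:     {100 * self.train_accuracy:.3f}%")
        if self.params.centers is not None:
            cv, cd = self.params.centers.vigilant, self.params.centers.drowsy
            lines.append(
                f"Stein centers:      vigilant {cv.iterations} it "
                f"(res {cv.residual:.2e}), drowsy {cd.iterations} it "
                f"(res {cd.residual:.2e})"
            )
        return "\n".join(lines)
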