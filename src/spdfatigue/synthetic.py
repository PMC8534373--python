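"""Synthetic EEG-like benchmark generator.

The generator emulates the statistical structure the detection method relies
on, with no claim of spectral realism: each driving state (vigilant / drowsy)
is defined by a smooth trajectory of seven segment-level covariance targets,
and a trial is a piecewise-stationary Gaussian signal whose 1 s block
covariances interpolate that trajectory.  Class trajectories share a base
covariance and a common temporal drift and differ by a class-specific
symmetric direction scaled by ``separation`` — at ``separation=0`` the two
classes are one generative process.  Per-trial variability is Wishart-style:
each trial's targets are a common-random-number Wishart draw around the class
targets with ``noise_df`` degrees of freedom (larger = less variability).

Reaction times are lognormal with class-conditional medians (0.45 s vigilant,
2.0 s drowsy by default), calibrated so the RT threshold rule reproduces the
generating class for the overwhelming majority of trials; draws landing in
the rule's dead zone are redrawn a bounded number of times.  Subjects carry
contiguous same-state runs of trials, and the global (smoothed) RT is
computed within each run.
"""

from __future__ import annotations

import warnings
from dataclasses import dataclass, field, replace

import numpy as np
import pandas as pd
from scipy.linalg import expm

from . import preprocessing as prep
from .preprocessing import DROWSY, EXCLUDED, VIGILANT

__all__ = [
    "GenConfig",
    "EEGTrial",
    "TrialSet",
    "make_class_trajectories",
    "generate_trial",
    "generate_dataset",
]


@dataclass(frozen=True)
class GenConfig:
    """Parameters of the synthetic benchmark.

    ``separation`` controls the inter-class distance of the covariance
    trajectories (0 = identical classes); ``noise_df`` is the Wishart degrees
    of freedom of per-trial covariance variability.
    """

    n_subjects: int = 6
    n_channels: int = 30
    fs: float = 250.0
    trial_len: float = 9.0
    trials_per_subject: tuple = (2, 179)
    separation: float = 1.0
    noise_df: float = 400.0
    seed: int = 0
    class_balance: float = 0.5
    drift_scale: float = 0.3
    rt_median_vigilant: float = 0.45
    rt_median_drowsy: float = 2.0
    rt_sigma_vigilant: float = 0.12
    rt_sigma_drowsy: float = 0.15
    max_rt_retries: int = 5

    @property
    def n_segments(self) -> int:
        return 7

    @property
    def samples_per_trial(self) -> int:
        return int(round(self.trial_len * self.fs))


@dataclass
class EEGTrial:
    """One trial: signal block, provenance and reaction-time information."""

    trial_id: int
    subject_id: int
    true_class: str  # generating state
    local_rt: float
    global_rt: float | None = None
    label: str | None = None  # assigned by the RT rule; may be 'excluded'
    signal: np.ndarray | None = None  # (channels, samples)


@dataclass
class TrialSet:
    """A generated dataset plus its generating configuration."""

    trials: list
    config: GenConfig
    trajectories: tuple  # (vigilant targets, drowsy targets)

    def __len__(self) -> int:
        return len(self.trials)

    def to_frame(self) -> pd.DataFrame:
        return pd.DataFrame(
            {
                "trial_id": [t.trial_id for t in self.trials],
                "subject_id": [t.subject_id for t in self.trials],
                "local_RT": [t.local_rt for t in self.trials],
                "global_RT": [t.global_rt for t in self.trials],
                "class": [t.true_class for t in self.trials],
                "label": [t.label for t in self.trials],
            }
        )

    def labeled(self) -> list:
        """Trials the RT rule labeled (drops the dead-zone exclusions)."""
        return [t for t in self.trials if t.label in (VIGILANT, DROWSY)]

    def labeled_arrays(self):
        """(signals, y, subjects) of labeled trials; y is 0=vigilant, 1=drowsy."""
        kept = self.labeled()
        if any(t.signal is None for t in kept):
            raise ValueError("dataset was generated without signals")
        X = np.stack([t.signal for t in kept])
        y = np.array([1 if t.label == DROWSY else 0 for t in kept])
        subj = np.array([t.subject_id for t in kept])
        return X, y, subj


def _random_symmetric(rng: np.random.Generator, n: int) -> np.ndarray:
    S = rng.standard_normal((n, n))
    S = 0.5 * (S + S.T)
    return S / np.linalg.norm(S)


def make_class_trajectories(cfg: GenConfig, rng: np.random.Generator | None = None):
    """Seven SPD covariance targets per class.

    Targets follow ``B^{1/2} expm(a_t T + separation * b_t * S_c) B^{1/2}``
    with shared base ``B`` and drift ``T`` and class directions ``S_c``; the
    construction is geodesic-style and SPD for every parameter value.
    """
    if cfg.separation < 0:
        raise ValueError("separation must be nonnegative")
    if cfg.separation == 0:
        warnings.warn(
            "separation is 0: both classes share one generative process",
            stacklevel=2,
        )
    rng = np.random.default_rng(cfg.seed if rng is None else rng)
    n = cfg.n_channels
    A = rng.standard_normal((n, 2 * n))
    base = np.eye(n) + (A @ A.T) / (2 * n)
    lam, U = np.linalg.eigh(base)
    sqrt_base = (U * np.sqrt(lam)) @ U.T
    drift = _random_symmetric(rng, n)
    s_v = _random_symmetric(rng, n)
    s_d = _random_symmetric(rng, n)
    traj_v, traj_d = [], []
    for t in range(cfg.n_segments):
        frac = t / (cfg.n_segments - 1)
        alpha = cfg.drift_scale * frac
        beta = 0.5 * (1.0 + frac)  # classes differ at every step, increasingly so
        for direction, out in ((s_v, traj_v), (s_d, traj_d)):
            M = expm(alpha * drift + cfg.separation * beta * direction)
            C = sqrt_base @ M @ sqrt_base
            out.append(0.5 * (C + C.T))
    return traj_v, traj_d


def _draw_rt(cfg: GenConfig, class_label: str, rng: np.random.Generator) -> float:
    if class_label == VIGILANT:
        med, sig = cfg.rt_median_vigilant, cfg.rt_sigma_vigilant
    else:
        med, sig = cfg.rt_median_drowsy, cfg.rt_sigma_drowsy
    return float(np.exp(np.log(med) + sig * rng.standard_normal()))


def generate_trial(
    class_label: str,
    trajectories,
    cfg: GenConfig,
    rng: np.random.Generator,
    trial_id: int = 0,
    subject_id: int = 0,
    with_signal: bool = True,
) -> EEGTrial:
    """Sample one trial of the requested class.

    The signal is built from nine 1 s zero-mean Gaussian blocks whose
    covariances linearly interpolate the trial's (Wishart-perturbed) segment
    targets, so sliding 3 s windows recover the class trajectory up to
    sampling noise.
    """
    if class_label not in (VIGILANT, DROWSY):
        raise ValueError(f"unknown class {class_label!r}")
    targets = trajectories[0] if class_label == VIGILANT else trajectories[1]
    rt = _draw_rt(cfg, class_label, rng)
    signal = None
    if with_signal:
        n = cfg.n_channels
        df = max(int(round(cfg.noise_df)), n + 1)
        Z = rng.standard_normal((n, df))
        ZZ = (Z @ Z.T) / df
        trial_targets = []
        for C in targets:
            L = np.linalg.cholesky(C)
            T = L @ ZZ @ L.T
            trial_targets.append(0.5 * (T + T.T))
        n_blocks = int(round(cfg.trial_len))
        samples_per_block = int(round(cfg.fs))
        blocks = []
        for b in range(n_blocks):
            # map block position onto the 7-target trajectory and interpolate
            pos = (cfg.n_segments - 1) * b / (n_blocks - 1)
            lo = int(np.floor(pos))
            hi = min(lo + 1, cfg.n_segments - 1)
            w = pos - lo
            Q = (1.0 - w) * trial_targets[lo] + w * trial_targets[hi]
            Lq = np.linalg.cholesky(Q)
            blocks.append(Lq @ rng.standard_normal((n, samples_per_block)))
        signal = np.concatenate(blocks, axis=1)
    return EEGTrial(
        trial_id=trial_id,
        subject_id=subject_id,
        true_class=class_label,
        local_rt=rt,
        signal=signal,
    )


def _relabel_run(run, cfg: GenConfig, rng: np.random.Generator) -> None:
    """Smooth RTs within a same-state run, label, and redraw dead-zone trials."""
    for _ in range(cfg.max_rt_retries):
        g = prep.global_rt([t.local_rt for t in run], n=2)
        done = True
        for t, gg in zip(run, g):
            t.global_rt = float(gg)
            t.label = prep.assign_label(t.local_rt, t.global_rt)
            if t.label == EXCLUDED:
                t.local_rt = _draw_rt(cfg, t.true_class, rng)
                done = False
        if done:
            return
    # final pass with whatever the last redraw produced
    g = prep.global_rt([t.local_rt for t in run], n=2)
    for t, gg in zip(run, g):
        t.global_rt = float(gg)
        t.label = prep.assign_label(t.local_rt, t.global_rt)


def generate_dataset(cfg: GenConfig, with_signals: bool = True) -> TrialSet:
    """Generate a full multi-subject dataset, deterministic under ``cfg.seed``.

    Each subject receives a trial count drawn uniformly from
    ``trials_per_subject`` and two contiguous same-state runs whose sizes
    split the count according to ``class_balance``.
    """
    if cfg.n_subjects < 2:
        raise ValueError("need at least 2 subjects (leave-one-subject-out undefined)")
    lo, hi = cfg.trials_per_subject
    if not (1 <= lo <= hi):
        raise ValueError(f"invalid trials_per_subject range {cfg.trials_per_subject}")
    rng = np.random.default_rng(cfg.seed)
    trajectories = make_class_trajectories(cfg, rng=rng)
    trials: list = []
    trial_id = 0
    for subject in range(cfg.n_subjects):
        n_trials = int(rng.integers(lo, hi + 1))
        n_vig = int(np.round(n_trials * (1.0 - cfg.class_balance)))
        n_vig = min(max(n_vig, 0), n_trials)
        runs = [(VIGILANT, n_vig), (DROWSY, n_trials - n_vig)]
        if rng.random() < 0.5:
            runs.reverse()
        for class_label, count in runs:
            run = []
            for _ in range(count):
                t = generate_trial(
                    class_label,
                    trajectories,
                    cfg,
                    rng,
                    trial_id=trial_id,
                    subject_id=subject,
                    with_signal=with_signals,
                )
                trial_id += 1
                run.append(t)
            if run:
                _relabel_run(run, cfg, rng)
                trials.extend(run)
    return TrialSet(trials=trials, config=cfg, trajectories=trajectories)
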