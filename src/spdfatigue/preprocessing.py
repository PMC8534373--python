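"""Signal conditioning, trial extraction and reaction-time labeling.

Recordings are zero-phase bandpass filtered (1-50 Hz by default), decimated
to 250 Hz, and cut into 9 s trials anchored 1 s before each lane-correction
response offset.  Labels derive from the reaction time (RT) of the
lane-departure event: the *local* RT of trial ``l`` is smoothed into a
*global* RT by a centered moving average over the ``2n+1`` surrounding trials
(``n=2`` by default); a trial is *vigilant* when both RTs are at most 0.62 s,
*drowsy* when both are at least 1.5 s, and *excluded* otherwise.
"""

from __future__ import annotations

import warnings
from dataclasses import dataclass

import numpy as np
from scipy import signal as sps

__all__ = [
    "PreprocessConfig",
    "RTRecord",
    "bandpass_downsample",
    "extract_trial",
    "global_rt",
    "assign_label",
    "label_rt_series",
    "VIGILANT",
    "DROWSY",
    "EXCLUDED",
    "THETA_VIGILANT",
    "THETA_DROWSY",
]

VIGILANT = "vigilant"
DROWSY = "drowsy"
EXCLUDED = "excluded"

#: RT thresholds (seconds) of the vigilant / drowsy decision rule
THETA_VIGILANT = 0.62
THETA_DROWSY = 1.5


@dataclass(frozen=True)
class PreprocessConfig:
    """Filtering / windowing parameters of the conditioning stage."""

    fs_in: float = 500.0
    fs_out: float = 250.0
    band: tuple = (1.0, 50.0)
    trial_window: tuple = (-1.0, 8.0)  # seconds relative to the response offset
    filter_order: int = 10

    def __post_init__(self):
        lo, hi = self.band
        if not (0.0 < lo < hi < self.fs_out / 2.0):
            raise ValueError(
                f"band {self.band} must lie strictly inside (0, {self.fs_out / 2}) Hz"
            )
        if self.fs_in % self.fs_out != 0:
            raise ValueError("fs_in must be an integer multiple of fs_out")


@dataclass(frozen=True)
class RTRecord:
    """Reaction times and label of one trial."""

    trial_index: int
    local_rt: float
    global_rt: float
    label: str

    def __post_init__(self):
        if self.local_rt <= 0:
            raise ValueError("local_rt must be positive")


def bandpass_downsample(raw: np.ndarray, cfg: PreprocessConfig) -> np.ndarray:
    """Zero-phase bandpass filter then anti-aliased decimation.

    ``raw`` is ``(channels, samples)`` at ``cfg.fs_in``; the output keeps the
    same channels at ``cfg.fs_out`` with length scaled by ``fs_out/fs_in``.
    """
    raw = np.asarray(raw, dtype=float)
    if raw.ndim != 2:
        raise ValueError(f"expected (channels, samples), got shape {raw.shape}")
    if not np.all(np.isfinite(raw)):
        raise ValueError("raw signal contains non-finite values")
    sos = sps.butter(cfg.filter_order, cfg.band, btype="bandpass", fs=cfg.fs_in,
                     output="sos")
    # forward-backward per biquad section with Gustafsson initial conditions:
    # zero phase with minimal edge transients even on short blocks
    filtered = raw
    for sec in sos:
        filtered = sps.filtfilt(sec[:3], sec[3:], filtered, axis=1, method="gust")
    q = int(cfg.fs_in // cfg.fs_out)
    if q == 1:
        return filtered
    return sps.decimate(filtered, q, ftype="fir", axis=1, zero_phase=True)


def extract_trial(
    signal: np.ndarray,
    response_offset_time: float,
    cfg: PreprocessConfig,
    fs: float | None = None,
    trial_name: str = "trial",
) -> np.ndarray:
    """Cut the 9 s trial window around one response offset.

    The window spans ``trial_window`` seconds relative to the offset
    (default -1 s to +8 s) as a half-open sample interval at sampling rate
    ``fs`` (``cfg.fs_out`` unless given).  Raises if the window leaves the
    recording.
    """
    signal = np.asarray(signal)
    fs = cfg.fs_out if fs is None else fs
    pre, post = cfg.trial_window
    start = int(round((response_offset_time + pre) * fs))
    stop = int(round((response_offset_time + post) * fs))
    if start < 0 or stop > signal.shape[1]:
        raise ValueError(
            f"{trial_name}: window samples [{start}, {stop}) outside recording "
            f"of {signal.shape[1]} samples"
        )
    return signal[:, start:stop]


def global_rt(local_rts, n: int = 2) -> np.ndarray:
    """Centered moving average of local reaction times.

    For trial ``l`` the window covers indices ``l-n .. l+n``; at the series
    boundaries the window is truncated to the available trials and divided by
    the actual count.
    """
    if n < 0:
        raise ValueError("n must be nonnegative")
    rts = np.asarray(local_rts, dtype=float)
    if rts.ndim != 1 or rts.size == 0:
        raise ValueError("local_rts must be a nonempty 1-D sequence")
    out = np.empty_like(rts)
    for l in range(rts.size):
        lo = max(0, l - n)
        hi = min(rts.size, l + n + 1)
        out[l] = rts[lo:hi].mean()
    return out


def assign_label(
    rt_local: float,
    rt_global: float,
    theta_v: float = THETA_VIGILANT,
    theta_d: float = THETA_DROWSY,
) -> str:
    """Threshold rule on the (local, global) RT pair.

    Vigilant iff both RTs are at most ``theta_v``; drowsy iff both are at
    least ``theta_d``; excluded otherwise.
    """
    if rt_local <= 0 or rt_global <= 0:
        raise ValueError("reaction times must be positive")
    if rt_local <= theta_v and rt_global <= theta_v:
        return VIGILANT
    if rt_local >= theta_d and rt_global >= theta_d:
        return DROWSY
    return EXCLUDED


def label_rt_series(local_rts, n: int = 2) -> list:
    """Label a whole RT series: smooth, threshold, and wrap into records."""
    g = global_rt(local_rts, n=n)
    return [
        RTRecord(trial_index=l, local_rt=float(rt), global_rt=float(gg),
                 label=assign_label(float(rt), float(gg)))
        for l, (rt, gg) in enumerate(zip(np.asarray(local_rts, dtype=float), g))
    ]
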