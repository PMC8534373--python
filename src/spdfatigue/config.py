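"""Run configuration: one serializable bundle of every stage's parameters.

A run config groups the generator, preprocessing, training and analysis
settings, can be loaded from a YAML file overriding the built-in defaults
(unknown keys are rejected), and hashes canonically so every output directory
can record exactly what produced it.
"""

from __future__ import annotations

import dataclasses
import hashlib
import json
from dataclasses import dataclass, field
from pathlib import Path

import yaml

from .fusion import TrainConfig
from .preprocessing import PreprocessConfig
from .synthetic import GenConfig

__all__ = ["RunConfig", "load_run_config", "config_hash", "write_provenance"]


@dataclass(frozen=True)
class AnalysisConfig:
    """Settings of the zeta and source analyses."""

    zeta_k: int = 3
    zeta_n_samples: int = 500
    zeta_omega: float = 0.9
    n_sources: int = 364
    kl_grid: int = 512


@dataclass(frozen=True)
class RunConfig:
    generate: GenConfig = field(default_factory=GenConfig)
    preprocess: PreprocessConfig = field(default_factory=PreprocessConfig)
    train: TrainConfig = field(default_factory=TrainConfig)
    analysis: AnalysisConfig = field(default_factory=AnalysisConfig)

    def to_dict(self) -> dict:
        d = dataclasses.asdict(self)
        d["generate"]["trials_per_subject"] = list(d["generate"]["trials_per_subject"])
        d["preprocess"]["band"] = list(d["preprocess"]["band"])
        d["preprocess"]["trial_window"] = list(d["preprocess"]["trial_window"])
        return d


_SECTIONS = {
    "generate": GenConfig,
    "preprocess": PreprocessConfig,
    "train": TrainConfig,
    "analysis": AnalysisConfig,
}

_TUPLE_FIELDS = {"trials_per_subject", "band", "trial_window"}


def load_run_config(path=None, overrides: dict | None = None) -> RunConfig:
    """Build a run config from defaults, a YAML file, and explicit overrides.

    Unknown sections or keys raise ``ValueError`` naming the offender.
    """
    data: dict = {}
    if path is not None:
        loaded = yaml.safe_load(Path(path).read_text()) or {}
        if not isinstance(loaded, dict):
            raise ValueError("run config file must hold a mapping")
        data.update(loaded)
    for section, keys in (overrides or {}).items():
        data.setdefault(section, {}).update(keys)
    kwargs = {}
    for section, payload in data.items():
        if section not in _SECTIONS:
            raise ValueError(
                f"unknown config section {section!r}; valid: {sorted(_SECTIONS)}"
            )
        cls = _SECTIONS[section]
        valid = {f.name for f in dataclasses.fields(cls)}
        bad = set(payload) - valid
        if bad:
            raise ValueError(f"unknown keys in [{section}]: {sorted(bad)}")
        payload = {
            k: tuple(v) if k in _TUPLE_FIELDS and isinstance(v, list) else v
            for k, v in payload.items()
        }
        kwargs[section] = cls(**payload)
    return RunConfig(**kwargs)


def config_hash(cfg: RunConfig) -> str:
    blob = json.dumps(cfg.to_dict(), sort_keys=True).encode()
    return hashlib.sha256(blob).hexdigest()[:16]


def write_provenance(out_dir, cfg: RunConfig) -> None:
    """Record the run config and its hash next to a stage's outputs."""
    out = Path(out_dir)
    out.mkdir(parents=True, exist_ok=True)
    payload = {"config": cfg.to_dict(), "config_hash": config_hash(cfg)}
    (out / "run_config.json").write_text(json.dumps(payload, indent=1))
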