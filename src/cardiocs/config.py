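"""Experiment configuration: a validated JSON-backed parameter tree.

Every stage of the pipeline has its own section with explicit defaults;
unknown keys are rejected so typos fail loudly.  One global seed drives all
randomness: each stage derives its own stream by stable hashing of the stage
name, so adding a stage never perturbs another stage's draws.
"""

from __future__ import annotations

import dataclasses
import json
import zlib
from dataclasses import dataclass, field
from pathlib import Path

from .errors import ConfigurationError


def stage_seed(global_seed: int, stage: str) -> int:
    """Deterministic per-stage substream seed (stable across runs and platforms)."""
    return (zlib.crc32(stage.encode("utf-8")) ^ (global_seed * 2654435761)) % 2**31


def _build(cls, data: dict, section: str):
    known = {f.name for f in dataclasses.fields(cls)}
    unknown = set(data) - known
    if unknown:
        raise ConfigurationError(f"unknown key(s) in '{section}': {sorted(unknown)}")
    kwargs = {}
    for f in dataclasses.fields(cls):
        if f.name in data:
            v = data[f.name]
            kwargs[f.name] = tuple(v) if isinstance(v, list) else v
    return cls(**kwargs)


@dataclass(frozen=True)
class SynthSection:
    kind: str = "ecg"
    n_subjects: int = 6
    windows_per_subject: int = 4
    jitter: float = 0.05
    heart_rate: float = 75.0
    fs: float = 500.0
    white_sd: float = 0.0
    baseline_amp: float = 0.0
    powerline_amp: float = 0.0


@dataclass(frozen=True)
class SensingSection:
    compression_ratio: float = 0.7
    window: int = 1024


@dataclass(frozen=True)
class RecoverySection:
    algorithm: str = "swamp"
    alpha: float = 0.83
    l0: int = 5
    delta_k: float = 0.3
    smax_fraction: float = 0.5
    eps1: float = 1e-3
    eps_relative: bool = True


@dataclass(frozen=True)
class DenoiseSection:
    enabled: bool = False
    wavelet_name: str = "coif3"
    levels: int = 8
    threshold_mode: str = "soft"
    remove_baseline: bool = False


@dataclass(frozen=True)
class FeaturesSection:
    aggregate: str = "mean"


@dataclass(frozen=True)
class IdentificationSection:
    c_grid: tuple = (10.0,)
    gamma_grid: tuple = (1.0,)
    cv_folds: int = 10
    normalization: str = "minmax"
    train_fraction: float = 0.5


_SECTIONS = {
    "synth": SynthSection,
    "sensing": SensingSection,
    "recovery": RecoverySection,
    "denoise": DenoiseSection,
    "features": FeaturesSection,
    "identification": IdentificationSection,
}


@dataclass(frozen=True)
class ExperimentConfig:
    seed: int = 0
    output_dir: str = "results"
    synth: SynthSection = field(default_factory=SynthSection)
    sensing: SensingSection = field(default_factory=SensingSection)
    recovery: RecoverySection = field(default_factory=RecoverySection)
    denoise: DenoiseSection = field(default_factory=DenoiseSection)
    features: FeaturesSection = field(default_factory=FeaturesSection)
    identification: IdentificationSection = field(default_factory=IdentificationSection)

    @classmethod
    def from_dict(cls, data: dict) -> "ExperimentConfig":
        top_known = {"seed", "output_dir", *_SECTIONS}
        unknown = set(data) - top_known
        if unknown:
            raise ConfigurationError(f"unknown top-level key(s): {sorted(unknown)}")
        kwargs = {}
        if "seed" in data:
            kwargs["seed"] = int(data["seed"])
        if "output_dir" in data:
            kwargs["output_dir"] = str(data["output_dir"])
        for name, section_cls in _SECTIONS.items():
            if name in data:
                kwargs[name] = _build(section_cls, data[name], name)
        return cls(**kwargs)

    @classmethod
    def from_json(cls, path) -> "ExperimentConfig":
        return cls.from_dict(json.loads(Path(path).read_text()))

    def to_dict(self) -> dict:
        return dataclasses.asdict(self)

    def write_json(self, path) -> None:
        Path(path).write_text(json.dumps(self.to_dict(), indent=1, default=list) + "\n")
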