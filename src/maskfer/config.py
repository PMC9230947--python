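"""Pipeline configuration: one validated object covering every stage.

Loadable from YAML with flat dotted sections matching the module names;
unknown keys are rejected so typos fail fast.  `config_hash` gives a
stable digest of the fully resolved configuration for logging and
report embedding.
"""

from __future__ import annotations

import hashlib
import json
from dataclasses import asdict, dataclass, field, replace
from pathlib import Path

import yaml

from maskfer.boundary import PeakThresholds
from maskfer.infinity import InfinityConfig
from maskfer.synthfaces import CLASSES


@dataclass(frozen=True)
class PreprocessConfig:
    apply_mask: bool = False
    mask_fraction: float = 0.5
    upper_fraction: float = 0.42


@dataclass(frozen=True)
class SeedConfig:
    window: int = 31
    polyorder: int = 3
    smooth_vertical: bool = False


@dataclass(frozen=True)
class BoundaryConfig:
    min_prominence: float = 25.5
    min_width: float = 3.0
    invert: bool = False

    def thresholds(self) -> PeakThresholds:
        return PeakThresholds(self.min_prominence, self.min_width)


@dataclass(frozen=True)
class InfinityShapeConfig:
    alpha: int = 2
    beta: float = 2.0
    c: float = 20.0
    n: int = 50
    sampling: str = "inclusive"
    height_ratio: float = 1.0

    def curve(self) -> InfinityConfig:
        return InfinityConfig(self.alpha, self.beta, self.c, self.n, self.sampling)


@dataclass(frozen=True)
class ClassifyConfig:
    class_names: tuple[str, ...] = CLASSES
    max_landmarks: int = 64
    hidden_size: int = 64
    conv_channels: tuple[int, int] = (32, 64)
    epochs: int = 30
    batch_size: int = 32
    learning_rate: float = 1e-3


@dataclass(frozen=True)
class FixtureConfig:
    n_per_class: int = 8
    profile: str = "ck"  # "ck" (236x96) or "rafdb" (100x46)


@dataclass(frozen=True)
class PipelineConfig:
    rng_seed: int = 0
    log_level: str = "INFO"
    preprocess: PreprocessConfig = field(default_factory=PreprocessConfig)
    seed: SeedConfig = field(default_factory=SeedConfig)
    infinity: InfinityShapeConfig = field(default_factory=InfinityShapeConfig)
    boundary: BoundaryConfig = field(default_factory=BoundaryConfig)
    classify: ClassifyConfig = field(default_factory=ClassifyConfig)
    fixtures: FixtureConfig = field(default_factory=FixtureConfig)

    def to_dict(self) -> dict:
        return asdict(self)

    def config_hash(self) -> str:
        payload = json.dumps(self.to_dict(), sort_keys=True, default=str)
        return hashlib.sha256(payload.encode()).hexdigest()[:12]


_SECTIONS = {
    "preprocess": PreprocessConfig,
    "seed": SeedConfig,
    "infinity": InfinityShapeConfig,
    "boundary": BoundaryConfig,
    "classify": ClassifyConfig,
    "fixtures": FixtureConfig,
}


def load_config(path=None, overrides: dict | None = None) -> PipelineConfig:
    """Build a PipelineConfig from a YAML file plus optional overrides.

    YAML layout mirrors the dataclass sections::

        rng_seed: 7
        boundary:
          min_prominence: 20
    """
    data: dict = {}
    if path is not None:
        data = yaml.safe_load(Path(path).read_text()) or {}
    if overrides:
        for key, val in overrides.items():
            section, _, leaf = key.partition(".")
            if leaf:
                data.setdefault(section, {})[leaf] = val
            else:
                data[section] = val
    kwargs: dict = {}
    for key, val in data.items():
        if key in _SECTIONS:
            cls = _SECTIONS[key]
            valid = cls.__dataclass_fields__
            unknown = set(val) - set(valid)
            if unknown:
                raise ValueError(f"unknown keys in section {key!r}: {sorted(unknown)}")
            coerced = {
                k: tuple(v) if isinstance(v, list) else v for k, v in val.items()
            }
            kwargs[key] = cls(**coerced)
        elif key in ("rng_seed", "log_level"):
            kwargs[key] = val
        else:
            raise ValueError(f"unknown config section {key!r}")
    return PipelineConfig(**kwargs)
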