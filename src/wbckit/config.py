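"""Pipeline configuration: one YAML file covering every stage.

The configuration is a nest of the per-module dataclasses.  Loading is
strict — unknown keys are rejected rather than ignored, so typos in a
config file fail loudly — and the canonical serialized form is hashed
into every run report for provenance.
"""

from __future__ import annotations

import dataclasses
import hashlib
from dataclasses import dataclass, field, fields

import yaml

from .classifier import Hyperparams
from .cnn import CNNConfig
from .segmentation import SegmentationConfig
from .sift import SIFTConfig

__all__ = ["PipelineConfig", "load_config", "save_config"]


@dataclass
class PipelineConfig:
    """Complete pipeline configuration."""

    segmentation: SegmentationConfig = field(default_factory=SegmentationConfig)
    sift: SIFTConfig = field(default_factory=SIFTConfig)
    cnn: CNNConfig = field(default_factory=CNNConfig)
    classifier: Hyperparams = field(default_factory=Hyperparams)
    rde_variant: str = "rms"
    crop_size: int = 64
    folds: int = 5
    seed: int = 0
    train_crops_per_class: int = 20

    def to_dict(self) -> dict:
        return dataclasses.asdict(self)

    def config_hash(self) -> str:
        """SHA-256 of the canonical YAML serialization."""
        canon = yaml.safe_dump(_plain(self.to_dict()), sort_keys=True)
        return hashlib.sha256(canon.encode()).hexdigest()


def _plain(obj):
    """YAML-safe structure: tuples to lists, numpy scalars to python."""
    if isinstance(obj, dict):
        return {k: _plain(v) for k, v in obj.items()}
    if isinstance(obj, (list, tuple)):
        return [_plain(v) for v in obj]
    if hasattr(obj, "item"):
        return obj.item()
    return obj


def _build(cls, data: dict, path: str):
    known = {f.name: f for f in fields(cls)}
    unknown = set(data) - set(known)
    if unknown:
        raise ValueError(f"unknown config key(s) under {path}: {sorted(unknown)}")
    kwargs = {}
    for name, value in data.items():
        ftype = known[name].type
        sub = _SUBCONFIGS.get(name)
        if sub is not None and isinstance(value, dict):
            kwargs[name] = _build(sub, value, f"{path}.{name}")
        elif isinstance(value, list):
            kwargs[name] = tuple(value)
        else:
            kwargs[name] = value
    return cls(**kwargs)


_SUBCONFIGS = {
    "segmentation": SegmentationConfig,
    "sift": SIFTConfig,
    "cnn": CNNConfig,
    "classifier": Hyperparams,
}


def load_config(path) -> PipelineConfig:
    """Load and validate a YAML configuration file."""
    with open(path) as fh:
        data = yaml.safe_load(fh) or {}
    if not isinstance(data, dict):
        raise ValueError("config file must contain a mapping")
    return _build(PipelineConfig, data, "config")


def save_config(cfg: PipelineConfig, path) -> None:
    with open(path, "w") as fh:
        yaml.safe_dump(_plain(cfg.to_dict()), fh, sort_keys=True)
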