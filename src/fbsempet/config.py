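"""Experiment configuration: nested sections, YAML round-trip, strict keys.

Defaults follow the simulation protocol: 2.08 mm pixels, 2.5 mm FWHM PSF,
10 iterations x 6 subsets, 500k / 100M count levels, Adam with lr 0.01 for
50 epochs at mini-batch 5.  Unknown keys are rejected so typos fail loudly.
"""

from __future__ import annotations

import dataclasses
import hashlib
import json
from dataclasses import dataclass, field

import yaml


@dataclass
class GeometryConfig:
    nx: int = 96
    ny: int = 96
    pixel_size_mm: float = 2.08
    n_angles: int = 120
    n_radial_bins: int = 128
    n_subsets: int = 6
    psf_fwhm_mm: float = 2.5
    normalisation: bool = True


@dataclass
class PhantomConfig:
    distribution: str = "train"
    lesion_contrast: float = 1.3
    n_lesions_min: int = 1
    n_lesions_max: int = 3


@dataclass
class CountsConfig:
    low: float = 5e5
    high: float = 1e8


@dataclass
class ReconConfig:
    method: str = "osem"          # mlem | osem | mapem | fbsem | inn
    n_iters: int = 10
    beta: float = 0.01
    gamma: float = 0.1


@dataclass
class NetworkConfig:
    iteration_dependent_nets: bool = True
    n_channels: int = 32
    gamma_init: float = 0.5
    internal_skip: bool = False
    global_sens_mode: bool = False


@dataclass
class TrainingSection:
    lr: float = 0.01
    epochs: int = 50
    batch_size: int = 5
    regime: str = "sequential_IS"


@dataclass
class EvaluationConfig:
    n_realisations: int = 20
    module_counts: tuple = (10, 20, 40, 60)


@dataclass
class SeedsConfig:
    master: int = 0
    normalisation: int = 1234
    data: int = 1
    network: int = 2
    training: int = 3


@dataclass
class DatasetConfig:
    n_train: int = 16
    n_val: int = 4
    n_test: int = 4


@dataclass
class ExperimentConfig:
    geometry: GeometryConfig = field(default_factory=GeometryConfig)
    phantom: PhantomConfig = field(default_factory=PhantomConfig)
    counts: CountsConfig = field(default_factory=CountsConfig)
    dataset: DatasetConfig = field(default_factory=DatasetConfig)
    recon: ReconConfig = field(default_factory=ReconConfig)
    network: NetworkConfig = field(default_factory=NetworkConfig)
    training: TrainingSection = field(default_factory=TrainingSection)
    evaluation: EvaluationConfig = field(default_factory=EvaluationConfig)
    seeds: SeedsConfig = field(default_factory=SeedsConfig)
    output_dir: str = "runs"

    # -- dict / yaml round-trip ---------------------------------------------
    def to_dict(self) -> dict:
        def conv(v):
            if dataclasses.is_dataclass(v):
                return {f.name: conv(getattr(v, f.name)) for f in dataclasses.fields(v)}
            if isinstance(v, tuple):
                return list(v)
            return v
        return conv(self)

    @classmethod
    def from_dict(cls, d: dict) -> "ExperimentConfig":
        cfg = cls()
        _apply(cfg, d, path="")
        return cfg

    @classmethod
    def from_yaml(cls, path: str) -> "ExperimentConfig":
        with open(path) as f:
            d = yaml.safe_load(f) or {}
        return cls.from_dict(d)

    def to_yaml(self, path: str):
        with open(path, "w") as f:
            yaml.safe_dump(self.to_dict(), f, sort_keys=False)

    def apply_overrides(self, overrides: list[str]):
        """Dotted-key overrides, e.g. 'geometry.nx=32'."""
        for ov in overrides:
            if "=" not in ov:
                raise ValueError(f"override {ov!r} is not key=value")
            key, val = ov.split("=", 1)
            parts = key.split(".")
            obj = self
            for p in parts[:-1]:
                if not hasattr(obj, p):
                    raise ValueError(f"unknown config section {p!r} in {key!r}")
                obj = getattr(obj, p)
            leaf = parts[-1]
            if not hasattr(obj, leaf):
                raise ValueError(f"unknown config key {key!r}")
            cur = getattr(obj, leaf)
            setattr(obj, leaf, _coerce(val, cur))

    def hash(self) -> str:
        blob = json.dumps(self.to_dict(), sort_keys=True).encode()
        return hashlib.sha256(blob).hexdigest()[:16]


def _apply(obj, d: dict, path: str):
    if not isinstance(d, dict):
        raise ValueError(f"config section {path or '<root>'} must be a mapping")
    fields = {f.name: f for f in dataclasses.fields(obj)}
    for k, v in d.items():
        if k not in fields:
            raise ValueError(f"unknown config key {path + k!r}")
        cur = getattr(obj, k)
        if dataclasses.is_dataclass(cur):
            _apply(cur, v, path + k + ".")
        else:
            setattr(obj, k, _coerce_value(v, cur, path + k))
    return obj


def _coerce_value(v, cur, key):
    if isinstance(cur, tuple):
        return tuple(v)
    if isinstance(cur, bool):
        if not isinstance(v, bool):
            raise ValueError(f"config key {key!r} expects a boolean")
        return v
    if isinstance(cur, int) and not isinstance(v, bool):
        return int(v)
    if isinstance(cur, float):
        return float(v)
    return v


def _coerce(val: str, cur):
    if isinstance(cur, bool):
        return val.lower() in ("1", "true", "yes", "on")
    if isinstance(cur, tuple):
        return tuple(int(x) for x in val.strip("[]()").split(","))
    if isinstance(cur, int):
        return int(val)
    if isinstance(cur, float):
        return float(val)
    return val
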