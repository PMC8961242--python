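"""Run configuration: one structured YAML file covering every stage."""

from __future__ import annotations

import dataclasses
import hashlib
import json
from pathlib import Path

import yaml

from .gan import NetworkConfig
from .sampler import AugmentParams

__all__ = ["PhantomConfig", "EvalConfig", "RunConfig", "config_hash"]


@dataclasses.dataclass
class PhantomConfig:
    """Synthetic cohort parameters."""

    shape: tuple[int, int, int] = (48, 48, 48)
    spacing: tuple[float, float, float] = (1.0, 1.0, 1.0)
    n_lesions: int = 8
    lesion_radius_range: tuple[float, float] = (1.0, 2.2)
    noise_sd: float = 0.02
    n_train: int = 8
    n_val: int = 2
    n_test: int = 4


@dataclasses.dataclass
class EvalConfig:
    tol_mm: float = 5.0
    z_thresh: float = 3.0
    min_area_mm2: float = 3.0
    stride: int | None = None


@dataclasses.dataclass
class RunConfig:
    seed: int = 0
    out_dir: str = "adir_run"
    phantom: PhantomConfig = dataclasses.field(default_factory=PhantomConfig)
    network: NetworkConfig = dataclasses.field(default_factory=NetworkConfig)
    augment: AugmentParams = dataclasses.field(default_factory=AugmentParams)
    eval: EvalConfig = dataclasses.field(default_factory=EvalConfig)

    def to_dict(self) -> dict:
        return dataclasses.asdict(self)

    def to_yaml(self, path) -> None:
        Path(str(path)).write_text(yaml.safe_dump(_plain(self.to_dict()), sort_keys=True))

    @classmethod
    def from_dict(cls, d: dict) -> "RunConfig":
        def build(klass, sub):
            fields = {f.name: f for f in dataclasses.fields(klass)}
            kwargs = {}
            for k, v in (sub or {}).items():
                if k not in fields:
                    raise ValueError(f"unknown config key {k!r} for {klass.__name__}")
                if isinstance(v, list):
                    v = tuple(v)
                kwargs[k] = v
            return klass(**kwargs)

        return cls(
            seed=int(d.get("seed", 0)),
            out_dir=str(d.get("out_dir", "adir_run")),
            phantom=build(PhantomConfig, d.get("phantom")),
            network=build(NetworkConfig, d.get("network")),
            augment=build(AugmentParams, d.get("augment")),
            eval=build(EvalConfig, d.get("eval")),
        )

    @classmethod
    def from_yaml(cls, path) -> "RunConfig":
        return cls.from_dict(yaml.safe_load(Path(str(path)).read_text()) or {})


def _plain(obj):
    if isinstance(obj, dict):
        return {k: _plain(v) for k, v in obj.items()}
    if isinstance(obj, (list, tuple)):
        return [_plain(v) for v in obj]
    return obj


def config_hash(config: RunConfig) -> str:
    """Stable hash of the full configuration (changes iff any field does)."""
    payload = json.dumps(_plain(config.to_dict()), sort_keys=True)
    return hashlib.sha256(payload.encode()).hexdigest()[:16]
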