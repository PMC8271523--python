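"""YAML run configuration: one file sets every seed and parameter.

The file has optional ``plant``, ``sensor``, ``sift``, ``train`` and
``benchmark`` sections whose keys mirror the corresponding dataclass
fields; omitted keys keep the package defaults.
"""

from __future__ import annotations

from dataclasses import asdict, dataclass, field, fields

import yaml

from .emd import SiftConfig
from .inverse_model import FAST_TRAIN, TrainConfig
from .plant_sim import PlantConfig
from .sensor_sim import SensorConfig


@dataclass
class BenchmarkSection:
    seed: int = 0
    n_train: int = 10
    n_test: int = 8
    drive_scale: float = 40.0


@dataclass
class RunConfig:
    plant: PlantConfig = field(default_factory=PlantConfig)
    sensor: SensorConfig | None = None   # None: derive the default noise level
    sift: SiftConfig = field(default_factory=SiftConfig)
    train: TrainConfig = field(default_factory=lambda: TrainConfig(**asdict(FAST_TRAIN)))
    benchmark: BenchmarkSection = field(default_factory=BenchmarkSection)


_SECTIONS = {
    "plant": PlantConfig,
    "sensor": SensorConfig,
    "sift": SiftConfig,
    "train": TrainConfig,
    "benchmark": BenchmarkSection,
}


def _build(cls, data: dict):
    valid = {f.name for f in fields(cls)}
    unknown = set(data) - valid
    if unknown:
        raise ValueError(f"unknown keys for {cls.__name__}: {sorted(unknown)}")
    return cls(**data)


def load_config(path) -> RunConfig:
    with open(path) as fh:
        raw = yaml.safe_load(fh) or {}
    unknown = set(raw) - set(_SECTIONS)
    if unknown:
        raise ValueError(f"unknown config sections: {sorted(unknown)}")
    kwargs = {}
    for name, cls in _SECTIONS.items():
        if name in raw:
            kwargs[name] = _build(cls, raw[name] or {})
    return RunConfig(**kwargs)


def dump_config(cfg: RunConfig, path) -> None:
    payload = {
        "plant": asdict(cfg.plant),
        "sift": asdict(cfg.sift),
        "train": asdict(cfg.train),
        "benchmark": asdict(cfg.benchmark),
    }
    if cfg.sensor is not None:
        payload["sensor"] = asdict(cfg.sensor)
    with open(path, "w") as fh:
        yaml.safe_dump(payload, fh, sort_keys=False)
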