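"""Run configuration: YAML round-trip of every tunable in the pipeline.

A `RunConfig` gathers the simulation, augmentation, model and split settings
used by the CLI; every run writes its resolved config next to its outputs so
a result can always be traced back to the exact parameters that produced it.
A reduced-scale ``smoke`` profile (64x64 images, 60 per class, 10 epochs) is
shipped for quick end-to-end runs; the ``full`` profile is the nominal
400x320 / 400-per-class / 50-epoch protocol.
"""

from __future__ import annotations

from dataclasses import asdict, dataclass, field, fields

import yaml

from .augment import AugmentationConfig
from .simulate import SimulationConfig
from .training import SplitPlan

__all__ = ["ModelConfig", "RunConfig", "PROFILES"]


@dataclass(frozen=True)
class ModelConfig:
    """Trainer hyperparameters (the architecture itself is fixed)."""

    dropout: float = 0.5
    optimizer: str = "adam"
    learning_rate: float = 1e-3
    batch_size: int = 16
    epochs: int = 50


@dataclass(frozen=True)
class RunConfig:
    simulation: SimulationConfig = field(default_factory=SimulationConfig)
    augmentation: AugmentationConfig = field(default_factory=AugmentationConfig)
    model: ModelConfig = field(default_factory=ModelConfig)
    split: SplitPlan = field(default_factory=SplitPlan)
    per_class: int = 400
    class_margin: float = 1.0
    seed: int = 0
    log_level: str = "INFO"

    def to_dict(self) -> dict:
        return asdict(self)

    @classmethod
    def from_dict(cls, d: dict) -> "RunConfig":
        kwargs = dict(d)
        section_types = {
            "simulation": SimulationConfig,
            "augmentation": AugmentationConfig,
            "model": ModelConfig,
            "split": SplitPlan,
        }
        for key, typ in section_types.items():
            if key in kwargs and isinstance(kwargs[key], dict):
                valid = {f.name for f in fields(typ)}
                unknown = set(kwargs[key]) - valid
                if unknown:
                    raise ValueError(f"unknown keys in '{key}': {sorted(unknown)}")
                kwargs[key] = typ(**kwargs[key])
        return cls(**kwargs)

    def to_yaml(self, path: str) -> None:
        with open(path, "w") as fh:
            yaml.safe_dump(self.to_dict(), fh, sort_keys=False)

    @classmethod
    def from_yaml(cls, path: str) -> "RunConfig":
        with open(path) as fh:
            return cls.from_dict(yaml.safe_load(fh) or {})


PROFILES: dict[str, RunConfig] = {
    "full": RunConfig(),
    "smoke": RunConfig(
        simulation=SimulationConfig(image_height=64, image_width=64),
        model=ModelConfig(epochs=10),
        per_class=60,
    ),
}
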