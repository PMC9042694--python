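"""Run configuration: one YAML file, one root seed, per-stage sections.

Every stage parameter lives in exactly one section.  The global ``seed`` is
propagated into each stage config; within a stage, randomness is drawn from
named substreams (synth, split, jitter, negatives, training, weights,
bootstrap), so a serialized config reproduces a run bit-for-bit.
"""

from __future__ import annotations

from dataclasses import asdict, dataclass, field, fields, replace
from pathlib import Path

import yaml

from .aggregation import AggregationRule
from .augmentation import AugmentConfig
from .mil import MILConfig
from .synthetic import SynthConfig
from .tiling import TilingConfig


@dataclass
class SplitConfig:
    train: float = 20 / 36
    validation: float = 6 / 36
    test: float = 10 / 36

    @property
    def fractions(self) -> tuple[float, float, float]:
        return (self.train, self.validation, self.test)


@dataclass
class EvalConfig:
    n_boot: int = 2000


@dataclass
class RunConfig:
    seed: int = 0
    outdir: str = "cytomil_run"
    synth: SynthConfig = field(default_factory=SynthConfig)
    split: SplitConfig = field(default_factory=SplitConfig)
    tiling: TilingConfig = field(default_factory=TilingConfig)
    augment: AugmentConfig = field(default_factory=AugmentConfig)
    mil: MILConfig = field(default_factory=MILConfig)
    aggregation: AggregationRule = field(default_factory=AggregationRule)
    evaluation: EvalConfig = field(default_factory=EvalConfig)

    def __post_init__(self) -> None:
        # the root seed is the single source of randomness
        self.synth = replace(self.synth, seed=self.seed)
        self.augment = replace(self.augment, seed=self.seed)
        self.mil = replace(self.mil, seed=self.seed)

    def to_dict(self) -> dict:
        return asdict(self)

    @classmethod
    def from_dict(cls, data: dict) -> "RunConfig":
        sections = {
            "synth": SynthConfig,
            "split": SplitConfig,
            "tiling": TilingConfig,
            "augment": AugmentConfig,
            "mil": MILConfig,
            "aggregation": AggregationRule,
            "evaluation": EvalConfig,
        }
        kwargs: dict = {}
        known = {f.name for f in fields(cls)}
        for key, value in data.items():
            if key not in known:
                raise ValueError(f"unknown config key {key!r}")
            if key in sections:
                kwargs[key] = sections[key](**value)
            else:
                kwargs[key] = value
        return cls(**kwargs)

    def to_yaml(self, path: str | Path) -> None:
        Path(path).write_text(yaml.safe_dump(self.to_dict(), sort_keys=False))

    @classmethod
    def from_yaml(cls, path: str | Path) -> "RunConfig":
        data = yaml.safe_load(Path(path).read_text())
        return cls.from_dict(data or {})
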