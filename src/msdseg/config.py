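"""Experiment configuration: one YAML file drives the whole pipeline.

A single master seed deterministically derives the per-stage seeds, so a
config file plus its seed fully reproduces a run.
"""

from __future__ import annotations

import dataclasses
from dataclasses import dataclass, field, fields

import numpy as np
import yaml

from .levelset import LevelSetConfig
from .msdensenet import NetworkConfig
from .phantom import PhantomConfig
from .training import TrainConfig


@dataclass
class InferenceConfig:
    patch: int = 32
    stride: int = 16


_REQUIRED = ("out_dir",)


@dataclass
class ExperimentConfig:
    out_dir: str = None
    seed: int = 0
    n_train: int = 3
    n_test: int = 2
    #: optional physical crop (mm) applied after normalization
    crop_mm: tuple = None
    phantom: PhantomConfig = field(default_factory=PhantomConfig)
    network: NetworkConfig = field(default_factory=NetworkConfig)
    train: TrainConfig = field(default_factory=TrainConfig)
    inference: InferenceConfig = field(default_factory=InferenceConfig)
    levelset: LevelSetConfig = field(default_factory=LevelSetConfig)

    def validate(self):
        for name in _REQUIRED:
            if getattr(self, name) is None:
                raise ValueError(f"missing required config field: {name}")
        if self.n_train < 1 or self.n_test < 1:
            raise ValueError("n_train and n_test must be >= 1")
        self.phantom.validate()
        self.network.validate()
        self.train.validate()
        self.levelset.validate()
        return self

    def stage_seeds(self):
        """Named per-stage seeds derived from the master seed."""
        ss = np.random.SeedSequence(self.seed)
        names = ("data", "train", "fixtures")
        vals = [int(s.generate_state(1)[0] & 0x7FFFFFFF) for s in ss.spawn(len(names))]
        return dict(zip(names, vals))

    def to_dict(self):
        return dataclasses.asdict(self)

    def to_yaml(self, path=None):
        def clean(obj):
            if isinstance(obj, dict):
                return {k: clean(v) for k, v in obj.items()}
            if isinstance(obj, (list, tuple)):
                return [clean(v) for v in obj]
            if isinstance(obj, (np.integer,)):
                return int(obj)
            if isinstance(obj, (np.floating,)):
                return float(obj)
            return obj
        text = yaml.safe_dump(clean(self.to_dict()), sort_keys=False)
        if path is not None:
            with open(path, "w") as fh:
                fh.write(text)
        return text

    @classmethod
    def from_dict(cls, raw: dict) -> "ExperimentConfig":
        raw = dict(raw)
        kwargs = {}
        sub = {"phantom": PhantomConfig, "network": NetworkConfig,
               "train": TrainConfig, "inference": InferenceConfig,
               "levelset": LevelSetConfig}
        valid = {f.name for f in fields(cls)}
        for key, val in raw.items():
            if key not in valid:
                raise ValueError(f"unknown config field: {key}")
            if key in sub and isinstance(val, dict):
                subvalid = {f.name for f in fields(sub[key])}
                bad = set(val) - subvalid
                if bad:
                    raise ValueError(f"unknown {key} config fields: {sorted(bad)}")
                kwargs[key] = sub[key](**{k: _tupleize(v) for k, v in val.items()})
            else:
                kwargs[key] = _tupleize(val)
        return cls(**kwargs).validate()

    @classmethod
    def from_yaml(cls, path) -> "ExperimentConfig":
        with open(path) as fh:
            raw = yaml.safe_load(fh)
        if not isinstance(raw, dict):
            raise ValueError(f"config file {path} does not hold a mapping")
        return cls.from_dict(raw)


def _tupleize(v):
    return tuple(v) if isinstance(v, list) else v
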