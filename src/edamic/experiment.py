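"""Experiment configuration and run manifests."""

from __future__ import annotations

import hashlib
import json
from dataclasses import dataclass, field
from datetime import datetime, timezone
from pathlib import Path

import yaml

import edamic
from edamic.detector.config import DetectorConfig
from edamic.edacontrol import ControllerConfig
from edamic.synthsample.config import SimConfig

_SECTIONS = ("sim", "train", "controller", "analysis")
_TOP_KEYS = {"seed", "out_dir", "channels"} | set(_SECTIONS)


@dataclass
class ExperimentConfig:
    """Nested sim/train/controller/analysis sections plus a master seed.

    Round-trips losslessly through YAML; unknown keys are rejected.
    """

    sim: SimConfig | None = None
    train: DetectorConfig | None = None
    controller: ControllerConfig | None = None
    analysis: dict = field(default_factory=dict)
    seed: int = 0
    out_dir: str = "."
    channels: list = field(default_factory=lambda: ["phase"])

    @classmethod
    def from_dict(cls, d: dict) -> "ExperimentConfig":
        unknown = set(d) - _TOP_KEYS
        if unknown:
            raise ValueError(f"unknown config keys: {sorted(unknown)}")
        kw: dict = {k: d[k] for k in ("seed", "out_dir", "channels") if k in d}
        if "sim" in d:
            kw["sim"] = SimConfig.from_dict(d["sim"])
        if "train" in d:
            kw["train"] = DetectorConfig.from_dict(d["train"])
        if "controller" in d:
            ctrl = dict(d["controller"])
            if "correlative_channels" in ctrl:
                ctrl["correlative_channels"] = tuple(ctrl["correlative_channels"])
            kw["controller"] = ControllerConfig(**ctrl)
        if "analysis" in d:
            kw["analysis"] = dict(d["analysis"])
        return cls(**kw)

    @classmethod
    def from_yaml(cls, path) -> "ExperimentConfig":
        with open(path) as fh:
            data = yaml.safe_load(fh) or {}
        return cls.from_dict(data)

    def to_dict(self) -> dict:
        out: dict = {"seed": self.seed, "out_dir": str(self.out_dir),
                     "channels": list(self.channels)}
        if self.sim is not None:
            out["sim"] = self.sim.to_dict()
        if self.train is not None:
            out["train"] = self.train.to_dict()
        if self.controller is not None:
            c = dict(self.controller.__dict__)
            c["correlative_channels"] = list(c["correlative_channels"])
            out["controller"] = c
        if self.analysis:
            out["analysis"] = dict(self.analysis)
        return out

    def to_yaml(self, path) -> None:
        Path(path).write_text(yaml.safe_dump(self.to_dict(), sort_keys=True))

    def config_hash(self) -> str:
        blob = json.dumps(self.to_dict(), sort_keys=True).encode()
        return hashlib.sha256(blob).hexdigest()[:16]


@dataclass
class RunManifest:
    config_hash: str
    seeds: list
    artifacts: list
    stage: str
    version: str = edamic.__version__
    timestamp: str = ""

    def write(self, directory) -> Path:
        directory = Path(directory)
        directory.mkdir(parents=True, exist_ok=True)
        self.timestamp = self.timestamp or datetime.now(timezone.utc).isoformat()
        path = directory / f"manifest_{self.stage}.json"
        path.write_text(json.dumps(self.__dict__, indent=2, sort_keys=True))
        return path
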