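"""Detector configuration."""

from __future__ import annotations

from dataclasses import dataclass, asdict, fields


@dataclass(frozen=True)
class DetectorConfig:
    n_time_points: int = 1
    stateful: bool = False
    depth: int = 2
    initial_filters: int = 16
    loss: str = "soft_focal"          # "bce" | "soft_focal"
    gamma: float = 2.0                # focusing exponent (soft focal only)
    sigma_label: float = 4.0          # px, Gaussian label spot sd
    learning_rate: float = 1e-3
    epochs: int = 30
    batch_size: int = 8
    grad_clip: float = 0.0            # global-norm clip; 0 disables
    warmup_frames: int = 0            # stateful: no-grad state warm-up frames
    seed: int = 0

    def __post_init__(self) -> None:
        if self.n_time_points < 1:
            raise ValueError("n_time_points must be >= 1")
        if self.stateful and self.n_time_points < 2:
            raise ValueError("stateful detectors require n_time_points >= 2")
        if self.depth < 1:
            raise ValueError("depth must be >= 1")
        if self.initial_filters < 1:
            raise ValueError("initial_filters must be >= 1")
        if self.loss not in ("bce", "soft_focal"):
            raise ValueError(f"unknown loss {self.loss!r}")
        if self.gamma < 0:
            raise ValueError("gamma must be >= 0")
        if self.warmup_frames < 0:
            raise ValueError("warmup_frames must be >= 0")
        if self.warmup_frames and not self.stateful:
            raise ValueError("warmup_frames requires stateful=True")

    def to_dict(self) -> dict:
        return asdict(self)

    @classmethod
    def from_dict(cls, d: dict) -> "DetectorConfig":
        known = {f.name for f in fields(cls)}
        unknown = set(d) - known
        if unknown:
            raise ValueError(f"unknown DetectorConfig keys: {sorted(unknown)}")
        return cls(**d)
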