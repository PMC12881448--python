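"""Simulation configuration.

Defaults encode the experimental constants used throughout: contacts arrive
on average every 3.1 min and last 20 s; divisions arrive at 1 per 3.2 min.
"""

from __future__ import annotations

from dataclasses import dataclass, asdict, fields


@dataclass(frozen=True)
class SimConfig:
    """Parameters of one synthetic time-lapse experiment.

    All rates, durations and sizes must be strictly positive (zero event
    rates are allowed: a zero-rate Poisson process simply produces nothing).
    A fixed ``seed`` makes every simulator output byte-identical.
    """

    height: int = 256
    width: int = 256
    pixel_size: float = 0.1          # um / pixel
    frame_rate: float = 1.0          # Hz
    duration: float = 600.0          # s
    n_mito: int = 6
    n_spheres: int = 6
    contact_rate: float = 1.0 / 3.1  # events / min
    contact_duration: float = 20.0   # s
    division_rate: float = 0.0       # events / min
    pre_constriction_window: int = 10  # frames of visible constriction
    n_ruffles: int = 2
    psf_sigma: float = 1.2           # px
    noise_sd: float = 0.02           # intensity units
    halo_gain: float = 0.6
    absorption: float = 0.5          # phase darkening of organelle interiors
    bleach_rate: float = 0.002       # fractional pool loss per fluo exposure
    hazard_coeff: float = 6.6e-7     # deaths per dose unit (mW*ms/mm^2)
    phase_dose_factor: float = 1.0 / 500.0  # phase dose relative to fluo
    poisson_noise: bool = False
    deform_amp: float = 2.0          # px of local tube bending at a contact
    seed: int = 0

    def __post_init__(self) -> None:
        positive = [
            "height", "width", "pixel_size", "frame_rate", "duration",
            "contact_duration", "psf_sigma",
        ]
        for name in positive:
            if getattr(self, name) <= 0:
                raise ValueError(f"SimConfig.{name} must be strictly positive")
        nonneg = [
            "n_mito", "n_spheres", "contact_rate", "division_rate",
            "pre_constriction_window", "n_ruffles", "noise_sd", "halo_gain",
            "absorption", "bleach_rate", "hazard_coeff", "phase_dose_factor",
        ]
        for name in nonneg:
            if getattr(self, name) < 0:
                raise ValueError(f"SimConfig.{name} must be non-negative")
        if self.contact_duration * self.frame_rate < 1:
            raise ValueError("contact_duration x frame_rate must be >= 1 frame")

    @property
    def n_frames(self) -> int:
        return int(round(self.duration * self.frame_rate))

    def to_dict(self) -> dict:
        return asdict(self)

    @classmethod
    def from_dict(cls, d: dict) -> "SimConfig":
        known = {f.name for f in fields(cls)}
        unknown = set(d) - known
        if unknown:
            raise ValueError(f"unknown SimConfig keys: {sorted(unknown)}")
        return cls(**d)
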