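"""Shared domain types: movies, events, organelle states, exposures."""

from __future__ import annotations

from dataclasses import dataclass, field
from typing import Optional

import numpy as np

#: Recognised channel tags. ``phase`` is the label-free transmitted-light
#: channel; everything else is fluorescence.
CHANNELS = (
    "phase", "mito_fluo", "ld_fluo", "lyso_fluo",
    "drp1_fluo", "tmre", "sytox", "hoechst",
)
FLUO_CHANNELS = tuple(c for c in CHANNELS if c != "phase")

EVENT_CLASSES = ("contact", "division")
POLARITIES = ("positive", "negative")


@dataclass
class TimeLapseMovie:
    """Ordered stack of single-channel 2D frames.

    ``frames`` is indexed ``(t, y, x)`` with the origin at the top-left.
    """

    frames: np.ndarray
    channel: str
    frame_rate: float
    pixel_size: float

    def __post_init__(self) -> None:
        self.frames = np.asarray(self.frames)
        if self.frames.ndim != 3:
            raise ValueError("frames must be a (t, y, x) stack")
        if self.channel not in CHANNELS:
            raise ValueError(f"unknown channel tag {self.channel!r}")
        if not np.all(np.isfinite(self.frames)):
            raise ValueError("frame intensities must be finite")
        if np.any(self.frames < 0):
            raise ValueError("frame intensities must be >= 0")

    @property
    def n_frames(self) -> int:
        return self.frames.shape[0]

    @property
    def shape(self) -> tuple:
        return self.frames.shape[1:]

    def __len__(self) -> int:
        return self.n_frames


@dataclass(frozen=True)
class EventRecord:
    """One annotated event: class, inclusive frame span, center, polarity.

    Negative records mark confirmed non-events used to balance training sets.
    """

    event_class: str
    t_start: int
    t_end: int
    x: float
    y: float
    polarity: str = "positive"

    def __post_init__(self) -> None:
        if self.event_class not in EVENT_CLASSES:
            raise ValueError(f"unknown event class {self.event_class!r}")
        if self.polarity not in POLARITIES:
            raise ValueError(f"unknown polarity {self.polarity!r}")
        if self.t_end < self.t_start:
            raise ValueError("t_end must be >= t_start")

    @property
    def n_frames(self) -> int:
        return self.t_end - self.t_start + 1

    def active_at(self, t: int) -> bool:
        return self.t_start <= t <= self.t_end


@dataclass(frozen=True)
class ExposureSpec:
    """What the microscope exposes at one time point."""

    modality: str                     # "surveillance" | "correlative"
    channels: tuple
    exposure_time: float = 100.0      # ms
    irradiance: float = 35.0          # mW/mm^2

    def __post_init__(self) -> None:
        if self.modality not in ("surveillance", "correlative"):
            raise ValueError(f"unknown modality {self.modality!r}")
        object.__setattr__(self, "channels", tuple(self.channels))
        for c in self.channels:
            if c not in CHANNELS:
                raise ValueError(f"unknown channel tag {c!r}")
        if "phase" not in self.channels:
            raise ValueError("every exposure acquires the phase channel")
        fluo = [c for c in self.channels if c != "phase"]
        if self.modality == "surveillance" and fluo:
            raise ValueError("surveillance exposes only phase")
        if self.modality == "correlative" and not fluo:
            raise ValueError("correlative requires >= 1 fluorescence channel")
        if self.exposure_time < 0 or self.irradiance < 0:
            raise ValueError("exposure_time and irradiance must be >= 0")

    @property
    def fluo_channels(self) -> tuple:
        return tuple(c for c in self.channels if c != "phase")


@dataclass
class Tube:
    """A tubular organelle: centerline control points plus half-width.

    ``points`` is an (n, 2) float array of (x, y) control points. A local
    constriction is described by (index into points, relative width factor).
    """

    points: np.ndarray
    width: float = 3.0
    constriction_at: Optional[int] = None
    constriction_factor: float = 1.0
    tmre_dark_span: Optional[tuple] = None  # (lo, hi) fractional arc positions


@dataclass
class Sphere:
    center: np.ndarray  # (x, y)
    radius: float = 5.0
    kind: str = "ld"    # "ld" | "lyso"


@dataclass
class SampleState:
    """Geometry of the sample at one time point."""

    tubes: list
    spheres: list
    ruffles: list              # list of (n, 2) polylines
    drp1_puncta: list = field(default_factory=list)  # [(x, y, amplitude)]
    contact_marks: list = field(default_factory=list)  # [(x, y)] active contacts


@dataclass
class CellSample:
    """A simulated sample: per-frame geometry plus viability bookkeeping.

    ``accumulated_dose`` only ever grows; once ``alive`` is False it never
    reverts. ``fluorophore_pool`` maps fluorescence channel -> fraction of
    unbleached fluorophore remaining.
    """

    states: list                      # SampleState per frame
    frame_rate: float
    pixel_size: float
    accumulated_dose: float = 0.0
    alive: bool = True
    fluorophore_pool: dict = field(default_factory=lambda: {c: 1.0 for c in FLUO_CHANNELS})
    dose_ledger: list = field(default_factory=list)

    @property
    def n_frames(self) -> int:
        return len(self.states)

    def add_dose(self, increment: float) -> None:
        if increment < 0:
            raise ValueError("dose increments must be >= 0")
        self.accumulated_dose += increment
        self.dose_ledger.append(increment)

    def kill(self) -> None:
        self.alive = False
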