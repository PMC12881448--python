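"""Duty-cycle arithmetic: frames per event under continuous imaging.

With events arriving on average every 3.1 min and 1 Hz imaging, continuous
fluorescence spends about 186 frames per event; a triggered burst of 20
frames is a ~9-fold reduction. At 1 per 3.2 min the continuous count is 192
and the reduction ~10-fold.
"""

from __future__ import annotations

from dataclasses import dataclass


@dataclass(frozen=True)
class DutyCycleModel:
    event_interval: float   # min between events
    event_duration: float   # s
    frame_rate: float       # Hz

    def __post_init__(self) -> None:
        if min(self.event_interval, self.event_duration, self.frame_rate) <= 0:
            raise ValueError("all DutyCycleModel fields must be positive")


def continuous_frames_per_event(model: DutyCycleModel) -> int:
    """Frames spent per event under continuous imaging:
    interval (min) x 60 x frame rate, rounded to the nearest integer."""
    return int(round(model.event_interval * 60.0 * model.frame_rate))


def fold_reduction(model: DutyCycleModel, triggered_frames: float) -> float:
    """Continuous frames per event divided by the triggered per-event count."""
    if triggered_frames == 0:
        raise ValueError("triggered_frames must be non-zero")
    return continuous_frames_per_event(model) / triggered_frames


def triggered_frames_per_event(model: DutyCycleModel) -> int:
    """Frames in one triggered burst: event duration x frame rate."""
    return int(round(model.event_duration * model.frame_rate))
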