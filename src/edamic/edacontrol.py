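"""The two-state acquisition machine: analyzer, interpreter, scheduler.

SURVEILLANCE acquires phase only; a score above the trigger threshold
switches to CORRELATIVE (phase + fluorescence) for at least
``min_correlative_frames``, and a fresh super-threshold score while
correlative re-arms the burst. Phase is acquired — and analyzed — in both
states, so the sample is continuously monitored. A detection at frame t
changes the modality of frame t + 1 (one-frame actuation latency).
"""

from __future__ import annotations

from dataclasses import dataclass, field
from typing import Optional

import numpy as np

from edamic.synthsample.config import SimConfig
from edamic.synthsample.exposure import correlative_spec, surveillance_spec
from edamic.synthsample.microscope import VirtualMicroscope
from edamic.synthsample.types import CellSample, ExposureSpec

SURVEILLANCE = "SURVEILLANCE"
CORRELATIVE = "CORRELATIVE"

STAY = "stay"
TO_CORRELATIVE = "to_correlative"
TO_SURVEILLANCE = "to_surveillance"


@dataclass(frozen=True)
class ControllerConfig:
    score_threshold_up: float = 0.5
    score_threshold_down: Optional[float] = None  # defaults to threshold_up
    min_correlative_frames: int = 20
    buffer_length: int = 1            # = detector n_time_points
    frame_rate: float = 1.0
    correlative_channels: tuple = ("mito_fluo",)
    exposure_time: float = 100.0
    irradiance: float = 35.0

    def __post_init__(self) -> None:
        down = self.threshold_down
        if not (0 <= self.score_threshold_up <= 1 and 0 <= down <= 1):
            raise ValueError("thresholds must lie in [0, 1]")
        if down > self.score_threshold_up:
            raise ValueError("threshold_down must be <= threshold_up")
        if self.min_correlative_frames < 1:
            raise ValueError("min_correlative_frames must be >= 1")
        if self.buffer_length < 1:
            raise ValueError("buffer_length must be >= 1")

    @property
    def threshold_down(self) -> float:
        return (self.score_threshold_up if self.score_threshold_down is None
                else self.score_threshold_down)


@dataclass
class AcquisitionState:
    mode: str = SURVEILLANCE
    frames_since_trigger: int = 0
    frame_buffer: list = field(default_factory=list)
    prev_above: bool = False


@dataclass(frozen=True)
class LogRecord:
    t: int
    mode: str
    channels: tuple
    max_score: float
    dose_increment: float
    cumulative_dose: float


@dataclass
class AcquisitionLog:
    records: list = field(default_factory=list)

    def append(self, rec: LogRecord) -> None:
        if self.records:
            if rec.t != self.records[-1].t + 1:
                raise ValueError("log records must be consecutive")
            if rec.cumulative_dose < self.records[-1].cumulative_dose:
                raise ValueError("cumulative dose must be non-decreasing")
        self.records.append(rec)

    def __len__(self) -> int:
        return len(self.records)

    @property
    def correlative_frames(self) -> list:
        return [r for r in self.records if r.mode == CORRELATIVE]

    @property
    def duty_cycle(self) -> float:
        if not self.records:
            return 0.0
        return len(self.correlative_frames) / len(self.records)


def analyzer_step(state: AcquisitionState, phase_frame: np.ndarray,
                  detector) -> np.ndarray:
    """Push the newest phase frame into the buffer and score it.

    The buffer holds the last ``n_time_points`` frames (left-padded by
    repetition while filling); the returned map scores the newest frame.
    """
    phase_frame = np.asarray(phase_frame, float)
    if state.frame_buffer and state.frame_buffer[-1].shape != phase_frame.shape:
        raise ValueError("frame shape mismatch")
    tp = detector.config.n_time_points
    state.frame_buffer.append(phase_frame)
    if len(state.frame_buffer) > tp:
        state.frame_buffer.pop(0)
    if getattr(detector.config, "stateful", False):
        return detector.step(phase_frame)
    window = state.frame_buffer
    if len(window) < tp:
        window = [window[0]] * (tp - len(window)) + window
    return detector.infer(np.stack(window))


def interpret(score_map: np.ndarray, state: AcquisitionState,
              config: ControllerConfig):
    """Threshold-with-memory state update; returns (decision, state)."""
    s = float(np.max(score_map))
    above = s > config.score_threshold_up
    rising = above and not state.prev_above
    state.prev_above = above
    if state.mode == SURVEILLANCE:
        if above:
            state.mode = CORRELATIVE
            state.frames_since_trigger = 0
            return TO_CORRELATIVE, state
        return STAY, state
    # CORRELATIVE: a fresh rising edge re-arms the burst; the burst ends only
    # after min_correlative_frames since the last (re-)trigger with the score
    # back under threshold_down
    if rising:
        state.frames_since_trigger = 0
        return STAY, state
    state.frames_since_trigger += 1
    if (state.frames_since_trigger >= config.min_correlative_frames
            and s < config.threshold_down):
        state.mode = SURVEILLANCE
        state.frames_since_trigger = 0
        return TO_SURVEILLANCE, state
    return STAY, state


def scheduler_next(decision: str, state: AcquisitionState,
                   config: ControllerConfig) -> ExposureSpec:
    """Exposure for the next time point given the interpreter's state."""
    if state.mode == CORRELATIVE:
        return correlative_spec(config.correlative_channels,
                                config.exposure_time, config.irradiance)
    return surveillance_spec(config.exposure_time, config.irradiance)


def run_eda(sample: CellSample, detector, controller_config: ControllerConfig,
            sim_config: SimConfig, on_frame=None) -> AcquisitionLog:
    """Closed loop over the whole trajectory; returns the audit log.

    ``on_frame(t, frames)`` — if given — receives every acquired channel
    dict (for movie export).
    """
    if hasattr(detector, "reset_state"):
        detector.reset_state()
    scope = VirtualMicroscope(sample, sim_config)
    state = AcquisitionState()
    log = AcquisitionLog()
    spec = surveillance_spec(controller_config.exposure_time,
                             controller_config.irradiance)
    for t in range(scope.n_frames):
        dose_before = sample.accumulated_dose
        frames = scope.acquire(t, spec)
        if on_frame is not None:
            on_frame(t, frames)
        score_map = analyzer_step(state, frames["phase"], detector)
        mode_at_t = spec.modality
        decision, state = interpret(score_map, state, controller_config)
        log.append(LogRecord(
            t=t,
            mode=CORRELATIVE if mode_at_t == "correlative" else SURVEILLANCE,
            channels=spec.channels,
            max_score=float(np.max(score_map)),
            dose_increment=sample.accumulated_dose - dose_before,
            cumulative_dose=sample.accumulated_dose,
        ))
        spec = scheduler_next(decision, state, controller_config)
    return log


@dataclass(frozen=True)
class CaptureStats:
    duty_cycle: float
    events_captured_fraction: float
    fluorescence_frames_per_captured_event: float
    dose_per_event: float
    n_events: int
    n_captured: int
    n_correlative_frames: int


def capture_stats(log: AcquisitionLog, events) -> CaptureStats:
    """Duty cycle and per-event fluorescence frame counts for one run."""
    total = len(log)
    corr = log.correlative_frames
    n_corr = len(corr)
    positives = [e for e in events if e.polarity == "positive"]
    corr_ts = {r.t for r in corr}
    captured = [e for e in positives
                if any(e.t_start <= t <= e.t_end for t in corr_ts)]
    n_cap = len(captured)
    frames_per_event = n_corr / n_cap if n_cap else float("nan")
    fluo_dose = sum(r.dose_increment for r in corr)
    dose_per_event = fluo_dose / n_cap if n_cap else float("nan")
    return CaptureStats(
        duty_cycle=n_corr / total if total else 0.0,
        events_captured_fraction=n_cap / len(positives) if positives else 1.0,
        fluorescence_frames_per_captured_event=frames_per_event,
        dose_per_event=dose_per_event,
        n_events=len(positives),
        n_captured=n_cap,
        n_correlative_frames=n_corr,
    )


class OracleDetector:
    """Scores straight from ground truth: a unit spot while an event is
    active, zero elsewhere. Used for controller-only experiments."""

    class _Cfg:
        n_time_points = 1
        stateful = False

    def __init__(self, events, shape, sigma: float = 4.0):
        self.events = [e for e in events if e.polarity == "positive"]
        self.shape = shape
        self.sigma = sigma
        self.config = self._Cfg()
        self._t = 0

    def reset_state(self) -> None:
        self._t = 0

    def infer(self, window) -> np.ndarray:
        t = self._t
        self._t += 1
        out = np.zeros(self.shape)
        yy, xx = np.mgrid[0:self.shape[0], 0:self.shape[1]]
        for ev in self.events:
            if ev.active_at(t):
                out = np.maximum(out, np.exp(
                    -((xx - ev.x) ** 2 + (yy - ev.y) ** 2) / (2 * self.sigma ** 2)))
        return out
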