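"""Event scheduling: homogeneous Poisson arrivals of contacts and divisions."""

from __future__ import annotations

import numpy as np

from edamic.synthsample.config import SimConfig
from edamic.synthsample.types import EventRecord


def _poisson_arrivals(rng: np.random.Generator, rate_per_s: float,
                      duration_s: float) -> np.ndarray:
    """Arrival times (s) of a homogeneous Poisson process on [0, duration)."""
    if rate_per_s <= 0:
        return np.empty(0)
    times = []
    t = rng.exponential(1.0 / rate_per_s)
    while t < duration_s:
        times.append(t)
        t += rng.exponential(1.0 / rate_per_s)
    return np.asarray(times)


def schedule_events(config: SimConfig, seed: int) -> list:
    """Draw the event schedule for one movie.

    Contacts arrive as a Poisson process at ``contact_rate`` (per minute) and
    span a fixed ``contact_duration``. Divisions arrive at ``division_rate``;
    each is preceded by ``pre_constriction_window`` frames of visible
    constriction, and ``t_end`` marks the scission frame. Events that would
    not fit inside the movie (including the constriction run-up) are dropped;
    a movie too short to host any event yields an empty list.

    Locations are provisional (uniform in bounds); :func:`simulate_sample`
    replaces them with geometry-consistent coordinates.
    """
    rng = np.random.default_rng(seed)
    c_rng, d_rng, loc_rng = rng.spawn(3)
    n_frames = config.n_frames
    fr = config.frame_rate
    events = []

    dur_frames = max(1, int(round(config.contact_duration * fr)))
    for t_s in _poisson_arrivals(c_rng, config.contact_rate / 60.0, config.duration):
        t0 = int(np.floor(t_s * fr))
        t1 = t0 + dur_frames - 1
        if t1 >= n_frames:
            continue
        x = float(loc_rng.uniform(0.15, 0.85) * config.width)
        y = float(loc_rng.uniform(0.15, 0.85) * config.height)
        events.append(EventRecord("contact", t0, t1, x, y, "positive"))

    pre = config.pre_constriction_window
    for t_s in _poisson_arrivals(d_rng, config.division_rate / 60.0, config.duration):
        t1 = int(np.floor(t_s * fr))
        t0 = t1 - pre + 1
        if t0 < 0 or t1 + 6 >= n_frames:  # leave room for daughter recoil
            continue
        x = float(loc_rng.uniform(0.15, 0.85) * config.width)
        y = float(loc_rng.uniform(0.15, 0.85) * config.height)
        events.append(EventRecord("division", t0, t1, x, y, "positive"))

    events.sort(key=lambda e: (e.t_start, e.t_end, e.event_class))
    return events
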