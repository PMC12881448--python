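"""Sample trajectory simulation.

Tubular organelles (mitochondria) move smoothly; spherical organelles
(droplets/lysosomes) diffuse; scripted contact events steer a sphere onto a
tube so that their boundaries touch for the whole event span, and scripted
divisions constrict a tube over a pre-constriction window before splitting
it into two recoiling daughters. Long-lived curvilinear ruffles persist for
the whole movie as false-positive bait.
"""

from __future__ import annotations

import numpy as np

from edamic.synthsample.config import SimConfig
from edamic.synthsample.types import (
    CellSample, EventRecord, SampleState, Sphere, Tube,
)

TUBE_WIDTH = 2.5          # half-width, px
RECOIL_FRAMES = 5
CONTACT_APPROACH = 4      # frames of steering before t_start
DRP1_LINGER = 8           # frames puncta persist on daughter tips


def _closest_point_on_polyline(points: np.ndarray, p: np.ndarray):
    """Closest point on the open polyline to p: (point, tangent, distance)."""
    a = points[:-1]
    b = points[1:]
    ab = b - a
    denom = np.einsum("ij,ij->i", ab, ab)
    denom = np.where(denom == 0, 1.0, denom)
    t = np.clip(np.einsum("ij,ij->i", p[None, :] - a, ab) / denom, 0.0, 1.0)
    proj = a + t[:, None] * ab
    d = np.linalg.norm(proj - p[None, :], axis=1)
    i = int(np.argmin(d))
    tangent = ab[i] / max(np.linalg.norm(ab[i]), 1e-9)
    return proj[i], tangent, float(d[i])


def polyline_point_distance(points: np.ndarray, p) -> float:
    """Exact distance from point p to the polyline."""
    return _closest_point_on_polyline(points, np.asarray(p, float))[2]


def tube_sphere_boundary_distance(state: SampleState) -> float:
    """Minimum boundary-to-boundary distance over all tube/sphere pairs.

    Zero (or negative) means touching (or overlapping).
    """
    best = np.inf
    for tube in state.tubes:
        for sph in state.spheres:
            d = polyline_point_distance(tube.points, sph.center)
            best = min(best, d - tube.width - sph.radius)
    return float(best)


def _random_tube(rng, cfg: SimConfig) -> Tube:
    n_ctrl = 10
    step = float(np.clip(0.035 * min(cfg.height, cfg.width), 3.0, 8.0))
    margin = 0.18
    start = np.array([
        rng.uniform(margin * cfg.width, (1 - margin) * cfg.width),
        rng.uniform(margin * cfg.height, (1 - margin) * cfg.height),
    ])
    angle = rng.uniform(0, 2 * np.pi)
    pts = [start]
    for _ in range(n_ctrl - 1):
        angle += rng.normal(0, 0.35)
        pts.append(pts[-1] + step * np.array([np.cos(angle), np.sin(angle)]))
    pts = np.asarray(pts)
    pts[:, 0] = np.clip(pts[:, 0], 4, cfg.width - 5)
    pts[:, 1] = np.clip(pts[:, 1], 4, cfg.height - 5)
    return Tube(points=pts, width=TUBE_WIDTH)


def _random_sphere(rng, cfg: SimConfig, kind: str) -> Sphere:
    margin = 0.12
    center = np.array([
        rng.uniform(margin * cfg.width, (1 - margin) * cfg.width),
        rng.uniform(margin * cfg.height, (1 - margin) * cfg.height),
    ])
    return Sphere(center=center, radius=float(rng.uniform(3.5, 5.5)), kind=kind)


RUFFLE_WIDTH = TUBE_WIDTH  # px: deliberately confusable with mitochondria
RUFFLE_PINCH_PERIOD = 16   # frames per pinch/recover cycle


def _random_ruffle(rng, cfg: SimConfig) -> "Tube":
    # a static, tube-like curvilinear fold near the field border: within any
    # short window its pinch phase mimics a division pre-constriction
    n_ctrl = 10
    step = float(np.clip(0.035 * min(cfg.height, cfg.width), 3.0, 8.0))
    margin = 0.12
    side = rng.integers(0, 4)
    if side == 0:
        start = np.array([rng.uniform(0.2, 0.5) * cfg.width,
                          margin * cfg.height])
    elif side == 1:
        start = np.array([rng.uniform(0.2, 0.5) * cfg.width,
                          (1 - margin) * cfg.height])
    elif side == 2:
        start = np.array([margin * cfg.width,
                          rng.uniform(0.2, 0.5) * cfg.height])
    else:
        start = np.array([(1 - margin) * cfg.width,
                          rng.uniform(0.2, 0.5) * cfg.height])
    angle = rng.uniform(0, 2 * np.pi)
    pts = [start]
    for _ in range(n_ctrl - 1):
        angle += rng.normal(0, 0.5)
        pts.append(pts[-1] + step * np.array([np.cos(angle), np.sin(angle)]))
    pts = np.asarray(pts)
    pts[:, 0] = np.clip(pts[:, 0], 3, cfg.width - 4)
    pts[:, 1] = np.clip(pts[:, 1], 3, cfg.height - 4)
    return Tube(points=pts, width=RUFFLE_WIDTH)


def _drift_step(rng, vel: np.ndarray, sd: float = 0.15, damp: float = 0.85):
    """Ornstein-Uhlenbeck style velocity update for smooth Brownian drift."""
    return damp * vel + rng.normal(0, sd, 2)


def _clamp_points(pts: np.ndarray, cfg: SimConfig) -> np.ndarray:
    pts[:, 0] = np.clip(pts[:, 0], 3, cfg.width - 4)
    pts[:, 1] = np.clip(pts[:, 1], 3, cfg.height - 4)
    return pts


class _ContactScript:
    """Per-event bookkeeping for steering a sphere onto a tube."""

    def __init__(self, event, tube_idx, sphere_idx):
        self.event = event
        self.tube_idx = tube_idx
        self.sphere_idx = sphere_idx
        self.realized_xy = None


class _DivisionScript:
    def __init__(self, event, tube_idx, ctrl_idx, recoil_dist):
        self.event = event
        self.tube_idx = tube_idx
        self.ctrl_idx = ctrl_idx
        self.recoil_dist = recoil_dist  # (d_left, d_right) px over RECOIL_FRAMES
        self.daughters = None           # indices after the split
        self.recoil_dirs = None
        self.realized_xy = None
        self.split_done = False


def _field_capacity_ok(cfg: SimConfig) -> bool:
    tube_area = 10 * 7 * (2 * TUBE_WIDTH)
    sphere_area = np.pi * 5.0 ** 2
    used = cfg.n_mito * tube_area + cfg.n_spheres * sphere_area
    return used <= 0.5 * cfg.height * cfg.width


def simulate_sample(config: SimConfig):
    """Simulate the full sample trajectory.

    Returns ``(sample, events)`` where ``sample.states`` holds one
    :class:`SampleState` per frame and ``events`` are the realized
    :class:`EventRecord` list with geometry-consistent coordinates.
    """
    from edamic.synthsample.events import schedule_events

    cfg = config
    if not _field_capacity_ok(cfg):
        raise ValueError("organelle counts exceed what fits in the field")

    geo_rng = np.random.default_rng([cfg.seed, 1])
    scheduled = schedule_events(cfg, cfg.seed)
    n_frames = cfg.n_frames

    tubes = [_random_tube(geo_rng, cfg) for _ in range(cfg.n_mito)]
    spheres = [
        _random_sphere(geo_rng, cfg, "ld" if i % 2 == 0 else "lyso")
        for i in range(cfg.n_spheres)
    ]
    ruffles = [_random_ruffle(geo_rng, cfg) for _ in range(cfg.n_ruffles)]
    ruffle_rng = np.random.default_rng([cfg.seed, 9])
    ruffle_phase = [int(ruffle_rng.integers(RUFFLE_PINCH_PERIOD))
                    for _ in ruffles]
    ruffle_site = [int(ruffle_rng.integers(2, max(3, len(r.points) - 2)))
                   for r in ruffles]

    tube_vel = [np.zeros(2) for _ in tubes]
    sphere_vel = [np.zeros(2) for _ in spheres]

    # assign actors to events up front; drop events that cannot be cast
    contacts, divisions = [], []
    busy_tubes: dict = {}
    busy_spheres: dict = {}
    for ev in scheduled:
        if ev.event_class == "contact":
            if not spheres or not tubes:
                continue
            cand_s = [i for i in range(len(spheres))
                      if all(ev.t_start > e.t_end or ev.t_end < e.t_start
                             for e in busy_spheres.get(i, []))]
            cand_t = [i for i in range(len(tubes))
                      if all(ev.t_start > e.t_end or ev.t_end < e.t_start
                             for e in busy_tubes.get(i, []))]
            if not cand_s or not cand_t:
                continue
            si = cand_s[int(geo_rng.integers(len(cand_s)))]
            ti = cand_t[int(geo_rng.integers(len(cand_t)))]
            busy_spheres.setdefault(si, []).append(ev)
            busy_tubes.setdefault(ti, []).append(ev)
            contacts.append(_ContactScript(ev, ti, si))
        else:
            cand_t = [i for i in range(len(tubes))
                      if all(ev.t_start > e.t_end or ev.t_end < e.t_start
                             for e in busy_tubes.get(i, []))]
            if not cand_t:
                continue
            ti = cand_t[int(geo_rng.integers(len(cand_t)))]
            busy_tubes.setdefault(ti, []).append(ev)
            d = geo_rng.uniform(3.0, 8.0, 2)
            divisions.append(_DivisionScript(ev, ti, ctrl_idx=5, recoil_dist=d))

    states = []
    realized: list = []
    # live tube list grows as divisions split tubes; scripts address tubes by
    # index into this list, daughters are appended at the end
    for t in range(n_frames):
        # --- motion ---
        for i, tube in enumerate(tubes):
            tube_vel[i] = _drift_step(geo_rng, tube_vel[i])
            tube.points = _clamp_points(tube.points + tube_vel[i], cfg)
            tube.points[1:-1] += geo_rng.normal(0, 0.05, (len(tube.points) - 2, 2))
        engaged = {s.sphere_idx for s in contacts
                   if s.event.t_start - CONTACT_APPROACH <= t <= s.event.t_end}
        for i, sph in enumerate(spheres):
            sphere_vel[i] = _drift_step(geo_rng, sphere_vel[i], sd=0.25)
            sph.center = sph.center + sphere_vel[i]
            sph.center[0] = np.clip(sph.center[0], 6, cfg.width - 7)
            sph.center[1] = np.clip(sph.center[1], 6, cfg.height - 7)
            if i in engaged:
                continue
            # keep free spheres clear of tubes so scripted contacts are the
            # only touching tube/sphere pairs; the 3 px gap stays resolvable
            # after PSF blur so "near" and "touching" remain distinguishable
            for tube in tubes:
                q, _, d = _closest_point_on_polyline(tube.points, sph.center)
                clearance = tube.width + sph.radius + 3.0
                if d < clearance:
                    normal = sph.center - q
                    nn = np.linalg.norm(normal)
                    if nn < 1e-9:
                        normal, nn = np.array([1.0, 0.0]), 1.0
                    sph.center = q + normal / nn * clearance
                    sph.center[0] = np.clip(sph.center[0], 6, cfg.width - 7)
                    sph.center[1] = np.clip(sph.center[1], 6, cfg.height - 7)

        drp1_puncta = []
        contact_marks = []

        # --- divisions: constriction, scission, recoil ---
        for script in divisions:
            ev = script.event
            tube = tubes[script.tube_idx]
            if ev.t_start <= t <= ev.t_end:
                if t == ev.t_start or script.ctrl_idx >= len(tube.points) - 1:
                    # pick the division site mid-tube; skip tubes that have
                    # become too short from earlier divisions
                    if len(tube.points) < 5:
                        script.abandoned = True
                    script.ctrl_idx = len(tube.points) // 2
                if getattr(script, "abandoned", False):
                    continue
                # narrow linearly over the pre-constriction window
                frac = (t - ev.t_start + 1) / max(1, ev.n_frames)
                tube.constriction_at = script.ctrl_idx
                tube.constriction_factor = float(1.0 - 0.85 * frac)
                site = tube.points[script.ctrl_idx]
                if t == ev.t_end:
                    script.realized_xy = site.copy()
                drp1_puncta.append((site[0], site[1], 1.0))
            elif (t == ev.t_end + 1 and not script.split_done
                  and not getattr(script, "abandoned", False)
                  and script.realized_xy is not None):
                i = script.ctrl_idx
                site = tube.points[i].copy()
                left = Tube(points=tube.points[: i + 1].copy(), width=tube.width)
                right = Tube(points=tube.points[i:].copy(), width=tube.width)
                # retract both new tips well clear of the scission point so
                # the daughter masks separate at the scission frame
                left.points[-1] = tube.points[i - 1] + 0.35 * (
                    tube.points[i] - tube.points[i - 1])
                right.points[0] = tube.points[i + 1] + 0.35 * (
                    tube.points[i] - tube.points[i + 1])
                dir_l = left.points[-2] - left.points[-1]
                dir_r = right.points[1] - right.points[0]
                dir_l /= max(np.linalg.norm(dir_l), 1e-9)
                dir_r /= max(np.linalg.norm(dir_r), 1e-9)
                tubes[script.tube_idx] = left
                tubes.append(right)
                tube_vel.append(tube_vel[script.tube_idx].copy())
                script.daughters = (script.tube_idx, len(tubes) - 1)
                script.recoil_dirs = (dir_l, dir_r)
                script.split_done = True
            if script.split_done and ev.t_end + 1 <= t <= ev.t_end + RECOIL_FRAMES:
                step_l = script.recoil_dist[0] / RECOIL_FRAMES
                step_r = script.recoil_dist[1] / RECOIL_FRAMES
                li, ri = script.daughters
                tubes[li].points = _clamp_points(
                    tubes[li].points + script.recoil_dirs[0] * step_l, cfg)
                tubes[ri].points = _clamp_points(
                    tubes[ri].points + script.recoil_dirs[1] * step_r, cfg)
            if script.split_done and t <= ev.t_end + DRP1_LINGER:
                li, ri = script.daughters
                decay = 1.0 - 0.5 * (t - ev.t_end - 1) / DRP1_LINGER
                tip_l = tubes[li].points[-1]
                tip_r = tubes[ri].points[0]
                drp1_puncta.append((tip_l[0], tip_l[1], decay))
                drp1_puncta.append((tip_r[0], tip_r[1], decay))

        # --- contacts: approach, touch, release ---
        for script in contacts:
            ev = script.event
            tube = tubes[script.tube_idx]
            sph = spheres[script.sphere_idx]
            if ev.t_start - CONTACT_APPROACH <= t < ev.t_start:
                q, _, d = _closest_point_on_polyline(tube.points, sph.center)
                remaining = ev.t_start - t
                target_gap = tube.width + sph.radius
                if d > target_gap:
                    frac = 1.0 / max(1, remaining)
                    sph.center = sph.center + frac * (
                        q + (sph.center - q) / max(d, 1e-9) * target_gap - sph.center)
            elif ev.t_start <= t <= ev.t_end:
                # deform the tube locally toward the sphere, then pin the
                # sphere at exact touching distance from the deformed line
                q, _, d = _closest_point_on_polyline(tube.points, sph.center)
                toward = (sph.center - q)
                nd = max(np.linalg.norm(toward), 1e-9)
                toward /= nd
                seg_d = np.linalg.norm(tube.points - q[None, :], axis=1)
                w = np.exp(-(seg_d / 8.0) ** 2)
                tube.points = tube.points + cfg.deform_amp / max(1, ev.n_frames) \
                    * w[:, None] * toward[None, :]
                q, _, d = _closest_point_on_polyline(tube.points, sph.center)
                normal = (sph.center - q) / max(np.linalg.norm(sph.center - q), 1e-9)
                sph.center = q + normal * (tube.width + sph.radius)
                touch = q + normal * tube.width
                contact_marks.append((float(touch[0]), float(touch[1])))
                if t == ev.t_start:
                    script.realized_xy = touch.copy()

        # --- TMRE flicker: transient subdomain potential loss (1-3 s) ---
        for tube in tubes:
            if tube.tmre_dark_span is not None:
                if t >= tube.tmre_dark_span[2]:
                    tube.tmre_dark_span = None  # recovers; no same-frame restart
            elif geo_rng.uniform() < 0.02 / max(cfg.frame_rate, 1e-9):
                lo = geo_rng.uniform(0.0, 0.6)
                hi = lo + geo_rng.uniform(0.25, 0.4)
                dur = int(round(geo_rng.uniform(1.0, 3.0) * cfg.frame_rate))
                tube.tmre_dark_span = (lo, min(hi, 1.0), t + max(1, dur))

        # ruffles pinch and recover on a fast cycle: within any 5-frame
        # window they mimic a division pre-constriction but never separate —
        # long-lived false-positive bait that only temporal context rejects
        for ri, ruf in enumerate(ruffles):
            phase = (t + ruffle_phase[ri]) % RUFFLE_PINCH_PERIOD
            if phase == 0:  # new cycle: pinch a fresh spot
                ruffle_site[ri] = int(ruffle_rng.integers(
                    2, max(3, len(ruf.points) - 2)))
            half = RUFFLE_PINCH_PERIOD / 2
            depth = 1.0 - abs(phase - half) / half  # 0 -> 1 -> 0 triangle
            ruf.constriction_at = ruffle_site[ri]
            ruf.constriction_factor = float(1.0 - 0.85 * depth)

        states.append(SampleState(
            tubes=[Tube(points=tb.points.copy(), width=tb.width,
                        constriction_at=tb.constriction_at,
                        constriction_factor=tb.constriction_factor,
                        tmre_dark_span=tb.tmre_dark_span)
                   for tb in tubes],
            spheres=[Sphere(center=sp.center.copy(), radius=sp.radius, kind=sp.kind)
                     for sp in spheres],
            ruffles=[Tube(points=r.points.copy(), width=r.width,
                          constriction_at=r.constriction_at,
                          constriction_factor=r.constriction_factor)
                     for r in ruffles],
            drp1_puncta=list(drp1_puncta),
            contact_marks=contact_marks,
        ))
        # constriction factors persist only while scripted
        for tube in tubes:
            tube.constriction_at = None
            tube.constriction_factor = 1.0

    for script in contacts + divisions:
        ev = script.event
        if script.realized_xy is None:
            continue
        x = float(np.clip(script.realized_xy[0], 0, cfg.width - 1))
        y = float(np.clip(script.realized_xy[1], 0, cfg.height - 1))
        realized.append(EventRecord(ev.event_class, ev.t_start, ev.t_end,
                                    x, y, "positive"))
    realized.sort(key=lambda e: (e.t_start, e.t_end, e.event_class))

    sample = CellSample(states=states, frame_rate=cfg.frame_rate,
                        pixel_size=cfg.pixel_size)
    return sample, realized


def sample_negative_events(config: SimConfig, events, states, n: int, seed: int):
    """Draw negative (non-event) records at event-free times/places and at
    ruffles, for balanced training sets."""
    rng = np.random.default_rng([seed, 4])
    cfg = config
    out = []
    span = max(1, int(round(cfg.contact_duration * cfg.frame_rate)))
    n_frames = len(states)
    attempts = 0
    while len(out) < n and attempts < 50 * n:
        attempts += 1
        t0 = int(rng.integers(0, max(1, n_frames - span)))
        t1 = t0 + span - 1
        if rng.uniform() < 0.4 and states[t0].ruffles:
            ruf = states[t0].ruffles[int(rng.integers(len(states[t0].ruffles)))]
            p = ruf.points[int(rng.integers(len(ruf.points)))]
            x, y = float(p[0]), float(p[1])
        else:
            x = float(rng.uniform(5, cfg.width - 6))
            y = float(rng.uniform(5, cfg.height - 6))
        clash = any(
            ev.polarity == "positive"
            and not (t1 < ev.t_start - 2 or t0 > ev.t_end + 2)
            and np.hypot(ev.x - x, ev.y - y) < 16
            for ev in events
        )
        if clash:
            continue
        out.append(EventRecord("contact", t0, t1, x, y, "negative"))
    return out
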