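"""Detection evaluation: peak extraction, matching, and F-beta scoring.

The F_beta score (beta = 0.1 by default) deliberately prioritizes precision
over recall: a false positive costs a needless fluorescence burst, while the
phase surveillance that covers a false negative is nearly free.
"""

from __future__ import annotations

from dataclasses import dataclass, field

import numpy as np
from skimage.feature import peak_local_max

DEFAULT_BETA = 0.1
DEFAULT_DIST_TOL = 10.0     # px
DEFAULT_TIME_TOL = 2        # frames
DEFAULT_MIN_DISTANCE = 8    # px, non-maximum suppression radius
DEFAULT_GRID = np.round(np.arange(0.01, 1.00, 0.01), 2)


@dataclass(frozen=True)
class Detection:
    t: int
    x: float
    y: float
    score: float


@dataclass
class MatchResult:
    true_positives: list = field(default_factory=list)   # matched detections
    false_positives: list = field(default_factory=list)  # unmatched detections
    false_negatives: list = field(default_factory=list)  # undetected events
    detected_events: list = field(default_factory=list)  # events with >= 1 match
    dist_tol: float = DEFAULT_DIST_TOL
    time_tol: int = DEFAULT_TIME_TOL

    @property
    def precision(self) -> float:
        n_pred = len(self.true_positives) + len(self.false_positives)
        if n_pred == 0:
            # no predictions: perfect if there was nothing to find
            return 1.0 if not self.false_negatives else 0.0
        return len(self.true_positives) / n_pred

    @property
    def recall(self) -> float:
        n_pos = len(self.detected_events) + len(self.false_negatives)
        if n_pos == 0:
            return 1.0
        return len(self.detected_events) / n_pos


@dataclass(frozen=True)
class EvalScores:
    precision: float
    recall: float
    f_beta: float
    beta: float = DEFAULT_BETA
    threshold: float = 0.5


def fbeta(precision: float, recall: float, beta: float = DEFAULT_BETA) -> float:
    """F_beta = (1 + beta^2) P R / (beta^2 P + R); 0 when P = R = 0."""
    if not (0 <= precision <= 1 and 0 <= recall <= 1):
        raise ValueError("precision and recall must lie in [0, 1]")
    denom = beta ** 2 * precision + recall
    if denom == 0:
        return 0.0
    return (1 + beta ** 2) * precision * recall / denom


def extract_peaks(score_map: np.ndarray, threshold: float,
                  min_distance: int = DEFAULT_MIN_DISTANCE,
                  t: int = 0) -> list:
    """Local maxima >= threshold, non-maximum suppressed within min_distance.

    Ties are broken by (score desc, y asc, x asc).
    """
    if not (0 < threshold < 1):
        raise ValueError("threshold must lie in (0, 1)")
    score_map = np.asarray(score_map, float)
    coords = peak_local_max(score_map, min_distance=int(min_distance),
                            threshold_abs=threshold, exclude_border=False)
    dets = [Detection(t=t, x=float(c), y=float(r), score=float(score_map[r, c]))
            for r, c in coords]
    dets.sort(key=lambda d: (-d.score, d.y, d.x))
    return dets


def extract_detections(score_maps, threshold: float,
                       min_distance: int = DEFAULT_MIN_DISTANCE) -> list:
    """Peaks from a per-frame sequence of score maps."""
    out = []
    for t, sm in enumerate(score_maps):
        out.extend(extract_peaks(sm, threshold, min_distance, t=t))
    return out


def _labeled_span(event):
    from edamic.detector.labels import labeled_frames
    return labeled_frames(event)


def match_events(detections, events, dist_tol: float = DEFAULT_DIST_TOL,
                 time_tol: int = DEFAULT_TIME_TOL,
                 span: str = "labeled") -> MatchResult:
    """Greedy one-to-one matching in ascending spatio-temporal distance.

    A detection matches a positive event when its spatial distance to the
    event center is <= dist_tol and its frame is within time_tol of the
    nearest labeled frame of the event. With ``span="active"`` the whole
    [t_start, t_end] span is matchable instead of just the labeled frames —
    appropriate for events whose appearance persists over their span.
    """
    if dist_tol < 0 or time_tol < 0:
        raise ValueError("tolerances must be >= 0")
    if span not in ("labeled", "active"):
        raise ValueError("span must be 'labeled' or 'active'")
    from scipy.optimize import linear_sum_assignment

    positives = [e for e in events if e.polarity == "positive"]
    # one matchable slot per (event, matchable frame): an event that fires on
    # several of its labeled frames absorbs one detection per frame, so a
    # perfect detector produces no duplicate false positives
    slots = []
    for ei, ev in enumerate(positives):
        frames_ = (_labeled_span(ev) if span == "labeled"
                   else range(ev.t_start, ev.t_end + 1))
        slots.extend((ei, tf) for tf in frames_)
    big = 1e9
    matched_d: dict = {}
    if detections and slots:
        cost = np.full((len(detections), len(slots)), big)
        for di, det in enumerate(detections):
            for si, (ei, tf) in enumerate(slots):
                if abs(det.t - tf) > time_tol:
                    continue
                d = float(np.hypot(det.x - positives[ei].x,
                                   det.y - positives[ei].y))
                if d <= dist_tol:
                    # small time penalty prefers the nearest frame slot
                    cost[di, si] = d + 1e-3 * abs(det.t - tf)
        rows, cols = linear_sum_assignment(cost)
        for r, c in zip(rows, cols):
            if cost[r, c] < big:
                matched_d[r] = slots[c][0]
    tp = [detections[i] for i in sorted(matched_d)]
    fp = [det for i, det in enumerate(detections) if i not in matched_d]
    hit_events = set(matched_d.values())
    detected = [positives[i] for i in sorted(hit_events)]
    fn = [ev for i, ev in enumerate(positives) if i not in hit_events]
    return MatchResult(true_positives=tp, false_positives=fp,
                       false_negatives=fn, detected_events=detected,
                       dist_tol=dist_tol, time_tol=time_tol)


def evaluate_at_threshold(score_maps, events, threshold: float,
                          beta: float = DEFAULT_BETA,
                          dist_tol: float = DEFAULT_DIST_TOL,
                          time_tol: int = DEFAULT_TIME_TOL,
                          min_distance: int = DEFAULT_MIN_DISTANCE,
                          span: str = "labeled") -> EvalScores:
    dets = extract_detections(score_maps, threshold, min_distance)
    m = match_events(dets, events, dist_tol, time_tol, span=span)
    p, r = m.precision, m.recall
    return EvalScores(precision=p, recall=r, f_beta=fbeta(p, r, beta),
                      beta=beta, threshold=threshold)


def optimize_threshold(score_maps, events, beta: float = DEFAULT_BETA,
                       grid=None, dist_tol: float = DEFAULT_DIST_TOL,
                       time_tol: int = DEFAULT_TIME_TOL,
                       min_distance: int = DEFAULT_MIN_DISTANCE,
                       span: str = "labeled"):
    """Pick the grid threshold maximizing F_beta; ties go to the lowest.

    Returns (threshold, EvalScores at that threshold). Raises if the event
    set contains no positives (F undefined for selection).
    """
    if grid is None:
        grid = DEFAULT_GRID
    if not any(e.polarity == "positive" for e in events):
        raise ValueError("threshold optimization needs >= 1 positive event")
    # extract once at the lowest threshold; filtering by score is exactly
    # equivalent to re-running NMS at each higher threshold (a suppressing
    # peak always scores at least as high as the peak it suppresses)
    base = extract_detections(score_maps, float(min(grid)), min_distance)
    best = None
    for thr in grid:
        dets = [d for d in base if d.score >= thr]
        m = match_events(dets, events, dist_tol, time_tol, span=span)
        p, r = m.precision, m.recall
        s = EvalScores(precision=p, recall=r, f_beta=fbeta(p, r, beta),
                       beta=beta, threshold=float(thr))
        if best is None or s.f_beta > best.f_beta + 1e-12:
            best = s
    return best.threshold, best


def select_best_model(runs):
    """argmax validation F_beta over (model, EvalScores) runs; ties keep the
    earliest run."""
    runs = list(runs)
    if not runs:
        raise ValueError("select_best_model needs >= 1 run")
    best_i = 0
    for i, (_, s) in enumerate(runs):
        if s.f_beta > runs[best_i][1].f_beta + 1e-12:
            best_i = i
    return runs[best_i][0]
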