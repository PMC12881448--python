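"""Multi-step label refinement: the consistency filter.

A first-pass detector (trained on ad hoc labels) scores every labeled frame
of each candidate event; a candidate is retained only if its per-frame peak
scores are consistently high — by default, mean peak score above 0.36.
"""

from __future__ import annotations

import numpy as np

from edamic.detector.labels import labeled_frames

CONSISTENCY_THRESHOLD = 0.36


def peak_score_near(score_map: np.ndarray, x: float, y: float,
                    radius: float) -> float:
    """Maximum score within ``radius`` px of (x, y)."""
    h, w = score_map.shape
    yy, xx = np.mgrid[0:h, 0:w]
    mask = (xx - x) ** 2 + (yy - y) ** 2 <= radius ** 2
    if not mask.any():
        return 0.0
    return float(score_map[mask].max())


def refine_labels(candidate_events, detector, frames,
                  consistency_threshold: float = CONSISTENCY_THRESHOLD,
                  match_radius: float = 10.0, reduce: str = "mean",
                  score_maps=None) -> list:
    """Return the candidates that pass the consistency filter.

    ``frames`` is the movie the candidates live in; ``score_maps`` may be
    passed to reuse precomputed per-frame maps. ``reduce`` is "mean"
    (default) or "min" over the per-frame peak scores.
    """
    if reduce not in ("mean", "min"):
        raise ValueError("reduce must be 'mean' or 'min'")
    if score_maps is None:
        score_maps = detector.infer_sequence(np.asarray(frames, float))
    reducer = np.mean if reduce == "mean" else np.min
    retained = []
    for ev in candidate_events:
        ts = [t for t in labeled_frames(ev) if 0 <= t < len(score_maps)]
        if not ts:
            raise ValueError(f"event {ev} has no labeled frames in the movie")
        peaks = [peak_score_near(score_maps[t], ev.x, ev.y, match_radius)
                 for t in ts]
        if reducer(peaks) > consistency_threshold:
            retained.append(ev)
    return retained
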