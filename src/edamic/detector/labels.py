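"""Gaussian heatmap training labels.

The last five frames of each positive event carry a unit-peak Gaussian spot
at the event site; overlapping spots combine by pixelwise maximum. Negative
or event-free frames are all-zero.
"""

from __future__ import annotations

from dataclasses import dataclass

import numpy as np

LABELED_FRAMES = 5  # the last five frames of a positive event are labeled


@dataclass
class HeatmapLabel:
    map: np.ndarray
    sigma_label: float

    def __post_init__(self) -> None:
        self.map = np.asarray(self.map, dtype=float)
        if self.map.min() < 0 or self.map.max() > 1:
            raise ValueError("label values must lie in [0, 1]")


def labeled_frames(event) -> range:
    """Frame indices of an event that receive a Gaussian label."""
    return range(max(event.t_start, event.t_end - LABELED_FRAMES + 1),
                 event.t_end + 1)


def render_labels(events, t: int, shape, sigma_label: float = 4.0) -> HeatmapLabel:
    """Render the heatmap label for frame ``t``.

    Only positive events whose labeled span (the last five frames, clipped to
    the event) covers ``t`` contribute; spots combine by maximum.
    """
    h, w = shape
    out = np.zeros(shape, dtype=float)
    yy, xx = np.mgrid[0:h, 0:w]
    for ev in events:
        if ev.polarity != "positive":
            continue
        if not (ev.x >= 0 and ev.x <= w - 1 and ev.y >= 0 and ev.y <= h - 1):
            raise ValueError(f"event center ({ev.x}, {ev.y}) outside shape {shape}")
        if t not in labeled_frames(ev):
            continue
        spot = np.exp(-((xx - ev.x) ** 2 + (yy - ev.y) ** 2)
                      / (2.0 * sigma_label ** 2))
        np.maximum(out, spot, out=out)
    return HeatmapLabel(map=np.clip(out, 0.0, 1.0), sigma_label=sigma_label)
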