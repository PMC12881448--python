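"""DRP1 partitioning after division: 3x3 daughter-tip intensity ratios."""

from __future__ import annotations

import warnings
from dataclasses import dataclass

import numpy as np

DEFAULT_CAMERA_OFFSET = 100.0
ROI_HALF = 1  # 3x3 regions of interest


@dataclass(frozen=True)
class TipPair:
    """Two 3x3 ROIs centered on the daughter-mitochondrion tips."""

    tip_a: tuple      # (x, y), integer pixel center
    tip_b: tuple
    camera_offset: float = DEFAULT_CAMERA_OFFSET

    def __post_init__(self) -> None:
        ax, ay = self.tip_a
        bx, by = self.tip_b
        if max(abs(ax - bx), abs(ay - by)) < 2 * ROI_HALF + 1:
            raise ValueError("tip ROIs must not overlap")


def _roi_sum(frame: np.ndarray, center) -> float:
    x, y = int(round(center[0])), int(round(center[1]))
    h, w = frame.shape
    if not (ROI_HALF <= x < w - ROI_HALF and ROI_HALF <= y < h - ROI_HALF):
        raise ValueError(f"ROI at ({x}, {y}) outside image")
    return float(frame[y - ROI_HALF:y + ROI_HALF + 1,
                       x - ROI_HALF:x + ROI_HALF + 1].sum())


def drp1_tip_ratio(fluo_frame: np.ndarray, tips: TipPair) -> float:
    """Higher-to-lower ratio of offset-corrected integrated tip intensities.

    Each 3x3 integrated intensity has 9x the camera offset subtracted and is
    floored at 0. A zero lower intensity yields inf (with a warning).
    """
    frame = np.asarray(fluo_frame, float)
    n_px = (2 * ROI_HALF + 1) ** 2
    a = max(_roi_sum(frame, tips.tip_a) - n_px * tips.camera_offset, 0.0)
    b = max(_roi_sum(frame, tips.tip_b) - n_px * tips.camera_offset, 0.0)
    hi, lo = max(a, b), min(a, b)
    if lo == 0:
        warnings.warn("lower tip intensity is zero; ratio is infinite")
        return float("inf")
    return hi / lo
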