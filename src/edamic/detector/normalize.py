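"""Input normalization: robust per-frame percentile scaling."""

from __future__ import annotations

import numpy as np


def percentile_normalize(frame: np.ndarray, lo: float = 1.0,
                         hi: float = 99.0) -> np.ndarray:
    """Map the lo-th percentile to 0 and the hi-th to 1, clipping to [0, 1].

    Robust to the bright halo outliers of phase-contrast frames. Constant
    frames map to all-zero.
    """
    frame = np.asarray(frame, float)
    p_lo, p_hi = np.percentile(frame, [lo, hi])
    if p_hi <= p_lo:
        return np.zeros_like(frame)
    return np.clip((frame - p_lo) / (p_hi - p_lo), 0.0, 1.0)


def normalize_stack(frames: np.ndarray) -> np.ndarray:
    return np.stack([percentile_normalize(f) for f in frames])
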