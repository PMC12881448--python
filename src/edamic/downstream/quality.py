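"""Image-quality metrics from marked organelle and background regions."""

from __future__ import annotations

from dataclasses import dataclass

import numpy as np


@dataclass(frozen=True)
class QualityMetrics:
    snr: float
    intensity_ratio: float
    contrast: float


def image_quality(mito_region, background_region) -> QualityMetrics:
    """SNR, intensity ratio, and Michelson-style contrast.

    ``snr`` is the mean signal in the organelle region divided by the
    standard deviation of the background region. Inputs are the pixel
    intensities of the two (disjoint) regions.
    """
    mito = np.asarray(mito_region, float).ravel()
    bg = np.asarray(background_region, float).ravel()
    if mito.size == 0 or bg.size == 0:
        raise ValueError("regions must be non-empty")
    bg_sd = float(bg.std())
    if bg_sd == 0:
        raise ValueError("zero-variance background region")
    m, b = float(mito.mean()), float(bg.mean())
    return QualityMetrics(
        snr=m / bg_sd,
        intensity_ratio=m / b if b != 0 else float("inf"),
        contrast=(m - b) / (m + b) if (m + b) != 0 else 0.0,
    )
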