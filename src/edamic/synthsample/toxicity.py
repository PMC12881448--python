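"""Cohort-level phototoxicity model for survival experiments.

Cells under continuous imaging at a fixed frame rate die with a per-frame
probability ``1 - exp(-hazard * dose_per_frame)``; phase-contrast delivers a
fixed small fraction of the fluorescence dose and the dark condition none.
The cohort can also render Hoechst/SYTOX nucleus frames (SYTOX enters the
nucleus at death) for testing the death-scoring pipeline.
"""

from __future__ import annotations

import numpy as np
from scipy.ndimage import gaussian_filter

from edamic.synthsample.exposure import DEFAULT_HAZARD, DEFAULT_PHASE_FACTOR

CONDITIONS = ("fluorescence", "phase", "dark")


class ToxicityCohort:
    """A cohort of cells imaged continuously under one condition."""

    def __init__(self, n_cells: int, condition: str, *,
                 duration: float = 3600.0, frame_rate: float = 1.0,
                 exposure_time: float = 100.0, irradiance: float = 35.0,
                 hazard_coeff: float = DEFAULT_HAZARD,
                 phase_dose_factor: float = DEFAULT_PHASE_FACTOR,
                 seed: int = 0):
        if condition not in CONDITIONS:
            raise ValueError(f"unknown condition {condition!r}")
        if n_cells < 1:
            raise ValueError("n_cells must be >= 1")
        self.n_cells = n_cells
        self.condition = condition
        self.duration = duration
        self.frame_rate = frame_rate
        self.exposure_time = exposure_time
        self.irradiance = irradiance
        self.hazard_coeff = hazard_coeff
        self.phase_dose_factor = phase_dose_factor
        self.seed = seed

    @property
    def dose_per_frame(self) -> float:
        base = self.irradiance * self.exposure_time
        if self.condition == "fluorescence":
            return base * (1.0 + self.phase_dose_factor)
        if self.condition == "phase":
            return base * self.phase_dose_factor
        return 0.0

    @property
    def per_frame_death_prob(self) -> float:
        return 1.0 - np.exp(-self.hazard_coeff * self.dose_per_frame)

    def death_times(self) -> np.ndarray:
        """Per-cell death time in seconds; inf for cells alive at the end."""
        p = self.per_frame_death_prob
        if p <= 0:
            return np.full(self.n_cells, np.inf)
        rng = np.random.default_rng([self.seed, 6])
        frames = rng.geometric(p, self.n_cells).astype(float)
        times = frames / self.frame_rate
        times[times > self.duration] = np.inf
        return times

    # --- nucleus rendering for the SYTOX/Hoechst scoring pipeline ---

    def nucleus_layout(self, shape=(256, 256), radius: float = 9.0):
        """Jittered-grid nucleus centers (x, y) for up to n_cells nuclei."""
        rng = np.random.default_rng([self.seed, 7])
        h, w = shape
        side = int(np.ceil(np.sqrt(self.n_cells)))
        pitch_x, pitch_y = w / side, h / side
        if min(pitch_x, pitch_y) < 2.5 * radius:
            raise ValueError("too many nuclei for the field")
        centers = []
        for i in range(self.n_cells):
            gx, gy = i % side, i // side
            cx = (gx + 0.5) * pitch_x + rng.uniform(-2, 2)
            cy = (gy + 0.5) * pitch_y + rng.uniform(-2, 2)
            centers.append((cx, cy))
        return np.asarray(centers), radius

    def render_nucleus_frames(self, sample_times, shape=(256, 256),
                              radius: float = 9.0, noise_sd: float = 0.01):
        """Render (hoechst, sytox) stacks at the given times (seconds).

        Hoechst marks every nucleus throughout; SYTOX fills a nucleus from
        its death time onward.
        """
        centers, radius = self.nucleus_layout(shape, radius)
        deaths = self.death_times()
        rng = np.random.default_rng([self.seed, 8])
        yy, xx = np.mgrid[0:shape[0], 0:shape[1]]
        masks = [((xx - cx) ** 2 + (yy - cy) ** 2) <= radius ** 2
                 for cx, cy in centers]
        hoechst, sytox = [], []
        for t_s in sample_times:
            h_img = np.zeros(shape)
            s_img = np.zeros(shape)
            for mask, dt in zip(masks, deaths):
                h_img[mask] = 1.0
                if t_s >= dt:
                    s_img[mask] = 1.0
            h_img = gaussian_filter(h_img, 1.0) + rng.normal(0, noise_sd, shape)
            s_img = gaussian_filter(s_img, 1.0) + rng.normal(0, noise_sd, shape)
            hoechst.append(np.clip(h_img, 0, None))
            sytox.append(np.clip(s_img, 0, None))
        return np.asarray(hoechst), np.asarray(sytox)
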