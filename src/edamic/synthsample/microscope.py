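"""The virtual microscope: the acquisition interface the controller drives."""

from __future__ import annotations

import numpy as np

from edamic.synthsample.config import SimConfig
from edamic.synthsample.exposure import apply_exposure
from edamic.synthsample.render import render_phase_frame, render_fluorescence_frame
from edamic.synthsample.types import CHANNELS, CellSample, ExposureSpec


class EndOfAcquisition(Exception):
    """Raised when a frame is requested past the end of the trajectory."""


class VirtualMicroscope:
    """Renders requested channels at a time point and books the light dose.

    Each :meth:`acquire` call applies exactly one exposure to the sample.
    Noise and death randomness are keyed on ``(seed, t, channel)`` so that
    the acquisition order never changes what a given frame looks like.
    """

    def __init__(self, sample: CellSample, config: SimConfig):
        self.sample = sample
        self.config = config

    @property
    def n_frames(self) -> int:
        return self.sample.n_frames

    def _noise_rng(self, t: int, channel: str):
        return np.random.default_rng(
            [self.config.seed, 3, t, CHANNELS.index(channel)])

    def acquire(self, t: int, spec: ExposureSpec) -> dict:
        """Acquire the channels in ``spec`` at frame index ``t``.

        Returns ``{channel: 2D frame}``; mutates the sample (dose, death,
        bleaching). Raises :class:`EndOfAcquisition` past the trajectory end.
        """
        if t < 0:
            raise ValueError("negative frame index")
        if t >= self.n_frames:
            raise EndOfAcquisition(t)
        state = self.sample.states[t]
        cfg = self.config
        frames = {}
        for channel in spec.channels:
            rng = self._noise_rng(t, channel)
            if channel == "phase":
                frames[channel] = render_phase_frame(state, cfg, rng=rng)
            else:
                pool = self.sample.fluorophore_pool[channel]
                frames[channel] = render_fluorescence_frame(
                    state, channel, cfg, rng=rng, pool=pool)
        apply_exposure(
            self.sample, spec,
            hazard_coeff=cfg.hazard_coeff,
            bleach_rate=cfg.bleach_rate,
            phase_dose_factor=cfg.phase_dose_factor,
            rng=np.random.default_rng([cfg.seed, 5, t]),
        )
        return frames
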