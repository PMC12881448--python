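"""Light-dose accounting: phototoxic hazard and photobleaching.

Dose is measured in irradiance x exposure-time units (mW*ms/mm^2). Each
fluorescence channel contributes a full dose increment; phase-contrast
contributes a fixed small fraction of one (default 1/500), which is what
makes the >= 100-fold phase/fluorescence excess-mortality contrast emerge
at the defaults.
"""

from __future__ import annotations

import numpy as np

from edamic.synthsample.types import CellSample, ExposureSpec

DEFAULT_HAZARD = 6.6e-7
DEFAULT_BLEACH = 0.002
DEFAULT_PHASE_FACTOR = 1.0 / 500.0


def dose_increment(spec: ExposureSpec,
                   phase_dose_factor: float = DEFAULT_PHASE_FACTOR) -> float:
    """Dose delivered by one exposure."""
    per_channel = spec.irradiance * spec.exposure_time
    n_fluo = len(spec.fluo_channels)
    return per_channel * (n_fluo + phase_dose_factor)


def apply_exposure(sample: CellSample, spec: ExposureSpec, *,
                   hazard_coeff: float = DEFAULT_HAZARD,
                   bleach_rate: float = DEFAULT_BLEACH,
                   phase_dose_factor: float = DEFAULT_PHASE_FACTOR,
                   rng=None) -> CellSample:
    """Apply one exposure to the sample (mutating it).

    The per-exposure death probability is ``1 - exp(-hazard * dose)``; dose
    keeps accumulating after death. Every fluorescence exposure bleaches
    that channel's fluorophore pool by ``bleach_rate``.
    """
    if spec.exposure_time < 0 or spec.irradiance < 0:
        raise ValueError("exposure and irradiance must be >= 0")
    if rng is None:
        rng = np.random.default_rng()
    dose = dose_increment(spec, phase_dose_factor)
    sample.add_dose(dose)
    if sample.alive and hazard_coeff > 0:
        p_death = 1.0 - np.exp(-hazard_coeff * dose)
        if rng.uniform() < p_death:
            sample.kill()
    for c in spec.fluo_channels:
        sample.fluorophore_pool[c] *= (1.0 - bleach_rate)
    return sample


def surveillance_spec(exposure_time: float = 100.0,
                      irradiance: float = 35.0) -> ExposureSpec:
    return ExposureSpec("surveillance", ("phase",), exposure_time, irradiance)


def correlative_spec(channels, exposure_time: float = 100.0,
                     irradiance: float = 35.0) -> ExposureSpec:
    chans = ("phase",) + tuple(c for c in channels if c != "phase")
    return ExposureSpec("correlative", chans, exposure_time, irradiance)
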