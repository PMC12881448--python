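"""Frame rendering: phase-contrast and fluorescence channels.

Phase rendering is deliberately phenomenological: organelle interiors absorb
(darker than background), boundaries carry a bright halo ring, and the image
is blurred by a Gaussian PSF with additive read noise. Non-goal: rigorous
Zernike-ring optics.
"""

from __future__ import annotations

import numpy as np
from scipy.ndimage import gaussian_filter, binary_dilation
from skimage.morphology import disk as disk_footprint

from edamic.synthsample.config import SimConfig
from edamic.synthsample.types import SampleState, Tube, FLUO_CHANNELS

PHASE_BACKGROUND = 1.0
FLUO_FLOOR = 0.02
DRP1_SIGMA = 1.5


def _resample_polyline(points: np.ndarray, spacing: float = 0.5):
    """Evenly resample a polyline; returns (samples (n,2), arc fractions)."""
    points = np.asarray(points, float)
    seg = np.diff(points, axis=0)
    seglen = np.hypot(seg[:, 0], seg[:, 1])
    total = float(seglen.sum())
    if total <= 0:
        return points[:1], np.zeros(1)
    n = max(2, int(total / spacing) + 1)
    s = np.linspace(0.0, total, n)
    cum = np.concatenate([[0.0], np.cumsum(seglen)])
    x = np.interp(s, cum, points[:, 0])
    y = np.interp(s, cum, points[:, 1])
    return np.c_[x, y], s / total


def _stamp_disks(mask: np.ndarray, samples: np.ndarray, radii: np.ndarray) -> None:
    """Union of disks at `samples` with per-sample `radii` (floored at 0.8 px
    so thin structures stay connected), vectorized over the bounding box."""
    h, w = mask.shape
    if len(samples) == 0:
        return
    radii = np.maximum(np.asarray(radii, float), 0.8)
    x, y = samples[:, 0], samples[:, 1]
    x0 = max(0, int(np.floor((x - radii).min())))
    x1 = min(w, int(np.ceil((x + radii).max())) + 1)
    y0 = max(0, int(np.floor((y - radii).min())))
    y1 = min(h, int(np.ceil((y + radii).max())) + 1)
    if x0 >= x1 or y0 >= y1:
        return
    yy, xx = np.mgrid[y0:y1, x0:x1]
    hit = np.zeros(yy.shape, dtype=bool)
    for c0 in range(0, len(samples), 64):  # chunk to bound memory
        xs, ys = x[c0:c0 + 64], y[c0:c0 + 64]
        r2 = radii[c0:c0 + 64] ** 2
        d2 = ((xx[..., None] - xs) ** 2 + (yy[..., None] - ys) ** 2)
        hit |= (d2 <= r2).any(axis=-1)
    mask[y0:y1, x0:x1] |= hit


def _tube_radii(tube: Tube, samples: np.ndarray, fracs: np.ndarray) -> np.ndarray:
    radii = np.full(len(samples), tube.width)
    if tube.constriction_at is not None and tube.constriction_factor < 1.0:
        site = tube.points[tube.constriction_at]
        d = np.linalg.norm(samples - site[None, :], axis=1)
        narrowing = 1.0 - (1.0 - tube.constriction_factor) * np.exp(-(d / 4.0) ** 2)
        radii = radii * narrowing
    return radii


def rasterize_tube(shape, tube: Tube, tmre_mask: bool = False) -> np.ndarray:
    """Boolean mask of one tube. With ``tmre_mask=True`` the tube's dark
    flicker span (if any) is excluded."""
    mask = np.zeros(shape, dtype=bool)
    samples, fracs = _resample_polyline(tube.points)
    radii = _tube_radii(tube, samples, fracs)
    if tmre_mask and tube.tmre_dark_span is not None:
        lo, hi, _ = tube.tmre_dark_span
        keep = (fracs < lo) | (fracs > hi)
        samples, radii = samples[keep], radii[keep]
    _stamp_disks(mask, samples, radii)
    return mask


def _sphere_mask(shape, sphere) -> np.ndarray:
    mask = np.zeros(shape, dtype=bool)
    _stamp_disks(mask, np.asarray([sphere.center]), np.asarray([sphere.radius]))
    return mask


def _ruffle_mask(shape, ruffle) -> np.ndarray:
    # ruffles rasterize exactly like tubes (including any pinch) so they are
    # morphologically confusable with constricted mitochondria
    return rasterize_tube(shape, ruffle)


def _finish(img: np.ndarray, cfg: SimConfig, rng) -> np.ndarray:
    img = gaussian_filter(img, cfg.psf_sigma)
    if cfg.poisson_noise:
        img = rng.poisson(np.clip(img, 0, None) * 200.0) / 200.0
    if cfg.noise_sd > 0:
        img = img + rng.normal(0.0, cfg.noise_sd, img.shape)
    return np.clip(img, 0.0, None)


def _default_rng(cfg: SimConfig):
    return np.random.default_rng([cfg.seed, 2])


def render_phase_frame(state: SampleState, config: SimConfig, rng=None) -> np.ndarray:
    """Render one phase-contrast frame from a sample state."""
    cfg = config
    shape = (cfg.height, cfg.width)
    if rng is None:
        rng = _default_rng(cfg)
    organelles = np.zeros(shape, dtype=bool)
    for tube in state.tubes:
        organelles |= rasterize_tube(shape, tube)
    for sph in state.spheres:
        organelles |= _sphere_mask(shape, sph)
    faint = np.zeros(shape, dtype=bool)
    for ruf in state.ruffles:
        faint |= _ruffle_mask(shape, ruf)

    img = np.full(shape, PHASE_BACKGROUND)
    img -= cfg.absorption * organelles
    img -= 0.85 * cfg.absorption * (faint & ~organelles)
    # membrane deformation at an active contact reads as extra local optical
    # density: a dark interface blob where sphere and tube press together
    if state.contact_marks:
        marks = np.zeros(shape, dtype=bool)
        pts = np.asarray(state.contact_marks, float)
        _stamp_disks(marks, pts, np.full(len(pts), 2.2))
        img -= 0.5 * cfg.absorption * marks
    if cfg.halo_gain > 0:
        footprint = disk_footprint(max(1, int(round(cfg.psf_sigma))))
        every = organelles | faint
        ring = binary_dilation(every, footprint) & ~every
        img += cfg.halo_gain * cfg.absorption * ring
    return _finish(img, cfg, rng)


def render_fluorescence_frame(state: SampleState, channel: str,
                              config: SimConfig, rng=None,
                              pool: float = 1.0) -> np.ndarray:
    """Render one fluorescence frame.

    Structure depends on the channel: mitochondrial markers fill tubes,
    droplet/lysosome markers fill their spheres, DRP1 renders puncta at
    division sites (both daughter tips after scission), and TMRE fills tubes
    minus transient flicker subdomains. Intensity scales with the remaining
    fluorophore ``pool``.
    """
    cfg = config
    if channel not in FLUO_CHANNELS:
        raise ValueError(f"unknown fluorescence channel {channel!r}")
    shape = (cfg.height, cfg.width)
    if rng is None:
        rng = _default_rng(cfg)
    structure = np.zeros(shape)
    if channel == "mito_fluo":
        for tube in state.tubes:
            structure[rasterize_tube(shape, tube)] = 1.0
    elif channel == "tmre":
        for tube in state.tubes:
            structure[rasterize_tube(shape, tube, tmre_mask=True)] = 1.0
    elif channel in ("ld_fluo", "lyso_fluo"):
        kind = "ld" if channel == "ld_fluo" else "lyso"
        for sph in state.spheres:
            if sph.kind == kind:
                structure[_sphere_mask(shape, sph)] = 1.0
    elif channel == "drp1_fluo":
        yy, xx = np.mgrid[0:cfg.height, 0:cfg.width]
        for (x, y, amp) in state.drp1_puncta:
            structure += amp * np.exp(
                -((xx - x) ** 2 + (yy - y) ** 2) / (2 * DRP1_SIGMA ** 2))
    # sytox / hoechst carry no structure in the organelle sample model;
    # nuclei live in the ToxicityCohort
    img = FLUO_FLOOR + pool * structure
    return _finish(img, cfg, rng)
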