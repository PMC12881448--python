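"""Cell-death scoring and survival-curve analysis.

Death onset is scored from SYTOX entry into Hoechst-segmented nuclei: both
channels are normalized on a local region twice the nucleus size and a
normalized-intensity ratio of 0.5 marks death. Survival curves are averaged
across replicates and fitted with an exponential decay.
"""

from __future__ import annotations

import warnings
from dataclasses import dataclass, field

import numpy as np
import pandas as pd
from scipy.ndimage import binary_fill_holes
from scipy.optimize import curve_fit
from skimage.filters import threshold_otsu
from skimage.measure import label, regionprops

DEATH_RATIO_CUTOFF = 0.5
MIN_NUCLEUS_AREA = 50  # px


@dataclass
class SurvivalTable:
    """Per-cell death/censoring records.

    Columns: cell_id, condition, replicate, time (s), dead (bool). ``time``
    is the death time for dead cells and the censoring time otherwise.
    """

    data: pd.DataFrame = field(default_factory=lambda: pd.DataFrame(
        columns=["cell_id", "condition", "replicate", "time", "dead"]))

    def __post_init__(self) -> None:
        required = {"cell_id", "condition", "replicate", "time", "dead"}
        if not required.issubset(self.data.columns):
            raise ValueError(f"SurvivalTable needs columns {sorted(required)}")
        if (self.data["time"] < 0).any():
            raise ValueError("times must be >= 0")
        if self.data["cell_id"].duplicated().any():
            raise ValueError("each cell appears once")

    @classmethod
    def from_records(cls, records) -> "SurvivalTable":
        return cls(pd.DataFrame.from_records(
            records, columns=["cell_id", "condition", "replicate", "time", "dead"]))

    @classmethod
    def from_death_times(cls, death_times, condition: str, duration: float,
                         replicate: int = 0, id_offset: int = 0) -> "SurvivalTable":
        """Build from per-cell death times (inf = survived to `duration`)."""
        rows = []
        for i, dt in enumerate(np.asarray(death_times, float)):
            dead = np.isfinite(dt) and dt <= duration
            rows.append((id_offset + i, condition, replicate,
                         float(dt) if dead else float(duration), bool(dead)))
        return cls.from_records(rows)

    def concat(self, other: "SurvivalTable") -> "SurvivalTable":
        return SurvivalTable(pd.concat([self.data, other.data],
                                       ignore_index=True))


def survival_curve(table: SurvivalTable, time_grid):
    """Fraction of cells alive at each grid time, mean +- SD over replicates.

    Returns (mean, sd) arrays over ``time_grid``. A censored cell counts as
    alive through its censoring time.
    """
    time_grid = np.asarray(time_grid, float)
    reps = sorted(table.data["replicate"].unique())
    if not reps:
        raise ValueError("empty survival table")
    curves = []
    for rep in reps:
        sub = table.data[table.data["replicate"] == rep]
        death = np.where(sub["dead"], sub["time"], np.inf)
        alive = (death[None, :] > time_grid[:, None]).mean(axis=1)
        curves.append(alive)
    curves = np.asarray(curves)
    return curves.mean(axis=0), curves.std(axis=0)


@dataclass(frozen=True)
class DecayFit:
    rate: float          # k, 1/s
    half_life: float     # ln 2 / k, s
    condition: str = ""
    goodness: float = 0.0  # residual sd
    clipped: bool = False

    def survival_at(self, t: float) -> float:
        return float(np.exp(-self.rate * t))


def fit_decay(time_grid, curve, condition: str = "") -> DecayFit:
    """Least-squares fit of S(t) = exp(-k t) to a survival curve."""
    t = np.asarray(time_grid, float)
    y = np.asarray(curve, float)
    if np.any((y < 0) | (y > 1)):
        raise ValueError("survival values must lie in [0, 1]")
    k0 = 1.0 / max(t.max(), 1e-9)
    clipped = False
    try:
        (k,), _ = curve_fit(lambda tt, kk: np.exp(-kk * tt), t, y,
                            p0=[k0], bounds=(0.0, np.inf), maxfev=10000)
    except RuntimeError:
        k = 0.0
    if k * t.max() < 1e-3:  # no measurable decay over the observed span
        k = 1e-12
        clipped = True
        warnings.warn("non-decaying survival curve; rate clipped")
    resid = y - np.exp(-k * t)
    return DecayFit(rate=float(k), half_life=float(np.log(2) / k),
                    condition=condition, goodness=float(np.std(resid)),
                    clipped=clipped)


def excess_mortality(fit_a: DecayFit, fit_b: DecayFit, t: float) -> float:
    """Fold excess mortality of condition a over b at time t:
    (1 - S_a(t)) / (1 - S_b(t))."""
    dead_a = 1.0 - fit_a.survival_at(t)
    dead_b = 1.0 - fit_b.survival_at(t)
    if dead_b == 0:
        return float("inf") if dead_a > 0 else 1.0
    return dead_a / dead_b


# --- SYTOX/Hoechst nucleus scoring ---

def _local_window(bbox, scale: float, shape):
    """Bounding box grown to `scale` times its size, clipped to the image."""
    y0, x0, y1, x1 = bbox
    cy, cx = (y0 + y1) / 2, (x0 + x1) / 2
    hh, hw = (y1 - y0) * scale / 2, (x1 - x0) * scale / 2
    return (max(0, int(cy - hh)), max(0, int(cx - hw)),
            min(shape[0], int(np.ceil(cy + hh))), min(shape[1], int(np.ceil(cx + hw))))


def _minmax(a: np.ndarray) -> np.ndarray:
    lo, hi = float(a.min()), float(a.max())
    if hi <= lo:
        return np.zeros_like(a)
    return (a - lo) / (hi - lo)


def nucleus_death_ratio(sytox_frame: np.ndarray, hoechst_frame: np.ndarray,
                        cutoff: float = DEATH_RATIO_CUTOFF) -> pd.DataFrame:
    """Per-nucleus SYTOX/Hoechst normalized-intensity ratios and dead flags.

    Nuclei are segmented from Hoechst (Otsu + hole filling + >= 50 px);
    both channels are min-max normalized within a window of twice the
    nucleus bounding box; a ratio >= ``cutoff`` flags death. Returns a
    DataFrame with columns (nucleus_id, x, y, ratio, dead); empty (with a
    warning) when no nuclei are found.
    """
    sytox = np.asarray(sytox_frame, float)
    hoechst = np.asarray(hoechst_frame, float)
    if sytox.shape != hoechst.shape:
        raise ValueError("frames must share a shape")
    try:
        thr = threshold_otsu(hoechst)
    except ValueError:
        thr = np.inf
    mask = binary_fill_holes(hoechst > thr)
    labels = label(mask)
    rows = []
    for region in regionprops(labels):
        if region.area < MIN_NUCLEUS_AREA:
            continue
        y0, x0, y1, x1 = _local_window(region.bbox, 2.0, hoechst.shape)
        nuc = labels[y0:y1, x0:x1] == region.label
        s_norm = _minmax(sytox[y0:y1, x0:x1])
        h_norm = _minmax(hoechst[y0:y1, x0:x1])
        h_mean = float(h_norm[nuc].mean())
        s_mean = float(s_norm[nuc].mean())
        ratio = s_mean / h_mean if h_mean > 0 else 0.0
        cy, cx = region.centroid
        rows.append((region.label, float(cx), float(cy), ratio, ratio >= cutoff))
    if not rows:
        warnings.warn("no nuclei found")
    return pd.DataFrame(rows, columns=["nucleus_id", "x", "y", "ratio", "dead"])


def recover_death_times(hoechst_stack, sytox_stack, sample_times,
                        cutoff: float = DEATH_RATIO_CUTOFF) -> pd.DataFrame:
    """Score every sampled frame pair and report each cell's death time.

    Cells are matched across frames by nearest nucleus centroid. Returns a
    DataFrame (cell_id, x, y, death_time) with NaN for surviving cells.
    """
    sample_times = np.asarray(sample_times, float)
    ref = nucleus_death_ratio(sytox_stack[0], hoechst_stack[0], cutoff)
    deaths = np.full(len(ref), np.nan)
    for ti, t_s in enumerate(sample_times):
        df = nucleus_death_ratio(sytox_stack[ti], hoechst_stack[ti], cutoff)
        for _, row in df[df["dead"]].iterrows():
            d = np.hypot(ref["x"] - row["x"], ref["y"] - row["y"])
            j = int(np.argmin(d))
            if np.isnan(deaths[j]):
                deaths[j] = t_s
    out = ref[["nucleus_id", "x", "y"]].copy()
    out = out.rename(columns={"nucleus_id": "cell_id"})
    out["death_time"] = deaths
    return out
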