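"""Synthetic scenes: coupled camera-greenness and satellite-NDVI series.

Every downstream stage of the pipeline (smoothing, changepoint
segmentation, threshold-date extraction, pairing, regression) is testable
against these generators because the true transition dates of the noiseless
seasonal curves are known analytically (by root-finding, to well below the
daily sampling resolution).

The seasonal cycle is a product-of-sigmoids double logistic,

    g(t) = baseline + amplitude * s(r_r (t - m_r)) * s(-r_f (t - m_f)),

with s the standard logistic function, m_r/m_f the rising/falling
midpoints (day of year) and r_r/r_f the rates (1/day).  This is the
standard generative form for seasonal vegetation-index trajectories.
Clouds, fog and snow depress apparent canopy greenness, so injected
outliers are downward spikes.
"""

from __future__ import annotations

import math
from dataclasses import dataclass, field

import numpy as np
import pandas as pd
from scipy.optimize import brentq, minimize_scalar
from scipy.special import expit

from .greenness import GreennessSeries

__all__ = [
    "CycleParams",
    "SceneTruth",
    "seasonal_curve",
    "true_threshold_dates",
    "generate_camera_series",
    "generate_satellite_series",
    "make_scene",
    "render_flat_image",
    "write_truth_csv",
]

#: vegetation-type codes used for camera regions of interest
VEG_TYPES = ("AG", "DB", "EN", "GR", "SH")

DEFAULT_FRACTIONS = (0.10, 0.25, 0.50)


@dataclass(frozen=True)
class CycleParams:
    """One seasonal greenness cycle (double-sigmoid parameters).

    Units: ``baseline``/``amplitude`` in index units (Gcc or NDVI),
    midpoints in day-of-year, rates in 1/day.
    """

    baseline: float
    amplitude: float
    rising_midpoint: float
    rising_rate: float
    falling_midpoint: float
    falling_rate: float

    def __post_init__(self) -> None:
        vals = (self.baseline, self.amplitude, self.rising_midpoint,
                self.rising_rate, self.falling_midpoint, self.falling_rate)
        if not all(math.isfinite(v) for v in vals):
            raise ValueError("CycleParams must be finite")
        if self.amplitude <= 0:
            raise ValueError("amplitude must be > 0")
        if self.rising_rate <= 0 or self.falling_rate <= 0:
            raise ValueError("rates must be > 0")
        if not self.rising_midpoint < self.falling_midpoint:
            raise ValueError("rising_midpoint must precede falling_midpoint")


def seasonal_curve(params, t):
    """Evaluate the noiseless seasonal curve at day-of-year ``t``.

    ``params`` may be a single :class:`CycleParams` or a list of
    non-overlapping cycles sharing a common baseline (e.g. a double-cropped
    agricultural year).  Vectorised over ``t``.
    """
    cycles = _as_cycles(params)
    t = np.asarray(t, dtype=float)
    out = np.full(t.shape, cycles[0].baseline)
    for c in cycles:
        out = out + c.amplitude * _bump(c, t)
    return out if out.shape else float(out)


def _bump(c: CycleParams, t):
    return expit(c.rising_rate * (t - c.rising_midpoint)) * \
        expit(-c.falling_rate * (t - c.falling_midpoint))


def _as_cycles(params) -> list[CycleParams]:
    if isinstance(params, CycleParams):
        return [params]
    cycles = list(params)
    if not cycles:
        raise ValueError("need at least one cycle")
    base = cycles[0].baseline
    if any(abs(c.baseline - base) > 1e-12 for c in cycles):
        raise ValueError("cycles summed within a year must share a baseline")
    _check_no_overlap(cycles)
    return cycles


def _check_no_overlap(cycles: list[CycleParams]) -> None:
    """Refuse overlapping cycles rather than resolving them.

    Two cycles overlap when the falling shoulder of one has not decayed
    (to within ~2% of amplitude, i.e. 4/rate beyond the midpoint) before
    the rising shoulder of the next begins.
    """
    ordered = sorted(cycles, key=lambda c: c.rising_midpoint)
    for a, b in zip(ordered, ordered[1:]):
        a_end = a.falling_midpoint + 4.0 / a.falling_rate
        b_start = b.rising_midpoint - 4.0 / b.rising_rate
        if a_end >= b_start:
            raise ValueError(
                f"overlapping cycles: one ends ~{a_end:.1f}, next starts ~{b_start:.1f}"
            )


def _curve_extrema(fn, t0: float, t1: float):
    """(vmin, vmax, t_peak) of a unimodal-ish seasonal callable on [t0, t1]."""
    grid = np.linspace(t0, t1, 1001)
    vals = fn(grid)
    i = int(np.argmax(vals))
    lo, hi = grid[max(i - 1, 0)], grid[min(i + 1, len(grid) - 1)]
    res = minimize_scalar(lambda t: -fn(np.array([t]))[0],
                          bounds=(lo, hi), method="bounded",
                          options={"xatol": 1e-6})
    t_peak = float(res.x)
    vmax = float(fn(np.array([t_peak]))[0])
    vmin = float(np.min(vals))
    return vmin, vmax, t_peak


def threshold_dates_of(fn, fractions=DEFAULT_FRACTIONS, t0: float = 1.0,
                       t1: float = 365.0) -> dict[tuple[str, float], float]:
    """Threshold-crossing dates of an arbitrary seasonal callable.

    For each fraction f the level is vmin + f*(vmax - vmin); the rising
    date is the crossing on [t0, t_peak], the falling date the crossing on
    [t_peak, t1], each found by Brent root-finding (well below 0.01 d).
    """
    for f in fractions:
        if not 0.0 < f < 1.0:
            raise ValueError("fractions must lie strictly in (0, 1)")
    vmin, vmax, t_peak = _curve_extrema(fn, t0, t1)
    dates: dict[tuple[str, float], float] = {}
    for f in fractions:
        level = vmin + f * (vmax - vmin)

        def g(t):
            return fn(np.array([t]))[0] - level

        if g(t0) < 0 < g(t_peak):
            dates[("rising", f)] = float(brentq(g, t0, t_peak, xtol=1e-6))
        if g(t1) < 0 < g(t_peak):
            dates[("falling", f)] = float(brentq(g, t_peak, t1, xtol=1e-6))
    return dates


def true_threshold_dates(params, fractions=DEFAULT_FRACTIONS,
                         t0: float = 1.0, t1: float = 365.0):
    """Analytic threshold dates of the noiseless curve.

    Single cycle -> dict keyed by (direction, fraction); a list of cycles
    -> list of such dicts, one per cycle in chronological order.
    """
    cycles = _as_cycles(params)
    if isinstance(params, CycleParams):
        return threshold_dates_of(lambda t: seasonal_curve(params, t),
                                  fractions, t0, t1)
    out = []
    bounds = _cycle_bounds(cycles, t0, t1)
    for c, (a, b) in zip(cycles, bounds):
        out.append(threshold_dates_of(lambda t, c=c: seasonal_curve(c, t),
                                      fractions, a, b))
    return out


def _cycle_bounds(cycles, t0, t1):
    ordered = sorted(cycles, key=lambda c: c.rising_midpoint)
    edges = [t0]
    for a, b in zip(ordered, ordered[1:]):
        edges.append(0.5 * (a.falling_midpoint + b.rising_midpoint))
    edges.append(t1)
    return list(zip(edges[:-1], edges[1:]))


@dataclass
class SceneTruth:
    """Ground truth for one synthetic site: camera cycles, satellite
    component signals, sub-pixel mixing across the 3x3 window, and the
    analytically known transition dates."""

    site_id: str
    latitude: float
    longitude: float
    roi_veg_type: str
    igbp_center: int
    cycles: dict[int, list[CycleParams]]
    ndvi_components: dict[int, list[CycleParams]]
    mixture_weights: np.ndarray  # (9, K); row i = pixel (i//3, i%3)
    fractions: tuple[float, ...] = DEFAULT_FRACTIONS
    true_dates: dict[tuple[int, str, float], float] = field(default_factory=dict)

    def __post_init__(self) -> None:
        if self.roi_veg_type not in VEG_TYPES:
            raise ValueError(f"unknown vegetation type {self.roi_veg_type!r}")
        w = np.asarray(self.mixture_weights, dtype=float)
        if w.shape[0] != 9:
            raise ValueError("mixture_weights must have 9 rows (3x3 window)")
        if np.any(w < 0) or not np.allclose(w.sum(axis=1), 1.0):
            raise ValueError("each pixel's mixture weights must be >= 0 and sum to 1")
        self.mixture_weights = w
        for year, cyc in self.ndvi_components.items():
            if len(cyc) != w.shape[1]:
                raise ValueError("component count must match weight columns")
        if not self.true_dates:
            # the (year, direction, fraction) map holds one date per key, so
            # it is filled from the first cycle; further cycles of a
            # multi-cycle year are reachable via true_threshold_dates(cycles)
            for year, cyc in self.cycles.items():
                d = true_threshold_dates(cyc[0], self.fractions)
                for (direction, f), doy in d.items():
                    self.true_dates[(year, direction, f)] = doy

    def mixture_ndvi(self, year: int, pixel: int = 4):
        """Noiseless NDVI callable for one pixel of the 3x3 window."""
        comps = self.ndvi_components[year]
        w = self.mixture_weights[pixel]

        def fn(t):
            t = np.asarray(t, dtype=float)
            out = np.zeros(t.shape)
            for wk, c in zip(w, comps):
                out = out + wk * seasonal_curve(c, t)
            return out

        return fn


def generate_camera_series(truth: SceneTruth, year: int,
                           noise_sd: float = 0.005,
                           outlier_rate: float = 0.02,
                           seed: int = 0,
                           samples_per_day: int = 1,
                           statistic: str = "mean") -> GreennessSeries:
    """Camera Gcc series for one site-year: curve + iid Gaussian noise +
    sparse downward (cloud/snow-like) outliers of 0.02-0.10 index units.

    Reproducible under a fixed seed; with zero noise and zero outlier rate
    the series equals the noiseless curve exactly.
    """
    if noise_sd < 0:
        raise ValueError("noise_sd must be >= 0")
    if not 0.0 <= outlier_rate < 0.2:
        raise ValueError("outlier_rate must be in [0, 0.2)")
    rng = np.random.default_rng(seed)
    if samples_per_day == 1:
        t = np.arange(1.0, 366.0)
    else:
        # samples spread through the middle of the day (solar-filtered hours)
        frac = (np.arange(samples_per_day) + 0.5) / samples_per_day * 0.5 + 0.25
        t = (np.arange(1, 366)[:, None] + frac[None, :]).ravel()
    gcc = seasonal_curve(truth.cycles[year], t)
    gcc = gcc + rng.normal(0.0, noise_sd, size=t.shape)
    is_out = rng.random(t.shape) < outlier_rate
    gcc = gcc - is_out * rng.uniform(0.02, 0.10, size=t.shape)
    gcc = np.clip(gcc, 0.0, 1.0)
    origin = pd.Timestamp(year=year, month=1, day=1)
    dates = origin + pd.to_timedelta(t - 1.0, unit="D")
    data = pd.DataFrame({"date": dates, "gcc": gcc})
    data.attrs["outlier_mask"] = is_out
    return GreennessSeries(site_id=truth.site_id, veg_type=truth.roi_veg_type,
                           statistic=statistic, data=data)


def generate_satellite_series(truth: SceneTruth, year: int, step: int = 16,
                              noise_sd: float = 0.01, jitter_sd: float = 5.0,
                              seed: int = 0, onset_fraction: float = 0.10,
                              band_total: float = 0.5):
    """Satellite side of a synthetic scene.

    Returns ``(window_df, dates)`` where ``window_df`` has one row per
    (pixel, composite date) with columns row, col, date, band1, band2,
    ndvi, and ``dates`` maps (year, direction) -> satellite transition
    day-of-year (greenup onset / dormancy onset).

    Each pixel's NDVI is the convex mixture of the component vegetation
    signals plus Gaussian noise, sampled every ``step`` days (each
    composite assigned to its period's first day).  Red/NIR reflectances
    are back-computed so band1 + band2 = ``band_total``.  The satellite
    dates are the true threshold crossings of the noiseless center-pixel
    mixture plus N(0, jitter_sd) jitter.
    """
    rng = np.random.default_rng(seed)
    t = np.arange(1.0, 366.0, float(step))
    rows = []
    for pixel in range(9):
        fn = truth.mixture_ndvi(year, pixel)
        ndvi = fn(t) + rng.normal(0.0, noise_sd, size=t.shape)
        ndvi = np.clip(ndvi, -1.0, 1.0)
        band2 = 0.5 * band_total * (1.0 + ndvi)
        band1 = band_total - band2
        for ti, n, b1, b2 in zip(t, ndvi, band1, band2):
            rows.append({"row": pixel // 3, "col": pixel % 3, "year": year,
                         "doy": ti, "band1": b1, "band2": b2, "ndvi": n})
    window_df = pd.DataFrame(rows)

    center = truth.mixture_ndvi(year, pixel=4)
    truth_dates = threshold_dates_of(center, fractions=(onset_fraction,))
    dates = {}
    for (direction, _f), doy in sorted(truth_dates.items()):
        dates[(year, direction)] = float(doy + rng.normal(0.0, jitter_sd))
    return window_df, dates


# ---------------------------------------------------------------------------
# Scene factory

_VEG_DEFAULTS = {
    # baseline, amplitude, rising mid, rising rate, falling mid, falling rate
    "DB": (0.33, 0.12, 130.0, 0.18, 280.0, 0.12),
    "AG": (0.32, 0.10, 150.0, 0.22, 255.0, 0.18),
    "EN": (0.34, 0.05, 120.0, 0.08, 290.0, 0.07),
    "GR": (0.32, 0.08, 110.0, 0.15, 250.0, 0.10),
    "SH": (0.31, 0.05, 115.0, 0.12, 265.0, 0.09),
}

#: a typical IGBP code for each camera vegetation type
_VEG_IGBP = {"AG": 12, "DB": 4, "EN": 1, "GR": 10, "SH": 7}

_NDVI_SCALE = dict(baseline=0.30, per_amp=4.0)  # Gcc amp 0.1 -> NDVI amp 0.4


def _ndvi_cycle(c: CycleParams) -> CycleParams:
    return CycleParams(baseline=_NDVI_SCALE["baseline"],
                       amplitude=min(0.6, _NDVI_SCALE["per_amp"] * c.amplitude),
                       rising_midpoint=c.rising_midpoint,
                       rising_rate=c.rising_rate,
                       falling_midpoint=c.falling_midpoint,
                       falling_rate=c.falling_rate)


def make_scene(site_id: str, veg_type: str, years, seed: int = 0,
               site_shift_sd: float = 15.0, year_shift_sd: float = 8.0,
               neighbor_veg: str | None = None,
               center_weight: float = 1.0,
               latitude: float = 44.0, longitude: float = -71.0) -> SceneTruth:
    """Build a SceneTruth with realistic between-site and between-year
    spread in transition dates.

    ``center_weight`` < 1 mixes a second vegetation component (phase-shifted
    ``neighbor_veg``) into the satellite pixels: the center pixel gets
    ``center_weight`` on the camera's own signal, edge pixels progressively
    less (landscape heterogeneity around the camera).
    """
    rng = np.random.default_rng(seed)
    base, amp, rm, rr, fm, fr = _VEG_DEFAULTS[veg_type]
    site_shift = rng.normal(0.0, site_shift_sd)
    cycles: dict[int, list[CycleParams]] = {}
    comps: dict[int, list[CycleParams]] = {}
    for year in np.atleast_1d(years):
        year = int(year)
        shift = site_shift + rng.normal(0.0, year_shift_sd)
        c = CycleParams(base, amp * float(rng.uniform(0.85, 1.15)),
                        rm + shift, rr, fm + shift, fr)
        cycles[year] = [c]
        own = _ndvi_cycle(c)
        if neighbor_veg is None:
            comps[year] = [own]
        else:
            nb, na, nrm, nrr, nfm, nfr = _VEG_DEFAULTS[neighbor_veg]
            nc = CycleParams(base, na, nrm + shift - 20.0, nrr,
                             nfm + shift + 20.0, nfr)
            comps[year] = [own, _ndvi_cycle(nc)]

    k = 1 if neighbor_veg is None else 2
    w = np.zeros((9, k))
    if k == 1:
        w[:, 0] = 1.0
    else:
        w[4] = (center_weight, 1.0 - center_weight)
        for p in range(9):
            if p == 4:
                continue
            cw = max(0.0, center_weight - 0.15 * (1 + (p in (0, 2, 6, 8))))
            w[p] = (cw, 1.0 - cw)
    return SceneTruth(site_id=site_id, latitude=latitude, longitude=longitude,
                      roi_veg_type=veg_type, igbp_center=_VEG_IGBP[veg_type],
                      cycles=cycles, ndvi_components=comps, mixture_weights=w)


# ---------------------------------------------------------------------------
# Plain-text / image output

def write_truth_csv(truth: SceneTruth, path) -> None:
    rows = [{"year": y, "direction": d, "fraction": f, "doy": doy}
            for (y, d, f), doy in sorted(truth.true_dates.items())]
    pd.DataFrame(rows).to_csv(path, index=False)


def render_flat_image(triplet, path, size=(16, 16)) -> None:
    """Write a flat-colour RGB image (exercises the image-reading front end)."""
    from PIL import Image

    r, g, b = (int(round(v)) for v in triplet)
    img = Image.new("RGB", size, (r, g, b))
    img.save(path)


def render_mask(path, size=(16, 16), inset: int = 2) -> None:
    """Binary ROI mask (nonzero = region of interest), border excluded."""
    from PIL import Image

    arr = np.zeros(size[::-1], dtype=np.uint8)
    arr[inset:-inset, inset:-inset] = 255
    Image.fromarray(arr, mode="L").save(path)
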