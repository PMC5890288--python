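"""Agreement statistics between camera and satellite transition dates.

Camera dates are paired one-to-one with same-direction satellite dates
within 90 days; each pair is classified "apples" (the camera ROI's
vegetation type matches the satellite pixel's IGBP landcover class) or
"oranges".  Agreement is quantified by the mean bias (MODIS - PhenoCam,
so negative = satellite earlier), Pearson's r, and Deming errors-in-
variables regression with error-variance ratio lambda = sigma_x^2 /
sigma_y^2 (lambda = 1 is orthogonal regression), with the RMS
perpendicular distance to the fitted line as the overall error metric:

    d = (y - (b0 + b1 x))^2 / (1 + b1^2)          [a squared distance]
    RMS = sqrt( sum(d_i) / (n - 2) )
"""

from __future__ import annotations

import logging
import warnings
from dataclasses import dataclass

import numpy as np
import pandas as pd
from scipy import stats

__all__ = [
    "APPLES_TABLE",
    "PairedTransition",
    "DemingResult",
    "pair_transitions",
    "wrap_doy",
    "classify_comparison",
    "bias_stats",
    "pearson_r",
    "deming_fit",
    "perpendicular_distance",
    "rms_distance",
    "summary_table",
]

log = logging.getLogger(__name__)

#: IGBP codes counted as "apples" for each camera ROI vegetation type
APPLES_TABLE: dict[str, frozenset[int]] = {
    "AG": frozenset({12, 14}),
    "DB": frozenset({4, 5}),
    "EN": frozenset({1, 5}),
    "GR": frozenset({10, 12, 14}),
}


@dataclass(frozen=True)
class PairedTransition:
    site_id: str
    year: int
    direction: str
    phenocam_doy: float
    modis_doy: float
    roi_veg_type: str
    igbp_code: int
    threshold_fraction: float
    delta: float  # modis - phenocam, days, on a continuous axis

    def __post_init__(self) -> None:
        if abs(self.delta) >= 90.0:
            raise ValueError("paired dates must differ by less than 90 days")


_PAIR_COLUMNS = ["site_id", "year", "direction", "threshold_fraction",
                 "veg_type", "igbp", "phenocam_doy", "modis_doy", "delta"]


def _abs_day(year, doy):
    return (np.asarray(year, dtype=float) - 2000.0) * 365.2425 + np.asarray(doy, dtype=float)


def pair_transitions(camera: pd.DataFrame, satellite: pd.DataFrame,
                     max_delta: float = 90.0) -> pd.DataFrame:
    """Match camera transition dates to satellite dates.

    ``camera`` needs columns site_id, year, direction, doy,
    threshold_fraction (plus veg_type); ``satellite`` needs site_id, year,
    direction, doy (plus igbp).  Matching is one-to-one per (site,
    direction, threshold fraction), greedy by smallest absolute date
    difference, restricted to same-direction dates differing by strictly
    less than ``max_delta`` days on a continuous (cross-year) axis.
    Unmatched dates are dropped and logged.
    """
    cam = camera.copy()
    sat = satellite.copy()
    cam["_abs"] = _abs_day(cam["year"], cam["doy"])
    sat["_abs"] = _abs_day(sat["year"], sat["doy"])
    rows = []
    n_unmatched = 0
    frac_key = "threshold_fraction" if "threshold_fraction" in cam.columns else None
    group_cols = ["site_id", "direction"] + ([frac_key] if frac_key else [])
    for key, cgrp in cam.groupby(group_cols):
        site, direction = key[0], key[1]
        sgrp = sat[(sat["site_id"] == site) & (sat["direction"] == direction)]
        if sgrp.empty:
            n_unmatched += len(cgrp)
            continue
        cand = []
        for ci, crow in cgrp.iterrows():
            for si, srow in sgrp.iterrows():
                delta = srow["_abs"] - crow["_abs"]
                if abs(delta) < max_delta:
                    cand.append((abs(delta), ci, si, delta))
        cand.sort(key=lambda c: c[0])
        used_c, used_s = set(), set()
        for _, ci, si, delta in cand:
            if ci in used_c or si in used_s:
                continue
            used_c.add(ci)
            used_s.add(si)
            crow, srow = cam.loc[ci], sat.loc[si]
            rows.append({
                "site_id": site, "year": int(crow["year"]),
                "direction": direction,
                "threshold_fraction": crow[frac_key] if frac_key else np.nan,
                "veg_type": crow.get("veg_type", ""),
                "igbp": int(srow["igbp"]) if "igbp" in srow else -1,
                "phenocam_doy": float(crow["doy"]),
                "modis_doy": float(srow["doy"]),
                "delta": float(delta),
            })
        n_unmatched += len(cgrp) - len(used_c)
    if n_unmatched:
        log.info("pair_transitions: %d camera dates left unmatched "
                 "(no same-direction satellite date within %.0f d)",
                 n_unmatched, max_delta)
    return pd.DataFrame(rows, columns=_PAIR_COLUMNS)


def wrap_doy(doy, direction):
    """Wrap day-of-year for cross-year analysis and display: rising dates
    after DOY 270 wrap to the start of the year (DOY < 0), falling dates
    before DOY 90 wrap to the end (DOY > 365).  Vectorised."""
    d = np.asarray(doy, dtype=float)
    scalar = d.ndim == 0
    d = np.atleast_1d(d).copy()
    if isinstance(direction, str):
        direction = np.full(d.shape, direction, dtype=object)
    direction = np.atleast_1d(np.asarray(direction, dtype=object))
    rising = direction == "rising"
    d[rising & (d > 270.0)] -= 365.0
    d[~rising & (d < 90.0)] += 365.0
    return float(d[0]) if scalar else d


def classify_comparison(roi_veg_type: str, igbp_code: int,
                        table: dict | None = None) -> str:
    """'apples' when the IGBP code is representative of the camera ROI's
    vegetation type, else 'oranges'."""
    table = APPLES_TABLE if table is None else table
    if roi_veg_type not in table:
        warnings.warn(f"vegetation type {roi_veg_type!r} not in the apples "
                      "table; classified as oranges", stacklevel=2)
        return "oranges"
    return "apples" if int(igbp_code) in table[roi_veg_type] else "oranges"


@dataclass
class BiasStats:
    n: int
    bias_mean: float   # mean(modis - phenocam), days
    bias_sd: float     # sample SD (n-1)
    sd_camera: float
    sd_modis: float


def _pairs_xy(pairs, wrap: bool = True):
    """(phenocam, modis) arrays from a pairs DataFrame or PairedTransition
    list, optionally with the cross-year DOY wrap applied."""
    if isinstance(pairs, pd.DataFrame):
        x = pairs["phenocam_doy"].to_numpy(dtype=float)
        y = pairs["modis_doy"].to_numpy(dtype=float)
        direction = pairs["direction"].to_numpy(dtype=object)
    else:
        x = np.array([p.phenocam_doy for p in pairs], dtype=float)
        y = np.array([p.modis_doy for p in pairs], dtype=float)
        direction = np.array([p.direction for p in pairs], dtype=object)
    if wrap and len(x):
        x = wrap_doy(x, direction)
        y = wrap_doy(y, direction)
    return x, y


def bias_stats(pairs, wrap: bool = True) -> BiasStats:
    """Mean and SD of the MODIS - PhenoCam date difference plus per-source
    date SDs (sample SD, n-1 denominator; SD undefined below n=2)."""
    x, y = _pairs_xy(pairs, wrap)
    n = len(x)
    if n == 0:
        raise ValueError("no pairs")
    delta = y - x
    sd = float(np.std(delta, ddof=1)) if n >= 2 else float("nan")
    return BiasStats(n=n, bias_mean=float(delta.mean()), bias_sd=sd,
                     sd_camera=float(np.std(x, ddof=1)) if n >= 2 else float("nan"),
                     sd_modis=float(np.std(y, ddof=1)) if n >= 2 else float("nan"))


def pearson_r(pairs, wrap: bool = True) -> float:
    """Product-moment correlation of the paired dates.

    Takes no lambda argument: the correlation is structurally insensitive
    to the Deming error-variance ratio."""
    x, y = _pairs_xy(pairs, wrap)
    if len(x) < 3:
        raise ValueError("need n >= 3 for a correlation")
    if np.std(x) == 0 or np.std(y) == 0:
        warnings.warn("zero variance; correlation undefined", stacklevel=2)
        return float("nan")
    return float(np.corrcoef(x, y)[0, 1])


@dataclass
class DemingResult:
    slope: float
    slope_se: float
    intercept: float
    intercept_se: float
    lam: float
    n: int
    rms_distance: float
    pearson_r: float
    bias_mean: float
    bias_sd: float
    p_slope_zero: float
    p_slope_one: float
    significant: bool  # slope != 0 at p < 0.05 and n >= 10 (reporting rule)
    degenerate: bool = False


def _deming_slope(x: np.ndarray, y: np.ndarray, lam: float) -> float:
    sxx = np.var(x, ddof=1)
    syy = np.var(y, ddof=1)
    sxy = np.cov(x, y, ddof=1)[0, 1]
    if sxy == 0:
        return float("nan")
    disc = (lam * syy - sxx) ** 2 + 4.0 * lam * sxy ** 2
    return float((lam * syy - sxx + np.sqrt(disc)) / (2.0 * lam * sxy))


def deming_fit(pairs, lam: float = 1.0, wrap: bool = True) -> DemingResult:
    """Deming errors-in-variables regression of satellite (y) on camera (x)
    dates with error-variance ratio lambda = sigma_x^2 / sigma_y^2.

    The slope is the closed-form errors-in-variables estimate; it reduces
    to orthogonal regression at lambda = 1, approaches the OLS y|x slope
    as lambda -> 0 (no x error) and 1/OLS(x|y) as lambda -> infinity.
    Standard errors are leave-one-out jackknife; slope tests against 0 and
    1 use t statistics with n - 2 degrees of freedom.
    """
    if lam <= 0:
        raise ValueError("lambda must be > 0")
    x, y = _pairs_xy(pairs, wrap)
    n = len(x)
    if n < 3:
        raise ValueError("need n >= 3 for a Deming fit")

    b1 = _deming_slope(x, y, lam)
    degenerate = not np.isfinite(b1)
    if degenerate:
        warnings.warn("covariance is zero; Deming fit degenerate", stacklevel=2)
    b0 = float(y.mean() - b1 * x.mean()) if not degenerate else float("nan")

    if degenerate:
        se1 = se0 = rms = p0 = p1 = float("nan")
    else:
        loo = np.empty((n, 2))
        idx = np.arange(n)
        for i in range(n):
            m = idx != i
            s = _deming_slope(x[m], y[m], lam)
            loo[i] = (s, y[m].mean() - s * x[m].mean())
        se1, se0 = np.sqrt((n - 1) / n * np.sum((loo - loo.mean(axis=0)) ** 2, axis=0))
        rms = rms_distance(pairs, b0, b1, wrap=wrap)
        dof = n - 2
        p0 = 2.0 * stats.t.sf(abs(b1 / se1), dof) if se1 > 0 else 0.0
        p1 = 2.0 * stats.t.sf(abs((b1 - 1.0) / se1), dof) if se1 > 0 else 0.0

    bias = bias_stats(pairs, wrap=wrap)
    try:
        r = pearson_r(pairs, wrap=wrap)
    except ValueError:
        r = float("nan")
    return DemingResult(slope=b1, slope_se=float(se1), intercept=b0,
                        intercept_se=float(se0), lam=lam, n=n,
                        rms_distance=float(rms), pearson_r=r,
                        bias_mean=bias.bias_mean, bias_sd=bias.bias_sd,
                        p_slope_zero=float(p0), p_slope_one=float(p1),
                        significant=bool(not degenerate and p0 < 0.05 and n >= 10),
                        degenerate=degenerate)


def perpendicular_distance(pair, b0: float, b1: float) -> float:
    """d = (y - (b0 + b1 x))^2 / (1 + b1^2): the squared perpendicular
    distance from a point to the line (sqrt(d) is the geometric point-line
    distance)."""
    if isinstance(pair, PairedTransition):
        x, y = pair.phenocam_doy, pair.modis_doy
    else:
        x, y = pair
    if not np.isfinite(b1):
        raise ValueError("slope must be finite")
    return float((y - (b0 + b1 * x)) ** 2 / (1.0 + b1 ** 2))


def rms_distance(pairs, b0: float, b1: float, wrap: bool = True) -> float:
    """sqrt( sum(d_i) / (n - 2) ): RMS distance perpendicular to the
    regression line with n - 2 degrees of freedom."""
    x, y = _pairs_xy(pairs, wrap)
    n = len(x)
    if n < 3:
        raise ValueError("rms distance needs n >= 3")
    d = (y - (b0 + b1 * x)) ** 2 / (1.0 + b1 ** 2)
    return float(np.sqrt(d.sum() / (n - 2)))


def summary_table(pairs: pd.DataFrame, lam: float = 1.0,
                  by=("veg_type", "comparison", "direction"),
                  min_n: int = 25, wrap: bool = True,
                  apples_table: dict | None = None):
    """Per-group agreement statistics in the layout of a published
    comparison table.

    Returns ``(main, full)`` DataFrames: ``full`` holds every group;
    ``main`` keeps groups with at least ``min_n`` pairs.  Deming slope and
    intercept columns are blanked (NaN) unless the slope differs from 0 at
    p < 0.05 with n >= 10.  A ``comparison`` column (apples/oranges) is
    derived from the apples table when not already present.
    """
    df = pairs.copy()
    if "comparison" in by and "comparison" not in df.columns:
        df["comparison"] = [classify_comparison(v, g, apples_table)
                            for v, g in zip(df["veg_type"], df["igbp"])]
    rows = []
    for key, grp in df.groupby(list(by)):
        key = key if isinstance(key, tuple) else (key,)
        row = dict(zip(by, key))
        row["n"] = len(grp)
        b = bias_stats(grp, wrap=wrap)
        row.update(sd_camera=b.sd_camera, sd_modis=b.sd_modis,
                   bias=b.bias_mean, bias_sd=b.bias_sd)
        if len(grp) >= 3:
            fit = deming_fit(grp, lam=lam, wrap=wrap)
            row["pearson_r"] = fit.pearson_r
            row["rms_distance"] = fit.rms_distance
            if fit.significant:
                row.update(slope=fit.slope, slope_se=fit.slope_se,
                           intercept=fit.intercept, intercept_se=fit.intercept_se)
        rows.append(row)
    cols = list(by) + ["n", "sd_camera", "sd_modis", "pearson_r", "bias",
                       "bias_sd", "slope", "slope_se", "intercept",
                       "intercept_se", "rms_distance"]
    full = pd.DataFrame(rows).reindex(columns=cols)
    main = full[full["n"] >= min_n].reset_index(drop=True)
    return main, full
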