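"""Transition-date extraction from greenness series.

The processing chain is: fit an optimally flexible smoothing spline (a
penalized cubic B-spline whose smoothing parameter minimises AIC), reject
outliers iteratively against the fit, re-fit, parse the smoothed curve
into greenness-rising and greenness-falling phases with PELT changepoint
detection on its first differences, and report the dates at which the
spline crosses 10/25/50% of each phase's seasonal amplitude, with a 90%
confidence interval derived from the spline's pointwise envelope.

AIC here is n*ln(RSS/n) + 2*edf with the effective degrees of freedom
taken as the trace of the smoother (hat) matrix.
"""

from __future__ import annotations

import logging
import warnings
from dataclasses import dataclass, field

import numpy as np
from scipy.interpolate import BSpline
from scipy.linalg import cho_factor, cho_solve

from .changepoint import pelt_mean_shift
from .greenness import GreennessSeries

__all__ = [
    "SplineFit",
    "PhaseSegment",
    "TransitionEstimate",
    "fit_spline_aic",
    "reject_outliers",
    "segment_phases_pelt",
    "extract_transition_dates",
    "transition_uncertainty",
    "select_best_statistic",
]

log = logging.getLogger(__name__)

#: z quantile for the pointwise 90% confidence envelope
_Z90 = 1.6448536269514722

DEFAULT_FRACTIONS = (0.10, 0.25, 0.50)

#: preference order used to break residual-variance ties
_STAT_PREFERENCE = ("mean", "p90", "p75", "p50")


@dataclass
class SplineFit:
    """A smoothed greenness trajectory.

    ``x`` is the (real-valued, 1-based) day axis, ``y`` the observations
    the fit used; ``ci_lower``/``ci_upper`` bound the pointwise 90%
    confidence envelope of the smoothed curve.
    """

    x: np.ndarray
    y: np.ndarray
    fitted: np.ndarray
    residuals: np.ndarray
    lam: float
    edf: float
    resid_var: float
    ci_lower: np.ndarray
    ci_upper: np.ndarray
    aic: float
    aic_grid: list[tuple[float, float]] = field(default_factory=list, repr=False)
    spline: BSpline | None = field(default=None, repr=False)
    hat_diag: np.ndarray | None = field(default=None, repr=False)

    def __call__(self, t):
        t = np.clip(np.asarray(t, dtype=float), self.x[0], self.x[-1])
        return self.spline(t)

    @property
    def n(self) -> int:
        return len(self.x)


@dataclass(frozen=True)
class PhaseSegment:
    """One greenness-rising or greenness-falling phase of the fitted curve."""

    direction: str  # "rising" | "falling"
    start: float    # day axis
    end: float
    vmin: float
    vmax: float
    i0: int         # index range into the fit arrays, inclusive
    i1: int

    @property
    def amplitude(self) -> float:
        return self.vmax - self.vmin


@dataclass
class TransitionEstimate:
    """A dated amplitude-threshold crossing with its 90% interval."""

    direction: str
    fraction: float
    date: float
    ci_lower: float
    ci_upper: float
    statistic: str = ""
    level: float = float("nan")
    segment: PhaseSegment | None = field(default=None, repr=False)
    ci_clipped: bool = False


def _resolve_xy(series, y):
    if isinstance(series, GreennessSeries):
        x = series.day_axis()
        yv = series.data["gcc"].to_numpy(dtype=float)
    else:
        x = np.asarray(series, dtype=float)
        yv = np.asarray(y, dtype=float)
    keep = np.isfinite(yv) & np.isfinite(x)
    return x[keep], yv[keep]


def _basis(x: np.ndarray, max_basis: int = 200):
    """Cubic B-spline design matrix with quantile-placed interior knots
    (one knot per ~3 observations, capped)."""
    n = len(x)
    n_interior = int(min(max(n // 3, 4), max_basis - 4, n - 4))
    qs = np.linspace(0.0, 1.0, n_interior + 2)[1:-1]
    interior = np.unique(np.quantile(x, qs))
    interior = interior[(interior > x[0]) & (interior < x[-1])]
    knots = np.concatenate([[x[0]] * 4, interior, [x[-1]] * 4])
    design = BSpline.design_matrix(x, knots, 3).toarray()
    return design, knots


def _second_diff_penalty(nb: int) -> np.ndarray:
    d = np.diff(np.eye(nb), n=2, axis=0)
    return d.T @ d


def fit_spline_aic(series, y=None, lam_grid=None, max_basis: int = 200) -> SplineFit:
    """Fit a penalized cubic smoothing spline, choosing the smoothing
    parameter on a log-spaced grid by AIC.

    ``series`` may be a :class:`GreennessSeries` or an x array paired with
    ``y``.  Requires at least 10 non-missing observations.
    """
    x, yv = _resolve_xy(series, y)
    n = len(x)
    if n < 10:
        raise ValueError(f"need >= 10 non-missing observations, got {n}")
    if np.any(np.diff(x) <= 0):
        order = np.argsort(x)
        x, yv = x[order], yv[order]
    if lam_grid is None:
        lam_grid = np.logspace(-4.0, 8.0, 13)

    b, knots = _basis(x, max_basis)
    nb = b.shape[1]
    btb = b.T @ b
    bty = b.T @ yv
    pen = _second_diff_penalty(nb)

    best = None
    grid = []
    for lam in lam_grid:
        try:
            c = cho_factor(btb + lam * pen + 1e-10 * np.eye(nb))
        except np.linalg.LinAlgError:  # pragma: no cover - jittered above
            continue
        coef = cho_solve(c, bty)
        fitted = b @ coef
        rss = float(np.sum((yv - fitted) ** 2))
        edf = float(np.trace(cho_solve(c, btb)))
        aic = n * np.log(max(rss, 1e-300) / n) + 2.0 * edf
        grid.append((float(lam), aic))
        # on AIC ties (e.g. an exactly reproduced constant), prefer smoother
        if best is None or aic < best[0] - 1e-9 or \
                (abs(aic - best[0]) <= 1e-9 and lam > best[1]):
            best = (aic, float(lam), coef, fitted, rss, edf, c)

    aic, lam, coef, fitted, rss, edf, c = best
    resid = yv - fitted
    resid_var = rss / max(n - edf, 1.0)
    v = cho_solve(c, b.T)
    hat_diag = np.maximum(np.einsum("ij,ji->i", b, v), 0.0)
    se = np.sqrt(resid_var * hat_diag)
    return SplineFit(x=x, y=yv, fitted=fitted, residuals=resid, lam=lam,
                     edf=edf, resid_var=resid_var,
                     ci_lower=fitted - _Z90 * se, ci_upper=fitted + _Z90 * se,
                     aic=aic, aic_grid=grid, spline=BSpline(knots, coef, 3),
                     hat_diag=hat_diag)


@dataclass
class OutlierResult:
    x: np.ndarray
    y: np.ndarray
    fit: SplineFit
    flags: np.ndarray  # boolean mask on the input observations
    aborted: bool = False


def reject_outliers(series, fit: SplineFit | None = None, y=None,
                    k: float = 3.0, max_iter: int = 5,
                    sigma_floor: float = 5e-4, **fit_kwargs) -> OutlierResult:
    """Iteratively flag points deviating more than ``k`` robust sigma from
    the spline, re-fitting after each pass.

    Robust sigma is 1.4826*MAD of the residuals, floored at
    ``sigma_floor`` (half the quantisation step of an 8-bit chromatic
    coordinate) so noise-free series are never self-flagged.  If more than
    30% of the points would be flagged the pass aborts with a warning and
    returns the unflagged data (a guard against degenerate fits).
    """
    x, yv = _resolve_xy(series, y)
    if fit is None:
        fit = fit_spline_aic(x, yv, **fit_kwargs)
    n0 = len(x)
    flags = np.zeros(n0, dtype=bool)
    for _ in range(max_iter):
        keep = ~flags
        resid = yv[keep] - fit.fitted
        # studentize by leverage: a spike at a high-leverage point (series
        # edge) drags the spline toward itself, hiding its raw residual
        if fit.hat_diag is not None:
            resid = resid / np.sqrt(1.0 - np.minimum(fit.hat_diag, 0.95))
        med = np.median(resid)
        sigma = max(1.4826 * np.median(np.abs(resid - med)), sigma_floor)
        new = np.abs(resid) > k * sigma
        if not new.any():
            break
        if flags.sum() + new.sum() > 0.3 * n0:
            warnings.warn("outlier rejection would flag >30% of points; "
                          "aborting flagging", stacklevel=2)
            fresh = fit_spline_aic(x, yv, **fit_kwargs)
            return OutlierResult(x=x, y=yv, fit=fresh,
                                 flags=np.zeros(n0, dtype=bool), aborted=True)
        idx = np.flatnonzero(keep)[new]
        flags[idx] = True
        fit = fit_spline_aic(x[~flags], yv[~flags], **fit_kwargs)
    return OutlierResult(x=x[~flags], y=yv[~flags], fit=fit, flags=flags)


def segment_phases_pelt(fit: SplineFit, penalty: float | None = None) -> list[PhaseSegment]:
    """Parse the fitted curve into rising/falling phases.

    PELT with a Gaussian mean-shift cost runs on the standardized first
    differences of the fitted curve (penalty default 3*ln n); each PELT
    segment is labelled by the sign of its mean first difference and
    adjacent same-direction segments are merged.  A flat series yields a
    single segment.
    """
    d = np.diff(fit.fitted)
    if len(d) == 0:
        return []
    value_range = float(fit.fitted.max() - fit.fitted.min())
    if value_range <= 1e-10 * max(1.0, float(np.abs(fit.fitted).max())):
        # numerically flat: a single phase, no transitions to find
        direction = "rising" if float(d.sum()) >= 0 else "falling"
        return [PhaseSegment(direction=direction, start=float(fit.x[0]),
                             end=float(fit.x[-1]), vmin=float(fit.fitted.min()),
                             vmax=float(fit.fitted.max()), i0=0,
                             i1=len(fit.fitted) - 1)]
    sd = float(np.std(d))
    z = d / sd if sd > 0 else d
    if penalty is None:
        penalty = 3.0 * np.log(fit.n)
    cps = pelt_mean_shift(z, penalty)
    bounds = [0] + cps + [len(d)]

    raw = []
    for a, b in zip(bounds[:-1], bounds[1:]):
        direction = "rising" if float(np.mean(d[a:b])) >= 0 else "falling"
        raw.append((direction, a, b))
    merged = [raw[0]]
    for direction, a, b in raw[1:]:
        if direction == merged[-1][0]:
            merged[-1] = (direction, merged[-1][1], b)
        else:
            merged.append((direction, a, b))

    # refine each phase boundary to the fitted curve's local extremum
    # between the two phases (a rising->falling boundary belongs at the
    # peak, falling->rising at the trough), so neither phase loses
    # amplitude to changepoint placement inside the seasonal plateau
    merged = [list(seg) for seg in merged]
    for left, right in zip(merged, merged[1:]):
        a, b = left[1], right[2]
        window = fit.fitted[a:b + 1]
        j = a + int(np.argmax(window) if left[0] == "rising" else np.argmin(window))
        j = min(max(j, a + 1), b - 1)
        left[2] = right[1] = j

    segs = []
    for direction, a, b in merged:
        vals = fit.fitted[a:b + 1]
        segs.append(PhaseSegment(direction=direction,
                                 start=float(fit.x[a]), end=float(fit.x[b]),
                                 vmin=float(vals.min()), vmax=float(vals.max()),
                                 i0=a, i1=b))
    return segs


def _crossings(xs, vals, level, direction):
    """All linearly interpolated crossing dates of ``level`` in the stated
    direction (upward for rising, downward for falling)."""
    if direction == "rising":
        hits = np.flatnonzero((vals[:-1] < level) & (vals[1:] >= level))
    else:
        hits = np.flatnonzero((vals[:-1] >= level) & (vals[1:] < level))
    frac = (level - vals[hits]) / (vals[hits + 1] - vals[hits])
    return xs[hits] + frac * (xs[hits + 1] - xs[hits])


def _cross_date(xs, vals, level, direction, which="first", anchor=None):
    """One crossing date of ``level``, or None if never crossed.

    With an ``anchor`` date (the phase's half-amplitude crossing), levels
    below half amplitude are located on the same monotone limb as the
    anchor: the crossing adjacent to it, not a spurious crossing produced
    by small fitted-curve wiggles in the seasonal plateau.
    """
    cross = _crossings(xs, vals, level, direction)
    if len(cross) == 0:
        return None
    if anchor is not None:
        # rising: last upward crossing at/before the anchor; falling:
        # first downward crossing at/after it (fall back to plain rule)
        before = cross[cross <= anchor + 1e-9]
        after = cross[cross >= anchor - 1e-9]
        if direction == "rising" and len(before):
            return float(before[-1])
        if direction == "falling" and len(after):
            return float(after[0])
    return float(cross[0] if which == "first" else cross[-1])


def phase_levels(segment: PhaseSegment, fit: SplineFit, fractions,
                 tail: float = 0.2):
    """Robust amplitude-fraction levels for a phase.

    The phase floor (ceiling) is the median of the fitted values in the
    lowest (highest) ``tail`` fraction of the raw value range, rather than
    the raw extrema: the spline's high-variance edges and plateau wiggles
    bias a plain min/max by several noise standard deviations, which at a
    10% threshold translates into day-scale date errors.
    """
    vals = fit.fitted[segment.i0:segment.i1 + 1]
    raw_amp = segment.amplitude
    floor = float(np.median(vals[vals <= segment.vmin + tail * raw_amp]))
    ceiling = float(np.median(vals[vals >= segment.vmax - tail * raw_amp]))
    amp = ceiling - floor
    return {f: floor + f * amp for f in fractions}, amp


def extract_transition_dates(segment: PhaseSegment, fit: SplineFit,
                             fractions=DEFAULT_FRACTIONS,
                             min_amplitude: float = 0.02,
                             crossing: str = "first",
                             statistic: str = "") -> list[TransitionEstimate]:
    """Dates at which the spline crosses each amplitude fraction of the
    phase, with 90% envelope-based intervals.

    Phases whose amplitude is below ``min_amplitude`` yield no dates (the
    minimum-amplitude gate: weak or failed seasonal cycles are not
    interpreted as transitions).
    """
    if segment.amplitude < min_amplitude:
        return []
    xs = fit.x[segment.i0:segment.i1 + 1]
    vals = fit.fitted[segment.i0:segment.i1 + 1]
    levels, amp = phase_levels(segment, fit, tuple(fractions) + (0.5,))
    if amp < min_amplitude:
        return []
    anchor = _cross_date(xs, vals, levels[0.5], segment.direction, crossing)
    out = []
    for f in fractions:
        level = levels[f]
        date = _cross_date(xs, vals, level, segment.direction, crossing,
                           anchor=anchor if f < 0.5 else None)
        if date is None:
            log.info("threshold %.0f%% never crossed in %s segment [%s, %s]",
                     100 * f, segment.direction, segment.start, segment.end)
            continue
        est = TransitionEstimate(direction=segment.direction, fraction=f,
                                 date=date, ci_lower=date, ci_upper=date,
                                 statistic=statistic, level=level,
                                 segment=segment)
        est.ci_lower, est.ci_upper = transition_uncertainty(est, fit)
        out.append(est)
    return sorted(out, key=lambda e: e.date)


def transition_uncertainty(estimate: TransitionEstimate,
                           fit: SplineFit) -> tuple[float, float]:
    """90% interval for a transition date from the spline's envelope.

    The bounds are the crossing dates of the threshold level with the
    envelope's upper and lower curves inside the phase (earliest and
    latest crossing consistent with the envelope); when an envelope curve
    never crosses, the bound is clipped to the segment edge and flagged.
    """
    seg = estimate.segment
    if seg is None:
        raise ValueError("estimate carries no segment context")
    sl = slice(seg.i0, seg.i1 + 1)
    xs = fit.x[sl]
    upper, lower = fit.ci_upper[sl], fit.ci_lower[sl]
    level = estimate.level

    def nearest(vals):
        cross = _crossings(xs, vals, level, seg.direction)
        if len(cross) == 0:
            return None
        return float(cross[np.argmin(np.abs(cross - estimate.date))])

    d_upper = nearest(upper)
    d_lower = nearest(lower)
    if seg.direction == "rising":
        lo, hi = d_upper, d_lower
    else:
        lo, hi = d_lower, d_upper
    clipped = lo is None or hi is None
    lo = seg.start if lo is None else lo
    hi = seg.end if hi is None else hi
    estimate.ci_clipped = clipped
    if clipped:
        log.info("envelope never crosses %.4f; CI clipped to segment edge", level)
    return min(lo, estimate.date), max(hi, estimate.date)


def select_best_statistic(fits: dict[str, SplineFit]) -> str:
    """Label of the candidate series with the lowest residual variance
    around its spline; ties broken mean > p90 > p75 > p50."""
    if len(fits) < 2:
        raise ValueError("need at least two candidate statistics")

    def rank(item):
        label, fit = item
        pref = _STAT_PREFERENCE.index(label) if label in _STAT_PREFERENCE else len(_STAT_PREFERENCE)
        return (fit.resid_var, pref)

    return min(sorted(fits.items()), key=rank)[0]
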