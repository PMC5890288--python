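# Methods

This note records the models, estimators and numerical choices behind
`phenomatch`, and what the synthetic experiments do and do not establish.

## Seasonal model and synthetic scenes

The generator's seasonal curve is a product-of-sigmoids double logistic,

    g(t) = baseline + amplitude · s(r_r (t − m_r)) · s(−r_f (t − m_f)),

with s the logistic function, midpoints m in day-of-year and rates r in
1/day. This is the standard generative shape for vegetation-index
trajectories: flat dormant baseline, sigmoid green-up, summer plateau,
sigmoid senescence. Multiple cycles in one year (double cropping, bimodal
grasslands) are supported by summing non-overlapping cycles on a common
baseline; overlapping cycles are refused rather than silently blended,
because their threshold dates would be ambiguous.

True transition dates are the crossings of `vmin + f·(vmax − vmin)` found
by Brent root-finding on the noiseless curve (precision ≪ 0.01 d), for
fractions f strictly inside (0, 1). They are the reference every
downstream error is measured against.

Default study conditions, chosen once to resemble mid-latitude camera
series: daily sampling over a calendar year; Gaussian Gcc noise with
SD 0.005; 2% outliers, always downward with uniform 0.02–0.10 magnitude,
because clouds, fog and snow depress apparent canopy greenness; vegetation
presets (baseline ≈ 0.31–0.34, amplitudes 0.05–0.12, green-up rates
0.08–0.22 d⁻¹) for deciduous (DB), agricultural (AG), evergreen (EN),
grassland (GR) and shrub (SH) types; between-site timing spread of
SD 15 d plus between-year SD 8 d. Satellite scenes mix component NDVI
signals convexly across a 3×3 pixel window (landscape heterogeneity) and
are sampled every 16 days, each composite assigned to its period's first
day; satellite transition dates carry Gaussian jitter of SD 5 d by
default, matching the day-scale uncertainty typical of satellite
phenology retrievals.

What the generator does **not** emulate: snow cover episodes, exposure
and white-balance drift, camera repositioning, mid-season disturbance
(harvest, drought browning), or serially correlated weather. Passing
tests therefore demonstrate the estimators' correctness and their noise
robustness under these conditions, not performance on arbitrary field
data.

## Greenness processing

Gcc = G/(R+G+B) on mean digital numbers over the ROI; a zero-sum triplet
is a missing value, not an error. Images are kept when the sun is at
least 10° above the horizon — geometric elevation, no refraction
correction, since the cut only needs degree-scale accuracy — and when the
mean digital number lies in (30, 230) (the data carry no canonical
bounds; these exclude clipped night and blown-out frames). Solar position
uses the NOAA spreadsheet algorithm (~0.01° class); timestamps must carry
a UTC offset, and naive timestamps are rejected outright because a silent
timezone error shifts solar geometry by whole hours.

Aggregation evaluates mean/median/75th/90th percentile over a centred
3-day window, sliding by default (`binned` reproduces the fixed-bin
layout of released 3-day products). Percentiles interpolate linearly
between order statistics. The per-site "best" statistic minimizes the
residual variance around the fitted spline; ties break in the order
mean > p90 > p75 > p50.

## Spline, outliers, phases, thresholds

The smoother is a penalized cubic B-spline (P-spline): quantile-placed
interior knots at roughly one per three observations (capped at ~200
basis functions), second-difference coefficient penalty, smoothing
parameter λ selected on a 13-point log grid spanning 1e−4…1e8 by
AIC = n·ln(RSS/n) + 2·edf with edf = trace of the hat matrix. Exact ties
(e.g. a constant series, reproduced exactly at every λ) resolve to the
smoothest candidate. The pointwise 90% envelope is fitted ± 1.645·σ̂·√hᵢᵢ
with σ̂² = RSS/(n − edf).

Outlier rejection iterates up to five times: residuals are studentized by
leverage (÷√(1−hᵢᵢ)) so that a spike at a high-leverage boundary point —
which drags the spline toward itself and hides its raw residual — is
still flagged; the scale is 1.4826·MAD floored at 5·10⁻⁴ (half the
quantization step of an 8-bit chromatic coordinate), so noise-free series
never self-flag; points beyond 3σ are removed and the spline re-fitted.
If more than 30% of the series would be flagged the pass aborts with a
warning, guarding against degenerate fits.

Phase parsing runs PELT (implemented here, exact under the Gaussian
mean-shift SSE cost, pruning constant 0) on the standardized first
differences of the fitted curve with penalty 3·ln n. Segments are
labelled rising/falling by the sign of their mean first difference,
adjacent same-direction segments merged, and each boundary refined to the
fitted curve's local extremum between the two phases — otherwise a
changepoint placed inside the seasonal plateau robs the adjacent phase of
amplitude and shifts its threshold dates by a day or more. A numerically
flat series (value range below 1e−10 relative) is one segment with no
transitions.

Threshold levels use a robust amplitude estimate: the phase floor and
ceiling are medians of the fitted values within the lowest/highest 20% of
the raw value range, not the raw extrema. The raw minimum is an
extreme-value statistic dominated by the spline's high-variance edges;
at a 10% threshold on a shallow grassland cycle that bias converts to
multi-day (occasionally multi-week) date errors. Crossing dates
interpolate linearly between fitted days. The first crossing is reported
(a transition *onset*; configurable to last), with sub-half-amplitude
levels anchored to the same monotone limb as the half-amplitude crossing
so that plateau wiggles cannot claim the date. Phases whose robust
amplitude falls below `min_amplitude` (default 0.02 Gcc; the value is
configuration, chosen at roughly 4σ of typical 3-day product noise)
return no dates — weak or failed cycles are not interpreted as
transitions. Confidence bounds are the crossings of the threshold level
with the envelope's upper and lower curves (the crossing nearest the
point estimate when several exist); if an envelope curve never crosses,
the bound clips to the segment edge and the estimate is flagged.

Dates are real-valued, 1-based day-of-year with the year carried
separately; cross-year series use a continuous day axis.

## Satellite side and pairing

NDVI, window envelope and IGBP majority are direct computations; majority
ties return "unresolved" rather than the lowest code, to avoid silent
class bias. Satellite transition dates are inputs (at most two cycles per
pixel-year-direction, both preserved).

Pairing is greedy one-to-one per (site, direction, threshold fraction) by
smallest absolute difference, restricted to strictly less than 90 days on
a continuous cross-year axis; a satellite date may pair with each
threshold fraction's camera date (the fractions are alternative
definitions of the same event, not competing events). The bias sign
convention is satellite − camera: negative means the satellite date is
earlier. For display and statistics, rising dates after DOY 270 wrap to
negative values and falling dates before DOY 90 wrap past 365, keeping
mid-winter transitions on one continuous axis; wrapped values are the
default for the regression statistics (configurable).

## Deming regression

λ is the x:y (camera:satellite) error-variance ratio σ²ₓ/σ²ᵧ; the slope

    b1 = [λ·s_yy − s_xx + √((λ·s_yy − s_xx)² + 4λ·s²_xy)] / (2λ·s_xy)

is the closed-form errors-in-variables estimate under that convention: it
equals orthogonal regression (the minimizer of summed perpendicular
distances) at λ = 1, tends to the OLS y|x slope as λ → 0, to the inverse
of the x|y OLS slope as λ → ∞, increases monotonically in λ, and obeys
the x↔y, λ→1/λ reciprocity. Standard errors are leave-one-out jackknife —
distribution-light and robust at the n ≈ 25–100 typical of per-group
tables; slope tests against 0 and 1 use t statistics with n − 2 df. The
summary table reports slope and intercept only when the slope differs
from 0 at p < 0.05 with n ≥ 10, and by default keeps groups with n ≥ 25.
The distance metric d = (y − (b0 + b1x))²/(1 + b1²) is a *squared*
perpendicular distance (its square root is the geometric point-to-line
distance); the RMS distance takes √(Σdᵢ/(n−2)) — one square root, n − 2
degrees of freedom.

One estimator property worth knowing: with λ fixed at 1 while the actual
error variances are unequal (camera ~1 d after smoothing vs satellite
5 d), the orthogonal slope carries a small positive bias ≈ (σ²ᵧ −
σ²ₓ)/(2·var(true dates)) — about +0.04 at the default cohort spread. That
is a property of orthogonal regression, not an implementation defect; the
λ-sensitivity analysis exists precisely to bound it.

## Problem sizes and determinism

The verification experiments use 100 synthetic site-years for
transition-date recovery (tolerance ±3 d), 100 random short series for
the PELT/DP equivalence, and 50 seeds × 50 site-years for the end-to-end
cohort — sizes at which the Monte-Carlo margins are comfortable while a
full test run stays in the low minutes on one CPU. All generators take
explicit integer seeds, and seeded runs are bit-reproducible; the
50-seed cohort criterion is evaluated on seed-averaged statistics (mean
slope-CI bounds, mean bias, mean r), since pooling all pairs into one fit
would instead resolve the λ = 1 estimator bias discussed above.

## Known limitations

- The AIC-selected P-spline can undersmooth at low noise; the robust
  floor/ceiling and crossing anchoring absorb most of the resulting date
  noise, but 10% thresholds on shallow (evergreen-like) cycles remain the
  least reliable outputs, consistent with their behaviour on real data.
- The confidence envelope is pointwise, not simultaneous; transition-date
  intervals inherit that interpretation.
- `filter_samples` is O(n) single-threaded Python over samples; for
  multi-year half-hourly archives, pre-filter by hour before calling it.
- The image front end reads whole frames into memory and supports one ROI
  mask per call; multi-ROI segmentation and ROI editing are out of scope.
- Satellite transition dates are consumed as given; no attempt is made to
  re-derive them from reflectance composites (the simple threshold deriver
  in the generator exists only to manufacture coupled synthetic truth).
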