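# phenomatch

Tools for comparing vegetation phenology seen from the ground and from
space. Near-surface cameras record canopy colour every half hour; polar
orbiters deliver 16-day vegetation-index composites and gridded
transition-date products. Both claim to observe the same green-up and
senescence, but they measure different things at different scales, and
ecologists who validate satellite phenology against camera networks need a
defensible way to quantify the agreement. `phenomatch` implements that
whole chain: camera colour summaries → canopy-greenness transition dates,
satellite reflectances → NDVI context and landcover representativeness,
and errors-in-variables regression statistics for the intercomparison —
plus a synthetic-scene generator with analytically known transition dates
so every stage can be verified without external downloads.

## The methods in brief

**Canopy greenness.** Each camera image contributes a mean RGB digital
number triplet over a vegetation region of interest; the green chromatic
coordinate is

    Gcc = G_DN / (R_DN + G_DN + B_DN),

computed only when the sun is ≥ 10° above the horizon and the image is
neither too dark nor too bright, then aggregated over a centred 3-day
moving window (mean, median, 75th or 90th percentile; the statistic with
the lowest residual variance around its spline can be selected per site).

**Transition dates.** A penalized cubic smoothing spline is fitted to the
series, with the smoothing parameter chosen by AIC
(`n·ln(RSS/n) + 2·edf`, edf = trace of the smoother matrix). Outliers are
rejected iteratively against the fit (3 robust-σ, leverage-studentized)
and the spline re-fitted. PELT changepoint detection on the fitted
curve's first differences parses greenness-rising and greenness-falling
phases; within each phase the dates at which the spline crosses 10%, 25%
and 50% of the seasonal amplitude are reported with 90% confidence
intervals from the spline envelope. Phases below a minimum amplitude
(default 0.02) yield no dates.

**Satellite context.** NDVI = (NIR − red)/(NIR + red) over a 3×3 pixel
window centred on the camera, its per-date min/max envelope as a
landscape-heterogeneity measure, and the majority IGBP landcover code of
the window. Satellite transition dates (greenup onset, dormancy onset)
are ingested, not derived.

**Intercomparison.** Camera and satellite dates moving in the same
direction and differing by < 90 days are paired one-to-one (greedy,
nearest first). Pairs are "apples" when the camera ROI's vegetation type
matches the pixel's IGBP class (AG↔{12,14}, DB↔{4,5}, EN↔{1,5},
GR↔{10,12,14}), else "oranges". Agreement per group: mean bias
(satellite − camera), Pearson's r, and Deming regression with
error-variance ratio λ = σ²ₓ/σ²ᵧ (λ = 1 is orthogonal regression),

    b1 = [λ·s_yy − s_xx + √((λ·s_yy − s_xx)² + 4λ·s²_xy)] / (2λ·s_xy),

jackknife standard errors, slope tests against 0 and 1, and the RMS
perpendicular distance √(Σ dᵢ/(n−2)) with dᵢ = (y−(b0+b1·x))²/(1+b1²).

## Worked example

```sh
python examples/extract_transition_dates.py
```

```
phase      threshold      DOY            90% CI    truth    err
rising         10%    114.1   [ 112.9,  115.1]    114.0   +0.1
rising         25%    120.3   [ 119.7,  120.8]    120.1   +0.1
rising         50%    126.6   [ 126.2,  127.0]    126.3   +0.3
falling        50%    276.0   [ 275.4,  276.7]    276.3   -0.2
falling        25%    285.9   [ 285.0,  286.7]    285.4   +0.5
falling        10%    294.9   [ 293.5,  296.6]    294.6   +0.3
```

Each row is one threshold crossing of the smoothed greenness curve for a
simulated deciduous site-year (noise SD 0.005, 2% cloud-like outliers):
spring green-up passed 10% of the seasonal amplitude on day 114.1 against
a true value of 114.0, and so on. `examples/compare_with_satellite.py`
runs a 10-site × 5-year cohort through the full pipeline and prints the
per-direction agreement table (slope ≈ 1, bias under a day, r ≈ 0.97);
`examples/deming_sensitivity.py` shows the slope's monotone dependence on
λ; `examples/image_to_greenness.py` exercises the image front end.

A thin CLI wraps the same stages:

```sh
phenomatch simulate --veg-type DB --year 2012 --seed 1 --out-prefix syn
phenomatch extract syn_camera.csv --out transitions.csv
phenomatch compare transitions.csv syn_satellite_dates.csv --out pairs.csv
phenomatch report pairs.csv --out-prefix report
```

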