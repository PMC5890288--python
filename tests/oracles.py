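"""Independent oracles used by the test suite.

These deliberately avoid the code paths they check: an exhaustive
O(n^2) dynamic-programming segmentation (no pruning), the PSA solar
position algorithm (Blanco-Muriel et al. 2001), a dense-grid bisection
threshold-date finder, and a sort-based percentile.
"""

from __future__ import annotations

from datetime import timezone

import numpy as np


def dp_segmentation(values, penalty: float):
    """Optimal penalised partition by exhaustive dynamic programming
    (Gaussian mean-shift SSE cost), considering every split point."""
    y = np.asarray(values, dtype=float)
    n = len(y)
    s1 = np.concatenate([[0.0], np.cumsum(y)])
    s2 = np.concatenate([[0.0], np.cumsum(y * y)])

    def cost(i, j):
        m = j - i
        s = s1[j] - s1[i]
        return s2[j] - s2[i] - s * s / m

    f = np.full(n + 1, np.inf)
    f[0] = -penalty
    prev = np.zeros(n + 1, dtype=int)
    for t in range(1, n + 1):
        best, arg = np.inf, 0
        for s in range(t):
            v = f[s] + cost(s, t) + penalty
            if v < best - 1e-12:
                best, arg = v, s
        f[t], prev[t] = best, arg
    cps = []
    t = n
    while t > 0:
        c = int(prev[t])
        if c > 0:
            cps.append(c)
        t = c
    return sorted(cps)


def psa_solar_elevation(timestamp, latitude: float, longitude: float) -> float:
    """PSA solar elevation (degrees), stated accuracy ~0.01 degrees."""
    ts = timestamp.astimezone(timezone.utc)
    jd = ts.timestamp() / 86400.0 + 2440587.5
    n = jd - 2451545.0
    hour = ts.hour + ts.minute / 60.0 + ts.second / 3600.0
    omega = 2.1429 - 0.0010394594 * n
    mean_long = 4.8950630 + 0.017202791698 * n
    mean_anom = 6.2400600 + 0.0172019699 * n
    ecl_long = (mean_long + 0.03341607 * np.sin(mean_anom)
                + 0.00034894 * np.sin(2 * mean_anom) - 0.0001134
                - 0.0000203 * np.sin(omega))
    obliq = 0.4090928 - 6.2140e-9 * n + 0.0000396 * np.cos(omega)
    ra = np.arctan2(np.cos(obliq) * np.sin(ecl_long), np.cos(ecl_long)) % (2 * np.pi)
    decl = np.arcsin(np.sin(obliq) * np.sin(ecl_long))
    gmst = 6.6974243242 + 0.0657098283 * n + hour
    lmst = np.deg2rad(gmst * 15.0 + longitude)
    ha = lmst - ra
    lat = np.deg2rad(latitude)
    zen = np.arccos(np.cos(lat) * np.cos(ha) * np.cos(decl)
                    + np.sin(decl) * np.sin(lat))
    zen += 4.26345151e-5 * np.sin(zen)  # parallax
    return float(90.0 - np.rad2deg(zen))


def grid_bisection_dates(fn, fractions, t0=1.0, t1=365.0, step=0.001):
    """Threshold dates by dense-grid scan + linear interpolation."""
    t = np.arange(t0, t1 + step, step)
    v = fn(t)
    vmin, vmax = v.min(), v.max()
    peak = int(np.argmax(v))
    out = {}
    for f in fractions:
        level = vmin + f * (vmax - vmin)
        rise = v[:peak + 1]
        idx = np.flatnonzero((rise[:-1] < level) & (rise[1:] >= level))
        if len(idx):
            j = idx[0]
            w = (level - v[j]) / (v[j + 1] - v[j])
            out[("rising", f)] = float(t[j] + w * step)
        fall = v[peak:]
        idx = np.flatnonzero((fall[:-1] >= level) & (fall[1:] < level))
        if len(idx):
            j = peak + idx[0]
            w = (level - v[j]) / (v[j + 1] - v[j])
            out[("falling", f)] = float(t[j] + w * step)
    return out


def sort_percentile(values, q: float) -> float:
    """Percentile with linear interpolation between order statistics,
    computed from first principles on the sorted sample."""
    v = np.sort(np.asarray(values, dtype=float))
    h = (len(v) - 1) * q / 100.0
    lo = int(np.floor(h))
    hi = min(lo + 1, len(v) - 1)
    return float(v[lo] + (h - lo) * (v[hi] - v[lo]))
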