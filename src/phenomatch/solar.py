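"""Solar elevation (geometric, no atmospheric refraction).

NOAA spreadsheet algorithm: geometric mean longitude/anomaly of the sun,
equation of center, apparent longitude, corrected obliquity, declination
and equation of time, then local hour angle from UTC and longitude.
Accuracy is of order 0.01 degrees for dates within a few centuries of
J2000, far beyond what a 10-degree elevation cut requires.  Timestamps
must carry a UTC offset; naive timestamps are rejected because a silently
wrong clock shifts the solar geometry by whole hours.
"""

from __future__ import annotations

from datetime import datetime, timezone

import numpy as np

__all__ = ["solar_elevation"]


def _to_utc(timestamp) -> datetime:
    ts = timestamp
    if hasattr(ts, "to_pydatetime"):
        ts = ts.to_pydatetime()
    if ts.tzinfo is None or ts.tzinfo.utcoffset(ts) is None:
        raise ValueError(
            "timestamp must be timezone-aware (naive timestamps are rejected "
            "to avoid silent solar-geometry errors)")
    return ts.astimezone(timezone.utc)


def solar_elevation(timestamp, latitude: float, longitude: float) -> float:
    """Geometric solar elevation in degrees above the horizon.

    ``longitude`` is positive east.  Returns a value in [-90, 90].
    """
    if not (-90.0 <= latitude <= 90.0 and -180.0 <= longitude <= 180.0):
        raise ValueError("invalid coordinates")
    ts = _to_utc(timestamp)
    jd = ts.timestamp() / 86400.0 + 2440587.5
    jc = (jd - 2451545.0) / 36525.0

    gml = np.deg2rad((280.46646 + jc * (36000.76983 + 0.0003032 * jc)) % 360.0)
    gma = np.deg2rad(357.52911 + jc * (35999.05029 - 0.0001537 * jc))
    ecc = 0.016708634 - jc * (0.000042037 + 0.0000001267 * jc)
    eqctr = (np.sin(gma) * (1.914602 - jc * (0.004817 + 0.000014 * jc))
             + np.sin(2 * gma) * (0.019993 - 0.000101 * jc)
             + np.sin(3 * gma) * 0.000289)
    true_long = np.rad2deg(gml) + eqctr
    omega = np.deg2rad(125.04 - 1934.136 * jc)
    app_long = np.deg2rad(true_long - 0.00569 - 0.00478 * np.sin(omega))

    mean_obliq = 23.0 + (26.0 + (21.448 - jc * (46.815 + jc * (0.00059 - jc * 0.001813))) / 60.0) / 60.0
    obliq = np.deg2rad(mean_obliq + 0.00256 * np.cos(omega))

    decl = np.arcsin(np.sin(obliq) * np.sin(app_long))

    var_y = np.tan(obliq / 2.0) ** 2
    eqtime = 4.0 * np.rad2deg(
        var_y * np.sin(2 * gml)
        - 2.0 * ecc * np.sin(gma)
        + 4.0 * ecc * var_y * np.sin(gma) * np.cos(2 * gml)
        - 0.5 * var_y ** 2 * np.sin(4 * gml)
        - 1.25 * ecc ** 2 * np.sin(2 * gma))  # minutes

    utc_minutes = ts.hour * 60.0 + ts.minute + ts.second / 60.0 + ts.microsecond / 6e7
    tst = (utc_minutes + eqtime + 4.0 * longitude) % 1440.0
    ha = np.deg2rad(tst / 4.0 - 180.0 if tst / 4.0 >= 0 else tst / 4.0 + 180.0)

    lat = np.deg2rad(latitude)
    cos_zen = np.sin(lat) * np.sin(decl) + np.cos(lat) * np.cos(decl) * np.cos(ha)
    zen = np.arccos(np.clip(cos_zen, -1.0, 1.0))
    return float(90.0 - np.rad2deg(zen))
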