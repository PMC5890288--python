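"""Satellite vegetation-index series and landcover context.

Works on a 3x3 pixel window of red/NIR nadir reflectances centred on the
camera location: NDVI = (NIR - red)/(NIR + red), the per-date min/max/
centre envelope across the window (a measure of landscape heterogeneity),
and the majority IGBP landcover code of the window.  Satellite transition
dates (greenup onset, dormancy onset) are ingested from CSV, not derived.
"""

from __future__ import annotations

import logging
from collections import Counter
from dataclasses import dataclass, field

import numpy as np
import pandas as pd

__all__ = [
    "ReflectancePair",
    "PixelWindow",
    "compute_ndvi",
    "window_envelope",
    "landcover_majority",
    "read_window_csv",
    "read_satellite_dates_csv",
]

log = logging.getLogger(__name__)


@dataclass(frozen=True)
class ReflectancePair:
    """Red (620-670 nm) and NIR (841-876 nm) nadir reflectances in [0, 1]."""

    band1: float
    band2: float

    def __post_init__(self) -> None:
        if not (0.0 <= self.band1 <= 1.0 and 0.0 <= self.band2 <= 1.0):
            raise ValueError("reflectances must lie in [0, 1]")


def compute_ndvi(pair) -> float:
    """NDVI = (band2 - band1)/(band1 + band2); zero-sum pairs are missing."""
    if isinstance(pair, ReflectancePair):
        b1, b2 = pair.band1, pair.band2
    else:
        b1, b2 = pair
    total = b1 + b2
    if total <= 0:
        return float("nan")
    return (b2 - b1) / total


@dataclass
class PixelWindow:
    """3x3 pixel window centred on the camera pixel.

    ``ndvi`` maps date -> array of 9 per-pixel NDVI values (row-major,
    centre at index 4; NaN = missing); ``igbp`` holds 9 integer landcover
    codes with None for masked cells.
    """

    ndvi: dict = field(default_factory=dict)
    igbp: list = field(default_factory=lambda: [None] * 9)

    def __post_init__(self) -> None:
        if len(self.igbp) != 9:
            raise ValueError("window must have exactly 9 cells")
        for k, v in self.ndvi.items():
            arr = np.asarray(v, dtype=float)
            if arr.shape != (9,):
                raise ValueError("each date needs 9 NDVI values")
            self.ndvi[k] = arr


def window_envelope(window: PixelWindow, date):
    """(min, max, centre) NDVI across the window at one date, ignoring
    missing pixels; all-missing dates yield (nan, nan, nan)."""
    vals = window.ndvi.get(date)
    if vals is None:
        raise KeyError(f"no data for date {date!r}")
    ok = np.isfinite(vals)
    if not ok.any():
        return (float("nan"),) * 3
    centre = float(vals[4]) if np.isfinite(vals[4]) else float("nan")
    return float(vals[ok].min()), float(vals[ok].max()), centre


def landcover_majority(window) -> int | None:
    """Modal IGBP code among unmasked cells; ties or all-masked -> None
    (unresolved: the caller decides, avoiding silent class bias)."""
    codes = window.igbp if isinstance(window, PixelWindow) else list(window)
    present = [c for c in codes if c is not None and not (
        isinstance(c, float) and np.isnan(c))]
    if not present:
        return None
    counts = Counter(int(c) for c in present).most_common()
    if len(counts) > 1 and counts[0][1] == counts[1][1]:
        log.info("landcover majority tie among %s; unresolved", counts[:2])
        return None
    return counts[0][0]


# ---------------------------------------------------------------------------
# I/O — flat CSV dialects (no HDF/EOS parsing)

def read_window_csv(path, igbp=None) -> PixelWindow:
    """Read per-pixel reflectances (columns: date or doy, row, col, band1,
    band2) into a PixelWindow of NDVI values."""
    df = pd.read_csv(path)
    datecol = "date" if "date" in df.columns else "doy"
    ndvi = {}
    for d, sub in df.groupby(datecol):
        vals = np.full(9, np.nan)
        for _, r in sub.iterrows():
            vals[int(r["row"]) * 3 + int(r["col"])] = compute_ndvi(
                (r["band1"], r["band2"]))
        ndvi[d] = vals
    return PixelWindow(ndvi=ndvi, igbp=list(igbp) if igbp is not None else [None] * 9)


def read_satellite_dates_csv(path) -> pd.DataFrame:
    """Satellite transition dates: columns pixel, year, direction, doy.

    At most two cycles per (pixel, year, direction) are accepted and both
    are preserved."""
    df = pd.read_csv(path)
    sizes = df.groupby(["pixel", "year", "direction"]).size()
    if (sizes > 2).any():
        raise ValueError("more than two cycles per pixel-year-direction")
    return df
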