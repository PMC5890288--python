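"""Canopy greenness (Gcc) from camera colour summaries.

The green chromatic coordinate of an image's region of interest is

    Gcc = G_DN / (R_DN + G_DN + B_DN),

the green share of the mean digital numbers over the ROI.  Images taken
with the sun below 10 degrees elevation, or that are too dark or too
bright, are discarded; the retained per-image values are then aggregated
over a centred 3-day moving window into daily series of the mean, median,
75th or 90th percentile.
"""

from __future__ import annotations

import logging
from dataclasses import dataclass, field
from datetime import datetime

import numpy as np
import pandas as pd

from .solar import solar_elevation

__all__ = [
    "RgbTriplet",
    "ImageSample",
    "GreennessSeries",
    "compute_gcc",
    "solar_elevation",
    "filter_samples",
    "aggregate_window",
    "read_image_samples_csv",
    "read_image_roi",
    "write_series_csv",
]

log = logging.getLogger(__name__)

STATISTICS = ("mean", "p50", "p75", "p90")


@dataclass(frozen=True)
class RgbTriplet:
    """Mean red/green/blue digital numbers over an ROI (0-255 each)."""

    r_dn: float
    g_dn: float
    b_dn: float

    def __post_init__(self) -> None:
        if min(self.r_dn, self.g_dn, self.b_dn) < 0:
            raise ValueError("digital numbers must be >= 0")

    def __iter__(self):
        return iter((self.r_dn, self.g_dn, self.b_dn))

    @property
    def brightness(self) -> float:
        return (self.r_dn + self.g_dn + self.b_dn) / 3.0


@dataclass(frozen=True)
class ImageSample:
    timestamp: datetime  # must be timezone-aware
    triplet: RgbTriplet
    latitude: float
    longitude: float

    def __post_init__(self) -> None:
        if not (-90.0 <= self.latitude <= 90.0 and -180.0 <= self.longitude <= 180.0):
            raise ValueError("invalid coordinates")


@dataclass
class GreennessSeries:
    """Daily greenness observations for one site x ROI.

    ``data`` holds columns ``date`` (strictly increasing timestamps) and
    ``gcc`` (in [0, 1]); an optional ``n`` column counts the per-image
    samples behind each aggregated value.
    """

    site_id: str
    veg_type: str
    statistic: str
    data: pd.DataFrame = field(repr=False)

    def __post_init__(self) -> None:
        d = self.data
        if not {"date", "gcc"} <= set(d.columns):
            raise ValueError("data needs 'date' and 'gcc' columns")
        if not d["date"].is_monotonic_increasing or d["date"].duplicated().any():
            raise ValueError("dates must be strictly increasing")
        g = d["gcc"].dropna()
        if len(g) and (g.min() < 0 or g.max() > 1):
            raise ValueError("gcc values must lie in [0, 1]")

    def __len__(self) -> int:
        return len(self.data)

    def day_axis(self) -> np.ndarray:
        """Continuous 1-based day-of-year axis (real-valued; crosses year
        boundaries monotonically relative to the first observation's year)."""
        dates = pd.to_datetime(self.data["date"])
        origin = pd.Timestamp(year=dates.iloc[0].year, month=1, day=1,
                              tz=dates.iloc[0].tz)
        return ((dates - origin) / pd.Timedelta(days=1)).to_numpy() + 1.0

    @property
    def year(self) -> int:
        return int(pd.to_datetime(self.data["date"]).iloc[0].year)


def compute_gcc(triplet) -> float:
    """Green chromatic coordinate of an RGB digital-number triplet.

    A zero-sum triplet is a missing value (NaN), not an error: all-black
    images occur in practice and must flow through as gaps.
    """
    r, g, b = triplet
    total = r + g + b
    if total <= 0:
        return float("nan")
    return g / total


def filter_samples(samples, min_elevation: float = 10.0,
                   brightness_bounds: tuple[float, float] = (30.0, 230.0)):
    """Retain samples with the sun at least ``min_elevation`` degrees up and
    mean brightness inside ``brightness_bounds`` (order preserved)."""
    low, high = brightness_bounds
    if not low < high:
        raise ValueError("brightness bounds must satisfy low < high")
    kept = [s for s in samples
            if low <= s.triplet.brightness <= high
            and solar_elevation(s.timestamp, s.latitude, s.longitude) >= min_elevation]
    if not kept:
        log.warning("filter_samples: no samples retained (n_in=%d)", len(list(samples)))
    return kept


def _percentile(values: np.ndarray, statistic: str) -> float:
    if statistic == "mean":
        return float(np.mean(values))
    q = {"p50": 50, "p75": 75, "p90": 90}[statistic]
    # linear interpolation between order statistics
    return float(np.percentile(values, q))


def aggregate_window(samples, statistic: str = "p90", window_days: int = 3,
                     mode: str = "sliding", site_id: str = "",
                     veg_type: str = "DB") -> GreennessSeries:
    """Aggregate per-image Gcc values into a daily greenness product.

    ``samples`` is a DataFrame with ``timestamp`` and ``gcc`` columns or a
    list of (timestamp, gcc) pairs.  ``mode='sliding'`` evaluates the
    statistic on a centred window for every calendar day with data;
    ``mode='binned'`` uses consecutive fixed ``window_days`` bins labelled
    by their centre day (the layout of released 3-day products).
    """
    if window_days < 1 or window_days % 2 == 0:
        raise ValueError("window_days must be odd and >= 1")
    if statistic not in STATISTICS:
        raise ValueError(f"statistic must be one of {STATISTICS}")
    if mode not in ("sliding", "binned"):
        raise ValueError("mode must be 'sliding' or 'binned'")

    df = samples if isinstance(samples, pd.DataFrame) else \
        pd.DataFrame(samples, columns=["timestamp", "gcc"])
    df = df.dropna(subset=["gcc"])
    ts = pd.to_datetime(df["timestamp"])
    days = ts.dt.normalize()
    half = window_days // 2

    rows = []
    if mode == "sliding":
        for day in sorted(days.unique()):
            m = (days >= day - pd.Timedelta(days=half)) & \
                (days <= day + pd.Timedelta(days=half))
            vals = df.loc[m.to_numpy(), "gcc"].to_numpy()
            rows.append({"date": day, "gcc": _percentile(vals, statistic),
                         "n": len(vals)})
    else:
        first = days.min()
        bin_idx = ((days - first) / pd.Timedelta(days=1)).astype(int) // window_days
        for b, sub in df.groupby(bin_idx.to_numpy()):
            centre = first + pd.Timedelta(days=int(b) * window_days + half)
            vals = sub["gcc"].to_numpy()
            rows.append({"date": centre, "gcc": _percentile(vals, statistic),
                         "n": len(vals)})
    out = pd.DataFrame(rows).sort_values("date").reset_index(drop=True)
    return GreennessSeries(site_id=site_id, veg_type=veg_type,
                           statistic=statistic, data=out)


# ---------------------------------------------------------------------------
# I/O

def read_image_samples_csv(path, latitude: float, longitude: float) -> list[ImageSample]:
    """Read a per-image CSV with columns timestamp, r_dn, g_dn, b_dn.

    Timestamps must carry a UTC offset (ISO 8601 with offset)."""
    df = pd.read_csv(path)
    samples = []
    for _, row in df.iterrows():
        ts = pd.Timestamp(row["timestamp"])
        if ts.tz is None:
            raise ValueError(f"naive timestamp in {path}: {row['timestamp']}")
        samples.append(ImageSample(timestamp=ts,
                                   triplet=RgbTriplet(row["r_dn"], row["g_dn"], row["b_dn"]),
                                   latitude=latitude, longitude=longitude))
    return samples


def read_image_roi(image_path, mask_path) -> RgbTriplet:
    """Mean DN triplet over the ROI (nonzero mask pixels) of an RGB image."""
    from PIL import Image

    img = np.asarray(Image.open(image_path).convert("RGB"), dtype=float)
    mask = np.asarray(Image.open(mask_path).convert("L")) > 0
    if mask.shape != img.shape[:2]:
        raise ValueError("mask shape does not match image")
    if not mask.any():
        raise ValueError("empty ROI mask")
    r, g, b = (img[..., i][mask].mean() for i in range(3))
    return RgbTriplet(r, g, b)


def write_series_csv(series: GreennessSeries, path) -> None:
    out = series.data.copy()
    out.insert(0, "site_id", series.site_id)
    out.insert(2, "statistic", series.statistic)
    cols = ["site_id", "date", "statistic", "gcc"] + \
        (["n"] if "n" in out.columns else [])
    out[cols].to_csv(path, index=False, date_format="%Y-%m-%dT%H:%M:%S%z")


def read_series_csv(path, veg_type: str = "DB") -> GreennessSeries:
    df = pd.read_csv(path, parse_dates=["date"])
    site = str(df["site_id"].iloc[0]) if "site_id" in df else ""
    stat = str(df["statistic"].iloc[0]) if "statistic" in df else "mean"
    keep = [c for c in ("date", "gcc", "n") if c in df.columns]
    return GreennessSeries(site_id=site, veg_type=veg_type, statistic=stat,
                           data=df[keep].reset_index(drop=True))
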