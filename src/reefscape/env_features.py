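"""Environmental descriptor scheme for seascape genomics.

Every raster series is summarised per pixel by three statistics — the
overall average (AVG), the highest calendar-month climatological mean (HM)
and the lowest (LM) — and, for daily series, by three standard deviations:
the SD of all daily values (SD.AVG) and the SDs of daily values within the
highest- and lowest-mean months (SD.HM, SD.LM).  Five daily variables
(SST, SSS, CHL, current speed, alkalinity) times six statistics, two
monthly variables (SPM, PAR) times three, plus the bleaching alert
frequency (BAF), depth and human population density give the standard
39-column feature table.

Heat stress follows the degree-heating convention: the daily hotspot is
the positive excess of SST over the maximum monthly-mean climatology
(MMM); an alert day is one whose trailing 14-day accumulated hotspot,
expressed in degC-weeks (sum / 7), reaches 4; BAF is the fraction of
alerted days.
"""

from __future__ import annotations

import tomllib
import warnings
from contextlib import contextmanager
from importlib import resources

import numpy as np
import pandas as pd

from reefscape.grids import KM_PER_DEG_LAT, RasterSeries, ReefGrid


@contextmanager
def _quiet_nan():
    """nan-reductions over all-NaN (land) pixels are expected."""
    with warnings.catch_warnings():
        warnings.filterwarnings("ignore", message="All-NaN slice")
        warnings.filterwarnings("ignore", message="Mean of empty slice")
        warnings.filterwarnings("ignore", message="Degrees of freedom")
        yield

DAILY_STATS = ("AVG", "HM", "LM", "SD.AVG", "SD.HM", "SD.LM")
MONTHLY_STATS = ("AVG", "HM", "LM")


def monthly_climatology(series: RasterSeries) -> np.ndarray:
    """Calendar-month climatological means, shape (12, R, C); months absent
    from the series are NaN.  Partial months at the series edges are
    included in their month's climatology."""
    months = series.month_index()
    out = np.full((12,) + series.grid.shape, np.nan)
    with _quiet_nan():
        for m in range(1, 13):
            sel = months == m
            if sel.any():
                out[m - 1] = np.nanmean(series.values[sel], axis=0)
    return out


def summary_stats(series: RasterSeries, temporal_kind: str) -> dict[str, np.ndarray]:
    """Per-pixel descriptor maps for one variable.

    ``temporal_kind`` is 'daily' (six statistics) or 'monthly' (three).
    All-missing pixels yield NaN throughout.
    """
    if temporal_kind not in ("daily", "monthly"):
        raise ValueError("temporal_kind must be 'daily' or 'monthly'")
    clim = monthly_climatology(series)
    with np.errstate(all="ignore"), _quiet_nan():
        avg = np.nanmean(series.values, axis=0)
        hm = np.nanmax(clim, axis=0)
        lm = np.nanmin(clim, axis=0)
    out = {"AVG": avg, "HM": hm, "LM": lm}
    if temporal_kind == "daily":
        months = series.month_index()
        hm_month = np.nanargmax(np.where(np.isnan(clim), -np.inf, clim), axis=0) + 1
        lm_month = np.nanargmin(np.where(np.isnan(clim), np.inf, clim), axis=0) + 1
        with np.errstate(all="ignore"), _quiet_nan():
            out["SD.AVG"] = np.nanstd(series.values, axis=0)
            out["SD.HM"] = _sd_within_month(series.values, months, hm_month)
            out["SD.LM"] = _sd_within_month(series.values, months, lm_month)
    for k in out:
        out[k] = np.where(series.mask, out[k], np.nan)
    return out


def _sd_within_month(values: np.ndarray, months: np.ndarray, month_of: np.ndarray) -> np.ndarray:
    """SD of daily values within one (per-pixel) calendar month."""
    sd = np.full(values.shape[1:], np.nan)
    for m in np.unique(month_of):
        pix = month_of == m
        sel = months == m
        if sel.any() and pix.any():
            with np.errstate(all="ignore"), _quiet_nan():
                sd[pix] = np.nanstd(values[sel][:, pix], axis=0)
    return sd


# ------------------------------------------------------------- alkalinity
def load_alkalinity_coefficients() -> dict:
    """Default polynomial coefficients (external reference values; see the
    packaged data file)."""
    with resources.files("reefscape.data").joinpath("alkalinity_subtropical.toml").open("rb") as fh:
        return tomllib.load(fh)


def alkalinity(
    sst_series: RasterSeries, sss_series: RasterSeries, coeffs: dict | None = None
) -> RasterSeries:
    """Seawater total alkalinity (umol/kg) from SST and SSS.

    Pointwise polynomial in (SSS - s0) and (SST - t0):
    AT = c0 + c1*dS + c2*dS^2 + c3*dT + c4*dT^2.  Missing in either input
    propagates.  Coefficients default to published subtropical reference
    values shipped as package data; pass ``coeffs`` to override.
    """
    if coeffs is None:
        coeffs = load_alkalinity_coefficients()
    if sst_series.values.shape != sss_series.values.shape:
        raise ValueError("SST and SSS series are not co-registered")
    ds = sss_series.values - coeffs["s0"]
    dt = sst_series.values - coeffs["t0"]
    at = (
        coeffs["c0"] + coeffs["c1"] * ds + coeffs["c2"] * ds**2
        + coeffs["c3"] * dt + coeffs["c4"] * dt**2
    )
    return RasterSeries(
        grid=sst_series.grid, times=sst_series.times, values=at,
        mask=sst_series.mask, name="AT", units="umol/kg",
    )


# ---------------------------------------------------------------- BAF
def max_monthly_mean(sst_series: RasterSeries) -> np.ndarray:
    """Per-pixel maximum of calendar-month climatological means (MMM)."""
    with _quiet_nan():
        return np.nanmax(monthly_climatology(sst_series), axis=0)


def bleaching_alert_frequency(
    sst_series: RasterSeries,
    climatology: np.ndarray | None = None,
    window_days: int = 14,
    threshold: float = 4.0,
    hotspot_floor: float = 0.0,
) -> np.ndarray:
    """Fraction of days under bleaching alert, per pixel, in [0, 1].

    Daily hotspot = max(0, SST - MMM), zeroed below ``hotspot_floor``; the
    trailing ``window_days`` hotspot sum divided by 7 is the accumulated
    heat stress in degC-weeks; a day is alerted when it reaches
    ``threshold``.  Only days with a full trailing window count.  The MMM
    climatology defaults to the series' own (:func:`max_monthly_mean`).
    """
    if sst_series.n_times < window_days:
        raise ValueError("series shorter than the accumulation window")
    if climatology is None:
        climatology = max_monthly_mean(sst_series)
    hot = np.maximum(sst_series.values - climatology[None], 0.0)
    hot = np.where(hot >= hotspot_floor, hot, 0.0)
    hot = np.nan_to_num(hot, nan=0.0)
    csum = np.cumsum(hot, axis=0)
    window_sum = csum[window_days - 1:].copy()
    window_sum[1:] -= csum[:-window_days]
    dhw = window_sum / 7.0
    alerts = (dhw >= threshold).sum(axis=0)
    baf = alerts / dhw.shape[0]
    return np.where(sst_series.mask, baf, np.nan)


# ----------------------------------------------------- spatial assignment
def buffer_mean(
    raster: np.ndarray, grid, points: pd.DataFrame, radius_km: float = 50.0
) -> np.ndarray:
    """Mean of raster pixels whose centers lie within a great-circle radius
    of each point (rows lon/lat).  Empty buffers yield NaN."""
    lats, lons = grid.lats(), grid.lons()
    plat = np.deg2rad(points["lat"].to_numpy(float))
    plon = np.deg2rad(points["lon"].to_numpy(float))
    glat = np.deg2rad(lats)[:, None] * np.ones_like(lons)[None, :]
    glon = np.ones_like(lats)[:, None] * np.deg2rad(lons)[None, :]
    out = np.empty(len(points))
    for i in range(len(points)):
        h = (
            np.sin((glat - plat[i]) / 2) ** 2
            + np.cos(glat) * np.cos(plat[i]) * np.sin((glon - plon[i]) / 2) ** 2
        )
        d = 2 * 6371.0 * np.arcsin(np.sqrt(np.clip(h, 0, 1)))
        sel = (d <= radius_km) & ~np.isnan(raster)
        with _quiet_nan():
            out[i] = np.nanmean(raster[sel]) if sel.any() else np.nan
    return out


def zonal_mean(raster: np.ndarray, reef_grid: ReefGrid) -> np.ndarray:
    """Mean of raster pixels belonging to each reef cell (NaN-aware)."""
    out = np.empty(len(reef_grid))
    with _quiet_nan():
        for i, pix in enumerate(reef_grid.cells["pixels"]):
            vals = np.array([raster[r, c] for (r, c) in pix], float)
            out[i] = np.nanmean(vals) if np.isfinite(vals).any() else np.nan
    return out


def extract_at_points(raster: np.ndarray, grid, points: pd.DataFrame,
                      mask: np.ndarray | None = None) -> np.ndarray:
    """Nearest-pixel raster value at each point (rows lon/lat); a point
    landing on a masked (land) pixel raises with the point named."""
    out = np.empty(len(points))
    for i, row in enumerate(points.itertuples()):
        r, c = grid.nearest_pixel(row.lon, row.lat)
        if mask is not None and not mask[r, c]:
            name = getattr(row, "id", i)
            raise ValueError(f"point {name!r} ({row.lon}, {row.lat}) falls on land")
        out[i] = raster[r, c]
    return out


# --------------------------------------------------------- feature tables
def build_feature_table(
    daily: dict[str, RasterSeries],
    monthly: dict[str, RasterSeries],
    static: dict[str, np.ndarray],
    assign,
) -> pd.DataFrame:
    """Assemble the descriptor table for sites or reef cells.

    ``daily``/``monthly`` map variable names to series; ``static`` maps
    names (e.g. BAF, DEPTH, POPDENS) to single 2-D maps; ``assign`` is a
    callable mapping a 2-D raster to a per-row vector (zonal or point
    extraction).  With 5 daily and 2 monthly variables plus 3 statics this
    yields the standard 39 columns.
    """
    cols: dict[str, np.ndarray] = {}
    for var, series in daily.items():
        for stat, m in summary_stats(series, "daily").items():
            cols[f"{var}.{stat}"] = assign(m)
    for var, series in monthly.items():
        for stat, m in summary_stats(series, "monthly").items():
            cols[f"{var}.{stat}"] = assign(m)
    for name, m in static.items():
        cols[name] = assign(m)
    return pd.DataFrame(cols)


def current_speed(u_series: RasterSeries, v_series: RasterSeries) -> RasterSeries:
    """Scalar current speed sqrt(u^2 + v^2), m/s."""
    return RasterSeries(
        grid=u_series.grid, times=u_series.times,
        values=np.hypot(u_series.values, v_series.values),
        mask=u_series.mask, name="CUR", units="m/s",
    )
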