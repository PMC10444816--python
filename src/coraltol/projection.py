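"""Future bleaching projections: delta-method bias correction of model SST,
future DHW under tolerance scenarios, bleaching events and high-frequency
bleaching trajectories with ensemble summaries.

Model (GCM-like) daily SST is seasonally adjusted against the observational
record over a shared baseline (1985–2010 by default) with the delta method:
subtract the model's smoothed daily climatology and add the observational
one, both smoothed with a circular 31-day running mean to remove daily-scale
noise. Future heat stress then uses the standard DHW algorithm with the
historical observational MMM (plus scenario offsets continued forward). A
year is a bleaching event when annual-max DHW reaches 8 °C-weeks (NOAA
Alert Level 2); a cell is in "high-frequency bleaching" in year y when at
least two events fall in the 10-year window centred on y (y−4 … y+5).
"""

from __future__ import annotations

import numpy as np
import pandas as pd
import xarray as xr

from .dhw import Climatology, ToleranceScenario, annual_max_dhw, dhw_for_series
from .series import DailySeries

BLEACHING_THRESHOLD = 8.0       # °C-weeks, Alert Level 2, reached or exceeded
HF_WINDOW_BEFORE = 4            # 10-year window centred on y: y−4 … y+5
HF_WINDOW_AFTER = 5
HF_MIN_EVENTS = 2
SMOOTH_WINDOW_DAYS = 31
DEFAULT_BASELINE = (1985, 2010)


def _fold_doy(index: pd.DatetimeIndex) -> np.ndarray:
    """Day-of-year 1..365 with Feb 29 folded into day 59 (leap-day handling)."""
    doy = index.dayofyear.to_numpy().copy()
    leap = index.is_leap_year
    doy[leap & (doy >= 60)] -= 1
    return doy


def smooth_daily_climatology(series: DailySeries,
                             baseline: tuple[int, int] = DEFAULT_BASELINE,
                             window: int = SMOOTH_WINDOW_DAYS) -> np.ndarray:
    """365 day-of-year means over the baseline, circularly smoothed.

    Day-of-year means are taken over the baseline years (Feb 29 folded into
    day 59), then a centred circular ``window``-day running mean removes
    daily-scale noise. ``window=1`` disables smoothing.
    """
    y0, y1 = int(baseline[0]), int(baseline[1])
    s0, s1 = series.years
    if y0 < s0 or y1 > s1:
        raise ValueError(
            f"baseline {y0}-{y1} not covered by series {series.cell_id!r} ({s0}-{s1})"
        )
    sub = series.sst[(series.dates.year >= y0) & (series.dates.year <= y1)]
    doy = _fold_doy(pd.DatetimeIndex(sub.index))
    raw = np.full(365, np.nan)
    grp = pd.Series(sub.to_numpy()).groupby(doy).mean()
    raw[grp.index.to_numpy() - 1] = grp.to_numpy()
    if np.any(np.isnan(raw)):
        missing = np.flatnonzero(np.isnan(raw)) + 1
        raise ValueError(f"baseline has no data for day(s) of year {missing[:5]}")
    return _circular_running_mean(raw, window)


def _circular_running_mean(values: np.ndarray, window: int) -> np.ndarray:
    if window <= 1:
        return values.copy()
    if window % 2 == 0:
        raise ValueError("smoothing window must be odd (centred)")
    half = window // 2
    padded = np.concatenate([values[-half:], values, values[:half]])
    kernel = np.ones(window) / window
    return np.convolve(padded, kernel, mode="valid")


def delta_correct(gcm: DailySeries, obs: DailySeries,
                  baseline: tuple[int, int] = DEFAULT_BASELINE,
                  window: int = SMOOTH_WINDOW_DAYS) -> DailySeries:
    """Delta-method seasonal adjustment of a model series against observations.

    adjusted(t) = gcm(t) − clim_gcm(doy t) + clim_obs(doy t), with both
    climatologies smoothed over the shared baseline. An identical model and
    observational series comes back unchanged; a constant model bias is
    removed exactly.
    """
    clim_g = smooth_daily_climatology(gcm, baseline, window)
    clim_o = smooth_daily_climatology(obs, baseline, window)
    doy = _fold_doy(gcm.dates)
    adj = gcm.sst.to_numpy() - clim_g[doy - 1] + clim_o[doy - 1]
    return DailySeries(gcm.cell_id, gcm.lat, gcm.lon,
                       pd.Series(adj, index=gcm.dates))


def detect_bleaching_years(annual_max: pd.Series,
                           threshold: float = BLEACHING_THRESHOLD) -> pd.Series:
    """Event ⇔ annual-max DHW ≥ 8 °C-weeks; missing years stay missing."""
    vals = annual_max.to_numpy(dtype=float)
    out = pd.Series(vals >= threshold, index=annual_max.index, dtype=object)
    out[~np.isfinite(vals)] = np.nan
    return out


def high_frequency_flags(events: pd.Series,
                         min_events: int = HF_MIN_EVENTS) -> pd.DataFrame:
    """Per-year high-frequency-bleaching flags over a centred decade.

    flag(y) ⇔ at least ``min_events`` events among years y−4 … y+5. Edge
    years use the truncated available window and carry ``truncated=True``.
    """
    years = np.asarray(events.index, dtype=int)
    ev = np.array([bool(v) if not pd.isna(v) else False
                   for v in pd.Series(events)])
    flags = np.zeros(len(years), dtype=bool)
    truncated = np.zeros(len(years), dtype=bool)
    for i, y in enumerate(years):
        lo, hi = y - HF_WINDOW_BEFORE, y + HF_WINDOW_AFTER
        in_win = (years >= lo) & (years <= hi)
        flags[i] = int(ev[in_win].sum()) >= min_events
        truncated[i] = lo < years.min() or hi > years.max()
    return pd.DataFrame({"hf_flag": flags, "truncated": truncated}, index=years)


def ensemble_trajectory(proportions: pd.DataFrame) -> pd.DataFrame:
    """Ensemble mean ± SE per year across GCM columns (SE = sd/√G).

    With a single GCM the mean is returned and SE is NaN with
    ``se_undefined=True``.
    """
    g = proportions.shape[1]
    if g < 1:
        raise ValueError("need at least one GCM column")
    mean = proportions.mean(axis=1)
    if g == 1:
        return pd.DataFrame({"mean": mean, "se": np.nan, "se_undefined": True})
    se = proportions.std(axis=1, ddof=1) / np.sqrt(g)
    return pd.DataFrame({"mean": mean, "se": se, "se_undefined": False})


# ---------------------------------------------------------------------------
# regridding operators (in-memory arrays; synthetic grids in tests)


def regrid_bilinear(da: xr.DataArray, lat, lon) -> xr.DataArray:
    """Bilinear interpolation onto target lat/lon (shared coarse GCM grid)."""
    return da.interp(lat=np.asarray(lat, float), lon=np.asarray(lon, float),
                     method="linear")


def regrid_nearest(da: xr.DataArray, lat, lon) -> xr.DataArray:
    """Nearest-neighbour overlay onto a fine (e.g. 0.05°) grid."""
    return da.interp(lat=np.asarray(lat, float), lon=np.asarray(lon, float),
                     method="nearest")


# ---------------------------------------------------------------------------
# end-to-end projection table


def project_cell(adjusted: DailySeries, clim: Climatology,
                 scenario: ToleranceScenario) -> pd.DataFrame:
    """Annual-max DHW, event and HF flags for one bias-corrected cell."""
    fld = dhw_for_series(adjusted, clim, scenario)
    amax = annual_max_dhw(fld)
    events = detect_bleaching_years(amax)
    hf = high_frequency_flags(events)
    return pd.DataFrame({
        "year": amax.index,
        "annual_max_dhw": amax.to_numpy(dtype=float),
        "bleaching_event": events.to_numpy(),
        "hf_flag": hf["hf_flag"].to_numpy(),
        "hf_truncated": hf["truncated"].to_numpy(),
    })


def project_ensemble(gcm_sst: dict[str, dict[str, DailySeries]],
                     obs_sst: dict[str, DailySeries],
                     clim: dict[str, Climatology],
                     scenario: ToleranceScenario, ssp: str,
                     baseline: tuple[int, int] = DEFAULT_BASELINE) -> pd.DataFrame:
    """Tidy projection table over cells × years × GCMs for one SSP/rate.

    ``gcm_sst`` maps gcm label → cell_id → model series; each series is
    delta-corrected against ``obs_sst`` over ``baseline`` first.
    """
    rows = []
    for gcm_label, cells in gcm_sst.items():
        for cid, series in cells.items():
            adj = delta_correct(series, obs_sst[cid], baseline)
            tab = project_cell(adj, clim[cid], scenario)
            tab.insert(0, "cell_id", cid)
            tab.insert(1, "gcm", gcm_label)
            tab.insert(2, "ssp", ssp)
            tab.insert(3, "rate", scenario.rate)
            rows.append(tab)
    return pd.concat(rows, ignore_index=True)


def hf_proportion_trajectory(table: pd.DataFrame) -> pd.DataFrame:
    """Per-year proportion of cells flagged, per GCM, plus ensemble mean ± SE."""
    prop = (table.pivot_table(index="year", columns="gcm", values="hf_flag",
                              aggfunc="mean"))
    out = ensemble_trajectory(prop)
    out.index.name = "year"
    return out
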