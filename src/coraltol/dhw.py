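"""Degree-heating-week (DHW) engine with tolerance-enhanced stress baselines.

Heat stress accumulation follows the NOAA Coral Reef Watch convention: the
daily HotSpot is the positive exceedance of SST over the maximum of monthly
mean climatologies (MMM), and DHW on day i is the 84-day rolling sum of
HotSpots/7, counting only days whose HotSpot is at least 1 °C. Thermal
tolerance enhancement is modelled as a stepwise annual increase Δ_y of the
stress baseline at a rate ρ (°C/decade) starting after a reference year, so
both the hotspot reference (MMM + Δ) and the effective MMM + Δ + 1 °C
accumulation threshold shift together.

Missing SST days are propagated, never imputed: a missing day yields a
missing HotSpot, and any missing HotSpot inside the 84-day window yields a
missing DHW for that day.
"""

from __future__ import annotations

from dataclasses import dataclass, field

import numpy as np
import pandas as pd

from .series import DailySeries

#: Length of the DHW accumulation window in days (12 weeks).
DHW_WINDOW_DAYS = 84
#: HotSpots below this value (°C) do not accumulate into DHW.
ACCUMULATION_CUTOFF = 1.0


@dataclass
class Climatology:
    """Monthly-mean climatology and its maximum (MMM) for one cell."""

    monthly_means: np.ndarray  # °C, Jan..Dec
    mmm: float                 # °C, max of the 12 monthly means
    period: tuple[int, int]    # [start_year, end_year], inclusive

    def __post_init__(self) -> None:
        self.monthly_means = np.asarray(self.monthly_means, dtype=float)
        if self.monthly_means.shape != (12,):
            raise ValueError("monthly_means must have 12 entries")
        if not np.isclose(self.mmm, np.nanmax(self.monthly_means)):
            raise ValueError("mmm must equal the maximum of the monthly means")
        if self.period[0] > self.period[1]:
            raise ValueError("climatology period is empty")


@dataclass
class ToleranceScenario:
    """Tolerance-enhancement rate ρ and the per-year baseline offsets it induces.

    Offsets are constant within each calendar year and step up at the Jan-1
    boundary (the end-of-year convention: steps land when temperatures are at
    their seasonal low), so Δ_y = ρ · max(0, y − start_year)/10.
    """

    rate: float        # °C per decade
    start_year: int
    offsets: dict[int, float] = field(repr=False)

    def offset_for(self, year: int) -> float:
        if year in self.offsets:
            return self.offsets[year]
        # extend linearly beyond the tabulated range (used by projections)
        return self.rate * max(0, year - self.start_year) / 10.0


@dataclass
class DHWSeries:
    """Per-day HotSpots and DHW for one cell, with warm-up flags.

    ``warmup`` marks the first 83 days, whose DHW is computed over the
    truncated available window; analyses should start after warm-up.
    """

    cell_id: str
    hotspots: pd.Series = field(repr=False)
    dhw: pd.Series = field(repr=False)
    warmup: pd.Series = field(repr=False)

    @property
    def dates(self) -> pd.DatetimeIndex:
        return pd.DatetimeIndex(self.dhw.index)


def compute_climatology(series: DailySeries, period: tuple[int, int]) -> Climatology:
    """Month-wise mean SST over ``period`` (inclusive year range) and its max.

    Every calendar month inside the period must contain at least one SST
    value; an entirely-empty month is an error naming the month. Feb 29
    participates in February's mean.
    """
    start, end = int(period[0]), int(period[1])
    y0, y1 = series.years
    if start < y0 or end > y1:
        raise ValueError(
            f"climatology period {start}-{end} outside data range {y0}-{y1}"
        )
    sub = series.sst[(series.dates.year >= start) & (series.dates.year <= end)]
    by_month = sub.groupby(sub.index.month).mean()
    means = np.full(12, np.nan)
    for m, v in by_month.items():
        means[m - 1] = v
    empty = [pd.Timestamp(2000, m, 1).strftime("%B") for m in range(1, 13)
             if np.isnan(means[m - 1])]
    if empty:
        raise ValueError(
            f"no SST data for month(s) {', '.join(empty)} within period {start}-{end}"
        )
    return Climatology(means, float(np.max(means)), (start, end))


def build_offsets(rate: float, years: tuple[int, int],
                  start_year: int = 1988) -> ToleranceScenario:
    """Tabulate baseline offsets Δ_y = rate · max(0, y − start_year)/10.

    ``rate`` is in °C/decade; each year past ``start_year`` adds rate/10 °C,
    applied at the boundary into that year.
    """
    if rate < 0:
        raise ValueError(f"enhancement rate must be non-negative, got {rate}")
    offsets = {y: rate * max(0, y - start_year) / 10.0
               for y in range(int(years[0]), int(years[1]) + 1)}
    return ToleranceScenario(float(rate), int(start_year), offsets)


def compute_hotspots(series: DailySeries, clim: Climatology,
                     scenario: ToleranceScenario | None = None) -> pd.Series:
    """Daily HotSpot_i = max(0, SST_i − (MMM + Δ_year)); missing SST propagates."""
    sst = series.sst
    if scenario is None:
        baseline = np.full(len(sst), clim.mmm)
    else:
        years = series.dates.year
        delta = np.array([scenario.offset_for(int(y)) for y in np.unique(years)])
        lut = dict(zip(np.unique(years), delta))
        baseline = clim.mmm + np.array([lut[int(y)] for y in years])
    hs = np.maximum(sst.to_numpy() - baseline, 0.0)
    hs[~np.isfinite(sst.to_numpy())] = np.nan
    return pd.Series(hs, index=sst.index)


def compute_dhw(hotspots: pd.Series, cell_id: str = "",
                cutoff: float = ACCUMULATION_CUTOFF) -> DHWSeries:
    """Rolling 84-day DHW in °C-weeks from daily HotSpots.

    Only days with HotSpot ≥ ``cutoff`` (1 °C; the boundary accumulates)
    contribute HotSpot/7. Any missing HotSpot inside the window makes that
    day's DHW missing. The first 83 days use the truncated window and are
    flagged as warm-up.
    """
    hs = np.asarray(hotspots, dtype=float)
    n = len(hs)
    contrib = np.where(np.isfinite(hs) & (hs >= cutoff), hs / 7.0, 0.0)
    # Accumulate each 84-day window oldest-day-first so the result is
    # bit-identical to a sequential per-window sum (adding 0.0 for
    # sub-cutoff days is an exact no-op).
    acc = np.zeros(n)
    for k in range(DHW_WINDOW_DAYS - 1, -1, -1):
        acc[k:] += contrib[: n - k]
    dhw = pd.Series(acc, index=hotspots.index)
    nan_in_window = (
        pd.Series(np.isnan(hs).astype(float), index=hotspots.index)
        .rolling(DHW_WINDOW_DAYS, min_periods=1).sum()
    )
    dhw[nan_in_window.to_numpy() > 0] = np.nan
    warmup = pd.Series(False, index=hotspots.index)
    warmup.iloc[: DHW_WINDOW_DAYS - 1] = True
    return DHWSeries(cell_id, pd.Series(hs, index=hotspots.index), dhw, warmup)


def dhw_for_series(series: DailySeries, clim: Climatology,
                   scenario: ToleranceScenario | None = None) -> DHWSeries:
    """Convenience: HotSpots then DHW for one cell under one scenario."""
    return compute_dhw(compute_hotspots(series, clim, scenario), series.cell_id)


def annual_max_dhw(dhw: DHWSeries, include_warmup: bool = False) -> pd.Series:
    """Per-calendar-year maximum DHW; years with all-missing DHW stay missing."""
    vals = dhw.dhw if include_warmup else dhw.dhw[~dhw.warmup]
    if vals.empty:
        return pd.Series(dtype=float)
    out = vals.groupby(vals.index.year).max()
    out.index.name = "year"
    return out


def annual_max_summary(per_cell: dict[str, pd.Series]) -> pd.DataFrame:
    """Cross-cell summary of annual maxima: mean, min and max per year."""
    df = pd.DataFrame(per_cell)
    return pd.DataFrame({
        "mean": df.mean(axis=1),
        "min": df.min(axis=1),
        "max": df.max(axis=1),
    })
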