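"""Daily SST series container and readers/writers.

A :class:`DailySeries` holds one georeferenced cell's daily sea-surface
temperature record on a strict daily calendar. Gaps are explicit NaNs, never
silently skipped; duplicate dates are rejected. Values outside a sanity window
(−5 … 40 °C) are rejected at construction, which catches unit errors (Kelvin,
tenths of a degree) early.
"""

from __future__ import annotations

from dataclasses import dataclass, field

import numpy as np
import pandas as pd
import xarray as xr

SST_SANITY_MIN = -5.0
SST_SANITY_MAX = 40.0

#: Width of a CoralTemp-style grid cell in decimal degrees.
CELL_SIZE_DEG = 0.05


@dataclass
class DailySeries:
    """Dated daily SST for one georeferenced cell.

    Parameters
    ----------
    cell_id : str
        Identifier of the grid cell.
    lat, lon : float
        Cell centre in decimal degrees.
    sst : pandas.Series
        Daily SST in °C indexed by a DatetimeIndex. The index is re-aligned
        to a complete daily calendar between its first and last date; days
        absent from the input become NaN (explicit missing markers).
    """

    cell_id: str
    lat: float
    lon: float
    sst: pd.Series = field(repr=False)

    def __post_init__(self) -> None:
        idx = pd.DatetimeIndex(self.sst.index)
        if idx.has_duplicates:
            dups = idx[idx.duplicated()].unique()
            raise ValueError(f"duplicate dates in series {self.cell_id!r}: {list(dups[:5])}")
        if not idx.is_monotonic_increasing:
            raise ValueError(f"dates must be strictly increasing in series {self.cell_id!r}")
        full = pd.date_range(idx[0], idx[-1], freq="D")
        values = pd.Series(np.asarray(self.sst, dtype=float), index=idx)
        values = values.reindex(full)  # make cadence gaps explicit NaNs
        finite = values.dropna()
        if len(finite) and ((finite < SST_SANITY_MIN) | (finite > SST_SANITY_MAX)).any():
            bad = finite[(finite < SST_SANITY_MIN) | (finite > SST_SANITY_MAX)]
            raise ValueError(
                f"SST outside sanity window [{SST_SANITY_MIN}, {SST_SANITY_MAX}] °C "
                f"in series {self.cell_id!r}, e.g. {bad.iloc[0]:.2f} on {bad.index[0].date()}"
            )
        self.sst = values

    @property
    def dates(self) -> pd.DatetimeIndex:
        return pd.DatetimeIndex(self.sst.index)

    @property
    def years(self) -> tuple[int, int]:
        return int(self.dates[0].year), int(self.dates[-1].year)

    def __len__(self) -> int:
        return len(self.sst)

    @classmethod
    def from_noleap(cls, cell_id: str, lat: float, lon: float,
                    start_year: int, values: np.ndarray) -> "DailySeries":
        """Build a series from a 365-day ("noleap") model calendar.

        Day-of-year d of year y maps to the Gregorian date with the same
        month/day; Feb 29 simply does not occur and is left missing in leap
        years. 360-day calendars have no faithful mapping and are rejected
        by :func:`reject_360_day`.
        """
        values = np.asarray(values, dtype=float)
        if values.size % 365 != 0:
            raise ValueError("noleap series length must be a multiple of 365")
        n_years = values.size // 365
        dates = []
        for i, y in enumerate(range(start_year, start_year + n_years)):
            base = pd.Timestamp(year=y, month=1, day=1)
            doy = np.arange(365)
            # skip Feb 29 (offset +1 from day index 59 onward in leap years)
            offs = doy + (doy >= 59).astype(int) if _is_leap(y) else doy
            dates.append(base + pd.to_timedelta(offs, unit="D"))
        idx = pd.DatetimeIndex(np.concatenate([d.values for d in dates]))
        return cls(cell_id, lat, lon, pd.Series(values, index=idx))


def _is_leap(year: int) -> bool:
    return (year % 4 == 0 and year % 100 != 0) or year % 400 == 0


def reject_360_day(calendar: str) -> None:
    """Raise for 360-day model calendars, which cannot map onto real dates."""
    if "360" in calendar:
        raise ValueError(
            "360-day model calendars are not supported: there is no faithful "
            "mapping onto the Gregorian calendar used by the observational record"
        )


# ---------------------------------------------------------------------------
# grid convention


def point_to_cell(lat: float, lon: float, cells: pd.DataFrame,
                  cell_size: float = CELL_SIZE_DEG) -> str:
    """Return the cell_id whose half-open interval [west, east) × [south, north)
    contains (lat, lon). ``cells`` needs columns cell_id, lat, lon (centres)."""
    half = cell_size / 2.0
    west = cells["lon"].to_numpy() - half
    south = cells["lat"].to_numpy() - half
    hit = (
        (lon >= west) & (lon < west + cell_size)
        & (lat >= south) & (lat < south + cell_size)
    )
    idx = np.flatnonzero(hit)
    if idx.size == 0:
        raise KeyError(f"no cell encapsulates point (lat={lat}, lon={lon})")
    return str(cells["cell_id"].iloc[idx[0]])


# ---------------------------------------------------------------------------
# IO


def read_sst_csv(path) -> dict[str, DailySeries]:
    """Read per-cell long-format CSV (cell_id, date ISO-8601, sst_c, lat, lon)."""
    df = pd.read_csv(path, parse_dates=["date"])
    required = {"cell_id", "date", "sst_c", "lat", "lon"}
    missing = required - set(df.columns)
    if missing:
        raise ValueError(f"SST CSV missing columns: {sorted(missing)}")
    out = {}
    for cid, grp in df.groupby("cell_id", sort=True):
        s = pd.Series(grp["sst_c"].to_numpy(), index=pd.DatetimeIndex(grp["date"]))
        out[str(cid)] = DailySeries(str(cid), float(grp["lat"].iloc[0]),
                                    float(grp["lon"].iloc[0]), s)
    return out


def write_sst_csv(series: dict[str, DailySeries], path) -> None:
    frames = []
    for cid in sorted(series):
        s = series[cid]
        frames.append(pd.DataFrame({
            "cell_id": cid,
            "date": s.dates.strftime("%Y-%m-%d"),
            "sst_c": s.sst.to_numpy(),
            "lat": s.lat,
            "lon": s.lon,
        }))
    pd.concat(frames, ignore_index=True).to_csv(path, index=False, float_format="%.6f")


def read_sst_netcdf(path) -> dict[str, DailySeries]:
    """Read CF-style gridded daily SST (dims time, lat, lon; variable ``sst``).

    Every grid point with at least one finite value becomes a cell named
    ``c<lat>_<lon>``. Uses xarray's scipy backend (classic NetCDF).
    """
    ds = xr.open_dataset(path, engine="scipy")
    cal = ds["time"].encoding.get("calendar", "standard")
    reject_360_day(str(cal))
    sst = ds["sst"]
    times = pd.DatetimeIndex(ds["time"].values)
    out = {}
    for lat in np.atleast_1d(ds["lat"].values):
        for lon in np.atleast_1d(ds["lon"].values):
            vals = np.asarray(sst.sel(lat=lat, lon=lon).values, dtype=float)
            if not np.isfinite(vals).any():
                continue
            cid = f"c{lat:.3f}_{lon:.3f}"
            out[cid] = DailySeries(cid, float(lat), float(lon),
                                   pd.Series(vals, index=times))
    ds.close()
    return out


def write_sst_netcdf(series: dict[str, DailySeries], path) -> None:
    """Write per-cell series back to a CF-style lat/lon/time grid (scipy engine)."""
    cids = sorted(series)
    lats = sorted({series[c].lat for c in cids})
    lons = sorted({series[c].lon for c in cids})
    t0 = min(series[c].dates[0] for c in cids)
    t1 = max(series[c].dates[-1] for c in cids)
    times = pd.date_range(t0, t1, freq="D")
    cube = np.full((len(times), len(lats), len(lons)), np.nan)
    li = {v: i for i, v in enumerate(lats)}
    lj = {v: j for j, v in enumerate(lons)}
    for c in cids:
        s = series[c]
        sub = s.sst.reindex(times)
        cube[:, li[s.lat], lj[s.lon]] = sub.to_numpy()
    ds = xr.Dataset(
        {"sst": (("time", "lat", "lon"), cube)},
        coords={"time": times, "lat": lats, "lon": lons},
    )
    ds["sst"].attrs.update(units="degC", long_name="sea surface temperature")
    ds.to_netcdf(path, engine="scipy")
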