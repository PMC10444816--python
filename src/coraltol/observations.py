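"""Bleaching survey records: severity scores, beta-ready proportions, DHW covariates.

Surveys record an ordinal bleaching severity score per site and date:
0 = no bleaching (0 %), 1 = mild (1–10 %), 2 = moderate (11–50 %),
3 = severe (> 50 %). For a beta-likelihood regression the scores are divided
by 3 and squeezed off the {0, 1} boundary with the Smithson–Verkuilen
transform (y·(n−1) + 0.5)/n, where n is the number of records in the
modelled dataset.
"""

from __future__ import annotations

import numpy as np
import pandas as pd

from .dhw import DHWSeries
from .series import point_to_cell

OBS_COLUMNS = ["record_id", "date", "day_known", "lat", "lon", "severity"]

_BIN_EDGES = (0.0, 10.0, 50.0)  # upper edges of scores 0,1,2; >50 is 3


def severity_from_percent(percent_bleached) -> np.ndarray | int:
    """Ordinal severity score from percent of corals bleached.

    0 % → 0; (0, 10] → 1; (10, 50] → 2; (50, 100] → 3.
    """
    p = np.asarray(percent_bleached, dtype=float)
    if np.any((p < 0) | (p > 100)):
        raise ValueError("percent bleached must be within [0, 100]")
    score = np.searchsorted(_BIN_EDGES, p, side="left")
    return score if score.ndim else int(score)


def transform_scores(scores, n: int) -> np.ndarray:
    """Map scores 0–3 to proportions strictly inside (0, 1).

    y = score/3, then (y·(n−1) + 0.5)/n with n the sample size of the
    modelled dataset; strictly increasing in score, → score/3 as n → ∞.
    """
    if n < 2:
        raise ValueError(f"sample size n must be at least 2, got {n}")
    s = np.asarray(scores, dtype=float)
    if np.any(~np.isin(s, [0.0, 1.0, 2.0, 3.0])):
        raise ValueError("severity scores must be integers in {0, 1, 2, 3}")
    y = s / 3.0
    return (y * (n - 1) + 0.5) / n


def load_observations(path) -> pd.DataFrame:
    """Read an observation CSV (record_id, date, day_known, lat, lon, severity
    [, percent]).

    ``date`` is ISO-8601; for month-only records the day is conventionally 15
    and ``day_known`` false. When a ``percent`` column is present it must be
    bin-consistent with ``severity`` or loading fails.
    """
    df = pd.read_csv(path, parse_dates=["date"])
    missing = set(OBS_COLUMNS) - set(df.columns)
    if missing:
        raise ValueError(f"observation CSV missing columns: {sorted(missing)}")
    if not df["severity"].isin([0, 1, 2, 3]).all():
        raise ValueError("severity must be an integer score in {0, 1, 2, 3}")
    df["day_known"] = df["day_known"].astype(bool)
    if "percent" in df.columns:
        has = df["percent"].notna()
        implied = severity_from_percent(df.loc[has, "percent"].to_numpy())
        bad = df.loc[has, "severity"].to_numpy() != implied
        if bad.any():
            rid = df.loc[has, "record_id"].to_numpy()[bad][0]
            raise ValueError(
                f"percent column inconsistent with severity bin (record {rid!r})"
            )
    return df


def write_observations(df: pd.DataFrame, path) -> None:
    out = df.copy()
    out["date"] = pd.DatetimeIndex(out["date"]).strftime("%Y-%m-%d")
    out.to_csv(path, index=False)


def attach_dhw(obs: pd.DataFrame, dhw_fields: dict[str, DHWSeries],
               cells: pd.DataFrame) -> pd.DataFrame:
    """Attach the encapsulating cell's DHW on each observation's date.

    Month-only records (day_known false) use the DHW of the 15th of the
    month. The cell is found by the half-open 0.05° grid convention. A date
    with missing DHW, or a point no cell covers, is an error naming the
    offender.
    """
    out = obs.copy()
    cell_ids, dhws = [], []
    for _, row in out.iterrows():
        cid = point_to_cell(float(row["lat"]), float(row["lon"]), cells)
        date = pd.Timestamp(row["date"])
        if not bool(row["day_known"]):
            date = date.replace(day=15)
        fld = dhw_fields.get(cid)
        if fld is None or date not in fld.dhw.index:
            raise KeyError(f"no DHW coverage for cell {cid!r} on {date.date()}")
        val = fld.dhw.loc[date]
        if not np.isfinite(val):
            raise ValueError(f"DHW missing on {date.date()} for cell {cid!r}")
        cell_ids.append(cid)
        dhws.append(float(val))
    out["cell_id"] = cell_ids
    out["dhw"] = dhws
    return out


def prepare_response(obs: pd.DataFrame, n: int | None = None) -> pd.DataFrame:
    """Add the transformed proportion column; n defaults to the record count."""
    out = obs.copy()
    n_eff = len(out) if n is None else int(n)
    out["proportion"] = transform_scores(out["severity"].to_numpy(), n_eff)
    return out
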