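"""Synthetic SST and bleaching-survey generator with known ground truth.

Emulates the statistical structure the analysis assumes, so every stage of
the pipeline is testable without satellite downloads: daily SST per cell
with a seasonal cycle, a linear warming trend, AR(1)-autocorrelated
anomalies and scheduled marine heatwaves; and bleaching surveys drawn from
the beta-logit response model with a Matérn-correlated latent field and a
known true tolerance-enhancement rate.

Default geometry is 20 cells on a 0.05° grid spanning roughly 100 km
(Palau-scale), which makes the 20 km Matérn correlation range meaningful.
The default heatwave schedule places three events of similar magnitude in
widely separated years (1998, 2010, 2017), so that divergent bleaching
responses between early and late events arise purely from the true
enhancement rate — the property the rate scan must detect.
"""

from __future__ import annotations

import json
from dataclasses import asdict, dataclass, field

import numpy as np
import pandas as pd
from scipy.signal import lfilter
from scipy.special import expit

from .dhw import DHWSeries, compute_climatology, build_offsets, dhw_for_series
from .observations import severity_from_percent
from .rate_scan import DEFAULT_RATES, run_rate_scan
from .series import CELL_SIZE_DEG, DailySeries
from .spatial import MaternParams, matern_covariance


@dataclass
class Heatwave:
    """A scheduled marine heatwave: half-sine SST pulse on the seasonal peak."""

    year: int
    duration_days: int = 75
    amplitude: float = 1.4      # °C above the seasonal cycle at pulse centre
    center_doy: int = 244       # around the seasonal SST maximum (early Sep)


@dataclass
class SyntheticTruth:
    """All generator parameters; stored with each dataset for reproducibility."""

    rho_true: float = 0.1           # °C/decade, true enhancement rate
    beta0: float = -3.5             # logit bleaching probability at DHW 0
    beta1: float = 0.6              # per °C-week logit slope
    theta: float = 10.0             # beta precision of percent-bleached
    matern: MaternParams = field(default_factory=lambda: MaternParams(20.0, 0.5))
    sst_mean: float = 28.5          # °C, Palau-like annual mean
    seasonal_amplitude: float = 1.0  # °C
    trend: float = 0.15             # °C/decade observed warming
    ar1_coef: float = 0.7           # daily anomaly persistence
    noise_sd: float = 0.2           # AR(1) innovation sd, °C
    heatwaves: tuple[Heatwave, ...] = (
        Heatwave(1998), Heatwave(2010), Heatwave(2017))
    start_year: int = 1988          # year the tolerance baseline starts rising
    seed: int = 0

    def to_json(self, path=None) -> str:
        payload = asdict(self)
        text = json.dumps(payload, indent=2)
        if path is not None:
            with open(path, "w") as fh:
                fh.write(text)
        return text


def default_cells(n_cells: int = 20, lat0: float = 7.0,
                  lon0: float = 134.45) -> pd.DataFrame:
    """n cells along a 0.05° meridional transect (~5.5 km spacing)."""
    return pd.DataFrame({
        "cell_id": [f"cell{i:02d}" for i in range(n_cells)],
        "lat": lat0 + CELL_SIZE_DEG * np.arange(n_cells),
        "lon": np.full(n_cells, lon0),
    })


def _ar1(n: int, coef: float, innov_sd: float, rng: np.random.Generator) -> np.ndarray:
    eps = rng.standard_normal(n) * innov_sd
    return lfilter([1.0], [1.0, -coef], eps)


def generate_sst(cells: pd.DataFrame, years: tuple[int, int],
                 truth: SyntheticTruth) -> dict[str, DailySeries]:
    """Per-cell daily SST: seasonal cycle + trend + AR(1) anomalies + heatwaves.

    Anomalies mix a shared regional AR(1) component with a smaller
    independent per-cell component (SST anomalies are spatially coherent at
    the ~100 km scale). Fully deterministic under ``truth.seed``.
    """
    if len(cells) < 1:
        raise ValueError("need at least one cell")
    y0, y1 = int(years[0]), int(years[1])
    if y1 - y0 + 1 < 5:
        raise ValueError("need at least 5 years of synthetic SST")
    if not (0 <= truth.ar1_coef < 1):
        raise ValueError("AR(1) coefficient must be in [0, 1)")
    if not (15.0 < truth.sst_mean < 33.0) or truth.noise_sd < 0:
        raise ValueError("SST parameters outside sanity bounds")
    rng = np.random.default_rng(truth.seed)
    dates = pd.date_range(f"{y0}-01-01", f"{y1}-12-31", freq="D")
    n = len(dates)
    doy = dates.dayofyear.to_numpy()
    frac_years = (dates - dates[0]).days.to_numpy() / 365.25
    seasonal = truth.seasonal_amplitude * np.sin(
        2.0 * np.pi * (doy - 152.75) / 365.0)
    trend = truth.trend / 10.0 * frac_years
    pulse = np.zeros(n)
    years_arr = dates.year.to_numpy()
    for hw in truth.heatwaves:
        center = np.flatnonzero((years_arr == hw.year) & (doy == hw.center_doy))
        if center.size == 0:
            continue
        t0 = center[0] - hw.duration_days // 2
        tt = np.arange(hw.duration_days)
        idx = t0 + tt
        ok = (idx >= 0) & (idx < n)
        pulse[idx[ok]] += hw.amplitude * np.sin(np.pi * (tt[ok] + 0.5) / hw.duration_days)

    regional = _ar1(n, truth.ar1_coef, truth.noise_sd * 0.8, rng)
    out = {}
    lat_span = max(cells["lat"].max() - cells["lat"].min(), 1e-9)
    for _, row in cells.iterrows():
        local = _ar1(n, truth.ar1_coef, truth.noise_sd * 0.6, rng)
        # mild meridional gradient: warmer toward the equatorward end
        offset = -0.1 * (row["lat"] - cells["lat"].min()) / lat_span
        sst = truth.sst_mean + offset + seasonal + trend + pulse + regional + local
        out[str(row["cell_id"])] = DailySeries(
            str(row["cell_id"]), float(row["lat"]), float(row["lon"]),
            pd.Series(sst, index=dates))
    return out


def true_dhw_fields(sst: dict[str, DailySeries], truth: SyntheticTruth,
                    clim_period: tuple[int, int] = (1985, 2012)) -> dict[str, DHWSeries]:
    """DHW per cell under the generator's true enhancement rate."""
    years = (min(s.years[0] for s in sst.values()),
             max(s.years[1] for s in sst.values()))
    scenario = build_offsets(truth.rho_true, years, truth.start_year)
    return {cid: dhw_for_series(s, compute_climatology(s, clim_period), scenario)
            for cid, s in sst.items()}


def default_survey_dates(truth: SyntheticTruth) -> list[str]:
    """Surveys during/after each heatwave plus non-event years (2014–2016)."""
    dates = []
    for hw in truth.heatwaves:
        dates += [f"{hw.year}-09-15", f"{hw.year}-10-01"]
    dates += ["2014-09-15", "2015-09-15", "2016-09-15"]
    return sorted(dates)


def generate_surveys(dhw_truth: dict[str, DHWSeries], cells: pd.DataFrame,
                     truth: SyntheticTruth, n_obs: int,
                     survey_dates=None, seed: int | None = None) -> pd.DataFrame:
    """Draw bleaching observations from the beta-logit response model.

    Sites are uniform within randomly chosen cells; a Matérn latent field u
    is drawn at the sites; percent-bleached comes from
    Beta(mean = logistic(beta0 + beta1·DHW + u), precision = theta),
    reported to whole percent as surveyors do (so sub-0.5 % bleaching is
    recorded as "no bleaching"), and binned to the ordinal severity score.
    Same seed → identical records.
    """
    if n_obs < 1:
        raise ValueError("n_obs must be at least 1")
    rng = np.random.default_rng(truth.seed + 1 if seed is None else seed)
    if survey_dates is None:
        survey_dates = default_survey_dates(truth)
    survey_dates = pd.DatetimeIndex(sorted(pd.Timestamp(d) for d in survey_dates))
    any_field = next(iter(dhw_truth.values()))
    if (survey_dates.min() < any_field.dates.min()
            or survey_dates.max() > any_field.dates.max()):
        raise ValueError("survey dates outside SST coverage")

    cell_ids = cells["cell_id"].to_numpy()
    pick_cell = rng.integers(0, len(cell_ids), size=n_obs)
    jit_lat = rng.uniform(-CELL_SIZE_DEG / 2, CELL_SIZE_DEG / 2, size=n_obs)
    jit_lon = rng.uniform(-CELL_SIZE_DEG / 2, CELL_SIZE_DEG / 2, size=n_obs)
    lat = cells["lat"].to_numpy()[pick_cell] + jit_lat * 0.999
    lon = cells["lon"].to_numpy()[pick_cell] + jit_lon * 0.999
    dates = survey_dates[rng.integers(0, len(survey_dates), size=n_obs)]

    dhw = np.array([
        float(dhw_truth[str(cell_ids[c])].dhw.loc[d])
        for c, d in zip(pick_cell, dates)
    ])
    cov = matern_covariance(lat, lon, truth.matern)
    u = np.linalg.cholesky(cov) @ rng.standard_normal(n_obs)
    pi = expit(truth.beta0 + truth.beta1 * dhw + u)
    percent = np.round(100.0 * rng.beta(pi * truth.theta, (1.0 - pi) * truth.theta))
    severity = severity_from_percent(percent)
    return pd.DataFrame({
        "record_id": [f"r{i:04d}" for i in range(n_obs)],
        "date": dates,
        "day_known": True,
        "lat": lat,
        "lon": lon,
        "severity": severity,
        "percent": percent,
        "true_dhw": dhw,
        "true_u": u,
    })


def simulate_beta_response(dhw, beta0: float, beta1: float, theta: float,
                           rng: np.random.Generator,
                           u: np.ndarray | None = None) -> np.ndarray:
    """Draw (0,1) responses directly from the fitted model's likelihood.

    Used for parameter-recovery studies of :class:`SpatialBetaModel`, where
    the generative model must match the fitted one exactly (no severity
    binning)."""
    d = np.asarray(dhw, dtype=float)
    eta = beta0 + beta1 * d + (0.0 if u is None else u)
    pi = expit(eta)
    y = rng.beta(pi * theta, (1.0 - pi) * theta)
    return np.clip(y, 1e-9, 1.0 - 1e-9)


def recovery_experiment(rho_true: float, n_obs: int = 300, replicates: int = 20,
                        master_seed: int = 0, rates=DEFAULT_RATES,
                        n_cells: int = 20, years: tuple[int, int] = (1985, 2020),
                        spatial: bool = False, draws: int = 200) -> dict:
    """End-to-end recovery: generate → scan → select, replicated.

    Each replicate generates fresh SST and surveys under ``rho_true``, runs
    the 13-rate scan, and records the selected rate. Reports the selection
    distribution, the modal rate, the fraction of replicates selecting
    within one grid step of truth, and 95%-interval coverage of (beta0,
    beta1) from the fit at the true rate.
    """
    rates = np.asarray(sorted(rates), dtype=float)
    step = float(np.min(np.diff(rates))) if len(rates) > 1 else 0.0
    seeds = np.random.SeedSequence(master_seed).generate_state(replicates) % (2 ** 31)
    selected, covered0, covered1, flat_warnings = [], [], [], 0
    for rep in range(replicates):
        seed = int(seeds[rep])
        truth = SyntheticTruth(rho_true=rho_true, seed=seed)
        cells = default_cells(n_cells)
        sst = generate_sst(cells, years, truth)
        clim = {cid: compute_climatology(s, (1985, 2012)) for cid, s in sst.items()}
        fields = true_dhw_fields(sst, truth)
        obs = generate_surveys(fields, cells, truth, n_obs)
        scan = run_rate_scan(sst, obs[["record_id", "date", "day_known", "lat",
                                       "lon", "severity"]],
                             clim, cells, rates, spatial=spatial,
                             seed=seed, draws=draws)
        selected.append(scan.best_rate)
        flat_warnings += int(scan.flat_profile)
        true_rate = float(rates[np.argmin(np.abs(rates - rho_true))])
        fit = scan.fits.get(true_rate)
        if fit is not None:
            ci = fit.conf_int()
            covered0.append(ci.loc["beta0", "lower"] <= truth.beta0 <= ci.loc["beta0", "upper"])
            covered1.append(ci.loc["beta1", "lower"] <= truth.beta1 <= ci.loc["beta1", "upper"])
    selected = np.asarray(selected)
    vals, counts = np.unique(selected, return_counts=True)
    modal = float(vals[np.argmax(counts)])
    within = float(np.mean(np.abs(selected - rho_true) <= step + 1e-9))
    return {
        "rho_true": float(rho_true),
        "replicates": int(replicates),
        "n_obs": int(n_obs),
        "selected_rates": selected.tolist(),
        "modal_rate": modal,
        "within_one_step": within,
        "flat_profile_warnings": int(flat_warnings),
        "coverage_beta0": float(np.mean(covered0)) if covered0 else np.nan,
        "coverage_beta1": float(np.mean(covered1)) if covered1 else np.nan,
        "grid_step": step,
        "master_seed": int(master_seed),
        "pass": bool(abs(modal - rho_true) <= step + 1e-9),
    }
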