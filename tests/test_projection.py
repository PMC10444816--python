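"""Projections: delta correction, bleaching events, high-frequency flags."""

import numpy as np
import pandas as pd
import pytest
import xarray as xr
from hypothesis import given, settings
from hypothesis import strategies as st

from coraltol import (
    DailySeries,
    build_offsets,
    compute_climatology,
    delta_correct,
    detect_bleaching_years,
    ensemble_trajectory,
    high_frequency_flags,
    hf_proportion_trajectory,
    project_cell,
    project_ensemble,
    regrid_bilinear,
    regrid_nearest,
    smooth_daily_climatology,
)
from coraltol.projection import _fold_doy
from coraltol.series import reject_360_day
from coraltol.synthetic import SyntheticTruth, default_cells, generate_sst

BOXCAR_365 = np.sin(31 * np.pi / 365) / (31 * np.sin(np.pi / 365))  # ≈ 0.98819


def naive_hf_flags(events):
    """Brute-force 10-year-window counter (y-4 .. y+5, >= 2 events)."""
    years = np.asarray(events.index, dtype=int)
    ev = np.asarray(events, dtype=bool)
    out = []
    for y in years:
        count = sum(bool(e) for yy, e in zip(years, ev) if y - 4 <= yy <= y + 5)
        out.append(count >= 2)
    return np.asarray(out)


@pytest.fixture(scope="module")
def obs_series():
    truth = SyntheticTruth(rho_true=0.0, seed=9)
    return generate_sst(default_cells(1), (1985, 2012), truth)["cell00"]


class TestSmoothClimatology:
    def test_constant_series_identity(self, constant_series):
        clim = smooth_daily_climatology(constant_series, (1985, 2010))
        np.testing.assert_allclose(clim, 28.0)

    def test_sinusoid_damped_by_boxcar_factor(self):
        idx = pd.date_range("1985-01-01", "2010-12-31", freq="D")
        fd = _fold_doy(idx)
        vals = 28.0 + np.sin(2 * np.pi * (fd - 1) / 365.0)
        s = DailySeries("c0", 7.0, 134.5, pd.Series(vals, index=idx))
        clim = smooth_daily_climatology(s, (1985, 2010))
        doy = np.arange(1, 366)
        expected = 28.0 + BOXCAR_365 * np.sin(2 * np.pi * (doy - 1) / 365.0)
        np.testing.assert_allclose(clim, expected, atol=1e-12)

    def test_single_spike_spread_by_linearity(self):
        idx = pd.date_range("1985-01-01", "1990-12-31", freq="D")
        vals = np.full(len(idx), 28.0)
        vals[np.flatnonzero(idx == "1987-07-01")[0]] += 5.0
        s = DailySeries("c0", 7.0, 134.5, pd.Series(vals, index=idx))
        clim = smooth_daily_climatology(s, (1985, 1990))
        n_years = 6
        spike_doy = pd.Timestamp("1987-07-01").dayofyear  # non-leap year
        assert clim[spike_doy - 1] == pytest.approx(28.0 + 5.0 / (31 * n_years))
        # mass spread over exactly 31 days
        assert np.sum(clim > 28.0 + 1e-12) == 31

    def test_uncovered_baseline_errors(self, constant_series):
        with pytest.raises(ValueError, match="not covered"):
            smooth_daily_climatology(constant_series, (1980, 2010))


class TestDeltaCorrect:
    def test_identity_when_gcm_equals_obs(self, obs_series):
        adj = delta_correct(obs_series, obs_series, (1985, 2010))
        np.testing.assert_array_equal(adj.sst.to_numpy(), obs_series.sst.to_numpy())

    def test_constant_bias_removed_exactly(self, obs_series):
        gcm = DailySeries("c0", obs_series.lat, obs_series.lon, obs_series.sst + 2.0)
        adj = delta_correct(gcm, obs_series, (1985, 2010))
        np.testing.assert_allclose(adj.sst, obs_series.sst, atol=1e-12)

    def test_seasonal_bias_corrected_in_window_interior(self, obs_series):
        fd = _fold_doy(obs_series.dates)
        bias = np.where((fd >= 150) & (fd <= 250), 1.5, 0.0)
        gcm = DailySeries("c0", obs_series.lat, obs_series.lon,
                          pd.Series(obs_series.sst.to_numpy() + bias,
                                    index=obs_series.dates))
        adj = delta_correct(gcm, obs_series, (1985, 2010))
        co = smooth_daily_climatology(obs_series, (1985, 2010))
        ca = smooth_daily_climatology(adj, (1985, 2010))
        # exact at least 31 days inside the biased season
        np.testing.assert_allclose(ca[180:219], co[180:219], atol=1e-9)

    def test_unsmoothed_identity_everywhere(self, obs_series):
        fd = _fold_doy(obs_series.dates)
        bias = np.where((fd >= 150) & (fd <= 250), 1.5, 0.0)
        gcm = DailySeries("c0", obs_series.lat, obs_series.lon,
                          pd.Series(obs_series.sst.to_numpy() + bias,
                                    index=obs_series.dates))
        adj = delta_correct(gcm, obs_series, (1985, 2010), window=1)
        co = smooth_daily_climatology(obs_series, (1985, 2010), window=1)
        ca = smooth_daily_climatology(adj, (1985, 2010), window=1)
        np.testing.assert_allclose(ca, co, atol=1e-9)

    def test_360_day_calendar_rejected(self):
        with pytest.raises(ValueError, match="360-day"):
            reject_360_day("360_day")

    def test_noleap_calendar_mapping(self):
        vals = np.tile(np.arange(365, dtype=float) / 100 + 25.0, 2)
        s = DailySeries.from_noleap("c0", 7.0, 134.5, 2003, vals)  # 2004 is leap
        assert s.sst.loc["2003-03-01"] == pytest.approx(25.59)
        assert s.sst.loc["2004-03-01"] == pytest.approx(25.59)
        assert pd.Timestamp("2004-02-29") in s.sst.index


class TestBleachingEvents:
    def test_threshold_boundary_included(self):
        am = pd.Series({2000: 8.0, 2001: 7.99, 2002: 0.0})
        ev = detect_bleaching_years(am)
        assert ev.loc[2000] == True and ev.loc[2001] == False  # noqa: E712

    def test_missing_year_stays_missing(self):
        ev = detect_bleaching_years(pd.Series({2000: np.nan, 2001: 9.0}))
        assert ev.isna().loc[2000] and ev.loc[2001] == True  # noqa: E712


class TestHighFrequencyFlags:
    def _events(self, years, true_years):
        return pd.Series([y in true_years for y in years], index=years)

    def test_two_events_in_window_flags_center(self):
        years = range(2000, 2021)
        ev = self._events(years, {2009, 2012})  # y-1 and y+2 around 2010
        flags = high_frequency_flags(ev)
        assert flags.loc[2010, "hf_flag"]

    def test_single_event_never_flags(self):
        years = range(2000, 2021)
        flags = high_frequency_flags(self._events(years, {2010}))
        assert not flags["hf_flag"].any()

    def test_annual_events_flag_everywhere(self):
        years = range(2000, 2021)
        flags = high_frequency_flags(self._events(years, set(years)))
        assert flags["hf_flag"].all()

    def test_truncation_marked_at_edges(self):
        years = range(2000, 2021)
        flags = high_frequency_flags(self._events(years, set()))
        assert flags.loc[2000, "truncated"] and flags.loc[2020, "truncated"]
        assert not flags.loc[2010, "truncated"]

    def test_events_outside_window_do_not_matter(self):
        years = range(2000, 2031)
        a = high_frequency_flags(self._events(years, {2001, 2002}))
        b = high_frequency_flags(self._events(years, {2001, 2002, 2025, 2026}))
        # flags for 2010 (window 2006..2015) identical in both
        assert a.loc[2010, "hf_flag"] == b.loc[2010, "hf_flag"] == False  # noqa: E712

    @settings(derandomize=True, max_examples=60)
    @given(st.integers(min_value=0, max_value=2 ** 32 - 1))
    def test_oracle_equivalence_random_event_strings(self, seed):
        rng = np.random.default_rng(seed)
        years = np.arange(2000, 2100)
        ev = pd.Series(rng.random(100) < 0.15, index=years)
        got = high_frequency_flags(ev)["hf_flag"].to_numpy()
        np.testing.assert_array_equal(got, naive_hf_flags(ev))


class TestEnsemble:
    def test_identical_gcms_zero_se(self):
        df = pd.DataFrame({"g1": [0.5, 0.7], "g2": [0.5, 0.7]})
        out = ensemble_trajectory(df)
        np.testing.assert_allclose(out["se"], 0.0)

    def test_two_gcm_example(self):
        out = ensemble_trajectory(pd.DataFrame({"g1": [0.2], "g2": [0.4]}))
        assert out["mean"].iloc[0] == pytest.approx(0.3)
        assert out["se"].iloc[0] == pytest.approx(0.1)

    def test_all_ones(self):
        out = ensemble_trajectory(pd.DataFrame({"g1": [1.0], "g2": [1.0], "g3": [1.0]}))
        assert out["mean"].iloc[0] == 1.0 and out["se"].iloc[0] == 0.0

    def test_single_gcm_se_undefined(self):
        out = ensemble_trajectory(pd.DataFrame({"g1": [0.2]}))
        assert out["se_undefined"].iloc[0] and np.isnan(out["se"].iloc[0])


class TestRegrid:
    def test_bilinear_exact_on_linear_field(self):
        lat = np.arange(5.0, 8.01, 1.0)
        lon = np.arange(130.0, 136.01, 1.0)
        data = lat[:, None] * 2.0 + lon[None, :] * 0.5
        da = xr.DataArray(data, coords={"lat": lat, "lon": lon}, dims=("lat", "lon"))
        out = regrid_bilinear(da, [5.5, 6.25], [131.5])
        np.testing.assert_allclose(out.values,
                                   np.array([[5.5 * 2 + 131.5 * 0.5],
                                             [6.25 * 2 + 131.5 * 0.5]]))

    def test_nearest_picks_closest_cell(self):
        lat = np.array([5.0, 6.0])
        lon = np.array([130.0, 131.0])
        da = xr.DataArray(np.array([[1.0, 2.0], [3.0, 4.0]]),
                          coords={"lat": lat, "lon": lon}, dims=("lat", "lon"))
        out = regrid_nearest(da, [5.1], [130.9])
        assert out.values[0, 0] == 2.0


class TestProjectionPipeline:
    @pytest.fixture(scope="class")
    def projection_setup(self):
        truth = SyntheticTruth(rho_true=0.0, seed=13, trend=0.8)
        cells = default_cells(3)
        obs_sst = generate_sst(cells, (1985, 2050), truth)
        clim = {cid: compute_climatology(s, (1985, 2012))
                for cid, s in obs_sst.items()}
        gcm_truth = SyntheticTruth(rho_true=0.0, seed=14, trend=0.8, sst_mean=29.5)
        gcm_sst = {"gcmA": generate_sst(cells, (1985, 2050), gcm_truth)}
        return obs_sst, gcm_sst, clim

    def test_table_schema_and_hf_consistency(self, projection_setup):
        obs_sst, gcm_sst, clim = projection_setup
        scenario = build_offsets(0.0, (1985, 2050))
        table = project_ensemble(gcm_sst, obs_sst, clim, scenario, ssp="ssp585")
        assert {"cell_id", "gcm", "ssp", "rate", "year", "annual_max_dhw",
                "bleaching_event", "hf_flag"} <= set(table.columns)
        traj = hf_proportion_trajectory(table)
        assert ((traj["mean"] >= 0) & (traj["mean"] <= 1)).all()

    def test_monotone_in_enhancement_rate(self, projection_setup):
        obs_sst, gcm_sst, clim = projection_setup
        prev = None
        for rate in [0.0, 0.15, 0.3]:
            scenario = build_offsets(rate, (1985, 2050))
            table = project_ensemble(gcm_sst, obs_sst, clim, scenario, ssp="x")
            key = table.set_index(["cell_id", "year"])
            if prev is not None:
                assert (key["annual_max_dhw"] <= prev["annual_max_dhw"] + 1e-9).all()
                assert key["bleaching_event"].sum() <= prev["bleaching_event"].sum()
                assert key["hf_flag"].sum() <= prev["hf_flag"].sum()
            prev = key

    def test_single_cell_projection(self, projection_setup):
        obs_sst, gcm_sst, clim = projection_setup
        adj = delta_correct(gcm_sst["gcmA"]["cell00"], obs_sst["cell00"])
        tab = project_cell(adj, clim["cell00"], build_offsets(0.1, (1985, 2050)))
        assert (tab["annual_max_dhw"].dropna() >= 0).all()
        assert tab["year"].is_monotonic_increasing
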