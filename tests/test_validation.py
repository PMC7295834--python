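"""Station comparison: windowing, observed MRT, metrics, cell extraction."""

import numpy as np
import pandas as pd
import pytest
from hypothesis import given, settings, strategies as st

from mrtgrid import STEFAN_BOLTZMANN, grid, validation
from mrtgrid.mrt import HumanConfig
from mrtgrid.synthetic import ClearSkyScene, make_flux_dataset, synthetic_station


def make_station(df, lat=47.0, lon=7.0, sid="TST"):
    return validation.StationSeries(station_id=sid, latitude=lat,
                                    longitude=lon, data=df)


class TestWindowAverage:
    def test_constant_series(self):
        idx = pd.date_range("2018-06-08", periods=48, freq="30min")
        s = pd.Series(42.0, index=idx)
        out = validation.window_average(s, 3)
        assert (out == 42.0).all()
        assert len(out) == 8

    def test_linear_ramp_midpoint(self):
        # samples at 0, 20, ..., 160 min within one 3-h window average to
        # the 80-min value of the ramp
        idx = pd.date_range("2018-06-08", periods=9, freq="20min")
        s = pd.Series(np.arange(9, dtype=float), index=idx)
        out = validation.window_average(s, 3)
        assert out.iloc[0] == pytest.approx(4.0)

    def test_sparse_window_missing(self):
        idx = pd.date_range("2018-06-08", periods=18, freq="10min")
        s = pd.Series(1.0, index=idx)
        s.iloc[2:] = np.nan  # 2 of 18 expected samples valid: under 50%
        out = validation.window_average(s, 3)
        assert np.isnan(out.iloc[0])

    def test_alignment_at_midnight(self):
        idx = pd.date_range("2018-06-08 02:00", periods=12, freq="1h")
        out = validation.window_average(pd.Series(1.0, index=idx), 3)
        assert out.index[0] == pd.Timestamp("2018-06-08 00:00")

    def test_bad_width(self):
        idx = pd.date_range("2018-06-08", periods=4, freq="1h")
        with pytest.raises(ValueError):
            validation.window_average(pd.Series(1.0, index=idx), 5)


class TestStationMRT:
    def test_black_body_enclosure(self):
        idx = pd.date_range("2018-06-08", periods=3, freq="1h")
        L = STEFAN_BOLTZMANN * 293.15 ** 4
        df = pd.DataFrame({"dni": 0.0, "s_diffuse": 0.0, "s_up": 0.0,
                           "l_dn": L, "l_up": L}, index=idx)
        out = validation.station_mrt(make_station(df))
        np.testing.assert_allclose(out["mrt_C"], 20.0, atol=1e-9)

    def test_reference_case_single_row(self):
        """The hand-checked sunny flux set, with the beam chosen so that
        fp·I* matches the reference once fp is known, lands on ≈ 41.3 °C."""
        idx = pd.DatetimeIndex([pd.Timestamp("2018-06-08 11:00")])
        probe = pd.DataFrame({"dni": 0.0, "s_diffuse": 100.0, "s_up": 50.0,
                              "l_dn": 350.0, "l_up": 420.0}, index=idx)
        from mrtgrid import solar
        from mrtgrid.mrt import projection_factor
        g = solar._g(158.0, 11.0)
        cz = solar.cos_solar_zenith(
            solar.solar_declination(g), 20.0,
            solar.solar_hour_angle(11.0, 0.0, solar.time_correction(g)))
        fp = float(np.asarray(projection_factor(solar.solar_elevation(cz))))
        df = probe.assign(dni=0.2 * 800.0 / fp)
        out = validation.station_mrt(make_station(df, lat=20.0, lon=0.0))
        assert out["mrt_C"].iloc[0] == pytest.approx(41.33, abs=0.01)

    def test_missing_component_propagates(self):
        idx = pd.date_range("2018-06-08", periods=2, freq="1h")
        df = pd.DataFrame({"dni": [0.0, 0.0], "s_diffuse": [10.0, np.nan],
                           "s_up": 5.0, "l_dn": 300.0, "l_up": 350.0},
                          index=idx)
        out = validation.station_mrt(make_station(df))
        assert np.isfinite(out["mrt_C"].iloc[0])
        assert np.isnan(out["mrt_C"].iloc[1])


class TestCompare:
    def test_identical_series(self):
        idx = pd.date_range("2018-01-01", periods=10, freq="3h")
        s = pd.Series(np.sin(np.arange(10.0)), index=idx)
        m = validation.compare(s, s)
        assert m["r_squared"] == pytest.approx(1.0)
        assert m["bias"] == 0.0 and m["rmse"] == 0.0
        assert m["n_pairs"] == 10

    def test_constant_offset(self):
        idx = pd.date_range("2018-01-01", periods=10, freq="3h")
        o = pd.Series(np.arange(10.0), index=idx)
        m = validation.compare(o + 2.0, o)
        assert m["r_squared"] == pytest.approx(1.0)
        assert m["bias"] == pytest.approx(2.0)
        assert m["rmse"] == pytest.approx(2.0)

    def test_hand_arithmetic(self):
        idx = pd.date_range("2018-01-01", periods=3, freq="3h")
        m = validation.compare(pd.Series([1.0, 2.0, 4.0], index=idx),
                               pd.Series([1.0, 2.0, 3.0], index=idx))
        assert m["bias"] == pytest.approx(1.0 / 3.0)
        assert m["rmse"] == pytest.approx(np.sqrt(1.0 / 3.0))
        # cov² / (var_m var_o) with population moments
        mm = np.array([1.0, 2.0, 4.0]); oo = np.array([1.0, 2.0, 3.0])
        cov = ((mm - mm.mean()) * (oo - oo.mean())).mean()
        assert m["r_squared"] == pytest.approx(
            cov ** 2 / (mm.var() * oo.var()))

    def test_zero_variance_r2_missing(self):
        idx = pd.date_range("2018-01-01", periods=5, freq="3h")
        m = validation.compare(pd.Series(1.0, index=idx),
                               pd.Series(np.arange(5.0), index=idx))
        assert np.isnan(m["r_squared"])

    def test_pairwise_complete(self):
        idx = pd.date_range("2018-01-01", periods=6, freq="3h")
        a = pd.Series([1, 2, np.nan, 4, 5, 6], index=idx, dtype=float)
        b = pd.Series([1, np.nan, 3, 4, 5, 6], index=idx, dtype=float)
        assert validation.compare(a, b)["n_pairs"] == 4

    @given(st.integers(0, 10_000))
    @settings(max_examples=50, deadline=None)
    def test_rmse_bias_identity(self, seed):
        """RMSE ≥ |bias| always, with RMSE² − bias² = error variance."""
        rng = np.random.default_rng(seed)
        idx = pd.date_range("2018-01-01", periods=50, freq="3h")
        m = pd.Series(rng.normal(0, 5, 50), index=idx)
        o = pd.Series(rng.normal(0, 5, 50), index=idx)
        r = validation.compare(m, o)
        assert r["rmse"] >= abs(r["bias"])
        err = (m - o).to_numpy()
        assert r["rmse"] ** 2 - r["bias"] ** 2 == pytest.approx(
            err.var(), rel=1e-9, abs=1e-9)

    def test_affine_invariance_of_r2(self):
        rng = np.random.default_rng(1)
        idx = pd.date_range("2018-01-01", periods=40, freq="3h")
        m = pd.Series(rng.normal(10, 3, 40), index=idx)
        o = pd.Series(0.5 * m.to_numpy() + rng.normal(0, 1, 40), index=idx)
        r0 = validation.compare(m, o)["r_squared"]
        r1 = validation.compare(3.0 * m + 7.0, o)["r_squared"]
        assert r1 == pytest.approx(r0, rel=1e-12)

    def test_perfect_model_noise_recovery(self):
        """Model = obs + N(0, σ): bias → 0 and RMSE → σ at n = 10 000."""
        rng = np.random.default_rng(2024)
        n, sigma = 10_000, 2.0
        idx = pd.date_range("2015-01-01", periods=n, freq="3h")
        obs = pd.Series(20 + 10 * np.sin(np.arange(n) / 50.0), index=idx)
        model = obs + rng.normal(0.0, sigma, n)
        r = validation.compare(model, obs)
        assert abs(r["bias"]) < 3 * sigma / np.sqrt(n)
        assert abs(r["rmse"] - sigma) < 3 * sigma / np.sqrt(2 * n)

    def test_too_few_pairs(self):
        idx = pd.date_range("2018-01-01", periods=1, freq="3h")
        with pytest.raises(ValueError):
            validation.compare(pd.Series([1.0], index=idx),
                               pd.Series([1.0], index=idx))


@pytest.fixture(scope="module")
def model_ds():
    import xarray as xr
    times = pd.date_range("2018-06-08 01:00", periods=4, freq="1h")
    vals = np.arange(4 * 3 * 4, dtype=float).reshape(4, 3, 4)
    return xr.Dataset(
        {"mrt": (("time", "latitude", "longitude"), vals)},
        coords={"time": times, "latitude": [40.0, 45.0, 50.0],
                "longitude": [0.0, 5.0, 10.0, 15.0]})


class TestExtractModelCell:
    def test_on_node(self, model_ds):
        s = validation.extract_model_cell(model_ds, 45.0, 10.0)
        np.testing.assert_array_equal(s.to_numpy(),
                                      model_ds["mrt"].values[:, 1, 2])

    def test_midway_breaks_to_lower_index(self, model_ds):
        s = validation.extract_model_cell(model_ds, 42.5, 2.5)
        np.testing.assert_array_equal(s.to_numpy(),
                                      model_ds["mrt"].values[:, 0, 0])

    def test_nearest(self, model_ds):
        s = validation.extract_model_cell(model_ds, 49.0, 1.0)
        np.testing.assert_array_equal(s.to_numpy(),
                                      model_ds["mrt"].values[:, 2, 0])

    def test_out_of_bounds_rejected(self, model_ds):
        with pytest.raises(ValueError):
            validation.extract_model_cell(model_ds, 60.0, 5.0)


class TestEndToEnd:
    def test_perfect_station_high_agreement(self):
        """A noise-free synthetic station compared against the model run on
        the same clear-sky scene: near-perfect correlation, small bias from
        interval-averaging vs instantaneous sampling."""
        scene = ClearSkyScene()
        lat, lon = 30.0, 0.0
        times = pd.date_range("2018-06-08 01:00", periods=24, freq="1h")
        flux = make_flux_dataset(scene, np.array([25.0, 30.0, 35.0]),
                                 np.array([-5.0, 0.0, 5.0]), times, 3600.0,
                                 sampling_seconds=600.0)
        model = grid.compute_mrt_field(flux, 3600.0)
        obs = synthetic_station(scene, lat, lon, "2018-06-08 00:10", 144,
                                step_seconds=600.0, seed=0)
        station = validation.StationSeries("SYN", lat, lon, 0.0, obs)
        report = validation.validate_stations(model, [station])
        row = report[report["variable"] == "mrt"].iloc[0]
        assert row["r_squared"] > 0.98
        assert abs(row["bias"]) < 3.0
        assert row["rmse"] < 5.0
        summary = validation.summarize_report(report)
        assert summary["n_stations"] == 1
        assert summary["mean_station_bias"] == pytest.approx(row["bias"])

    def test_tsv_round_trip(self, tmp_path):
        scene = ClearSkyScene()
        obs = synthetic_station(scene, 47.0, 7.0, "2018-06-08", 36,
                                noise_sd=3.0, missing_rate=0.1, seed=9)
        st_ = validation.StationSeries("CAB", 47.0, 7.0, 10.0, obs)
        path = tmp_path / "CAB.tsv"
        validation.write_station_tsv(st_, path)
        back = validation.read_station_tsv(path)
        assert back.station_id == "CAB"
        assert back.latitude == 47.0
        pd.testing.assert_frame_equal(back.data, st_.data,
                                      check_freq=False, atol=1e-9)

    def test_station_series_validation(self):
        idx = pd.DatetimeIndex(["2018-01-01", "2018-01-01"])  # duplicate
        df = pd.DataFrame({c: [1.0, 2.0] for c in validation.STATION_COLUMNS},
                          index=idx)
        with pytest.raises(ValueError):
            validation.StationSeries("X", 0.0, 0.0, 0.0, df)
        with pytest.raises(ValueError):
            validation.StationSeries("X", 95.0, 0.0)
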