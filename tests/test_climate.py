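import math

import numpy as np
import pandas as pd
import pytest
from scipy import stats

from dendrovigor import climate as cl
from conftest import make_climate


def write_csv(tmp_path, text, name="clim.csv"):
    p = tmp_path / name
    p.write_text(text)
    return p


class TestReadDailyClimate:
    def test_well_formed_file_reads_identically(self, tmp_path):
        p = write_csv(tmp_path, "date,tx,tn,tm,prec\n"
                                "2000-01-01,10,2,6,0\n"
                                "2000-01-02,11,3,7,1.5\n"
                                "2000-01-03,12,4,8,0\n")
        clim = cl.read_daily_climate(p, latitude=41.3, elevation=900)
        assert len(clim) == 3
        assert clim.flags == []
        assert clim.data["tm"].tolist() == [6.0, 7.0, 8.0]

    def test_missing_tm_column_derived_from_tx_tn(self, tmp_path):
        p = write_csv(tmp_path, "date,tx,tn,prec\n"
                                "2000-01-01,10,2,0\n"
                                "2000-01-02,11,3,0\n")
        clim = cl.read_daily_climate(p, latitude=41.3, elevation=900)
        assert clim.data["tm"].tolist() == [6.0, 7.0]

    def test_short_temperature_gap_linear_fill(self, tmp_path):
        # hand interpolation: tx 10 .. .. 16 -> 12, 14
        p = write_csv(tmp_path, "date,tx,tn,tm,prec\n"
                                "2000-01-01,10,0,5,0\n"
                                "2000-01-02,,0,5,0\n"
                                "2000-01-03,,0,5,0\n"
                                "2000-01-04,16,0,8,0\n")
        clim = cl.read_daily_climate(p, latitude=41.3, elevation=900)
        assert clim.data["tx"].tolist() == [10.0, 12.0, 14.0, 16.0]
        assert any("tx" in f for f in clim.flags)

    def test_long_gap_and_inverted_range_raise(self, tmp_path):
        rows = "".join(f"2000-01-{d:02d},,0,5,0\n" for d in range(2, 9))
        p = write_csv(tmp_path,
                      "date,tx,tn,tm,prec\n2000-01-01,10,0,5,0\n" + rows
                      + "2000-01-09,10,0,5,0\n")
        with pytest.raises(ValueError, match="gap"):
            cl.read_daily_climate(p, latitude=41.3, elevation=900)
        p2 = write_csv(tmp_path, "date,tx,tn,tm,prec\n2000-01-01,5,10,7,0\n",
                       name="bad.csv")
        with pytest.raises(ValueError, match="Tn > Tx"):
            cl.read_daily_climate(p2, latitude=41.3, elevation=900)

    def test_missing_precip_zero_filled(self, tmp_path):
        p = write_csv(tmp_path, "date,tx,tn,tm,prec\n"
                                "2000-01-01,10,2,6,\n"
                                "2000-01-02,11,3,7,2\n")
        clim = cl.read_daily_climate(p, latitude=41.3, elevation=900)
        assert clim.data["prec"].tolist() == [0.0, 2.0]
        assert any("precip" in f for f in clim.flags)


class TestPenmanMonteith:
    def test_calm_saturated_dark_day_gives_zero(self):
        # u2 = 0 and RH = 100% null the aerodynamic term; rs = 0 makes the
        # radiation term non-positive, so ET0 clips at 0
        clim = make_climate([20.0, 20.0], rs=0.0, u2=0.0, rh=100.0)
        pet = cl.penman_monteith_pet(clim)
        assert (pet == 0).all()

    def test_reduced_data_day_matches_hand_computation(self):
        """Step-by-step FAO-56 computation for Tm=20, Tx=25, Tn=15,
        41.3°N, 900 m, DOY 150, reduced-data pathway (u2=2, ea from Tn)."""
        tm, tx, tn, lat, z, j = 20.0, 25.0, 15.0, 41.3, 900.0, 150
        e0 = lambda t: 0.6108 * math.exp(17.27 * t / (t + 237.3))
        delta = 4098 * e0(tm) / (tm + 237.3) ** 2
        patm = 101.3 * ((293 - 0.0065 * z) / 293) ** 5.26
        gamma = 0.000665 * patm
        es, ea = (e0(tx) + e0(tn)) / 2, e0(tn)
        phi = math.radians(lat)
        dr = 1 + 0.033 * math.cos(2 * math.pi * j / 365)
        dec = 0.409 * math.sin(2 * math.pi * j / 365 - 1.39)
        ws = math.acos(-math.tan(phi) * math.tan(dec))
        ra = (24 * 60 / math.pi) * 0.0820 * dr * (
            ws * math.sin(phi) * math.sin(dec)
            + math.cos(phi) * math.cos(dec) * math.sin(ws))
        rs = 0.16 * math.sqrt(tx - tn) * ra
        rso = (0.75 + 2e-5 * z) * ra
        rnl = (4.903e-9 * ((tx + 273.16) ** 4 + (tn + 273.16) ** 4) / 2
               * (0.34 - 0.14 * math.sqrt(ea)) * (1.35 * rs / rso - 0.35))
        rn = 0.77 * rs - rnl
        expected = ((0.408 * delta * rn
                     + gamma * 900 / (tm + 273) * 2.0 * (es - ea))
                    / (delta + gamma * (1 + 0.34 * 2.0)))
        assert expected == pytest.approx(4.2053, abs=1e-3)  # frozen oracle

        idx = pd.date_range("2001-05-30", periods=1)  # DOY 150
        clim = cl.DailyClimateSeries(
            pd.DataFrame({"tx": [tx], "tn": [tn], "tm": [tm], "prec": [0.0]},
                         index=idx), latitude=lat, elevation=z)
        assert cl.penman_monteith_pet(clim).iloc[0] == pytest.approx(expected,
                                                                     abs=1e-9)

    def test_wind_increases_et0_under_vpd(self):
        clim1 = make_climate([20.0] * 3, u2=2.0)
        clim2 = make_climate([20.0] * 3, u2=4.0)
        assert (cl.penman_monteith_pet(clim2) > cl.penman_monteith_pet(clim1)).all()

    def test_pet_nonnegative_on_synthetic_climate(self, default_climate):
        pet = cl.penman_monteith_pet(default_climate)
        assert (pet >= 0).all()

    def test_negative_temperature_range_raises(self):
        clim = make_climate([5.0] * 2)
        clim.data.loc[clim.data.index[0], "tx"] = 0.0
        clim.data.loc[clim.data.index[0], "tn"] = 0.0
        clim.data.loc[clim.data.index[1], "tx"] = 4.0
        clim.data.loc[clim.data.index[1], "tn"] = 4.5  # Tn > Tx
        clim.data["tm"] = 2.0
        with pytest.raises(ValueError):
            cl.penman_monteith_pet(clim)


class TestWaterBalance:
    def test_balance_is_p_minus_pet(self, default_climate):
        pet = cl.penman_monteith_pet(default_climate)
        wb = cl.water_balance(default_climate, pet, "year")
        assert np.allclose(wb["balance"], wb["p"] - wb["pet"])

    def test_monthly_sums_to_annual(self, default_climate):
        pet = cl.penman_monteith_pet(default_climate)
        monthly = cl.water_balance(default_climate, pet, "month")
        annual = cl.water_balance(default_climate, pet, "year")
        agg = monthly.groupby("year")["balance"].sum()
        merged = annual.set_index("year")["balance"]
        common = agg.index.intersection(merged.index)
        assert np.allclose(agg.loc[common], merged.loc[common], atol=1e-9)

    def test_annual_balance_negative_in_mediterranean_regime(self, default_climate):
        pet = cl.penman_monteith_pet(default_climate)
        wb = cl.water_balance(default_climate, pet, "year")
        assert wb["balance"].mean() < 0

    def test_equal_p_and_pet_balance_zero(self):
        clim = make_climate([15.0] * 365, prec=np.full(365, 2.0))
        pet = pd.Series(2.0, index=clim.data.index)
        wb = cl.water_balance(clim, pet, "year")
        assert np.allclose(wb["balance"], 0.0)

    def test_winter_assigned_to_january_year(self, default_climate):
        pet = cl.penman_monteith_pet(default_climate)
        seas = cl.seasonal_summary(default_climate, pet)
        dec_tm = default_climate.data.loc["1950-12", "tm"].sum()
        janfeb_tm = default_climate.data.loc["1951-01":"1951-02", "tm"].sum()
        ndays = (31 + len(default_climate.data.loc["1951-01":"1951-02"]))
        row = seas[(seas["year"] == 1951) & (seas["season"] == "winter")]
        assert row["tm"].iloc[0] == pytest.approx((dec_tm + janfeb_tm) / ndays)


def brute_force_mann_kendall(x):
    n = len(x)
    s = 0
    for i in range(n):
        for j in range(i + 1, n):
            s += np.sign(x[j] - x[i])
    pairs = [(i, j) for i in range(n) for j in range(i + 1, n)]
    nc = sum(1 for i, j in pairs if x[j] > x[i])
    nd = sum(1 for i, j in pairs if x[j] < x[i])
    # tau-b denominator with tie correction
    _, counts = np.unique(x, return_counts=True)
    t = counts[counts > 1]
    n0 = n * (n - 1) / 2
    denom = math.sqrt(n0 - (t * (t - 1) / 2).sum()) * math.sqrt(n0)
    return int(s), (nc - nd) / denom if denom else 0.0


class TestMannKendall:
    def test_strictly_increasing(self):
        res = cl.mann_kendall_trend(np.arange(10.0))
        assert res.tau == pytest.approx(1.0)
        assert res.s == 45
        assert res.sen_slope == pytest.approx(1.0)

    def test_constant_series(self):
        res = cl.mann_kendall_trend(np.full(12, 3.0))
        assert res.s == 0
        assert res.tau == 0.0

    def test_matches_brute_force_on_random_series(self):
        rng = np.random.default_rng(5)
        for _ in range(100):
            n = int(rng.integers(8, 51))
            x = rng.normal(size=n)
            if rng.random() < 0.3:
                x = np.round(x)  # induce ties
            res = cl.mann_kendall_trend(x)
            s, tau = brute_force_mann_kendall(x)
            assert res.s == s
            assert res.tau == pytest.approx(tau, abs=1e-12)

    def test_tau_agrees_with_scipy_kendalltau(self):
        rng = np.random.default_rng(11)
        x = rng.normal(size=30)
        res = cl.mann_kendall_trend(x)
        assert res.tau == pytest.approx(stats.kendalltau(np.arange(30), x).statistic,
                                        abs=1e-12)

    def test_too_short_raises(self):
        with pytest.raises(ValueError):
            cl.mann_kendall_trend([1.0, 2.0])


class TestAnomalies:
    def test_zero_at_reference_mean(self):
        assert cl.standardized_anomaly(5.0, 5.0, 2.0) == 0.0

    def test_drought_year_anomaly_arithmetic(self):
        # long-term balance mean -728 mm, SD 167 mm; a -1155 mm year
        z = cl.standardized_anomaly(-1155.0, -728.0, 167.0)
        assert z == pytest.approx((-1155 + 728) / 167)
        assert z == pytest.approx(-2.56, abs=0.005)

    def test_reference_series_standardizes_to_unit(self):
        rng = np.random.default_rng(3)
        x = rng.normal(10, 4, 200)
        z = cl.standardized_anomaly(x, x.mean(), x.std(ddof=1))
        assert abs(z.mean()) < 1e-12
        assert z.std(ddof=1) == pytest.approx(1.0, abs=1e-12)

    def test_threshold_standard_normal(self):
        x = np.concatenate([np.zeros(50) - 1, np.zeros(50) + 1])  # mean 0 sd~1
        thr = cl.anomaly_thresholds(x, (0.05, 0.01))
        sd = np.std(x, ddof=1)
        assert thr[0.05] == pytest.approx(-1.645 * sd, abs=1e-3)
        assert thr[0.01] == pytest.approx(-2.326 * sd, abs=1e-3)

    def test_zero_sd_raises(self):
        with pytest.raises(ValueError):
            cl.standardized_anomaly(1.0, 0.0, 0.0)
        with pytest.raises(ValueError):
            cl.anomaly_thresholds(np.ones(10))
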