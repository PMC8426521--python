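import math

import numpy as np
import pandas as pd
import pytest

from dendrovigor import vs_model as vs
from dendrovigor.synthetic_data import SyntheticConfig, generate_daily_climate
from conftest import make_climate


P = vs.VSParameters()


class TestParameters:
    def test_eighteen_parameters(self):
        assert len(P.to_vector()) == 18

    def test_bad_knot_order_rejected(self):
        with pytest.raises(ValueError):
            vs.VSParameters(t1=10, t2=5)
        with pytest.raises(ValueError):
            vs.VSParameters(w4=0.5, wcap=0.4)

    def test_vector_to_params_enforces_ordering(self):
        rng = np.random.default_rng(0)
        for _ in range(50):
            v = np.array([rng.uniform(lo, hi) for lo, hi in vs.DEFAULT_BOUNDS])
            p = vs.vector_to_params(v)  # must not raise
            assert p.t1 < p.t2 <= p.t3 < p.t4
            assert p.w1 < p.w2 <= p.w3 < p.w4 <= p.wcap


class TestModifiers:
    def test_knots_and_midpoint(self):
        assert vs.growth_modifier_temperature((P.t1 + P.t2) / 2, P) == pytest.approx(0.5)
        assert vs.growth_modifier_temperature(P.t2, P) == 1.0
        assert vs.growth_modifier_temperature(P.t1, P) == 0.0
        assert vs.growth_modifier_temperature(P.t4, P) == 0.0
        assert vs.growth_modifier_moisture((P.w3 + P.w4) / 2, P) == pytest.approx(0.5)
        assert vs.growth_modifier_moisture(P.w2, P) == 1.0

    def test_grid_matches_pointwise_piecewise_oracle(self):
        def oracle(x, k1, k2, k3, k4):
            if x <= k1 or x >= k4:
                return 0.0
            if x < k2:
                return (x - k1) / (k2 - k1)
            if x <= k3:
                return 1.0
            return (k4 - x) / (k4 - k3)

        grid = np.linspace(-5, 40, 301)
        gt = vs.growth_modifier_temperature(grid, P)
        for x, g in zip(grid, gt):
            assert g == pytest.approx(oracle(x, P.t1, P.t2, P.t3, P.t4))
        wgrid = np.linspace(0, 0.45, 200)
        gw = vs.growth_modifier_moisture(wgrid, P)
        for x, g in zip(wgrid, gw):
            assert g == pytest.approx(oracle(x, P.w1, P.w2, P.w3, P.w4))


class TestSolarModifier:
    def test_solstice_is_annual_maximum(self):
        ge = vs.solar_modifier(np.arange(1, 366), 41.3)
        assert ge.max() == pytest.approx(1.0)
        assert 165 <= np.argmax(ge) + 1 <= 180

    def test_equator_nearly_constant(self):
        ge = vs.solar_modifier(np.arange(1, 366), 0.0)
        assert np.ptp(ge) < 0.02

    def test_day_length_matches_independent_astronomy(self):
        # independent oracle: declination 23.45 sin(360(284+J)/365) degrees
        lat = 41.3
        for j in (15, 105, 172, 265, 355):
            dec = math.radians(23.45) * math.sin(2 * math.pi * (284 + j) / 365)
            ws = math.acos(max(-1, min(1, -math.tan(math.radians(lat))
                                       * math.tan(dec))))
            oracle_hours = 24 / math.pi * ws
            ours = vs.day_length_hours(np.array([j]), lat)[0]
            assert ours == pytest.approx(oracle_hours, rel=0.01)

    def test_polar_latitude_rejected(self):
        with pytest.raises(ValueError):
            vs.solar_modifier(np.arange(1, 10), 70.0)


class TestSoilMoistureStep:
    def test_no_fluxes_leaves_moisture_unchanged(self):
        p = vs.VSParameters(k3=0.0)
        w, snow, *_ = vs.soil_moisture_step(0.2, 0.0, 0.0, 10.0, 0.0, p)
        assert w == pytest.approx(0.2)
        assert snow == 0.0

    def test_hand_computed_balance(self):
        p = vs.VSParameters()
        w0, rain, tm, gr_prev = 0.2, 10.0, 15.0, 0.5
        w, snow, infil, transp, drain, clipped = vs.soil_moisture_step(
            w0, 0.0, rain, tm, gr_prev, p)
        assert infil == pytest.approx(min(p.k1 * rain, p.pmax))
        assert transp == pytest.approx(p.k2 * gr_prev)
        assert drain == pytest.approx(p.k3 * w0 * p.droot)
        assert w == pytest.approx(w0 + (infil - transp - drain) / p.droot)
        assert not clipped

    def test_saturating_rain_clips_at_capacity(self):
        p = vs.VSParameters(pmax=500.0)
        w, *_ , clipped = vs.soil_moisture_step(0.39, 0.0, 400.0, 15.0, 0.0, p)
        assert w == p.wcap
        assert clipped

    def test_snow_accumulates_then_melts(self):
        p = vs.VSParameters()
        w, snow, infil, *_ = vs.soil_moisture_step(0.2, 0.0, 5.0, -2.0, 0.0, p)
        assert snow == 5.0 and infil == 0.0
        w2, snow2, infil2, *_ = vs.soil_moisture_step(w, snow, 0.0, 2.0, 0.0, p)
        melt = min(5.0, p.ksm * 2.0)
        assert snow2 == pytest.approx(5.0 - melt)
        assert infil2 == pytest.approx(p.k1 * melt)

    def test_mass_balance_closes_without_clipping(self):
        # replay a random forcing; with clipping inactive the bucket closes
        # to 1e-9 mm
        rng = np.random.default_rng(14)
        p = vs.VSParameters()
        w, snow = 0.25, 0.0
        tot_i = tot_e = tot_d = 0.0
        w_start = w
        for _ in range(500):
            prec = rng.gamma(0.8, 3.0) * (rng.random() < 0.3)
            tm = rng.uniform(5, 25)
            gr = rng.uniform(0, 0.4)
            w, snow, i, e, d, clipped = vs.soil_moisture_step(
                w, snow, prec, tm, gr, p)
            assert not clipped
            tot_i += i
            tot_e += e
            tot_d += d
        assert (w - w_start) * p.droot == pytest.approx(tot_i - tot_e - tot_d,
                                                        abs=1e-9)


@pytest.fixture(scope="module")
def med_climate():
    cfg = SyntheticConfig(start_year=1990, end_year=2009, divergence_year=2000)
    return generate_daily_climate(cfg)


class TestSimulate:
    def test_all_cold_year_is_dormant(self):
        clim = make_climate(np.full(730, -5.0), diurnal=4.0)
        sim = vs.simulate(clim, P)
        assert (sim.daily["gr"] == 0).all()
        assert (sim.annual == 0).all()
        assert (sim.daily["limitation"] == 0).all()

    def test_optimal_plateau_gives_ge(self):
        # temperature on the plateau, heavy regular rain keeps W in [w2, w3]
        n = 730
        prec = np.full(n, 3.0)
        clim = make_climate(np.full(n, 18.0), prec=prec, diurnal=6.0)
        p = vs.VSParameters(w0=0.2, k2=1.0, k3=0.02)
        sim = vs.simulate(clim, p)
        act = sim.daily[sim.daily["active"]]
        assert len(act) > 0
        w_ok = ((act["w"] >= p.w2) & (act["w"] <= p.w3)).to_numpy()
        assert w_ok.all()  # forcing keeps the bucket inside the plateau
        ge = vs.solar_modifier(act["doy"].to_numpy(), clim.latitude)
        assert np.allclose(act["gr"], ge, atol=1e-12)
        assert (act["limitation"] == 3).all()

    def test_constant_forcing_annual_index_closed_form(self):
        n = 365 * 2
        prec = np.full(n, 3.0)
        clim = make_climate(np.full(n, 18.0), prec=prec, diurnal=6.0,
                            start="2001-01-01")
        p = vs.VSParameters(w0=0.2, k2=1.0, k3=0.02)
        sim = vs.simulate(clim, p)
        # independent accumulation: growth starts once sum(Tm) >= Tbeg,
        # i.e. after ceil(100/18) = 6 days, and every active day is optimal
        start_day = math.ceil(p.tbeg / 18.0)
        ge = vs.solar_modifier(np.arange(1, 366), clim.latitude)
        expected_y2 = ge[start_day - 1:].sum()
        assert sim.annual.loc[2002] == pytest.approx(expected_y2, rel=1e-9)

    def test_gr_bounded_by_modifiers_and_classes_match_rule(self, med_climate):
        sim = vs.simulate(med_climate, P)
        act = sim.daily[sim.daily["active"]]
        assert (act["gr"] <= np.minimum(act["gt"], act["gw"]) + 1e-12).all()
        gt, gw = act["gt"].to_numpy(), act["gw"].to_numpy()
        cls = act["limitation"].to_numpy()
        expected = np.where(gt < gw, 1, np.where(gw < gt, 2,
                            np.where(gt == 1.0, 3, 4)))
        assert (cls == expected).all()

    def test_halving_precipitation_never_increases_annual_index(self, med_climate):
        sim_full = vs.simulate(med_climate, P)
        half = type(med_climate)(
            med_climate.data.assign(prec=med_climate.data["prec"] * 0.5),
            latitude=med_climate.latitude, elevation=med_climate.elevation)
        sim_half = vs.simulate(half, P)
        diff = sim_half.annual - sim_full.annual
        assert (diff <= 1e-9).all()
        assert (diff < -1e-6).any()

    def test_simulation_deterministic(self, med_climate):
        s1 = vs.simulate(med_climate, P)
        s2 = vs.simulate(med_climate, P)
        pd.testing.assert_frame_equal(s1.daily, s2.daily)


class TestAnnualIndex:
    def test_standardized_contract(self, med_climate):
        sim = vs.simulate(med_climate, P)
        z = vs.annual_growth_index(sim, (1990, 2009))
        assert z.mean() == pytest.approx(0.0, abs=1e-12)
        assert z.std(ddof=1) == pytest.approx(1.0, abs=1e-12)

    def test_degenerate_annual_series_raises(self):
        sim = vs.VSSimulation(daily=pd.DataFrame(),
                              annual=pd.Series(5.0, index=np.arange(2000, 2012)),
                              params=P)
        with pytest.raises(ValueError, match="variance"):
            vs.annual_growth_index(sim, (2000, 2011))


@pytest.fixture(scope="module")
def pseudo_obs(med_climate):
    sim = vs.simulate(med_climate, vs.VSParameters())
    ann = sim.annual
    return (ann - ann.mean()) / ann.std(ddof=1)


class TestCalibration:

    def test_noise_free_self_consistency(self, med_climate, pseudo_obs):
        res = vs.calibrate(med_climate, pseudo_obs, calib_period=(1990, 2009),
                           seed=1, maxiter=40, popsize=8)
        assert res.r_calibration >= 0.99

    def test_noisy_recovery_and_verification(self, med_climate, pseudo_obs):
        rng = np.random.default_rng(4)
        noisy = pseudo_obs + rng.normal(0, 0.5, len(pseudo_obs))
        res = vs.calibrate(med_climate, noisy, calib_period=(1990, 1999),
                           seed=2)
        res = vs.verify(res, med_climate, noisy, verif_period=(2000, 2009))
        assert res.r_calibration >= 0.6
        assert np.isfinite(res.r_verification)
        assert res.rmse_verification >= 0

    def test_fixed_seed_reproducible(self, med_climate, pseudo_obs):
        r1 = vs.calibrate(med_climate, pseudo_obs, calib_period=(1990, 2009),
                          seed=5, maxiter=5, popsize=4)
        r2 = vs.calibrate(med_climate, pseudo_obs, calib_period=(1990, 2009),
                          seed=5, maxiter=5, popsize=4)
        assert np.allclose(r1.params.to_vector(), r2.params.to_vector())
        assert r1.r_calibration == r2.r_calibration


class TestLimitationSummary:
    def test_fractions_partition_and_drought_peaks_in_summer(self, med_climate):
        sim = vs.simulate(med_climate, P)
        out = vs.limitation_summary(sim, (1990, 1999), (2000, 2009))
        for period in ("A", "B"):
            frac = out[period]["class_fractions"]
            assert sum(frac.values()) == pytest.approx(1.0)
            by_doy = out[period]["class_by_doy"]
            sums = by_doy.sum(axis=1)
            assert np.allclose(sums, 1.0)
        # Mediterranean summer: moisture limitation dominates midsummer DOYs
        by_doy = out["B"]["class_by_doy"]
        summer = by_doy.loc[(by_doy.index >= 180) & (by_doy.index <= 240)]
        assert summer["moisture"].mean() > 0.8

    def test_empty_period_raises(self, med_climate):
        sim = vs.simulate(med_climate, P)
        with pytest.raises(ValueError):
            vs.limitation_summary(sim, (1800, 1805), (1990, 1999))
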