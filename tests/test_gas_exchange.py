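import numpy as np
import pytest
from hypothesis import given, settings
from hypothesis import strategies as st

from endophys.gas_exchange import (
    GasExchangeError,
    GasExchangeSeries,
    compute_ewl,
    compute_gas_exchange,
    correct_series,
    find_steady_window,
    fit_baseline,
    saturation_vapor_pressure_kPa,
)
from endophys.synthetic_data import ChamberConfig, simulate_trace, PhysioTruth
from helpers import brute_force_window, random_vo2_series


def make_series(x, dt=15.0):
    x = np.asarray(x, dtype=float)
    t = np.arange(len(x)) * dt
    return GasExchangeSeries(
        time_s=t,
        vo2_ml_h=x,
        vco2_ml_h=0.85 * x,
        ewl_mg_h=np.abs(x),
        t_probe_C=np.full(len(x), 25.0),
        sample_interval_s=dt,
    )


class TestBaseline:
    def trace_with_baselines(self, pre_o2, post_o2, pre_n=80, animal_n=240, post_n=80):
        from endophys.io_calibration import RawTrace, TrialMeta

        n = pre_n + animal_n + post_n
        phase = np.array(
            ["baseline_pre"] * pre_n + ["animal"] * animal_n + ["baseline_post"] * post_n
        )
        o2 = np.concatenate(
            [np.full(pre_n, pre_o2), np.full(animal_n, 0.2060), np.full(post_n, post_o2)]
        )
        return RawTrace(
            time_s=np.arange(n) * 15.0,
            o2_frac=o2,
            co2_frac=np.full(n, 0.0004),
            rh_pct=np.full(n, 1.0),
            t_probe_C=np.full(n, 25.0),
            flow_stpd_ml_min=np.full(n, 3000.0),
            phase=phase,
            meta=TrialMeta(animal_id="A", population_id="p", barometric_pressure_kPa=101.325),
        )

    def test_equal_baselines_give_constant_drift(self):
        bl = fit_baseline(self.trace_with_baselines(0.2095, 0.2095))
        ts = np.array([0.0, 2000.0, 5000.0])
        assert np.allclose(bl.o2.at(ts), 0.2095)

    def test_drift_slope_is_two_point_line(self):
        # pre mean at its midpoint, post mean at its midpoint, linear between
        trace = self.trace_with_baselines(0.2090, 0.2100)
        bl = fit_baseline(trace)
        pre_mid = trace.time_s[trace.phase == "baseline_pre"].mean()
        post_mid = trace.time_s[trace.phase == "baseline_post"].mean()
        expected_slope = (0.2100 - 0.2090) / (post_mid - pre_mid)
        assert bl.o2.slope_per_s == pytest.approx(expected_slope, rel=1e-12)
        assert bl.o2.at(pre_mid) == pytest.approx(0.2090, rel=1e-12)

    def test_short_baseline_raises_naming_phase(self):
        trace = self.trace_with_baselines(0.2095, 0.2095, pre_n=10)
        with pytest.raises(GasExchangeError, match="baseline_pre"):
            fit_baseline(trace)


class TestMassBalance:
    def test_equal_volume_exchange(self):
        # N2 fractions equal on both sides => VE = VI exactly, RER = 1
        vo2, vco2, ve = compute_gas_exchange(0.2065, 0.0034, 0.2095, 0.0004, 3000.0)
        assert ve == pytest.approx(3000.0, abs=1e-9)
        assert vo2 == pytest.approx(540.0, abs=1e-9)
        assert vco2 == pytest.approx(540.0, abs=1e-9)

    def test_unequal_volume_exchange(self):
        vo2, vco2, ve = compute_gas_exchange(0.2050, 0.0040, 0.2095, 0.0004, 3000.0)
        assert ve == pytest.approx(2996.59, abs=0.01)
        assert vo2 == pytest.approx(852.0, abs=0.05)
        assert vco2 == pytest.approx(647.2, abs=0.05)

    def test_no_animal_means_zero_rates(self):
        vo2, vco2, _ = compute_gas_exchange(0.2095, 0.0004, 0.2095, 0.0004, 3000.0)
        assert vo2 == 0.0 and vco2 == 0.0

    def test_impossible_fractions_raise(self):
        with pytest.raises(GasExchangeError):
            compute_gas_exchange(0.7, 0.4, 0.2095, 0.0004, 3000.0)
        with pytest.raises(GasExchangeError):
            compute_gas_exchange(0.2, 0.004, 0.2095, 0.0004, -5.0)

    @given(
        vo2=st.floats(1.0, 3000.0),
        rer=st.floats(0.5, 1.2),
        flow=st.floats(500.0, 8000.0),
        fi_o2=st.floats(0.15, 0.25),
        fi_co2=st.floats(0.0, 0.01),
    )
    @settings(max_examples=120, deadline=None)
    def test_nitrogen_conservation_round_trip(self, vo2, rer, flow, fi_o2, fi_co2):
        """Forward-simulating the dry mixture and inverting recovers the
        truth to 1e-9 relative error: the algebra is exact."""
        vco2 = rer * vo2
        vi = flow
        ve = vi - vo2 / 60.0 + vco2 / 60.0
        fe_o2 = (vi * fi_o2 - vo2 / 60.0) / ve
        fe_co2 = (vi * fi_co2 + vco2 / 60.0) / ve
        if fe_o2 < 0 or fe_co2 >= 1 or fe_o2 + fe_co2 >= 1:
            return  # physically impossible draw
        got_vo2, got_vco2, got_ve = compute_gas_exchange(fe_o2, fe_co2, fi_o2, fi_co2, vi)
        assert got_vo2 == pytest.approx(vo2, rel=1e-9)
        assert got_vco2 == pytest.approx(vco2, rel=1e-9, abs=1e-9)
        assert got_ve == pytest.approx(ve, rel=1e-12)

    def test_rer_one_implies_ve_equals_vi(self):
        vo2 = 600.0
        vi = 2500.0
        ve = vi  # equal molar exchange
        fe_o2 = (vi * 0.2095 - vo2 / 60.0) / ve
        fe_co2 = (vi * 0.0004 + vo2 / 60.0) / ve
        _, _, got_ve = compute_gas_exchange(fe_o2, fe_co2, 0.2095, 0.0004, vi)
        assert got_ve == pytest.approx(vi, rel=1e-14)


class TestEWL:
    def test_dry_air_gives_zero(self):
        assert compute_ewl(0.0, 25.0, 3000.0) == 0.0

    def test_psychrometric_hand_case(self):
        assert saturation_vapor_pressure_kPa(25.0) == pytest.approx(3.1616, abs=2e-4)
        ewl = compute_ewl(25.0, 25.0, 2996.6, 101.325)
        assert ewl == pytest.approx(1136.0, rel=5e-4)

    def test_linear_in_flow(self):
        one = compute_ewl(40.0, 20.0, 1500.0)
        two = compute_ewl(40.0, 20.0, 3000.0)
        assert two == pytest.approx(2 * one, rel=1e-12)

    @given(
        rh=st.floats(1.0, 99.0),
        drh=st.floats(0.01, 1.0),
        t=st.floats(0.0, 40.0),
        dt=st.floats(0.01, 2.0),
    )
    @settings(max_examples=60, deadline=None)
    def test_monotone_in_rh_and_temperature(self, rh, drh, t, dt):
        base = compute_ewl(rh, t, 3000.0)
        assert compute_ewl(min(rh + drh, 100.0), t, 3000.0) > base
        assert compute_ewl(rh, t + dt, 3000.0) > base

    def test_vapor_exceeding_pressure_raises(self):
        with pytest.raises(GasExchangeError):
            compute_ewl(100.0, 90.0, 3000.0, bp_kPa=50.0)


class TestCorrectSeries:
    def test_null_animal_gives_zero_series(self):
        # animal phase identical to baselines: no gas exchange, no vapor
        from endophys.io_calibration import RawTrace, TrialMeta

        n = 400
        phase = np.array(["baseline_pre"] * 100 + ["animal"] * 200 + ["baseline_post"] * 100)
        trace = RawTrace(
            time_s=np.arange(n) * 15.0,
            o2_frac=np.full(n, 0.2095),
            co2_frac=np.full(n, 0.0004),
            rh_pct=np.full(n, 1.0),
            t_probe_C=np.full(n, 25.0),
            flow_stpd_ml_min=np.full(n, 3000.0),
            phase=phase,
            meta=TrialMeta(
                animal_id="A", population_id="p", barometric_pressure_kPa=101.325
            ),
        )
        series = correct_series(trace, fit_baseline(trace), settle_tau=0.0)
        assert np.allclose(series.vo2_ml_h, 0.0, atol=1e-9)
        assert np.allclose(series.vco2_ml_h, 0.0, atol=1e-9)
        assert np.allclose(series.ewl_mg_h, 0.0, atol=1e-9)

    def test_injected_o2_drift_is_removed(self, quiet_chamber):
        """A linear O2 baseline drift must not bias recovered VO2."""
        truth = PhysioTruth(vo2_ml_h=600.0, vco2_ml_h=510.0, ewl_mg_h=700.0, tb_C=35.0, rer=0.85)
        from dataclasses import replace

        drifty = replace(quiet_chamber, o2_drift_per_h=-3e-4)
        clean_tr = simulate_trace(truth, quiet_chamber, 0, ta=26.0, mass_g=2000.0)
        drift_tr = simulate_trace(truth, drifty, 0, ta=26.0, mass_g=2000.0)
        for tr in (clean_tr, drift_tr):
            series = correct_series(tr, fit_baseline(tr))
            win = find_steady_window(series)
            assert win.means["vo2_ml_h"] == pytest.approx(600.0, rel=1e-3)

    def test_generator_round_trip_at_steady_state(self, arid_trial):
        trace, truth, _ = arid_trial
        series = correct_series(trace, fit_baseline(trace))
        win = find_steady_window(series)
        assert win.means["vo2_ml_h"] == pytest.approx(truth.vo2_ml_h, rel=1e-3)
        assert win.means["vco2_ml_h"] == pytest.approx(truth.vco2_ml_h, rel=1e-3)
        assert win.means["ewl_mg_h"] == pytest.approx(truth.ewl_mg_h, rel=1e-3)


class TestSteadyWindow:
    def test_constant_series_selects_entire_phase(self):
        series = make_series(np.full(200, 500.0))
        win = find_steady_window(series, min_duration_s=600.0)
        assert win.steady
        assert win.start_s == 0.0
        assert win.n_samples == 200

    def test_plateau_is_found(self):
        # 60 min at 600 with a 25-min plateau at 500, noise SD 5
        rng = np.random.default_rng(3)
        x = np.full(240, 600.0)
        x[100:200] = 500.0
        x = x + rng.normal(0, 5, 240)
        series = make_series(x)
        win = find_steady_window(series, min_duration_s=1200.0)
        assert win.steady
        assert win.means["vo2_ml_h"] == pytest.approx(500.0, rel=0.02)
        assert 100 * 15.0 <= win.start_s and win.end_s <= 200 * 15.0
        s, L, steady = brute_force_window(series)
        assert (win.start_s, win.n_samples, win.steady) == (series.time_s[s], L, steady)

    def test_monotone_decline_is_flagged_non_steady(self):
        x = np.linspace(900.0, 300.0, 120)  # -40%/h everywhere
        win = find_steady_window(make_series(x), min_duration_s=1200.0)
        assert not win.steady

    def test_short_phase_raises(self):
        with pytest.raises(GasExchangeError):
            find_steady_window(make_series(np.full(10, 500.0)), min_duration_s=1200.0)

    @pytest.mark.parametrize("seed", range(12))
    def test_agrees_with_bruteforce_on_random_series(self, seed):
        rng = np.random.default_rng(seed)
        series = random_vo2_series(rng)
        win = find_steady_window(series, min_duration_s=600.0)
        s, L, steady = brute_force_window(series, min_duration_s=600.0)
        assert win.steady == steady
        assert win.start_s == series.time_s[s]
        assert win.n_samples == L
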