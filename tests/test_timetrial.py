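"""Time-trial analysis: resampling, peaks, requirement, deficit integration."""

import numpy as np
import pytest

from skicap import (
    BaselineMeasurement,
    StageMeasurement,
    TimeTrialSeries,
    anaerobic_rate_series,
    compute_peaks,
    estimate_all_methods,
    fit_demand_model,
    integrate_anaerobic_capacity,
    lactate_o2_deficit,
    metabolic_rate_weir,
    required_metabolic_rate,
    resample_to_1hz,
)


def make_series(n=240, speed=13.6, vo2=4.5, rer=1.12):
    return TimeTrialSeries(
        t=np.arange(n, dtype=float),
        speed_kmh=np.full(n, speed),
        vo2_l_min=np.full(n, vo2),
        rer=np.full(n, rer),
    )


class TestResample:
    def test_identity_on_1hz_input(self):
        t = np.arange(10.0)
        v = np.linspace(0, 9, 10)
        t2, v2 = resample_to_1hz(t, v)
        assert np.array_equal(t2, t) and np.allclose(v2, v)

    def test_linear_midpoint(self):
        t2, v2 = resample_to_1hz([0.0, 2.0], [0.0, 4.0])
        assert np.allclose(t2, [0, 1, 2]) and np.allclose(v2, [0, 2, 4])

    def test_246hz_ramp_is_exact(self):
        t = np.arange(0, 240, 1 / 2.46)
        v = 3.0 + 0.05 * t  # linear in time
        t2, v2 = resample_to_1hz(t, v)
        assert np.max(np.abs(v2 - (3.0 + 0.05 * t2))) < 1e-12

    def test_non_monotone_rejected(self):
        with pytest.raises(ValueError):
            resample_to_1hz([0.0, 2.0, 1.0], [0.0, 1.0, 2.0])


class TestPeaks:
    def test_constant_series(self, ds_conditions):
        p = compute_peaks(make_series(vo2=4.0), ds_conditions)
        assert p.vo2peak_l_min == pytest.approx(4.0)

    def test_linear_ramp_peak_is_final_window_mean(self, ds_conditions):
        n = 240
        vo2 = np.linspace(0, 4, n)
        s = make_series(n)
        s.vo2_l_min = vo2
        p = compute_peaks(s, ds_conditions)
        assert p.vo2peak_l_min == pytest.approx(vo2[-30:].mean())
        assert p.vo2peak_l_min == pytest.approx(3.758, abs=0.001)
        assert p.vo2peak_l_min <= vo2.max()

    def test_peak_aerobic_rate_at_rer_one(self):
        from skicap import TestConditions

        cond = TestConditions(incline_deg=6.5, mu_r=0.0215, body_mass_kg=76.0, system_mass_kg=80.0)
        p = compute_peaks(make_series(vo2=5.0), cond)
        assert p.peak_aerobic_mr_w_kg == pytest.approx(5.0 * 20920.0 / 60.0 / 80.0)
        assert p.peak_aerobic_mr_w_kg == pytest.approx(21.79, abs=0.01)

    def test_short_series_rejected(self, ds_conditions):
        with pytest.raises(ValueError):
            compute_peaks(make_series(n=20), ds_conditions)


class TestRequiredRate:
    def test_fixed_ge_division(self, ds_conditions):
        s = make_series(speed=13.6)
        power_per_kg = 13.6 / 3.6 * ds_conditions.power_per_kg_per_ms()
        mr = required_metabolic_rate(s, power_per_kg / 20.0, ds_conditions)
        assert np.allclose(mr, 20.0)

    def test_linear_model_constant_speed(self, ds_conditions):
        m = fit_demand_model([(v, 1.0 + 2.0 * v) for v in (6, 7, 8, 9)], None, "linear")
        s = make_series(speed=10.0)
        mr = required_metabolic_rate(s, m, ds_conditions)
        assert np.allclose(mr, 21.0)

    def test_zero_intercept_model_equals_matching_fixed_ge(self, ds_conditions):
        factor = ds_conditions.power_per_kg_per_ms() / 3.6
        m = fit_demand_model([(v, 4.8 * factor * v) for v in (6, 7, 8, 9)], None, "linear")
        s = make_series(speed=13.6)
        mr_model = required_metabolic_rate(s, m, ds_conditions)
        mr_ge = required_metabolic_rate(s, 1.0 / 4.8, ds_conditions)
        assert np.allclose(mr_model, mr_ge)

    def test_invalid_ge_rejected(self, ds_conditions):
        with pytest.raises(ValueError):
            required_metabolic_rate(make_series(), 0.0, ds_conditions)


class TestAnaerobicRate:
    def test_identity_and_constant_gap(self, ds_conditions):
        s = make_series(vo2=4.5, rer=1.00)
        mr_ae = metabolic_rate_weir(4.5, 1.00) / ds_conditions.system_mass_kg
        assert np.allclose(anaerobic_rate_series(np.full(240, mr_ae), s, ds_conditions), 0.0)
        mr_an = anaerobic_rate_series(np.full(240, mr_ae + 5.0), s, ds_conditions)
        assert np.allclose(mr_an, 5.0)

    def test_rer_clamped_at_one(self, ds_conditions):
        """Supramaximal RER 1.15 must be converted with the 5.0 factor, not 5.165."""
        s = make_series(vo2=4.5, rer=1.15)
        mr_req = np.full(240, 25.0)
        clamped = anaerobic_rate_series(mr_req, s, ds_conditions, clamp_rer=True)
        raw = anaerobic_rate_series(mr_req, s, ds_conditions, clamp_rer=False)
        expect_clamped = 25.0 - metabolic_rate_weir(4.5, 1.00) / ds_conditions.system_mass_kg
        assert np.allclose(clamped, expect_clamped)
        # raw RER > 1 inflates the aerobic rate, so clamping raises the deficit
        assert np.all(clamped > raw)

    def test_misaligned_lengths_rejected(self, ds_conditions):
        with pytest.raises(ValueError):
            anaerobic_rate_series(np.zeros(100), make_series(), ds_conditions)


class TestIntegration:
    def test_constant_rate(self):
        e_an, deficit = integrate_anaerobic_capacity(np.full(240, 10.0))
        assert e_an == pytest.approx(2.4)
        assert deficit == pytest.approx(114.72, abs=0.05)

    def test_zero_series(self):
        assert integrate_anaerobic_capacity(np.zeros(240)) == (0.0, 0.0)

    def test_deficit_is_o2_equivalent_of_energy(self):
        from skicap import O2_EQ_ML_PER_J

        rng = np.random.default_rng(3)
        mr = rng.normal(5, 3, 240)
        e_an, deficit = integrate_anaerobic_capacity(mr)
        assert deficit == pytest.approx(e_an * 1000.0 * O2_EQ_ML_PER_J, rel=1e-12)


class TestLactateMethod:
    @pytest.mark.parametrize(
        "pre,post,expected",
        [(2.06, 11.72, 43), (1.88, 12.56, 48)],
    )
    def test_group_mean_values(self, pre, post, expected):
        assert round(lactate_o2_deficit(pre, post)) == expected

    def test_no_delta_no_deficit(self):
        assert lactate_o2_deficit(3.0, 3.0) == 0.0
        assert lactate_o2_deficit(3.0, 2.0) < 0.0  # negative delta passes through

    def test_bad_fraction_rejected(self):
        with pytest.raises(ValueError):
            lactate_o2_deficit(2.0, 10.0, lactic_fraction=0.0)


class TestEstimateAllMethods:
    def _athlete(self, cond, demand, speeds, tt_speed, vo2_tt):
        stages = []
        for i, v in enumerate(speeds):
            rer = 0.89 + 0.06 * i / (len(speeds) - 1)
            vo2 = demand(v) * cond.system_mass_kg * 60.0 / (4184.0 * (1.1 * rer + 3.9))
            stages.append(StageMeasurement(speed_kmh=v, vo2_l_min=vo2, rer=rer))
        baseline = BaselineMeasurement(vo2_l_min=0.0, rer=0.85)
        series = make_series(speed=tt_speed, vo2=vo2_tt, rer=1.12)
        return stages, baseline, series

    def test_zero_intercept_linear_all_methods_agree(self, ds_conditions):
        cond = ds_conditions
        demand = lambda v: 1.9 * v
        stages, baseline, series = self._athlete(cond, demand, [6.2, 7.2, 8.2, 9.2, 9.7], 13.6, 4.8)
        est = estimate_all_methods(stages, baseline, series, cond)
        deficits = [est[m].o2_deficit_ml_kg for m in ("8+Y_LIN", "8-Y_LIN", "8+Y_POL", "8-Y_POL", "GE_AVG", "GE_LAST")]
        assert np.allclose(deficits, deficits[0], atol=1e-6)

    def test_ge_avg_equals_ge_last_for_constant_ge(self, ds_conditions):
        demand = lambda v: 1.9 * v
        stages, baseline, series = self._athlete(ds_conditions, demand, [6.2, 7.2, 8.2, 9.2], 13.6, 4.8)
        est = estimate_all_methods(stages, baseline, series, ds_conditions)
        assert est["GE_AVG"].o2_deficit_ml_kg == pytest.approx(est["GE_LAST"].o2_deficit_ml_kg, abs=1e-9)

    def test_accounting_identity(self, ds_conditions):
        """Accumulated demand = accumulated aerobic energy + E_an, exactly."""
        from skicap.timetrial import aerobic_rate_series

        demand = lambda v: 0.5 + 1.8 * v
        stages, baseline, series = self._athlete(ds_conditions, demand, [6.2, 7.2, 8.2, 9.2], 13.6, 4.8)
        est = estimate_all_methods(stages, baseline, series, ds_conditions)
        mr_ae_sum = float(np.sum(aerobic_rate_series(series, ds_conditions)))
        for mid in ("8-Y_LIN", "GE_AVG"):
            mr_req_sum = est[mid].mr_tt_req_mean_w_kg * 240.0
            assert mr_req_sum == pytest.approx(mr_ae_sum + est[mid].e_an_kj_kg * 1000.0, rel=1e-12)

    def test_lactate_included_when_lactates_given(self, ds_conditions):
        demand = lambda v: 1.9 * v
        stages, baseline, series = self._athlete(ds_conditions, demand, [6.2, 7.2, 8.2, 9.2], 13.6, 4.8)
        est = estimate_all_methods(
            stages, baseline, series, ds_conditions, lactate_pre_mmol=2.0, lactate_post_mmol=11.0
        )
        assert "LACTATE" in est
        assert est["LACTATE"].o2_deficit_ml_kg == pytest.approx(9.0 * 3.0 / 0.67)
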