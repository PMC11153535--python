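import numpy as np
import pytest
from scipy.integrate import quad

import ivoct
from ivoct import schedules
from ivoct.schedules import (
    ExtrapolationError,
    FlowWaveform,
    blood_inflow_waveform,
    build_continuous,
    build_intermittent,
    dosage,
    peclet_number,
    reynolds_number,
)


class TestDosage:
    def test_default_continuous_scheme_total(self):
        wf = build_continuous(4.5, 0.8, 4.0)
        assert dosage(wf, 7.2) == pytest.approx(14.4, abs=1e-9)

    def test_default_intermittent_scheme_total(self):
        wf = build_intermittent(4.5, 0.8, (2, 3, 4, 5))
        assert dosage(wf, 7.2) == pytest.approx(8.0, abs=1e-3)

    def test_zero_waveform(self):
        wf = FlowWaveform(np.array([0.0, 7.2]), np.zeros(2))
        assert dosage(wf, 7.2) == 0.0

    def test_additive_over_disjoint_windows_and_linear(self):
        wf = build_continuous(3.0, 1.0, 3.0)
        v_total = dosage(wf, 7.2)
        assert dosage(wf, 2.0) + (v_total - dosage(wf, 2.0)) == pytest.approx(v_total)
        assert dosage(wf.scaled(2.0), 7.2) == pytest.approx(2.0 * v_total)

    def test_horizon_beyond_support_raises_for_nonzero_tail(self):
        wf = FlowWaveform(np.array([0.0, 1.0]), np.array([1.0, 1.0]))
        with pytest.raises(ExtrapolationError):
            dosage(wf, 2.0)


class TestContinuous:
    def test_rectangle_area_with_ramps(self):
        wf = build_continuous(4.5, 0.8, 4.0)
        assert dosage(wf, 7.2) == pytest.approx(4.5 * 3.2, rel=1e-9)

    def test_degenerate_interval_is_empty(self):
        wf = build_continuous(4.5, 2.0, 2.0)
        assert dosage(wf, 7.2) == 0.0

    def test_doubling_peak_doubles_dosage(self):
        v1 = dosage(build_continuous(2.0, 1.0, 3.0), 7.2)
        v2 = dosage(build_continuous(4.0, 1.0, 3.0), 7.2)
        assert v2 == pytest.approx(2.0 * v1)


class TestIntermittent:
    def test_default_per_cycle_volume(self):
        wf = build_intermittent(4.5, 0.8, (2,))
        assert dosage(wf, 7.2) == pytest.approx(4.5 * 0.8 / 1.8, abs=1e-4)

    def test_triangular_single_cycle(self):
        wf = build_intermittent(5.0, 1.0, (3,))
        assert dosage(wf, 7.2) == pytest.approx(2.0, abs=1e-6)

    def test_vanishing_exponent_approaches_rectangle(self):
        # x^a -> 1 pointwise as a -> 0: the burst fills the whole cycle
        wf = build_intermittent(4.5, 0.01, (2,))
        rect = 4.5 * 0.8
        assert dosage(wf, 7.2) == pytest.approx(rect / 1.01, rel=1e-3)

    def test_duplicate_cycles_rejected(self):
        with pytest.raises(ValueError):
            build_intermittent(4.5, 0.8, (2, 2))

    def test_per_cycle_formula_against_brute_force_quadrature(self):
        """peak * T / (a + 1) vs numerical integration, 50 random shapes."""
        rng = np.random.default_rng(7)
        for _ in range(50):
            peak = rng.uniform(0.5, 10.0)
            a = rng.uniform(0.2, 5.0)
            analytic = peak * 0.8 / (a + 1.0)
            brute, _ = quad(lambda t: peak * (t / 0.4) ** a, 0.0, 0.4)
            brute2, _ = quad(lambda t: peak * ((0.8 - t) / 0.4) ** a, 0.4, 0.8)
            assert brute + brute2 == pytest.approx(analytic, rel=1e-6)
            wf = build_intermittent(peak, a, (2,))
            assert dosage(wf, 7.2) == pytest.approx(analytic, rel=1e-3)


class TestBloodInflow:
    def test_periodicity(self):
        wf = blood_inflow_waveform()
        t = np.linspace(0.0, 0.8, 57)
        np.testing.assert_allclose(wf(t), wf(t + 0.8), atol=1e-12)

    def test_zero_peak_gives_zero_waveform(self):
        wf = blood_inflow_waveform(peak_rate=0.0)
        assert np.all(wf(np.linspace(0, 7.2, 100)) == 0.0)

    def test_mean_flow_positive_and_systolic_peak_in_first_half(self):
        wf = blood_inflow_waveform()
        t = np.linspace(0.0, 0.8, 801)
        q = wf(t)
        assert np.trapezoid(q, t) > 0
        assert t[np.argmax(q)] < 0.4

    def test_default_peak_calibrated_to_reynolds_770(self):
        wf = blood_inflow_waveform()
        c = ivoct.PhysicalConstants()
        mu = ivoct.mixture_viscosity(0.45, c.plasma_viscosity)
        re = reynolds_number(wf.rates.max(), 4.0, c.whole_blood_density, mu)
        assert re == pytest.approx(770.0, rel=0.02)


class TestDimensionlessNumbers:
    def test_combined_peak_reynolds_number(self):
        wf = blood_inflow_waveform()
        q = wf.rates.max() + 4.5  # blood systole plus saline injection
        re = reynolds_number(q, 4.0, 1000.0, 9.0e-4)
        assert re == pytest.approx(3092.0, rel=0.05)

    def test_zero_flow(self):
        assert reynolds_number(0.0, 4.0, 1000.0, 9e-4) == 0.0

    def test_peclet_magnitude_for_peak_lumen_velocity(self):
        area = np.pi * (0.002**2 - 0.00045**2)
        u = (blood_inflow_waveform().rates.max() + 4.5) * 1e-6 / area
        pe = peclet_number(u, 0.004, 9.08e-14)
        assert 1e10 <= pe <= 1e11

    def test_peclet_linear_scaling(self):
        assert peclet_number(2.0, 3.0, 1e-13) == pytest.approx(
            6.0 * peclet_number(1.0, 1.0, 1e-13)
        )
        with pytest.raises(ValueError):
            peclet_number(1.0, 1.0, 0.0)


def test_default_schemes_share_peak_rate(base_config):
    sch = ivoct.default_schemes(base_config)
    cont_peak = sch["continuous"].waveform.rates.max()
    inter_peak = sch["intermittent"].waveform.rates.max()
    assert cont_peak == pytest.approx(inter_peak)


def test_waveform_csv_round_trip(tmp_path):
    wf = build_continuous(4.5, 0.8, 4.0)
    path = tmp_path / "wf.csv"
    schedules.waveform_to_csv(wf, str(path))
    back = schedules.waveform_from_csv(str(path))
    np.testing.assert_allclose(back.times, wf.times)
    np.testing.assert_allclose(back.rates, wf.rates)
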