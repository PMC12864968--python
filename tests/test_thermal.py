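"""DSC: baseline subtraction, enthalpy closure, onset/peak, glass transition."""

import warnings

import numpy as np
import pytest

from pouchchar.errors import ValidationError
from pouchchar.synthetic import ThermogramScenario, gen_thermogram
from pouchchar.thermal import (
    Thermogram,
    glass_transition,
    integrate_enthalpy,
    melting_event,
    subtract_baseline,
)


def clean_peak_thermogram(center=80.0, width=2.0, area=67.40, sign=-1,
                          slope=0.002, intercept=0.05, noise=0.0, seed=0):
    return gen_thermogram(ThermogramScenario(
        baseline_slope=slope, baseline_intercept=intercept,
        peaks=((center, width, area, sign),), noise_sd=noise, seed=seed))


class TestBaseline:
    def test_pure_linear_signal_corrects_to_zero(self):
        tg = gen_thermogram(ThermogramScenario(baseline_slope=0.01,
                                               baseline_intercept=-0.3))
        bl = subtract_baseline(tg, (10, 40), (120, 150))
        assert np.max(np.abs(bl.corrected)) < 1e-9

    def test_peak_recovered_after_subtraction(self):
        tg = clean_peak_thermogram()
        bl = subtract_baseline(tg, (20, 50), (110, 140))
        clean = gen_thermogram(ThermogramScenario(peaks=((80.0, 2.0, 67.40, -1),)))
        assert np.allclose(bl.corrected, clean.heat_flow, atol=1e-9)
        assert not bl.contaminated

    def test_anchors_inside_peak_flagged(self):
        tg = clean_peak_thermogram()
        with pytest.warns(UserWarning):
            bl = subtract_baseline(tg, (74, 78), (82, 86))
        assert bl.contaminated

    def test_window_outside_range_rejected(self):
        tg = clean_peak_thermogram()
        with pytest.raises(ValidationError):
            subtract_baseline(tg, (-50, -40), (110, 140))


class TestEnthalpy:
    def test_quadrature_closure_reference_area(self):
        tg = clean_peak_thermogram(area=67.40)
        bl = subtract_baseline(tg, (20, 50), (110, 140))
        dh = integrate_enthalpy(tg.temperatures, bl.corrected, (60, 100), tg.ramp)
        assert dh == pytest.approx(67.40, rel=0.005)

    def test_zero_signal_zero_enthalpy(self):
        tg = gen_thermogram(ThermogramScenario())
        assert integrate_enthalpy(tg.temperatures, tg.heat_flow, (60, 100), 10.0) == 0.0

    def test_doubling_ramp_halves_enthalpy(self):
        tg = clean_peak_thermogram()
        bl = subtract_baseline(tg, (20, 50), (110, 140))
        dh1 = integrate_enthalpy(tg.temperatures, bl.corrected, (60, 100), 10.0)
        dh2 = integrate_enthalpy(tg.temperatures, bl.corrected, (60, 100), 20.0)
        assert dh2 == pytest.approx(dh1 / 2)

    def test_enthalpy_invariant_to_baseline(self):
        results = []
        for slope, intercept in ((0.0, 0.0), (0.01, -0.5), (-0.003, 2.0)):
            tg = clean_peak_thermogram(slope=slope, intercept=intercept)
            bl = subtract_baseline(tg, (20, 50), (110, 140))
            results.append(integrate_enthalpy(tg.temperatures, bl.corrected,
                                              (60, 100), tg.ramp))
        assert np.ptp(results) < 1e-6 * max(results)


class TestMeltingEvent:
    def test_gaussian_peak_location(self):
        tg = clean_peak_thermogram(center=150.8, width=1.5)
        bl = subtract_baseline(tg, (20, 50), (100, 130))
        ev = melting_event(tg.temperatures, bl.corrected, (140, 160), tg.ramp)
        assert ev.peak_T == pytest.approx(150.8, abs=0.1)
        assert ev.onset_T <= ev.peak_T

    def test_triangle_pulse_onset(self):
        # triangle rising from 147.1 C at constant slope: the tangent at any
        # edge point extrapolates back to exactly 147.1
        T = np.arange(130.0, 160.0, 0.1)
        s = np.where((T >= 147.1) & (T <= 151.0), -(T - 147.1) * 0.4, 0.0)
        s = np.where(T > 151.0, np.minimum(0.0, -(151.0 - 147.1) * 0.4 + (T - 151.0) * 0.8), s)
        ev = melting_event(T, s, (140, 155), 10.0)
        assert ev.onset_T == pytest.approx(147.1, abs=0.1)

    def test_flat_signal_no_event(self):
        T = np.arange(0.0, 160.0, 0.1)
        assert melting_event(T, np.zeros_like(T), (60, 100), 10.0) is None

    def test_positive_sign_convention_also_detected(self):
        tg = clean_peak_thermogram(sign=+1)
        bl = subtract_baseline(tg, (20, 50), (110, 140))
        ev = melting_event(tg.temperatures, bl.corrected, (60, 100), tg.ramp,
                           endo_down=False)
        assert ev.peak_T == pytest.approx(80.0, abs=0.1)
        assert ev.enthalpy == pytest.approx(67.40, rel=0.005)

    def test_onset_never_exceeds_peak_across_widths(self):
        for width in (0.5, 1.0, 2.0, 4.0):
            tg = clean_peak_thermogram(center=100.0, width=width)
            bl = subtract_baseline(tg, (20, 50), (130, 155))
            ev = melting_event(tg.temperatures, bl.corrected, (80, 120), tg.ramp)
            assert ev.onset_T <= ev.peak_T


class TestGlassTransition:
    def test_sigmoid_step_midpoint(self):
        tg = gen_thermogram(ThermogramScenario(steps=((104.0, 1.5, -0.02),)))
        ev = glass_transition(tg, (90, 120), min_step=0.001)
        assert ev.kind == "glass_transition"
        assert ev.onset_T == pytest.approx(104.0, abs=0.1)

    def test_sloped_baseline_does_not_bias_midpoint(self):
        # instrument drift of 0.002 W/g per C is several times the step
        # height over the window; side-line fitting must absorb it
        tg = gen_thermogram(ThermogramScenario(
            baseline_slope=0.002, baseline_intercept=0.05,
            steps=((104.0, 1.5, -0.02),)))
        ev = glass_transition(tg, (90, 120), min_step=0.001)
        assert ev.onset_T == pytest.approx(104.0, abs=0.5)

    def test_flat_baseline_no_event(self):
        tg = gen_thermogram(ThermogramScenario())
        assert glass_transition(tg, (90, 120), min_step=0.001) is None

    def test_step_below_noise_threshold_no_event(self):
        tg = gen_thermogram(ThermogramScenario(steps=((104.0, 1.5, -0.001),),
                                               noise_sd=0.002, seed=3))
        with warnings.catch_warnings():
            warnings.simplefilter("ignore")
            assert glass_transition(tg, (90, 120)) is None


class TestThermogramValidation:
    def test_non_increasing_temperatures_rejected(self):
        with pytest.raises(ValidationError):
            Thermogram(np.array([0.0, 1.0, 1.0]), np.zeros(3), ramp=10.0)

    def test_zero_ramp_rejected(self):
        with pytest.raises(ValidationError):
            Thermogram(np.array([0.0, 1.0]), np.zeros(2), ramp=0.0)
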