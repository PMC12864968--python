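"""Density stack: USP tap rule, pycnometry, CI/HR/porosity/flow class."""

import numpy as np
import pytest
from hypothesis import given, settings
from hypothesis import strategies as st

from pouchchar.errors import NeedsMoreTapsError, ValidationError
from pouchchar.powder import (
    PycnometerRun,
    TappedSeries,
    carr_index,
    classify_flow,
    hausner_ratio,
    porosity_percent,
    pycnometer_sample_volume,
    select_pycnometer_runs,
    summarize_density,
    tapped_density_converge,
    untapped_bulk_density,
)
from pouchchar.study import DENSITIES, PRODUCTS

#: Published derived columns (CI, HR, P%) recomputed from the published
#: rounded densities; Volt porosity is a rounding-boundary cell where the
#: recomputation differs from print by just over 0.05 and is checked at its
#: own observed gap.
PUBLISHED_DERIVED = {
    "on!": (20.02, 1.250, 48.109),
    "Zyn": (16.68, 1.200, 63.208),
    "Velo": (16.32, 1.195, 45.839),
    "Dryft": (23.91, 1.314, 45.359),
    "Rogue": (12.85, 1.147, 38.620),
    "Volt": (50.38, 2.015, 38.999),
    "Loop": (36.90, 1.585, 55.739),
}
ROUNDING_BOUNDARY_POROSITY = {"Volt"}  # recomputed 39.049 vs printed 38.999


class TestUntapped:
    def test_arithmetic(self):
        assert untapped_bulk_density(15.80) == pytest.approx(0.632)
        assert untapped_bulk_density(25.0) == pytest.approx(1.0)

    def test_zero_mass_rejected(self):
        with pytest.raises(ValidationError):
            untapped_bulk_density(0.0)


class TestTappedRule:
    def test_rule_walkthrough_converges_at_third_block(self):
        s = TappedSeries(100.0, (160.0, 130.0, 128.0))
        vol, rho = tapped_density_converge(s)
        assert vol == 128.0
        assert rho == pytest.approx(0.78125)

    def test_needs_more_taps(self):
        with pytest.raises(NeedsMoreTapsError):
            tapped_density_converge(TappedSeries(100.0, (160.0, 150.0)))

    def test_constant_volumes_converge_immediately(self):
        vol, rho = tapped_density_converge(TappedSeries(100.0, (140.0, 140.0)))
        assert vol == 140.0
        assert rho == pytest.approx(100.0 / 140.0)

    def test_increasing_volumes_rejected(self):
        with pytest.raises(ValidationError):
            TappedSeries(100.0, (130.0, 140.0))


class TestPycnometer:
    def test_volume_arithmetic(self):
        run = PycnometerRun(P1=20.0, P2=12.0, V_chamber=10.0, V_reference=10.0,
                            sample_mass=5.0)
        assert pycnometer_sample_volume(run) == pytest.approx(10 + 10 * (1 - 5 / 3))

    def test_equal_pressures_formula_limit(self):
        run = PycnometerRun(P1=10.0, P2=10.0, V_chamber=10.0, V_reference=10.0,
                            sample_mass=5.0)
        assert pycnometer_sample_volume(run) == pytest.approx(10.0)

    @settings(derandomize=True, max_examples=100)
    @given(st.floats(min_value=1.01, max_value=5.0),
           st.floats(min_value=1.0, max_value=20.0),
           st.floats(min_value=1.0, max_value=20.0))
    def test_sample_volume_below_chamber_when_p1_exceeds_p2(self, ratio, vc, vr):
        run = PycnometerRun(P1=10.0 * ratio, P2=10.0, V_chamber=vc,
                            V_reference=vr, sample_mass=1.0)
        assert pycnometer_sample_volume(run) < vc

    def test_run_selection_early_triple(self):
        triple, rho, converged = select_pycnometer_runs([1.523, 1.5231, 1.5229])
        assert converged
        assert rho == pytest.approx(np.mean([1.523, 1.5231, 1.5229]))

    def test_run_selection_final_three_fallback(self):
        vals = [1.50, 1.60, 1.55, 1.552, 1.5521]
        triple, rho, converged = select_pycnometer_runs(vals)
        assert triple == tuple(vals[-3:])
        assert not converged

    def test_identical_values_select_first_triple(self):
        triple, rho, converged = select_pycnometer_runs([1.5] * 5)
        assert converged and rho == 1.5

    def test_too_few_runs_rejected(self):
        with pytest.raises(ValidationError):
            select_pycnometer_runs([1.5, 1.5])


class TestDerivedMetrics:
    @pytest.mark.parametrize("product", PRODUCTS)
    def test_full_table_recomputation(self, product):
        d = DENSITIES[product]
        ci_ref, hr_ref, p_ref = PUBLISHED_DERIVED[product]
        assert carr_index(d["rho_UB"], d["rho_TB"]) == pytest.approx(ci_ref, abs=0.05)
        assert hausner_ratio(d["rho_UB"], d["rho_TB"]) == pytest.approx(hr_ref, abs=0.001)
        p_tol = 0.06 if product in ROUNDING_BOUNDARY_POROSITY else 0.05
        assert porosity_percent(d["rho_TB"], d["rho_T"]) == pytest.approx(p_ref, abs=p_tol)

    def test_equal_densities_degenerate_values(self):
        assert carr_index(0.7, 0.7) == 0.0
        assert hausner_ratio(0.7, 0.7) == 1.0
        assert porosity_percent(1.5, 1.5) == 0.0

    @settings(derandomize=True, max_examples=200)
    @given(st.floats(min_value=0.1, max_value=1.5),
           st.floats(min_value=0.1, max_value=1.5))
    def test_ci_hr_identity(self, rho_ub, rho_tb):
        import warnings as _w
        with _w.catch_warnings():
            _w.simplefilter("ignore")  # inverted pairs warn by design
            ci = carr_index(rho_ub, rho_tb)
            hr = hausner_ratio(rho_ub, rho_tb)
        assert ci == pytest.approx((1 - 1 / hr) * 100, abs=1e-9)

    def test_porosity_strictly_decreasing_toward_true_density(self):
        ps = [porosity_percent(rho_tb, 1.5) for rho_tb in np.linspace(0.5, 1.49, 20)]
        assert all(a > b for a, b in zip(ps, ps[1:]))

    def test_inverted_densities_warn_not_raise(self):
        with pytest.warns(UserWarning):
            assert carr_index(0.8, 0.7) < 0


class TestFlowClassification:
    def test_volt_poor_concordant(self):
        fc = classify_flow(50.38, 2.015)
        assert fc.label == "poor" and fc.concordant

    def test_dryft_discordant(self):
        fc = classify_flow(23.91, 1.314)
        assert not fc.concordant
        assert not fc.poor_by_ci and fc.poor_by_hr

    def test_free_flowing(self):
        fc = classify_flow(0.0, 1.0)
        assert fc.label == "free-flowing" and fc.concordant

    def test_summary_assembles_consistently(self):
        d = DENSITIES["Loop"]
        s = summarize_density("Loop", d["rho_UB"], d["rho_TB"], d["rho_T"])
        assert s.flow_class.label == "poor"
        assert s.ordering_ok
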