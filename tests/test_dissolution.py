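"""First-order model: profile construction, normalization, fitting, prediction."""

import numpy as np
import pytest

from pouchchar.dissolution import (
    DissolutionProfile,
    KineticFit,
    ProductRecord,
    average_profile,
    cumulate_fractions,
    first_order_release,
    fit_first_order,
    percent_of_M0,
    percent_of_total_release,
    percent_released_from_content,
    predict_percent_released,
)
from pouchchar.errors import AlignmentError, UndefinedNormalizationError, ValidationError
from pouchchar.study import KINETICS
from pouchchar.synthetic import DissolutionScenario, gen_dissolution


def make_profile(times, fractions, name="x", rep=0):
    return cumulate_fractions(name, rep, times, fractions)


class TestProfileConstruction:
    def test_prefix_sum(self):
        p = make_profile([4, 8, 12], [2, 1, 1])
        assert np.array_equal(p.cumulative_mg, [2, 3, 4])

    def test_all_zero_fractions(self):
        p = make_profile([4, 8, 12], [0, 0, 0])
        assert np.array_equal(p.cumulative_mg, [0, 0, 0])

    def test_negative_fraction_rejected(self):
        with pytest.raises(ValidationError):
            make_profile([4, 8], [1, -0.1])

    def test_inconsistent_cumulative_rejected(self):
        with pytest.raises(ValidationError):
            DissolutionProfile("x", 0, np.array([4.0, 8.0]),
                               np.array([1.0, 1.0]), np.array([1.0, 3.0]))

    def test_round_trip_with_generator(self, noise_free_profiles):
        for reps in noise_free_profiles.values():
            p = reps[0]
            rebuilt = make_profile(p.times, np.diff(np.concatenate([[0], p.cumulative_mg])))
            assert np.allclose(rebuilt.cumulative_mg, p.cumulative_mg, atol=1e-12)


class TestNormalization:
    def test_percent_of_total_ends_at_exactly_100(self, noise_free_profiles):
        for reps in noise_free_profiles.values():
            assert percent_of_total_release(reps[0])[-1] == 100.0

    def test_percent_of_total_arithmetic(self):
        p = make_profile([4, 8, 12], [2, 1, 1])
        assert np.allclose(percent_of_total_release(p), [50, 75, 100])

    def test_percent_of_total_closed_form_zyn_at_20min(self):
        # fastest product, k = 0.103/min: 100*(1-e^-2.06)/(1-e^-6.18) = 87.44
        t = np.array([4, 8, 12, 16, 20, 30, 40, 50, 60.0])
        cum = first_order_release(t, 5.350, 0.103)
        p = make_profile(t, np.diff(np.concatenate([[0], cum])))
        pct = percent_of_total_release(p)
        expected = 100 * (1 - np.exp(-2.06)) / (1 - np.exp(-6.18))
        assert pct[t == 20][0] == pytest.approx(expected, abs=1e-9)
        assert expected == pytest.approx(87.44, abs=0.01)

    def test_zero_total_release_rejected(self):
        p = make_profile([4, 8], [0, 0])
        with pytest.raises(UndefinedNormalizationError):
            percent_of_total_release(p)

    def test_percent_of_M0(self):
        p = make_profile([4.0], [4.2])
        fit = KineticFit(M0=8.4, k=0.1, rss=0.0, converged=True, n_points=9)
        assert percent_of_M0(p, fit)[0] == pytest.approx(50.0)

    def test_percent_of_M0_equals_model_for_generated_data(self):
        t = np.array([4, 8, 12, 16, 20, 30, 40, 50, 60.0])
        cum = first_order_release(t, 8.380, 0.080)
        p = make_profile(t, np.diff(np.concatenate([[0], cum])))
        fit = KineticFit(M0=8.380, k=0.080, rss=0.0, converged=True, n_points=9)
        assert np.allclose(percent_of_M0(p, fit), 100 * (1 - np.exp(-0.080 * t)), atol=1e-9)


class TestFitting:
    @pytest.mark.parametrize("product", ["on!", "Loop", "Zyn", "Volt"])
    def test_noise_free_recovery(self, product, time_grid):
        m0, k = KINETICS[product]
        cum = first_order_release(time_grid, m0, k)
        fit = fit_first_order(time_grid, cum)
        assert fit.converged
        assert fit.M0 == pytest.approx(m0, abs=1e-3)
        assert fit.k == pytest.approx(k, abs=1e-4)

    def test_fit_agrees_with_grid_search_oracle(self, time_grid):
        rng = np.random.default_rng(42)
        cum = first_order_release(time_grid, 6.0, 0.06) + rng.normal(0, 0.1, time_grid.size)
        cum = np.maximum.accumulate(np.clip(cum, 0, None))
        fit = fit_first_order(time_grid, cum)

        def rss(m0, k):
            return np.sum((first_order_release(time_grid, m0, k) - cum) ** 2)

        m0s = np.linspace(0.8 * fit.M0, 1.2 * fit.M0, 201)
        ks = np.linspace(0.5 * fit.k, 1.5 * fit.k, 201)
        grid = np.array([[rss(m, q) for q in ks] for m in m0s])
        i, j = np.unravel_index(np.argmin(grid), grid.shape)
        assert fit.rss <= grid[i, j] + 1e-9
        assert m0s[i] == pytest.approx(fit.M0, rel=5e-3)
        assert ks[j] == pytest.approx(fit.k, rel=5e-3)

    def test_constant_series_flagged(self, time_grid):
        fit = fit_first_order(time_grid, np.full(time_grid.size, 5.0))
        assert not fit.converged

    def test_too_few_points_rejected(self):
        with pytest.raises(ValidationError):
            fit_first_order(np.array([4.0, 8.0]), np.array([1.0, 2.0]))

    def test_recovery_under_replicate_noise(self, time_grid):
        # 2% additive noise relative to M0, 12 replicates: median recovery
        # within 2% (M0) / 5% (k) at each reference parameter regime
        for product, (m0, k) in KINETICS.items():
            sc = DissolutionScenario(product, m0, k, M0_cv=0, k_cv=0,
                                     noise_sd=0.02 * m0, n_replicates=12, seed=123)
            fits = [fit_first_order(p) for p in gen_dissolution(sc)]
            assert np.median([f.M0 for f in fits]) == pytest.approx(m0, rel=0.02)
            assert np.median([f.k for f in fits]) == pytest.approx(k, rel=0.05)

    def test_model_curve_increasing_concave(self, time_grid):
        y = first_order_release(time_grid, 5.0, 0.08)
        assert np.all(np.diff(y) > 0)
        assert np.all(np.diff(np.diff(y) / np.diff(time_grid)) < 0)


class TestPrediction:
    def test_loop_prints_72_percent_at_60min(self):
        assert round(predict_percent_released(0.021, 60.0)) == 72

    def test_zero_time(self):
        assert predict_percent_released(0.08, 0.0) == 0.0

    def test_asymptote(self):
        assert predict_percent_released(0.08, 1e6) == pytest.approx(100.0, abs=1e-6)


class TestContentNormalization:
    def test_arithmetic(self):
        p = make_profile([4, 8], [4.0, 4.0])
        rec = ProductRecord("x", 0.5, 8.0, 8.2)
        assert percent_released_from_content(p, rec) == pytest.approx(100 * 8.0 / 8.2)

    def test_equal_gives_100(self):
        p = make_profile([4.0], [8.2])
        rec = ProductRecord("x", 0.5, 8.0, 8.2)
        assert percent_released_from_content(p, rec) == pytest.approx(100.0)

    def test_zero_release(self):
        p = make_profile([4.0], [0.0])
        rec = ProductRecord("x", 0.5, 8.0, 8.2)
        assert percent_released_from_content(p, rec) == 0.0

    def test_invalid_record(self):
        with pytest.raises(ValidationError):
            ProductRecord("x", 0.5, 8.0, -1.0)


class TestAveraging:
    def test_identical_replicates_zero_sd(self):
        reps = [make_profile([4, 8], [2, 2], rep=i) for i in range(2)]
        m = average_profile(reps)
        assert np.all(m.sd_mg == 0)

    def test_hand_arithmetic(self):
        a = make_profile([4, 8], [2, 2], rep=0)   # cumulative [2, 4]
        b = make_profile([4, 8], [4, 2], rep=1)   # cumulative [4, 6]
        m = average_profile([a, b])
        assert np.allclose(m.mean_mg, [3, 5])
        assert np.allclose(m.sd_mg, np.sqrt(2.0))

    def test_single_replicate_flagged(self):
        m = average_profile([make_profile([4, 8], [1, 1])])
        assert not m.sd_defined
        assert np.all(m.sd_mg == 0)

    def test_mismatched_grids_rejected(self):
        a = make_profile([4, 8], [1, 1], rep=0)
        b = make_profile([4, 12], [1, 1], rep=1)
        with pytest.raises(AlignmentError):
            average_profile([a, b])
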