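"""Exponential stripping, half-life arithmetic and dose/peak relations."""

import numpy as np
import pytest

from guanokin import (
    BiexponentialFit,
    FitConfig,
    bateman,
    effective_input_half_life,
    elimination_fraction,
    fit_elimination,
    fit_full,
    half_life,
    peak_from_dose,
    predict_M,
    solve_dose,
    strip_input,
    superpose_doses,
)
from guanokin.kinetics import MonotonicityWarning, analytic_tmax

LN2 = np.log(2.0)


def biexp_points(a_el, b_el, a_in, b_in, times_h):
    t = np.asarray(times_h, dtype=float)
    return list(zip(t, a_el * np.exp(b_el * t) - a_in * np.exp(b_in * t)))


class TestHalfLifeArithmetic:
    def test_half_life_inverts_rate(self):
        assert half_life(-LN2) == pytest.approx(1.0, rel=1e-12)
        assert half_life(-0.0130782) == pytest.approx(53.0, abs=0.05)
        assert half_life(-0.01) == pytest.approx(2 * half_life(-0.02), rel=1e-12)

    def test_zero_rate_undefined(self):
        with pytest.raises(ValueError):
            half_life(0.0)

    def test_elimination_fraction_five_and_four_half_lives(self):
        assert elimination_fraction(5) == pytest.approx(0.96875)
        assert round(100 * elimination_fraction(5)) == 97
        assert elimination_fraction(4) == pytest.approx(0.9375)
        assert round(100 * elimination_fraction(4)) == 94
        assert elimination_fraction(0) == 0.0

    def test_elimination_fraction_strictly_increasing_to_one(self):
        ks = np.linspace(0, 30, 200)
        fr = np.array([elimination_fraction(k) for k in ks])
        assert np.all(np.diff(fr) > 0)
        assert fr[-1] == pytest.approx(1.0, abs=1e-9)

    @pytest.mark.parametrize(
        "t_half,n,expected,tol",
        [(43.0, 5.5, 7.8, 0.05), (43.2, 5.5, 7.85, 0.01), (10.0, 1.0, 10.0, 1e-12)],
    )
    def test_effective_input_half_life(self, t_half, n, expected, tol):
        assert effective_input_half_life(t_half, n) == pytest.approx(
            expected, abs=tol
        )


class TestStripping:
    def test_exact_single_exponential_recovered(self):
        t = np.array([10.0, 40.0, 90.0, 160.0])
        a, b = 0.8, -0.02
        a_hat, b_hat = fit_elimination(list(zip(t, a * np.exp(b * t))))
        assert a_hat == pytest.approx(a, rel=1e-9)
        assert b_hat == pytest.approx(b, rel=1e-9)

    def test_constant_series_warns_not_declining(self):
        with pytest.warns(MonotonicityWarning):
            a_hat, b_hat = fit_elimination([(0.0, 0.4), (50.0, 0.4), (100.0, 0.4)])
        assert b_hat == pytest.approx(0.0, abs=1e-12)

    def test_nonpositive_values_and_short_series_rejected(self):
        with pytest.raises(ValueError, match="non-positive"):
            fit_elimination([(0.0, 0.5), (10.0, 0.0), (20.0, 0.1)])
        with pytest.raises(ValueError, match="at least 2"):
            fit_elimination([(0.0, 0.5)])

    def test_terminal_phase_of_bateman_recovers_slow_rate(self):
        k_in, k_out = 0.08, 0.013078  # elimination t1/2 = 53 h
        t_max = np.log(k_in / k_out) / (k_in - k_out)
        t = np.linspace(3 * t_max, 3 * t_max + 300, 12)
        pts = list(zip(t, bateman(t, 1.0, k_in, k_out)))
        _, b_el = fit_elimination(pts)
        assert abs(-b_el - k_out) / k_out < 0.02

    def test_strip_recovers_input_rate_with_matched_amplitudes(self):
        a, b_el, b_in = 1.5, -0.013, -0.05
        t = np.array([2.0, 6.0, 12.0, 20.0, 30.0, 40.0, 60.0, 90.0, 150.0])
        pts = biexp_points(a, b_el, a, b_in, t)
        a_in, b_in_hat = strip_input(pts, (a, b_el), knot="paper")
        assert a_in == a  # knot policy forces the crossing
        assert b_in_hat == pytest.approx(b_in, rel=1e-6)

    def test_free_knot_recovers_both_input_parameters(self):
        a_el, b_el, a_in, b_in = 1.2, -0.013, 0.9, -0.06
        t = np.linspace(1.0, 120.0, 15)
        pts = biexp_points(a_el, b_el, a_in, b_in, t)
        a_hat, b_hat = strip_input(
            pts, (a_el, b_el), knot="free", window_end_h=120.0
        )
        assert a_hat == pytest.approx(a_in, rel=1e-6)
        assert b_hat == pytest.approx(b_in, rel=1e-6)

    def test_pure_elimination_data_has_no_input_phase(self):
        t = np.linspace(0.0, 100.0, 8)
        pts = list(zip(t, 0.7 * np.exp(-0.02 * t)))
        with pytest.raises(ValueError, match="input phase already complete"):
            strip_input(pts, (0.7, -0.02))


class TestPredictM:
    def test_matched_amplitudes_cross_at_origin(self):
        fit = BiexponentialFit(a_el=1.4, b_el=-0.013, a_in=1.4, b_in=-0.05)
        assert predict_M(fit, 0.0) == 0.0

    def test_analytic_tmax_matches_grid_search(self):
        b_el, b_in = -0.0131, -0.0415
        fit = BiexponentialFit(a_el=1.7, b_el=b_el, a_in=1.7, b_in=b_in)
        grid = np.linspace(0.0, 600.0, 2_000_001)
        t_grid = grid[np.argmax(predict_M(fit, grid))]
        assert analytic_tmax(b_el, b_in) == pytest.approx(t_grid, abs=1e-3)
        assert fit.t_max_h == pytest.approx(t_grid, abs=1e-3)

    def test_power_shortens_input_half_life_by_factor_n(self):
        # (e^{b t})^n = e^{n b t}: the input term's half-decay time is t_half/n
        b_in, n = -0.05, 5.5
        fit = BiexponentialFit(a_el=1.0, b_el=-0.005, a_in=1.0, b_in=b_in, n=n)
        t_half_in = LN2 / -b_in
        input_term = lambda t: (fit.a_in * np.exp(fit.b_in * t)) ** fit.n
        assert input_term(t_half_in / n) == pytest.approx(
            input_term(0.0) / 2.0, rel=1e-12
        )
        assert fit.t_half_in_effective_h == pytest.approx(t_half_in / n, rel=1e-12)

    def test_n_equal_one_reduces_to_plain_biexponential(self):
        t = np.linspace(0.0, 300.0, 50)
        f1 = BiexponentialFit(a_el=1.3, b_el=-0.013, a_in=1.3, b_in=-0.04, n=1.0)
        manual = 1.3 * np.exp(-0.013 * t) - 1.3 * np.exp(-0.04 * t)
        assert np.allclose(predict_M(f1, t), np.maximum(manual, 0), rtol=1e-12)

    def test_prediction_nonnegative_iff_input_faster(self):
        t = np.linspace(0.0, 500.0, 200)
        ok = BiexponentialFit(a_el=1.0, b_el=-0.01, a_in=1.0, b_in=-0.05)
        assert np.all(ok._raw(t) >= -1e-12)
        bad = BiexponentialFit(a_el=1.0, b_el=-0.05, a_in=1.0, b_in=-0.01)
        assert np.any(bad._raw(t) < 0)


class TestDosePeak:
    def test_zero_dose_gives_zero_peak(self):
        assert peak_from_dose(0.0, -0.04, -0.013, 50.0) == 0.0

    def test_solve_dose_round_trips(self):
        peak = peak_from_dose(2.7, -0.04, -0.013, 50.0)
        assert solve_dose(peak, -0.04, -0.013, 50.0) == pytest.approx(
            2.7, rel=1e-12
        )

    def test_peak_formula_matches_dense_grid_maximum(self):
        b_el, b_in, dv = -0.013, -0.0415, 1.9
        t_max = analytic_tmax(b_el, b_in)
        scale = b_in / (b_in - b_el)
        grid = np.linspace(0.0, 800.0, 400_001)
        curve = dv * scale * (np.exp(b_el * grid) - np.exp(b_in * grid))
        assert peak_from_dose(dv, b_in, b_el, t_max) == pytest.approx(
            curve.max(), rel=1e-6
        )

    def test_degenerate_rates_rejected(self):
        with pytest.raises(ValueError):
            peak_from_dose(1.0, -0.02, -0.02, 10.0)


class TestSuperposition:
    def setup_method(self):
        self.fit = BiexponentialFit(a_el=1.0, b_el=-0.013, a_in=1.0, b_in=-0.05)

    def test_single_dose_at_zero_equals_predict(self):
        t = np.linspace(0.0, 400.0, 97)
        assert np.allclose(
            superpose_doses(self.fit, [0.0])(t), predict_M(self.fit, t)
        )

    def test_two_simultaneous_doses_double_the_curve(self):
        t = np.linspace(0.0, 400.0, 97)
        assert np.allclose(
            superpose_doses(self.fit, [0.0, 0.0])(t),
            2 * predict_M(self.fit, t),
        )

    def test_delayed_doses_attenuate_relative_peak(self):
        t = np.linspace(0.0, 2000.0, 4001)
        m = 4
        curve = superpose_doses(self.fit, [0.0, 100.0, 200.0, 300.0])(t)
        single_peak = predict_M(self.fit, t).max()
        assert curve.max() <= m * single_peak + 1e-12
        assert curve.max() < m * single_peak  # strict for delayed pulses


class TestFullPipeline:
    def test_noiseless_biexponential_recovered_exactly(self):
        a, b_el, b_in = 1.6, -0.013, -0.05  # rates separated ~3.8x
        t = np.array(
            [1.0, 3.0, 6.0, 10.0, 16.0, 24.0, 40.0, 60.0, 90.0, 140.0, 200.0, 280.0]
        )
        fit = fit_full(biexp_points(a, b_el, a, b_in, t))
        assert fit.n == 1.0
        assert abs(fit.b_el - b_el) / abs(b_el) < 1e-6
        assert abs(fit.b_in - b_in) / abs(b_in) < 1e-6
        assert fit.a_el == pytest.approx(a, rel=1e-6)

    def test_power_law_curve_recovers_n(self):
        a, b_el, b_in, n = 1.5, -0.013, -0.016, 5.5
        # grid covers the rise (zero-crossing ~24 h, peak ~50 h) and tail
        t = np.array(
            [26.0, 30.0, 36.0, 42.0, 48.0, 60.0, 72.0, 96.0,
             120.0, 150.0, 200.0, 260.0]
        )
        y = a * np.exp(b_el * t) - (a * np.exp(b_in * t)) ** n
        fit = fit_full(list(zip(t, y)))
        assert abs(fit.n - n) <= 0.5
        assert abs(fit.b_el - b_el) / abs(b_el) < 0.01

    def test_too_few_points_rejected(self):
        with pytest.raises(ValueError, match="at least 4"):
            fit_full([(1.0, 0.1), (2.0, 0.2), (3.0, 0.1)])

    def test_excluded_outlier_is_recorded_not_fitted(self):
        a, b_el, b_in = 1.6, -0.013, -0.05
        t = np.array([2.0, 8.0, 20.0, 40.0, 80.0, 140.0, 200.0])
        pts = biexp_points(a, b_el, a, b_in, t) + [(168.0, 0.9)]  # wild point
        cfg = FitConfig(exclusions=(168.0,))
        fit = fit_full(pts, cfg)
        assert fit.excluded_points == [168.0]
        assert abs(fit.b_el - b_el) / abs(b_el) < 1e-6
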