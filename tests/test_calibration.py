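"""Calibration regression, quantification limits and carryover."""

import numpy as np
import pytest
from hypothesis import given, settings
from hypothesis import strategies as st

from metaboquant.calibration import (
    CalibrationSeries,
    CurveFit,
    check_carryover,
    determine_loq,
    fit_curve,
    make_serial_dilution,
    select_model,
)
from metaboquant.errors import CalibrationError
from metaboquant.synthetic import simulate_calibration

from conftest import wls_poly_oracle


class TestSerialDilution:
    def test_default_design_exceeds_thousandfold(self):
        levels = make_serial_dilution(1000.0)
        assert len(levels) == 11
        assert levels[-1] / levels[0] == 1024.0
        assert levels[0] == 0.9765625

    def test_two_levels(self):
        assert list(make_serial_dilution(1000.0, 2, 10.0)) == [100.0, 1000.0]

    @given(
        top=st.floats(0.1, 1e6),
        n=st.integers(2, 15),
        factor=st.floats(1.1, 10.0),
    )
    @settings(max_examples=50, deadline=None)
    def test_geometric_series_properties(self, top, n, factor):
        levels = make_serial_dilution(top, n, factor)
        assert len(levels) == n
        assert np.all(np.diff(levels) > 0)
        assert levels[-1] == pytest.approx(top)
        assert levels[-1] / levels[0] == pytest.approx(factor ** (n - 1))

    def test_nonpositive_top_rejected(self):
        with pytest.raises(CalibrationError):
            make_serial_dilution(0.0)


ALL_VARIANTS = [
    ("linear", None, None),
    ("linear", None, "inv_x"),
    ("linear", "loglog", None),
    ("quadratic", None, None),
    ("quadratic", None, "inv_x"),
    ("quadratic", "loglog", None),
]


class TestFit:
    def test_noiseless_linear(self):
        x = make_serial_dilution(100.0, 8, 2.0)
        fit = fit_curve(CalibrationSeries("m", x, 2.0 * x))
        assert fit.coefficients == pytest.approx([0.0, 2.0], abs=1e-10)
        assert fit.r_squared == pytest.approx(1.0)

    def test_noiseless_quadratic(self):
        x = make_serial_dilution(10.0, 8, 2.0)
        fit = fit_curve(CalibrationSeries("m", x, x**2), model="quadratic")
        assert fit.coefficients[2] == pytest.approx(1.0, abs=1e-8)
        assert fit.r_squared == pytest.approx(1.0)

    @pytest.mark.parametrize("model,transform,weighting", ALL_VARIANTS)
    def test_oracle_equivalence(self, model, transform, weighting):
        """Every regression variant matches loop-coded normal equations."""
        rng = np.random.default_rng(42)
        order = 1 if model == "linear" else 2
        for _ in range(20):
            nominal = make_serial_dilution(
                float(rng.uniform(5, 20)), int(rng.integers(6, 12)), 2.0
            )
            response = (0.5 + 2.0 * nominal + 0.01 * nominal**2) * (
                1 + rng.normal(0, 0.05, len(nominal))
            )
            series = CalibrationSeries("m", nominal, response)
            fit = fit_curve(series, model, transform, weighting)
            if transform == "loglog":
                x, y = np.log(nominal), np.log(response)
                w = np.ones_like(x)
            else:
                x, y = nominal, response
                w = 1.0 / nominal if weighting == "inv_x" else np.ones_like(x)
            expected = wls_poly_oracle(x, y, w, order)
            np.testing.assert_allclose(fit.coefficients, expected, rtol=1e-10)

    def test_r2_invariant_to_concentration_rescaling(self):
        series, _ = simulate_calibration(5, noise_cv=5.0)
        f1 = fit_curve(series)
        f2 = fit_curve(
            CalibrationSeries("m", series.nominal * 7.0, series.response)
        )
        assert f1.r_squared == pytest.approx(f2.r_squared, rel=1e-12)

    def test_loglog_r2_invariant_to_response_rescaling(self):
        series, _ = simulate_calibration(5, noise_cv=5.0)
        f1 = fit_curve(series, transform="loglog")
        f2 = fit_curve(
            CalibrationSeries("m", series.nominal, series.response * 13.0),
            transform="loglog",
        )
        assert f1.r_squared == pytest.approx(f2.r_squared, rel=1e-12)

    def test_loglog_forces_unweighted(self):
        series, _ = simulate_calibration(1)
        with pytest.warns(UserWarning, match="forcing weighting"):
            fit = fit_curve(series, transform="loglog", weighting="inv_x")
        assert fit.weighting is None

    def test_insufficient_levels(self):
        with pytest.raises(CalibrationError, match="levels"):
            fit_curve(CalibrationSeries("m", [1.0, 2.0], [1.0, 2.0]))

    def test_loglog_rejects_nonpositive_response(self):
        x = make_serial_dilution(10.0, 6, 2.0)
        y = 2.0 * x
        y[0] = 0.0
        with pytest.raises(CalibrationError, match="positive"):
            fit_curve(CalibrationSeries("m", x, y), transform="loglog")


class TestBackCalculate:
    def test_linear_inverse(self):
        x = make_serial_dilution(100.0, 8, 2.0)
        fit = fit_curve(CalibrationSeries("m", x, 2.0 * x))
        assert fit.back_calculate(10.0) == pytest.approx(5.0)

    def test_loglog_identity_curve(self):
        x = make_serial_dilution(100.0, 8, 2.0)
        fit = fit_curve(CalibrationSeries("m", x, x), transform="loglog")
        assert fit.back_calculate(3.7) == pytest.approx(3.7, rel=1e-10)

    def test_quadratic_round_trip(self):
        rng = np.random.default_rng(0)
        x = make_serial_dilution(50.0, 9, 2.0)
        y = 1.0 + 3.0 * x + 0.02 * x**2
        fit = fit_curve(CalibrationSeries("m", x, y), model="quadratic")
        conc = rng.uniform(x[0], x[-1], 1000)
        back = fit.back_calculate(fit.predict(conc))
        np.testing.assert_allclose(back, conc, rtol=1e-8)

    def test_monotone_within_quantifiable_range(self):
        series, _ = simulate_calibration(11, noise_cv=5.0)
        fit = fit_curve(series, weighting="inv_x")
        responses = np.linspace(
            fit.predict(fit.lloq), fit.predict(fit.uloq), 200
        )
        back = fit.back_calculate(responses)
        assert np.all(np.diff(back) > 0)

    def test_uninvertible_response_flags_not_raises(self):
        x = make_serial_dilution(100.0, 8, 2.0)
        fit = fit_curve(
            CalibrationSeries("m", x, x), transform="loglog"
        )
        assert np.isnan(fit.back_calculate(-1.0))


class TestSelectModel:
    def test_tie_prefers_simpler(self):
        x = make_serial_dilution(10.0, 8, 2.0)
        series = CalibrationSeries("m", x, 2.0 * x)
        fit = select_model(series, [("linear", None, None), ("quadratic", None, None)])
        assert fit.model == "linear"

    def test_detects_true_curvature(self):
        rng = np.random.default_rng(3)
        x = make_serial_dilution(100.0, 11, 2.0)
        y = (x + 0.05 * x**2) * (1 + rng.normal(0, 0.01, len(x)))
        fit = select_model(
            CalibrationSeries("m", x, y),
            [("linear", None, "inv_x"), ("quadratic", None, "inv_x")],
        )
        assert fit.model == "quadratic"

    def test_single_candidate_returned(self):
        series, _ = simulate_calibration(9)
        fit = select_model(series, [("linear", "loglog", None)])
        assert (fit.model, fit.transform) == ("linear", "loglog")


class TestLOQ:
    def _fit_with_accuracy(self, acc):
        nominal = make_serial_dilution(1000.0, len(acc), 2.0)
        fit = CurveFit(
            hmdb_id="m", model="linear", transform=None, weighting=None,
            coefficients=np.array([0.0, 1.0]), r_squared=1.0,
            nominal=nominal, response=nominal,
        )
        fit.backcalc_accuracy = np.asarray(acc, dtype=float)
        return fit

    def test_all_levels_pass(self):
        fit = self._fit_with_accuracy([100.0] * 11)
        lloq, uloq = determine_loq(fit)
        assert lloq == fit.nominal[0]
        assert uloq == fit.nominal[-1]

    def test_failing_lowest_level_moves_lloq_up(self):
        fit = self._fit_with_accuracy([130.0] + [100.0] * 10)
        lloq, _ = determine_loq(fit)
        assert lloq == fit.nominal[1]

    def test_twenty_percent_band_only_at_lowest(self):
        # 118% passes at level 1 (±20) but would fail elsewhere (±15)
        fit = self._fit_with_accuracy([118.0, 100.0, 118.0, 100.0])
        lloq, uloq = determine_loq(fit)
        assert (lloq, uloq) == (fit.nominal[0], fit.nominal[1])

    def test_no_passing_level_rejected(self):
        fit = self._fit_with_accuracy([150.0] * 6)
        assert determine_loq(fit) == (None, None)

    def test_loq_window_is_contiguous_passing_run(self):
        """Every level inside the reported [LLOQ, ULOQ] passes its accuracy
        band, so any concentration flagged quantifiable is bracketed by a
        fully-passing window (checked over 100 seeded noisy curves)."""
        for seed in range(100):
            series, _ = simulate_calibration(seed, noise_cv=10.0)
            fit = fit_curve(series, weighting="inv_x")
            if fit.rejected:
                continue
            acc = np.asarray(fit.backcalc_accuracy)
            inside = (series.nominal >= fit.lloq) & (series.nominal <= fit.uloq)
            bands = np.where(series.nominal == fit.nominal[0], 20.0, 15.0)
            assert np.all(np.abs(acc[inside] - 100.0) <= bands[inside])
            # the window endpoints are themselves calibration levels
            assert fit.lloq in series.nominal and fit.uloq in series.nominal


class TestCarryover:
    @pytest.mark.parametrize(
        "blank,lloq,expected_pct,expected_pass",
        [(10, 100, 10.0, True), (25, 100, 25.0, False), (0, 100, 0.0, True)],
    )
    def test_classification(self, blank, lloq, expected_pct, expected_pass):
        pct, passed = check_carryover(blank, lloq)
        assert pct == pytest.approx(expected_pct)
        assert passed is expected_pass

    def test_zero_lloq_area_rejected(self):
        with pytest.raises(CalibrationError):
            check_carryover(5.0, 0.0)


def test_simulated_linearity_headline():
    """11-point curves over a 1024-fold range with 5% proportional noise fit
    log-log linear with R² >= 0.980 in at least 95% of 200 seeds."""
    ok = 0
    for seed in range(200):
        series, _ = simulate_calibration(seed, noise_cv=5.0)
        fit = fit_curve(series, transform="loglog")
        ok += fit.r_squared >= 0.980
    assert ok >= 190
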