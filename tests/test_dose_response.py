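"""Dose-response fitting and LC estimation against independent oracles."""

import numpy as np
import pytest
from scipy.special import ndtr, ndtri

from mixtox import (
    BioassayRecord,
    DomainError,
    FitError,
    MortalityTable,
    aggregate_mortality,
    bootstrap_lc_ci,
    estimate_lc,
    fit_linear_logdose,
    fit_probit,
    serial_dilution,
    simulate_bioassay,
)


def _table(doses, fractions, n=90.0, unit="mg/L"):
    doses = np.asarray(doses, dtype=float)
    frac = np.asarray(fractions, dtype=float)
    n = np.full_like(doses, n)
    return MortalityTable("t", unit, doses, n, n * frac, frac, frac)


def _ols_normal_equations(x, y):
    """Independent closed-form OLS oracle via the normal equations."""
    X = np.column_stack([np.ones_like(x), x])
    beta = np.linalg.solve(X.T @ X, X.T @ y)
    return beta[1], beta[0]  # slope, intercept


class TestLinearFit:
    def test_exact_line_recovered(self, exact_line_table):
        fit = fit_linear_logdose(exact_line_table)
        assert fit.slope == pytest.approx(10.0, rel=1e-9)
        assert fit.intercept == pytest.approx(30.0, rel=1e-9)
        assert fit.r_squared == pytest.approx(1.0, abs=1e-9)
        assert fit.chi_squared_gof == pytest.approx(0.0, abs=1e-9)

    def test_matches_normal_equation_oracle_on_noisy_data(self):
        rng = np.random.default_rng(7)
        for _ in range(100):
            doses = 10.0 ** np.sort(rng.uniform(-1, 3, size=5))
            frac = np.clip(rng.uniform(0, 1, size=5), 0, 1)
            table = _table(doses, frac)
            fit = fit_linear_logdose(table)
            slope, intercept = _ols_normal_equations(np.log10(doses), frac * 100)
            assert fit.slope == pytest.approx(slope, rel=1e-10)
            assert fit.intercept == pytest.approx(intercept, rel=1e-10)

    def test_single_dose_is_fit_error(self):
        with pytest.raises(FitError):
            fit_linear_logdose(_table([1.0], [0.5]))

    def test_constant_response_zero_slope_with_warning(self):
        with pytest.warns(UserWarning, match="zero-slope"):
            fit = fit_linear_logdose(_table([1.0, 10.0, 100.0], [0.4, 0.4, 0.4]))
        assert fit.slope == 0.0
        with pytest.raises(DomainError):
            estimate_lc(fit, 0.5)

    def test_lc50_scales_with_dose_rescaling(self, exact_line_table):
        lc = estimate_lc(fit_linear_logdose(exact_line_table), 0.5)
        scaled = _table(
            exact_line_table.doses * 7.5,
            exact_line_table.corrected_mortality,
        )
        lc_scaled = estimate_lc(fit_linear_logdose(scaled), 0.5)
        assert lc_scaled.value == pytest.approx(7.5 * lc.value, rel=1e-9)


class TestEstimateLc:
    def test_linear_inverse_prediction(self, exact_line_table):
        # 50 = 10x + 30 -> log10 LC50 = 2
        lc = estimate_lc(fit_linear_logdose(exact_line_table), 0.5)
        assert lc.value == pytest.approx(100.0, rel=1e-9)

    def test_probit_quantile_arithmetic(self):
        from mixtox.dose_response import DoseResponseFit

        fit = DoseResponseFit("probit", slope=1.0, intercept=0.0, r_squared=1.0,
                              chi_squared_gof=0.0, dose_unit="mg/L", n_doses=5)
        assert estimate_lc(fit, 0.5).value == pytest.approx(1.0, rel=1e-12)
        assert estimate_lc(fit, 0.9).value == pytest.approx(10 ** ndtri(0.9), rel=1e-12)

    def test_invalid_target_fraction(self, exact_line_table):
        fit = fit_linear_logdose(exact_line_table)
        with pytest.raises(DomainError):
            estimate_lc(fit, 0.0)


class TestProbitFit:
    def test_recovers_truth_at_large_n(self):
        # data generated exactly from Phi(a + b log10 d) at n = 1e5 per dose
        a, b = -1.0, 2.0
        doses = np.array([0.1, 0.5, 1.0, 5.0, 50.0])
        p = ndtr(a + b * np.log10(doses))
        rng = np.random.default_rng(123)
        recs = [
            BioassayRecord("t", float(d), "mg/L", 100000, int(rng.binomial(100000, pi)), 0)
            for d, pi in zip(doses, p)
        ]
        fit = fit_probit(recs)
        assert fit.intercept == pytest.approx(a, rel=0.01)
        assert fit.slope == pytest.approx(b, rel=0.01)

    def test_two_dose_fit_is_saturated(self):
        p = ndtr(np.array([-0.5, 0.5]))
        recs = [
            BioassayRecord("t", d, "mg/L", 1000, int(round(1000 * pi)), 0)
            for d, pi in zip((1.0, 10.0), p)
        ]
        fit = fit_probit(recs)
        assert fit.chi_squared_gof == pytest.approx(0.0, abs=1e-4)

    def test_complete_separation_aborts_with_guidance(self):
        recs = [
            BioassayRecord("t", 1.0, "mg/L", 30, 0, 0),
            BioassayRecord("t", 10.0, "mg/L", 30, 30, 0),
        ]
        with pytest.raises(FitError, match="separation|unbounded"):
            fit_probit(recs)

    def test_agrees_with_linear_fit_on_symmetric_midrange_curve(self):
        # probit truth spanning ~10-90% mortality, no sampling noise
        doses = np.array([0.3, 1.0, 3.0, 10.0, 30.0])
        p = ndtr(1.2 * np.log10(doses / 3.0))
        recs = [
            BioassayRecord("t", float(d), "mg/L", 3000, int(round(3000 * pi)), 0)
            for d, pi in zip(doses, p)
        ]
        lc_probit = estimate_lc(fit_probit(recs), 0.5).value
        lc_linear = estimate_lc(fit_linear_logdose(aggregate_mortality(recs)), 0.5).value
        assert lc_linear == pytest.approx(lc_probit, rel=0.05)


class TestBootstrapLcCi:
    @pytest.fixture
    def records(self):
        series = serial_dilution(100.0, 10, 5)
        return simulate_bioassay(1.0, 1.5, series, seed=5)

    def test_same_seed_identical_ci(self, records):
        a = bootstrap_lc_ci(records, n_boot=200, seed=9)
        b = bootstrap_lc_ci(records, n_boot=200, seed=9)
        assert (a.ci_low, a.ci_high) == (b.ci_low, b.ci_high)

    def test_ci_brackets_estimate(self, records):
        lc = bootstrap_lc_ci(records, n_boot=200, seed=9)
        assert lc.ci_low <= lc.value <= lc.ci_high

    def test_coverage_near_nominal(self):
        # 200 repeated experiments with known LC50; CI should cover truth
        # in roughly the nominal fraction of them
        series = serial_dilution(100.0, 10, 5)
        truth = 1.0
        hits = 0
        for i in range(200):
            recs = simulate_bioassay(truth, 1.5, series, seed=1000 + i)
            lc = bootstrap_lc_ci(recs, n_boot=300, seed=i)
            hits += lc.ci_low <= truth <= lc.ci_high
        assert 0.88 <= hits / 200 <= 0.99
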