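"""The toxicity-index chain, CTC classification and its additive reference."""

import numpy as np
import pytest
from hypothesis import given
from hypothesis import strategies as st

from mixtox import (
    DomainError,
    InputDataError,
    MixtureRatio,
    UnitMismatchError,
    additive_lc50,
    classify_interaction,
    compute_ctc,
    ctc_bootstrap,
    simulate_mixture_experiment,
)

positive_lc = st.floats(1e-3, 1e3)
ratio_strategy = st.floats(0.0, 1.0).map(lambda w: MixtureRatio(w, 1.0 - w))


class TestMixtureRatio:
    @pytest.mark.parametrize(
        "parts, expected",
        [((9, 1), (0.9, 0.1)), ((1, 1), (0.5, 0.5)), ((3, 1), (0.75, 0.25)), ((1, 4), (0.2, 0.8))],
    )
    def test_normalization(self, parts, expected):
        r = MixtureRatio.from_parts(*parts)
        assert (r.w_a, r.w_b) == pytest.approx(expected)

    def test_zero_sum_rejected(self):
        with pytest.raises(InputDataError):
            MixtureRatio.from_parts(0, 0)

    def test_fractions_must_be_normalized(self):
        with pytest.raises(InputDataError):
            MixtureRatio(0.5, 0.6)


class TestComputeCtc:
    def test_all_equal_lc50s_give_additive_mixture(self):
        res = compute_ctc(2.0, 2.0, 2.0, MixtureRatio.from_parts(1, 1))
        assert res.ti_b == pytest.approx(100.0)
        assert res.theoretical_ti == pytest.approx(100.0)
        assert res.actual_ti == pytest.approx(100.0)
        assert res.ctc == pytest.approx(100.0)
        assert res.label == "cumulative"

    def test_worked_chain(self):
        # ti_b = 200, theoretical = 150, actual = 250 -> ctc = 166.67
        res = compute_ctc(10.0, 5.0, 4.0, MixtureRatio.from_parts(1, 1))
        assert res.ti_b == pytest.approx(200.0)
        assert res.theoretical_ti == pytest.approx(150.0)
        assert res.actual_ti == pytest.approx(250.0)
        assert res.ctc == pytest.approx(250.0 / 150.0 * 100.0, rel=1e-12)
        assert res.label == "synergism"

    def test_unit_mismatch_is_hard_error(self):
        with pytest.raises(UnitMismatchError):
            compute_ctc(1.0, 1.0, 1.0, MixtureRatio.from_parts(1, 1),
                        unit_a="mg/L", unit_b="conidia/mL", unit_m="mg/L")

    @pytest.mark.parametrize("bad", [0.0, -1.0, float("inf"), float("nan")])
    def test_nonpositive_lc50_rejected(self, bad):
        with pytest.raises(DomainError):
            compute_ctc(bad, 1.0, 1.0, MixtureRatio.from_parts(1, 1))

    @given(a=positive_lc, b=positive_lc, r=ratio_strategy)
    def test_additivity_identity(self, a, b, r):
        """At the harmonic-mean additive LC50, CTC is exactly 100."""
        lc_m = additive_lc50(a, b, r)
        res = compute_ctc(a, b, lc_m, r)
        assert res.ctc == pytest.approx(100.0, rel=1e-9)
        assert res.label == "cumulative"

    @given(a=positive_lc, b=positive_lc, m=positive_lc, r=ratio_strategy)
    def test_closed_form_equivalence(self, a, b, m, r):
        """The four-step TI chain equals 100 * additive_lc50 / lc50_m."""
        res = compute_ctc(a, b, m, r)
        assert res.ctc == pytest.approx(100.0 * additive_lc50(a, b, r) / m, rel=1e-9)

    @given(a=positive_lc, b=positive_lc, m=positive_lc, r=ratio_strategy)
    def test_reference_swap_invariance(self, a, b, m, r):
        """Indexing on B instead of A leaves the CTC unchanged."""
        res_ab = compute_ctc(a, b, m, r)
        res_ba = compute_ctc(b, a, m, r.swapped())
        assert res_ba.ctc == pytest.approx(res_ab.ctc, rel=1e-9)

    @given(a=positive_lc, b=positive_lc, m=positive_lc, r=ratio_strategy, c=st.floats(1e-3, 1e3))
    def test_scale_invariance(self, a, b, m, r, c):
        res = compute_ctc(a, b, m, r)
        res_scaled = compute_ctc(c * a, c * b, c * m, r)
        assert res_scaled.ctc == pytest.approx(res.ctc, rel=1e-9)

    @given(a=positive_lc, b=positive_lc, m=positive_lc, r=ratio_strategy)
    def test_halving_mixture_lc50_doubles_ctc(self, a, b, m, r):
        res = compute_ctc(a, b, m, r)
        res_half = compute_ctc(a, b, m / 2.0, r)
        assert res_half.ctc == pytest.approx(2.0 * res.ctc, rel=1e-9)


class TestClassifyInteraction:
    @pytest.mark.parametrize(
        "ctc, label",
        [
            (294.23, "synergism"),
            (104.18, "cumulative"),
            (86.60, "cumulative"),
            (54.41, "antagonism"),
            (41.03, "antagonism"),
            (120.0, "cumulative"),  # boundary inclusive
            (80.0, "cumulative"),
            (120.0001, "synergism"),
            (79.9999, "antagonism"),
        ],
    )
    def test_thresholds(self, ctc, label):
        assert classify_interaction(ctc) == label

    def test_nonpositive_rejected(self):
        with pytest.raises(DomainError):
            classify_interaction(0.0)


class TestAdditiveLc50:
    def test_equal_components_any_ratio(self):
        for parts in [(9, 1), (1, 1), (1, 9)]:
            assert additive_lc50(3.0, 3.0, MixtureRatio.from_parts(*parts)) == pytest.approx(3.0)

    def test_harmonic_mean_arithmetic(self):
        assert additive_lc50(10.0, 5.0, MixtureRatio.from_parts(1, 1)) == pytest.approx(20.0 / 3.0)

    def test_pure_component_limit(self):
        assert additive_lc50(10.0, 5.0, MixtureRatio(1.0, 0.0)) == pytest.approx(10.0)


class TestCtcBootstrap:
    def test_same_seed_identical_ci(self, mixture_experiment):
        _, a, b, m, _ = mixture_experiment
        r = MixtureRatio.from_parts(1, 4)
        res1 = ctc_bootstrap(a, b, m, r, n_boot=200, seed=3)
        res2 = ctc_bootstrap(a, b, m, r, n_boot=200, seed=3)
        assert (res1.ci_low, res1.ci_high, res1.ctc) == (res2.ci_low, res2.ci_high, res2.ctc)

    def test_ci_brackets_point_estimate_and_truth_is_plausible(self, mixture_experiment):
        cfg, a, b, m, truth = mixture_experiment
        res = ctc_bootstrap(a, b, m, cfg.ratio, n_boot=500, seed=3)
        assert res.ci_low <= res.ctc <= res.ci_high
        assert res.ci_low < 2 * truth["ctc"] and res.ci_high > truth["ctc"] / 2
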