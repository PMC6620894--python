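import math

import numpy as np
import pandas as pd
import pytest
from hypothesis import given, settings
from hypothesis import strategies as st

from conftest import make_sequence
from hoverbayes.errors import (
    ConstantResponseError,
    DegenerateTableError,
    EmptyGroupError,
    NormalizationError,
)
from hoverbayes.group_stats import (
    chi_squared_association,
    fit_correctness_model,
    fit_error_model,
    hellinger,
    permutation_test,
    screen_discriminative,
    transition_odds_ratio,
)
from hoverbayes.interaction import TRANSITION_PAIRS, bigram_transitions, pool_group
from hoverbayes.simulate import (
    biased_matrix,
    markov_sequence,
    uniform_matrix,
)

DWELL = {a: (6.0, 0.5) for a in "T F nF FA FnA nFA nFnA Q".split()}


def _tables(rng, n, matrix, stop=0.05):
    return [
        bigram_transitions(markov_sequence(matrix, None, stop, DWELL, rng, f"x{i}"))
        for i in range(n)
    ]


class TestHellinger:
    def test_identical_distributions(self):
        p = np.full(56, 1 / 56)
        assert hellinger(p, p) == 0.0

    def test_disjoint_supports(self):
        p = np.zeros(56)
        q = np.zeros(56)
        p[0] = 1.0
        q[1] = 1.0
        assert hellinger(p, q) == pytest.approx(1.0)

    def test_closed_form_example(self):
        p = np.zeros(56)
        q = np.zeros(56)
        p[0] = p[1] = 0.5
        q[0] = 1.0
        # closed form sqrt(1 - sqrt(0.5))
        assert hellinger(p, q) == pytest.approx(math.sqrt(1 - math.sqrt(0.5)))
        assert hellinger(p, q) == pytest.approx(0.5412, abs=5e-5)

    def test_unnormalized_rejected(self):
        p = np.full(56, 1 / 56)
        with pytest.raises(NormalizationError):
            hellinger(p, p * 2)

    @given(
        raw_p=st.lists(st.floats(0.0, 1.0), min_size=8, max_size=8),
        raw_q=st.lists(st.floats(0.0, 1.0), min_size=8, max_size=8),
    )
    def test_symmetry_and_bounds(self, raw_p, raw_q):
        p = np.array(raw_p) + 1e-9
        q = np.array(raw_q) + 1e-9
        p /= p.sum()
        q /= q.sum()
        d = hellinger(p, q)
        assert d == pytest.approx(hellinger(q, p))
        assert 0.0 <= d <= 1.0 + 1e-12

    def test_accepts_transition_tables(self):
        t = bigram_transitions(make_sequence(["Q", "F", "FA", "T"]))
        assert hellinger(t, t) == 0.0


class TestPermutationTest:
    def test_observed_equals_pooled_hellinger(self, rng):
        a = _tables(rng, 10, uniform_matrix())
        b = _tables(rng, 10, uniform_matrix())
        res = permutation_test(a, b, n_perm=50, seed=0)
        expected = hellinger(pool_group(a), pool_group(b))
        assert res.hd_observed == pytest.approx(expected)

    def test_reproducible_given_seed(self, rng):
        a = _tables(rng, 8, uniform_matrix())
        b = _tables(rng, 8, uniform_matrix())
        r1 = permutation_test(a, b, n_perm=200, seed=7)
        r2 = permutation_test(a, b, n_perm=200, seed=7)
        assert r1 == r2

    def test_p_value_floor(self, rng):
        a = _tables(rng, 5, uniform_matrix())
        b = _tables(rng, 5, uniform_matrix())
        res = permutation_test(a, b, n_perm=99, seed=0)
        assert res.p_value >= 1 / 100

    def test_detects_strong_difference(self, rng):
        strong = biased_matrix({("F", "T"): 8.0, ("nF", "T"): 8.0})
        a = _tables(rng, 75, uniform_matrix())
        b = _tables(rng, 75, strong)
        res = permutation_test(a, b, n_perm=400, seed=0, mode="label_permutation")
        assert res.p_value <= 0.01

    def test_empty_group_rejected(self, rng):
        a = _tables(rng, 5, uniform_matrix())
        with pytest.raises(EmptyGroupError):
            permutation_test(a, [], n_perm=10, seed=0)

    def test_unknown_mode_rejected(self, rng):
        a = _tables(rng, 5, uniform_matrix())
        with pytest.raises(ValueError):
            permutation_test(a, a, n_perm=10, seed=0, mode="jackknife")

    def test_null_p_values_superuniform(self, rng):
        # reduced-n audit: rejection rate at alpha=0.2 should not exceed 0.2
        # by more than Monte-Carlo error
        rejections = 0
        n_exp = 40
        for i in range(n_exp):
            a = _tables(rng, 15, uniform_matrix())
            b = _tables(rng, 15, uniform_matrix())
            res = permutation_test(a, b, n_perm=99, seed=i, mode="label_permutation")
            rejections += res.p_value <= 0.2
        assert rejections / n_exp <= 0.2 + 2.5 * math.sqrt(0.2 * 0.8 / n_exp)


class TestOddsRatio:
    def test_derived_example(self):
        or_value, lo, hi = transition_odds_ratio(20, 100, 10, 100)
        assert or_value == pytest.approx((0.2 / 0.8) / (0.1 / 0.9))
        assert or_value == pytest.approx(2.25)
        assert lo < or_value < hi

    def test_equal_frequencies_give_unit_or(self):
        or_value, lo, hi = transition_odds_ratio(30, 300, 10, 100)
        assert or_value == pytest.approx(1.0)
        assert lo < 1.0 < hi

    @given(
        ca=st.integers(0, 50),
        cb=st.integers(0, 50),
        ta=st.integers(51, 200),
        tb=st.integers(51, 200),
    )
    def test_antisymmetry_under_group_swap(self, ca, cb, ta, tb):
        or_ab, lo_ab, hi_ab = transition_odds_ratio(ca, ta, cb, tb)
        or_ba, lo_ba, hi_ba = transition_odds_ratio(cb, tb, ca, ta)
        assert or_ab == pytest.approx(1.0 / or_ba)
        assert lo_ab == pytest.approx(1.0 / hi_ba)
        assert hi_ab == pytest.approx(1.0 / lo_ba)

    def test_haldane_correction_for_zero_cells(self):
        or_value, lo, hi = transition_odds_ratio(0, 100, 10, 100)
        assert math.isfinite(or_value) and or_value > 0
        assert math.isfinite(lo) and math.isfinite(hi)

    def test_ci_coverage_at_moderate_counts(self, rng):
        # ~95% of Wald CIs should cover the true OR
        p_true, q_true = 0.15, 0.05
        true_or = (p_true / (1 - p_true)) / (q_true / (1 - q_true))
        n = 400
        covered = 0
        reps = 300
        for _ in range(reps):
            ca = rng.binomial(n, p_true)
            cb = rng.binomial(n, q_true)
            _, lo, hi = transition_odds_ratio(ca, n, cb, n)
            covered += lo <= true_or <= hi
        assert covered / reps == pytest.approx(0.95, abs=0.04)

    def test_invalid_inputs(self):
        with pytest.raises(ValueError):
            transition_odds_ratio(5, 0, 1, 10)
        with pytest.raises(ValueError):
            transition_odds_ratio(11, 10, 1, 10)


class TestScreening:
    def test_identical_groups_nothing_flagged(self, rng):
        pooled = pool_group(_tables(rng, 30, uniform_matrix()))
        results = screen_discriminative(pooled, pooled)
        assert len(results) == 56
        assert not any(r.discriminative for r in results)

    def test_planted_effect_flagged(self, rng):
        strong = biased_matrix({("F", "T"): 10.0})
        a = pool_group(_tables(rng, 120, uniform_matrix(), stop=0.03))
        b = pool_group(_tables(rng, 120, strong, stop=0.03))
        results = screen_discriminative(a, b, min_frequency=30)
        flagged = {r.transition for r in results if r.discriminative}
        assert ("F", "T") in flagged
        # planted direction: transition more frequent in group B -> OR < 1
        ft = next(r for r in results if r.transition == ("F", "T"))
        assert ft.odds_ratio < 1.0

    def test_min_frequency_threshold_suppresses(self, rng):
        a = pool_group(_tables(rng, 40, uniform_matrix()))
        b = pool_group(_tables(rng, 40, biased_matrix({("F", "T"): 10.0})))
        huge = screen_discriminative(a, b, min_frequency=10**9)
        assert not any(r.discriminative for r in huge)

    def test_sorted_by_abs_log_or(self, rng):
        a = pool_group(_tables(rng, 20, uniform_matrix()))
        b = pool_group(_tables(rng, 20, biased_matrix({("F", "T"): 5.0})))
        results = screen_discriminative(a, b)
        mags = [abs(math.log(r.odds_ratio)) for r in results]
        assert mags == sorted(mags, reverse=True)

    def test_invariants_hold(self, rng):
        a = pool_group(_tables(rng, 20, uniform_matrix()))
        b = pool_group(_tables(rng, 20, biased_matrix({("Q", "T"): 4.0})))
        for r in screen_discriminative(a, b, min_frequency=5):
            assert r.ci_low <= r.odds_ratio <= r.ci_high
            if r.discriminative:
                assert not (r.ci_low <= 1.0 <= r.ci_high)
                assert r.max_frequency >= 5


class TestChiSquared:
    def test_identical_rows(self):
        res = chi_squared_association([[30, 70], [30, 70]])
        assert res.chi_squared == pytest.approx(0.0)
        assert res.cramers_v == pytest.approx(0.0)

    def test_against_direct_formula(self):
        a, b, c, d = 30, 48, 11, 67
        n = a + b + c + d
        chi2_oracle = n * (a * d - b * c) ** 2 / (
            (a + b) * (c + d) * (a + c) * (b + d)
        )
        res = chi_squared_association([[a, b], [c, d]])
        assert res.chi_squared == pytest.approx(chi2_oracle)
        assert res.df == 1
        assert res.cramers_v == pytest.approx(math.sqrt(chi2_oracle / n))

    def test_bonferroni_adjustment_and_cap(self):
        res = chi_squared_association([[30, 48], [11, 67]], n_comparisons=4)
        assert res.correction == "bonferroni"
        assert res.p_adjusted == pytest.approx(min(1.0, res.p_raw * 4))
        null = chi_squared_association([[50, 50], [51, 49]], n_comparisons=1000)
        assert null.p_adjusted == 1.0

    def test_p_adjusted_at_least_p_raw(self):
        res = chi_squared_association([[30, 48], [11, 67]], n_comparisons=4)
        assert res.p_adjusted >= res.p_raw

    def test_zero_marginal_rejected(self):
        with pytest.raises(DegenerateTableError):
            chi_squared_association([[0, 0], [10, 20]])


def _simulate_correctness(rng, n=400, beta_format=-1.4, beta_dgm=0.6, beta_num=0.2):
    fmt = rng.integers(0, 2, n)
    dgm = rng.integers(0, 2, n)
    num = rng.normal(4.0, 0.7, n)
    logit = -0.5 + beta_format * fmt + beta_dgm * dgm + beta_num * (num - 4.0)
    p = 1 / (1 + np.exp(-logit))
    correct = rng.random(n) < p
    return pd.DataFrame(
        {
            "correct": correct,
            "format": np.where(fmt == 1, "probability", "frequency"),
            "study": np.where(dgm == 1, "fixed_values", "experience_matched"),
            "numeracy": num,
        }
    )


class TestRegressions:
    def test_logistic_recovers_planted_effect(self, rng):
        covered = 0
        reps = 60
        for _ in range(reps):
            records = _simulate_correctness(rng)
            fit = fit_correctness_model(records)
            est, lo, hi = fit.coefficients["format_probability"]
            covered += lo <= math.exp(-1.4) <= hi
        assert covered / reps >= 0.9

    def test_logistic_null_coverage(self, rng):
        covered = 0
        reps = 60
        for _ in range(reps):
            records = _simulate_correctness(rng, beta_format=0.0)
            fit = fit_correctness_model(records)
            est, lo, hi = fit.coefficients["format_probability"]
            covered += lo <= 1.0 <= hi
        assert covered / reps == pytest.approx(0.95, abs=0.07)

    def test_constant_response_raises(self, rng):
        records = _simulate_correctness(rng, n=50)
        records["correct"] = True
        with pytest.raises(ConstantResponseError):
            fit_correctness_model(records)

    def test_constant_predictor_dropped(self, rng):
        records = _simulate_correctness(rng, n=200)
        records["study"] = "experience_matched"
        fit = fit_correctness_model(records)
        assert "dgm_fixed" not in fit.coefficients
        assert any(f.startswith("dropped_constant") for f in fit.flags)

    def test_perfect_separation_flagged(self):
        records = pd.DataFrame(
            {
                "correct": [True] * 20 + [False] * 20,
                "format": ["frequency"] * 20 + ["probability"] * 20,
                "study": ["experience_matched"] * 40,
                "numeracy": list(np.linspace(3, 5, 40)),
            }
        )
        fit = fit_correctness_model(records)
        assert "perfect_separation" in fit.flags
        _, lo, hi = fit.coefficients["format_probability"]
        assert math.isnan(lo) and math.isnan(hi)

    def test_linear_model_recovers_slope(self, rng):
        n = 300
        fmt = rng.integers(0, 2, n)
        led = rng.normal(0.0, 0.5, n)
        y = 0.1 + 0.4 * fmt + 0.6 * led + rng.normal(0, 0.3, n)
        records = pd.DataFrame(
            {
                "log_relative_error": y,
                "format": np.where(fmt == 1, "probability", "frequency"),
                "log_experience_deviation": led,
            }
        )
        fit = fit_error_model(records)
        est, lo, hi = fit.coefficients["log_experience_deviation"]
        assert lo <= 0.6 <= hi
        est_f, lo_f, hi_f = fit.coefficients["format_probability"]
        assert lo_f <= 0.4 <= hi_f
        assert fit.scale == "model_scale"
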