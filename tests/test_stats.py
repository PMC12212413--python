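"""Response labeling, Mann-Whitney, logistic regression, ROC/AUC and the comparison table."""

import itertools

import numpy as np
import pandas as pd
import pytest
from hypothesis import given, settings
from hypothesis import strategies as st

from petmr_habitats import (
    CohortSpec,
    binarize_outcome,
    classify_response,
    frequency_table,
    generate_lesion_cohort,
    logistic_fit,
    mann_whitney,
    metric_comparison_table,
    rank_auc,
    roc_auc,
)


def enumeration_mw(a, b):
    """Brute-force Mann-Whitney: U for group a and the exact two-sided p by
    enumerating every assignment of the combined values to the two groups."""
    a, b = list(a), list(b)

    def u_stat(x, y):
        return sum(1.0 if xi > yi else 0.5 if xi == yi else 0.0 for xi in x for yi in y)

    u_obs = u_stat(a, b)
    mu = len(a) * len(b) / 2.0
    combined = a + b
    count = total = 0
    for idx in itertools.combinations(range(len(combined)), len(a)):
        xs = [combined[i] for i in idx]
        ys = [combined[i] for i in range(len(combined)) if i not in idx]
        if abs(u_stat(xs, ys) - mu) >= abs(u_obs - mu) - 1e-12:
            count += 1
        total += 1
    return u_obs, count / total


def pair_counting_auc(scores, outcome):
    """Brute-force AUC: concordant positive-negative pairs, ties at 0.5."""
    s = np.asarray(scores, float)
    y = np.asarray(outcome, bool)
    pos, neg = s[y], s[~y]
    total = conc = 0.0
    for p in pos:
        for n in neg:
            conc += 1.0 if p > n else 0.5 if p == n else 0.0
            total += 1
    return conc / total


class TestResponseRules:
    @pytest.mark.parametrize(
        "baseline,followup,expected",
        [
            (20.0, 13.0, "responding"),   # -35% >= 30% reduction
            (20.0, 14.0, "responding"),   # exactly -30%
            (20.0, 25.0, "progressing"),  # +25% >= 20% increase
            (20.0, 24.0, "progressing"),  # exactly +20%
            (20.0, 20.0, "stable"),
            (20.0, 14.1, "stable"),
            (20.0, 0.0, "responding"),    # complete disappearance
        ],
    )
    def test_classification(self, baseline, followup, expected):
        assert classify_response(baseline, followup) == expected

    def test_zero_baseline_rejected(self):
        with pytest.raises(ValueError, match="baseline"):
            classify_response(0.0, 5.0)

    @pytest.mark.parametrize(
        "category,expected",
        [("responding", "favorable"), ("stable", "favorable"), ("progressing", "nonresponding")],
    )
    def test_binarize(self, category, expected):
        assert binarize_outcome(category) == expected

    def test_binarize_unknown_rejected(self):
        with pytest.raises(ValueError, match="unknown"):
            binarize_outcome("mixed")


class TestMannWhitney:
    def test_fully_separated_small_groups(self):
        u, p = mann_whitney([1, 2, 3], [4, 5, 6])
        assert u == 0.0
        assert p == pytest.approx(0.100, abs=1e-12)

    def test_identical_groups_u_is_half_pairs(self):
        u, _ = mann_whitney([1, 2, 2, 5], [1, 2, 2, 5])
        assert u == 4 * 4 / 2

    def test_interleaved_matches_enumeration(self):
        u, p = mann_whitney([1, 3, 5], [2, 4, 6])
        u_ref, p_ref = enumeration_mw([1, 3, 5], [2, 4, 6])
        assert u == u_ref
        assert p == pytest.approx(p_ref, abs=1e-12)

    def test_exact_mode_matches_enumeration_on_random_small_samples(self):
        rng = np.random.default_rng(12)
        for _ in range(60):
            na = int(rng.integers(1, 6))
            nb = int(rng.integers(1, 11 - na))
            vals = rng.permutation(np.arange(na + nb, dtype=float) + rng.normal(0, 0.01))
            a, b = vals[:na], vals[na:]  # distinct values, no ties
            u, p = mann_whitney(a, b)
            u_ref, p_ref = enumeration_mw(a, b)
            assert u == pytest.approx(u_ref)
            assert p == pytest.approx(p_ref, abs=1e-12)

    def test_empty_group_rejected(self):
        with pytest.raises(ValueError, match="nonempty"):
            mann_whitney([], [1.0])

    def test_type_i_error_near_nominal(self):
        """Under the null the test rejects at ~ the nominal 5% level."""
        rng = np.random.default_rng(99)
        rejections = sum(
            mann_whitney(rng.normal(size=25), rng.normal(size=20))[1] < 0.05
            for _ in range(400)
        )
        assert 0.02 <= rejections / 400 <= 0.09


class TestLogistic:
    def test_two_by_two_equals_log_odds_ratio(self):
        # outcome-by-feature table (8,2;2,8): beta = ln(8*8/(2*2)) = ln 16
        x = np.r_[np.ones(8), np.zeros(2), np.ones(2), np.zeros(8)]
        y = np.r_[np.ones(10), np.zeros(10)].astype(int)
        fit = logistic_fit(x, y)
        assert fit.coefficients[0] == pytest.approx(np.log(16.0), abs=1e-6)
        assert not fit.separation_flag

    def test_constant_feature_balanced_classes(self):
        x = np.full(20, 3.0)
        y = np.r_[np.ones(10), np.zeros(10)].astype(int)
        with pytest.warns(UserWarning, match="constant"):
            fit = logistic_fit(x, y)
        assert fit.coefficients[0] == 0.0
        assert fit.intercept == pytest.approx(0.0, abs=1e-12)

    def test_perfect_separation_flagged_ranking_usable(self):
        x = np.r_[np.arange(10.0), np.arange(20.0, 30.0)]
        y = np.r_[np.zeros(10), np.ones(10)].astype(int)
        fit = logistic_fit(x, y)
        assert fit.separation_flag
        assert rank_auc(fit.fitted_probabilities, y) == 1.0

    def test_single_class_rejected(self):
        with pytest.raises(ValueError, match="class"):
            logistic_fit(np.arange(5.0), np.ones(5, dtype=int))

    def test_sign_recovery_on_generated_cohorts(self):
        """ADC coefficient sign is correct in >= 95% of seeded 1-SD-effect cohorts."""
        correct = 0
        reps = 60
        for seed in range(reps):
            df = generate_lesion_cohort(CohortSpec(n_lesions=100, adc_effect_sd=1.0, seed=seed))
            y = (df.outcome == "favorable").to_numpy().astype(int)
            fit = logistic_fit(df.adc_mean.to_numpy(), y)
            correct += fit.coefficients[0] > 0
        assert correct / reps >= 0.95


class TestRocAuc:
    def test_separable_scores_auc_one(self):
        r = roc_auc([1, 2, 3, 10, 11, 12], [0, 0, 0, 1, 1, 1], n_boot=50, seed=0)
        assert r.auc == 1.0

    def test_all_tied_scores_auc_half(self):
        r = roc_auc([5.0] * 8, [0, 1] * 4, n_boot=50, seed=0)
        assert r.auc == 0.5

    def test_worked_example_three_of_four_pairs(self):
        r = roc_auc([0.1, 0.4, 0.35, 0.8], [0, 0, 1, 1], n_boot=50, seed=0)
        assert r.auc == 0.75

    @settings(deadline=None, max_examples=50, derandomize=True)
    @given(
        st.lists(st.floats(-5, 5, allow_nan=False), min_size=2, max_size=20),
        st.integers(0, 2**16),
    )
    def test_rank_formula_equals_pair_counting(self, scores, seed):
        rng = np.random.default_rng(seed)
        y = rng.integers(0, 2, len(scores))
        if y.all() or not y.any():
            y[0] = 1 - y[0]
        assert rank_auc(scores, y) == pytest.approx(pair_counting_auc(scores, y), abs=1e-12)

    def test_invariant_under_monotone_transform(self):
        rng = np.random.default_rng(3)
        s = rng.normal(size=30)
        y = rng.integers(0, 2, 30)
        y[:2] = [0, 1]
        assert rank_auc(s, y) == pytest.approx(rank_auc(np.exp(s), y), abs=1e-12)

    def test_bootstrap_ci_reproducible_and_ordered(self):
        rng = np.random.default_rng(4)
        s = rng.normal(size=40)
        y = rng.integers(0, 2, 40)
        y[:2] = [0, 1]
        a = roc_auc(s, y, n_boot=300, seed=42)
        b = roc_auc(s, y, n_boot=300, seed=42)
        assert (a.ci_lower, a.ci_upper) == (b.ci_lower, b.ci_upper)
        assert a.ci_lower <= a.ci_upper
        c = roc_auc(s, y, n_boot=300, seed=43)
        assert (a.ci_lower, a.ci_upper) != (c.ci_lower, c.ci_upper)

    def test_one_class_rejected(self):
        with pytest.raises(ValueError, match="class"):
            roc_auc([1.0, 2.0], [1, 1], n_boot=10, seed=0)


class TestComparisonTable:
    def test_identical_classes_equal_means(self):
        rng = np.random.default_rng(5)
        half = pd.DataFrame({"suv_mean": rng.normal(3, 1, 20), "adc_mean": rng.normal(1.3, 0.4, 20)})
        df = pd.concat(
            [half.assign(outcome="favorable"), half.assign(outcome="nonresponding")],
            ignore_index=True,
        )
        with pytest.warns(UserWarning, match="absent"):
            table = metric_comparison_table(df)
        for _, row in table.iterrows():
            assert row.favorable_mean == pytest.approx(row.nonresponding_mean)

    def test_large_adc_shift_detected(self):
        df = generate_lesion_cohort(CohortSpec(n_lesions=100, adc_effect_sd=3.0, seed=6))
        table = metric_comparison_table(df).set_index("metric")
        assert table.loc["adc_mean", "p_value"] < 0.001

    def test_holm_adjustment_monotone(self):
        df = generate_lesion_cohort(CohortSpec(n_lesions=60, seed=7))
        table = metric_comparison_table(df, holm=True)
        assert (table.p_holm >= table.p_value - 1e-15).all()


class TestFrequencyTable:
    def test_counts_and_rounded_percentages(self):
        s = pd.Series(["bone"] * 26 + ["breast"] * 5 + ["brain"] * 3 + ["soft tissue"] * 6 + ["liver"] * 2)
        t = frequency_table(s, order=["brain", "breast", "bone", "soft tissue", "liver"])
        assert t["count"].tolist() == [3, 5, 26, 6, 2]
        assert t.percent_rounded.tolist() == [7, 12, 62, 14, 5]
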