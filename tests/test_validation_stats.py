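import itertools
import math
from fractions import Fraction

import numpy as np
import pandas as pd
import pytest
from hypothesis import given
from hypothesis import strategies as st
from hypothesis.extra.numpy import arrays

from ramdi.errors import DataError, ValidationError
from ramdi.simulator import CohortSimSpec, synth_cohort
from ramdi.validation_stats import (
    bland_altman,
    cohort_report,
    linear_regression,
    mann_whitney_u,
    render_report,
    roc_auc,
    spearman_rho,
)


# ---------------------------------------------------------------------------
# Independent brute-force oracles
# ---------------------------------------------------------------------------

def oracle_spearman(x, y):
    """rho via the rank-Pearson definition; exact p by full enumeration."""
    from scipy.stats import rankdata

    rx, ry = rankdata(x), rankdata(y)

    def rho_of(r2):
        r2 = np.asarray(r2, float)
        num = np.sum((rx - rx.mean()) * (r2 - r2.mean()))
        den = math.sqrt(np.sum((rx - rx.mean()) ** 2) * np.sum((r2 - r2.mean()) ** 2))
        return num / den

    obs = rho_of(ry)
    count = total = 0
    for perm in itertools.permutations(ry):
        if abs(rho_of(perm)) >= abs(obs) - 1e-12:
            count += 1
        total += 1
    return obs, Fraction(count, total)


def oracle_mann_whitney(a, b):
    """U by pair counting; exact two-sided p by label-arrangement enumeration."""
    a, b = list(a), list(b)
    n1, n2 = len(a), len(b)

    def u_of(aa, bb):
        u = 0.0
        for x in aa:
            for y in bb:
                u += (x < y) + 0.5 * (x == y)
        return u

    obs = u_of(a, b)
    pooled = a + b
    mu = n1 * n2 / 2
    count = total = 0
    for a_idx in itertools.combinations(range(n1 + n2), n1):
        aa = [pooled[i] for i in a_idx]
        bb = [pooled[i] for i in range(n1 + n2) if i not in a_idx]
        if abs(u_of(aa, bb) - mu) >= abs(obs - mu) - 1e-9:
            count += 1
        total += 1
    return obs, Fraction(count, total)


# ---------------------------------------------------------------------------
# Bland-Altman
# ---------------------------------------------------------------------------

class TestBlandAltman:
    def test_identical_measurements(self):
        ba = bland_altman([1.0, 2.0, 3.0], [1.0, 2.0, 3.0])
        assert ba.mean_diff == 0.0 and ba.sd_diff == 0.0

    def test_hand_computed_differences(self):
        # d = (-1, -2, -3): mean -2, sample SD 1, limits (-4, 0)
        ba = bland_altman([1, 2, 3], [2, 4, 6])
        assert ba.mean_diff == -2.0
        assert ba.sd_diff == 1.0
        assert (ba.lower_limit, ba.upper_limit) == (-4.0, 0.0)
        assert ba.all_within_limits()

    @given(
        d=arrays(np.float64, 10, elements=st.floats(-100, 100)),
        c=st.floats(-1e3, 1e3),
    )
    def test_translation_invariance(self, d, c):
        x = np.linspace(0, 9, 10)
        y = x - d
        a = bland_altman(x, y)
        b = bland_altman(x + c, y + c)
        assert a.mean_diff == pytest.approx(b.mean_diff, abs=1e-9)
        assert a.sd_diff == pytest.approx(b.sd_diff, abs=1e-9)

    def test_minimum_pairs_enforced(self):
        with pytest.raises(DataError):
            bland_altman([1.0], [2.0])


# ---------------------------------------------------------------------------
# Spearman
# ---------------------------------------------------------------------------

class TestSpearman:
    def test_monotone_maps_to_unity(self):
        r = spearman_rho([1, 2, 3, 4, 5], [10, 100, 1000, 10000, 100000])
        assert r.rho == pytest.approx(1.0)
        rr = spearman_rho([1, 2, 3, 4, 5], [5, 4, 3, 2, 1])
        assert rr.rho == pytest.approx(-1.0)

    def test_small_sample_exact_p(self):
        # all 24 pairings: |rho| >= 0.8 for 8 of them (1 each at +-1, 3 each at +-0.8)
        r = spearman_rho([1, 2, 3, 4], [1, 3, 2, 4])
        assert r.rho == pytest.approx(0.8)
        assert r.p_value == pytest.approx(8 / 24)
        assert r.method == "exact_permutation"

    def test_constant_input_flagged_undefined(self):
        r = spearman_rho([1, 1, 1, 1], [1, 2, 3, 4])
        assert np.isnan(r.rho) and r.method == "undefined"

    @pytest.mark.parametrize("n", [3, 4, 5, 6])
    def test_matches_enumeration_oracle(self, n):
        rng = np.random.default_rng(n)
        for trial in range(4):
            x = rng.integers(0, n, size=n).astype(float)  # ties included
            y = rng.integers(0, n, size=n).astype(float)
            if np.unique(x).size < 2 or np.unique(y).size < 2:
                continue
            res = spearman_rho(x, y)
            rho_o, p_o = oracle_spearman(x, y)
            assert res.rho == pytest.approx(rho_o, abs=1e-12)
            assert res.p_value == pytest.approx(float(p_o), abs=1e-12)

    def test_large_sample_t_approximation_reasonable(self):
        rng = np.random.default_rng(0)
        x = rng.normal(size=60)
        y = x + rng.normal(size=60)
        res = spearman_rho(x, y)
        from scipy.stats import spearmanr

        ref = spearmanr(x, y)
        assert res.rho == pytest.approx(ref.statistic, abs=1e-12)
        assert res.p_value == pytest.approx(ref.pvalue, rel=0.05)


# ---------------------------------------------------------------------------
# Mann-Whitney
# ---------------------------------------------------------------------------

class TestMannWhitney:
    def test_extreme_separation_small_sample(self):
        res = mann_whitney_u([1, 2], [3, 4])
        assert res.u_statistic == 4.0          # every a below every b
        assert res.p_value == pytest.approx(2 / 6)
        assert res.u_complement == 0.0

    def test_identical_multisets_centered(self):
        res = mann_whitney_u([1, 2, 3], [1, 2, 3])
        assert res.u_statistic == 4.5          # n1*n2/2

    def test_large_shift_minimum_attainable_p(self):
        res = mann_whitney_u([1, 2, 3], [1001, 1002, 1003])
        assert res.p_value == pytest.approx(2 / math.comb(6, 3))

    @pytest.mark.parametrize("n1,n2", [(2, 2), (3, 3), (2, 5), (4, 4), (3, 5)])
    def test_matches_enumeration_oracle(self, n1, n2):
        rng = np.random.default_rng(10 * n1 + n2)
        for trial in range(4):
            a = rng.integers(0, 5, size=n1).astype(float)  # ties included
            b = rng.integers(0, 5, size=n2).astype(float)
            res = mann_whitney_u(a, b)
            u_o, p_o = oracle_mann_whitney(a, b)
            assert res.u_statistic == pytest.approx(u_o, abs=1e-12)
            assert res.p_value == pytest.approx(float(p_o), abs=1e-12)

    def test_tie_free_recursion_matches_reference(self):
        from scipy.stats import mannwhitneyu

        rng = np.random.default_rng(1)
        a = rng.normal(size=18)
        b = rng.normal(0.5, 1.0, size=20)
        res = mann_whitney_u(a, b)
        ref = mannwhitneyu(b, a, alternative="two-sided", method="exact")
        assert res.method == "exact_recursion"
        assert res.u_statistic == pytest.approx(ref.statistic)
        assert res.p_value == pytest.approx(ref.pvalue, abs=1e-12)

    def test_empty_group_rejected(self):
        with pytest.raises(DataError):
            mann_whitney_u([], [1.0])


# ---------------------------------------------------------------------------
# Linear regression
# ---------------------------------------------------------------------------

class TestLinearRegression:
    def test_exact_line(self):
        x = np.arange(10, dtype=float)
        res = linear_regression(2 * x + 1, pd.DataFrame({"x": x}))
        assert res.coefficients["x"]["coef"] == pytest.approx(2.0)
        assert res.coefficients["intercept"]["coef"] == pytest.approx(1.0)
        assert res.r_squared == pytest.approx(1.0)

    def test_hand_computed_ols(self):
        res = linear_regression([1, 2, 2, 3], pd.DataFrame({"x": [1.0, 2, 3, 4]}))
        assert res.coefficients["x"]["coef"] == pytest.approx(0.6)
        assert res.coefficients["intercept"]["coef"] == pytest.approx(0.5)

    def test_categorical_reference_level(self):
        df = pd.DataFrame({"sex": ["male", "female", "male", "female", "male", "female"]})
        y = [1.0, 2.0, 1.1, 2.1, 0.9, 1.9]
        res = linear_regression(y, df, reference_levels={"sex": "male"})
        assert res.reference_levels == {"sex": "male"}
        assert res.coefficients["sex[female]"]["coef"] == pytest.approx(1.0)

    def test_collinear_columns_named(self):
        df = pd.DataFrame({"a": [1.0, 2, 3, 4, 5], "b": [2.0, 4, 6, 8, 10]})
        with pytest.raises(DataError, match="b"):
            linear_regression(np.arange(5, dtype=float), df)

    def test_confidence_interval_coverage(self):
        # simulated y = 0.02 score + noise at the cohort's size: the 95% CI
        # should cover the true slope in nearly all replicates
        rng = np.random.default_rng(7)
        hits = 0
        for _ in range(200):
            score = rng.uniform(0, 30, size=96)
            y = 0.02 * score + rng.normal(0, 0.2, size=96)
            res = linear_regression(y, pd.DataFrame({"score": score}))
            c = res.coefficients["score"]
            hits += c["ci_low"] <= 0.02 <= c["ci_high"]
        assert hits >= 180


# ---------------------------------------------------------------------------
# ROC
# ---------------------------------------------------------------------------

class TestROC:
    def test_perfect_separation(self):
        res = roc_auc([1, 2, 3, 10, 11, 12], [0, 0, 0, 1, 1, 1], n_boot=100)
        assert res.auc == 1.0
        assert 3 < res.cutoff <= 10
        assert res.sensitivity == 1.0 and res.specificity == 1.0

    def test_null_scores_near_half(self):
        rng = np.random.default_rng(4)
        scores = rng.normal(size=2000)
        labels = rng.integers(0, 2, size=2000)
        res = roc_auc(scores, labels, n_boot=50)
        assert 0.45 <= res.auc <= 0.55

    def test_single_class_rejected(self):
        with pytest.raises(DataError):
            roc_auc([1.0, 2.0], [1, 1])

    def test_curve_monotone(self):
        rng = np.random.default_rng(5)
        scores = np.round(rng.normal(size=200), 1)  # ties
        labels = (scores + rng.normal(size=200) > 0).astype(int)
        res = roc_auc(scores, labels, n_boot=50)
        assert np.all(np.diff(res.fpr) >= 0) and np.all(np.diff(res.tpr) >= 0)
        assert res.auc_ci[0] <= res.auc <= res.auc_ci[1]


# ---------------------------------------------------------------------------
# Cohort report
# ---------------------------------------------------------------------------

@pytest.fixture(scope="module")
def cohort():
    return synth_cohort(CohortSimSpec(seed=17))[0]


class TestCohortReport:

    def test_planted_correlation_recovered(self, cohort):
        rep = cohort_report(cohort, seed=0)
        for col in ("fhs10_lipids", "fhs10_bmi", "fhs30_lipids_full"):
            assert rep["spearman"][col]["rho"] == pytest.approx(0.70, abs=0.12)
        assert rep["group_comparison"]["p_value"] < 0.001

    def test_deterministic_given_seed(self, cohort):
        assert cohort_report(cohort, seed=1) == cohort_report(cohort, seed=1)

    def test_missing_columns_listed(self, cohort):
        with pytest.raises(ValidationError, match="ukpds"):
            cohort_report(cohort.drop(columns=["ukpds"]))

    def test_null_group_difference_rarely_significant(self):
        # identical index distributions across groups: p should exceed 0.05
        # in the overwhelming majority of replicates
        rng = np.random.default_rng(3)
        calm = 0
        for _ in range(50):
            vals = rng.lognormal(mean=-1.2, sigma=0.4, size=96)
            groups = np.array(["control"] * 50 + ["t2dm"] * 46)
            p = mann_whitney_u(vals[groups == "control"], vals[groups == "t2dm"]).p_value
            calm += p > 0.05
        assert calm >= 45

    def test_text_rendering_mentions_significance_note(self, cohort):
        text = render_report(cohort_report(cohort, seed=0))
        assert "P value < 0.01" in text
        assert "AUC" in text
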