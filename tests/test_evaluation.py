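"""Metric definitions against brute-force oracles; OLS and Wilcoxon checks."""

import itertools

import numpy as np
import pytest

from chainrank import (
    compare_methods,
    confusion,
    distribution_summary,
    auc_distribution_regression,
    fpr,
    roc_auc,
    sensitivity,
    specificity,
)
from chainrank.evaluation import ConfusionCounts


def brute_force_confusion(y, p, thr=0.5):
    tp = fp = fn = tn = 0
    for yi, pi in zip(y, p):
        pred = pi >= thr
        if yi == 1 and pred:
            tp += 1
        elif yi == 0 and pred:
            fp += 1
        elif yi == 1:
            fn += 1
        else:
            tn += 1
    return tp, fp, fn, tn


def pair_counting_auc(y, s):
    cases = [si for yi, si in zip(y, s) if yi == 1]
    controls = [si for yi, si in zip(y, s) if yi == 0]
    total = 0.0
    for c in cases:
        for h in controls:
            total += 1.0 if c > h else (0.5 if c == h else 0.0)
    return total / (len(cases) * len(controls))


class TestConfusionAndRates:
    def test_tiny_example(self):
        c = confusion(np.array([1, 0]), np.array([0.9, 0.1]))
        assert (c.tp, c.fp, c.fn, c.tn) == (1, 0, 0, 1)

    def test_all_above_threshold(self):
        c = confusion(np.array([1, 0, 0]), np.array([0.9, 0.8, 0.5]))
        assert c.fn == 0 and c.tn == 0

    def test_brute_force_oracle_100_instances(self, rng):
        for _ in range(100):
            n = rng.integers(5, 50)
            y = rng.integers(0, 2, n)
            p = rng.random(n)
            c = confusion(y, p)
            assert (c.tp, c.fp, c.fn, c.tn) == brute_force_confusion(y, p)
            assert c.n == n

    def test_rate_examples(self):
        assert sensitivity(ConfusionCounts(3, 0, 1, 0)) == 0.75
        c = ConfusionCounts(0, 4, 0, 0)
        assert specificity(c) == 0.0 and fpr(c) == 1.0

    def test_specificity_plus_fpr_is_one(self, rng):
        for _ in range(50):
            c = ConfusionCounts(*rng.integers(0, 20, 4))
            if c.tn + c.fp > 0:
                assert abs(specificity(c) + fpr(c) - 1) < 1e-12

    def test_undefined_rates_return_none(self):
        assert sensitivity(ConfusionCounts(0, 1, 0, 1)) is None
        assert specificity(ConfusionCounts(1, 0, 1, 0)) is None

    def test_length_mismatch_rejected(self):
        with pytest.raises(ValueError):
            confusion(np.array([1, 0]), np.array([0.5]))


class TestRocAuc:
    def test_perfect_and_tied(self):
        y = np.array([1, 1, 0, 0])
        assert roc_auc(y, np.array([0.9, 0.8, 0.2, 0.1])) == 1.0
        assert roc_auc(y, np.full(4, 0.5)) == 0.5

    def test_pair_counting_oracle(self, rng):
        for _ in range(100):
            n = rng.integers(6, 40)
            y = np.r_[1, 0, rng.integers(0, 2, n - 2)]
            s = np.round(rng.random(n), 2)  # rounded -> ties occur
            assert abs(roc_auc(y, s) - pair_counting_auc(y, s)) < 1e-12

    def test_score_negation_identity(self, rng):
        y = np.r_[1, 0, rng.integers(0, 2, 18)]
        s = rng.normal(size=20)  # tie-free almost surely
        assert abs(roc_auc(y, s) + roc_auc(y, -s) - 1) < 1e-12

    def test_invariance_under_monotone_transform(self, rng):
        y = np.r_[1, 0, rng.integers(0, 2, 28)]
        s = rng.random(30)
        assert roc_auc(y, s) == roc_auc(y, np.exp(3 * s))

    def test_one_class_rejected(self):
        with pytest.raises(ValueError):
            roc_auc(np.ones(5), np.random.rand(5))


class TestDistributionSummary:
    def test_normal_limits(self):
        x = np.random.default_rng(0).normal(size=(1000, 100))
        d = distribution_summary(x)
        assert abs(d.skewness) < 0.05
        assert abs(d.kurtosis) < 0.1
        assert abs(d.mean) < 0.05 and abs(d.std - 1) < 0.05

    def test_exponential_skewness(self):
        x = np.random.default_rng(1).exponential(size=100_000)
        d = distribution_summary(x.reshape(-1, 1))
        assert abs(d.skewness - 2.0) < 0.1
        assert abs(d.kurtosis - 6.0) < 0.5

    def test_constant_matrix(self):
        d = distribution_summary(np.full((4, 3), 7.0))
        assert d.std == 0 and d.min == d.max == d.mean == d.p50 == 7.0

    def test_quantile_ordering(self, rng):
        d = distribution_summary(rng.lognormal(0, 2, size=(30, 8)))
        assert d.min <= d.p25 <= d.p50 <= d.p75 <= d.max


class TestAucRegression:
    def test_exact_linear_fit(self):
        # hand-computable: auc = 0.5 + 0.01*kurt - 0.02*skew, no noise
        records = []
        rng = np.random.default_rng(2)
        for _ in range(12):
            k, s = rng.normal(size=2)
            records.append(
                {"auc": 0.5 + 0.01 * k - 0.02 * s, "kurtosis": k, "skewness": s}
            )
        rep = auc_distribution_regression(records)
        assert abs(rep["r_squared"] - 1) < 1e-10
        assert rep["residual_se"] < 1e-8
        assert abs(rep["coefficients"]["const"]["estimate"] - 0.5) < 1e-10
        assert abs(rep["coefficients"]["kurtosis"]["estimate"] - 0.01) < 1e-10
        assert abs(rep["coefficients"]["skewness"]["estimate"] + 0.02) < 1e-10

    def test_three_point_closed_form(self):
        # y = 1 + 2x through 3 points with one residual pattern known exactly
        records = [
            {"auc": 1.0, "kurtosis": 0.0},
            {"auc": 3.0, "kurtosis": 1.0},
            {"auc": 5.0, "kurtosis": 2.0},
        ]
        rep = auc_distribution_regression(records, predictors=("kurtosis",))
        assert abs(rep["coefficients"]["kurtosis"]["estimate"] - 2.0) < 1e-12
        assert abs(rep["coefficients"]["const"]["estimate"] - 1.0) < 1e-12
        assert abs(rep["r_squared"] - 1.0) < 1e-12

    def test_null_predictor_p_value_roughly_uniform(self):
        # under the null the p-value should not concentrate near 0
        rng = np.random.default_rng(3)
        pvals = []
        for _ in range(200):
            records = [
                {"auc": rng.normal(), "kurtosis": rng.normal()} for _ in range(25)
            ]
            rep = auc_distribution_regression(records, predictors=("kurtosis",))
            pvals.append(rep["coefficients"]["kurtosis"]["p_value"])
        from scipy.stats import kstest

        assert kstest(pvals, "uniform").pvalue > 0.01

    def test_correlation_matrix_contains_attributes(self):
        rng = np.random.default_rng(4)
        records = [
            {
                "auc": rng.random(),
                "time_s": rng.random(),
                "kurtosis": rng.normal(),
                "skewness": rng.normal(),
                "std": rng.random(),
            }
            for _ in range(10)
        ]
        rep = auc_distribution_regression(records)
        corr = rep["correlations"]
        assert {"auc", "time_s", "kurtosis", "skewness", "std"} <= set(corr.columns)

    def test_too_few_records_rejected(self):
        with pytest.raises(ValueError):
            auc_distribution_regression(
                [{"auc": 1.0, "kurtosis": 0.0, "skewness": 0.0}] * 3
            )


class TestCompareMethods:
    def test_rank_sum_exact_enumeration(self):
        """p for [1,2,3] vs [4,5,6] equals exact enumeration over C(6,3)=20."""
        res = compare_methods([1, 2, 3], [4, 5, 6], paired=False)
        # exact two-sided p: enumerate all rank assignments
        ranks = range(1, 7)
        observed = 1 + 2 + 3
        sums = [sum(c) for c in itertools.combinations(ranks, 3)]
        lo = sum(1 for s in sums if s <= observed) / len(sums)
        hi = sum(1 for s in sums if s >= observed) / len(sums)
        exact = min(1.0, 2 * min(lo, hi))
        assert abs(res.p_value - exact) < 1e-12
        assert exact == 0.1
        assert res.test == "rank-sum"

    def test_identical_paired_vectors_flagged_degenerate(self):
        res = compare_methods([0.7, 0.8, 0.9], [0.7, 0.8, 0.9], paired=True)
        assert res.degenerate and res.p_value == 1.0

    def test_signed_rank_matches_scipy_exact(self):
        from scipy.stats import wilcoxon

        a = np.array([0.70, 0.72, 0.81, 0.65, 0.77, 0.90, 0.62])
        b = a + np.array([0.011, -0.02, 0.03, 0.015, -0.01, 0.021, 0.04])
        res = compare_methods(a, b, paired=True)
        expected = wilcoxon(a, b, alternative="two-sided", method="exact").pvalue
        assert abs(res.p_value - expected) < 1e-12

    @pytest.mark.parametrize("case_seed", range(10))
    def test_permutation_oracle(self, case_seed):
        """Rank-sum p matches a 1e5-draw permutation null within MC error."""
        rng = np.random.default_rng(case_seed)
        n, m = rng.integers(5, 12, 2)
        a = rng.normal(0, 1, n)
        b = rng.normal(rng.uniform(-1, 1), 1, m)
        res = compare_methods(a, b, paired=False)

        pooled = np.concatenate([a, b])
        from scipy.stats import rankdata

        ranks = rankdata(pooled)
        obs = ranks[:n].sum()
        draws = 100_000
        idx = np.argsort(rng.random((draws, n + m)), axis=1)[:, :n]
        null = ranks[idx].sum(axis=1)
        mu = n * (n + m + 1) / 2
        p_perm = np.mean(np.abs(null - mu) >= abs(obs - mu) - 1e-12)
        mc_err = 4 * np.sqrt(p_perm * (1 - p_perm) / draws) + 0.01
        assert abs(res.p_value - p_perm) <= mc_err

    def test_too_small_groups_rejected(self):
        with pytest.raises(ValueError):
            compare_methods([1, 2], [3, 4], paired=False)
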