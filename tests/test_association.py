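"""Quantile stratification, regression models and nonparametric group tests."""

import numpy as np
import pytest
from scipy import stats

from fhprs.association import (
    FitError,
    StratificationError,
    assign_quantiles,
    group_compare,
    linear_assoc,
    logistic_quartile_or,
    quantile_labels,
)


class TestQuantiles:
    def test_tertiles_of_1_to_9(self):
        labels = quantile_labels(np.arange(1, 10), 3)
        assert labels.tolist() == [1, 1, 1, 2, 2, 2, 3, 3, 3]

    def test_quartiles_of_1_to_8(self):
        labels = quantile_labels(np.arange(1, 9), 4)
        assert labels.tolist() == [1, 1, 2, 2, 3, 3, 4, 4]

    def test_tie_on_cut_point_goes_low(self):
        labels = quantile_labels([1.0, 2.0, 2.0, 3.0], 2)
        # the median is exactly 2.0; both 2.0s belong to the lower stratum
        assert labels.tolist() == [1, 1, 1, 2]

    def test_balanced_sizes_with_distinct_values(self):
        rng = np.random.default_rng(0)
        labels = quantile_labels(rng.normal(size=1000), 4)
        counts = np.bincount(labels)[1:]
        assert counts.sum() == 1000
        assert np.abs(counts - 250).max() <= 1

    def test_too_few_distinct_values(self):
        with pytest.raises(StratificationError):
            quantile_labels([1.0, 1.0, 1.0, 2.0], 3)

    def test_assignment_objects(self):
        out = assign_quantiles([10.0, 20.0, 30.0], 3, subject_ids=["a", "b", "c"])
        assert [(q.subject_id, q.label) for q in out] == [("a", 1), ("b", 2), ("c", 3)]
        assert all(q.k == 3 for q in out)


def _ols_oracle(x, y):
    """Closed-form simple least squares: slope, intercept, r2, two-sided p."""
    x, y = np.asarray(x), np.asarray(y)
    n = x.size
    sxx = np.sum((x - x.mean()) ** 2)
    sxy = np.sum((x - x.mean()) * (y - y.mean()))
    slope = sxy / sxx
    intercept = y.mean() - slope * x.mean()
    resid = y - intercept - slope * x
    ss_res, ss_tot = np.sum(resid ** 2), np.sum((y - y.mean()) ** 2)
    r2 = 1.0 - ss_res / ss_tot
    se = np.sqrt(ss_res / (n - 2) / sxx)
    t = slope / se
    p = 2.0 * stats.t.sf(abs(t), df=n - 2)
    return slope, intercept, r2, p


class TestLinearAssoc:
    def test_noiseless_line(self):
        x = np.arange(10.0)
        res = linear_assoc(2.0 * x + 1.0, x)
        assert res.slope == pytest.approx(2.0)
        assert res.intercept == pytest.approx(1.0)
        assert res.r2 == pytest.approx(1.0)

    @pytest.mark.parametrize("seed", [1, 2, 3])
    def test_matches_closed_form_oracle(self, seed):
        rng = np.random.default_rng(seed)
        x = rng.normal(size=30)
        y = 1.5 * x + rng.normal(size=30)
        res = linear_assoc(y, x)
        slope, intercept, r2, p = _ols_oracle(x, y)
        assert res.slope == pytest.approx(slope, abs=1e-8)
        assert res.intercept == pytest.approx(intercept, abs=1e-8)
        assert res.r2 == pytest.approx(r2, abs=1e-8)
        assert res.p_value == pytest.approx(p, abs=1e-8)
        n, p_pred = 30, 1
        adj = 1 - (1 - r2) * (n - 1) / (n - p_pred - 1)
        assert res.adjusted_r2 == pytest.approx(adj, abs=1e-8)

    def test_null_slope_within_three_se(self):
        rng = np.random.default_rng(42)
        x = rng.normal(size=10_000)
        y = rng.normal(size=10_000)
        res = linear_assoc(y, x)
        assert abs(res.slope) < 3.0 * res.slope_se

    def test_adjusted_r2_with_covariates(self):
        rng = np.random.default_rng(9)
        n = 200
        x = rng.normal(size=n)
        cov = np.column_stack([rng.normal(size=n), rng.normal(size=n)])
        y = x + cov @ [0.5, -0.5] + rng.normal(size=n)
        import pandas as pd
        res = linear_assoc(y, x, covariates=pd.DataFrame(cov, columns=["a", "b"]))
        adj = 1 - (1 - res.r2) * (n - 1) / (n - 3 - 1)
        assert res.adjusted_r2 == pytest.approx(adj, abs=1e-10)
        assert res.adjusted_r2 <= res.r2

    def test_rank_deficient_design(self):
        import pandas as pd
        x = np.arange(20.0)
        with pytest.raises(FitError, match="rank"):
            linear_assoc(x, x, covariates=pd.DataFrame({"dup": x}))


def _sim_logistic(rng, n, q_logodds=(0.0, 0.0, 0.0, 0.0)):
    quart = rng.integers(1, 5, size=n)
    age = rng.normal(55, 9, size=n)
    male = rng.random(n) < 0.45
    eta = -3.0 + 0.04 * (age - 55) + 0.6 * male + np.asarray(q_logodds)[quart - 1]
    y = rng.random(n) < 1.0 / (1.0 + np.exp(-eta))
    return y, quart, age, male


class TestLogisticQuartiles:
    def test_null_quartile_cis_cover_one(self):
        rng = np.random.default_rng(2024)
        y, quart, age, male = _sim_logistic(rng, 2000)
        res = logistic_quartile_or(y, quart, age, male)
        for k in (2, 3, 4):
            assert res.quartile_or[k].covers(1.0)
        assert res.trend_or.covers(1.0)

    def test_signal_recovered(self):
        rng = np.random.default_rng(7)
        y, quart, age, male = _sim_logistic(rng, 6000, q_logodds=(0, 0.2, 0.4, 0.9))
        res = logistic_quartile_or(y, quart, age, male)
        assert res.quartile_or[4].or_ > 1.5
        assert res.quartile_or[4].covers(np.exp(0.9))
        assert res.trend_or.or_ > 1.0

    def test_single_class_outcome_rejected(self):
        rng = np.random.default_rng(1)
        _, quart, age, male = _sim_logistic(rng, 200)
        with pytest.raises(FitError):
            logistic_quartile_or(np.zeros(200), quart, age, male)

    def test_separation_detected(self):
        rng = np.random.default_rng(3)
        _, quart, age, male = _sim_logistic(rng, 300)
        y = age > 55  # perfectly separated by the age covariate
        with pytest.raises(FitError):
            logistic_quartile_or(y, quart, age, male)

    def test_sex_label_coding(self):
        rng = np.random.default_rng(5)
        y, quart, age, male = _sim_logistic(rng, 1500)
        res_bool = logistic_quartile_or(y, quart, age, male)
        labels = np.where(male, "M", "F")
        res_lab = logistic_quartile_or(y, quart, age, labels)
        assert res_bool.sex_or.or_ == pytest.approx(res_lab.sex_or.or_)


class TestGroupCompare:
    def test_published_mi_counts_chi_square(self):
        # previous myocardial infarction: 75/491 vs 46/193
        res = group_compare(table=[[75, 416], [46, 147]])
        assert res.test == "chi-square"
        assert res.p_value == pytest.approx(0.011, abs=0.001)

    def test_published_stroke_counts_chi_square(self):
        res = group_compare(table=[[21, 470], [9, 184]])
        assert res.p_value == pytest.approx(0.988, abs=0.001)

    def test_two_by_two_uses_continuity_correction(self):
        # without Yates the same MI table gives p ~ 0.008
        chi2_un, p_un, _, _ = stats.chi2_contingency([[75, 416], [46, 147]],
                                                     correction=False)
        res = group_compare(table=[[75, 416], [46, 147]])
        assert res.p_value > p_un

    def test_identical_groups_mann_whitney_p_one(self):
        res = group_compare(values=[5.0] * 6, groups=["a"] * 3 + ["b"] * 3)
        assert res.test == "mann-whitney"
        assert res.p_value == pytest.approx(1.0)

    def test_auto_dispatch_three_groups_kruskal_with_posthoc(self):
        rng = np.random.default_rng(11)
        values = np.concatenate([rng.normal(0, 1, 40), rng.normal(0, 1, 40),
                                 rng.normal(3, 1, 40)])
        groups = np.repeat(["a", "b", "c"], 40)
        res = group_compare(values=values, groups=groups)
        assert res.test == "kruskal-wallis"
        assert res.p_value < 0.05
        assert res.posthoc is not None and len(res.posthoc) == 3
        assert all(0 <= p <= 1 for p in res.posthoc.values())
        assert res.posthoc["a vs b"] > 0.05 and res.posthoc["a vs c"] < 0.05

    def test_summaries_report_medians(self):
        res = group_compare(values=[1.0, 2.0, 3.0, 11.0, 12.0, 13.0],
                            groups=["x"] * 3 + ["y"] * 3)
        assert res.summaries["x"]["median"] == 2.0
        assert res.summaries["y"]["n"] == 3

    def test_empty_group_rejected(self):
        with pytest.raises(ValueError):
            group_compare(values=[1.0, 2.0], groups=["a", "a"])
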