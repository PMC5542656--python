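from itertools import combinations

import numpy as np
import pandas as pd
import pytest
from hypothesis import given, settings
from hypothesis import strategies as st
from scipy import stats as sps

from caninegbv.cohort_io import Contingency2x2
from caninegbv.stats_core import (
    CollinearityError,
    SeparationError,
    StatsError,
    auc_rank,
    fit_logistic,
    kruskal_wallis,
    odds_ratio,
    relative_risk,
    score_test,
    stepwise_select,
    wald_test,
)


def brute_force_auc(scores, labels):
    """O(n^2) case-control pair counting."""
    scores = np.asarray(scores, float)
    labels = np.asarray(labels)
    cases = scores[labels == 1]
    controls = scores[labels == 0]
    wins = sum((c > k) + 0.5 * (c == k) for c in cases for k in controls)
    return wins / (len(cases) * len(controls))


class TestKruskalWallis:
    def test_two_group_hand_computation(self):
        # rank sums 6 and 15 -> H = 12/(6*7) * (12 + 75) - 21 = 3.857
        res = kruskal_wallis([1, 2, 3, 4, 5, 6], ["a", "a", "a", "b", "b", "b"])
        assert res.statistic == pytest.approx(3.857, abs=5e-4)
        assert res.df == 1

    def test_matches_scipy_with_ties(self):
        rng = np.random.default_rng(0)
        x = rng.integers(0, 6, size=90).astype(float)  # heavy ties
        g = rng.integers(0, 3, size=90)
        ours = kruskal_wallis(x, g)
        ref = sps.kruskal(x[g == 0], x[g == 1], x[g == 2])
        assert ours.statistic == pytest.approx(ref.statistic, rel=1e-12)
        assert ours.p_value == pytest.approx(ref.pvalue, rel=1e-12)

    @pytest.mark.parametrize(
        "values", [[1.0, 2.0, 2.0, 3.0, 5.0, 7.0], [4.0, 4.0, 1.0, 2.0, 6.0, 3.0, 8.0, 5.0]]
    )
    def test_permutation_mean_is_k_minus_one(self, values):
        # over the exhaustive label permutation distribution E[H] = k - 1,
        # including under midrank ties
        n = len(values)
        values = np.asarray(values)
        stats = []
        for group_a in combinations(range(n), n // 2):
            g = np.zeros(n, dtype=int)
            g[list(group_a)] = 1
            stats.append(kruskal_wallis(values, g).statistic)
        assert np.mean(stats) == pytest.approx(1.0, rel=1e-10)

    def test_degenerate_inputs_rejected(self):
        with pytest.raises(StatsError, match="identical"):
            kruskal_wallis([2.0, 2.0, 2.0, 2.0], [0, 0, 1, 1])
        with pytest.raises(StatsError, match="two groups"):
            kruskal_wallis([1.0, 2.0], [0, 0])


class TestFitLogistic:
    def test_single_binary_covariate_closed_form(self):
        # 2x2 cells (10,10,20,40): MLE slope = ln(cross-product ratio) = ln 2
        x = np.repeat([1.0, 0.0], [20, 60])
        y = np.concatenate([np.ones(10), np.zeros(10), np.ones(20), np.zeros(40)])
        fit = fit_logistic(np.column_stack([np.ones(80), x]), y, ["(intercept)", "x"])
        assert fit.converged
        assert fit.coefficients[1] == pytest.approx(np.log(2.0), abs=1e-10)

    def test_matches_statsmodels(self):
        sm = pytest.importorskip("statsmodels.api")
        rng = np.random.default_rng(1)
        n = 400
        x = np.column_stack([np.ones(n), rng.normal(size=n), rng.integers(0, 3, n)])
        y = (rng.random(n) < 1 / (1 + np.exp(-(0.3 * x[:, 1] - 0.4 * x[:, 2])))).astype(float)
        ours = fit_logistic(x, y)
        ref = sm.Logit(y, x).fit(disp=0)
        np.testing.assert_allclose(ours.coefficients, ref.params, rtol=1e-6)
        np.testing.assert_allclose(
            np.sqrt(np.diag(ours.covariance)), ref.bse, rtol=1e-5
        )
        assert ours.log_likelihood == pytest.approx(ref.llf, rel=1e-10)

    def test_score_equations_vanish(self):
        rng = np.random.default_rng(2)
        n = 300
        x = np.column_stack([np.ones(n), rng.normal(size=(n, 3))])
        y = (rng.random(n) < 0.4).astype(float)
        fit = fit_logistic(x, y)
        resid = x.T @ (y - fit.fitted_probabilities)
        assert np.abs(resid).max() < 1e-8

    def test_constant_outcome_rejected(self):
        x = np.column_stack([np.ones(10), np.arange(10.0)])
        with pytest.raises(SeparationError, match="constant"):
            fit_logistic(x, np.zeros(10))

    def test_complete_separation_flagged(self):
        x = np.column_stack([np.ones(20), np.repeat([0.0, 1.0], 10)])
        y = np.repeat([0.0, 1.0], 10)
        with pytest.raises(SeparationError, match="separation"):
            fit_logistic(x, y)

    def test_collinear_design_rejected(self):
        rng = np.random.default_rng(3)
        z = rng.normal(size=50)
        x = np.column_stack([np.ones(50), z, 2 * z])
        y = (rng.random(50) < 0.5).astype(float)
        with pytest.raises(CollinearityError):
            fit_logistic(x, y)


class TestScoreTest:
    def test_constant_candidate_is_zero(self):
        y = np.repeat([0.0, 1.0, 0.0], [5, 5, 2])
        fit = fit_logistic(np.ones((12, 1)), y)
        chi2, p = score_test(fit, np.full(12, 3.0))
        assert chi2 == 0.0 and p == 1.0

    def test_intercept_only_equals_pearson_chi2(self):
        # with a binary candidate, the Rao score test at the null fit is the
        # Pearson chi-square of the induced 2x2 table
        rng = np.random.default_rng(4)
        z = (rng.random(200) < 0.35).astype(float)
        y = (rng.random(200) < 0.25 + 0.1 * z).astype(float)
        fit = fit_logistic(np.ones((200, 1)), y)
        chi2, _ = score_test(fit, z)
        table = np.array(
            [[(y[z == a] == b).sum() for b in (0, 1)] for a in (0, 1)]
        )
        ref = sps.chi2_contingency(table, correction=False).statistic
        assert chi2 == pytest.approx(ref, rel=1e-10)

    def test_collinear_candidate_rejected(self):
        rng = np.random.default_rng(5)
        z = rng.normal(size=100)
        y = (rng.random(100) < 0.5).astype(float)
        fit = fit_logistic(np.column_stack([np.ones(100), z]), y)
        with pytest.raises(CollinearityError):
            score_test(fit, 3.0 * z)


class TestStepwise:
    def test_zero_entry_threshold_gives_empty_model(self):
        rng = np.random.default_rng(6)
        cands = pd.DataFrame({"a": rng.normal(size=100), "b": rng.normal(size=100)})
        y = (rng.random(100) < 0.5).astype(float)
        trace, fit = stepwise_select(cands, y, slentry=0.0)
        assert trace.final_terms == [] and trace.steps == []
        assert fit.term_names == ["(intercept)"]

    def test_planted_strong_effect_selected(self):
        # per-allele log-OR 0.7 at n=1000 gives essentially certain detection
        rng = np.random.default_rng(7)
        n = 1000
        signal = rng.integers(0, 3, n).astype(float)
        noise = pd.DataFrame(
            {f"n{j}": rng.integers(0, 3, n).astype(float) for j in range(5)}
        )
        eta = -1.5 + 0.7 * signal
        y = (rng.random(n) < 1 / (1 + np.exp(-eta))).astype(float)
        cands = pd.concat([pd.Series(signal, name="signal"), noise], axis=1)
        trace, fit = stepwise_select(cands, y)
        assert "signal" in trace.final_terms
        entered = [s.term for s in trace.steps if s.action == "enter"]
        assert entered[0] == "signal"
        # entry p-values respected the threshold at their step
        assert all(s.p_value <= 0.05 for s in trace.steps if s.action == "enter")

    def test_wald_stay_removes_weak_terms(self):
        # a term that enters first can be displaced once a dominating,
        # correlated predictor enters; slstay then removes it
        rng = np.random.default_rng(8)
        n = 600
        strong = rng.normal(size=n)
        weak = 0.8 * strong + 0.6 * rng.normal(size=n)
        eta = 1.2 * strong
        y = (rng.random(n) < 1 / (1 + np.exp(-eta))).astype(float)
        cands = pd.DataFrame({"weak": weak, "strong": strong})
        trace, fit = stepwise_select(cands, y)
        assert trace.final_terms == ["strong"] or set(trace.final_terms) == {
            "strong",
            "weak",
        }
        for term in trace.final_terms:
            assert wald_test(fit, term)[1] <= 0.05


class TestAuc:
    def test_perfect_and_tied(self):
        assert auc_rank([1, 2], [0, 1]) == 1.0
        assert auc_rank([3, 3, 3, 3], [0, 0, 1, 1]) == 0.5

    def test_matches_pair_counting_oracle(self):
        rng = np.random.default_rng(9)
        scores = rng.integers(0, 10, 150).astype(float)  # ties guaranteed
        labels = (rng.random(150) < 0.4).astype(int)
        assert auc_rank(scores, labels) == pytest.approx(
            brute_force_auc(scores, labels), abs=1e-12
        )

    def test_complement_under_score_negation(self):
        rng = np.random.default_rng(10)
        scores = rng.normal(size=80)
        labels = (rng.random(80) < 0.5).astype(int)
        assert auc_rank(scores, labels) + auc_rank(-scores, labels) == pytest.approx(1.0)

    @given(st.integers(0, 2**31 - 1))
    @settings(max_examples=25, derandomize=True, deadline=None)
    def test_invariant_under_increasing_transforms(self, seed):
        rng = np.random.default_rng(seed)
        scores = rng.normal(size=40)
        labels = np.array([0, 1] * 20)
        base = auc_rank(scores, labels)
        assert auc_rank(np.exp(scores), labels) == pytest.approx(base)
        assert auc_rank(3 * scores + 7, labels) == pytest.approx(base)

    def test_single_class_rejected(self):
        with pytest.raises(StatsError, match="both label classes"):
            auc_rank([1.0, 2.0], [1, 1])


class TestEffectMeasures:
    def test_odds_ratio_null_and_zero_cell(self):
        assert odds_ratio(Contingency2x2(5, 5, 5, 5)).point == pytest.approx(1.0)
        with pytest.raises(StatsError, match="zero cell"):
            odds_ratio(Contingency2x2(0, 5, 5, 5))

    def test_relative_risk_null_and_boundaries(self):
        assert relative_risk((10, 100), (10, 100)).point == pytest.approx(1.0)
        with pytest.raises(StatsError, match="unexposed"):
            relative_risk((5, 50), (0, 50))
        with pytest.raises(StatsError, match="exposed"):
            relative_risk((0, 50), (5, 50))

    def test_ci_brackets_point(self):
        est = odds_ratio(Contingency2x2(12, 34, 26, 58))
        assert est.ci_low <= est.point <= est.ci_high

    @pytest.mark.parametrize("cells", [(10, 10, 20, 40), (12, 30, 9, 51), (7, 3, 11, 19)])
    def test_wald_or_equals_cross_product_or(self, cells):
        # single-binary-covariate logistic Wald OR == 2x2 Woolf OR, CI included
        a, b, c, d = cells
        x = np.repeat([1.0, 0.0], [a + b, c + d])
        y = np.concatenate([np.ones(a), np.zeros(b), np.ones(c), np.zeros(d)])
        fit = fit_logistic(np.column_stack([np.ones(len(y)), x]), y, ["(intercept)", "x"])
        wald = fit.wald_or("x")
        table = odds_ratio(Contingency2x2(a, b, c, d))
        assert wald.point == pytest.approx(table.point, rel=1e-6)
        assert wald.ci_low == pytest.approx(table.ci_low, rel=1e-6)
        assert wald.ci_high == pytest.approx(table.ci_high, rel=1e-6)
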