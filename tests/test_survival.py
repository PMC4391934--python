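import numpy as np
import pandas as pd
import pytest
from lifelines import CoxPHFitter

from qdki67 import (
    cox_fit,
    km_fit,
    logrank_test,
    roc_auc,
    two_group_logrank_chi2,
)
from qdki67.errors import NoSignalError, SeparationError, ValidationError


class TestKaplanMeier:
    def test_all_censored_survival_stays_one(self):
        curve = km_fit([3.0, 8.0, 12.0], [0, 0, 0])
        assert np.all(curve.survival == 1.0)
        assert curve.survival_at(100.0) == 1.0

    def test_single_subject_steps_to_zero_at_event(self):
        curve = km_fit([5.0], [1])
        assert curve.survival_at(4.999) == 1.0
        assert curve.survival_at(5.0) == 0.0

    def test_six_subject_hand_computation(self):
        # subjects at t = 1..6, censored at t = 3; product-limit by hand:
        # S(1)=5/6, S(2)=5/6*4/5=2/3, S(4)=2/3*2/3=4/9, S(5)=4/9*1/2=2/9, S(6)=0
        curve = km_fit([1, 2, 3, 4, 5, 6], [1, 1, 0, 1, 1, 1])
        np.testing.assert_allclose(curve.times, [0, 1, 2, 4, 5, 6])
        np.testing.assert_allclose(
            curve.survival, [1.0, 5 / 6, 2 / 3, 4 / 9, 2 / 9, 0.0]
        )
        np.testing.assert_allclose(curve.at_risk, [6, 6, 5, 3, 2, 1])

    def test_no_censoring_equals_empirical_survival(self, rng):
        times = rng.exponential(10.0, size=40)
        curve = km_fit(times, np.ones(40, int))
        for t in [1.0, 5.0, 12.0]:
            assert curve.survival_at(t) == pytest.approx(np.mean(times > t))

    def test_non_positive_times_rejected(self):
        with pytest.raises(ValidationError):
            km_fit([0.0, 2.0], [1, 1])


class TestLogrank:
    def test_identical_groups_give_zero_statistic(self):
        times = np.array([2.0, 4.0, 7.0, 9.0, 12.0])
        events = np.array([1, 0, 1, 1, 0])
        both_t = np.concatenate([times, times])
        both_e = np.concatenate([events, events])
        groups = np.array(["A"] * 5 + ["B"] * 5)
        result = logrank_test(both_t, both_e, groups)
        assert result.chi_square == pytest.approx(0.0, abs=1e-12)
        assert result.df == 1

    def test_two_group_chi2_matches_lifelines(self, rng):
        from lifelines.statistics import logrank_test as ll_logrank

        times = rng.exponential(12.0, 30)
        events = rng.random(30) < 0.7
        mask = rng.random(30) < 0.5
        ours = two_group_logrank_chi2(times, events, mask)
        ref = ll_logrank(
            times[mask], times[~mask], events[mask], events[~mask]
        ).test_statistic
        assert ours == pytest.approx(ref, rel=1e-9)

    def test_p_close_to_permutation_reference_at_n20(self, rng):
        # 10,000-permutation reference; the analytic p is chi-square
        # asymptotic, so allow Monte-Carlo error plus a small asymptotic gap
        times = rng.exponential(20.0, 20)
        times[:10] *= 0.5
        events = (rng.random(20) < 0.8).astype(int)
        mask = np.arange(20) < 10
        result = logrank_test(times, events, np.where(mask, "A", "B"))
        observed = two_group_logrank_chi2(times, events, mask)
        count = 0
        n_perm = 10_000
        perm_rng = np.random.default_rng(2024)
        for _ in range(n_perm):
            count += two_group_logrank_chi2(times, events, perm_rng.permutation(mask)) >= observed - 1e-12
        p_mc = count / n_perm
        mc_sigma = np.sqrt(p_mc * (1 - p_mc) / n_perm)
        assert abs(result.p - p_mc) <= 3 * mc_sigma + 0.03

    def test_complete_separation_is_highly_significant(self):
        # all group-A events strictly before any group-B event, no censoring
        times = np.array([1, 2, 3, 4, 5, 11, 12, 13, 14, 15], float)
        events = np.ones(10, int)
        groups = np.array(["A"] * 5 + ["B"] * 5)
        assert logrank_test(times, events, groups).p < 0.01

    def test_single_group_rejected(self):
        with pytest.raises(ValidationError):
            logrank_test([1.0, 2.0], [1, 1], ["A", "A"])

    def test_no_events_rejected(self):
        with pytest.raises(NoSignalError):
            logrank_test([1.0, 2.0], [0, 0], ["A", "B"])


def _breslow_partial_loglik(beta, x, times, events):
    """Independent scalar-covariate partial log-likelihood for grid search."""
    ll = 0.0
    for t in np.unique(times[events == 1]):
        dead = (times == t) & (events == 1)
        at_risk = times >= t
        ll += beta * x[dead].sum() - dead.sum() * np.log(np.exp(beta * x[at_risk]).sum())
    return ll


class TestCox:
    def test_five_subject_grid_search_oracle(self):
        times = np.array([1.0, 2.0, 3.0, 4.0, 5.0])
        events = np.ones(5, int)
        x = np.array([1.0, 0.0, 1.0, 0.0, 0.0])
        fit = cox_fit(x[:, None], times, events)
        grid = np.arange(-5.0, 5.0, 1e-4)
        loglik = [_breslow_partial_loglik(b, x, times, events) for b in grid]
        oracle = grid[int(np.argmax(loglik))]
        assert fit.coef[0] == pytest.approx(oracle, abs=1e-3)
        assert fit.log_likelihood == pytest.approx(max(loglik), abs=1e-6)

    def test_null_covariate_ci_contains_one(self, rng):
        times = rng.exponential(20.0, 200)
        events = (rng.random(200) < 0.7).astype(int)
        x = rng.permutation(np.arange(200) % 2).astype(float)
        fit = cox_fit(x[:, None], times, events)
        assert abs(fit.coef[0]) < 0.5
        assert fit.ci_low[0] <= 1.0 <= fit.ci_high[0]

    def test_duplicated_relabeled_data_gives_zero_coefficient(self, rng):
        times = np.tile(rng.exponential(10.0, 20), 2)
        events = np.tile((rng.random(20) < 0.8).astype(int), 2)
        x = np.concatenate([np.zeros(20), np.ones(20)])
        fit = cox_fit(x[:, None], times, events)
        assert fit.coef[0] == pytest.approx(0.0, abs=1e-6)

    def test_matches_lifelines_on_tie_free_data(self, rng):
        # Breslow and Efron coincide without ties, so lifelines (Efron)
        # is a valid independent reference here
        n = 80
        x1 = rng.normal(size=n)
        x2 = (rng.random(n) < 0.4).astype(float)
        times = rng.exponential(10.0 / np.exp(0.5 * x1), n)
        events = (rng.random(n) < 0.8).astype(int)
        frame = pd.DataFrame({"t": times, "e": events, "x1": x1, "x2": x2})
        ref = CoxPHFitter().fit(frame, duration_col="t", event_col="e")
        fit = cox_fit(frame[["x1", "x2"]], times, events)
        np.testing.assert_allclose(fit.coef, ref.params_.to_numpy(), atol=1e-5)
        np.testing.assert_allclose(fit.se, ref.standard_errors_.to_numpy(), atol=1e-5)

    def test_efron_option_matches_lifelines_with_ties(self, rng):
        times = np.round(rng.exponential(10.0, 60)) + 1.0
        events = (rng.random(60) < 0.8).astype(int)
        x = rng.normal(size=60)
        frame = pd.DataFrame({"t": times, "e": events, "x": x})
        ref = CoxPHFitter().fit(frame, duration_col="t", event_col="e")
        fit = cox_fit(x[:, None], times, events, ties="efron")
        assert fit.coef[0] == pytest.approx(float(ref.params_.iloc[0]), abs=1e-5)

    def test_hazard_ratio_equals_exp_coef_and_ci_ordering(self, rng):
        times = rng.exponential(10.0, 100)
        events = (rng.random(100) < 0.7).astype(int)
        x = rng.normal(size=100)
        fit = cox_fit(x[:, None], times, events)
        assert fit.hazard_ratio[0] == pytest.approx(np.exp(fit.coef[0]))
        assert fit.ci_low[0] <= fit.hazard_ratio[0] <= fit.ci_high[0]

    def test_perfect_separation_flagged(self):
        # covariate perfectly ordered with event times: monotone likelihood
        times = np.arange(1.0, 21.0)
        events = np.ones(20, int)
        x = np.arange(20.0)[::-1]
        with pytest.raises(SeparationError):
            cox_fit(x[:, None], times, events)

    def test_constant_covariate_rejected(self):
        with pytest.raises(ValidationError):
            cox_fit(np.ones((10, 1)), np.arange(1.0, 11.0), np.ones(10, int))


class TestROC:
    def test_perfect_separation_gives_auc_one(self):
        result = roc_auc([0.1, 0.2, 0.8, 0.9], [0, 0, 1, 1])
        assert result.auc == 1.0
        assert result.p < 0.001

    def test_constant_predictor_gives_half(self):
        result = roc_auc([1.0, 1.0, 1.0, 1.0], [0, 1, 0, 1])
        assert result.auc == 0.5

    def test_binary_predictor_equals_sens_plus_spec_over_two(self, rng):
        # 2x2 table: AUC = (sensitivity + specificity) / 2, checked against
        # exhaustive concordant/tied pair counting
        predictor = (rng.random(60) < 0.4).astype(float)
        outcome = (rng.random(60) < 0.5).astype(int)
        result = roc_auc(predictor, outcome)
        sens = predictor[outcome == 1].mean()
        spec = 1.0 - predictor[outcome == 0].mean()
        assert result.auc == pytest.approx((sens + spec) / 2.0)
        pairs = 0.0
        cases = predictor[outcome == 1]
        controls = predictor[outcome == 0]
        for c in cases:
            for k in controls:
                pairs += 1.0 if c > k else (0.5 if c == k else 0.0)
        assert result.auc == pytest.approx(pairs / (len(cases) * len(controls)))

    def test_auc_invariant_under_monotone_transform(self, rng):
        predictor = rng.lognormal(0.0, 1.0, 50)
        outcome = (rng.random(50) < 0.4).astype(int)
        base = roc_auc(predictor, outcome)
        transformed = roc_auc(np.log(predictor), outcome)
        assert transformed.auc == pytest.approx(base.auc)
        assert transformed.ci == pytest.approx(base.ci)

    def test_single_class_rejected(self):
        with pytest.raises(ValidationError):
            roc_auc([0.1, 0.5], [1, 1])

    def test_ci_contains_auc(self, rng):
        predictor = rng.normal(size=80) + 0.8 * (np.arange(80) < 30)
        outcome = (np.arange(80) < 30).astype(int)
        result = roc_auc(predictor, outcome)
        assert result.ci[0] <= result.auc <= result.ci[1]
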