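import numpy as np
import pandas as pd
import pytest

from protsig.exceptions import ValidationError
from protsig.survival import (
    cox_fit,
    cox_partial_loglik,
    interaction_lrt,
    kaplan_meier,
    log_rank,
)


def logrank_oracle(time, event, group):
    """Tabulated per-event-time 2x2 hypergeometric O/E/V computation."""
    time = np.asarray(time, dtype=float)
    event = np.asarray(event, dtype=int)
    group = np.asarray(group, dtype=int)
    oe, var = 0.0, 0.0
    for t in np.unique(time[event == 1]):
        at_risk = time >= t
        n = at_risk.sum()
        n1 = (at_risk & (group == 1)).sum()
        d = ((time == t) & (event == 1)).sum()
        d1 = ((time == t) & (event == 1) & (group == 1)).sum()
        oe += d1 - d * n1 / n
        if n > 1:
            var += d * (n1 / n) * (1 - n1 / n) * (n - d) / (n - 1)
    return oe**2 / var


class TestKaplanMeier:
    def test_no_censoring_is_empirical_survival(self):
        km = kaplan_meier([1.0, 2.0, 3.0], [1, 1, 1])
        np.testing.assert_allclose(km.survival, [2 / 3, 1 / 3, 0.0])
        np.testing.assert_allclose(km.event_times, [1.0, 2.0, 3.0])

    def test_hand_worked_censored_example(self):
        # 1 censored, events at 2 and 3: S(2) = 1/2, S(3) = 0
        km = kaplan_meier([1.0, 2.0, 3.0], [0, 1, 1])
        np.testing.assert_allclose(km.event_times, [2.0, 3.0])
        np.testing.assert_allclose(km.survival, [0.5, 0.0])

    def test_survival_at_zero_is_one(self, rng):
        time = rng.exponential(5.0, 30)
        event = rng.binomial(1, 0.7, 30)
        km = kaplan_meier(time, event)
        assert km.survival_at(0.0) == 1.0
        assert (np.diff(km.survival) <= 1e-15).all()

    def test_no_censoring_equals_one_minus_ecdf(self, rng):
        time = np.round(rng.exponential(5.0, 50), 1)
        km = kaplan_meier(time, np.ones(50))
        for t, s in zip(km.event_times, km.survival):
            assert s == pytest.approx(np.mean(time > t), abs=1e-12)

    def test_tied_event_and_censoring_events_first(self):
        # censored at t=2 still at risk for the event at t=2
        km = kaplan_meier([2.0, 2.0], [1, 0])
        np.testing.assert_allclose(km.survival, [0.5])

    def test_no_subjects_errors(self):
        with pytest.raises(ValidationError):
            kaplan_meier([], [])


class TestLogRank:
    def test_identical_groups_give_zero(self):
        time = [1.0, 2.0, 3.0, 1.0, 2.0, 3.0]
        event = [1, 1, 0, 1, 1, 0]
        res = log_rank(time, event, [0, 0, 0, 1, 1, 1])
        assert res.chi_square == pytest.approx(0.0, abs=1e-12)
        assert res.p_value == pytest.approx(1.0)

    def test_six_subject_worked_example_matches_oracle(self):
        time = [1.0, 3.0, 5.0, 2.0, 4.0, 6.0]
        event = [1, 1, 1, 1, 1, 1]
        group = [0, 0, 0, 1, 1, 1]
        res = log_rank(time, event, group)
        assert res.chi_square == pytest.approx(logrank_oracle(time, event, group), abs=1e-12)

    def test_matches_oracle_with_ties_and_censoring(self, rng):
        for _ in range(50):
            n = int(rng.integers(6, 40))
            time = np.round(rng.exponential(5.0, n), 0) + 1
            event = rng.binomial(1, 0.7, n)
            group = rng.binomial(1, 0.5, n)
            if event.sum() == 0 or len(np.unique(group)) < 2:
                continue
            res = log_rank(time, event, group)
            assert res.chi_square == pytest.approx(
                logrank_oracle(time, event, group), abs=1e-12
            )
            assert 0 <= res.p_value <= 1 and res.chi_square >= 0

    def test_duplicated_data_scales_chi_square(self, rng):
        n, k = 60, 3
        time = rng.exponential(5.0, n)
        event = rng.binomial(1, 0.8, n)
        group = np.repeat([0, 1], n // 2)
        base = log_rank(time, event, group).chi_square
        dup = log_rank(np.tile(time, k), np.tile(event, k), np.tile(group, k)).chi_square
        assert dup / base == pytest.approx(k, rel=0.05)

    def test_one_empty_group_errors(self):
        with pytest.raises(ValidationError):
            log_rank([1.0, 2.0], [1, 1], [0, 0])


def simulate_cox_data(rng, n, beta, censor_scale=None):
    x = rng.normal(size=(n, len(beta)))
    t = rng.exponential(1.0 / (0.1 * np.exp(x @ beta)))
    if censor_scale is None:
        return t, np.ones(n, dtype=int), x
    c = rng.uniform(0, censor_scale, n)
    return np.minimum(t, c), (t <= c).astype(int), x


class TestCoxFit:
    def test_constant_covariate_errors_with_name(self, rng):
        time = rng.exponential(1.0, 20)
        covs = pd.DataFrame({"ok": rng.normal(size=20), "flat": np.ones(20)})
        with pytest.raises(ValidationError, match="flat"):
            cox_fit(time, np.ones(20), covs)

    def test_two_group_parameter_recovery(self, rng):
        """True log HR 0.7, n=2000, ~30% censoring: estimate within 0.1."""
        n = 2000
        group = rng.binomial(1, 0.5, n).astype(float)
        t = rng.exponential(1.0 / (0.1 * np.exp(0.7 * group)))
        c = rng.uniform(0, 30.0, n)
        time, event = np.minimum(t, c), (t <= c).astype(int)
        assert 0.15 < 1 - event.mean() < 0.45
        fit = cox_fit(time, event, group[:, None])
        assert fit.converged
        assert fit.coefficients.iloc[0] == pytest.approx(0.7, abs=0.1)

    def test_score_equation_satisfied_at_fit(self, rng):
        for _ in range(25):
            n = int(rng.integers(30, 120))
            p = int(rng.integers(1, 4))
            time, event, x = simulate_cox_data(rng, n, rng.normal(0, 0.5, p), censor_scale=20.0)
            if event.sum() < p + 2:
                continue
            fit = cox_fit(time, event, x)
            _, grad = cox_partial_loglik(time, event, x, fit.coefficients.to_numpy())
            assert np.abs(grad).max() < 1e-6

    def test_matches_lifelines_with_ties(self, rng):
        from lifelines import CoxPHFitter

        time, event, x = simulate_cox_data(rng, 150, [0.5, -0.3], censor_scale=25.0)
        time = np.round(time, 0) + 1.0  # force tied event times
        fit = cox_fit(time, event, x)
        frame = pd.DataFrame(x, columns=["a", "b"])
        frame["T"], frame["E"] = time, event
        ref = CoxPHFitter().fit(frame, "T", "E")
        np.testing.assert_allclose(fit.coefficients, ref.params_.to_numpy(), atol=1e-5)
        np.testing.assert_allclose(fit.standard_errors, ref.standard_errors_.to_numpy(), atol=1e-5)
        assert fit.log_likelihood == pytest.approx(ref.log_likelihood_, abs=1e-6)

    def test_time_rescaling_leaves_coefficients(self, rng):
        time, event, x = simulate_cox_data(rng, 100, [0.4], censor_scale=20.0)
        fit_days = cox_fit(time * 30.4, event, x)
        fit_months = cox_fit(time, event, x)
        np.testing.assert_allclose(
            fit_days.coefficients, fit_months.coefficients, rtol=1e-6
        )

    def test_covariate_rescaling_divides_coefficient(self, rng):
        time, event, x = simulate_cox_data(rng, 100, [0.4], censor_scale=20.0)
        c = 2.5
        fit = cox_fit(time, event, x)
        fit_scaled = cox_fit(time, event, x * c)
        assert fit_scaled.coefficients.iloc[0] == pytest.approx(
            fit.coefficients.iloc[0] / c, rel=1e-6
        )

    def test_perfect_separation_flags_non_convergence(self):
        time = np.array([1.0, 2.0, 3.0, 4.0, 5.0, 6.0])
        event = np.ones(6, dtype=int)
        x = np.array([[1.0], [1.0], [1.0], [0.0], [0.0], [0.0]])  # monotone likelihood
        with pytest.warns(UserWarning, match="converge"):
            fit = cox_fit(time, event, x)
        assert not fit.converged

    def test_summary_table_shape(self, rng):
        time, event, x = simulate_cox_data(rng, 80, [0.3, -0.2])
        fit = cox_fit(time, event, pd.DataFrame(x, columns=["a", "b"]))
        table = fit.summary()
        assert list(table.columns) == ["coef", "HR", "se", "HR_lower_95", "HR_upper_95", "p"]
        np.testing.assert_allclose(table["HR"], np.exp(table["coef"]))
        assert ((table["HR_lower_95"] <= table["HR"]) & (table["HR"] <= table["HR_upper_95"])).all()


class TestInteractionLRT:
    def _data(self, rng, n=200, interaction=0.0):
        treatment = rng.binomial(1, 0.5, n)
        score = rng.normal(size=n)
        lp = -0.3 * treatment + 0.2 * score + interaction * treatment * score
        t = rng.exponential(1.0 / (0.05 * np.exp(lp)))
        c = rng.uniform(0, 60.0, n)
        return np.minimum(t, c), (t <= c).astype(int), score, treatment

    def test_statistic_non_negative(self, rng):
        for _ in range(10):
            time, event, score, treatment = self._data(rng)
            stat, p, full, reduced = interaction_lrt(time, event, score, treatment)
            assert stat >= 0.0
            assert 0 <= p <= 1
            assert full.log_likelihood >= reduced.log_likelihood - 1e-9

    def test_affine_score_rescaling_leaves_statistic(self, rng):
        time, event, score, treatment = self._data(rng, interaction=0.8)
        stat, _, _, _ = interaction_lrt(time, event, score, treatment)
        stat_scaled, _, _, _ = interaction_lrt(time, event, 3.0 * score + 11.0, treatment)
        assert stat_scaled == pytest.approx(stat, rel=1e-6)

    def test_detects_strong_interaction(self, rng):
        time, event, score, treatment = self._data(rng, n=500, interaction=1.2)
        stat, p, _, _ = interaction_lrt(time, event, score, treatment)
        assert p < 0.01

    def test_arm_without_events_errors(self, rng):
        time, event, score, treatment = self._data(rng)
        event = event.copy()
        event[treatment == 1] = 0
        with pytest.raises(ValidationError):
            interaction_lrt(time, event, score, treatment)

    def test_with_covariates(self, rng):
        time, event, score, treatment = self._data(rng)
        covs = pd.DataFrame({"age": rng.normal(55, 10, len(time))})
        stat, p, full, reduced = interaction_lrt(time, event, score, treatment, covariates=covs)
        assert "age" in full.coefficients.index and "age" in reduced.coefficients.index
        assert "treatment_x_score" in full.coefficients.index
        assert "treatment_x_score" not in reduced.coefficients.index
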