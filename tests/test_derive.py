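import warnings

import numpy as np
import pandas as pd
import pytest
from scipy import stats

from protsig import simulate_cohort, simulate_null_cohort, SimulationConfig
from protsig.datatypes import ExpressionMatrix, GroupLabels
from protsig.derive import _welch_arrays, benjamini_hochberg, derive_signature, robust_welch_test
from protsig.exceptions import DegenerateDataError, ValidationError
from protsig.grouping import quartile_groups


def bh_oracle(p):
    """Literal double-loop implementation of the BH step-up definition."""
    p = np.asarray(p, dtype=float)
    m = len(p)
    order = np.argsort(p, kind="stable")
    q = np.empty(m)
    for out_pos, i in enumerate(order):
        candidates = []
        for rank_j, j in enumerate(order, start=1):
            if p[j] >= p[i]:
                candidates.append(min(1.0, p[j] * m / rank_j))
        q[i] = min(candidates)
    return q


class TestWelch:
    def test_identical_groups_give_zero_statistic_unit_p(self, rng):
        x = rng.normal(size=10)
        res = robust_welch_test(x, x)
        assert res.statistic == 0.0 and res.p_value == 1.0

    def test_classic_hand_example(self):
        # x=(1,2,3), y=(4,5,6): t = -3/sqrt(2/3), df = 4 by symmetry
        res = robust_welch_test([1, 2, 3], [4, 5, 6], mode="classic")
        assert res.statistic == pytest.approx(-3.6742346, abs=1e-6)
        assert res.df == pytest.approx(4.0)
        assert res.p_value == pytest.approx(0.0213116, abs=1e-6)

    def test_classic_matches_scipy_welch(self, rng):
        for _ in range(50):
            x = rng.normal(size=rng.integers(3, 20))
            y = rng.normal(1.0, 2.0, size=rng.integers(3, 20))
            res = robust_welch_test(x, y, mode="classic")
            ref = stats.ttest_ind(x, y, equal_var=False)
            assert res.statistic == pytest.approx(ref.statistic, rel=1e-12)
            assert res.p_value == pytest.approx(ref.pvalue, rel=1e-9)

    def test_robust_mode_null_calibration(self, rng):
        """Null rejection at alpha=0.05 stays within 5% +/- 1.5% (n=20/20)."""
        reps = 5000
        x = rng.normal(size=(reps, 20))
        y = rng.normal(size=(reps, 20))
        _, p, _, _, _ = _welch_arrays(x, y, "robust")
        assert (p < 0.05).mean() == pytest.approx(0.05, abs=0.015)

    def test_zero_dispersion_different_medians_is_infinite(self):
        res = robust_welch_test([1.0, 1.0, 1.0], [2.0, 2.0, 2.0])
        assert np.isinf(res.statistic) and res.p_value == 0.0

    def test_zero_dispersion_equal_medians_errors(self):
        with pytest.raises(DegenerateDataError):
            robust_welch_test([1.0, 1.0, 1.0], [1.0, 1.0, 1.0])

    def test_needs_three_per_group(self):
        with pytest.raises(ValidationError):
            robust_welch_test([1.0, 2.0], [1.0, 2.0, 3.0])

    def test_robust_ignores_gross_outlier(self, rng):
        x = np.concatenate([rng.normal(2.0, 0.5, 14), [500.0]])
        y = rng.normal(0.0, 0.5, 15)
        assert robust_welch_test(x, y).p_value < 0.01


class TestBenjaminiHochberg:
    def test_hand_example_all_equal(self):
        np.testing.assert_allclose(
            benjamini_hochberg([0.01, 0.02, 0.03, 0.04]), [0.04, 0.04, 0.04, 0.04]
        )

    def test_single_p_identity(self):
        assert benjamini_hochberg([0.37])[0] == pytest.approx(0.37)

    def test_out_of_range_rejected(self):
        with pytest.raises(ValidationError):
            benjamini_hochberg([0.1, 1.5])

    def test_matches_double_loop_oracle(self, rng):
        for _ in range(100):
            p = rng.random(int(rng.integers(1, 40)))
            np.testing.assert_allclose(benjamini_hochberg(p), bh_oracle(p), atol=1e-12)

    def test_bh_never_below_smallest_p(self, rng):
        p = rng.random(50)
        assert benjamini_hochberg(p).min() >= p.min() - 1e-15


def _toy_labeled_matrix(rng, n_genes=60, n_per_group=8, effect=3.0):
    samples = [f"s{i}" for i in range(2 * n_per_group)]
    values = rng.normal(size=(n_genes, 2 * n_per_group))
    values[:10, :n_per_group] += effect * np.where(np.arange(10) % 2 == 0, 1, -1)[:, None]
    matrix = ExpressionMatrix(
        pd.DataFrame(values, index=[f"g{i}" for i in range(n_genes)], columns=samples)
    )
    labels = GroupLabels(
        pd.Series(["high"] * n_per_group + ["low"] * n_per_group, index=samples)
    )
    return matrix, labels


class TestDeriveSignature:
    def test_sign_flip_negates_coefficients_keeps_p(self, rng):
        matrix, labels = _toy_labeled_matrix(rng)
        sig, table = derive_signature(matrix, labels)
        flipped_labels = GroupLabels(
            labels.labels.map({"high": "low", "low": "high"})
        )
        sig_f, table_f = derive_signature(matrix, flipped_labels)
        np.testing.assert_allclose(table_f.statistic, -table.statistic, atol=1e-12)
        np.testing.assert_allclose(table_f.p_value, table.p_value, atol=1e-12)
        np.testing.assert_allclose(table_f.fdr, table.fdr, atol=1e-12)
        assert dict(sig_f.entries) == {g: -c for g, c in sig.entries}

    def test_fdr_threshold_monotonicity(self, rng):
        matrix, labels = _toy_labeled_matrix(rng)
        previous = set()
        for threshold in (0.001, 0.01, 0.05, 0.2, 1.0):
            with warnings.catch_warnings():
                warnings.simplefilter("ignore")
                sig, _ = derive_signature(matrix, labels, fdr_threshold=threshold)
            selected = set(sig.genes)
            assert previous <= selected
            previous = selected

    def test_infinite_fold_threshold_gives_empty_signature_with_warning(self, rng):
        matrix, labels = _toy_labeled_matrix(rng)
        with pytest.warns(UserWarning, match="no genes"):
            sig, _ = derive_signature(matrix, labels, fold_threshold=np.inf)
        assert len(sig) == 0

    def test_missing_group_errors(self, rng):
        matrix, labels = _toy_labeled_matrix(rng)
        all_high = GroupLabels(pd.Series("high", index=labels.labels.index))
        with pytest.raises(ValidationError):
            derive_signature(matrix, all_high)

    def test_strong_planted_signal_recovered_with_signs(self, rng):
        matrix, labels = _toy_labeled_matrix(rng, effect=3.0)
        sig, _ = derive_signature(matrix, labels)
        expected = {f"g{i}": 1 if i % 2 == 0 else -1 for i in range(10)}
        found = dict(sig.entries)
        hits = sum(1 for g, c in expected.items() if found.get(g) == c)
        assert hits >= 8
        assert sum(1 for g in found if g not in expected) <= 2

    def test_null_cohorts_select_few_genes(self):
        """Over 100 null replicates, mean selected genes <= 2% of n_genes."""
        total_selected = 0
        for seed in range(100):
            cohort = simulate_null_cohort(
                SimulationConfig(
                    n_samples=60, n_genes=500, n_signature_genes=10, seed=seed
                )
            )
            labels = quartile_groups(cohort.protein)
            with warnings.catch_warnings():
                warnings.simplefilter("ignore")
                sig, _ = derive_signature(cohort.expression, labels)
            total_selected += len(sig)
        assert total_selected / 100 <= 0.02 * 500

    def test_sensitivity_non_decreasing_in_effect_size(self):
        """Selection sensitivity grows with the planted effect (matched seeds)."""
        sensitivities = []
        for effect in (0.5, 1.0, 1.5, 2.0):
            hits = 0
            for seed in (1, 2, 3):
                cohort = simulate_cohort(
                    SimulationConfig(
                        n_samples=80, n_genes=300, n_signature_genes=30,
                        effect_size=effect, seed=seed,
                    )
                )
                labels = quartile_groups(cohort.protein)
                with warnings.catch_warnings():
                    warnings.simplefilter("ignore")
                    sig, _ = derive_signature(cohort.expression, labels)
                truth = dict(cohort.truth_signature.entries)
                hits += sum(1 for g, c in sig.entries if truth.get(g) == c)
            sensitivities.append(hits)
        assert sensitivities == sorted(sensitivities)
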