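"""Reduction, stacked regression, epsilon and the within-subject F-test."""

import numpy as np
import pytest
from hypothesis import given, settings
from hypothesis import strategies as st
from scipy import stats

from rmanova import (
    Design,
    EffectCoding,
    enumerate_cells,
    enumerate_effects,
    main_effect_coding,
)
from rmanova.rm_engine import (
    EigenSpectrum,
    epsilon_from_eigenvalues,
    f_test,
    gg_epsilon,
    reduce_rows,
    stacked_regression,
    test_within_effect as within_effect_test,
)

ALT_CONTRAST = EffectCoding(
    factors=(1,),
    matrix=np.array([[-1, 1, -1, 1, -1, 1]], dtype=float).T,
    column_labels=((2,),),
    name="alt",
)


class TestReduceRows:
    def test_worked_reduction_example(self):
        """Centering [-2 4 3 -7 1 1] and projecting onto [-1 1 -1 1 -1 1]
        gives elements of magnitude 2/3, alternating in sign across cells.

        The slope of the centered row on this contrast is -2/3, so the
        fitted row starts at +2/3 (the projection is sign-definite even
        though printed accounts of this example sometimes flip it)."""
        raw = np.array([[-2.0, 4.0, 3.0, -7.0, 1.0, 1.0]])
        reduced = reduce_rows(raw, ALT_CONTRAST)
        np.testing.assert_allclose(np.abs(reduced), 2.0 / 3.0, atol=1e-12)
        np.testing.assert_allclose(
            reduced[0], 2.0 / 3.0 * np.array([1, -1, 1, -1, 1, -1]), atol=1e-12
        )

    def test_constant_row_reduces_to_zero(self):
        raw = np.full((1, 6), 5.0)
        np.testing.assert_allclose(reduce_rows(raw, ALT_CONTRAST), 0.0, atol=1e-12)

    def test_full_contrast_basis_reproduces_centered_row(self, rng, design_2x3):
        """Projection onto the complete (cells-1)-dim contrast space is the
        identity on centered rows."""
        effects = enumerate_effects(design_2x3)
        full = EffectCoding(
            factors=(0, 1),
            matrix=np.hstack([e.matrix for e in effects]),
            column_labels=tuple((0,) for _ in range(5)),
            name="full",
        )
        raw = rng.standard_normal((4, 6))
        centered = raw - raw.mean(axis=1, keepdims=True)
        np.testing.assert_allclose(reduce_rows(raw, full), centered, atol=1e-10)

    def test_projection_idempotent_and_rows_zero_sum(self, rng, effects_2x3):
        raw = rng.standard_normal((7, 6))
        for eff in effects_2x3.values():
            reduced = reduce_rows(raw, eff)
            np.testing.assert_allclose(reduce_rows(reduced, eff), reduced, atol=1e-10)
            np.testing.assert_allclose(reduced.sum(axis=1), 0.0, atol=1e-10)

    def test_dimension_mismatch_rejected(self, rng, effects_2x3):
        with pytest.raises(ValueError):
            reduce_rows(rng.standard_normal((3, 5)), effects_2x3["A"])


class TestStackedRegression:
    def test_identical_rows_leave_no_error_variance(self, effects_2x3):
        row = np.array([1.0, -1.0, 0.0, -1.0, 1.0, 0.0])
        reduced = reduce_rows(np.tile(row, (6, 1)), effects_2x3["B"])
        ssm, sse = stacked_regression(reduced, effects_2x3["B"])
        assert sse == pytest.approx(0.0, abs=1e-12)
        assert ssm > 0

    def test_antisymmetric_rows_cancel_model_ss(self, effects_2x3):
        row = np.array([1.0, -1.0, 0.0, -1.0, 1.0, 0.0])
        data = np.vstack([np.tile(row, (3, 1)), np.tile(-row, (3, 1))])
        reduced = reduce_rows(data, effects_2x3["B"])
        ssm, sse = stacked_regression(reduced, effects_2x3["B"])
        assert ssm == pytest.approx(0.0, abs=1e-12)

    def test_matches_normal_equations_oracle(self, rng, effects_2x3):
        """ss_model/ss_error agree with a direct least-squares fit of the
        stacked outcome on the replicated, centered coding columns."""
        data = rng.standard_normal((8, 6))
        eff = effects_2x3["B"]
        reduced = reduce_rows(data, eff)
        ssm, sse = stacked_regression(reduced, eff)
        y = reduced.ravel(order="F")
        X = np.repeat(eff.matrix.astype(float), 8, axis=0)
        y = y - y.mean()
        X = X - X.mean(axis=0)
        beta = np.linalg.solve(X.T @ X, X.T @ y)
        fitted = X @ beta
        assert ssm == pytest.approx(float(fitted @ fitted), rel=1e-10)
        assert sse == pytest.approx(float((y - fitted) @ (y - fitted)), rel=1e-10)
        assert ssm + sse == pytest.approx(float(y @ y), rel=1e-10)


class TestEpsilon:
    def test_equal_eigenvalues_give_one(self):
        eps, spec = epsilon_from_eigenvalues(np.array([2.0, 2.0]))
        assert eps == pytest.approx(1.0)
        assert spec.nonzero_count == 2

    def test_three_one_spectrum_gives_point_eight(self):
        eps, _ = epsilon_from_eigenvalues(np.array([3.0, 1.0]))
        assert eps == pytest.approx(0.8)

    def test_single_nonzero_eigenvalue_gives_one(self):
        eps, spec = epsilon_from_eigenvalues(np.array([5.0, 0.0, 0.0]))
        assert eps == pytest.approx(1.0)
        assert spec.nonzero_count == 1

    def test_constructed_covariance_spectrum(self):
        """A reduced matrix built to have covariance eigenvalues (3, 1)
        yields epsilon 0.8 through the full covariance path."""
        a = np.array([-1.5, -1.5, 1.5, 1.5])  # sample variance 3
        b = np.sqrt(3) / 2 * np.array([-1.0, 1.0, -1.0, 1.0])  # variance 1
        v1 = np.array([1.0, -1.0, 0.0]) / np.sqrt(2)
        v2 = np.array([1.0, 1.0, -2.0]) / np.sqrt(6)
        reduced = np.outer(a, v1) + np.outer(b, v2)
        eps, spec = gg_epsilon(reduced)
        assert eps == pytest.approx(0.8, abs=1e-10)
        assert spec.nonzero_count == 2

    def test_zero_matrix_degenerates_with_warning(self):
        with pytest.warns(UserWarning, match="degenerate"):
            eps, _ = gg_epsilon(np.zeros((4, 6)))
        assert eps == 1.0

    def test_epsilon_bounds_random_data(self, rng, effects_2x3):
        for _ in range(20):
            reduced = reduce_rows(rng.standard_normal((9, 6)), effects_2x3["B"])
            eps, spec = gg_epsilon(reduced)
            assert 1.0 / spec.nonzero_count - 1e-12 <= eps <= 1.0 + 1e-12


class TestFTest:
    def test_zero_error_flags_infinite_f(self):
        with pytest.warns(UserWarning, match="zero error"):
            F, p, pes = f_test(3.0, 0.0, 1, 9)
        assert np.isinf(F) and p == 0.0 and pes == 1.0

    def test_zero_model_ss(self):
        F, p, pes = f_test(0.0, 5.0, 2, 18)
        assert F == 0.0 and p == pytest.approx(1.0) and pes == 0.0

    def test_equal_mean_squares_give_f_one(self):
        F, _, _ = f_test(4.0, 4.0, 2.0, 2.0)
        assert F == pytest.approx(1.0)

    def test_epsilon_only_applied_beyond_one_df(self):
        _, p_single, _ = f_test(3.0, 6.0, 1, 9, epsilon=0.5)
        assert p_single == pytest.approx(float(stats.f.sf(4.5, 1, 9)))
        _, p_multi, _ = f_test(3.0, 6.0, 2, 18, epsilon=0.5)
        assert p_multi == pytest.approx(float(stats.f.sf(4.5, 1.0, 9.0)))


class TestWithinEffect:
    def test_two_level_factor_equals_paired_t(self, rng):
        """F of a 2-level factor equals the squared paired t between the two
        level means, and the p-values coincide."""
        design = Design((2, 3))
        eff = enumerate_effects(design)[0]
        data = rng.standard_normal((12, 6)) + rng.standard_normal((12, 1))
        res = within_effect_test(data, eff)
        t, p = stats.ttest_rel(data[:, 3:].mean(axis=1), data[:, :3].mean(axis=1))
        assert res.F == pytest.approx(t**2, abs=1e-10)
        assert res.p == pytest.approx(p, abs=1e-12)
        assert res.epsilon == 1.0
        assert res.df_model == 1 and res.df_error == 11

    def test_multilevel_factor_equals_classical_decomposition(self, rng):
        """F of a 4-level factor equals effect MS over effect-x-subject MS."""
        data = rng.standard_normal((9, 4))
        design = Design((4,))
        res = within_effect_test(data, enumerate_effects(design)[0])
        n, L = data.shape
        grand, colm, rowm = data.mean(), data.mean(0), data.mean(1)
        ss_a = n * ((colm - grand) ** 2).sum()
        ss_as = ((data - colm - rowm[:, None] + grand) ** 2).sum()
        F_classic = (ss_a / (L - 1)) / (ss_as / ((n - 1) * (L - 1)))
        assert res.F == pytest.approx(F_classic, rel=1e-10)
        assert res.df_model == 3 and res.df_error == 24

    def test_agrees_with_statsmodels_anovarm(self, rng):
        """Independent cross-check of the uncorrected F against AnovaRM."""
        import pandas as pd
        from statsmodels.stats.anova import AnovaRM

        data = rng.standard_normal((10, 3))
        res = within_effect_test(data, enumerate_effects(Design((3,)))[0])
        long = pd.DataFrame(
            {
                "s": np.repeat(np.arange(10), 3),
                "c": np.tile(np.arange(3), 10),
                "y": data.ravel(),
            }
        )
        table = AnovaRM(long, "y", "s", within=["c"]).fit().anova_table
        assert res.F == pytest.approx(float(table["F Value"].iloc[0]), rel=1e-8)

    def test_basis_invariance(self, rng, effects_2x3):
        """Any invertible recombination of an effect's contrast columns
        leaves F, p, epsilon and partial eta squared unchanged."""
        data = rng.standard_normal((10, 6))
        eff = effects_2x3["B"]
        T = np.array([[2.0, 1.0], [0.5, -1.0]])  # invertible
        recoded = EffectCoding(eff.factors, eff.matrix @ T, eff.column_labels, "B'")
        r1 = within_effect_test(data, eff)
        r2 = within_effect_test(data, recoded)
        assert r1.F == pytest.approx(r2.F, rel=1e-9)
        assert r1.p == pytest.approx(r2.p, rel=1e-9)
        assert r1.epsilon == pytest.approx(r2.epsilon, rel=1e-9)
        assert r1.partial_eta2 == pytest.approx(r2.partial_eta2, rel=1e-9)

    def test_orthogonal_perturbation_leaves_effect_unchanged(self, rng, effects_2x3):
        """Adding structure confined to another effect's contrast space does
        not move the tested effect's statistics."""
        data = rng.standard_normal((10, 6))
        r1 = within_effect_test(data, effects_2x3["B"])
        shifted = data + 3.0 * effects_2x3["A"].matrix[:, 0]  # pure A-space shift
        r2 = within_effect_test(shifted, effects_2x3["B"])
        assert r1.F == pytest.approx(r2.F, rel=1e-9)
        assert r1.ss_model == pytest.approx(r2.ss_model, rel=1e-9)

    def test_partial_eta2_identity(self, rng, effects_2x3):
        res = within_effect_test(rng.standard_normal((8, 6)), effects_2x3["A:B"])
        assert res.partial_eta2 == pytest.approx(
            res.ss_model / (res.ss_model + res.ss_error)
        )

    def test_missing_rows_dropped_with_warning(self, effects_2x3, rng):
        data = rng.standard_normal((5, 6))
        data[2, 4] = np.nan
        with pytest.warns(UserWarning, match="missing"):
            res = within_effect_test(data, effects_2x3["A"])
        assert res.df_error == 3  # 4 complete subjects

    def test_single_subject_rejected(self, effects_2x3):
        with pytest.raises(ValueError):
            within_effect_test(np.ones((1, 6)), effects_2x3["A"])


@settings(deadline=None, max_examples=25, derandomize=True)
@given(st.integers(min_value=0, max_value=10_000))
def test_f_t2_equivalence_property(seed):
    """For any 2-level one-factor dataset, F is exactly the squared paired t."""
    rng = np.random.default_rng(seed)
    data = rng.standard_normal((rng.integers(3, 15), 2))
    res = within_effect_test(data, enumerate_effects(Design((2,)))[0])
    t, _ = stats.ttest_rel(data[:, 1], data[:, 0])
    assert res.F == pytest.approx(t**2, abs=1e-9)
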