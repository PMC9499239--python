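import numpy as np
import pandas as pd
import pytest

from crosstalk.bootstrap import DifferentialEdge
from crosstalk.io import LigandTargetMatrix
from crosstalk.ltr import (
    LtrFit,
    LtrFold,
    autocrine_control,
    bn_ltr_agreement,
    build_design,
    condition_lfc,
    degenerate_fraction,
    fit_ltr,
    random_matrix_control,
    rank_ligands,
    run_ltr_pair,
)
from crosstalk.simulate import simulate_ligand_effect
from .conftest import make_expr


def planted_regression(rng, n_targets=200, n_ligands=20, n_active=3, noise=0.0):
    """Noiseless (or noisy) T = A @ alpha* with known sparse alpha*."""
    I = rng.uniform(0.2, 1.0, (n_targets, n_ligands)) * (
        rng.random((n_targets, n_ligands)) < 0.4
    )
    L = rng.normal(0, 1, n_ligands)
    alpha = np.zeros(n_ligands)
    idx = rng.choice(n_ligands, n_active, replace=False)
    alpha[idx] = rng.uniform(1, 2, n_active)
    A = pd.DataFrame(
        I * L,
        index=[f"t{i}" for i in range(n_targets)],
        columns=[f"l{j}" for j in range(n_ligands)],
    )
    T = pd.Series(A.to_numpy() @ alpha + noise * rng.normal(size=n_targets), index=A.index)
    return A, T, pd.Series(alpha, index=A.columns)


class TestConditionLfc:
    def test_closed_form(self):
        expr = make_expr({("s1", "a", "A"): 4, ("s2", "b", "A"): 4}, n_genes=1)
        expr.X[:4, 0] = 3.0
        expr.X[4:, 0] = 1.0
        lfc = condition_lfc(expr, "A", "a", "b", pseudocount=1.0)
        assert lfc.iloc[0] == pytest.approx(np.log(2))

    def test_identical_conditions_all_zero(self):
        expr = make_expr({("s1", "a", "A"): 3, ("s2", "b", "A"): 3}, n_genes=5)
        expr.X[3:] = expr.X[:3]
        lfc = condition_lfc(expr, "A", "a", "b")
        np.testing.assert_allclose(lfc.to_numpy(), 0.0, atol=1e-12)

    def test_doubling_one_condition_increases_lfc(self):
        expr = make_expr({("s1", "a", "A"): 3, ("s2", "b", "A"): 3}, n_genes=5, seed=2)
        base = condition_lfc(expr, "A", "a", "b")
        expr2 = expr.copy()
        expr2.X[expr2.obs["condition"] == "a"] *= 2.0
        boosted = condition_lfc(expr2, "A", "a", "b")
        assert (boosted >= base - 1e-12).all()

    def test_missing_cell_type_raises(self, tiny_expr):
        with pytest.raises(ValueError, match="absent"):
            condition_lfc(tiny_expr, "Z", "case", "control")


class TestBuildDesign:
    def test_identity_prior_gives_diagonal(self, identity_prior):
        L = pd.Series({"l1": 2.0, "l2": 3.0})
        A = build_design(identity_prior, L)
        np.testing.assert_allclose(A.to_numpy(), np.diag([2.0, 3.0]))

    def test_zero_expression_zero_design(self, identity_prior):
        A = build_design(identity_prior, pd.Series({"l1": 0.0, "l2": 0.0}))
        np.testing.assert_allclose(A.to_numpy(), 0.0)

    def test_matches_loop_oracle(self, rng):
        table = pd.DataFrame(
            rng.uniform(size=(5, 4)),
            index=[f"t{i}" for i in range(5)],
            columns=[f"l{j}" for j in range(4)],
        )
        prior = LigandTargetMatrix.from_frame(table)
        L = pd.Series(rng.normal(size=4), index=table.columns)
        A = build_design(prior, L)
        for t in table.index:
            for l in table.columns:
                assert A.loc[t, l] == pytest.approx(table.loc[t, l] * L[l])

    def test_empty_intersection_raises(self, identity_prior):
        with pytest.raises(ValueError, match="no ligand"):
            build_design(identity_prior, pd.Series({"other": 1.0}))


class TestFitLtr:
    def test_noiseless_recovery(self, rng):
        A, T, alpha = planted_regression(rng)
        fit = fit_ltr(A, T, seed=0)
        assert not fit.degenerate
        assert fit.mean_pearson >= 0.99
        support = set(alpha[alpha != 0].index)
        for fold in fit.folds:
            recovered = set(fold.alpha[fold.alpha.abs() > 1e-6].index)
            assert recovered >= support

    def test_agrees_with_reference_cv_lasso(self, rng):
        # independent route: sklearn's own cross-validated LASSO on the same
        # noiseless problem recovers the same active set
        from sklearn.linear_model import LassoCV

        A, T, alpha = planted_regression(rng, n_targets=120)
        ref = LassoCV(cv=5, random_state=0).fit(A.to_numpy(), T.to_numpy())
        ref_support = set(A.columns[np.abs(ref.coef_) > 1e-6])
        assert ref_support >= set(alpha[alpha != 0].index)
        ours = fit_ltr(A, T, seed=0)
        assert set().union(
            *[set(f.alpha[f.alpha.abs() > 1e-6].index) for f in ours.folds]
        ) >= set(alpha[alpha != 0].index)

    def test_shuffled_targets_near_zero_correlation(self, rng):
        A, T, _ = planted_regression(rng)
        T_shuffled = pd.Series(rng.permutation(T.to_numpy()), index=T.index)
        fit = fit_ltr(A, T_shuffled, seed=1)
        if not fit.degenerate and np.isfinite(fit.mean_pearson):
            assert abs(fit.mean_pearson) < 0.15

    def test_too_few_targets_raises(self, rng):
        A, T, _ = planted_regression(rng, n_targets=4)
        with pytest.raises(ValueError, match="fold"):
            fit_ltr(A, T.iloc[:4], n_folds=5)

    def test_shared_coefficient_prediction_contract(self, rng):
        # prediction of any target must be sum_l A[t,l]*alpha[l] + bias with
        # one alpha vector per fold, shared across targets
        A, T, _ = planted_regression(rng, n_targets=60)
        fit = fit_ltr(A, T, seed=2)
        fold = fit.folds[0]
        assert list(fold.alpha.index) == list(A.columns)


class TestRankLigands:
    def _fit(self, alphas):
        folds = tuple(
            LtrFold(alpha=pd.Series(a, index=["l1", "l2"]), lam=0.1, pearson=0.5)
            for a in alphas
        )
        return LtrFit(folds=folds, degenerate=all((np.array(a) == 0).all() for a in alphas))

    def test_single_fold_product(self):
        fit = self._fit([[1.0, 0.0]])
        L = pd.Series({"l1": 2.0, "l2": 5.0})
        ranking = rank_ligands(fit, L)
        assert ranking.iloc[0]["ligand"] == "l1"
        assert ranking.iloc[0]["score"] == pytest.approx(2.0)
        assert ranking.iloc[1]["score"] == pytest.approx(0.0)

    def test_constant_folds_equal_single_fold(self):
        L = pd.Series({"l1": 1.5, "l2": -2.0})
        one = rank_ligands(self._fit([[0.5, 1.0]]), L)
        five = rank_ligands(self._fit([[0.5, 1.0]] * 5), L)
        pd.testing.assert_frame_equal(one, five)

    def test_negative_lfc_positive_alpha_negative_score_ranked_by_magnitude(self):
        fit = self._fit([[1.0, 0.2]])
        L = pd.Series({"l1": -3.0, "l2": 1.0})
        ranking = rank_ligands(fit, L)
        assert ranking.iloc[0]["ligand"] == "l1"
        assert ranking.iloc[0]["score"] == pytest.approx(-3.0)

    def test_degenerate_fit_empty_ranking(self):
        fit = self._fit([[0.0, 0.0]])
        assert rank_ligands(fit, pd.Series({"l1": 1.0, "l2": 1.0})).empty


class TestControls:
    def test_paracrine_beats_autocrine_on_planted_effect(self):
        wins = 0
        for seed in range(3):
            expr, prior, alpha, info = simulate_ligand_effect(seed=seed)
            fit, _ = run_ltr_pair(
                expr, prior, info["sender"], info["receiver"],
                info["cond_a"], info["cond_b"], seed=seed,
            )
            auto, _ = autocrine_control(
                expr, prior, info["receiver"], info["cond_a"], info["cond_b"], seed=seed
            )
            para = fit.mean_pearson if not fit.degenerate else -1.0
            contra = auto.mean_pearson if not auto.degenerate else -1.0
            wins += para > contra
        assert wins >= 2

    def test_autocrine_wins_when_effect_is_autocrine(self):
        expr, prior, alpha, info = simulate_ligand_effect(seed=0, autocrine=True)
        fit, _ = run_ltr_pair(
            expr, prior, info["sender"], info["receiver"],
            info["cond_a"], info["cond_b"], seed=0,
        )
        auto, _ = autocrine_control(
            expr, prior, info["receiver"], info["cond_a"], info["cond_b"], seed=0
        )
        a = auto.mean_pearson if not auto.degenerate else -1.0
        p = fit.mean_pearson if not fit.degenerate else -1.0
        assert a > p

    def test_random_matrix_mostly_degenerate_on_planted_effect(self, rng):
        A, T, _ = planted_regression(rng)
        prior = LigandTargetMatrix.from_frame(
            pd.DataFrame(
                rng.uniform(0.2, 1.0, A.shape) * (rng.random(A.shape) < 0.4),
                index=A.index, columns=A.columns,
            )
        )
        L = pd.Series(rng.normal(size=A.shape[1]), index=A.columns)
        real_design = build_design(prior, L)
        T_real = pd.Series(
            real_design.to_numpy() @ np.r_[np.ones(3), np.zeros(A.shape[1] - 3)],
            index=A.index,
        )
        real_fit = fit_ltr(real_design, T_real, seed=0)
        assert not real_fit.degenerate
        shuffled = random_matrix_control(prior, T_real, L, n_shuffles=5, seed=0)
        assert degenerate_fraction(shuffled) >= 0.6

    def test_shuffling_constant_prior_is_noop(self, rng):
        table = pd.DataFrame(
            np.full((20, 3), 0.5), index=[f"t{i}" for i in range(20)],
            columns=["l1", "l2", "l3"],
        )
        prior = LigandTargetMatrix(table=table)
        L = pd.Series([1.0, -1.0, 0.5], index=table.columns)
        T = pd.Series(rng.normal(size=20), index=table.index)
        fits = random_matrix_control(prior, T, L, n_shuffles=2, seed=3)
        direct = fit_ltr(build_design(prior, L), T, seed=3)
        for f in fits:
            for fold, ref in zip(f.folds, direct.folds):
                pd.testing.assert_series_equal(fold.alpha, ref.alpha)

    def test_reproducible_with_fixed_seed(self, rng):
        A, T, _ = planted_regression(rng, n_targets=60)
        prior = LigandTargetMatrix(table=pd.DataFrame(
            rng.uniform(0.1, 1, A.shape), index=A.index, columns=A.columns))
        L = pd.Series(rng.normal(size=A.shape[1]), index=A.columns)
        a = random_matrix_control(prior, T, L, n_shuffles=2, seed=9)
        b = random_matrix_control(prior, T, L, n_shuffles=2, seed=9)
        for fa, fb in zip(a, b):
            for x, y in zip(fa.folds, fb.folds):
                pd.testing.assert_series_equal(x.alpha, y.alpha)


class TestAgreement:
    def _edges(self, counts):
        return [
            DifferentialEdge(pair=(f"A{i}", f"B{i}"), case_count=c, control_count=0)
            for i, c in enumerate(counts)
        ]

    def _fit(self, pearson):
        fold = LtrFold(alpha=pd.Series({"l": 1.0}), lam=0.1, pearson=pearson)
        return LtrFit(folds=(fold,), degenerate=False)

    def test_exact_linear_relation_gives_r_one(self):
        counts = [25, 40, 60, 90]
        edges = self._edges(counts)
        fits = {e.pair: self._fit(0.1 * np.log(c)) for e, c in zip(edges, counts)}
        table, r = bn_ltr_agreement(edges, fits)
        assert r == pytest.approx(1.0)

    def test_constant_y_flagged(self):
        edges = self._edges([25, 40, 60])
        fits = {e.pair: self._fit(0.5) for e in edges}
        table, r = bn_ltr_agreement(edges, fits)
        assert np.isnan(r) and table.attrs["correlation_flag"] == "zero variance"

    def test_too_few_pairs_flagged(self):
        edges = self._edges([25, 10])
        fits = {e.pair: self._fit(0.5) for e in edges}
        table, r = bn_ltr_agreement(edges, fits)
        assert np.isnan(r) and "fewer than 3" in table.attrs["correlation_flag"]

    def test_matches_closed_form_pearson(self, rng):
        counts = rng.integers(21, 100, 50)
        edges = self._edges(list(counts))
        ys = rng.normal(size=50)
        fits = {e.pair: self._fit(y) for e, y in zip(edges, ys)}
        table, r = bn_ltr_agreement(edges, fits)
        x = np.log(counts)
        expected = ((x - x.mean()) * (ys - ys.mean())).sum() / (
            np.sqrt(((x - x.mean()) ** 2).sum() * ((ys - ys.mean()) ** 2).sum())
        )
        assert r == pytest.approx(expected, abs=1e-12)
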