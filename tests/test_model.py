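"""SVR fitting, hyperparameter selection, permutation inference."""

import itertools

import numpy as np
import pytest

from svrlsm.lesions import expand_map
from svrlsm.model import (
    HyperParams,
    SvrLsm,
    beta_map,
    cv_mse,
    default_grid,
    fit_svr,
    make_folds,
    patch_inference,
    select_params,
    sensitivity_map,
    weighted_rbf_kernel,
)


@pytest.fixture
def toy_problem():
    rng = np.random.default_rng(11)
    X = (rng.random((24, 40)) < 0.35).astype(float)
    X[:, X.sum(0) == 0] = 1
    y = 1.0 - 0.8 * X[:, 0] * 0.6 - 0.1 * rng.random(24)
    y = (y - y.min()) / (y.max() - y.min())
    return X, y


class TestHyperParams:
    def test_bounds_enforced(self):
        with pytest.raises(ValueError):
            HyperParams(1e10, 1.0)
        with pytest.raises(ValueError):
            HyperParams(1.0, 1e-10)

    def test_default_grid_decade_steps(self):
        grid = default_grid()
        assert len(grid) == 12 * 13
        costs = sorted({hp.cost for hp in grid})
        assert costs[0] == pytest.approx(1e-2) and costs[-1] == pytest.approx(1e9)


class TestKernelEquivalence:
    def test_patch_kernel_equals_voxel_kernel(self, toy_matrix):
        """Multiplicity-weighted patch kernel == plain kernel on voxels."""
        lm, pm = toy_matrix
        for gamma in (1e-3, 1e-2, 0.1):
            Kv = weighted_rbf_kernel(lm.matrix.astype(float), gamma)
            Kp = weighted_rbf_kernel(
                pm.matrix.astype(float), gamma, pm.patch_sizes
            )
            assert np.abs(Kv - Kp).max() <= 1e-10

    def test_expanded_betas_equal_voxel_betas(self, toy_matrix):
        lm, pm = toy_matrix
        rng = np.random.default_rng(5)
        y = rng.random(lm.n_subjects)
        hp = HyperParams(10.0, 1e-2)
        bv = beta_map(fit_svr(lm.matrix.astype(float), y, hp), lm.matrix.astype(float))
        Xp = pm.matrix.astype(float)
        bp = beta_map(fit_svr(Xp, y, hp, multiplicities=pm.patch_sizes), Xp)
        expanded = expand_map(bp, pm, lm).reshape(-1)[lm.voxel_index]
        assert np.abs(bv - expanded).max() <= 1e-10


class TestFitSvr:
    def test_constant_y_rejected(self, toy_problem):
        X, _ = toy_problem
        with pytest.raises(ValueError, match="constant"):
            fit_svr(X, np.full(X.shape[0], 0.5), HyperParams(1, 0.01))

    def test_nonfinite_rejected(self, toy_problem):
        X, y = toy_problem
        y = y.copy()
        y[0] = np.nan
        with pytest.raises(ValueError):
            fit_svr(X, y, HyperParams(1, 0.01))

    def test_training_error_decreases_with_cost(self, toy_problem):
        """More cost = less regularization = better training fit."""
        from sklearn.svm import SVR

        X, y = toy_problem
        mses = []
        for c in (0.1, 10.0, 1000.0):
            hp = HyperParams(c, 1e-2, epsilon=0.01)
            K = weighted_rbf_kernel(X, hp.gamma)
            svr = SVR(kernel="precomputed", C=hp.cost, epsilon=hp.epsilon)
            svr.fit(K, y)
            mses.append(np.mean((svr.predict(K) - y) ** 2))
        assert mses[0] >= mses[1] >= mses[2]

    def test_sign_coherence(self, toy_problem):
        """Negating y negates the beta map (epsilon-SVR symmetry)."""
        X, y = toy_problem
        hp = HyperParams(1.0, 1e-2)
        b_pos = beta_map(fit_svr(X, y, hp), X)
        b_neg = beta_map(fit_svr(X, -y, hp), X)
        scale = np.abs(b_pos).max()
        assert np.abs(b_pos + b_neg).max() <= 1e-3 * max(scale, 1.0) + 1e-6

    def test_single_support_vector_beta_is_lesion_row(self):
        from svrlsm.model import FittedSvr

        X = (np.random.default_rng(0).random((5, 7)) < 0.5).astype(float)
        f = FittedSvr(
            dual_coef=np.array([1.0]), support=np.array([2]),
            intercept=0.0, params=HyperParams(1, 0.01),
        )
        assert np.array_equal(beta_map(f, X), X[2])

    def test_linear_limit_matches_primal_weights(self):
        """At tiny gamma and large cost, back-projected betas track the
        primal weights of a linear SVR."""
        from sklearn.svm import SVR

        rng = np.random.default_rng(8)
        X = (rng.random((30, 40)) < 0.4).astype(float)
        y = 0.5 * X[:, :5].mean(1) + 0.25 + rng.normal(0, 0.02, 30)
        lin = SVR(kernel="linear", C=10, epsilon=0.01).fit(X, y)
        b = beta_map(fit_svr(X, y, HyperParams(1e6, 1e-6, 0.01)), X)
        assert np.corrcoef(b, lin.coef_.ravel())[0, 1] > 0.99

    def test_sensitivity_map_correlates_with_backprojection(self, toy_problem):
        X, y = toy_problem
        hp = HyperParams(10.0, 1e-2)
        f = fit_svr(X, y, hp)
        s = sensitivity_map(f, X)
        b = beta_map(f, X)
        assert np.corrcoef(s, b)[0, 1] > 0.5


class TestCvMse:
    def test_predictable_signal_gives_small_error(self):
        rng = np.random.default_rng(9)
        X = (rng.random((40, 10)) < 0.5).astype(float)
        y = 0.2 + 0.6 * X[:, 3]  # exactly determined by one patch
        mse = cv_mse(X, y, HyperParams(1e4, 0.05, epsilon=0.001), k=5, seed=0)
        assert mse < 0.01

    def test_leave_one_out_matches_direct_computation(self):
        rng = np.random.default_rng(10)
        X = (rng.random((8, 6)) < 0.5).astype(float)
        y = rng.random(8)
        hp = HyperParams(1.0, 0.1)
        folds = make_folds(8, 8, np.random.default_rng(0))
        got = cv_mse(X, y, hp, folds=folds)
        errs = []
        for train, test in folds:
            f = fit_svr(X[train], y[train], hp)
            K = weighted_rbf_kernel(X[test], hp.gamma, Y=X[train][f.support])
            pred = K @ f.dual_coef + f.intercept
            errs.append(np.mean((pred - y[test]) ** 2))
        assert got == pytest.approx(np.mean(errs), rel=1e-8)

    def test_k_exceeding_n_rejected(self, toy_problem):
        X, y = toy_problem
        with pytest.raises(ValueError):
            cv_mse(X, y, HyperParams(1, 0.01), k=X.shape[0] + 1)

    def test_duplicated_rows_tolerated(self):
        rng = np.random.default_rng(12)
        X = np.tile((rng.random((5, 8)) < 0.5).astype(float), (4, 1))
        y = rng.random(20)
        assert np.isfinite(cv_mse(X, y, HyperParams(1, 0.1), k=5, seed=1))


class TestSelectParams:
    def test_addone_formula_single_permutation(self, toy_problem):
        """With one permutation worse than the real fit, p = (1+0)/(1+1)."""
        X, y = toy_problem
        res = select_params(X, y, [HyperParams(10, 1e-2)], n_perm=1, seed=0)
        assert res.model_p in (0.5, 1.0)
        hp, mse, p = res.grid[0]
        assert p == res.model_p

    def test_perm_p_lower_bound(self, toy_problem):
        X, y = toy_problem
        res = select_params(X, y, [HyperParams(1, 1e-2)], n_perm=19, seed=0)
        assert all(p >= 1 / 20 for _, _, p in res.grid)

    def test_null_perm_p_near_uniform(self):
        """With y independent of X, a single pair's perm_p averages ~0.5."""
        rng = np.random.default_rng(13)
        ps = []
        for rep in range(30):
            X = (rng.random((20, 15)) < 0.4).astype(float)
            y = rng.random(20)
            res = select_params(X, y, [HyperParams(1, 1e-2)], n_perm=39, seed=rep)
            ps.append(res.model_p)
        assert abs(np.mean(ps) - 0.5) < 0.15

    def test_signal_detected(self, toy_problem):
        X, y = toy_problem
        grid = [HyperParams(c, g) for c in (1, 100) for g in (1e-3, 1e-1)]
        res = select_params(X, y, grid, n_perm=99, seed=3)
        assert res.model_p <= 0.05

    def test_deterministic_given_seed(self, toy_problem):
        X, y = toy_problem
        grid = [HyperParams(1, 1e-2), HyperParams(10, 1e-3)]
        a = select_params(X, y, grid, n_perm=29, seed=5)
        b = select_params(X, y, grid, n_perm=29, seed=5)
        assert a == b

    def test_tie_break_prefers_lower_cv_mse_then_smaller_params(self, toy_problem):
        X, y = toy_problem
        grid = [HyperParams(100, 1e-1), HyperParams(0.1, 1e-3)]
        res = select_params(X, y, grid, n_perm=9, seed=2)
        min_p = min(p for _, _, p in res.grid)
        tied = [(hp, mse) for hp, mse, p in res.grid if p == min_p]
        expected = min(tied, key=lambda t: (t[1], t[0].cost, t[0].gamma))[0]
        assert res.chosen == expected


class TestPatchInference:
    def test_positive_beta_never_significant(self, toy_problem):
        X, y = toy_problem
        res = patch_inference(X, y, HyperParams(10, 1e-2), n_perm=49, seed=1)
        assert not np.any(res.significant_patches & (res.patch_betas >= 0))
        assert np.all((res.patch_p > 0) & (res.patch_p <= 1))

    def test_matches_exhaustive_permutation_oracle(self):
        """At n=6 the Monte-Carlo p-values sit within 2 SE of the exact
        720-permutation values for every patch."""
        rng = np.random.default_rng(3)
        X = (rng.random((6, 12)) < 0.5).astype(float)
        X = X[:, X.sum(0) > 0]
        y = rng.random(6)
        hp = HyperParams(1.0, 0.1)
        from svrlsm.model import weighted_rbf_kernel as kern

        K = kern(X, hp.gamma)
        obs = beta_map(fit_svr(X, y, hp, kernel=K), X)
        count = np.zeros(X.shape[1])
        for p in itertools.permutations(range(6)):
            b = beta_map(fit_svr(X, y[list(p)], hp, kernel=K), X)
            count += b <= obs
        exact = count / 720
        n_mc = 500
        res = patch_inference(X, y, hp, n_perm=n_mc, seed=7)
        se = np.sqrt(exact * (1 - exact) / n_mc)
        # allow the add-one offset of the estimator on top of 2 SE
        assert np.all(np.abs(res.patch_p - exact) <= 2 * se + 2 / (n_mc + 1))

    def test_fdr_mode_is_no_less_strict(self, toy_problem):
        X, y = toy_problem
        hp = HyperParams(10, 1e-2)
        plain = patch_inference(X, y, hp, n_perm=99, seed=2)
        fdr = patch_inference(X, y, hp, n_perm=99, seed=2, fdr=True)
        assert np.array_equal(plain.patch_p, fdr.patch_p)
        assert np.all(fdr.significant_patches <= plain.significant_patches)

    def test_deterministic_and_reused_permutations(self, toy_problem):
        X, y = toy_problem
        hp = HyperParams(1, 1e-2)
        a = patch_inference(X, y, hp, n_perm=29, seed=4)
        b = patch_inference(X, y, hp, n_perm=29, seed=4)
        assert np.array_equal(a.patch_p, b.patch_p)
        c = patch_inference(X, y, hp, n_perm=29, seed=99)
        assert not np.array_equal(a.patch_p, c.patch_p)


class TestModelObject:
    def test_fit_with_fixed_params_matches_functions(self, toy_matrix):
        lm, pm = toy_matrix
        rng = np.random.default_rng(21)
        y = rng.random(lm.n_subjects)
        hp = HyperParams(1, 1e-2)
        model = SvrLsm(y, pm, lesion_matrix=lm)
        res = model.fit(params=hp, n_perm=19, seed=6)
        direct = patch_inference(
            pm.matrix.astype(float), y, hp, n_perm=19, seed=6,
            multiplicities=pm.patch_sizes,
        )
        assert np.array_equal(res.patch_p, direct.patch_p)
        assert np.array_equal(res.patch_betas, direct.patch_betas)

    def test_summary_reports_key_facts(self, toy_matrix):
        lm, pm = toy_matrix
        y = np.random.default_rng(22).random(lm.n_subjects)
        res = SvrLsm(y, pm, lesion_matrix=lm).fit(
            params=HyperParams(1, 1e-2), n_perm=19, seed=0
        )
        text = res.summary()
        assert "gamma" in text and "significant patches" in text

    def test_volumes_have_grid_shape(self, toy_matrix):
        lm, pm = toy_matrix
        y = np.random.default_rng(23).random(lm.n_subjects)
        res = SvrLsm(y, pm, lesion_matrix=lm).fit(
            params=HyperParams(1, 1e-2), n_perm=19, seed=0
        )
        assert res.beta_volume().shape == lm.grid_shape
        assert res.p_volume().shape == lm.grid_shape
        sig = res.significance_volume()
        assert set(np.unique(sig)) <= {0.0, 1.0}
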