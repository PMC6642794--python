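"""FSMKL: ranking, grouping, kernel enumeration, the SVR dual, the
SimpleMKL loop and feature importance — each against an independent oracle
where the contract admits one."""

import numpy as np
import pytest
from scipy.optimize import minimize

from viscomp import fsmkl
from viscomp.fsmkl import (
    DEFAULT_KERNEL_BANK,
    CandidateKernel,
    FSMKLConfig,
    KernelSpec,
    compute_gram,
    enumerate_subset_kernels,
    feature_importance,
    filter_rank,
    fit_simplemkl,
    fsmkl_select,
    group_features,
    predict,
    svr_dual_solve,
)


# --------------------------------------------------------------------------
# oracles
# --------------------------------------------------------------------------

def svr_dual_qp_oracle(K, y, C, epsilon):
    """Brute-force solution of the epsilon-SVR dual by generic constrained
    optimization over (alpha+, alpha-)."""
    n = len(y)

    def neg_obj(z):
        ap, am = z[:n], z[n:]
        a = ap - am
        return 0.5 * a @ K @ a + epsilon * (ap + am).sum() - y @ a

    cons = [{"type": "eq", "fun": lambda z: np.sum(z[:n] - z[n:])}]
    bounds = [(0, C)] * (2 * n)
    best = None
    for start in (np.zeros(2 * n), np.full(2 * n, C / 4)):
        res = minimize(neg_obj, start, bounds=bounds, constraints=cons,
                       method="SLSQP", options={"maxiter": 2000, "ftol": 1e-14})
        if best is None or res.fun < best.fun:
            best = res
    alpha = best.x[:n] - best.x[n:]
    return alpha, -best.fun


def mkl_objective(grams, y, d, C, epsilon):
    K = np.tensordot(d, grams, axes=1)
    alpha, _ = svr_dual_solve(K, y, C, epsilon)
    return (-0.5 * alpha @ K @ alpha - epsilon * np.abs(alpha).sum()
            + y @ alpha)


# --------------------------------------------------------------------------
# ranking and grouping
# --------------------------------------------------------------------------

class TestRanking:
    def test_target_copy_ranked_first(self, rng):
        X = rng.standard_normal((50, 4))
        y = X[:, 2].copy()
        assert filter_rank(X, y)[0] == 2

    def test_ranking_is_complete_permutation(self, rng):
        X = rng.standard_normal((40, 7))
        y = rng.permutation(40).astype(float)
        assert sorted(filter_rank(X, y)) == list(range(7))

    def test_planted_correlation_order_recovered(self):
        """Columns with planted correlations 0.9/0.5/0.1/0/0 must rank in
        that order (oracle = the correlations themselves)."""
        rng = np.random.default_rng(0)
        n = 4000
        y = rng.standard_normal(n)
        strengths = [0.9, 0.5, 0.1, 0.0, 0.0]
        X = np.column_stack([
            r * y + np.sqrt(1 - r * r) * rng.standard_normal(n)
            for r in strengths])
        order = filter_rank(X, y)
        assert list(order[:3]) == [0, 1, 2]

    def test_constant_feature_ranks_last(self, rng):
        X = rng.standard_normal((50, 3))
        X[:, 1] = 7.0
        y = X[:, 0] + 0.1 * rng.standard_normal(50)
        assert filter_rank(X, y)[-1] == 1

    def test_too_few_samples_error(self):
        with pytest.raises(ValueError):
            filter_rank(np.zeros((2, 3)), np.zeros(2))


class TestGrouping:
    def test_recovers_planted_blocks(self):
        """Two |r|~0.95 blocks, zero across: complete linkage at rho=0.8
        must return exactly the planted partition (oracle: by construction
        this equals connected components of the thresholded graph)."""
        rng = np.random.default_rng(1)
        n = 500
        z1, z2 = rng.standard_normal((2, n))
        X = np.column_stack(
            [z1 + 0.2 * rng.standard_normal(n) for _ in range(3)]
            + [z2 + 0.2 * rng.standard_normal(n) for _ in range(3)])
        groups = group_features(X, rho=0.8)
        assert sorted(map(sorted, groups)) == [[0, 1, 2], [3, 4, 5]]

    def test_independent_features_stay_singletons(self, rng):
        X = rng.standard_normal((300, 5))
        groups = group_features(X, rho=0.8)
        assert sorted(map(sorted, groups)) == [[0], [1], [2], [3], [4]]

    def test_identical_features_one_group(self, rng):
        x = rng.standard_normal(100)
        X = np.column_stack([x, x, -x])  # |corr| = 1 throughout
        assert group_features(X, rho=0.8) == [[0, 1, 2]]

    def test_partition_property(self, rng):
        X = rng.standard_normal((60, 12))
        groups = group_features(X, rho=0.5)
        flat = sorted(f for g in groups for f in g)
        assert flat == list(range(12))


class TestEnumeration:
    def test_candidate_count_formula(self):
        ranking = np.arange(4)
        cands = enumerate_subset_kernels([[0, 1, 2, 3]], ranking,
                                         DEFAULT_KERNEL_BANK)
        assert len(cands) == 3 * 11  # subsets of size 2,3,4 x 11 specs

    def test_mixed_group_sizes(self):
        groups = [[0, 1, 2, 3, 4], [5, 6, 7], [8, 9]]
        specs = [KernelSpec("gaussian", sigma=1.0),
                 KernelSpec("polynomial", degree=2)]
        cands = enumerate_subset_kernels(groups, np.arange(10), specs)
        assert len(cands) == (4 + 2 + 1) * 2

    def test_singletons_contribute_nothing(self):
        cands = enumerate_subset_kernels([[0], [1]], np.arange(2),
                                         DEFAULT_KERNEL_BANK)
        assert cands == []

    def test_subsets_nested_by_rank(self):
        ranking = np.array([3, 1, 0, 2])  # rank order: 3 best
        cands = enumerate_subset_kernels([[0, 1, 2, 3]], ranking,
                                         [KernelSpec("gaussian", sigma=1.0)])
        subsets = [c.subset for c in cands]
        assert subsets == [(3, 1), (3, 1, 0), (3, 1, 0, 2)]

    def test_empty_spec_list_error(self):
        with pytest.raises(ValueError):
            enumerate_subset_kernels([[0, 1]], np.arange(2), [])


# --------------------------------------------------------------------------
# gram computation
# --------------------------------------------------------------------------

class TestGram:
    def test_gaussian_unit_diagonal(self, rng):
        X = rng.standard_normal((10, 4))
        K, dm = compute_gram(X, (0, 2), KernelSpec("gaussian", sigma=0.5))
        assert np.allclose(np.diag(K), 1.0)
        assert dm == pytest.approx(1.0)

    def test_polynomial_degree_one_formula(self, rng):
        X = rng.standard_normal((8, 3))
        K, dm = compute_gram(X, (1,) * 0 + (1, 2), KernelSpec("polynomial", degree=1))
        raw = X[:, [1, 2]] @ X[:, [1, 2]].T + 1.0
        assert np.allclose(K * dm, raw)

    def test_duplicate_rows_equal_entries(self, rng):
        X = rng.standard_normal((6, 3))
        X[3] = X[1]
        K, _ = compute_gram(X, (0, 1, 2), KernelSpec("gaussian", sigma=1.0))
        assert K[1, 1] == pytest.approx(K[1, 3])
        assert K[3, 3] == pytest.approx(K[1, 3])

    def test_psd_and_symmetric(self, rng):
        X = rng.standard_normal((15, 5))
        for spec in DEFAULT_KERNEL_BANK:
            K, _ = compute_gram(X, (0, 1, 3), spec)
            assert np.allclose(K, K.T, atol=1e-10)
            w = np.linalg.eigvalsh(K)
            assert w.min() > -1e-8

    def test_bank_grams_match_direct_computation(self, rng):
        """The incremental prefix-sharing path must equal per-candidate
        direct evaluation."""
        X = rng.standard_normal((12, 6))
        groups = [[0, 1, 2, 3], [4, 5]]
        cands = enumerate_subset_kernels(groups, np.arange(6),
                                         DEFAULT_KERNEL_BANK)
        grams, dms = fsmkl._bank_grams(X, X, cands)
        for m, c in enumerate(cands):
            K, dm = compute_gram(X, c.subset, c.spec)
            assert np.allclose(grams[m], K, atol=1e-10)
            assert dms[m] == pytest.approx(dm)


# --------------------------------------------------------------------------
# SVR dual
# --------------------------------------------------------------------------

class TestSVRDual:
    def test_constant_target_inside_tube(self):
        K = np.eye(5)
        alpha, b = svr_dual_solve(K, np.full(5, 2.0), C=1.0, epsilon=0.1)
        assert np.allclose(alpha, 0.0)
        assert b == pytest.approx(2.0, abs=0.1)

    def test_linear_data_matches_ols(self):
        """Linear kernel, large C, tiny epsilon: predictions must agree with
        the closed-form least-squares line."""
        x = np.array([0.0, 1.0, 2.0, 3.0])
        y = 2.0 * x + 1.0
        K = np.outer(x, x) + 1.0
        alpha, b = svr_dual_solve(K, y, C=1e4, epsilon=1e-6)
        pred = K @ alpha + b
        assert np.allclose(pred, y, atol=1e-3)

    @pytest.mark.parametrize("seed", [0, 1, 2])
    def test_matches_brute_force_qp(self, seed):
        """Tiny instances: dual objective must match a generic QP solution."""
        rng = np.random.default_rng(seed)
        n = 6
        X = rng.standard_normal((n, 2))
        K = X @ X.T + 1.0
        y = rng.standard_normal(n)
        C, eps = 2.0, 0.05
        alpha, b = svr_dual_solve(K, y, C, eps)
        obj = (-0.5 * alpha @ K @ alpha - eps * np.abs(alpha).sum() + y @ alpha)
        _, obj_oracle = svr_dual_qp_oracle(K, y, C, eps)
        assert obj == pytest.approx(obj_oracle, abs=1e-6)
        assert np.all(np.abs(alpha) <= C + 1e-8)
        assert abs(alpha.sum()) < 1e-6


# --------------------------------------------------------------------------
# SimpleMKL loop
# --------------------------------------------------------------------------

def _toy_kernels(rng, n=30, m=3):
    X = rng.standard_normal((n, 4))
    cands = []
    for i in range(m):
        subset = (i % 4, (i + 1) % 4)
        spec = KernelSpec("gaussian", sigma=0.5 + 0.5 * i)
        K, dm = compute_gram(X, subset, spec)
        cands.append(CandidateKernel(subset=subset, spec=spec, gram=K,
                                     diag_mean=dm))
    return X, cands


class TestSimpleMKL:
    def test_single_kernel_equivalent_to_svr(self, rng):
        X, cands = _toy_kernels(rng, m=1)
        y = rng.standard_normal(30)
        sol = fit_simplemkl(cands[:1], y, C=5.0, epsilon=0.01)
        assert sol.weights == pytest.approx([1.0])
        alpha, b = svr_dual_solve(cands[0].gram, y, C=5.0, epsilon=0.01)
        pred_mkl = predict(sol, np.stack([cands[0].gram]))
        assert np.allclose(pred_mkl, cands[0].gram @ alpha + b, atol=1e-8)

    def test_two_identical_kernels_match_single(self, rng):
        X, cands = _toy_kernels(rng, m=1)
        y = rng.standard_normal(30)
        twin = CandidateKernel(subset=cands[0].subset, spec=cands[0].spec,
                               gram=cands[0].gram.copy(),
                               diag_mean=cands[0].diag_mean)
        sol2 = fit_simplemkl([cands[0], twin], y, C=5.0, epsilon=0.01)
        sol1 = fit_simplemkl(cands[:1], y, C=5.0, epsilon=0.01)
        K = np.stack([cands[0].gram, twin.gram])
        assert np.allclose(predict(sol2, K),
                           predict(sol1, K[:1]), atol=1e-6)

    def test_signal_kernel_dominates_noise_kernel(self):
        """y generated through kernel 1; its weight must exceed 0.9 (oracle:
        a simplex grid search agrees the signal kernel wins)."""
        rng = np.random.default_rng(3)
        n = 40
        X = rng.standard_normal((n, 4))
        Ksig, dm1 = compute_gram(X, (0, 1), KernelSpec("gaussian", sigma=1.0))
        Knoise, dm2 = compute_gram(rng.standard_normal((n, 4)), (2, 3),
                                   KernelSpec("gaussian", sigma=1.0))
        coef = rng.standard_normal(n)
        y = Ksig @ coef
        y = (y - y.mean()) / y.std()
        cands = [CandidateKernel((0, 1), KernelSpec("gaussian", sigma=1.0),
                                 Ksig, dm1),
                 CandidateKernel((2, 3), KernelSpec("gaussian", sigma=1.0),
                                 Knoise, dm2)]
        sol = fit_simplemkl(cands, y, C=10.0, epsilon=0.01)
        assert sol.weights[0] > 0.9
        # oracle: grid over the simplex prefers d_1 ~ 1 as well
        grams = np.stack([Ksig, Knoise])
        objs = [mkl_objective(grams, y, np.array([w, 1 - w]), 10.0, 0.01)
                for w in np.linspace(0, 1, 21)]
        assert np.argmin(objs) >= 18

    @pytest.mark.parametrize("seed", range(5))
    def test_simplex_and_monotonicity_invariants(self, seed):
        rng = np.random.default_rng(seed)
        X, cands = _toy_kernels(rng, m=3)
        y = rng.standard_normal(30)
        sol = fit_simplemkl(cands, y, C=5.0, epsilon=0.05)
        assert sol.weights.sum() == pytest.approx(1.0, abs=1e-8)
        assert np.all(sol.weights >= 0)
        assert np.all(np.diff(sol.trace) <= 1e-9)

    def test_small_instance_matches_simplex_grid_oracle(self):
        """n=6, m=2: the final objective must be within 1e-4 of the best
        simplex grid point (step 0.01) with exact inner solves."""
        rng = np.random.default_rng(7)
        n, C, eps = 6, 2.0, 0.05
        X = rng.standard_normal((n, 3))
        K1, d1 = compute_gram(X, (0, 1), KernelSpec("gaussian", sigma=1.0))
        K2, d2 = compute_gram(X, (1, 2), KernelSpec("polynomial", degree=2))
        y = rng.standard_normal(n)
        cands = [CandidateKernel((0, 1), KernelSpec("gaussian", sigma=1.0), K1, d1),
                 CandidateKernel((1, 2), KernelSpec("polynomial", degree=2), K2, d2)]
        sol = fit_simplemkl(cands, y, C=C, epsilon=eps, tol=1e-8, max_iter=500)
        grams = np.stack([K1, K2])
        grid = [mkl_objective(grams, y, np.array([w, 1 - w]), C, eps)
                for w in np.arange(0, 1.0001, 0.01)]
        assert sol.trace[-1] <= min(grid) + 1e-4

    def test_prediction_on_training_points(self, rng):
        X, cands = _toy_kernels(rng, m=2)
        y = rng.standard_normal(30)
        sol = fit_simplemkl(cands, y, C=5.0, epsilon=0.01)
        grams = np.stack([c.gram for c in cands])
        pred = predict(sol, grams)
        K = np.tensordot(sol.weights, grams, axes=1)
        assert np.allclose(pred, K @ sol.alpha + sol.bias, atol=1e-10)

    def test_misaligned_kernel_lists_error(self, rng):
        X, cands = _toy_kernels(rng, m=2)
        y = rng.standard_normal(30)
        sol = fit_simplemkl(cands, y, C=5.0, epsilon=0.01)
        with pytest.raises(ValueError):
            predict(sol, np.stack([cands[0].gram]))


# --------------------------------------------------------------------------
# importance and end-to-end
# --------------------------------------------------------------------------

class TestImportance:
    def _solution(self, weights, subsets):
        kernels = [CandidateKernel(s, KernelSpec("gaussian", sigma=1.0))
                   for s in subsets]
        sol = fsmkl.MKLSolution(weights=np.asarray(weights, float),
                                alpha=np.zeros(3), bias=0.0, C=1.0,
                                epsilon=0.1)
        return sol, kernels

    def test_single_kernel_table(self):
        sol, kernels = self._solution([1.0], [(0, 1)])
        table = feature_importance(sol, kernels, n_features=4)
        w = table.set_index("feature")["accumulated_weight"]
        assert w[0] == w[1] == 1.0
        assert w[2] == w[3] == 0.0

    def test_overlapping_subsets_arithmetic(self):
        sol, kernels = self._solution([0.6, 0.4], [(0, 1), (0, 2)])
        table = feature_importance(sol, kernels, n_features=3).set_index("feature")
        assert table.loc[0, "accumulated_weight"] == pytest.approx(1.0)
        assert table.loc[0, "kernel_count"] == 2
        assert table.loc[1, "accumulated_weight"] == pytest.approx(0.6)
        assert table.loc[2, "accumulated_weight"] == pytest.approx(0.4)

    @pytest.mark.parametrize("seed", range(3))
    def test_conservation_identity(self, seed):
        """Sum of accumulated weights = sum_m d_m |subset_m| over active
        kernels, exactly."""
        rng = np.random.default_rng(seed)
        subsets = [tuple(rng.choice(8, size=rng.integers(2, 5), replace=False))
                   for _ in range(5)]
        d = rng.dirichlet(np.ones(5))
        sol, kernels = self._solution(d, subsets)
        table = feature_importance(sol, kernels, n_features=8)
        lhs = table["accumulated_weight"].sum()
        rhs = sum(dm * len(s) for dm, s in zip(d, subsets)
                  if dm > sol.weight_floor)
        assert lhs == pytest.approx(rhs, abs=1e-12)


class TestEndToEnd:
    def test_recovery_on_planted_groups(self, small_table):
        X, y, truth = small_table
        model = fsmkl_select(X, y, FSMKLConfig())
        sel = set(model.selected_features_)
        planted = set(truth.informative_features)
        assert len(sel & planted) / len(planted) >= 0.8
        pred = model.predict(X)
        assert np.corrcoef(pred, y)[0, 1] ** 2 > 0.8

    def test_duplicate_columns_get_equal_importance(self, rng):
        n = 60
        z = rng.standard_normal(n)
        X = np.column_stack([z, z, rng.standard_normal(n)])
        y = z + 0.1 * rng.standard_normal(n)
        model = fsmkl_select(X, y, FSMKLConfig())
        imp = model.importance_.set_index("feature")["accumulated_weight"]
        assert imp[0] == pytest.approx(imp[1], rel=1e-6)

    def test_column_permutation_leaves_predictions_unchanged(self, rng):
        n = 80
        z = rng.standard_normal((n, 2))
        X = np.column_stack([z[:, 0], z[:, 0] + 0.1 * rng.standard_normal(n),
                             z[:, 1], z[:, 1] + 0.1 * rng.standard_normal(n)])
        y = z[:, 0] - z[:, 1] + 0.1 * rng.standard_normal(n)
        config = FSMKLConfig()
        model = fsmkl_select(X, y, config)
        perm = [2, 3, 0, 1]
        model_p = fsmkl_select(X[:, perm], y, config)
        Xnew = rng.standard_normal((10, 4)) * 0.5
        assert np.allclose(model.predict(Xnew), model_p.predict(Xnew[:, perm]),
                           atol=1e-6)

    def test_all_singletons_fails_loudly(self, rng):
        X = rng.standard_normal((50, 4))
        y = rng.standard_normal(50)
        with pytest.raises(ValueError, match="singleton"):
            fsmkl_select(X, y, FSMKLConfig(rho=0.999))

    def test_permuted_target_selection_is_chance_level(self, small_table):
        """With a permuted target the planted features get no preferential
        treatment: the overlap of the selected set with the planted set
        stays near the planted fraction of all features."""
        X, y, truth = small_table
        rng = np.random.default_rng(9)
        model = fsmkl_select(X, rng.permutation(y), FSMKLConfig())
        sel = np.zeros(X.shape[1], bool)
        sel[model.selected_features_] = True
        planted = np.zeros(X.shape[1], bool)
        planted[truth.informative_features] = True
        frac_in_planted = sel[planted].mean()
        frac_overall = sel.mean()
        assert abs(frac_in_planted - frac_overall) < 0.35
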