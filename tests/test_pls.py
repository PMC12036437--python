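import itertools

import numpy as np
import pytest
from sklearn.base import clone

from tnmpls.pls import (
    RegularizedPLS,
    deflate,
    fit_rpls,
    pls_svd_component,
    project_l1_ball_unit_sphere,
    rpls_component,
    select_lambda_connectivity,
    select_lambda_phenotype,
)


def centered(rng, n, p):
    A = rng.standard_normal((n, p))
    return A - A.mean(axis=0)


def rank1_data(rng, n, p, q, b_support=None):
    """Noiseless rank-1 two-block data with known loadings."""
    t = rng.standard_normal(n)
    t -= t.mean()
    a = rng.standard_normal(p)
    a /= np.linalg.norm(a)
    b = np.zeros(q)
    if b_support is None:
        b = rng.standard_normal(q)
    else:
        b[list(b_support)] = 1.0
    b /= np.linalg.norm(b)
    return np.outer(t, a), np.outer(t, b), a, b


class TestProjection:
    def test_inactive_constraint_returns_normalized(self, rng):
        z = rng.standard_normal(6)
        c = np.abs(z).sum() / np.linalg.norm(z) + 0.1
        w = project_l1_ball_unit_sphere(z, c)
        assert np.allclose(w, z / np.linalg.norm(z), atol=1e-12)

    def test_radius_one_is_one_hot_with_lowest_index_ties(self):
        w = project_l1_ball_unit_sphere(np.array([2.0, -3.0, 3.0, 1.0]), 1.0)
        assert np.array_equal(w, [0.0, -1.0, 0.0, 0.0])

    def test_matches_dense_grid_search_oracle(self):
        z = np.array([3.0, 1.0, 0.5])
        c = 1.2
        w = project_l1_ball_unit_sphere(z, c)
        # independent oracle: dense grid over the soft threshold
        best, best_obj = None, -np.inf
        for delta in np.linspace(0, np.abs(z).max() - 1e-9, 200001):
            s = np.sign(z) * np.maximum(np.abs(z) - delta, 0)
            nrm = np.linalg.norm(s)
            if nrm == 0:
                continue
            cand = s / nrm
            if np.abs(cand).sum() <= c and z @ cand > best_obj:
                best, best_obj = cand, z @ cand
        # the bisection may only beat the discretized oracle
        assert z @ w >= best_obj - 1e-6
        assert np.allclose(w, best, atol=1e-3)
        assert np.abs(w).sum() <= c + 1e-8
        assert np.linalg.norm(w) == pytest.approx(1.0, abs=1e-10)

    def test_zero_vector_rejected(self):
        with pytest.raises(ValueError, match="zero vector"):
            project_l1_ball_unit_sphere(np.zeros(3), 1.5)


class TestSVDComponent:
    def test_symmetric_case_gives_leading_eigenvector(self, rng):
        X = centered(rng, 12, 5)
        comp = pls_svd_component(X, X)
        eigval, eigvec = np.linalg.eigh(X.T @ X)
        lead = eigvec[:, -1]
        assert abs(comp.u @ lead) == pytest.approx(1.0, abs=1e-10)
        assert abs(comp.v @ lead) == pytest.approx(1.0, abs=1e-10)

    def test_rank1_recovery(self, rng):
        X, Y, a, b = rank1_data(rng, 20, 7, 4)
        comp = pls_svd_component(X, Y)
        assert abs(comp.u @ a) >= 1 - 1e-6
        assert abs(comp.v @ b) >= 1 - 1e-6

    def test_matches_full_svd_oracle(self, rng):
        for _ in range(10):
            X, Y = centered(rng, 8, 5), centered(rng, 8, 3)
            comp = pls_svd_component(X, Y)
            U, s, Vt = np.linalg.svd(X.T @ Y)
            assert abs(comp.u @ U[:, 0]) >= 1 - 1e-10
            assert abs(comp.v @ Vt[0]) >= 1 - 1e-10
            assert comp.covariance == pytest.approx(s[0], abs=1e-10)

    def test_zero_cross_covariance(self):
        X = np.array([[1.0], [-1.0]])
        Y = np.zeros((2, 2))
        with pytest.raises(ValueError, match="identically zero"):
            pls_svd_component(X, Y)


class TestRPLSComponent:
    def test_vacuous_constraints_reduce_to_svd(self, rng):
        for _ in range(5):
            X, Y = centered(rng, 10, 6), centered(rng, 10, 4)
            ref = pls_svd_component(X, Y)
            comp = rpls_component(X, Y, lambda_x=6, lambda_y=4)
            assert abs(comp.u @ ref.u) >= 1 - 1e-8
            assert abs(comp.v @ ref.v) >= 1 - 1e-8
            assert comp.covariance == pytest.approx(ref.covariance, abs=1e-8)

    def test_two_sparse_truth_recovered_vs_exhaustive_search(self, rng):
        X, Y, _, b = rank1_data(rng, 25, 10, 5, b_support=(1, 3))
        comp = rpls_component(X, Y, lambda_y=1.45)
        assert set(np.flatnonzero(comp.v)) == {1, 3}
        # oracle: best 2-subset under the constrained objective
        M = X.T @ Y
        best_obj, best_sub = -np.inf, None
        for sub in itertools.combinations(range(5), 2):
            v = np.zeros(5)
            z = np.linalg.svd(M[:, list(sub)])[2][0]
            v[list(sub)] = z
            if np.abs(v).sum() <= 1.45:
                u = M @ v
                nrm = np.linalg.norm(u)
                if nrm == 0:
                    continue
                u /= nrm
                if u @ M @ v > best_obj:
                    best_obj, best_sub = u @ M @ v, set(sub)
        assert set(np.flatnonzero(comp.v)) == best_sub

    def test_maximal_regularization_is_one_sparse(self, rng):
        X, Y = centered(rng, 12, 8), centered(rng, 12, 5)
        comp = rpls_component(X, Y, lambda_y=1.0)
        assert np.count_nonzero(comp.v) == 1

    def test_feasibility_and_unit_norms(self, rng):
        X, Y = centered(rng, 15, 10), centered(rng, 15, 6)
        comp = rpls_component(X, Y, lambda_x=2.5, lambda_y=1.8)
        assert np.linalg.norm(comp.u) == pytest.approx(1.0, abs=1e-10)
        assert np.linalg.norm(comp.v) == pytest.approx(1.0, abs=1e-10)
        assert np.abs(comp.u).sum() <= 2.5 + 1e-8
        assert np.abs(comp.v).sum() <= 1.8 + 1e-8
        assert comp.covariance >= 0

    def test_lambda_out_of_range(self, rng):
        X, Y = centered(rng, 10, 4), centered(rng, 10, 3)
        with pytest.raises(ValueError, match="lambda_phenotype"):
            rpls_component(X, Y, lambda_y=5.0)


class TestDeflation:
    def test_rank1_data_fully_removed(self, rng):
        X, Y, _, _ = rank1_data(rng, 15, 6, 4)
        comp = pls_svd_component(X, Y)
        Xr, Yr = deflate(X, Y, comp)
        assert np.linalg.norm(Xr) < 1e-8
        assert np.linalg.norm(Yr) < 1e-8

    def test_residual_orthogonal_to_scores(self, rng):
        X, Y = centered(rng, 12, 7), centered(rng, 12, 5)
        comp = pls_svd_component(X, Y)
        Xr, Yr = deflate(X, Y, comp)
        assert np.max(np.abs(Xr.T @ comp.x_scores)) < 1e-10
        assert np.max(np.abs(Yr.T @ comp.y_scores)) < 1e-10

    def test_second_orthogonal_factor_recovered(self, rng):
        n = 40
        t1, t2 = rng.standard_normal((2, n))
        t1 -= t1.mean()
        t2 -= t2.mean() + (t2 - t2.mean()) @ t1 / (t1 @ t1) * 0  # keep raw
        t2 = t2 - (t2 @ t1) / (t1 @ t1) * t1  # orthogonalize
        a1, a2 = np.eye(6)[0], np.eye(6)[3]
        b1, b2 = np.eye(4)[0], np.eye(4)[2]
        X = 3 * np.outer(t1, a1) + np.outer(t2, a2)
        Y = 3 * np.outer(t1, b1) + np.outer(t2, b2)
        c1 = pls_svd_component(X, Y)
        Xr, Yr = deflate(X, Y, c1)
        c2 = pls_svd_component(Xr, Yr)
        assert abs(c2.u @ a2) >= 0.999
        assert abs(c2.v @ b2) >= 0.999


class TestLambdaSelection:
    def test_already_sparse_solution_selects_top_of_grid(self, rng):
        X, Y, _, _ = rank1_data(rng, 20, 8, 5, b_support=(0, 2))
        lam, record = select_lambda_phenotype(X, Y, max_features=3,
                                              scale=False)
        assert lam == 5.0
        assert record["nnz_v1"].iloc[-1] <= 3

    def test_single_feature_cap_forces_lambda_one(self, rng):
        X = centered(rng, 20, 6)
        Y = centered(rng, 20, 4)
        lam, record = select_lambda_phenotype(X, Y, max_features=1,
                                              scale=False)
        above_one = record[record["lambda_phenotype"] > 1.0]
        if (above_one["nnz_v1"] >= 2).all():
            assert lam == 1.0

    def test_selection_consistent_with_grid_recount(self, cohort_domains):
        X, Y, _ = cohort_domains
        lam, record = select_lambda_phenotype(X, Y, max_features=3)
        ok = record[record["nnz_v1"] <= 3]
        assert lam == ok["lambda_phenotype"].max()
        comp_nnz = int(
            record.loc[record["lambda_phenotype"] == lam, "nnz_v1"].iloc[0]
        )
        model = fit_rpls(X, Y, n_components=1, lambda_phenotype=lam)
        assert np.count_nonzero(model.y_weights_[:, 0]) == comp_nnz

    def test_density_target_one_keeps_dense_solution(self, rng):
        X, Y = centered(rng, 20, 12), centered(rng, 20, 4)
        lam, record = select_lambda_connectivity(
            X, Y, target_density=1.0, n_grid=10, scale=False)
        # ties resolve to the smallest lambda achieving a dense solution
        selected = record.loc[
            record["lambda_connectivity"] == lam, "density_u1"].iloc[0]
        assert selected == 1.0
        assert record["density_u1"].iloc[-1] == 1.0

    def test_tiny_density_target_selects_near_maximal_sparsity(self, rng):
        X, Y = centered(rng, 20, 12), centered(rng, 20, 4)
        lam, record = select_lambda_connectivity(
            X, Y, target_density=1 / 12, n_grid=20, scale=False)
        dens = record.loc[
            record["lambda_connectivity"] == lam, "density_u1"].iloc[0]
        assert dens <= 2 / 12 + 1e-12


class TestEstimator:
    def test_single_component_percentage_is_100(self, rng):
        X, Y = rng.standard_normal((15, 6)), rng.standard_normal((15, 4))
        model = RegularizedPLS(n_components=1).fit(X, Y)
        assert np.allclose(model.covariance_percentages_, [100.0])

    def test_three_planted_factors_rank_by_strength(self, rng):
        n = 60
        T = rng.standard_normal((n, 3))
        T -= T.mean(axis=0)
        T, _ = np.linalg.qr(T)
        strengths = np.array([5.0, 3.0, 1.5])
        A = rng.standard_normal((3, 12))
        B = rng.standard_normal((3, 6))
        X = (T * strengths) @ A + 0.01 * rng.standard_normal((n, 12))
        Y = (T * strengths) @ B + 0.01 * rng.standard_normal((n, 6))
        model = RegularizedPLS(n_components=3, scale=False).fit(X, Y)
        assert np.all(np.diff(model.covariances_) < 0)
        assert model.covariance_percentages_[0] == 100.0

    def test_unregularized_scores_match_deflated_svd_oracle(self, rng):
        X, Y = rng.standard_normal((12, 8)), rng.standard_normal((12, 5))
        model = RegularizedPLS(n_components=3, scale=False).fit(X, Y)
        Xc = X - X.mean(axis=0)
        Yc = Y - Y.mean(axis=0)
        for k in range(3):
            s = np.linalg.svd(Xc.T @ Yc, compute_uv=False)[0]
            assert model.covariances_[k] == pytest.approx(s, abs=1e-8)
            comp = model.components_[k]
            Xc, Yc = deflate(Xc, Yc, comp)

    def test_score_orthogonality_across_components(self, cohort_domains):
        X, Y, _ = cohort_domains
        model = RegularizedPLS(n_components=3).fit(X, Y)
        for scores in (model.x_scores_, model.y_scores_):
            corr = np.corrcoef(scores, rowvar=False)
            off = corr - np.diag(np.diag(corr))
            assert np.max(np.abs(off)) < 1e-8

    def test_determinism_bitwise(self, cohort_domains):
        X, Y, _ = cohort_domains
        m1 = RegularizedPLS(n_components=2, lambda_phenotype=1.5).fit(X, Y)
        m2 = RegularizedPLS(n_components=2, lambda_phenotype=1.5).fit(X, Y)
        assert np.array_equal(m1.x_weights_, m2.x_weights_)
        assert np.array_equal(m1.y_weights_, m2.y_weights_)
        assert np.array_equal(m1.covariances_, m2.covariances_)

    def test_sign_convention_largest_phenotype_weight_positive(
        self, cohort_domains
    ):
        X, Y, _ = cohort_domains
        model = RegularizedPLS(n_components=2).fit(X, Y)
        for k in range(2):
            v = model.y_weights_[:, k]
            assert v[np.argmax(np.abs(v))] > 0

    def test_component_one_agrees_with_sklearn_plssvd(self, cohort_domains):
        from sklearn.cross_decomposition import PLSSVD

        X, Y, _ = cohort_domains
        model = RegularizedPLS(n_components=1).fit(X, Y)
        ref = PLSSVD(n_components=1).fit(X, Y)
        cos_u = abs(model.x_weights_[:, 0] @ ref.x_weights_[:, 0])
        cos_v = abs(model.y_weights_[:, 0] @ ref.y_weights_[:, 0])
        assert cos_u >= 1 - 1e-8
        assert cos_v >= 1 - 1e-8

    def test_sklearn_contract(self, rng):
        model = RegularizedPLS(n_components=2, lambda_phenotype=2.0)
        params = model.get_params()
        assert params["lambda_phenotype"] == 2.0
        cloned = clone(model)
        X, Y = rng.standard_normal((10, 5)), rng.standard_normal((10, 4))
        cloned.fit(X, Y)
        xs, ys = cloned.transform(X, Y)
        assert np.allclose(xs, cloned.x_scores_[:, :1] * 0 + xs)
        assert xs.shape == (10, 2) and ys.shape == (10, 2)
        # transform of the training data reproduces component-1 scores
        assert np.allclose(xs[:, 0], cloned.x_scores_[:, 0], atol=1e-10)

    def test_too_many_components_rejected(self, rng):
        X, Y = rng.standard_normal((6, 10)), rng.standard_normal((6, 3))
        with pytest.raises(ValueError, match="n_components"):
            RegularizedPLS(n_components=4).fit(X, Y)


class TestMonotonicity:
    def test_nnz_nondecreasing_in_lambda(self, rng):
        for _ in range(5):
            X = rng.standard_normal((15, 12))
            Y = rng.standard_normal((15, 6))
            _, record = select_lambda_phenotype(X, Y, scale=False)
            nnz = record["nnz_v1"].to_numpy()
            assert np.all(np.diff(nnz) >= 0)
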