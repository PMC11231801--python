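"""The sparse-CCA core: PMD solver, deflation, CV hygiene, inference."""

import numpy as np
import pytest
from hypothesis import given, settings, strategies as st

from fcsubtypes.latent import (
    LatentModel,
    SCCAHyperparams,
    ZeroDirectionError,
    bh_fdr,
    cv_select,
    fit_latent,
    fit_pca,
    fit_scca,
    impute_nps,
    permutation_test,
    pmd_rank1,
    support_recovery,
)
from fcsubtypes.synthetic import GeneratorConfig, generate_cohort, generate_null


def _standardized(x):
    return (x - x.mean(0)) / x.std(0, ddof=1)


class TestPCA:
    def test_two_planted_dimensions_selected(self, rng):
        n = 200
        z = rng.standard_normal((n, 2))
        load = np.zeros((2, 12))
        load[0, :4] = 3.0
        load[1, 4:8] = 3.0
        x = z @ load + 0.05 * rng.standard_normal((n, 12))
        model = fit_pca(x, variance_threshold=0.8)
        assert model.n_components == 2

    def test_full_rank_at_threshold_one(self, rng):
        x = rng.standard_normal((30, 12))
        model = fit_pca(x, variance_threshold=1.0 - 1e-12)
        assert model.n_components == 12

    def test_matches_eigendecomposition_oracle(self, rng):
        x = rng.standard_normal((20, 12))
        model = fit_pca(x, n_components=12)
        cov = np.cov(x, rowvar=False)
        w, v = np.linalg.eigh(cov)
        w, v = w[::-1], v[:, ::-1]
        np.testing.assert_allclose(
            model.explained_variance_ratio_, w / w.sum(), atol=1e-8
        )
        for k in range(12):
            cosine = abs(model.components_[k] @ v[:, k])
            assert cosine == pytest.approx(1.0, abs=1e-8)

    def test_scores_decorrelated(self, rng):
        x = rng.standard_normal((50, 12))
        model = fit_pca(x, n_components=5)
        scores = model.transform(x)
        c = np.cov(scores, rowvar=False)
        off = c - np.diag(np.diag(c))
        assert np.abs(off).max() < 1e-10

    def test_threshold_validation(self, rng):
        with pytest.raises(ValueError):
            fit_pca(rng.standard_normal((10, 4)), variance_threshold=1.5)

    def test_missing_entries_rejected_and_imputed(self):
        x = np.array([[1.0, np.nan], [2.0, 3.0], [0.0, 1.0]])
        with pytest.raises(ValueError, match="impute"):
            fit_pca(x, n_components=1)
        filled, count = impute_nps(x, "zero")
        assert count == 1 and filled[0, 1] == 0.0
        filled, _ = impute_nps(x, "median")
        assert filled[0, 1] == 2.0


class TestPMDRank1:
    def test_unpenalized_limit_is_svd(self):
        for s in range(10):
            rng = np.random.default_rng(s)
            c = rng.standard_normal((20, 6))
            res = pmd_rank1(c, np.sqrt(20), np.sqrt(6))
            d1 = np.linalg.svd(c, compute_uv=False)[0]
            assert res.d == pytest.approx(d1, abs=1e-6)

    def test_maximal_sparsity_one_hot(self):
        c = np.full((4, 3), 0.01)
        c[2, 1] = 5.0
        res = pmd_rank1(c, 1.0, 1.0)
        assert np.flatnonzero(np.abs(res.u) > 1e-8).tolist() == [2]
        assert np.flatnonzero(np.abs(res.v) > 1e-8).tolist() == [1]
        assert res.d == pytest.approx(5.0, rel=1e-3)

    def test_constraints_satisfied(self, rng):
        c = rng.standard_normal((15, 5))
        res = pmd_rank1(c, 2.0, 1.5)
        assert np.linalg.norm(res.u) <= 1 + 1e-8
        assert np.linalg.norm(res.v) <= 1 + 1e-8
        assert np.abs(res.u).sum() <= 2.0 + 1e-6
        assert np.abs(res.v).sum() <= 1.5 + 1e-6
        assert res.d >= 0

    @settings(deadline=None, max_examples=30)
    @given(st.integers(0, 10_000))
    def test_objective_ascends(self, seed):
        rng = np.random.default_rng(seed)
        p, q = int(rng.integers(3, 20)), int(rng.integers(2, 8))
        c = rng.standard_normal((p, q))
        c1 = float(rng.uniform(1.0, np.sqrt(p)))
        c2 = float(rng.uniform(1.0, np.sqrt(q)))
        res = pmd_rank1(c, c1, c2)
        assert np.all(np.diff(res.objective_trace) >= -1e-9)

    def test_zero_matrix_rejected(self):
        with pytest.raises(ZeroDirectionError):
            pmd_rank1(np.zeros((4, 3)), 1.5, 1.2)

    def test_penalty_bounds_validated(self, rng):
        c = rng.standard_normal((4, 3))
        with pytest.raises(ValueError):
            pmd_rank1(c, 0.5, 1.2)
        with pytest.raises(ValueError):
            pmd_rank1(c, 1.5, 5.0)


class TestFitSCCA:
    def test_penalties_one_matches_top2_svd(self, rng):
        x = rng.standard_normal((60, 12))
        y = rng.standard_normal((60, 5))
        hp = SCCAHyperparams(penalty_x=1.0, penalty_y=1.0, n_components=2, n_pcs=5)
        m = fit_scca(x, y, hp)
        c = _standardized(x).T @ _standardized(y)
        sv = np.linalg.svd(c, compute_uv=False)
        np.testing.assert_allclose(m.d, sv[:2], atol=1e-6)
        assert m.r[0] >= m.r[1]

    def test_sparsity_monotone_in_penalty(self, rng):
        x = rng.standard_normal((50, 40))
        y = rng.standard_normal((50, 6))
        nnz = []
        for pen in [1.0, 0.9, 0.8, 0.7, 0.6, 0.5, 0.4, 0.3, 0.2, 0.1]:
            hp = SCCAHyperparams(penalty_x=pen, penalty_y=1.0,
                                 n_components=1, n_pcs=6)
            m = fit_scca(x, y, hp)
            nnz.append(int((np.abs(m.u[:, 0]) > 1e-12).sum()))
        assert all(a >= b for a, b in zip(nnz, nnz[1:]))

    def test_covariance_accounting(self, benchmark_cohort):
        c = benchmark_cohort
        hp = SCCAHyperparams(0.6, 0.6, n_components=4, n_pcs=7)
        m = fit_latent(c.edges, c.nps, hp).scca
        assert m.cov_explained.sum() == pytest.approx(1.0)
        assert np.all(m.d >= 0)
        assert np.all(np.diff(m.d) <= 1e-8)  # deflation removes the leading part

    def test_too_many_components_rejected(self, rng):
        x, y = rng.standard_normal((30, 10)), rng.standard_normal((30, 3))
        with pytest.raises(ValueError, match="n_components"):
            fit_scca(x, y, SCCAHyperparams(1.0, 1.0, n_components=4, n_pcs=3))

    def test_orientation_rule(self, benchmark_cohort):
        c = benchmark_cohort
        hp = SCCAHyperparams(0.6, 0.6, 2, 7)
        m = fit_latent(c.edges, c.nps, hp).scca
        for k in range(m.n_components):
            j = np.argmax(np.abs(m.v[:, k]))
            assert m.v[j, k] > 0

    def test_planted_support_recovered(self, benchmark_cohort):
        c = benchmark_cohort
        hp = SCCAHyperparams(0.6, 0.6, 2, 7)
        m = fit_latent(c.edges, c.nps, hp).scca
        recall, precision = support_recovery(m.u[:, 0], c.true_edge_weights[0])
        assert recall >= 0.8 and precision >= 0.8


class TestTransform:
    def test_training_scores_reproduced_exactly(self, small_cohort):
        c = small_cohort
        hp = SCCAHyperparams(0.7, 0.7, 2, 5)
        model = fit_latent(c.edges, c.nps, hp)
        xs1, ys1 = model.transform(c.edges, c.nps)
        xs2, ys2 = model.transform(c.edges, c.nps)
        assert np.array_equal(xs1, xs2) and np.array_equal(ys1, ys2)
        fit_scores = ((c.edges - model.scca.x_mean) / model.scca.x_scale) @ model.scca.u
        np.testing.assert_array_equal(xs1, fit_scores)

    def test_centered_zero_vector_maps_to_zero(self, small_cohort):
        c = small_cohort
        model = fit_latent(c.edges, c.nps, SCCAHyperparams(0.7, 0.7, 1, 5))
        xs, _ = model.transform(model.scca.x_mean[None, :], c.nps[:1])
        np.testing.assert_allclose(xs, 0.0, atol=1e-12)

    def test_dimension_mismatch_reported(self, small_cohort):
        c = small_cohort
        model = fit_latent(c.edges, c.nps, SCCAHyperparams(0.7, 0.7, 1, 5))
        with pytest.raises(ValueError, match="expected"):
            model.scca.transform_x(c.edges[:, :10])

    def test_heldout_recovery_of_true_latent(self, benchmark_cohort):
        c = benchmark_cohort
        hp = SCCAHyperparams(0.6, 0.6, 2, 7)
        model = fit_latent(c.edges, c.nps, hp)
        rep = generate_cohort(c.config, replicate_seed=4242)
        xs, _ = model.transform(rep.edges, rep.nps)
        r = abs(np.corrcoef(xs[:, 0], rep.true_latent[:, 0])[0, 1])
        assert r > 0.4

    def test_json_round_trip(self, small_cohort):
        c = small_cohort
        model = fit_latent(c.edges, c.nps, SCCAHyperparams(0.7, 0.7, 2, 5))
        clone = LatentModel.from_json(model.to_json())
        xs1, ys1 = model.transform(c.edges, c.nps)
        xs2, ys2 = clone.transform(c.edges, c.nps)
        np.testing.assert_allclose(xs1, xs2, atol=1e-12)
        np.testing.assert_allclose(ys1, ys2, atol=1e-12)


class TestCVSelect:
    def test_single_point_grid_returned(self, small_cohort):
        c = small_cohort
        cv = cv_select(c.edges, c.nps, n_pcs_grid=(5,), penalty_grid=(0.6,),
                       n_folds=5, seed=0)
        assert cv.best_n_pcs == 5 and cv.best_penalty == 0.6
        assert len(cv.table) == 5  # folds x 1 grid point x 1 component

    def test_pure_noise_selects_near_zero_correlation(self):
        vals = []
        for s in range(8):
            x, y = generate_null(80, 60, 12, seed=s)
            cv = cv_select(x, y, n_pcs_grid=(5,), penalty_grid=(0.6,),
                           n_folds=5, seed=s)
            vals.append(cv.means["mean_r"].iloc[0])
        assert abs(np.mean(vals)) < 0.1

    def test_fold_size_floor(self, rng):
        x, y = rng.standard_normal((12, 8)), rng.standard_normal((12, 4))
        with pytest.raises(ValueError, match="fewer than 3"):
            cv_select(x, y, n_pcs_grid=(2,), penalty_grid=(0.8,), n_folds=6)

    def test_no_leakage_from_heldout_fold(self, small_cohort):
        # corrupting the held-out fold's rows must not change the model
        # fitted for that fold (it trains on the other folds only)
        c = small_cohort
        kwargs = dict(n_pcs_grid=(5,), penalty_grid=(0.6,), n_folds=4,
                      seed=3, return_models=True)
        cv1 = cv_select(c.edges, c.nps, **kwargs)
        from sklearn.model_selection import KFold

        folds = list(KFold(4, shuffle=True, random_state=3).split(c.edges))
        test0 = folds[0][1]
        edges2 = c.edges.copy()
        nps2 = c.nps.astype(float).copy()
        edges2[test0] = 1e6 * np.sign(edges2[test0] + 0.1)
        nps2[test0] = 3.0
        cv2 = cv_select(edges2, nps2, **kwargs)
        m1 = cv1.fold_models[0]["model"]
        m2 = cv2.fold_models[0]["model"]
        np.testing.assert_array_equal(m1.scca.u, m2.scca.u)
        np.testing.assert_array_equal(m1.pca.components_, m2.pca.components_)


class TestPermutation:
    def test_add_one_formula_extremes(self, rng):
        x = rng.standard_normal((30, 8))
        y = x[:, :3] + 0.01 * rng.standard_normal((30, 3))
        hp = SCCAHyperparams(1.0, 1.0, 1, 3)
        res = permutation_test(x, y, hp, n_perm=1, seed=0)
        assert res.p[0] == pytest.approx(0.5)  # null beaten: (1+0)/(1+1)

    def test_planted_signal_detected_with_cv_statistic(self):
        cfg = GeneratorConfig(n_participants=200, n_rois=20, seed=1)
        c = generate_cohort(cfg)
        hp = SCCAHyperparams(0.6, 0.6, 1, 7)
        filled, _ = impute_nps(c.nps)
        from fcsubtypes.latent import fit_pca as _fit_pca

        pca = _fit_pca(filled, n_components=7)
        res = permutation_test(c.edges, pca.transform(filled), hp,
                               n_perm=50, seed=0, statistic="cv", cv_folds=5)
        assert res.p[0] < 0.05

    def test_q_dominates_p(self, rng):
        x, y = generate_null(60, 20, 6, seed=5)
        hp = SCCAHyperparams(0.8, 0.8, 3, 6)
        res = permutation_test(x, y, hp, n_perm=30, seed=1)
        assert np.all(res.q >= res.p - 1e-12)


class TestBHFDR:
    def test_single_and_tied(self):
        assert bh_fdr(np.array([0.03]))[0] == pytest.approx(0.03)
        np.testing.assert_allclose(bh_fdr(np.array([0.2, 0.2, 0.2])), 0.2)

    def test_matches_stepup_enumeration(self):
        # brute-force step-up: q_(i) = min_{j>=i} p_(j) * m / j
        p = np.array([0.01, 0.02, 0.03, 0.5])
        m = len(p)
        order = np.argsort(p)
        expected = np.empty(m)
        for rank, idx in enumerate(order, start=1):
            expected[idx] = min(
                p[order[j - 1]] * m / j for j in range(rank, m + 1)
            )
        np.testing.assert_allclose(bh_fdr(p), expected, atol=1e-12)

    def test_invalid_p_rejected(self):
        with pytest.raises(ValueError):
            bh_fdr(np.array([0.1, 1.2]))

    @settings(deadline=None, max_examples=30)
    @given(st.lists(st.floats(0, 1), min_size=1, max_size=20))
    def test_monotone_in_rank(self, ps):
        q = bh_fdr(np.array(ps))
        order = np.argsort(ps)
        assert np.all(np.diff(q[order]) >= -1e-12)
        assert np.all(q >= np.array(ps) - 1e-12)
        assert np.all(q <= 1 + 1e-12)
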