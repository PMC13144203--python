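"""Alternating Poisson regression driver: block updates, extrapolation,
model/results objects."""

import numpy as np
import pytest

from poistopics import (
    DataError,
    FitConfig,
    PoissonNMF,
    fit_pnmf,
    fit_topic_model,
    multiplicative_update,
    extrapolated_iterate,
    progress_report,
    simulate_topic_data,
    update_block,
    pnmf_objective,
)
from poistopics.poisreg import EPS_FLOOR


@pytest.fixture(scope="module")
def dataset():
    X, L, F = simulate_topic_data(40, 30, 3, 150, separation=0.8, seed=11)
    return X


def _random_hw(X, K, seed):
    r = np.random.default_rng(seed)
    H = r.gamma(1.0, 1.0, size=(X.n, K)) + 0.05
    W = r.gamma(1.0, 1.0, size=(X.m, K)) + 0.05
    scale = np.sqrt(X.row_sums.sum() / (H.sum(0) @ W.sum(0)))
    return H * scale, W * scale


class TestUpdateBlock:
    def test_em_inner1_equals_multiplicative_update(self, dataset):
        H0, W0 = _random_hw(dataset, 3, 0)
        H1 = update_block(dataset, W0, H0, method="em", inner_iter=1)
        W1 = update_block(dataset, H1, W0, method="em", inner_iter=1)
        Hm, Wm = multiplicative_update(dataset, H0, W0)
        np.testing.assert_allclose(H1, Hm, rtol=1e-13, atol=1e-13)
        np.testing.assert_allclose(W1, Wm, rtol=1e-13, atol=1e-13)

    @pytest.mark.parametrize("method", ["em", "cd"])
    def test_subproblem_order_invariance(self, dataset, method):
        """Permuting the subproblems (rows of X and of H) permutes the
        result bitwise: the subproblems are independent."""
        H0, W0 = _random_hw(dataset, 3, 1)
        H1 = update_block(dataset, W0, H0, method=method, inner_iter=2)
        perm = np.random.default_rng(5).permutation(dataset.n)
        from poistopics import CountMatrix

        Xp = CountMatrix(dataset.csr[perm])
        H1p = update_block(Xp, W0, H0[perm], method=method, inner_iter=2)
        np.testing.assert_array_equal(H1p, H1[perm])

    def test_zero_support_topic_driven_to_floor(self):
        from poistopics import CountMatrix

        X = CountMatrix([[2, 1], [1, 2]])
        H = np.array([[1.0, 0.0], [1.0, 0.0]])  # topic 2 has no loading
        W0 = np.ones((2, 2))
        W1 = update_block(X, H, W0, method="em", inner_iter=1, block="factors")
        assert np.all(W1[:, 1] == EPS_FLOOR)

    def test_square_matrix_needs_explicit_block(self):
        from poistopics import CountMatrix

        X = CountMatrix(np.eye(3) + 1)
        B = np.ones((3, 2))
        with pytest.raises(ValueError, match="square"):
            update_block(X, B, B, method="em")
        out = update_block(X, B, B, method="em", block="loadings")
        assert out.shape == (3, 2)


class TestMultiplicativeUpdate:
    def test_objective_monotone_over_many_applications(self, dataset):
        H, W = _random_hw(dataset, 3, 2)
        f = pnmf_objective(dataset, H, W)
        for _ in range(200):
            H, W = multiplicative_update(dataset, H, W)
            f_new = pnmf_objective(dataset, H, W)
            assert f_new <= f + 1e-10 * abs(f)
            f = f_new

    def test_interior_stationary_point_fixed(self):
        # X = H W^T exactly: every ratio x/lambda is 1, so the update is the
        # identity at this interior stationary point
        from poistopics import CountMatrix

        H = np.array([[1.0, 1.0], [2.0, 1.0]])
        W = np.array([[1.0, 1.0], [1.0, 2.0], [3.0, 1.0]])
        X = CountMatrix(H @ W.T)
        H2, W2 = multiplicative_update(X, H, W)
        np.testing.assert_allclose(H2, H, rtol=1e-12)
        np.testing.assert_allclose(W2, W, rtol=1e-12)


class TestExtrapolatedIterate:
    def test_beta_zero_is_identity(self):
        cur = np.array([[1.0, 2.0]])
        prev = np.array([[0.5, 3.0]])
        np.testing.assert_array_equal(extrapolated_iterate(cur, prev, 0.0), cur)

    def test_equal_iterates_fixed(self):
        cur = np.array([[1.0, 2.0]])
        np.testing.assert_array_equal(extrapolated_iterate(cur, cur, 0.7), cur)

    def test_negative_excursion_floored(self):
        cur = np.array([[0.1]])
        prev = np.array([[1.0]])
        out = extrapolated_iterate(cur, prev, 0.5)
        assert out[0, 0] == EPS_FLOOR


class TestFitPnmf:
    def test_same_seed_bitwise_identical(self, dataset):
        cfg = FitConfig(K=3, method="cd", num_outer=20, seed=7, tol_rel_obj=0.0)
        a = fit_pnmf(dataset, cfg)
        b = fit_pnmf(dataset, cfg)
        np.testing.assert_array_equal(a.H, b.H)
        np.testing.assert_array_equal(a.W, b.W)
        assert a.objective == b.objective

    def test_em_trace_monotone(self, dataset):
        cfg = FitConfig(K=3, method="em", num_outer=60, seed=5, tol_rel_obj=0.0)
        res = fit_pnmf(dataset, cfg)
        objs = np.array([r.objective for r in res.trace])
        assert np.all(np.diff(objs) <= 1e-10 * np.abs(objs[:-1]))

    def test_returned_fit_is_best_of_trace(self, dataset):
        cfg = FitConfig(K=3, method="cd", num_outer=40, seed=2,
                        extrapolate=True, extrapolate_start=5, tol_rel_obj=0.0)
        res = fit_pnmf(dataset, cfg)
        objs = [r.objective for r in res.trace]
        assert res.objective <= min(objs) + 1e-12
        assert res.objective == pytest.approx(
            pnmf_objective(dataset, res.H, res.W), rel=1e-10
        )

    def test_cd_at_least_as_good_as_em_from_shared_init(self, dataset):
        kw = dict(K=3, num_outer=80, seed=4, init_prefit_iters=10,
                  tol_rel_obj=0.0)
        f_cd = fit_pnmf(dataset, FitConfig(method="cd", **kw)).objective
        f_em = fit_pnmf(dataset, FitConfig(method="em", **kw)).objective
        assert f_cd <= f_em + 1e-6

    def test_zero_row_rejected_with_guidance(self):
        from poistopics import CountMatrix

        X = CountMatrix(np.array([[1, 2], [0, 0], [2, 1]]))
        with pytest.raises(DataError, match="filter"):
            PoissonNMF(X, 2)

    def test_transpose_symmetry(self, dataset):
        """Fitting X^T with the blocks' roles swapped gives the same
        objective: the Poisson objective is symmetric in (H, W)."""
        H0, W0 = _random_hw(dataset, 3, 8)
        model = PoissonNMF(dataset, 3)
        res = model.fit(H0=H0, W0=W0, method="em", num_outer=1, inner_iter=1,
                        tol_rel_obj=0.0)
        f = res.objective
        # on X^T the roles swap: the H-block of X is the factors block of
        # X^T, so mirroring the update order reproduces the same subproblems
        Xt = dataset.T
        H1 = update_block(Xt, W0, H0, method="em", inner_iter=1, block="factors")
        W1 = update_block(Xt, H1, W0, method="em", inner_iter=1, block="loadings")
        ft = pnmf_objective(Xt, W1, H1)
        assert ft == pytest.approx(f, rel=1e-10)


class TestExtrapolation:
    def test_extrapolated_not_worse_than_plain(self, dataset):
        kw = dict(K=3, method="cd", num_outer=60, seed=9, tol_rel_obj=0.0)
        plain = fit_pnmf(dataset, FitConfig(**kw))
        extra = fit_pnmf(dataset, FitConfig(extrapolate=True,
                                            extrapolate_start=20, **kw))
        assert extra.objective <= plain.objective + 1e-6

    def test_beta_recorded_once_active(self, dataset):
        cfg = FitConfig(K=3, method="cd", num_outer=30, seed=9,
                        extrapolate=True, extrapolate_start=10, tol_rel_obj=0.0)
        res = fit_pnmf(dataset, cfg)
        flags = [r.extrapolated for r in res.trace]
        assert not any(flags[:9]) and all(flags[9:])
        assert all(r.beta > 0 for r in res.trace if r.extrapolated)


class TestFitTopicModel:
    def test_simplex_constraints(self, dataset):
        tm = fit_topic_model(dataset, FitConfig(K=3, num_outer=20, seed=1))
        np.testing.assert_allclose(tm.L.sum(axis=1), 1.0, atol=1e-12)
        np.testing.assert_allclose(tm.F.sum(axis=0), 1.0, atol=1e-12)
        assert np.all(tm.s > 0) and np.all(tm.u > 0)

    def test_document_scales_converge_to_row_totals(self):
        X, _, _ = simulate_topic_data(20, 30, 2, 120, separation=0.9, seed=21)
        tm = fit_topic_model(
            X, FitConfig(K=2, method="cd", num_outer=2000, seed=3,
                         tol_rel_obj=0.0)
        )
        t = X.row_sums
        assert np.max(np.abs(tm.s - t) / t) <= 1e-4

    def test_cd_loglik_at_least_em(self, dataset):
        kw = dict(K=3, num_outer=80, seed=6, init_prefit_iters=10,
                  tol_rel_obj=0.0)
        cd = fit_topic_model(dataset, FitConfig(method="cd", **kw))
        em = fit_topic_model(dataset, FitConfig(method="em", **kw))
        assert cd.loglik >= em.loglik - 1e-6

    def test_summary_mentions_loglik(self, dataset):
        res = fit_pnmf(dataset, FitConfig(K=3, num_outer=5, seed=1))
        text = res.summary()
        assert "objective" in text and "loglik" in text
        assert "topics (K):      3" in res.to_topic_model().summary()


class TestProgressReport:
    def test_single_record(self, dataset):
        res = fit_pnmf(dataset, FitConfig(K=3, num_outer=1, seed=1))
        table = progress_report(res)
        assert len(table) == 1
        assert table["delta_best"].iloc[0] == 0.0

    def test_deltas_nonnegative_and_csv_round_trip(self, dataset, tmp_path):
        res = fit_pnmf(dataset, FitConfig(K=3, num_outer=15, seed=1,
                                          tol_rel_obj=0.0))
        table = progress_report(res)
        assert (table["delta_best"] >= 0).all()
        p = tmp_path / "progress.csv"
        table.to_csv(p, index=False, float_format="%.17g")
        import pandas as pd

        back = pd.read_csv(p, float_precision="round_trip")
        np.testing.assert_array_equal(back["objective"], table["objective"])
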