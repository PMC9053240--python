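import numpy as np
import pytest

from neurogsp import (
    fit_pls,
    loocv_q2,
    permutation_gate,
    select_ncomp,
    transfer_r2,
    vip,
    vip_agreement,
    vip_sweep,
)
from neurogsp.pls import ConstantOutcomeError, _null_r2_one_component


class TestFitPls:
    def test_first_component_weight_is_xty(self, rng):
        X = rng.standard_normal((25, 8))
        y = rng.standard_normal(25)
        m = fit_pls(X, y, 1)
        Xs = (X - X.mean(0)) / X.std(0, ddof=1)
        ys = (y - y.mean()) / y.std(ddof=1)
        w_closed = Xs.T @ ys
        w_closed /= np.linalg.norm(w_closed)
        cos = abs(m.x_weights[:, 0] @ w_closed)
        assert cos == pytest.approx(1.0, abs=1e-10)

    def test_full_rank_components_reach_ols_r2(self, rng):
        X = rng.standard_normal((20, 4))
        y = rng.standard_normal(20)
        m = fit_pls(X, y, 4)
        Z = np.column_stack([np.ones(20), X])
        beta = np.linalg.lstsq(Z, y, rcond=None)[0]
        r2_ols = 1 - np.sum((y - Z @ beta) ** 2) / np.sum((y - y.mean()) ** 2)
        assert m.r2_train == pytest.approx(r2_ols, abs=1e-8)

    def test_exact_linear_outcome_r2_one(self, rng):
        # with orthogonal (or single) predictors the first PLS direction is
        # exactly the informative column, so one component fits y perfectly
        x = rng.standard_normal(15)
        m = fit_pls(x[:, None], 2.0 * x + 5.0, 1)
        assert m.r2_train == pytest.approx(1.0, abs=1e-10)
        G = rng.standard_normal((16, 3))
        Q, _ = np.linalg.qr(G - G.mean(axis=0))  # orthogonal, zero-mean cols
        y = 2.0 * Q[:, 1] + 5.0
        m3 = fit_pls(Q, y, 1)
        assert m3.r2_train == pytest.approx(1.0, abs=1e-10)

    def test_rank_bound_enforced(self, rng):
        X = rng.standard_normal((6, 10))
        with pytest.raises(ValueError, match="rank"):
            fit_pls(X, rng.standard_normal(6), 6)

    def test_predict_undoes_standardization(self, rng):
        X = rng.standard_normal((30, 5)) * 7 + 3
        y = rng.standard_normal(30) * 11 - 4
        m = fit_pls(X, y, 2)
        resid = y - m.predict(X)
        assert 1 - resid @ resid / np.sum((y - y.mean()) ** 2) == \
            pytest.approx(m.r2_train, abs=1e-10)


class TestVip:
    def test_single_feature_vip_is_one(self, rng):
        m = fit_pls(rng.standard_normal((10, 1)), rng.standard_normal(10), 1)
        assert vip(m).iloc[0] == pytest.approx(1.0, abs=1e-12)

    def test_mean_squared_vip_is_one(self, rng):
        for p, a in [(5, 1), (12, 3)]:
            m = fit_pls(rng.standard_normal((30, p)), rng.standard_normal(30), a)
            assert (vip(m) ** 2).mean() == pytest.approx(1.0, abs=1e-8)

    def test_two_orthogonal_features_hand_formula(self, rng):
        # y correlated only with feature 1: with one component,
        # VIP_j = sqrt(2) * |w_j| / ||w||
        n = 40
        x1 = rng.standard_normal(n)
        x2 = rng.standard_normal(n)
        x2 -= (x2 @ x1) / (x1 @ x1) * x1  # orthogonalize
        y = x1 + 0.1 * rng.standard_normal(n)
        X = np.column_stack([x1, x2])
        m = fit_pls(X, y, 1)
        w = m.x_weights[:, 0]
        expected = np.sqrt(2) * np.abs(w) / np.linalg.norm(w)
        np.testing.assert_allclose(vip(m).to_numpy(), expected, atol=1e-10)
        v = vip(m)
        assert v.iloc[0] > 1.0 > v.iloc[1]


class TestSelectNcomp:
    def test_recovers_two_factor_latent_structure(self, rng):
        n = 50
        t1, t2 = rng.standard_normal(n), rng.standard_normal(n)
        X = np.outer(t1, rng.standard_normal(6)) \
            + np.outer(t2, rng.standard_normal(6))   # exact rank-2 design
        y = t1 + t2
        assert select_ncomp(X, y, 4) == 2

    def test_pure_noise_picks_one(self, rng):
        X = rng.standard_normal((20, 5))
        y = rng.standard_normal(20)
        assert select_ncomp(X, y, 3) in (1, 2)  # tie toward fewer on flat MSEP
        assert select_ncomp(X, y, 3, force_one=True) == 1


class TestPermutationGate:
    def test_vectorized_null_equals_sklearn_refits(self, rng):
        X = rng.standard_normal((12, 4))
        y = rng.standard_normal(12)
        Xs = (X - X.mean(0)) / X.std(0, ddof=1)
        ys = (y - y.mean()) / y.std(ddof=1)
        rng_a = np.random.default_rng(5)
        null_vec = _null_r2_one_component(Xs, ys, 20, rng_a)
        rng_b = np.random.default_rng(5)
        order = np.argsort(rng_b.random((20, 12)), axis=1)
        null_loop = np.array([fit_pls(X, y[order[b]], 1).r2_train
                              for b in range(20)])
        np.testing.assert_allclose(null_vec, null_loop, atol=1e-10)

    def test_single_feature_null_mean_matches_analytic(self, rng):
        # E[r^2] = 1/(n-1) for independent Gaussian pairs
        n = 10
        g = permutation_gate(rng.standard_normal((n, 1)),
                             rng.standard_normal(n), n_perm=5000, seed=2)
        se = g.null_r2.std(ddof=1) / np.sqrt(g.n_perm)
        assert abs(g.null_mean - 1.0 / (n - 1)) < 3 * se
        assert not g.is_overfit

    def test_full_feature_model_is_overfit(self, rng):
        X = rng.standard_normal((20, 132))
        y = rng.standard_normal(20)
        g = permutation_gate(X, y, n_perm=2000, seed=3)
        assert g.is_overfit
        assert g.null_mean > 0.5

    def test_seed_reproducible_and_stable_across_seeds(self, rng):
        X = rng.standard_normal((15, 6))
        y = rng.standard_normal(15)
        g1 = permutation_gate(X, y, n_perm=5000, seed=11)
        g2 = permutation_gate(X, y, n_perm=5000, seed=11)
        np.testing.assert_array_equal(g1.null_r2, g2.null_r2)
        g3 = permutation_gate(X, y, n_perm=5000, seed=12)
        assert abs(g1.p_observed - g3.p_observed) < 0.02
        assert 0.0 <= g1.p_observed <= 1.0

    def test_constant_outcome_named_error(self, rng):
        with pytest.raises(ConstantOutcomeError):
            permutation_gate(rng.standard_normal((10, 2)), np.ones(10),
                             n_perm=10, seed=1)

    def test_seed_is_mandatory(self, rng):
        with pytest.raises(ValueError, match="seed"):
            permutation_gate(rng.standard_normal((10, 2)),
                             rng.standard_normal(10))


class TestVipSweep:
    def test_zero_threshold_keeps_all_features(self, rng):
        X = rng.standard_normal((15, 6))
        y = rng.standard_normal(15)
        cands = vip_sweep(X, y, thresholds=[0.0], seed=1, n_perm=50)
        assert len(cands) == 1
        assert len(cands[0].feature_names) == 6

    def test_threshold_above_max_vip_skipped(self, rng):
        X = rng.standard_normal((15, 6))
        y = rng.standard_normal(15)
        cands = vip_sweep(X, y, thresholds=[50.0], seed=1, n_perm=50)
        assert cands == []

    def test_planted_feature_survives_below_its_vip(self, rng):
        X = rng.standard_normal((30, 20))
        y = X[:, 4] + 0.2 * rng.standard_normal(30)
        full = fit_pls(X, y, 1)
        v4 = vip(full).iloc[4]
        cands = vip_sweep(X, y, thresholds=np.arange(0.5, v4, 0.3), seed=2,
                          n_perm=50)
        assert all("f4" in c.feature_names for c in cands)


class TestLoocv:
    def test_noiseless_signal_recovered_exactly(self, rng):
        X = rng.standard_normal((20, 10))
        y = 3.0 * X[:, 2]
        cv = loocv_q2(X, y, seed=4, n_perm=100)
        assert cv.q2 == pytest.approx(1.0, abs=1e-6)

    def test_q2_invariant_to_outcome_rescaling(self, rng):
        X = rng.standard_normal((15, 8))
        y = X[:, 0] + rng.standard_normal(15)
        a = loocv_q2(X, y, seed=6, n_perm=100).q2
        b = loocv_q2(X, 10.0 * y - 3.0, seed=6, n_perm=100).q2
        assert a == pytest.approx(b, abs=1e-8)

    def test_inclusion_matrix_dimensions(self, rng):
        X = rng.standard_normal((12, 7))
        y = X[:, 1] + rng.standard_normal(12)
        cv = loocv_q2(X, y, seed=8, n_perm=100)
        assert cv.inclusion.shape == (7, 12)
        assert cv.q2 <= 1.0 and cv.q2_no_leak <= 1.0

    def test_held_out_selection_rule_is_optimistic_on_null(self, rng):
        # the source protocol's fold rule consults the held-out label;
        # on pure-noise data it must dominate the no-leakage variant
        diffs = []
        for s in range(6):
            X = rng.standard_normal((16, 40))
            y = rng.standard_normal(16)
            cv = loocv_q2(X, y, seed=s, n_perm=200)
            diffs.append(cv.q2 - cv.q2_no_leak)
        assert np.mean(diffs) > 0

    def test_planted_feature_dominates_fold_models(self, rng):
        # parameter recovery: standardized effect 0.7 on one feature
        rates = []
        for s in range(15):
            X = rng.standard_normal((20, 30))
            f = (X[:, 3] - X[:, 3].mean()) / X[:, 3].std(ddof=1)
            y = 0.7 * f + np.sqrt(1 - 0.49) * rng.standard_normal(20)
            cv = loocv_q2(X, y, seed=s, n_perm=200)
            rates.append(cv.inclusion.iloc[3].mean())
        assert np.mean(rates) > 0.8


class TestTransferAndAgreement:
    def test_transfer_to_training_cohort_equals_training_r2(self, rng):
        X = rng.standard_normal((20, 6))
        y = X[:, 0] + rng.standard_normal(20)
        m = fit_pls(X, y, 1)
        assert transfer_r2(m, X, y) == pytest.approx(m.r2_train, abs=1e-10)

    def test_shared_generative_process_transfers(self, rng):
        n = 300
        Xa, Xb = rng.standard_normal((n, 10)), rng.standard_normal((n, 10))
        ya = Xa[:, 2] + 0.5 * rng.standard_normal(n)
        yb = Xb[:, 2] + 0.5 * rng.standard_normal(n)
        m = fit_pls(Xa, ya, 1)
        assert abs(transfer_r2(m, Xb, yb) - m.r2_train) < 0.1

    def test_disjoint_signals_do_not_transfer(self, rng):
        n = 200
        Xa, Xb = rng.standard_normal((n, 10)), rng.standard_normal((n, 10))
        ya = Xa[:, 1] + 0.3 * rng.standard_normal(n)
        yb = Xb[:, 7] + 0.3 * rng.standard_normal(n)
        m = fit_pls(Xa, ya, 1)
        assert transfer_r2(m, Xb, yb) < 0.1

    def test_kendall_tau_extremes_and_null(self, rng):
        v = rng.random(132)
        assert vip_agreement(v, v) == pytest.approx(1.0)
        assert vip_agreement(v, -v) == pytest.approx(-1.0)
        taus = [abs(vip_agreement(rng.random(132), rng.random(132)))
                for _ in range(20)]
        assert np.mean([t < 0.2 for t in taus]) >= 0.95
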