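"""Bias-regularized matrix factorization: update rules, recovery, invariants."""
import numpy as np
import pytest

from presympto.completion import (
    CompletionHyperparams, CompletionModel, complete_matrix, fit_completion,
    fold_in_rows, init_model, objective, observed_rmse, predict_entry,
    sgd_epoch,
)
from presympto.errors import ConfigurationError, DataError, NumericalError


def planted_matrix(seed, n=60, cols=24, k=2, noise=0.0):
    rng = np.random.default_rng(seed)
    mu = 1.0
    br = rng.normal(0, 0.5, n)
    bc = rng.normal(0, 0.5, cols)
    P = rng.normal(0, 0.7, (n, k))
    Q = rng.normal(0, 0.7, (cols, k))
    signal = mu + br[:, None] + bc[None, :] + P @ Q.T
    X = signal + noise * signal.std() * rng.standard_normal(signal.shape)
    return X, signal


class TestInitModel:
    def test_constant_matrix_mu(self):
        X = np.full((4, 5), 3.25)
        model = init_model(X.shape, CompletionHyperparams(seed=0), X=X,
                           mask=np.ones_like(X, bool))
        assert model.mu == 3.25
        assert not model.b_row.any() and not model.b_col.any()

    def test_seeded_determinism(self):
        h = CompletionHyperparams(seed=9)
        a = init_model((6, 7), h)
        b = init_model((6, 7), h)
        np.testing.assert_array_equal(a.P, b.P)
        np.testing.assert_array_equal(a.Q, b.Q)

    def test_nothing_to_fit(self):
        X = np.zeros((3, 3))
        with pytest.raises(DataError, match="nothing to fit"):
            init_model(X.shape, CompletionHyperparams(), X=X,
                       mask=np.zeros_like(X, bool))

    def test_bad_hyperparams_rejected(self):
        with pytest.raises(ConfigurationError):
            CompletionHyperparams(k=0).validate()
        with pytest.raises(ConfigurationError):
            CompletionHyperparams(alpha=-1.0).validate()


class TestSgdEpoch:
    def test_zero_step_is_fixed_point(self, rng):
        X = rng.standard_normal((5, 6))
        mask = np.ones_like(X, bool)
        model = init_model(X.shape, CompletionHyperparams(alpha=0.0, seed=1),
                           X=X, mask=mask)
        P0, Q0 = model.P.copy(), model.Q.copy()
        sgd_epoch(model, X, mask)
        np.testing.assert_array_equal(model.P, P0)
        np.testing.assert_array_equal(model.Q, Q0)
        assert not model.b_row.any()

    def test_single_entry_update_matches_hand_computation(self):
        # 2x2, K=1, one observed entry at (0, 1): per-entry factor update
        # then the batch bias update, evaluated by hand.
        alpha, lam = 0.1, 0.01
        hyper = CompletionHyperparams(k=1, alpha=alpha, lam=lam, seed=0)
        X = np.array([[0.0, 2.0], [0.0, 0.0]])
        mask = np.zeros_like(X, bool)
        mask[0, 1] = True
        model = CompletionModel(
            P=np.array([[0.5], [0.0]]), Q=np.array([[0.0], [0.25]]),
            b_row=np.array([0.1, 0.0]), b_col=np.array([0.0, -0.2]),
            mu=1.0, hyper=hyper, rng=np.random.default_rng(0),
        )
        e = 2.0 - (1.0 + 0.1 - 0.2 + 0.5 * 0.25)       # Eq.10 residual
        p_new = 0.5 + alpha * (2 * e * 0.25 - lam * 0.5)
        q_new = 0.25 + alpha * (2 * e * 0.5 - lam * 0.25)
        sgd_epoch(model, X, mask)
        assert model.P[0, 0] == pytest.approx(p_new, abs=1e-12)
        assert model.Q[1, 0] == pytest.approx(q_new, abs=1e-12)
        # bias update uses the post-pass residual averaged over observed cells
        e2 = 2.0 - (1.0 + 0.1 - 0.2 + p_new * q_new)
        assert model.b_row[0] == pytest.approx(
            0.1 + alpha * (2 * e2 - lam * 0.1), abs=1e-12)
        assert model.b_col[1] == pytest.approx(
            -0.2 + alpha * (2 * e2 - lam * (-0.2)), abs=1e-12)
        assert model.b_row[1] == pytest.approx(0.0, abs=1e-12)

    def test_single_entry_residual_decays_monotonically(self):
        hyper = CompletionHyperparams(k=1, alpha=0.02, lam=0.0, seed=3)
        X = np.array([[1.5]])
        mask = np.ones_like(X, bool)
        model = init_model(X.shape, hyper, X=X, mask=mask)
        errors = []
        for _ in range(50):
            sgd_epoch(model, X, mask)
            errors.append(abs(X[0, 0] - predict_entry(model, 0, 0)))
        assert all(b <= a + 1e-12 for a, b in zip(errors, errors[1:]))
        assert errors[-1] < errors[0]


class TestFitCompletion:
    def test_rank1_exact_factorization(self, rng):
        u = rng.standard_normal(20)
        v = rng.standard_normal(8)
        X = np.outer(u, v)
        hyper = CompletionHyperparams(k=1, alpha=0.01, lam=0.0,
                                      max_epochs=4000, tol=0.0, seed=0)
        model = fit_completion(X, np.ones_like(X, bool), hyper)
        assert observed_rmse(model, X, np.ones_like(X, bool)) < 1e-3

    def test_planted_recovery_beats_mean_imputation(self):
        X, signal = planted_matrix(5, noise=0.1)
        rng = np.random.default_rng(6)
        mask = np.ones_like(X, bool)
        d = 6
        for b in rng.permutation(X.shape[0] * 4)[:28]:  # 4 blocks of 6 cols
            i, r = divmod(int(b), 4)
            mask[i, r * d:(r + 1) * d] = False
        hyper = CompletionHyperparams(k=2, alpha=2e-3, lam=1e-5,
                                      max_epochs=1500, tol=1e-8, seed=1)
        model = fit_completion(X, mask, hyper)
        Z = complete_matrix(model, X, mask).Z
        held = ~mask
        rmse = np.sqrt(np.mean((Z[held] - signal[held]) ** 2))
        col_means = np.array([X[mask[:, j], j].mean()
                              for j in range(X.shape[1])])
        rmse_mean = np.sqrt(np.mean(
            (np.tile(col_means, (X.shape[0], 1))[held] - signal[held]) ** 2))
        assert rmse_mean / rmse >= 2.0

    def test_study_defaults_recorded(self):
        hyper = CompletionHyperparams()
        assert hyper.alpha == pytest.approx(2.0e-5)
        assert hyper.lam == pytest.approx(1.0e-5)
        X = np.full((3, 3), 2.0)
        model = fit_completion(X, np.ones_like(X, bool),
                               CompletionHyperparams(max_epochs=2))
        assert model.hyper.alpha == pytest.approx(2.0e-5)
        assert model.hyper.lam == pytest.approx(1.0e-5)

    def test_objective_never_worse_than_init_and_history_recorded(self):
        X, _ = planted_matrix(8)
        mask = np.ones_like(X, bool)
        hyper = CompletionHyperparams(k=2, alpha=1e-3, lam=1e-5,
                                      max_epochs=50, tol=0.0, seed=2)
        init = init_model(X.shape, hyper, X=X, mask=mask)
        model = fit_completion(X, mask, hyper)
        assert objective(model, X, mask) <= objective(init, X, mask)
        assert len(model.history) == 50

    def test_bit_reproducible(self):
        X, _ = planted_matrix(9)
        mask = np.ones_like(X, bool)
        hyper = CompletionHyperparams(k=2, alpha=1e-3, max_epochs=30, seed=4)
        a = fit_completion(X, mask, hyper)
        b = fit_completion(X, mask, hyper)
        np.testing.assert_array_equal(a.P, b.P)
        np.testing.assert_array_equal(a.b_row, b.b_row)
        assert a.history == b.history

    def test_divergence_raises_with_advice(self):
        X, _ = planted_matrix(10)
        hyper = CompletionHyperparams(k=2, alpha=5.0, max_epochs=50, seed=0)
        with pytest.raises(NumericalError, match="alpha"):
            fit_completion(X, np.ones_like(X, bool), hyper)


class TestPredictAndComplete:
    def test_zero_model_predicts_mu(self):
        model = CompletionModel(
            P=np.zeros((2, 1)), Q=np.zeros((3, 1)),
            b_row=np.zeros(2), b_col=np.zeros(3), mu=1.5,
            hyper=CompletionHyperparams(k=1),
        )
        assert predict_entry(model, 1, 2) == 1.5

    def test_hand_evaluated_prediction(self):
        model = CompletionModel(
            P=np.array([[2.0]]), Q=np.array([[3.0]]),
            b_row=np.array([0.5]), b_col=np.array([-0.25]), mu=1.0,
            hyper=CompletionHyperparams(k=1),
        )
        assert predict_entry(model, 0, 0) == pytest.approx(7.25)

    def test_transpose_symmetry(self):
        rng = np.random.default_rng(3)
        model = CompletionModel(
            P=rng.standard_normal((4, 2)), Q=rng.standard_normal((5, 2)),
            b_row=rng.standard_normal(4), b_col=rng.standard_normal(5),
            mu=0.3, hyper=CompletionHyperparams(),
        )
        swapped = CompletionModel(P=model.Q, Q=model.P, b_row=model.b_col,
                                  b_col=model.b_row, mu=model.mu,
                                  hyper=model.hyper)
        assert predict_entry(model, 2, 4) == pytest.approx(
            predict_entry(swapped, 4, 2))

    def test_index_out_of_range(self):
        model = init_model((2, 2), CompletionHyperparams(seed=0))
        with pytest.raises(IndexError):
            predict_entry(model, 2, 0)

    def test_all_observed_copied_verbatim(self, rng):
        X = rng.standard_normal((6, 4))
        mask = np.ones_like(X, bool)
        model = fit_completion(X, mask,
                               CompletionHyperparams(alpha=1e-3, max_epochs=5,
                                                     seed=0))
        Z = complete_matrix(model, X, mask)
        np.testing.assert_array_equal(Z.Z, X)
        assert not Z.provenance.any()

    def test_missing_block_equals_model_predictions(self, rng):
        X = rng.standard_normal((6, 8))
        mask = np.ones_like(X, bool)
        mask[:, 2:4] = False
        model = fit_completion(X, mask,
                               CompletionHyperparams(alpha=1e-3, max_epochs=5,
                                                     seed=0))
        Z = complete_matrix(model, X, mask)
        np.testing.assert_array_equal(Z.Z[mask], X[mask])
        for i in range(6):
            for j in (2, 3):
                assert Z.Z[i, j] == pytest.approx(predict_entry(model, i, j))
        assert Z.provenance.sum() == 12

    def test_shape_mismatch_rejected(self, rng):
        X = rng.standard_normal((4, 4))
        model = init_model((3, 4), CompletionHyperparams(seed=0))
        with pytest.raises(DataError):
            complete_matrix(model, X, np.ones_like(X, bool))


class TestFoldIn:
    def test_fold_in_recovers_new_row(self):
        X, signal = planted_matrix(12, n=40, cols=12, noise=0.0)
        mask = np.ones_like(X, bool)
        hyper = CompletionHyperparams(k=2, alpha=2e-3, lam=1e-6,
                                      max_epochs=1500, tol=1e-9, seed=1)
        model = fit_completion(X[:-1], mask[:-1], hyper)
        new_mask = np.ones((1, 12), bool)
        new_mask[0, 6:] = False  # fold in from half the columns
        folded = fold_in_rows(model, X[-1:], new_mask, epochs=400)
        pred = folded.predictions()[0, 6:]
        rmse = np.sqrt(np.mean((pred - signal[-1, 6:]) ** 2))
        assert rmse < 0.5 * np.std(signal)
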