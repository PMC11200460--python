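"""Bias-regularized matrix factorization for structured missing data.

The observed feature matrix X (rows = observation units, columns =
region x feature pairs) is approximated by

    x_hat_ij = mu + b_row[i] + b_col[j] + p_i . q_j

where mu is the mean of the observed entries, b_row / b_col are per-row and
per-column bias terms, and P, Q are K-dimensional latent factors.  The model
is fitted by stochastic gradient descent over the observed entries only:

    p_ik <- p_ik + alpha * (2 e_ij q_jk - lambda p_ik)
    q_jk <- q_jk + alpha * (2 e_ij p_ik - lambda q_jk)

with e_ij = x_ij - x_hat_ij, visiting observed entries in a seed-fixed
shuffled order each epoch; after each pass the biases receive a batch update
driven by the row-wise / column-wise mean residuals:

    b_row[i] <- b_row[i] + alpha * (2 ave(e_i.) - lambda b_row[i])
    b_col[j] <- b_col[j] + alpha * (2 ave(e_.j) - lambda b_col[j])

(a fully-online bias variant is available behind ``online_bias``).  The
completed matrix Z copies observed entries verbatim and fills missing ones
with the model prediction, so completion never alters observed data.

The per-entry inner loop is JIT-compiled with numba when available.
"""
from __future__ import annotations

import copy
from dataclasses import dataclass, field

import numpy as np

from .errors import ConfigurationError, DataError, NumericalError

try:  # pragma: no cover - exercised implicitly
    from numba import njit as _njit

    _HAVE_NUMBA = True
except ImportError:  # pragma: no cover
    _HAVE_NUMBA = False

    def _njit(*args, **kwargs):
        def deco(f):
            return f
        return deco if not (args and callable(args[0])) else args[0]


@dataclass
class CompletionHyperparams:
    """Hyperparameters of the regularized factorization.

    ``alpha`` and ``lam`` default to the study values 2.0e-5 and 1.0e-5.  The
    latent dimension K, epoch cap, stopping tolerance (relative change of the
    observed-entry RMSE) and initialization scale are engineering defaults.
    """

    k: int = 2
    alpha: float = 2.0e-5
    lam: float = 1.0e-5
    max_epochs: int = 5000
    tol: float = 1.0e-6
    seed: int = 0
    init_scale: float = 0.1
    online_bias: bool = False

    def validate(self) -> None:
        if self.k < 1:
            raise ConfigurationError(f"K must be >= 1, got {self.k}")
        if self.alpha < 0:
            raise ConfigurationError(f"alpha must be >= 0, got {self.alpha}")
        if self.lam < 0:
            raise ConfigurationError(f"lambda must be >= 0, got {self.lam}")
        if self.tol < 0:
            raise ConfigurationError(f"tol must be >= 0, got {self.tol}")
        if self.max_epochs < 1:
            raise ConfigurationError("max_epochs must be >= 1")


@dataclass
class CompletionModel:
    """Fitted factors, biases and global mean, plus the fitting history."""

    P: np.ndarray
    Q: np.ndarray
    b_row: np.ndarray
    b_col: np.ndarray
    mu: float
    hyper: CompletionHyperparams
    history: list = field(default_factory=list)
    rng: np.random.Generator | None = None

    def predictions(self) -> np.ndarray:
        return (
            self.mu
            + self.b_row[:, None]
            + self.b_col[None, :]
            + self.P @ self.Q.T
        )

    def copy(self) -> "CompletionModel":
        return CompletionModel(
            P=self.P.copy(), Q=self.Q.copy(),
            b_row=self.b_row.copy(), b_col=self.b_col.copy(),
            mu=self.mu, hyper=self.hyper,
            history=list(self.history), rng=self.rng,
        )


@dataclass
class CompletedMatrix:
    """Z: observed entries verbatim, missing entries imputed.

    ``provenance`` is True where the entry was imputed.
    """

    Z: np.ndarray
    provenance: np.ndarray

    def block(self, m: int, d: int) -> np.ndarray:
        """The m-th region column block Z_m (N x d)."""
        return self.Z[:, m * d:(m + 1) * d]


def init_model(shape: tuple[int, int], hyper: CompletionHyperparams,
               X: np.ndarray | None = None,
               mask: np.ndarray | None = None) -> CompletionModel:
    """Gaussian factor initialization (scale init_scale/sqrt(K)), zero biases.

    mu is the mean of the observed entries (0 if X/mask not supplied).
    """
    hyper.validate()
    n, m = shape
    if n < 1 or m < 1:
        raise ConfigurationError(f"shape must be positive, got {shape}")
    rng = np.random.default_rng(hyper.seed)
    scale = hyper.init_scale / np.sqrt(hyper.k)
    P = rng.standard_normal((n, hyper.k)) * scale
    Q = rng.standard_normal((m, hyper.k)) * scale
    mu = 0.0
    if X is not None and mask is not None:
        if not mask.any():
            raise DataError("nothing to fit: no observed entries")
        mu = float(np.asarray(X, dtype=float)[mask].mean())
    return CompletionModel(
        P=P, Q=Q,
        b_row=np.zeros(n), b_col=np.zeros(m),
        mu=mu, hyper=hyper, rng=rng,
    )


@_njit(cache=True)
def _sgd_pass(P, Q, b_row, b_col, mu, rows, cols, vals, order,
              alpha, lam, online_bias, n_row_obs, n_col_obs):
    k = P.shape[1]
    for t in range(order.shape[0]):
        e_idx = order[t]
        i = rows[e_idx]
        j = cols[e_idx]
        pred = mu + b_row[i] + b_col[j]
        for kk in range(k):
            pred += P[i, kk] * Q[j, kk]
        e = vals[e_idx] - pred
        for kk in range(k):
            pik = P[i, kk]
            qjk = Q[j, kk]
            P[i, kk] = pik + alpha * (2.0 * e * qjk - lam * pik)
            Q[j, kk] = qjk + alpha * (2.0 * e * pik - lam * qjk)
        if online_bias:
            b_row[i] += alpha * (2.0 * e / n_row_obs[i] - lam * b_row[i])
            b_col[j] += alpha * (2.0 * e / n_col_obs[j] - lam * b_col[j])


@_njit(cache=True)
def _fold_in_pass(P_new, Q, b_new, b_col, mu, rows, cols, vals, order,
                  alpha, lam):
    k = P_new.shape[1]
    for t in range(order.shape[0]):
        e_idx = order[t]
        i = rows[e_idx]
        j = cols[e_idx]
        pred = mu + b_new[i] + b_col[j]
        for kk in range(k):
            pred += P_new[i, kk] * Q[j, kk]
        e = vals[e_idx] - pred
        for kk in range(k):
            P_new[i, kk] += alpha * (2.0 * e * Q[j, kk] - lam * P_new[i, kk])


def _residuals(model: CompletionModel, X: np.ndarray,
               mask: np.ndarray) -> np.ndarray:
    E = np.where(mask, X - model.predictions(), 0.0)
    return E


def objective(model: CompletionModel, X: np.ndarray, mask: np.ndarray) -> float:
    """Regularized squared-error objective (for monitoring)."""
    E = _residuals(model, X, mask)
    lam = model.hyper.lam
    penalty = (
        np.sum(model.b_row ** 2) + np.sum(model.b_col ** 2)
        + np.sum(model.P ** 2) + np.sum(model.Q ** 2)
    )
    return float(np.sum(E ** 2) + 0.5 * lam * penalty)


def observed_rmse(model: CompletionModel, X: np.ndarray,
                  mask: np.ndarray) -> float:
    E = _residuals(model, X, mask)
    return float(np.sqrt(np.sum(E ** 2) / mask.sum()))


def sgd_epoch(model: CompletionModel, X: np.ndarray,
              mask: np.ndarray) -> CompletionModel:
    """One full pass over the observed entries (in place), then bias update."""
    if model.rng is None:
        model.rng = np.random.default_rng(model.hyper.seed)
    rows, cols = np.nonzero(mask)
    vals = np.ascontiguousarray(X[rows, cols], dtype=float)
    order = model.rng.permutation(rows.size)
    n_row_obs = np.maximum(mask.sum(axis=1), 1).astype(np.float64)
    n_col_obs = np.maximum(mask.sum(axis=0), 1).astype(np.float64)
    _sgd_pass(
        model.P, model.Q, model.b_row, model.b_col, model.mu,
        rows.astype(np.int64), cols.astype(np.int64), vals,
        order.astype(np.int64),
        float(model.hyper.alpha), float(model.hyper.lam),
        model.hyper.online_bias, n_row_obs, n_col_obs,
    )
    if not model.hyper.online_bias:
        E = _residuals(model, X, mask)
        alpha, lam = model.hyper.alpha, model.hyper.lam
        ave_row = E.sum(axis=1) / n_row_obs
        ave_col = E.sum(axis=0) / n_col_obs
        model.b_row += alpha * (2.0 * ave_row - lam * model.b_row)
        model.b_col += alpha * (2.0 * ave_col - lam * model.b_col)
    if not (np.all(np.isfinite(model.P)) and np.all(np.isfinite(model.Q))
            and np.all(np.isfinite(model.b_row))
            and np.all(np.isfinite(model.b_col))):
        raise NumericalError(
            "SGD diverged (non-finite parameters); try a smaller alpha"
        )
    return model


def fit_completion(X: np.ndarray, mask: np.ndarray,
                   hyper: CompletionHyperparams | None = None
                   ) -> CompletionModel:
    """Fit the factorization; returns the epoch with the best observed RMSE.

    Stops early once the relative change of the observed RMSE drops below
    ``hyper.tol``.  The regularized objective of the returned model is
    guaranteed not to exceed its value at initialization.
    """
    hyper = hyper if hyper is not None else CompletionHyperparams()
    X = np.asarray(X, dtype=float)
    mask = np.asarray(mask, dtype=bool)
    if X.shape != mask.shape:
        raise DataError(f"X shape {X.shape} != mask shape {mask.shape}")
    if not mask.any():
        raise DataError("nothing to fit: no observed entries")
    model = init_model(X.shape, hyper, X=X, mask=mask)
    initial_objective = objective(model, X, mask)
    best = model.copy()
    best_rmse = observed_rmse(model, X, mask)
    prev_rmse = best_rmse
    for _ in range(hyper.max_epochs):
        sgd_epoch(model, X, mask)
        rmse = observed_rmse(model, X, mask)
        if not np.isfinite(rmse):
            raise NumericalError(
                "SGD diverged (non-finite RMSE); try a smaller alpha"
            )
        model.history.append(rmse)
        if rmse < best_rmse:
            best_rmse = rmse
            best = model.copy()
        if prev_rmse > 0 and abs(prev_rmse - rmse) / prev_rmse < hyper.tol:
            break
        prev_rmse = rmse
    best.history = list(model.history)
    if objective(best, X, mask) > initial_objective * (1 + 1e-12) + 1e-12:
        raise NumericalError(
            "fit did not improve the regularized objective; try a smaller alpha"
        )
    return best


def predict_entry(model: CompletionModel, i: int, j: int) -> float:
    """mu + b_row[i] + b_col[j] + p_i . q_j"""
    if not (0 <= i < model.P.shape[0] and 0 <= j < model.Q.shape[0]):
        raise IndexError(f"entry ({i}, {j}) out of range")
    return float(
        model.mu + model.b_row[i] + model.b_col[j]
        + model.P[i] @ model.Q[j]
    )


def complete_matrix(model: CompletionModel, X: np.ndarray,
                    mask: np.ndarray) -> CompletedMatrix:
    """Copy observed entries verbatim; impute missing ones from the model."""
    X = np.asarray(X, dtype=float)
    mask = np.asarray(mask, dtype=bool)
    if X.shape != mask.shape:
        raise DataError(f"X shape {X.shape} != mask shape {mask.shape}")
    if X.shape != (model.P.shape[0], model.Q.shape[0]):
        raise DataError(
            f"model fitted on shape {(model.P.shape[0], model.Q.shape[0])}, "
            f"got {X.shape}"
        )
    Z = np.where(mask, X, model.predictions())
    return CompletedMatrix(Z=Z, provenance=~mask)


def fold_in_rows(model: CompletionModel, X_new: np.ndarray,
                 mask_new: np.ndarray, epochs: int = 200) -> CompletionModel:
    """Estimate factors and biases for unseen rows with Q, b_col, mu frozen.

    Used by the strict leave-mouse-out mode: the held-out mouse's rows are
    folded into a model fitted on training mice only, using only the new
    rows' observed entries.  Returns a model over the new rows that shares
    Q, b_col and mu with ``model``.
    """
    X_new = np.asarray(X_new, dtype=float)
    mask_new = np.asarray(mask_new, dtype=bool)
    hyper = model.hyper
    rng = np.random.default_rng(hyper.seed + 1)
    scale = hyper.init_scale / np.sqrt(hyper.k)
    P_new = rng.standard_normal((X_new.shape[0], hyper.k)) * scale
    b_new = np.zeros(X_new.shape[0])
    rows, cols = np.nonzero(mask_new)
    if rows.size == 0:
        return CompletionModel(
            P=P_new, Q=model.Q, b_row=b_new, b_col=model.b_col,
            mu=model.mu, hyper=hyper,
        )
    vals = np.ascontiguousarray(X_new[rows, cols], dtype=float)
    n_row_obs = np.maximum(mask_new.sum(axis=1), 1).astype(float)
    alpha, lam = hyper.alpha, hyper.lam
    rows64 = rows.astype(np.int64)
    cols64 = cols.astype(np.int64)
    for _ in range(epochs):
        order = rng.permutation(rows.size).astype(np.int64)
        _fold_in_pass(P_new, model.Q, b_new, model.b_col, model.mu,
                      rows64, cols64, vals, order, alpha, lam)
        pred = (model.mu + b_new[:, None] + model.b_col[None, :]
                + P_new @ model.Q.T)
        ave_row = np.where(mask_new, X_new - pred, 0.0).sum(axis=1) / n_row_obs
        b_new += alpha * (2.0 * ave_row - lam * b_new)
    if not np.all(np.isfinite(P_new)) or not np.all(np.isfinite(b_new)):
        raise NumericalError("fold-in diverged; try a smaller alpha")
    return CompletionModel(
        P=P_new, Q=model.Q, b_row=b_new, b_col=model.b_col,
        mu=model.mu, hyper=hyper,
    )
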