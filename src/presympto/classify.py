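"""Top-R feature assembly, the four classifiers and leave-mouse-out evaluation.

The projected per-region features are concatenated in descending
cross-loading order up to rank R, giving a per-window vector of length
D_p * R.  Four classifiers are compared: pooled-covariance LDA, KNN with
k = 9 and Euclidean distance, a linear soft-margin SVM, and an extreme
learning machine (1000 sigmoid hidden units with fixed random Gaussian input
weights and a ridge least-squares readout).

Evaluation is leave-mouse-out: every fold holds out all windows of one mouse
and trains on the remaining mice; per-mouse accuracy is the fraction of the
held-out mouse's windows classified correctly, and summary accuracies are
unweighted means over mice.  In the default transductive mode the completion
and sMVCCA stages are fitted once on the full cohort (the label view does
include the held-out mouse there); the strict mode refits both stages per
fold on training mice only and folds the held-out mouse in through fixed
projections — use it when any leakage through the unsupervised stages must
be excluded.
"""
from __future__ import annotations

from dataclasses import dataclass, field, replace
from typing import Callable, Mapping, Sequence

import numpy as np
import pandas as pd
from sklearn.discriminant_analysis import LinearDiscriminantAnalysis
from sklearn.neighbors import KNeighborsClassifier
from sklearn.svm import SVC

from .errors import ConfigurationError, DataError
from .smvcca import ProjectedFeatures


@dataclass(frozen=True)
class ClassifierSpec:
    """One classifier configuration.

    Defaults follow the study setup: 9 KNN neighbors, linear SVM kernel,
    1000 ELM hidden units.  The SVM cost, ELM activation and ELM ridge are
    engineering defaults.  ``seed`` fixes the ELM input weights.
    """

    kind: str
    knn_neighbors: int = 9
    svm_cost: float = 1.0
    elm_hidden: int = 1000
    elm_ridge: float = 1.0e-6
    elm_activation: str = "sigmoid"
    seed: int = 0

    def __post_init__(self) -> None:
        if self.kind not in ("lda", "knn", "svm", "elm"):
            raise ConfigurationError(f"unknown classifier kind {self.kind!r}")


def default_specs(seed: int = 0, **overrides) -> list[ClassifierSpec]:
    """The four study classifiers with shared overrides."""
    return [ClassifierSpec(kind=k, seed=seed, **overrides)
            for k in ("lda", "knn", "svm", "elm")]


class ELMClassifier:
    """Extreme learning machine: random input layer + ridge readout.

    Input weights and biases are drawn once from a unit Gaussian (seed-fixed)
    and never trained; the hidden layer applies a sigmoid (or tanh); the
    readout solves the regularized normal equations
    (H^T H + ridge I) W = H^T Y for one-hot targets Y and predicts by argmax.
    """

    def __init__(self, n_hidden: int = 1000, ridge: float = 1.0e-6,
                 activation: str = "sigmoid", seed: int = 0) -> None:
        if activation not in ("sigmoid", "tanh"):
            raise ConfigurationError(f"unknown activation {activation!r}")
        self.n_hidden = n_hidden
        self.ridge = ridge
        self.activation = activation
        self.seed = seed

    def _hidden(self, X: np.ndarray) -> np.ndarray:
        A = X @ self.W_in_ + self.b_in_
        if self.activation == "sigmoid":
            return 1.0 / (1.0 + np.exp(-A))
        return np.tanh(A)

    def fit(self, X: np.ndarray, y: Sequence) -> "ELMClassifier":
        X = np.asarray(X, dtype=float)
        y = np.asarray(y)
        self.classes_ = np.unique(y)
        if self.classes_.size < 2:
            raise DataError("ELM training requires >= 2 classes")
        rng = np.random.default_rng(self.seed)
        self.W_in_ = rng.standard_normal((X.shape[1], self.n_hidden))
        self.b_in_ = rng.standard_normal(self.n_hidden)
        H = self._hidden(X)
        Y = (y[:, None] == self.classes_[None, :]).astype(float)
        A = H.T @ H + self.ridge * np.eye(self.n_hidden)
        self.W_out_ = np.linalg.solve(A, H.T @ Y)
        return self

    def decision_function(self, X: np.ndarray) -> np.ndarray:
        return self._hidden(np.asarray(X, dtype=float)) @ self.W_out_

    def predict(self, X: np.ndarray) -> np.ndarray:
        scores = self.decision_function(X)
        return self.classes_[np.argmax(scores, axis=1)]


def fit_classifier(spec: ClassifierSpec, X: np.ndarray, y: Sequence):
    """Train one classifier; errors on single-class training data."""
    y = np.asarray(y)
    if np.unique(y).size < 2:
        raise DataError("training fold contains a single class")
    if spec.kind == "lda":
        model = LinearDiscriminantAnalysis()
    elif spec.kind == "knn":
        model = KNeighborsClassifier(n_neighbors=spec.knn_neighbors)
    elif spec.kind == "svm":
        model = SVC(kernel="linear", C=spec.svm_cost)
    else:
        model = ELMClassifier(
            n_hidden=spec.elm_hidden, ridge=spec.elm_ridge,
            activation=spec.elm_activation, seed=spec.seed,
        )
    return model.fit(np.asarray(X, dtype=float), y)


@dataclass
class TopRFeatures:
    """Concatenated projections of the R top-ranked regions (N x D_p*R)."""

    matrix: np.ndarray
    regions_used: tuple[str, ...]
    r: int
    d_p: int


def build_topR_features(projected: ProjectedFeatures, ranking: Sequence[str],
                        r: int) -> TopRFeatures:
    """Stack the projections of the top-R regions in rank order."""
    if not 1 <= r <= len(ranking):
        raise ConfigurationError(
            f"R must lie in [1, {len(ranking)}], got {r}"
        )
    index = {name: i for i, name in enumerate(projected.region_names)}
    used = tuple(ranking[:r])
    blocks = [projected.per_view[index[name]] for name in used]
    return TopRFeatures(
        matrix=np.hstack(blocks), regions_used=used, r=r, d_p=projected.d_p,
    )


def _check_folds(mouse_labels: Mapping[str, str]) -> None:
    counts: dict[str, int] = {}
    for lab in mouse_labels.values():
        counts[lab] = counts.get(lab, 0) + 1
    if len(counts) < 2 or min(counts.values()) < 2:
        raise DataError(
            "leave-mouse-out requires >= 2 mice per class so that every "
            f"training fold keeps both classes (class counts: {counts})"
        )


def leave_mouse_out(
    X: np.ndarray,
    row_mouse: Sequence[str],
    mouse_labels: Mapping[str, str],
    spec: ClassifierSpec,
    mode: str = "transductive",
    refit: Callable[[str], tuple[np.ndarray, np.ndarray]] | None = None,
) -> pd.DataFrame:
    """One fold per mouse; per-mouse accuracy over that mouse's windows.

    In transductive mode the rows of ``X`` are fixed features and folds only
    partition rows.  In strict mode ``refit`` must map a held-out mouse id to
    (X_train_rows, X_test_rows) recomputed without that mouse.  The returned
    table records the mode and asserts that no test row index enters
    training.
    """
    if mode not in ("transductive", "strict"):
        raise ConfigurationError(f"unknown evaluation mode {mode!r}")
    if mode == "strict" and refit is None:
        raise ConfigurationError("strict mode requires a refit callable")
    X = np.asarray(X, dtype=float)
    row_mouse = np.asarray(row_mouse)
    _check_folds(mouse_labels)
    mice = list(dict.fromkeys(row_mouse.tolist()))
    y_rows = np.array([mouse_labels[m] for m in row_mouse])
    records = []
    for test_mouse in mice:
        test_idx = np.nonzero(row_mouse == test_mouse)[0]
        train_idx = np.nonzero(row_mouse != test_mouse)[0]
        assert np.intersect1d(test_idx, train_idx).size == 0, \
            "test windows leaked into the training fold"
        if mode == "transductive":
            X_train, X_test = X[train_idx], X[test_idx]
        else:
            X_train, X_test = refit(test_mouse)
            if X_train.shape[0] != train_idx.size or \
                    X_test.shape[0] != test_idx.size:
                raise DataError("refit returned inconsistent fold sizes")
        model = fit_classifier(spec, X_train, y_rows[train_idx])
        pred = model.predict(X_test)
        acc = float(np.mean(pred == mouse_labels[test_mouse]))
        records.append(
            (spec.kind, test_mouse, mouse_labels[test_mouse],
             test_idx.size, acc)
        )
    table = pd.DataFrame(
        records,
        columns=["classifier", "mouse", "label", "n_windows", "accuracy"],
    )
    table.attrs["mode"] = mode
    table.attrs["n_folds"] = len(mice)
    return table


def sweep_R(
    projected_or_provider,
    ranking: Sequence[str],
    row_mouse: Sequence[str],
    mouse_labels: Mapping[str, str],
    specs: Sequence[ClassifierSpec],
    r_values: Sequence[int],
    mode: str = "transductive",
    refit_factory: Callable[[str, int], tuple[np.ndarray, np.ndarray]] | None = None,
) -> tuple[pd.DataFrame, dict]:
    """Full (classifier x R x mouse) evaluation grid plus a summary.

    ``projected_or_provider`` is a :class:`ProjectedFeatures` in transductive
    mode; in strict mode ``refit_factory(test_mouse, r)`` supplies per-fold
    train/test features.  The summary reports, per classifier, the
    accuracy-vs-R curve and the argmax R (smallest R attaining the maximum
    mean accuracy).
    """
    tables = []
    for r in r_values:
        if mode == "transductive":
            top = build_topR_features(projected_or_provider, ranking, r)
            X_r = top.matrix
            refit = None
        else:
            X_r = np.zeros((len(list(row_mouse)), 1))  # placeholder, unused
            refit = (lambda rr: lambda mouse: refit_factory(mouse, rr))(r)
        for spec in specs:
            table = leave_mouse_out(
                X_r, row_mouse, mouse_labels, spec, mode=mode, refit=refit,
            )
            table.insert(1, "R", r)
            tables.append(table)
    grid = pd.concat(tables, ignore_index=True)
    grid.attrs["mode"] = mode
    summary: dict = {"mode": mode, "per_classifier": {}}
    for spec in specs:
        sub = grid[grid["classifier"] == spec.kind]
        curve = sub.groupby("R")["accuracy"].mean()
        curve = curve.reindex(sorted(r_values))
        best = curve.max()
        argmax_r = int(curve.index[np.nonzero(curve.to_numpy() >= best - 1e-12)[0][0]])
        summary["per_classifier"][spec.kind] = {
            "accuracy_vs_R": {int(r): float(a) for r, a in curve.items()},
            "argmax_R": argmax_r,
            "best_accuracy": float(best),
        }
    return grid, summary
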