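"""Reference models and the fit/predict/score contract.

The stopping rule is model-agnostic in principle, but it is defined and
evaluated against two L2-regularized linear reference models: ridge
regression for continuous targets and L2-penalized logistic regression for
binary targets.  Model fitting always includes cross-validated tuning of
the regularization strength over a small grid, and out-of-fold predictions
are produced with the tuning nested inside each outer fold so that every
performance estimate is free of selection leakage.

Features are standardized (center + scale) with constants learned on the
training partition only; regularized linear models require comparable
feature scales and per-fold standardization avoids train/test leakage.
"""

from __future__ import annotations

from dataclasses import dataclass, field

import numpy as np

from ._seeds import rng_from, spawn_seeds
from .dataset import Dataset

__all__ = [
    "Scorer",
    "SCORERS",
    "default_scorer_id",
    "ModelSpec",
    "FittedModel",
    "PredictionSample",
    "make_folds",
    "min_feasible_size",
    "fit_tuned",
    "predict",
    "cv_predict",
    "score",
]


@dataclass(frozen=True)
class Scorer:
    """A higher-is-better performance score.

    All scorers are oriented so that larger is better; the stopping rule's
    comparisons (tangent gain, smallest effect of interest) rely on this
    uniform orientation.  ``chance_level`` is the reference value expected
    under no association (computed from a dataset, e.g. the majority-class
    rate for accuracy).
    """

    id: str
    task: str
    lower: float
    upper: float

    def __call__(self, truth: np.ndarray, prediction: np.ndarray) -> float:
        return score(truth, prediction, self)

    def chance_level(self, dataset: Dataset) -> float:
        if self.id == "accuracy":
            return dataset.chance_level()
        if self.id == "explained_variance":
            return 0.0
        # neg MAE of predicting the target mean
        y = dataset.target
        return float(-np.mean(np.abs(y - y.mean())))


SCORERS: dict[str, Scorer] = {
    "accuracy": Scorer("accuracy", "classification", 0.0, 1.0),
    "neg_mean_absolute_error": Scorer(
        "neg_mean_absolute_error", "regression", -np.inf, 0.0
    ),
    "explained_variance": Scorer("explained_variance", "regression", -np.inf, 1.0),
}


def default_scorer_id(task: str) -> str:
    return "accuracy" if task == "classification" else "neg_mean_absolute_error"


def score(truth, predictions, scorer: Scorer | str) -> float:
    """Score paired (truth, prediction) values with a named scorer.

    accuracy: fraction of exact label matches.
    neg_mean_absolute_error: -mean|truth - pred|.
    explained_variance: 1 - Var(truth - pred) / Var(truth).
    """
    if isinstance(scorer, str):
        scorer = SCORERS[scorer]
    truth = np.asarray(truth, dtype=float)
    predictions = np.asarray(predictions, dtype=float)
    if truth.size == 0 or predictions.size == 0:
        raise ValueError("empty score input")
    if truth.shape != predictions.shape:
        raise ValueError("truth and predictions must have equal length")
    # direct formulas (equivalent to sklearn.metrics; asserted by tests) —
    # these run millions of times inside bootstrap loops
    if scorer.id == "accuracy":
        return float(np.mean(truth == predictions))
    if scorer.id == "neg_mean_absolute_error":
        return float(-np.mean(np.abs(truth - predictions)))
    if scorer.id == "explained_variance":
        if np.var(truth) == 0:
            raise ValueError("zero-variance target")
        return float(1.0 - np.var(truth - predictions) / np.var(truth))
    raise KeyError(f"unknown scorer {scorer.id!r}")


@dataclass(frozen=True)
class ModelSpec:
    """Configuration of the reference model: task, regularization grid for
    cross-validated tuning, fold count and scorer."""

    task: str
    regularization_grid: tuple[float, ...] = (0.1, 1.0, 10.0)
    cv_folds: int = 5
    scorer_id: str | None = None

    def __post_init__(self) -> None:
        if not self.regularization_grid:
            raise ValueError("regularization grid must be non-empty")
        if any(g <= 0 for g in self.regularization_grid):
            raise ValueError("regularization values must be positive")
        if self.cv_folds < 2:
            raise ValueError("cv_folds must be >= 2")
        sid = self.scorer_id or default_scorer_id(self.task)
        if SCORERS[sid].task != self.task:
            raise ValueError(f"scorer {sid!r} incompatible with task {self.task!r}")
        object.__setattr__(self, "scorer_id", sid)

    @property
    def scorer(self) -> Scorer:
        return SCORERS[self.scorer_id]


@dataclass(frozen=True)
class FittedModel:
    """A finalized linear model: coefficients on standardized features plus
    the preprocessing constants learned from its training data.  Sufficient
    to reproduce predictions on new data without refitting."""

    coefficients: np.ndarray
    intercept: float
    chosen_regularization: float
    center: np.ndarray
    scale: np.ndarray
    task: str
    n_train: int
    classes: np.ndarray | None = field(default=None)

    @property
    def p(self) -> int:
        return self.coefficients.shape[0]


@dataclass(frozen=True)
class PredictionSample:
    """Paired out-of-fold (truth, prediction) values from nested CV."""

    truth: np.ndarray
    prediction: np.ndarray
    scorer_id: str

    def __post_init__(self) -> None:
        if len(self.truth) != len(self.prediction):
            raise ValueError("truth and prediction must be aligned")

    @property
    def n(self) -> int:
        return len(self.truth)

    def score(self) -> float:
        return score(self.truth, self.prediction, self.scorer_id)


# ---------------------------------------------------------------------------
# folds


def _effective_k(dataset: Dataset, spec: ModelSpec) -> int:
    """k = min(requested, largest k with >= 2 members of each class per fold
    for classification, or >= 2 observations per fold for regression).

    At the very smallest samples (fewer than 4 of the minority class) this
    degrades to 2 folds with >= 1 member of each class per fold, so that
    tuning stays defined down to two observations per class.
    """
    if dataset.task == "classification":
        _, counts = np.unique(dataset.target, return_counts=True)
        minority = int(counts.min())
        k_max = minority // 2 if minority >= 4 else (2 if minority >= 2 else 0)
    else:
        k_max = dataset.n // 2
    return min(spec.cv_folds, k_max)


def min_feasible_size(dataset: Dataset, spec: ModelSpec) -> int:
    """Smallest (stratified) subsample size on which *nested* CV is still
    well-posed under ``spec``: the outer split (>= 2 folds) must leave a
    training part that the inner tuning loop can itself cross-validate
    (>= 2 folds with >= 2 members of each class per fold)."""
    if dataset.task == "classification":
        _, counts = np.unique(dataset.target, return_counts=True)
        minority_frac = counts.min() / dataset.n
        # minority count m*f >= 8: outer 2-fold leaves >= 4 for inner 2-fold
        return int(np.ceil(8.0 / minority_frac))
    return 8


def make_folds(dataset: Dataset, spec: ModelSpec, seed: int) -> list[np.ndarray]:
    """Seeded CV fold assignment: stratified round-robin for classification,
    contiguous blocks of a shuffled index for regression.

    Returns a partition of ``range(n)`` into k test-index arrays.
    """
    k = _effective_k(dataset, spec)
    if k < 2:
        raise ValueError("insufficient sample for cross-validation")
    rng = rng_from(seed)
    n = dataset.n
    folds: list[list[int]] = [[] for _ in range(k)]
    if dataset.task == "classification":
        for label in np.unique(dataset.target):
            idx = np.flatnonzero(dataset.target == label)
            idx = rng.permutation(idx)
            for j, i in enumerate(idx):
                folds[j % k].append(int(i))
    else:
        perm = rng.permutation(n)
        for j, block in enumerate(np.array_split(perm, k)):
            folds[j].extend(int(i) for i in block)
    return [np.sort(np.array(f, dtype=int)) for f in folds]


# ---------------------------------------------------------------------------
# fitting


def _standardize_params(X: np.ndarray) -> tuple[np.ndarray, np.ndarray]:
    center = X.mean(axis=0)
    scale = X.std(axis=0)
    scale = np.where(scale == 0, 1.0, scale)
    return center, scale


def _fit_ridge(X: np.ndarray, y: np.ndarray, reg: float) -> tuple[np.ndarray, float]:
    """Closed-form ridge with unpenalized intercept: center X and y, solve
    (Xc'Xc + reg I) w = Xc'yc.  Direct normal-equation solve; the bootstrap
    loops fit tens of thousands of these tiny models, so avoiding estimator
    overhead matters."""
    xm = X.mean(axis=0)
    ym = y.mean()
    Xc = X - xm
    A = Xc.T @ Xc
    A[np.diag_indices_from(A)] += reg
    w = np.linalg.solve(A, Xc.T @ (y - ym))
    return w, float(ym - xm @ w)


def _fit_logistic(
    X: np.ndarray,
    y01: np.ndarray,
    reg: float,
    tol: float = 1e-7,
    max_iter: int = 50,
    warm_start: np.ndarray | None = None,
) -> tuple[np.ndarray, float]:
    """L2-penalized logistic regression by Newton-IRLS (unpenalized
    intercept), minimizing sum log(1+exp(-y z)) + (reg/2)||w||^2.

    Matches scikit-learn's LogisticRegression with C = 1/reg to solver
    tolerance (asserted by a cross-check test); implemented directly for
    the same reason as :func:`_fit_ridge`.
    """
    n, p = X.shape
    Xa = np.hstack([X, np.ones((n, 1))])
    beta = np.zeros(p + 1) if warm_start is None else warm_start.copy()
    pen = np.append(np.full(p, reg), 0.0)  # intercept unpenalized
    for _ in range(max_iter):
        z = np.clip(Xa @ beta, -35.0, 35.0)
        mu = 1.0 / (1.0 + np.exp(-z))
        grad = Xa.T @ (mu - y01) + pen * beta
        if np.max(np.abs(grad)) < tol * max(1.0, n):
            break
        w = mu * (1.0 - mu)
        H = (Xa * w[:, None]).T @ Xa
        H[np.diag_indices_from(H)] += pen + 1e-12
        beta = beta - np.linalg.solve(H, grad)
    return beta[:p], float(beta[p])


def _fit_linear(
    X: np.ndarray, y: np.ndarray, task: str, reg: float
) -> tuple[np.ndarray, float]:
    """Fit the reference linear model on already-standardized features."""
    if task == "regression":
        return _fit_ridge(X, y, reg)
    classes = np.unique(y)
    return _fit_logistic(X, (y == classes[-1]).astype(float), reg)


def _predict_raw(
    X: np.ndarray, coef: np.ndarray, intercept: float, center, scale
) -> np.ndarray:
    Xs = (X - center) / scale
    return Xs @ coef + intercept


def _labels_from_linear(z: np.ndarray, classes: np.ndarray) -> np.ndarray:
    # decision threshold at linear score 0 (probability 0.5)
    return np.where(z > 0, classes[1], classes[0])


def fit_tuned(dataset: Dataset, spec: ModelSpec, seed: int) -> FittedModel:
    """Fit the reference model with cross-validated regularization tuning.

    The regularization value maximizing mean k-fold CV score over the grid
    is selected (ties broken toward the *largest* grid value, i.e. stronger
    regularization), then the model is refit on the full input with
    preprocessing constants recomputed on the full input.  Deterministic
    given ``seed``.
    """
    if dataset.task == "classification" and np.unique(dataset.target).size < 2:
        raise ValueError("degenerate target")
    folds = make_folds(dataset, spec, seed)
    scorer = spec.scorer
    grid = sorted(spec.regularization_grid)
    fold_scores = np.empty((len(folds), len(grid)))
    for f, test_idx in enumerate(folds):
        # fold-level work (standardization, Gram matrix, warm starts) is
        # shared across the regularization grid
        train_mask = np.ones(dataset.n, dtype=bool)
        train_mask[test_idx] = False
        Xtr, ytr = dataset.features[train_mask], dataset.target[train_mask]
        center, scale = _standardize_params(Xtr)
        Xs = (Xtr - center) / scale
        Xte = (dataset.features[test_idx] - center) / scale
        yte = dataset.target[test_idx]
        if dataset.task == "regression":
            xm = Xs.mean(axis=0)
            Xc = Xs - xm
            ym = ytr.mean()
            G = Xc.T @ Xc
            rhs = Xc.T @ (ytr - ym)
            diag = np.diag_indices_from(G)
            for j, reg in enumerate(grid):
                A = G.copy()
                A[diag] += reg
                w = np.linalg.solve(A, rhs)
                pred = Xte @ w + (ym - xm @ w)
                fold_scores[f, j] = score(yte, pred, scorer)
        else:
            y01 = (ytr == dataset.classes[-1]).astype(float)
            beta = None
            for j, reg in enumerate(grid[::-1]):  # strongest first: stabler warm start
                coef, b = _fit_logistic(Xs, y01, reg, warm_start=beta)
                beta = np.append(coef, b)
                pred = _labels_from_linear(Xte @ coef + b, dataset.classes)
                fold_scores[f, len(grid) - 1 - j] = score(yte, pred, scorer)
    best_reg, best_score = None, -np.inf
    for reg, mean_score in zip(grid, fold_scores.mean(axis=0)):
        if mean_score >= best_score:  # ascending grid: ties pick largest reg
            best_score, best_reg = float(mean_score), reg
    center, scale = _standardize_params(dataset.features)
    coef, b = _fit_linear(
        (dataset.features - center) / scale, dataset.target, dataset.task, best_reg
    )
    return FittedModel(
        coefficients=coef,
        intercept=b,
        chosen_regularization=float(best_reg),
        center=center,
        scale=scale,
        task=dataset.task,
        n_train=dataset.n,
        classes=dataset.classes,
    )


def predict(model: FittedModel, features: np.ndarray) -> np.ndarray:
    """Apply stored preprocessing, then the linear predictor.

    Classification returns hard labels via a decision threshold at linear
    score 0.
    """
    X = np.asarray(features, dtype=float)
    if X.ndim != 2 or X.shape[1] != model.p:
        raise ValueError("feature mismatch")
    z = _predict_raw(X, model.coefficients, model.intercept, model.center, model.scale)
    if model.task == "classification":
        return _labels_from_linear(z, model.classes)
    return z


def cv_predict(dataset: Dataset, spec: ModelSpec, seed: int) -> PredictionSample:
    """Nested-CV out-of-fold predictions.

    Every observation is predicted by a model that never saw it; the
    regularization tuning runs inside each outer training fold (via
    :func:`fit_tuned` on that fold), so the resulting (truth, prediction)
    pairs give an unbiased performance sample.
    """
    outer_seed, *inner_seeds = spawn_seeds(seed, 1 + spec.cv_folds)
    folds = make_folds(dataset, spec, outer_seed)
    oof = np.empty(dataset.n, dtype=float)
    for i, test_idx in enumerate(folds):
        train_mask = np.ones(dataset.n, dtype=bool)
        train_mask[test_idx] = False
        train = dataset.subset(np.flatnonzero(train_mask))
        model = fit_tuned(train, spec, inner_seeds[i % len(inner_seeds)])
        oof[test_idx] = predict(model, dataset.features[test_idx])
    return PredictionSample(
        truth=dataset.target.copy(), prediction=oof, scorer_id=spec.scorer_id
    )
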