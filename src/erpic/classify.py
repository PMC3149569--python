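"""SVM classification with nested cross-validated forward feature selection.

Subjects are classified case vs control with an RBF-kernel support vector
machine on standardized features.  Model assessment uses stratified 10-fold
cross-validation with confusion counts pooled over the held-out folds
(case is the positive class).  Feature subsets are chosen by greedy
sequential forward selection up to ``k_max`` features, with the number of
retained features decided by a tolerance-based elbow on the accuracy trace.
Standardization, optional univariate pre-screening, hyperparameter tuning
and feature selection are always computed on training data only, so
held-out estimates carry no information leakage; :func:`nested_cv` wraps
selection itself inside each outer training fold for an unbiased estimate.
"""

from __future__ import annotations

from dataclasses import dataclass, field
from typing import Sequence

import numpy as np
import pandas as pd
from sklearn.model_selection import StratifiedKFold
from sklearn.svm import SVC

from .errors import InvalidInputError, InvalidParameterError
from .features import FeatureMatrix

POSITIVE = "case"
NEGATIVE = "control"


@dataclass(frozen=True)
class CVConfig:
    """Cross-validation and SVM tuning configuration.

    ``inner_grid`` lists candidate (cost, kernel-width) pairs; ``gamma`` may
    be the string "scale".  A single-entry grid disables the inner search.
    """

    n_folds: int = 10
    stratified: bool = True
    seed: int = 0
    inner_grid: tuple[tuple[float, float | str], ...] = ((1.0, "scale"),)
    inner_folds: int = 5

    def __post_init__(self) -> None:
        if self.n_folds < 2:
            raise InvalidParameterError("n_folds must be >= 2")
        if not self.inner_grid:
            raise InvalidParameterError("inner_grid must be non-empty")


@dataclass
class StandardizationParams:
    mean: np.ndarray
    sd: np.ndarray
    constant: np.ndarray  # bool flags for zero-variance columns


@dataclass
class SelectionStep:
    key: str
    accuracy: float
    sensitivity: float
    specificity: float


@dataclass
class SelectionTrace:
    """Forward-selection path: one step per added feature."""

    steps: list[SelectionStep]
    chosen_k: int
    k_max: int
    tolerance: float

    @property
    def chosen_keys(self) -> list[str]:
        return [s.key for s in self.steps[: self.chosen_k]]


@dataclass
class ClassifierReport:
    """Pooled classification metrics (fractions in [0, 1])."""

    accuracy: float
    sensitivity: float | None
    specificity: float | None
    per_fold_accuracies: tuple[float, ...] = ()
    fold_averaged_accuracy: float | None = None
    selected_features: tuple[str, ...] = ()
    model_desc: dict = field(default_factory=dict)
    single_class: bool = False
    n: int = 0


# ---------------------------------------------------------------------------
# Helpers


def _as_xy(
    features: FeatureMatrix | pd.DataFrame | np.ndarray,
    labels: Sequence[str] | None = None,
) -> tuple[np.ndarray, np.ndarray, list[str]]:
    if isinstance(features, FeatureMatrix):
        X = features.values.to_numpy(dtype=float)
        y = features.groups.to_numpy() if labels is None else np.asarray(labels)
        keys = list(features.values.columns)
    elif isinstance(features, pd.DataFrame):
        X = features.to_numpy(dtype=float)
        y = np.asarray(labels)
        keys = list(features.columns)
    else:
        X = np.asarray(features, dtype=float)
        if X.ndim == 1:
            X = X[:, None]
        y = np.asarray(labels)
        keys = [f"f{i}" for i in range(X.shape[1])]
    if y is None or len(y) != X.shape[0]:
        raise InvalidInputError("labels must align with feature rows")
    return X, y, keys


def standardize(
    train: np.ndarray | pd.DataFrame,
    apply_to: np.ndarray | pd.DataFrame | None = None,
) -> tuple[np.ndarray, np.ndarray | None, StandardizationParams]:
    """Column-wise z-scoring with training-data parameters only.

    Zero-variance columns are centered and flagged (scale left at 1).
    """
    Xt = np.asarray(train, dtype=float)
    mean = Xt.mean(axis=0)
    sd = Xt.std(axis=0)
    constant = sd == 0
    sd_safe = np.where(constant, 1.0, sd)
    params = StandardizationParams(mean, sd_safe, constant)
    out_train = (Xt - mean) / sd_safe
    out_apply = None
    if apply_to is not None:
        out_apply = (np.asarray(apply_to, dtype=float) - mean) / sd_safe
    return out_train, out_apply, params


def _folds(y: np.ndarray, config: CVConfig) -> list[tuple[np.ndarray, np.ndarray]]:
    classes, counts = np.unique(y, return_counts=True)
    if len(classes) < 2:
        raise InvalidInputError("need both classes for cross-validation")
    if config.stratified and counts.min() < config.n_folds:
        raise InvalidInputError(
            f"need >= {config.n_folds} subjects per class for "
            f"{config.n_folds}-fold stratified CV (min class size {counts.min()})"
        )
    skf = StratifiedKFold(
        n_splits=config.n_folds, shuffle=True, random_state=config.seed
    )
    return [(tr, te) for tr, te in skf.split(np.zeros(len(y)), y)]


def _resolve_gamma(gamma: float | str, X: np.ndarray) -> float:
    if gamma == "scale":
        var = X.var()
        return 1.0 / (X.shape[1] * var) if var > 0 else 1.0
    return float(gamma)


def _fit_predict(
    Xtr: np.ndarray, ytr: np.ndarray, Xte: np.ndarray, C: float, gamma: float | str
) -> np.ndarray:
    svc = SVC(C=C, kernel="rbf", gamma=gamma)
    svc.fit(Xtr, ytr)
    return svc.predict(Xte)


def _tune(
    Xtr: np.ndarray, ytr: np.ndarray, config: CVConfig
) -> tuple[float, float | str]:
    """Pick the (C, gamma) pair with best inner-CV accuracy (ties: first)."""
    if len(config.inner_grid) == 1:
        return config.inner_grid[0]
    n_inner = min(config.inner_folds, int(np.unique(ytr, return_counts=True)[1].min()))
    skf = StratifiedKFold(n_splits=max(2, n_inner), shuffle=True,
                          random_state=config.seed)
    splits = list(skf.split(Xtr, ytr))
    best, best_acc = config.inner_grid[0], -1.0
    for C, gamma in config.inner_grid:
        hits = 0
        for itr, ite in splits:
            pred = _fit_predict(Xtr[itr], ytr[itr], Xtr[ite], C, gamma)
            hits += int((pred == ytr[ite]).sum())
        acc = hits / len(ytr)
        if acc > best_acc:
            best, best_acc = (C, gamma), acc
    return best


def _pooled_report(
    y: np.ndarray, pred: np.ndarray, fold_accs: list[float]
) -> ClassifierReport:
    tp = int(np.sum((y == POSITIVE) & (pred == POSITIVE)))
    tn = int(np.sum((y == NEGATIVE) & (pred == NEGATIVE)))
    fn = int(np.sum((y == POSITIVE) & (pred != POSITIVE)))
    fp = int(np.sum((y == NEGATIVE) & (pred != NEGATIVE)))
    n = len(y)
    sens = tp / (tp + fn) if (tp + fn) else None
    spec = tn / (tn + fp) if (tn + fp) else None
    return ClassifierReport(
        accuracy=(tp + tn) / n,
        sensitivity=sens,
        specificity=spec,
        per_fold_accuracies=tuple(fold_accs),
        fold_averaged_accuracy=float(np.mean(fold_accs)) if fold_accs else None,
        single_class=(sens is None or spec is None),
        n=n,
    )


# ---------------------------------------------------------------------------
# Cross-validated evaluation


def cv_evaluate(
    features: FeatureMatrix | pd.DataFrame | np.ndarray,
    labels: Sequence[str] | None = None,
    config: CVConfig = CVConfig(),
) -> ClassifierReport:
    """Stratified k-fold CV of an RBF-SVM on the given feature columns.

    Standardization and (if the grid has several entries) hyperparameter
    tuning are redone inside each training fold; metrics are pooled
    confusion counts over all held-out predictions.
    """
    X, y, _ = _as_xy(features, labels)
    folds = _folds(y, config)
    pred = np.empty(len(y), dtype=y.dtype)
    fold_accs = []
    for tr, te in folds:
        Xtr, Xte, _ = standardize(X[tr], X[te])
        C, gamma = _tune(Xtr, y[tr], config)
        pred[te] = _fit_predict(Xtr, y[tr], Xte, C, gamma)
        fold_accs.append(float(np.mean(pred[te] == y[te])))
    return _pooled_report(y, pred, fold_accs)


# ---------------------------------------------------------------------------
# Forward selection


def _welch_t(X: np.ndarray, y: np.ndarray) -> np.ndarray:
    """|Welch t| per column, vectorized; 0 where undefined."""
    a, b = X[y == POSITIVE], X[y == NEGATIVE]
    va = a.var(axis=0, ddof=1) / max(len(a), 1)
    vb = b.var(axis=0, ddof=1) / max(len(b), 1)
    denom = np.sqrt(va + vb)
    with np.errstate(invalid="ignore", divide="ignore"):
        t = (a.mean(axis=0) - b.mean(axis=0)) / denom
    return np.abs(np.nan_to_num(t))


def forward_select(
    features: FeatureMatrix | pd.DataFrame | np.ndarray,
    labels: Sequence[str] | None = None,
    config: CVConfig = CVConfig(),
    k_max: int = 10,
    tolerance: float = 0.01,
    screen_top: int | None = None,
) -> SelectionTrace:
    """Greedy sequential forward selection of up to ``k_max`` features.

    At each step the candidate maximizing pooled CV accuracy is added
    (ties broken by lower column index).  ``chosen_k`` is the smallest k
    such that no later step improves accuracy by more than ``tolerance``.
    With ``screen_top`` the candidate pool is first reduced to the
    ``screen_top`` columns with the largest |Welch t| on the given data —
    when called on a training fold this uses training data only.
    """
    X, y, keys = _as_xy(features, labels)
    if X.shape[1] < 1:
        raise InvalidInputError("need at least one candidate feature")
    cand_idx = np.arange(X.shape[1])
    if screen_top is not None and screen_top < len(cand_idx):
        t = _welch_t(X, y)
        top = np.sort(np.argsort(-t, kind="stable")[:screen_top])
        cand_idx = cand_idx[top]

    folds = _folds(y, config)
    # Pre-standardize every fold once; candidate evaluation then just slices.
    fold_data = []
    for tr, te in folds:
        Xtr, Xte, _ = standardize(X[tr][:, cand_idx], X[te][:, cand_idx])
        fold_data.append((tr, te, Xtr, Xte))
    C, gamma = config.inner_grid[0]
    single = len(config.inner_grid) == 1

    chosen: list[int] = []  # positions within cand_idx
    steps: list[SelectionStep] = []
    remaining = list(range(len(cand_idx)))
    for _ in range(min(k_max, len(remaining) + len(chosen))):
        best_pos, best_acc, best_pred = -1, -1.0, None
        for pos in remaining:
            cols = chosen + [pos]
            pred = np.empty(len(y), dtype=y.dtype)
            for tr, te, Xtr, Xte in fold_data:
                if single:
                    pred[te] = _fit_predict(Xtr[:, cols], y[tr], Xte[:, cols], C, gamma)
                else:
                    Cb, gb = _tune(Xtr[:, cols], y[tr], config)
                    pred[te] = _fit_predict(Xtr[:, cols], y[tr], Xte[:, cols], Cb, gb)
            acc = float(np.mean(pred == y))
            if acc > best_acc:  # strict: ties keep the lower column index
                best_pos, best_acc, best_pred = pos, acc, pred
        chosen.append(best_pos)
        remaining.remove(best_pos)
        rep = _pooled_report(y, best_pred, [])
        steps.append(
            SelectionStep(
                keys[cand_idx[best_pos]], rep.accuracy,
                rep.sensitivity or 0.0, rep.specificity or 0.0,
            )
        )
        if not remaining:
            break

    accs = [s.accuracy for s in steps]
    chosen_k = len(steps)
    for k in range(1, len(steps) + 1):
        later = accs[k:]
        if not later or max(later) <= accs[k - 1] + tolerance:
            chosen_k = k
            break
    return SelectionTrace(steps, chosen_k, k_max, tolerance)


# ---------------------------------------------------------------------------
# Final model and external validation


@dataclass
class TrainedModel:
    """A trained RBF-SVM with frozen standardization and feature identity.

    Prediction is computed from the stored support vectors, so a model
    deserialized from JSON reproduces decision values exactly.
    """

    feature_keys: tuple[str, ...]
    mean: np.ndarray
    sd: np.ndarray
    C: float
    gamma: float
    support_vectors: np.ndarray
    dual_coef: np.ndarray
    intercept: float
    classes: tuple[str, str]  # (negative-decision class, positive-decision class)

    def decision_function(self, features: FeatureMatrix | pd.DataFrame) -> np.ndarray:
        df = features.values if isinstance(features, FeatureMatrix) else features
        missing = [k for k in self.feature_keys if k not in df.columns]
        if missing:
            raise InvalidInputError(f"missing feature keys: {missing}")
        X = df.loc[:, list(self.feature_keys)].to_numpy(dtype=float)
        Z = (X - self.mean) / self.sd
        d2 = (
            (Z ** 2).sum(axis=1)[:, None]
            + (self.support_vectors ** 2).sum(axis=1)[None, :]
            - 2.0 * Z @ self.support_vectors.T
        )
        K = np.exp(-self.gamma * np.maximum(d2, 0.0))
        return K @ self.dual_coef + self.intercept

    def predict(self, features: FeatureMatrix | pd.DataFrame) -> np.ndarray:
        dec = self.decision_function(features)
        return np.where(dec > 0, self.classes[1], self.classes[0])

    def to_dict(self) -> dict:
        return {
            "feature_keys": list(self.feature_keys),
            "mean": self.mean.tolist(),
            "sd": self.sd.tolist(),
            "C": self.C,
            "gamma": self.gamma,
            "support_vectors": self.support_vectors.tolist(),
            "dual_coef": self.dual_coef.tolist(),
            "intercept": self.intercept,
            "classes": list(self.classes),
        }

    @classmethod
    def from_dict(cls, d: dict) -> "TrainedModel":
        return cls(
            tuple(d["feature_keys"]),
            np.asarray(d["mean"], dtype=float),
            np.asarray(d["sd"], dtype=float),
            float(d["C"]),
            float(d["gamma"]),
            np.asarray(d["support_vectors"], dtype=float),
            np.asarray(d["dual_coef"], dtype=float),
            float(d["intercept"]),
            (d["classes"][0], d["classes"][1]),
        )


def train_final(
    features: FeatureMatrix,
    keys: Sequence[str],
    config: CVConfig = CVConfig(),
    evaluate: bool = True,
) -> tuple[TrainedModel, ClassifierReport]:
    """Train the final SVM on all subjects using the selected feature subset.

    Hyperparameters are tuned by inner CV over ``config.inner_grid`` on the
    full training data; the report carries CV metrics of the frozen subset.
    """
    if not keys:
        raise InvalidInputError("selected feature subset is empty")
    sub = features.subset(list(keys))
    X, y, _ = _as_xy(sub)
    if len(np.unique(y)) < 2:
        raise InvalidInputError("training labels contain a single class")
    Z, _, params = standardize(X)
    C, gamma = _tune(Z, y, config)
    gamma_val = _resolve_gamma(gamma, Z)
    svc = SVC(C=C, kernel="rbf", gamma=gamma_val)
    svc.fit(Z, y)
    model = TrainedModel(
        feature_keys=tuple(keys),
        mean=params.mean,
        sd=params.sd,
        C=float(C),
        gamma=float(gamma_val),
        support_vectors=svc.support_vectors_.copy(),
        dual_coef=svc.dual_coef_[0].copy(),
        intercept=float(svc.intercept_[0]),
        classes=(str(svc.classes_[0]), str(svc.classes_[1])),
    )
    if evaluate:
        report = cv_evaluate(sub, config=config)
    else:  # resubstitution-only report (used inside nested CV for speed)
        train_acc = float(np.mean(svc.predict(Z) == y))
        report = ClassifierReport(accuracy=train_acc, sensitivity=None,
                                  specificity=None, n=len(y))
    report.selected_features = tuple(keys)
    report.model_desc = {"kernel": "rbf", "C": float(C), "gamma": float(gamma_val)}
    return model, report


def external_validate(
    model: TrainedModel, validation_features: FeatureMatrix
) -> ClassifierReport:
    """Apply a frozen model to an external sample and report accuracy.

    For a single-class validation sample (e.g. all cases) only accuracy and
    the corresponding class rate are defined; the report flags this and
    leaves the other rate as None.
    """
    if len(validation_features.values) == 0:
        raise InvalidInputError("validation set is empty")
    pred = model.predict(validation_features)
    y = validation_features.groups.to_numpy()
    rep = _pooled_report(y, pred, [])
    rep.selected_features = model.feature_keys
    return rep


# ---------------------------------------------------------------------------
# Nested cross-validation


def nested_cv(
    features: FeatureMatrix,
    config: CVConfig = CVConfig(),
    k_max: int = 10,
    tolerance: float = 0.01,
    screen_top: int | None = None,
    final_grid: tuple[tuple[float, float | str], ...] | None = None,
) -> tuple[ClassifierReport, list[list[str]]]:
    """Unbiased CV: feature selection repeated inside every training fold.

    Returns the pooled outer-fold report and the per-fold chosen key lists.
    """
    X, y, keys = _as_xy(features)
    folds = _folds(y, config)
    df = features.values
    pred = np.empty(len(y), dtype=y.dtype)
    fold_accs, per_fold_keys = [], []
    for tr, te in folds:
        sub = FeatureMatrix(df.iloc[tr], features.groups.iloc[tr])
        trace = forward_select(
            sub, config=config, k_max=k_max,
            tolerance=tolerance, screen_top=screen_top,
        )
        chosen = trace.chosen_keys
        per_fold_keys.append(chosen)
        fit_cfg = config if final_grid is None else CVConfig(
            n_folds=config.n_folds, stratified=config.stratified,
            seed=config.seed, inner_grid=final_grid,
            inner_folds=config.inner_folds,
        )
        model, _ = train_final(sub, chosen, fit_cfg, evaluate=False)
        pred[te] = model.predict(df.iloc[te])
        fold_accs.append(float(np.mean(pred[te] == y[te])))
    return _pooled_report(y, pred, fold_accs), per_fold_keys
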