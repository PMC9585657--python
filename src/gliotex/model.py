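"""Standardization, LASSO feature selection, kernel SVM, cross-validation.

The modeling chain is: z-score standardization (parameters fitted on
training data only) → L1-penalized logistic regression over a descending
penalty grid with the penalty chosen at minimum mean cross-validated
binomial deviance, retaining the features with non-zero coefficients →
polynomial-kernel support vector machine (degrees 1/2/3 = linear /
quadratic / cubic) → pooled out-of-fold evaluation: rank-based AUC per
class and a confusion matrix at the decision-score sign threshold.

By default feature selection is re-fitted inside every cross-validation
training fold (leakage-safe); ``global_selection=True`` reproduces the simpler
design of a single global selection on the full data before CV.

The LASSO penalty follows the glmnet convention: the objective is
``(1/n) * sum(logistic deviance) + lam * ||w||_1``, so ``lam_max``
(the smallest penalty shrinking every coefficient to zero) is
``max |X^T (y - ybar)| / n`` on standardized features.
"""

from __future__ import annotations

import dataclasses

import numpy as np
import pandas as pd
from scipy import stats
from sklearn.linear_model import LogisticRegression
from sklearn.model_selection import StratifiedKFold
from sklearn.svm import SVC

KERNELS = ("linear", "quadratic", "cubic")
_KERNEL_DEGREE = {"linear": 1, "quadratic": 2, "cubic": 3}


# ---------------------------------------------------------------------------
# standardization
# ---------------------------------------------------------------------------

@dataclasses.dataclass
class StandardizationParams:
    """Per-feature training mean/SD; constant features are dropped."""

    feature_names: list[str]
    mean: np.ndarray
    sd: np.ndarray
    dropped: list[str]


def zscore_fit(train: pd.DataFrame, columns: list[str]) -> StandardizationParams:
    """Fit z-score parameters on training columns (population SD).

    Constant columns (SD == 0) are dropped with a record in ``dropped``.
    """
    if len(train) < 2:
        raise ValueError("need at least 2 training samples")
    X = train[columns].to_numpy(dtype=float)
    mean = X.mean(axis=0)
    sd = X.std(axis=0)
    keep = sd > 0
    dropped = [c for c, k in zip(columns, keep) if not k]
    kept = [c for c, k in zip(columns, keep) if k]
    return StandardizationParams(kept, mean[keep], sd[keep], dropped)


def zscore_apply(table: pd.DataFrame, params: StandardizationParams) -> np.ndarray:
    X = table[params.feature_names].to_numpy(dtype=float)
    return (X - params.mean) / params.sd


def zscore_fit_apply(
    train: pd.DataFrame, columns: list[str], other: pd.DataFrame | None = None
):
    """Fit on train, transform train (and optionally held-out data)."""
    params = zscore_fit(train, columns)
    Xtr = zscore_apply(train, params)
    if other is None:
        return Xtr, params
    return Xtr, zscore_apply(other, params), params


# ---------------------------------------------------------------------------
# LASSO selection
# ---------------------------------------------------------------------------

@dataclasses.dataclass
class SelectionResult:
    lambda_grid: np.ndarray
    chosen_lambda: float
    feature_names: list[str]          # retained (non-zero) features
    coefficients: np.ndarray          # coefficients of retained features
    cv_deviance: np.ndarray           # mean CV deviance per lambda (inf = pruned)


def lasso_max_penalty(X: np.ndarray, y: np.ndarray) -> float:
    """Smallest penalty at which every LASSO coefficient is zero."""
    y = np.asarray(y, dtype=float)
    r = y - y.mean()
    return float(np.max(np.abs(X.T @ r)) / len(y))


def default_lambda_grid(
    lam_max: float, n_points: int = 40, ratio: float | None = None, n_gt_p: bool = False
) -> np.ndarray:
    """Descending log-spaced penalty grid from ``lam_max`` down to
    ``ratio * lam_max``. The default ratio follows the glmnet convention:
    1e-2 when there are fewer samples than features, 1e-4 otherwise."""
    if ratio is None:
        ratio = 1e-4 if n_gt_p else 1e-2
    return np.geomspace(lam_max, ratio * lam_max, n_points)


def _l1_logistic(
    X: np.ndarray, y: np.ndarray, lam: float, tol: float = 1e-7, max_iter: int = 2000
) -> LogisticRegression:
    # objective (1/n)*dev + lam*||w||_1  <=>  sklearn C = 1 / (n * lam)
    C = 1.0 / max(len(y) * lam, 1e-12)
    clf = LogisticRegression(l1_ratio=1.0, C=C, solver="liblinear", max_iter=max_iter, tol=tol)
    clf.fit(X, y)
    return clf


def _binomial_deviance(y: np.ndarray, p: np.ndarray) -> float:
    eps = 1e-12
    p = np.clip(p, eps, 1 - eps)
    return float(-2.0 * np.mean(y * np.log(p) + (1 - y) * np.log(1 - p)))


def lasso_select(
    X: np.ndarray,
    y: np.ndarray,
    feature_names: list[str],
    lambda_grid: np.ndarray | None = None,
    cv_folds: int = 10,
    seed: int = 0,
    n_lambda: int = 40,
) -> SelectionResult:
    """L1-penalized logistic path with CV choice of the penalty.

    ``X`` must already be standardized; ``y`` binary in {0, 1} with both
    classes present. The penalty is chosen at the minimum mean CV binomial
    deviance ("lambda.min"); the retained set is the features with non-zero
    coefficients at that penalty, refitted on all of ``X``.
    """
    X = np.asarray(X, dtype=float)
    y = np.asarray(y, dtype=int)
    if len(np.unique(y)) < 2:
        raise ValueError("both classes required")
    if lambda_grid is None:
        lambda_grid = default_lambda_grid(
            lasso_max_penalty(X, y), n_points=n_lambda, n_gt_p=X.shape[0] > X.shape[1]
        )
    lambda_grid = np.asarray(lambda_grid, dtype=float)
    if lambda_grid.size == 0:
        raise ValueError("empty lambda grid")
    lambda_grid = np.sort(lambda_grid)[::-1]

    n_folds = min(cv_folds, int(np.bincount(y).min()))
    if n_folds < 2:
        raise ValueError("minority class too small for CV")
    skf = StratifiedKFold(n_splits=n_folds, shuffle=True, random_state=seed)
    folds = list(skf.split(X, y))
    # walk the path from lam_max downward; once the mean CV deviance has not
    # improved for `patience` consecutive penalties the curve is past its
    # minimum and the remaining (densest, slowest) fits are pruned
    patience = 8
    dev = np.full(lambda_grid.size, np.inf)
    best_k = 0
    for k, lam in enumerate(lambda_grid):
        total = 0.0
        for tr, te in folds:
            # path fits use a looser tolerance; only the final refit is tight
            clf = _l1_logistic(X[tr], y[tr], lam, tol=1e-4, max_iter=150)
            p = clf.predict_proba(X[te])[:, 1]
            total += _binomial_deviance(y[te], p)
        dev[k] = total / n_folds
        if dev[k] < dev[best_k]:
            best_k = k
        elif k - best_k >= patience:
            break

    chosen = float(lambda_grid[best_k])
    final = _l1_logistic(X, y, chosen)
    coefs = final.coef_.ravel()
    nz = np.abs(coefs) > 0
    return SelectionResult(
        lambda_grid=lambda_grid,
        chosen_lambda=chosen,
        feature_names=[f for f, keep in zip(feature_names, nz) if keep],
        coefficients=coefs[nz],
        cv_deviance=dev,
    )


# ---------------------------------------------------------------------------
# SVM
# ---------------------------------------------------------------------------

@dataclasses.dataclass
class TrainedClassifier:
    kernel: str
    svc: SVC
    standardization: StandardizationParams | None
    feature_names: list[str]

    def decision_scores(self, X: np.ndarray) -> np.ndarray:
        return self.svc.decision_function(X)

    def predict(self, X: np.ndarray) -> np.ndarray:
        return (self.decision_scores(X) > 0).astype(int)


def svm_train(
    X: np.ndarray,
    y: np.ndarray,
    kernel: str = "quadratic",
    C: float = 1.0,
    feature_names: list[str] | None = None,
    standardization: StandardizationParams | None = None,
) -> TrainedClassifier:
    """Fit a polynomial-kernel SVM on standardized features.

    ``kernel`` is linear/quadratic/cubic (polynomial degree 1/2/3, unit
    scale, zero offset, box constraint ``C``).
    """
    if kernel not in KERNELS:
        raise ValueError(f"unknown kernel {kernel!r}; expected one of {KERNELS}")
    if C <= 0:
        raise ValueError("C must be positive")
    y = np.asarray(y, dtype=int)
    if len(np.unique(y)) < 2:
        raise ValueError("both classes required for SVM training")
    degree = _KERNEL_DEGREE[kernel]
    if degree == 1:
        svc = SVC(kernel="linear", C=C)
    else:
        svc = SVC(kernel="poly", degree=degree, gamma=1.0, coef0=0.0, C=C)
    svc.fit(np.asarray(X, dtype=float), y)
    return TrainedClassifier(kernel, svc, standardization, feature_names or [])


# ---------------------------------------------------------------------------
# metrics
# ---------------------------------------------------------------------------

@dataclasses.dataclass
class ConfusionMatrix:
    tp: int
    tn: int
    fp: int
    fn: int

    def __post_init__(self) -> None:
        if min(self.tp, self.tn, self.fp, self.fn) < 0:
            raise ValueError("negative counts")

    @property
    def total(self) -> int:
        return self.tp + self.tn + self.fp + self.fn

    def swapped(self) -> "ConfusionMatrix":
        """The same table with the opposite class designated positive."""
        return ConfusionMatrix(tp=self.tn, tn=self.tp, fp=self.fn, fn=self.fp)


@dataclasses.dataclass
class ClassMetrics:
    sensitivity: float | None
    specificity: float | None
    ppv: float | None
    npv: float | None
    fnr: float | None
    accuracy: float


def _ratio(num: int, den: int) -> float | None:
    return None if den == 0 else num / den


def confusion_metrics(cm: ConfusionMatrix) -> ClassMetrics:
    """Derived diagnostic rates; 0/0 ratios are reported as missing (None)."""
    if cm.total == 0:
        raise ValueError("empty confusion matrix")
    sens = _ratio(cm.tp, cm.tp + cm.fn)
    return ClassMetrics(
        sensitivity=sens,
        specificity=_ratio(cm.tn, cm.tn + cm.fp),
        ppv=_ratio(cm.tp, cm.tp + cm.fp),
        npv=_ratio(cm.tn, cm.tn + cm.fn),
        fnr=None if sens is None else 1.0 - sens,
        accuracy=(cm.tp + cm.tn) / cm.total,
    )


def roc_auc(scores: np.ndarray, labels: np.ndarray) -> float:
    """Rank-based (Mann–Whitney) AUC with half-credit for tied scores."""
    scores = np.asarray(scores, dtype=float)
    y = np.asarray(labels, dtype=int)
    n_pos = int(y.sum())
    n_neg = len(y) - n_pos
    if n_pos == 0 or n_neg == 0:
        raise ValueError("both classes required for AUC")
    ranks = stats.rankdata(scores)
    return float((ranks[y == 1].sum() - n_pos * (n_pos + 1) / 2) / (n_pos * n_neg))


# ---------------------------------------------------------------------------
# cross-validation
# ---------------------------------------------------------------------------

@dataclasses.dataclass
class CVResult:
    scores: np.ndarray            # pooled out-of-fold decision scores
    predictions: np.ndarray       # pooled out-of-fold 0/1 predictions
    y_true: np.ndarray
    fold_assignment: np.ndarray   # test-fold id per sample
    auc_positive: float           # positive class designated positive
    auc_negative: float           # negative class designated positive
    confusion: ConfusionMatrix
    metrics: ClassMetrics
    retained_features: list[list[str]]   # per fold (or single global set)
    seed: int


def crossvalidate(
    table: pd.DataFrame,
    feature_cols: list[str],
    splits: list[tuple[np.ndarray, np.ndarray]],
    kernel: str = "quadratic",
    C: float = 1.0,
    select: bool = True,
    global_selection: bool = False,
    lambda_grid: np.ndarray | None = None,
    selection_cv_folds: int = 10,
    n_lambda: int = 40,
    seed: int = 0,
    positive_label: str = "mutant",
) -> CVResult:
    """Fit-and-score over precomputed splits, pooling out-of-fold scores.

    Standardization and (by default) LASSO selection are re-fitted inside
    each training fold. ``global_selection=True`` instead performs one global
    selection on the full standardized table before the CV loop. The
    confusion matrix uses the decision-score sign; AUC is rank-based and
    reported with either class designated positive.
    """
    y = (table["label"].to_numpy() == positive_label).astype(int)
    n = len(table)
    scores = np.full(n, np.nan)
    fold_of = np.full(n, -1, dtype=int)
    retained: list[list[str]] = []

    global_features: list[str] | None = None
    if select and global_selection:
        Xall, params_all = zscore_fit_apply(table, feature_cols)
        sel = lasso_select(Xall, y, params_all.feature_names,
                           lambda_grid, selection_cv_folds, seed, n_lambda)
        global_features = sel.feature_names
        retained.append(global_features)

    for fold_id, (tr, te) in enumerate(splits):
        train, test = table.iloc[tr], table.iloc[te]
        ytr = y[tr]
        if len(np.unique(ytr)) < 2:
            raise ValueError(f"fold {fold_id}: training data lacks one class")
        cols = feature_cols
        if global_features is not None:
            cols = global_features
        Xtr, Xte, params = zscore_fit_apply(train, cols, test)
        if select and not global_selection:
            sel = lasso_select(Xtr, ytr, params.feature_names,
                               lambda_grid, selection_cv_folds, seed + fold_id, n_lambda)
            use = sel.feature_names if sel.feature_names else params.feature_names
            retained.append(sel.feature_names)
            idx = [params.feature_names.index(f) for f in use]
            Xtr, Xte = Xtr[:, idx], Xte[:, idx]
        clf = svm_train(Xtr, ytr, kernel, C)
        scores[te] = clf.decision_scores(Xte)
        fold_of[te] = fold_id

    if np.isnan(scores).any():
        raise RuntimeError("some samples were never scored out-of-fold")
    preds = (scores > 0).astype(int)
    cm = ConfusionMatrix(
        tp=int(((preds == 1) & (y == 1)).sum()),
        tn=int(((preds == 0) & (y == 0)).sum()),
        fp=int(((preds == 1) & (y == 0)).sum()),
        fn=int(((preds == 0) & (y == 1)).sum()),
    )
    auc_pos = roc_auc(scores, y)
    auc_neg = roc_auc(-scores, 1 - y)
    return CVResult(
        scores=scores,
        predictions=preds,
        y_true=y,
        fold_assignment=fold_of,
        auc_positive=auc_pos,
        auc_negative=auc_neg,
        confusion=cm,
        metrics=confusion_metrics(cm),
        retained_features=retained,
        seed=seed,
    )
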