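"""Nested cross-validated classification with exact Shapley attributions.

Binary group comparisons (e.g. control vs strongly treated) over the
behavioural feature table, with three model families — SVM, random
forest and k-nearest neighbours — tuned by grid search in a stratified
4x4 nested cross-validation. Features are standardised inside each
training portion only (no leakage); outer-fold predictions are pooled
into one overall confusion matrix. Feature influence is quantified with
exact Shapley values computed by full coalition enumeration against a
background set, so the efficiency identity (attributions sum to
prediction minus baseline) holds to machine precision.
"""

from __future__ import annotations

import itertools
import math
import warnings
from dataclasses import dataclass, field
from typing import Callable, Mapping, Sequence

import numpy as np
import pandas as pd
from sklearn.base import clone
from sklearn.ensemble import RandomForestClassifier
from sklearn.model_selection import StratifiedKFold
from sklearn.neighbors import KNeighborsClassifier
from sklearn.pipeline import Pipeline
from sklearn.preprocessing import StandardScaler
from sklearn.svm import SVC

from .errors import InvalidParameterError, StratificationError
from .features import FEATURE_COLUMNS

__all__ = [
    "GridSpec",
    "CVResult",
    "ConfusionMetrics",
    "ShapExplanation",
    "ComparisonResult",
    "make_model",
    "nested_cv",
    "confusion_metrics",
    "exact_shapley",
    "explain_matrix",
    "compare_groups",
]

MODEL_NAMES = ("svm", "rf", "knn")


@dataclass(frozen=True)
class GridSpec:
    """Hyperparameter grids.

    Defaults: SVM C over the decade ladder 0.01..100 with linear and rbf
    kernels; random forest with 20-300 trees and depth 2-5; KNN with k
    in 3..15 (odd). Candidate order is simplest-first (smaller C, fewer
    and shallower trees, larger k) so grid-search ties resolve toward
    the simpler model.
    """

    svm_c: tuple[float, ...] = (0.01, 0.1, 1.0, 10.0, 100.0)
    svm_kernels: tuple[str, ...] = ("linear", "rbf")
    rf_n_estimators: tuple[int, ...] = (20, 50, 100, 150, 200, 250, 300)
    rf_max_depth: tuple[int, ...] = (2, 3, 4, 5)
    knn_k: tuple[int, ...] = (3, 5, 7, 9, 11, 13, 15)

    def __post_init__(self):
        if not (self.svm_c and self.svm_kernels and self.rf_n_estimators
                and self.rf_max_depth and self.knn_k):
            raise InvalidParameterError("grids must be non-empty")

    def candidates(self, model: str) -> list[dict]:
        if model == "svm":
            return [{"C": c, "kernel": k}
                    for c in sorted(self.svm_c) for k in self.svm_kernels]
        if model == "rf":
            return [{"n_estimators": n, "max_depth": d}
                    for n in sorted(self.rf_n_estimators)
                    for d in sorted(self.rf_max_depth)]
        if model == "knn":
            return [{"n_neighbors": k} for k in sorted(self.knn_k, reverse=True)]
        raise InvalidParameterError(f"unknown model '{model}'")


def make_model(model: str, params: dict, seed: int = 0) -> Pipeline:
    """Standardiser + classifier pipeline for one hyperparameter setting."""
    if model == "svm":
        clf = SVC(C=params["C"], kernel=params["kernel"],
                  random_state=seed % (2 ** 31))
    elif model == "rf":
        clf = RandomForestClassifier(n_estimators=params["n_estimators"],
                                     max_depth=params["max_depth"],
                                     random_state=seed % (2 ** 31))
    elif model == "knn":
        clf = KNeighborsClassifier(n_neighbors=params["n_neighbors"])
    else:
        raise InvalidParameterError(f"unknown model '{model}'")
    return Pipeline([("scale", StandardScaler()), ("clf", clf)])


@dataclass
class ConfusionMetrics:
    accuracy: float
    precision: float
    recall: float
    f1: float


def confusion_metrics(cm: np.ndarray) -> ConfusionMetrics:
    """Accuracy, precision, recall, F1 from a binary confusion matrix.

    Layout: rows = true class (0, 1), columns = predicted; class 1 is
    positive. Zero-denominator ratios are NaN with a warning.
    """
    cm = np.asarray(cm)
    if cm.shape != (2, 2):
        raise InvalidParameterError("confusion matrix must be 2x2")
    if (cm < 0).any() or cm.sum() == 0:
        raise InvalidParameterError("entries must be non-negative with positive total")
    tn, fp = float(cm[0, 0]), float(cm[0, 1])
    fn, tp = float(cm[1, 0]), float(cm[1, 1])
    acc = (tp + tn) / (tp + tn + fp + fn)

    def _ratio(num, den, name):
        if den == 0:
            warnings.warn(f"{name} undefined (zero denominator)")
            return float("nan")
        return num / den

    prec = _ratio(tp, tp + fp, "precision")
    rec = _ratio(tp, tp + fn, "recall")
    if math.isnan(prec) or math.isnan(rec) or prec + rec == 0:
        f1 = 0.0 if (prec == 0 or rec == 0) and not (math.isnan(prec) or math.isnan(rec)) else float("nan")
    else:
        f1 = 2 * prec * rec / (prec + rec)
    return ConfusionMetrics(accuracy=acc, precision=prec, recall=rec, f1=f1)


@dataclass
class CVResult:
    """Pooled nested-CV outcome for one model family."""

    model: str
    confusion: np.ndarray
    fold_params: list[dict]
    accuracy: float
    precision: float
    recall: float
    f1: float
    seed: int


def _select_params(X: np.ndarray, y: np.ndarray, model: str, grid: GridSpec,
                   k_inner: int, seed: int) -> dict:
    """Inner grid search: mean accuracy over stratified folds; first
    candidate wins ties (candidates are ordered simplest-first). The
    fold count shrinks to the smallest class when the training portion
    is very small."""
    min_class = int(np.bincount(y, minlength=2).min())
    if min_class < 2:
        raise StratificationError("need >= 2 training samples per class")
    inner = StratifiedKFold(n_splits=min(k_inner, min_class), shuffle=True,
                            random_state=seed % (2 ** 31))
    splits = list(inner.split(X, y))
    best_params, best_score = None, -np.inf
    for params in grid.candidates(model):
        scores = []
        try:
            for tr, te in splits:
                pipe = make_model(model, params, seed=seed)
                pipe.fit(X[tr], y[tr])
                scores.append(float((pipe.predict(X[te]) == y[te]).mean()))
        except ValueError:
            continue  # infeasible for this training size (e.g. k > n)
        score = float(np.mean(scores))
        if score > best_score:
            best_score, best_params = score, params
    if best_params is None:
        raise StratificationError("no hyperparameter candidate is feasible "
                                  "for this training-set size")
    return best_params


def nested_cv(X, y, model: str, grid: GridSpec | None = None,
              k_outer: int = 4, k_inner: int = 4, seed: int = 0) -> CVResult:
    """Stratified nested cross-validation for one model family.

    The outer loop estimates generalisation; per outer-training set the
    inner loop grid-searches hyperparameters by mean accuracy.
    Standardisation is fitted inside each training portion. Outer test
    predictions are pooled into a single confusion matrix. Deterministic
    under ``seed``.
    """
    grid = grid or GridSpec()
    X = np.asarray(X, dtype=float)
    y = np.asarray(y).astype(int)
    if set(np.unique(y)) - {0, 1}:
        raise InvalidParameterError("labels must be binary 0/1")
    counts = np.bincount(y, minlength=2)
    if (counts < k_outer).any():
        raise StratificationError(
            f"each class needs >= {k_outer} samples for {k_outer}-fold stratification")
    outer = StratifiedKFold(n_splits=k_outer, shuffle=True,
                            random_state=seed % (2 ** 31))
    cm = np.zeros((2, 2), dtype=int)
    fold_params: list[dict] = []
    for i, (tr, te) in enumerate(outer.split(X, y)):
        params = _select_params(X[tr], y[tr], model, grid, k_inner,
                                seed=seed * 31 + i + 1)
        fold_params.append(params)
        pipe = make_model(model, params, seed=seed * 31 + i + 1)
        pipe.fit(X[tr], y[tr])
        pred = pipe.predict(X[te])
        for t, p in zip(y[te], pred):
            cm[t, p] += 1
    m = confusion_metrics(cm)
    return CVResult(model=model, confusion=cm, fold_params=fold_params,
                    accuracy=m.accuracy, precision=m.precision,
                    recall=m.recall, f1=m.f1, seed=seed)


@dataclass
class ShapExplanation:
    """Exact Shapley attribution of one prediction.

    ``baseline`` is the mean prediction over the background set;
    ``values`` sum to ``prediction - baseline`` exactly (efficiency).
    """

    values: np.ndarray
    baseline: float
    prediction: float


def exact_shapley(predict_fn: Callable[[np.ndarray], np.ndarray],
                  x: np.ndarray, background: np.ndarray,
                  max_features: int = 15) -> ShapExplanation:
    """Shapley values by full coalition enumeration.

    The value of a coalition S is the mean prediction over
    background-completed inputs in which features in S take the sample's
    values. All 2^d coalitions are evaluated in one batched call, and
    each feature receives its exactly weighted average marginal
    contribution — no sampling approximation.

    Raises an error beyond ``max_features`` features (enumeration cost
    doubles per feature; use a sampling approximation at that scale,
    which this package deliberately does not provide).
    """
    x = np.asarray(x, dtype=float).ravel()
    background = np.atleast_2d(np.asarray(background, dtype=float))
    d = x.size
    if background.shape[1] != d:
        raise InvalidParameterError("background width must match the sample")
    if background.shape[0] == 0:
        raise InvalidParameterError("background must be non-empty")
    if d > max_features:
        raise InvalidParameterError(
            f"{d} features exceed the exact-enumeration limit ({max_features}); "
            "a sampling-based approximation would be required")
    n_bg = background.shape[0]
    n_sub = 1 << d
    # one batched prediction over every coalition x background row
    big = np.tile(background, (n_sub, 1))
    for m in range(n_sub):
        rows = slice(m * n_bg, (m + 1) * n_bg)
        for i in range(d):
            if m >> i & 1:
                big[rows, i] = x[i]
    preds = np.asarray(predict_fn(big), dtype=float).reshape(n_sub, n_bg)
    v = preds.mean(axis=1)

    fact = [math.factorial(k) for k in range(d + 1)]
    weights = [fact[s] * fact[d - s - 1] / fact[d] for s in range(d)]
    popcount = np.array([bin(m).count("1") for m in range(n_sub)])
    values = np.zeros(d)
    for i in range(d):
        bit = 1 << i
        without = np.flatnonzero((np.arange(n_sub) & bit) == 0)
        w = np.array([weights[s] for s in popcount[without]])
        values[i] = float(np.sum(w * (v[without | bit] - v[without])))
    return ShapExplanation(values=values, baseline=float(v[0]),
                           prediction=float(v[-1]))


def explain_matrix(predict_fn, X: np.ndarray, background: np.ndarray,
                   max_features: int = 15) -> np.ndarray:
    """Exact Shapley values for every row of X; returns (n, d)."""
    X = np.atleast_2d(np.asarray(X, dtype=float))
    return np.stack([exact_shapley(predict_fn, row, background, max_features).values
                     for row in X])


PAIR_ALIASES = {
    "control-lc30": ("control", "lc30"),
    "control-lc10": ("control", "lc10"),
    "lc10-lc30": ("lc10", "lc30"),
}


@dataclass
class ComparisonResult:
    pair: tuple[str, str]
    results: dict[str, CVResult]
    mean_accuracy: float
    mean_precision: float
    shap_summary: pd.Series | None
    shap_values: pd.DataFrame | None


def compare_groups(table: pd.DataFrame, pair, models: Sequence[str] = MODEL_NAMES,
                   grid: GridSpec | None = None, seed: int = 0,
                   feature_cols: Sequence[str] = tuple(FEATURE_COLUMNS),
                   group_col: str = "group", k_outer: int = 4, k_inner: int = 4,
                   shap: bool = True, shap_model: str = "knn",
                   shap_background: int = 64,
                   shap_max_samples: int = 16) -> ComparisonResult:
    """One binary comparison over the feature table, all requested models.

    Runs :func:`nested_cv` per model family and averages accuracy and
    precision across families. When ``shap`` is on, Shapley summaries are
    computed for the KNN model (its class-1 neighbourhood proportion is a
    probability-like output, so attributions are not step functions):
    per outer fold, hyperparameters are re-selected on the training
    portion, the pipeline refitted, and up to ``shap_max_samples`` test
    rows explained against a training background capped at
    ``shap_background`` rows by seeded subsampling.
    """
    grid = grid or GridSpec()
    if isinstance(pair, str):
        key = pair.lower()
        if key not in PAIR_ALIASES:
            raise InvalidParameterError(
                f"unknown pair '{pair}'; expected one of {sorted(PAIR_ALIASES)} "
                "or a (group_a, group_b) tuple")
        pair = PAIR_ALIASES[key]
    ga, gb = pair
    present = set(table[group_col].unique())
    if ga not in present or gb not in present:
        raise InvalidParameterError(f"groups {pair} not both present in the table")
    sub = table[table[group_col].isin([ga, gb])]
    X = sub[list(feature_cols)].to_numpy(dtype=float)
    y = (sub[group_col] == gb).to_numpy().astype(int)

    results = {m: nested_cv(X, y, m, grid, k_outer, k_inner, seed) for m in models}
    mean_acc = float(np.mean([r.accuracy for r in results.values()]))
    mean_prec = float(np.nanmean([r.precision for r in results.values()]))

    shap_summary = shap_df = None
    if shap and shap_model in models:
        rng = np.random.default_rng(seed % (2 ** 31))
        outer = StratifiedKFold(n_splits=k_outer, shuffle=True,
                                random_state=seed % (2 ** 31))
        all_vals, all_rows = [], []
        for i, (tr, te) in enumerate(outer.split(X, y)):
            params = _select_params(X[tr], y[tr], shap_model, grid, k_inner,
                                    seed=seed * 31 + i + 1)
            pipe = make_model(shap_model, params, seed=seed * 31 + i + 1)
            pipe.fit(X[tr], y[tr])
            bg_idx = tr if len(tr) <= shap_background else rng.choice(
                tr, size=shap_background, replace=False)
            te_idx = te if len(te) <= shap_max_samples else rng.choice(
                te, size=shap_max_samples, replace=False)
            fn = lambda A: pipe.predict_proba(A)[:, 1]
            vals = explain_matrix(fn, X[te_idx], X[bg_idx])
            all_vals.append(vals)
            all_rows.extend(te_idx.tolist())
        V = np.vstack(all_vals)
        shap_df = pd.DataFrame(V, columns=list(feature_cols))
        shap_df.insert(0, "row", all_rows)
        shap_summary = shap_df[list(feature_cols)].abs().mean()
    return ComparisonResult(pair=(ga, gb), results=results,
                            mean_accuracy=mean_acc, mean_precision=mean_prec,
                            shap_summary=shap_summary, shap_values=shap_df)
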