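"""Supervised models for the three prediction tasks, with 10-fold
cross-validation, greedy forward feature selection and the evaluation
metrics used throughout: MCC, F1, balanced accuracy and AUC for
classification; Pearson, Spearman, Kendall (tau-b), MSE and RMSE for
regression.

Four learner families are supported with fixed hyperparameters (random
forest and extra trees with 300 estimators; a single-hidden-layer MLP with
relu activation and the adam solver; an RBF-kernel SVM).  Aggregate
cross-validation metrics are computed on pooled out-of-fold predictions;
per-fold means are reported alongside, since the two conventions can differ
noticeably (e.g. mean-of-folds ROC vs pooled ROC).
"""

from __future__ import annotations

import logging
import math
from dataclasses import dataclass, field
from typing import Optional, Sequence

import numpy as np
import pandas as pd
from scipy import stats
from sklearn.ensemble import (
    ExtraTreesClassifier,
    ExtraTreesRegressor,
    RandomForestClassifier,
    RandomForestRegressor,
)
from sklearn.metrics import roc_auc_score
from sklearn.model_selection import KFold, StratifiedKFold
from sklearn.neural_network import MLPClassifier, MLPRegressor
from sklearn.svm import SVC, SVR

from .chem_io import TYPE_VOCABULARY

logger = logging.getLogger(__name__)

FAMILIES = ("random_forest", "extra_trees", "mlp", "svm")


class UndefinedMetricError(ValueError):
    """A metric is undefined for the given inputs (single class, constant
    vector, ...)."""


class FoldError(ValueError):
    """Cross-validation folding cannot satisfy its preconditions."""


class SmallClassError(ValueError):
    """A class has too few examples to train on."""


# ---------------------------------------------------------------------------
# model specs


@dataclass(frozen=True)
class ModelSpec:
    """A learner family bound to a task with fixed hyperparameters.

    ``overrides`` may replace any estimator parameter explicitly (recorded in
    reports); everything else stays at the stated defaults.
    """

    family: str
    task: str  # "classification" or "regression"
    seed: int = 0
    overrides: tuple = ()  # tuple of (param, value) pairs, hashable

    def __post_init__(self):
        if self.family not in FAMILIES:
            raise ValueError(f"unknown family {self.family!r}; choose from {FAMILIES}")
        if self.task not in ("classification", "regression"):
            raise ValueError(f"task must be classification or regression")


def build_estimator(spec: ModelSpec):
    """Instantiate the scikit-learn estimator for a spec."""
    clf = spec.task == "classification"
    if spec.family == "random_forest":
        est = (RandomForestClassifier if clf else RandomForestRegressor)(
            n_estimators=300, random_state=spec.seed, n_jobs=1
        )
    elif spec.family == "extra_trees":
        est = (ExtraTreesClassifier if clf else ExtraTreesRegressor)(
            n_estimators=300, random_state=spec.seed, n_jobs=1
        )
    elif spec.family == "mlp":
        est = (MLPClassifier if clf else MLPRegressor)(
            activation="relu",
            solver="adam",
            hidden_layer_sizes=(100,),
            max_iter=500,
            random_state=spec.seed,
        )
    else:  # svm
        est = SVC(kernel="rbf", C=1.0, gamma="scale") if clf else SVR(kernel="rbf")
    if spec.overrides:
        est.set_params(**dict(spec.overrides))
    return est


# ---------------------------------------------------------------------------
# metrics


def _as_binary(v, name: str) -> np.ndarray:
    arr = np.asarray(v)
    if arr.ndim != 1 or arr.size == 0:
        raise UndefinedMetricError(f"{name} must be a non-empty 1-d array")
    uniq = set(np.unique(arr).tolist())
    if not uniq <= {0, 1}:
        raise UndefinedMetricError(f"{name} must be binary 0/1, got values {sorted(uniq)}")
    return arr.astype(int)


def confusion_metrics_from_table(tp: int, fp: int, fn: int, tn: int) -> dict:
    """MCC, F1 and balanced accuracy from a 2x2 confusion table.

    MCC with a zero denominator is defined as 0 (logged), so degenerate
    all-one-class predictions never crash a fold.
    """
    tp, fp, fn, tn = (int(v) for v in (tp, fp, fn, tn))
    if min(tp, fp, fn, tn) < 0 or tp + fp + fn + tn == 0:
        raise UndefinedMetricError("confusion table must be non-negative and non-empty")
    denom = math.sqrt(
        float(tp + fp) * float(tp + fn) * float(tn + fp) * float(tn + fn)
    )
    if denom == 0:
        logger.debug("MCC denominator zero (tp=%d fp=%d fn=%d tn=%d); using 0", tp, fp, fn, tn)
        mcc = 0.0
    else:
        mcc = (tp * tn - fp * fn) / denom
    f1 = 2 * tp / (2 * tp + fp + fn) if (2 * tp + fp + fn) > 0 else 0.0
    tpr = tp / (tp + fn) if (tp + fn) > 0 else 0.0
    tnr = tn / (tn + fp) if (tn + fp) > 0 else 0.0
    bacc = 0.5 * (tpr + tnr)
    return {"MCC": float(mcc), "F1": float(f1), "BACC": float(bacc)}


def confusion_metrics(y, yhat) -> dict:
    """MCC, F1 and balanced accuracy for binary labels/predictions."""
    y = _as_binary(y, "y")
    yhat = _as_binary(yhat, "yhat")
    if y.size != yhat.size:
        raise UndefinedMetricError("y and yhat must have equal length")
    tp = int(np.sum((y == 1) & (yhat == 1)))
    fp = int(np.sum((y == 0) & (yhat == 1)))
    fn = int(np.sum((y == 1) & (yhat == 0)))
    tn = int(np.sum((y == 0) & (yhat == 0)))
    return confusion_metrics_from_table(tp, fp, fn, tn)


def auc(y, scores) -> float:
    """ROC AUC: the probability that a random positive outranks a random
    negative, ties counted one half (rank / Mann-Whitney formulation)."""
    y = _as_binary(y, "y")
    scores = np.asarray(scores, dtype=float)
    if len(set(y.tolist())) < 2:
        raise UndefinedMetricError("AUC undefined: both classes must be present")
    return float(roc_auc_score(y, scores))


def regression_metrics(y, yhat) -> dict:
    """Pearson, Spearman, Kendall tau-b, MSE and RMSE.

    Correlations are undefined for constant inputs; the raised error still
    carries ``mse``/``rmse`` attributes so callers can keep the error terms.
    """
    y = np.asarray(y, dtype=float)
    yhat = np.asarray(yhat, dtype=float)
    if y.size != yhat.size or y.size < 3:
        raise UndefinedMetricError("need equal-length vectors of length >= 3")
    mse = float(np.mean((y - yhat) ** 2))
    rmse = float(math.sqrt(mse))
    if np.var(y) == 0 or np.var(yhat) == 0:
        err = UndefinedMetricError(
            "correlations undefined for constant input (MSE/RMSE still available)"
        )
        err.mse, err.rmse = mse, rmse
        raise err
    pearson = float(stats.pearsonr(y, yhat).statistic)
    spearman = float(stats.spearmanr(y, yhat).statistic)
    kendall = float(stats.kendalltau(y, yhat, variant="b").statistic)
    return {
        "Pearson": pearson,
        "Spearman": spearman,
        "Kendall": kendall,
        "MSE": mse,
        "RMSE": rmse,
    }


# ---------------------------------------------------------------------------
# cross-validation


@dataclass
class EvalReport:
    """Per-fold and aggregate metrics for one model/task.

    ``pooled`` metrics are computed on pooled out-of-fold predictions (the
    aggregation convention, recorded in ``notes``); ``fold_mean`` averages
    the per-fold metrics instead.
    """

    task: str
    family: str
    k: int
    seed: int
    per_fold: list
    pooled: dict
    fold_mean: dict
    oof_prediction: np.ndarray
    oof_score: Optional[np.ndarray] = None
    selected_features: Optional[list] = None
    notes: dict = field(default_factory=dict)

    def to_dict(self) -> dict:
        return {
            "task": self.task,
            "family": self.family,
            "k": self.k,
            "seed": self.seed,
            "per_fold": self.per_fold,
            "pooled": self.pooled,
            "fold_mean": self.fold_mean,
            "selected_features": self.selected_features,
            "notes": self.notes,
        }


def _scores_for(est, X) -> Optional[np.ndarray]:
    if hasattr(est, "predict_proba"):
        return est.predict_proba(X)[:, -1]
    if hasattr(est, "decision_function"):
        return est.decision_function(X)
    return None


def _to_array(X):
    if isinstance(X, pd.DataFrame):
        return X.to_numpy(dtype=float)
    return np.asarray(X, dtype=float)


def cross_validate(
    spec: ModelSpec, X, y, k: int = 10, seed: Optional[int] = None
) -> EvalReport:
    """k-fold cross-validation (stratified for classification).

    Deterministic given the seed.  Raises :class:`FoldError` when a class is
    too small to appear in every fold, suggesting a smaller k.
    """
    X = _to_array(X)
    y = np.asarray(y)
    if X.shape[0] != y.size:
        raise ValueError("X and y length mismatch")
    if X.shape[0] < k:
        raise FoldError(f"n={X.shape[0]} < k={k}")
    seed = spec.seed if seed is None else seed
    clf = spec.task == "classification"
    if clf:
        y = _as_binary(y, "y")
        counts = np.bincount(y, minlength=2)
        if counts.min() < k:
            raise FoldError(
                f"smallest class has {counts.min()} examples < k={k}; use a smaller k"
            )
        splitter = StratifiedKFold(n_splits=k, shuffle=True, random_state=seed)
        folds = splitter.split(X, y)
    else:
        y = y.astype(float)
        splitter = KFold(n_splits=k, shuffle=True, random_state=seed)
        folds = splitter.split(X)

    oof_pred = np.empty(y.size, dtype=float)
    oof_score = np.empty(y.size, dtype=float) if clf else None
    have_scores = True
    per_fold = []
    for fold_i, (tr, te) in enumerate(folds):
        est = build_estimator(spec)
        est.fit(X[tr], y[tr])
        pred = est.predict(X[te])
        oof_pred[te] = pred
        entry = {"fold": fold_i, "n_test": int(te.size)}
        if clf:
            if len(set(y[te].tolist())) < 2:
                raise FoldError(
                    f"fold {fold_i} lost a class despite stratification; use a smaller k"
                )
            entry.update(confusion_metrics(y[te], pred.astype(int)))
            scores = _scores_for(est, X[te])
            if scores is None:
                have_scores = False
            else:
                oof_score[te] = scores
                entry["AUC"] = auc(y[te], scores)
        else:
            try:
                entry.update(regression_metrics(y[te], pred))
            except UndefinedMetricError as exc:
                entry.update({"MSE": exc.mse, "RMSE": exc.rmse})
        per_fold.append(entry)

    if clf:
        pooled = confusion_metrics(y, oof_pred.astype(int))
        if have_scores:
            pooled["AUC"] = auc(y, oof_score)
        else:
            oof_score = None
    else:
        pooled = regression_metrics(y, oof_pred)
    metric_names = [m for m in per_fold[0] if m not in ("fold", "n_test")]
    fold_mean = {
        m: float(np.mean([f[m] for f in per_fold if m in f])) for m in metric_names
    }
    return EvalReport(
        task=spec.task,
        family=spec.family,
        k=k,
        seed=seed,
        per_fold=per_fold,
        pooled=pooled,
        fold_mean=fold_mean,
        oof_prediction=oof_pred,
        oof_score=oof_score,
        notes={
            "aggregate_convention": "pooled out-of-fold predictions",
            "overrides": dict(spec.overrides),
        },
    )


# ---------------------------------------------------------------------------
# greedy forward feature selection


def greedy_select(
    X,
    y,
    spec: ModelSpec,
    metric: Optional[str] = None,
    patience: int = 3,
    k: int = 10,
    seed: Optional[int] = None,
    max_features: Optional[int] = None,
) -> list:
    """Bottom-up greedy feature selection.

    Starting from the empty set, each round adds the single feature that
    maximises the cross-validated metric (MCC for classification, Pearson r
    for regression by default); ties go to the earlier column.  Selection
    stops after ``patience`` consecutive rounds without improvement and
    returns the best-scoring prefix (feature names for DataFrames, column
    indices otherwise).
    """
    names = list(X.columns) if isinstance(X, pd.DataFrame) else list(range(np.asarray(X).shape[1]))
    Xa = _to_array(X)
    if Xa.shape[1] < 2:
        raise ValueError("need at least 2 candidate features")
    metric = metric or ("MCC" if spec.task == "classification" else "Pearson")

    def score(cols) -> float:
        try:
            report = cross_validate(spec, Xa[:, cols], y, k=k, seed=seed)
            return report.pooled.get(metric, -math.inf)
        except (UndefinedMetricError, FoldError):
            return -math.inf

    selected: list = []
    best_score = -math.inf
    best_prefix_len = 0
    stall = 0
    limit = max_features or len(names)
    while len(selected) < limit and stall < patience:
        remaining = [j for j in range(len(names)) if j not in selected]
        if not remaining:
            break
        round_scores = [(score(selected + [j]), -j) for j in remaining]
        best_j = remaining[int(np.argmax([s for s, _ in round_scores]))]
        # argmax returns the first maximum, which is the lowest column index
        round_best = max(s for s, _ in round_scores)
        selected.append(best_j)
        if round_best > best_score:
            best_score = round_best
            best_prefix_len = len(selected)
            stall = 0
        else:
            stall += 1
    chosen = selected[:best_prefix_len] if best_prefix_len else selected[:patience]
    return [names[j] for j in chosen]


# ---------------------------------------------------------------------------
# outlier trimming and classification-by-regression


@dataclass
class OutlierTrim:
    retained: np.ndarray
    removed: np.ndarray
    metrics_before: Optional[dict]
    metrics_after: Optional[dict]


def remove_outliers(y, yhat, fraction: float = 0.10) -> OutlierTrim:
    """Drop the ``floor(fraction * n)`` points with the largest absolute
    residual |y - yhat| (ties broken by original index) and recompute the
    correlation metrics on the retained points."""
    if not (0 <= fraction < 1):
        raise ValueError("fraction must lie in [0, 1)")
    y = np.asarray(y, dtype=float)
    yhat = np.asarray(yhat, dtype=float)
    n = y.size
    n_remove = int(math.floor(fraction * n))
    resid = np.abs(y - yhat)
    order = np.lexsort((np.arange(n), -resid))  # largest residual, then index
    removed = np.sort(order[:n_remove])
    retained = np.sort(order[n_remove:])

    def _safe(idx):
        try:
            return regression_metrics(y[idx], yhat[idx])
        except UndefinedMetricError:
            return None

    return OutlierTrim(
        retained=retained,
        removed=removed,
        metrics_before=_safe(np.arange(n)),
        metrics_after=_safe(retained),
    )


def classify_by_regression(yhat, cutoff: float = 6.0) -> np.ndarray:
    """Binarise predicted pK_i at a potency cut-off; the boundary is
    inclusive (pK_i >= cutoff is called positive)."""
    return (np.asarray(yhat, dtype=float) >= cutoff).astype(int)


# ---------------------------------------------------------------------------
# binding-mode (type) classifiers


PAIRWISE_TASKS = (
    ("I_vs_II", ("I", "II")),
    ("I_vs_I1/2", ("I", "I1/2")),
    ("I1/2_vs_II", ("I1/2", "II")),
)
ALLOSTERIC_TASK = "allosteric_vs_rest"

#: tree-based models everywhere except the I1/2-vs-II contrast, where the
#: multilayer perceptron performs best
DEFAULT_TYPE_FAMILIES = {
    "I_vs_II": "extra_trees",
    "I_vs_I1/2": "extra_trees",
    "I1/2_vs_II": "mlp",
    ALLOSTERIC_TASK: "extra_trees",
}


@dataclass
class TypePrediction:
    votes: dict  # task name -> predicted class ("allosteric_vs_rest" -> bool)
    final_type: str
    tie_flag: bool


@dataclass
class TypeClassifierSet:
    """Four fitted binary binding-mode models plus the voting rule."""

    models: dict
    families: dict
    seed: int

    def predict(self, X) -> list:
        X = _to_array(X)
        pair_preds = {
            name: self.models[name].predict(X) for name, _ in PAIRWISE_TASKS
        }
        allo = self.models[ALLOSTERIC_TASK].predict(X).astype(int)
        out = []
        for i in range(X.shape[0]):
            votes = {name: str(pair_preds[name][i]) for name, _ in PAIRWISE_TASKS}
            votes[ALLOSTERIC_TASK] = bool(allo[i])
            final, tie = type_vote(votes)
            out.append(TypePrediction(votes=votes, final_type=final, tie_flag=tie))
        return out


def train_type_classifiers(
    X, types, specs: Optional[dict] = None, seed: int = 0
) -> TypeClassifierSet:
    """Train the four binary binding-mode models.

    Three pairwise contrasts (I vs II, I vs I1/2, I1/2 vs II) are trained on
    the two relevant classes only; allosteric-vs-rest is trained on all
    molecules.  Classes with fewer than 2 examples raise
    :class:`SmallClassError` naming the class (the allosteric class is tiny
    in practice and this path must be explicit).
    """
    X = _to_array(X)
    types = np.asarray([str(t) for t in types])
    bad = sorted(set(types.tolist()) - set(TYPE_VOCABULARY))
    if bad:
        raise ValueError(f"unknown type labels {bad}; vocabulary is {TYPE_VOCABULARY}")
    counts = {c: int(np.sum(types == c)) for c in TYPE_VOCABULARY}
    models, families = {}, {}
    for name, (a, b) in PAIRWISE_TASKS:
        for cls in (a, b):
            if counts[cls] < 2:
                raise SmallClassError(
                    f"class {cls!r} has {counts[cls]} examples; cannot train {name}"
                )
        family = (specs or {}).get(name, DEFAULT_TYPE_FAMILIES[name])
        mask = (types == a) | (types == b)
        est = build_estimator(ModelSpec(family=family, task="classification", seed=seed))
        est.fit(X[mask], types[mask])
        models[name] = est
        families[name] = family
    if counts["allosteric"] < 2:
        raise SmallClassError(
            f"class 'allosteric' has {counts['allosteric']} examples; "
            f"cannot train {ALLOSTERIC_TASK}"
        )
    family = (specs or {}).get(ALLOSTERIC_TASK, DEFAULT_TYPE_FAMILIES[ALLOSTERIC_TASK])
    est = build_estimator(ModelSpec(family=family, task="classification", seed=seed))
    est.fit(X, (types == "allosteric").astype(int))
    models[ALLOSTERIC_TASK] = est
    families[ALLOSTERIC_TASK] = family
    return TypeClassifierSet(models=models, families=families, seed=seed)


def type_vote(votes: dict) -> tuple:
    """Merge the four binary outcomes into a final binding-mode call.

    The allosteric-vs-rest flag has precedence; otherwise the class winning
    the most of the three pairwise contests is returned.  A three-way tie
    (cyclic votes) falls back to Type I -- the majority class -- with the tie
    flagged.
    """
    for name, _ in PAIRWISE_TASKS:
        if name not in votes:
            raise ValueError(f"missing pairwise prediction {name!r}")
    if ALLOSTERIC_TASK not in votes:
        raise ValueError(f"missing prediction {ALLOSTERIC_TASK!r}")
    if votes[ALLOSTERIC_TASK]:
        return "allosteric", False
    wins = {"I": 0, "I1/2": 0, "II": 0}
    for name, pair in PAIRWISE_TASKS:
        winner = str(votes[name])
        if winner not in pair:
            raise ValueError(f"{name} predicted {winner!r}, expected one of {pair}")
        wins[winner] += 1
    top = max(wins.values())
    leaders = [c for c, w in wins.items() if w == top]
    if len(leaders) == 1:
        return leaders[0], False
    return "I", True
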