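"""Training and evaluating the cooperative-vs-competitive classifier.

The protocol: stratified 70/30 split (train side rounded up), random
undersampling of the majority class in the training partition, five-fold
cross-validation repeated 10 times for model assessment, then a Random
Forest (500 trees, 22 variables per split) evaluated on the held-out test
set against four benchmarks (SVM, logistic regression, decision tree, kNN).
Scores are class probabilities for the cooperative class.
"""

from __future__ import annotations

import warnings
from dataclasses import dataclass, field

import numpy as np
import pandas as pd
from sklearn.ensemble import RandomForestClassifier
from sklearn.linear_model import LogisticRegression
from sklearn.metrics import roc_curve
from sklearn.model_selection import RepeatedStratifiedKFold
from sklearn.neighbors import KNeighborsClassifier
from sklearn.pipeline import Pipeline
from sklearn.preprocessing import StandardScaler
from sklearn.svm import SVC
from sklearn.tree import DecisionTreeClassifier

from .features import FEATURE_COLUMNS, KEY_COLUMNS

__all__ = [
    "LABEL_POSITIVE",
    "LABEL_NEGATIVE",
    "ModelSpec",
    "CrossValSpec",
    "TrainedModel",
    "EvaluationReport",
    "stratified_split",
    "undersample_majority",
    "cross_validate",
    "train_model",
    "evaluate",
    "permutation_importance",
    "score_triplets",
]

LABEL_POSITIVE = "cooperative"
LABEL_NEGATIVE = "competitive"

ALGORITHMS = ("random_forest", "svm", "logistic_regression", "decision_tree", "knn")


@dataclass(frozen=True)
class ModelSpec:
    """Which algorithm to fit and with what hyperparameters.

    Random-forest defaults follow the protocol: 500 trees, 22 variables
    sampled per split (clamped to the feature count with a warning if the
    matrix is narrower).
    """

    algorithm: str = "random_forest"
    n_trees: int = 500
    vars_per_split: int = 22
    hyperparams: dict = field(default_factory=dict)

    def __post_init__(self) -> None:
        if self.algorithm not in ALGORITHMS:
            raise ValueError(f"unknown algorithm {self.algorithm!r}; choose from {ALGORITHMS}")


@dataclass(frozen=True)
class CrossValSpec:
    folds: int = 5
    repeats: int = 10

    def __post_init__(self) -> None:
        if self.folds < 2:
            raise ValueError("folds must be >= 2")


@dataclass
class TrainedModel:
    """A fitted estimator plus the frozen feature schema it expects."""

    estimator: object
    feature_columns: list[str]
    spec: ModelSpec

    def predict_proba_positive(self, x: pd.DataFrame) -> np.ndarray:
        self._check_schema(x)
        probs = self.estimator.predict_proba(x[self.feature_columns].to_numpy(float))
        pos_idx = list(self.estimator.classes_).index(LABEL_POSITIVE)
        return probs[:, pos_idx]

    def _check_schema(self, x: pd.DataFrame) -> None:
        missing = [c for c in self.feature_columns if c not in x.columns]
        if missing:
            raise ValueError(f"feature matrix is missing columns: {missing}")


@dataclass
class EvaluationReport:
    accuracy: float
    f1: float
    sensitivity: float
    specificity: float
    precision: float
    auc: float
    confusion: tuple[int, int, int, int]  # (TP, FP, FN, TN)
    roc_points: list[tuple[float, float]]


def _feature_cols(data: pd.DataFrame) -> list[str]:
    cols = [c for c in FEATURE_COLUMNS if c in data.columns]
    if not cols:  # fall back to everything that is not a key/label column
        cols = [c for c in data.columns if c not in KEY_COLUMNS + ["label"]]
    return cols


def stratified_split(
    data: pd.DataFrame, train_fraction: float = 0.7, seed: int = 0
) -> tuple[pd.DataFrame, pd.DataFrame]:
    """Per-class split: ``ceil(fraction * n_class)`` rows to train, rest to test.

    The ceiling convention makes 211 positives put 148 in training.  Both
    partitions are seed-deterministic, disjoint and exhaustive.
    """
    if not 0 < train_fraction < 1:
        raise ValueError("train_fraction must be in (0, 1)")
    rng = np.random.default_rng(seed)
    train_parts, test_parts = [], []
    for label, grp in data.groupby("label", sort=True):
        if len(grp) < 2:
            raise ValueError(f"class {label!r} has fewer than 2 rows")
        order = rng.permutation(len(grp))
        n_train = int(np.ceil(train_fraction * len(grp)))
        train_parts.append(grp.iloc[order[:n_train]])
        test_parts.append(grp.iloc[order[n_train:]])
    train = pd.concat(train_parts).reset_index(drop=True)
    test = pd.concat(test_parts).reset_index(drop=True)
    return train, test


def undersample_majority(train: pd.DataFrame, seed: int = 0) -> pd.DataFrame:
    """Subsample the majority class (without replacement) to the minority count."""
    counts = train["label"].value_counts()
    if (counts == 0).any() or len(counts) < 2:
        raise ValueError("both classes must be present")
    minority = counts.idxmin()
    n_min = int(counts.min())
    rng = np.random.default_rng(seed)
    parts = []
    for label, grp in train.groupby("label", sort=True):
        if label == minority or len(grp) == n_min:
            parts.append(grp)
        else:
            take = rng.choice(len(grp), size=n_min, replace=False)
            parts.append(grp.iloc[np.sort(take)])
    return pd.concat(parts).reset_index(drop=True)


def _build_estimator(spec: ModelSpec, n_features: int, seed: int):
    if spec.algorithm == "random_forest":
        mtry = spec.vars_per_split
        if mtry > n_features:
            warnings.warn(
                f"vars_per_split={mtry} exceeds feature count {n_features}; clamping",
                stacklevel=3,
            )
            mtry = n_features
        return RandomForestClassifier(
            n_estimators=spec.n_trees,
            max_features=mtry,
            random_state=seed,
            **spec.hyperparams,
        )
    if spec.algorithm == "decision_tree":
        return DecisionTreeClassifier(random_state=seed, **spec.hyperparams)
    # distance/margin based models get z-scored features (fit on train only)
    if spec.algorithm == "svm":
        core = SVC(probability=True, random_state=seed, **spec.hyperparams)
    elif spec.algorithm == "logistic_regression":
        core = LogisticRegression(max_iter=2000, random_state=seed, **spec.hyperparams)
    else:  # knn
        core = KNeighborsClassifier(**spec.hyperparams)
    return Pipeline([("scale", StandardScaler()), ("model", core)])


def train_model(train: pd.DataFrame, spec: ModelSpec | None = None, seed: int = 0) -> TrainedModel:
    """Fit one classifier on a labeled feature matrix."""
    spec = spec or ModelSpec()
    cols = _feature_cols(train)
    if train["label"].nunique() < 2:
        raise ValueError("training data must contain both classes")
    est = _build_estimator(spec, len(cols), seed)
    est.fit(train[cols].to_numpy(float), train["label"].to_numpy())
    return TrainedModel(estimator=est, feature_columns=cols, spec=spec)


def cross_validate(
    train: pd.DataFrame,
    spec: ModelSpec | None = None,
    cv: CrossValSpec | None = None,
    seed: int = 0,
) -> dict:
    """Repeated stratified k-fold assessment; AUC is the selection metric.

    Returns per-fold AUCs plus their mean and standard deviation over the
    ``folds x repeats`` fits.
    """
    spec = spec or ModelSpec()
    cv = cv or CrossValSpec()
    counts = train["label"].value_counts()
    if cv.folds > counts.min():
        raise ValueError(f"folds={cv.folds} exceeds minority class size {counts.min()}")
    cols = _feature_cols(train)
    x = train[cols].to_numpy(float)
    y = train["label"].to_numpy()
    splitter = RepeatedStratifiedKFold(n_splits=cv.folds, n_repeats=cv.repeats, random_state=seed)
    aucs = []
    for fit_i, (tr, te) in enumerate(splitter.split(x, y)):
        est = _build_estimator(spec, len(cols), seed + fit_i)
        est.fit(x[tr], y[tr])
        pos = list(est.classes_).index(LABEL_POSITIVE)
        scores = est.predict_proba(x[te])[:, pos]
        aucs.append(_auc_from_scores(scores, y[te] == LABEL_POSITIVE))
    aucs = np.array(aucs)
    return {
        "metric": "auc",
        "per_fold": aucs.tolist(),
        "mean": float(aucs.mean()),
        "sd": float(aucs.std(ddof=1)),
        "n_fits": len(aucs),
    }


def _auc_from_scores(scores: np.ndarray, is_pos: np.ndarray) -> float:
    if is_pos.all() or (~is_pos).all():
        raise ValueError("AUC undefined on a single-class set")
    fpr, tpr, _ = roc_curve(is_pos, scores)
    return float(np.trapezoid(tpr, fpr))


def evaluate(model: TrainedModel, test: pd.DataFrame, threshold: float = 0.5) -> EvaluationReport:
    """Confusion-based metrics at ``threshold`` plus a full ROC sweep and AUC."""
    if len(test) == 0 or test["label"].nunique() < 2:
        raise ValueError("test set must be non-empty with both classes")
    scores = model.predict_proba_positive(test)
    is_pos = (test["label"] == LABEL_POSITIVE).to_numpy()
    pred_pos = scores >= threshold
    tp = int((pred_pos & is_pos).sum())
    fp = int((pred_pos & ~is_pos).sum())
    fn = int((~pred_pos & is_pos).sum())
    tn = int((~pred_pos & ~is_pos).sum())
    accuracy = (tp + tn) / len(test)
    sensitivity = tp / (tp + fn) if tp + fn else 0.0
    specificity = tn / (tn + fp) if tn + fp else 0.0
    precision = tp / (tp + fp) if tp + fp else 0.0
    f1 = (
        2 * precision * sensitivity / (precision + sensitivity)
        if precision + sensitivity
        else 0.0
    )
    fpr, tpr, _ = roc_curve(is_pos, scores)
    return EvaluationReport(
        accuracy=accuracy,
        f1=f1,
        sensitivity=sensitivity,
        specificity=specificity,
        precision=precision,
        auc=float(np.trapezoid(tpr, fpr)),
        confusion=(tp, fp, fn, tn),
        roc_points=list(zip(fpr.tolist(), tpr.tolist())),
    )


def permutation_importance(
    model: TrainedModel,
    data: pd.DataFrame,
    n_permutations: int = 20,
    seed: int = 0,
) -> pd.DataFrame:
    """Mean decrease in accuracy when each feature column is shuffled.

    For every feature, the drop from baseline accuracy is averaged over
    ``n_permutations`` independent shuffles of that column; features are
    ranked descending (rank 1 = most important).  A constant column's
    importance is exactly 0.
    """
    cols = model.feature_columns
    x = data[cols].to_numpy(float)
    y = data["label"].to_numpy()
    rng = np.random.default_rng(seed)
    baseline = float((model.estimator.predict(x) == y).mean())
    drops = np.zeros(len(cols))
    for j, col in enumerate(cols):
        if np.all(x[:, j] == x[0, j]):
            continue  # permuting constants changes nothing
        acc = 0.0
        xp = x.copy()
        for _ in range(n_permutations):
            xp[:, j] = x[rng.permutation(len(x)), j]
            acc += float((model.estimator.predict(xp) == y).mean())
        drops[j] = baseline - acc / n_permutations
    table = pd.DataFrame({"feature": cols, "mean_decrease_accuracy": drops})
    table = table.sort_values(
        ["mean_decrease_accuracy", "feature"], ascending=[False, True]
    ).reset_index(drop=True)
    table["rank"] = np.arange(1, len(cols) + 1)
    return table


def score_triplets(
    model: TrainedModel,
    rows,
    thresholds: tuple[float, ...] = (0.5, 0.9),
    chunk_size: int = 50_000,
) -> tuple[pd.DataFrame, dict[float, int]]:
    """Score a feature-matrix stream; bounded memory, order preserved.

    ``rows`` may be a DataFrame or an iterable of DataFrame chunks.  Returns
    the per-triplet score table (key columns when present, plus ``score``)
    and the count of rows at or above each threshold.
    """
    if isinstance(rows, pd.DataFrame):
        df = rows
        rows = (df.iloc[i : i + chunk_size] for i in range(0, len(df), max(1, chunk_size)))
    out = []
    counts = {t: 0 for t in thresholds}
    for chunk in rows:
        scores = model.predict_proba_positive(chunk)
        keys = [c for c in KEY_COLUMNS if c in chunk.columns]
        part = chunk[keys].copy() if keys else pd.DataFrame(index=chunk.index)
        part["score"] = scores
        out.append(part)
        for t in thresholds:
            counts[t] += int((scores >= t).sum())
    table = pd.concat(out).reset_index(drop=True) if out else pd.DataFrame(columns=["score"])
    return table, counts
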