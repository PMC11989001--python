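"""Multi-model layer classification with confusion-matrix metrics.

Feature tables (FTIR band integrals, cell-wall or nutraceutical assays)
are classified into epidermal layers with a fixed registry of seven
standard algorithms: logistic regression, RBF-kernel SVM, k-nearest
neighbours, decision tree, random forest, gradient boosting and a
single-hidden-layer neural network.  Evaluation follows the common
single stratified 70/30 train-test split; metrics are classification
accuracy CA = (TP+TN)/(TP+TN+FP+FN) and precision TP/(TP+FP), computed
one-vs-rest per class and aggregated, plus a row-normalized confusion
matrix and permutation feature importance.
"""

from __future__ import annotations

from dataclasses import dataclass, field

import numpy as np
import pandas as pd
from sklearn.ensemble import GradientBoostingClassifier, RandomForestClassifier
from sklearn.inspection import permutation_importance
from sklearn.linear_model import LogisticRegression
from sklearn.neighbors import KNeighborsClassifier
from sklearn.neural_network import MLPClassifier
from sklearn.pipeline import make_pipeline
from sklearn.preprocessing import StandardScaler
from sklearn.svm import SVC
from sklearn.tree import DecisionTreeClassifier

MODEL_NAMES = (
    "logistic_regression",
    "svm",
    "knn",
    "decision_tree",
    "random_forest",
    "gradient_boosting",
    "neural_network",
)


def make_model(name: str, seed: int = 0):
    """Instantiate a registry model with its default hyperparameters.

    Scale-sensitive learners (logistic regression, SVM, kNN, the neural
    network) are wrapped in a standardization pipeline.
    """
    if name == "logistic_regression":
        return make_pipeline(
            StandardScaler(), LogisticRegression(max_iter=2000, random_state=seed)
        )
    if name == "svm":
        return make_pipeline(StandardScaler(), SVC(C=1.0, kernel="rbf", random_state=seed))
    if name == "knn":
        return make_pipeline(StandardScaler(), KNeighborsClassifier(n_neighbors=5))
    if name == "decision_tree":
        return DecisionTreeClassifier(random_state=seed)
    if name == "random_forest":
        return RandomForestClassifier(n_estimators=100, random_state=seed)
    if name == "gradient_boosting":
        return GradientBoostingClassifier(n_estimators=100, random_state=seed)
    if name == "neural_network":
        return make_pipeline(
            StandardScaler(),
            MLPClassifier(
                hidden_layer_sizes=(100,), max_iter=1000, random_state=seed
            ),
        )
    raise KeyError(f"unknown model {name!r}; registry: {MODEL_NAMES}")


@dataclass
class ClassificationReport:
    """Metrics of one fitted model on the held-out test split."""

    model: str
    ca: float
    precision_macro: float
    precision_weighted: float
    confusion_percent: pd.DataFrame  # rows = true, cols = predicted, row %
    importances: dict[str, float] = field(default_factory=dict)
    split_seed: int = 0
    n_test: int = 0


def _split_features(table: pd.DataFrame, target: str = "layer"):
    feature_cols = [
        c
        for c in table.columns
        if c not in (target, "sample_id", "onion_id")
        and pd.api.types.is_numeric_dtype(table[c])
    ]
    if not feature_cols:
        raise ValueError("no numeric feature columns found")
    X = table[feature_cols]
    if X.isna().any().any():
        raise ValueError("feature table contains missing values; imputation is out of scope")
    y = table[target].astype(str)
    if y.nunique() < 2:
        raise ValueError("need at least two classes")
    return X.to_numpy(dtype=float), y.to_numpy(), feature_cols


def split_train_test(
    table: pd.DataFrame,
    fraction: float = 0.7,
    seed: int = 0,
    target: str = "layer",
) -> tuple[pd.DataFrame, pd.DataFrame]:
    """Stratified train/test split of a feature table.

    Within each class, ``round(fraction * n)`` samples go to training
    (remainder to test), shuffled by ``seed``.  The two frames are
    disjoint and exhaustive; identical seeds give identical splits.
    """
    if not 0.0 < fraction < 1.0:
        raise ValueError("fraction must be in (0, 1)")
    rng = np.random.default_rng(seed)
    train_idx: list[int] = []
    test_idx: list[int] = []
    for cls, grp in table.groupby(target, sort=True):
        idx = grp.index.to_numpy()
        if idx.size < 2:
            raise ValueError(f"class {cls!r} has fewer than 2 samples; cannot stratify")
        perm = rng.permutation(idx)
        n_train = int(round(fraction * idx.size))
        n_train = min(max(n_train, 1), idx.size - 1)  # both splits non-empty
        train_idx.extend(perm[:n_train])
        test_idx.extend(perm[n_train:])
    return table.loc[sorted(train_idx)], table.loc[sorted(test_idx)]


def classification_accuracy(tp: int, tn: int, fp: int, fn: int) -> float:
    """CA = (TP + TN) / (TP + TN + FP + FN)."""
    for v in (tp, tn, fp, fn):
        if v < 0:
            raise ValueError("counts must be non-negative")
    total = tp + tn + fp + fn
    if total == 0:
        raise ValueError("undefined metric: all counts are zero")
    return (tp + tn) / total


def precision_score(tp: int, fp: int) -> float:
    """Precision = TP / (TP + FP)."""
    if tp < 0 or fp < 0:
        raise ValueError("counts must be non-negative")
    if tp + fp == 0:
        raise ValueError("undefined metric: no predicted positives")
    return tp / (tp + fp)


def confusion_counts(
    y_true: np.ndarray, y_pred: np.ndarray, classes: list[str] | None = None
) -> pd.DataFrame:
    """Raw confusion counts, rows = true class, columns = predicted."""
    if classes is None:
        classes = sorted(set(y_true) | set(y_pred))
    mat = pd.DataFrame(0, index=classes, columns=classes, dtype=int)
    for t, p in zip(y_true, y_pred):
        mat.loc[t, p] += 1
    return mat


def ovr_counts(counts: pd.DataFrame, cls: str) -> tuple[int, int, int, int]:
    """One-vs-rest (TP, TN, FP, FN) for one class from a confusion matrix."""
    total = int(counts.to_numpy().sum())
    tp = int(counts.loc[cls, cls])
    fp = int(counts[cls].sum()) - tp
    fn = int(counts.loc[cls].sum()) - tp
    tn = total - tp - fp - fn
    return tp, tn, fp, fn


def evaluate_predictions(
    y_true: np.ndarray, y_pred: np.ndarray
) -> tuple[float, float, float, pd.DataFrame]:
    """CA, macro precision, weighted precision and row-% confusion matrix.

    CA is the fraction of correctly classified cases (the diagonal of
    the confusion matrix over its total), which coincides with the
    (TP+TN)/(TP+TN+FP+FN) formula in the two-class case.  Precision is
    TP/(TP+FP) per class one-vs-rest; classes with no predicted
    positives contribute 0.  Macro averages classes equally, weighted
    averages by class support.
    """
    counts = confusion_counts(np.asarray(y_true), np.asarray(y_pred))
    total = counts.to_numpy().sum()
    ca = float(np.trace(counts.to_numpy())) / total
    precisions, supports = [], []
    for cls in counts.index:
        tp, _, fp, _ = ovr_counts(counts, cls)
        precisions.append(precision_score(tp, fp) if tp + fp > 0 else 0.0)
        supports.append(counts.loc[cls].sum())
    precisions_arr = np.array(precisions)
    supports_arr = np.array(supports, dtype=float)
    macro = float(precisions_arr.mean())
    weighted = float((precisions_arr * supports_arr).sum() / supports_arr.sum())
    row_sums = counts.sum(axis=1).replace(0, 1)
    percent = counts.div(row_sums, axis=0) * 100.0
    return ca, macro, weighted, percent


def feature_importance(
    model,
    X: np.ndarray,
    y: np.ndarray,
    feature_names: list[str],
    seed: int = 0,
    n_repeats: int = 10,
) -> dict[str, float]:
    """Permutation importance shares per feature.

    The mean accuracy drop when a feature column is shuffled
    (``n_repeats`` times) is clipped at zero and normalized so the
    positive drops sum to 1.  A single-feature model gets importance 1
    by convention; if no feature produces a positive drop, all shares
    are 0.
    """
    if len(feature_names) == 1:
        return {feature_names[0]: 1.0}
    res = permutation_importance(
        model, X, y, n_repeats=n_repeats, random_state=seed, scoring="accuracy"
    )
    drops = np.clip(res.importances_mean, 0.0, None)
    total = drops.sum()
    shares = drops / total if total > 0 else drops
    return dict(zip(feature_names, shares.tolist()))


def run_model_suite(
    table: pd.DataFrame,
    models: tuple[str, ...] = MODEL_NAMES,
    fraction: float = 0.7,
    seed: int = 0,
    target: str = "layer",
    importance: bool = True,
    n_repeats: int = 10,
) -> list[ClassificationReport]:
    """Fit and evaluate the model registry on one stratified split.

    Each named model is trained on the ``fraction`` training part and
    evaluated on the held-out rest; reports are sorted by CA
    descending.  All stochastic components (split, model seeds,
    permutation importance) derive from ``seed``.
    """
    for name in models:
        if name not in MODEL_NAMES:
            raise KeyError(f"unknown model {name!r}; registry: {MODEL_NAMES}")
    train, test = split_train_test(table, fraction=fraction, seed=seed, target=target)
    X_tr, y_tr, feats = _split_features(train, target)
    X_te, y_te, _ = _split_features(test, target)
    reports = []
    for name in models:
        model = make_model(name, seed=seed)
        model.fit(X_tr, y_tr)
        y_pred = model.predict(X_te)
        ca, macro, weighted, percent = evaluate_predictions(y_te, y_pred)
        imps = (
            feature_importance(model, X_te, y_te, feats, seed=seed, n_repeats=n_repeats)
            if importance
            else {}
        )
        reports.append(
            ClassificationReport(
                model=name,
                ca=ca,
                precision_macro=macro,
                precision_weighted=weighted,
                confusion_percent=percent,
                importances=imps,
                split_seed=seed,
                n_test=len(y_te),
            )
        )
    reports.sort(key=lambda r: r.ca, reverse=True)
    return reports
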