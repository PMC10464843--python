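"""Random-forest classification of per-residue contact energies.

The continuous per-residue CDR3-peptide contact energy is discretized into
five equal-frequency classes; a recursive-feature-elimination pass driven by
forest importances selects an informative subset of the 94 pair descriptors;
a random forest trained on the 70% training split is evaluated on the held
out 30% with a confusion matrix, exact-binomial accuracy CI, Cohen's kappa
and a McNemar test against the majority-class baseline.
"""

from __future__ import annotations

import warnings
from dataclasses import dataclass, field
from typing import Sequence

import numpy as np
import pandas as pd
from scipy import stats as sps
from sklearn.ensemble import RandomForestClassifier
from sklearn.metrics import cohen_kappa_score, confusion_matrix
from sklearn.model_selection import StratifiedKFold, train_test_split

__all__ = [
    "MLDataset",
    "RFEResult",
    "EvalMetrics",
    "discretize_quantiles",
    "make_dataset",
    "rfe_select",
    "train_eval",
    "DEFAULT_SIZES",
]

DEFAULT_SIZES = tuple(range(1, 21)) + (25, 30, 40, 60, 94)
N_CLASSES = 5
TRAIN_FRACTION = 0.7
N_TREES = 500


def discretize_quantiles(
    values: Sequence[float], k: int = N_CLASSES
) -> tuple[np.ndarray, np.ndarray]:
    """Equal-frequency class labels and the inner bin edges used.

    Edges sit at the i/k percentiles of ``values`` and are returned so the
    same bins can be reused on a held-out split.  Heavy ties can leave fewer
    effective classes; that is reported as a warning, not an error.
    """
    values = np.asarray(values, dtype=float)
    if len(values) < k:
        raise ValueError(f"need at least {k} values to form {k} quantile bins")
    edges = np.quantile(values, np.arange(1, k) / k)
    labels = np.searchsorted(edges, values, side="left")
    effective = len(np.unique(labels))
    if effective < k:
        warnings.warn(
            f"ties reduce {k} quantile bins to {effective} effective class(es)",
            stacklevel=2,
        )
    return labels, edges


@dataclass
class MLDataset:
    """Feature matrix, discretized target and a fixed train/test split."""

    x: pd.DataFrame
    y: np.ndarray
    edges: np.ndarray
    train_idx: np.ndarray
    test_idx: np.ndarray
    binning: str = "pooled"

    @property
    def x_train(self) -> pd.DataFrame:
        return self.x.iloc[self.train_idx]

    @property
    def x_test(self) -> pd.DataFrame:
        return self.x.iloc[self.test_idx]

    @property
    def y_train(self) -> np.ndarray:
        return self.y[self.train_idx]

    @property
    def y_test(self) -> np.ndarray:
        return self.y[self.test_idx]


def make_dataset(
    features: pd.DataFrame,
    target: Sequence[float],
    k: int = N_CLASSES,
    train_fraction: float = TRAIN_FRACTION,
    seed: int = 0,
    binning: str = "pooled",
) -> MLDataset:
    """Discretize the target and split 70/30 stratified by class.

    ``binning="pooled"`` fits the quantile edges on all rows before the
    split (the default order of operations); ``"train"`` fits them on the
    training rows only and reuses them on the test rows.
    """
    target = np.asarray(target, dtype=float)
    idx = np.arange(len(target))
    if binning == "pooled":
        y, edges = discretize_quantiles(target, k)
        train_idx, test_idx = train_test_split(
            idx, train_size=train_fraction, random_state=seed, stratify=y
        )
    elif binning == "train":
        train_idx, test_idx = train_test_split(
            idx, train_size=train_fraction, random_state=seed
        )
        y_train, edges = discretize_quantiles(target[train_idx], k)
        y = np.searchsorted(edges, target, side="left")
    else:
        raise ValueError(f"unknown binning {binning!r}")
    return MLDataset(
        x=features.reset_index(drop=True), y=y, edges=edges,
        train_idx=np.sort(train_idx), test_idx=np.sort(test_idx), binning=binning,
    )


@dataclass
class RFEResult:
    selected: list[str]
    ranking: list[str]  # best first, full feature order
    cv_scores: dict[int, float]
    best_size: int


def _forest(seed: int, n_estimators: int) -> RandomForestClassifier:
    return RandomForestClassifier(
        n_estimators=n_estimators, random_state=seed, n_jobs=1
    )


def rfe_select(
    dataset: MLDataset,
    sizes: Sequence[int] = DEFAULT_SIZES,
    cv_folds: int = 10,
    seed: int = 0,
    n_estimators: int = N_TREES,
    elimination_step: float = 0.1,
) -> RFEResult:
    """Recursive feature elimination on the training split only.

    Features are ranked by repeatedly fitting a forest and dropping the
    least important ``elimination_step`` fraction (mean decrease in
    impurity); each candidate subset size is then scored by stratified
    cross-validated accuracy of a fresh forest on the training rows, and the
    smallest size within one standard error of the best mean score wins.
    """
    x, y = dataset.x_train, dataset.y_train
    if len(x) < cv_folds:
        raise ValueError("fewer training rows than CV folds")
    sizes = sorted({s for s in sizes if 1 <= s <= x.shape[1]})

    # ranking pass
    remaining = list(x.columns)
    eliminated: list[str] = []
    while len(remaining) > 1:
        forest = _forest(seed, n_estimators).fit(x[remaining], y)
        importances = pd.Series(forest.feature_importances_, index=remaining)
        n_drop = max(1, int(len(remaining) * elimination_step))
        worst = importances.sort_values(kind="stable").index[:n_drop]
        for name in worst:
            eliminated.append(name)
            remaining.remove(name)
    ranking = remaining + eliminated[::-1]  # best first

    # size selection pass
    cv = StratifiedKFold(n_splits=cv_folds, shuffle=True, random_state=seed)
    cv_scores: dict[int, float] = {}
    cv_se: dict[int, float] = {}
    for size in sizes:
        cols = ranking[:size]
        scores = []
        for train, test in cv.split(x, y):
            forest = _forest(seed, n_estimators).fit(x.iloc[train][cols], y[train])
            scores.append(forest.score(x.iloc[test][cols], y[test]))
        cv_scores[size] = float(np.mean(scores))
        cv_se[size] = float(np.std(scores, ddof=1) / np.sqrt(len(scores)))
    best = max(sizes, key=lambda s: cv_scores[s])
    threshold = cv_scores[best] - cv_se[best]
    best_size = min(s for s in sizes if cv_scores[s] >= threshold)
    return RFEResult(
        selected=ranking[:best_size], ranking=ranking,
        cv_scores=cv_scores, best_size=best_size,
    )


@dataclass
class EvalMetrics:
    accuracy: float
    accuracy_ci95: tuple[float, float]
    kappa: float
    mcnemar_p: float
    confusion: pd.DataFrame
    n_test: int
    baseline: str = "majority_class"
    seed: int = 0
    params: dict = field(default_factory=dict)


def train_eval(
    dataset: MLDataset,
    features: Sequence[str],
    seed: int = 0,
    n_estimators: int = N_TREES,
) -> EvalMetrics:
    """Fit a forest on the training split and evaluate on the test split."""
    cols = list(features)
    forest = _forest(seed, n_estimators).fit(dataset.x_train[cols], dataset.y_train)
    pred = forest.predict(dataset.x_test[cols])
    y_test = dataset.y_test
    n = len(y_test)
    correct = int(np.sum(pred == y_test))
    accuracy = correct / n
    ci = sps.binomtest(correct, n).proportion_ci(confidence_level=0.95, method="exact")

    classes = np.unique(dataset.y)
    missing = [c for c in classes if c not in y_test]
    if missing:
        warnings.warn(
            f"class(es) {missing} absent from the test split; their confusion "
            "rows are zero", stacklevel=2,
        )
    kappa = float(cohen_kappa_score(y_test, pred, labels=classes))
    cm = pd.DataFrame(
        confusion_matrix(y_test, pred, labels=classes), index=classes, columns=classes
    )

    # McNemar vs predicting the majority training class everywhere
    majority = np.bincount(dataset.y_train).argmax()
    base_correct = y_test == majority
    model_correct = pred == y_test
    b = int(np.sum(model_correct & ~base_correct))
    c = int(np.sum(~model_correct & base_correct))
    from statsmodels.stats.contingency_tables import mcnemar

    table = [[int(np.sum(model_correct & base_correct)), b],
             [c, int(np.sum(~model_correct & ~base_correct))]]
    mc = mcnemar(table, exact=True)
    return EvalMetrics(
        accuracy=accuracy,
        accuracy_ci95=(float(ci.low), float(ci.high)),
        kappa=kappa,
        mcnemar_p=float(mc.pvalue),
        confusion=cm,
        n_test=n,
        seed=seed,
        params={"n_estimators": n_estimators, "n_features": len(cols)},
    )
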