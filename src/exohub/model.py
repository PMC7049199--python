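"""Boosted-regression-tree classification of the adjusted phenotype.

Models are regressors trained on the adjusted integer phenotype; continuous
predictions are mapped to classes by sign (``> 0`` -> ASD, ``< 0`` -> SCZ,
exact 0 -> SCZ with a logged tie).  Evaluation reports accuracy, per-class
precision/recall, the no-information rate, a one-sided exact binomial test of
accuracy > NIR, and a Clopper-Pearson 95% interval.

Backed by scikit-learn's :class:`~sklearn.ensemble.GradientBoostingRegressor`
(regularized gradient-boosted trees with impurity-gain feature importances).
"""

from __future__ import annotations

import logging
from dataclasses import dataclass, field
from typing import Mapping, Sequence

import numpy as np
from scipy.stats import binomtest
from sklearn.ensemble import GradientBoostingRegressor
from sklearn.metrics import precision_score, recall_score
from sklearn.model_selection import StratifiedKFold, train_test_split

logger = logging.getLogger(__name__)

POSITIVE_CLASS = "ASD"
NEGATIVE_CLASS = "SCZ"

#: Small fixed hyperparameter grid; the winner on a held-out validation slice
#: of the training data is kept.
DEFAULT_GRID = [
    {"max_depth": d, "learning_rate": lr} for d in (3, 6) for lr in (0.1, 0.3)
]
DEFAULT_FIXED = {
    "n_estimators": 500,
    "n_iter_no_change": 10,
    "validation_fraction": 0.1,
    "max_features": "sqrt",  # column subsampling: large speedup, mild regularization
}


@dataclass
class SplitPlan:
    """Balanced per-class 70:30 (by default) partition of sample indices."""

    train_idx: np.ndarray
    test_idx: np.ndarray
    per_class_train: dict[str, int]
    per_class_test: dict[str, int]
    train_fraction: float
    seed: int

    def __post_init__(self) -> None:
        if set(self.train_idx) & set(self.test_idx):
            raise ValueError("train and test indices overlap")


@dataclass
class FittedBooster:
    estimator: GradientBoostingRegressor
    feature_names: list[str]
    params: dict
    seed: int

    def predict(self, X: np.ndarray) -> np.ndarray:
        return self.estimator.predict(np.asarray(X, dtype=float))


@dataclass
class ModelReport:
    continuous_predictions: np.ndarray
    mapped_classes: np.ndarray
    accuracy: float
    precision: float
    recall: float
    nir: float
    p_value_acc_gt_nir: float
    ci95: tuple[float, float]
    n_test: int
    tie_count: int = 0
    important_features: list[tuple[str, float]] = field(default_factory=list)
    important_genes: list[str] = field(default_factory=list)

    def to_dict(self) -> dict:
        return {
            "accuracy": self.accuracy,
            "precision": self.precision,
            "recall": self.recall,
            "nir": self.nir,
            "p_value_acc_gt_nir": self.p_value_acc_gt_nir,
            "ci95": list(self.ci95),
            "n_test": self.n_test,
            "tie_count": self.tie_count,
            "n_important_features": len(self.important_features),
            "important_genes": self.important_genes,
        }


@dataclass
class CVReport:
    fold_reports: list[ModelReport]
    accuracy: float
    precision: float
    recall: float
    nir: float

    def to_dict(self) -> dict:
        return {
            "k": len(self.fold_reports),
            "accuracy": self.accuracy,
            "precision": self.precision,
            "recall": self.recall,
            "nir": self.nir,
            "folds": [r.to_dict() for r in self.fold_reports],
        }


def balance_and_split(
    labels: Sequence[str],
    train_fraction: float = 0.70,
    seed: int = 0,
    selection: str = "first_n",
) -> SplitPlan:
    """Subsample the larger class to the smaller's size, then split per class.

    ``selection='first_n'`` keeps the first n of the larger class in input
    order; ``'random'`` samples them with the seed.  The per-class train count
    is ``round(train_fraction * n_per_class)``; the test set is the remainder.
    """
    labels = np.asarray(labels)
    classes, counts = np.unique(labels, return_counts=True)
    if len(classes) != 2:
        raise ValueError(f"expected exactly 2 classes, got {list(classes)}")
    if counts.min() < 2:
        raise ValueError("each class needs at least 2 samples")
    n_keep = int(counts.min())
    rng = np.random.default_rng(seed)

    kept: list[np.ndarray] = []
    for cls in classes:
        idx = np.flatnonzero(labels == cls)
        if len(idx) > n_keep:
            if selection == "first_n":
                idx = idx[:n_keep]
            elif selection == "random":
                idx = np.sort(rng.choice(idx, size=n_keep, replace=False))
            else:
                raise ValueError(f"unknown selection {selection!r}")
        kept.append(idx)

    n_train = int(round(train_fraction * n_keep))
    if n_train < 1 or n_train >= n_keep:
        raise ValueError(
            f"train_fraction={train_fraction} leaves an empty train or test set "
            f"for per-class n={n_keep}"
        )
    train_parts, test_parts = [], []
    for idx in kept:
        perm = rng.permutation(len(idx))
        train_parts.append(idx[np.sort(perm[:n_train])])
        test_parts.append(idx[np.sort(perm[n_train:])])
    train_idx = np.sort(np.concatenate(train_parts))
    test_idx = np.sort(np.concatenate(test_parts))
    return SplitPlan(
        train_idx=train_idx,
        test_idx=test_idx,
        per_class_train={str(c): n_train for c in classes},
        per_class_test={str(c): n_keep - n_train for c in classes},
        train_fraction=train_fraction,
        seed=seed,
    )


def train_regressor(
    X_train: np.ndarray,
    y_train: np.ndarray,
    feature_names: Sequence[str],
    hyperparams: Mapping | None = None,
    seed: int = 0,
) -> FittedBooster:
    """Fit gradient-boosted regression trees on the adjusted phenotype.

    With ``hyperparams=None`` a small fixed grid is searched; candidates are
    fit on 85% of the training data (with internal early stopping) and scored
    by squared error on the remaining 15% validation slice.
    """
    X = np.asarray(X_train, dtype=float)
    y = np.asarray(y_train, dtype=float)
    if np.isnan(X).any() or np.isnan(y).any():
        raise ValueError("NaN values in training data")
    if hyperparams is not None:
        params = {**DEFAULT_FIXED, **hyperparams}
        est = GradientBoostingRegressor(random_state=seed, **params)
        est.fit(X, y)
        return FittedBooster(est, list(feature_names), dict(params), seed)

    strat = np.sign(y).astype(int)
    if len(np.unique(strat)) < 2:
        strat = None
    X_fit, X_val, y_fit, y_val = train_test_split(
        X, y, test_size=0.15, random_state=seed, stratify=strat
    )
    best, best_mse, best_params = None, np.inf, None
    for cell in DEFAULT_GRID:
        params = {**DEFAULT_FIXED, **cell}
        est = GradientBoostingRegressor(random_state=seed, **params)
        est.fit(X_fit, y_fit)
        mse = float(np.mean((est.predict(X_val) - y_val) ** 2))
        logger.info("grid cell %s -> validation MSE %.4f", cell, mse)
        if mse < best_mse:
            best, best_mse, best_params = est, mse, params
    return FittedBooster(best, list(feature_names), dict(best_params), seed)


def map_prediction(pred: float) -> str:
    """Sign-based class mapping; exact 0 goes to SCZ with a logged tie."""
    if not np.isfinite(pred):
        raise ValueError("prediction must be finite")
    if pred > 0:
        return POSITIVE_CLASS
    if pred == 0:
        logger.info("prediction exactly 0 mapped to %s (tie)", NEGATIVE_CLASS)
    return NEGATIVE_CLASS


def map_predictions(preds: np.ndarray) -> tuple[np.ndarray, int]:
    preds = np.asarray(preds, dtype=float)
    if not np.all(np.isfinite(preds)):
        raise ValueError("predictions must be finite")
    ties = int((preds == 0).sum())
    if ties:
        logger.info("%d predictions exactly 0 mapped to %s (ties)", ties, NEGATIVE_CLASS)
    return np.where(preds > 0, POSITIVE_CLASS, NEGATIVE_CLASS), ties


def evaluate(
    model: FittedBooster,
    X_test: np.ndarray,
    labels_test: Sequence[str],
    positive_class: str = POSITIVE_CLASS,
) -> ModelReport:
    """Score mapped predictions against the original class labels."""
    labels_test = np.asarray(labels_test)
    if len(labels_test) == 0:
        raise ValueError("empty test set")
    preds = model.predict(X_test)
    mapped, ties = map_predictions(preds)

    n = len(labels_test)
    correct = int((mapped == labels_test).sum())
    accuracy = correct / n
    _, class_counts = np.unique(labels_test, return_counts=True)
    nir = float(class_counts.max() / n)
    if len(class_counts) == 1:
        logger.warning("single-class test set; NIR = 1 and the report is degenerate")
    precision = float(
        precision_score(labels_test, mapped, pos_label=positive_class, zero_division=0)
    )
    recall = float(recall_score(labels_test, mapped, pos_label=positive_class, zero_division=0))
    p_value = float(binomtest(correct, n, p=nir, alternative="greater").pvalue)
    ci = binomtest(correct, n).proportion_ci(confidence_level=0.95, method="exact")

    importances = model.estimator.feature_importances_
    ranked = sorted(
        (
            (name, float(imp))
            for name, imp in zip(model.feature_names, importances)
            if imp > 0
        ),
        key=lambda t: (-t[1], t[0]),
    )
    return ModelReport(
        continuous_predictions=preds,
        mapped_classes=mapped,
        accuracy=accuracy,
        precision=precision,
        recall=recall,
        nir=nir,
        p_value_acc_gt_nir=p_value,
        ci95=(float(ci.low), float(ci.high)),
        n_test=n,
        tie_count=ties,
        important_features=ranked,
    )


def cross_validate(
    X: np.ndarray,
    y: np.ndarray,
    labels: Sequence[str],
    feature_names: Sequence[str],
    k: int = 5,
    seed: int = 0,
    hyperparams: Mapping | None = None,
) -> CVReport:
    """Stratified k-fold train/evaluate with fold-averaged metrics."""
    labels = np.asarray(labels)
    if k < 2:
        raise ValueError("k must be >= 2")
    _, counts = np.unique(labels, return_counts=True)
    if k > counts.min():
        raise ValueError(f"k={k} exceeds the smallest class size ({counts.min()})")
    X = np.asarray(X, dtype=float)
    y = np.asarray(y, dtype=float)
    skf = StratifiedKFold(n_splits=k, shuffle=True, random_state=seed)
    reports = []
    for fold, (tr, te) in enumerate(skf.split(X, labels)):
        booster = train_regressor(
            X[tr], y[tr], feature_names, hyperparams=hyperparams, seed=seed + fold
        )
        reports.append(evaluate(booster, X[te], labels[te]))
    return CVReport(
        fold_reports=reports,
        accuracy=float(np.mean([r.accuracy for r in reports])),
        precision=float(np.mean([r.precision for r in reports])),
        recall=float(np.mean([r.recall for r in reports])),
        nir=float(np.mean([r.nir for r in reports])),
    )


def important_genes(
    model: FittedBooster,
    feature_kind: str = "snv",
    variant_to_gene: Mapping[str, str] | None = None,
) -> list[str]:
    """Genes behind the positive-importance features, best rank first.

    For ``feature_kind='snv'`` features are variant ids mapped through
    ``variant_to_gene`` with duplicates collapsed keeping the best rank; for
    ``'gene'`` the feature names are the genes themselves.
    """
    importances = model.estimator.feature_importances_
    ranked = sorted(
        ((name, float(imp)) for name, imp in zip(model.feature_names, importances) if imp > 0),
        key=lambda t: (-t[1], t[0]),
    )
    if feature_kind == "gene":
        return [name for name, _ in ranked]
    if feature_kind != "snv":
        raise ValueError(f"unknown feature_kind {feature_kind!r}")
    if variant_to_gene is None:
        raise ValueError("variant_to_gene required for feature_kind='snv'")
    genes: list[str] = []
    seen: set[str] = set()
    for name, _ in ranked:
        g = variant_to_gene[name]
        if g not in seen:
            seen.add(g)
            genes.append(g)
    return genes


def overlap_genes(list_snv: Sequence[str], list_gene: Sequence[str]) -> list[str]:
    """Intersection of two ranked gene lists, ordered by ascending mean rank."""
    rank_a = {g: i for i, g in enumerate(list_snv)}
    rank_b = {g: i for i, g in enumerate(list_gene)}
    common = set(rank_a) & set(rank_b)
    return sorted(common, key=lambda g: ((rank_a[g] + rank_b[g]) / 2.0, g))
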