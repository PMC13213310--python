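"""Supervised discriminant-wavenumber identification.

A random forest (100 trees, Gini impurity, fixed seed 42) is trained to
separate tissue classes; stratified 10-fold cross-validation reports
generalization accuracy, and mean impurity-decrease importances — normalized
to sum to one — rank the wavenumbers.  The forest is a ranking device here,
not a deployed classifier: the top-k (default 15) wavenumbers feed the
downstream embedding stage.
"""

from __future__ import annotations

import logging
from dataclasses import dataclass, field

import numpy as np
import pandas as pd
from sklearn.base import BaseEstimator
from sklearn.ensemble import RandomForestClassifier
from sklearn.model_selection import StratifiedKFold, cross_val_score
from sklearn.utils.validation import check_X_y, check_is_fitted

from .exceptions import LabelError, ParameterError, StratificationError

logger = logging.getLogger(__name__)


@dataclass(frozen=True)
class RFConfig:
    """Forest and cross-validation settings."""

    n_trees: int = 100
    split_criterion: str = "gini"
    n_folds: int = 10
    seed: int = 42
    class_balancing: str = "balanced_subsample"
    top_k: int = 15

    def __post_init__(self) -> None:
        if self.n_folds < 2:
            raise ParameterError("n_folds must be >= 2")
        if self.split_criterion != "gini":
            raise ParameterError("only the Gini splitting criterion is supported")
        if self.class_balancing not in ("balanced_subsample", "none"):
            raise ParameterError("class_balancing must be 'balanced_subsample' or 'none'")


@dataclass(frozen=True)
class FeatureRanking:
    """Wavenumbers in descending importance with fold statistics."""

    wavenumbers: np.ndarray
    importances: np.ndarray
    cv_accuracy_mean: float
    cv_accuracy_sd: float
    cv_fold_accuracies: np.ndarray = field(default_factory=lambda: np.array([]))

    def __post_init__(self) -> None:
        imp = np.asarray(self.importances, dtype=float)
        if np.any(np.diff(imp) > 1e-12):
            raise ParameterError("importances must be sorted non-increasing")
        if imp.size and abs(imp.sum() - 1.0) > 1e-9:
            raise ParameterError("importances must sum to 1")

    def to_frame(self) -> pd.DataFrame:
        return pd.DataFrame(
            {
                "rank": np.arange(1, len(self.wavenumbers) + 1),
                "wavenumber_cm-1": self.wavenumbers,
                "importance": self.importances,
            }
        )


class WavenumberRanker(BaseEstimator):
    """Random-forest wavenumber ranker with stratified CV.

    ``fit(X, y)`` runs stratified k-fold cross-validation, then refits the
    forest on all data with the fixed seed.  "Stratifying sampling during
    tree construction" is implemented as a class-balanced bootstrap per tree
    (``class_weight='balanced_subsample'``); set ``class_balancing='none'``
    to leave only the CV folds stratified.

    Attributes
    ----------
    importances_ : ndarray of shape (n_channels,)
        Mean impurity-decrease importance per channel, summing to 1.
    cv_scores_ : ndarray of shape (n_folds,)
        Per-fold accuracies.
    forest_ : RandomForestClassifier
        The final ensemble refit on all data.
    """

    def __init__(
        self,
        n_trees: int = 100,
        n_folds: int = 10,
        seed: int = 42,
        class_balancing: str = "balanced_subsample",
        top_k: int = 15,
    ) -> None:
        self.n_trees = n_trees
        self.n_folds = n_folds
        self.seed = seed
        self.class_balancing = class_balancing
        self.top_k = top_k

    def fit(self, X, y):
        RFConfig(
            n_trees=self.n_trees, n_folds=self.n_folds, seed=self.seed,
            class_balancing=self.class_balancing, top_k=self.top_k,
        )
        X, y = check_X_y(X, y, dtype=float)
        classes, counts = np.unique(y, return_counts=True)
        if classes.size < 2:
            raise LabelError(f"need >= 2 classes, got {classes.tolist()}")
        if counts.min() < self.n_folds:
            raise StratificationError(
                f"smallest class has {counts.min()} members, fewer than "
                f"{self.n_folds} folds"
            )
        forest = RandomForestClassifier(
            n_estimators=self.n_trees,
            criterion="gini",
            random_state=self.seed,
            class_weight=(
                "balanced_subsample" if self.class_balancing == "balanced_subsample" else None
            ),
            n_jobs=1,
        )
        cv = StratifiedKFold(n_splits=self.n_folds, shuffle=True, random_state=self.seed)
        self.cv_scores_ = cross_val_score(forest, X, y, cv=cv, scoring="accuracy")
        self.forest_ = forest.fit(X, y)
        raw = self.forest_.feature_importances_
        total = raw.sum()
        # A forest of pure-leaf stumps on constant data yields all-zero
        # importances; fall back to uniform so the ranking stays a distribution.
        self.importances_ = raw / total if total > 0 else np.full(raw.size, 1.0 / raw.size)
        self.n_features_in_ = X.shape[1]
        logger.info(
            "RF CV accuracy %.3f +/- %.3f over %d folds",
            self.cv_scores_.mean(), self.cv_scores_.std(), self.n_folds,
        )
        return self

    def ranking(self, axis: np.ndarray) -> FeatureRanking:
        """Map channel importances onto wavenumbers, descending importance.

        Ties are broken by ascending wavenumber.
        """
        check_is_fitted(self, "importances_")
        axis = np.asarray(axis, dtype=float)
        if axis.size != self.importances_.size:
            raise ParameterError("axis length does not match number of fitted channels")
        order = np.lexsort((axis, -self.importances_))
        return FeatureRanking(
            wavenumbers=axis[order],
            importances=self.importances_[order],
            cv_accuracy_mean=float(self.cv_scores_.mean()),
            cv_accuracy_sd=float(self.cv_scores_.std()),
            cv_fold_accuracies=self.cv_scores_.copy(),
        )


def train_rf_cv(
    X: np.ndarray, labels: np.ndarray, config: RFConfig | None = None
) -> tuple[WavenumberRanker, dict[str, float]]:
    """Train the ranking forest with stratified CV; returns (ranker, metrics)."""
    cfg = config or RFConfig()
    ranker = WavenumberRanker(
        n_trees=cfg.n_trees, n_folds=cfg.n_folds, seed=cfg.seed,
        class_balancing=cfg.class_balancing, top_k=cfg.top_k,
    )
    ranker.fit(X, labels)
    metrics = {
        "cv_accuracy_mean": float(ranker.cv_scores_.mean()),
        "cv_accuracy_sd": float(ranker.cv_scores_.std()),
    }
    return ranker, metrics


def rank_wavenumbers(ranker: WavenumberRanker, axis: np.ndarray) -> FeatureRanking:
    """Importance-ordered wavenumbers from a fitted ranker."""
    return ranker.ranking(axis)


def select_top_k(ranking: FeatureRanking, k: int) -> np.ndarray:
    """The k highest-importance wavenumbers, ordered by importance."""
    if k <= 0:
        raise ParameterError(f"k must be positive, got {k}")
    if k > len(ranking.wavenumbers):
        raise ParameterError(
            f"k={k} exceeds ranking length {len(ranking.wavenumbers)}"
        )
    return ranking.wavenumbers[:k].copy()
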