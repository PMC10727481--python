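"""Stratified split, classifier suite, 5-fold CV model selection.

The suite mirrors the families a point-and-click classification tool offers
at comparable presets: fine/medium decision trees, linear/quadratic
discriminant analysis, logistic regression, linear/RBF support vector
machines, k-nearest neighbours with k in {1, 5, 10} under euclidean and
cosine distance, and bagged/boosted tree ensembles.  Each family is scored by
stratified 5-fold cross-validated accuracy on the training set; the winner
(ties broken by the listing order above) is refit on the full training set
and used for test-set prediction.

Cosine k-NN is the family the study's best window settled on: with min-max
normalised features the cosine distance 1 - x.y/(|x||y|) compares trajectory
*shapes* irrespective of overall scale (a zero vector is at distance 1 from
everything).
"""

from __future__ import annotations

import warnings
from dataclasses import dataclass, field

import numpy as np
import pandas as pd
from sklearn.base import BaseEstimator, ClassifierMixin, clone
from sklearn.discriminant_analysis import (LinearDiscriminantAnalysis,
                                           QuadraticDiscriminantAnalysis)
from sklearn.ensemble import AdaBoostClassifier, BaggingClassifier
from sklearn.linear_model import LogisticRegression
from sklearn.model_selection import StratifiedKFold, cross_val_score
from sklearn.neighbors import KNeighborsClassifier
from sklearn.svm import SVC
from sklearn.tree import DecisionTreeClassifier
from sklearn.utils.validation import check_X_y, check_array, check_is_fitted


@dataclass
class SplitSpec:
    train_fraction: float = 0.8
    seed: int = 0


def _round_half_up(x: float) -> int:
    return int(np.floor(x + 0.5))


def stratified_split(labels, spec: SplitSpec | None = None) -> tuple[np.ndarray, np.ndarray]:
    """Seeded stratified train/test split; returns positional index arrays.

    Per-class test counts are round(test_fraction * class size), adjusted by
    largest remainder so they sum to round(test_fraction * n); every class
    keeps at least one member on each side (classes of size < 2 are an error).
    On a 15/22 two-class cohort this yields a 30/7 split with a 3 + 4 test set.
    """
    if spec is None:
        spec = SplitSpec()
    y = np.asarray(labels)
    n = y.size
    test_frac = 1.0 - spec.train_fraction
    classes, counts = np.unique(y, return_counts=True)
    if counts.min() < 2:
        raise ValueError("every class needs at least 2 members to split")
    n_test_total = _round_half_up(test_frac * n)

    raw = {c: test_frac * k for c, k in zip(classes, counts)}
    size = dict(zip(classes, counts))
    n_test = {c: int(np.clip(_round_half_up(raw[c]), 1, size[c] - 1)) for c in classes}
    # largest-remainder adjustment toward the overall total
    while sum(n_test.values()) != n_test_total:
        if sum(n_test.values()) < n_test_total:
            cands = [c for c in classes if n_test[c] < size[c] - 1]
            c = max(cands, key=lambda c: raw[c] - n_test[c])
            n_test[c] += 1
        else:
            cands = [c for c in classes if n_test[c] > 1]
            c = min(cands, key=lambda c: raw[c] - n_test[c])
            n_test[c] -= 1

    rng = np.random.default_rng(spec.seed)
    train_idx, test_idx = [], []
    for c in classes:
        idx = np.flatnonzero(y == c)
        rng.shuffle(idx)
        test_idx.append(idx[: n_test[c]])
        train_idx.append(idx[n_test[c]:])
    return np.sort(np.concatenate(train_idx)), np.sort(np.concatenate(test_idx))


def split_table(table: pd.DataFrame, spec: SplitSpec | None = None):
    """Stratified split of a feature table on its ``label`` column."""
    tr, te = stratified_split(table["label"].to_numpy(), spec)
    return table.iloc[tr], table.iloc[te]


def default_classifier_suite(random_state: int = 0) -> list[tuple[str, object]]:
    """(name, estimator) presets; the list order is the CV tie-break order."""
    rs = random_state
    knns = []
    for metric in ("euclidean", "cosine"):
        for k in (1, 5, 10):
            knns.append((f"knn_{metric}_{k}",
                         KNeighborsClassifier(n_neighbors=k, metric=metric)))
    return [
        ("fine_tree", DecisionTreeClassifier(max_leaf_nodes=100, random_state=rs)),
        ("medium_tree", DecisionTreeClassifier(max_leaf_nodes=20, random_state=rs)),
        # lsqr + shrinkage stays well-defined when a fold has fewer samples
        # per class than features (n ~ 30 training patients, 19 features)
        ("linear_discriminant", LinearDiscriminantAnalysis(solver="lsqr",
                                                           shrinkage="auto")),
        ("quadratic_discriminant", QuadraticDiscriminantAnalysis(reg_param=0.1)),
        ("logistic", LogisticRegression(max_iter=2000)),
        ("linear_svm", SVC(kernel="linear", random_state=rs)),
        ("rbf_svm", SVC(kernel="rbf", gamma="scale", random_state=rs)),
        *knns,
        ("bagged_trees", BaggingClassifier(n_estimators=30, random_state=rs)),
        ("boosted_trees", AdaBoostClassifier(n_estimators=30, random_state=rs)),
    ]

#: families whose decision boundary can realise any linear separation
LINEAR_CAPABLE = ("linear_discriminant", "logistic", "linear_svm")


@dataclass
class CVResult:
    scores: list = field(default_factory=list)  # (name, cv accuracy) in suite order
    winner: str = ""
    winner_accuracy: float = 0.0
    n_folds: int = 5

    def as_table(self) -> pd.DataFrame:
        return pd.DataFrame(self.scores, columns=["classifier", "cv_accuracy"])


class PatternClassifierCV(ClassifierMixin, BaseEstimator):
    """Fit the whole suite, keep the best cross-validated classifier.

    Parameters
    ----------
    classifiers : list of (name, estimator) or None
        Candidate suite; None means :func:`default_classifier_suite`.
    cv : int
        Requested number of stratified folds (reduced with a warning when a
        class has fewer members).
    random_state : int
        Seeds fold shuffling and every stochastic classifier.

    Attributes
    ----------
    cv_result_ : CVResult
    best_name_ : str
    best_estimator_ : fitted classifier
    classes_ : ndarray
    """

    def __init__(self, classifiers=None, cv: int = 5, random_state: int = 0):
        self.classifiers = classifiers
        self.cv = cv
        self.random_state = random_state

    def fit(self, X, y):
        X, y = check_X_y(X, y, dtype=float)
        self.classes_, counts = np.unique(y, return_counts=True)
        folds = self.cv
        if counts.min() < folds:
            folds = max(2, int(counts.min()))
            warnings.warn(f"reducing CV folds to {folds} (smallest class)")
        skf = StratifiedKFold(n_splits=folds, shuffle=True,
                              random_state=self.random_state)
        suite = self.classifiers or default_classifier_suite(self.random_state)

        min_fold_train = (folds - 1) * (len(y) // folds)
        scores = []
        for name, est in suite:
            est = clone(est)
            if isinstance(est, KNeighborsClassifier) and est.n_neighbors > min_fold_train:
                warnings.warn(f"{name}: clamping n_neighbors to {min_fold_train}")
                est.set_params(n_neighbors=min_fold_train)
            with warnings.catch_warnings():
                warnings.simplefilter("ignore")  # collinearity/convergence chatter
                # a family that cannot be fit on this data (e.g. a singular
                # per-class covariance) scores NaN and is never the winner
                try:
                    folds_acc = cross_val_score(est, X, y, cv=skf,
                                                scoring="accuracy",
                                                error_score=np.nan)
                    acc = float(folds_acc.mean())
                except ValueError:  # every fold failed to fit
                    acc = float("nan")
            scores.append((name, acc, est))

        ranked = [-np.inf if np.isnan(s[1]) else s[1] for s in scores]
        best_i = int(np.argmax(ranked))  # first max wins ties
        name, acc, est = scores[best_i]
        with warnings.catch_warnings():
            warnings.simplefilter("ignore")
            self.best_estimator_ = est.fit(X, y)
        self.best_name_ = name
        self.cv_result_ = CVResult(scores=[(n, a) for n, a, _ in scores],
                                   winner=name, winner_accuracy=acc, n_folds=folds)
        return self

    def predict(self, X):
        check_is_fitted(self, "best_estimator_")
        return self.best_estimator_.predict(check_array(X, dtype=float))


def train_suite(X, y, classifiers=None, folds: int = 5, seed: int = 0) -> PatternClassifierCV:
    """Functional wrapper: fit a :class:`PatternClassifierCV` and return it."""
    return PatternClassifierCV(classifiers=classifiers, cv=folds,
                               random_state=seed).fit(X, y)
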