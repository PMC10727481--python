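"""Symmetrical-uncertainty feature selection.

Symmetrical uncertainty between two discrete variables,

    SU(X, Y) = 2 * IG(X; Y) / (H(X) + H(Y)),

with H the empirical Shannon entropy and IG = H(X) + H(Y) - H(X, Y), is a
[0, 1]-normalised mutual-information measure (SU = 0 by convention when
H(X) + H(Y) = 0).  A feature is kept when its SU with the class exceeds a
threshold (default 0.9) AND exceeds its SU with every other feature — i.e. it
is more correlated with the class than with any competitor.  Continuous
features are discretised into equal-frequency bins first; integer-valued
columns (clinical ordinal scores) are treated as already discrete.

Note the redundancy semantics of the pairwise clause: two identical copies of
a perfectly class-aligned feature reject each other (SU(f, g) = 1 is never
exceeded), and an empty selection is reported as such with a warning so the
caller can fall back to the full feature set.  A sequential fast-correlation
(FCBF-style) mode is available as an alternative reading of the pairwise
clause.
"""

from __future__ import annotations

import warnings
from dataclasses import dataclass, field

import numpy as np
import pandas as pd
from sklearn.base import BaseEstimator
from sklearn.feature_selection import SelectorMixin
from sklearn.utils.validation import check_is_fitted


def discretize(values, n_bins: int = 3) -> np.ndarray:
    """Equal-frequency binning; ties broken by original order; constants -> one bin."""
    x = np.asarray(values)
    if n_bins < 2:
        raise ValueError("n_bins must be >= 2")
    n = x.size
    if n == 0:
        raise ValueError("empty vector")
    if np.all(x == x.flat[0]):
        return np.zeros(n, dtype=int)
    order = np.argsort(x, kind="stable")
    ranks = np.empty(n, dtype=int)
    ranks[order] = np.arange(n)
    return (ranks * n_bins) // n


def _entropy(labels: np.ndarray) -> float:
    _, counts = np.unique(labels, return_counts=True)
    p = counts / counts.sum()
    return float(-(p * np.log2(p)).sum())


def symmetrical_uncertainty(x, y) -> float:
    x = np.asarray(x)
    y = np.asarray(y)
    if x.size != y.size:
        raise ValueError("length mismatch")
    if x.size < 2:
        raise ValueError("need at least 2 observations")
    hx = _entropy(x)
    hy = _entropy(y)
    if hx + hy == 0:
        return 0.0
    _, xi = np.unique(x, return_inverse=True)
    _, yi = np.unique(y, return_inverse=True)
    hxy = _entropy(xi * (yi.max() + 1) + yi)
    ig = hx + hy - hxy
    return float(np.clip(2.0 * ig / (hx + hy), 0.0, 1.0))


def _is_integral(col: np.ndarray) -> bool:
    return bool(np.all(np.isfinite(col)) and np.all(col == np.round(col)))


def _discretize_matrix(X: pd.DataFrame, n_bins: int, discrete: str | list) -> dict:
    out = {}
    for c in X.columns:
        col = X[c].to_numpy()
        treat_discrete = (c in discrete) if isinstance(discrete, (list, tuple, set)) \
            else (discrete == "auto" and _is_integral(col.astype(float)))
        out[c] = col.astype(int) if treat_discrete else discretize(col, n_bins)
    return out


@dataclass
class SelectionResult:
    ranking: list = field(default_factory=list)  # (feature, SU-to-class), descending
    su_to_class: dict = field(default_factory=dict)
    su_matrix: pd.DataFrame | None = None
    selected: list = field(default_factory=list)
    threshold: float = 0.9
    n_bins: int = 3
    fallback: bool = False  # empty selection -> downstream uses all features

    def to_dict(self) -> dict:
        return {
            "ranking": [[f, su] for f, su in self.ranking],
            "su_to_class": self.su_to_class,
            "su_matrix": self.su_matrix.to_dict() if self.su_matrix is not None else None,
            "selected": self.selected,
            "threshold": self.threshold,
            "n_bins": self.n_bins,
            "fallback": self.fallback,
        }


def cfs_select(
    X: pd.DataFrame,
    y,
    threshold: float = 0.9,
    n_bins: int = 3,
    discrete: str | list = "auto",
    mode: str = "all_pairs",
) -> SelectionResult:
    """Correlation-based selection via symmetrical uncertainty.

    ``mode='all_pairs'`` is the literal rule: keep f iff SU(f, class) >
    threshold and SU(f, class) > SU(f, g) for every other feature g.
    ``mode='fcbf'`` applies the pairwise clause sequentially against already
    accepted (stronger) features only.
    """
    if X.shape[1] < 2:
        raise ValueError("need at least 2 features")
    y = np.asarray(y)
    disc = _discretize_matrix(X, n_bins, discrete)
    names = list(X.columns)

    su_class = {f: symmetrical_uncertainty(disc[f], y) for f in names}
    order = sorted(names, key=lambda f: (-su_class[f], names.index(f)))

    mat = pd.DataFrame(np.eye(len(names)), index=names, columns=names)
    for i, f in enumerate(names):
        for g in names[i + 1:]:
            su = symmetrical_uncertainty(disc[f], disc[g])
            mat.loc[f, g] = mat.loc[g, f] = su

    selected: list[str] = []
    if mode == "all_pairs":
        for f in order:
            if su_class[f] <= threshold:
                continue
            others = [g for g in names if g != f]
            if all(su_class[f] > mat.loc[f, g] for g in others):
                selected.append(f)
    elif mode == "fcbf":
        for f in order:
            if su_class[f] <= threshold:
                continue
            if all(su_class[f] > mat.loc[f, g] for g in selected):
                selected.append(f)
    else:
        raise ValueError("mode must be 'all_pairs' or 'fcbf'")

    if not selected:
        warnings.warn("no feature passed the SU selection rule; "
                      "downstream should fall back to all features")
    return SelectionResult(
        ranking=[(f, su_class[f]) for f in order],
        su_to_class=su_class,
        su_matrix=mat,
        selected=selected,
        threshold=threshold,
        n_bins=n_bins,
        fallback=not selected,
    )


class SymmetricalUncertaintySelector(SelectorMixin, BaseEstimator):
    """sklearn-style selector wrapping :func:`cfs_select`.

    With ``fallback_to_all=True`` (default) an empty selection keeps every
    feature so the selector stays usable inside a Pipeline; the
    ``used_fallback_`` attribute records that this happened.
    """

    def __init__(self, threshold: float = 0.9, n_bins: int = 3,
                 discrete: str | list = "auto", mode: str = "all_pairs",
                 fallback_to_all: bool = True):
        self.threshold = threshold
        self.n_bins = n_bins
        self.discrete = discrete
        self.mode = mode
        self.fallback_to_all = fallback_to_all

    def fit(self, X, y):
        if isinstance(X, pd.DataFrame):
            frame = X
            self.feature_names_in_ = np.asarray(X.columns, dtype=object)
        else:
            X = np.asarray(X, dtype=float)
            frame = pd.DataFrame(X, columns=[f"x{i}" for i in range(X.shape[1])])
        self.n_features_in_ = frame.shape[1]
        self.result_ = cfs_select(frame, y, threshold=self.threshold,
                                  n_bins=self.n_bins, discrete=self.discrete,
                                  mode=self.mode)
        self.su_to_class_ = self.result_.su_to_class
        self.su_matrix_ = self.result_.su_matrix
        self.selected_features_ = list(self.result_.selected)
        self.used_fallback_ = self.result_.fallback and self.fallback_to_all
        mask = np.asarray([c in self.result_.selected for c in frame.columns])
        if self.used_fallback_:
            mask = np.ones(frame.shape[1], dtype=bool)
        self.support_mask_ = mask
        return self

    def _get_support_mask(self):
        check_is_fitted(self, "support_mask_")
        return self.support_mask_

    def transform(self, X):
        mask = self._get_support_mask()
        if isinstance(X, pd.DataFrame):
            return X.loc[:, mask]
        return np.asarray(X)[:, mask]
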