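"""Trajectory features on the first-W-days window and min-max normalisation.

Feature families (computed on the first W daily intensities, W in {5,6,7,8}):

* statistical — mean, median, sample SD, IQR, maximum, min-max range, RMS;
* amplitude — intensity on day 1, mean amplitude deviation
  (mean |x_i - mean(x)|);
* morphological — OLS slope of intensity on the 1-based day index, the
  coefficients a, b, c of the least-squares cubic y = a x^3 + b x^2 + c x + d
  (d is fitted but not emitted), mean first-order difference, and mean
  second-order difference;
* clinical — Barthel Index (BI), Fracture Mobility Score (FMS), Functional
  Ambulation Categories (FAC), Montreal Cognitive Assessment (MoCA).

Min-max normalisation x' = (x - min) / (max - min) is fitted on a designated
row subset (normally the training set) and applied to all rows; values
outside the fitted range map outside [0, 1].
"""

from __future__ import annotations

import warnings
from dataclasses import dataclass

import numpy as np
import pandas as pd
from sklearn.base import BaseEstimator, TransformerMixin
from sklearn.utils.validation import check_array, check_is_fitted

STATISTICAL = ["mean", "median", "sd", "iqr", "max", "minmax_range", "rms"]
AMPLITUDE = ["intensity_day1", "mean_amplitude_deviation"]
MORPHOLOGICAL = ["slope", "coef_a", "coef_b", "coef_c",
                 "mean_first_order_diff", "mean_second_order_diff"]
CLINICAL = ["BI", "FMS", "FAC", "MoCA"]

TRAJECTORY_FEATURES = STATISTICAL + AMPLITUDE + MORPHOLOGICAL
ALL_FEATURES = TRAJECTORY_FEATURES + CLINICAL

VALID_WINDOWS = (5, 6, 7, 8)


def _check_window(values: np.ndarray, min_len: int) -> np.ndarray:
    x = np.asarray(values, dtype=float)
    if x.ndim != 1 or x.size < min_len:
        raise ValueError(f"window needs >= {min_len} values")
    if np.isnan(x).any():
        raise ValueError("window contains NaN; exclude the patient upstream")
    return x


def statistical_features(window) -> dict:
    x = _check_window(window, 2)
    q1, q3 = np.percentile(x, [25, 75])  # linear-interpolation quantiles
    return {
        "mean": float(x.mean()),
        "median": float(np.median(x)),
        "sd": float(x.std(ddof=1)),
        "iqr": float(q3 - q1),
        "max": float(x.max()),
        "minmax_range": float(x.max() - x.min()),
        "rms": float(np.sqrt(np.mean(x**2))),
    }


def amplitude_features(window) -> dict:
    x = _check_window(window, 2)
    return {
        "intensity_day1": float(x[0]),
        "mean_amplitude_deviation": float(np.mean(np.abs(x - x.mean()))),
    }


def cubic_fit(window) -> tuple[float, float, float, float]:
    """Least-squares cubic y = a x^3 + b x^2 + c x + d on x = 1..W."""
    x = _check_window(window, 4)
    days = np.arange(1, x.size + 1, dtype=float)
    a, b, c, d = np.polyfit(days, x, 3)
    return float(a), float(b), float(c), float(d)


def morphological_features(window) -> dict:
    x = _check_window(window, 4)
    days = np.arange(1, x.size + 1, dtype=float)
    slope = float(np.polyfit(days, x, 1)[0])
    a, b, c, _ = cubic_fit(x)
    d1 = np.diff(x)
    d2 = np.diff(x, n=2)
    return {
        "slope": slope,
        "coef_a": a,
        "coef_b": b,
        "coef_c": c,
        "mean_first_order_diff": float(d1.mean()),
        "mean_second_order_diff": float(d2.mean()),
    }


def trajectory_features(window) -> dict:
    """All 15 trajectory (non-clinical) features of one window, in order."""
    out = {}
    out.update(statistical_features(window))
    out.update(amplitude_features(window))
    out.update(morphological_features(window))
    return {k: out[k] for k in TRAJECTORY_FEATURES}


class TrajectoryFeatureExtractor(TransformerMixin, BaseEstimator):
    """Transform (n_patients, >=window) daily intensities into feature rows.

    Parameters
    ----------
    window : int in {5, 6, 7, 8}
        Number of leading rehabilitation days used.
    """

    def __init__(self, window: int = 7):
        self.window = window

    def fit(self, X, y=None):
        if self.window not in VALID_WINDOWS:
            raise ValueError(f"window must be one of {VALID_WINDOWS}")
        X = check_array(X)
        if X.shape[1] < self.window:
            raise ValueError("fewer days than the requested window")
        self.n_features_in_ = X.shape[1]
        return self

    def transform(self, X):
        check_is_fitted(self, "n_features_in_")
        X = check_array(X)
        rows = [list(trajectory_features(row[: self.window]).values()) for row in X]
        return np.asarray(rows)

    def get_feature_names_out(self, input_features=None):
        return np.asarray(TRAJECTORY_FEATURES, dtype=object)


def assemble_feature_table(
    daily: pd.DataFrame,
    patients: pd.DataFrame,
    window: int,
    include_clinical: bool = True,
) -> tuple[pd.DataFrame, list[str]]:
    """One feature row per patient for the first ``window`` days.

    ``daily`` has columns patient_id/rehab_day/intensity; ``patients`` carries
    the clinical scores and the pattern label.  Patients missing any of the
    first ``window`` days are excluded and listed in the returned report.
    """
    if window not in VALID_WINDOWS:
        raise ValueError(f"window must be one of {VALID_WINDOWS}")
    wide = daily.pivot(index="patient_id", columns="rehab_day", values="intensity")
    pats = patients.set_index("patient_id")

    rows, excluded = [], []
    for pid in pats.index:
        if pid not in wide.index:
            excluded.append(pid)
            continue
        need = [d for d in range(1, window + 1)]
        vals = wide.loc[pid].reindex(need).to_numpy(dtype=float)
        if np.isnan(vals).any():
            excluded.append(pid)
            continue
        row = {"patient_id": pid}
        row.update(trajectory_features(vals))
        if include_clinical:
            for c in CLINICAL:
                row[c] = pats.at[pid, c]
        row["label"] = pats.at[pid, "label"]
        rows.append(row)
    table = pd.DataFrame(rows).set_index("patient_id")
    return table, excluded


class MinMaxNormalizer(TransformerMixin, BaseEstimator):
    """Min-max scaling fitted on a reference subset; constant columns dropped.

    A feature that is constant on the fit rows carries no range information;
    it is flagged with a warning and removed from the transformed output.
    """

    def fit(self, X, y=None):
        X = check_array(X)
        self.n_features_in_ = X.shape[1]
        self.data_min_ = X.min(axis=0)
        self.data_max_ = X.max(axis=0)
        self.keep_ = self.data_max_ > self.data_min_
        if not self.keep_.all():
            dropped = np.flatnonzero(~self.keep_)
            warnings.warn(f"dropping constant feature column(s) {dropped.tolist()}")
        return self

    def transform(self, X):
        check_is_fitted(self, "data_min_")
        X = check_array(X)
        span = self.data_max_ - self.data_min_
        out = (X - self.data_min_) / np.where(span > 0, span, 1.0)
        return out[:, self.keep_]

    def get_feature_names_out(self, input_features=None):
        check_is_fitted(self, "keep_")
        if input_features is None:
            input_features = np.asarray([f"x{i}" for i in range(self.n_features_in_)],
                                        dtype=object)
        return np.asarray(input_features, dtype=object)[self.keep_]


@dataclass
class NormalizationParams:
    feature_min: pd.Series
    feature_max: pd.Series
    dropped: list[str]


def minmax_normalize(
    table: pd.DataFrame, fit_rows=None
) -> tuple[pd.DataFrame, NormalizationParams]:
    """Normalise the feature columns of a table (label column passed through).

    ``fit_rows`` selects the rows (e.g. the training set) on which the
    per-feature min and max are computed; other rows are transformed with the
    same parameters and may fall outside [0, 1].
    """
    feat_cols = [c for c in table.columns if c != "label"]
    fit = table.loc[fit_rows, feat_cols] if fit_rows is not None else table[feat_cols]
    lo, hi = fit.min(), fit.max()
    dropped = [c for c in feat_cols if not hi[c] > lo[c]]
    if dropped:
        warnings.warn(f"dropping constant feature column(s) {dropped}")
    kept = [c for c in feat_cols if c not in dropped]
    out = table[kept].copy()
    for c in kept:
        out[c] = (table[c] - lo[c]) / (hi[c] - lo[c])
    if "label" in table.columns:
        out["label"] = table["label"]
    return out, NormalizationParams(lo[kept], hi[kept], dropped)
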