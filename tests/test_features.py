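"""Window features, cubic fits, normalisation, feature-table assembly."""

import numpy as np
import pandas as pd
import pytest
from hypothesis import given, strategies as st
from sklearn.preprocessing import MinMaxScaler

from actipat.features import (ALL_FEATURES, CLINICAL, TRAJECTORY_FEATURES,
                              MinMaxNormalizer, TrajectoryFeatureExtractor,
                              amplitude_features, assemble_feature_table,
                              cubic_fit, minmax_normalize,
                              morphological_features, statistical_features,
                              trajectory_features)
from actipat.synthetic import CohortSpec, cohort_frames, generate_cohort


def test_statistical_features_hand_oracle():
    f = statistical_features([1, 2, 3, 4, 5])
    assert f["mean"] == 3 and f["median"] == 3 and f["max"] == 5
    assert f["minmax_range"] == 4
    assert f["rms"] == pytest.approx(np.sqrt(11))
    assert f["sd"] == pytest.approx(np.sqrt(2.5))
    c = statistical_features([2, 2, 2, 2, 2])
    assert c == {"mean": 2, "median": 2, "sd": 0, "iqr": 0, "max": 2,
                 "minmax_range": 0, "rms": 2}


def test_amplitude_features_examples():
    assert amplitude_features([4, 4, 4]) == {"intensity_day1": 4,
                                             "mean_amplitude_deviation": 0}
    assert amplitude_features([0, 10])["mean_amplitude_deviation"] == 5
    assert amplitude_features([1, 2, 3, 4, 5])["mean_amplitude_deviation"] == \
        pytest.approx(1.2)


def test_nan_window_rejected():
    with pytest.raises(ValueError, match="NaN"):
        statistical_features([1.0, np.nan, 3.0])


@given(st.permutations(list(range(7))))
def test_order_free_statistics_are_permutation_invariant(perm):
    base = np.array([0.5, 1.0, 1.7, 2.1, 3.0, 3.3, 4.9])
    a = statistical_features(base)
    b = statistical_features(base[list(perm)])
    for k in a:
        assert a[k] == pytest.approx(b[k])


@pytest.mark.parametrize("w", [5, 6, 7, 8])
def test_cubic_coefficients_recovered_on_noiseless_cubic(w):
    x = np.arange(1, w + 1, dtype=float)
    y = 2 * x**3 - x**2 + 3 * x + 1
    a, b, c, d = cubic_fit(y)
    assert (a, b, c, d) == pytest.approx((2, -1, 3, 1), abs=1e-8)


def test_morphological_features_on_linear_series():
    f = morphological_features([1, 2, 3, 4, 5])
    assert f["slope"] == pytest.approx(1)
    assert f["mean_first_order_diff"] == pytest.approx(1)
    assert f["mean_second_order_diff"] == pytest.approx(0, abs=1e-12)
    assert f["coef_a"] == pytest.approx(0, abs=1e-9)
    assert f["coef_b"] == pytest.approx(0, abs=1e-9)


def test_slope_matches_normal_equation_oracle(rng):
    for _ in range(200):
        w = int(rng.integers(5, 9))
        y = rng.standard_normal(w)
        x = np.arange(1, w + 1)
        expected = (w * (x * y).sum() - x.sum() * y.sum()) / \
            (w * (x**2).sum() - x.sum() ** 2)
        assert morphological_features(y)["slope"] == pytest.approx(expected)


def test_constant_window_feature_values():
    f = trajectory_features(np.full(7, 3.0))
    for name in ("mean", "median", "max", "rms", "intensity_day1"):
        assert f[name] == pytest.approx(3.0)
    for name in ("sd", "iqr", "minmax_range", "mean_amplitude_deviation",
                 "slope", "coef_a", "coef_b", "mean_first_order_diff",
                 "mean_second_order_diff"):
        assert f[name] == pytest.approx(0.0, abs=1e-9)


def test_extractor_transformer_api(rng):
    X = rng.random((10, 9)) + 0.5
    ext = TrajectoryFeatureExtractor(window=7).fit(X)
    F = ext.transform(X)
    assert F.shape == (10, len(TRAJECTORY_FEATURES))
    assert list(ext.get_feature_names_out()) == TRAJECTORY_FEATURES
    with pytest.raises(ValueError):
        TrajectoryFeatureExtractor(window=9).fit(X)


def test_minmax_normalize_examples_and_idempotence():
    table = pd.DataFrame({"f": [2.0, 4.0, 6.0], "label": list("aab")},
                         index=["p1", "p2", "p3"])
    out, params = minmax_normalize(table)
    np.testing.assert_allclose(out["f"], [0, 0.5, 1.0])
    out2, _ = minmax_normalize(out)
    np.testing.assert_allclose(out2["f"], out["f"])  # idempotent on fit rows


def test_minmax_test_rows_can_leave_unit_interval():
    table = pd.DataFrame({"f": [2.0, 6.0, 8.0], "label": list("aba")},
                         index=["p1", "p2", "p3"])
    out, _ = minmax_normalize(table, fit_rows=["p1", "p2"])
    assert out.loc["p3", "f"] == pytest.approx(1.5)


def test_minmax_constant_feature_dropped_with_warning():
    table = pd.DataFrame({"f": [1.0, 1.0, 1.0], "g": [0.0, 1.0, 2.0],
                          "label": list("aab")})
    with pytest.warns(UserWarning, match="constant"):
        out, params = minmax_normalize(table)
    assert "f" not in out.columns and params.dropped == ["f"]


def test_minmax_normalizer_matches_sklearn(rng):
    X = rng.random((20, 5)) * 10
    ours = MinMaxNormalizer().fit(X).transform(X)
    theirs = MinMaxScaler().fit_transform(X)
    np.testing.assert_allclose(ours, theirs)


def test_assemble_feature_table_shapes_and_determinism():
    daily, patients = cohort_frames(generate_cohort(CohortSpec(seed=13)))
    table, excluded = assemble_feature_table(daily, patients, 7)
    assert excluded == []
    assert table.shape == (37, len(ALL_FEATURES) + 1)  # 19 features + label
    assert list(table.columns) == ALL_FEATURES + ["label"]
    bare, _ = assemble_feature_table(daily, patients, 7, include_clinical=False)
    assert bare.shape[1] == len(TRAJECTORY_FEATURES) + 1  # 15 features + label
    table2, _ = assemble_feature_table(daily, patients, 7)
    pd.testing.assert_frame_equal(table, table2)


def test_assemble_excludes_patients_with_missing_window_days():
    daily, patients = cohort_frames(generate_cohort(CohortSpec(seed=13)))
    pid = patients["patient_id"].iloc[0]
    daily = daily[~((daily["patient_id"] == pid) & (daily["rehab_day"] == 3))]
    table, excluded = assemble_feature_table(daily, patients, 7)
    assert excluded == [pid]
    assert table.shape[0] == 36
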