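"""Equal-frequency discretisation, symmetrical uncertainty, the selection rule."""

import math

import numpy as np
import pandas as pd
import pytest
from hypothesis import given, strategies as st

from actipat.selection import (SymmetricalUncertaintySelector, cfs_select,
                               discretize, symmetrical_uncertainty)


def su_from_joint_table(counts: np.ndarray) -> float:
    """Brute-force oracle: SU straight from a joint count table."""
    counts = np.asarray(counts, dtype=float)
    n = counts.sum()
    p = counts / n

    def h(probs):
        probs = probs[probs > 0]
        return float(-(probs * np.log2(probs)).sum())

    hx, hy, hxy = h(p.sum(axis=1)), h(p.sum(axis=0)), h(p.ravel())
    if hx + hy == 0:
        return 0.0
    return 2 * (hx + hy - hxy) / (hx + hy)


def labels_from_joint_table(counts: np.ndarray):
    xs, ys = [], []
    for i, row in enumerate(counts):
        for j, c in enumerate(row):
            xs += [i] * int(c)
            ys += [j] * int(c)
    return np.array(xs), np.array(ys)


def test_discretize_examples():
    np.testing.assert_array_equal(discretize(np.arange(1, 11), 2),
                                  [0] * 5 + [1] * 5)
    np.testing.assert_array_equal(discretize(np.full(9, 4.2), 3), np.zeros(9))
    with pytest.raises(ValueError):
        discretize([1, 2, 3], 1)


@given(st.lists(st.floats(-100, 100), min_size=2, max_size=50),
       st.integers(2, 5))
def test_discretize_bin_counts_differ_by_at_most_one(values, n_bins):
    bins = discretize(np.array(values), n_bins)
    if len(set(values)) == 1:
        assert set(bins) == {0}
        return
    counts = np.bincount(bins, minlength=n_bins)
    assert counts.max() - counts.min() <= 1


def test_discretize_rank_based_hence_monotone_invariant(rng):
    x = rng.standard_normal(40)
    np.testing.assert_array_equal(discretize(x, 3), discretize(np.exp(x), 3))


def test_su_perfect_dependence_and_independence():
    x = np.array([0, 1] * 20)
    assert symmetrical_uncertainty(x, x) == pytest.approx(1.0)
    # all four combinations equally frequent => factorised joint
    a = np.array([0, 0, 1, 1] * 10)
    b = np.array([0, 1, 0, 1] * 10)
    assert symmetrical_uncertainty(a, b) == pytest.approx(0.0, abs=1e-12)


def test_su_matches_brute_force_oracle_on_2x2():
    table = np.array([[30, 10], [10, 30]])
    x, y = labels_from_joint_table(table)
    assert symmetrical_uncertainty(x, y) == pytest.approx(su_from_joint_table(table))


def test_su_symmetry_and_errors(rng):
    x = rng.integers(0, 3, 30)
    y = rng.integers(0, 2, 30)
    assert symmetrical_uncertainty(x, y) == pytest.approx(symmetrical_uncertainty(y, x))
    with pytest.raises(ValueError):
        symmetrical_uncertainty(x, y[:-1])


def _noise_frame(rng, n, n_noise=3):
    return pd.DataFrame({f"noise{i}": rng.standard_normal(n)
                         for i in range(n_noise)})


def test_class_aligned_discrete_feature_selected_alone(rng):
    y = np.array([0, 1] * 30)
    X = _noise_frame(rng, 60)
    X.insert(0, "oracle", y.astype(float))  # integral -> treated as discrete
    res = cfs_select(X, y, threshold=0.9)
    assert res.selected == ["oracle"]
    assert res.ranking[0][0] == "oracle"
    assert res.ranking[0][1] == pytest.approx(1.0)


def test_duplicated_perfect_features_reject_each_other(rng):
    y = np.array([0, 1] * 30)
    X = _noise_frame(rng, 60)
    X["copy1"] = y.astype(float)
    X["copy2"] = y.astype(float)
    with pytest.warns(UserWarning, match="fall back"):
        res = cfs_select(X, y, threshold=0.9)
    assert res.selected == [] and res.fallback
    # the sequential mode keeps the stronger (earlier-ranked) copy
    res_fcbf = cfs_select(X, y, threshold=0.9, mode="fcbf")
    assert res_fcbf.selected == ["copy1"]


def test_threshold_zero_keeps_class_informative_independent_features(rng):
    y = np.array([0] * 30 + [1] * 30)
    X = pd.DataFrame({
        "informative": y + rng.normal(0, 0.05, 60),
        "noise": rng.standard_normal(60),
    })
    res = cfs_select(X, y, threshold=0.0, n_bins=2)
    assert "informative" in res.selected


def test_selection_invariant_to_column_order_and_monotone_transforms(rng):
    y = np.array([0, 1] * 25)
    X = pd.DataFrame({"a": rng.standard_normal(50) + y,
                      "b": rng.standard_normal(50)})
    r1 = cfs_select(X, y, threshold=0.2)
    r2 = cfs_select(X[["b", "a"]], y, threshold=0.2)
    assert set(r1.selected) == set(r2.selected)
    X3 = X.copy()
    X3["a"] = np.exp(X3["a"])  # strictly monotone
    r3 = cfs_select(X3, y, threshold=0.2)
    assert r1.su_to_class["a"] == pytest.approx(r3.su_to_class["a"])


def test_su_matrix_symmetric_unit_diagonal(table_w7):
    X = table_w7.drop(columns=["label"]).iloc[:, :6]
    res = cfs_select(X, table_w7["label"].to_numpy(), threshold=0.9)
    m = res.su_matrix.to_numpy()
    np.testing.assert_allclose(m, m.T)
    np.testing.assert_allclose(np.diag(m), 1.0)


def test_selector_estimator_fallback_and_masking(rng):
    y = np.array([0, 1] * 20)
    X = rng.standard_normal((40, 4))
    sel = SymmetricalUncertaintySelector(threshold=0.9).fit(X, y)
    assert sel.used_fallback_  # noise never clears 0.9
    assert sel.transform(X).shape == X.shape
    X[:, 2] = y  # plant a perfect integral feature
    sel = SymmetricalUncertaintySelector(threshold=0.9).fit(X, y)
    assert not sel.used_fallback_
    assert sel.transform(X).shape == (40, 1)


def test_intensity_day1_ranks_top_on_default_cohort(default_frames):
    """Day-1 intensity is among the strongest class correlates for all windows."""
    from actipat.features import assemble_feature_table
    daily, patients = default_frames
    for w in (5, 6, 7, 8):
        table, _ = assemble_feature_table(daily, patients, w)
        res = cfs_select(table.drop(columns=["label"]),
                         table["label"].to_numpy(), threshold=0.9)
        top5 = [f for f, _ in res.ranking[:5]]
        assert "intensity_day1" in top5, (w, top5)


def test_curvature_contrast_promotes_coefficient_b():
    """Quadratic-coefficient informativeness tracks the class curvature gap.

    When the S-shape class bends inside the observation window (inflection
    near day 5), coef_b ranks in the top half of the SU ranking for the
    windows that span the bend and carries much more class information than
    on a cohort whose S-shape class is still flat in week 1; day-1 intensity
    stays a top correlate throughout.
    """
    from actipat.features import assemble_feature_table
    from actipat.synthetic import CohortSpec, cohort_frames, generate_cohort

    def su_rank(spec, w):
        daily, patients = cohort_frames(generate_cohort(spec))
        table, _ = assemble_feature_table(daily, patients, w)
        res = cfs_select(table.drop(columns=["label"]),
                         table["label"].to_numpy(), threshold=0.9)
        names = [f for f, _ in res.ranking]
        return names, res.su_to_class

    bent_params = {
        "upward_linear": {"i0": (2.0, 0.4, 0.0), "s": (0.25, 0.06, 0.02)},
        "s_shape": {"L0": (0.5, 0.15, 0.0), "L1": (8.0, 1.5, 1.0),
                    "t0_frac": (0.2, 0.02, 0.1), "k": (1.2, 0.1, 0.5)},
    }
    bent = CohortSpec(n_patients=120, seed=21, archetype_params=bent_params,
                      stay_by_class={"upward_linear": (16.0, 5.0),
                                     "s_shape": (25.0, 3.0)})
    flat = CohortSpec(n_patients=120, seed=21)  # inflection mid-stay, far out

    for w in (7, 8):
        names_b, su_b = su_rank(bent, w)
        names_f, su_f = su_rank(flat, w)
        assert names_b.index("intensity_day1") < 5
        assert names_f.index("intensity_day1") < 5
        n_feat = len(names_b)
        assert names_b.index("coef_b") < n_feat // 2, (w, names_b)
        assert su_b["coef_b"] > su_f["coef_b"] + 0.1
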