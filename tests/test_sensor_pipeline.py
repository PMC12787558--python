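"""Tabular pipeline: imputation, encoding, standardization, alignment,
stratified splitting."""

import json

import numpy as np
import pandas as pd
import pytest
from hypothesis import given, settings
from hypothesis import strategies as st

from treefuse.sensors import (
    SensorSchema,
    align_by_tree_id,
    apply_standardization,
    default_schema,
    encode_features,
    fit_standardization,
    impute_missing,
    invert_target_standardization,
    one_hot_encode,
    stratified_split,
    StandardizationStats,
)


@pytest.fixture()
def toy_schema():
    return SensorSchema(
        continuous_columns=("x", "y"),
        categorical_columns={"species": ("a", "b", "c")},
    )


def toy_table(**overrides):
    base = {
        "tree_id": ["t1", "t2", "t3", "t4"],
        "x": [1.0, np.nan, 3.0, 2.0],
        "y": [0.0, 10.0, 5.0, 5.0],
        "species": ["a", "a", None, "b"],
    }
    base.update(overrides)
    return pd.DataFrame(base)


def test_impute_mean_and_mode(toy_schema):
    out = impute_missing(toy_table(), toy_schema)
    assert out["x"].tolist() == [1.0, 2.0, 3.0, 2.0]  # mean of observed
    assert out["species"].tolist() == ["a", "a", "a", "b"]  # mode
    # observed entries unchanged
    assert out["y"].tolist() == [0.0, 10.0, 5.0, 5.0]


def test_impute_errors(toy_schema):
    with pytest.raises(ValueError, match="x"):
        impute_missing(toy_table(x=[np.nan] * 4), toy_schema)
    with pytest.raises(KeyError):
        impute_missing(toy_table().drop(columns=["y"]), toy_schema)


def test_one_hot_blocks_sum_to_one(toy_schema):
    table = toy_table().fillna({"species": "a"})
    enc = one_hot_encode(table, toy_schema)
    assert enc.shape == (4, 3)
    np.testing.assert_array_equal(enc.sum(axis=1), np.ones(4))
    assert enc[3, 1] == 1.0  # "b" is index 1


def test_one_hot_strict_policy_rejects_unknown(toy_schema):
    table = toy_table(species=["a", "z", "a", "b"])
    with pytest.raises(ValueError, match="z"):
        one_hot_encode(table, toy_schema)
    enc = one_hot_encode(table, toy_schema, allow_unknown=True)
    assert enc[1].sum() == 0.0  # all-zeros block under the documented flag


def test_schema_invariants():
    with pytest.raises(ValueError):
        SensorSchema(continuous_columns=("x",), categorical_columns={"x": ("a",)})
    with pytest.raises(ValueError):
        SensorSchema(continuous_columns=(), categorical_columns={"s": ()})
    schema = default_schema()
    assert schema.encoded_width == 14 + 12 + 4


def test_standardization_unit_variance_and_round_trip(toy_schema):
    table = impute_missing(toy_table(), toy_schema)
    table["O2_rate"] = [2.0, 4.0, 6.0, 8.0]
    table["CO2_rate"] = [3.0, 5.0, 7.0, 9.0]
    stats = fit_standardization(table, toy_schema)
    out = apply_standardization(table, stats)
    for col in ("x", "y", "O2_rate", "CO2_rate"):
        assert abs(out[col].mean()) < 1e-9
        assert abs(out[col].to_numpy().std() - 1.0) < 1e-9  # population sd
    back = invert_target_standardization(out["O2_rate"].to_numpy(),
                                         "O2_rate", stats)
    np.testing.assert_allclose(back, table["O2_rate"], rtol=1e-12)


def test_standardization_simple_example(toy_schema):
    table = pd.DataFrame({"x": [0.0, 10.0], "y": [1.0, 2.0],
                          "species": ["a", "b"]})
    stats = fit_standardization(table, toy_schema)
    assert stats.feature_mean["x"] == 5.0
    assert stats.feature_sd["x"] == 5.0
    out = apply_standardization(table, stats)
    assert out["x"].tolist() == [-1.0, 1.0]


def test_zero_variance_column_is_an_error(toy_schema):
    table = pd.DataFrame({"x": [7.0, 7.0, 7.0], "y": [1.0, 2.0, 3.0],
                          "species": ["a", "b", "a"]})
    with pytest.raises(ValueError, match="zero variance"):
        fit_standardization(table, toy_schema)
    stats = fit_standardization(table, toy_schema, drop_zero_variance=True)
    assert "x" not in stats.feature_mean
    enc = encode_features(table, toy_schema, stats)
    assert enc.shape[1] == 1 + 3  # dropped column excluded


@settings(max_examples=30, deadline=None)
@given(st.lists(st.floats(min_value=-1e6, max_value=1e6), min_size=3,
                max_size=40).filter(lambda v: np.std(v) > 1e-9))
def test_zscore_round_trip_property(values):
    arr = np.asarray(values, dtype=np.float64)
    stats = StandardizationStats({}, {}, {"O2_rate": float(arr.mean())},
                                 {"O2_rate": float(arr.std())})
    z = (arr - arr.mean()) / arr.std()
    back = invert_target_standardization(z, "O2_rate", stats)
    np.testing.assert_allclose(back, arr, rtol=1e-9, atol=1e-9)


def test_pipeline_idempotence(toy_schema):
    table = impute_missing(toy_table(), toy_schema)
    once = impute_missing(table, toy_schema)
    pd.testing.assert_frame_equal(table, once)
    stats = fit_standardization(table, toy_schema)
    enc1 = encode_features(table, toy_schema, stats)
    enc2 = encode_features(table, toy_schema, stats)
    np.testing.assert_array_equal(enc1, enc2)
    assert enc1.shape[1] == toy_schema.encoded_width


def test_stats_json_round_trip(tmp_path, toy_schema):
    table = impute_missing(toy_table(), toy_schema)
    table["O2_rate"] = [1.0, 2.0, 3.0, 4.0]
    stats = fit_standardization(table, toy_schema)
    path = tmp_path / "stats.json"
    stats.to_json(path)
    loaded = StandardizationStats.from_json(path)
    assert loaded.feature_mean == stats.feature_mean
    assert loaded.target_sd == stats.target_sd
    with open(path) as fh:
        assert set(json.load(fh)) == {"feature_mean", "feature_sd",
                                      "target_mean", "target_sd"}


def test_align_by_tree_id_reports_unmatched():
    images = pd.DataFrame({"tree_id": ["t1", "t2", "t3"], "image_path": list("pqr")})
    table = pd.DataFrame({"tree_id": ["t2", "t3", "t4"], "x": [1, 2, 3]})
    paired, dropped = align_by_tree_id(images, table)
    assert sorted(paired["tree_id"]) == ["t2", "t3"]
    assert dropped == ["t1", "t4"]


def test_align_duplicate_id_is_error():
    images = pd.DataFrame({"tree_id": ["t1", "t2"], "image_path": list("pq")})
    table = pd.DataFrame({"tree_id": ["t2", "t2"], "x": [1, 2]})
    with pytest.raises(ValueError, match="duplicate"):
        align_by_tree_id(images, table)


def test_stratified_split_counts_and_determinism():
    labels = np.repeat([0, 1, 2, 3], [40, 30, 20, 10])
    table = pd.DataFrame({"health_class": labels, "v": np.arange(100)})
    train, test = stratified_split(table, seed=3)
    counts = test["health_class"].value_counts()
    for cls, expected in zip([0, 1, 2, 3], [8, 6, 4, 2]):
        assert abs(counts[cls] - expected) <= 1
    # stratification bound: test proportions within 1/|test| of the full set
    for cls in range(4):
        full_p = (labels == cls).mean()
        test_p = (test["health_class"] == cls).mean()
        assert abs(test_p - full_p) <= 1 / len(test) + 1e-12
    train2, test2 = stratified_split(table, seed=3)
    pd.testing.assert_frame_equal(test, test2)
    # partition: disjoint and exhaustive
    assert set(train["v"]) | set(test["v"]) == set(range(100))
    assert not set(train["v"]) & set(test["v"])


def test_stratified_split_rejects_singleton_class():
    table = pd.DataFrame({"health_class": [0, 0, 1], "v": [1, 2, 3]})
    with pytest.raises(ValueError, match="fewer than 2"):
        stratified_split(table)
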