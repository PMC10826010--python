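"""Dataset types, CSV round trips and preprocessing operations."""

import numpy as np
import pandas as pd
import pytest
from hypothesis import given, settings
from hypothesis import strategies as st

from stsg.core_data import (
    decode_categoricals,
    encode_categoricals,
    filter_subjects,
    forward_fill,
    interpolate_missing,
    inverse_scale,
    read_dataset,
    read_dataset_dir,
    scale_minmax,
    truncate_to_common_length,
    write_dataset,
    write_dataset_dir,
)
from stsg.core_data.types import VariableSchema
from stsg.errors import (
    AlignmentError,
    SchemaError,
    UnknownCategoryError,
    UnrecoverableSubjectError,
)

from conftest import build_dataset


class TestIO:
    def test_round_trip_identity(self, exercise_ds, tmp_path):
        write_dataset_dir(exercise_ds, str(tmp_path))
        back = read_dataset_dir(str(tmp_path))
        assert back.static.frame.equals(exercise_ds.static.frame)
        assert back.series.subject_ids == exercise_ds.series.subject_ids
        for a, b in zip(exercise_ds.series.values, back.series.values):
            assert np.array_equal(a, b)
        assert [s.name for s in back.schema] == [s.name for s in exercise_ds.schema]

    def test_round_trip_with_missing_and_delimiter_labels(self, tmp_path):
        ds = build_dataset(
            {"a": [1.0, np.nan, 3.0], "b": [4.0, 5.0, 6.0]},
            static_rows={"a": {"grp": "x,y"}, "b": {"grp": "plain"}},
            categories={"grp": ("x,y", "plain")},
        )
        write_dataset_dir(ds, str(tmp_path))
        back = read_dataset_dir(str(tmp_path))
        assert list(back.static.frame["grp"]) == ["x,y", "plain"]
        assert np.isnan(back.series.values[0][1, 0])

    def test_empty_subject_dataset_round_trip(self, tmp_path):
        ds = build_dataset({})
        # degenerate: headers only
        write_dataset_dir(ds, str(tmp_path))
        back = read_dataset_dir(str(tmp_path))
        assert back.n_subjects == 0

    def test_missing_declared_column_is_schema_error(self, exercise_ds, tmp_path):
        write_dataset_dir(exercise_ds, str(tmp_path))
        schema = list(exercise_ds.schema) + [VariableSchema("HRX", "numeric", "dynamic")]
        with pytest.raises(SchemaError, match="HRX"):
            read_dataset(
                str(tmp_path / "static.csv"), str(tmp_path / "series.csv"), schema
            )

    def test_mismatched_subject_sets_reported(self, exercise_ds, tmp_path):
        write_dataset_dir(exercise_ds, str(tmp_path))
        static = pd.read_csv(tmp_path / "static.csv")
        extra = static.iloc[[0]].copy()
        extra["subject_id"] = "s9"
        pd.concat([static, extra]).to_csv(tmp_path / "static.csv", index=False)
        with pytest.raises(AlignmentError, match="s9"):
            read_dataset_dir(str(tmp_path))


class TestInterpolation:
    def test_midpoint_gap(self):
        ds = build_dataset({"a": [1.0, np.nan, 3.0]})
        out, excluded = interpolate_missing(ds, max_missing_per_subject=30)
        assert excluded == []
        assert np.allclose(out.series.values[0][:, 0], [1.0, 2.0, 3.0])

    def test_exclusion_over_budget(self):
        vals = np.ones(40)
        vals[:31] = np.nan
        ds = build_dataset({"bad": vals, "good": np.ones(40)})
        out, excluded = interpolate_missing(ds, max_missing_per_subject=30)
        assert excluded == ["bad"]
        assert out.subject_ids == ["good"]

    def test_boundary_nearest_valid_extension(self):
        ds = build_dataset({"a": [np.nan, 2.0, np.nan]})
        out, _ = interpolate_missing(ds, 30)
        # oracle: independent gap filling under the nearest-valid rule
        raw = np.array([np.nan, 2.0, np.nan])
        expected = (
            pd.Series(raw).interpolate(limit_direction="both").to_numpy()
        )
        assert np.allclose(out.series.values[0][:, 0], expected)
        assert np.allclose(out.series.values[0][:, 0], [2.0, 2.0, 2.0])

    def test_complete_dataset_unchanged(self, exercise_ds):
        out, excluded = interpolate_missing(exercise_ds, 0)
        assert excluded == []
        for a, b in zip(out.series.values, exercise_ds.series.values):
            assert np.array_equal(a, b)

    def test_all_missing_variable_is_unrecoverable(self):
        ds = build_dataset({"a": np.full(5, np.nan)})
        with pytest.raises(UnrecoverableSubjectError):
            interpolate_missing(ds, max_missing_per_subject=30)


class TestForwardFill:
    @pytest.mark.parametrize(
        "raw,expected",
        [
            ([5.0, np.nan, np.nan, 7.0], [5.0, 5.0, 5.0, 7.0]),
            ([1.0, 2.0, 3.0], [1.0, 2.0, 3.0]),
            ([np.nan, 3.0, np.nan], [3.0, 3.0, 3.0]),
        ],
    )
    def test_fill_values(self, raw, expected):
        ds = build_dataset({"a": raw})
        out = forward_fill(ds)
        # oracle: scan-based reference fill
        ref, last = [], None
        for v in raw:
            if not np.isnan(v):
                last = v
            ref.append(last)
        first_valid = next(v for v in raw if not np.isnan(v))
        ref = [first_valid if v is None else v for v in ref]
        assert np.allclose(out.series.values[0][:, 0], ref)
        assert np.allclose(out.series.values[0][:, 0], expected)

    def test_idempotent(self):
        ds = build_dataset({"a": [np.nan, 1.0, np.nan, 4.0, np.nan]})
        once = forward_fill(ds)
        twice = forward_fill(once)
        assert np.array_equal(once.series.values[0], twice.series.values[0])


class TestTruncate:
    def test_min_rule(self):
        ds = build_dataset({"a": np.arange(5.0), "b": np.arange(7.0), "c": np.arange(9.0)})
        out = truncate_to_common_length(ds)
        assert out.series.T == 5
        assert np.allclose(out.series.values[2][:, 0], np.arange(5.0))

    def test_equal_lengths_unchanged(self, exercise_ds):
        out = truncate_to_common_length(exercise_ds)
        assert out.series.T == exercise_ds.series.T

    def test_degenerate_min_one(self):
        ds = build_dataset({"a": [1.0], "b": np.arange(1000.0)})
        assert truncate_to_common_length(ds).series.T == 1

    def test_zero_length_subject_rejected(self):
        ds = build_dataset({"a": np.empty((0, 1)), "b": np.ones((3, 1))})
        with pytest.raises(SchemaError, match="a"):
            truncate_to_common_length(ds)


class TestEncoding:
    def test_label_codes_follow_schema_order(self):
        ds = build_dataset(
            {"a": [1.0], "b": [2.0]},
            static_rows={"a": {"gender": "F"}, "b": {"gender": "M"}},
            categories={"gender": ("F", "M")},
        )
        enc = encode_categoricals(ds, "label")
        assert list(enc.static.frame["gender"]) == [0, 1]

    def test_onehot_rows_sum_to_one(self, icu_ds):
        enc = encode_categoricals(icu_ds, "onehot")
        eth_cols = [c for c in enc.static.frame.columns if c.startswith("ethnicity__")]
        assert len(eth_cols) == 5
        assert np.allclose(enc.static.frame[eth_cols].sum(axis=1), 1.0)

    @pytest.mark.parametrize("scheme", ["label", "onehot"])
    def test_encode_decode_round_trip(self, icu_ds, scheme):
        back = decode_categoricals(encode_categoricals(icu_ds, scheme))
        assert back.static.frame.equals(icu_ds.static.frame)

    def test_unknown_category_rejected(self):
        ds = build_dataset(
            {"a": [1.0]},
            static_rows={"a": {"gender": "X"}},
            categories={"gender": ("F", "M")},
        )
        with pytest.raises(UnknownCategoryError, match="X"):
            encode_categoricals(ds, "label")


class TestScaling:
    def test_affine_map(self):
        ds = build_dataset({"a": [2.0], "b": [4.0], "c": [6.0]})
        scaled, state = scale_minmax(ds)
        col = np.concatenate([v[:, 0] for v in scaled.series.values])
        assert np.allclose(sorted(col), [0.0, 0.5, 1.0])

    def test_constant_column(self):
        ds = build_dataset({"a": [3.0, 3.0]})
        scaled, state = scale_minmax(ds)
        assert np.allclose(scaled.series.values[0][:, 0], 0.0)
        back = inverse_scale(scaled, state)
        assert np.allclose(back.series.values[0][:, 0], 3.0)

    def test_inverse_composition_identity(self, exercise_ds):
        scaled, state = scale_minmax(exercise_ds)
        back = inverse_scale(scaled, state)
        for a, b in zip(exercise_ds.series.values, back.series.values):
            assert np.allclose(a, b, atol=1e-9)
        assert np.allclose(
            back.static.frame["age"], exercise_ds.static.frame["age"], atol=1e-9
        )
        stacked = np.stack(scaled.series.values)
        assert stacked.min() >= 0.0 and stacked.max() <= 1.0


class TestFilter:
    def test_threshold_predicate_matches_brute_force(self, exercise_ds):
        thr = 120.0
        j = exercise_ds.series.variables.index("HR")
        out, excluded = filter_subjects(
            exercise_ds, lambda row, arr, vs: arr[:, vs.index("HR")].mean() > thr
        )
        expected = [
            sid
            for sid, arr in zip(exercise_ds.subject_ids, exercise_ds.series.values)
            if arr[:, j].mean() > thr
        ]
        assert out.subject_ids == expected
        assert len(excluded) + len(expected) == exercise_ds.n_subjects

    def test_always_true_is_identity(self, exercise_ds):
        out, excluded = filter_subjects(exercise_ds, lambda *_: True)
        assert excluded == [] and out.subject_ids == exercise_ds.subject_ids


@settings(max_examples=25, deadline=None)
@given(
    data=st.lists(
        st.lists(
            st.one_of(st.none(), st.floats(-50, 50, allow_nan=False)),
            min_size=4,
            max_size=10,
        ),
        min_size=1,
        max_size=4,
    )
)
def test_forward_fill_idempotent_property(data):
    """forward_fill(forward_fill(d)) == forward_fill(d) on arbitrary gaps."""
    series = {}
    for i, row in enumerate(data):
        vals = [np.nan if v is None else v for v in row]
        if all(np.isnan(v) for v in vals):
            vals[0] = 0.0
        series[f"s{i}"] = vals
    ds = build_dataset(series)
    once = forward_fill(ds)
    twice = forward_fill(once)
    for a, b in zip(once.series.values, twice.series.values):
        assert np.array_equal(a, b)
    assert not once.series.has_missing()
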