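"""Generic preprocessing for static+series datasets.

Operations mirror the usual cleaning pipeline for longitudinal health data:
subject exclusion by missingness budget, linear interpolation, forward
filling, truncation to a common length, categorical encoding, min-max
scaling, and predicate-based subject filtering. All operations are pure:
they return new datasets and never mutate their input.

Boundary rule for gap filling (applied by both :func:`interpolate_missing`
and :func:`forward_fill`): a missing prefix is backfilled from the first
valid sample and a missing suffix holds the last valid value
(nearest-valid extension). This keeps subjects with edge gaps instead of
discarding them.
"""

from __future__ import annotations

from typing import Callable

import numpy as np
import pandas as pd

from ..errors import SchemaError, STSGError, UnknownCategoryError, UnrecoverableSubjectError
from .types import (
    LongitudinalDataset,
    ScalingState,
    SeriesBlock,
    StaticTable,
    VariableSchema,
    replace_encoding,
)


def interpolate_missing(
    dataset: LongitudinalDataset, max_missing_per_subject: int = 30
) -> tuple[LongitudinalDataset, list[str]]:
    """Exclude heavily gapped subjects, linearly interpolate the rest.

    A subject whose *total* missing dynamic samples (summed over variables)
    exceeds ``max_missing_per_subject`` is removed and reported. Remaining
    gaps are linearly interpolated between the nearest valid neighbours,
    with nearest-valid extension at the boundaries.

    Returns
    -------
    (dataset, excluded_subject_ids)
    """
    excluded: list[str] = []
    keep_ids: list[str] = []
    new_values: list[np.ndarray] = []
    for sid, arr in zip(dataset.series.subject_ids, dataset.series.values):
        n_missing = int(np.isnan(arr).sum())
        if n_missing > max_missing_per_subject:
            excluded.append(sid)
            continue
        out = arr.copy()
        for j, var in enumerate(dataset.series.variables):
            col = out[:, j]
            valid = ~np.isnan(col)
            if not valid.any():
                raise UnrecoverableSubjectError(
                    f"subject {sid!r}: variable {var!r} has no valid sample"
                )
            if not valid.all():
                t = np.arange(len(col))
                out[:, j] = np.interp(t, t[valid], col[valid])
        keep_ids.append(sid)
        new_values.append(out)

    series = SeriesBlock(
        keep_ids, list(dataset.series.variables), new_values, dataset.series.time_unit
    )
    static = StaticTable(dataset.static.frame.loc[keep_ids].copy())
    return LongitudinalDataset(list(dataset.schema), static, series), excluded


def forward_fill(dataset: LongitudinalDataset) -> LongitudinalDataset:
    """Impute each missing cell with the most recent preceding valid value.

    A missing prefix is backfilled from the first valid sample. Idempotent;
    raises :class:`UnrecoverableSubjectError` if a subject has a variable
    with no valid sample at all.
    """
    new_values = []
    for sid, arr in zip(dataset.series.subject_ids, dataset.series.values):
        df = pd.DataFrame(arr, columns=list(dataset.series.variables))
        all_nan = df.columns[df.isna().all()]
        if len(all_nan):
            raise UnrecoverableSubjectError(
                f"subject {sid!r}: variable {all_nan[0]!r} has no valid sample"
            )
        new_values.append(df.ffill().bfill().to_numpy(dtype=float))
    series = SeriesBlock(
        list(dataset.series.subject_ids),
        list(dataset.series.variables),
        new_values,
        dataset.series.time_unit,
    )
    return LongitudinalDataset(list(dataset.schema), dataset.static.copy(), series)


def truncate_to_common_length(dataset: LongitudinalDataset) -> LongitudinalDataset:
    """Truncate every subject's series to the length of the shortest one."""
    for sid, arr in zip(dataset.series.subject_ids, dataset.series.values):
        if arr.shape[0] == 0:
            raise SchemaError(f"subject {sid!r} has zero samples")
    T = min(dataset.series.lengths)
    series = SeriesBlock(
        list(dataset.series.subject_ids),
        list(dataset.series.variables),
        [arr[:T].copy() for arr in dataset.series.values],
        dataset.series.time_unit,
    )
    return LongitudinalDataset(list(dataset.schema), dataset.static.copy(), series)


def encode_categoricals(
    dataset: LongitudinalDataset, scheme: str = "onehot"
) -> LongitudinalDataset:
    """Encode static categorical variables with the given scheme.

    ``label`` maps categories to integer codes in schema order; ``onehot``
    replaces the column with ``|categories|`` indicator columns (each row sums
    to 1). Dynamic categorical variables support ``label`` encoding only.
    """
    if scheme not in ("label", "onehot"):
        raise SchemaError(f"unknown encoding scheme {scheme!r}")
    frame = dataset.static.frame.copy()
    schema_out: list[VariableSchema] = []
    new_cols: dict[str, pd.Series | pd.DataFrame] = {}
    order: list[str] = []
    for s in dataset.schema:
        if s.kind != "categorical" or s.encoding != "none":
            schema_out.append(s)
            if s.component == "static":
                order.extend(s.table_columns())
            continue
        if s.component == "dynamic":
            raise SchemaError(
                f"dynamic categorical variable {s.name!r} must stay label-coded"
            )
        cats = list(s.categories or ())
        col = frame[s.name].astype(str)
        bad = sorted(set(col) - set(cats))
        if bad:
            raise UnknownCategoryError(
                f"variable {s.name!r}: values {bad} outside declared categories"
            )
        codes = col.map({c: i for i, c in enumerate(cats)})
        if scheme == "label":
            new_cols[s.name] = codes.astype(int)
            order.append(s.name)
        else:
            for i, c in enumerate(cats):
                name = f"{s.name}__{c}"
                new_cols[name] = (codes == i).astype(float)
                order.append(name)
        schema_out.append(replace_encoding(s, scheme))

    for name, col in new_cols.items():
        frame[name] = col
    frame = frame[order]
    return LongitudinalDataset(schema_out, StaticTable(frame), dataset.series.copy())


def decode_categoricals(dataset: LongitudinalDataset) -> LongitudinalDataset:
    """Invert :func:`encode_categoricals` exactly (one-hot decoded by argmax)."""
    frame = dataset.static.frame.copy()
    schema_out: list[VariableSchema] = []
    order: list[str] = []
    new_cols: dict[str, pd.Series] = {}
    for s in dataset.schema:
        if s.component != "static":
            schema_out.append(s)
            continue
        if s.kind != "categorical" or s.encoding == "none":
            schema_out.append(s)
            order.extend(s.table_columns())
            continue
        cats = list(s.categories or ())
        if s.encoding == "label":
            codes = frame[s.name].astype(int)
            if codes.min() < 0 or codes.max() >= len(cats):
                raise UnknownCategoryError(
                    f"variable {s.name!r}: code outside 0..{len(cats) - 1}"
                )
            new_cols[s.name] = codes.map(dict(enumerate(cats)))
        else:
            block = frame[s.onehot_columns].to_numpy(dtype=float)
            new_cols[s.name] = pd.Series(
                [cats[i] for i in block.argmax(axis=1)], index=frame.index
            )
        order.append(s.name)
        schema_out.append(replace_encoding(s, "none"))
    for name, col in new_cols.items():
        frame[name] = col
    frame = frame[order]
    return LongitudinalDataset(schema_out, StaticTable(frame), dataset.series.copy())


def scale_minmax(
    dataset: LongitudinalDataset,
) -> tuple[LongitudinalDataset, ScalingState]:
    """Min-max scale numeric variables into [0, 1].

    Encoded categorical columns are left untouched. Constant variables map
    to 0 and invert back to the constant.
    """
    state = ScalingState(applied=True)
    frame = dataset.static.frame.copy()
    for s in dataset.schema:
        if s.kind != "numeric":
            continue
        if s.component == "static":
            col = frame[s.name].to_numpy(dtype=float)
            state.ranges[s.name] = (float(np.nanmin(col)), float(np.nanmax(col)))
            frame[s.name] = state.forward(s.name, col)
        else:
            j = dataset.series.variables.index(s.name)
            allv = np.concatenate([arr[:, j] for arr in dataset.series.values])
            state.ranges[s.name] = (float(np.nanmin(allv)), float(np.nanmax(allv)))
    new_values = []
    for arr in dataset.series.values:
        out = arr.copy()
        for j, var in enumerate(dataset.series.variables):
            if var in state.ranges:
                out[:, j] = state.forward(var, arr[:, j])
        new_values.append(out)
    series = SeriesBlock(
        list(dataset.series.subject_ids),
        list(dataset.series.variables),
        new_values,
        dataset.series.time_unit,
    )
    return LongitudinalDataset(list(dataset.schema), StaticTable(frame), series), state


def inverse_scale(dataset: LongitudinalDataset, state: ScalingState) -> LongitudinalDataset:
    """Invert :func:`scale_minmax` (elementwise identity within 1e-9)."""
    frame = dataset.static.frame.copy()
    for s in dataset.schema:
        if s.kind != "numeric" or s.name not in state.ranges:
            continue
        if s.component == "static":
            frame[s.name] = state.inverse(s.name, frame[s.name].to_numpy(dtype=float))
    new_values = []
    for arr in dataset.series.values:
        out = arr.copy()
        for j, var in enumerate(dataset.series.variables):
            if var in state.ranges:
                out[:, j] = state.inverse(var, arr[:, j])
        new_values.append(out)
    series = SeriesBlock(
        list(dataset.series.subject_ids),
        list(dataset.series.variables),
        new_values,
        dataset.series.time_unit,
    )
    return LongitudinalDataset(list(dataset.schema), StaticTable(frame), series)


def filter_subjects(
    dataset: LongitudinalDataset,
    predicate: Callable[[pd.Series, np.ndarray, list[str]], bool],
) -> tuple[LongitudinalDataset, list[str]]:
    """Keep subjects satisfying ``predicate(static_row, series, variables)``.

    Returns the filtered dataset and the list of excluded subject ids. A
    predicate that raises on some subject is reported with that subject's id.
    """
    keep: list[str] = []
    excluded: list[str] = []
    for i, sid in enumerate(dataset.subject_ids):
        row = dataset.static.frame.iloc[i]
        arr = dataset.series.values[i]
        try:
            ok = bool(predicate(row, arr, list(dataset.series.variables)))
        except Exception as exc:  # noqa: BLE001 - rewrap with subject context
            raise STSGError(f"predicate failed on subject {sid!r}: {exc}") from exc
        (keep if ok else excluded).append(sid)
    return dataset.subset(keep), excluded
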