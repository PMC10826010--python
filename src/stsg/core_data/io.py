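"""CSV + YAML I/O for the static/series dataset representation.

On disk a dataset is three text files:

* ``static.csv`` — header ``subject_id,<static columns...>``, one row per subject;
* ``series.csv`` — header ``subject_id,t,<dynamic variables...>``, long format,
  ``t`` ascending (0..T_s-1) within each subject;
* ``schema.yaml`` — a list of variable declarations (name/kind/component/
  categories/encoding).

Missing values are written as empty fields; both empty fields and the literal
``NA`` are accepted on read.
"""

from __future__ import annotations

import os

import numpy as np
import pandas as pd
import yaml

from ..errors import AlignmentError, SchemaError
from .types import (
    LongitudinalDataset,
    SeriesBlock,
    StaticTable,
    VariableSchema,
    check_schema,
)

_NA_VALUES = ["", "NA"]


def write_schema(schema: list[VariableSchema], path: str) -> None:
    entries = []
    for s in schema:
        e: dict = {"name": s.name, "kind": s.kind, "component": s.component}
        if s.categories is not None:
            e["categories"] = list(s.categories)
        if s.encoding != "none":
            e["encoding"] = s.encoding
        entries.append(e)
    with open(path, "w") as fh:
        yaml.safe_dump(entries, fh, sort_keys=False)


def read_schema(path: str) -> list[VariableSchema]:
    with open(path) as fh:
        entries = yaml.safe_load(fh)
    schema = [
        VariableSchema(
            name=str(e["name"]),
            kind=e["kind"],
            component=e["component"],
            categories=tuple(map(str, e["categories"])) if "categories" in e else None,
            encoding=e.get("encoding", "none"),
        )
        for e in entries
    ]
    check_schema(schema)
    return schema


def read_dataset(
    static_path: str, series_path: str, schema: list[VariableSchema]
) -> LongitudinalDataset:
    """Read the CSV pair into a :class:`LongitudinalDataset`.

    Subjects present in only one file are rejected with an
    :class:`~stsg.errors.AlignmentError` listing the offenders.
    """
    check_schema(schema)
    static_schema = [s for s in schema if s.component == "static"]
    dynamic_schema = [s for s in schema if s.component == "dynamic"]

    static_df = pd.read_csv(
        static_path, dtype={"subject_id": str}, na_values=_NA_VALUES,
        keep_default_na=False, float_precision="round_trip"
    )
    series_df = pd.read_csv(
        series_path, dtype={"subject_id": str}, na_values=_NA_VALUES,
        keep_default_na=False, float_precision="round_trip"
    )

    if "subject_id" not in static_df.columns:
        raise SchemaError("static file lacks column 'subject_id'")
    for col in ("subject_id", "t"):
        if col not in series_df.columns:
            raise SchemaError(f"series file lacks column {col!r}")

    expected_static = []
    for s in static_schema:
        expected_static.extend(s.table_columns())
    for col in expected_static:
        if col not in static_df.columns:
            raise SchemaError(f"static file lacks column {col!r} declared in schema")
    dyn_names = [s.name for s in dynamic_schema]
    for col in dyn_names:
        if col not in series_df.columns:
            raise SchemaError(f"series file lacks column {col!r} declared in schema")

    static_ids = [str(s) for s in static_df["subject_id"]]
    series_ids_order = list(dict.fromkeys(str(s) for s in series_df["subject_id"]))
    only_static = sorted(set(static_ids) - set(series_ids_order))
    only_series = sorted(set(series_ids_order) - set(static_ids))
    if only_static or only_series:
        raise AlignmentError(
            f"subject sets differ between files (static-only: {only_static}, "
            f"series-only: {only_series})"
        )

    frame = static_df.set_index("subject_id")[expected_static]
    frame.index = frame.index.astype(str)
    for s in static_schema:
        for col in s.table_columns():
            if s.kind == "numeric" or s.encoding in ("label", "onehot"):
                frame[col] = pd.to_numeric(frame[col])
            else:
                frame[col] = frame[col].astype(object).where(frame[col].notna(), np.nan)

    values = []
    grouped = dict(tuple(series_df.groupby("subject_id", sort=False)))
    for sid in static_ids:
        g = grouped[sid].sort_values("t")
        t = g["t"].to_numpy()
        if len(t) and not np.array_equal(t, np.arange(len(t))):
            raise SchemaError(f"subject {sid!r}: time index must be 0..T-1 ascending")
        values.append(g[dyn_names].to_numpy(dtype=float) if dyn_names else
                      np.empty((len(g), 0)))

    series = SeriesBlock(static_ids, dyn_names, values)
    return LongitudinalDataset(list(schema), StaticTable(frame), series)


def write_dataset(
    dataset: LongitudinalDataset,
    static_path: str,
    series_path: str,
    schema_path: str | None = None,
) -> None:
    """Write a dataset as the standard CSV pair (+ optional schema file).

    ``read_dataset(write_dataset(d))`` reproduces ``d`` exactly.
    """
    static_df = dataset.static.frame.reset_index(names="subject_id")
    static_df.to_csv(static_path, index=False, na_rep="")

    dyn = list(dataset.series.variables)
    rows = []
    for sid, arr in zip(dataset.series.subject_ids, dataset.series.values):
        df = pd.DataFrame(arr, columns=dyn)
        df.insert(0, "t", np.arange(arr.shape[0]))
        df.insert(0, "subject_id", sid)
        rows.append(df)
    if rows:
        series_df = pd.concat(rows, ignore_index=True)
    else:
        series_df = pd.DataFrame(columns=["subject_id", "t", *dyn])
    series_df.to_csv(series_path, index=False, na_rep="")

    if schema_path is not None:
        write_schema(dataset.schema, schema_path)


def write_dataset_dir(dataset: LongitudinalDataset, out_dir: str) -> None:
    """Write ``static.csv``, ``series.csv`` and ``schema.yaml`` under ``out_dir``."""
    os.makedirs(out_dir, exist_ok=True)
    write_dataset(
        dataset,
        os.path.join(out_dir, "static.csv"),
        os.path.join(out_dir, "series.csv"),
        os.path.join(out_dir, "schema.yaml"),
    )


def read_dataset_dir(in_dir: str) -> LongitudinalDataset:
    schema = read_schema(os.path.join(in_dir, "schema.yaml"))
    return read_dataset(
        os.path.join(in_dir, "static.csv"),
        os.path.join(in_dir, "series.csv"),
        schema,
    )
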