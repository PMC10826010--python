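"""Domain types for datasets that pair subject metadata with longitudinal series.

A dataset has two components: a *static* table (one row per subject, values that
do not change over the measurement window: age, sex, ...) and a *dynamic* block
(per-subject multivariate time series on an integer time axis 0..T-1). The two
components share one ordered subject list, and a list of
:class:`VariableSchema` entries types every column.
"""

from __future__ import annotations

from dataclasses import dataclass, field, replace

import numpy as np
import pandas as pd

from ..errors import AlignmentError, SchemaError

KINDS = ("numeric", "categorical")
COMPONENTS = ("static", "dynamic")
ENCODINGS = ("none", "label", "onehot")


@dataclass(frozen=True)
class VariableSchema:
    """Declares one variable: its name, type, component and encoding state.

    Parameters
    ----------
    name
        Unique variable identifier.
    kind
        ``"numeric"`` or ``"categorical"``.
    component
        ``"static"`` (metadata) or ``"dynamic"`` (time series).
    categories
        Ordered category labels; required for categorical variables. The order
        fixes label-encoding codes and one-hot column order.
    encoding
        Current representation of the column(s) in the table:
        ``"none"`` (raw labels), ``"label"`` (integer codes) or ``"onehot"``
        (one indicator column per category, named ``name__category``).
    """

    name: str
    kind: str
    component: str
    categories: tuple[str, ...] | None = None
    encoding: str = "none"

    def __post_init__(self) -> None:
        if self.kind not in KINDS:
            raise SchemaError(f"unknown kind {self.kind!r} for variable {self.name!r}")
        if self.component not in COMPONENTS:
            raise SchemaError(
                f"unknown component {self.component!r} for variable {self.name!r}"
            )
        if self.encoding not in ENCODINGS:
            raise SchemaError(
                f"unknown encoding {self.encoding!r} for variable {self.name!r}"
            )
        if self.kind == "categorical":
            if not self.categories:
                raise SchemaError(f"categorical variable {self.name!r} needs categories")
            object.__setattr__(self, "categories", tuple(str(c) for c in self.categories))
        elif self.encoding != "none":
            raise SchemaError(f"numeric variable {self.name!r} cannot be encoded")

    @property
    def onehot_columns(self) -> list[str]:
        assert self.categories is not None
        return [f"{self.name}__{c}" for c in self.categories]

    def table_columns(self) -> list[str]:
        """Column names this variable currently occupies in a table."""
        if self.kind == "categorical" and self.encoding == "onehot":
            return self.onehot_columns
        return [self.name]


def check_schema(schema: list[VariableSchema]) -> None:
    names = [s.name for s in schema]
    if len(set(names)) != len(names):
        dupes = sorted({n for n in names if names.count(n) > 1})
        raise SchemaError(f"duplicate variable names: {dupes}")


@dataclass
class StaticTable:
    """Per-subject metadata: one row per subject, indexed by subject id."""

    frame: pd.DataFrame  # index = subject ids (ordered), columns per schema

    @property
    def subject_ids(self) -> list[str]:
        return [str(s) for s in self.frame.index]

    @property
    def n_subjects(self) -> int:
        return len(self.frame)

    def copy(self) -> "StaticTable":
        return StaticTable(self.frame.copy())


@dataclass
class SeriesBlock:
    """Per-subject multivariate series; possibly ragged before truncation.

    ``values[i]`` is a ``(T_i, n_variables)`` float array for subject
    ``subject_ids[i]``; missing samples are NaN.
    """

    subject_ids: list[str]
    variables: list[str]
    values: list[np.ndarray]
    time_unit: str = "step"

    def __post_init__(self) -> None:
        if len(self.subject_ids) != len(self.values):
            raise AlignmentError("one value array per subject required")
        self.subject_ids = [str(s) for s in self.subject_ids]
        cleaned = []
        for sid, arr in zip(self.subject_ids, self.values):
            arr = np.asarray(arr, dtype=float)
            if arr.ndim != 2 or arr.shape[1] != len(self.variables):
                raise SchemaError(
                    f"subject {sid!r}: series array must be (T, {len(self.variables)})"
                )
            cleaned.append(arr)
        self.values = cleaned

    @property
    def n_subjects(self) -> int:
        return len(self.subject_ids)

    @property
    def lengths(self) -> list[int]:
        return [arr.shape[0] for arr in self.values]

    @property
    def is_aligned(self) -> bool:
        return len(set(self.lengths)) <= 1

    @property
    def T(self) -> int:
        lengths = set(self.lengths)
        if len(lengths) != 1:
            raise SchemaError("series block is ragged; truncate to a common length first")
        return lengths.pop()

    def stacked(self) -> np.ndarray:
        """``(n_subjects, T, n_variables)`` array; requires aligned lengths."""
        _ = self.T
        return np.stack(self.values, axis=0)

    def has_missing(self) -> bool:
        return any(np.isnan(arr).any() for arr in self.values)

    def copy(self) -> "SeriesBlock":
        return SeriesBlock(
            list(self.subject_ids),
            list(self.variables),
            [arr.copy() for arr in self.values],
            self.time_unit,
        )


@dataclass
class LongitudinalDataset:
    """Aligned static table + series block + variable schema."""

    schema: list[VariableSchema]
    static: StaticTable
    series: SeriesBlock

    def __post_init__(self) -> None:
        self.validate()

    def validate(self) -> None:
        check_schema(self.schema)
        if self.static.subject_ids != self.series.subject_ids:
            only_static = set(self.static.subject_ids) - set(self.series.subject_ids)
            only_series = set(self.series.subject_ids) - set(self.static.subject_ids)
            raise AlignmentError(
                "static and series subject lists differ "
                f"(static-only: {sorted(only_static)}, series-only: {sorted(only_series)})"
            )
        static_cols: list[str] = []
        for s in self.static_schema:
            static_cols.extend(s.table_columns())
        table_cols = list(self.static.frame.columns)
        missing = [c for c in static_cols if c not in table_cols]
        extra = [c for c in table_cols if c not in static_cols]
        if missing:
            raise SchemaError(f"static table lacks columns {missing}")
        if extra:
            raise SchemaError(f"static table has undeclared columns {extra}")
        dyn_names = [s.name for s in self.dynamic_schema]
        if dyn_names != list(self.series.variables):
            raise SchemaError(
                f"dynamic schema {dyn_names} does not match series variables "
                f"{list(self.series.variables)}"
            )

    @property
    def static_schema(self) -> list[VariableSchema]:
        return [s for s in self.schema if s.component == "static"]

    @property
    def dynamic_schema(self) -> list[VariableSchema]:
        return [s for s in self.schema if s.component == "dynamic"]

    @property
    def subject_ids(self) -> list[str]:
        return self.static.subject_ids

    @property
    def n_subjects(self) -> int:
        return self.static.n_subjects

    def schema_for(self, name: str) -> VariableSchema:
        for s in self.schema:
            if s.name == name:
                return s
        raise SchemaError(f"no variable named {name!r}")

    def copy(self) -> "LongitudinalDataset":
        return LongitudinalDataset(list(self.schema), self.static.copy(), self.series.copy())

    def subset(self, keep_ids: list[str]) -> "LongitudinalDataset":
        """Subset to the given subjects, preserving current order."""
        keep = [sid for sid in self.subject_ids if sid in set(keep_ids)]
        idx = {sid: i for i, sid in enumerate(self.series.subject_ids)}
        static = StaticTable(self.static.frame.loc[keep].copy())
        series = SeriesBlock(
            keep,
            list(self.series.variables),
            [self.series.values[idx[sid]].copy() for sid in keep],
            self.series.time_unit,
        )
        return LongitudinalDataset(list(self.schema), static, series)


@dataclass
class ScalingState:
    """Per-variable (min, max) pairs captured by min-max scaling.

    Constant variables (max == min) map to 0 and invert back to the constant.
    """

    ranges: dict[str, tuple[float, float]] = field(default_factory=dict)
    applied: bool = False

    def forward(self, name: str, x: np.ndarray) -> np.ndarray:
        lo, hi = self.ranges[name]
        if hi > lo:
            return (x - lo) / (hi - lo)
        return np.zeros_like(np.asarray(x, dtype=float))

    def inverse(self, name: str, x: np.ndarray) -> np.ndarray:
        lo, hi = self.ranges[name]
        if hi > lo:
            return np.asarray(x, dtype=float) * (hi - lo) + lo
        return np.full_like(np.asarray(x, dtype=float), lo)


def replace_encoding(schema: VariableSchema, encoding: str) -> VariableSchema:
    return replace(schema, encoding=encoding)
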