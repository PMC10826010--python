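import numpy as np
import pandas as pd
import pytest

from stsg.core_data.types import (
    LongitudinalDataset,
    SeriesBlock,
    StaticTable,
    VariableSchema,
)
from stsg.fixtures import FixtureSpec, make_exercise_fixture, make_icu_fixture


@pytest.fixture(scope="session")
def exercise_ds() -> LongitudinalDataset:
    """Small exercise-family dataset shared by read-only tests."""
    return make_exercise_fixture(FixtureSpec(30, 32, 123))


@pytest.fixture(scope="session")
def icu_ds() -> LongitudinalDataset:
    return make_icu_fixture(FixtureSpec(12, 48, 7, family="icu"))


def build_dataset(series_by_subject, static_rows=None, dyn_vars=None, categories=None):
    """Hand-assemble a small dataset.

    ``series_by_subject``: {subject_id: (T, n_vars) array-like}.
    ``static_rows``: {subject_id: {col: value}} (optional; defaults to one
    numeric column ``x`` = 0.0).
    """
    ids = list(series_by_subject)
    values = [np.asarray(series_by_subject[s], dtype=float) for s in ids]
    values = [v[:, None] if v.ndim == 1 else v for v in values]
    n_vars = values[0].shape[1] if values else 1
    dyn_vars = dyn_vars or [f"v{j}" for j in range(n_vars)]
    if static_rows is None:
        static_rows = {s: {"x": 0.0} for s in ids}
    frame = pd.DataFrame(
        [static_rows[s] for s in ids],
        index=pd.Index(ids, name="subject_id"),
        columns=["x"] if not ids else None,
    )
    schema = []
    for col in frame.columns:
        if categories and col in categories:
            schema.append(
                VariableSchema(col, "categorical", "static", categories=categories[col])
            )
        else:
            schema.append(VariableSchema(col, "numeric", "static"))
    schema += [VariableSchema(v, "numeric", "dynamic") for v in dyn_vars]
    return LongitudinalDataset(schema, StaticTable(frame), SeriesBlock(ids, dyn_vars, values))
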