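"""Series summary statistics and coherent coupling.

Coupling pairs synthetic metadata rows with series from a pool (real series
for approach A1, separately synthesized series for A2) so that the distance
between the synthesized summary statistics (per-variable max/min/mean,
treated as extra metadata columns) and the pool's actual summaries is as
small as possible. Two strategies are provided: ``hungarian`` solves the
optimal assignment problem; ``greedy`` pairs rows in input order with the
nearest unused pool subject. Pairings are injective — each pool series is
used at most once.

Distances are Euclidean in summary space, computed by default on per-column
z-scores fitted on the pool (so variables on different scales contribute
comparably); the raw-space option is retained via ``standardize=False``.
"""

from __future__ import annotations

from dataclasses import dataclass, replace

import numpy as np
import pandas as pd
from scipy.optimize import linear_sum_assignment
from scipy.spatial.distance import cdist

from .core_data.types import (
    LongitudinalDataset,
    SeriesBlock,
    StaticTable,
    VariableSchema,
)
from .errors import AlignmentError, CapacityError, STSGError

SUMMARY_STATS = ("max", "min", "mean")


@dataclass
class SeriesSummary:
    """Per-subject max/min/mean of each dynamic variable."""

    frame: pd.DataFrame  # index = subject ids; columns = f"{var}_{stat}"
    variables: list[str]

    @property
    def subject_ids(self) -> list[str]:
        return [str(s) for s in self.frame.index]

    @property
    def columns(self) -> list[str]:
        return list(self.frame.columns)


@dataclass
class CouplingResult:
    pairing: dict[int, str]  # synthetic row index -> pool subject id
    distances: np.ndarray  # per-pair distance, aligned with row order
    method: str

    @property
    def total_distance(self) -> float:
        return float(self.distances.sum())


def summarize_series(data: LongitudinalDataset | SeriesBlock) -> SeriesSummary:
    """Exact per-subject max/min/mean per dynamic variable."""
    series = data.series if isinstance(data, LongitudinalDataset) else data
    if series.has_missing():
        raise STSGError("series contain missing values; preprocess first")
    cols: dict[str, np.ndarray] = {}
    for j, var in enumerate(series.variables):
        per = np.stack(
            [
                [arr[:, j].max(), arr[:, j].min(), arr[:, j].mean()]
                for arr in series.values
            ]
        )
        cols[f"{var}_max"] = per[:, 0]
        cols[f"{var}_min"] = per[:, 1]
        cols[f"{var}_mean"] = per[:, 2]
    frame = pd.DataFrame(cols, index=pd.Index(series.subject_ids, name="subject_id"))
    order = [f"{v}_{s}" for v in series.variables for s in SUMMARY_STATS]
    return SeriesSummary(frame[order], list(series.variables))


def summary_schema(summary: SeriesSummary) -> list[VariableSchema]:
    return [VariableSchema(c, "numeric", "static") for c in summary.columns]


def augment_metadata(
    static: StaticTable, summary: SeriesSummary
) -> tuple[StaticTable, list[VariableSchema]]:
    """Append summary columns to a static table (returns table + their schema).

    Subjects must match in content and order.
    """
    if static.subject_ids != summary.subject_ids:
        raise AlignmentError("static table and summary subjects differ")
    frame = pd.concat([static.frame, summary.frame], axis=1)
    return StaticTable(frame), summary_schema(summary)


def strip_summary_columns(static: StaticTable, summary_cols: list[str]) -> StaticTable:
    keep = [c for c in static.frame.columns if c not in set(summary_cols)]
    return StaticTable(static.frame[keep].copy())


def _distance_matrix(
    synth: np.ndarray, pool: np.ndarray, standardize: bool
) -> np.ndarray:
    if standardize:
        mu = pool.mean(axis=0)
        sd = pool.std(axis=0)
        sd = np.where(sd > 0, sd, 1.0)
        synth = (synth - mu) / sd
        pool = (pool - mu) / sd
    return cdist(synth, pool, metric="euclidean")


def couple(
    synthetic_augmented: StaticTable,
    pool: tuple[SeriesBlock, SeriesSummary],
    schema: list[VariableSchema],
    method: str = "hungarian",
    standardize: bool = True,
    keep_summaries: bool = False,
) -> tuple[LongitudinalDataset, CouplingResult]:
    """Pair synthetic metadata rows with pool series by summary distance.

    ``schema`` declares the synthetic static table's variables (including the
    summary columns). The output dataset carries the synthetic static columns
    (summary columns dropped unless ``keep_summaries``) joined to the paired
    pool series; each pool series is used at most once.
    """
    pool_series, pool_summary = pool
    n_synth = synthetic_augmented.n_subjects
    n_pool = pool_series.n_subjects
    if n_synth > n_pool:
        raise CapacityError(
            f"{n_synth} synthetic rows but only {n_pool} series in the pool"
        )
    summary_cols = pool_summary.columns
    missing = [c for c in summary_cols if c not in synthetic_augmented.frame.columns]
    if missing:
        raise STSGError(f"synthetic table lacks summary columns {missing}")

    synth_s = synthetic_augmented.frame[summary_cols].to_numpy(dtype=float)
    pool_s = pool_summary.frame[summary_cols].to_numpy(dtype=float)
    dist = _distance_matrix(synth_s, pool_s, standardize)

    if method == "hungarian":
        rows, cols = linear_sum_assignment(dist)
        assignment = dict(zip(rows.tolist(), cols.tolist()))
    elif method == "greedy":
        used: set[int] = set()
        assignment = {}
        for i in range(n_synth):
            order = np.argsort(dist[i])
            j = next(int(c) for c in order if int(c) not in used)
            used.add(j)
            assignment[i] = j
    else:
        raise STSGError(f"unknown coupling method {method!r}")

    per_pair = np.array([dist[i, assignment[i]] for i in range(n_synth)])
    pairing = {i: pool_series.subject_ids[assignment[i]] for i in range(n_synth)}

    static = synthetic_augmented
    schema_out = list(schema)
    if not keep_summaries:
        static = strip_summary_columns(static, summary_cols)
        schema_out = [s for s in schema_out if s.name not in set(summary_cols)]

    ids = static.subject_ids
    values = [pool_series.values[assignment[i]].copy() for i in range(n_synth)]
    series = SeriesBlock(ids, list(pool_series.variables), values, pool_series.time_unit)
    dyn_schema = [
        VariableSchema(v, "numeric", "dynamic") for v in pool_series.variables
    ]
    dataset = LongitudinalDataset(schema_out + dyn_schema, static, series)
    return dataset, CouplingResult(pairing, per_pair, method)


def brute_force_assignment(dist: np.ndarray) -> tuple[dict[int, int], float]:
    """Exhaustive minimum-cost injective assignment (oracle; n <= ~8)."""
    from itertools import permutations

    n, m = dist.shape
    best, best_perm = np.inf, None
    for perm in permutations(range(m), n):
        total = sum(dist[i, j] for i, j in enumerate(perm))
        if total < best:
            best, best_perm = total, perm
    assert best_perm is not None
    return dict(enumerate(best_perm)), float(best)
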