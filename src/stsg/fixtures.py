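"""Seeded fixture datasets with the statistical structure of real study data.

Two families are provided:

* ``exercise`` — graded-exercise-test shaped data: static metadata
  {age, sex, height, weight, temperature, humidity} and five cardiorespiratory
  series {HR, VO2, VCO2, RR, VE} following a warmup plateau, a linear ramp,
  a saturation plateau and a recovery phase. All five series share a
  subject-level effort amplitude, so dynamic-dynamic correlations are nonzero
  by construction; the amplitude depends on age/sex/weight with a strength set
  by ``metadata_effect``, so static-summary correlations are tunable from
  zero (``metadata_effect=0``) to strong.

* ``icu`` — critical-care shaped data: binary gender and a 5-class ethnicity
  as static variables, and six step-like hourly series
  {systolic, diastolic, fio2, urine, vasopressor, gcs} driven by a
  piecewise-constant latent severity state (well suited to forward-fill
  testing).

Every generator is a deterministic function of its :class:`FixtureSpec` seed.

Generating equations for the exercise family (constants fixed here):

    A_i   = 80 + m * (3*z_age + 4*male + 2*z_wt) + 6*f_i        (effort amplitude)
    HR_it = 75   + A_i * ramp(t)        + eps,  sd 3.0
    VO2_it = 0.5 + 0.040 * A_i * ramp(t) + eps, sd 0.08
    VCO2_it = 0.45 + 0.042 * A_i * ramp(t) + eps, sd 0.08
    RR_it = 15   + 0.25 * A_i * ramp(t) + eps,  sd 1.0
    VE_it = 10   + 0.90 * A_i * ramp(t) + eps,  sd 2.5

where ``m = metadata_effect``, ``z_age``/``z_wt`` are standardized age and
weight, ``f_i ~ N(0,1)`` is a subject fitness latent independent of the
metadata, and ``ramp(t)`` is the warmup/ramp/plateau/recovery profile in
[0, 1].
"""

from __future__ import annotations

from dataclasses import dataclass

import numpy as np
import pandas as pd

from .core_data.types import (
    LongitudinalDataset,
    SeriesBlock,
    StaticTable,
    VariableSchema,
)
from .errors import ConfigurationError

EXERCISE_STATIC = ["age", "sex", "height", "weight", "temperature", "humidity"]
EXERCISE_DYNAMIC = ["HR", "VO2", "VCO2", "RR", "VE"]
ICU_ETHNICITIES = ("white", "black", "hispanic", "asian", "other")
ICU_DYNAMIC = ["systolic", "diastolic", "fio2", "urine", "vasopressor", "gcs"]


@dataclass(frozen=True)
class FixtureSpec:
    """Parameters of a fixture draw.

    ``metadata_effect`` scales how strongly static variables drive the series
    shape (0 decouples them); ``missing_rate`` is applied by
    :func:`inject_missingness` when requested through :func:`make_fixture`.
    """

    n_subjects: int
    T: int
    seed: int
    family: str = "exercise"
    missing_rate: float = 0.0
    metadata_effect: float = 1.0

    def __post_init__(self) -> None:
        if self.n_subjects < 2:
            raise ConfigurationError("n_subjects must be >= 2")
        if self.T < 8:
            raise ConfigurationError("T must be >= 8")
        if not (0.0 <= self.missing_rate < 1.0):
            raise ConfigurationError("missing_rate must lie in [0, 1)")
        if self.metadata_effect < 0:
            raise ConfigurationError("metadata_effect must be >= 0")
        if self.family not in ("exercise", "icu"):
            raise ConfigurationError(f"unknown family {self.family!r}")


def _ramp_profile(T: int) -> np.ndarray:
    """Warmup 0, linear ramp to 1, saturation plateau, recovery decay to 0.3."""
    t = np.arange(T) / max(T - 1, 1)
    prof = np.zeros(T)
    ramp = (t >= 0.15) & (t < 0.70)
    prof[ramp] = (t[ramp] - 0.15) / 0.55
    prof[(t >= 0.70) & (t < 0.85)] = 1.0
    rec = t >= 0.85
    prof[rec] = 1.0 - 0.7 * (t[rec] - 0.85) / 0.15
    return prof


def make_exercise_fixture(spec: FixtureSpec) -> LongitudinalDataset:
    """Draw an exercise-test shaped dataset (see module docstring)."""
    if spec.family != "exercise":
        raise ConfigurationError("spec.family must be 'exercise'")
    rng = np.random.default_rng(spec.seed)
    n, T, m = spec.n_subjects, spec.T, spec.metadata_effect

    age = np.clip(rng.normal(29.0, 8.0, n), 16.0, 60.0)
    male = rng.random(n) < 0.85
    height = rng.normal(175.0, 8.0, n)
    weight = 73.0 + 0.35 * (height - 175.0) + rng.normal(0.0, 8.0, n)
    temperature = rng.normal(22.9, 2.0, n)
    humidity = np.clip(rng.normal(47.0, 8.0, n), 10.0, 95.0)

    z_age = (age - 29.0) / 8.0
    z_wt = (weight - 73.0) / 10.0
    fitness = rng.normal(0.0, 1.0, n)
    amplitude = 80.0 + m * (3.0 * z_age + 4.0 * male + 2.0 * z_wt) + 6.0 * fitness

    prof = _ramp_profile(T)
    base = {"HR": 75.0, "VO2": 0.5, "VCO2": 0.45, "RR": 15.0, "VE": 10.0}
    gain = {"HR": 1.0, "VO2": 0.040, "VCO2": 0.042, "RR": 0.25, "VE": 0.90}
    noise_sd = {"HR": 3.0, "VO2": 0.08, "VCO2": 0.08, "RR": 1.0, "VE": 2.5}

    values = []
    for i in range(n):
        arr = np.empty((T, len(EXERCISE_DYNAMIC)))
        for j, var in enumerate(EXERCISE_DYNAMIC):
            arr[:, j] = (
                base[var]
                + gain[var] * amplitude[i] * prof
                + rng.normal(0.0, noise_sd[var], T)
            )
        values.append(arr)

    ids = [f"s{i:04d}" for i in range(n)]
    frame = pd.DataFrame(
        {
            "age": age,
            "sex": np.where(male, "M", "F"),
            "height": height,
            "weight": weight,
            "temperature": temperature,
            "humidity": humidity,
        },
        index=pd.Index(ids, name="subject_id"),
    )
    schema = [
        VariableSchema("age", "numeric", "static"),
        VariableSchema("sex", "categorical", "static", categories=("F", "M")),
        VariableSchema("height", "numeric", "static"),
        VariableSchema("weight", "numeric", "static"),
        VariableSchema("temperature", "numeric", "static"),
        VariableSchema("humidity", "numeric", "static"),
    ] + [VariableSchema(v, "numeric", "dynamic") for v in EXERCISE_DYNAMIC]
    series = SeriesBlock(ids, list(EXERCISE_DYNAMIC), values, time_unit="step")
    return LongitudinalDataset(schema, StaticTable(frame), series)


def make_icu_fixture(spec: FixtureSpec, gender_balance: float = 0.5) -> LongitudinalDataset:
    """Draw a critical-care shaped dataset with step-like hourly series.

    ``gender_balance`` is the probability of the "M" gender label. A
    piecewise-constant latent severity path (segment lengths geometric with
    mean 8 steps) drives all six series; within a segment each series is
    exactly constant, so the data exercises forward-fill style imputation
    naturally.
    """
    if spec.family != "icu":
        raise ConfigurationError("spec.family must be 'icu'")
    if not (0.0 < gender_balance < 1.0):
        raise ConfigurationError("gender_balance must lie in (0, 1)")
    rng = np.random.default_rng(spec.seed)
    n, T, m = spec.n_subjects, spec.T, spec.metadata_effect

    male = rng.random(n) < gender_balance
    eth_probs = np.array([0.40, 0.25, 0.15, 0.12, 0.08])
    eth_idx = rng.choice(len(ICU_ETHNICITIES), size=n, p=eth_probs)
    base_sev = m * (0.4 * male + 0.15 * (eth_idx - 2.0)) + rng.normal(0.0, 1.0, n)

    values = []
    for i in range(n):
        # piecewise-constant severity path
        sev = np.empty(T)
        t0 = 0
        while t0 < T:
            seg = int(rng.geometric(1.0 / 8.0))
            level = base_sev[i] + rng.normal(0.0, 0.5)
            sev[t0 : t0 + seg] = level
            t0 += seg
        arr = np.empty((T, len(ICU_DYNAMIC)))
        arr[:, 0] = 110.0 - 8.0 * sev  # systolic
        arr[:, 1] = 0.6 * arr[:, 0] - 5.0 + rng.normal(0.0, 2.0)  # diastolic offset
        arr[:, 2] = np.clip(0.21 + 0.08 * np.maximum(sev, 0.0), 0.21, 1.0)  # fio2
        arr[:, 3] = np.maximum(60.0 - 15.0 * sev, 0.0)  # urine
        arr[:, 4] = (sev > 1.0).astype(float)  # vasopressor on/off
        arr[:, 5] = np.clip(np.round(13.0 - 2.0 * sev), 3, 15)  # gcs
        values.append(arr)

    ids = [f"p{i:04d}" for i in range(n)]
    frame = pd.DataFrame(
        {
            "gender": np.where(male, "M", "F"),
            "ethnicity": [ICU_ETHNICITIES[k] for k in eth_idx],
        },
        index=pd.Index(ids, name="subject_id"),
    )
    schema = [
        VariableSchema("gender", "categorical", "static", categories=("F", "M")),
        VariableSchema("ethnicity", "categorical", "static", categories=ICU_ETHNICITIES),
    ] + [VariableSchema(v, "numeric", "dynamic") for v in ICU_DYNAMIC]
    series = SeriesBlock(ids, list(ICU_DYNAMIC), values, time_unit="hour")
    return LongitudinalDataset(schema, StaticTable(frame), series)


def make_fixture(spec: FixtureSpec, **kwargs) -> LongitudinalDataset:
    """Dispatch on ``spec.family`` and apply ``spec.missing_rate`` if nonzero."""
    if spec.family == "exercise":
        ds = make_exercise_fixture(spec, **kwargs)
    else:
        ds = make_icu_fixture(spec, **kwargs)
    if spec.missing_rate > 0:
        ds = inject_missingness(ds, spec.missing_rate, seed=spec.seed + 1)
    return ds


def inject_missingness(
    dataset: LongitudinalDataset,
    rate: float,
    pattern: str = "random",
    seed: int = 0,
    block_length: int = 8,
) -> LongitudinalDataset:
    """Mask dynamic cells at the given rate, reproducibly.

    ``random`` masks exactly ``round(rate * total_cells)`` uniformly chosen
    cells. ``block`` masks contiguous runs of ``block_length`` samples within
    one subject/variable at a time until the same count is reached (the last
    run is trimmed so the total is exact).
    """
    if not (0.0 <= rate < 1.0):
        raise ConfigurationError("rate must lie in [0, 1)")
    if rate == 0.0:
        return dataset.copy()
    rng = np.random.default_rng(seed)
    out = dataset.copy()
    sizes = [arr.size for arr in out.series.values]
    total = int(sum(sizes))
    k = int(round(rate * total))
    if k == 0:
        return out

    if pattern == "random":
        flat_idx = rng.choice(total, size=k, replace=False)
        offsets = np.cumsum([0] + sizes)
        for idx in flat_idx:
            s = int(np.searchsorted(offsets, idx, side="right") - 1)
            local = idx - offsets[s]
            arr = out.series.values[s]
            arr[np.unravel_index(local, arr.shape)] = np.nan
        return out
    if pattern == "block":
        masked = 0
        n_vars = len(out.series.variables)
        while masked < k:
            s = int(rng.integers(len(out.series.values)))
            arr = out.series.values[s]
            j = int(rng.integers(n_vars))
            run = min(block_length, k - masked)
            start = int(rng.integers(max(arr.shape[0] - run, 0) + 1))
            seg = arr[start : start + run, j]
            newly = int((~np.isnan(seg)).sum())
            seg[:] = np.nan
            masked += newly
        return out
    raise ConfigurationError(f"unknown pattern {pattern!r}")


def mask_block(
    dataset: LongitudinalDataset, subject_id: str, variable: str, start: int, length: int
) -> LongitudinalDataset:
    """Mask one targeted contiguous run (handy for exclusion-rule tests)."""
    out = dataset.copy()
    i = out.series.subject_ids.index(subject_id)
    j = out.series.variables.index(variable)
    out.series.values[i][start : start + length, j] = np.nan
    return out
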