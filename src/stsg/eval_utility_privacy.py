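"""Utility via TSTR-vs-TRTR comparison; privacy via a cosine-distance
membership inference attack (MIA).

Utility: twin regressors (the regression counterparts of the DLA classifier
settings) are trained once on real training data (TRTR) and once on
synthetic data (TSTR), both tested on the same held-out real set. Each
model's mean absolute error (MAE) is recorded and the two MAE vectors are
compared with cosine similarity — 1 means training on synthetic data is
indistinguishable, error-wise, from training on real data.

Privacy: an adversary holds a fraction of the generator's training subjects
plus the public synthetic data. Each candidate (known member or an
equal-count non-member drawn from a disjoint holdout) is flagged "disclosed"
when any synthetic record lies within a cosine distance threshold of it;
attack precision is members-flagged / all-flagged (0 when nothing is
flagged). Records are flattened and per-column min-max normalized on the
union before distances are computed, so no single large-scale column
dominates.
"""

from __future__ import annotations

import warnings
from dataclasses import dataclass, field

import numpy as np
import pandas as pd
from scipy.spatial.distance import cdist
from sklearn.ensemble import RandomForestRegressor
from sklearn.neighbors import KNeighborsRegressor
from sklearn.neural_network import MLPRegressor
from sklearn.preprocessing import StandardScaler
from sklearn.svm import LinearSVR
from sklearn.tree import DecisionTreeRegressor

from .core_data.types import LongitudinalDataset
from .errors import STSGError
from .eval_resemblance import flatten_records

# ---------------------------------------------------------------------------
# TSTR / TRTR


@dataclass
class TSTRResult:
    target: str
    regressors: list[str]
    mae_trtr: np.ndarray
    mae_tstr: np.ndarray
    similarity: float
    seed: int


def default_regressors(seed: int) -> dict[str, object]:
    """Regression twins of the real-vs-synthetic classifier settings."""
    return {
        "RF": RandomForestRegressor(n_estimators=100, random_state=seed),
        "KNN": KNeighborsRegressor(n_neighbors=10),
        "DT": DecisionTreeRegressor(random_state=seed),
        "SVM": LinearSVR(C=100, max_iter=300, random_state=seed),
        "MLP": MLPRegressor(
            hidden_layer_sizes=(64, 32),
            activation="relu",
            solver="adam",
            batch_size=200,
            learning_rate_init=0.001,
            max_iter=100,
            random_state=seed,
        ),
    }


def _regression_table(
    dataset: LongitudinalDataset, target: str, n_series_points: int
) -> tuple[np.ndarray, np.ndarray]:
    """Features = flattened record minus target-derived columns; y = target mean."""
    records = flatten_records(dataset, n_series_points=n_series_points)
    target_cols = [
        c
        for c in records.columns
        if c == target or c.startswith(f"{target}_")
    ]
    if f"{target}_mean" not in records.columns:
        raise STSGError(f"target {target!r} is not a dynamic variable of the dataset")
    y = records[f"{target}_mean"].to_numpy(dtype=float)
    X = records.drop(columns=target_cols).to_numpy(dtype=float)
    return X, y


def tstr_trtr(
    real_train: LongitudinalDataset,
    real_test: LongitudinalDataset,
    synth: LongitudinalDataset,
    target: str,
    regressors: dict[str, object] | None = None,
    seed: int = 0,
    n_series_points: int = 16,
) -> TSTRResult:
    """Train-on-synthetic-test-on-real against train-on-real-test-on-real.

    The regression task predicts the per-subject time mean of ``target`` from
    every other flattened feature. Both twins are tested on ``real_test``.
    """
    X_tr, y_tr = _regression_table(real_train, target, n_series_points)
    X_te, y_te = _regression_table(real_test, target, n_series_points)
    X_sy, y_sy = _regression_table(synth, target, n_series_points)
    if y_tr.std() == 0:
        raise STSGError(f"target {target!r} has zero variance in the training data")

    names, mae_trtr, mae_tstr = [], [], []
    models = regressors if regressors is not None else default_regressors(seed)
    with warnings.catch_warnings():
        warnings.simplefilter("ignore")
        for name, model in models.items():
            twin = type(model)(**model.get_params())
            for m, (X, y) in ((model, (X_tr, y_tr)), (twin, (X_sy, y_sy))):
                scaler = StandardScaler().fit(X)
                try:
                    m.fit(scaler.transform(X), y)
                except Exception as exc:  # noqa: BLE001
                    raise STSGError(f"regressor {name!r} failed to train: {exc}") from exc
                pred = m.predict(scaler.transform(X_te))
                err = float(np.abs(pred - y_te).mean())
                (mae_trtr if m is model else mae_tstr).append(err)
            names.append(name)
    a, b = np.asarray(mae_trtr), np.asarray(mae_tstr)
    similarity = float((a * b).sum() / (np.linalg.norm(a) * np.linalg.norm(b)))
    return TSTRResult(target, names, a, b, similarity, seed)


# ---------------------------------------------------------------------------
# membership inference attack


@dataclass
class MIAEntry:
    known_fraction: float
    precision: float
    n_flagged: int
    n_members_flagged: int
    seed: int


@dataclass
class MIAResult:
    threshold: float
    entries: list[MIAEntry] = field(default_factory=list)

    @property
    def known_fractions(self) -> list[float]:
        return [e.known_fraction for e in self.entries]

    @property
    def precisions(self) -> list[float]:
        return [e.precision for e in self.entries]

    def to_frame(self) -> pd.DataFrame:
        return pd.DataFrame(
            {
                "known_fraction": self.known_fractions,
                "precision": self.precisions,
                "n_flagged": [e.n_flagged for e in self.entries],
            }
        )


def _as_records(data, n_series_points: int) -> np.ndarray:
    if isinstance(data, pd.DataFrame):
        return data.to_numpy(dtype=float)
    if isinstance(data, np.ndarray):
        return data
    return flatten_records(data, n_series_points=n_series_points).to_numpy(dtype=float)


def mia(
    real_train,
    real_holdout,
    synth,
    known_fraction: float,
    threshold: float = 0.2,
    seed: int = 0,
    n_series_points: int = 16,
) -> MIAEntry:
    """One membership-inference evaluation at a single known fraction."""
    if not (0.0 < known_fraction <= 1.0):
        raise STSGError("known_fraction must lie in (0, 1]")
    train = _as_records(real_train, n_series_points)
    hold = _as_records(real_holdout, n_series_points)
    sy = _as_records(synth, n_series_points)
    if train.shape[1] != hold.shape[1] or train.shape[1] != sy.shape[1]:
        raise STSGError("record tables must share columns")

    # per-column min-max normalization on the union
    union = np.vstack([train, hold, sy])
    lo, hi = union.min(axis=0), union.max(axis=0)
    span = np.where(hi > lo, hi - lo, 1.0)
    train, hold, sy = ((a - lo) / span for a in (train, hold, sy))

    rng = np.random.default_rng(seed)
    n_known = max(1, int(round(known_fraction * len(train))))
    members = train[rng.permutation(len(train))[:n_known]]
    if len(hold) < n_known:
        raise STSGError(
            f"holdout has {len(hold)} records; {n_known} non-members required"
        )
    non_members = hold[rng.permutation(len(hold))[:n_known]]

    candidates = np.vstack([members, non_members])
    is_member = np.arange(len(candidates)) < n_known
    dist = cdist(sy, candidates, metric="cosine")
    flagged = (dist <= threshold).any(axis=0)
    n_flagged = int(flagged.sum())
    n_tp = int((flagged & is_member).sum())
    precision = float(n_tp / n_flagged) if n_flagged else 0.0
    return MIAEntry(known_fraction, precision, n_flagged, n_tp, seed)


def mia_curve(
    real_train,
    real_holdout,
    synth,
    fractions: tuple[float, ...] = (0.1, 0.2, 0.3, 0.4, 0.5),
    threshold: float = 0.2,
    seed: int = 0,
    n_series_points: int = 16,
) -> MIAResult:
    """MIA precision over a grid of adversary-known fractions.

    Each fraction uses the deterministic seed ``seed + i`` so that curve
    entries coincide with single-fraction calls made with the same seeds.
    """
    result = MIAResult(threshold=threshold)
    for i, frac in enumerate(fractions):
        result.entries.append(
            mia(
                real_train,
                real_holdout,
                synth,
                frac,
                threshold=threshold,
                seed=seed + i,
                n_series_points=n_series_points,
            )
        )
    return result
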