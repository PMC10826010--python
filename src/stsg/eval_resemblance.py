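"""Resemblance metrics: mixed-type association matrix and its preservation
score, Data Labelling Analysis (DLA), precision-recall distributions (PRD)
with the F_gamma summary, and autocorrelation MAE.

Record representation: for metrics that operate on per-record tables (DLA,
PRD, and the utility/privacy metrics that reuse :func:`flatten_records`),
each subject is flattened to
``[static numeric, one-hot categoricals, per-variable series summaries,
evenly downsampled series values]``. Associations are computed on variables,
not flattened records: static variables plus (optionally) the per-subject
series summaries and per-subject series means.
"""

from __future__ import annotations

import warnings
from dataclasses import dataclass

import numpy as np
import pandas as pd
from scipy.stats import chi2_contingency
from sklearn.cluster import KMeans
from sklearn.ensemble import RandomForestClassifier
from sklearn.metrics import roc_auc_score
from sklearn.model_selection import train_test_split
from sklearn.neighbors import KNeighborsClassifier
from sklearn.neural_network import MLPClassifier
from sklearn.preprocessing import StandardScaler
from sklearn.svm import LinearSVC
from sklearn.tree import DecisionTreeClassifier

from .core_data.types import LongitudinalDataset, SeriesBlock
from .coupling import summarize_series
from .errors import InsufficientDataError, STSGError

# ---------------------------------------------------------------------------
# record flattening


def flatten_records(
    dataset: LongitudinalDataset,
    n_series_points: int = 16,
    include_summaries: bool = True,
) -> pd.DataFrame:
    """Flatten each subject to one numeric record (see module docstring).

    Series are represented by ``min(T, n_series_points)`` evenly spaced
    samples per variable, keeping the record dimension bounded for long
    series.
    """
    cols: dict[str, np.ndarray] = {}
    for s in dataset.static_schema:
        if s.encoding != "none":
            raise STSGError("flatten_records expects a decoded dataset")
        if s.kind == "numeric":
            cols[s.name] = dataset.static.frame[s.name].to_numpy(dtype=float)
        else:
            lab = dataset.static.frame[s.name].astype(str).to_numpy()
            for c in s.categories or ():
                cols[f"{s.name}__{c}"] = (lab == c).astype(float)
    if dataset.series.variables:
        stacked = dataset.series.stacked()
        if include_summaries:
            summ = summarize_series(dataset)
            for c in summ.columns:
                cols[c] = summ.frame[c].to_numpy(dtype=float)
        T = stacked.shape[1]
        pts = np.unique(np.linspace(0, T - 1, min(T, n_series_points)).astype(int))
        for j, var in enumerate(dataset.series.variables):
            for k, t in enumerate(pts):
                cols[f"{var}_t{t}"] = stacked[:, t, j]
    return pd.DataFrame(cols, index=dataset.static.frame.index)


# ---------------------------------------------------------------------------
# association matrix


@dataclass
class AssociationMatrix:
    """Square mixed-type association matrix over named variables.

    Numeric-numeric cells hold Pearson r in [-1, 1]; categorical-categorical
    cells hold Cramer's V in [0, 1]; mixed cells hold the R^2 of regressing
    the numeric feature on the categorical indicators (equivalently the
    between-group share of variance). Cells that are undefined because a
    feature has zero variance are NaN and flagged in ``defined``.
    """

    variables: list[str]
    matrix: np.ndarray
    defined: np.ndarray

    def lower_triangle(self) -> tuple[np.ndarray, np.ndarray]:
        """Values and defined-mask of the strict lower triangle, flattened."""
        n = len(self.variables)
        tri = np.tril_indices(n, k=-1)
        return self.matrix[tri], self.defined[tri]


def cramers_v(table: np.ndarray | pd.DataFrame) -> float:
    """Cramer's V = sqrt(chi2 / (n * min(rows-1, cols-1))).

    Zero-marginal rows/columns are dropped before the chi-squared test; a
    table that degenerates to a single row or column has V = 0.
    """
    t = np.asarray(table, dtype=float)
    if (t < 0).any() or t.sum() <= 0:
        raise STSGError("contingency table must be nonnegative with positive total")
    t = t[t.sum(axis=1) > 0][:, t.sum(axis=0) > 0]
    if min(t.shape) < 2:
        return 0.0
    chi2 = chi2_contingency(t, correction=False)[0]
    n = t.sum()
    denom = n * (min(t.shape) - 1)
    return float(np.sqrt(chi2 / denom))


def _pearson(x: np.ndarray, y: np.ndarray) -> float:
    if x.std() == 0 or y.std() == 0:
        return np.nan
    return float(np.corrcoef(x, y)[0, 1])


def _eta_squared(numeric: np.ndarray, labels: np.ndarray) -> float:
    """R^2 of regressing a numeric feature on categorical indicators."""
    total = ((numeric - numeric.mean()) ** 2).sum()
    if total == 0:
        return np.nan
    if len(np.unique(labels)) < 2:
        return np.nan
    within = 0.0
    for lab in np.unique(labels):
        grp = numeric[labels == lab]
        within += ((grp - grp.mean()) ** 2).sum()
    return float(1.0 - within / total)


def mixed_association_matrix(
    dataset: LongitudinalDataset,
    include: tuple[str, ...] = ("static", "dynamic", "summaries"),
) -> AssociationMatrix:
    """Association matrix over static variables and series-derived columns.

    ``include`` selects variable groups: ``static`` (metadata), ``dynamic``
    (each series variable represented by its per-subject time mean) and
    ``summaries`` (per-variable max/min columns; the mean is covered by
    ``dynamic``).
    """
    if dataset.n_subjects < 2:
        raise InsufficientDataError("need at least 2 subjects for associations")
    columns: dict[str, tuple[str, np.ndarray]] = {}  # name -> (kind, values)
    if "static" in include:
        for s in dataset.static_schema:
            if s.kind == "numeric":
                columns[s.name] = (
                    "numeric",
                    dataset.static.frame[s.name].to_numpy(dtype=float),
                )
            else:
                columns[s.name] = (
                    "categorical",
                    dataset.static.frame[s.name].astype(str).to_numpy(),
                )
    if dataset.series.variables and ({"dynamic", "summaries"} & set(include)):
        summ = summarize_series(dataset)
        for var in dataset.series.variables:
            if "dynamic" in include:
                columns[var] = (
                    "numeric",
                    summ.frame[f"{var}_mean"].to_numpy(dtype=float),
                )
            if "summaries" in include:
                for stat in ("max", "min"):
                    name = f"{var}_{stat}"
                    columns[name] = ("numeric", summ.frame[name].to_numpy(dtype=float))

    names = list(columns)
    k = len(names)
    mat = np.full((k, k), np.nan)
    for i in range(k):
        kind_i, x = columns[names[i]]
        if kind_i == "numeric":
            mat[i, i] = np.nan if x.std() == 0 else 1.0
        else:
            mat[i, i] = np.nan if len(np.unique(x)) < 2 else 1.0
        for j in range(i):
            kind_j, y = columns[names[j]]
            if kind_i == "numeric" and kind_j == "numeric":
                v = _pearson(x, y)
            elif kind_i == "categorical" and kind_j == "categorical":
                if len(np.unique(x)) < 2 or len(np.unique(y)) < 2:
                    v = np.nan
                else:
                    v = cramers_v(pd.crosstab(x, y).to_numpy())
            else:
                num, lab = (x, y) if kind_i == "numeric" else (y, x)
                v = _eta_squared(num, lab)
            mat[i, j] = mat[j, i] = v
    return AssociationMatrix(names, mat, np.isfinite(mat))


def correlation_similarity(
    real_assoc: AssociationMatrix,
    synth_assoc: AssociationMatrix,
    printed_variant: bool = False,
) -> float:
    """Cosine similarity between the strict lower triangles of two matrices.

    Cells undefined on either side are excluded pairwise. The default is the
    standard cosine (dot product over the product of Euclidean norms);
    ``printed_variant`` divides by the product of the coordinate sums
    instead, which is unbounded and kept only for comparability.
    """
    if real_assoc.variables != synth_assoc.variables:
        raise STSGError("association matrices cover different variables")
    x, dx = real_assoc.lower_triangle()
    y, dy = synth_assoc.lower_triangle()
    ok = dx & dy
    if not ok.any():
        raise STSGError("all association cells are undefined; similarity undefined")
    x, y = x[ok], y[ok]
    if printed_variant:
        return float((x * y).sum() / (x.sum() * y.sum()))
    nx, ny = np.linalg.norm(x), np.linalg.norm(y)
    if nx == 0 or ny == 0:
        raise STSGError("zero-norm association vector; similarity undefined")
    return float((x * y).sum() / (nx * ny))


# ---------------------------------------------------------------------------
# data labelling analysis


def default_classifiers(seed: int) -> dict[str, object]:
    """The five real-vs-synthetic classifiers with their fixed settings."""
    return {
        "RF": RandomForestClassifier(n_estimators=100, criterion="gini", random_state=seed),
        "KNN": KNeighborsClassifier(n_neighbors=10),
        "DT": DecisionTreeClassifier(criterion="gini", random_state=seed),
        "SVM": LinearSVC(C=100, max_iter=300),
        "MLP": MLPClassifier(
            hidden_layer_sizes=(64, 32),
            activation="relu",
            solver="adam",
            batch_size=200,
            learning_rate_init=0.001,
            max_iter=100,
            random_state=seed,
        ),
    }


def dla(
    real: LongitudinalDataset | pd.DataFrame,
    synth: LongitudinalDataset | pd.DataFrame,
    classifiers: dict[str, object] | None = None,
    test_size: float = 0.3,
    seed: int = 0,
    n_series_points: int = 16,
) -> dict[str, float]:
    """Train classifiers to distinguish real (label 0) from synthetic (1).

    Returns per-classifier held-out AUROC plus their mean. Values near 0.5
    mean the classifiers cannot tell the sources apart.
    """
    r = real if isinstance(real, pd.DataFrame) else flatten_records(real, n_series_points)
    s = synth if isinstance(synth, pd.DataFrame) else flatten_records(synth, n_series_points)
    if list(r.columns) != list(s.columns):
        raise STSGError("real and synthetic record tables must share columns")
    X = np.vstack([r.to_numpy(float), s.to_numpy(float)])
    y = np.concatenate([np.zeros(len(r)), np.ones(len(s))])
    X_tr, X_te, y_tr, y_te = train_test_split(
        X, y, test_size=test_size, stratify=y, random_state=seed
    )
    scaler = StandardScaler().fit(X_tr)
    X_tr, X_te = scaler.transform(X_tr), scaler.transform(X_te)
    out: dict[str, float] = {}
    models = classifiers if classifiers is not None else default_classifiers(seed)
    with warnings.catch_warnings():
        warnings.simplefilter("ignore")
        for name, model in models.items():
            model.fit(X_tr, y_tr)
            if hasattr(model, "predict_proba"):
                score = model.predict_proba(X_te)[:, 1]
            else:
                score = model.decision_function(X_te)
            out[name] = float(roc_auc_score(y_te, score))
    out["mean"] = float(np.mean([v for k, v in out.items() if k != "mean"]))
    return out


# ---------------------------------------------------------------------------
# precision-recall distributions


@dataclass
class PRDCurve:
    """Ordered (alpha, beta) = (precision, recall) pairs in the unit square."""

    points: np.ndarray  # (n_angles, 2)
    settings: dict

    @property
    def alphas(self) -> np.ndarray:
        return self.points[:, 0]

    @property
    def betas(self) -> np.ndarray:
        return self.points[:, 1]


def prd_from_histograms(p, q, n_angles: int = 1001, epsilon: float = 1e-10) -> PRDCurve:
    """PRD of two discrete distributions over shared bins.

    ``p`` is the real distribution, ``q`` the synthetic one. For each slope
    ``lambda = tan(theta)`` with theta swept over (0, pi/2):
    ``alpha = sum_c min(lambda * p_c, q_c)`` and
    ``beta = sum_c min(p_c, q_c / lambda)``.
    """
    p = np.asarray(p, dtype=float)
    q = np.asarray(q, dtype=float)
    if p.shape != q.shape:
        raise STSGError("histograms must share bins")
    p = p / p.sum()
    q = q / q.sum()
    angles = np.linspace(epsilon, np.pi / 2 - epsilon, n_angles)
    lam = np.tan(angles)
    alpha = np.minimum(lam[:, None] * p[None, :], q[None, :]).sum(axis=1)
    beta = np.minimum(p[None, :], q[None, :] / lam[:, None]).sum(axis=1)
    pts = np.clip(np.stack([alpha, beta], axis=1), 0.0, 1.0)
    return PRDCurve(pts, {"n_angles": n_angles, "mode": "histogram"})


def prd_curve(
    real_records: pd.DataFrame | np.ndarray,
    synth_records: pd.DataFrame | np.ndarray,
    n_clusters: int = 20,
    n_angles: int = 1001,
    seed: int = 0,
) -> PRDCurve:
    """Cluster the pooled records and compare per-cluster histograms."""
    r = np.asarray(real_records, dtype=float)
    s = np.asarray(synth_records, dtype=float)
    if len(r) == 0 or len(s) == 0:
        raise STSGError("both record sets must be nonempty")
    pool = np.vstack([r, s])
    pool = StandardScaler().fit_transform(pool)
    km = KMeans(n_clusters=min(n_clusters, len(pool)), random_state=seed, n_init=10)
    labels = km.fit_predict(pool)
    k = km.n_clusters
    p = np.bincount(labels[: len(r)], minlength=k).astype(float)
    q = np.bincount(labels[len(r) :], minlength=k).astype(float)
    curve = prd_from_histograms(p, q, n_angles=n_angles)
    curve.settings.update({"n_clusters": k, "seed": seed, "mode": "clustered"})
    return curve


def f_gamma(curve: PRDCurve, gamma: float = 8.0) -> float:
    """Maximum F_gamma over the curve; gamma > 1 weighs recall higher."""
    if gamma <= 0:
        raise STSGError("gamma must be positive")
    a, b = curve.alphas, curve.betas
    denom = gamma**2 * a + b
    with np.errstate(invalid="ignore", divide="ignore"):
        f = (1 + gamma**2) * a * b / denom
    f = np.where(denom > 0, f, 0.0)
    return float(f.max()) if len(f) else 0.0


# ---------------------------------------------------------------------------
# autocorrelation


def _sample_acf(rows: np.ndarray, nlags: int) -> np.ndarray:
    """Sample ACF at lags 1..nlags for each row of ``rows`` ((n, T) array)."""
    x = rows - rows.mean(axis=1, keepdims=True)
    T = x.shape[1]
    denom = (x * x).sum(axis=1)
    out = np.empty((x.shape[0], nlags))
    for lag in range(1, nlags + 1):
        num = (x[:, :-lag] * x[:, lag:]).sum(axis=1)
        with np.errstate(invalid="ignore", divide="ignore"):
            out[:, lag - 1] = num / denom
    out[denom == 0] = np.nan
    return out


def autocorrelation_mae(
    real: SeriesBlock | LongitudinalDataset,
    synth: SeriesBlock | LongitudinalDataset,
    max_lag: int | None = None,
) -> dict[str, float]:
    """MAE between mean autocorrelation functions, per variable + mean.

    For each dynamic variable, the sample ACF at lags ``1..max_lag`` is
    averaged over subjects separately for the real and synthetic blocks; the
    reported value is the mean absolute difference of those two mean
    functions. Variables that are constant for every subject on either side
    are masked with a warning.
    """
    r = real.series if isinstance(real, LongitudinalDataset) else real
    s = synth.series if isinstance(synth, LongitudinalDataset) else synth
    if list(r.variables) != list(s.variables):
        raise STSGError("series blocks must share variables")
    if r.has_missing() or s.has_missing():
        raise STSGError("series contain missing values; preprocess first")
    T = min(r.T, s.T)
    nlags = min(40, T - 1) if max_lag is None else max_lag
    if nlags >= T:
        raise STSGError(f"max_lag must be < T = {T}")
    out: dict[str, float] = {}
    for j, var in enumerate(r.variables):
        acf_r = _sample_acf(np.stack([arr[:T, j] for arr in r.values]), nlags)
        acf_s = _sample_acf(np.stack([arr[:T, j] for arr in s.values]), nlags)
        mean_r = np.nanmean(acf_r, axis=0)
        mean_s = np.nanmean(acf_s, axis=0)
        if np.isnan(mean_r).any() or np.isnan(mean_s).any():
            warnings.warn(f"variable {var!r} constant for all subjects; masked")
            out[var] = np.nan
            continue
        out[var] = float(np.abs(mean_r - mean_s).mean())
    vals = [v for v in out.values() if np.isfinite(v)]
    out["mean"] = float(np.mean(vals)) if vals else np.nan
    return out
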