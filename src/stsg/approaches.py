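"""Orchestration of the three generation approaches and their evaluation.

* A1 — generate synthetic metadata (augmented with series summary
  statistics) and couple it to the *real* series pool; every output series
  is bit-identical to a real one.
* A2 — generate metadata and series separately, summarize the synthetic
  series, and couple metadata to the synthetic pool.
* A3 — generate metadata and series jointly in a single model; no coupling.

Evaluation uses pseudo-cross-validation: one trained setup is sampled
``n_folds`` times (default 8) with distinct seeds, every enabled metric is
computed per fold, and results are aggregated as mean +/- sample std.
Approaches are compared metric-by-metric with Welch two-sample t-tests at a
configurable significance level.
"""

from __future__ import annotations

import hashlib
import json
import os
from dataclasses import dataclass, field, replace

import numpy as np
import pandas as pd
from scipy import stats

from .core_data.types import LongitudinalDataset
from .coupling import CouplingResult, augment_metadata, couple, summarize_series
from .errors import ConfigurationError, STSGError
from .eval_resemblance import (
    autocorrelation_mae,
    correlation_similarity,
    dla,
    f_gamma,
    flatten_records,
    mixed_association_matrix,
    prd_curve,
)
from .eval_utility_privacy import tstr_trtr
from .generators import (
    DGANConfig,
    TrainedGenerator,
    WGANGPConfig,
    sample,
    train_baseline,
    train_dgan,
    train_wgan_gp,
)

DEFAULT_METRICS = (
    "correlation_similarity",
    "dla_auroc",
    "prd_f8",
    "autocorrelation_mae",
    "tstr_similarity",
)


@dataclass
class RunConfig:
    """Configuration of one approach run + its evaluation."""

    approach: str = "A3"
    backend: str = "baseline"
    backend_config: object | None = None  # WGANGPConfig | DGANConfig | {"jitter": ...}
    n_folds: int = 8
    seed: int = 0
    coupling_method: str = "hungarian"
    train_per_fold: bool = False
    metrics: tuple[str, ...] = DEFAULT_METRICS
    tstr_target: str | None = None
    n_series_points: int = 16
    dla_test_size: float = 0.3
    prd_clusters: int = 20
    prd_angles: int = 1001

    def __post_init__(self) -> None:
        if self.approach not in ("A1", "A2", "A3"):
            raise ConfigurationError(f"unknown approach {self.approach!r}")
        if self.backend not in ("baseline", "wgan_gp", "dgan"):
            raise ConfigurationError(f"unknown backend {self.backend!r}")
        if self.n_folds < 2:
            raise ConfigurationError("n_folds must be >= 2 for aggregate statistics")

    def fold_seeds(self) -> list[int]:
        return [self.seed + 1 + 17 * i for i in range(self.n_folds)]


def _train(config: RunConfig, dataset: LongitudinalDataset, mode: str, seed_shift: int = 0):
    bc = config.backend_config
    if config.backend == "baseline":
        opts = dict(bc or {})
        return train_baseline(
            dataset,
            jitter=float(opts.get("jitter", 0.0)),
            seed=config.seed + seed_shift,
            mode=mode,
        )
    if config.backend == "wgan_gp":
        cfg = bc if isinstance(bc, WGANGPConfig) else WGANGPConfig(**(bc or {}))
        cfg = replace(cfg, seed=cfg.seed + seed_shift)
        return train_wgan_gp(dataset, cfg, mode=mode)
    # DGAN is a joint model; for metadata- or series-only use it is trained
    # jointly and the relevant component is kept at sampling time.
    cfg = bc if isinstance(bc, DGANConfig) else DGANConfig(**(bc or {}))
    cfg = replace(cfg, seed=cfg.seed + seed_shift)
    return train_dgan(dataset, cfg)


def _sample_component(gen: TrainedGenerator, n: int, seed: int, component: str):
    """Sample and keep the requested component (handles joint-only backends)."""
    out = sample(gen, n, seed)
    if isinstance(out, LongitudinalDataset):
        if component == "metadata":
            return out.static
        if component == "series":
            return out.series
        return out
    return out


@dataclass
class FoldOutputs:
    datasets: list[LongitudinalDataset]
    couplings: list[CouplingResult | None]
    provenance: dict


def run_a1(real: LongitudinalDataset, config: RunConfig) -> FoldOutputs:
    """Synthetic metadata coupled to the real series pool, per fold."""
    summary = summarize_series(real)
    aug_static, extra_schema = augment_metadata(real.static, summary)
    aug_schema = list(real.static_schema) + extra_schema + list(real.dynamic_schema)
    aug_ds = LongitudinalDataset(aug_schema, aug_static, real.series.copy())
    static_schema = list(real.static_schema) + extra_schema

    datasets, couplings = [], []
    gen = None if config.train_per_fold else _train(config, aug_ds, "metadata_only")
    for k, fs in enumerate(config.fold_seeds()):
        g = _train(config, aug_ds, "metadata_only", seed_shift=k + 1) if gen is None else gen
        synth_static = _sample_component(g, real.n_subjects, fs, "metadata")
        ds, cr = couple(
            synth_static,
            (real.series, summary),
            static_schema,
            method=config.coupling_method,
        )
        datasets.append(ds)
        couplings.append(cr)
    return FoldOutputs(datasets, couplings, {"approach": "A1", "coupling": config.coupling_method})


def run_a2(real: LongitudinalDataset, config: RunConfig) -> FoldOutputs:
    """Separately generated metadata and series, coupled per fold."""
    summary = summarize_series(real)
    aug_static, extra_schema = augment_metadata(real.static, summary)
    aug_schema = list(real.static_schema) + extra_schema + list(real.dynamic_schema)
    aug_ds = LongitudinalDataset(aug_schema, aug_static, real.series.copy())
    static_schema = list(real.static_schema) + extra_schema

    gen_meta = None if config.train_per_fold else _train(config, aug_ds, "metadata_only")
    gen_series = None if config.train_per_fold else _train(config, real, "series_only")
    datasets, couplings = [], []
    for k, fs in enumerate(config.fold_seeds()):
        gm = (
            _train(config, aug_ds, "metadata_only", seed_shift=k + 1)
            if gen_meta is None
            else gen_meta
        )
        gs = (
            _train(config, real, "series_only", seed_shift=k + 101)
            if gen_series is None
            else gen_series
        )
        synth_static = _sample_component(gm, real.n_subjects, fs, "metadata")
        synth_series = _sample_component(gs, real.n_subjects, fs + 5000, "series")
        synth_summary = summarize_series(synth_series)
        ds, cr = couple(
            synth_static,
            (synth_series, synth_summary),
            static_schema,
            method=config.coupling_method,
        )
        datasets.append(ds)
        couplings.append(cr)
    return FoldOutputs(datasets, couplings, {"approach": "A2", "coupling": config.coupling_method})


def run_a3(real: LongitudinalDataset, config: RunConfig) -> FoldOutputs:
    """Jointly generated metadata + series; no coupling step."""
    gen = None if config.train_per_fold else _train(config, real, "joint")
    datasets = []
    for k, fs in enumerate(config.fold_seeds()):
        g = _train(config, real, "joint", seed_shift=k + 1) if gen is None else gen
        out = _sample_component(g, real.n_subjects, fs, "joint")
        datasets.append(out)
    return FoldOutputs(datasets, [None] * config.n_folds, {"approach": "A3", "coupling": "none"})


def run_approach(real: LongitudinalDataset, config: RunConfig) -> FoldOutputs:
    return {"A1": run_a1, "A2": run_a2, "A3": run_a3}[config.approach](real, config)


# ---------------------------------------------------------------------------
# evaluation report


@dataclass
class EvaluationReport:
    folds: pd.DataFrame  # index = fold, columns = metrics
    provenance: dict = field(default_factory=dict)

    @property
    def metrics(self) -> list[str]:
        return list(self.folds.columns)

    def aggregates(self) -> pd.DataFrame:
        return pd.DataFrame(
            {
                "metric": self.metrics,
                "mean": [float(self.folds[m].mean()) for m in self.metrics],
                "std": [float(self.folds[m].std(ddof=1)) for m in self.metrics],
            }
        )

    def to_dir(self, out_dir: str) -> None:
        os.makedirs(out_dir, exist_ok=True)
        folds = self.folds.copy()
        folds.insert(0, "fold", self.folds.index)
        folds.to_csv(os.path.join(out_dir, "fold_metrics.csv"), index=False)
        self.aggregates().to_csv(os.path.join(out_dir, "aggregates.csv"), index=False)
        with open(os.path.join(out_dir, "provenance.json"), "w") as fh:
            json.dump(self.provenance, fh, indent=2, sort_keys=True)

    @classmethod
    def from_dir(cls, in_dir: str) -> "EvaluationReport":
        folds = pd.read_csv(os.path.join(in_dir, "fold_metrics.csv")).set_index("fold")
        folds.index.name = None
        with open(os.path.join(in_dir, "provenance.json")) as fh:
            prov = json.load(fh)
        return cls(folds, prov)


def _config_hash(config: RunConfig) -> str:
    return hashlib.sha256(repr(config).encode()).hexdigest()[:12]


def evaluate_fold(
    real: LongitudinalDataset,
    synth: LongitudinalDataset,
    config: RunConfig,
    fold_seed: int,
    real_assoc=None,
    tstr_split=None,
) -> dict[str, float]:
    """Compute every enabled metric for one synthetic fold."""
    out: dict[str, float] = {}
    if "correlation_similarity" in config.metrics:
        ra = real_assoc if real_assoc is not None else mixed_association_matrix(real)
        sa = mixed_association_matrix(synth)
        out["correlation_similarity"] = correlation_similarity(ra, sa)
    if "dla_auroc" in config.metrics:
        out["dla_auroc"] = dla(
            real,
            synth,
            test_size=config.dla_test_size,
            seed=fold_seed,
            n_series_points=config.n_series_points,
        )["mean"]
    if "prd_f8" in config.metrics:
        r = flatten_records(real, config.n_series_points)
        s = flatten_records(synth, config.n_series_points)
        curve = prd_curve(
            r, s, n_clusters=config.prd_clusters, n_angles=config.prd_angles, seed=fold_seed
        )
        out["prd_f8"] = f_gamma(curve, gamma=8.0)
    if "autocorrelation_mae" in config.metrics:
        out["autocorrelation_mae"] = autocorrelation_mae(real, synth)["mean"]
    if "tstr_similarity" in config.metrics:
        if tstr_split is None:
            tstr_split = _tstr_split(real, config.seed)
        train_ds, test_ds = tstr_split
        target = config.tstr_target or real.series.variables[0]
        out["tstr_similarity"] = tstr_trtr(
            train_ds,
            test_ds,
            synth,
            target,
            seed=config.seed,
            n_series_points=config.n_series_points,
        ).similarity
    return out


def _tstr_split(real: LongitudinalDataset, seed: int, test_frac: float = 0.3):
    rng = np.random.default_rng(seed)
    ids = list(real.subject_ids)
    perm = rng.permutation(len(ids))
    n_test = max(1, int(round(test_frac * len(ids))))
    test_ids = [ids[i] for i in perm[:n_test]]
    train_ids = [ids[i] for i in perm[n_test:]]
    return real.subset(train_ids), real.subset(test_ids)


def pseudo_cross_validate(real: LongitudinalDataset, config: RunConfig) -> EvaluationReport:
    """Run the configured approach, evaluate every fold, aggregate.

    Deterministic given the config seed: identical configs produce
    byte-identical report directories.
    """
    outputs = run_approach(real, config)
    real_assoc = (
        mixed_association_matrix(real)
        if "correlation_similarity" in config.metrics
        else None
    )
    tstr_split = (
        _tstr_split(real, config.seed) if "tstr_similarity" in config.metrics else None
    )
    rows = []
    for k, (ds, fs) in enumerate(zip(outputs.datasets, config.fold_seeds())):
        try:
            rows.append(evaluate_fold(real, ds, config, fs, real_assoc, tstr_split))
        except STSGError as exc:
            raise STSGError(f"evaluation failed on fold {k}: {exc}") from exc
    folds = pd.DataFrame(rows)
    provenance = {
        "approach": config.approach,
        "backend": config.backend,
        "n_folds": config.n_folds,
        "seed": config.seed,
        "fold_seeds": config.fold_seeds(),
        "coupling": outputs.provenance.get("coupling"),
        "config_hash": _config_hash(config),
    }
    return EvaluationReport(folds, provenance)


def compare_approaches(
    report_a: EvaluationReport, report_b: EvaluationReport, sl: float = 0.05
) -> pd.DataFrame:
    """Welch two-sample t-test per metric across folds.

    Identical fold vectors give p = 1 (no evidence of difference) by
    convention; two different constant vectors give p = 0.
    """
    if set(report_a.metrics) != set(report_b.metrics):
        raise STSGError("reports cover different metric sets")
    rows = []
    for m in report_a.metrics:
        a = report_a.folds[m].to_numpy(dtype=float)
        b = report_b.folds[m].to_numpy(dtype=float)
        if len(a) < 2 or len(b) < 2:
            raise STSGError("need at least 2 folds per report for a t-test")
        if a.std(ddof=1) == 0 and b.std(ddof=1) == 0:
            p = 1.0 if a.mean() == b.mean() else 0.0
        else:
            p = float(stats.ttest_ind(a, b, equal_var=False).pvalue)
        rows.append({"metric": m, "p_value": p, "significant": bool(p < sl)})
    return pd.DataFrame(rows)
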