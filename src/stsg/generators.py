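"""Generative backends behind one contract: WGAN-GP with a correlation
alignment loss, a DGAN-style metadata-conditioned recurrent generator, and a
fast deterministic resampling baseline.

All backends train on a flat design matrix built from a complete (no missing
values) dataset: static numeric variables min-max scaled to [0, 1], static
categoricals one-hot encoded, and each subject's series min-max scaled and
flattened time-major. Sampling inverts the representation (inverse scaling,
argmax decoding) and returns domain objects.

The WGAN-GP generator loss is

    L_G = -E[D(G(z))] + lambda * sum_{i>j} | r_hat_ij - r_ij |

where the second term penalises the L1 disparity between the synthetic and
real inter-variable Pearson correlations, computed per batch over the numeric
columns of the design matrix. The critic is trained with the standard
interpolated-sample gradient penalty (coefficient 10) and is updated
``critic_updates_per_gen`` times per generator step.

The DGAN backend generates metadata with an MLP and conditions a recurrent
network on it at every step, emitting ``S`` records per iteration; an
auxiliary critic judges the metadata alone and a combined critic judges
metadata plus series, both with gradient penalties.
"""

from __future__ import annotations

import math
from dataclasses import dataclass, field
from typing import Callable

import numpy as np
import pandas as pd

from .core_data.types import (
    LongitudinalDataset,
    ScalingState,
    SeriesBlock,
    StaticTable,
    VariableSchema,
)
from .errors import ConfigurationError, DivergenceError, STSGError
from .nn import MLP, Adam, Critic, RNNCell, Tensor, concat, interpolate_pairs, softmax

MODES = ("metadata_only", "series_only", "joint")


# ---------------------------------------------------------------------------
# design matrix


@dataclass
class ColumnBlock:
    name: str
    kind: str  # "numeric" | "onehot" | "series"
    start: int
    stop: int
    categories: tuple[str, ...] | None = None


@dataclass
class DesignLayout:
    """Maps between a dataset and its flat [0, 1] design-matrix encoding."""

    mode: str
    static_schema: list[VariableSchema]
    dynamic_schema: list[VariableSchema]
    scaling: ScalingState
    T: int
    blocks: list[ColumnBlock]
    dim: int

    @property
    def numeric_idx(self) -> np.ndarray:
        idx: list[int] = []
        for b in self.blocks:
            if b.kind in ("numeric", "series"):
                idx.extend(range(b.start, b.stop))
        return np.asarray(idx, dtype=int)

    @property
    def meta_dim(self) -> int:
        return sum(b.stop - b.start for b in self.blocks if b.kind != "series")

    @property
    def dyn_vars(self) -> list[str]:
        return [s.name for s in self.dynamic_schema]


def build_design(dataset: LongitudinalDataset, mode: str) -> tuple[np.ndarray, DesignLayout]:
    """Encode a complete dataset into a flat design matrix in [0, 1]."""
    if mode not in MODES:
        raise ConfigurationError(f"unknown mode {mode!r}")
    if mode != "metadata_only" and dataset.series.has_missing():
        raise STSGError("dataset contains missing dynamic values; preprocess first")
    for s in dataset.schema:
        if s.encoding != "none":
            raise STSGError("pass a decoded dataset; encoding is handled internally")

    scaling = ScalingState(applied=True)
    cols: list[np.ndarray] = []
    blocks: list[ColumnBlock] = []
    pos = 0

    if mode in ("metadata_only", "joint"):
        for s in dataset.static_schema:
            if s.kind == "numeric":
                x = dataset.static.frame[s.name].to_numpy(dtype=float)
                scaling.ranges[s.name] = (float(np.min(x)), float(np.max(x)))
                cols.append(scaling.forward(s.name, x)[:, None])
                blocks.append(ColumnBlock(s.name, "numeric", pos, pos + 1))
                pos += 1
            else:
                cats = list(s.categories or ())
                lab = dataset.static.frame[s.name].astype(str).to_numpy()
                onehot = (lab[:, None] == np.asarray(cats)[None, :]).astype(float)
                cols.append(onehot)
                blocks.append(
                    ColumnBlock(s.name, "onehot", pos, pos + len(cats), tuple(cats))
                )
                pos += len(cats)

    T = dataset.series.T if dataset.series.n_subjects else 0
    if mode in ("series_only", "joint"):
        stacked = dataset.series.stacked()  # (n, T, nv)
        for j, s in enumerate(dataset.dynamic_schema):
            v = stacked[:, :, j]
            scaling.ranges[s.name] = (float(v.min()), float(v.max()))
            stacked[:, :, j] = scaling.forward(s.name, v)
        flat = stacked.reshape(stacked.shape[0], -1)  # time-major
        cols.append(flat)
        blocks.append(ColumnBlock("__series__", "series", pos, pos + flat.shape[1]))
        pos += flat.shape[1]

    X = np.concatenate(cols, axis=1) if cols else np.empty((dataset.n_subjects, 0))
    layout = DesignLayout(
        mode=mode,
        static_schema=list(dataset.static_schema),
        dynamic_schema=list(dataset.dynamic_schema),
        scaling=scaling,
        T=T,
        blocks=blocks,
        dim=pos,
    )
    return X, layout


def decode_design(X: np.ndarray, layout: DesignLayout, id_prefix: str = "syn"):
    """Invert :func:`build_design` on generated rows.

    Returns a :class:`StaticTable` for metadata_only, a :class:`SeriesBlock`
    for series_only, and a :class:`LongitudinalDataset` for joint mode.
    One-hot blocks are decoded by argmax; numeric columns are inverse scaled.
    """
    n = X.shape[0]
    ids = [f"{id_prefix}{i:05d}" for i in range(n)]
    static_cols: dict[str, np.ndarray | list] = {}
    series_block: SeriesBlock | None = None
    for b in layout.blocks:
        if b.kind == "numeric":
            static_cols[b.name] = layout.scaling.inverse(b.name, X[:, b.start])
        elif b.kind == "onehot":
            cats = list(b.categories or ())
            static_cols[b.name] = [cats[i] for i in X[:, b.start : b.stop].argmax(axis=1)]
        else:
            nv = len(layout.dynamic_schema)
            cube = X[:, b.start : b.stop].reshape(n, layout.T, nv).copy()
            for j, s in enumerate(layout.dynamic_schema):
                cube[:, :, j] = layout.scaling.inverse(s.name, cube[:, :, j])
            series_block = SeriesBlock(ids, layout.dyn_vars, [cube[i] for i in range(n)])

    if layout.mode == "series_only":
        assert series_block is not None
        return series_block
    frame = pd.DataFrame(static_cols, index=pd.Index(ids, name="subject_id"))
    frame = frame[[s.name for s in layout.static_schema]]
    static = StaticTable(frame)
    if layout.mode == "metadata_only":
        return static
    assert series_block is not None
    schema = list(layout.static_schema) + list(layout.dynamic_schema)
    return LongitudinalDataset(schema, static, series_block)


# ---------------------------------------------------------------------------
# configs


@dataclass
class WGANGPConfig:
    epochs: int = 5000
    batch_size: int = 64
    critic_updates_per_gen: int = 5
    learning_rate: float = 1e-3
    lambda_align: float = 10.0
    gp_coefficient: float = 10.0
    noise_dim: int = 32
    hidden: tuple[int, ...] = (128, 128)
    seed: int = 0

    def __post_init__(self) -> None:
        if min(self.epochs, self.batch_size, self.critic_updates_per_gen, self.noise_dim) < 1:
            raise ConfigurationError("counts must be >= 1")
        if self.learning_rate <= 0 or self.lambda_align < 0 or self.gp_coefficient < 0:
            raise ConfigurationError("rates must be positive, coefficients >= 0")


@dataclass
class DGANConfig:
    S: int = 12
    epochs: int = 5000
    batch_size: int = 64
    learning_rate: float = 1e-3
    gp_coefficient: float = 10.0
    critic_updates_per_gen: int = 1
    meta_hidden: tuple[int, ...] = (128, 128)
    rnn_hidden: int = 128
    noise_dim: int = 32
    pad_series: bool = True
    seed: int = 0

    def __post_init__(self) -> None:
        if min(self.S, self.epochs, self.batch_size, self.rnn_hidden, self.noise_dim) < 1:
            raise ConfigurationError("counts must be >= 1")
        if self.learning_rate <= 0 or self.gp_coefficient < 0:
            raise ConfigurationError("learning rate must be positive, gp >= 0")


class _BaselineSampler:
    def __init__(self, X: np.ndarray, num_idx: np.ndarray, jitter: float):
        self.X = X
        self.num_idx = num_idx
        self.jitter = jitter
        self.col_std = X[:, num_idx].std(axis=0) if len(num_idx) else np.empty(0)

    def __call__(self, n_out: int, rng: np.random.Generator) -> np.ndarray:
        n_real = self.X.shape[0]
        take = rng.permutation(n_real)[:n_out]
        if n_out > n_real:
            extra = rng.integers(0, n_real, size=n_out - n_real)
            take = np.concatenate([take, extra])
        out = self.X[take].copy()
        if self.jitter > 0 and len(self.num_idx):
            noise = rng.normal(size=(n_out, len(self.num_idx))) * (
                self.jitter * self.col_std
            )
            out[:, self.num_idx] = np.clip(out[:, self.num_idx] + noise, 0.0, 1.0)
        return out


class _WGANSampler:
    def __init__(self, G: MLP, noise_dim: int):
        self.G = G
        self.noise_dim = noise_dim

    def __call__(self, n_out: int, rng: np.random.Generator) -> np.ndarray:
        z = rng.normal(size=(n_out, self.noise_dim))
        return self.G(Tensor(z)).data


class _DGANSampler:
    def __init__(self, meta_gen, rnn, out_layer, onehot_blocks, meta_dim, K, S, T, nv, noise_dim):
        self.meta_gen = meta_gen
        self.rnn = rnn
        self.out_layer = out_layer
        self.onehot_blocks = sorted(onehot_blocks)
        self.meta_dim = meta_dim
        self.K = K
        self.S = S
        self.T = T
        self.nv = nv
        self.noise_dim = noise_dim

    def gen_meta(self, z: Tensor) -> Tensor:
        raw = self.meta_gen(z)
        pieces, pos = [], 0
        for start, stop in self.onehot_blocks:
            if start > pos:
                pieces.append(raw[:, pos:start].sigmoid())
            pieces.append(softmax(raw[:, start:stop], axis=1))
            pos = stop
        if pos < self.meta_dim:
            pieces.append(raw[:, pos : self.meta_dim].sigmoid())
        return concat(pieces, axis=1) if len(pieces) > 1 else pieces[0]

    def gen_series(self, meta_t: Tensor, z_seq: np.ndarray) -> Tensor:
        B = meta_t.data.shape[0]
        h = Tensor(np.zeros((B, self.rnn.W_hh.data.shape[0])))
        chunks = []
        for k in range(self.K):
            x = concat([meta_t, Tensor(z_seq[:, k, :])], axis=1)
            h = self.rnn(x, h)
            chunks.append(self.out_layer(h))
        return concat(chunks, axis=1)  # (B, T_pad * nv), time-major

    def __call__(self, n_out: int, rng: np.random.Generator) -> np.ndarray:
        z_meta = rng.normal(size=(n_out, self.noise_dim))
        z_seq = rng.normal(size=(n_out, self.K, self.noise_dim))
        m = self.gen_meta(Tensor(z_meta)).data
        s = self.gen_series(Tensor(m), z_seq).data
        T_pad = self.K * self.S
        s = s.reshape(n_out, T_pad, self.nv)[:, : self.T, :].reshape(
            n_out, self.T * self.nv
        )
        return np.concatenate([m, s], axis=1)


@dataclass
class TrainedGenerator:
    """A fitted backend plus everything needed to sample domain objects.

    Picklable: persisting the object stores the fitted parameters, the
    captured schema/scaling layout and the training-loss trace.
    """

    backend: str
    mode: str
    layout: DesignLayout
    loss_trace: pd.DataFrame
    _sampler: Callable[[int, np.random.Generator], np.ndarray]
    config: object | None = None
    provenance: dict = field(default_factory=dict)

    def sample_matrix(self, n: int, rng: np.random.Generator) -> np.ndarray:
        return self._sampler(n, rng)


def sample(generator: TrainedGenerator, n: int, seed: int, id_prefix: str = "syn"):
    """Draw ``n`` records from a trained generator (seeded, reproducible)."""
    if n <= 0:
        raise ConfigurationError("n must be positive")
    rng = np.random.default_rng(seed)
    X = generator.sample_matrix(n, rng)
    return decode_design(X, generator.layout, id_prefix=id_prefix)


# ---------------------------------------------------------------------------
# alignment penalty


def correlation_alignment_penalty(real_assoc, synth_assoc, lambda_align: float) -> float:
    """lambda * sum over the strict lower triangle of |r_hat - r|.

    Accepts plain square arrays or objects with a ``.matrix`` attribute
    (e.g. an association matrix); undefined (NaN) cells are excluded
    pairwise.
    """
    r = np.asarray(getattr(real_assoc, "matrix", real_assoc), dtype=float)
    rhat = np.asarray(getattr(synth_assoc, "matrix", synth_assoc), dtype=float)
    if r.shape != rhat.shape or r.ndim != 2 or r.shape[0] != r.shape[1]:
        raise STSGError("association matrices must be square and of equal shape")
    tri = np.tril(np.ones_like(r, dtype=bool), k=-1)
    ok = tri & np.isfinite(r) & np.isfinite(rhat)
    return float(lambda_align * np.abs(rhat[ok] - r[ok]).sum())


def _alignment_penalty_tensor(
    fake: Tensor, num_idx: np.ndarray, real_batch: np.ndarray, lam: float
) -> Tensor:
    """Differentiable batch-level alignment penalty (numeric columns only)."""
    k = len(num_idx)
    if k < 2 or lam == 0:
        return Tensor(0.0)
    with np.errstate(invalid="ignore", divide="ignore"):
        r = np.corrcoef(real_batch[:, num_idx], rowvar=False)
    tri = np.tril(np.ones((k, k)), k=-1)
    tri = tri * np.isfinite(r)
    r = np.nan_to_num(r)
    sub = fake[:, num_idx]
    B = sub.data.shape[0]
    xc = sub - sub.mean(axis=0, keepdims=True)
    var = (xc * xc).mean(axis=0)
    z = xc * ((var + 1e-8) ** -0.5)
    R = z.transpose() @ z * (1.0 / B)
    return ((R - r).abs() * tri).sum() * lam


# ---------------------------------------------------------------------------
# WGAN-GP


def _check_finite(value: float, what: str, step: int) -> None:
    if not math.isfinite(value):
        raise DivergenceError(f"non-finite {what} at step {step}")


def train_wgan_gp(
    dataset: LongitudinalDataset, config: WGANGPConfig, mode: str = "joint"
) -> TrainedGenerator:
    """Train the WGAN-GP backend with the alignment loss (seeded)."""
    X, layout = build_design(dataset, mode)
    n, d = X.shape
    if n == 0 or d == 0:
        raise STSGError("empty dataset or empty design matrix")
    rng = np.random.default_rng(config.seed)
    G = MLP(rng, [config.noise_dim, *config.hidden, d], "relu", "sigmoid")
    D = Critic(rng, [d, *config.hidden, 1])
    opt_g = Adam(G.params, lr=config.learning_rate)
    opt_d = Adam(D.params, lr=config.learning_rate)
    num_idx = layout.numeric_idx
    B = min(config.batch_size, n)

    rows = []
    step = 0
    for epoch in range(config.epochs):
        perm = rng.permutation(n)
        d_losses, g_advs, aligns = [], [], []
        for b0 in range(0, n, B):
            batch = X[perm[b0 : b0 + B]]
            if batch.shape[0] < 2:
                continue
            for _ in range(config.critic_updates_per_gen):
                z = rng.normal(size=(batch.shape[0], config.noise_dim))
                fake = G(Tensor(z)).data
                real_t, fake_t = Tensor(batch), Tensor(fake)
                d_loss = D(fake_t).mean() - D(real_t).mean()
                if config.gp_coefficient > 0:
                    interp = interpolate_pairs(rng, batch, fake)
                    d_loss = d_loss + config.gp_coefficient * D.gradient_penalty(interp)
                opt_d.zero_grad()
                d_loss.backward()
                opt_d.step()
                step += 1
                _check_finite(float(d_loss.data), "critic loss", step)
                d_losses.append(float(d_loss.data))
            z = rng.normal(size=(batch.shape[0], config.noise_dim))
            fake = G(Tensor(z))
            adv = -D(fake).mean()
            align = _alignment_penalty_tensor(fake, num_idx, batch, config.lambda_align)
            g_loss = adv + align
            opt_g.zero_grad()
            for p in D.params:
                p.grad = None
            g_loss.backward()
            opt_g.step()
            step += 1
            _check_finite(float(g_loss.data), "generator loss", step)
            g_advs.append(float(adv.data))
            aligns.append(float(align.data))
        rows.append(
            {
                "epoch": epoch,
                "critic_loss": float(np.mean(d_losses)),
                "generator_adv": float(np.mean(g_advs)),
                "alignment_penalty": float(np.mean(aligns)),
            }
        )

    trace = pd.DataFrame(rows)
    sampler = _WGANSampler(G, config.noise_dim)
    return TrainedGenerator(
        backend="wgan_gp",
        mode=mode,
        layout=layout,
        loss_trace=trace,
        _sampler=sampler,
        config=config,
    )


# ---------------------------------------------------------------------------
# DGAN


def dgan_iterations(T: int, S: int, pad_series: bool = True) -> int:
    """Number of recurrent iterations for series length T at S records each."""
    if T % S == 0:
        return T // S
    if not pad_series:
        raise ConfigurationError(f"S={S} does not divide T={T} and padding is disabled")
    return math.ceil(T / S)


def train_dgan(dataset: LongitudinalDataset, config: DGANConfig) -> TrainedGenerator:
    """Train the metadata-conditioned recurrent backend (joint mode)."""
    X, layout = build_design(dataset, "joint")
    n = X.shape[0]
    if n == 0:
        raise STSGError("empty dataset")
    meta_dim = layout.meta_dim
    nv = len(layout.dynamic_schema)
    T = layout.T
    K = dgan_iterations(T, config.S, config.pad_series)
    T_pad = K * config.S

    meta = X[:, :meta_dim]
    series = X[:, meta_dim:].reshape(n, T, nv)
    if T_pad > T:  # right-pad by repeating the last sample
        pad = np.repeat(series[:, -1:, :], T_pad - T, axis=1)
        series = np.concatenate([series, pad], axis=1)
    series_flat = series.reshape(n, T_pad * nv)

    rng = np.random.default_rng(config.seed)
    meta_gen = MLP(rng, [config.noise_dim, *config.meta_hidden, meta_dim], "relu", None)
    rnn = RNNCell(rng, meta_dim + config.noise_dim, config.rnn_hidden)
    out_layer = MLP(rng, [config.rnn_hidden, config.S * nv], "relu", "sigmoid")
    d_aux = Critic(rng, [meta_dim, 128, 128, 1])
    d_comb = Critic(rng, [meta_dim + T_pad * nv, 128, 128, 1])

    gen_params = meta_gen.params + rnn.params + out_layer.params
    opt_g = Adam(gen_params, lr=config.learning_rate)
    opt_aux = Adam(d_aux.params, lr=config.learning_rate)
    opt_comb = Adam(d_comb.params, lr=config.learning_rate)

    onehot_blocks = [
        (b.start, b.stop) for b in layout.blocks if b.kind == "onehot"
    ]
    sampler = _DGANSampler(
        meta_gen, rnn, out_layer, onehot_blocks, meta_dim, K, config.S, T, nv,
        config.noise_dim,
    )

    def forward(B: int):
        z_meta = rng.normal(size=(B, config.noise_dim))
        z_seq = rng.normal(size=(B, K, config.noise_dim))
        m = sampler.gen_meta(Tensor(z_meta))
        s = sampler.gen_series(m, z_seq)
        return m, s

    B = min(config.batch_size, n)
    rows = []
    step = 0
    for epoch in range(config.epochs):
        perm = rng.permutation(n)
        aux_l, comb_l, g_l = [], [], []
        for b0 in range(0, n, B):
            idx = perm[b0 : b0 + B]
            if len(idx) < 2:
                continue
            meta_b, series_b = meta[idx], series_flat[idx]
            joint_b = np.concatenate([meta_b, series_b], axis=1)
            for _ in range(config.critic_updates_per_gen):
                m_f, s_f = forward(len(idx))
                meta_fake = m_f.data
                joint_fake = np.concatenate([meta_fake, s_f.data], axis=1)

                aux_loss = d_aux(Tensor(meta_fake)).mean() - d_aux(Tensor(meta_b)).mean()
                aux_loss = aux_loss + config.gp_coefficient * d_aux.gradient_penalty(
                    interpolate_pairs(rng, meta_b, meta_fake)
                )
                opt_aux.zero_grad()
                aux_loss.backward()
                opt_aux.step()

                comb_loss = (
                    d_comb(Tensor(joint_fake)).mean() - d_comb(Tensor(joint_b)).mean()
                )
                comb_loss = comb_loss + config.gp_coefficient * d_comb.gradient_penalty(
                    interpolate_pairs(rng, joint_b, joint_fake)
                )
                opt_comb.zero_grad()
                comb_loss.backward()
                opt_comb.step()
                step += 1
                _check_finite(float(aux_loss.data), "auxiliary critic loss", step)
                _check_finite(float(comb_loss.data), "combined critic loss", step)
                aux_l.append(float(aux_loss.data))
                comb_l.append(float(comb_loss.data))

            m_f, s_f = forward(len(idx))
            joint_f = concat([m_f, s_f], axis=1)
            g_loss = -d_comb(joint_f).mean() - d_aux(m_f).mean()
            opt_g.zero_grad()
            for p in d_aux.params + d_comb.params:
                p.grad = None
            g_loss.backward()
            opt_g.step()
            step += 1
            _check_finite(float(g_loss.data), "generator loss", step)
            g_l.append(float(g_loss.data))
        rows.append(
            {
                "epoch": epoch,
                "aux_critic_loss": float(np.mean(aux_l)),
                "combined_critic_loss": float(np.mean(comb_l)),
                "generator_loss": float(np.mean(g_l)),
            }
        )

    trace = pd.DataFrame(rows)
    return TrainedGenerator(
        backend="dgan",
        mode="joint",
        layout=layout,
        loss_trace=trace,
        _sampler=sampler,
        config=config,
        provenance={"iterations": K, "T_pad": T_pad},
    )


# ---------------------------------------------------------------------------
# baseline


def train_baseline(
    dataset: LongitudinalDataset, jitter: float = 0.0, seed: int = 0, mode: str = "joint"
) -> TrainedGenerator:
    """Deterministic resampling baseline with optional Gaussian jitter.

    Sampling draws real rows without replacement while ``n <= n_real`` (a
    permutation, so at ``n == n_real`` and ``jitter == 0`` the output is the
    real multiset exactly) and with replacement for any excess. Jitter adds
    seeded Gaussian noise of scale ``jitter * per-column std`` to numeric
    columns, clipped back to the scaled range.
    """
    if jitter < 0:
        raise ConfigurationError("jitter must be >= 0")
    X, layout = build_design(dataset, mode)
    sampler = _BaselineSampler(X, layout.numeric_idx, jitter)
    trace = pd.DataFrame([{"epoch": 0, "loss": 0.0}])
    return TrainedGenerator(
        backend="baseline",
        mode=mode,
        layout=layout,
        loss_trace=trace,
        _sampler=sampler,
        config={"jitter": jitter, "seed": seed},
    )
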