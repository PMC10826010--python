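"""Generator backends: alignment penalty, baseline semantics, GAN smoke runs."""

import numpy as np
import pytest

from stsg.errors import ConfigurationError, STSGError
from stsg.fixtures import FixtureSpec, make_exercise_fixture
from stsg.generators import (
    DGANConfig,
    WGANGPConfig,
    build_design,
    correlation_alignment_penalty,
    decode_design,
    dgan_iterations,
    sample,
    train_baseline,
    train_dgan,
    train_wgan_gp,
)


class TestAlignmentPenalty:
    def test_identical_matrices_give_zero(self):
        m = np.array([[1.0, 0.4], [0.4, 1.0]])
        assert correlation_alignment_penalty(m, m, 10.0) == 0.0

    def test_zero_coefficient_gives_zero(self):
        a = np.array([[1.0, 0.4], [0.4, 1.0]])
        b = np.array([[1.0, -0.9], [-0.9, 1.0]])
        assert correlation_alignment_penalty(a, b, 0.0) == 0.0

    def test_two_variable_hand_case(self):
        r = np.array([[1.0, 0.5], [0.5, 1.0]])
        rhat = np.array([[1.0, 0.3], [0.3, 1.0]])
        assert correlation_alignment_penalty(r, rhat, 10.0) == pytest.approx(2.0)

    def test_symmetric_in_arguments(self):
        rng = np.random.default_rng(0)
        a, b = rng.uniform(-1, 1, (4, 4)), rng.uniform(-1, 1, (4, 4))
        assert correlation_alignment_penalty(a, b, 3.0) == pytest.approx(
            correlation_alignment_penalty(b, a, 3.0)
        )

    def test_homogeneous_in_lambda(self):
        rng = np.random.default_rng(1)
        a, b = rng.uniform(-1, 1, (3, 3)), rng.uniform(-1, 1, (3, 3))
        one = correlation_alignment_penalty(a, b, 1.0)
        assert correlation_alignment_penalty(a, b, 7.5) == pytest.approx(7.5 * one)

    def test_shape_mismatch_rejected(self):
        with pytest.raises(STSGError):
            correlation_alignment_penalty(np.eye(2), np.eye(3), 1.0)


class TestDesignMatrix:
    @pytest.mark.parametrize("mode", ["metadata_only", "series_only", "joint"])
    def test_round_trip_through_decode(self, exercise_ds, mode):
        X, layout = build_design(exercise_ds, mode)
        assert X.min() >= 0.0 and X.max() <= 1.0
        out = decode_design(X, layout)
        if mode in ("metadata_only", "joint"):
            static = out if mode == "metadata_only" else out.static
            assert np.allclose(
                static.frame["age"], exercise_ds.static.frame["age"], atol=1e-9
            )
            assert list(static.frame["sex"]) == list(exercise_ds.static.frame["sex"])
        if mode in ("series_only", "joint"):
            series = out if mode == "series_only" else out.series
            for a, b in zip(series.values, exercise_ds.series.values):
                assert np.allclose(a, b, atol=1e-6)


class TestBaseline:
    def test_jitter_zero_produces_verbatim_records(self, exercise_ds):
        gen = train_baseline(exercise_ds, jitter=0.0, mode="joint")
        synth = sample(gen, exercise_ds.n_subjects, seed=5)
        real = np.sort(exercise_ds.static.frame["age"].to_numpy())
        got = np.sort(synth.static.frame["age"].to_numpy())
        assert np.allclose(real, got, atol=1e-9)
        real_series = sorted(a.tobytes() for a in exercise_ds.series.values)
        # decoded series round-trip within float tolerance; compare rounded
        for arr in synth.series.values:
            assert any(
                np.allclose(arr, b, atol=1e-6) for b in exercise_ds.series.values
            )

    def test_jitter_preserves_means(self):
        ds = make_exercise_fixture(FixtureSpec(200, 16, 3))
        gen = train_baseline(ds, jitter=0.1, mode="metadata_only")
        synth = sample(gen, 1000, seed=7)
        for col in ("age", "height", "weight"):
            real = ds.static.frame[col].to_numpy()
            se = real.std() / np.sqrt(1000) + abs(real.mean()) * 1e-12
            # resampling + jitter noise: allow 3 combined standard errors
            tol = 3 * np.sqrt(real.var() / 1000 + (0.1 * real.std()) ** 2 / 1000)
            assert abs(synth.frame[col].mean() - real.mean()) < max(tol, 3 * se)

    def test_seeded_determinism(self, exercise_ds):
        gen = train_baseline(exercise_ds, jitter=0.3)
        a = sample(gen, 10, seed=3)
        b = sample(gen, 10, seed=3)
        assert a.static.frame.equals(b.static.frame)
        assert all(np.array_equal(x, y) for x, y in zip(a.series.values, b.series.values))

    def test_oversampling_allowed(self, exercise_ds):
        gen = train_baseline(exercise_ds, jitter=0.0)
        synth = sample(gen, exercise_ds.n_subjects * 2, seed=1)
        assert synth.n_subjects == exercise_ds.n_subjects * 2

    def test_nonpositive_n_rejected(self, exercise_ds):
        gen = train_baseline(exercise_ds)
        with pytest.raises(ConfigurationError):
            sample(gen, 0, seed=1)


SMOKE_DS = None


def _smoke_ds():
    global SMOKE_DS
    if SMOKE_DS is None:
        SMOKE_DS = make_exercise_fixture(FixtureSpec(20, 16, 5))
    return SMOKE_DS


class TestWGANGP:
    def test_one_epoch_smoke(self):
        ds = _smoke_ds()
        cfg = WGANGPConfig(epochs=1, batch_size=10, seed=1)
        gen = train_wgan_gp(ds, cfg, mode="joint")
        assert len(gen.loss_trace) == 1
        assert np.isfinite(gen.loss_trace.to_numpy()[:, 1:].astype(float)).all()
        synth = sample(gen, 7, seed=2)
        assert synth.n_subjects == 7
        assert synth.series.T == ds.series.T
        assert set(synth.static.frame["sex"]) <= {"F", "M"}

    def test_seeded_determinism(self):
        ds = _smoke_ds()
        cfg = WGANGPConfig(epochs=2, batch_size=10, seed=3)
        t1 = train_wgan_gp(ds, cfg).loss_trace
        t2 = train_wgan_gp(ds, cfg).loss_trace
        assert t1.equals(t2)

    def test_metadata_only_mode_returns_static_table(self):
        ds = _smoke_ds()
        gen = train_wgan_gp(ds, WGANGPConfig(epochs=1, batch_size=10, seed=1), "metadata_only")
        out = sample(gen, 5, seed=1)
        assert out.frame.shape[0] == 5
        assert "age" in out.frame.columns

    def test_scaled_outputs_in_unit_range(self):
        ds = _smoke_ds()
        gen = train_wgan_gp(ds, WGANGPConfig(epochs=1, batch_size=10, seed=1))
        rng = np.random.default_rng(0)
        X = gen.sample_matrix(20, rng)
        assert X.min() >= 0.0 and X.max() <= 1.0


class TestDGAN:
    @pytest.mark.parametrize("T,S,expected", [(48, 6, 8), (228, 12, 19), (50, 6, 9)])
    def test_iteration_count(self, T, S, expected):
        assert dgan_iterations(T, S) == expected

    def test_padding_disabled_rejects_incompatible(self):
        with pytest.raises(ConfigurationError):
            dgan_iterations(50, 6, pad_series=False)

    def test_one_epoch_smoke_two_discriminators(self):
        ds = _smoke_ds()
        cfg = DGANConfig(S=4, epochs=1, batch_size=10, seed=1)
        gen = train_dgan(ds, cfg)
        row = gen.loss_trace.iloc[0]
        assert np.isfinite(row["aux_critic_loss"])
        assert np.isfinite(row["combined_critic_loss"])
        assert np.isfinite(row["generator_loss"])
        synth = sample(gen, 6, seed=2)
        assert synth.series.T == ds.series.T
        assert synth.n_subjects == 6

    def test_seeded_determinism(self):
        ds = _smoke_ds()
        cfg = DGANConfig(S=4, epochs=2, batch_size=10, seed=9)
        assert train_dgan(ds, cfg).loss_trace.equals(train_dgan(ds, cfg).loss_trace)

    def test_incompatible_length_padded_and_trimmed(self):
        ds = _smoke_ds()  # T = 16, S = 5 -> K = 4, T_pad = 20
        gen = train_dgan(ds, DGANConfig(S=5, epochs=1, batch_size=10, seed=1))
        assert gen.provenance["iterations"] == 4
        synth = sample(gen, 3, seed=1)
        assert synth.series.T == 16
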