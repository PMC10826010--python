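"""Resemblance metrics: associations, DLA, PRD, autocorrelation."""

import numpy as np
import pandas as pd
import pytest

from stsg.core_data.types import SeriesBlock
from stsg.errors import InsufficientDataError, STSGError
from stsg.eval_resemblance import (
    AssociationMatrix,
    PRDCurve,
    autocorrelation_mae,
    correlation_similarity,
    cramers_v,
    dla,
    f_gamma,
    flatten_records,
    mixed_association_matrix,
    prd_curve,
    prd_from_histograms,
)
from stsg.fixtures import FixtureSpec, make_exercise_fixture, make_icu_fixture

from conftest import build_dataset


class TestCramersV:
    @pytest.mark.parametrize(
        "table,expected",
        [
            ([[10, 0], [0, 10]], 1.0),  # perfect association
            ([[5, 5], [5, 5]], 0.0),  # exact independence
            ([[8, 2], [3, 7]], 0.5025),  # chi2 = 5.0505, n = 20
        ],
    )
    def test_hand_cases(self, table, expected):
        assert cramers_v(np.array(table)) == pytest.approx(expected, abs=1e-4)

    def test_permutation_invariance(self):
        t = np.array([[8, 2, 1], [3, 7, 4]])
        v = cramers_v(t)
        assert cramers_v(t[:, [2, 0, 1]]) == pytest.approx(v)
        assert cramers_v(t[[1, 0], :]) == pytest.approx(v)

    def test_zero_marginal_dropped(self):
        assert cramers_v(np.array([[10, 0, 0], [0, 10, 0]])) == pytest.approx(1.0)

    def test_invalid_table_rejected(self):
        with pytest.raises(STSGError):
            cramers_v(np.array([[0, 0], [0, 0]]))


class TestAssociationMatrix:
    def test_perfect_linear_pair_is_one(self):
        ds = build_dataset(
            {f"s{i}": [float(i)] * 4 for i in range(10)},
            static_rows={f"s{i}": {"a": float(i), "b": 2.0 * i + 1} for i in range(10)},
        )
        m = mixed_association_matrix(ds, include=("static",))
        ia, ib = m.variables.index("a"), m.variables.index("b")
        assert m.matrix[ia, ib] == pytest.approx(1.0)

    def test_independent_mixed_pair_near_zero(self):
        rng = np.random.default_rng(0)
        n = 2000
        ds = build_dataset(
            {f"s{i}": [0.0, 1.0] for i in range(n)},
            static_rows={
                f"s{i}": {"num": float(rng.normal()), "cat": rng.choice(["a", "b"])}
                for i in range(n)
            },
            categories={"cat": ("a", "b")},
        )
        m = mixed_association_matrix(ds, include=("static",))
        i, j = m.variables.index("num"), m.variables.index("cat")
        assert abs(m.matrix[i, j]) < 0.05

    def test_row_shuffle_invariance(self, exercise_ds):
        m1 = mixed_association_matrix(exercise_ds)
        shuffled = exercise_ds.subset(list(reversed(exercise_ds.subject_ids)))
        m2 = mixed_association_matrix(shuffled)
        assert np.allclose(
            np.nan_to_num(m1.matrix), np.nan_to_num(m2.matrix), atol=1e-9
        )

    def test_symmetry_and_masking(self, icu_ds):
        m = mixed_association_matrix(icu_ds)
        assert np.allclose(
            np.nan_to_num(m.matrix), np.nan_to_num(m.matrix.T), atol=1e-12
        )

    def test_zero_variance_feature_masked_not_zeroed(self):
        ds = build_dataset(
            {f"s{i}": [1.0, 2.0] for i in range(5)},
            static_rows={f"s{i}": {"const": 7.0, "var": float(i)} for i in range(5)},
        )
        m = mixed_association_matrix(ds, include=("static",))
        i, j = m.variables.index("const"), m.variables.index("var")
        assert np.isnan(m.matrix[i, j]) and not m.defined[i, j]

    def test_single_subject_rejected(self):
        ds = build_dataset({"only": [1.0, 2.0]})
        with pytest.raises(InsufficientDataError):
            mixed_association_matrix(ds)


class TestCorrelationSimilarity:
    def _mat(self, lower):
        """2x2 (one off-diagonal cell) or 3x3 matrices from lower-tri values."""
        k = 2 if len(lower) == 1 else 3
        m = np.eye(k)
        idx = list(zip(*np.tril_indices(k, -1)))
        for (i, j), v in zip(idx, lower):
            m[i, j] = m[j, i] = v
        return AssociationMatrix([f"v{i}" for i in range(k)], m, np.isfinite(m))

    def test_identity_is_one(self):
        a = self._mat([0.5, 0.2, -0.3])
        assert correlation_similarity(a, a) == pytest.approx(1.0, abs=1e-12)

    def test_orthogonal_vectors_zero(self):
        a = self._mat([1.0, 0.0, 0.0])
        b = self._mat([0.0, 1.0, 0.0])
        assert correlation_similarity(a, b) == pytest.approx(0.0, abs=1e-12)

    def test_hand_case_inv_sqrt2(self):
        a = self._mat([1.0, 1.0, 0.0])
        b = self._mat([1.0, 0.0, 0.0])
        assert correlation_similarity(a, b) == pytest.approx(0.7071, abs=1e-4)

    def test_scale_invariance(self):
        a = self._mat([0.5, 0.2, -0.3])
        b = self._mat([0.25, 0.1, -0.15])
        assert correlation_similarity(a, b) == pytest.approx(1.0, abs=1e-12)

    def test_undefined_cells_excluded_pairwise(self):
        a = self._mat([0.5, np.nan, -0.3])
        b = self._mat([0.5, 0.9, -0.3])
        assert correlation_similarity(a, b) == pytest.approx(1.0, abs=1e-12)

    def test_all_masked_rejected(self):
        a = self._mat([np.nan])
        with pytest.raises(STSGError):
            correlation_similarity(a, a)

    def test_printed_variant_formula(self):
        a = self._mat([1.0, 1.0, 0.0])
        b = self._mat([1.0, 0.0, 0.0])
        # dot / (sum * sum) = 1 / (2 * 1)
        assert correlation_similarity(a, b, printed_variant=True) == pytest.approx(0.5)


class TestDLA:
    def test_same_distribution_near_chance(self):
        ds = make_exercise_fixture(FixtureSpec(2000, 16, 11))
        half1 = ds.subset(ds.subject_ids[:1000])
        half2 = ds.subset(ds.subject_ids[1000:])
        res = dla(half1, half2, seed=0)
        assert 0.4 <= res["mean"] <= 0.6

    def test_shifted_distribution_separable(self):
        ds = make_exercise_fixture(FixtureSpec(300, 16, 12))
        r = flatten_records(ds.subset(ds.subject_ids[:150]))
        s = flatten_records(ds.subset(ds.subject_ids[150:]))
        s = s + 10 * pd.concat([r, s]).std()
        assert dla(r, s, seed=0)["mean"] > 0.95

    def test_reports_five_configured_classifiers(self, exercise_ds):
        gen = exercise_ds.subset(exercise_ds.subject_ids[:15])
        other = exercise_ds.subset(exercise_ds.subject_ids[15:])
        res = dla(gen, other, seed=1)
        assert set(res) == {"RF", "KNN", "DT", "SVM", "MLP", "mean"}

    def test_column_mismatch_rejected(self, exercise_ds, icu_ds):
        with pytest.raises(STSGError):
            dla(exercise_ds, icu_ds)


def _prd_oracle(p, q, lams):
    """Independent lambda sweep of the two-histogram formulas."""
    p = np.asarray(p) / np.sum(p)
    q = np.asarray(q) / np.sum(q)
    pts = []
    for lam in lams:
        alpha = sum(min(lam * pc, qc) for pc, qc in zip(p, q))
        beta = sum(min(pc, qc / lam) for pc, qc in zip(p, q))
        pts.append((alpha, beta))
    return np.array(pts)


class TestPRD:
    @pytest.mark.parametrize(
        "p,q",
        [
            ((0.5, 0.5), (1.0, 0.0)),
            ((0.3, 0.3, 0.4), (0.1, 0.6, 0.3)),
        ],
    )
    def test_histogram_mode_matches_lambda_sweep(self, p, q):
        curve = prd_from_histograms(p, q, n_angles=101)
        eps = 1e-10
        lams = np.tan(np.linspace(eps, np.pi / 2 - eps, 101))
        oracle = np.clip(_prd_oracle(p, q, lams), 0, 1)
        assert np.allclose(curve.points, oracle, atol=1e-12)

    def test_identical_distributions_reach_one_one(self):
        curve = prd_from_histograms((0.25, 0.25, 0.5), (0.25, 0.25, 0.5))
        best = curve.points.min(axis=1).max()
        assert best == pytest.approx(1.0, abs=1e-6)

    def test_disjoint_supports_all_zero(self):
        curve = prd_from_histograms((1.0, 0.0), (0.0, 1.0))
        assert np.allclose(curve.points, 0.0, atol=1e-9)

    def test_points_in_unit_square(self):
        rng = np.random.default_rng(4)
        p, q = rng.random(10), rng.random(10)
        curve = prd_from_histograms(p, q)
        assert (curve.points >= 0).all() and (curve.points <= 1).all()

    def test_role_swap_mirrors_curve(self):
        """Swapping the real/synthetic roles mirrors the curve: every (a, b)
        of PRD(p, q) appears as (b, a) on PRD(q, p)."""
        p, q = (0.7, 0.3), (0.4, 0.6)
        fwd = prd_from_histograms(p, q, n_angles=2001).points
        rev = prd_from_histograms(q, p, n_angles=2001).points
        for a, b in fwd[::200]:
            d = np.abs(rev - [b, a]).sum(axis=1).min()
            assert d < 5e-3

    def test_clustered_mode_on_identical_samples(self, exercise_ds):
        r = flatten_records(exercise_ds)
        curve = prd_curve(r, r.copy(), n_clusters=5, seed=0)
        assert f_gamma(curve) == pytest.approx(1.0, abs=1e-9)


class TestFGamma:
    @pytest.mark.parametrize(
        "alpha,beta,gamma,expected",
        [
            (0.5, 0.5, 8.0, 0.5),  # alpha == beta implies F == alpha
            (1.0, 0.0, 8.0, 0.0),  # zero recall
            (0.9, 0.6, 8.0, 0.6031),  # 65 * 0.54 / 58.2
            (0.0, 0.0, 8.0, 0.0),
        ],
    )
    def test_hand_cases(self, alpha, beta, gamma, expected):
        curve = PRDCurve(np.array([[alpha, beta]]), {})
        assert f_gamma(curve, gamma) == pytest.approx(expected, abs=1e-4)

    def test_monotone_in_alpha_and_beta(self):
        base = f_gamma(PRDCurve(np.array([[0.5, 0.5]]), {}))
        assert f_gamma(PRDCurve(np.array([[0.6, 0.5]]), {})) >= base
        assert f_gamma(PRDCurve(np.array([[0.5, 0.6]]), {})) >= base

    def test_alpha_equals_beta_for_any_gamma(self):
        for g in (0.5, 1.0, 8.0, 20.0):
            curve = PRDCurve(np.array([[0.37, 0.37]]), {})
            assert f_gamma(curve, g) == pytest.approx(0.37)

    def test_invalid_gamma(self):
        with pytest.raises(STSGError):
            f_gamma(PRDCurve(np.array([[0.5, 0.5]]), {}), gamma=0.0)


class TestAutocorrelation:
    def test_identity_gives_zero(self, exercise_ds):
        res = autocorrelation_mae(exercise_ds, exercise_ds)
        assert res["mean"] == pytest.approx(0.0, abs=1e-12)

    def test_white_noise_both_sides_small(self):
        rng = np.random.default_rng(8)
        mk = lambda seed: SeriesBlock(
            [f"s{i}" for i in range(500)],
            ["w"],
            [np.random.default_rng(seed * 10_000 + i).normal(size=(128, 1)) for i in range(500)],
        )
        res = autocorrelation_mae(mk(1), mk(2), max_lag=20)
        assert res["mean"] < 0.05

    def test_ar1_versus_white_noise_lag_one(self):
        rng = np.random.default_rng(9)
        n, T, phi = 500, 256, 0.9
        ar_vals = []
        for i in range(n):
            e = rng.normal(size=T)
            x = np.empty(T)
            x[0] = e[0]
            for t in range(1, T):
                x[t] = phi * x[t - 1] + e[t]
            ar_vals.append(x[:, None])
        ar = SeriesBlock([f"a{i}" for i in range(n)], ["v"], ar_vals)
        wn = SeriesBlock(
            [f"w{i}" for i in range(n)], ["v"], [rng.normal(size=(T, 1)) for _ in range(n)]
        )
        res = autocorrelation_mae(ar, wn, max_lag=1)
        assert res["mean"] == pytest.approx(phi, abs=0.1)

    def test_constant_variable_masked_with_warning(self):
        const = SeriesBlock(["a", "b"], ["c"], [np.ones((16, 1)), np.ones((16, 1))])
        with pytest.warns(UserWarning, match="constant"):
            res = autocorrelation_mae(const, const, max_lag=4)
        assert np.isnan(res["c"])
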