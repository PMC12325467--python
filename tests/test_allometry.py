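import itertools

import numpy as np
import pytest

from shellont.allometry import (
    cac_scores,
    fit_allometry,
    fit_allometry_with_sex,
    predict_shape_at,
    predline_scores,
)
from shellont.exceptions import DegenerateDataError, SampleSizeError


def linear_shapes(rng, n=12, p=15, noise=0.0):
    """Shapes moving linearly along a fixed direction with size."""
    size = np.sort(rng.uniform(1.0, 2.0, size=n))
    direction = rng.normal(size=p)
    direction /= np.linalg.norm(direction)
    shapes = np.outer(size, direction) + rng.normal(scale=noise, size=(n, p))
    return shapes, size, direction


def brute_force_f(shapes, size):
    """Independent F statistic: explicit least squares fit and SS split."""
    n = shapes.shape[0]
    x = np.column_stack([np.ones(n), size])
    beta, *_ = np.linalg.lstsq(x, shapes, rcond=None)
    fitted = x @ beta
    ss_model = np.sum((fitted - shapes.mean(axis=0)) ** 2)
    ss_res = np.sum((shapes - fitted) ** 2)
    return (ss_model / 1.0) / (ss_res / (n - 2))


class TestFitAllometry:
    def test_perfectly_linear_data(self, rng):
        shapes, size, _ = linear_shapes(rng)
        fit = fit_allometry(shapes, size, n_perm=99, seed=0)
        assert fit.r2 == pytest.approx(1.0, abs=1e-10)
        assert fit.p_value == pytest.approx(1.0 / 100.0)

    def test_r2_matches_independent_residual_computation(self, rng):
        shapes, size, _ = linear_shapes(rng, noise=0.3)
        fit = fit_allometry(shapes, size, n_perm=49, seed=0)
        n = shapes.shape[0]
        x = np.column_stack([np.ones(n), size])
        beta, *_ = np.linalg.lstsq(x, shapes, rcond=None)
        ss_res = np.sum((shapes - x @ beta) ** 2)
        ss_tot = np.sum((shapes - shapes.mean(axis=0)) ** 2)
        assert fit.r2 == pytest.approx(1.0 - ss_res / ss_tot, abs=1e-8)
        assert fit.f_stat == pytest.approx(brute_force_f(shapes, size), rel=1e-8)

    def test_exhaustive_permutation_p_is_exact_at_n5(self, rng):
        shapes = rng.normal(size=(5, 9))
        size = rng.uniform(1.0, 2.0, size=5)
        fit = fit_allometry(shapes, size, n_perm=None)
        f_obs = brute_force_f(shapes, size)
        count = sum(
            brute_force_f(shapes[list(perm)], size) >= f_obs - 1e-12
            for perm in itertools.permutations(range(5))
        )
        assert fit.p_value == pytest.approx(count / 120.0)

    def test_null_type_one_error_rate(self):
        """Shapes independent of size: empirical rejection rate at alpha=0.05
        stays near nominal over 500 fixed-seed null replicates."""
        rng = np.random.default_rng(1234)
        rejections = 0
        for _ in range(500):
            shapes = rng.normal(size=(10, 6))
            size = rng.uniform(1.0, 2.0, size=10)
            fit = fit_allometry(shapes, size, n_perm=199, seed=int(rng.integers(2**31)))
            rejections += fit.p_value <= 0.05
        assert 0.03 <= rejections / 500 <= 0.07

    def test_guards(self, rng):
        with pytest.raises(SampleSizeError):
            fit_allometry(rng.normal(size=(3, 6)), np.arange(3.0), n_perm=9)
        with pytest.raises(DegenerateDataError):
            fit_allometry(rng.normal(size=(6, 6)), np.ones(6), n_perm=9)


class TestCac:
    def test_recovers_planted_direction(self, rng):
        shapes, size, direction = linear_shapes(rng, n=30, noise=0.005)
        axis, scores = cac_scores(shapes, size)
        assert abs(axis @ direction) >= 0.99
        assert np.linalg.norm(axis) == pytest.approx(1.0, abs=1e-10)

    def test_scores_centred_and_oriented_with_size(self, rng):
        shapes, size, _ = linear_shapes(rng, noise=0.2)
        _, scores = cac_scores(shapes, size)
        assert scores.mean() == pytest.approx(0.0, abs=1e-10)
        assert np.corrcoef(scores, size)[0, 1] >= 0.0

    def test_orientation_holds_for_negated_direction(self, rng):
        shapes, size, _ = linear_shapes(rng, noise=0.1)
        _, scores = cac_scores(-shapes, size)
        assert np.corrcoef(scores, size)[0, 1] >= 0.0

    def test_invariant_under_joint_rotation(self, rng):
        shapes, size, _ = linear_shapes(rng, n=10, p=12, noise=0.1)
        q, _ = np.linalg.qr(rng.normal(size=(12, 12)))
        _, scores = cac_scores(shapes, size)
        _, scores_rot = cac_scores(shapes @ q, size)
        np.testing.assert_allclose(scores_rot, scores, atol=1e-8)


class TestPredline:
    def test_rank_correlated_with_size(self, rng):
        shapes, size, _ = linear_shapes(rng, noise=0.1)
        fit = fit_allometry(shapes, size, n_perm=9, seed=0)
        order = np.argsort(size)
        assert np.all(np.diff(fit.predline_scores[order]) > 0)

    def test_zero_slope_model_gives_zero_scores(self, rng):
        from shellont.allometry import predline_scores_from_fitted

        size = rng.uniform(1.0, 2.0, size=10)
        out = predline_scores_from_fitted(np.zeros((10, 6)), size)
        assert np.all(np.abs(out) < 1e-10)

    def test_matches_pc1_of_fitted_values_oracle(self, rng):
        shapes, size, _ = linear_shapes(rng, n=14, noise=0.4)
        fit = fit_allometry(shapes, size, n_perm=9, seed=0)
        pl = predline_scores(fit, shapes)
        n = shapes.shape[0]
        x = np.column_stack([np.ones(n), size])
        beta, *_ = np.linalg.lstsq(x, shapes, rcond=None)
        fitted = x @ beta
        fitted_c = fitted - fitted.mean(axis=0)
        eigvals, eigvecs = np.linalg.eigh(fitted_c.T @ fitted_c)
        pc1 = fitted_c @ eigvecs[:, -1]
        if np.corrcoef(pc1, size)[0, 1] < 0:
            pc1 = -pc1
        np.testing.assert_allclose(pl, pc1, atol=1e-8)


class TestPredictShapeAt:
    def test_mean_score_gives_mean_shape(self, rng):
        shapes, size, _ = linear_shapes(rng, noise=0.3)
        _, scores = cac_scores(shapes, size)
        pred = predict_shape_at(scores, shapes, [scores.mean()])
        np.testing.assert_allclose(pred[0], shapes.mean(axis=0), atol=1e-8)

    def test_noiseless_linear_data_predicts_exactly(self, rng):
        shapes, size, _ = linear_shapes(rng, noise=0.0)
        _, scores = cac_scores(shapes, size)
        target_rows = [2, 7]
        pred = predict_shape_at(scores, shapes, scores[target_rows])
        np.testing.assert_allclose(pred, shapes[target_rows], atol=1e-8)

    def test_percentile_endpoints_match_least_squares_oracle(self, rng):
        shapes, size, _ = linear_shapes(rng, n=40, noise=0.05)
        _, scores = cac_scores(shapes, size)
        lo, hi = np.percentile(scores, [5, 95])
        pred = predict_shape_at(scores, shapes, [lo, hi])
        x = np.column_stack([np.ones_like(scores), scores])
        beta, *_ = np.linalg.lstsq(x, shapes, rcond=None)
        expected = np.array([[1.0, lo], [1.0, hi]]) @ beta
        np.testing.assert_allclose(pred, expected, atol=1e-8)

    def test_shaped_input_returns_configurations(self, rng):
        shapes = rng.normal(size=(8, 5, 3))
        scores = rng.normal(size=8)
        pred = predict_shape_at(scores, shapes, [0.0, 0.1])
        assert pred.shape == (2, 5, 3)


class TestSexModel:
    @staticmethod
    def _size_driven(rng, n=20, p=12, sex_offset=0.0, size_effect=1.0):
        size = np.sort(rng.uniform(1.0, 2.0, size=n))
        sex = np.array(["female", "male"] * (n // 2))
        direction = rng.normal(size=p)
        direction /= np.linalg.norm(direction)
        sex_dir = rng.normal(size=p)
        sex_dir /= np.linalg.norm(sex_dir)
        shapes = (
            size_effect * np.outer(size, direction)
            + sex_offset * np.outer(sex == "male", sex_dir)
            + rng.normal(scale=0.05, size=(n, p))
        )
        return shapes, size, sex

    def test_random_sex_labels_rarely_significant(self):
        rng = np.random.default_rng(99)
        non_sig = 0
        for _ in range(100):
            shapes, size, sex = self._size_driven(rng)
            rng.shuffle(sex)
            fit = fit_allometry_with_sex(
                shapes, size, sex, n_perm=99, seed=int(rng.integers(2**31))
            )
            non_sig += fit.p_sex > 0.05
        assert non_sig >= 90

    def test_strong_sex_offset_dominates(self, rng):
        shapes, size, sex = self._size_driven(rng, sex_offset=2.0, size_effect=0.0)
        fit = fit_allometry_with_sex(shapes, size, sex, n_perm=199, seed=3)
        assert fit.z_sex > fit.z_size
        assert fit.delta_z < 0

    def test_label_swap_leaves_p_sex_stable(self, rng):
        shapes, size, sex = self._size_driven(rng, sex_offset=0.4)
        swapped = np.where(sex == "male", "female", "male")
        a = fit_allometry_with_sex(shapes, size, sex, n_perm=499, seed=11)
        b = fit_allometry_with_sex(shapes, size, swapped, n_perm=499, seed=11)
        assert abs(a.p_sex - b.p_sex) <= 0.05

    def test_single_sex_rejected(self, rng):
        shapes, size, sex = self._size_driven(rng)
        with pytest.raises(DegenerateDataError):
            fit_allometry_with_sex(
                shapes, size, ["female"] * len(size), n_perm=9, seed=0
            )

    def test_unknown_sex_excluded_with_warning(self, rng):
        shapes, size, sex = self._size_driven(rng)
        sex = sex.astype(object)
        sex[0] = "unknown"
        with pytest.warns(UserWarning, match="unknown-sex"):
            fit = fit_allometry_with_sex(shapes, size, sex, n_perm=9, seed=0)
        assert fit.n == len(size) - 1
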