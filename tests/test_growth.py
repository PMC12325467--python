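import math

import numpy as np
import pytest

from shellont.exceptions import DegenerateDataError, SampleSizeError
from shellont.growth import (
    GompertzFit,
    ThresholdResult,
    asymptote_threshold,
    distance85_threshold,
    fit_gompertz,
    gompertz,
    pct_of_max,
    summarize_thresholds,
)
from shellont.io import MaxSizeTable


class TestFitGompertz:
    def test_zero_noise_parameter_recovery(self):
        x = np.linspace(5.0, 120.0, 20)
        y = gompertz(x, 0.0, 1.0, 0.1, 50.0)
        fit = fit_gompertz(x, y, seed=0)
        assert fit.converged
        np.testing.assert_allclose(
            fit.params, (0.0, 1.0, 0.1, 50.0), atol=1e-6
        )
        assert fit.rss < 1e-12

    def test_value_at_inflection_is_closed_form(self):
        c, d, k, x0 = -0.3, 0.9, 0.07, 80.0
        assert gompertz(x0, c, d, k, x0) == pytest.approx(
            c + (d - c) * math.exp(-1.0)
        )

    def test_asymptote_estimation_under_noise(self):
        """Moderate noise: the asymptote estimate stays within 2% of truth
        (median over seeded replicates)."""
        rng = np.random.default_rng(5)
        c, d, k, x0 = 0.0, 1.0, 0.08, 60.0
        errors = []
        for _ in range(200):
            x = rng.uniform(5.0, 200.0, size=200)
            y = gompertz(x, c, d, k, x0) + rng.normal(0, 0.05 * (d - c), size=200)
            fit = fit_gompertz(x, y, seed=int(rng.integers(2**31)), n_starts=4)
            errors.append(abs(fit.upper_d - d))
        assert np.median(errors) < 0.02 * (d - c)

    def test_flat_scores_rejected(self):
        with pytest.raises(DegenerateDataError):
            fit_gompertz(np.linspace(1, 10, 8), np.ones(8), seed=0)

    def test_small_sample_rejected(self):
        with pytest.raises(SampleSizeError):
            fit_gompertz([1, 2, 3, 4], [0, 1, 2, 3], seed=0)

    def test_rss_never_worse_than_null_model_when_converged(self, rng):
        x = rng.uniform(10, 200, size=40)
        y = gompertz(x, 0.0, 1.0, 0.05, 90.0) + rng.normal(0, 0.1, size=40)
        fit = fit_gompertz(x, y, seed=1)
        null_rss = np.sum((y - y.mean()) ** 2)
        assert fit.rss <= null_rss + 1e-9


class TestAsymptoteThreshold:
    @staticmethod
    def _fit(c=0.0, d=1.0, k=0.1, x0=50.0, se_d=0.03):
        cov = np.zeros((4, 4))
        cov[1, 1] = se_d**2
        return GompertzFit(
            lower_c=c,
            upper_d=d,
            rate_k=k,
            inflection_x0=x0,
            covariance=cov,
            converged=True,
            rss=0.0,
        )

    def test_closed_form_inversion(self):
        # L = 0.95 exactly: choose SE so that d - z*SE = 0.95 at 90% CI
        from scipy.stats import norm

        z = norm.ppf(0.95)
        fit = self._fit(se_d=0.05 / z)
        x = asymptote_threshold(fit, ci_level=0.90)
        assert x == pytest.approx(50.0 - 10.0 * math.log(-math.log(0.95)), abs=1e-9)
        assert x == pytest.approx(79.7, abs=0.01)

    def test_zero_se_means_no_threshold(self):
        assert asymptote_threshold(self._fit(se_d=0.0)) is None

    def test_huge_se_means_no_threshold(self):
        assert asymptote_threshold(self._fit(se_d=5.0)) is None

    def test_matches_dense_grid_search(self):
        fit = self._fit(se_d=0.02)
        x = asymptote_threshold(fit, ci_level=0.90)
        from scipy.stats import norm

        lower = fit.upper_d - norm.ppf(0.95) * fit.se_asymptote()
        grid = np.arange(0.0, 300.0, 0.01)
        hit = grid[np.nonzero(fit.predict(grid) >= lower)[0][0]]
        assert x == pytest.approx(hit, abs=0.01)

    def test_decreases_with_lower_ci_level(self):
        fit = self._fit(se_d=0.02)
        x90 = asymptote_threshold(fit, ci_level=0.90)
        x50 = asymptote_threshold(fit, ci_level=0.50)
        assert x50 > x90  # narrower CI -> bound closer to d -> later crossing


def trajectory_data(g_params, n=40, x_range=(20.0, 250.0), p=18, seed=0, noise=0.0):
    """Shapes moving along a fixed direction by a Gompertz function of SCL."""
    rng = np.random.default_rng(seed)
    x = np.sort(rng.uniform(*x_range, size=n))
    direction = rng.normal(size=p)
    direction /= np.linalg.norm(direction)
    scores = gompertz(x, *g_params)
    shapes = np.outer(scores, direction)
    if noise:
        shapes = shapes + rng.normal(scale=noise, size=shapes.shape)
    return x, scores, shapes


class TestDistance85Threshold:
    def test_linear_trajectory_gives_min_plus_085_range(self, rng):
        n = 30
        x = np.sort(rng.uniform(30.0, 200.0, size=n))
        direction = rng.normal(size=12)
        shapes = np.outer(x, direction / np.linalg.norm(direction))
        thr = distance85_threshold(
            x, x.copy(), shapes, max_scl_mm=250.0, trajectory="linear"
        )
        expected = x.min() + 0.85 * (250.0 - x.min())
        grid_step = (250.0 - x.min()) / 999
        assert abs(thr - expected) <= grid_step

    def test_ratio_one_returns_max(self, rng):
        x = np.sort(rng.uniform(30.0, 200.0, size=20))
        direction = rng.normal(size=9)
        shapes = np.outer(x, direction)
        thr = distance85_threshold(
            x, x.copy(), shapes, max_scl_mm=240.0, ratio=1.0, trajectory="linear"
        )
        assert thr == pytest.approx(240.0)

    def test_gompertz_trajectory_matches_analytic_solution(self):
        from shellont.simulate import analytic_distance85

        g = (0.0, 1.0, 0.04, 120.0)
        x, scores, shapes = trajectory_data(g, seed=3)
        max_scl = 300.0
        thr = distance85_threshold(x, scores, shapes, max_scl_mm=max_scl, seed=0)
        expected = analytic_distance85(g, x.min(), max_scl)
        grid_step = (max_scl - x.min()) / 999
        assert abs(thr - expected) <= grid_step

    def test_monotone_in_ratio(self):
        g = (0.0, 1.0, 0.04, 120.0)
        x, scores, shapes = trajectory_data(g, seed=4, noise=0.01)
        thresholds = [
            distance85_threshold(
                x, scores, shapes, max_scl_mm=300.0, ratio=r, seed=0
            )
            for r in (0.5, 0.7, 0.85, 0.95)
        ]
        assert all(a <= b + 1e-9 for a, b in zip(thresholds, thresholds[1:]))

    def test_flat_trajectory_rejected(self, rng):
        x = np.sort(rng.uniform(30.0, 200.0, size=10))
        shapes = np.tile(rng.normal(size=8), (10, 1))
        with pytest.raises((DegenerateDataError, ValueError)):
            distance85_threshold(
                x, rng.normal(size=10), shapes, max_scl_mm=250.0, trajectory="linear"
            )

    def test_both_threshold_methods_agree_on_clean_sigmoid(self):
        """On noiseless sigmoid data with a bootstrap-estimated asymptote SE,
        the asymptote-CI and 85%-distance thresholds land within 5% SCL."""
        g = (0.0, 1.0, 0.06, 100.0)
        rng = np.random.default_rng(8)
        x = np.sort(rng.uniform(10.0, 280.0, size=25))
        y = gompertz(x, *g) + rng.normal(0, 0.12, size=25)
        fit = fit_gompertz(x, y, seed=2)
        # residual bootstrap for SE(d)
        resid = y - fit.predict(x)
        d_hats = []
        for _ in range(100):
            y_b = fit.predict(x) + rng.choice(resid, size=resid.size, replace=True)
            d_hats.append(fit_gompertz(x, y_b, seed=3, n_starts=3).upper_d)
        cov = fit.covariance.copy()
        cov[1, 1] = np.var(d_hats, ddof=1)
        boot_fit = GompertzFit(*fit.params, cov, True, fit.rss)
        asym = asymptote_threshold(boot_fit, ci_level=0.90)
        direction = rng.normal(size=12)
        shapes = np.outer(gompertz(x, *g), direction / np.linalg.norm(direction))
        d85 = distance85_threshold(x, y, shapes, max_scl_mm=300.0, seed=1)
        assert asym is not None
        assert abs(asym - d85) <= 0.05 * 300.0


class TestPctOfMax:
    def test_basic_percentages(self):
        table = MaxSizeTable.from_records([("A", 200.0, 180.0)])
        pf, pm, sex_used = pct_of_max(130.0, "A", table)
        assert pf == pytest.approx(65.0)
        assert pm == pytest.approx(130.0 / 180.0 * 100)
        assert sex_used == "both"

    def test_threshold_at_max_is_100(self):
        table = MaxSizeTable.from_records([("A", 200.0, 200.0)])
        pf, pm, _ = pct_of_max(200.0, "A", table)
        assert pf == pm == pytest.approx(100.0)

    def test_dimorphic_species_uses_larger_sex(self):
        table = MaxSizeTable.from_records([("A", 250.0, 180.0)])
        _, _, sex_used = pct_of_max(
            130.0, "A", table, dimorphic=True, larger_sex="female"
        )
        assert sex_used == "female"
        with pytest.raises(ValueError):
            pct_of_max(130.0, "A", table, dimorphic=True)


class TestSummarizeThresholds:
    @staticmethod
    def _result(species, pct, proxy="cac"):
        return ThresholdResult(
            species=species,
            proxy=proxy,
            asymptote_threshold_mm=None,
            distance85_threshold_mm=pct * 2.0,  # max 200 mm
            pct_of_max_female=pct,
            pct_of_max_male=pct,
            sex_used="both",
        )

    def test_median_min_max(self):
        results = [self._result(s, p) for s, p in zip("abc", (57.0, 67.0, 75.0))]
        summary = summarize_thresholds(results)
        stats = summary["cac"]["distance85_pct"]
        assert stats["median"] == pytest.approx(67.0)
        assert stats["min"] == pytest.approx(57.0)
        assert stats["max"] == pytest.approx(75.0)

    def test_single_species_collapses(self):
        summary = summarize_thresholds([self._result("a", 66.0)])
        stats = summary["cac"]["distance85_pct"]
        assert stats["median"] == stats["min"] == stats["max"] == pytest.approx(66.0)

    def test_empty_input_rejected(self):
        with pytest.raises(ValueError):
            summarize_thresholds([])
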