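"""Gompertz shape-growth curves and adult-size thresholds.

A species' shape-proxy scores (CAC or multivariate shape) plotted against
straight carapace length (SCL) behave like a growth curve: rapid change
followed by a stationary phase.  A four-parameter Gompertz function

    f(x) = c + (d - c) * exp(-exp(-k * (x - x0)))

is fitted by nonlinear least squares (lower plateau c, upper asymptote d,
rate k, inflection x0).  Two thresholds estimate the minimum SCL at which a
shell can be called adult-shaped:

* **asymptote threshold** — the SCL at which the curve first reaches the
  lower bound of a Wald confidence interval around the asymptote d
  (none when the data show no plateau);
* **85%-distance threshold** — the SCL at which the predicted shape has
  covered 85% of the Procrustes distance between the smallest specimen's
  predicted shape and the predicted shape at the species' largest recorded
  size.

Thresholds are reported as percentages of the maximum recorded SCL for each
sex; for species with strong sexual size dimorphism the larger sampled sex's
record is the headline value.
"""

from __future__ import annotations

import math
import warnings
from dataclasses import dataclass

import numpy as np
from scipy import optimize, stats

from .exceptions import ConvergenceError, DegenerateDataError, SampleSizeError
from .allometry import predict_shape_at
from .io import MaxSizeTable

__all__ = [
    "GompertzFit",
    "ThresholdResult",
    "gompertz",
    "fit_gompertz",
    "asymptote_threshold",
    "distance85_threshold",
    "pct_of_max",
    "summarize_thresholds",
]


def gompertz(x, c, d, k, x0):
    """Gompertz curve c + (d - c) * exp(-exp(-k * (x - x0)))."""
    inner = np.clip(-k * (np.asarray(x, dtype=float) - x0), -700.0, 700.0)
    return c + (d - c) * np.exp(-np.exp(inner))


@dataclass
class GompertzFit:
    """Nonlinear least-squares Gompertz fit."""

    lower_c: float
    upper_d: float
    rate_k: float
    inflection_x0: float
    covariance: np.ndarray  # (4,4), or (3,3) when the lower plateau is fixed
    converged: bool
    rss: float
    fixed_lower: bool = False

    @property
    def params(self) -> tuple[float, float, float, float]:
        return (self.lower_c, self.upper_d, self.rate_k, self.inflection_x0)

    def predict(self, x):
        return gompertz(x, *self.params)

    def se_asymptote(self) -> float:
        """Wald standard error of the upper asymptote d."""
        idx = 0 if self.fixed_lower else 1
        var = self.covariance[idx, idx]
        return float(np.sqrt(var)) if np.isfinite(var) and var >= 0 else math.nan


@dataclass
class ThresholdResult:
    """Adult-size thresholds for one species and shape proxy."""

    species: str
    proxy: str  # "cac" or "multivariate"
    asymptote_threshold_mm: float | None
    distance85_threshold_mm: float
    pct_of_max_female: float
    pct_of_max_male: float
    sex_used: str  # "both", "female" or "male"

    @property
    def headline_pct(self) -> float:
        """Percentage of maximum recorded SCL for the reporting sex
        (the larger of the two records when both sexes apply)."""
        if self.sex_used == "female":
            return self.pct_of_max_female
        if self.sex_used == "male":
            return self.pct_of_max_male
        return min(self.pct_of_max_female, self.pct_of_max_male)


def _self_start(x: np.ndarray, y: np.ndarray) -> tuple[float, float, float, float]:
    """Initial Gompertz parameters from the data.

    x0 starts at the SCL of steepest local score change (largest
    finite-difference slope between size-ordered neighbours); k from the
    score range over the SCL interquartile range.
    """
    order = np.argsort(x)
    xs, ys = x[order], y[order]
    c0, d0 = float(ys.min()), float(ys.max())
    dx = np.diff(xs)
    with np.errstate(divide="ignore", invalid="ignore"):
        slopes = np.where(dx > 0, np.diff(ys) / dx, 0.0)
    if slopes.size and np.any(np.abs(slopes) > 0):
        i = int(np.argmax(np.abs(slopes)))
        x00 = float(0.5 * (xs[i] + xs[i + 1]))
    else:
        x00 = float(np.median(xs))
    iqr = float(np.subtract(*np.percentile(xs, [75, 25])))
    spread = iqr if iqr > 0 else float(np.ptp(xs)) / 2.0
    if spread <= 0:
        spread = 1.0
    # At the inflection the Gompertz slope is k*(d-c)/e; matching the range
    # covered over ~one spread gives k ~ e/spread as the scale.
    k0 = math.e / spread
    return c0, d0, k0, x00


def fit_gompertz(
    scl,
    score,
    fix_lower: bool = False,
    seed: int | None = None,
    n_starts: int = 8,
    maxfev: int = 5000,
) -> GompertzFit:
    """Fit the Gompertz curve by multi-start nonlinear least squares.

    Starts from self-start values plus ``n_starts - 1`` jittered variants
    (seeded); the converged fit with the lowest residual sum of squares wins.
    ``fix_lower`` pins the lower plateau at 0 (3-parameter variant).
    A fit that never converges is returned with ``converged=False`` only if
    at least one start produced parameters; if every start fails a
    :class:`ConvergenceError` is raised.
    """
    x = np.asarray(scl, dtype=float).ravel()
    y = np.asarray(score, dtype=float).ravel()
    if x.size != y.size:
        raise ValueError("scl and score must have the same length")
    if x.size < 5:
        raise SampleSizeError(f"Gompertz fit needs n >= 5, got {x.size}")
    if np.any(x <= 0):
        raise ValueError("SCL values must be strictly positive")
    if np.ptp(y) == 0.0:
        raise DegenerateDataError("all scores equal: nothing to fit")

    c0, d0, k0, x00 = _self_start(x, y)
    rng = np.random.default_rng(seed)
    span = float(np.ptp(x))
    yrange = d0 - c0

    if fix_lower:
        def model(xx, d, k, x0):
            return gompertz(xx, 0.0, d, k, x0)

        base = np.array([d0, k0, x00])
    else:
        model = gompertz
        base = np.array([c0, d0, k0, x00])

    best = None
    for i in range(n_starts):
        p0 = base.copy()
        if i > 0:
            jitter = rng.normal(size=p0.size)
            if fix_lower:
                p0[0] += 0.3 * yrange * jitter[0]
                p0[1] *= math.exp(0.7 * jitter[1])
                p0[2] += 0.25 * span * jitter[2]
            else:
                p0[0] -= abs(0.3 * yrange * jitter[0])
                p0[1] += 0.3 * yrange * jitter[1]
                p0[2] *= math.exp(0.7 * jitter[2])
                p0[3] += 0.25 * span * jitter[3]
        # keep the rate positive
        p0[-2] = abs(p0[-2]) or k0
        try:
            with warnings.catch_warnings():
                warnings.simplefilter("ignore")
                popt, pcov = optimize.curve_fit(
                    model, x, y, p0=p0, maxfev=maxfev, method="lm"
                )
            rss = float(np.sum((y - model(x, *popt)) ** 2))
        except (RuntimeError, optimize.OptimizeWarning, ValueError):
            continue
        if not np.all(np.isfinite(popt)):
            continue
        if best is None or rss < best[2]:
            best = (popt, pcov, rss)

    if best is None:
        raise ConvergenceError("no Gompertz start converged")
    popt, pcov, rss = best
    null_rss = float(np.sum((y - y.mean()) ** 2))
    converged = bool(np.all(np.isfinite(pcov))) and rss <= null_rss * (1 + 1e-9)
    if fix_lower:
        d, k, x0 = popt
        c = 0.0
    else:
        c, d, k, x0 = popt
    if k < 0:
        # A negative rate with swapped plateaus describes the same curve;
        # normalise to k > 0 by exchanging the roles of c and d only when it
        # leaves predictions unchanged (it does not, so just flag it).
        converged = False
    return GompertzFit(
        lower_c=float(c),
        upper_d=float(d),
        rate_k=float(k),
        inflection_x0=float(x0),
        covariance=np.asarray(pcov, dtype=float),
        converged=converged,
        rss=rss,
        fixed_lower=fix_lower,
    )


def asymptote_threshold(fit: GompertzFit, ci_level: float = 0.90) -> float | None:
    """SCL at which the curve reaches the lower Wald confidence bound of its
    asymptote.

    With L = d - z * SE(d) (z the upper quantile for the two-sided
    ``ci_level`` interval), the closed-form inversion is
    x = x0 - (1/k) * ln(-ln((L - c)/(d - c))).  Returns ``None`` when the
    bound falls at or below the lower plateau, at or above the asymptote, or
    when the fit shows no plateau (non-finite SE).
    """
    if not fit.converged:
        raise ConvergenceError("asymptote threshold requires a converged fit")
    c, d, k, x0 = fit.params
    se = fit.se_asymptote()
    if not math.isfinite(se):
        return None
    z = stats.norm.ppf(0.5 + ci_level / 2.0)
    lower = d - z * se
    if lower <= c or lower >= d or k <= 0:
        return None
    frac = (lower - c) / (d - c)
    return float(x0 - math.log(-math.log(frac)) / k)


def distance85_threshold(
    scl,
    proxy_scores,
    aligned_shapes,
    max_scl_mm: float,
    n_grid: int = 1000,
    ratio: float = 0.85,
    trajectory: str = "gompertz",
    seed: int | None = None,
) -> float:
    """Smallest SCL at which the predicted shape covers ``ratio`` of the
    Procrustes distance from the smallest specimen's shape to the shape at
    the largest recorded size.

    Scores are predicted on a grid of ``n_grid`` sizes from the smallest
    sampled SCL to ``max_scl_mm`` from a trajectory regression of score on
    SCL (``trajectory="gompertz"`` fits the Gompertz curve;
    ``"linear"`` an ordinary straight line), mapped to shapes by linear
    shape-on-score regression, and the distance profile — monotonised by
    running maximum to absorb numerical noise — is thresholded at
    ``ratio`` of its final value.
    """
    x = np.asarray(scl, dtype=float).ravel()
    scores = np.asarray(proxy_scores, dtype=float).ravel()
    shapes = np.asarray(aligned_shapes, dtype=float)
    if x.size < 4:
        raise SampleSizeError("distance threshold needs >= 4 specimens")
    if max_scl_mm < x.max():
        raise ValueError(
            f"max_scl_mm={max_scl_mm} below largest sampled SCL {x.max():.1f}"
        )
    grid = np.linspace(x.min(), max_scl_mm, n_grid)
    if trajectory == "gompertz":
        fit = fit_gompertz(x, scores, seed=seed)
        pred_scores = fit.predict(grid)
    elif trajectory == "linear":
        slope, intercept = np.polyfit(x, scores, 1)
        pred_scores = intercept + slope * grid
    else:
        raise ValueError(f"unknown trajectory {trajectory!r}")

    with warnings.catch_warnings():
        warnings.simplefilter("ignore")
        pred_shapes = predict_shape_at(scores, shapes, pred_scores)
    flat = pred_shapes.reshape(n_grid, -1)
    d = np.linalg.norm(flat - flat[0], axis=1)
    d = np.maximum.accumulate(d)
    total = d[-1]
    if total == 0.0:
        raise DegenerateDataError("flat trajectory: zero total shape distance")
    hits = np.nonzero(d >= ratio * total)[0]
    return float(grid[hits[0]])


def pct_of_max(
    threshold_mm: float,
    species: str,
    max_table: MaxSizeTable,
    dimorphic: bool = False,
    larger_sex: str | None = None,
) -> tuple[float, float, str]:
    """Threshold as percentage of the maximum recorded SCL per sex.

    For strongly size-dimorphic species the headline record is the larger
    sampled sex (caller-supplied); otherwise both sexes apply.
    """
    max_f = max_table.max_for(species, "female")
    max_m = max_table.max_for(species, "male")
    pct_f = 100.0 * threshold_mm / max_f
    pct_m = 100.0 * threshold_mm / max_m
    if dimorphic:
        if larger_sex not in ("female", "male"):
            raise ValueError("dimorphic species need larger_sex='female'|'male'")
        sex_used = larger_sex
    else:
        sex_used = "both"
    return pct_f, pct_m, sex_used


def summarize_thresholds(results: list[ThresholdResult]) -> dict:
    """Median/min/max of per-species threshold percentages per proxy, plus
    the same statistics (and the mean) for the asymptote-based thresholds."""
    if not results:
        raise ValueError("no threshold results to summarise")
    summary: dict = {}
    for proxy in sorted({r.proxy for r in results}):
        sub = [r for r in results if r.proxy == proxy]
        pct = np.array([r.headline_pct for r in sub])
        entry = {
            "n_species": len(sub),
            "distance85_pct": {
                "median": float(np.median(pct)),
                "min": float(pct.min()),
                "max": float(pct.max()),
            },
        }
        asym = [
            r.asymptote_threshold_mm for r in sub if r.asymptote_threshold_mm is not None
        ]
        if asym:
            # express in % of the same per-species maxima as the headline
            asym_pct = np.array(
                [
                    100.0
                    * r.asymptote_threshold_mm
                    / (r.distance85_threshold_mm / (r.headline_pct / 100.0))
                    for r in sub
                    if r.asymptote_threshold_mm is not None
                ]
            )
            entry["asymptote_pct"] = {
                "mean": float(asym_pct.mean()),
                "min": float(asym_pct.min()),
                "max": float(asym_pct.max()),
                "n": len(asym),
            }
        summary[proxy] = entry
    return summary
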