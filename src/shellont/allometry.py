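"""Allometric shape regression with permutation inference.

Shape (the flattened Procrustes-aligned coordinates) is regressed on
log10 centroid size.  Significance comes from residual randomization in a
permutation procedure (RRPP): residuals of the reduced model are permuted
across specimens, added back to the reduced fitted values, and the F
statistic recomputed; the p-value is the proportion of permuted F values at
least as large as the observed one (observed counted once in numerator and
denominator).  The effect size Z is the standardised position of ln F within
the permuted ln F distribution.

Two one-dimensional trajectory scores summarise the allometric signal:

* **CAC** (common allometric component): specimen scores on the unit vector
  in shape space proportional to the covariance of shape with size.
* **PredLine** ("multivariate shape"): first principal component scores of
  the model's fitted shape values.

Both are sign-oriented so they correlate non-negatively with size, so
shape-growth curves rise.
"""

from __future__ import annotations

import itertools
import math
from dataclasses import dataclass

import numpy as np

from .exceptions import DegenerateDataError, SampleSizeError

__all__ = [
    "AllometricFit",
    "SexModelFit",
    "fit_allometry",
    "fit_allometry_with_sex",
    "cac_scores",
    "predline_scores",
    "predict_shape_at",
]


@dataclass
class AllometricFit:
    """Shape-on-size regression with RRPP inference and trajectory scores."""

    species: str
    n: int
    r2: float
    f_stat: float
    z_score: float
    p_value: float
    coefficient_matrix: np.ndarray  # (2, P): intercept row, slope row
    cac_axis: np.ndarray  # (P,), unit norm
    cac_scores: np.ndarray  # (n,)
    predline_scores: np.ndarray  # (n,)
    size_values: np.ndarray  # (n,) log10 centroid size


@dataclass
class SexModelFit:
    """Sequential (size, then sex) RRPP model on adequately sexed specimens."""

    species: str
    n: int
    z_size: float
    z_sex: float
    p_size: float
    p_sex: float

    @property
    def delta_z(self) -> float:
        return self.z_size - self.z_sex


def _check_shapes_size(shapes: np.ndarray, size: np.ndarray, min_n: int = 4):
    shapes = np.asarray(shapes, dtype=float)
    size = np.asarray(size, dtype=float).ravel()
    if shapes.ndim != 2:
        shapes = shapes.reshape(shapes.shape[0], -1)
    n = shapes.shape[0]
    if size.shape[0] != n:
        raise ValueError(f"{n} shapes but {size.shape[0]} size values")
    if n < min_n:
        raise SampleSizeError(f"need at least {min_n} specimens, got {n}")
    if not np.all(np.isfinite(size)):
        raise ValueError("non-finite size values")
    if np.ptp(size) == 0.0:
        raise DegenerateDataError("size predictor has zero variance")
    return shapes, size, n


def _f_stat_quadratic(gram: np.ndarray, s_unit: np.ndarray, ss_total: float, n: int):
    """F for the single-predictor model via the Gram-matrix quadratic form.

    ``gram`` is Yc @ Yc.T for centred shapes Yc, ``s_unit`` the centred
    predictor scaled to unit norm; SS_model = s'G s, the projection of shape
    variation onto the predictor direction.
    """
    ss_model = float(s_unit @ gram @ s_unit)
    ss_res = ss_total - ss_model
    df_res = n - 2
    if ss_res <= 0.0:
        return math.inf, ss_model
    return (ss_model / 1.0) / (ss_res / df_res), ss_model


def _z_from_lnf(f_obs: float, f_perm: np.ndarray) -> float:
    with np.errstate(divide="ignore"):
        lnf = np.log(f_perm[f_perm > 0])
    if lnf.size < 2 or np.std(lnf) == 0.0:
        return math.nan
    ln_obs = math.log(f_obs) if f_obs > 0 else -math.inf
    return float((ln_obs - lnf.mean()) / lnf.std(ddof=1))


def fit_allometry(
    aligned_shapes,
    log_size,
    n_perm: int | None = 999,
    seed: int | None = None,
    species: str = "",
) -> AllometricFit:
    """Multivariate regression of shape on (log) size with RRPP inference.

    ``n_perm=None`` enumerates all n! orderings (exact test; only sensible
    for n <= ~8), in which case p is the exact fraction of orderings with
    F >= F_obs.  Otherwise ``n_perm`` random permutations of the reduced
    (intercept-only) model residuals are drawn and
    p = (1 + #{F_perm >= F_obs}) / (1 + n_perm).
    """
    y, s, n = _check_shapes_size(aligned_shapes, log_size)
    yc = y - y.mean(axis=0)
    sc = s - s.mean()
    s_unit = sc / np.linalg.norm(sc)
    gram = yc @ yc.T
    ss_total = float(np.trace(gram))
    if ss_total == 0.0:
        raise DegenerateDataError("shapes have zero variance")

    f_obs, ss_model = _f_stat_quadratic(gram, s_unit, ss_total, n)
    r2 = ss_model / ss_total

    # Permuting reduced-model (intercept-only) residuals row-wise is
    # equivalent to permuting the predictor against the shapes.
    if n_perm is None:
        perms = itertools.permutations(range(n))
        f_perm = np.array(
            [
                _f_stat_quadratic(gram, s_unit[list(p)], ss_total, n)[0]
                for p in perms
            ]
        )
        p_value = float(np.mean(f_perm >= f_obs))
        n_eff = f_perm.size
    else:
        rng = np.random.default_rng(seed)
        f_perm = np.empty(n_perm)
        for i in range(n_perm):
            f_perm[i] = _f_stat_quadratic(
                gram, s_unit[rng.permutation(n)], ss_total, n
            )[0]
        p_value = float((1 + np.sum(f_perm >= f_obs)) / (1 + n_perm))
        n_eff = n_perm
    z = _z_from_lnf(f_obs, f_perm)

    # Coefficients of flattened shape on [1, centred size].
    beta1 = (yc.T @ sc) / float(sc @ sc)  # (P,) slope per coordinate
    beta0 = y.mean(axis=0)
    coef = np.vstack([beta0, beta1])

    axis, cac = cac_scores(y, s)
    pl = predline_scores_from_fitted(np.outer(sc, beta1), s)

    return AllometricFit(
        species=species,
        n=n,
        r2=float(r2),
        f_stat=float(f_obs),
        z_score=z,
        p_value=p_value,
        coefficient_matrix=coef,
        cac_axis=axis,
        cac_scores=cac,
        predline_scores=pl,
        size_values=s,
    )


def cac_scores(aligned_shapes, log_size) -> tuple[np.ndarray, np.ndarray]:
    """Common allometric component: unit axis of size-associated shape change
    and specimen scores on it.

    axis ∝ Yc' sc / (sc' sc) with Yc the centred flattened shapes and sc the
    centred size; scores are Yc @ axis, sign-oriented so they correlate
    non-negatively with size.
    """
    y, s, _ = _check_shapes_size(aligned_shapes, log_size)
    yc = y - y.mean(axis=0)
    sc = s - s.mean()
    axis = (yc.T @ sc) / float(sc @ sc)
    norm = np.linalg.norm(axis)
    if norm == 0.0:
        raise DegenerateDataError("no covariance between shape and size")
    axis = axis / norm
    scores = yc @ axis
    if float(scores @ sc) < 0:
        axis = -axis
        scores = -scores
    return axis, scores


def predline_scores_from_fitted(fitted_centred: np.ndarray, size: np.ndarray):
    """PC1 scores of centred fitted shape values, oriented with size."""
    u, sv, vt = np.linalg.svd(fitted_centred, full_matrices=False)
    if sv.size == 0 or sv[0] == 0.0:
        return np.zeros(fitted_centred.shape[0])
    scores = u[:, 0] * sv[0]
    sc = size - np.mean(size)
    if float(scores @ sc) < 0:
        scores = -scores
    return scores


def predline_scores(fit: AllometricFit, aligned_shapes) -> np.ndarray:
    """PredLine ("multivariate shape") scores from a fitted model: PC1 of the
    model's predicted shape values, sign-oriented with size."""
    y = np.asarray(aligned_shapes, dtype=float).reshape(fit.n, -1)
    s = fit.size_values
    sc = s - s.mean()
    fitted_centred = np.outer(sc, fit.coefficient_matrix[1])
    del y  # fitted values depend on the model, not the raw shapes
    return predline_scores_from_fitted(fitted_centred, s)


def predict_shape_at(fit_scores, aligned_shapes, targets) -> np.ndarray:
    """Predict shapes at given trajectory-score values.

    Linear least-squares regression of each flattened-shape coordinate on the
    score; evaluated at ``targets``.  Prediction at the mean score is the mean
    shape.  Returns an (m, K, 3) array when the input shapes are (n, K, 3),
    else (m, P).
    """
    scores = np.asarray(fit_scores, dtype=float).ravel()
    shapes = np.asarray(aligned_shapes, dtype=float)
    orig_shape = shapes.shape[1:]
    y = shapes.reshape(shapes.shape[0], -1)
    targets = np.atleast_1d(np.asarray(targets, dtype=float))
    sc = scores - scores.mean()
    denom = float(sc @ sc)
    if denom == 0.0:
        raise DegenerateDataError("trajectory scores have zero variance")
    lo, hi = scores.min(), scores.max()
    span = hi - lo
    if np.any((targets < lo - 0.5 * span) | (targets > hi + 0.5 * span)):
        import warnings

        warnings.warn("predicting far outside the observed score range", stacklevel=2)
    slope = (y - y.mean(axis=0)).T @ sc / denom  # (P,)
    pred = y.mean(axis=0) + np.outer(targets - scores.mean(), slope)
    if len(orig_shape) == 2:
        return pred.reshape(len(targets), *orig_shape)
    return pred


def _sequential_rrpp(
    y: np.ndarray, designs: list[np.ndarray], n_perm: int, rng: np.random.Generator
):
    """Sequential (type-I) RRPP over a nested design sequence.

    ``designs`` is [X_0 (intercept), X_1, ..., X_T (full)].  For term t the
    reduced model is X_{t-1}; its residuals are permuted, added back to its
    fitted values, and the term's F recomputed on the permuted response.
    Returns per-term (f_obs, z, p).
    """
    n = y.shape[0]
    hats = []
    for x in designs:
        q, _ = np.linalg.qr(x)
        hats.append(q @ q.T)
    dfs = [np.linalg.matrix_rank(x) for x in designs]
    df_res_full = n - dfs[-1]

    def term_stats(y_use: np.ndarray) -> np.ndarray:
        fitted = [h @ y_use for h in hats]
        ss_fit = [float(np.sum(f * f)) for f in fitted]
        ss_res_full = float(np.sum((y_use - fitted[-1]) ** 2))
        out = np.empty(len(designs) - 1)
        for t in range(1, len(designs)):
            ss_term = ss_fit[t] - ss_fit[t - 1]
            df_term = dfs[t] - dfs[t - 1]
            denom = ss_res_full / df_res_full if df_res_full > 0 else np.nan
            out[t - 1] = (ss_term / df_term) / denom if denom > 0 else math.inf
        return out

    f_obs = term_stats(y)
    n_terms = len(f_obs)
    f_perm = np.empty((n_perm, n_terms))
    for t in range(1, len(designs)):
        fitted_red = hats[t - 1] @ y
        resid_red = y - fitted_red
        for i in range(n_perm):
            perm = rng.permutation(n)
            y_perm = fitted_red + resid_red[perm]
            f_perm[i, t - 1] = term_stats(y_perm)[t - 1]

    stats = []
    for t in range(n_terms):
        p = float((1 + np.sum(f_perm[:, t] >= f_obs[t])) / (1 + n_perm))
        z = _z_from_lnf(f_obs[t], f_perm[:, t])
        stats.append((float(f_obs[t]), z, p))
    return stats


def fit_allometry_with_sex(
    aligned_shapes,
    log_size,
    sex,
    n_perm: int = 999,
    seed: int | None = None,
    species: str = "",
) -> SexModelFit:
    """Shape ~ size + sex with sequential RRPP evaluation of both terms.

    Specimens of unknown sex are excluded; both sexes must retain at least
    two specimens.  The size term is tested against the intercept-only
    reduced model, the sex term against the size-only model, each with its
    own residual randomization.
    """
    y = np.asarray(aligned_shapes, dtype=float)
    y = y.reshape(y.shape[0], -1)
    s = np.asarray(log_size, dtype=float).ravel()
    sex = np.asarray([str(x) for x in sex])
    known = np.isin(sex, ["female", "male"])
    if not known.all():
        import warnings

        warnings.warn(
            f"excluding {int((~known).sum())} unknown-sex specimens from the "
            "sex model",
            stacklevel=2,
        )
    y, s, sex = y[known], s[known], sex[known]
    n_f = int(np.sum(sex == "female"))
    n_m = int(np.sum(sex == "male"))
    if n_f < 2 or n_m < 2:
        raise DegenerateDataError(
            f"sex model needs >= 2 specimens per sex (female={n_f}, male={n_m})"
        )
    y, s, n = _check_shapes_size(y, s, min_n=5)
    yc = y - y.mean(axis=0)
    ones = np.ones((n, 1))
    x_size = np.column_stack([ones, s - s.mean()])
    x_full = np.column_stack([x_size, (sex == "male").astype(float)])
    rng = np.random.default_rng(seed)
    stats = _sequential_rrpp(yc, [ones, x_size, x_full], n_perm, rng)
    (_, z_size, p_size), (_, z_sex, p_sex) = stats
    return SexModelFit(
        species=species, n=n, z_size=z_size, z_sex=z_sex, p_size=p_size, p_sex=p_sex
    )
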