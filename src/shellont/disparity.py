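"""Ontogenetic stage clustering and morphological disparity.

Specimens are clustered within species into three a-priori ontogenetic
stages — 'small', 'intermediate', 'large' — by Ward-linkage hierarchical
clustering on the (standardised) shape-proxy score and carapace length.
Disparity of the pooled stages is measured two ways:

* **sum of ranges (SoR)** over ordination (PC) axes — total spread of
  occupied shape space, sensitive to sample size, hence bootstrapped and
  rarefied;
* **Procrustes variance (PV)** — mean squared Procrustes distance of group
  members to their group mean shape.

Group CIs come from bootstrap percentiles; pairwise stage differences are
tested with an overlapping-confidence-interval z statistic (midpoints scaled
by implied standard errors), Bonferroni-adjusted.
"""

from __future__ import annotations

import math
from dataclasses import dataclass

import numpy as np
from scipy import stats
from scipy.cluster.hierarchy import fcluster, linkage

from .exceptions import DegenerateDataError, SampleSizeError

__all__ = [
    "StageAssignment",
    "DisparityResult",
    "ZouTest",
    "STAGE_NAMES",
    "stage_clusters",
    "sum_of_ranges",
    "procrustes_variance",
    "bootstrap_disparity",
    "zou_ci_test",
    "bonferroni",
]

STAGE_NAMES = ("small", "intermediate", "large")


@dataclass(frozen=True)
class StageAssignment:
    specimen_id: str
    stage: str


@dataclass
class DisparityResult:
    stage: str
    n: int
    observed: float
    ci: tuple[float, float] | None
    metric: str  # "sor" or "pv"
    n_boot: int
    rarefy_n: int | None


@dataclass
class ZouTest:
    pair: str
    statistic: float
    p_raw: float
    p_bonferroni: float = math.nan


def stage_clusters(
    proxy_scores,
    scl,
    specimen_ids=None,
    k: int = 3,
) -> list[StageAssignment]:
    """Assign specimens to k ontogenetic stages by Ward clustering.

    Both variables are standardised to zero mean and unit variance (carapace
    length in mm would otherwise dwarf the shape score), pairwise Euclidean
    distances are grouped by Ward linkage, the tree cut at ``k``, and cluster
    labels ordered by ascending mean SCL ('small' < 'intermediate' <
    'large' for k=3).
    """
    scores = np.asarray(proxy_scores, dtype=float).ravel()
    sizes = np.asarray(scl, dtype=float).ravel()
    n = scores.size
    if sizes.size != n:
        raise ValueError("proxy_scores and scl must have the same length")
    if n < k:
        raise SampleSizeError(f"need at least k={k} specimens, got {n}")
    if specimen_ids is None:
        specimen_ids = [f"spec_{i}" for i in range(n)]

    cols = []
    for v in (scores, sizes):
        sd = v.std(ddof=0)
        cols.append((v - v.mean()) / sd if sd > 0 else np.zeros_like(v))
    if all(np.all(c == 0) for c in cols):
        raise DegenerateDataError("zero variance in both clustering variables")
    data = np.column_stack(cols)
    labels = fcluster(linkage(data, method="ward"), t=k, criterion="maxclust")

    order = np.argsort(
        [sizes[labels == lab].mean() for lab in np.unique(labels)]
    )
    names = (
        list(STAGE_NAMES)
        if k == 3
        else [f"stage_{i + 1}" for i in range(k)]
    )
    rank = {lab: names[r] for r, lab in enumerate(np.unique(labels)[order])}
    return [
        StageAssignment(str(sid), rank[lab]) for sid, lab in zip(specimen_ids, labels)
    ]


def sum_of_ranges(pc_scores) -> float:
    """Sum over ordination axes of the per-axis score range (max - min)."""
    x = np.atleast_2d(np.asarray(pc_scores, dtype=float))
    if x.shape[0] < 1:
        raise SampleSizeError("sum of ranges needs at least one point")
    return float(np.sum(x.max(axis=0) - x.min(axis=0)))


def procrustes_variance(aligned_shapes, group_labels=None):
    """Mean squared Procrustes distance of group members to the group mean
    shape, per group (a single value for unlabelled input)."""
    x = np.asarray(aligned_shapes, dtype=float)
    x = x.reshape(x.shape[0], -1)

    def _pv(sub: np.ndarray) -> float:
        if sub.shape[0] < 2:
            raise SampleSizeError("Procrustes variance needs >= 2 members")
        centred = sub - sub.mean(axis=0)
        return float(np.mean(np.sum(centred**2, axis=1)))

    if group_labels is None:
        return _pv(x)
    labels = np.asarray(group_labels)
    return {str(g): _pv(x[labels == g]) for g in np.unique(labels)}


def _metric_fn(metric: str):
    if metric == "sor":
        return sum_of_ranges
    if metric == "pv":
        return procrustes_variance
    raise ValueError(f"unknown metric {metric!r}")


def bootstrap_disparity(
    data,
    groups,
    metric: str = "sor",
    n_boot: int = 1000,
    rarefy_n: int | None = None,
    ci: float = 0.95,
    seed: int | None = None,
) -> dict[str, DisparityResult]:
    """Observed disparity and bootstrap percentile CI per group.

    Each replicate resamples the group with replacement (to ``rarefy_n``
    specimens when rarefying, else to the group's own size) and recomputes
    the metric.  Rarefaction uses one common ``rarefy_n`` for every group so
    range-based metrics are compared at equal sample size.
    """
    x = np.asarray(data, dtype=float)
    x = x.reshape(x.shape[0], -1)
    labels = np.asarray([str(g) for g in groups])
    if labels.size != x.shape[0]:
        raise ValueError("groups must label every row of data")
    fn = _metric_fn(metric)
    rng = np.random.default_rng(seed)
    out: dict[str, DisparityResult] = {}
    uniq = [g for g in dict.fromkeys(labels)]  # stable order of appearance
    sizes = {g: int(np.sum(labels == g)) for g in uniq}
    if rarefy_n is not None:
        too_small = [g for g in uniq if sizes[g] < rarefy_n]
        if too_small:
            raise ValueError(
                f"rarefy_n={rarefy_n} exceeds group size for {too_small}"
            )
    alpha = (1.0 - ci) / 2.0
    for g in uniq:
        sub = x[labels == g]
        observed = fn(sub)
        if n_boot <= 0:
            out[g] = DisparityResult(g, sizes[g], observed, None, metric, 0, rarefy_n)
            continue
        m = rarefy_n if rarefy_n is not None else sizes[g]
        reps = np.empty(n_boot)
        for b in range(n_boot):
            idx = rng.integers(0, sizes[g], size=m)
            reps[b] = fn(sub[idx])
        lo, hi = np.percentile(reps, [100 * alpha, 100 * (1 - alpha)])
        out[g] = DisparityResult(
            g, sizes[g], observed, (float(lo), float(hi)), metric, n_boot, rarefy_n
        )
    return out


def zou_ci_test(
    ci_a: tuple[float, float],
    ci_b: tuple[float, float],
    ci_level: float = 0.95,
    pair: str = "",
    method: str = "midpoint",
) -> ZouTest:
    """Overlapping-confidence-interval test between two group CIs.

    The default ``midpoint`` statistic treats each interval's half-width as
    z * SE: statistic = |m_a - m_b| / sqrt(SE_a^2 + SE_b^2), with a
    two-sided normal p-value.  Values above 1.96 indicate non-overlapping
    95% CIs.  ``method="zou2007"`` uses the original asymmetric
    overlap construction for the CI of the difference; its statistic is the
    scale factor by which the relevant half-widths would have to grow for
    the difference interval to touch zero (same p-value convention).
    """
    (lo_a, hi_a), (lo_b, hi_b) = ci_a, ci_b
    if lo_a > hi_a or lo_b > hi_b:
        raise ValueError("interval bounds must satisfy lo <= hi")
    z = stats.norm.ppf(0.5 + ci_level / 2.0)
    m_a, m_b = (lo_a + hi_a) / 2.0, (lo_b + hi_b) / 2.0
    diff = m_a - m_b
    if method == "midpoint":
        se_a = (hi_a - lo_a) / (2.0 * z)
        se_b = (hi_b - lo_b) / (2.0 * z)
        denom = math.hypot(se_a, se_b)
    elif method == "zou2007":
        # Half-widths on the sides facing each other.
        if diff >= 0:
            w_a = m_a - lo_a
            w_b = hi_b - m_b
        else:
            w_a = hi_a - m_a
            w_b = m_b - lo_b
        denom = math.hypot(w_a, w_b) / z
    else:
        raise ValueError(f"unknown method {method!r}")
    if denom == 0.0:
        if diff == 0.0:
            return ZouTest(pair=pair, statistic=0.0, p_raw=1.0)
        return ZouTest(pair=pair, statistic=math.inf, p_raw=0.0)
    statistic = abs(diff) / denom
    p = float(2.0 * stats.norm.sf(statistic))
    return ZouTest(pair=pair, statistic=float(statistic), p_raw=p)


def bonferroni(p_values) -> list[float]:
    """Bonferroni adjustment: p * m capped at 1."""
    ps = list(p_values)
    for p in ps:
        if not (0.0 < p <= 1.0):
            raise ValueError(f"p-value {p} outside (0, 1]")
    m = len(ps)
    return [min(1.0, p * m) for p in ps]
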