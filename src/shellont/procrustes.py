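"""Procrustes superimposition, shape distance and ordination.

Implements classic generalized Procrustes analysis (GPA): every configuration
is centred, scaled to unit centroid size, and iteratively rotated to the
running mean shape until the consensus stabilises.  Rotations are proper
(reflections excluded) because left/right anatomical identity of shell
landmarks must be preserved.  Shape distances are Euclidean norms between
superimposed configurations; ordination is PCA of flattened aligned
coordinates, optionally after orthogonal projection into the tangent space at
the consensus.
"""

from __future__ import annotations

from dataclasses import dataclass
from pathlib import Path

import numpy as np
import pandas as pd

from .exceptions import (
    ConvergenceError,
    DegenerateDataError,
    DimensionError,
    SampleSizeError,
)
from .io import LandmarkConfig

__all__ = [
    "AlignedSample",
    "PCAResult",
    "centroid_size",
    "opa_align",
    "gpa",
    "procrustes_distance",
    "pca",
    "landmark_displacement_map",
    "tangent_project",
]


def _as_coords(config) -> np.ndarray:
    if isinstance(config, LandmarkConfig):
        return config.coords
    arr = np.asarray(config, dtype=float)
    if arr.ndim != 2 or arr.shape[1] != 3:
        raise DimensionError(f"expected (K, 3) coordinates, got {arr.shape}")
    return arr


def centroid_size(config) -> float:
    """Root summed squared distances of the landmarks to their centroid."""
    coords = _as_coords(config)
    if coords.shape[0] < 2:
        raise DimensionError("centroid size needs at least 2 landmarks")
    centred = coords - coords.mean(axis=0)
    cs = float(np.sqrt(np.sum(centred**2)))
    if cs == 0.0:
        raise DegenerateDataError("all landmarks coincide: zero centroid size")
    return cs


def _optimal_rotation(mobile_c: np.ndarray, reference_c: np.ndarray) -> np.ndarray:
    """Proper rotation R minimising ||mobile_c @ R - reference_c||_F.

    Reflection is excluded by forcing det(R) = +1.
    """
    h = mobile_c.T @ reference_c
    u, _, vt = np.linalg.svd(h)
    d = np.sign(np.linalg.det(u @ vt))
    s = np.diag([1.0, 1.0, d])
    return u @ s @ vt


def opa_align(mobile, reference, scale: bool = False):
    """Ordinary Procrustes alignment of ``mobile`` onto ``reference``.

    Translates, rotates (and optionally scales) ``mobile`` to minimise the
    summed squared coordinate differences to ``reference`` over proper rigid
    motions.  Returns ``(aligned, residual)`` where *residual* is the root
    summed squared difference after alignment.
    """
    m = _as_coords(mobile)
    r = _as_coords(reference)
    if m.shape != r.shape:
        raise DimensionError(f"shape mismatch: {m.shape} vs {r.shape}")
    m_cent = m.mean(axis=0)
    r_cent = r.mean(axis=0)
    m_c = m - m_cent
    r_c = r - r_cent
    rot = _optimal_rotation(m_c, r_c)
    aligned_c = m_c @ rot
    if scale:
        denom = float(np.sum(aligned_c * aligned_c))
        if denom == 0.0:
            raise DegenerateDataError("cannot scale a degenerate configuration")
        s = float(np.sum(aligned_c * r_c)) / denom
        aligned_c = aligned_c * s
    aligned = aligned_c + r_cent
    residual = float(np.linalg.norm(aligned_c - r_c))
    return aligned, residual


@dataclass
class AlignedSample:
    """Result of a generalized Procrustes analysis.

    ``aligned`` holds unit-centroid-size configurations rotated to the
    consensus; ``centroid_sizes`` are the original sizes removed by the
    scaling step.
    """

    consensus: np.ndarray  # (K, 3)
    aligned: np.ndarray  # (N, K, 3)
    centroid_sizes: np.ndarray  # (N,)
    n_iterations: int
    specimen_ids: list[str] | None = None

    @property
    def n(self) -> int:
        return self.aligned.shape[0]

    @property
    def k(self) -> int:
        return self.aligned.shape[1]

    def flattened(self, tangent: bool = False) -> np.ndarray:
        """(N, 3K) matrix of aligned shapes, optionally tangent-projected."""
        flat = self.aligned.reshape(self.n, -1)
        if tangent:
            return tangent_project(flat, self.consensus.ravel())
        return flat

    def to_directory(self, path: str | Path) -> None:
        path = Path(path)
        path.mkdir(parents=True, exist_ok=True)
        ids = self.specimen_ids or [f"spec_{i}" for i in range(self.n)]
        pd.DataFrame(self.consensus, columns=["x", "y", "z"]).to_csv(
            path / "consensus.csv", index=False
        )
        rows = []
        for sid, conf in zip(ids, self.aligned):
            for j, (x, y, z) in enumerate(conf, start=1):
                rows.append((sid, j, x, y, z))
        pd.DataFrame(
            rows, columns=["specimen_id", "landmark_index", "x", "y", "z"]
        ).to_csv(path / "aligned.csv", index=False)
        pd.DataFrame({"specimen_id": ids, "centroid_size": self.centroid_sizes}).to_csv(
            path / "centroid_sizes.tsv", sep="\t", index=False
        )


def tangent_project(flat: np.ndarray, consensus_flat: np.ndarray) -> np.ndarray:
    """Orthogonal projection of unit-size shapes onto the tangent hyperplane
    at the consensus (the plane through the consensus normal to it)."""
    c = consensus_flat / np.linalg.norm(consensus_flat)
    return flat + np.outer(1.0 - flat @ c, c)


def gpa(
    configs,
    tol: float = 1e-8,
    max_iter: int = 100,
    specimen_ids: list[str] | None = None,
) -> AlignedSample:
    """Generalized Procrustes analysis.

    Each configuration is centred and scaled to unit centroid size, then all
    are iteratively rotated to the current consensus; the consensus is the
    coordinate-wise mean rescaled to unit centroid size.  Convergence is
    declared when the root-mean-square change of the consensus coordinates
    falls below ``tol``.
    """
    coords = [_as_coords(c) for c in configs]
    if specimen_ids is None and configs and isinstance(configs[0], LandmarkConfig):
        specimen_ids = [c.specimen_id for c in configs]
    n = len(coords)
    if n < 2:
        raise SampleSizeError("GPA needs at least 2 configurations")
    k = coords[0].shape[0]
    for c in coords:
        if c.shape[0] != k:
            raise DimensionError("all configurations must share the landmark count")

    sizes = np.array([centroid_size(c) for c in coords])
    unit = np.stack(
        [(c - c.mean(axis=0)) / s for c, s in zip(coords, sizes)]
    )  # (N, K, 3)

    # Initial consensus: first configuration.
    consensus = unit[0].copy()
    consensus /= np.linalg.norm(consensus)
    n_it = 0
    for n_it in range(1, max_iter + 1):
        for i in range(n):
            rot = _optimal_rotation(unit[i], consensus)
            unit[i] = unit[i] @ rot
        new_consensus = unit.mean(axis=0)
        new_consensus -= new_consensus.mean(axis=0)
        norm = np.linalg.norm(new_consensus)
        if norm == 0.0:
            raise DegenerateDataError("degenerate consensus (zero centroid size)")
        new_consensus /= norm
        change = float(np.sqrt(np.mean((new_consensus - consensus) ** 2)))
        consensus = new_consensus
        if change < tol:
            break
    else:
        raise ConvergenceError(
            f"GPA did not converge in {max_iter} iterations (last change {change:.3e})"
        )

    # Final pass so every configuration is rotated to the converged consensus.
    for i in range(n):
        rot = _optimal_rotation(unit[i], consensus)
        unit[i] = unit[i] @ rot

    return AlignedSample(
        consensus=consensus,
        aligned=unit,
        centroid_sizes=sizes,
        n_iterations=n_it,
        specimen_ids=specimen_ids,
    )


def procrustes_distance(a, b, pre_aligned: bool = True) -> float:
    """Shape distance between two configurations.

    With ``pre_aligned`` the Euclidean norm of the coordinate difference is
    returned directly (appropriate for GPA output); otherwise both shapes are
    centred, scaled to unit centroid size and optimally rotated first.
    """
    ca = _as_coords(a)
    cb = _as_coords(b)
    if ca.shape != cb.shape:
        raise DimensionError(f"shape mismatch: {ca.shape} vs {cb.shape}")
    if pre_aligned:
        return float(np.linalg.norm(ca - cb))
    ua = (ca - ca.mean(axis=0)) / centroid_size(ca)
    ub = (cb - cb.mean(axis=0)) / centroid_size(cb)
    rot = _optimal_rotation(ua, ub)
    return float(np.linalg.norm(ua @ rot - ub))


@dataclass
class PCAResult:
    """Principal component decomposition of flattened shapes."""

    scores: np.ndarray  # (N, D)
    axes: np.ndarray  # (D, P) orthonormal rows
    variances: np.ndarray  # (D,) non-increasing
    mean: np.ndarray  # (P,)

    def to_tsv(self, path: str | Path, specimen_ids: list[str] | None = None) -> None:
        d = self.scores.shape[1]
        df = pd.DataFrame(self.scores, columns=[f"PC{i + 1}" for i in range(d)])
        if specimen_ids is not None:
            df.insert(0, "specimen_id", specimen_ids)
        df.to_csv(path, sep="\t", index=False)


def pca(sample, tangent: bool = True) -> PCAResult:
    """PCA of aligned shapes (or any (N, P) matrix).

    Accepts an :class:`AlignedSample` (flattened, by default after tangent
    projection) or a raw matrix.  Variances use the n-1 denominator and sum to
    the total sample variance of the centred data.
    """
    if isinstance(sample, AlignedSample):
        x = sample.flattened(tangent=tangent)
    else:
        x = np.asarray(sample, dtype=float)
    n = x.shape[0]
    if n < 3:
        raise SampleSizeError("PCA needs at least 3 observations")
    mean = x.mean(axis=0)
    xc = x - mean
    u, s, vt = np.linalg.svd(xc, full_matrices=False)
    variances = s**2 / (n - 1)
    scores = u * s
    return PCAResult(scores=scores, axes=vt, variances=variances, mean=mean)


def landmark_displacement_map(a, b) -> np.ndarray:
    """Per-landmark Euclidean distances between two configurations,
    normalised by their maximum to the 0-1 range (0/0 defined as 0)."""
    ca = _as_coords(a)
    cb = _as_coords(b)
    if ca.shape != cb.shape:
        raise DimensionError(f"shape mismatch: {ca.shape} vs {cb.shape}")
    d = np.linalg.norm(ca - cb, axis=1)
    m = d.max()
    if m == 0.0:
        return np.zeros_like(d)
    return d / m
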