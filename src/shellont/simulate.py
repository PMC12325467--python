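"""Synthetic ontogenetic landmark growth series with known ground truth.

Each synthetic species is a schematic half-ellipsoid "shell" of K = 20
landmarks (landmark 1 the anteriormost point, landmark 12 the
posteriormost, so carapace length can be measured between them).  A
specimen of straight carapace length x has shape

    base + g(x) * deformation_axis + sex terms + noise,

where g is a Gompertz function of x and the default deformation axis
stretches the shell anteroposteriorly while narrowing it transversely — the
dominant ontogenetic trend in real shells ("elongate and narrow").  The
deformation axis is constructed orthogonal to translation, rotation and
scaling of the base shape, so Procrustes superimposition removes the random
digitising transform applied afterwards without distorting the planted
signal.  Noise is isotropic Gaussian per coordinate, applied in shape space
before the similarity transform.

The closed-form Gompertz makes the 85%-distance adult-size threshold
solvable analytically, giving every species a ground truth against which
pipeline recovery can be measured.
"""

from __future__ import annotations

import json
import math
from dataclasses import dataclass, field
from pathlib import Path

import numpy as np
from scipy import optimize

from .exceptions import IntegrityError, SampleSizeError
from .growth import gompertz
from .io import (
    LandmarkConfig,
    MaxSizeTable,
    SpeciesDataset,
    SpecimenRecord,
    write_landmarks,
    write_metadata,
)

__all__ = [
    "SpeciesProfile",
    "GroundTruth",
    "half_ellipsoid_shell",
    "elongation_axis",
    "orthogonalize_to_similarity",
    "analytic_distance85",
    "profile_with_target_pct",
    "generate_species",
    "generate_panel",
    "write_panel",
    "default_panel_profiles",
]

K_DEFAULT = 20
ANTERIOR_IDX = 0  # 1-based landmark 1
POSTERIOR_IDX = 11  # 1-based landmark 12


def half_ellipsoid_shell(
    ap: float = 1.0, width: float = 0.7, height: float = 0.45
) -> np.ndarray:
    """Schematic 20-landmark carapace: a half-ellipsoid with rim and dome
    points.  Landmark 1 (index 0) is the anterior pole, landmark 12
    (index 11) the posterior pole.  Centred, unit centroid size."""
    deg = np.deg2rad

    def rim(theta):
        return [width * math.sin(deg(theta)), ap * math.cos(deg(theta)), 0.0]

    def dome(theta, alt):
        ca = math.cos(deg(alt))
        return [
            width * ca * math.sin(deg(theta)),
            ap * ca * math.cos(deg(theta)),
            height * math.sin(deg(alt)),
        ]

    pts = [rim(0)]  # 0: anterior pole
    pts += [rim(t) for t in (30, 60, 90, 120, 150)]  # 1-5: right rim
    pts += [dome(t, 45) for t in (0, 72, 144, 216, 288)]  # 6-10: dome ring
    pts.append(rim(180))  # 11: posterior pole
    pts += [rim(t) for t in (210, 240, 270, 300, 330)]  # 12-16: left rim
    pts.append([0.0, 0.0, height])  # 17: apex
    pts.append(dome(0, 70))  # 18: anterior dome
    pts.append(dome(180, 70))  # 19: posterior dome
    coords = np.array(pts)
    coords -= coords.mean(axis=0)
    coords /= np.linalg.norm(coords)
    return coords


def _similarity_basis(base: np.ndarray) -> np.ndarray:
    """Orthonormal basis (rows) of the similarity-transform directions at
    ``base``: 3 translations, 3 infinitesimal rotations, 1 scaling."""
    k = base.shape[0]
    gens = []
    for axis in range(3):
        t = np.zeros((k, 3))
        t[:, axis] = 1.0
        gens.append(t.ravel())
    x, y, z = base[:, 0], base[:, 1], base[:, 2]
    gens.append(np.column_stack([-y, x, np.zeros(k)]).ravel())  # about z
    gens.append(np.column_stack([np.zeros(k), -z, y]).ravel())  # about x
    gens.append(np.column_stack([z, np.zeros(k), -x]).ravel())  # about y
    gens.append(base.ravel())  # scaling
    q, _ = np.linalg.qr(np.array(gens).T)
    return q.T


def orthogonalize_to_similarity(vec: np.ndarray, base: np.ndarray) -> np.ndarray:
    """Project a shape-space vector orthogonal to translation, rotation and
    scaling of ``base``, renormalised to unit length."""
    v = np.asarray(vec, dtype=float).ravel().copy()
    scale = np.linalg.norm(v)
    for b in _similarity_basis(base):
        v -= (v @ b) * b
    n = np.linalg.norm(v)
    if n <= 1e-10 * scale:
        raise ValueError("vector lies entirely in the similarity subspace")
    return v / n


def elongation_axis(base: np.ndarray) -> np.ndarray:
    """Default deformation: stretch the anteroposterior (y) axis, shrink the
    transverse (x) and dorsoventral (z) axes, orthogonal to similarity
    transforms of ``base``.  Unit norm, flattened."""
    x, y, z = base[:, 0], base[:, 1], base[:, 2]
    sy = float(np.sum(y * y))
    sxz = float(np.sum(x * x) + np.sum(z * z))
    beta = sy / sxz  # makes the raw axis orthogonal to pure scaling
    raw = np.column_stack([-beta * x, y, -beta * z]).ravel()
    return orthogonalize_to_similarity(raw, base)


@dataclass
class SpeciesProfile:
    """Generator settings for one synthetic species.

    ``gompertz`` gives (c, d, k, x0) of the deformation magnitude (in
    Procrustes-distance units) as a function of SCL in mm; ``noise_sd`` is
    the per-coordinate Gaussian SD in shape space.
    """

    species: str
    gompertz: tuple[float, float, float, float] = (0.0, 0.12, 0.02, 150.0)
    scl_range: tuple[float, float] = (40.0, 285.0)
    max_recorded_scl: tuple[float, float] = (300.0, 300.0)  # (female, male)
    n_specimens: int = 25
    noise_sd: float = 0.005
    sampler: str = "uniform"  # or "size_biased"
    sex_size_shift: float = 0.0  # fractional female size advantage
    sex_shape_shift: np.ndarray | None = None  # flattened, added to females
    dimorphic: bool = False
    larger_sex: str | None = None
    base_shape: np.ndarray = field(default_factory=half_ellipsoid_shell)
    deformation_axis: np.ndarray | None = None

    def __post_init__(self) -> None:
        c, d, k, x0 = self.gompertz
        if d <= c:
            raise ValueError("Gompertz upper plateau d must exceed lower c")
        lo, hi = self.scl_range
        if not 0 < lo < hi:
            raise ValueError("scl_range must satisfy 0 < min < max")
        if hi > max(self.max_recorded_scl):
            raise ValueError("scl_range exceeds maximum recorded SCL")
        if self.deformation_axis is None:
            self.deformation_axis = elongation_axis(self.base_shape)
        axis = np.asarray(self.deformation_axis, dtype=float).ravel()
        if not math.isclose(float(np.linalg.norm(axis)), 1.0, rel_tol=1e-8):
            raise ValueError("deformation_axis must have unit norm")
        self.deformation_axis = axis

    def max_scl(self) -> float:
        if self.dimorphic and self.larger_sex == "male":
            return self.max_recorded_scl[1]
        if self.dimorphic and self.larger_sex == "female":
            return self.max_recorded_scl[0]
        return max(self.max_recorded_scl)


@dataclass
class GroundTruth:
    """Planted quantities a correct pipeline should recover."""

    species: str
    true_distance85_mm: float
    true_pct_of_max: float
    true_has_sex_effect: bool


def analytic_distance85(
    g_params: tuple[float, float, float, float],
    x_min: float,
    x_max: float,
    ratio: float = 0.85,
) -> float:
    """Closed-form solution of (g(x) - g(x_min)) / (g(x_max) - g(x_min)) =
    ratio for a Gompertz g.  Because shape moves linearly along a fixed axis,
    the Procrustes-distance fraction equals the score fraction."""
    c, d, k, x0 = g_params
    # Work with complements via expm1/log1p so plateaus near 0 and 1 stay
    # accurate: with E(x) = exp(-u), u = exp(-k(x - x0)),
    #   1 - target = (1 - ratio)(1 - E_min) + ratio (1 - E_max).
    u_min = math.exp(min(-k * (x_min - x0), 700.0))
    u_max = math.exp(min(-k * (x_max - x0), 700.0))
    a = -math.expm1(-u_min)  # 1 - E(x_min)
    b = -math.expm1(-u_max)  # 1 - E(x_max)
    one_minus_target = min(max((1.0 - ratio) * a + ratio * b, 1e-300), 1.0 - 1e-15)
    u_t = -math.log1p(-one_minus_target)
    return x0 - math.log(u_t) / k


def profile_with_target_pct(
    species: str,
    target_pct: float,
    k: float = 0.02,
    scl_range: tuple[float, float] = (40.0, 285.0),
    max_recorded: float = 300.0,
    **kwargs,
) -> SpeciesProfile:
    """Build a profile whose analytic 85%-distance threshold lands at
    ``target_pct`` percent of the maximum recorded SCL, by solving for the
    Gompertz inflection point x0."""
    target_mm = target_pct / 100.0 * max_recorded
    lo = scl_range[0]

    def gap(x0: float) -> float:
        return (
            analytic_distance85((0.0, 1.0, k, x0), lo, max_recorded) - target_mm
        )

    x0 = optimize.brentq(gap, lo - 10.0 / k, max_recorded + 10.0 / k, xtol=1e-10)
    return SpeciesProfile(
        species=species,
        gompertz=(0.0, kwargs.pop("d", 0.12), k, x0),
        scl_range=scl_range,
        max_recorded_scl=(max_recorded, max_recorded),
        **kwargs,
    )


def _random_rotation(rng: np.random.Generator) -> np.ndarray:
    a = rng.normal(size=(3, 3))
    q, r = np.linalg.qr(a)
    q *= np.sign(np.diag(r))
    if np.linalg.det(q) < 0:
        q[:, 0] = -q[:, 0]
    return q


def generate_species(
    profile: SpeciesProfile, seed
) -> tuple[SpeciesDataset, GroundTruth]:
    """Draw one species' growth series.

    SCL values come from the profile's sampler (``"size_biased"`` skews
    toward large specimens, mimicking museum collections).  Each shape is the
    base deformed by g(SCL) along the deformation axis, with sex terms and
    isotropic noise, then randomly rotated, translated and scaled so the raw
    coordinates carry an arbitrary digitising frame; the scale is chosen so
    the landmark-1-to-12 distance equals the specimen's SCL in mm.
    """
    if profile.n_specimens < 2:
        raise SampleSizeError("need at least 2 specimens per species")
    rng = np.random.default_rng(seed)
    n = profile.n_specimens
    lo, hi = profile.scl_range
    if profile.sampler == "uniform":
        scl = rng.uniform(lo, hi, size=n)
    elif profile.sampler == "size_biased":
        scl = lo + (hi - lo) * rng.beta(2.0, 1.2, size=n)
    else:
        raise ValueError(f"unknown sampler {profile.sampler!r}")
    sex = rng.choice(["female", "male"], size=n)
    if profile.sex_size_shift:
        female = sex == "female"
        scl[female] = np.minimum(
            scl[female] * (1.0 + profile.sex_size_shift),
            profile.max_recorded_scl[0],
        )

    base_flat = profile.base_shape.ravel()
    axis = profile.deformation_axis
    c, d, k, x0 = profile.gompertz
    g = gompertz(scl, c, d, k, x0)

    specimens = []
    for i in range(n):
        flat = base_flat + g[i] * axis
        if profile.sex_shape_shift is not None and sex[i] == "female":
            flat = flat + np.asarray(profile.sex_shape_shift, dtype=float).ravel()
        shape = flat.reshape(-1, 3)
        shape = shape + rng.normal(0.0, profile.noise_sd, size=shape.shape)
        span = np.linalg.norm(shape[ANTERIOR_IDX] - shape[POSTERIOR_IDX])
        shape = shape * (scl[i] / span)
        shape = shape @ _random_rotation(rng) + rng.uniform(-500, 500, size=3)
        sid = f"{profile.species}_{i:03d}"
        specimens.append(
            (
                LandmarkConfig(sid, shape),
                SpecimenRecord(sid, profile.species, sex[i], float(scl[i])),
            )
        )

    x_max = profile.max_scl()
    t85 = analytic_distance85(profile.gompertz, lo, x_max)
    truth = GroundTruth(
        species=profile.species,
        true_distance85_mm=t85,
        true_pct_of_max=100.0 * t85 / x_max,
        true_has_sex_effect=profile.sex_shape_shift is not None,
    )
    return SpeciesDataset(profile.species, specimens), truth


def generate_panel(
    profiles: list[SpeciesProfile], seed
) -> tuple[list[SpeciesDataset], list[GroundTruth]]:
    """Generate a multi-species panel with independent per-species streams
    (adding a species does not perturb the others' draws)."""
    if not profiles:
        raise ValueError("need at least one profile")
    names = [p.species for p in profiles]
    if len(set(names)) != len(names):
        raise IntegrityError("duplicate species names in panel")
    import zlib

    datasets, truths = [], []
    for p in profiles:
        child = np.random.SeedSequence(
            [int(seed), zlib.crc32(p.species.encode()) & 0x7FFFFFFF]
        )
        ds, gt = generate_species(p, child)
        datasets.append(ds)
        truths.append(gt)
    return datasets, truths


def max_size_table_for(profiles: list[SpeciesProfile]) -> MaxSizeTable:
    return MaxSizeTable.from_records(
        [(p.species, p.max_recorded_scl[0], p.max_recorded_scl[1]) for p in profiles]
    )


def write_panel(
    datasets: list[SpeciesDataset],
    truths: list[GroundTruth],
    profiles: list[SpeciesProfile],
    out_dir: str | Path,
    landmark_format: str = "tps",
) -> dict[str, Path]:
    """Write a panel in the pipeline's input formats: landmarks (TPS or long
    CSV), metadata TSV, max-size TSV and ground_truth.json."""
    out = Path(out_dir)
    out.mkdir(parents=True, exist_ok=True)
    configs = [c for ds in datasets for c in ds.configs()]
    records = [r for ds in datasets for r in ds.records()]
    lm_path = out / ("landmarks.tps" if landmark_format == "tps" else "landmarks.csv")
    write_landmarks(configs, lm_path, format=landmark_format)
    meta_path = out / "metadata.tsv"
    write_metadata(records, meta_path)
    max_path = out / "max_sizes.tsv"
    max_size_table_for(profiles).to_tsv(max_path)
    gt_path = out / "ground_truth.json"
    gt_path.write_text(
        json.dumps(
            {
                t.species: {
                    "true_distance85_mm": t.true_distance85_mm,
                    "true_pct_of_max": t.true_pct_of_max,
                    "true_has_sex_effect": t.true_has_sex_effect,
                }
                for t in truths
            },
            indent=2,
        )
    )
    return {
        "landmarks": lm_path,
        "metadata": meta_path,
        "max_sizes": max_path,
        "ground_truth": gt_path,
    }


def default_panel_profiles(
    n_species: int = 10,
    pct_low: float = 55.0,
    pct_high: float = 75.0,
    n_specimens: int = 25,
    noise_sd: float = 0.005,
    axis_spread: float = 0.5,
) -> list[SpeciesProfile]:
    """Panel of species whose planted 85%-distance thresholds span
    ``pct_low``-``pct_high`` percent of the maximum recorded SCL.

    All species share the juvenile base shape but each gets its own
    deformation axis — the common elongate-and-narrow trend blended with a
    fixed species-specific component of relative weight ``axis_spread`` —
    so juveniles are similar across species while adults diverge, the
    structure real ontogenetic shell data show.  The axes are part of the
    panel definition (fixed per species), not of the sampling randomness.
    """
    targets = np.linspace(pct_low, pct_high, n_species)
    base = half_ellipsoid_shell()
    common = elongation_axis(base)
    profiles = []
    for i, t in enumerate(targets):
        rng = np.random.default_rng(np.random.SeedSequence([0xA11CE, i]))
        own = orthogonalize_to_similarity(rng.normal(size=base.size), base)
        axis = orthogonalize_to_similarity(common + axis_spread * own, base)
        profiles.append(
            profile_with_target_pct(
                f"species_{i + 1:02d}",
                float(t),
                n_specimens=n_specimens,
                noise_sd=noise_sd,
                base_shape=base,
                deformation_axis=axis,
            )
        )
    return profiles
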