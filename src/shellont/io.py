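"""Reading, writing and filtering of landmark datasets.

Landmark configurations are exchanged in two plain-text formats:

* **TPS** — blocks of the form ``LM3=<K>`` followed by K lines of
  ``x y z`` coordinates and an ``ID=<specimen>`` line.  This is the 3D dialect
  of the classic thin-plate-spline landmark file.
* **long CSV** — columns ``specimen_id, landmark_index, x, y, z`` with
  1-based landmark indices.

Specimen metadata travels in a TSV/CSV with columns
``specimen_id, species, sex, scl_mm`` where *scl_mm* is straight carapace
length in millimetres.  Per-species maximum recorded straight carapace
lengths (one row per species, separate female and male records) come from a
TSV with columns ``species, max_scl_female_mm, max_scl_male_mm``.

Landmark indices are 1-based in every user-facing interface; arrays are
0-indexed internally.
"""

from __future__ import annotations

import math
import warnings
from dataclasses import dataclass, field
from pathlib import Path
from typing import Iterable, Literal, Sequence

import numpy as np
import pandas as pd

from .exceptions import (
    DimensionError,
    FormatError,
    IntegrityError,
    SpeciesLookupError,
)

__all__ = [
    "LandmarkConfig",
    "SpecimenRecord",
    "MaxSizeTable",
    "SpeciesDataset",
    "SEX_NORMALIZATION",
    "read_landmarks",
    "write_landmarks",
    "read_metadata",
    "write_metadata",
    "read_max_size_table",
    "scl_from_landmarks",
    "filter_ontogenetic_series",
]

#: Canonical sex vocabulary.  Anything not listed maps to ``"unknown"``;
#: unsexed museum specimens are common and never an error.
SEX_NORMALIZATION: dict[str, str] = {
    "f": "female",
    "female": "female",
    "m": "male",
    "male": "male",
    "u": "unknown",
    "unknown": "unknown",
    "": "unknown",
}


@dataclass(frozen=True)
class LandmarkConfig:
    """One specimen's landmark configuration in original digitising space."""

    specimen_id: str
    coords: np.ndarray  # (K, 3), millimetres

    def __post_init__(self) -> None:
        coords = np.asarray(self.coords, dtype=float)
        if coords.ndim != 2 or coords.shape[1] != 3:
            raise DimensionError(
                f"{self.specimen_id}: coords must be (K, 3), got {coords.shape}"
            )
        if coords.shape[0] < 3:
            raise DimensionError(f"{self.specimen_id}: need at least 3 landmarks")
        if not np.all(np.isfinite(coords)):
            raise DimensionError(f"{self.specimen_id}: non-finite coordinates")
        object.__setattr__(self, "coords", coords)

    @property
    def k(self) -> int:
        return self.coords.shape[0]


@dataclass
class SpecimenRecord:
    """Metadata for one specimen."""

    specimen_id: str
    species: str
    sex: str = "unknown"
    scl_mm: float | None = None

    def __post_init__(self) -> None:
        self.sex = SEX_NORMALIZATION.get(str(self.sex).strip().lower(), "unknown")
        if self.scl_mm is not None:
            if isinstance(self.scl_mm, float) and math.isnan(self.scl_mm):
                self.scl_mm = None
            elif self.scl_mm <= 0:
                raise ValueError(
                    f"{self.specimen_id}: scl_mm must be positive, got {self.scl_mm}"
                )


@dataclass
class MaxSizeTable:
    """Maximum recorded straight carapace length per species and sex (mm)."""

    table: pd.DataFrame  # index: species; columns: max_scl_female_mm, max_scl_male_mm

    REQUIRED = ("max_scl_female_mm", "max_scl_male_mm")

    def __post_init__(self) -> None:
        df = self.table
        if df.index.has_duplicates:
            dupes = df.index[df.index.duplicated()].tolist()
            raise IntegrityError(f"duplicate species in max-size table: {dupes}")
        for col in self.REQUIRED:
            if col not in df.columns:
                raise FormatError(f"max-size table missing column {col!r}")
            if (df[col] <= 0).any():
                raise ValueError(f"non-positive values in {col}")

    @classmethod
    def from_records(cls, rows: Iterable[tuple[str, float, float]]) -> "MaxSizeTable":
        df = pd.DataFrame(
            rows, columns=["species", "max_scl_female_mm", "max_scl_male_mm"]
        ).set_index("species")
        return cls(df)

    def max_for(self, species: str, sex: str = "both") -> float:
        """Maximum recorded SCL; ``sex='both'`` returns the species record
        (the larger of the two sexes)."""
        if species not in self.table.index:
            raise SpeciesLookupError(f"species {species!r} not in max-size table")
        row = self.table.loc[species]
        if sex == "female":
            return float(row["max_scl_female_mm"])
        if sex == "male":
            return float(row["max_scl_male_mm"])
        return float(row.max())

    def to_tsv(self, path: str | Path) -> None:
        self.table.to_csv(path, sep="\t")


@dataclass
class SpeciesDataset:
    """All specimens of one species: paired landmark configs and records."""

    species: str
    specimens: list[tuple[LandmarkConfig, SpecimenRecord]] = field(default_factory=list)

    def __post_init__(self) -> None:
        for config, record in self.specimens:
            if record.species != self.species:
                raise IntegrityError(
                    f"record {record.specimen_id} labelled {record.species!r} "
                    f"inside dataset {self.species!r}"
                )
        ks = {c.k for c, _ in self.specimens}
        if len(ks) > 1:
            raise DimensionError(
                f"{self.species}: mixed landmark counts {sorted(ks)}"
            )

    @property
    def n(self) -> int:
        return len(self.specimens)

    def scl_values(self) -> np.ndarray:
        return np.array(
            [r.scl_mm if r.scl_mm is not None else np.nan for _, r in self.specimens]
        )

    def configs(self) -> list[LandmarkConfig]:
        return [c for c, _ in self.specimens]

    def records(self) -> list[SpecimenRecord]:
        return [r for _, r in self.specimens]


# ---------------------------------------------------------------------------
# Landmark I/O
# ---------------------------------------------------------------------------

def read_landmarks(
    path: str | Path, format: Literal["tps", "csv-long"] | None = None
) -> list[LandmarkConfig]:
    """Read landmark configurations from a TPS or long-format CSV file.

    The format is inferred from the file extension when not given
    (``.tps`` -> TPS, else CSV).  All specimens must share the same landmark
    count K.
    """
    path = Path(path)
    if format is None:
        format = "tps" if path.suffix.lower() == ".tps" else "csv-long"
    if format == "tps":
        configs = _read_tps(path)
    elif format == "csv-long":
        configs = _read_csv_long(path)
    else:
        raise ValueError(f"unknown landmark format {format!r}")
    _validate_uniform_k(configs)
    return configs


def _read_tps(path: Path) -> list[LandmarkConfig]:
    configs: list[LandmarkConfig] = []
    lines = Path(path).read_text().splitlines()
    i = 0
    while i < len(lines):
        line = lines[i].strip()
        if not line:
            i += 1
            continue
        if not line.upper().startswith("LM3="):
            raise FormatError(f"expected 'LM3=' block, got {line!r}", line=i + 1)
        try:
            k = int(line.split("=", 1)[1])
        except ValueError:
            raise FormatError(f"bad landmark count in {line!r}", line=i + 1) from None
        coords = np.empty((k, 3))
        for j in range(k):
            i += 1
            if i >= len(lines):
                raise FormatError("unexpected end of file inside block", line=i)
            parts = lines[i].split()
            if len(parts) != 3:
                raise FormatError(
                    f"expected 3 coordinates, got {len(parts)}", line=i + 1
                )
            try:
                coords[j] = [float(p) for p in parts]
            except ValueError:
                raise FormatError(f"bad coordinate {lines[i]!r}", line=i + 1) from None
        i += 1
        if i >= len(lines) or not lines[i].strip().upper().startswith("ID="):
            raise FormatError("missing ID= line after coordinates", line=i + 1)
        specimen_id = lines[i].split("=", 1)[1].strip()
        configs.append(LandmarkConfig(specimen_id, coords))
        i += 1
    return configs


def _read_csv_long(path: Path) -> list[LandmarkConfig]:
    df = pd.read_csv(path)
    required = {"specimen_id", "landmark_index", "x", "y", "z"}
    missing = required - set(df.columns)
    if missing:
        raise FormatError(f"long CSV missing columns {sorted(missing)}")
    configs = []
    for specimen_id, group in df.groupby("specimen_id", sort=False):
        group = group.sort_values("landmark_index")
        idx = group["landmark_index"].to_numpy()
        if not np.array_equal(idx, np.arange(1, len(idx) + 1)):
            raise FormatError(
                f"{specimen_id}: landmark_index must be 1..K without gaps"
            )
        configs.append(
            LandmarkConfig(str(specimen_id), group[["x", "y", "z"]].to_numpy(float))
        )
    return configs


def _validate_uniform_k(configs: Sequence[LandmarkConfig]) -> None:
    if not configs:
        return
    k0 = configs[0].k
    for c in configs:
        if c.k != k0:
            raise DimensionError(
                f"specimen {c.specimen_id} has {c.k} landmarks, expected {k0}"
            )


def write_landmarks(
    configs: Sequence[LandmarkConfig],
    path: str | Path,
    format: Literal["tps", "csv-long"] | None = None,
) -> None:
    """Write landmark configurations; inverse of :func:`read_landmarks`."""
    path = Path(path)
    if format is None:
        format = "tps" if path.suffix.lower() == ".tps" else "csv-long"
    if format == "tps":
        with open(path, "w") as fh:
            for c in configs:
                fh.write(f"LM3={c.k}\n")
                for row in c.coords:
                    fh.write(f"{row[0]:.12g} {row[1]:.12g} {row[2]:.12g}\n")
                fh.write(f"ID={c.specimen_id}\n")
    else:
        frames = []
        for c in configs:
            frames.append(
                pd.DataFrame(
                    {
                        "specimen_id": c.specimen_id,
                        "landmark_index": np.arange(1, c.k + 1),
                        "x": c.coords[:, 0],
                        "y": c.coords[:, 1],
                        "z": c.coords[:, 2],
                    }
                )
            )
        pd.concat(frames, ignore_index=True).to_csv(path, index=False)


# ---------------------------------------------------------------------------
# Metadata I/O
# ---------------------------------------------------------------------------

def read_metadata(path: str | Path) -> list[SpecimenRecord]:
    """Read specimen metadata (TSV or CSV, sniffed)."""
    df = pd.read_csv(path, sep=None, engine="python")
    required = {"specimen_id", "species", "sex", "scl_mm"}
    missing = required - set(df.columns)
    if missing:
        raise FormatError(f"metadata missing columns {sorted(missing)}")
    ids = df["specimen_id"].astype(str)
    if ids.duplicated().any():
        dupes = ids[ids.duplicated()].tolist()
        raise IntegrityError(f"duplicate specimen_id: {dupes}")
    records = []
    for _, row in df.iterrows():
        scl = row["scl_mm"]
        scl = None if pd.isna(scl) else float(scl)
        sex = "" if pd.isna(row["sex"]) else str(row["sex"])
        records.append(
            SpecimenRecord(str(row["specimen_id"]), str(row["species"]), sex, scl)
        )
    return records


def write_metadata(records: Sequence[SpecimenRecord], path: str | Path) -> None:
    pd.DataFrame(
        {
            "specimen_id": [r.specimen_id for r in records],
            "species": [r.species for r in records],
            "sex": [r.sex for r in records],
            "scl_mm": [r.scl_mm for r in records],
        }
    ).to_csv(path, sep="\t", index=False)


def read_max_size_table(path: str | Path) -> MaxSizeTable:
    df = pd.read_csv(path, sep=None, engine="python")
    if "species" not in df.columns:
        raise FormatError("max-size table missing 'species' column")
    return MaxSizeTable(df.set_index("species"))


# ---------------------------------------------------------------------------
# Derived quantities and filtering
# ---------------------------------------------------------------------------

def scl_from_landmarks(
    config: LandmarkConfig, anterior_idx: int = 1, posterior_idx: int = 12
) -> float:
    """Straight carapace length as the distance between the anteriormost and
    posteriormost shell landmarks (1-based indices; defaults 1 and 12)."""
    for idx in (anterior_idx, posterior_idx):
        if not 1 <= idx <= config.k:
            raise IndexError(
                f"landmark index {idx} out of range 1..{config.k} "
                f"for {config.specimen_id}"
            )
    d = float(
        np.linalg.norm(config.coords[anterior_idx - 1] - config.coords[posterior_idx - 1])
    )
    if d == 0.0:
        warnings.warn(
            f"{config.specimen_id}: anterior and posterior landmarks coincide",
            stacklevel=2,
        )
    return d


def filter_ontogenetic_series(
    datasets: Sequence[SpeciesDataset],
    min_n: int = 8,
    min_fold: float = 3.0,
    exclude_species: Sequence[str] = (),
    max_table: MaxSizeTable | None = None,
    exclude_specimens: Sequence[str] = (),
    fill_scl_specimens: Sequence[str] = (),
) -> tuple[list[SpeciesDataset], pd.DataFrame]:
    """Subset species to usable ontogenetic series.

    Keeps a species when it retains at least ``min_n`` specimens and its
    largest specimen is at least ``min_fold`` times the smallest
    (max(SCL)/min(SCL) >= min_fold, inclusive).  Species named in
    ``exclude_species`` are dropped outright; specimens named in
    ``exclude_specimens`` are dropped when their SCL exceeds the species'
    maximum recorded SCL in ``max_table`` (suspected misidentifications).
    Specimens named in ``fill_scl_specimens`` get a missing SCL filled from
    the anterior/posterior landmark distance before any check.

    Returns the surviving datasets plus a filter log (``entity, action,
    reason`` rows) recording every drop.
    """
    log_rows: list[tuple[str, str, str]] = []
    fill_set = set(fill_scl_specimens)
    drop_candidates = set(exclude_specimens)
    excluded_species = set(exclude_species)
    out: list[SpeciesDataset] = []

    for ds in datasets:
        if ds.species in excluded_species:
            log_rows.append((ds.species, "drop_species", "named exclusion"))
            continue
        kept: list[tuple[LandmarkConfig, SpecimenRecord]] = []
        for config, record in ds.specimens:
            if record.scl_mm is None and record.specimen_id in fill_set:
                record = SpecimenRecord(
                    record.specimen_id,
                    record.species,
                    record.sex,
                    scl_from_landmarks(config),
                )
                log_rows.append(
                    (record.specimen_id, "fill_scl", "from landmarks 1-12")
                )
            if record.scl_mm is None:
                raise ValueError(
                    f"{record.specimen_id}: missing SCL; fill it or list the "
                    "specimen in fill_scl_specimens"
                )
            if record.specimen_id in drop_candidates:
                if max_table is None:
                    raise SpeciesLookupError(
                        "oversize check requested but no max-size table given"
                    )
                max_scl = max_table.max_for(record.species, "both")
                if record.scl_mm > max_scl:
                    log_rows.append(
                        (
                            record.specimen_id,
                            "drop_specimen",
                            f"SCL {record.scl_mm:.1f} mm exceeds species "
                            f"maximum {max_scl:.1f} mm",
                        )
                    )
                    continue
            kept.append((config, record))
        if len(kept) < min_n:
            log_rows.append(
                (ds.species, "drop_species", f"n={len(kept)} < min_n={min_n}")
            )
            continue
        scl = np.array([r.scl_mm for _, r in kept])
        fold = scl.max() / scl.min()
        if fold < min_fold:
            log_rows.append(
                (
                    ds.species,
                    "drop_species",
                    f"fold change {fold:.2f} < min_fold={min_fold}",
                )
            )
            continue
        out.append(SpeciesDataset(ds.species, kept))

    log = pd.DataFrame(log_rows, columns=["entity", "action", "reason"])
    return out, log
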