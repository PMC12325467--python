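import numpy as np
import pytest

from shellont.io import LandmarkConfig, SpecimenRecord, SpeciesDataset, MaxSizeTable
from shellont.simulate import (
    SpeciesProfile,
    generate_species,
    half_ellipsoid_shell,
    elongation_axis,
)


@pytest.fixture
def rng():
    return np.random.default_rng(20240901)


@pytest.fixture
def base_shell():
    return half_ellipsoid_shell()


@pytest.fixture
def shell_axis(base_shell):
    return elongation_axis(base_shell)


@pytest.fixture
def random_configs(rng):
    """Six random 12-landmark configurations."""
    return [rng.normal(size=(12, 3)) for _ in range(6)]


@pytest.fixture
def quiet_species():
    """One synthetic species with mild noise, fixed seed."""
    profile = SpeciesProfile("quiet", noise_sd=0.004, n_specimens=24)
    return generate_species(profile, seed=7)


def make_dataset(species, scl_values, k=12, seed=0):
    """Small helper: a SpeciesDataset of random configs with given SCLs."""
    rng = np.random.default_rng(seed)
    specimens = []
    for i, scl in enumerate(scl_values):
        sid = f"{species}_{i}"
        specimens.append(
            (
                LandmarkConfig(sid, rng.normal(size=(k, 3))),
                SpecimenRecord(sid, species, "unknown", float(scl)),
            )
        )
    return SpeciesDataset(species, specimens)


@pytest.fixture
def toy_max_table():
    return MaxSizeTable.from_records(
        [("A", 200.0, 180.0), ("B", 150.0, 150.0), ("C", 140.0, 160.0)]
    )
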