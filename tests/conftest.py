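import pytest
from hypothesis import settings

from mitoperm.species_model import (
    SpeciesRecord,
    ThermoProtocol,
    load_reference_dataset,
)


settings.register_profile("deterministic", derandomize=True)
settings.load_profile("deterministic")


@pytest.fixture(scope="session")
def protocol() -> ThermoProtocol:
    return ThermoProtocol()


@pytest.fixture(scope="session")
def dataset():
    return load_reference_dataset()


@pytest.fixture
def toy_species() -> SpeciesRecord:
    """A small nonlinear two-mode species with both solvent energies."""
    return SpeciesRecord(
        name="toy",
        charge=1,
        mass=277.3,
        moments_of_inertia=(1500.0, 2500.0, 3500.0),
        frequencies=(100.0, 500.0),
        energy_by_solvent={"aqueous": -120.0, "apolar": -76.0},
    )
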