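"""Domain types, validation and the packaged reference dataset.

A :class:`SpeciesRecord` carries everything the RRHO machinery needs for one
chemical species: an electronic energy (including continuum-solvation terms)
per solvent, harmonic frequencies, and the geometry-derived constants for the
translational and rotational partition functions.  Energies are stored in
kJ mol^-1 relative to a per-record-declared common reference; every cycle in
this package only ever uses *differences*, so the absolute offset is
irrelevant and never interpreted.

The packaged reference dataset (:func:`load_reference_dataset`) contains the
published component free energies for water->hexane transfer, ion-pairing and
dimerisation of TPMP-derived species, and the per-reference pKa predictions
anchored to benzoic and phenylacetic acid.  Dimer energies are stored per
mole of monomer exactly as published, with an explicit ``per_monomer`` flag,
so no silent factor-of-two decision is made downstream.
"""

from __future__ import annotations

from dataclasses import dataclass, field
from importlib import resources
from typing import Literal, Mapping

import yaml
from pydantic import BaseModel, ConfigDict, Field, model_validator

AQUEOUS = "aqueous"
APOLAR = "apolar"

SOLVENT_LABELS = (AQUEOUS, APOLAR)


class SpeciesValidationError(ValueError):
    """A species record violates one of its invariants."""


class SpeciesRecord(BaseModel):
    """Thermochemical inputs for one chemical species.

    Parameters
    ----------
    name:
        Species label, unique within a dataset.
    charge:
        Net charge in elementary charges.
    n_monomers:
        1 for single species and ion pairs, 2 for self-complementary
        zwitterion dimers (energies of dimers are conventionally reported per
        mole of monomer).
    mass:
        Molecular mass in atomic mass units.
    moments_of_inertia:
        The three principal moments in amu * Angstrom^2.  All zero denotes a
        monatomic species; exactly one (near-)zero value denotes a linear
        species.
    symmetry_number:
        Rotational symmetry number (1 for the typical low-symmetry TPP
        species).
    frequencies:
        Harmonic wavenumbers in cm^-1.  All must be strictly positive:
        records with imaginary modes are not minima and are rejected.
    energy_by_solvent:
        Solvent label -> electronic energy including electrostatic and
        non-electrostatic solvation, kJ mol^-1 on a declared common
        reference.
    """

    model_config = ConfigDict(frozen=True)

    name: str
    charge: int = 0
    n_monomers: int = 1
    mass: float = Field(gt=0.0)
    moments_of_inertia: tuple[float, float, float] = (0.0, 0.0, 0.0)
    symmetry_number: int = Field(default=1, ge=1)
    frequencies: tuple[float, ...] = ()
    energy_by_solvent: dict[str, float] = Field(default_factory=dict)

    @model_validator(mode="after")
    def _check_invariants(self) -> "SpeciesRecord":
        if self.n_monomers not in (1, 2):
            raise SpeciesValidationError(
                f"species {self.name!r}: n_monomers must be 1 or 2, "
                f"got {self.n_monomers}"
            )
        for i, nu in enumerate(self.frequencies):
            if nu <= 0.0:
                raise SpeciesValidationError(
                    f"species {self.name!r}: mode {i} has wavenumber "
                    f"{nu} cm^-1; imaginary/zero modes indicate the structure "
                    "is not a minimum"
                )
        if any(m < 0.0 for m in self.moments_of_inertia):
            raise SpeciesValidationError(
                f"species {self.name!r}: negative principal moment of inertia"
            )
        return self

    def energy(self, solvent: str) -> float:
        """Electronic + solvation energy in ``solvent`` (kJ mol^-1)."""
        try:
            return self.energy_by_solvent[solvent]
        except KeyError:
            raise SpeciesValidationError(
                f"species {self.name!r}: no energy for solvent "
                f"{solvent!r} (have {sorted(self.energy_by_solvent)})"
            ) from None


def validate_species(
    record: SpeciesRecord,
    required_solvents: tuple[str, ...] = (),
) -> SpeciesRecord:
    """Re-check the invariants of ``record`` and return it unchanged.

    Pydantic enforces the invariants at construction; this re-entry point
    exists so pipelines can assert validity of records arriving from files
    or generators, and additionally require specific solvents.
    """
    SpeciesRecord.model_validate(record.model_dump())
    for solvent in required_solvents:
        if solvent not in record.energy_by_solvent:
            raise SpeciesValidationError(
                f"species {record.name!r}: missing energy for solvent "
                f"{solvent!r}"
            )
    return record


class SolventContext(BaseModel):
    """Metadata describing one of the two phases of the partition model.

    No continuum computation is performed here: permittivity and refractive
    index are descriptive metadata.  Water models the aqueous phase; hexane
    is the apolar stand-in for the hydrophobic membrane core.
    """

    model_config = ConfigDict(frozen=True)

    label: Literal["aqueous", "apolar"]
    relative_permittivity: float = Field(ge=1.0)
    refractive_index: float = Field(gt=0.0)


#: Water and hexane as conventionally parameterised in continuum models.
DEFAULT_SOLVENTS: dict[str, SolventContext] = {
    AQUEOUS: SolventContext(
        label=AQUEOUS, relative_permittivity=78.3553, refractive_index=1.3334
    ),
    APOLAR: SolventContext(
        label=APOLAR, relative_permittivity=1.8819, refractive_index=1.3749
    ),
}


class ThermoProtocol(BaseModel):
    """Thermodynamic conventions for a free-energy evaluation.

    Defaults correspond to the standard thermochemistry protocol:
    T = 298.15 K, gas standard pressure p = 100 kPa, solution standard
    concentration c* = 1 mol L^-1, unscaled frequencies with a 100 cm^-1
    quasi-harmonic floor.  The relative-pKa protocol uses
    ``frequency_scale = 0.972`` with the same floor.

    ``external_dof`` exists for degenerate/diagnostic evaluations: when
    False, translational and rotational contributions are suppressed and the
    liberational term reduces to the bare standard-state shift.
    """

    model_config = ConfigDict(frozen=True)

    temperature: float = Field(default=298.15, gt=0.0)
    pressure_standard: float = Field(default=100_000.0, gt=0.0)
    concentration_standard: float = Field(default=1.0, gt=0.0)
    frequency_scale: float = Field(default=1.0, gt=0.0)
    frequency_floor: float = Field(default=100.0, ge=0.0)
    external_dof: bool = True


#: Frequency handling used for the relative-pKa route.
PKA_PROTOCOL = ThermoProtocol(frequency_scale=0.972, frequency_floor=100.0)


@dataclass(frozen=True)
class CycleComponents:
    """Published component free energies for one species or aggregate.

    All values in kJ mol^-1; dimer rows are per mole of monomer
    (``per_monomer`` is True).  ``combined_printed`` and
    ``preference_printed`` are the published derived columns, kept separate
    from anything this package recomputes.
    """

    label: str
    charge: int
    n_monomers: int
    transfer_aq_to_hex: float
    per_monomer: bool = False
    pairing_aq: float | None = None
    combined_printed: float | None = None
    preference_printed: float | None = None
    baseline: str | None = None
    counter_ion: bool = False


@dataclass(frozen=True)
class ReferenceDataset:
    """The packaged reference values consumed by the cycle and pKa modules."""

    cycles: dict[str, CycleComponents]
    pka_predictions: dict[str, dict[str, float]]
    pka_experiment: dict[str, float]
    pka_summaries: dict[str, tuple[float, float]]
    standard_state_shift: float
    notes: dict[str, dict] = field(default_factory=dict)

    def __getitem__(self, label: str) -> CycleComponents:
        return self.cycles[label]

    @property
    def free_species(self) -> dict[str, CycleComponents]:
        return {
            k: v for k, v in self.cycles.items() if v.pairing_aq is None
        }

    @property
    def aggregates(self) -> dict[str, CycleComponents]:
        return {
            k: v for k, v in self.cycles.items() if v.pairing_aq is not None
        }


def _load_yaml_resource(name: str) -> dict:
    path = resources.files("mitoperm.data").joinpath(name)
    with path.open("r", encoding="utf-8") as fh:
        return yaml.safe_load(fh)


def load_reference_dataset() -> ReferenceDataset:
    """Load the packaged component free energies and pKa reference table.

    Returns
    -------
    ReferenceDataset
        ``cycles`` maps species/aggregate labels (e.g. ``"TPMP+"``,
        ``"TPMP+.Cl-"``, ``"(TPMP+-CH2COO-)2-conf2"``) to their published
        transfer/pairing components; ``pka_predictions`` maps compounds to
        per-reference-acid predicted pKa values, with the experimental
        anchors in ``pka_experiment``.
    """
    raw_cycles = _load_yaml_resource("reference_cycles.yaml")
    raw_pka = _load_yaml_resource("reference_pka.yaml")

    cycles: dict[str, CycleComponents] = {}
    for label, entry in raw_cycles["species"].items():
        cycles[label] = CycleComponents(
            label=label,
            charge=entry["charge"],
            n_monomers=entry.get("n_monomers", 1),
            transfer_aq_to_hex=float(entry["transfer_aq_to_apolar"]),
            counter_ion=entry.get("counter_ion", False),
        )
    for label, entry in raw_cycles["aggregates"].items():
        cycles[label] = CycleComponents(
            label=label,
            charge=entry["charge"],
            n_monomers=entry.get("n_monomers", 1),
            per_monomer=entry.get("per_monomer", False),
            transfer_aq_to_hex=float(entry["transfer_aq_to_apolar"]),
            pairing_aq=float(entry["pairing_aq"]),
            combined_printed=float(entry["combined_printed"]),
            preference_printed=float(entry["preference_printed"]),
            baseline=entry["baseline"],
        )

    summaries = {
        k: (float(v["mean"]), float(v["half_range"]))
        for k, v in raw_pka.get("summaries_printed", {}).items()
    }
    return ReferenceDataset(
        cycles=cycles,
        pka_predictions={
            comp: {ref: float(x) for ref, x in preds.items()}
            for comp, preds in raw_pka["predictions"].items()
        },
        pka_experiment={
            name: float(entry["pka_experimental"])
            for name, entry in raw_pka["references"].items()
        },
        pka_summaries=summaries,
        standard_state_shift=float(
            raw_cycles["standard_state_shift_printed"]
        ),
        notes=raw_cycles.get("notes", {}),
    )


def reference_dataset_as_mapping(dataset: ReferenceDataset) -> dict:
    """Serialise a :class:`ReferenceDataset` back to plain mappings.

    Inverse of the YAML layout read by :func:`load_reference_dataset`;
    used by the round-trip tests and the ``fixture`` CLI subcommand.
    """
    species: dict[str, dict] = {}
    aggregates: dict[str, dict] = {}
    for label, c in dataset.cycles.items():
        if c.pairing_aq is None:
            species[label] = {
                "charge": c.charge,
                "n_monomers": c.n_monomers,
                "transfer_aq_to_apolar": c.transfer_aq_to_hex,
            }
            if c.counter_ion:
                species[label]["counter_ion"] = True
        else:
            aggregates[label] = {
                "charge": c.charge,
                "n_monomers": c.n_monomers,
                "per_monomer": c.per_monomer,
                "baseline": c.baseline,
                "transfer_aq_to_apolar": c.transfer_aq_to_hex,
                "pairing_aq": c.pairing_aq,
                "combined_printed": c.combined_printed,
                "preference_printed": c.preference_printed,
            }
    return {
        "standard_state_shift_printed": dataset.standard_state_shift,
        "species": species,
        "aggregates": aggregates,
        "notes": dataset.notes,
    }


__all__ = [
    "AQUEOUS",
    "APOLAR",
    "SOLVENT_LABELS",
    "DEFAULT_SOLVENTS",
    "PKA_PROTOCOL",
    "SpeciesRecord",
    "SpeciesValidationError",
    "SolventContext",
    "ThermoProtocol",
    "CycleComponents",
    "ReferenceDataset",
    "validate_species",
    "load_reference_dataset",
    "reference_dataset_as_mapping",
]
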