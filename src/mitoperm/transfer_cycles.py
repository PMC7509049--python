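"""Water->apolar transfer, ion-pairing and dimerisation cycles.

A lipophilic ion can cross the apolar core of a membrane either as the free
ion or together with a counter-ion (or a second, self-complementary
zwitterion) as a net-neutral aggregate.  The two routes are compared through
a thermodynamic cycle built from three component free energies, all in the
Ben-Naim ``*`` standard state:

* ``transfer``   -- dt_G*(S, aq -> apolar), the difference in solvation free
  energy of S between the two phases;
* ``pairing``    -- dip_G*(aq), the aqueous association free energy,
  including the particle-number standard-state term;
* ``combined``   -- pairing + transfer of the aggregate, the cost of
  crossing as the pair/dimer starting from free aqueous ions;
* ``preference`` -- combined minus the transfer of the baseline free
  species; negative values mean the paired route is the cheaper way across.

Dimer energies follow the per-mole-of-monomer convention throughout.
"""

from __future__ import annotations

from dataclasses import dataclass
from typing import Mapping, Sequence

from pydantic import BaseModel, ConfigDict

from mitoperm.rrho_thermo import solution_free_energy, standard_state_shift
from mitoperm.species_model import (
    APOLAR,
    AQUEOUS,
    ReferenceDataset,
    SpeciesRecord,
    SpeciesValidationError,
    ThermoProtocol,
)


class CycleError(ValueError):
    """A cycle is ill-posed (charge imbalance, missing baseline, ...)."""


@dataclass(frozen=True)
class CycleRow:
    """One assembled row of the transfer/pairing summary (kJ mol^-1).

    ``combined``/``preference`` are recomputed from the components;
    ``combined_printed``/``preference_printed`` carry published values when
    the row comes from the reference dataset, so rounding discrepancies of
    the published derived columns stay visible instead of being silently
    overwritten.
    """

    label: str
    transfer: float
    pairing: float | None = None
    combined: float | None = None
    preference: float | None = None
    per_monomer: bool = False
    baseline: str | None = None
    combined_printed: float | None = None
    preference_printed: float | None = None


class PairingReaction(BaseModel):
    """An association reaction M + X -> [M.X] (or 2 Z -> Z2).

    ``reactants`` lists (species name, stoichiometric coefficient); the
    product has coefficient 1.  ``baseline_species`` names the free species
    whose lone transfer defines the crossing-preference comparison --
    conventionally the phosphonium-bearing species (the cation for
    cation.Cl- pairs, the zwitterion for zwitterion dimers and Na+ pairs).
    """

    model_config = ConfigDict(frozen=True)

    reactants: tuple[tuple[str, int], ...]
    product: str
    baseline_species: str | None = None

    @property
    def particle_number_change(self) -> int:
        """Signed sum of stoichiometric coefficients (products - reactants);
        -1 for A + B -> AB."""
        return 1 - sum(nu for _, nu in self.reactants)


def transfer_free_energy(
    species: SpeciesRecord,
    protocol: ThermoProtocol,
    *,
    per_monomer: bool = False,
) -> float:
    """dt_G*(S, aq -> apolar) = G*(S, apolar) - G*(S, aqueous), kJ mol^-1.

    Thermal RRHO terms cancel because the record shares one frequency list
    across solvents.  With ``per_monomer`` the result is divided by the
    record's monomer count (the dimer reporting convention).
    """
    dg = solution_free_energy(
        species, APOLAR, protocol
    ) - solution_free_energy(species, AQUEOUS, protocol)
    if per_monomer:
        dg /= species.n_monomers
    return dg


def pairing_free_energy(
    reaction: PairingReaction,
    free_energies: Mapping[str, float],
    protocol: ThermoProtocol,
    *,
    charges: Mapping[str, int] | None = None,
    per_monomer: bool = False,
    n_monomers_product: int = 1,
) -> float:
    """Aqueous association free energy dip_G*(aq), kJ mol^-1.

    ``G*(product) - sum nu_i G*(reactant_i)`` plus the particle-number
    standard-state term ``dG_conv * sum_i nu_i`` (signed coefficients,
    -1 for A + B -> AB, so association is *stabilised* by 8.0 kJ mol^-1 at
    the defaults).  When ``charges`` is supplied, charge conservation is
    enforced.  ``per_monomer`` divides by ``n_monomers_product`` per the
    dimer convention.
    """
    if charges is not None:
        q_react = sum(
            charges[name] * nu for name, nu in reaction.reactants
        )
        q_prod = charges[reaction.product]
        if q_react != q_prod:
            raise CycleError(
                f"charge imbalance in {reaction.product!r}: reactants carry "
                f"{q_react:+d}, product {q_prod:+d}"
            )
    try:
        raw = free_energies[reaction.product] - sum(
            nu * free_energies[name] for name, nu in reaction.reactants
        )
    except KeyError as exc:
        raise CycleError(f"missing aqueous free energy for {exc}") from None
    dg = raw + standard_state_shift(protocol) * reaction.particle_number_change
    if per_monomer:
        dg /= n_monomers_product
    return dg


def crossing_preference(combined: float, baseline_transfer: float) -> float:
    """Paired-route cost relative to the free species, kJ mol^-1.

    ``combined - baseline_transfer``; negative means crossing as the
    pair/dimer is thermodynamically preferred.  Both arguments must be on
    the same per-monomer basis.
    """
    return combined - baseline_transfer


def round_half_away(x: float) -> int:
    """Round to the nearest integer, halves away from zero (the convention
    of the published tables)."""
    import math

    return int(math.floor(x + 0.5)) if x >= 0 else int(math.ceil(x - 0.5))


def build_summary_table(dataset: ReferenceDataset) -> list[CycleRow]:
    """Assemble the four-column transfer/pairing summary from the packaged
    component free energies.

    Free-ion rows carry only a transfer; aggregate rows get
    ``combined = pairing + transfer`` and
    ``preference = combined - transfer(baseline)`` recomputed from the
    components, with the published derived values carried alongside.
    """
    rows: list[CycleRow] = []
    for label, comp in dataset.cycles.items():
        if comp.pairing_aq is None:
            rows.append(
                CycleRow(label=label, transfer=comp.transfer_aq_to_hex)
            )
            continue
        if comp.baseline is None or comp.baseline not in dataset.cycles:
            raise CycleError(
                f"aggregate {label!r} declares no known baseline species"
            )
        baseline_transfer = dataset.cycles[comp.baseline].transfer_aq_to_hex
        combined = comp.pairing_aq + comp.transfer_aq_to_hex
        rows.append(
            CycleRow(
                label=label,
                transfer=comp.transfer_aq_to_hex,
                pairing=comp.pairing_aq,
                combined=combined,
                preference=crossing_preference(combined, baseline_transfer),
                per_monomer=comp.per_monomer,
                baseline=comp.baseline,
                combined_printed=comp.combined_printed,
                preference_printed=comp.preference_printed,
            )
        )
    return rows


def summary_from_species(
    species: Mapping[str, SpeciesRecord],
    reactions: Sequence[PairingReaction],
    protocol: ThermoProtocol,
) -> list[CycleRow]:
    """Build summary rows from full species records and pairing reactions.

    The species-record route to the same table :func:`build_summary_table`
    produces from published components: aqueous free energies feed the
    pairing step, both solvents feed the transfers, and the baseline free
    species must be declared on every reaction.
    """
    g_aq = {
        name: solution_free_energy(rec, AQUEOUS, protocol)
        for name, rec in species.items()
    }
    charges = {name: rec.charge for name, rec in species.items()}
    rows: list[CycleRow] = []
    seen_in_pairs: set[str] = set()
    for rxn in reactions:
        if rxn.baseline_species is None:
            raise CycleError(
                f"reaction forming {rxn.product!r} declares no baseline "
                "free species"
            )
        product = species[rxn.product]
        per_monomer = product.n_monomers > 1
        pairing = pairing_free_energy(
            rxn,
            g_aq,
            protocol,
            charges=charges,
            per_monomer=per_monomer,
            n_monomers_product=product.n_monomers,
        )
        transfer = transfer_free_energy(
            product, protocol, per_monomer=per_monomer
        )
        baseline_transfer = transfer_free_energy(
            species[rxn.baseline_species], protocol
        )
        combined = pairing + transfer
        rows.append(
            CycleRow(
                label=rxn.product,
                transfer=transfer,
                pairing=pairing,
                combined=combined,
                preference=crossing_preference(combined, baseline_transfer),
                per_monomer=per_monomer,
                baseline=rxn.baseline_species,
            )
        )
        seen_in_pairs.add(rxn.product)
    for name, rec in species.items():
        if name not in seen_in_pairs:
            rows.append(
                CycleRow(
                    label=name,
                    transfer=transfer_free_energy(rec, protocol),
                )
            )
    return rows


def table_discrepancies(rows: Sequence[CycleRow]) -> dict[str, dict[str, float]]:
    """Integer-rounded recomputed-vs-published deviations per aggregate row.

    Deviations of +-1 kJ/mol reflect rounding of unprinted underlying
    values rather than assembly errors; the report keeps them visible.
    """
    out: dict[str, dict[str, float]] = {}
    for row in rows:
        if row.combined is None:
            continue
        entry: dict[str, float] = {}
        if row.combined_printed is not None:
            entry["combined"] = (
                round_half_away(row.combined) - row.combined_printed
            )
        if row.preference_printed is not None:
            entry["preference"] = (
                round_half_away(row.preference) - row.preference_printed
            )
        if entry:
            out[row.label] = entry
    return out


__all__ = [
    "CycleError",
    "CycleRow",
    "PairingReaction",
    "transfer_free_energy",
    "pairing_free_energy",
    "crossing_preference",
    "build_summary_table",
    "summary_from_species",
    "table_discrepancies",
    "round_half_away",
]
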