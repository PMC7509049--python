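"""Generators with analytically known answers for every pipeline stage.

Each generator inverts the forward computation it feeds: species records
are built by back-solving the electronic energy from a target solution free
energy, acid systems by back-solving the deprotonation free energy from a
target pKa, and flux scenarios come with the closed-form steady state of
the corresponding regime.  Recovery of the targets -- not chemical realism
-- is the design goal.  All randomness flows through one integer-seeded
:class:`numpy.random.Generator` so output is reproducible bit-for-bit.
"""

from __future__ import annotations

from dataclasses import dataclass
from typing import Mapping, Sequence

import numpy as np
from pydantic import BaseModel, ConfigDict, Field

from mitoperm.flux_simulator import (
    FluxScenario,
    InitialAmounts,
    RateParameters,
)
from mitoperm.pka_reference import AcidSystem, rt_ln10
from mitoperm.rrho_thermo import (
    adjust_frequencies,
    thermal_components,
)
from mitoperm.species_model import (
    APOLAR,
    AQUEOUS,
    SpeciesRecord,
    ThermoProtocol,
)


class GeneratorSpec(BaseModel):
    """Controls for :func:`make_harmonic_species`.

    ``target_transfers`` lists the water->apolar transfer free energies
    (kJ/mol) the generated species must reproduce exactly; one species per
    entry.  ``noise_scale`` perturbs the *aqueous baseline* free energies
    only, so targets are preserved under noise.
    """

    model_config = ConfigDict(frozen=True)

    seed: int
    target_transfers: tuple[float, ...] = (44.0,)
    n_modes: int = Field(default=6, ge=0)
    frequency_range: tuple[float, float] = (120.0, 3200.0)
    noise_scale: float = Field(default=0.0, ge=0.0)

    @property
    def n_species(self) -> int:
        return len(self.target_transfers)


def _random_record_shell(
    rng: np.random.Generator, name: str, spec: GeneratorSpec
) -> dict:
    lo, hi = spec.frequency_range
    if lo <= 0.0:
        raise ValueError(
            "frequency_range must be strictly positive: generated species "
            "must satisfy the no-imaginary-modes invariant"
        )
    return {
        "name": name,
        "charge": int(rng.integers(-1, 2)),
        "n_monomers": 1,
        "mass": float(rng.uniform(150.0, 450.0)),
        "moments_of_inertia": tuple(
            float(x) for x in np.sort(rng.uniform(500.0, 5000.0, size=3))
        ),
        "symmetry_number": 1,
        "frequencies": tuple(
            float(x) for x in np.sort(rng.uniform(lo, hi, size=spec.n_modes))
        ),
    }


def make_harmonic_species(
    spec: GeneratorSpec,
    protocol: ThermoProtocol | None = None,
) -> list[SpeciesRecord]:
    """Species whose transfer free energies equal the spec's targets.

    The electronic energies are back-computed so the *solution free
    energies* (thermal terms included) hit a random aqueous baseline and
    baseline + target in the apolar phase; the forward transfer computation
    then returns the target to floating-point precision.
    """
    protocol = protocol or ThermoProtocol()
    rng = np.random.default_rng(spec.seed)
    records: list[SpeciesRecord] = []
    for i, target in enumerate(spec.target_transfers):
        shell = _random_record_shell(rng, f"synthetic-{i}", spec)
        probe = SpeciesRecord(
            **shell,
            energy_by_solvent={AQUEOUS: 0.0, APOLAR: 0.0},
        )
        adjusted = adjust_frequencies(probe.frequencies, protocol)
        thermal = thermal_components(
            probe.model_copy(update={"frequencies": tuple(adjusted)}),
            protocol,
        ).thermal_total
        g_aq = float(rng.uniform(-500.0, 500.0))
        if spec.noise_scale > 0.0:
            g_aq += float(rng.normal(0.0, spec.noise_scale))
        records.append(
            SpeciesRecord(
                **shell,
                energy_by_solvent={
                    AQUEOUS: g_aq - thermal,
                    APOLAR: g_aq + target - thermal,
                },
            )
        )
    return records


def make_pka_dataset(
    targets: Mapping[str, float],
    references: Mapping[str, float],
    seed: int,
    noise_scale: float = 0.0,
    n_replicates: int = 1,
) -> tuple[dict[str, list[AcidSystem]], dict[str, AcidSystem]]:
    """Acid systems whose anchored pKa predictions recover the targets.

    The references are generated mutually consistent: each carries the same
    experimental-minus-calculated offset ``delta``, so every anchor yields
    exactly the target for every compound (zero half-range).  With
    ``noise_scale`` > 0 (in pKa log-units) each replicate's deprotonation
    free energy is perturbed by N(0, noise_scale * RT ln 10).

    Returns ``(compounds, reference_systems)`` with ``compounds[name]`` a
    list of ``n_replicates`` acid systems.
    """
    rng = np.random.default_rng(seed)
    scale = rt_ln10()
    delta = float(rng.uniform(-3.0, 3.0))
    ref_systems: dict[str, AcidSystem] = {}
    for name, pka_expt in references.items():
        g_ha = float(rng.uniform(-200.0, 200.0))
        ref_systems[name] = AcidSystem(
            name=name,
            G_HA=g_ha,
            G_A=g_ha + (pka_expt - delta) * scale,
            pka_experimental=pka_expt,
        )
    compounds: dict[str, list[AcidSystem]] = {}
    for name, target in targets.items():
        reps: list[AcidSystem] = []
        for rep in range(n_replicates):
            g_ha = float(rng.uniform(-200.0, 200.0))
            dga = (target - delta) * scale
            if noise_scale > 0.0:
                dga += float(rng.normal(0.0, noise_scale * scale))
            reps.append(
                AcidSystem(
                    name=f"{name}#{rep}" if n_replicates > 1 else name,
                    G_HA=g_ha,
                    G_A=g_ha + dga,
                )
            )
        compounds[name] = reps
    return compounds, ref_systems


@dataclass(frozen=True)
class FluxTruthcase:
    """A flux scenario bundled with its analytic expectation."""

    regime: str
    scenario: FluxScenario
    rates: RateParameters
    initial: InitialAmounts
    expected: dict[str, float]


REGIMES = ("lock_in", "dimer_leak", "uncoupled")


def make_flux_truthcase(regime: str, seed: int) -> FluxTruthcase:
    """Scenario + rates + analytically solved steady state for a regime.

    * ``uncoupled``  -- no potential, no pH gradient: detailed balance, all
      in/out concentration ratios 1.
    * ``lock_in``    -- dimer and zwitterion efflux switched off, acid
      protonated fraction negligible: hydrolysed material is trapped, so
      the matrix acid pool absorbs the entire conserved total.
    * ``dimer_leak`` -- equal pH, dimer efflux on, external volume 2000x
      the matrix: the conserved pool equilibrates to equal total
      concentrations, leaving a matrix fraction 1/2001 (< 1 %).
    """
    rng = np.random.default_rng(seed)
    total = float(rng.uniform(5.0e-9, 2.0e-8))  # mol, incubation scale
    if regime == "uncoupled":
        scenario = FluxScenario(
            volume_out=1.0e-3,
            volume_in=1.0e-3,
            pH_out=7.2,
            pH_in=7.2,
            membrane_potential_program=((0.0, 0.0),),
            pKa=4.2,
        )
        rates = RateParameters(
            k_cation_perm=0.2, k_hydrolysis=0.0, K_dimer=0.0,
            k_dimer_perm=0.2, k_zwitterion_perm=0.05,
        )
        initial = InitialAmounts(ester_out=total / 2, acid_out=total / 2)
        expected = {"concentration_ratio": 1.0}
    elif regime == "lock_in":
        # 100:1 volume ratio keeps the uptake timescale (volume_out /
        # (k_cation volume_in)) short enough to reach the absorbing state
        scenario = FluxScenario(
            volume_out=1.0e-4,
            volume_in=1.0e-6,
            pH_out=7.2,
            pH_in=8.0,
            membrane_potential_program=((0.0, -160.0),),
            pKa=0.0,  # acid never re-protonates appreciably
        )
        rates = RateParameters(
            k_cation_perm=2.0, k_hydrolysis=0.2, K_dimer=1.0e3,
            k_dimer_perm=0.0, k_zwitterion_perm=0.0,
        )
        initial = InitialAmounts(ester_out=total)
        expected = {"matrix_acid_pool": total}
    elif regime == "dimer_leak":
        v_in = 1.0e-6
        scenario = FluxScenario(
            volume_out=2000.0 * v_in,
            volume_in=v_in,
            pH_out=8.0,
            pH_in=8.0,
            membrane_potential_program=((0.0, -160.0),),
            pKa=2.0,
        )
        rates = RateParameters(
            k_cation_perm=5.0, k_hydrolysis=0.5, K_dimer=1.0e4,
            k_dimer_perm=0.5, k_zwitterion_perm=0.0,
        )
        initial = InitialAmounts(ester_out=total)
        expected = {"matrix_acid_fraction": 1.0 / 2001.0}
    else:
        raise ValueError(
            f"unknown regime {regime!r}; expected one of {REGIMES}"
        )
    return FluxTruthcase(
        regime=regime,
        scenario=scenario,
        rates=rates,
        initial=initial,
        expected=expected,
    )


def make_pairing_cycle(
    seed: int,
    target_pairing: float,
    target_pair_transfer: float,
    target_free_transfer: float,
    protocol: ThermoProtocol | None = None,
) -> tuple[dict[str, SpeciesRecord], Sequence[float]]:
    """Four-state synthetic system for Hess-cycle closure checks.

    Builds records for a cation M, a counter-ion X and the pair MX with
    aqueous/apolar free energies chosen so the pairing, pair-transfer and
    free-transfer free energies equal the targets.  Returns the records and
    the targets in that order.
    """
    from mitoperm.rrho_thermo import standard_state_shift

    protocol = protocol or ThermoProtocol()
    rng = np.random.default_rng(seed)
    shift = standard_state_shift(protocol)
    spec = GeneratorSpec(seed=int(rng.integers(0, 2**31 - 1)),
                         target_transfers=(target_free_transfer,))
    base = make_harmonic_species(spec, protocol)[0]
    m = base.model_copy(update={"name": "M", "charge": 1})
    # X: arbitrary transfer; pair MX positioned so pairing hits its target
    spec_x = GeneratorSpec(seed=int(rng.integers(0, 2**31 - 1)),
                           target_transfers=(float(rng.uniform(50, 250)),))
    x = make_harmonic_species(spec_x, protocol)[0].model_copy(
        update={"name": "X", "charge": -1}
    )
    from mitoperm.rrho_thermo import solution_free_energy

    g_m_aq = solution_free_energy(m, AQUEOUS, protocol)
    g_x_aq = solution_free_energy(x, AQUEOUS, protocol)
    # pairing = G(MX,aq) - G(M,aq) - G(X,aq) - shift  (particle change -1)
    g_mx_aq = target_pairing + g_m_aq + g_x_aq + shift
    spec_mx = GeneratorSpec(seed=int(rng.integers(0, 2**31 - 1)),
                            target_transfers=(target_pair_transfer,))
    mx_shell = make_harmonic_species(spec_mx, protocol)[0]
    adjusted = adjust_frequencies(mx_shell.frequencies, protocol)
    thermal = thermal_components(
        mx_shell.model_copy(update={"frequencies": tuple(adjusted)}),
        protocol,
    ).thermal_total
    mx = mx_shell.model_copy(
        update={
            "name": "MX",
            "charge": 0,
            "energy_by_solvent": {
                AQUEOUS: g_mx_aq - thermal,
                APOLAR: g_mx_aq + target_pair_transfer - thermal,
            },
        }
    )
    return (
        {"M": m, "X": x, "MX": mx},
        (target_pairing, target_pair_transfer, target_free_transfer),
    )


__all__ = [
    "GeneratorSpec",
    "FluxTruthcase",
    "REGIMES",
    "make_harmonic_species",
    "make_pka_dataset",
    "make_flux_truthcase",
    "make_pairing_cycle",
]
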