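"""Quasi-harmonic RRHO free energies and Ben-Naim standard-state algebra.

Thermal contributions to solution free energies are evaluated in the
ideal-gas / rigid-rotor / harmonic-oscillator approximation.  Low harmonic
frequencies, for which the harmonic-oscillator entropy diverges spuriously,
are handled quasi-harmonically: each wavenumber is first multiplied by the
protocol's scale factor and then raised to the protocol's floor
(100 cm^-1 by default) if it falls below it.

Standard states follow the Ben-Naim fixed-concentration convention (denoted
``*``, c* = 1 mol L^-1) for solutes in solution, with the usual gas-phase
standard state at p = 100 kPa.  The liberational free energy of a solute --
the solution-phase replacement of gas-phase translation -- is

    G_lib*(S, sln) = G_trans(S, g) + dG_conv,

where ``dG_conv = RT ln(RT c* / p)`` is the compression work converting
between the two standard states (8.0 kJ mol^-1 at 298.15 K).  For a reaction
in solution that changes the particle number, the free energy picks up
``dG_conv`` multiplied by the signed sum of stoichiometric coefficients.

All energies are in kJ mol^-1; wavenumbers in cm^-1.  Physical constants are
CODATA values taken from :mod:`scipy.constants`.
"""

from __future__ import annotations

import math
from dataclasses import dataclass
from typing import Sequence

import numpy as np
from scipy import constants

from mitoperm.species_model import (
    SpeciesRecord,
    SpeciesValidationError,
    ThermoProtocol,
)

_R = constants.R  # J mol^-1 K^-1
_H = constants.h
_KB = constants.k
_C_CM = constants.c * 100.0  # speed of light in cm s^-1
_NA = constants.N_A
_AMU = constants.atomic_mass  # kg
_ANG2 = 1.0e-20  # m^2 per Angstrom^2

#: Relative tolerance below which a principal moment counts as zero
#: (monatomic / linear bookkeeping).
_INERTIA_ZERO_RTOL = 1.0e-9


@dataclass(frozen=True)
class ThermoComponents:
    """Per-term breakdown of the RRHO thermal free energy (kJ mol^-1).

    ``total_liberational`` satisfies the identity
    ``translational + standard_state_shift`` exactly: in the Ben-Naim
    convention the liberational term of a solute equals its gas-phase
    translational free energy plus the standard-state conversion.
    """

    zpe: float
    translational: float
    rotational: float
    vibrational_thermal: float
    standard_state_shift: float
    total_liberational: float

    @property
    def thermal_total(self) -> float:
        """Everything added to the electronic energy for G*(S, sln)."""
        return (
            self.zpe
            + self.vibrational_thermal
            + self.rotational
            + self.total_liberational
        )


def adjust_frequencies(
    frequencies: Sequence[float], protocol: ThermoProtocol
) -> list[float]:
    """Scale then floor harmonic wavenumbers, preserving order.

    Each wavenumber is multiplied by ``protocol.frequency_scale`` first and
    only then compared against ``protocol.frequency_floor``; a scaled value
    just below the floor (e.g. 102 * 0.972 = 99.144 cm^-1) is therefore
    raised.  Nonpositive inputs are rejected: they indicate an imaginary
    mode, i.e. a structure that is not a minimum.
    """
    out: list[float] = []
    for i, nu in enumerate(frequencies):
        if nu <= 0.0:
            raise SpeciesValidationError(
                f"mode {i}: nonpositive wavenumber {nu} cm^-1"
            )
        scaled = nu * protocol.frequency_scale
        out.append(max(scaled, protocol.frequency_floor))
    return out


def standard_state_shift(protocol: ThermoProtocol) -> float:
    """Gas (p) -> solution (c*) standard-state conversion, kJ mol^-1.

    ``RT ln(RT c* / p)``; 8.0 kJ mol^-1 for the defaults (298.15 K,
    100 kPa, 1 mol L^-1).
    """
    T = protocol.temperature
    c_star = protocol.concentration_standard * 1000.0  # mol m^-3
    return _R * T * math.log(_R * T * c_star / protocol.pressure_standard) / 1000.0


def _classify_rotor(moments: Sequence[float]) -> str:
    """'atom', 'linear' or 'nonlinear' from the principal moments."""
    m = sorted(moments)
    largest = m[-1]
    if largest <= 0.0:
        return "atom"
    zeros = [x for x in m if x <= largest * _INERTIA_ZERO_RTOL]
    if len(zeros) >= 2:
        raise SpeciesValidationError(
            "two principal moments of inertia are zero but the largest is "
            "not; no physical rotor has this shape"
        )
    return "linear" if len(zeros) == 1 else "nonlinear"


def _translational_g(mass_amu: float, protocol: ThermoProtocol) -> float:
    """Molar translational Gibbs energy at p (kJ mol^-1), Sackur-Tetrode."""
    T = protocol.temperature
    m = mass_amu * _AMU
    q_over_n = (2.0 * math.pi * m * _KB * T / _H**2) ** 1.5 * (
        _KB * T / protocol.pressure_standard
    )
    return -_R * T * math.log(q_over_n) / 1000.0


def _rotational_g(
    moments: Sequence[float], symmetry_number: int, protocol: ThermoProtocol
) -> float:
    """Molar rigid-rotor rotational Gibbs energy (kJ mol^-1)."""
    kind = _classify_rotor(moments)
    if kind == "atom":
        return 0.0
    T = protocol.temperature
    si = [m * _AMU * _ANG2 for m in moments]
    if kind == "linear":
        inertia = max(si)
        q_rot = 8.0 * math.pi**2 * inertia * _KB * T / (
            symmetry_number * _H**2
        )
    else:
        ia, ib, ic = si
        q_rot = (
            math.sqrt(math.pi)
            / symmetry_number
            * (8.0 * math.pi**2 * _KB * T / _H**2) ** 1.5
            * math.sqrt(ia * ib * ic)
        )
    return -_R * T * math.log(q_rot) / 1000.0


def zero_point_energy(frequencies: Sequence[float]) -> float:
    """Harmonic zero-point vibrational energy, kJ mol^-1."""
    nus = np.asarray(frequencies, dtype=float)
    return float(_NA * _H * _C_CM * nus.sum() / 2.0) / 1000.0


def vibrational_thermal_g(
    frequencies: Sequence[float], temperature: float
) -> float:
    """Thermal harmonic-oscillator free energy beyond ZPE, kJ mol^-1.

    ``RT sum_i ln(1 - exp(-h c nu_i / k T))``; always negative for a
    non-empty mode list, and shrinking in magnitude as frequencies rise.
    """
    if len(frequencies) == 0:
        return 0.0
    nus = np.asarray(frequencies, dtype=float)
    x = _H * _C_CM * nus / (_KB * temperature)
    return float(_R * temperature * np.log1p(-np.exp(-x)).sum()) / 1000.0


def thermal_components(
    species: SpeciesRecord, protocol: ThermoProtocol
) -> ThermoComponents:
    """RRHO thermal terms for a species whose frequencies are already
    quasi-harmonically adjusted (see :func:`adjust_frequencies`).

    Monatomic species (all moments zero, no modes) get neither rotational
    nor vibrational terms; linear species get the two-degree-of-freedom
    rotor.  A species with vibrational modes but all-zero moments of inertia
    is rejected as unphysical.
    """
    kind = _classify_rotor(species.moments_of_inertia)
    if kind == "atom" and len(species.frequencies) > 0:
        raise SpeciesValidationError(
            f"species {species.name!r}: has vibrational modes but all "
            "principal moments of inertia are zero"
        )
    shift = standard_state_shift(protocol)
    if protocol.external_dof:
        translational = _translational_g(species.mass, protocol)
        rotational = _rotational_g(
            species.moments_of_inertia, species.symmetry_number, protocol
        )
    else:
        translational = 0.0
        rotational = 0.0
    zpe = zero_point_energy(species.frequencies)
    vib = vibrational_thermal_g(species.frequencies, protocol.temperature)
    return ThermoComponents(
        zpe=zpe,
        translational=translational,
        rotational=rotational,
        vibrational_thermal=vib,
        standard_state_shift=shift,
        total_liberational=translational + shift,
    )


def solution_free_energy(
    species: SpeciesRecord, solvent: str, protocol: ThermoProtocol
) -> float:
    """Ben-Naim solution free energy G*(S, sln) in kJ mol^-1.

    Electronic + solvation energy for ``solvent`` plus ZPE, vibrational and
    rotational thermal terms and the liberational free energy.  The record's
    single frequency list is shared across solvents, so thermal terms cancel
    in any transfer difference.  Frequencies are adjusted (scale-then-floor)
    here; do not pre-adjust the record.
    """
    electronic = species.energy(solvent)
    adjusted = adjust_frequencies(species.frequencies, protocol)
    comps = thermal_components(
        species.model_copy(update={"frequencies": tuple(adjusted)}),
        protocol,
    )
    return electronic + comps.thermal_total


__all__ = [
    "ThermoComponents",
    "adjust_frequencies",
    "standard_state_shift",
    "zero_point_energy",
    "vibrational_thermal_g",
    "thermal_components",
    "solution_free_energy",
]
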