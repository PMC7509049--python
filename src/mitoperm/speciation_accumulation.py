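"""Henderson-Hasselbalch speciation and Nernstian accumulation.

A lipophilic cation distributes across the inner mitochondrial membrane
according to the Nernst equation: with the matrix-side potential written as
negative-inside (the convention used throughout this package), a monocation
accumulates ``exp(-z F dpsi / RT)``-fold, about 1,000-fold at -180 mV and
37 C.  A TPP compound bearing a weak carboxylic acid gains a second driving
force: only the protonated (cationic) form permeates and equilibrates
Nernstianly, while the higher matrix pH (~8.0 vs ~7.2 in the cytosol) tips
the internal acid-base equilibrium toward the impermeant zwitterion,
enhancing total accumulation by the speciation factor

    (1 + 10^(pH_in - pKa)) / (1 + 10^(pH_out - pKa)),

4-10-fold for a pKa around 4.9.  This module is purely equilibrium
thermodynamics; kinetic phenomena (e.g. efflux of zwitterion dimers) live in
:mod:`mitoperm.flux_simulator`.
"""

from __future__ import annotations

import math
from dataclasses import dataclass

from scipy import constants
from pydantic import BaseModel, ConfigDict, Field

_F = constants.value("Faraday constant")  # C mol^-1
_R = constants.R

#: Physiological default temperature (37 C), distinct from the 298.15 K
#: thermochemistry default.
PHYSIOLOGICAL_TEMPERATURE = 310.15


class AccumulationScenario(BaseModel):
    """Conditions for the equilibrium accumulation model.

    ``membrane_potential`` is the matrix-side potential in mV,
    negative-inside: cations accumulate when it is negative.
    """

    model_config = ConfigDict(frozen=True)

    pH_out: float = Field(default=7.2, ge=0.0, le=14.0)
    pH_in: float = Field(default=8.0, ge=0.0, le=14.0)
    membrane_potential: float = -160.0
    charge: int = 1
    pKa: float = 4.9
    temperature: float = Field(default=PHYSIOLOGICAL_TEMPERATURE, gt=0.0)


def protonated_fraction(pH: float, pKa: float) -> float:
    """Fraction of a monoprotic acid in the protonated form.

    ``1 / (1 + 10^(pH - pKa))``, in (0, 1); exactly 0.5 at pH = pKa.
    """
    return 1.0 / (1.0 + 10.0 ** (pH - pKa))


def nernst_ratio(
    membrane_potential: float,
    charge: int = 1,
    temperature: float = PHYSIOLOGICAL_TEMPERATURE,
) -> float:
    """Equilibrium in/out ratio of a permeant ion.

    ``exp(-z F dpsi / RT)`` with ``membrane_potential`` in mV,
    negative-inside; ~10 per -61.5 mV for a monocation at 37 C.
    """
    psi = membrane_potential * 1.0e-3
    return math.exp(-charge * _F * psi / (_R * temperature))


def acid_accumulation(
    scenario: AccumulationScenario,
) -> tuple[float, float]:
    """Total accumulation ratio of a TPP weak acid and its pH-gradient part.

    The protonated cation equilibrates per :func:`nernst_ratio`; summing
    both protonation states in each compartment gives

        ACR_total = nernst * (1 + 10^(pH_in - pKa)) / (1 + 10^(pH_out - pKa)).

    Returns ``(ACR_total, pH_enhancement_factor)``, the second being the
    speciation quotient alone (exactly 1 with no pH gradient; bounded above
    by ``10^(pH_in - pH_out)``).
    """
    ratio = nernst_ratio(
        scenario.membrane_potential, scenario.charge, scenario.temperature
    )
    factor = (1.0 + 10.0 ** (scenario.pH_in - scenario.pKa)) / (
        1.0 + 10.0 ** (scenario.pH_out - scenario.pKa)
    )
    return ratio * factor, factor


@dataclass(frozen=True)
class NigericinReport:
    """Accumulation ratios before/after collapsing the pH gradient.

    Nigericin exchanges K+ for H+: it abolishes the pH gradient and, by
    diverting the proton-motive force entirely into its electrical
    component, raises the magnitude of the membrane potential.  A pure
    cation's ACR therefore increases, while an acid-bearing cation loses
    its speciation bonus -- the acid/control ACR ratio drops.
    """

    acid_baseline: float
    acid_nigericin: float
    control_baseline: float
    control_nigericin: float

    @property
    def ratio_baseline(self) -> float:
        return self.acid_baseline / self.control_baseline

    @property
    def ratio_nigericin(self) -> float:
        return self.acid_nigericin / self.control_nigericin

    @property
    def ratio_change(self) -> float:
        """nigericin/baseline change of the acid:control ACR ratio
        (< 1 when the pH gradient was contributing)."""
        return self.ratio_nigericin / self.ratio_baseline


def nigericin_response(
    scenario: AccumulationScenario, potential_shift: float
) -> NigericinReport:
    """Compare acid and pKa-free control ACRs under baseline and nigericin.

    The nigericin condition sets ``pH_in = pH_out`` and makes the membrane
    potential more negative by ``potential_shift`` mV (>= 0).
    """
    if potential_shift < 0:
        raise ValueError("potential_shift must increase |dpsi|, got < 0")
    control_baseline = nernst_ratio(
        scenario.membrane_potential, scenario.charge, scenario.temperature
    )
    acid_baseline, _ = acid_accumulation(scenario)
    shifted = scenario.model_copy(
        update={
            "pH_in": scenario.pH_out,
            "membrane_potential": scenario.membrane_potential
            - potential_shift,
        }
    )
    control_nigericin = nernst_ratio(
        shifted.membrane_potential, shifted.charge, shifted.temperature
    )
    acid_nigericin, _ = acid_accumulation(shifted)
    return NigericinReport(
        acid_baseline=acid_baseline,
        acid_nigericin=acid_nigericin,
        control_baseline=control_baseline,
        control_nigericin=control_nigericin,
    )


__all__ = [
    "PHYSIOLOGICAL_TEMPERATURE",
    "AccumulationScenario",
    "NigericinReport",
    "protonated_fraction",
    "nernst_ratio",
    "acid_accumulation",
    "nigericin_response",
]
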