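"""Reference-acid-anchored relative pKa prediction.

Absolute pKa computation from continuum-solvation free energies is dominated
by the poorly known proton solvation free energy.  The relative scheme used
here cancels that term against a reference acid HRef with an experimentally
known pKa:

    pKa(HA) = lg(e) * dG_a(HA) / (RT) + pKa_expt(HRef) - pKa_calc(HRef)

with ``dG_a(HA) = G*(A-) - G*(HA)`` and
``pKa_calc(HRef) = lg(e) * dG_a(HRef) / (RT)``.  Equivalently the predicted
pKa is the reference's experimental value shifted by
``(dG_a(HA) - dG_a(HRef)) / (RT ln 10)`` -- one pKa unit per
RT ln 10 = 5.708 kJ mol^-1 at 298.15 K.

Predictions anchored to several references are combined as
mean +- half-range.  For exact inputs the difference between two anchors'
predictions is the same constant for every compound, which
:func:`reference_consistency_offset` turns into a table-level diagnostic.
"""

from __future__ import annotations

import math
from dataclasses import dataclass
from typing import Mapping, Sequence

from scipy import constants
from pydantic import BaseModel, ConfigDict

_R_KJ = constants.R / 1000.0  # kJ mol^-1 K^-1

DEFAULT_TEMPERATURE = 298.15


class PkaError(ValueError):
    """Ill-posed pKa computation (missing anchor, empty input, ...)."""


class AcidSystem(BaseModel):
    """A conjugate acid-base pair on a common free-energy reference.

    ``G_HA`` and ``G_A`` are the solution free energies (kJ mol^-1) of the
    protonated form and conjugate base; only their difference ``dG_a``
    enters any prediction, so the absolute offset must merely be shared
    between an acid and its reference.  Reference acids carry
    ``pka_experimental``.
    """

    model_config = ConfigDict(frozen=True)

    name: str
    G_HA: float
    G_A: float
    pka_experimental: float | None = None

    @property
    def dG_a(self) -> float:
        """Deprotonation free energy G*(A-) - G*(HA), kJ mol^-1."""
        return self.G_A - self.G_HA


def rt_ln10(temperature: float = DEFAULT_TEMPERATURE) -> float:
    """RT ln 10 in kJ mol^-1 (5.708 at 298.15 K): one pKa unit."""
    return _R_KJ * temperature * math.log(10.0)


def pka_from_reference(
    acid: AcidSystem,
    reference: AcidSystem,
    temperature: float = DEFAULT_TEMPERATURE,
) -> float:
    """Predict pKa(acid) anchored to one reference acid.

    An affine, strictly increasing function of ``acid.dG_a`` with slope
    ``lg(e)/(RT)``; predicting the reference from itself returns its
    experimental value exactly.
    """
    if reference.pka_experimental is None:
        raise PkaError(
            f"reference acid {reference.name!r} carries no experimental pKa"
        )
    return (
        (acid.dG_a - reference.dG_a) / rt_ln10(temperature)
        + reference.pka_experimental
    )


def combine_references(
    predictions: Sequence[float],
) -> tuple[float, float]:
    """Aggregate per-reference predictions as (mean, half-range).

    Half-range is ``(max - min) / 2``; for the two-reference case this is
    the only aggregation consistent with reporting {2.4, 2.6} as
    2.5 +- 0.1.
    """
    if len(predictions) == 0:
        raise PkaError("cannot combine an empty set of predictions")
    lo, hi = min(predictions), max(predictions)
    return (sum(predictions) / len(predictions), (hi - lo) / 2.0)


@dataclass(frozen=True)
class OffsetDiagnostics:
    """Cross-reference consistency report for a prediction table.

    ``offsets[ref][compound]`` is prediction(ref) - prediction(first ref).
    Analytically this difference is the same for every compound (it equals
    the difference of the anchors' experimental-minus-calculated offsets),
    so any spread beyond rounding flags an inconsistent table.
    """

    reference_order: tuple[str, ...]
    offsets: dict[str, dict[str, float]]
    consistent: dict[str, bool]
    tolerance: float


def reference_consistency_offset(
    table: Mapping[str, Mapping[str, float]],
    rounding: float = 0.1,
) -> OffsetDiagnostics:
    """Per-compound offsets between anchors, and whether they are constant.

    ``table`` maps compound -> {reference -> predicted pKa}.  Each
    non-first reference is compared against the first; an anchor is flagged
    inconsistent when its per-compound offsets spread by more than twice
    the rounding quantum of the table entries.  Tables with fewer than two
    references yield empty diagnostics.
    """
    refs: list[str] = []
    for preds in table.values():
        for ref in preds:
            if ref not in refs:
                refs.append(ref)
    tolerance = 2.0 * rounding
    if len(refs) < 2:
        return OffsetDiagnostics(tuple(refs), {}, {}, tolerance)
    first = refs[0]
    offsets: dict[str, dict[str, float]] = {}
    consistent: dict[str, bool] = {}
    for ref in refs[1:]:
        per_compound = {
            compound: preds[ref] - preds[first]
            for compound, preds in table.items()
            if ref in preds and first in preds
        }
        offsets[ref] = per_compound
        values = list(per_compound.values())
        consistent[ref] = (
            len(values) == 0 or (max(values) - min(values)) <= tolerance
        )
    return OffsetDiagnostics(tuple(refs), offsets, consistent, tolerance)


__all__ = [
    "AcidSystem",
    "PkaError",
    "OffsetDiagnostics",
    "DEFAULT_TEMPERATURE",
    "rt_ln10",
    "pka_from_reference",
    "combine_references",
    "reference_consistency_offset",
]
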