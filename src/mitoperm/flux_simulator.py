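"""Two-compartment kinetic model of ester uptake and zwitterion-dimer efflux.

The mechanism simulated here explains why TPP carboxylic acids generated
inside mitochondria by ester hydrolysis are not retained:

* the ester cation crosses the inner membrane driven by the membrane
  potential and accumulates in the matrix;
* matrix esterases hydrolyse it to the carboxylic acid, which at matrix pH
  exists almost exclusively as the net-neutral zwitterion;
* two zwitterions associate into a neutral head-to-tail dimer, which leaks
  back out driven purely by its concentration gradient, independent of the
  membrane potential.

Protonation and dimerisation are treated as instantaneous equilibria within
each compartment (they are fast compared with permeation and avoid a stiff
system); the dynamic states are the ester amount and the total acid pool
(monomer basis, dimer-bound material included) per compartment.  Cation
fluxes use the symmetric form ``k (c_out - c_in exp(z F psi / RT))`` whose
fixed point is exactly the Nernst ratio; neutral species respond to the
concentration difference only.  Rate constants are structural parameters --
no published rates exist for this mechanism, so simulator claims are
directional, never quantitative fits.

The membrane-potential program is piecewise constant so that uncoupling
(potential -> 0 at an event time) is represented exactly.
"""

from __future__ import annotations

import math
from dataclasses import dataclass

import numpy as np
import pandas as pd
from scipy import constants
from scipy.integrate import solve_ivp
from pydantic import BaseModel, ConfigDict, Field, model_validator

from mitoperm.speciation_accumulation import PHYSIOLOGICAL_TEMPERATURE

_F = constants.value("Faraday constant")
_R = constants.R


class SimulationError(RuntimeError):
    """The ODE integrator failed; carries the solver's diagnostic."""


class FluxScenario(BaseModel):
    """Compartment geometry, pH values and potential program.

    ``membrane_potential_program`` is a piecewise-constant schedule of
    (time s, potential mV) pairs, negative-inside convention, starting at
    t = 0.  The default volumes reflect a standard mitochondrial
    incubation: ~1 uL matrix per mg protein at 0.5 mg protein per mL in a
    2 mL chamber, i.e. a matrix:medium volume ratio of 5e-4.
    """

    model_config = ConfigDict(frozen=True)

    volume_out: float = Field(default=2.0e-3, gt=0.0)
    volume_in: float = Field(default=1.0e-6, gt=0.0)
    pH_out: float = Field(default=7.2, ge=0.0, le=14.0)
    pH_in: float = Field(default=8.0, ge=0.0, le=14.0)
    membrane_potential_program: tuple[tuple[float, float], ...] = (
        (0.0, -160.0),
    )
    pKa: float = 4.2
    temperature: float = Field(default=PHYSIOLOGICAL_TEMPERATURE, gt=0.0)

    @model_validator(mode="after")
    def _check_program(self) -> "FluxScenario":
        times = [t for t, _ in self.membrane_potential_program]
        if not times or times[0] != 0.0:
            raise ValueError(
                "membrane_potential_program must start at t = 0"
            )
        if any(b <= a for a, b in zip(times, times[1:])):
            raise ValueError(
                "membrane_potential_program times must strictly increase"
            )
        return self

    def potential_at(self, t: float) -> float:
        """Potential (mV) in force at time ``t``."""
        value = self.membrane_potential_program[0][1]
        for t_seg, v in self.membrane_potential_program:
            if t_seg <= t:
                value = v
            else:
                break
        return value


class RateParameters(BaseModel):
    """Kinetic and fast-equilibrium parameters of the transport model.

    ``k_cation_perm`` scales permeation of every cationic form (ester
    cation and protonated acid), biased by the instantaneous potential;
    ``k_hydrolysis`` is the matrix esterase rate; ``K_dimer`` the aqueous
    zwitterion-dimerisation equilibrium constant (M^-1, fast);
    ``k_dimer_perm`` the neutral-dimer permeation rate and
    ``k_zwitterion_perm`` the monomeric-zwitterion rate, 0 by default
    because the bare zwitterion is taken to be membrane-impermeant.
    First-order rates are per second on the matrix-volume concentration
    scale.  ``K_dimer`` can be derived from an aqueous dimerisation free
    energy via :func:`dimer_constant_from_free_energy`.
    """

    model_config = ConfigDict(frozen=True)

    k_cation_perm: float = Field(default=0.05, ge=0.0)
    k_hydrolysis: float = Field(default=0.01, ge=0.0)
    K_dimer: float = Field(default=1.0e3, ge=0.0)
    k_dimer_perm: float = Field(default=0.05, ge=0.0)
    k_zwitterion_perm: float = Field(default=0.0, ge=0.0)


class InitialAmounts(BaseModel):
    """Starting amounts in mol (acid pools on the monomer basis)."""

    model_config = ConfigDict(frozen=True)

    ester_out: float = Field(default=0.0, ge=0.0)
    ester_in: float = Field(default=0.0, ge=0.0)
    acid_out: float = Field(default=0.0, ge=0.0)
    acid_in: float = Field(default=0.0, ge=0.0)


def dimer_constant_from_free_energy(
    dg_pairing: float, temperature: float = PHYSIOLOGICAL_TEMPERATURE
) -> float:
    """K_dimer (M^-1) from an aqueous dimerisation free energy in kJ/mol.

    ``K = exp(-dG / RT)`` on the 1 mol/L standard state; ties the simulator
    to a pairing free energy from :mod:`mitoperm.transfer_cycles`.
    """
    return math.exp(-dg_pairing * 1000.0 / (_R * temperature))


def speciate_pool(
    c_total: float, pH: float, pKa: float, K_dimer: float
) -> tuple[float, float, float]:
    """Split a total acid concentration (monomer basis) into equilibrium
    (c_HA, c_Z, c_D) concentrations.

    Protonation is pinned by pH and pKa (c_Z / c_HA = 10^(pH - pKa));
    dimerisation satisfies c_D = K c_Z^2.  Mass balance
    ``c_HA + c_Z + 2 c_D = c_total`` gives a quadratic solved in a
    cancellation-free form.
    """
    if c_total <= 0.0:
        return 0.0, 0.0, 0.0
    r = 10.0 ** (pH - pKa)  # zwitterion : protonated
    a = 1.0 + 1.0 / r
    if K_dimer == 0.0:
        c_z = c_total / a
    else:
        c_z = 2.0 * c_total / (a + math.sqrt(a * a + 8.0 * K_dimer * c_total))
    return c_z / r, c_z, K_dimer * c_z * c_z


@dataclass(frozen=True)
class Trajectory:
    """Deterministic solution of the two-compartment model.

    Amounts in mol on the time grid; ``acid_*`` is the monomeric acid
    (protonated + zwitterion), ``dimer_*`` the dimer amount, so total
    phosphonium is ``ester + acid + 2 * dimer`` summed over compartments.
    """

    times: np.ndarray
    ester_out: np.ndarray
    ester_in: np.ndarray
    pool_out: np.ndarray
    pool_in: np.ndarray
    scenario: FluxScenario
    rates: RateParameters

    def _split(self, pool: np.ndarray, volume: float, pH: float):
        mono = np.empty_like(pool)
        dimer = np.empty_like(pool)
        for i, p in enumerate(pool):
            c_ha, c_z, c_d = speciate_pool(
                max(p, 0.0) / volume, pH, self.scenario.pKa,
                self.rates.K_dimer,
            )
            mono[i] = (c_ha + c_z) * volume
            dimer[i] = c_d * volume
        return mono, dimer

    @property
    def acid_out(self) -> np.ndarray:
        return self._split(
            self.pool_out, self.scenario.volume_out, self.scenario.pH_out
        )[0]

    @property
    def acid_in(self) -> np.ndarray:
        return self._split(
            self.pool_in, self.scenario.volume_in, self.scenario.pH_in
        )[0]

    @property
    def dimer_out(self) -> np.ndarray:
        return self._split(
            self.pool_out, self.scenario.volume_out, self.scenario.pH_out
        )[1]

    @property
    def dimer_in(self) -> np.ndarray:
        return self._split(
            self.pool_in, self.scenario.volume_in, self.scenario.pH_in
        )[1]

    def total_phosphonium(self) -> np.ndarray:
        """Conserved total (mol): ester + acid + 2 x dimer, both sides."""
        return self.ester_out + self.ester_in + self.pool_out + self.pool_in

    def to_frame(self) -> pd.DataFrame:
        """Time series of amounts (mol) as a tidy DataFrame."""
        return pd.DataFrame(
            {
                "time_s": self.times,
                "ester_out_mol": self.ester_out,
                "ester_in_mol": self.ester_in,
                "acid_out_mol": self.acid_out,
                "acid_in_mol": self.acid_in,
                "dimer_out_mol": self.dimer_out,
                "dimer_in_mol": self.dimer_in,
                "total_mol": self.total_phosphonium(),
            }
        )


def _rhs_factory(
    scenario: FluxScenario, rates: RateParameters, potential_mv: float
):
    v_out, v_in = scenario.volume_out, scenario.volume_in
    v_ref = v_in
    theta = math.exp(
        _F * potential_mv * 1.0e-3 / (_R * scenario.temperature)
    )

    def rhs(_t: float, y: np.ndarray) -> np.ndarray:
        e_out, e_in, p_out, p_in = y
        c_e_out = max(e_out, 0.0) / v_out
        c_e_in = max(e_in, 0.0) / v_in
        ha_out, z_out, d_out = speciate_pool(
            max(p_out, 0.0) / v_out, scenario.pH_out, scenario.pKa,
            rates.K_dimer,
        )
        ha_in, z_in, d_in = speciate_pool(
            max(p_in, 0.0) / v_in, scenario.pH_in, scenario.pKa,
            rates.K_dimer,
        )
        j_ester = rates.k_cation_perm * v_ref * (c_e_out - c_e_in * theta)
        j_ha = rates.k_cation_perm * v_ref * (ha_out - ha_in * theta)
        j_z = rates.k_zwitterion_perm * v_ref * (z_out - z_in)
        j_d = rates.k_dimer_perm * v_ref * (d_out - d_in)
        hydrolysis = rates.k_hydrolysis * max(e_in, 0.0)
        return np.array(
            [
                -j_ester,
                j_ester - hydrolysis,
                -j_ha - j_z - 2.0 * j_d,
                j_ha + j_z + 2.0 * j_d + hydrolysis,
            ]
        )

    return rhs


def _integrate_segment(
    scenario: FluxScenario,
    rates: RateParameters,
    y0: np.ndarray,
    t0: float,
    t1: float,
    t_eval: np.ndarray,
    potential_mv: float,
) -> tuple[np.ndarray, np.ndarray]:
    rhs = _rhs_factory(scenario, rates, potential_mv)
    scale = max(float(np.sum(np.abs(y0))), 1.0e-300)
    sol = solve_ivp(
        rhs,
        (t0, t1),
        y0,
        method="LSODA",
        t_eval=t_eval if t_eval.size else None,
        rtol=1.0e-10,
        atol=scale * 1.0e-14,
        dense_output=False,
    )
    if not sol.success:
        raise SimulationError(
            f"integration failed on [{t0}, {t1}] at potential "
            f"{potential_mv} mV: {sol.message}"
        )
    y_end = sol.y[:, -1] if sol.y.size else y0
    if t_eval.size:
        return sol.y.T, y_end
    return np.empty((0, 4)), y_end


def simulate(
    scenario: FluxScenario,
    rates: RateParameters,
    initial: InitialAmounts,
    t_grid: np.ndarray,
) -> Trajectory:
    """Integrate the mass-action model over ``t_grid`` (s, increasing).

    The grid's first point is the initial time.  Integration proceeds
    segment-by-segment between potential-program breakpoints so the
    piecewise-constant potential is honoured exactly.
    """
    t_grid = np.asarray(t_grid, dtype=float)
    if t_grid.ndim != 1 or t_grid.size < 2 or np.any(np.diff(t_grid) <= 0):
        raise ValueError("t_grid must be a strictly increasing 1-D array")
    y = np.array(
        [
            initial.ester_out,
            initial.ester_in,
            initial.acid_out,
            initial.acid_in,
        ]
    )
    t_start, t_end = float(t_grid[0]), float(t_grid[-1])
    breaks = [
        t for t, _ in scenario.membrane_potential_program
        if t_start < t < t_end
    ]
    edges = [t_start, *breaks, t_end]
    rows = [y.copy()]
    for a, b in zip(edges, edges[1:]):
        inner = t_grid[(t_grid > a) & (t_grid <= b)]
        seg_eval = np.unique(np.append(inner, b))
        seg_rows, y = _integrate_segment(
            scenario, rates, y, a, b, seg_eval, scenario.potential_at(a)
        )
        for t_pt, row in zip(seg_eval, seg_rows):
            if np.any(np.isclose(t_grid, t_pt, rtol=0.0, atol=1e-12)):
                rows.append(row)
    out = np.vstack(rows)
    if out.shape[0] != t_grid.size:
        raise SimulationError(
            "internal grid bookkeeping error: "
            f"{out.shape[0]} rows for {t_grid.size} grid points"
        )
    return Trajectory(
        times=t_grid,
        ester_out=out[:, 0],
        ester_in=out[:, 1],
        pool_out=out[:, 2],
        pool_in=out[:, 3],
        scenario=scenario,
        rates=rates,
    )


def uncoupling_event(
    scenario: FluxScenario,
    rates: RateParameters,
    initial: InitialAmounts,
    t_grid: np.ndarray,
    t_event: float,
) -> Trajectory:
    """Simulate with the membrane potential collapsed to 0 from ``t_event``.

    Mimics adding an uncoupler (e.g. FCCP): the program is truncated at the
    event and a 0 mV segment appended.  An event at the grid start is
    identical to simulating with no potential throughout.
    """
    t_grid = np.asarray(t_grid, dtype=float)
    if not (t_grid[0] <= t_event <= t_grid[-1]):
        raise ValueError("t_event must lie within the simulated window")
    if t_event <= t_grid[0]:
        program: tuple[tuple[float, float], ...] = ((0.0, 0.0),)
    else:
        kept = tuple(
            (t, v)
            for t, v in scenario.membrane_potential_program
            if t < t_event
        )
        program = kept + ((t_event, 0.0),)
    uncoupled = scenario.model_copy(
        update={"membrane_potential_program": program}
    )
    return simulate(uncoupled, rates, initial, t_grid)


def resuspension_event(
    scenario: FluxScenario,
    rates: RateParameters,
    initial: InitialAmounts,
    t_grid: np.ndarray,
    t_event: float,
    fresh_volume_out: float | None = None,
) -> Trajectory:
    """Pellet-and-resuspend: zero the external amounts at ``t_event``.

    Matrix amounts carry over; the external compartment restarts empty with
    ``fresh_volume_out`` (default: unchanged volume).  Returns a stitched
    trajectory on the full grid; the grid point at or immediately after the
    event reflects the fresh medium.
    """
    t_grid = np.asarray(t_grid, dtype=float)
    if not (t_grid[0] < t_event < t_grid[-1]):
        raise ValueError("t_event must lie strictly inside the grid")
    before_mask = t_grid <= t_event
    grid_before = np.unique(np.append(t_grid[before_mask], t_event))
    first = simulate(scenario, rates, initial, grid_before)
    carried = InitialAmounts(
        ester_out=0.0,
        ester_in=max(float(first.ester_in[-1]), 0.0),
        acid_out=0.0,
        acid_in=max(float(first.pool_in[-1]), 0.0),
    )
    # the potential in force at the event is held constant afterwards
    fresh = scenario.model_copy(
        update={
            "volume_out": fresh_volume_out or scenario.volume_out,
            "membrane_potential_program": (
                (0.0, scenario.potential_at(t_event)),
            ),
        }
    )
    after_times = t_grid[~before_mask]
    grid_after = np.unique(np.append(0.0, after_times - t_event))
    second = simulate(fresh, rates, carried, grid_after)
    n_before = int(before_mask.sum())

    def stitch(a: np.ndarray, b: np.ndarray) -> np.ndarray:
        return np.concatenate([a[:n_before], b[-len(after_times):]])

    return Trajectory(
        times=t_grid,
        ester_out=stitch(first.ester_out, second.ester_out),
        ester_in=stitch(first.ester_in, second.ester_in),
        pool_out=stitch(first.pool_out, second.pool_out),
        pool_in=stitch(first.pool_in, second.pool_in),
        scenario=fresh,
        rates=rates,
    )


__all__ = [
    "FluxScenario",
    "RateParameters",
    "InitialAmounts",
    "Trajectory",
    "SimulationError",
    "dimer_constant_from_free_energy",
    "speciate_pool",
    "simulate",
    "uncoupling_event",
    "resuspension_event",
]
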