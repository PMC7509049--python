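# Methods

`mitoperm` models how triphenylphosphonium (TPP) compounds bearing a
carboxylic acid move across the mitochondrial inner membrane: the
thermodynamics of crossing the apolar membrane core (as free ions, ion
pairs, or zwitterion dimers), the acid-base speciation that controls which
forms are available, and the kinetics of ester-mediated delivery and
zwitterion-dimer escape. This note records the models, their assumptions,
the defaults and why, and what the synthetic-data machinery does and does
not demonstrate.

## Thermochemistry (rrho_thermo)

Solution free energies are assembled as

    G*(S, sln) = E_elec+solv + ZPE + G_vib(T) + G_rot(T) + G_lib*,

where `E_elec+solv` is an input (an electronic energy including continuum
electrostatic and non-electrostatic solvation, produced upstream by
quantum-chemistry software and supplied per solvent in the species record),
and the thermal terms follow the ideal-gas / rigid-rotor /
harmonic-oscillator model at T = 298.15 K, p° = 100 kPa:

* **ZPE** `sum_i N_A h c nu_i / 2`;
* **vibrational** `RT sum_i ln(1 - exp(-h c nu_i / kT))`;
* **rotational** rigid-rotor with 0 / 2 / 3 degrees of freedom for
  monatomic / linear / nonlinear species (principal moments in amu Å², a
  moment counting as zero below 1e-9 of the largest; counter-ions such as
  Cl⁻ and Na⁺ need the monatomic branch);
* **translational** Sackur–Tetrode at p°.

**Quasi-harmonic floor.** Harmonic entropies of soft modes are unreliable,
so each wavenumber is multiplied by the protocol's scale factor (1.0 by
default; 0.972 in the pKa protocol) and then raised to the 100 cm⁻¹ floor
if below it. The scale-then-floor order matters (102 × 0.972 = 99.1 → 100)
and is applied once, inside `solution_free_energy`; applying the 0.972
protocol twice would double-scale. Scaling and flooring are applied to all
vibrational terms, ZPE included — the alternative (floor only the entropy)
changes nothing downstream here because every reported cycle uses
differences of species that share a frequency list.

**Standard states.** Solutes use the Ben-Naim fixed-concentration standard
state (`*`, c* = 1 mol/L); gases the 100 kPa state (`°`). The liberational
free energy replacing gas-phase translation in solution satisfies
`G_lib* = G_trans° + ΔG°→*` with `ΔG°→* = RT ln(RT c*/p°)` = 8.0 kJ/mol at
the defaults, and reactions changing particle number pick up `ΔG°→* × Σν`
(signed stoichiometric coefficients; −1 for A + B → AB). The identity
`total_liberational = translational + standard_state_shift` holds exactly by
construction and is property-tested.

One frequency list per record is shared across solvents. Solvent-specific
frequency sets are rare in practice and would complicate the schema; the
consequence is that thermal terms cancel exactly in every transfer
difference, which is also what makes target-inverting generators possible.
Physical constants are CODATA values from `scipy.constants`.
`ThermoProtocol.external_dof=False` suppresses translation and rotation for
degenerate/diagnostic evaluations only.

## Transfer, pairing, dimerisation (transfer_cycles)

Membrane crossing is approximated by water → hexane transfer,
`Δ_t G*(S) = G*(S, hexane) − G*(S, water)`. Crossing as a neutral aggregate
is the two-step cycle: aqueous association `Δ_ip G*(aq)` (including the
particle-number term, so association of two particles is *favoured* by
8.0 kJ/mol relative to the raw free-energy difference) followed by transfer
of the aggregate. The **ion-pair preference** is
`(Δ_ip G* + Δ_t G*(aggregate)) − Δ_t G*(baseline)`, negative when the paired
route is cheaper. The baseline is always the phosphonium-bearing free
species (the cation for cation·Cl⁻ pairs, the zwitterion for Na⁺ pairs and
dimers) — the only convention under which the published derived columns
close arithmetically (58 − 44 = 14 etc.). Dimer energies are per mole of
monomer throughout, with an explicit flag.

The packaged reference dataset stores the published component values
exactly as printed. Recomputing the derived columns by integer arithmetic
(round-half-away-from-zero) reproduces most rows exactly; a few differ by
1–3 kJ/mol because the original derived columns came from unrounded
underlying values (e.g. the CH₂-dimer conformer-2 row prints components
30 + 12 next to a combined value of 41). `table_discrepancies` reports
these side by side instead of silently preferring either number.

## Relative pKa (pka_reference)

pKa is predicted *relative to a reference acid* with known experimental
pKa: `pKa(HA) = lg(e) ΔG_a(HA)/(RT) + pKa_expt(HRef) − pKa_calc(HRef)`,
with `ΔG_a = G*(A⁻) − G*(HA)`. The proton's solvation free energy cancels;
one pKa unit corresponds to RT ln 10 = 5.708 kJ/mol at 298.15 K (pKa work
defaults to 298.15 K, the protocol temperature, not physiological T).
Predictions from several anchors are combined as **mean ± half-range** —
the only reading under which {2.4, 2.6} aggregates to 2.5 ± 0.1. Because
the prediction is affine in ΔG_a, the difference between two anchors'
predictions is compound-independent; `reference_consistency_offset` checks
this constancy (tolerance: twice the rounding quantum) as a table-level
sanity diagnostic.

## Equilibrium accumulation (speciation_accumulation)

Protonation follows Henderson–Hasselbalch,
`f_HA = 1/(1 + 10^(pH − pKa))`; a permeant monocation distributes by the
Nernst equation `exp(−zFΔψ/RT)` (Δψ in mV, negative-inside — the sign
convention is stated in every interface because it is the classic bug).
For a TPP weak acid whose protonated cation is the only permeant form, the
total accumulation ratio is

    ACR = exp(−zFΔψ/RT) × (1 + 10^(pH_in − pKa)) / (1 + 10^(pH_out − pKa)),

the equilibrium model for pH-gradient-enhanced uptake; the speciation
quotient alone is the pH-enhancement factor, bounded by 10^ΔpH and ≈ 6.3
for pKa 4.9 between pH 7.2 and 8.0. Defaults: pH 7.2/8.0, 310.15 K.
The nigericin comparison collapses ΔpH to zero while making Δψ more
negative by a stated shift; a pure cation's ACR then rises while the
acid:control ACR ratio falls. This module is purely thermodynamic — the
observation that low-pKa acids show no *net* uptake is kinetic and handled
by the flux simulator. Hydrophobic adsorption to membranes is deliberately
not modelled.

## Kinetic model (flux_simulator)

Two well-mixed compartments (external medium, matrix) exchange through
mass-action fluxes:

* cationic forms (ester cation, protonated acid):
  `J = k (c_out − c_in exp(zFΔψ/RT)) V_ref`, whose fixed point is exactly
  the Nernst ratio — the simplest flux law consistent with the equilibrium
  model above;
* neutral dimer (and optionally the bare zwitterion):
  `J = k (c_out − c_in) V_ref`, potential-independent;
* matrix hydrolysis: first-order ester → acid.

Protonation and dimerisation are **instantaneous equilibria** within each
compartment (they are fast relative to permeation; resolving them would
make the system needlessly stiff). The dynamic state is therefore four
amounts (ester and total acid pool per compartment); the pool is split at
evaluation time by a cancellation-free quadratic
(`c_HA + c_Z + 2Kc_Z² = c_T` with `c_Z/c_HA = 10^(pH−pKa)`).
`K_dimer` can be tied to a computed dimerisation free energy via
`K = exp(−Δ_ip G*/RT)`.

Defaults: matrix:medium volume ratio 5 × 10⁻⁴ (1 µL matrix per mg protein
at 0.5 mg/mL in 2 mL), Δψ −160 mV, pH 7.2/8.0, 310.15 K. Rate constants
(permeation 0.05 s⁻¹, hydrolysis 0.01 s⁻¹, K_dimer 10³ M⁻¹) are structural
choices giving minute-scale uptake/hydrolysis/efflux; no measured rates
exist for this mechanism, so every simulator claim is directional (which
pathway dominates, which way a perturbation moves the system), never a
quantitative fit. `k_zwitterion_perm` defaults to 0 — the bare zwitterion
is taken to be impermeant; whether trace monomer permeation contributes is
an open question the parameter leaves accessible.

Integration uses `scipy.integrate.solve_ivp` (LSODA, rtol 1e-10, atol
scaled to the total amount), segmented at the breakpoints of the
piecewise-constant potential program so events are honoured exactly.
Uncoupling truncates the program and appends a 0 mV segment; resuspension
zeroes the external amounts, optionally with a fresh external volume, and
holds the potential in force at the event constant afterwards (later
breakpoints are dropped — the experiments this mirrors keep a constant
potential after resuspension). Total phosphonium
(ester + acid + 2 × dimer over both compartments) is conserved by
construction and checked to ≤ 1e-8 relative in tests.

## Synthetic data and what passing tests show

Generators invert the forward mathematics rather than sampling plausible
chemistry: species records back-solve electronic energies from target
transfer free energies; acid systems back-solve ΔG_a from target pKa values
using mutually consistent anchors; flux truth-cases pair a scenario with
the closed-form steady state of its regime (detailed balance; absorbing
lock-in; conserved-pool partitioning 1/(1 + V_out/V_in)). The lock-in
regime uses a 100:1 volume ratio and faster permeation than the defaults so
its absorbing state is reached on a few-thousand-second horizon; the
dimer-leak regime keeps the 2000:1 ratio. All randomness flows through one
seeded `numpy` generator.

Consequently, green tests demonstrate that the *algebra and numerics* are
right — standard-state bookkeeping, cycle closure, pKa anchoring,
conservation, fixed points — and that the published desk-scale numbers are
reproduced from the packaged component energies. They do not validate the
underlying electronic-structure energies (inputs here), real membrane
kinetics (no measured rates), adsorption, or a third compartment; those are
out of scope.

## Numerical choices and edge cases

* Rounding for table reproduction: integers, half away from zero;
  pKa and free-energy reports 1 decimal place — the precision of the
  published values. ±1 integer discrepancies are flagged as rounding, not
  failures.
* Degenerate rotors: all moments zero → monatomic (no rotation; vibrational
  modes then rejected as unphysical); exactly one zero → linear (single
  nonzero moment used); two zeros with a nonzero third → rejected.
* Empty frequency lists are valid (atoms); empty prediction lists and empty
  summary baselines are errors, not silent defaults.
* Speciation quadratic solved as `2c_T/(a + sqrt(a² + 8Kc_T))` to avoid
  cancellation at small K c_T.
* Acceptance-style runs use 31–121-point grids over 300–6000 s horizons;
  LSODA's adaptive stepping makes the reported values insensitive to grid
  density (checked by a convergence test).
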