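# Annotated example of a flux-simulator scenario for `mitoperm simulate`.
#
# Volumes in litres; the default geometry mirrors a mitochondrial
# incubation (~1 uL matrix per mg protein, 0.5 mg/mL in 2 mL).  The
# membrane potential program is piecewise constant [time_s, mV] with the
# negative-inside convention; appending [300.0, 0.0] would model adding an
# uncoupler at t = 300 s.  Rates are per second on the matrix-volume
# concentration scale; K_dimer is the aqueous zwitterion-dimerisation
# equilibrium constant in 1/M.
scenario:
  volume_out: 2.0e-3
  volume_in: 1.0e-6
  pH_out: 7.2
  pH_in: 8.0
  membrane_potential_program:
    - [0.0, -160.0]
  pKa: 2.5
  temperature: 310.15
rates:
  k_cation_perm: 0.5
  k_hydrolysis: 0.05
  K_dimer: 1.0e4
  k_dimer_perm: 0.5
  k_zwitterion_perm: 0.0
initial:
  ester_out: 1.0e-8      # mol; 5 uM in 2 mL
  ester_in: 0.0
  acid_out: 0.0
  acid_in: 0.0
time_grid:
  start: 0.0
  stop: 600.0
  n: 121
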