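# Annotated example of the species-record schema (mitoperm-species/1).
#
# One document lists any number of species.  Energies are electronic +
# solvation free energies in kJ/mol on a common reference declared by the
# producer of the file; mitoperm only ever uses differences, so the absolute
# offset is irrelevant.  Frequencies are harmonic wavenumbers in cm^-1 and
# must all be positive (structures with imaginary modes are rejected).
# Moments of inertia are the three principal values in amu*A^2: all zero
# marks a monatomic species, exactly one zero a linear one.
schema: mitoperm-species/1
units:
  energy: kJ/mol
  frequency: cm^-1
  mass: amu
  inertia: amu*A^2
species:
  - name: demo-cation
    charge: 1
    n_monomers: 1          # 2 for zwitterion dimers (per-monomer reporting)
    mass: 277.3
    moments_of_inertia: [1500.0, 2500.0, 3500.0]
    symmetry_number: 1
    frequencies: [85.0, 120.0, 410.0, 995.0, 1600.0, 3010.0]
    energy_by_solvent:
      aqueous: -120.0
      apolar: -76.0        # transfer = -76 - (-120) = 44 kJ/mol
  - name: chloride
    charge: -1
    n_monomers: 1
    mass: 35.45
    moments_of_inertia: [0.0, 0.0, 0.0]   # monatomic: no rotation
    symmetry_number: 1
    frequencies: []
    energy_by_solvent:
      aqueous: -310.0
      apolar: -153.0
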