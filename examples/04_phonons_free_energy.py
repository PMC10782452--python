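"""Harmonic phonons and vibrational free energy with embedded forces.

Finite displacements (0.005 A) are generated in a phonon supercell, each
displaced supercell gets embedded high-level forces (periodic low level
plus monomer/dimer corrections), force constants follow by central
differences, and the dynamical matrix is sampled on a q-grid. The result
is the phonon spectrum, zero-point energy and harmonic Helmholtz free
energy per molecule.
"""

import numpy as np

import multembed as me

crystal = me.make_toy_molecular_crystal("diatomic", "cubic", a=4.0, z=1,
                                        jitter=0.03, seed=2)
low = me.make_calculator(me.ToyPotentialSpec(pair_enabled=False), "low")
high = me.make_calculator(me.ToyPotentialSpec(pair_enabled=True, r_c=3.5),
                          "high")

plan, records = me.generate_displacements(crystal, amplitude=0.005,
                                          min_length=7.9)
print(f"phonon supercell {plan.repeats}, {len(plan.crystal)} atoms, "
      f"{len(records)} displacements")
force_sets = me.corrected_force_sets(low, high, plan, records, cutoff=3.5)
ph = me.harmonic_spectrum(force_sets, q_min_length=20.0)

gamma = ph.frequencies[0]
print(f"Gamma frequencies (cm^-1): {np.round(gamma, 2)}")
print(f"ZPVE: {ph.zpve:.4f} kJ/mol per molecule")
for t in (100.0, 200.0, 300.0):
    print(f"F_vib({t:.0f} K) = {ph.free_energy(t):+.4f} kJ/mol per molecule")

# The three near-zero entries are the acoustic modes; the high modes are
# the intramolecular stretches. F_vib decreases with temperature as the
# entropic -T S_vib term grows.
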