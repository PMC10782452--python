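"""Murnaghan equation of state from embedded single-point energies.

Scans the unit-cell volume of a toy crystal, computes the dimer-level
embedded energy at each volume and fits the Murnaghan form to locate the
equilibrium volume V0 and bulk modulus B0 - the same workflow used to
cross-validate the embedded stress tensor against lattice relaxations.
"""

import numpy as np

import multembed as me

base = me.make_toy_molecular_crystal("diatomic", "cubic", a=4.0, z=1)
low = me.make_calculator(me.ToyPotentialSpec(pair_enabled=False), "low")
spec_high = me.ToyPotentialSpec(pair_enabled=True, r_c=5.0)
high = me.make_calculator(spec_high, "high")

scales = np.linspace(0.96, 1.06, 9)
volumes, energies = [], []
for s in scales:
    crystal = me.Crystal(base.lattice * s, base.species,
                         base.positions * s, pbc=True)
    res = me.embed_energy(low, high, crystal, order=2, cutoff=5.0)
    volumes.append(crystal.volume)
    energies.append(res.energy)
    print(f"a = {4.0 * s:.3f} A  V = {crystal.volume:8.3f} A^3  "
          f"E = {res.energy:+.6f} eV")

fit = me.fit_murnaghan(volumes, energies)
print(f"\nMurnaghan fit: V0 = {fit['V0']:.3f} A^3, "
      f"E0 = {fit['E0']:+.6f} eV, B0 = {fit['B0']:.4f} eV/A^3 "
      f"({fit['B0']*160.2176:.2f} GPa), B0' = {fit['B0p']:.3f}")
print(f"fit residual: {fit['residual']:.2e} eV")

# V0 marks the equilibrium volume of the embedded (= high-level, here
# exactly) potential energy surface; B0 is its curvature, the bulk modulus.
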