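# multembed

Subtractive multimer embedding for molecular crystals: approximate an
expensive periodic "high-level" method (e.g. a hybrid density functional)
by a cheap periodic "low-level" calculation plus monomer, dimer and trimer
corrections evaluated on isolated fragments — for energies, forces, stress
tensors and finite-displacement harmonic phonons.

## Who this is for

Molecular-crystal modellers (lattice energies, polymorph ranking, crystal
structure prediction, vibrational free energies) who need hybrid-level
accuracy but cannot afford fully periodic hybrid calculations. Fragment
corrections replace the periodic high-level calculation with a modest
number of isolated monomer/dimer/trimer calculations, reused across
symmetry-equivalent copies.

## The model

The periodic high-level energy is approximated as

```
E_per^high ≈ E_per^low + Σ_i n_i ΔE_i
           + Σ_{i<j} (n_ij/2) ΔE_ij^int
           + Σ_{i<j<k} (n_ijk/3) ΔE3_ijk
```

where every `Δ` is a high-minus-low difference on the same isolated
geometry, `E_ij^int = E(ij) − E(i) − E(j)` is the dimer interaction
energy, `ΔE3` the nonadditive three-body energy, and `n` counts the
multimer's molecules inside the reference unit cell. Dimers and trimers
enter when their shortest intermolecular atom–atom distance is below a
cutoff (all three pairs, for trimers). Forces and the virial stress are
corrected analogously up to the dimer level, which is what lattice
relaxation and phonon force sets use. Symmetry-equivalent multimers are
merged by a permutation-aware RMSD so each unique fragment is computed
once. See `docs/methods.md` for the full account.

Verification is built in: for analytic toy potentials of strictly finite
range the embedding is *exactly* solvable against brute-force periodic
lattice sums, and the test suite holds it to machine precision.

## Worked example

Lattice energy of a toy crystal, order by order
(`python examples/02_embedded_lattice_energy.py`):

```
periodic high-level lattice energy (oracle): -26.933934 kJ/mol
ME1 (monomers)    : -0.093359 kJ/mol  (error +2.68e+01)
ME2 (+ dimers)    : -27.104320 kJ/mol  (error -1.70e-01)
ME3 (+ trimers)   : -26.933934 kJ/mol  (error +7.11e-15)
```

Monomer corrections alone miss the intermolecular binding entirely; dimer
corrections recover it to a fraction of a kJ/mol; trimer corrections make
the embedding exact here because the toy high level contains nothing
beyond three-molecule interactions within the cutoff.

Enumerating the multimers of the ammonia crystal
(`python examples/01_enumerate_multimers.py`):

```
ammonia cell: 16 atoms, 4 molecules
dimers: 42 instances (total central-cell weight 48) -> 2 unique, multiplicities [21, 21]
trimers: 76 instances (total central-cell weight 96) -> 4 unique, multiplicities [10, 30, 27, 9]
```

A 3 Å-cutoff trimer-level calculation would need 42 dimer and 76 trimer
fragment evaluations without symmetry; deduplication reduces that to a
handful of unique fragments whose corrections are reused via their
multiplicities.

Other examples: embedded forces/stress vs the periodic oracle (`03`),
phonons and vibrational free energies from corrected force sets (`04`),
and a Murnaghan equation-of-state fit of embedded energies (`05`).

## Command line

A thin CLI wraps the library:

```
multembed --task enumerate --structure ammonia.cif --cutoff 3.0 --out report.json
multembed --task energy --structure crystal.extxyz --order 3 --cutoff 4.0 \
          --low toy-low --high toy-high-3b --out report.json
```

Tasks: `energy`, `latt`, `forces`, `stress`, `phonon`, `enumerate`.
Structures are read from CIF (symmetry expanded to P1) or extended XYZ; a
YAML config file (`--config`) may replace flags, and giving a field in
both places is an explicit error. Reports are deterministic JSON
documents echoing the configuration.

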