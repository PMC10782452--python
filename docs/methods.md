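# Methods

## The subtractive multimer embedding model

`multembed` approximates the result of an expensive periodic calculation
("high level", e.g. a hybrid density functional) by a cheap periodic
calculation ("low level", e.g. a GGA functional) plus corrections evaluated
on isolated fragments — whole molecules (monomers), pairs (dimers) and
triples (trimers) extracted from the crystal:

    E_per^high ≈ E_per^low + Σ_i n_i ΔE_i
                + Σ_{i<j} (n_ij / 2) ΔE_ij^int
                + Σ_{i<j<k} (n_ijk / 3) ΔE3_ijk

Every Δ is a high-minus-low difference of the same quantity evaluated on
the same isolated geometry. `E_ij^int = E(ij) − E(i) − E(j)` is the dimer
interaction energy, and the trimer term uses the *nonadditive* three-body
energy `E3_ijk = E_ijk^int − E_ij^int − E_ik^int − E_jk^int`, which is what
remains of a trimer's interaction after its three dimer interactions are
removed. The sums run over the molecules of a supercell; `n` counts how
many of a multimer's monomers lie in the reference unit cell, so a multimer
shared between cells contributes only its per-cell share.

Two assembly choices deserve justification because they are genuinely open:

- **The `n/k` prefactor** (k = multimer order). With it, summing the
  corrections over all multimers of the supercell reproduces, term by term,
  the periodic lattice sum of any finite-range intermolecular potential
  whose range the cutoff covers. Each translation class of dimers
  contributes its interaction exactly once per cell (a cell-internal dimer
  has n = 2, weight 2/2 = 1; a boundary-crossing dimer appears in two
  translated copies with n = 1, weight 1/2 each), and likewise for trimers
  with n/3. Any other prefactor breaks this telescoping.
- **Nonadditive trimer deltas.** Using the total trimer interaction of the
  three-molecule fragment would double-count every dimer correction already
  applied; the nonadditive combination adds exactly the three-body part.
  The total trimer interaction energy remains available as its own
  operation.

Both choices are enforced by the exactness tests: for a high level equal to
the low level plus a switched finite-range intermolecular pair potential,
dimer embedding with cutoff ≥ the potential range reproduces the
brute-force periodic high-level energy, forces and stress to machine
precision; adding a three-body term whose support obeys the all-pairs
cutoff rule, trimer embedding is exact again and the dimer→trimer
difference equals the per-cell three-body lattice energy.

The lattice energy per molecule is `E_latt = (E_cell/Z − E_mon)` converted
to kJ/mol (1 eV = 96.485332 kJ/mol), with `E_mon` the isolated-monomer
energy; it is negative for bound crystals.

## Multimer selection and supercell construction

Molecules are perceived from a covalent-radius heuristic: atoms A, B are
bonded iff `d(A,B) < 1.2 (r_cov(A) + r_cov(B))`, with bonds allowed to
cross periodic boundaries; each connected component is unwrapped into a
geometrically whole molecule, and a component that revisits an atom at a
different lattice offset is rejected as a covalent network. The 1.2 scale
is the standard heuristic; it is configurable per run and per element.

A dimer (trimer) is included when its shortest intermolecular atom–atom
distance is strictly below the multimer cutoff (for trimers, all three
molecular pairs must satisfy the rule). Distances are computed on the
unwrapped Cartesian geometries — no minimum image inside or between
molecules; the supercell provides the images explicitly. The supercell
replicates the unit cell by `m_i = ceil((cutoff + 2 D_mol + margin)/h_i)`
cells in direction i (`h_i` = perpendicular cell width, `D_mol` = largest
molecular diameter, margin 0.1 Å). The factor 2 on `D_mol` accounts for
both molecules of a candidate pair extending away from their reference
atoms; an enlargement-invariance test (adding one more cell per direction
changes nothing) validates the bound.

## Symmetry deduplication

Equivalent multimers are grouped by a permutation-aware RMSD: both
geometries are centred, their principal (geometric) inertia axes aligned —
trying the four proper axis-sign combinations, so mirror images are *never*
identified (chirality-safe) — the atom order of the second geometry is
re-matched within each element class by linear assignment (exact for a
fixed orientation), and rotation and permutation are then refined
alternately with Kabsch superposition until stable. For small systems the
result matches an exhaustive search over all element-preserving
permutations with optimal superposition per permutation.

The duplicate tolerance defaults to 1e-3 Å. That value targets realistic
use, where symmetry-equivalent fragments agree to optimizer/SCF noise; it
is far below the geometric gap between genuinely distinct multimer classes
in ordered crystals. Two caveats are documented deliberately:

- In *jittered* (deliberately desymmetrized) test crystals, instances are
  either exact translations (RMSD ~1e-15) or distinct by ≳1e-2 Å, so the
  machine-precision exactness tests use a 1e-8 Å tolerance; with the 1e-3
  default, borderline merges substitute a representative's correction and
  limit agreement to ~1e-7 eV.
- Exact-congruence grouping can merge *more* than crystal symmetry
  predicts: multimers that are accidentally congruent (identical
  interatomic-distance multisets) without a space-group operation relating
  them. Such merges are physically exact — congruent fragments have
  identical isolated energies — and are verified in the tests by comparing
  sorted distance multisets. For the cubic ammonia cell at a 3 Å cutoff
  this yields 4 unique trimer classes where a weaker inertia-only
  alignment produces up to 17.

## Forces and stress

Embedded forces (dimer level) are
`f(a) = f_per^low(a) + Δf_i(a) + Σ_j Δf_ij^int(a)` for atom a of
central-cell molecule i, with the dimer sum over all partners within the
cutoff in any cell, and `f_ij^int(a) = f_ij(a) − f_mono(a)` the interaction
force. The embedded stress is the analytic strain derivative of the
embedded energy:

    σ_pq = σ_pq^low − (1/V) Σ_multimers (n/k) Σ_a Δf_p(a) (r_q(a) − r_q^cm)

The sign and position reference were fixed operationally by requiring
agreement with central-difference strain derivatives of the embedded
energy (verified to ~1e-11 eV/Å³). Positions are referenced to each
multimer's centroid: since the correction forces of every multimer sum to
zero analytically, this makes the term exactly invariant under rigid
translations of the crystal without changing its value. Trimer-level
forces and stress are out of scope.

## Phonons

Harmonic phonons use finite displacements of ±0.005 Å along the Cartesian
axes in a supercell whose perpendicular widths all exceed 12 Å by default
(both configurable). Each displaced supercell is treated as a periodic
cell and given embedded (dimer-level) forces; force constants follow by
central differences; the dynamical matrix is diagonalized on a
Γ-centred q-grid with `n_i |a_i|` above 50 Å by default. "Symmetry
reduction" of displacements uses lattice translations only (reduced mode
displaces one copy of each primitive atom; brute-force mode displaces all
supercell atoms; both give identical force constants by construction —
point-group reduction is not implemented). An optional acoustic-sum-rule
projection absorbs row sums into the self-terms. Imaginary modes are
reported as negative cm⁻¹ magnitudes. LO-TO (non-analytic Γ) corrections
are not applied.

Thermodynamics: `F_vib(T) = (1/(W Z)) Σ_{q,s} w_q [ħω/2 +
k_B T ln(1 − e^(−ħω/k_B T))]` per molecule, CODATA constants, with modes
below 1e-2 cm⁻¹ (including imaginary ones) skipped; `F_vib(0)` is the
ZPVE. Tabulated 0–300 K in 10 K steps by default.

Efficiency: corrected force sets share one evaluation cache keyed by a
translation-invariant geometry hash (coordinates centred and rounded to
1e-8 Å), so every multimer untouched by a displacement is evaluated once
across the whole force-set run; brute-force mode disables sharing and must
agree exactly.

A numerical note: acoustic eigenvalues of the dynamical matrix sit at the
double-precision cancellation floor (~1e-16·‖D‖), and ν ∝ √λ amplifies
that to ~1e-5 cm⁻¹. Zero-frequency modes can therefore not be compared
more tightly than ~1e-4 cm⁻¹ in any double-precision pipeline; non-zero
modes agree with analytic references to better than 1e-9 cm⁻¹.

## The toy potentials (what the tests do and do not show)

The synthetic generator builds small molecular crystals (diatomic or
linear triatomic motifs, 1/2/4 molecules per cubic or orthorhombic cell,
seeded Gaussian jitter to break symmetry) and analytic potentials
implementing the calculator contract:

- intramolecular harmonic bonds (default k = 30 eV/Å², r0 = 1.1 Å);
- an intermolecular 12-6 pair potential (ε = 0.02 eV, σ = 2.8 Å) switched
  to zero over the last 0.5 Å before its cutoff with a C² quintic switch,
  so energies, forces and the virial are continuous and finite-difference
  checks are clean;
- optionally a three-body term `ν / (r12 r13 r23)³` (a simplified
  triple-dipole radial form) acting on atom triples spanning three
  distinct molecules, every pair distance switched below its own cutoff —
  mirroring the all-pairs trimer rule so trimer embedding can be exact.

The brute-force reference (`periodic_reference`) evaluates the same
potential by an explicit real-space sum over a block of image cells,
weighting each interaction instance by (central atoms)/(instance size); it
shares only the scalar potential formulas with the calculator, none of the
summation or weighting code, and the two agree to ≤1e-10 in all
quantities.

What passing these tests shows: the enumeration, weights, deduplication,
correction assembly, force/stress algebra and the phonon machinery are
exact for finite-range interactions. What it does not show: behaviour
under long-range electrostatics/Ewald sums, basis-set superposition
effects, SCF noise, or the *physical* convergence of the many-body
expansion for real intermolecular interactions — for a DFT pair the
embedding error is controlled by the compatibility of the two levels, not
by this implementation.

## Problem sizes and defaults used in the shipped tests

Toy crystals of 2–12 atoms (1–4 molecules) per cell; embedding cutoffs
3.5–5 Å; phonon supercells of 8 Å minimum width (16–32 atoms) and q-grids
from a 20 Å rule — sizes chosen so the whole suite and the acceptance
script run in well under a minute each while every exactness property is
tested at machine precision, where system size is irrelevant. The ammonia
worked example uses a 16-atom P2₁3 cell built from published
neutron-diffraction parameters; its multimer counts at a 3 Å cutoff are
stable under the small geometry differences between experimental and
optimized structures.

## Known limitations

- No counterpoise/BSSE handling; fragments are evaluated in vacuum.
- Trimer corrections for forces and stress are not implemented.
- No space-group-theoretic deduplication; grouping is geometric RMSD.
- Disorder/partial occupancy and covalent frameworks are rejected.
- The toy potentials contain no electrostatics; Ewald summation is out of
  scope.
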