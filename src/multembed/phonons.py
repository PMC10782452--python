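"""Harmonic phonons from finite displacements with embedded forces.

The pipeline mirrors the standard finite-displacement scheme: build a
phonon supercell whose perpendicular width exceeds a minimum length in
every direction, displace atoms by +/- a small amplitude along the
Cartesian axes, collect forces for every displaced supercell, assemble
force constants by central differences, and diagonalize the dynamical
matrix on a q-grid. The embedding enters only through the force sets: each
displaced supercell is treated as a periodic cell and its forces are the
embedded high-level forces (periodic low level + monomer/dimer
corrections), so the whole harmonic machinery downstream is agnostic of
the embedding.

Displacement "symmetry reduction" here exploits lattice translations: in
reduced mode only the primitive-cell atoms are displaced and the remaining
force-constant rows follow by translation; brute-force mode displaces
every supercell atom. Frequencies are reported in cm^-1 with imaginary
modes as negative magnitudes; thermodynamics (ZPVE, vibrational Helmholtz
free energy) are normalized per molecule.
"""

from __future__ import annotations

import itertools
from dataclasses import dataclass, field
from pathlib import Path

import numpy as np
from scipy import constants

from ._elements import atomic_mass
from .embedding import EV_TO_KJ_PER_MOL, EvalCache, embed_forces
from .structures import BondParams, Crystal, detect_molecules

#: sqrt(eV / (amu A^2)) expressed as a wavenumber in cm^-1
_EV_A2_AMU_TO_CM1 = (
    np.sqrt(constants.e / (constants.atomic_mass * 1e-20))
    / (2.0 * np.pi * constants.c * 100.0)
)
#: h c * (1 cm^-1) in eV
_CM1_TO_EV = constants.h * constants.c * 100.0 / constants.e
#: Boltzmann constant in eV/K
_KB_EV = constants.k / constants.e


@dataclass
class PhononSupercell:
    """A replicated primitive cell with atom <-> (primitive atom, cell) maps."""

    crystal: Crystal               # the supercell as a periodic structure
    primitive: Crystal
    repeats: tuple[int, int, int]
    atom_prim: np.ndarray          # supercell atom -> primitive atom index
    atom_cell: np.ndarray          # supercell atom -> integer cell offset (3,)

    @property
    def n_cells(self) -> int:
        return int(np.prod(self.repeats))


@dataclass
class DisplacementRecord:
    """One finite displacement of one supercell atom."""

    atom_index: int
    displacement: np.ndarray       # Cartesian A, |d| = amplitude

    def displaced(self, supercell: Crystal) -> Crystal:
        c = supercell.copy()
        c.positions[self.atom_index] = c.positions[self.atom_index] + self.displacement
        return c


@dataclass
class ForceSet:
    """Forces for every displacement of a phonon supercell."""

    plan: PhononSupercell
    records: list[tuple[DisplacementRecord, np.ndarray]] = field(default_factory=list)


@dataclass
class PhononResult:
    """Frequencies, DOS and harmonic thermodynamics."""

    qpoints: np.ndarray            # fractional, (nq, 3)
    weights: np.ndarray            # (nq,), sums to 1
    frequencies: np.ndarray        # (nq, 3N) cm^-1, sorted; imaginary negative
    n_molecules: int               # molecules per primitive cell (Z)
    zpve: float                    # kJ/mol per molecule
    temperatures: np.ndarray       # K
    f_vib: np.ndarray              # kJ/mol per molecule, per temperature
    dos_grid: np.ndarray | None = None
    dos: np.ndarray | None = None

    def free_energy(self, t: float) -> float:
        """F_vib(T) in kJ/mol per molecule (from the tabulated grid)."""
        return float(np.interp(t, self.temperatures, self.f_vib))


def build_phonon_supercell(crystal: Crystal, min_length: float = 12.0,
                           max_atoms: int = 20000) -> PhononSupercell:
    """Replicate the cell until every perpendicular width exceeds ``min_length``."""
    widths = crystal.perpendicular_widths()
    reps = tuple(int(np.floor(min_length / w)) + 1 for w in widths)
    n = len(crystal) * int(np.prod(reps))
    if n > max_atoms:
        raise ValueError(
            f"phonon supercell would contain {n} atoms (> {max_atoms}); "
            "raise max_atoms explicitly if this is intended")
    species: list[str] = []
    positions: list[np.ndarray] = []
    atom_prim: list[int] = []
    atom_cell: list[tuple[int, int, int]] = []
    for off in itertools.product(*[range(r) for r in reps]):
        shift = np.asarray(off, dtype=float) @ crystal.lattice
        for p in range(len(crystal)):
            species.append(crystal.species[p])
            positions.append(crystal.positions[p] + shift)
            atom_prim.append(p)
            atom_cell.append(off)
    sc = Crystal(crystal.lattice * np.asarray(reps, dtype=float)[:, None],
                 species, np.vstack(positions), pbc=True)
    return PhononSupercell(sc, crystal, reps, np.asarray(atom_prim),
                           np.asarray(atom_cell))


def generate_displacements(crystal: Crystal, amplitude: float = 0.005,
                           min_length: float = 12.0, mode: str = "reduced",
                           max_atoms: int = 20000
                           ) -> tuple[PhononSupercell, list[DisplacementRecord]]:
    """Create +/- Cartesian displacements on the phonon supercell.

    ``mode="reduced"`` displaces one copy of each primitive atom (the rest
    follow by lattice translation); ``mode="all"`` displaces every supercell
    atom (6N records), which is the brute-force reference.
    """
    if amplitude <= 0:
        raise ValueError("amplitude must be positive")
    plan = build_phonon_supercell(crystal, min_length, max_atoms)
    if mode == "reduced":
        targets = [int(np.where((plan.atom_prim == p)
                                & (plan.atom_cell == 0).all(axis=1))[0][0])
                   for p in range(len(crystal))]
    elif mode == "all":
        targets = list(range(len(plan.crystal)))
    else:
        raise ValueError("mode must be 'reduced' or 'all'")
    records = []
    for a in targets:
        for axis in range(3):
            for sign in (+1.0, -1.0):
                d = np.zeros(3)
                d[axis] = sign * amplitude
                records.append(DisplacementRecord(a, d))
    return plan, records


def corrected_force_sets(low, high, plan: PhononSupercell,
                         records: list[DisplacementRecord], cutoff: float,
                         mode: str = "efficient",
                         bond_params: BondParams | None = None,
                         cache: EvalCache | None = None) -> ForceSet:
    """Embedded high-level forces for every displaced supercell.

    Each displaced supercell is treated as the periodic cell and its forces
    are ``embed_forces`` of that geometry (dimer-level embedding). In
    ``efficient`` mode all records share one evaluation cache, so every
    multimer untouched by a displacement is computed once and reused; in
    ``brute`` mode every record is evaluated from scratch. Both modes
    produce identical forces.
    """
    if mode not in ("efficient", "brute"):
        raise ValueError("mode must be 'efficient' or 'brute'")
    shared = cache or EvalCache()
    fs = ForceSet(plan=plan)
    for rec in records:
        displaced = rec.displaced(plan.crystal)
        c = shared if mode == "efficient" else EvalCache()
        out = embed_forces(low, high, displaced, cutoff,
                           bond_params=bond_params, cache=c)
        fs.records.append((rec, out.forces))
    return fs


# ---------------------------------------------------------------------------
# force constants and the dynamical matrix


def force_constants(force_set: ForceSet) -> tuple[np.ndarray, list[int]]:
    """Central-difference force constants.

    Returns ``(phi, displaced_atoms)`` with ``phi[d, alpha, s, beta] =
    -dF_s,beta / d u_(displaced_atoms[d]),alpha`` in eV/A^2.
    """
    by_atom: dict[int, dict[tuple[int, int], np.ndarray]] = {}
    amp = None
    for rec, forces in force_set.records:
        d = rec.displacement
        axis = int(np.argmax(np.abs(d)))
        sign = 1 if d[axis] > 0 else -1
        amp = abs(float(d[axis]))
        by_atom.setdefault(rec.atom_index, {})[(axis, sign)] = forces
    displaced = sorted(by_atom)
    nsc = len(force_set.plan.crystal)
    phi = np.zeros((len(displaced), 3, nsc, 3))
    for di, a in enumerate(displaced):
        recs = by_atom[a]
        for axis in range(3):
            if (axis, 1) not in recs or (axis, -1) not in recs:
                raise ValueError(
                    f"incomplete force set: atom {a} axis {axis} lacks +/- pair")
            phi[di, axis] = -(recs[(axis, 1)] - recs[(axis, -1)]) / (2.0 * amp)
    return phi, displaced


def full_force_constants(phi_prim: np.ndarray, displaced: list[int],
                         plan: PhononSupercell) -> np.ndarray:
    """Expand primitive-row force constants to all supercell rows.

    Uses lattice translations: the row of atom (p, L) is the row of (p, 0)
    with columns permuted by the translation L (periodic wrap in the
    supercell). Input rows must be the cell-(0,0,0) primitive atoms.
    """
    nsc = len(plan.crystal)
    nprim = len(plan.primitive)
    reps = np.asarray(plan.repeats)
    # index lookup: (prim atom, cell offset) -> supercell atom
    lookup = {}
    for s in range(nsc):
        lookup[(int(plan.atom_prim[s]), tuple(int(x) for x in plan.atom_cell[s]))] = s
    row_of_prim = {}
    for di, a in enumerate(displaced):
        p = int(plan.atom_prim[a])
        if (plan.atom_cell[a] == 0).all():
            row_of_prim[p] = di
    if len(row_of_prim) != nprim:
        raise ValueError("need displaced rows for every primitive atom in cell 0")
    full = np.zeros((nsc, 3, nsc, 3))
    for s in range(nsc):
        p = int(plan.atom_prim[s])
        ls = plan.atom_cell[s]
        src = row_of_prim[p]
        for t in range(nsc):
            pt = int(plan.atom_prim[t])
            lt = (plan.atom_cell[t] - ls) % reps
            t_src = lookup[(pt, tuple(int(x) for x in lt))]
            full[s, :, t, :] = phi_prim[src, :, t_src, :]
    return full


def _apply_asr(phi: np.ndarray, displaced: list[int], plan: PhononSupercell
               ) -> np.ndarray:
    """Acoustic-sum-rule projection: self-terms absorb the row sums."""
    phi = phi.copy()
    for di, a in enumerate(displaced):
        rowsum = phi[di].sum(axis=1)            # (3, 3)
        phi[di, :, a, :] -= rowsum
    return phi


def dynamical_matrix(phi_prim: np.ndarray, displaced: list[int],
                     plan: PhononSupercell, q_frac: np.ndarray) -> np.ndarray:
    """Dynamical matrix at fractional q (of the primitive reciprocal cell)."""
    nprim = len(plan.primitive)
    reps = np.asarray(plan.repeats)
    masses = np.array([atomic_mass(s) for s in plan.primitive.species])
    row_of_prim = {}
    for di, a in enumerate(displaced):
        if (plan.atom_cell[a] == 0).all():
            row_of_prim[int(plan.atom_prim[a])] = di
    if len(row_of_prim) != nprim:
        raise ValueError("need displaced rows for every primitive atom in cell 0")
    # minimum-image cell offsets for smooth Fourier interpolation
    cells = plan.atom_cell.astype(int)
    centered = ((cells + reps // 2) % reps) - reps // 2
    phases = np.exp(2j * np.pi * (centered @ np.asarray(q_frac)))
    d = np.zeros((3 * nprim, 3 * nprim), dtype=complex)
    for p in range(nprim):
        row = phi_prim[row_of_prim[p]]          # (3, nsc, 3)
        for s in range(len(plan.crystal)):
            ps = int(plan.atom_prim[s])
            block = row[:, s, :] * phases[s]
            d[3 * p:3 * p + 3, 3 * ps:3 * ps + 3] += (
                block / np.sqrt(masses[p] * masses[ps]))
    return 0.5 * (d + d.conj().T)


def _frequencies_cm1(dyn: np.ndarray) -> np.ndarray:
    """Eigenfrequencies in cm^-1; imaginary modes as negative magnitudes."""
    evals = np.linalg.eigvalsh(dyn)
    return np.sort(np.sign(evals) * np.sqrt(np.abs(evals)) * _EV_A2_AMU_TO_CM1)


def qpoint_grid(crystal: Crystal, min_length: float = 50.0
                ) -> tuple[np.ndarray, np.ndarray]:
    """Uniform Gamma-centred q-grid satisfying n_i |a_i| > min_length."""
    lengths = np.linalg.norm(crystal.lattice, axis=1)
    ns = [int(np.floor(min_length / x)) + 1 for x in lengths]
    pts = [np.array(idx, dtype=float) / np.array(ns)
           for idx in itertools.product(*[range(n) for n in ns])]
    q = np.vstack(pts)
    w = np.full(len(q), 1.0 / len(q))
    return q, w


def harmonic_spectrum(force_set: ForceSet, q_min_length: float = 50.0,
                      asr: bool = True, acoustic_tol: float = 1e-2,
                      temperatures: np.ndarray | None = None,
                      bond_params: BondParams | None = None,
                      dos_points: int = 400, dos_sigma: float = 5.0
                      ) -> PhononResult:
    """Diagonalize the corrected force constants on a q-grid.

    Computes frequencies (cm^-1), a Gaussian-smeared DOS, the ZPVE and the
    harmonic vibrational Helmholtz free energy per molecule on a 0-300 K
    grid (10 K steps by default). Modes below ``acoustic_tol`` (cm^-1) are
    excluded from the thermodynamic sums.
    """
    plan = force_set.plan
    phi, displaced = force_constants(force_set)
    # reduce brute-force (all-atom) sets to the primitive rows
    if asr:
        phi = _apply_asr(phi, displaced, plan)
    qpts, weights = qpoint_grid(plan.primitive, q_min_length)
    freqs = np.vstack([
        _frequencies_cm1(dynamical_matrix(phi, displaced, plan, q))
        for q in qpts])
    z = len(detect_molecules(plan.primitive, bond_params))
    if temperatures is None:
        temperatures = np.arange(0.0, 301.0, 10.0)
    temperatures = np.asarray(temperatures, dtype=float)
    f_vib = np.array([
        vibrational_free_energy(freqs, weights, t, z, acoustic_tol)
        for t in temperatures])
    zpve = vibrational_free_energy(freqs, weights, 0.0, z, acoustic_tol)
    grid = np.linspace(min(freqs.min(), 0.0) - 3 * dos_sigma,
                       freqs.max() + 3 * dos_sigma, dos_points)
    dos = np.zeros_like(grid)
    for fq, w in zip(freqs, weights):
        for nu in fq:
            dos += w * np.exp(-0.5 * ((grid - nu) / dos_sigma) ** 2)
    dos /= dos_sigma * np.sqrt(2.0 * np.pi)
    return PhononResult(qpoints=qpts, weights=weights, frequencies=freqs,
                        n_molecules=z, zpve=zpve, temperatures=temperatures,
                        f_vib=f_vib, dos_grid=grid, dos=dos)


def vibrational_free_energy(frequencies: np.ndarray, weights: np.ndarray,
                            t: float, z: int, acoustic_tol: float = 1e-2
                            ) -> float:
    """Harmonic F_vib(T) in kJ/mol per molecule.

    ``F = (1/(W Z)) sum_q w_q sum_s [ h c nu / 2
    + k_B T ln(1 - exp(-h c nu / k_B T)) ]`` with modes below
    ``acoustic_tol`` cm^-1 (including imaginary ones) skipped. ``T = 0``
    returns the ZPVE.
    """
    if t < 0:
        raise ValueError("temperature must be non-negative")
    if z < 1:
        raise ValueError("Z must be at least 1")
    freqs = np.atleast_2d(np.asarray(frequencies, dtype=float))
    weights = np.asarray(weights, dtype=float)
    total_w = weights.sum()
    f = 0.0
    for fq, w in zip(freqs, weights):
        nu = fq[fq > acoustic_tol]
        e = nu * _CM1_TO_EV
        f += w * float((0.5 * e).sum())
        if t > 0:
            f += w * _KB_EV * t * float(np.log1p(-np.exp(-e / (_KB_EV * t))).sum())
    return f / (total_w * z) * EV_TO_KJ_PER_MOL


# ---------------------------------------------------------------------------
# FORCE_SETS text convention (phonopy-compatible)


def write_force_sets(path, force_set: ForceSet) -> None:
    """Write displacements + forces in the FORCE_SETS text convention."""
    lines = [str(len(force_set.plan.crystal)), str(len(force_set.records))]
    for rec, forces in force_set.records:
        lines.append("")
        lines.append(str(rec.atom_index + 1))
        lines.append(" ".join(f"{x:20.16f}" for x in rec.displacement))
        for f in forces:
            lines.append(" ".join(f"{x:15.10f}" for x in f))
    Path(path).write_text("\n".join(lines) + "\n")


def read_force_sets(path, plan: PhononSupercell) -> ForceSet:
    """Read a FORCE_SETS file back into a :class:`ForceSet`."""
    tokens = Path(path).read_text().split("\n")
    tokens = [t for t in tokens if t.strip()]
    natom = int(tokens[0])
    ndisp = int(tokens[1])
    if natom != len(plan.crystal):
        raise ValueError("FORCE_SETS atom count does not match the supercell")
    fs = ForceSet(plan=plan)
    pos = 2
    for _ in range(ndisp):
        atom = int(tokens[pos]) - 1
        disp = np.array([float(x) for x in tokens[pos + 1].split()])
        forces = np.array([[float(x) for x in tokens[pos + 2 + i].split()]
                           for i in range(natom)])
        fs.records.append((DisplacementRecord(atom, disp), forces))
        pos += 2 + natom
    return fs
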