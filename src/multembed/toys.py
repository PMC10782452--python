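"""Analytic toy potentials and toy molecular crystals.

These play the role of the low- and high-level electronic-structure
methods during verification: a cheap "low" level (intramolecular harmonic
bonds only) and a "high" level that adds finite-range *intermolecular*
terms — a smoothly switched 12-6 pair potential and, optionally, a
triple-dipole-like three-body term that is active only when all three pair
distances lie inside its cutoff. Because every added term has strictly
finite range, the subtractive multimer embedding of the high level into
the low level is *exact* once the multimer cutoff reaches the potential
range, which is what the test suite exploits.

Energies are eV, forces eV/A, stress eV/A^3. Forces are analytic
gradients; the stress is the analytic virial, both switched smoothly
(quintic switch, C^2) so finite-difference checks are clean.

:func:`periodic_reference` is a deliberately independent brute-force
lattice sum over an explicit block of image cells; it shares the scalar
potential formulas with :func:`make_calculator` but none of the summation
or weighting code.
"""

from __future__ import annotations

import itertools
from dataclasses import dataclass, field

import numpy as np
from scipy.spatial.distance import cdist

from .structures import BondParams, Cluster, Crystal, detect_molecules


@dataclass(frozen=True)
class ToyPotentialSpec:
    """Parameters of the analytic toy potential.

    intra : harmonic bond k (eV/A^2) and rest length r0 (A), applied to every
        perceived covalent bond.
    pair : 12-6 potential (well depth ``epsilon`` eV, size ``sigma`` A)
        between atoms of *different* molecules, smoothly switched to zero
        over ``[r_c - switch_width, r_c]``.
    three_body : product form ``nu / (r12 r13 r23)^3`` (nu in eV A^9) acting
        on atom triples that span *three distinct molecules* (a stand-in for
        nonadditive intermolecular dispersion); each pair distance is
        switched over ``[r_c3 - switch_width, r_c3]`` and the term vanishes
        unless all three distances are below ``r_c3``.
    """

    intra_enabled: bool = True
    intra_k: float = 30.0
    intra_r0: float = 1.10

    pair_enabled: bool = True
    epsilon: float = 0.02
    sigma: float = 2.8
    r_c: float = 6.0
    switch_width: float = 0.5

    three_body_enabled: bool = False
    nu: float = 50.0
    r_c3: float = 4.5

    bond_scale: float = 1.2

    def __post_init__(self):
        if self.pair_enabled and not (0 < self.switch_width < self.r_c):
            raise ValueError("switch width must lie in (0, r_c)")
        if self.three_body_enabled and not (0 < self.switch_width < self.r_c3):
            raise ValueError("switch width must lie in (0, r_c3)")

    @property
    def bond_params(self) -> BondParams:
        return BondParams(scale=self.bond_scale)

    @property
    def max_range(self) -> float:
        r = 0.0
        if self.pair_enabled:
            r = max(r, self.r_c)
        if self.three_body_enabled:
            r = max(r, self.r_c3)
        return r


# -- scalar potential pieces (shared by calculator and reference) -----------

def _switch(r: float, r_c: float, w: float) -> tuple[float, float]:
    """Quintic smoothstep from 1 at ``r_c - w`` down to 0 at ``r_c``.

    Returns (S, dS/dr)."""
    r_on = r_c - w
    if r <= r_on:
        return 1.0, 0.0
    if r >= r_c:
        return 0.0, 0.0
    t = (r - r_on) / w
    s = 1.0 - t ** 3 * (10.0 - 15.0 * t + 6.0 * t * t)
    ds = -(30.0 * t * t - 60.0 * t ** 3 + 30.0 * t ** 4) / w
    return s, ds


def pair_energy(r: float, spec: ToyPotentialSpec) -> tuple[float, float]:
    """Switched 12-6 pair energy and its r-derivative."""
    if r >= spec.r_c:
        return 0.0, 0.0
    sr6 = (spec.sigma / r) ** 6
    lj = 4.0 * spec.epsilon * (sr6 * sr6 - sr6)
    dlj = 4.0 * spec.epsilon * (-12.0 * sr6 * sr6 + 6.0 * sr6) / r
    s, ds = _switch(r, spec.r_c, spec.switch_width)
    return s * lj, s * dlj + ds * lj


def bond_energy(r: float, spec: ToyPotentialSpec) -> tuple[float, float]:
    """Harmonic bond energy and its r-derivative."""
    d = r - spec.intra_r0
    return 0.5 * spec.intra_k * d * d, spec.intra_k * d


def three_body_energy(r12: float, r13: float, r23: float, spec: ToyPotentialSpec
                      ) -> tuple[float, float, float, float]:
    """Switched triple-dipole-like product term.

    Returns (U, dU/dr12, dU/dr13, dU/dr23)."""
    rc, w = spec.r_c3, spec.switch_width
    if r12 >= rc or r13 >= rc or r23 >= rc:
        return 0.0, 0.0, 0.0, 0.0
    s12, ds12 = _switch(r12, rc, w)
    s13, ds13 = _switch(r13, rc, w)
    s23, ds23 = _switch(r23, rc, w)
    core = spec.nu / (r12 * r13 * r23) ** 3
    u = core * s12 * s13 * s23
    # product rule on s_ab * core, with d(core)/dr_ab = -3 core / r_ab
    d12 = s13 * s23 * (ds12 * core + s12 * (-3.0 * core / r12))
    d13 = s12 * s23 * (ds13 * core + s13 * (-3.0 * core / r13))
    d23 = s12 * s13 * (ds23 * core + s23 * (-3.0 * core / r23))
    return u, d12, d13, d23


# -- molecule bookkeeping ----------------------------------------------------

def _molecule_ids_and_bonds(structure, spec: ToyPotentialSpec
                            ) -> tuple[np.ndarray, np.ndarray, list[tuple[int, int]]]:
    """Unwrapped positions, per-atom molecule ids and intramolecular bond list.

    For a periodic crystal the positions are the unwrapped (whole-molecule)
    coordinates; for a cluster they are the input coordinates."""
    bp = spec.bond_params
    if isinstance(structure, Crystal) and structure.fully_periodic:
        monomers = detect_molecules(structure, bp)
        n = len(structure)
        pos = np.empty((n, 3))
        mol = np.empty(n, dtype=int)
        for mi, m in enumerate(monomers):
            pos[m.atom_indices] = m.unwrapped_positions
            mol[m.atom_indices] = mi
    else:
        pos = np.asarray(structure.positions, dtype=float)
        n = len(pos)
        d = cdist(pos, pos)
        radii = np.array([bp.radius(s) for s in structure.species])
        thr = bp.scale * (radii[:, None] + radii[None, :])
        adj = (d < thr) & ~np.eye(n, dtype=bool)
        mol = np.full(n, -1, dtype=int)
        comp = 0
        for start in range(n):
            if mol[start] >= 0:
                continue
            stack = [start]
            mol[start] = comp
            while stack:
                i = stack.pop()
                for j in np.where(adj[i])[0]:
                    if mol[j] < 0:
                        mol[j] = comp
                        stack.append(j)
            comp += 1
    # intramolecular bonds on (unwrapped) geometry
    bonds: list[tuple[int, int]] = []
    radii = np.array([bp.radius(s) for s in structure.species])
    thr = bp.scale * (radii[:, None] + radii[None, :])
    d = cdist(pos, pos)
    ii, jj = np.where((d < thr) & (mol[:, None] == mol[None, :]))
    for i, j in zip(ii.tolist(), jj.tolist()):
        if i < j:
            bonds.append((i, j))
    return pos, mol, bonds


# -- the calculator ----------------------------------------------------------

class ToyCalculator:
    """CalculatorContract implementation for :class:`ToyPotentialSpec`.

    ``evaluate(structure, periodic)`` returns ``{"energy", "forces"}`` and,
    for periodic structures, ``"stress"``. Deterministic; analytic forces
    and virial stress."""

    def __init__(self, spec: ToyPotentialSpec, name: str = "toy"):
        self.spec = spec
        self.name = name

    def evaluate(self, structure, periodic: bool) -> dict:
        if periodic:
            if not isinstance(structure, Crystal) or not structure.fully_periodic:
                raise ValueError("periodic evaluation requires a fully periodic Crystal")
            return self._evaluate_periodic(structure)
        return self._evaluate_isolated(structure)

    # isolated (gas-phase) mode: plain double/triple sums
    def _evaluate_isolated(self, structure) -> dict:
        spec = self.spec
        pos, mol, bonds = _molecule_ids_and_bonds(structure, spec)
        n = len(pos)
        energy = 0.0
        forces = np.zeros((n, 3))
        if spec.intra_enabled:
            for i, j in bonds:
                d = pos[j] - pos[i]
                r = float(np.linalg.norm(d))
                u, du = bond_energy(r, spec)
                energy += u
                g = du * d / r
                forces[i] += g
                forces[j] -= g
        if spec.pair_enabled:
            for i in range(n):
                for j in range(i + 1, n):
                    if mol[i] == mol[j]:
                        continue
                    d = pos[j] - pos[i]
                    r = float(np.linalg.norm(d))
                    if r >= spec.r_c:
                        continue
                    u, du = pair_energy(r, spec)
                    energy += u
                    g = du * d / r
                    forces[i] += g
                    forces[j] -= g
        if spec.three_body_enabled:
            for i, j, k in itertools.combinations(range(n), 3):
                if len({mol[i], mol[j], mol[k]}) != 3:
                    continue
                e, gi, gj, gk = self._triple_gradient(pos[i], pos[j], pos[k])
                energy += e
                forces[i] -= gi
                forces[j] -= gj
                forces[k] -= gk
        return {"energy": energy, "forces": forces}

    def _triple_gradient(self, ri, rj, rk):
        """Energy and gradients (dU/dr_x) of one three-body triple."""
        spec = self.spec
        d12 = rj - ri
        d13 = rk - ri
        d23 = rk - rj
        r12 = float(np.linalg.norm(d12))
        r13 = float(np.linalg.norm(d13))
        r23 = float(np.linalg.norm(d23))
        u, g12, g13, g23 = three_body_energy(r12, r13, r23, spec)
        if u == 0.0 and g12 == g13 == g23 == 0.0:
            z = np.zeros(3)
            return 0.0, z, z, z
        e12 = d12 / r12
        e13 = d13 / r13
        e23 = d23 / r23
        gi = -g12 * e12 - g13 * e13
        gj = g12 * e12 - g23 * e23
        gk = g13 * e13 + g23 * e23
        return u, gi, gj, gk

    # periodic mode: centered image-shell sums with uniform 1/k weights
    def _evaluate_periodic(self, crystal: Crystal) -> dict:
        spec = self.spec
        pos, mol, bonds = _molecule_ids_and_bonds(crystal, spec)
        n = len(pos)
        lat = crystal.lattice
        vol = crystal.volume
        energy = 0.0
        forces = np.zeros((n, 3))
        stress = np.zeros((3, 3))

        if spec.intra_enabled:
            for i, j in bonds:
                d = pos[j] - pos[i]
                r = float(np.linalg.norm(d))
                u, du = bond_energy(r, spec)
                energy += u
                g = du * d / r
                forces[i] += g
                forces[j] -= g
                stress += du / r * np.outer(d, d)

        rmax = spec.max_range
        if rmax > 0.0 and (spec.pair_enabled or spec.three_body_enabled):
            widths = crystal.perpendicular_widths()
            span = float(np.linalg.norm(pos.max(axis=0) - pos.min(axis=0)))
            ranges = [range(-m, m + 1) for m in
                      (int(np.ceil((rmax + span) / w)) + 1 for w in widths)]
            offsets = list(itertools.product(*ranges))
            shifts = [np.asarray(o, dtype=float) @ lat for o in offsets]
            ns = len(shifts)
            # image list, layout images[j*ns + oi] = pos[j] + shifts[oi]
            images = np.vstack([pos[j] + s for j in range(n) for s in shifts])
            img_atom = np.repeat(np.arange(n), ns)
            img_zero = np.zeros(len(images), dtype=bool)
            oi0 = offsets.index((0, 0, 0))
            img_zero[oi0::ns] = True
            for i in range(n):
                dvec = images - pos[i]
                dist = np.linalg.norm(dvec, axis=1)
                if spec.pair_enabled:
                    near = np.where((dist < spec.r_c) & (dist > 1e-9)
                                    & ~(img_zero & (mol[img_atom] == mol[i])))[0]
                    for idx in near:
                        r = float(dist[idx])
                        u, du = pair_energy(r, spec)
                        d = dvec[idx]
                        energy += 0.5 * u
                        forces[i] += du * d / r     # full pair force on centre
                        stress += 0.5 * du / r * np.outer(d, d)
                if spec.three_body_enabled:
                    cand = np.where((dist < spec.r_c3) & (dist > 1e-9))[0]
                    mol_i = (int(mol[i]), oi0)
                    for a_i in range(len(cand)):
                        for b_i in range(a_i + 1, len(cand)):
                            ia, ib = int(cand[a_i]), int(cand[b_i])
                            mol_a = (int(mol[img_atom[ia]]), ia % ns)
                            mol_b = (int(mol[img_atom[ib]]), ib % ns)
                            if len({mol_i, mol_a, mol_b}) != 3:
                                continue  # three distinct molecules only
                            rj, rk = images[ia], images[ib]
                            if np.linalg.norm(rk - rj) >= spec.r_c3:
                                continue
                            u, gi, gj, gk = self._triple_gradient(pos[i], rj, rk)
                            if u == 0.0:
                                continue
                            # each triple instance is visited once per vertex
                            # (3x in total) -> uniform 1/3 weights throughout
                            energy += u / 3.0
                            forces[i] -= gi / 3.0
                            forces[int(img_atom[ia])] -= gj / 3.0
                            forces[int(img_atom[ib])] -= gk / 3.0
                            stress += (np.outer(gi, pos[i]) + np.outer(gj, rj)
                                       + np.outer(gk, rk)) / 3.0
        stress = (stress + stress.T) / (2.0 * vol)
        return {"energy": energy, "forces": forces, "stress": stress}


def make_calculator(spec: ToyPotentialSpec, name: str = "toy") -> ToyCalculator:
    """Build a :class:`ToyCalculator` for the given potential spec."""
    return ToyCalculator(spec, name=name)


_MOTIFS = {
    # species, local coordinates (A); both motifs are centrosymmetric
    "diatomic": (("N", "N"), np.array([[0.0, 0.0, -0.55], [0.0, 0.0, 0.55]])),
    "triatomic": (("O", "C", "O"),
                  np.array([[0.0, 0.0, -1.16], [0.0, 0.0, 0.0], [0.0, 0.0, 1.16]])),
}

_Z_SITES = {
    1: [(0.5, 0.5, 0.5)],
    2: [(0.25, 0.25, 0.25), (0.75, 0.75, 0.75)],
    4: [(0.25, 0.25, 0.25), (0.75, 0.75, 0.25),
        (0.75, 0.25, 0.75), (0.25, 0.75, 0.75)],
}

_AXES = [np.eye(3),
         np.array([[0.0, 0.0, 1.0], [1.0, 0.0, 0.0], [0.0, 1.0, 0.0]]),
         np.array([[0.0, 1.0, 0.0], [0.0, 0.0, 1.0], [1.0, 0.0, 0.0]])]


def make_toy_molecular_crystal(motif: str = "diatomic", lattice: str = "cubic",
                               a: float = 4.0, z: int = 1, jitter: float = 0.0,
                               seed: int = 0) -> Crystal:
    """Build a reproducible toy molecular crystal.

    ``z`` molecules (1, 2 or 4) of the requested motif are placed at fixed
    fractional sites with deterministically rotated orientations; ``jitter``
    adds seeded per-atom Gaussian noise (A) to break symmetry. Raises if any
    two molecules come closer than 1 A (overlap guard).
    """
    if motif not in _MOTIFS:
        raise ValueError(f"unknown motif {motif!r}")
    if z not in _Z_SITES:
        raise ValueError(f"z must be one of {sorted(_Z_SITES)}")
    if lattice == "cubic":
        cell = np.diag([a, a, a])
    elif lattice == "orthorhombic":
        cell = np.diag([a, 1.15 * a, 1.3 * a])
    else:
        raise ValueError(f"unknown lattice {lattice!r}")
    species_motif, local = _MOTIFS[motif]
    rng = np.random.default_rng(seed)
    species: list[str] = []
    positions: list[np.ndarray] = []
    for k, site in enumerate(_Z_SITES[z]):
        center = np.asarray(site) @ cell
        rot = _AXES[k % 3]
        coords = local @ rot.T + center
        species.extend(species_motif)
        positions.append(coords)
    pos = np.vstack(positions)
    if jitter > 0.0:
        pos = pos + rng.normal(0.0, jitter, size=pos.shape)
    # overlap guard on the builder's own motif assignment: the check must
    # run before bond perception, which would misread overlapping motifs as
    # a percolating network
    mol_coords = np.split(pos, z)
    sep = _min_intermolecular_gap(cell, mol_coords)
    if sep < 1.0:
        raise ValueError(
            f"molecules overlap (min intermolecular distance {sep:.2f} A)")
    crystal = Crystal(cell, species, pos, pbc=True)
    monos = detect_molecules(crystal)
    if len(monos) != z:
        raise ValueError("molecule perception did not recover the requested z")
    return crystal


def _min_intermolecular_gap(cell: np.ndarray, mol_coords) -> float:
    best = np.inf
    for off in itertools.product((-1, 0, 1), repeat=3):
        shift = np.asarray(off, dtype=float) @ cell
        for mi, p1 in enumerate(mol_coords):
            for mj, p2 in enumerate(mol_coords):
                if off == (0, 0, 0) and mi == mj:
                    continue
                best = min(best, float(cdist(p1, p2 + shift).min()))
    return best


def periodic_reference(spec: ToyPotentialSpec, crystal: Crystal, radius: float
                       ) -> dict:
    """Brute-force periodic reference: explicit real-space lattice sum.

    Sums all pair/triple interaction instances involving at least one
    central-cell atom over an explicit block of image cells out to
    ``radius``, weighting each unordered instance by (number of central
    atoms)/(instance size). Independent of the summation code in
    :class:`ToyCalculator`; used as the oracle for the embedding exactness
    tests.
    """
    if radius < spec.max_range:
        raise ValueError("radius must cover the longest-ranged potential term")
    pos, mol, bonds = _molecule_ids_and_bonds(crystal, spec)
    n = len(pos)
    lat = crystal.lattice
    widths = crystal.perpendicular_widths()
    span = float(np.linalg.norm(pos.max(axis=0) - pos.min(axis=0)))
    m_counts = [int(np.ceil((radius + span) / w)) + 1 for w in widths]

    # explicit image atom list: (position, source atom, is_central)
    img_pos: list[np.ndarray] = []
    img_src: list[int] = []
    img_central: list[bool] = []
    img_mol: list[tuple[int, tuple[int, int, int]]] = []
    for off in itertools.product(*[range(-m, m + 1) for m in m_counts]):
        shift = np.asarray(off, dtype=float) @ lat
        for j in range(n):
            img_pos.append(pos[j] + shift)
            img_src.append(j)
            img_central.append(off == (0, 0, 0))
            img_mol.append((int(mol[j]), off))
    P = np.vstack(img_pos)
    src = np.asarray(img_src)
    central = np.asarray(img_central)

    energy = 0.0
    forces = np.zeros((n, 3))
    stress = np.zeros((3, 3))

    if spec.intra_enabled:
        for i, j in bonds:   # every central molecule's bonds, once each
            d = pos[j] - pos[i]
            r = float(np.linalg.norm(d))
            u, du = bond_energy(r, spec)
            energy += u
            forces[i] += du * d / r
            forces[j] -= du * d / r
            stress += du / r * np.outer(d, d)

    central_idx = np.where(central)[0]
    if spec.pair_enabled:
        for ia in central_idx:
            i = int(src[ia])
            dvec = P - P[ia]
            dist = np.linalg.norm(dvec, axis=1)
            for ib in np.where((dist < spec.r_c) & (dist > 1e-9))[0]:
                if img_mol[ia] == img_mol[int(ib)]:
                    continue  # intramolecular
                r = float(dist[ib])
                u, du = pair_energy(r, spec)
                d = dvec[ib]
                # unordered-instance weight n_c/2; the loop visits an
                # instance once per central endpoint
                energy += 0.5 * u
                forces[i] += du * d / r
                stress += 0.5 * du / r * np.outer(d, d)
    if spec.three_body_enabled:
        for ia in central_idx:
            i = int(src[ia])
            dvec = P - P[ia]
            dist = np.linalg.norm(dvec, axis=1)
            cand = np.where((dist < spec.r_c3) & (dist > 1e-9))[0]
            for x in range(len(cand)):
                for y in range(x + 1, len(cand)):
                    ib, ic = int(cand[x]), int(cand[y])
                    if len({img_mol[int(ia)], img_mol[ib], img_mol[ic]}) != 3:
                        continue  # three distinct molecules only
                    d_bc = float(np.linalg.norm(P[ic] - P[ib]))
                    if d_bc >= spec.r_c3:
                        continue
                    r_ab = float(dist[ib])
                    r_ac = float(dist[ic])
                    u, g_ab, g_ac, g_bc = three_body_energy(r_ab, r_ac, d_bc, spec)
                    if u == 0.0 and g_ab == g_ac == g_bc == 0.0:
                        continue
                    energy += u / 3.0
                    e_ab = dvec[ib] / r_ab
                    e_ac = dvec[ic] / r_ac
                    e_bc = (P[ic] - P[ib]) / d_bc
                    ga = -g_ab * e_ab - g_ac * e_ac      # dU/dr_a
                    gb = g_ab * e_ab - g_bc * e_bc
                    gc = g_ac * e_ac + g_bc * e_bc
                    forces[i] -= ga          # full force on the central vertex
                    # the b/c shares arrive when those vertices are central
                    stress += (np.outer(ga, P[ia]) + np.outer(gb, P[ib])
                               + np.outer(gc, P[ic])) / 3.0
    vol = crystal.volume
    stress = (stress + stress.T) / (2.0 * vol)
    return {"energy": energy, "forces": forces, "stress": stress}
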