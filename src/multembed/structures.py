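"""Periodic molecular crystals: containers, molecule perception, supercells.

A molecular crystal is represented by a :class:`Crystal` (cell vectors +
atoms). Molecules are perceived from a covalent-radii bond heuristic with
bonds allowed to cross periodic boundaries; every molecule is returned
*unwrapped*, i.e. geometrically whole, as a :class:`Monomer`. Supercells
sized for a given multimer cutoff are built by whole-molecule replication
so that any molecule that could lie within the cutoff of a central-cell
molecule is guaranteed to be present.

All coordinates are Cartesian Angstrom; fractional coordinates appear only
internally and at I/O boundaries. Energies elsewhere in the package are eV.
"""

from __future__ import annotations

import itertools
from dataclasses import dataclass, field

import numpy as np
from scipy.spatial.distance import cdist

from ._elements import covalent_radius


@dataclass(frozen=True)
class BondParams:
    """Covalent bond-perception parameters.

    Atoms A and B are bonded iff their distance is below
    ``scale * (r_cov(A) + r_cov(B))``. ``radii`` overrides the built-in
    covalent radii per element (useful for toy species).
    """

    scale: float = 1.2
    radii: dict[str, float] = field(default_factory=dict)

    def __post_init__(self) -> None:
        if self.scale <= 0:
            raise ValueError("bond scale must be positive")
        if any(r <= 0 for r in self.radii.values()):
            raise ValueError("covalent radii must be positive")

    def radius(self, symbol: str) -> float:
        if symbol in self.radii:
            return self.radii[symbol]
        return covalent_radius(symbol)

    def threshold(self, a: str, b: str) -> float:
        return self.scale * (self.radius(a) + self.radius(b))


class Crystal:
    """A periodic (or partially periodic) atomic structure.

    Parameters
    ----------
    lattice : (3, 3) array
        Cell vectors as rows, in Angstrom.
    species : sequence of str
        Element symbols, one per atom.
    positions : (N, 3) array
        Cartesian coordinates in Angstrom.
    pbc : bool or 3-tuple of bool
        Periodic boundary conditions per direction.
    """

    def __init__(self, lattice, species, positions, pbc=True):
        self.lattice = np.array(lattice, dtype=float).reshape(3, 3)
        self.species = tuple(str(s) for s in species)
        self.positions = np.array(positions, dtype=float).reshape(-1, 3)
        if isinstance(pbc, (bool, np.bool_)):
            pbc = (bool(pbc),) * 3
        self.pbc = tuple(bool(p) for p in pbc)
        if len(self.species) != len(self.positions):
            raise ValueError("species and positions must have equal length")
        if not np.all(np.isfinite(self.positions)):
            raise ValueError("positions must be finite")
        if not np.all(np.isfinite(self.lattice)):
            raise ValueError("lattice must be finite")
        if all(self.pbc) and abs(np.linalg.det(self.lattice)) <= 0:
            raise ValueError("fully periodic cell must have positive volume")

    def __len__(self) -> int:
        return len(self.species)

    @property
    def volume(self) -> float:
        """Unit-cell volume |det(lattice)| in cubic Angstrom."""
        return abs(float(np.linalg.det(self.lattice)))

    @property
    def fully_periodic(self) -> bool:
        return all(self.pbc)

    def fractional(self) -> np.ndarray:
        """Fractional coordinates of all atoms."""
        return self.positions @ np.linalg.inv(self.lattice)

    def perpendicular_widths(self) -> np.ndarray:
        """Perpendicular width of the cell along each lattice direction.

        h_i = V / |a_j x a_k|, the slab thickness available in direction i.
        """
        a, b, c = self.lattice
        v = abs(float(np.linalg.det(self.lattice)))
        return np.array([
            v / np.linalg.norm(np.cross(b, c)),
            v / np.linalg.norm(np.cross(c, a)),
            v / np.linalg.norm(np.cross(a, b)),
        ])

    def copy(self) -> "Crystal":
        return Crystal(self.lattice.copy(), self.species, self.positions.copy(), self.pbc)

    def __repr__(self) -> str:
        return f"Crystal(n_atoms={len(self)}, pbc={self.pbc})"


class Cluster:
    """An isolated (gas-phase) group of atoms, e.g. an extracted multimer."""

    def __init__(self, species, positions):
        self.species = tuple(str(s) for s in species)
        self.positions = np.array(positions, dtype=float).reshape(-1, 3)
        if len(self.species) != len(self.positions):
            raise ValueError("species and positions must have equal length")
        if not np.all(np.isfinite(self.positions)):
            raise ValueError("positions must be finite")

    def __len__(self) -> int:
        return len(self.species)

    def __repr__(self) -> str:
        return f"Cluster(n_atoms={len(self)})"


@dataclass(eq=False)
class Monomer:
    """A single whole molecule perceived in a crystal or supercell.

    ``unwrapped_positions`` resolve periodic images so the molecule is
    geometrically whole; ``cell_offset`` is the integer lattice translation
    of the molecule's reference atom (its smallest atom index);
    ``in_central_cell`` flags monomers whose reference atom lies in the
    (0,0,0) cell.
    """

    parent: object
    atom_indices: np.ndarray
    unwrapped_positions: np.ndarray
    cell_offset: tuple[int, int, int]
    in_central_cell: bool

    @property
    def species(self) -> tuple[str, ...]:
        return tuple(self.parent.species[i] for i in self.atom_indices)

    @property
    def centroid(self) -> np.ndarray:
        return self.unwrapped_positions.mean(axis=0)

    @property
    def diameter(self) -> float:
        """Largest intramolecular atom-atom distance."""
        if len(self.atom_indices) == 1:
            return 0.0
        d = cdist(self.unwrapped_positions, self.unwrapped_positions)
        return float(d.max())

    def as_cluster(self) -> Cluster:
        return Cluster(self.species, self.unwrapped_positions)

    def translated(self, shift: np.ndarray, cell_offset: tuple[int, int, int],
                   in_central_cell: bool, parent=None,
                   atom_indices: np.ndarray | None = None) -> "Monomer":
        return Monomer(
            parent=self.parent if parent is None else parent,
            atom_indices=self.atom_indices if atom_indices is None else atom_indices,
            unwrapped_positions=self.unwrapped_positions + shift,
            cell_offset=cell_offset,
            in_central_cell=in_central_cell,
        )


def _bond_image_range(crystal: Crystal, max_threshold: float) -> list[range]:
    widths = crystal.perpendicular_widths()
    out = []
    for i in range(3):
        if crystal.pbc[i]:
            m = int(np.ceil(max_threshold / widths[i]))
            out.append(range(-m, m + 1))
        else:
            out.append(range(0, 1))
    return out


def detect_molecules(crystal: Crystal, params: BondParams | None = None) -> list[Monomer]:
    """Perceive whole molecules in a periodic crystal.

    Atoms are bonded iff their distance (including periodic images) is below
    the covalent-radii threshold of ``params``. Each connected component is
    unwrapped into a geometrically whole molecule. Raises ``ValueError`` if a
    component percolates through the lattice (a covalent network rather than
    a molecular crystal).

    Returned monomers are ordered by their smallest atom index; every atom
    belongs to exactly one monomer.
    """
    params = params or BondParams()
    n = len(crystal)
    if n == 0:
        return []
    radii = np.array([params.radius(s) for s in crystal.species])
    thr = params.scale * (radii[:, None] + radii[None, :])

    # candidate bonds (i, j, image offset) with distance below threshold
    bonds: list[list[tuple[int, np.ndarray]]] = [[] for _ in range(n)]
    ranges = _bond_image_range(crystal, float(thr.max()))
    pos = crystal.positions
    lat = crystal.lattice
    for off in itertools.product(*ranges):
        shift = np.asarray(off, dtype=float) @ lat
        d = cdist(pos, pos + shift)
        ii, jj = np.where(d < thr)
        for i, j in zip(ii.tolist(), jj.tolist()):
            if i == j and off == (0, 0, 0):
                continue
            bonds[i].append((j, np.asarray(off, dtype=int)))

    # BFS with integer cell offsets; a revisit at a different offset means
    # the "molecule" is an infinite covalent network.
    assigned = np.full(n, -1, dtype=int)
    offsets = np.zeros((n, 3), dtype=int)
    monomers: list[Monomer] = []
    for start in range(n):
        if assigned[start] >= 0:
            continue
        comp = len(monomers)
        assigned[start] = comp
        offsets[start] = 0
        queue = [start]
        members = [start]
        while queue:
            i = queue.pop()
            for j, off in bonds[i]:
                total = offsets[i] + off
                if assigned[j] < 0:
                    assigned[j] = comp
                    offsets[j] = total
                    queue.append(j)
                    members.append(j)
                elif not np.array_equal(offsets[j], total):
                    raise ValueError(
                        "covalent network percolates through the lattice; "
                        "not a molecular crystal"
                    )
        members = sorted(members)
        idx = np.asarray(members, dtype=int)
        unwrapped = pos[idx] + offsets[idx].astype(float) @ lat
        # reference atom = smallest index; its home cell defines the offset
        frac_ref = unwrapped[0] @ np.linalg.inv(lat)
        cell_off = tuple(int(x) for x in np.floor(frac_ref + 1e-10))
        monomers.append(Monomer(
            parent=crystal,
            atom_indices=idx,
            unwrapped_positions=unwrapped,
            cell_offset=cell_off,
            in_central_cell=(cell_off == (0, 0, 0)),
        ))
    monomers.sort(key=lambda m: int(m.atom_indices[0]))
    return monomers


def min_intermolecular_distance(a: Monomer, b: Monomer) -> float:
    """Shortest atom-atom distance between two distinct monomers (Angstrom).

    Computed on the unwrapped Cartesian geometries (no minimum image)."""
    if a is b or (
        np.array_equal(a.atom_indices, b.atom_indices)
        and np.allclose(a.unwrapped_positions, b.unwrapped_positions)
    ):
        raise ValueError("a and b are the same supercell monomer")
    return float(cdist(a.unwrapped_positions, b.unwrapped_positions).min())


class Supercell(Crystal):
    """A replicated crystal carrying whole-molecule tags.

    Atoms of the central (0,0,0) cell come first and map one-to-one onto the
    parent crystal's atoms via ``central_map`` (supercell index of parent
    atom ``i`` is ``central_map[i]``). ``monomers`` lists every whole
    molecule in the supercell with its replication offset and central-cell
    flag; ``monomer_unit_index`` gives, per supercell monomer, the index of
    the parent-cell monomer it replicates.
    """

    def __init__(self, lattice, species, positions, parent: Crystal,
                 monomers: list[Monomer], monomer_unit_index: np.ndarray,
                 central_map: np.ndarray, repeats: tuple[int, int, int]):
        super().__init__(lattice, species, positions, pbc=parent.pbc)
        self.parent = parent
        self.monomers = monomers
        self.monomer_unit_index = monomer_unit_index
        self.central_map = central_map
        self.repeats = repeats

    @property
    def central_monomers(self) -> list[Monomer]:
        return [m for m in self.monomers if m.in_central_cell]


def build_supercell(crystal: Crystal, cutoff: float, margin: float = 0.1,
                    bond_params: BondParams | None = None) -> Supercell:
    """Build a supercell large enough for multimer enumeration at ``cutoff``.

    Molecules are first perceived in the unit cell and then replicated whole
    over lattice offsets ``-m_i..m_i`` with
    ``m_i = ceil((cutoff + 2 D_mol + margin) / h_i)`` where ``h_i`` is the
    perpendicular cell width and ``D_mol`` the largest molecular diameter.
    This guarantees that every molecule whose minimum intermolecular
    atom-atom distance to any central-cell molecule could be below the
    cutoff is present (atoms stray at most ``D_mol`` from their molecule's
    reference atom on either side).
    """
    if cutoff <= 0:
        raise ValueError("cutoff must be positive")
    if not crystal.fully_periodic:
        raise ValueError("supercell construction requires a fully periodic crystal")
    unit_monomers = detect_molecules(crystal, bond_params)
    d_mol = max(m.diameter for m in unit_monomers)
    widths = crystal.perpendicular_widths()
    reach = cutoff + 2.0 * d_mol + margin
    m_counts = tuple(int(np.ceil(reach / w)) for w in widths)

    offsets = [(0, 0, 0)] + sorted(
        (o for o in itertools.product(
            *[range(-m, m + 1) for m in m_counts]) if o != (0, 0, 0))
    )
    lat = crystal.lattice
    species: list[str] = []
    positions: list[np.ndarray] = []
    monomers: list[Monomer] = []
    unit_index: list[int] = []
    central_map = np.full(len(crystal), -1, dtype=int)
    sc = None  # assigned after construction; monomers re-parented below
    atom_counter = 0
    records = []  # (unit monomer idx, offset, atom index block)
    for off in offsets:
        shift = np.asarray(off, dtype=float) @ lat
        for k, mono in enumerate(unit_monomers):
            na = len(mono.atom_indices)
            block = np.arange(atom_counter, atom_counter + na)
            species.extend(mono.species)
            positions.append(mono.unwrapped_positions + shift)
            if off == (0, 0, 0):
                central_map[mono.atom_indices] = block
            records.append((k, off, block, shift))
            unit_index.append(k)
            atom_counter += na

    sc_lattice = lat * np.asarray(
        [2 * m + 1 for m in m_counts], dtype=float)[:, None]
    sc = Supercell(
        lattice=sc_lattice,
        species=species,
        positions=np.vstack(positions),
        parent=crystal,
        monomers=[],
        monomer_unit_index=np.asarray(unit_index, dtype=int),
        central_map=central_map,
        repeats=tuple(2 * m + 1 for m in m_counts),
    )
    for (k, off, block, shift) in records:
        mono = unit_monomers[k]
        total_off = tuple(int(a + b) for a, b in zip(mono.cell_offset, off))
        monomers.append(Monomer(
            parent=sc,
            atom_indices=block,
            unwrapped_positions=mono.unwrapped_positions + shift,
            cell_offset=total_off,
            in_central_cell=(off == (0, 0, 0)),
        ))
    sc.monomers = monomers
    return sc
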