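"""Structure I/O: extended XYZ (with ``Lattice=`` header) and CIF.

CIF reading goes through gemmi and expands the symmetry-generated sites to
P1, which is what the embedding pipeline works on. The extended-XYZ dialect
understood here is the common one: a comment line carrying
``Lattice="ax ay az bx by bz cx cy cz"`` plus an optional
``Properties=species:S:1:pos:R:3`` declaration and ``pbc=`` flags.
"""

from __future__ import annotations

import re
import shlex
from pathlib import Path

import numpy as np

from .structures import Cluster, Crystal


def read_structure(path) -> Crystal | Cluster:
    """Read a structure from a ``.cif`` / ``.xyz`` / ``.extxyz`` file."""
    p = Path(path)
    suffix = p.suffix.lower()
    if suffix == ".cif":
        return read_cif(p)
    if suffix in (".xyz", ".extxyz"):
        return read_extxyz(p)
    raise ValueError(f"unsupported structure format: {p.suffix!r}")


def read_cif(path) -> Crystal:
    """Read a CIF file, expanding symmetry to a P1 cell."""
    import gemmi

    st = gemmi.read_small_structure(str(path))
    if len(st.sites) == 0:
        raise ValueError(f"no atom sites found in {path}")
    cell = st.cell
    lattice = np.array(cell.orth.mat.tolist(), dtype=float).T  # rows = cell vectors
    species: list[str] = []
    frac: list[list[float]] = []
    seen: list[np.ndarray] = []
    for site in st.get_all_unit_cell_sites():
        f = np.array([site.fract.x, site.fract.y, site.fract.z]) % 1.0
        # get_all_unit_cell_sites already merges special positions; keep a
        # defensive duplicate check against numerically coincident sites.
        if any(np.linalg.norm(((f - g + 0.5) % 1.0) - 0.5) < 1e-4 for g in seen):
            continue
        seen.append(f)
        species.append(site.element.name)
        frac.append(f.tolist())
    positions = np.asarray(frac) @ lattice
    return Crystal(lattice, species, positions, pbc=True)


_KV_RE = re.compile(r"(\w+)=")


def _parse_comment(comment: str) -> dict[str, str]:
    out: dict[str, str] = {}
    for token in shlex.split(comment):
        if "=" in token:
            k, v = token.split("=", 1)
            out[k.lower()] = v
    return out


def read_extxyz(path) -> Crystal | Cluster:
    """Read the first frame of an (extended) XYZ file."""
    lines = Path(path).read_text().splitlines()
    if len(lines) < 2:
        raise ValueError(f"truncated XYZ file: {path}")
    n = int(lines[0].split()[0])
    fields = _parse_comment(lines[1])
    species: list[str] = []
    positions: list[list[float]] = []
    for line in lines[2:2 + n]:
        parts = line.split()
        species.append(parts[0])
        positions.append([float(x) for x in parts[1:4]])
    if len(species) != n:
        raise ValueError(f"XYZ header promises {n} atoms, found {len(species)}")
    if "lattice" in fields:
        vals = [float(x) for x in fields["lattice"].split()]
        if len(vals) != 9:
            raise ValueError("Lattice= must contain 9 numbers")
        lattice = np.array(vals).reshape(3, 3)
        pbc = (True, True, True)
        if "pbc" in fields:
            pbc = tuple(tok in ("T", "True", "1") for tok in fields["pbc"].split())
        return Crystal(lattice, species, positions, pbc=pbc)
    return Cluster(species, positions)


def write_extxyz(path, structure: Crystal | Cluster, comment_extra: str = "") -> None:
    """Write a structure as extended XYZ (positions kept to 1e-10 A)."""
    lines = [str(len(structure))]
    if isinstance(structure, Crystal):
        lat = " ".join(f"{x:.12f}" for x in structure.lattice.ravel())
        pbc = " ".join("T" if p else "F" for p in structure.pbc)
        header = f'Lattice="{lat}" Properties=species:S:1:pos:R:3 pbc="{pbc}"'
    else:
        header = "Properties=species:S:1:pos:R:3"
    if comment_extra:
        header += " " + comment_extra
    lines.append(header)
    for s, r in zip(structure.species, structure.positions):
        lines.append(f"{s:2s} {r[0]:.12f} {r[1]:.12f} {r[2]:.12f}")
    Path(path).write_text("\n".join(lines) + "\n")
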