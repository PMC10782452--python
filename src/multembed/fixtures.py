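"""Reference crystal fixtures for examples and tests.

The ammonia cell here is a *synthetic stand-in* constructed from published
neutron-diffraction crystallographic parameters of ammonia phase I (cubic
space group P2_1 3, Z = 4, N on the Wyckoff 4a site (u, u, u), H on the
general 12b site), not a deposited quantum-chemically optimized geometry.
Its geometric multimer counts at a 3 A cutoff (42 dimer and 76 trimer
instances) are robust to the small parameter differences between the
experimental and optimized structures.
"""

from __future__ import annotations

import numpy as np

from .structures import Crystal

#: CIF text for the synthetic ammonia phase-I cell (P2_1 3, a = 5.048 A).
AMMONIA_CIF = """\
data_ammonia_phase_I_synthetic
_cell_length_a     5.048
_cell_length_b     5.048
_cell_length_c     5.048
_cell_angle_alpha  90.0
_cell_angle_beta   90.0
_cell_angle_gamma  90.0
_space_group_name_H-M_alt  'P 21 3'
_space_group_IT_number     198
loop_
_space_group_symop_operation_xyz
'x, y, z'
'-x+1/2, -y, z+1/2'
'-x, y+1/2, -z+1/2'
'x+1/2, -y+1/2, -z'
'z, x, y'
'z+1/2, -x+1/2, -y'
'-z+1/2, -x, y+1/2'
'-z, x+1/2, -y+1/2'
'y, z, x'
'-y, z+1/2, -x+1/2'
'y+1/2, -z+1/2, -x'
'-y+1/2, -z, x+1/2'
loop_
_atom_site_label
_atom_site_type_symbol
_atom_site_fract_x
_atom_site_fract_y
_atom_site_fract_z
N1 N 0.2107 0.2107 0.2107
H1 H 0.3740 0.2616 0.1106
"""


def ammonia_crystal() -> Crystal:
    """The synthetic ammonia phase-I cell (16 atoms, 4 NH3 molecules).

    Built by expanding the P2_1 3 symmetry of :data:`AMMONIA_CIF` to P1.
    """
    import tempfile
    from pathlib import Path

    from .io import read_cif

    with tempfile.TemporaryDirectory() as td:
        p = Path(td) / "ammonia.cif"
        p.write_text(AMMONIA_CIF)
        crystal = read_cif(p)
    if len(crystal) != 16:
        raise RuntimeError("ammonia cell expansion produced an unexpected atom count")
    return crystal
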