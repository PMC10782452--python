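"""Enumerate and deduplicate the multimers of the ammonia crystal.

Builds the cubic ammonia phase-I cell (P2_1 3, Z = 4), extracts every dimer
and trimer whose shortest intermolecular atom-atom distance is below a 3 A
cutoff, and collapses symmetry-equivalent copies into unique representatives.
The instance counts are the number of fragment calculations a high-level
method would need without symmetry; the unique counts are what actually has
to be computed.
"""

import multembed as me
from multembed.fixtures import ammonia_crystal

crystal = ammonia_crystal()
print(f"ammonia cell: {len(crystal)} atoms, "
      f"{len(me.detect_molecules(crystal))} molecules")

supercell = me.build_supercell(crystal, cutoff=3.0)
for order, label in [(2, "dimers"), (3, "trimers")]:
    instances = me.enumerate_multimers(supercell, order, cutoff=3.0)
    unique = me.deduplicate(instances, tol=1e-3)
    weights = sum(i.weight for i in instances)
    print(f"{label}: {len(instances)} instances (total central-cell weight "
          f"{weights}) -> {len(unique)} unique, multiplicities "
          f"{[g.multiplicity for g in unique]}")

# Each unique multimer would be evaluated once at the high level and its
# correction reused for every symmetry-equivalent copy via the multiplicity.
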