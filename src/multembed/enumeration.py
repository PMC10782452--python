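"""Dimer/trimer enumeration, central-cell weights, and symmetry dedup.

Dimers are kept when their shortest intermolecular atom-atom distance is
strictly below the multimer cutoff; trimers require *all three* molecular
pairs to satisfy that rule. Every multimer carries a central-cell weight
``n`` (how many of its monomers lie in the reference unit cell); instances
with ``n = 0`` are never emitted, and each unordered pair/triple appears at
most once.

Symmetry-equivalent instances are collapsed into unique representatives by
a permutation-aware RMSD: the principal inertia axes of the two geometries
are aligned (proper rotations only, so enantiomers stay distinct), the
atom order of the second is optimally re-matched within each element class
by linear assignment, and the superposition is refined. Duplicate grouping
is greedy against existing representatives.
"""

from __future__ import annotations

import itertools
from dataclasses import dataclass, field

import numpy as np
from scipy.optimize import linear_sum_assignment
from scipy.spatial.distance import cdist

from .structures import Monomer, Supercell, min_intermolecular_distance

INF = float("inf")


@dataclass
class MultimerInstance:
    """A monomer/dimer/trimer instance extracted from the supercell."""

    order: int
    monomers: tuple[Monomer, ...]
    weight: int                      # n = number of central-cell constituents
    pair_min_distances: tuple[float, ...]
    unit_ids: tuple[int, ...] = ()   # parent-cell monomer ids, for bookkeeping
    sc_ids: tuple[int, ...] = ()     # supercell monomer indices

    @property
    def species(self) -> tuple[str, ...]:
        return tuple(s for m in self.monomers for s in m.species)

    @property
    def positions(self) -> np.ndarray:
        return np.vstack([m.unwrapped_positions for m in self.monomers])


@dataclass
class UniqueMultimer:
    """A group of symmetry-equivalent instances with summed weight."""

    representative_species: tuple[str, ...]
    representative_positions: np.ndarray
    instances: list[MultimerInstance] = field(default_factory=list)

    @property
    def total_weight(self) -> int:
        return sum(inst.weight for inst in self.instances)

    @property
    def multiplicity(self) -> int:
        return len(self.instances)


def _monomer_key(sc: Supercell, idx: int) -> tuple:
    m = sc.monomers[idx]
    return (int(sc.monomer_unit_index[idx]), m.cell_offset)


def enumerate_multimers(supercell: Supercell, order: int, cutoff: float
                        ) -> list[MultimerInstance]:
    """Enumerate all dimer (order 2) or trimer (order 3) instances.

    Each unordered pair/triple is emitted once, with its central-cell weight
    ``n``; only instances with ``n > 0`` are returned, in a deterministic
    order (sorted by constituent monomer indices).
    """
    if order not in (2, 3):
        raise ValueError("order must be 2 or 3")
    _check_coverage(supercell, cutoff)
    monos = supercell.monomers
    nmono = len(monos)
    central = [i for i in range(nmono) if monos[i].in_central_cell]
    central_set = set(central)

    # coarse prefilter on centroid distances
    centroids = np.vstack([m.centroid for m in monos])
    radii = np.array([
        cdist(m.unwrapped_positions, m.centroid[None]).max() if len(m.atom_indices) > 1
        else 0.0 for m in monos])

    def within(i: int, j: int) -> float | None:
        """min intermolecular distance if possibly < cutoff, else None."""
        gap = np.linalg.norm(centroids[i] - centroids[j]) - radii[i] - radii[j]
        if gap >= cutoff:
            return None
        d = min_intermolecular_distance(monos[i], monos[j])
        return d if d < cutoff else None

    # neighbour sets of central monomers (needed for both orders)
    neighbors: dict[int, dict[int, float]] = {}
    for i in central:
        nb: dict[int, float] = {}
        for j in range(nmono):
            if j == i:
                continue
            d = within(i, j)
            if d is not None:
                nb[j] = d
        neighbors[i] = nb

    instances: list[MultimerInstance] = []
    if order == 2:
        seen: set[tuple[int, int]] = set()
        for i in central:
            for j, d in neighbors[i].items():
                key = (min(i, j), max(i, j))
                if key in seen:
                    continue
                seen.add(key)
                w = sum(1 for k in key if k in central_set)
                if w == 0:
                    continue
                instances.append(MultimerInstance(
                    order=2,
                    monomers=(monos[key[0]], monos[key[1]]),
                    weight=w,
                    pair_min_distances=(d,),
                    unit_ids=tuple(int(supercell.monomer_unit_index[k]) for k in key),
                    sc_ids=key,
                ))
        instances.sort(key=lambda t: tuple(
            _monomer_key(supercell, i) for i in t.sc_ids))
    else:
        # candidate vertex set: central monomers plus their neighbours
        cand = sorted(set(central) | {j for i in central for j in neighbors[i]})
        pair_d: dict[tuple[int, int], float] = {}
        for i in central:
            for j, d in neighbors[i].items():
                pair_d[(min(i, j), max(i, j))] = d
        # edges among non-central candidates
        noncentral = [c for c in cand if c not in central_set]
        for a_idx in range(len(noncentral)):
            for b_idx in range(a_idx + 1, len(noncentral)):
                i, j = noncentral[a_idx], noncentral[b_idx]
                d = within(i, j)
                if d is not None:
                    pair_d[(i, j)] = d
        adj: dict[int, set[int]] = {c: set() for c in cand}
        for (i, j) in pair_d:
            adj[i].add(j)
            adj[j].add(i)
        seen3: set[tuple[int, int, int]] = set()
        for i in cand:
            for j in adj[i]:
                if j <= i:
                    continue
                for k in adj[i] & adj[j]:
                    if k <= j:
                        continue
                    key = (i, j, k)
                    if key in seen3:
                        continue
                    seen3.add(key)
                    w = sum(1 for t in key if t in central_set)
                    if w == 0:
                        continue
                    dists = (pair_d[(i, j)], pair_d[(i, k)], pair_d[(j, k)])
                    instances.append(MultimerInstance(
                        order=3,
                        monomers=(monos[i], monos[j], monos[k]),
                        weight=w,
                        pair_min_distances=dists,
                        unit_ids=tuple(int(supercell.monomer_unit_index[t]) for t in key),
                        sc_ids=key,
                    ))
        instances.sort(key=lambda t: tuple(
            _monomer_key(supercell, i) for i in t.sc_ids))
    return instances


def _check_coverage(supercell: Supercell, cutoff: float) -> None:
    """Raise if the supercell cannot guarantee completeness at ``cutoff``."""
    d_mol = max(m.diameter for m in supercell.monomers)
    widths = supercell.parent.perpendicular_widths()
    for w, reps in zip(widths, supercell.repeats):
        m = (reps - 1) // 2
        if m * w < cutoff + 2.0 * d_mol:
            raise ValueError(
                f"supercell (repeats {supercell.repeats}) does not guarantee "
                f"coverage for cutoff {cutoff} A; rebuild with build_supercell"
            )


# ---------------------------------------------------------------------------
# permutation-aware RMSD


def _inertia_axes(positions: np.ndarray) -> np.ndarray:
    """Principal axes (rows) of the geometric inertia tensor."""
    r = positions - positions.mean(axis=0)
    inertia = np.eye(3) * (r ** 2).sum() - r.T @ r
    _, vecs = np.linalg.eigh(inertia)
    axes = vecs.T
    if np.linalg.det(axes) < 0:
        axes[2] = -axes[2]
    return axes


def _kabsch(p: np.ndarray, q: np.ndarray) -> np.ndarray:
    """Optimal proper rotation R minimizing ||p - q R^T|| (rows are points)."""
    h = q.T @ p
    u, _, vt = np.linalg.svd(h)
    d = np.sign(np.linalg.det(u @ vt))
    diag = np.diag([1.0, 1.0, d])
    return (u @ diag @ vt).T


def _best_permutation(p: np.ndarray, q: np.ndarray,
                      classes: list[np.ndarray]) -> np.ndarray:
    """Element-preserving permutation of q minimizing sum |p - q[perm]|^2.

    For a fixed relative orientation this is exactly solvable per element
    class by linear assignment.
    """
    perm = np.empty(len(p), dtype=int)
    for cls in classes:
        cost = cdist(p[cls], q[cls], metric="sqeuclidean")
        rows, cols = linear_sum_assignment(cost)
        perm[cls[rows]] = cls[cols]
    return perm


def multimer_rmsd(species_a, pos_a, species_b, pos_b, refine_iter: int = 5) -> float:
    """Permutation- and rotation-invariant RMSD between two multimers.

    Aligns the principal inertia axes of the two geometries (trying the four
    proper axis-sign combinations), optimally permutes atoms within element
    classes, then refines rotation and permutation alternately. Mirror
    images are *not* identified (proper rotations only). Returns ``inf`` if
    the element multisets differ.
    """
    species_a = tuple(species_a)
    species_b = tuple(species_b)
    if sorted(species_a) != sorted(species_b):
        return INF
    pa = np.asarray(pos_a, dtype=float)
    pb = np.asarray(pos_b, dtype=float)
    pa = pa - pa.mean(axis=0)
    pb = pb - pb.mean(axis=0)
    n = len(pa)
    if n == 1:
        return 0.0

    # element classes on the reference ordering of a; b is re-sorted so that
    # classes refer to identical index sets in both
    elems = sorted(set(species_a))
    idx_a = {e: np.array([i for i, s in enumerate(species_a) if s == e]) for e in elems}
    idx_b = {e: np.array([i for i, s in enumerate(species_b) if s == e]) for e in elems}
    # reorder b so its element layout matches a
    order_b = np.concatenate([idx_b[e] for e in elems])
    order_a = np.concatenate([idx_a[e] for e in elems])
    inv_a = np.argsort(order_a)
    pb = pb[order_b][inv_a]  # now pb[i] has species_a[i]'s element
    classes = [idx_a[e] for e in elems]

    axes_a = _inertia_axes(pa)
    axes_b = _inertia_axes(pb)
    pa_al = pa @ axes_a.T

    best = INF
    for signs in ((1, 1, 1), (1, -1, -1), (-1, 1, -1), (-1, -1, 1)):
        flip = np.diag(signs).astype(float)
        pb_al = pb @ axes_b.T @ flip.T
        perm = _best_permutation(pa_al, pb_al, classes)
        q = pb_al[perm]
        for _ in range(refine_iter):
            rot = _kabsch(pa_al, q)
            q_rot = pb_al @ rot.T
            new_perm = _best_permutation(pa_al, q_rot, classes)
            if np.array_equal(new_perm, perm):
                q = q_rot[new_perm]
                break
            perm = new_perm
            q = q_rot[perm]
        rot = _kabsch(pa_al, q)
        rmsd = float(np.sqrt(((pa_al - q @ rot.T) ** 2).sum() / n))
        best = min(best, rmsd)
    return best


def instance_rmsd(a: MultimerInstance, b: MultimerInstance) -> float:
    return multimer_rmsd(a.species, a.positions, b.species, b.positions)


def deduplicate(instances: list[MultimerInstance], tol: float = 1e-3
                ) -> list[UniqueMultimer]:
    """Greedily group instances whose permutation RMSD is below ``tol``.

    Weight is conserved exactly: the sum of ``total_weight`` over the groups
    equals the sum of ``n`` over the raw instances.
    """
    if instances and len({i.order for i in instances}) > 1:
        raise ValueError("all instances must have the same order")
    groups: list[UniqueMultimer] = []
    for inst in instances:
        placed = False
        for g in groups:
            r = multimer_rmsd(g.representative_species, g.representative_positions,
                              inst.species, inst.positions)
            if r < tol:
                g.instances.append(inst)
                placed = True
                break
        if not placed:
            groups.append(UniqueMultimer(
                representative_species=inst.species,
                representative_positions=inst.positions.copy(),
                instances=[inst],
            ))
    return groups


def export_unique_multimers(groups: list[UniqueMultimer], directory,
                            prefix: str = "multimer") -> list[str]:
    """Write each unique multimer as extended XYZ plus a TSV bookkeeping table.

    Returns the written fragment file names."""
    from pathlib import Path

    from .io import write_extxyz
    from .structures import Cluster

    directory = Path(directory)
    directory.mkdir(parents=True, exist_ok=True)
    names = []
    rows = ["index\torder\tmultiplicity\ttotal_weight\tunit_ids\tpair_min_distances"]
    for i, g in enumerate(groups):
        name = f"{prefix}_{i:04d}.xyz"
        inst = g.instances[0]
        extra = (f'order={inst.order} total_weight={g.total_weight} '
                 f'multiplicity={g.multiplicity}')
        write_extxyz(directory / name,
                     Cluster(g.representative_species, g.representative_positions),
                     comment_extra=extra)
        names.append(name)
        dists = ",".join(f"{d:.4f}" for d in inst.pair_min_distances)
        ids = ",".join(str(u) for u in inst.unit_ids)
        rows.append(f"{i}\t{inst.order}\t{g.multiplicity}\t{g.total_weight}\t{ids}\t{dists}")
    (directory / f"{prefix}_table.tsv").write_text("\n".join(rows) + "\n")
    return names
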