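"""Subtractive multimer embedding: energies, forces, stress.

The periodic high-level result is approximated as the periodic low-level
result plus high-minus-low corrections evaluated on isolated multimers
extracted from a supercell:

    E ~= E_per^low + sum_i n_i dE_i + sum_{i<j} (n_ij/2) dE_ij^int
                   + sum_{i<j<k} (n_ijk/3) dE3_ijk

where ``n`` counts the multimer's monomers inside the reference unit cell,
``dE_i`` is the monomer high-low energy difference, ``dE^int`` the dimer
interaction-energy difference and ``dE3`` the *nonadditive* three-body
difference (trimer interaction minus its three dimer interactions). The
``n/k`` prefactor for an order-k multimer is the unique convention that
telescopes to the periodic limit: for a high level that adds a
finite-range intermolecular potential to the low level, embedding with a
cutoff at least the potential range reproduces the periodic high-level
energy, forces and stress exactly (the test suite's master property).

Forces and stress corrections run up to dimers. The stress correction is
the strain derivative of the energy correction,

    sigma = sigma^low - (1/V) sum_multimers (n/k) sum_a df(a) (x) (r_a - r_cm)

with positions referenced to each multimer's centroid, which makes the
term exactly invariant under rigid translations.

Isolated-multimer evaluations are cached by a translation-invariant
geometry hash, so symmetry-equivalent translated instances are computed
once; on top of that, energy corrections are evaluated once per *unique*
multimer (permutation-RMSD deduplication) and reused via multiplicities.
"""

from __future__ import annotations

from dataclasses import dataclass, field

import numpy as np
from scipy import constants

from .enumeration import MultimerInstance, deduplicate, enumerate_multimers
from .structures import BondParams, Cluster, Crystal, build_supercell

#: 1 eV in kJ/mol
EV_TO_KJ_PER_MOL = constants.e * constants.Avogadro / 1000.0


class CalculatorError(RuntimeError):
    """A calculator failed; the message carries multimer provenance."""


class EvalCache:
    """Cache of calculator evaluations keyed by geometry.

    Isolated geometries are keyed translation-invariantly (coordinates
    referenced to the centroid, rounded to 1e-8 A), periodic ones by cell +
    coordinates. Forces are stored as immutable copies.
    """

    def __init__(self) -> None:
        self._store: dict = {}
        self.hits = 0
        self.misses = 0

    @staticmethod
    def _key(calc, structure, periodic: bool):
        pos = np.asarray(structure.positions, dtype=float)
        if periodic:
            lat = np.round(structure.lattice, 8)
            pos = np.round(pos, 8)
            return (calc.name, True, structure.species, lat.tobytes(), pos.tobytes())
        pos = np.round(pos - pos.mean(axis=0), 8)
        return (calc.name, False, structure.species, pos.tobytes())

    def evaluate(self, calc, structure, periodic: bool, provenance: str = "") -> dict:
        key = self._key(calc, structure, periodic)
        if key in self._store:
            self.hits += 1
            return self._store[key]
        try:
            out = calc.evaluate(structure, periodic)
        except Exception as exc:  # noqa: BLE001 - re-raise with provenance
            raise CalculatorError(
                f"calculator {calc.name!r} failed on {provenance or 'structure'}: {exc}"
            ) from exc
        out = dict(out)
        out["forces"] = np.array(out["forces"], dtype=float)
        out["forces"].setflags(write=False)
        self._store[key] = out
        self.misses += 1
        return out


@dataclass
class CorrectionTerm:
    """One multimer's high-minus-low correction, for reporting."""

    kind: str                       # monomer | dimer_int | trimer_nonadd
    order: int
    weight: int                     # n (summed over instances if grouped)
    multiplicity: int
    delta_e: float                  # eV, per single instance


@dataclass
class EmbeddingResult:
    """Embedded quantities with an additive breakdown."""

    energy: float | None = None
    forces: np.ndarray | None = None
    stress: np.ndarray | None = None
    breakdown: dict = field(default_factory=dict)
    terms: list[CorrectionTerm] = field(default_factory=list)
    counts: dict = field(default_factory=dict)
    cache: EvalCache | None = None


# ---------------------------------------------------------------------------
# interaction energies / forces on isolated multimers


def _cluster(monomers) -> Cluster:
    species = tuple(s for m in monomers for s in m.species)
    pos = np.vstack([m.unwrapped_positions for m in monomers])
    return Cluster(species, pos)


def dimer_interaction(calc, monomers, cache: EvalCache | None = None,
                      with_forces: bool = True) -> dict:
    """Interaction energy (and forces) of a dimer under one calculator.

    ``E_int = E(ij) - E(i) - E(j)`` with all systems isolated;
    ``f_int(a) = f_ij(a) - f_mono(a)`` per dimer atom (monomer order i, j).
    """
    cache = cache or EvalCache()
    a, b = monomers
    out_ab = cache.evaluate(calc, _cluster((a, b)), False, "dimer")
    out_a = cache.evaluate(calc, a.as_cluster(), False, "monomer")
    out_b = cache.evaluate(calc, b.as_cluster(), False, "monomer")
    e_int = out_ab["energy"] - out_a["energy"] - out_b["energy"]
    result = {"E_int": e_int}
    if with_forces:
        f_mono = np.vstack([out_a["forces"], out_b["forces"]])
        result["f_int"] = np.array(out_ab["forces"]) - f_mono
    return result


def trimer_interaction_energy(calc, monomers, cache: EvalCache | None = None) -> float:
    """Trimer interaction energy ``E(ijk) - E(i) - E(j) - E(k)`` (isolated)."""
    cache = cache or EvalCache()
    i, j, k = monomers
    e_ijk = cache.evaluate(calc, _cluster((i, j, k)), False, "trimer")["energy"]
    e_monos = sum(cache.evaluate(calc, m.as_cluster(), False, "monomer")["energy"]
                  for m in (i, j, k))
    return e_ijk - e_monos


def three_body_nonadditive(calc, monomers, cache: EvalCache | None = None) -> float:
    """Nonadditive three-body energy of a trimer.

    ``E3 = E_int(ijk) - E_int(ij) - E_int(ik) - E_int(jk)``; identically
    zero for any pairwise-additive calculator."""
    cache = cache or EvalCache()
    i, j, k = monomers
    e3 = trimer_interaction_energy(calc, (i, j, k), cache)
    for pair in ((i, j), (i, k), (j, k)):
        e3 -= dimer_interaction(calc, pair, cache, with_forces=False)["E_int"]
    return e3


# ---------------------------------------------------------------------------
# embedding drivers


def _delta_e(low, high, monomers, kind: str, cache: EvalCache) -> float:
    """High-minus-low energy delta of one multimer."""
    if kind == "monomer":
        c = monomers[0].as_cluster()
        return (cache.evaluate(high, c, False, "monomer")["energy"]
                - cache.evaluate(low, c, False, "monomer")["energy"])
    if kind == "dimer_int":
        return (dimer_interaction(high, monomers, cache, with_forces=False)["E_int"]
                - dimer_interaction(low, monomers, cache, with_forces=False)["E_int"])
    if kind == "trimer_nonadd":
        return (three_body_nonadditive(high, monomers, cache)
                - three_body_nonadditive(low, monomers, cache))
    raise ValueError(kind)


def _monomer_instances(supercell) -> list[MultimerInstance]:
    out = []
    for idx, m in enumerate(supercell.monomers):
        if m.in_central_cell:
            out.append(MultimerInstance(
                order=1, monomers=(m,), weight=1, pair_min_distances=(),
                unit_ids=(int(supercell.monomer_unit_index[idx]),),
                sc_ids=(idx,),
            ))
    return out


def embed_energy(low, high, crystal: Crystal, order: int, cutoff: float,
                 dedup_tol: float = 1e-3, margin: float = 0.1,
                 bond_params: BondParams | None = None,
                 cache: EvalCache | None = None,
                 use_dedup: bool = True) -> EmbeddingResult:
    """Embedded periodic high-level energy up to the given multimer order.

    Returns an :class:`EmbeddingResult` whose ``breakdown`` holds the
    additive terms ``periodic_low``, ``monomer_corr``, ``dimer_corr`` and
    ``trimer_corr`` (eV); their sum equals ``energy`` to machine precision.
    """
    if order not in (1, 2, 3):
        raise ValueError("order must be 1, 2 or 3")
    cache = cache or EvalCache()
    e_low = cache.evaluate(low, crystal, True, "periodic cell")["energy"]
    sc = build_supercell(crystal, cutoff, margin=margin, bond_params=bond_params)

    breakdown = {"periodic_low": e_low, "monomer_corr": 0.0,
                 "dimer_corr": 0.0, "trimer_corr": 0.0}
    terms: list[CorrectionTerm] = []
    counts: dict = {}

    plans = [("monomer", 1, _monomer_instances(sc))]
    if order >= 2:
        plans.append(("dimer_int", 2, enumerate_multimers(sc, 2, cutoff)))
    if order == 3:
        plans.append(("trimer_nonadd", 3, enumerate_multimers(sc, 3, cutoff)))

    for kind, k, instances in plans:
        counts[f"order{k}_instances"] = len(instances)
        counts[f"order{k}_total_weight"] = sum(i.weight for i in instances)
        dest = {1: "monomer_corr", 2: "dimer_corr", 3: "trimer_corr"}[k]
        if use_dedup:
            groups = deduplicate(instances, tol=dedup_tol)
            counts[f"order{k}_unique"] = len(groups)
            for g in groups:
                de = _delta_e(low, high, g.instances[0].monomers, kind, cache)
                breakdown[dest] += (g.total_weight / k) * de
                terms.append(CorrectionTerm(kind, k, g.total_weight,
                                            g.multiplicity, de))
        else:
            for inst in instances:
                de = _delta_e(low, high, inst.monomers, kind, cache)
                breakdown[dest] += (inst.weight / k) * de
                terms.append(CorrectionTerm(kind, k, inst.weight, 1, de))

    energy = sum(breakdown.values())
    return EmbeddingResult(energy=energy, breakdown=breakdown, terms=terms,
                           counts=counts, cache=cache)


def _central_atom_inverse(sc) -> dict[int, int]:
    """Map supercell atom index -> parent crystal atom index (central cell)."""
    return {int(sc_idx): int(orig) for orig, sc_idx in enumerate(sc.central_map)}


def embed_forces(low, high, crystal: Crystal, cutoff: float,
                 margin: float = 0.1, bond_params: BondParams | None = None,
                 cache: EvalCache | None = None) -> EmbeddingResult:
    """Embedded high-level forces on the unit-cell atoms (dimer level).

    ``f(a) = f_per^low(a) + df_i(a) + sum_j df_ij^int(a)`` for atom ``a`` of
    central-cell monomer ``i``; the dimer sum runs over all partners within
    the cutoff regardless of which cell they live in.
    """
    cache = cache or EvalCache()
    out_low = cache.evaluate(low, crystal, True, "periodic cell")
    forces = np.array(out_low["forces"], dtype=float)
    sc = build_supercell(crystal, cutoff, margin=margin, bond_params=bond_params)
    inv = _central_atom_inverse(sc)

    # monomer corrections
    for inst in _monomer_instances(sc):
        m = inst.monomers[0]
        c = m.as_cluster()
        df = (cache.evaluate(high, c, False, "monomer")["forces"]
              - cache.evaluate(low, c, False, "monomer")["forces"])
        for local, sc_idx in enumerate(m.atom_indices):
            forces[inv[int(sc_idx)]] += df[local]

    # dimer interaction-force corrections
    for inst in enumerate_multimers(sc, 2, cutoff):
        fi_high = dimer_interaction(high, inst.monomers, cache)["f_int"]
        fi_low = dimer_interaction(low, inst.monomers, cache)["f_int"]
        df = fi_high - fi_low
        offset = 0
        for m in inst.monomers:
            if m.in_central_cell:
                for local, sc_idx in enumerate(m.atom_indices):
                    forces[inv[int(sc_idx)]] += df[offset + local]
            offset += len(m.atom_indices)

    return EmbeddingResult(forces=forces, cache=cache)


def embed_stress(low, high, crystal: Crystal, cutoff: float,
                 margin: float = 0.1, bond_params: BondParams | None = None,
                 cache: EvalCache | None = None) -> EmbeddingResult:
    """Embedded high-level stress tensor (dimer level), eV/A^3, symmetrized.

    The correction is the analytic strain derivative of the energy
    correction; each multimer's positions are referenced to its centroid so
    the term is exactly translation invariant.
    """
    cache = cache or EvalCache()
    out_low = cache.evaluate(low, crystal, True, "periodic cell")
    if "stress" not in out_low:
        raise CalculatorError(f"calculator {low.name!r} returned no stress")
    stress = np.array(out_low["stress"], dtype=float)
    vol = crystal.volume
    sc = build_supercell(crystal, cutoff, margin=margin, bond_params=bond_params)

    corr = np.zeros((3, 3))
    for inst in _monomer_instances(sc):
        m = inst.monomers[0]
        c = m.as_cluster()
        df = (cache.evaluate(high, c, False, "monomer")["forces"]
              - cache.evaluate(low, c, False, "monomer")["forces"])
        r = m.unwrapped_positions - m.unwrapped_positions.mean(axis=0)
        corr += inst.weight / 1.0 * df.T @ r

    for inst in enumerate_multimers(sc, 2, cutoff):
        fi_high = dimer_interaction(high, inst.monomers, cache)["f_int"]
        fi_low = dimer_interaction(low, inst.monomers, cache)["f_int"]
        df = fi_high - fi_low
        pos = np.vstack([m.unwrapped_positions for m in inst.monomers])
        r = pos - pos.mean(axis=0)
        corr += (inst.weight / 2.0) * df.T @ r

    stress = stress - corr / vol
    stress = 0.5 * (stress + stress.T)
    return EmbeddingResult(stress=stress, cache=cache)


def lattice_energy(e_cell: float, z: int, e_mon: float) -> float:
    """Lattice energy per molecule in kJ/mol.

    ``(E_cell/Z - E_mon)`` converted from eV; negative for bound crystals.
    """
    if z <= 0:
        raise ValueError("Z must be a positive molecule count")
    return (e_cell / z - e_mon) * EV_TO_KJ_PER_MOL
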