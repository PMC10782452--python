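"""Embedding core: interaction energies, embedded E/f/sigma, exactness."""

import itertools

import numpy as np
import pytest

import multembed as me
from conftest import numerical_stress
from multembed.toys import three_body_energy


def _dimer_monomers(crystal, cutoff=5.0):
    sc = me.build_supercell(crystal, cutoff)
    inst = me.enumerate_multimers(sc, 2, cutoff)
    return inst[0].monomers


class TestDimerInteraction:
    def test_zero_for_noninteracting_calculator(self, toy_z2, calc_low):
        out = me.dimer_interaction(calc_low, _dimer_monomers(toy_z2))
        assert out["E_int"] == pytest.approx(0.0, abs=1e-14)
        assert np.abs(out["f_int"]).max() < 1e-14

    def test_single_atom_pair_at_lj_minimum_gives_minus_epsilon(self):
        spec = me.ToyPotentialSpec(intra_enabled=False, pair_enabled=True,
                                   epsilon=0.03, sigma=2.0, r_c=6.0)
        calc = me.make_calculator(spec)
        r_min = 2 ** (1 / 6) * spec.sigma  # inside the unswitched region
        cr = me.Crystal(np.eye(3) * 40.0, ["He", "He"],
                        [[10, 10, 10], [10 + r_min, 10, 10]], pbc=True)
        monos = me.detect_molecules(cr)
        out = me.dimer_interaction(calc, monos)
        assert out["E_int"] == pytest.approx(-spec.epsilon, abs=1e-14)

    def test_interaction_forces_match_finite_differences(self, toy_z2,
                                                         calc_three_body):
        monos = _dimer_monomers(toy_z2)
        out = me.dimer_interaction(calc_three_body, monos)
        h = 1e-5
        na = len(monos[0].atom_indices)
        pos = np.vstack([m.unwrapped_positions for m in monos])
        num = np.zeros_like(out["f_int"])
        for i in range(len(pos)):
            for ax in range(3):
                for sign in (+1, -1):
                    p = pos.copy()
                    p[i, ax] += sign * h
                    ma = me.Monomer(monos[0].parent, monos[0].atom_indices,
                                    p[:na], (0, 0, 0), True)
                    mb = me.Monomer(monos[1].parent, monos[1].atom_indices,
                                    p[na:], (0, 0, 0), False)
                    e = me.dimer_interaction(calc_three_body, (ma, mb),
                                             with_forces=False)["E_int"]
                    num[i, ax] -= sign * e / (2 * h)
        assert np.abs(out["f_int"] - num).max() < 1e-6


class TestTrimerInteraction:
    def _trimer(self, crystal, cutoff=5.0):
        sc = me.build_supercell(crystal, cutoff)
        return me.enumerate_multimers(sc, 3, cutoff)[0].monomers

    def test_zero_for_noninteracting_calculator(self, toy_z2, calc_low):
        assert me.trimer_interaction_energy(
            calc_low, self._trimer(toy_z2)) == pytest.approx(0.0, abs=1e-14)

    def test_pairwise_calculator_equals_sum_of_dimer_interactions(
            self, toy_z2, calc_pair):
        i, j, k = self._trimer(toy_z2)
        e3 = me.trimer_interaction_energy(calc_pair, (i, j, k))
        pair_sum = sum(
            me.dimer_interaction(calc_pair, p, with_forces=False)["E_int"]
            for p in ((i, j), (i, k), (j, k)))
        assert e3 == pytest.approx(pair_sum, abs=1e-12)

    def test_three_body_term_recovered_on_top_of_pairwise(
            self, toy_z2, spec_three_body, calc_three_body, calc_pair):
        trimer = self._trimer(toy_z2)
        e3 = me.trimer_interaction_energy(calc_three_body, trimer)
        pair_part = me.trimer_interaction_energy(calc_pair, trimer)
        # direct closed-form evaluation of the three-body term over all atom
        # triples spanning the three distinct molecules of the trimer
        pos = np.vstack([m.unwrapped_positions for m in trimer])
        mol = np.concatenate([[mi] * len(m.atom_indices)
                              for mi, m in enumerate(trimer)])
        direct = 0.0
        for a, b, c in itertools.combinations(range(len(pos)), 3):
            if len({mol[a], mol[b], mol[c]}) != 3:
                continue
            r_ab = np.linalg.norm(pos[b] - pos[a])
            r_ac = np.linalg.norm(pos[c] - pos[a])
            r_bc = np.linalg.norm(pos[c] - pos[b])
            direct += three_body_energy(r_ab, r_ac, r_bc, spec_three_body)[0]
        assert e3 == pytest.approx(pair_part + direct, abs=1e-12)


class TestThreeBodyNonadditive:
    def test_zero_for_pairwise_calculator(self, toy_z2, calc_pair):
        sc = me.build_supercell(toy_z2, 5.0)
        for inst in me.enumerate_multimers(sc, 3, 5.0)[:5]:
            assert abs(me.three_body_nonadditive(calc_pair, inst.monomers)) < 1e-12

    def test_permutation_invariance(self, toy_z2, calc_three_body):
        sc = me.build_supercell(toy_z2, 5.0)
        monos = me.enumerate_multimers(sc, 3, 5.0)[0].monomers
        vals = [me.three_body_nonadditive(calc_three_body, p)
                for p in itertools.permutations(monos)]
        assert np.ptp(vals) < 1e-12

    def test_pure_three_body_toy_matches_closed_form(self, spec_three_body):
        spec = me.ToyPotentialSpec(intra_enabled=False, pair_enabled=False,
                                   three_body_enabled=True, r_c3=4.5, nu=5.0)
        calc = me.make_calculator(spec)
        # three single-atom molecules in a triangle
        box = np.eye(3) * 40.0
        pts = np.array([[10, 10, 10], [13, 10, 10], [11.5, 12.4, 10.0]])
        cr = me.Crystal(box, ["He"] * 3, pts, pbc=True)
        monos = me.detect_molecules(cr)
        e3 = me.three_body_nonadditive(calc, monos)
        r12 = np.linalg.norm(pts[1] - pts[0])
        r13 = np.linalg.norm(pts[2] - pts[0])
        r23 = np.linalg.norm(pts[2] - pts[1])
        assert e3 == pytest.approx(
            three_body_energy(r12, r13, r23, spec)[0], abs=1e-14)


class TestEmbedEnergy:
    def test_high_equals_low_reproduces_periodic_low(self, toy_z2, calc_low):
        res = me.embed_energy(calc_low, calc_low, toy_z2, order=3, cutoff=5.0)
        e_low = calc_low.evaluate(toy_z2, True)["energy"]
        assert res.energy == pytest.approx(e_low, abs=1e-14)
        assert res.breakdown["monomer_corr"] == 0.0
        assert res.breakdown["dimer_corr"] == 0.0
        assert res.breakdown["trimer_corr"] == 0.0

    def test_breakdown_sums_to_energy(self, toy_z2, calc_low, calc_three_body):
        res = me.embed_energy(calc_low, calc_three_body, toy_z2, 3, 5.0)
        assert res.energy == pytest.approx(sum(res.breakdown.values()),
                                           rel=1e-12)

    def test_me2_reproduces_pairwise_lattice_sum(self, toy_z2, calc_low,
                                                 calc_pair, spec_pair):
        # jittered crystal: duplicates are exact translations only, so a
        # tight dedup tolerance keeps the grouping exact
        res = me.embed_energy(calc_low, calc_pair, toy_z2, 2, spec_pair.r_c,
                              dedup_tol=1e-8)
        ref = me.periodic_reference(spec_pair, toy_z2, radius=6.0)
        assert abs(res.energy - ref["energy"]) < 1e-9

    def test_me3_exact_and_me2_misses_three_body_part(
            self, toy_z2, calc_low, calc_three_body, spec_three_body):
        ref = me.periodic_reference(spec_three_body, toy_z2, radius=6.0)
        res3 = me.embed_energy(calc_low, calc_three_body, toy_z2, 3, 5.0,
                               dedup_tol=1e-8)
        assert abs(res3.energy - ref["energy"]) < 1e-9
        res2 = me.embed_energy(calc_low, calc_three_body, toy_z2, 2, 5.0,
                               dedup_tol=1e-8)
        spec_3b_only = me.ToyPotentialSpec(
            intra_enabled=False, pair_enabled=False, three_body_enabled=True,
            r_c3=spec_three_body.r_c3, nu=spec_three_body.nu,
            switch_width=spec_three_body.switch_width)
        e3_cell = me.periodic_reference(spec_3b_only, toy_z2, radius=6.0)["energy"]
        assert res3.energy - res2.energy == pytest.approx(e3_cell, abs=1e-9)

    def test_order_telescoping(self, toy_z2, calc_low, calc_three_body):
        r1 = me.embed_energy(calc_low, calc_three_body, toy_z2, 1, 5.0,
                             dedup_tol=1e-8)
        r2 = me.embed_energy(calc_low, calc_three_body, toy_z2, 2, 5.0,
                             dedup_tol=1e-8)
        r3 = me.embed_energy(calc_low, calc_three_body, toy_z2, 3, 5.0,
                             dedup_tol=1e-8)
        assert r2.energy == pytest.approx(
            r1.energy + r2.breakdown["dimer_corr"], abs=1e-12)
        assert r3.energy == pytest.approx(
            r2.energy + r3.breakdown["trimer_corr"], abs=1e-12)

    def test_dedup_and_instancewise_paths_agree(self, toy_sym, calc_low,
                                                calc_pair):
        a = me.embed_energy(calc_low, calc_pair, toy_sym, 2, 5.0, use_dedup=True)
        b = me.embed_energy(calc_low, calc_pair, toy_sym, 2, 5.0, use_dedup=False)
        assert a.energy == pytest.approx(b.energy, abs=1e-10)
        assert a.counts["order2_unique"] < a.counts["order2_instances"]

    def test_translational_invariance(self, toy_z2, calc_low, calc_pair):
        res = me.embed_energy(calc_low, calc_pair, toy_z2, 2, 5.0)
        shifted = me.Crystal(toy_z2.lattice, toy_z2.species,
                             toy_z2.positions + np.array([0.31, -1.27, 0.64]),
                             pbc=True)
        res_s = me.embed_energy(calc_low, calc_pair, shifted, 2, 5.0)
        assert abs(res.energy - res_s.energy) < 1e-10

    def test_invalid_order_rejected(self, toy_z2, calc_low, calc_pair):
        with pytest.raises(ValueError):
            me.embed_energy(calc_low, calc_pair, toy_z2, 4, 5.0)


class TestEmbedForces:
    def test_high_equals_low_gives_periodic_low_forces(self, toy_z2, calc_low):
        res = me.embed_forces(calc_low, calc_low, toy_z2, cutoff=5.0)
        f_low = calc_low.evaluate(toy_z2, True)["forces"]
        assert np.abs(res.forces - f_low).max() < 1e-14

    def test_me2_matches_periodic_high_forces(self, toy_z2, calc_low,
                                              calc_pair, spec_pair):
        res = me.embed_forces(calc_low, calc_pair, toy_z2, cutoff=spec_pair.r_c)
        ref = me.periodic_reference(spec_pair, toy_z2, radius=6.0)
        assert np.abs(res.forces - ref["forces"]).max() < 1e-8

    def test_matches_finite_differences_of_embed_energy(self, toy_z2, calc_low,
                                                        calc_pair):
        res = me.embed_forces(calc_low, calc_pair, toy_z2, cutoff=5.0)
        h = 1e-4
        num = np.zeros_like(res.forces)
        for i in range(len(toy_z2)):
            for ax in range(3):
                p = toy_z2.copy()
                p.positions[i, ax] += h
                m = toy_z2.copy()
                m.positions[i, ax] -= h
                ep = me.embed_energy(calc_low, calc_pair, p, 2, 5.0,
                                     use_dedup=False).energy
                em = me.embed_energy(calc_low, calc_pair, m, 2, 5.0,
                                     use_dedup=False).energy
                num[i, ax] = -(ep - em) / (2 * h)
        assert np.abs(res.forces - num).max() < 1e-5


class TestEmbedStress:
    def test_high_equals_low_gives_low_stress(self, toy_z2, calc_low):
        res = me.embed_stress(calc_low, calc_low, toy_z2, cutoff=5.0)
        s_low = calc_low.evaluate(toy_z2, True)["stress"]
        assert np.abs(res.stress - s_low).max() < 1e-14

    def test_symmetry_of_output(self, toy_z2, calc_low, calc_pair):
        res = me.embed_stress(calc_low, calc_pair, toy_z2, cutoff=5.0)
        assert np.array_equal(res.stress, res.stress.T)

    def test_me2_matches_periodic_high_stress(self, toy_z2, calc_low,
                                              calc_pair, spec_pair):
        res = me.embed_stress(calc_low, calc_pair, toy_z2, cutoff=spec_pair.r_c)
        ref = me.periodic_reference(spec_pair, toy_z2, radius=6.0)
        assert np.abs(res.stress - ref["stress"]).max() < 1e-10

    def test_matches_numerical_strain_derivative(self, toy_z2, calc_low,
                                                 calc_pair):
        res = me.embed_stress(calc_low, calc_pair, toy_z2, cutoff=5.0)
        num = numerical_stress(
            lambda c: me.embed_energy(calc_low, calc_pair, c, 2, 5.0,
                                      use_dedup=False).energy,
            toy_z2, h=1e-5)
        assert np.abs(res.stress - num).max() < 1e-6

    def test_translational_invariance(self, toy_z2, calc_low, calc_pair):
        res = me.embed_stress(calc_low, calc_pair, toy_z2, cutoff=5.0)
        shifted = me.Crystal(toy_z2.lattice, toy_z2.species,
                             toy_z2.positions + np.array([1.5, 0.2, -0.7]),
                             pbc=True)
        res_s = me.embed_stress(calc_low, calc_pair, shifted, cutoff=5.0)
        assert np.abs(res.stress - res_s.stress).max() < 1e-10


class TestLatticeEnergy:
    def test_arithmetic(self):
        assert me.lattice_energy(-10.0, 2, -4.0) == pytest.approx(
            -me.EV_TO_KJ_PER_MOL, rel=1e-12)
        assert me.lattice_energy(2 * (-4.0), 2, -4.0) == 0.0

    def test_invalid_z(self):
        with pytest.raises(ValueError):
            me.lattice_energy(-10.0, 0, -4.0)

    def test_toy_crystal_against_lattice_sum_oracle(self, toy_sym, calc_low,
                                                    calc_pair, spec_pair):
        res = me.embed_energy(calc_low, calc_pair, toy_sym, 2, spec_pair.r_c)
        monos = me.detect_molecules(toy_sym)
        e_mon = calc_pair.evaluate(monos[0].as_cluster(), False)["energy"]
        e_latt = me.lattice_energy(res.energy, len(monos), e_mon)
        ref = me.periodic_reference(spec_pair, toy_sym, radius=6.0)
        expected = (ref["energy"] / len(monos) - e_mon) * me.EV_TO_KJ_PER_MOL
        assert e_latt == pytest.approx(expected, abs=1e-8)
        assert e_latt < 0.0  # bound crystal


class TestEvalCache:
    def test_translated_geometries_share_entries(self, toy_z1, calc_low,
                                                 calc_pair):
        cache = me.EvalCache()
        me.embed_energy(calc_low, calc_pair, toy_z1, 2, 5.0, cache=cache,
                        use_dedup=False)
        assert cache.hits > 0

    def test_calculator_failure_carries_provenance(self, toy_z2):
        class Broken:
            name = "broken"

            def evaluate(self, structure, periodic):
                raise RuntimeError("no isolated-system support")

        with pytest.raises(me.CalculatorError, match="broken"):
            me.embed_energy(Broken(), Broken(), toy_z2, 1, 3.0)
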