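"""Shared fixtures: toy crystals, calculators and the ammonia cell."""

from __future__ import annotations

import numpy as np
import pytest

import multembed as me


@pytest.fixture(scope="session")
def ammonia():
    """Synthetic ammonia phase-I cell (P2_1 3, 16 atoms, Z = 4)."""
    from multembed.fixtures import ammonia_crystal

    return ammonia_crystal()


@pytest.fixture(scope="session")
def spec_low():
    """Low level: intramolecular springs only."""
    return me.ToyPotentialSpec(pair_enabled=False)


@pytest.fixture(scope="session")
def spec_pair():
    """High level: low + finite-range intermolecular pair potential."""
    return me.ToyPotentialSpec(pair_enabled=True, r_c=5.0)


@pytest.fixture(scope="session")
def spec_three_body():
    """High level with pair + three-body terms."""
    return me.ToyPotentialSpec(pair_enabled=True, r_c=5.0,
                               three_body_enabled=True, r_c3=4.0, nu=5.0)


@pytest.fixture(scope="session")
def calc_low(spec_low):
    return me.make_calculator(spec_low, "low")


@pytest.fixture(scope="session")
def calc_pair(spec_pair):
    return me.make_calculator(spec_pair, "high-pair")


@pytest.fixture(scope="session")
def calc_three_body(spec_three_body):
    return me.make_calculator(spec_three_body, "high-3b")


@pytest.fixture(scope="session")
def toy_z1():
    """One diatomic per cubic cell, jittered off symmetry."""
    return me.make_toy_molecular_crystal("diatomic", "cubic", a=4.0, z=1,
                                         jitter=0.05, seed=3)


@pytest.fixture(scope="session")
def toy_z2():
    """Two diatomics per cubic cell, jittered off symmetry."""
    return me.make_toy_molecular_crystal("diatomic", "cubic", a=4.0, z=2,
                                         jitter=0.05, seed=7)


@pytest.fixture(scope="session")
def toy_sym():
    """Symmetric (unjittered) two-molecule crystal."""
    return me.make_toy_molecular_crystal("diatomic", "cubic", a=4.0, z=2)


def numerical_forces(calc, crystal, h=1e-5):
    """Central-difference forces of a calculator on a periodic crystal."""
    num = np.zeros((len(crystal), 3))
    for i in range(len(crystal)):
        for ax in range(3):
            p = crystal.copy()
            p.positions[i, ax] += h
            m = crystal.copy()
            m.positions[i, ax] -= h
            num[i, ax] = -(calc.evaluate(p, True)["energy"]
                           - calc.evaluate(m, True)["energy"]) / (2 * h)
    return num


def numerical_stress(energy_fn, crystal, h=1e-6):
    """Central-difference strain derivative (1/V) dE/d(eps) of any E(crystal)."""
    vol = crystal.volume
    num = np.zeros((3, 3))
    for p in range(3):
        for q in range(p, 3):
            eps = np.zeros((3, 3))
            eps[p, q] += h
            eps[q, p] += h
            if p == q:
                eps[p, q] = h

            def energy(sign):
                f = np.eye(3) + sign * eps
                c = me.Crystal(crystal.lattice @ f.T, crystal.species,
                               crystal.positions @ f.T, crystal.pbc)
                return energy_fn(c)

            d = (energy(+1) - energy(-1)) / (2 * h)
            num[p, q] = num[q, p] = d / vol if p == q else d / (2 * vol)
    return num
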