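"""Units, interaction model and system validation."""

import math

import numpy as np
import pytest
from hypothesis import given, strategies as st

from spmedl.model import (
    HARD_OVERLAP,
    Macroion,
    Species,
    SystemSpec,
    bjerrum_length,
    debye_kappa,
    macroion_potential,
    macroion_valence,
    mixed_electrolyte,
    molar_to_number_density,
    pair_potential,
    surface_charge_density,
    validate_system,
)


@pytest.mark.parametrize(
    "molarity,expected",
    [(0.0, 0.0), (1.0, 0.602214076), (27.75, 16.71144)],
)
def test_molar_conversion(molarity, expected):
    assert molar_to_number_density(molarity) == pytest.approx(expected, rel=1e-5)


def test_molar_conversion_rejects_negative():
    with pytest.raises(ValueError):
        molar_to_number_density(-0.1)


def test_bjerrum_length_water():
    lb = bjerrum_length(78.5, 298.0)
    assert lb == pytest.approx(0.714, abs=5e-4)
    # 1/eps and 1/T scaling
    assert bjerrum_length(157.0, 298.0) == pytest.approx(lb / 2.0, rel=1e-12)
    assert bjerrum_length(78.5, 596.0) == pytest.approx(lb / 2.0, rel=1e-12)


@pytest.mark.parametrize(
    "Q,R,Z",
    [(0.102, 1.5, 18.0), (0.0, 2.0, 0.0), (0.408, 1.5, 72.0)],
)
def test_macroion_valence_examples(Q, R, Z):
    assert macroion_valence(Q, R) == pytest.approx(Z, abs=0.01)


@given(
    Q=st.floats(-1.0, 1.0, allow_nan=False),
    R=st.floats(0.1, 20.0, allow_nan=False),
)
def test_valence_charge_roundtrip(Q, R):
    Z = macroion_valence(Q, R)
    back = surface_charge_density(Z, R)
    assert back == pytest.approx(Q, rel=1e-12, abs=1e-15)


@pytest.fixture(scope="module")
def base_system():
    return SystemSpec(
        species=mixed_electrolyte(1.0, 0.5, 27.75),
        macroion=Macroion.from_surface_charge(0.102, 1.5),
    )


def test_pair_potential_shapes(base_system):
    sp = base_system
    mg, na, cl, solv = sp.species
    # solvent pairs are pure hard spheres
    assert pair_potential(solv, solv, 1.0, sp) == 0.0
    assert pair_potential(solv, solv, 0.1, sp) == HARD_OVERLAP
    # hard overlap sentinel must give an exactly-zero Boltzmann factor
    assert math.exp(-pair_potential(mg, cl, 0.3, sp)) == 0.0
    # Coulomb value beyond contact
    assert pair_potential(na, na, 1.0, sp) == pytest.approx(sp.lambda_b, rel=1e-6)
    # symmetry over all pairs
    for a in sp.species:
        for b in sp.species:
            r = 0.5 * (a.diameter + b.diameter) * 1.7
            assert pair_potential(a, b, r, sp) == pair_potential(b, a, r, sp)


def test_macroion_potential(base_system):
    sp = base_system
    mg, na, cl, solv = sp.species
    M = sp.macroion
    assert macroion_potential(solv, M, M.radius + solv.diameter, sp) == 0.0
    # wall location for the smallest cation
    assert macroion_potential(mg, M, 1.606, sp) == HARD_OVERLAP
    assert macroion_potential(mg, M, 1.607, sp) < np.inf
    val = macroion_potential(cl, M, 2.0, sp)
    assert val == pytest.approx(-18.0 * sp.lambda_b / 2.0, rel=1e-3)


def test_potentials_decay_as_inverse_r(base_system):
    sp = base_system
    na, cl = sp.species[1], sp.species[2]
    r = 0.7 * 1.45 ** np.arange(12)
    ru = np.array([r_ * pair_potential(na, cl, r_, sp) for r_ in r])
    assert np.all(np.abs(ru - ru[0]) <= 1e-12 * np.abs(ru[0]))
    rm = np.array([r_ * macroion_potential(cl, sp.macroion, r_, sp) for r_ in r + 2.0])
    assert np.all(np.abs(rm - rm[0]) <= 1e-12 * np.abs(rm[0]))


def test_validate_base_system(base_system):
    report = validate_system(base_system)
    assert report.macroion_valence == pytest.approx(18.0, abs=0.01)
    # solvent packing fraction (pi/6) * 16.711 * 0.31875^3
    assert report.packing_fractions[3] == pytest.approx(0.2834, abs=2e-3)
    assert report.kappa == pytest.approx(5.20, abs=0.01)
    assert report.debye_length == pytest.approx(0.192, abs=1e-3)


def test_validate_rejects_charge_imbalance():
    sp = SystemSpec(
        species=(Species("Na", 0.3, 1, 1.0),),
        macroion=Macroion.from_valence(1.0, 1.0),
    )
    with pytest.raises(ValueError, match="electroneutrality"):
        validate_system(sp)


def test_validate_rejects_overpacking():
    sp = SystemSpec(
        species=(Species("solvent", 0.4, 0, 40.0),),
        macroion=Macroion.from_valence(0.0, 1.0),
    )
    with pytest.raises(ValueError, match="packing"):
        validate_system(sp)


def test_two_solvents_rejected():
    with pytest.raises(ValueError, match="solvent"):
        SystemSpec(
            species=(Species("s1", 0.3, 0, 1.0), Species("s2", 0.3, 0, 1.0)),
            macroion=Macroion.from_valence(0.0, 1.0),
        )


def test_inconsistent_macroion_rejected():
    with pytest.raises(ValueError, match="inconsistent"):
        Macroion(radius=1.5, valence=20.0, surface_charge_density=0.102)


def test_debye_kappa_examples():
    none = SystemSpec(
        species=(Species("solvent", 0.3, 0, 10.0),),
        macroion=Macroion.from_valence(0.0, 1.0),
    )
    assert debye_kappa(none) == 0.0
    nacl = SystemSpec(
        species=(Species("Na", 0.3, 1, 1.0), Species("Cl", 0.3, -1, 1.0)),
        macroion=Macroion.from_valence(0.0, 1.0),
    )
    assert debye_kappa(nacl) == pytest.approx(3.29, abs=0.01)
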