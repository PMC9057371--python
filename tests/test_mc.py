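"""Monte Carlo engine: setup, Ewald sums, sampling and binning."""

import math
import warnings

import numpy as np
import pytest

from spmedl import _mc_kernels as K
from spmedl import mc
from spmedl.model import Macroion, Species, SystemSpec, mixed_electrolyte


@pytest.fixture(scope="module")
def paper_spec():
    return SystemSpec(
        species=mixed_electrolyte(1.0, 0.5, 27.75),
        macroion=Macroion.from_valence(18.0, 1.5),
    )


@pytest.fixture(scope="module")
def desk_spec():
    return SystemSpec(
        species=mixed_electrolyte(0.1, 0.05, 5.0),
        macroion=Macroion.from_valence(8.0, 1.0),
    )


def test_target_counts_paper_cell(paper_spec):
    """Printed concentrations in an L = 6 nm cell give the documented counts."""
    counts = mc.target_counts(paper_spec, 6.0)
    assert counts["Na"] == 130
    assert counts["Mg"] == 65
    assert counts["Cl"] == 130 + 2 * 65 + 18  # exact neutrality incl. Z_M


def test_counts_neutral_for_uncharged_macroion():
    spec = SystemSpec(
        species=(Species("Na", 0.3, 1, 0.5), Species("Cl", 0.3, -1, 0.5)),
        macroion=Macroion.from_valence(0.0, 1.0),
    )
    counts = mc.target_counts(spec, 5.0)
    assert counts["Na"] == counts["Cl"]


def test_initial_configuration_deterministic(desk_spec):
    with warnings.catch_warnings():
        warnings.simplefilter("ignore")
        a = mc.build_initial_configuration(desk_spec, 5.0, seed=42)
        b = mc.build_initial_configuration(desk_spec, 5.0, seed=42)
        c = mc.build_initial_configuration(desk_spec, 5.0, seed=43)
    np.testing.assert_array_equal(a.positions, b.positions)
    assert not np.array_equal(a.positions, c.positions)
    # exact cell neutrality including the macroion
    assert float(np.sum(a.charges)) == 0.0
    # no overlaps in the inserted configuration
    _, overlap = K.total_real_energy(
        a.positions, a.charges, a.diameters, a.L, 1.0, a.spec.lambda_b, 0
    )
    assert not overlap


def test_dense_cell_falls_back_to_lattice_start():
    """Near the sequential-insertion jamming density the builder switches to
    a lattice start and anneals it to an overlap-free configuration."""
    spec = SystemSpec(
        species=(Species("hs", 0.32, 0, 32.0),),  # eta ~ 0.33
        macroion=Macroion.from_valence(0.0, 0.3),
    )
    with pytest.warns(UserWarning, match="lattice"):
        cfg = mc.build_initial_configuration(spec, 3.0, seed=5, max_attempts=20)
    _, overlap = K.total_real_energy(
        cfg.positions, cfg.charges, cfg.diameters, cfg.L, 1.0, spec.lambda_b, 0
    )
    assert not overlap
    assert cfg.counts["hs"] == round(32.0 * 0.602214076 * 27.0)


def _two_charge_config(d, L):
    spec = SystemSpec(
        species=(Species("p", 1e-3, 1, 0.0), Species("m", 1e-3, -1, 0.0)),
        macroion=Macroion.from_valence(0.0, 1e-3),
    )
    pos = np.array([[0.0, 0.0, 0.0], [d, 0.0, 0.0]])
    return mc.MCConfiguration(
        spec, L, pos, np.array([1.0, -1.0]), np.full(2, 1e-3),
        np.array([0, 1]), np.ones(2, dtype=bool), 1, K.seed_state(1),
    )


def test_isolated_pair_energy_is_bare_coulomb():
    """Two opposite charges in a huge cell: Ewald reduces to -lb/d."""
    d = 1.0
    cfg = _two_charge_config(d, L=60.0)
    u = mc.ewald_energy(cfg, mc.EwaldControls(alpha_over_l=6.0, nmax2=80))
    lb = cfg.spec.lambda_b
    assert u == pytest.approx(-lb / d, abs=1e-4 * lb)


def _rock_salt_config(d):
    L = 2.0 * d
    spec = SystemSpec(
        species=(Species("p", 1e-3, 1, 0.0), Species("m", 1e-3, -1, 0.0)),
        macroion=Macroion.from_valence(0.0, 1e-3),
    )
    pos, q = [], []
    for ix in range(2):
        for iy in range(2):
            for iz in range(2):
                pos.append([ix * d, iy * d, iz * d])
                q.append(1.0 if (ix + iy + iz) % 2 == 0 else -1.0)
    n = len(q)
    return mc.MCConfiguration(
        spec, L, np.array(pos), np.array(q, dtype=float), np.full(n, 1e-3),
        np.zeros(n, dtype=np.int64), np.ones(n, dtype=bool), 1, K.seed_state(1),
    )


def evjen_madelung(m=9):
    """Direct lattice summation with Evjen fractional boundary weights."""
    idx = np.arange(-m, m + 1)
    X, Y, Z = np.meshgrid(idx, idx, idx, indexing="ij")
    w = np.ones_like(X, dtype=float)
    for A in (X, Y, Z):
        w *= np.where(np.abs(A) == m, 0.5, 1.0)
    q = np.where((X + Y + Z) % 2 == 0, 1.0, -1.0)
    r = np.sqrt(X**2 + Y**2 + Z**2).astype(float)
    mask = r > 0
    return -np.sum(q[mask] * w[mask] / r[mask])


def test_rock_salt_madelung_vs_direct_summation():
    d = 0.4
    cfg = _rock_salt_config(d)
    lb = cfg.spec.lambda_b
    u = mc.ewald_energy(cfg, mc.EwaldControls(alpha_over_l=6.0, nmax2=120))
    per_ion_lattice_sum = 2.0 * u / cfg.n_particles  # sum_j u_ij per ion
    alpha_ewald = -per_ion_lattice_sum * d / lb
    alpha_direct = evjen_madelung()
    assert alpha_direct == pytest.approx(1.747565, abs=2e-5)
    assert alpha_ewald == pytest.approx(alpha_direct, rel=1e-4)


def test_ewald_alpha_independence():
    cfg = _rock_salt_config(0.4)
    us = [
        mc.ewald_energy(cfg, mc.EwaldControls(alpha_over_l=a, nmax2=130))
        for a in (4.0, 5.0, 6.0, 7.0, 8.0)
    ]
    ref = us[2]
    for u in us:
        assert u == pytest.approx(ref, rel=1e-6)


def test_ewald_kspace_cutoff_converged():
    cfg = _rock_salt_config(0.4)
    u1 = mc.ewald_energy(cfg, mc.EwaldControls(alpha_over_l=6.0, nmax2=60))
    u2 = mc.ewald_energy(cfg, mc.EwaldControls(alpha_over_l=6.0, nmax2=240))
    assert u1 == pytest.approx(u2, rel=1e-6)


def test_ewald_zero_for_neutral_particles():
    spec = SystemSpec(
        species=(Species("hs", 0.2, 0, 1.0),),
        macroion=Macroion.from_valence(0.0, 0.3),
    )
    with warnings.catch_warnings():
        warnings.simplefilter("ignore")
        cfg = mc.build_initial_configuration(spec, 4.0, seed=1)
    assert mc.ewald_energy(cfg) == 0.0


def test_ewald_rejects_non_neutral_cell():
    cfg = _two_charge_config(1.0, L=10.0)
    cfg.charges = np.array([1.0, 0.0])
    with pytest.raises(ValueError, match="neutral"):
        mc.ewald_energy(cfg)


def test_zero_displacement_sweep_accepts_everything(desk_spec):
    with warnings.catch_warnings():
        warnings.simplefilter("ignore")
        cfg = mc.build_initial_configuration(desk_spec, 5.0, seed=7)
    before = cfg.positions.copy()
    accepted = mc.metropolis_sweep(cfg, displacement=0.0)
    assert accepted == int(np.sum(cfg.mobile))
    np.testing.assert_array_equal(cfg.positions, before)


def test_energy_bookkeeping_against_full_recompute(desk_spec):
    """Running dU accumulation equals a fresh Ewald evaluation."""
    sched = mc.MCSchedule(
        equilibration=100, production=600, blocks=10, recompute_every=1, bin_width=0.1
    )
    with warnings.catch_warnings():
        warnings.simplefilter("ignore")
        rep = mc.run_simulation(desk_spec, 5.0, seed=5, schedule=sched)
    assert rep.energy_drift < 1e-8


def test_zero_production_gives_empty_valid_report(desk_spec):
    sched = mc.MCSchedule(equilibration=10, production=0, blocks=10, bin_width=0.1)
    with warnings.catch_warnings():
        warnings.simplefilter("ignore")
        rep = mc.run_simulation(desk_spec, 5.0, seed=5, schedule=sched)
    assert rep.rho.shape[0] == 4
    assert np.all(rep.rho == 0.0)


def test_binning_conservation_under_halving():
    """Halving the bin width preserves integrated shell counts."""
    rng = np.random.default_rng(0)
    pos = rng.uniform(0, 4.0, size=(500, 3))
    species = np.zeros(500, dtype=np.int64)
    coarse = np.zeros((1, 10))
    fine = np.zeros((1, 20))
    K.bin_counts(pos, species, 4.0, 0.2, 10, coarse)
    K.bin_counts(pos, species, 4.0, 0.1, 20, fine)
    np.testing.assert_array_equal(coarse[0], fine[0].reshape(10, 2).sum(axis=1))


def test_uniform_points_bin_to_flat_density():
    rng = np.random.default_rng(1)
    L, n, samples = 6.0, 4000, 40
    counts = np.zeros((1, 25))
    for _ in range(samples):
        pos = rng.uniform(0, L, size=(n, 3))
        K.bin_counts(pos, np.zeros(n, dtype=np.int64), L, 0.1, 25, counts)
    r, rho = mc.bin_density_profiles(counts, 0.1, samples)
    target = n / L**3
    se = np.sqrt(counts[0]) / (samples * (4 * math.pi / 3) * np.diff((0.1 * np.arange(26)) ** 3))
    assert np.all(np.abs(rho[0] - target) < 4.0 * se + 1e-9)
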