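"""DFT assembly and solver behaviour on cheap systems (heavy runs live in
the acceptance suite and the shared session fixtures)."""

import math
import warnings

import numpy as np
import pytest

from spmedl.dft import DFTControls, DFTProblem, solve_dft
from spmedl.grid import RadialGrid
from spmedl.model import Macroion, Species, SystemSpec, debye_kappa, mixed_electrolyte


def _cheap_controls(**kw):
    kw.setdefault("el_kernel_mode", "wl")
    kw.setdefault("h", 0.02)
    return DFTControls(**kw)


@pytest.fixture(scope="module")
def desk_problem():
    spec = SystemSpec(
        species=mixed_electrolyte(0.1, 0.05, 5.0),
        macroion=Macroion.from_valence(8.0, 1.0),
    )
    with warnings.catch_warnings():
        warnings.simplefilter("ignore")
        return DFTProblem(spec, controls=_cheap_controls())


def test_uniform_input_is_fixed_point():
    """Bulk profiles around an uncharged macroion map to themselves."""
    spec = SystemSpec(
        species=mixed_electrolyte(0.1, 0.05, 5.0),
        macroion=Macroion.from_valence(0.0, 1.0),
    )
    with warnings.catch_warnings():
        warnings.simplefilter("ignore")
        problem = DFTProblem(spec, controls=_cheap_controls())
    rho_u = np.tile(spec.bulk_densities[:, None], (1, problem.grid.n))
    out = problem.rhs(rho_u, uniform_fill=True)
    dev = np.max(np.abs(out - rho_u) / spec.bulk_densities[:, None])
    assert dev < 1e-10


def test_solvent_el_term_is_zero(desk_problem):
    spec = desk_problem.spec
    rng = np.random.default_rng(3)
    rho = spec.bulk_densities[:, None] * rng.uniform(
        0.5, 1.5, size=(4, desk_problem.grid.n)
    )
    el = desk_problem.c1_el_difference(rho)
    np.testing.assert_array_equal(el[3], 0.0)


def test_el_term_vanishes_for_uniform_input(desk_problem):
    spec = desk_problem.spec
    rho_u = np.tile(spec.bulk_densities[:, None], (1, desk_problem.grid.n))
    el = desk_problem.c1_el_difference(rho_u, uniform_fill=True)
    assert np.max(np.abs(el)) < 1e-12


def test_el_term_matches_brute_force_quadrature(desk_problem):
    """Gaussian bump in one ionic species vs direct 3D quadrature of the kernel."""
    spec = desk_problem.spec
    grid = desk_problem.grid
    rho = np.tile(spec.bulk_densities[:, None], (1, grid.n))
    bump = 0.5 * spec.bulk_densities[2] * np.exp(
        -0.5 * ((grid.r - 1.8) / 0.15) ** 2
    )
    rho[2] = spec.bulk_densities[2] + bump
    el = desk_problem.c1_el_difference(rho, uniform_fill=True)

    # brute force for species 0 (Mg) at one radius
    kern = desk_problem.kernels
    lbzz = spec.lambda_b * spec.valences[0] * spec.valences[2]
    sij = 0.5 * (spec.diameters[0] + spec.diameters[2])
    n = 40
    xs = np.linspace(-sij, sij, n)
    X, Y, Z = np.meshgrid(xs, xs, xs, indexing="ij")
    r_eval = 1.8
    S = np.sqrt(X**2 + Y**2 + Z**2)
    inside = (S <= sij) & (S > 0)
    dv = (xs[1] - xs[0]) ** 3
    K = np.zeros_like(S)
    K[inside] = kern.el(0, 2, S[inside]) + lbzz / S[inside]
    rr = np.sqrt(X**2 + Y**2 + (Z + r_eval) ** 2)
    dr_rho = 0.5 * spec.bulk_densities[2] * np.exp(-0.5 * ((rr - 1.8) / 0.15) ** 2)
    brute = np.sum(K * dr_rho) * dv
    approx = np.interp(r_eval, grid.r, el[0])
    assert approx == pytest.approx(brute, rel=1e-2)


def test_hs_only_system_reduces_to_neutral_wall(desk_problem):
    """Q=0 with all charges off converges to the pure hard-sphere wall profile."""
    spec = SystemSpec(
        species=(Species("hs", 0.3, 0, 8.0),),
        macroion=Macroion.from_valence(0.0, 1.0),
    )
    with warnings.catch_warnings():
        warnings.simplefilter("ignore")
        sol = solve_dft(spec, controls=DFTControls(h=0.01, r_max=3.0))
    assert sol.converged
    assert np.all(sol.psi == 0.0)
    # contact enhancement at a neutral hard wall, decaying to bulk
    mask = sol.rho[0] > 0
    assert sol.rho[0][mask][0] > spec.bulk_densities[0]
    assert sol.rho[0, -1] == pytest.approx(spec.bulk_densities[0], rel=1e-4)


@pytest.fixture(scope="module")
def weak_coupling_solution():
    spec = SystemSpec(
        species=(Species("Na", 0.3, 1, 0.05), Species("Cl", 0.3, -1, 0.05)),
        macroion=Macroion.from_valence(5.0, 1.5),
    )
    with warnings.catch_warnings():
        warnings.simplefilter("ignore")
        sol = solve_dft(
            spec, controls=DFTControls(h=0.02, r_max=1.5 + 12.0, el_kernel_mode="wl")
        )
    assert sol.converged
    return spec, sol


def test_bulk_recovery_and_neutrality(weak_coupling_solution):
    spec, sol = weak_coupling_solution
    np.testing.assert_allclose(
        sol.rho[:, -10:], np.tile(spec.bulk_densities[:, None], (1, 10)), rtol=1e-4
    )
    assert sol.psi[-1] == 0.0


def test_debye_tail_slope(weak_coupling_solution):
    """log |psi| decays linearly with slope -kappa at weak coupling."""
    spec, sol = weak_coupling_solution
    kappa = debye_kappa(spec)
    r = sol.r
    band = (r > 2.5) & (r < 2.5 + 3.0 / kappa)
    y = np.log(np.abs(sol.psi[band] * r[band]))
    slope, intercept = np.polyfit(r[band], y, 1)
    resid = y - (slope * r[band] + intercept)
    r2 = 1.0 - np.sum(resid**2) / np.sum((y - y.mean()) ** 2)
    assert r2 > 0.999
    assert slope == pytest.approx(-kappa, rel=0.05)


def test_discrete_poisson_consistency(weak_coupling_solution):
    """(1/r)(r psi)'' = -4 pi lb q on the converged profiles, to O(h^2)."""
    spec, sol = weak_coupling_solution
    r, h = sol.r, sol.grid.h
    u = r * sol.psi
    lap = (u[:-2] - 2.0 * u[1:-1] + u[2:]) / h**2 / r[1:-1]
    q = sol.charge_density(spec.valences)
    rhs = -4.0 * math.pi * spec.lambda_b * q[1:-1]
    scale = np.max(np.abs(rhs))
    np.testing.assert_allclose(lap, rhs, atol=5e-3 * scale)


def test_divergence_reported():
    spec = SystemSpec(
        species=mixed_electrolyte(1.0, 0.5, 27.75),
        macroion=Macroion.from_surface_charge(0.408, 1.5),
    )
    with warnings.catch_warnings():
        warnings.simplefilter("ignore")
        prob = DFTProblem(
            spec, controls=_cheap_controls(max_iter=40, tol=1e-14)
        )
        with pytest.warns(UserWarning, match="not converged"):
            sol = prob.solve()
    assert not sol.converged
    assert len(sol.residual_history) == 40


def test_grid_invariants():
    g = RadialGrid(r_min=1.5, r_max=3.0, h=0.01)
    assert g.n == 151
    assert g.r[0] == pytest.approx(1.5) and g.r[-1] == pytest.approx(3.0)
    with pytest.raises(ValueError):
        RadialGrid(r_min=0.0, r_max=1.0, h=0.01)
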