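"""Weighted-density approximation: kernels, uniform preservation, modes."""

import math

import numpy as np
import pytest

from spmedl.grid import RadialGrid
from spmedl.hs import c1_hs_gradient, uniform_c1_hs
from spmedl.model import Macroion, Species, SystemSpec, mixed_electrolyte
from spmedl.wda import WDAOperator, weight_kernel

SIGMA4 = np.array([0.2125, 0.265625, 0.425, 0.31875])


@pytest.fixture(scope="module")
def spec():
    return SystemSpec(
        species=mixed_electrolyte(1.0, 0.5, 27.75),
        macroion=Macroion.from_surface_charge(0.102, 1.5),
    )


@pytest.fixture(scope="module")
def operator(spec):
    grid = RadialGrid(r_min=1.5, r_max=3.5, h=0.02, pad=0.5)
    return WDAOperator(spec, grid)


def test_weight_kernel_normalization_random_states():
    rng = np.random.default_rng(11)
    for _ in range(20):
        f = rng.uniform(0.05, 1.0, size=4)
        eta = rng.uniform(0.05, 0.45)
        w = (math.pi / 6.0) * SIGMA4**3
        rho = f / np.sum(f * w) * eta
        i, j = rng.integers(0, 4, size=2)
        contact = 0.5 * (SIGMA4[i] + SIGMA4[j])
        s = np.linspace(0.0, contact, 3000)
        integral = np.trapezoid(
            4.0 * math.pi * s**2 * weight_kernel(i, j, s, rho, SIGMA4), s
        )
        assert integral == pytest.approx(1.0, rel=1e-5)


def test_weight_kernel_zero_density_is_uniform_ball():
    s = np.linspace(0.0, 0.4, 200)
    w = weight_kernel(0, 2, s, np.zeros(4), SIGMA4)
    contact = 0.5 * (SIGMA4[0] + SIGMA4[2])
    vol = (4.0 / 3.0) * math.pi * contact**3
    np.testing.assert_allclose(w[s < contact], 1.0 / vol, rtol=1e-9)
    assert np.all(w[s > contact] == 0.0)


def test_uniform_profiles_are_preserved(spec, operator):
    """Bulk input maps to bulk weighted densities and zero c1 difference."""
    rho_u = np.tile(spec.bulk_densities[:, None], (1, operator.grid.n))
    field = operator.weighted_densities(rho_u, uniform_fill=True)
    for a in range(4):
        for b in range(4):
            np.testing.assert_allclose(
                field.rho_bar[a, b], spec.bulk_densities[b], rtol=1e-12
            )
    c1 = operator.c1_profile(field)
    np.testing.assert_allclose(
        c1, operator.c1_bulk()[:, None] * np.ones((1, operator.grid.n)), rtol=1e-10
    )


def test_zero_density_profiles_give_zero_field(spec, operator):
    field = operator.weighted_densities(np.zeros((4, operator.grid.n)))
    # beyond-r_max bulk extension contributes only near the outer edge
    interior = operator.grid.r < operator.grid.r_max - 0.5
    assert np.max(np.abs(field.rho_bar[:, :, interior])) == 0.0


def test_step_profile_smoothed_and_bounded(spec, operator):
    """A step in one species produces a smoothed step bounded by the inputs."""
    rho = np.tile(spec.bulk_densities[:, None], (1, operator.grid.n))
    step = operator.grid.r > 2.5
    rho[2] = np.where(step, 1.5 * spec.bulk_densities[2], 0.5 * spec.bulk_densities[2])
    field = operator.weighted_densities(rho, uniform_fill=True)
    rb = field.rho_bar[0, 2]
    lo, hi = 0.5 * spec.bulk_densities[2], 1.5 * spec.bulk_densities[2]
    interior = (operator.grid.r > 1.6) & (operator.grid.r < operator.grid.r_max - 0.5)
    assert np.all(rb[interior] >= lo - 1e-10) and np.all(rb[interior] <= hi + 1e-10)
    # smoothed: strictly between the plateaus near the step
    near = np.abs(operator.grid.r - 2.5) < 0.1
    assert np.all(rb[near] > lo * 1.01) and np.all(rb[near] < hi * 0.99)


def test_c1_profile_at_doubled_bulk_density(spec, operator):
    """Composition is preserved: a field at 2x bulk gives the uniform value at 2x bulk."""
    from spmedl.wda import WeightedDensityField

    N = 5
    rb = np.tile(2.0 * spec.bulk_densities[None, :, None], (4, 1, N))
    c1 = operator.c1_profile(WeightedDensityField(operator.grid, rb, "bulk_weights"))
    expected = uniform_c1_hs(2.0 * spec.bulk_densities, spec.diameters)
    for a in range(4):
        np.testing.assert_allclose(c1[a], expected[a], rtol=1e-12)


def test_c1_monotone_decreasing_in_total_density(spec, operator):
    """c1 (= -beta mu_ex) decreases monotonically along a bulk-scaling ramp."""
    from spmedl.wda import WeightedDensityField

    scales = np.linspace(0.2, 1.6, 30)
    rb = np.tile(spec.bulk_densities[None, :, None], (4, 1, scales.size)) * scales
    c1 = operator.c1_profile(WeightedDensityField(operator.grid, rb, "bulk_weights"))
    assert np.all(np.diff(c1, axis=1) < 0.0)


def test_self_consistent_mode_agrees_to_first_order():
    """bulk-weight and self-consistent modes differ at second order in drho."""
    spec = SystemSpec(
        species=(Species("hs", 0.3, 0, 8.0),),
        macroion=Macroion.from_valence(0.0, 1.0),
    )
    grid = RadialGrid(r_min=1.0, r_max=2.2, h=0.06, pad=0.35)
    op_b = WDAOperator(spec, grid, mode="bulk_weights")
    op_s = WDAOperator(spec, grid, mode="self_consistent")
    diffs = []
    amps = (0.02, 0.04)
    for amp in amps:
        rho = spec.bulk_densities[:, None] * (
            1.0 + amp * np.sin(3.0 * grid.r)[None, :]
        )
        fb = op_b.weighted_densities(rho, uniform_fill=True)
        fs = op_s.weighted_densities(rho, uniform_fill=True)
        diffs.append(np.max(np.abs(fb.rho_bar - fs.rho_bar)) / spec.bulk_densities[0])
    # doubling the modulation quadruples (not doubles) the disagreement
    ratio = diffs[1] / max(diffs[0], 1e-300)
    assert ratio > 3.0


def test_consistency_derivative_example(spec):
    """Numeric d c1_i/d rho_j equals the kernel volume integral (module contract)."""
    rho = spec.bulk_densities
    grad = c1_hs_gradient(rho, spec.diameters)
    eps = 1e-6
    for i, j in [(0, 2), (3, 1)]:
        dp = rho.copy()
        dm = rho.copy()
        dp[j] += eps
        dm[j] -= eps
        numeric = (
            uniform_c1_hs(dp, spec.diameters)[i] - uniform_c1_hs(dm, spec.diameters)[i]
        ) / (2.0 * eps)
        assert numeric == pytest.approx(grad[i, j], rel=1e-6)
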