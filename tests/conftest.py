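"""Shared fixtures: study conditions and cached (session-scoped) solutions.

The expensive converged solutions (base-condition DFT with and without
solvent, the URMGC baseline, the desk-scale Monte Carlo run) are computed
once per session and shared between the unit and acceptance tests.
"""

from __future__ import annotations

import warnings

import numpy as np
import pytest
from hypothesis import HealthCheck, settings

from spmedl.dft import DFTControls, DFTProblem
from spmedl.mc import EwaldControls, MCSchedule, run_simulation
from spmedl.model import Macroion, SystemSpec, mixed_electrolyte
from spmedl.pb import solve_urmgc

settings.register_profile(
    "ci",
    derandomize=True,
    max_examples=25,
    deadline=None,
    suppress_health_check=[HealthCheck.too_slow],
)
settings.load_profile("ci")


# -- study conditions --------------------------------------------------------


@pytest.fixture(scope="session")
def base_spec() -> SystemSpec:
    """The common study condition: 1 M NaCl + 0.5 M MgCl2, solvent 27.75 M,
    R = 1.5 nm, Q = 0.102 C m^-2."""
    return SystemSpec(
        species=mixed_electrolyte(1.0, 0.5, 27.75),
        macroion=Macroion.from_surface_charge(0.102, 1.5),
    )


@pytest.fixture(scope="session")
def base_nosolvent_spec() -> SystemSpec:
    return SystemSpec(
        species=mixed_electrolyte(1.0, 0.5, 0.0),
        macroion=Macroion.from_surface_charge(0.102, 1.5),
    )


@pytest.fixture(scope="session")
def desk_spec() -> SystemSpec:
    """Scaled-down cross-validation condition: R = 1 nm, Z_M = 8,
    0.1 M NaCl + 0.05 M MgCl2, solvent 5 M."""
    return SystemSpec(
        species=mixed_electrolyte(0.1, 0.05, 5.0),
        macroion=Macroion.from_valence(8.0, 1.0),
    )


# -- cached solutions --------------------------------------------------------


@pytest.fixture(scope="session")
def base_dft(base_spec):
    """Converged DFT on the base condition at the default grid step."""
    problem = DFTProblem(base_spec)
    solution = problem.solve()
    assert solution.converged
    return problem, solution


@pytest.fixture(scope="session")
def base_dft_coarse(base_spec):
    """Same condition at twice the grid step (for the O(h^2) check)."""
    problem = DFTProblem(base_spec, controls=DFTControls(h=base_spec.diameters.min() / 20.0))
    with warnings.catch_warnings():
        warnings.simplefilter("ignore")
        solution = problem.solve()
    assert solution.converged
    return problem, solution


@pytest.fixture(scope="session")
def base_nosolvent_dft(base_nosolvent_spec):
    problem = DFTProblem(base_nosolvent_spec)
    solution = problem.solve()
    assert solution.converged
    return problem, solution


@pytest.fixture(scope="session")
def base_urmgc(base_spec):
    solution = solve_urmgc(base_spec)
    assert solution.converged
    return solution


@pytest.fixture(scope="session")
def desk_mc(desk_spec):
    """Block-averaged MC run on the desk-scale condition.

    The cell edge satisfies the double-layer size rule L >= 2 (R + 4/kappa)
    (= 6.9 nm here), keeping periodic-image contamination of the profiles
    below statistical error."""
    schedule = MCSchedule(
        equilibration=3000,
        production=18_000,
        blocks=12,
        bin_width=0.1,
        sample_every=2,
        recompute_every=1,
    )
    with warnings.catch_warnings():
        warnings.simplefilter("ignore")
        report = run_simulation(desk_spec, L=7.0, seed=20260925, schedule=schedule,
                                ewald=EwaldControls())
    return report


def realized_cell_spec(spec: SystemSpec, counts: dict[str, int], L: float) -> SystemSpec:
    """The thermodynamic state actually realized by an integer-count cell.

    Canonical cells hold rounded particle numbers (plus the neutralizing
    counterions, which belong to the double layer, not the reservoir), so
    the far-field concentrations differ slightly from the nominal ones.
    This rebuilds a SystemSpec at those realized concentrations — the state
    a grand-canonical method must be run at to compare like with like.
    """
    from spmedl.model import Species, number_density_to_molar

    Z = spec.macroion.valence
    v_free = L**3 - (4.0 * np.pi / 3.0) * float(np.mean(spec.contact_radii)) ** 3
    new = []
    for s in spec.species:
        n = counts[s.label]
        if s.valence != 0 and s.valence * Z < 0:
            n = n - abs(Z) / abs(s.valence)  # neutralizing excess is not reservoir
        new.append(
            Species(s.label, s.diameter, s.valence, number_density_to_molar(n / v_free))
        )
    # enforce exact reservoir electroneutrality on the counterion
    imb = sum(s.valence * s.bulk_concentration for s in new)
    fixed = []
    for s in new:
        if s.valence != 0 and s.valence * Z < 0 and imb != 0:
            fixed.append(
                Species(s.label, s.diameter, s.valence,
                        s.bulk_concentration - imb / s.valence)
            )
            imb = 0
        else:
            fixed.append(s)
    return SystemSpec(
        species=tuple(fixed),
        macroion=spec.macroion,
        dielectric_constant=spec.dielectric_constant,
        temperature=spec.temperature,
    )


@pytest.fixture(scope="session")
def desk_dft_matched(desk_spec, desk_mc):
    """DFT at the thermodynamic state realized by the MC cell."""
    spec = realized_cell_spec(desk_spec, desk_mc.meta["counts"], desk_mc.L)
    problem = DFTProblem(spec, controls=DFTControls(h=desk_spec.diameters.min() / 25.0))
    solution = problem.solve()
    assert solution.converged
    return spec, solution
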