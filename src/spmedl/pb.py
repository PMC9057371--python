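"""Unequal-radius modified Gouy-Chapman (URMGC) reference solver.

Nonlinear Poisson-Boltzmann theory for point ions around the charged
sphere, retaining only the species-specific distances of closest approach
(Stern shells) of the primitive model.  In reduced units (psi in k_BT/e,
lengths in nm):

    (1/r^2) d/dr ( r^2 dpsi/dr ) = -4 pi lambda_B sum_a z_a rho0_a
                                     e^{-z_a psi(r)} theta(r - R - sigma_a/2),

with the Gauss-law surface condition ``psi'(R) = -lambda_B Z_M / R^2`` and
``psi(r_max) = 0``.  The neutral solvent plays no role in a point-ion
theory and is excluded entirely.  Solved with a damped Newton method on the
finite-difference system (tridiagonal Jacobian), with an automatic Picard
fallback; the URMGC profiles are the completely monotonic baseline against
which the correlation-driven structure of the DFT/MC results is judged.

Also provides the linearized (Debye-Hueckel) closed form used as an
analytic oracle in the weak-coupling limit.
"""

from __future__ import annotations

import math
from dataclasses import dataclass

import numpy as np
from scipy.linalg import solve_banded

from .grid import RadialGrid, RadialProfileSet
from .model import SystemSpec, debye_kappa, validate_system

__all__ = ["PBControls", "solve_urmgc", "dh_potential"]


@dataclass
class PBControls:
    h: float | None = None
    r_max: float | None = None
    tol: float = 1e-10
    max_iter: int = 200
    max_backtrack: int = 30


def _pb_charge(psi: np.ndarray, z: np.ndarray, rho0: np.ndarray, mask: np.ndarray):
    """Boltzmann charge density q(r) and its psi-derivative, with Stern exclusions."""
    boltz = np.exp(np.clip(-z[:, None] * psi[None, :], -200.0, 200.0)) * mask
    dens = rho0[:, None] * boltz
    q = np.tensordot(z, dens, axes=(0, 0))
    dq = -np.tensordot(z**2, dens, axes=(0, 0))
    return q, dq, dens


def solve_urmgc(
    spec: SystemSpec,
    grid: RadialGrid | None = None,
    controls: PBControls | None = None,
) -> RadialProfileSet:
    """Solve the URMGC equation; returns profiles in the common container.

    The residual of the discrete system is driven below ``controls.tol``
    (max-norm, k_BT/e nm^-2 units of the Poisson operator).
    """
    ctrl = controls or PBControls()
    validate_system(spec)
    ions = spec.without_solvent()
    R = spec.macroion.radius
    lb = spec.lambda_b
    Z = spec.macroion.valence
    kappa = debye_kappa(spec)
    if grid is None:
        h = ctrl.h if ctrl.h is not None else float(np.min(ions.diameters)) / 50.0
        r_max = ctrl.r_max
        if r_max is None:
            reach = max(12.0 / kappa, 4.0) if kappa > 0 else 10.0 * R
            r_max = R + reach
        grid = RadialGrid(r_min=R, r_max=r_max, h=h)
    r = grid.r
    h = grid.h
    n = grid.n
    z = ions.valences
    rho0 = ions.bulk_densities
    mask = r[None, :] >= (R + ions.diameters[:, None] / 2.0) - 1e-12

    # Unknowns u_i = r_i psi_i, i = 0..n-1; u_{n-1} = 0 (outer Dirichlet).
    # Interior: (u_{i-1} - 2 u_i + u_{i+1})/h^2 = -4 pi lb r_i q_i.
    # Surface Neumann (second order, ghost node eliminated):
    #   psi'(R) = -lb Z / R^2 with psi = u/r =>
    #   (u_1 - u_{-1})/(2h) = u_0/R - lb Z/R, and the i=0 Poisson row.
    def residual(u):
        psi = u / r
        q, dq, _ = _pb_charge(psi, z, rho0, mask)
        res = np.empty(n)
        res[1:-1] = (u[:-2] - 2.0 * u[1:-1] + u[2:]) / h**2 + 4.0 * math.pi * lb * r[1:-1] * q[1:-1]
        # ghost u_{-1} = u_1 - 2h(u_0/R - lb Z/R):
        res[0] = (2.0 * u[1] - 2.0 * u[0] - 2.0 * h * (u[0] / R - lb * Z / R)) / h**2 \
            + 4.0 * math.pi * lb * r[0] * q[0]
        res[-1] = u[-1]
        return res, dq

    def jacobian_banded(dq):
        ab = np.zeros((3, n))
        ab[0, 1:] = 1.0 / h**2  # superdiagonal
        ab[2, :-1] = 1.0 / h**2  # subdiagonal
        ab[1, :] = -2.0 / h**2 + 4.0 * math.pi * lb * dq  # note dq multiplies psi = u/r -> r q'(u) * (1/r)
        ab[0, 1] = 2.0 / h**2
        ab[1, 0] = -2.0 / h**2 - 2.0 / (h * R) + 4.0 * math.pi * lb * dq[0]
        ab[1, -1] = 1.0
        ab[0, -1] = 0.0
        ab[2, -2] = 0.0
        return ab

    # Initial guess: linearized (DH) potential from the innermost Stern shell.
    a0 = float(np.min(R + ions.diameters / 2.0))
    if kappa > 0:
        psi = lb * Z * np.exp(-kappa * (r - a0)) / (r * (1.0 + kappa * a0))
    else:
        psi = lb * Z * (1.0 / r - 1.0 / r[-1])
    u = r * psi
    res, dq = residual(u)
    rnorm = float(np.max(np.abs(res)))
    it = 0
    newton_ok = True
    for it in range(1, ctrl.max_iter + 1):
        if rnorm < ctrl.tol:
            break
        ab = jacobian_banded(dq)
        try:
            du = solve_banded((1, 1), ab, -res)
        except Exception:
            newton_ok = False
            break
        step = 1.0
        for _ in range(ctrl.max_backtrack):
            res_new, dq_new = residual(u + step * du)
            rn = float(np.max(np.abs(res_new)))
            if rn < rnorm or not math.isfinite(rnorm):
                break
            step *= 0.5
        else:
            newton_ok = False
            break
        u = u + step * du
        res, dq, rnorm = res_new, dq_new, rn
    else:
        newton_ok = False

    if not newton_ok:  # damped Picard fallback on the integral form
        u, rnorm, it2 = _picard_fallback(r, h, R, lb, Z, z, rho0, mask, u, ctrl)
        it += it2

    psi = u / r
    _, _, dens = _pb_charge(psi, z, rho0, mask)
    return RadialProfileSet(
        grid=grid,
        rho=dens,
        psi=psi,
        converged=bool(rnorm < max(ctrl.tol, 1e-8)),
        residual_history=np.array([rnorm]),
        meta={"model": "urmgc", "iterations": it, "residual": rnorm},
    )


def _picard_fallback(r, h, R, lb, Z, z, rho0, mask, u, ctrl):
    """Slow but robust fallback: under-relaxed sweeps of the Gauss-law update."""
    n = len(r)
    mix = 0.05
    rnorm = math.inf
    for it in range(1, 200_000):
        psi = u / r
        q, _, _ = _pb_charge(psi, z, rho0, mask)
        inner = np.concatenate(([0.0], np.cumsum(0.5 * (q[1:] * r[1:] ** 2 + q[:-1] * r[:-1] ** 2) * np.diff(r))))
        s_int = np.concatenate(([0.0], np.cumsum(0.5 * (q[1:] * r[1:] + q[:-1] * r[:-1]) * np.diff(r))))
        psi_new = lb * Z / r + 4.0 * math.pi * lb * (inner / r + (s_int[-1] - s_int))
        psi_new -= psi_new[-1]
        rnorm = float(np.max(np.abs(psi_new - psi)))
        u = r * ((1.0 - mix) * psi + mix * psi_new)
        if rnorm < 1e-12:
            break
    return u, rnorm, it


def dh_potential(Z_M: float, lambda_b: float, kappa: float, a: float, r) -> np.ndarray:
    """Linearized double-layer potential (k_BT/e) outside a common closest approach ``a``.

        beta e psi(r) = Z_M lambda_B e^{-kappa (r - a)} / [ r (1 + kappa a) ].

    Reduces to the bare Coulomb form for kappa = 0.
    """
    r = np.asarray(r, dtype=float)
    return Z_M * lambda_b * np.exp(-kappa * (r - a)) / (r * (1.0 + kappa * a))
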