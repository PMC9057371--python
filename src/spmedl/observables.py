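"""Derived double-layer observables: integrated charge, charge reversal, compactness.

The central diagnostic is the integrated charge distribution

    P(r) = Z_M + 4 pi sum_a z_a int_R^r s^2 rho_a(s) ds,

the net charge (in e) enclosed within radius r, macroion included, so that
``P(R) = Z_M`` and global electroneutrality gives ``P(r_max) -> 0``.
Charge reversal (CR) is flagged where ``P(r) Z_M < 0``; surface charge
amplification where ``|P(r)| > |Z_M|`` with matching sign; the adsorbed
charge amplification is ``dZ_M = max_r P(r) - Z_M``.

The width of the double layer is condensed into the capacitive compactness
``tau_c``: the radius of the ideal counter-charge shell of a spherical
capacitor that reproduces the surface potential,

    1/tau_c = 1/R - beta e psi_0 / (lambda_B Z_M),

with ``psi_0 = psi(R)``.  Perfect screening at contact gives tau_c -> R; a
diffuse layer pushes tau_c outward; an unscreened macroion has no finite
capacitor radius (tau_c = +inf, flagged).
"""

from __future__ import annotations

import math
from dataclasses import dataclass

import numpy as np

from .grid import RadialProfileSet
from .model import SystemSpec

__all__ = [
    "integrated_charge",
    "ionic_integrated_charge",
    "classify_charge_state",
    "capacitive_compactness",
    "ObservableSet",
    "compute_observables",
]


def ionic_integrated_charge(profiles: RadialProfileSet, spec: SystemSpec) -> np.ndarray:
    """Ion-cloud-only running integral 4 pi sum_a z_a int_R^r s^2 rho_a ds (e)."""
    r = profiles.r
    q = profiles.charge_density(spec.valences)
    y = r**2 * q
    cum = np.concatenate(([0.0], np.cumsum(0.5 * (y[1:] + y[:-1]) * np.diff(r))))
    return 4.0 * math.pi * cum


def integrated_charge(profiles: RadialProfileSet, spec: SystemSpec) -> np.ndarray:
    """Net enclosed charge P(r) in e, macroion included: P(R) = Z_M, P(inf) -> 0."""
    return spec.macroion.valence + ionic_integrated_charge(profiles, spec)


@dataclass(frozen=True)
class ChargeState:
    cr: bool
    cr_radius: float | None
    amplification: bool
    amplification_radius: float | None
    delta_z: float


def classify_charge_state(
    P: np.ndarray, r: np.ndarray, Z_M: float, rel_tol: float = 1e-6
) -> ChargeState:
    """Charge-reversal / amplification flags from an integrated-charge curve.

    CR at the first radius where ``P(r) Z_M < 0``; amplification where
    ``|P| > |Z_M|`` with the sign of Z_M (radius of max |P| reported);
    ``delta_z = max_r P - Z_M``.  Undefined for an uncharged macroion.
    ``rel_tol`` (in units of |Z_M|) keeps quadrature-level noise around
    P = 0 from raising spurious flags.
    """
    if Z_M == 0:
        raise ValueError("charge-state classification undefined for Z_M = 0")
    P = np.asarray(P, dtype=float)
    atol = rel_tol * abs(Z_M)
    signed = P * np.sign(Z_M)
    cr_idx = np.nonzero(signed < -atol)[0]
    cr = cr_idx.size > 0
    cr_radius = float(r[cr_idx[0]]) if cr else None
    amp_mask = (np.abs(P) > abs(Z_M) + atol) & (signed > 0)
    amplification = bool(np.any(amp_mask))
    if amplification:
        idx = np.nonzero(amp_mask)[0]
        amp_radius = float(r[idx[np.argmax(np.abs(P[idx]))]])
    else:
        amp_radius = None
    return ChargeState(
        cr=cr,
        cr_radius=cr_radius,
        amplification=amplification,
        amplification_radius=amp_radius,
        delta_z=float(np.max(P) - Z_M),
    )


def capacitive_compactness(psi0: float, Z_M: float, R: float, lambda_b: float) -> float:
    """Capacitive compactness tau_c (nm) from the surface potential psi0 (k_BT/e).

    ``1/tau_c = 1/R - psi0 / (lambda_B Z_M)``; returns +inf when the double
    layer provides no net screening (psi0 >= bare Coulomb value).
    """
    if Z_M == 0:
        raise ValueError("tau_c undefined for an uncharged macroion")
    inv = 1.0 / R - psi0 / (lambda_b * Z_M)
    if inv <= 0:
        return math.inf
    return 1.0 / inv


@dataclass(frozen=True)
class ObservableSet:
    """Scalar summary of one converged/equilibrated profile set."""

    z_m: float
    psi0: float
    tau_c: float
    delta_z: float
    cr: bool
    cr_radius: float | None
    amplification: bool
    amplification_radius: float | None
    neutrality_residual: float  # |P(r_max)| / |Z_M|

    def row(self) -> str:
        cr_r = f"{self.cr_radius:.6g}" if self.cr_radius is not None else "NA"
        return (
            f"{self.z_m:.6g} {self.psi0:.6g} {self.tau_c:.6g} "
            f"{self.delta_z:.6g} {cr_r}"
        )


def compute_observables(
    profiles: RadialProfileSet, spec: SystemSpec, psi0_at: str = "surface"
) -> ObservableSet:
    """All scalar observables of a profile set.

    ``psi0_at`` selects where the surface potential is read: ``"surface"``
    (r = R, the default) or ``"contact"`` (the innermost distance of closest
    approach).
    """
    if psi0_at not in ("surface", "contact"):
        raise ValueError(f"unknown psi0_at {psi0_at!r}")
    r = profiles.r
    P = integrated_charge(profiles, spec)
    Z = spec.macroion.valence
    if psi0_at == "surface":
        psi0 = float(profiles.psi[0])
    else:
        a0 = float(np.min(spec.contact_radii))
        psi0 = float(np.interp(a0, r, profiles.psi))
    state = classify_charge_state(P, r, Z)
    tau = capacitive_compactness(psi0, Z, spec.macroion.radius, spec.lambda_b)
    return ObservableSet(
        z_m=Z,
        psi0=psi0,
        tau_c=tau,
        delta_z=state.delta_z,
        cr=state.cr,
        cr_radius=state.cr_radius,
        amplification=state.amplification,
        amplification_radius=state.amplification_radius,
        neutrality_residual=float(abs(P[-1]) / abs(Z)) if Z != 0 else float(abs(P[-1])),
    )
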