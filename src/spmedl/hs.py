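"""Uniform hard-sphere mixture thermodynamics and Percus-Yevick pair DCF.

Both the one-particle direct correlation function (DCF) of the uniform
mixture, ``c1_i = -beta mu_i^ex``, and the two-particle DCF ``c2_ij(r)`` are
generated from a single excess free-energy density (the scaled-particle /
PY-compressibility functional of the four scalar measures n0..n3 and the two
vector measures).  Evaluating its second derivative in the uniform limit
yields *exactly* the analytic Percus-Yevick solution for additive
hard-sphere mixtures, and guarantees the thermodynamic consistency relation

    d c1_i / d rho_j  =  integral c2_ij(s) d^3 s

analytically, which the weighted-density approximation (``wda`` module)
relies on for its kernel normalization.

Notation: per-species radius ``R_i = sigma_i / 2``; scalar measures of the
uniform mixture ``n0 = sum rho_i``, ``n1 = sum rho_i R_i``,
``n2 = sum rho_i 4 pi R_i^2``, ``n3 = sum rho_i (4 pi/3) R_i^3`` (= total
packing fraction).
"""

from __future__ import annotations

import math

import numpy as np

__all__ = [
    "scalar_measures",
    "uniform_c1_hs",
    "c1_hs_gradient",
    "py_hs_dcf",
    "py_contact_distance",
]

_4PI = 4.0 * math.pi


def _measure_weights(diameters: np.ndarray) -> np.ndarray:
    """Per-species geometric weights xi = (1, R, 4 pi R^2, 4 pi R^3/3), shape (4, ns)."""
    R = np.asarray(diameters, dtype=float) / 2.0
    return np.stack([np.ones_like(R), R, _4PI * R**2, (_4PI / 3.0) * R**3])


def scalar_measures(rho, diameters) -> np.ndarray:
    """Uniform scalar measures (n0, n1, n2, n3); rho may be (ns,) or (ns, N)."""
    rho = np.asarray(rho, dtype=float)
    xi = _measure_weights(diameters)
    return np.tensordot(xi, rho, axes=(1, 0))


def _phi_first(n: np.ndarray) -> np.ndarray:
    """First derivatives (phi_0..phi_3) of the excess free energy density."""
    n0, n1, n2, n3 = n
    D = 1.0 - n3
    if np.any(D <= 0):
        raise ValueError("total packing fraction must be < 1")
    return np.stack(
        [
            -np.log(D),
            n2 / D,
            n1 / D + n2**2 / (8.0 * math.pi * D**2),
            n0 / D + n1 * n2 / D**2 + n2**3 / (12.0 * math.pi * D**3),
        ]
    )


def _phi_second(n: np.ndarray) -> dict:
    """Non-zero second derivatives of the free energy density at a uniform state.

    Scalar block keys '03','12','13','23','22','33'; vector block keys
    'v12' (n_v1.n_v2 coefficient) and 'v22' (n_v2.n_v2 coefficient).
    """
    n0, n1, n2, n3 = n
    D = 1.0 - n3
    return {
        "03": 1.0 / D,
        "12": 1.0 / D,
        "13": n2 / D**2,
        "23": n1 / D**2 + n2**2 / (_4PI * D**3),
        "22": n2 / (_4PI * D**2),
        "33": n0 / D**2 + 2.0 * n1 * n2 / D**3 + n2**3 / (_4PI * D**4),
        "v12": -1.0 / D,
        "v22": -n2 / (_4PI * D**2),
    }


def uniform_c1_hs(rho, diameters) -> np.ndarray:
    """One-particle hard-sphere DCF ``c1_i = -beta mu_i^ex`` of the uniform mixture.

    ``rho`` has shape (ns,) or (ns, N) for N density states evaluated at once;
    the result has the same shape.  Zero at zero density; raises for total
    packing fraction >= 1.
    """
    n = scalar_measures(rho, diameters)
    phi = _phi_first(n)
    xi = _measure_weights(diameters)
    return -np.tensordot(xi.T, phi, axes=(1, 0))


def c1_hs_gradient(rho, diameters) -> np.ndarray:
    """Density gradient ``d c1_i / d rho_j`` of the uniform mixture, shape (ns, ns[, N]).

    Equals ``- sum_ab phi_ab xi_a^i xi_b^j`` (vector measures integrate to
    zero and do not contribute), i.e. exactly ``integral c2_ij d^3 s``.
    """
    n = scalar_measures(rho, diameters)
    p = _phi_second(n)
    xi = _measure_weights(diameters)
    ns = xi.shape[1]
    phi2 = np.zeros((4, 4) + np.shape(n[0]))
    for key, val in p.items():
        if key.startswith("v"):
            continue
        a, b = int(key[0]), int(key[1])
        phi2[a, b] += val
        if a != b:
            phi2[b, a] += val
    # grad[i, j] = - xi_a^i phi2[a,b] xi_b^j
    return -np.einsum("ai,ab...,bj->ij...", xi, phi2, xi)


# ---------------------------------------------------------------------------
# Geometric cross-correlations of the weight functions (closed forms).
# a, b are the two radii; r is the centre separation (array).


def _conv_shell_shell(a: float, b: float, r: np.ndarray) -> np.ndarray:
    """(delta_a * delta_b)(r) = 2 pi a b / r on |a-b| <= r <= a+b."""
    band = (r >= abs(a - b)) & (r <= a + b)
    return np.where(band, 2.0 * math.pi * a * b / r, 0.0)


def _conv_shell_ball(a: float, b: float, r: np.ndarray) -> np.ndarray:
    """(delta_a * Theta_b)(r): area of the radius-a shell lying inside the radius-b ball."""
    out = np.zeros_like(r)
    inside = r <= b - a  # entire shell inside the ball
    out[inside] = _4PI * a**2
    band = (r >= abs(a - b)) & (r <= a + b) & ~inside
    rb = r[band]
    out[band] = (math.pi * a / rb) * (b**2 - (rb - a) ** 2)
    return out


def _conv_ball_ball(a: float, b: float, r: np.ndarray) -> np.ndarray:
    """(Theta_a * Theta_b)(r): overlap volume of two balls."""
    out = np.zeros_like(r)
    small = min(a, b)
    inside = r <= abs(a - b)
    out[inside] = (_4PI / 3.0) * small**3
    band = (r > abs(a - b)) & (r <= a + b)
    rb = r[band]
    out[band] = (
        math.pi
        * (a + b - rb) ** 2
        * (rb**2 + 2.0 * rb * (a + b) - 3.0 * (a - b) ** 2)
        / (12.0 * rb)
    )
    return out


def _conv_vector(a: float, b: float, r: np.ndarray) -> np.ndarray:
    """Contracted convolution of the outward unit-vector shell weights."""
    band = (r >= abs(a - b)) & (r <= a + b)
    return np.where(band, (math.pi / r) * (a**2 + b**2 - r**2), 0.0)


def py_contact_distance(diameters, i: int, j: int) -> float:
    return 0.5 * (diameters[i] + diameters[j])


def py_hs_dcf(rho, diameters, i: int, j: int, s) -> np.ndarray:
    """Percus-Yevick pair DCF ``c2_ij(s)`` of the uniform additive HS mixture.

    Piecewise polynomial (plus 1/s pieces for unequal sizes) inside the
    contact distance ``(sigma_i + sigma_j)/2``; identically zero beyond it;
    symmetric in (i, j).  In the zero-density limit it reduces to the Mayer
    bond, -1 inside contact.
    """
    s = np.atleast_1d(np.asarray(s, dtype=float))
    if np.any(s < 0):
        raise ValueError("separation must be >= 0")
    diam = np.asarray(diameters, dtype=float)
    a, b = diam[i] / 2.0, diam[j] / 2.0
    # Clamp to avoid 0/0 at the origin for equal radii; the individual 1/s
    # divergences cancel analytically between the shell and vector terms.
    r = np.maximum(s, 1e-9 * (a + b))

    n = scalar_measures(np.asarray(rho, dtype=float), diam)
    p = _phi_second(n)

    A_ab = _conv_shell_ball(a, b, r)
    A_ba = _conv_shell_ball(b, a, r)
    W = _conv_shell_shell(a, b, r)
    B = _conv_ball_ball(a, b, r)
    V = _conv_vector(a, b, r)

    total = (
        p["03"] * (A_ab / (_4PI * a**2) + A_ba / (_4PI * b**2))
        + p["12"] * (W / (_4PI * a) + W / (_4PI * b))
        + p["13"] * (A_ab / (_4PI * a) + A_ba / (_4PI * b))
        + p["23"] * (A_ab + A_ba)
        + p["22"] * W
        + p["33"] * B
        + p["v12"] * (V / (_4PI * a) + V / (_4PI * b))
        + p["v22"] * V
    )
    out = -total
    out[s > a + b] = 0.0
    return out
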