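"""Radial grids, spherically reduced convolutions, and profile containers.

All nonuniform fields live on a uniform radial grid starting at the macroion
surface ``r = R``.  The three-dimensional convolutions of the DFT,
``(f * K)(r) = int d^3 r' f(r') K(|r - r'|)``, reduce by spherical symmetry
to

    (f * K)(r) = (2 pi / r) int dr' r' f(r') [ J(r + r') - J(|r - r'|) ],

with ``J(x) = int_0^x s K(s) ds``.  Kernels are represented by their inner
cumulative integral ``J`` plus an optional exact ``A/s`` tail beyond a
contact distance (for the Coulombic MSA kernels), so that the tail is
handled analytically.  The double integral is discretized by the trapezoid
rule and precompiled into a dense matrix per kernel: every DFT iteration is
then a handful of matrix-vector products.

Convolutions need the integrand down to ``r' = 0`` (the excluded volume
inside the macroion, where densities vanish but density *differences* do
not) and slightly beyond ``r_max`` (where profiles are at bulk), so the grid
carries an extended node set covering ``[~0, r_max + pad]``; profiles are
embedded into it with zeros below the surface and bulk values beyond
``r_max``.
"""

from __future__ import annotations

import math
import warnings
from dataclasses import dataclass, field

import numpy as np

__all__ = [
    "RadialGrid",
    "RadialProfileSet",
    "KernelIntegral",
    "conv_matrix",
    "spherical_convolution",
    "mep_from_charge_density",
]


@dataclass(frozen=True)
class RadialGrid:
    """Uniform radial grid from the macroion surface ``R`` to ``r_max``.

    ``pad`` extends the internal node set beyond ``r_max`` (bulk region
    used by finite-range convolutions); nodes below ``R`` down to (almost)
    the origin are always carried.
    """

    r_min: float
    r_max: float
    h: float
    pad: float = 0.0

    n: int = field(init=False)
    r: np.ndarray = field(init=False, repr=False)
    r_ext: np.ndarray = field(init=False, repr=False)
    i0: int = field(init=False)

    def __post_init__(self) -> None:
        if self.r_min <= 0 or self.r_max <= self.r_min or self.h <= 0:
            raise ValueError("require 0 < r_min < r_max and h > 0")
        n = int(round((self.r_max - self.r_min) / self.h)) + 1
        m_lo = int(math.floor((self.r_min - 1e-12) / self.h))
        m_hi = int(math.ceil(self.pad / self.h))
        idx = np.arange(-m_lo, n + m_hi)
        r_ext = self.r_min + self.h * idx
        object.__setattr__(self, "n", n)
        object.__setattr__(self, "r_ext", r_ext)
        object.__setattr__(self, "r", r_ext[m_lo : m_lo + n])
        object.__setattr__(self, "i0", m_lo)

    @property
    def n_ext(self) -> int:
        return len(self.r_ext)

    def embed(self, f: np.ndarray, bulk: float = 0.0, below: float = 0.0) -> np.ndarray:
        """Extend a physical-grid field to the internal node set.

        ``below`` fills the nodes under the macroion surface (zero for real
        profiles; the bulk value when checking the uniform-fluid limit of
        the functional), ``bulk`` fills beyond ``r_max``.
        """
        out = np.full(self.n_ext, below, dtype=float)
        out[self.i0 : self.i0 + self.n] = f
        out[self.i0 + self.n :] = bulk
        return out

    def trapezoid_weights_ext(self) -> np.ndarray:
        w = np.full(self.n_ext, self.h)
        w[0] = w[-1] = 0.5 * self.h
        return w


def default_grid(spec, kappa: float, h: float | None = None, r_max: float | None = None) -> RadialGrid:
    """Grid defaults: ``h = sigma_min/40``, ``r_max = R + max(10/kappa, 8 sigma_max)``."""
    sig = spec.diameters
    R = spec.macroion.radius
    if h is None:
        h = float(np.min(sig)) / 40.0
    if r_max is None:
        reach = 8.0 * float(np.max(sig))
        if kappa > 0:
            reach = max(reach, 10.0 / kappa)
        r_max = R + reach
    if h > float(np.min(sig)) / 20.0 + 1e-15:
        warnings.warn(
            f"grid step {h:.4g} nm is coarser than sigma_min/20; profiles may be under-resolved",
            stacklevel=2,
        )
    return RadialGrid(r_min=R, r_max=r_max, h=h, pad=float(np.max(sig)) + h)


class KernelIntegral:
    """Cumulative radial moment ``J(x) = int_0^x s K(s) ds`` of a kernel.

    Built from a tabulated short-range part on ``[0, s_cut]`` plus an
    optional exact ``A/s`` tail beyond ``s_cut`` (so ``J(x > s_cut) =
    J(s_cut) + A (x - s_cut)``).  Without a tail the kernel is treated as
    identically zero beyond ``s_cut``.
    """

    def __init__(
        self,
        s: np.ndarray,
        K: np.ndarray | None = None,
        tail_coeff: float | None = None,
        moment: np.ndarray | None = None,
    ):
        self.s = np.asarray(s, dtype=float)
        self.s_cut = float(self.s[-1])
        if moment is None:
            if K is None:
                raise ValueError("provide K or moment")
            self.K = np.asarray(K, dtype=float)
            integrand = self.s * self.K
        else:
            # First moment s*K given directly (lets kernels with an
            # integrable 1/s singularity at the origin be tabulated exactly).
            integrand = np.asarray(moment, dtype=float)
            with np.errstate(divide="ignore", invalid="ignore"):
                self.K = np.where(self.s > 0, integrand / self.s, 0.0)
        self.J_table = np.concatenate(
            ([0.0], np.cumsum(0.5 * (integrand[1:] + integrand[:-1]) * np.diff(self.s)))
        )
        self.tail_coeff = tail_coeff

    @classmethod
    def from_function(
        cls, K, s_cut: float, n: int = 4001, tail_coeff: float | None = None
    ) -> "KernelIntegral":
        s = np.linspace(0.0, s_cut, n)
        return cls(s, np.asarray(K(s), dtype=float), tail_coeff=tail_coeff)

    def __call__(self, x) -> np.ndarray:
        x = np.asarray(x, dtype=float)
        out = np.interp(np.clip(x, 0.0, self.s_cut), self.s, self.J_table)
        if self.tail_coeff is not None:
            out = out + self.tail_coeff * np.maximum(x - self.s_cut, 0.0)
        return out

    def full_integral(self) -> float:
        """``int K d^3 s`` of the short-range part (tail excluded)."""
        return 4.0 * math.pi * float(np.trapezoid(self.s**2 * self.K, self.s))


def conv_matrix(grid: RadialGrid, J: KernelIntegral, normalize: bool = False) -> np.ndarray:
    """Dense operator mapping an extended-grid field to ``(f * K)`` on the physical grid.

    With ``normalize=True`` each row is rescaled so that the discrete
    operator maps the constant field to exactly 1 (weighted-density kernels
    must preserve uniform profiles to machine precision).
    """
    r_out = grid.r[:, None]
    r_in = grid.r_ext[None, :]
    w = grid.trapezoid_weights_ext()[None, :]
    M = (2.0 * math.pi / r_out) * w * r_in * (J(r_out + r_in) - J(np.abs(r_out - r_in)))
    if normalize:
        rowsum = M.sum(axis=1)
        if np.any(rowsum <= 0):
            raise ValueError("cannot normalize kernel rows with non-positive sums")
        M = M / rowsum[:, None]
    return M


def spherical_convolution(f_ext: np.ndarray, grid: RadialGrid, J: KernelIntegral) -> np.ndarray:
    """One-off spherically reduced convolution (physical-grid output)."""
    return conv_matrix(grid, J) @ f_ext


def mep_from_charge_density(r: np.ndarray, q: np.ndarray, Z_M: float, lambda_b: float) -> np.ndarray:
    """Mean electrostatic potential (k_BT/e) from the ionic charge density.

    Two-term Gauss-law form, robust whether or not the profile is globally
    electroneutral:

        beta e psi(r) = lambda_B Z_M / r
                      + 4 pi lambda_B [ (1/r) int_R^r s^2 q ds + int_r^rmax s q ds ],

    shifted so that psi(r_max) = 0.  ``q = sum_alpha z_alpha rho_alpha`` on
    the physical grid ``r``.
    """
    inner = _cumtrapz(r**2 * q, r)
    s_int = _cumtrapz(r * q, r)
    outer_sq = s_int[-1] - s_int
    psi = lambda_b * Z_M / r + 4.0 * math.pi * lambda_b * (inner / r + outer_sq)
    return psi - psi[-1]


def _cumtrapz(y: np.ndarray, x: np.ndarray) -> np.ndarray:
    out = np.zeros_like(y)
    out[1:] = np.cumsum(0.5 * (y[1:] + y[:-1]) * np.diff(x))
    return out


@dataclass
class RadialProfileSet:
    """Per-species densities and the MEP on one radial grid.

    ``rho`` has shape (n_species, grid.n) in nm^-3; ``psi`` is the mean
    electrostatic potential in k_BT/e, pinned to zero at ``r_max``.
    """

    grid: RadialGrid
    rho: np.ndarray
    psi: np.ndarray
    converged: bool = False
    residual_history: np.ndarray = field(default_factory=lambda: np.empty(0))
    meta: dict = field(default_factory=dict)

    @property
    def r(self) -> np.ndarray:
        return self.grid.r

    def charge_density(self, valences: np.ndarray) -> np.ndarray:
        return np.tensordot(valences, self.rho, axes=(0, 0))

    def copy(self) -> "RadialProfileSet":
        return RadialProfileSet(
            grid=self.grid,
            rho=self.rho.copy(),
            psi=self.psi.copy(),
            converged=self.converged,
            residual_history=self.residual_history.copy(),
            meta=dict(self.meta),
        )
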