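"""Partially perturbative density functional theory of the spherical double layer.

The equilibrium density profile of each component around the macroion
satisfies

    rho_a(r) = rho0_a exp{ -z_a psi(r)
                           + [c1hs_a(r) - c1hs_a(bulk)]
                           + [c1el_a(r) - c1el_a(bulk)] },

with psi the mean electrostatic potential (k_BT/e) generated by the
macroion and all ionic charge, the hard-sphere term evaluated through the
weighted-density approximation (:mod:`spmedl.wda`), and the electrostatic
residual treated perturbatively around the uniform fluid:

    c1el_a(r) - c1el_a(bulk) = sum_b int c2el_ab(|r - r'|) [rho_b(r') - rho0_b] d^3r',

with the bulk MSA kernels of :mod:`spmedl.msa`.  Densities vanish inside
each species' distance of closest approach R + sigma_a/2.  The fixed point
is reached by damped Picard iteration with adaptive mixing; psi is
recomputed from the current densities at every step (the two-term Gauss-law
form, valid away from global electroneutrality), never iterated
independently, so the pair (rho, psi) stays consistent.
"""

from __future__ import annotations

import logging
import math
import warnings
from dataclasses import dataclass

import numpy as np

from . import msa
from .grid import (
    KernelIntegral,
    RadialGrid,
    RadialProfileSet,
    conv_matrix,
    default_grid,
    mep_from_charge_density,
)
from .model import SystemSpec, debye_kappa, validate_system
from .wda import WDAOperator

__all__ = ["DFTControls", "DFTProblem", "solve_dft", "c1_el_profile"]

log = logging.getLogger(__name__)

_EXP_CLIP = 30.0  # cap on the Boltzmann exponent during iteration


@dataclass
class DFTControls:
    """Numerical controls of the Picard solver.

    Defaults: grid step sigma_min/40, outer radius R + max(10/kappa,
    8 sigma_max), initial mixing 0.05 (doubling after 200 stable steps up to
    ``mixing_max``, halving on residual growth), relative tolerance 1e-7.
    """

    h: float | None = None
    r_max: float | None = None
    mixing: float = 0.05
    mixing_max: float = 0.4
    tol: float = 1e-7
    max_iter: int = 50_000
    wda_mode: str = "bulk_weights"
    el_kernel_mode: str = "oz"
    msa_include_solvent: bool = True
    log_every: int = 0


class DFTProblem:
    """Precompiled operators (grid, WDA, electrostatic kernels) for one system.

    Building this object is the expensive part (bulk MSA solve plus dense
    convolution matrices); :meth:`solve` can then be called repeatedly, e.g.
    to warm-start from a previous solution.
    """

    def __init__(self, spec: SystemSpec, grid: RadialGrid | None = None,
                 controls: DFTControls | None = None):
        self.spec = spec
        self.controls = controls or DFTControls()
        validate_system(spec)
        self.kappa = debye_kappa(spec)
        self.grid = grid or default_grid(
            spec, self.kappa, h=self.controls.h, r_max=self.controls.r_max
        )
        self.wda = WDAOperator(spec, self.grid, mode=self.controls.wda_mode)
        self.kernels = msa.MSAKernels(
            spec,
            include_solvent=self.controls.msa_include_solvent,
            mode=self.controls.el_kernel_mode,
        )
        z = spec.valences
        ns = spec.n_species
        # The convolution kernels are the *short-range* electrostatic DCFs
        # c2el_ij(s) + lambda_B z_i z_j / s (zero beyond contact): the
        # Coulomb tail of the MSA kernel is the ionic mean field, which the
        # density equation already carries through psi, and convolving it
        # again would double-count it.
        self._el_M = {}
        for i in range(ns):
            for j in range(i, ns):
                if z[i] == 0 or z[j] == 0 or self.kappa == 0:
                    continue
                sij = 0.5 * (spec.diameters[i] + spec.diameters[j])
                lbzz = spec.lambda_b * z[i] * z[j]
                s_tab = np.linspace(0.0, sij, 4001)
                moment = s_tab * self.kernels.el(i, j, s_tab) + lbzz
                J = KernelIntegral(s_tab, moment=moment)
                M = conv_matrix(self.grid, J)
                self._el_M[(i, j)] = self._el_M[(j, i)] = M
        self._c1_bulk = self.wda.c1_bulk()
        self._mask = (self.grid.r[None, :] >= spec.contact_radii[:, None] - 1e-12)

    # -- pieces -------------------------------------------------------------

    def mep(self, rho: np.ndarray) -> np.ndarray:
        q = np.tensordot(self.spec.valences, rho, axes=(0, 0))
        return mep_from_charge_density(
            self.grid.r, q, self.spec.macroion.valence, self.spec.lambda_b
        )

    def c1_hs_difference(self, rho: np.ndarray, uniform_fill: bool = False) -> np.ndarray:
        field = self.wda.weighted_densities(rho, uniform_fill=uniform_fill)
        return self.wda.c1_profile(field) - self._c1_bulk[:, None]

    def c1_el_difference(self, rho: np.ndarray, uniform_fill: bool = False) -> np.ndarray:
        ns = self.spec.n_species
        rho0 = self.spec.bulk_densities
        out = np.zeros((ns, self.grid.n))
        if not self._el_M:
            return out
        drho_ext = {
            b: self.grid.embed(
                rho[b], bulk=rho0[b], below=rho0[b] if uniform_fill else 0.0
            )
            - rho0[b]
            for b in range(ns)
            if self.spec.valences[b] != 0
        }
        for (i, j), M in self._el_M.items():
            if j < i:
                continue
            out[i] += M @ drho_ext[j]
            if i != j:
                out[j] += M @ drho_ext[i]
        return out

    def rhs(
        self,
        rho: np.ndarray,
        psi: np.ndarray | None = None,
        uniform_fill: bool = False,
    ) -> np.ndarray:
        """Right-hand side of the density equation for given profiles.

        ``uniform_fill`` fills the macroion interior with bulk fluid and
        skips the hard-wall cutoff: the uniform-limit diagnostic in which
        bulk profiles must be an exact fixed point.
        """
        if psi is None:
            psi = self.mep(rho)
        z = self.spec.valences
        expo = (
            -z[:, None] * psi[None, :]
            + self.c1_hs_difference(rho, uniform_fill=uniform_fill)
            + self.c1_el_difference(rho, uniform_fill=uniform_fill)
        )
        expo = np.clip(expo, -700.0, _EXP_CLIP)
        out = self.spec.bulk_densities[:, None] * np.exp(expo)
        if uniform_fill:
            return out
        return np.where(self._mask, out, 0.0)

    def initial_guess(self) -> np.ndarray:
        """Boltzmann profiles in the bare Debye-Hueckel potential; bulk solvent."""
        spec = self.spec
        r = self.grid.r
        a = float(np.mean(spec.contact_radii))
        kap = self.kappa
        Z = spec.macroion.valence
        if kap > 0:
            psi0 = (
                spec.lambda_b * Z * np.exp(-kap * (r - a)) / (r * (1.0 + kap * a))
            )
        else:
            psi0 = spec.lambda_b * Z * (1.0 / r - 1.0 / r[-1])
        z = spec.valences
        expo = np.clip(-z[:, None] * psi0[None, :], -50.0, 10.0)
        rho = spec.bulk_densities[:, None] * np.exp(expo)
        return np.where(self._mask, rho, 0.0)

    # -- solver -------------------------------------------------------------

    def solve(self, rho_start: np.ndarray | None = None) -> RadialProfileSet:
        """Damped Picard iteration, mixing in exponent space.

        The iterate is the Boltzmann exponent eta_a(r) = ln(rho_a/rho0_a):
        successive substitution on eta (rather than on rho itself) keeps
        transient contact spikes multiplicative and bounded, which is what
        makes the loop stable at high packing and strong coupling.  The
        convergence criterion stays on the density scale,
        max |rho_rhs - rho| / rho0 < tol.
        """
        ctrl = self.controls
        spec = self.spec
        rho0 = spec.bulk_densities
        safe0 = np.where(rho0 > 0, rho0, 1.0)
        if rho_start is None:
            rho = self.initial_guess()
        else:
            rho = np.where(self._mask, rho_start, 0.0)
        with np.errstate(divide="ignore"):
            eta = np.where(
                self._mask & (rho > 0), np.log(np.maximum(rho, 1e-300) / safe0[:, None]), -_EXP_CLIP
            )
        m = ctrl.mixing
        residuals = []
        prev_res = math.inf
        stable = 0
        rising = 0
        converged = False
        scale = safe0[:, None]
        for it in range(1, ctrl.max_iter + 1):
            rho = np.where(self._mask, rho0[:, None] * np.exp(np.clip(eta, -_EXP_CLIP, _EXP_CLIP)), 0.0)
            psi = self.mep(rho)
            expo = np.clip(
                -spec.valences[:, None] * psi[None, :]
                + self.c1_hs_difference(rho)
                + self.c1_el_difference(rho),
                -_EXP_CLIP,
                _EXP_CLIP,
            )
            new = np.where(self._mask, rho0[:, None] * np.exp(expo), 0.0)
            res = float(np.max(np.abs(new - rho) / scale))
            residuals.append(res)
            if ctrl.log_every and it % ctrl.log_every == 0:
                log.info("iter %d residual %.3e mixing %.3g", it, res, m)
            if res < ctrl.tol:
                rho = new
                converged = True
                break
            if res > 2.0 * prev_res:
                rising += 1
                stable = 0
                m = max(0.5 * m, 1e-3)
                if rising >= 50:
                    raise RuntimeError(
                        f"Picard iteration diverging (residual rose 50 consecutive "
                        f"steps, now {res:.3e}); retry with smaller mixing"
                    )
            else:
                if res <= prev_res:
                    rising = 0
                stable += 1
                if stable >= 200:
                    m = min(2.0 * m, ctrl.mixing_max)
                    stable = 0
            prev_res = max(res, 1e-300)
            eta = np.where(self._mask, (1.0 - m) * eta + m * expo, -_EXP_CLIP)
        if not converged:
            warnings.warn(
                f"DFT not converged after {ctrl.max_iter} iterations "
                f"(residual {residuals[-1]:.3e}); returning partial result",
                stacklevel=2,
            )
        psi = self.mep(rho)
        return RadialProfileSet(
            grid=self.grid,
            rho=rho,
            psi=psi,
            converged=converged,
            residual_history=np.asarray(residuals),
            meta={
                "model": "dft",
                "iterations": len(residuals),
                "mixing_final": m,
                "wda_mode": ctrl.wda_mode,
                "el_kernel_mode": ctrl.el_kernel_mode,
                "gamma_msa": self.kernels.params.gamma,
                "kappa": self.kappa,
            },
        )


def solve_dft(
    spec: SystemSpec,
    grid: RadialGrid | None = None,
    controls: DFTControls | None = None,
    rho_start: np.ndarray | None = None,
) -> RadialProfileSet:
    """Convenience wrapper: build the operators and iterate to convergence."""
    return DFTProblem(spec, grid=grid, controls=controls).solve(rho_start=rho_start)


def c1_el_profile(problem: DFTProblem, profiles: RadialProfileSet) -> np.ndarray:
    """Electrostatic perturbation term (already the bulk-referenced difference)."""
    return problem.c1_el_difference(profiles.rho)
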