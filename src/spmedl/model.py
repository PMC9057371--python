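"""Core model definitions: species, macroion, system specification, interactions.

The physical system is a single rigid spherical macroion of radius ``R`` (nm)
carrying a uniform surface charge density ``Q`` (C m^-2), immersed in a
solvent primitive model (SPM) electrolyte: small ions are charged hard
spheres, the solvent is a neutral hard sphere, and the dielectric background
is a uniform continuum of relative permittivity ``epsilon``.

Reduced units are used throughout the package:

* lengths in nanometres,
* energies in units of ``k_B T``,
* charges in units of the elementary charge ``e``.

The only places where SI constants appear are :func:`bjerrum_length`,
:func:`macroion_valence` / :func:`surface_charge_density` and
:func:`molar_to_number_density`; everything downstream works in reduced
units, with the Coulomb coupling carried entirely by the Bjerrum length
``lambda_B = e^2 / (4 pi eps0 eps k_B T)``.
"""

from __future__ import annotations

import math
from dataclasses import dataclass, field, replace
from typing import Sequence

import numpy as np

__all__ = [
    "ELEMENTARY_CHARGE",
    "AVOGADRO",
    "BOLTZMANN",
    "VACUUM_PERMITTIVITY",
    "HARD_OVERLAP",
    "Species",
    "Macroion",
    "SystemSpec",
    "ValidationReport",
    "molar_to_number_density",
    "number_density_to_molar",
    "bjerrum_length",
    "macroion_valence",
    "surface_charge_density",
    "pair_potential",
    "macroion_potential",
    "debye_kappa",
    "validate_system",
    "mixed_electrolyte",
]

# CODATA 2018 exact values.
ELEMENTARY_CHARGE = 1.602176634e-19  # C
AVOGADRO = 6.02214076e23  # mol^-1
BOLTZMANN = 1.380649e-23  # J K^-1
VACUUM_PERMITTIVITY = 8.8541878128e-12  # F m^-1

#: Sentinel for hard-core overlap.  Contract: any Boltzmann factor computed
#: from it must evaluate to exactly zero, hence ``math.inf`` and not a large
#: finite float.
HARD_OVERLAP = math.inf

# Maximum total packing fraction accepted by validate_system (FCC close packing).
_MAX_PACKING = 0.74


def molar_to_number_density(c: float) -> float:
    """Convert a molar concentration (mol/L) to a number density in nm^-3.

    Exact linear map ``c * N_A * 1e-24`` (one litre is 1e24 nm^3).
    """
    if c < 0:
        raise ValueError(f"concentration must be non-negative, got {c}")
    return c * AVOGADRO * 1e-24


def number_density_to_molar(rho: float) -> float:
    """Inverse of :func:`molar_to_number_density`."""
    return rho / (AVOGADRO * 1e-24)


def bjerrum_length(epsilon: float, temperature: float) -> float:
    """Bjerrum length ``e^2 / (4 pi eps0 eps k_B T)`` in nm.

    For water-like conditions (eps = 78.5, T = 298 K) this is 0.714 nm.
    """
    if epsilon <= 0 or temperature <= 0:
        raise ValueError("epsilon and temperature must be positive")
    lb_m = ELEMENTARY_CHARGE**2 / (
        4.0 * math.pi * VACUUM_PERMITTIVITY * epsilon * BOLTZMANN * temperature
    )
    return lb_m * 1e9


def macroion_valence(Q: float, R: float) -> float:
    """Macroion valence ``Z_M = 4 pi R^2 Q / e`` for ``Q`` in C m^-2, ``R`` in nm."""
    if R <= 0:
        raise ValueError("macroion radius must be positive")
    area_m2 = 4.0 * math.pi * (R * 1e-9) ** 2
    return Q * area_m2 / ELEMENTARY_CHARGE


def surface_charge_density(Z_M: float, R: float) -> float:
    """Surface charge density (C m^-2) of a macroion of valence ``Z_M`` and radius ``R`` nm."""
    if R <= 0:
        raise ValueError("macroion radius must be positive")
    area_m2 = 4.0 * math.pi * (R * 1e-9) ** 2
    return Z_M * ELEMENTARY_CHARGE / area_m2


@dataclass(frozen=True)
class Species:
    """A small-ion or solvent component of the electrolyte.

    Parameters
    ----------
    label:
        Human-readable tag (e.g. ``"Mg"``, ``"solvent"``).
    diameter:
        Hard-sphere diameter sigma_alpha in nm.
    valence:
        Integer charge z_alpha in units of e; 0 marks the neutral solvent.
    bulk_concentration:
        Reservoir molarity (mol/L).
    """

    label: str
    diameter: float
    valence: int
    bulk_concentration: float

    def __post_init__(self) -> None:
        if self.diameter <= 0:
            raise ValueError(f"{self.label}: diameter must be positive")
        if self.bulk_concentration < 0:
            raise ValueError(f"{self.label}: bulk concentration must be >= 0")

    @property
    def bulk_density(self) -> float:
        """Bulk number density rho^0 in nm^-3."""
        return molar_to_number_density(self.bulk_concentration)

    @property
    def is_solvent(self) -> bool:
        return self.valence == 0


@dataclass(frozen=True)
class Macroion:
    """The central colloidal sphere.

    ``valence`` (e) and ``surface_charge_density`` (C m^-2) are redundant and
    must agree through ``Z_M = 4 pi R^2 Q / e``; use the class methods
    :meth:`from_surface_charge` or :meth:`from_valence` to build a consistent
    instance from either one.
    """

    radius: float
    valence: float
    surface_charge_density: float = field(default=float("nan"))

    def __post_init__(self) -> None:
        if self.radius <= 0:
            raise ValueError("macroion radius must be positive")
        if math.isnan(self.surface_charge_density):
            object.__setattr__(
                self,
                "surface_charge_density",
                surface_charge_density(self.valence, self.radius),
            )
        else:
            expected = macroion_valence(self.surface_charge_density, self.radius)
            scale = max(abs(expected), abs(self.valence), 1e-30)
            if abs(expected - self.valence) > 1e-9 * scale:
                raise ValueError(
                    "inconsistent macroion: valence "
                    f"{self.valence} vs {expected} implied by Q"
                )

    @classmethod
    def from_surface_charge(cls, Q: float, radius: float) -> "Macroion":
        return cls(radius=radius, valence=macroion_valence(Q, radius), surface_charge_density=Q)

    @classmethod
    def from_valence(cls, Z_M: float, radius: float) -> "Macroion":
        return cls(radius=radius, valence=Z_M)


@dataclass(frozen=True)
class SystemSpec:
    """Full physical specification of one SPM double-layer problem.

    This is the single source of physical truth consumed by every solver in
    the package.  Invariants (checked by :func:`validate_system`): bulk
    electroneutrality of the ionic species, at most one neutral (solvent)
    species, and a total packing fraction below close packing.
    """

    species: tuple[Species, ...]
    macroion: Macroion
    dielectric_constant: float = 78.5
    temperature: float = 298.0

    def __post_init__(self) -> None:
        object.__setattr__(self, "species", tuple(self.species))
        if not self.species:
            raise ValueError("at least one species is required")
        if self.dielectric_constant <= 0 or self.temperature <= 0:
            raise ValueError("dielectric constant and temperature must be positive")
        if sum(1 for s in self.species if s.is_solvent) > 1:
            raise ValueError("at most one neutral species (the solvent) is allowed")

    # -- derived reduced-unit quantities -----------------------------------

    @property
    def n_species(self) -> int:
        return len(self.species)

    @property
    def lambda_b(self) -> float:
        """Bjerrum length in nm."""
        return bjerrum_length(self.dielectric_constant, self.temperature)

    @property
    def diameters(self) -> np.ndarray:
        return np.array([s.diameter for s in self.species])

    @property
    def valences(self) -> np.ndarray:
        return np.array([float(s.valence) for s in self.species])

    @property
    def bulk_densities(self) -> np.ndarray:
        """Per-species bulk number densities rho^0_alpha (nm^-3)."""
        return np.array([s.bulk_density for s in self.species])

    @property
    def packing_fractions(self) -> np.ndarray:
        return (math.pi / 6.0) * self.bulk_densities * self.diameters**3

    @property
    def contact_radii(self) -> np.ndarray:
        """Distance of closest approach R + sigma_alpha/2 per species (nm)."""
        return self.macroion.radius + self.diameters / 2.0

    def without_solvent(self) -> "SystemSpec":
        """Copy of the spec with the neutral component removed (ions only)."""
        ions = tuple(s for s in self.species if not s.is_solvent)
        return replace(self, species=ions)


def pair_potential(a: Species, b: Species, r: float, spec: SystemSpec) -> float:
    """Pair interaction u_ab(r) in k_BT between two mobile components.

    Hard-sphere repulsion inside the additive contact distance
    (sigma_a + sigma_b)/2, Coulomb tail ``lambda_B z_a z_b / r`` outside.
    Neutral pairs reduce to pure hard spheres.
    """
    if r <= 0:
        raise ValueError("separation must be positive")
    contact = 0.5 * (a.diameter + b.diameter)
    if r < contact:
        return HARD_OVERLAP
    return spec.lambda_b * a.valence * b.valence / r


def macroion_potential(a: Species, M: Macroion, r: float, spec: SystemSpec) -> float:
    """Interaction of species ``a`` with the macroion, in k_BT.

    Hard wall at ``R + sigma_a/2`` plus a bare Coulomb term
    ``lambda_B Z_M z_a / r`` (zero for the solvent, which sees only the wall).
    """
    if r <= 0:
        raise ValueError("separation must be positive")
    if r < M.radius + 0.5 * a.diameter:
        return HARD_OVERLAP
    return spec.lambda_b * M.valence * a.valence / r


def debye_kappa(spec: SystemSpec) -> float:
    """Inverse Debye screening length kappa = sqrt(4 pi lambda_B sum rho_i z_i^2), nm^-1."""
    s2 = float(np.sum(spec.bulk_densities * spec.valences**2))
    return math.sqrt(4.0 * math.pi * spec.lambda_b * s2)


@dataclass(frozen=True)
class ValidationReport:
    """Summary emitted by :func:`validate_system`."""

    macroion_valence: float
    debye_length: float
    kappa: float
    packing_fractions: tuple[float, ...]
    total_packing_fraction: float

    def __str__(self) -> str:  # pragma: no cover - cosmetic
        etas = ", ".join(f"{x:.4f}" for x in self.packing_fractions)
        return (
            f"Z_M = {self.macroion_valence:.3f}, kappa = {self.kappa:.4f} nm^-1 "
            f"(Debye length {self.debye_length:.4f} nm), eta = [{etas}] "
            f"(total {self.total_packing_fraction:.4f})"
        )


def validate_system(spec: SystemSpec, charge_tol: float = 1e-9) -> ValidationReport:
    """Check the SystemSpec invariants and report derived screening quantities.

    Raises ``ValueError`` on bulk charge imbalance, more than one solvent
    species (already rejected at construction) or packing at/above close
    packing.
    """
    rho = spec.bulk_densities
    z = spec.valences
    imbalance = float(np.sum(rho * z))
    scale = float(np.sum(rho * np.abs(z))) or 1.0
    if abs(imbalance) > charge_tol * scale:
        raise ValueError(
            f"bulk electroneutrality violated: sum z*rho = {imbalance:g} nm^-3"
        )
    etas = spec.packing_fractions
    eta_tot = float(etas.sum())
    if eta_tot >= _MAX_PACKING:
        raise ValueError(
            f"total packing fraction {eta_tot:.3f} >= {_MAX_PACKING} (close packing)"
        )
    kappa = debye_kappa(spec)
    return ValidationReport(
        macroion_valence=spec.macroion.valence,
        debye_length=(1.0 / kappa if kappa > 0 else math.inf),
        kappa=kappa,
        packing_fractions=tuple(float(x) for x in etas),
        total_packing_fraction=eta_tot,
    )


def mixed_electrolyte(
    c_nacl: float,
    c_mgcl2: float,
    c_solvent: float,
    sigma: float = 0.2125,
    ratio: Sequence[float] = (1.0, 1.25, 2.0, 1.5),
) -> tuple[Species, ...]:
    """Build the standard four-component NaCl/MgCl2 + solvent species set.

    The smallest diameter ``sigma`` belongs to the multivalent cation; the
    diameter ratio Mg:Na:Cl:solvent defaults to 1 : 1.25 : 2 : 1.5.  The
    chloride concentration is fixed by electroneutrality,
    ``c_Cl = c_NaCl + 2 c_MgCl2``.  A zero solvent concentration drops the
    neutral component entirely (primitive-model limit).
    """
    species = [
        Species("Mg", sigma * ratio[0], +2, c_mgcl2),
        Species("Na", sigma * ratio[1], +1, c_nacl),
        Species("Cl", sigma * ratio[2], -1, c_nacl + 2.0 * c_mgcl2),
    ]
    if c_solvent > 0:
        species.append(Species("solvent", sigma * ratio[3], 0, c_solvent))
    return tuple(species)
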