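"""Configuration files, fixture registry, profile I/O and synthetic profiles.

The system file is YAML with a fixed schema::

    system:
      epsilon: 78.5
      T_K: 298.0
      macroion: {R_nm: 1.5, Q_C_per_m2: 0.102}   # or Z_M, or both (checked)
      species:
        - {label: Mg, diameter_nm: 0.2125, valence: 2, concentration_M: 0.5}
        - ...

Unknown keys anywhere are rejected.  Profile files are plain columnar text
(17 significant digits, i.e. full double precision) with a provenance
header, readable back to bit-identical arrays.

The fixture registry reproduces every parameter combination printed in the
source study's figure captions: the common base is the 1 M NaCl + 0.5 M
MgCl2 mixture with solvent at 27.75 M around a macroion of R = 1.5 nm and
Q = 0.102 C m^-2 (diameter ratio 1 : 1.25 : 2 : 1.5 on sigma = 0.2125 nm,
eps = 78.5, T = 298 K); variants sweep the solvent concentration, the
surface charge density of either sign, the salt content, the macroion
radius and the small-ion diameter.
"""

from __future__ import annotations

import importlib.metadata
import math
from dataclasses import dataclass, field

import numpy as np
import yaml

from .grid import RadialGrid, RadialProfileSet, mep_from_charge_density
from .model import (
    Macroion,
    Species,
    SystemSpec,
    macroion_valence,
    mixed_electrolyte,
)

__all__ = [
    "RunConfig",
    "load_config",
    "dump_config",
    "spec_from_dict",
    "spec_to_dict",
    "paper_fixture",
    "fixture_names",
    "write_profiles",
    "read_profiles",
    "synthetic_profile",
]

_SPECIES_KEYS = {"label", "diameter_nm", "valence", "concentration_M"}
_MACROION_KEYS = {"R_nm", "Q_C_per_m2", "Z_M"}
_SYSTEM_KEYS = {"epsilon", "T_K", "macroion", "species"}
_SOLVER_KEYS = {
    "dft": {"rmax_nm", "step_nm", "mixing", "tol", "max_iter", "wda_mode",
            "el_kernel_mode", "msa_include_solvent"},
    "pb": {"rmax_nm", "step_nm", "tol"},
    "mc": {"box_nm", "seed", "equilibration", "sweeps", "blocks", "bin_nm",
           "sample_every", "alpha_over_l", "nmax2"},
    "observables": {"psi0_at"},
}
_TOP_KEYS = {"system", "fixture"} | set(_SOLVER_KEYS)


@dataclass
class RunConfig:
    """Fully resolved configuration of one run."""

    spec: SystemSpec
    dft: dict = field(default_factory=dict)
    pb: dict = field(default_factory=dict)
    mc: dict = field(default_factory=dict)
    observables: dict = field(default_factory=dict)
    source: str = ""


def _check_keys(d: dict, allowed: set, where: str) -> None:
    unknown = set(d) - allowed
    if unknown:
        raise ValueError(f"unknown keys in {where}: {sorted(unknown)}")


def spec_from_dict(d: dict) -> SystemSpec:
    _check_keys(d, _SYSTEM_KEYS, "system")
    mac = d["macroion"]
    _check_keys(mac, _MACROION_KEYS, "system.macroion")
    R = float(mac["R_nm"])
    if "Q_C_per_m2" in mac and "Z_M" in mac:
        z_from_q = macroion_valence(float(mac["Q_C_per_m2"]), R)
        z = float(mac["Z_M"])
        if abs(z_from_q - z) > 1e-6 * max(abs(z), abs(z_from_q), 1.0):
            raise ValueError(
                f"macroion Q and Z_M inconsistent: Z from Q = {z_from_q}, Z_M = {z}"
            )
        macro = Macroion.from_valence(z, R)
    elif "Q_C_per_m2" in mac:
        macro = Macroion.from_surface_charge(float(mac["Q_C_per_m2"]), R)
    elif "Z_M" in mac:
        macro = Macroion.from_valence(float(mac["Z_M"]), R)
    else:
        raise ValueError("macroion needs Q_C_per_m2 or Z_M")
    species = []
    for s in d["species"]:
        _check_keys(s, _SPECIES_KEYS, f"species[{s.get('label', '?')}]")
        species.append(
            Species(
                label=str(s["label"]),
                diameter=float(s["diameter_nm"]),
                valence=int(s["valence"]),
                bulk_concentration=float(s["concentration_M"]),
            )
        )
    return SystemSpec(
        species=tuple(species),
        macroion=macro,
        dielectric_constant=float(d.get("epsilon", 78.5)),
        temperature=float(d.get("T_K", 298.0)),
    )


def spec_to_dict(spec: SystemSpec) -> dict:
    return {
        "epsilon": spec.dielectric_constant,
        "T_K": spec.temperature,
        "macroion": {
            "R_nm": spec.macroion.radius,
            "Q_C_per_m2": spec.macroion.surface_charge_density,
            "Z_M": spec.macroion.valence,
        },
        "species": [
            {
                "label": s.label,
                "diameter_nm": s.diameter,
                "valence": s.valence,
                "concentration_M": s.bulk_concentration,
            }
            for s in spec.species
        ],
    }


def load_config(path) -> RunConfig:
    """Parse and fully resolve a YAML run configuration; unknown keys rejected."""
    with open(path) as fh:
        raw = yaml.safe_load(fh) or {}
    _check_keys(raw, _TOP_KEYS, "top level")
    if "fixture" in raw and "system" in raw:
        raise ValueError("give either 'system' or 'fixture', not both")
    if "fixture" in raw:
        spec = paper_fixture(str(raw["fixture"]))
    elif "system" in raw:
        spec = spec_from_dict(raw["system"])
    else:
        raise ValueError("configuration needs a 'system' or 'fixture' section")
    sections = {}
    for sub, allowed in _SOLVER_KEYS.items():
        sec = raw.get(sub, {}) or {}
        _check_keys(sec, allowed, sub)
        sections[sub] = sec
    return RunConfig(spec=spec, source=str(path), **sections)


def dump_config(cfg: RunConfig, path) -> None:
    out = {"system": spec_to_dict(cfg.spec)}
    for sub in _SOLVER_KEYS:
        sec = getattr(cfg, sub)
        if sec:
            out[sub] = sec
    with open(path, "w") as fh:
        yaml.safe_dump(out, fh, sort_keys=False)


# ---------------------------------------------------------------------------
# Fixture registry.

_BASE = dict(c_nacl=1.0, c_mgcl2=0.5, c_solvent=27.75, sigma=0.2125, R=1.5, Q=0.102)


def _fixtures() -> dict[str, dict]:
    reg: dict[str, dict] = {"base": dict(_BASE)}
    # solvent-concentration sweep
    for tag, cs in zip("abcd", (15.0, 20.0, 25.0, 30.0)):
        reg[f"fig2{tag}"] = dict(_BASE, c_solvent=cs)
        reg[f"fig3{tag}"] = dict(_BASE, c_solvent=cs)
    # surface-charge sweeps, both signs
    for tag, Q in zip("abcd", (0.102, 0.204, 0.306, 0.408)):
        reg[f"fig4{tag}"] = dict(_BASE, Q=Q)
        reg[f"fig5{tag}"] = dict(_BASE, Q=Q)
        reg[f"fig6{tag}"] = dict(_BASE, Q=-Q)
        reg[f"fig7{tag}"] = dict(_BASE, Q=-Q)
    # electrolyte-concentration sweep
    for tag, (cn, cm) in zip("abcd", ((0.01, 0.005), (0.1, 0.05), (1.0, 0.5), (2.0, 1.0))):
        reg[f"fig8{tag}"] = dict(_BASE, c_nacl=cn, c_mgcl2=cm)
        reg[f"fig9{tag}"] = dict(_BASE, c_nacl=cn, c_mgcl2=cm)
    # macroion-radius sweep
    for tag, R in zip("abcd", (0.5, 1.0, 1.5, 6.0)):
        reg[f"fig10{tag}"] = dict(_BASE, R=R)
        reg[f"fig11{tag}"] = dict(_BASE, R=R)
    # bulk-water solvent at low salt
    for tag, Q in zip("abcd", (0.102, 0.204, 0.306, 0.408)):
        reg[f"fig12{tag}"] = dict(_BASE, c_nacl=0.1, c_mgcl2=0.05, c_solvent=55.55, Q=Q)
        reg[f"fig13{tag}"] = dict(_BASE, c_nacl=0.1, c_mgcl2=0.05, c_solvent=55.55, Q=Q)
    # small-ion-diameter sweep (compactness study)
    for tag, sig in zip("abc", (0.1, 0.15, 0.2125)):
        reg[f"fig14{tag}"] = dict(_BASE, sigma=sig)
    reg["fig15"] = dict(_BASE)
    return reg


_REGISTRY = _fixtures()


def fixture_names() -> tuple[str, ...]:
    return tuple(sorted(_REGISTRY))


def paper_fixture(name: str) -> SystemSpec:
    """System specification for one registered study condition."""
    try:
        p = _REGISTRY[name]
    except KeyError:
        raise KeyError(
            f"unknown fixture {name!r}; known: {', '.join(fixture_names())}"
        ) from None
    return SystemSpec(
        species=mixed_electrolyte(p["c_nacl"], p["c_mgcl2"], p["c_solvent"], sigma=p["sigma"]),
        macroion=Macroion.from_surface_charge(p["Q"], p["R"]),
    )


# ---------------------------------------------------------------------------
# Profile files.


def _version() -> str:
    try:
        return importlib.metadata.version("spmedl")
    except importlib.metadata.PackageNotFoundError:  # pragma: no cover
        return "unknown"


def write_profiles(path, profiles: RadialProfileSet, spec: SystemSpec,
                   extra_columns: dict | None = None) -> None:
    """Columnar text profile dump with a provenance header.

    Columns: ``r_nm``, one density per species (nm^-3), ``psi_kT_per_e``,
    then any extra columns (e.g. the integrated charge).  Deterministic
    formatting at full double precision so files re-parse bit-identically.
    """
    cols = [profiles.r] + [profiles.rho[a] for a in range(spec.n_species)] + [profiles.psi]
    names = ["r_nm"] + [f"rho_{s.label}" for s in spec.species] + ["psi_kT_per_e"]
    for name, arr in (extra_columns or {}).items():
        cols.append(np.asarray(arr))
        names.append(name)
    header_lines = [
        f"spmedl {_version()}",
        f"model={profiles.meta.get('model', 'unknown')} converged={profiles.converged}",
        "system=" + yaml.safe_dump(spec_to_dict(spec), default_flow_style=True, width=1_000_000).strip(),
        "meta=" + yaml.safe_dump(
            {k: v for k, v in profiles.meta.items() if isinstance(v, (int, float, str, bool))},
            default_flow_style=True,
            width=1_000_000,
        ).strip(),
        " ".join(names),
    ]
    np.savetxt(path, np.column_stack(cols), header="\n".join(header_lines), fmt="%.17g")


def read_profiles(path) -> tuple[np.ndarray, list[str], dict]:
    """Read a profile file back: (data array, column names, header metadata)."""
    names: list[str] = []
    meta: dict = {}
    with open(path) as fh:
        for line in fh:
            if not line.startswith("#"):
                break
            text = line[1:].strip()
            if text.startswith("system="):
                meta["system"] = yaml.safe_load(text[len("system="):])
            elif text.startswith("meta="):
                meta.update(yaml.safe_load(text[len("meta="):]) or {})
            elif text.startswith("model="):
                for tok in text.split():
                    k, _, v = tok.partition("=")
                    meta[k] = v
            elif text and " " in text and not text.startswith("spmedl"):
                names = text.split()
    data = np.loadtxt(path)
    return np.atleast_2d(data), names, meta


# ---------------------------------------------------------------------------
# Synthetic analytic profiles (test fixtures with closed-form observables).


def synthetic_profile(kind: str, spec: SystemSpec, **params) -> RadialProfileSet:
    """Analytic profile sets with closed-form P(r) and psi(r).

    Kinds:

    * ``uniform`` — every species at bulk density everywhere (P(r) = Z_M);
    * ``shell`` — a Gaussian shell at ``r0`` (width ``width``) carrying total
      charge ``charge`` in e, placed on the first charged species;
    * ``exponential_screening`` — a linearized-theory cloud with decay
      ``kappa`` outside closest approach ``a``, integrating to -Z_M.
    """
    R = spec.macroion.radius
    r_max = params.pop("r_max", R + 6.0)
    h = params.pop("h", 0.005)
    grid = RadialGrid(r_min=R, r_max=r_max, h=h)
    r = grid.r
    ns = spec.n_species
    rho = np.zeros((ns, grid.n))
    if kind == "uniform":
        rho[:] = spec.bulk_densities[:, None]
    elif kind == "shell":
        r0 = params.pop("r0")
        charge = params.pop("charge")
        width = params.pop("width", 0.02)
        idx = next(a for a, s in enumerate(spec.species) if s.valence != 0)
        z = spec.species[idx].valence
        prof = np.exp(-0.5 * ((r - r0) / width) ** 2)
        norm = np.trapezoid(4.0 * math.pi * r**2 * prof, r)
        rho[idx] = (charge / z) * prof / norm
    elif kind == "exponential_screening":
        kappa = params.pop("kappa")
        a = params.pop("a", float(np.min(spec.contact_radii)))
        idx = next(a_ for a_, s in enumerate(spec.species) if s.valence != 0)
        z = spec.species[idx].valence
        prof = np.where(r >= a, np.exp(-kappa * r) / r, 0.0)
        norm = np.trapezoid(4.0 * math.pi * r**2 * prof, r)
        rho[idx] = (-spec.macroion.valence / z) * prof / norm
    else:
        raise ValueError(f"unknown synthetic profile kind {kind!r}")
    if params:
        raise TypeError(f"unused parameters: {sorted(params)}")
    q = np.tensordot(spec.valences, rho, axes=(0, 0))
    psi = mep_from_charge_density(r, q, spec.macroion.valence, spec.lambda_b)
    return RadialProfileSet(grid=grid, rho=rho, psi=psi, converged=True,
                            meta={"model": f"synthetic:{kind}"})
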