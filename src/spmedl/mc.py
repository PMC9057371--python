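"""Canonical Metropolis Monte Carlo of the SPM cell with Ewald electrostatics.

A cubic periodic cell of edge L holds the macroion fixed at the centre (a
point charge Z_M with hard radius R) and exactly enough small ions for
overall neutrality, plus the neutral solvent.  Sampling is standard
single-particle Metropolis translations; Coulomb energies use Ewald
summation with conducting boundary conditions; densities are accumulated in
spherical shells around the macroion and the mean electrostatic potential
is computed from the binned charge density with the same quadrature the DFT
uses.  Production is split into blocks (>= 10) whose scatter provides the
standard errors.
"""

from __future__ import annotations

import math
import warnings
from dataclasses import dataclass, field

import numpy as np

from . import _mc_kernels as K
from .grid import mep_from_charge_density
from .model import SystemSpec, debye_kappa, validate_system

__all__ = [
    "EwaldControls",
    "MCSchedule",
    "MCConfiguration",
    "MCRunReport",
    "build_initial_configuration",
    "ewald_energy",
    "metropolis_sweep",
    "run_simulation",
    "bin_density_profiles",
]


@dataclass
class EwaldControls:
    """Ewald splitting parameter (units of 1/L) and reciprocal cutoff |n|^2."""

    alpha_over_l: float = 6.0
    nmax2: int = 42

    def tables(self, L: float, lambda_b: float):
        alpha = self.alpha_over_l / L
        nmax = int(math.floor(math.sqrt(self.nmax2)))
        kx, ky, kz, wk = [], [], [], []
        two_pi_over_l = 2.0 * math.pi / L
        for nx in range(0, nmax + 1):
            ny_lo = -nmax if nx > 0 else 0
            for ny in range(ny_lo, nmax + 1):
                nz_lo = -nmax if (nx > 0 or ny > 0) else 1
                for nz in range(nz_lo, nmax + 1):
                    n2 = nx * nx + ny * ny + nz * nz
                    if n2 == 0 or n2 > self.nmax2:
                        continue
                    k2 = (two_pi_over_l**2) * n2
                    kx.append(two_pi_over_l * nx)
                    ky.append(two_pi_over_l * ny)
                    kz.append(two_pi_over_l * nz)
                    wk.append(
                        (4.0 * math.pi * lambda_b / L**3)
                        * math.exp(-k2 / (4.0 * alpha**2))
                        / k2
                    )
        return (
            alpha,
            np.asarray(kx),
            np.asarray(ky),
            np.asarray(kz),
            np.asarray(wk),
        )


@dataclass
class MCConfiguration:
    """Cell state: positions (macroion first, fixed), species tags, RNG stream."""

    spec: SystemSpec
    L: float
    positions: np.ndarray  # (N, 3) in [0, L)
    charges: np.ndarray
    diameters: np.ndarray
    species_index: np.ndarray  # -1 for the macroion
    mobile: np.ndarray
    seed: int
    rng_state: np.ndarray
    counts: dict = field(default_factory=dict)

    @property
    def n_particles(self) -> int:
        return len(self.charges)

    def copy(self) -> "MCConfiguration":
        return MCConfiguration(
            self.spec,
            self.L,
            self.positions.copy(),
            self.charges.copy(),
            self.diameters.copy(),
            self.species_index.copy(),
            self.mobile.copy(),
            self.seed,
            self.rng_state.copy(),
            dict(self.counts),
        )


def target_counts(spec: SystemSpec, L: float) -> dict[str, int]:
    """Integer particle counts: round(rho L^3), then exact neutrality.

    The neutrality correction (including Z_M, which must itself be integer)
    is absorbed by a monovalent species of the appropriate sign.
    """
    Z = spec.macroion.valence
    if abs(Z - round(Z)) > 0.5 - 1e-9:
        raise ValueError("macroion valence too far from an integer for a neutral cell")
    if abs(Z - round(Z)) > 1e-9:
        warnings.warn(
            f"macroion valence {Z:.6g} represented as {round(Z):d} in the cell "
            "(exact neutrality requires integer charges)",
            stacklevel=2,
        )
    Z = int(round(Z))
    V = L**3
    counts = {s.label: int(round(s.bulk_density * V)) for s in spec.species}
    imbalance = int(round(sum(s.valence * counts[s.label] for s in spec.species))) + Z
    if imbalance != 0:
        # Absorb the correction in the counterion (the species opposite in
        # sign to the macroion, which supplies the neutralizing excess),
        # monovalent preferred; fall back to any divisible charged species.
        def rank(s):
            return (0 if s.valence * Z < 0 else 1, abs(s.valence))

        for s in sorted(spec.species, key=rank):
            if s.valence != 0 and imbalance % s.valence == 0:
                new = counts[s.label] - imbalance // s.valence
                if new >= 0:
                    counts[s.label] = new
                    imbalance = 0
                    break
        if imbalance != 0:
            raise ValueError("cannot balance cell charge with available species")
    return counts


def build_initial_configuration(
    spec: SystemSpec, L: float, seed: int, max_attempts: int = 20_000
) -> MCConfiguration:
    """Random sequential insertion of ions and solvent around the fixed macroion.

    Deterministic given the seed.  A warning is emitted if the cell is
    smaller than the recommended ``L >= 2 (R + 4/kappa)``.  If sequential
    insertion stalls (``max_attempts`` failures per remaining particle, as
    happens near the random-sequential-addition jamming density), the
    configuration falls back to a jittered lattice start annealed by
    scramble sweeps until no hard overlaps remain.
    """
    validate_system(spec)
    kappa = debye_kappa(spec)
    if kappa > 0 and L < 2.0 * (spec.macroion.radius + 4.0 / kappa):
        warnings.warn(
            f"cell edge L={L:.3g} nm below the recommended 2(R + 4/kappa) = "
            f"{2*(spec.macroion.radius + 4/kappa):.3g} nm; periodic-image "
            "effects may not be negligible",
            stacklevel=2,
        )
    counts = target_counts(spec, L)
    n_total = 1 + sum(counts.values())
    pos = np.zeros((n_total, 3))
    sig = np.zeros(n_total)
    q = np.zeros(n_total)
    spidx = np.full(n_total, -1, dtype=np.int64)
    mobile = np.ones(n_total, dtype=np.bool_)

    pos[0] = 0.5 * L
    sig[0] = 2.0 * spec.macroion.radius
    q[0] = float(round(spec.macroion.valence))
    mobile[0] = False

    state = K.seed_state(seed)
    row = 1
    # Insert large species first (random sequential addition packs better).
    order = sorted(range(spec.n_species), key=lambda a: -spec.species[a].diameter)
    lattice_needed = False
    for a in order:
        s = spec.species[a]
        n_a = counts[s.label]
        placed = K.insert_random(pos, sig, row, n_a, s.diameter, L, state, max_attempts)
        if placed < n_a:
            lattice_needed = True
        q[row : row + n_a] = float(s.valence)
        sig[row : row + n_a] = s.diameter
        spidx[row : row + n_a] = a
        row += n_a
    if lattice_needed:
        warnings.warn(
            "random insertion stalled; falling back to a lattice start with "
            "scramble sweeps",
            stacklevel=2,
        )
        _lattice_start(pos, sig, q, mobile, spec, L, state)
    return MCConfiguration(
        spec=spec,
        L=L,
        positions=pos,
        charges=q,
        diameters=sig,
        species_index=spidx,
        mobile=mobile,
        seed=seed,
        rng_state=state,
        counts=counts,
    )


def _lattice_start(pos, sig, q, mobile, spec: SystemSpec, L: float, state,
                   max_scramble: int = 5000) -> None:
    """Jittered simple-cubic start for the mobile particles, annealed by
    hard-sphere scramble sweeps until the configuration is overlap-free."""
    n_mobile = int(np.sum(mobile))
    per_side = int(math.ceil(n_mobile ** (1.0 / 3.0)))
    spacing = L / per_side
    sites = []
    for i in range(per_side):
        for j in range(per_side):
            for k in range(per_side):
                sites.append(((i + 0.5) * spacing, (j + 0.5) * spacing, (k + 0.5) * spacing))
    rows = np.nonzero(mobile)[0]
    # fill sites farthest from the fixed macroion first (central sites that
    # would overlap its core are used only when the cell is nearly full)
    centre = 0.5 * L
    ranked = sorted(
        sites,
        key=lambda p: -math.sqrt(
            (p[0] - centre) ** 2 + (p[1] - centre) ** 2 + (p[2] - centre) ** 2
        ),
    )
    for row, site in zip(rows, ranked):
        pos[row, 0] = site[0] % L
        pos[row, 1] = site[1] % L
        pos[row, 2] = site[2] % L
    # scramble with hard-sphere-only moves until overlap-free
    empty = np.zeros(0)
    u_run = np.zeros(1)
    q0 = np.zeros_like(q)  # electrostatics off while annealing contacts
    disp = 0.35 * spacing
    for sweep_no in range(max_scramble):
        K.sweep(pos, q0, sig, mobile, L, 1.0, spec.lambda_b, empty, empty,
                empty, empty, empty, empty, disp, state, u_run)
        if sweep_no % 10 == 9:
            _, overlap = K.total_real_energy(pos, q0, sig, L, 1.0, spec.lambda_b, 0)
            if not overlap:
                return
    raise RuntimeError(
        "lattice scramble failed to remove hard overlaps; packing too high"
    )


def ewald_energy(
    config: MCConfiguration,
    ewald: EwaldControls | None = None,
    nshell: int | None = None,
) -> float:
    """Total Coulomb energy (k_BT) of the configuration: real + reciprocal + self.

    ``nshell`` controls the real-space image expansion (``None``: choose
    automatically so erfc is negligible at the truncation radius; 0 forces
    minimum image, the convention used incrementally during sampling).
    Raises for a non-neutral cell.
    """
    ew = ewald or EwaldControls()
    spec = config.spec
    if abs(float(np.sum(config.charges))) > 1e-9:
        raise ValueError("Ewald energy requires a neutral cell")
    lam = spec.lambda_b
    alpha, kx, ky, kz, wk = ew.tables(config.L, lam)
    if nshell is None:
        reach = 5.0 / alpha
        nshell = max(0, int(math.ceil(reach / config.L - 0.5)))
    u_real, overlap = K.total_real_energy(
        config.positions, config.charges, config.diameters, config.L, alpha, lam, nshell
    )
    if overlap:
        return math.inf
    sre, sim = K.structure_factor(config.positions, config.charges, kx, ky, kz)
    u_recip = K.recip_energy(sre, sim, wk)
    u_self = K.self_energy(config.charges, alpha, lam)
    return u_real + u_recip + u_self


def metropolis_sweep(
    config: MCConfiguration,
    displacement: float,
    ewald: EwaldControls | None = None,
    _cache: dict | None = None,
) -> int:
    """One attempted translation per mobile particle; returns acceptances.

    Convenience wrapper around the compiled kernel for tests and short
    runs; :func:`run_simulation` drives the same kernel with persistent
    Ewald state.
    """
    ew = ewald or EwaldControls()
    lam = config.spec.lambda_b
    if _cache is None or "wk" not in _cache:
        alpha, kx, ky, kz, wk = ew.tables(config.L, lam)
        sre, sim = K.structure_factor(config.positions, config.charges, kx, ky, kz)
        _cache = {"alpha": alpha, "kx": kx, "ky": ky, "kz": kz, "wk": wk,
                  "sre": sre, "sim": sim, "u": np.zeros(1)}
    return K.sweep(
        config.positions,
        config.charges,
        config.diameters,
        config.mobile,
        config.L,
        _cache["alpha"],
        lam,
        _cache["kx"],
        _cache["ky"],
        _cache["kz"],
        _cache["wk"],
        _cache["sre"],
        _cache["sim"],
        displacement,
        config.rng_state,
        _cache["u"],
    )


@dataclass
class MCSchedule:
    """Sweep counts and sampling controls of one simulation."""

    equilibration: int = 20_000
    production: int = 100_000
    blocks: int = 10
    bin_width: float | None = None  # default sigma_min / 10
    sample_every: int = 1
    displacement: float | None = None  # start value; auto-tuned in equilibration
    acceptance_target: tuple[float, float] = (0.35, 0.50)
    tune_every: int = 100
    recompute_every: int = 0  # full-energy refresh interval (0 = never)


@dataclass
class MCRunReport:
    """Binned profiles with block statistics plus run provenance."""

    spec: SystemSpec
    L: float
    seed: int
    schedule: MCSchedule
    acceptance: float
    displacement: float
    r: np.ndarray
    rho: np.ndarray  # (ns, nbins) block-mean densities
    rho_se: np.ndarray
    psi: np.ndarray
    psi_se: np.ndarray
    block_rho: np.ndarray  # (blocks, ns, nbins)
    energy_drift: float = 0.0
    meta: dict = field(default_factory=dict)


def bin_density_profiles(
    counts: np.ndarray, bin_width: float, n_samples: int
) -> tuple[np.ndarray, np.ndarray]:
    """Convert accumulated shell counts to densities.

    Returns (bin centres, rho) with exact shell volumes
    ``(4 pi / 3)(r_{k+1}^3 - r_k^3)``.
    """
    ns, nbins = counts.shape
    edges = bin_width * np.arange(nbins + 1)
    vol = (4.0 * math.pi / 3.0) * np.diff(edges**3)
    centers = 0.5 * (edges[:-1] + edges[1:])
    rho = counts / (vol[None, :] * max(n_samples, 1))
    return centers, rho


def _mep_from_binned(r, rho, spec: SystemSpec):
    q = np.tensordot(spec.valences, rho, axes=(0, 0))
    return mep_from_charge_density(r, q, spec.macroion.valence, spec.lambda_b)


def run_simulation(
    spec: SystemSpec,
    L: float,
    seed: int,
    schedule: MCSchedule | None = None,
    ewald: EwaldControls | None = None,
    config: MCConfiguration | None = None,
) -> MCRunReport:
    """Equilibrate, tune the displacement into the target acceptance window,
    then run block-averaged production; reproducible given the seed."""
    sched = schedule or MCSchedule()
    ew = ewald or EwaldControls()
    if config is None:
        config = build_initial_configuration(spec, L, seed)
    lam = spec.lambda_b
    alpha, kx, ky, kz, wk = ew.tables(L, lam)
    sre, sim = K.structure_factor(config.positions, config.charges, kx, ky, kz)
    u_run = np.zeros(1)
    u_run[0] = ewald_energy(config, ew, nshell=0)

    sig_min = float(np.min(spec.diameters))
    n_mobile_est = max(int(np.sum(config.mobile)), 1)
    spacing = (L**3 / n_mobile_est) ** (1.0 / 3.0)
    disp = (
        sched.displacement
        if sched.displacement is not None
        else max(0.5 * sig_min, 0.25 * spacing)
    )
    lo, hi = sched.acceptance_target

    def do_sweeps(n):
        acc = 0
        for _ in range(n):
            acc += K.sweep(
                config.positions, config.charges, config.diameters, config.mobile,
                L, alpha, lam, kx, ky, kz, wk, sre, sim, disp, config.rng_state, u_run,
            )
        return acc

    n_mobile = int(np.sum(config.mobile))
    # --- equilibration with displacement tuning -------------------------
    done = 0
    while done < sched.equilibration:
        chunk = min(sched.tune_every, sched.equilibration - done)
        acc = do_sweeps(chunk) / (chunk * n_mobile)
        if acc > hi:
            disp = min(disp * 1.5, L / 4.0)
        elif acc < lo:
            disp = max(disp / 1.5, 1e-4 * sig_min)
        done += chunk

    # --- production ------------------------------------------------------
    bin_width = sched.bin_width if sched.bin_width is not None else sig_min / 10.0
    nbins = int(math.floor(0.5 * L / bin_width))
    ns = spec.n_species
    blocks = max(sched.blocks, 1)
    per_block = sched.production // blocks
    block_counts = np.zeros((blocks, ns, nbins))
    block_samples = np.zeros(blocks, dtype=np.int64)
    acc_total = 0
    drift = 0.0
    for b in range(blocks):
        counts = np.zeros((ns, nbins))
        for sw in range(per_block):
            acc_total += K.sweep(
                config.positions, config.charges, config.diameters, config.mobile,
                L, alpha, lam, kx, ky, kz, wk, sre, sim, disp, config.rng_state, u_run,
            )
            if (sw + 1) % sched.sample_every == 0:
                K.bin_counts(
                    config.positions, config.species_index, L, bin_width, nbins, counts
                )
                block_samples[b] += 1
        block_counts[b] = counts
        if sched.recompute_every:
            u_full = ewald_energy(config, ew, nshell=0)
            drift = max(drift, abs(u_full - u_run[0]) / max(abs(u_full), 1.0))
            u_run[0] = u_full

    total_sweeps = blocks * per_block
    acceptance = acc_total / max(total_sweeps * n_mobile, 1)
    if total_sweeps > 0 and not (0.01 <= acceptance <= 0.99):
        warnings.warn(
            f"production acceptance {acceptance:.3f} outside [0.01, 0.99]",
            stacklevel=2,
        )

    r, _ = bin_density_profiles(np.zeros((ns, nbins)), bin_width, 1)
    if total_sweeps > 0:
        brho = np.stack(
            [
                bin_density_profiles(block_counts[b], bin_width, block_samples[b])[1]
                for b in range(blocks)
            ]
        )
        rho = brho.mean(axis=0)
        rho_se = brho.std(axis=0, ddof=1) / math.sqrt(blocks) if blocks > 1 else np.zeros_like(rho)
        bpsi = np.stack([_mep_from_binned(r, brho[b], spec) for b in range(blocks)])
        psi = bpsi.mean(axis=0)
        psi_se = bpsi.std(axis=0, ddof=1) / math.sqrt(blocks) if blocks > 1 else np.zeros_like(psi)
    else:
        brho = np.zeros((blocks, ns, nbins))
        rho = np.zeros((ns, nbins))
        rho_se = np.zeros_like(rho)
        psi = np.zeros(nbins)
        psi_se = np.zeros(nbins)

    return MCRunReport(
        spec=spec,
        L=L,
        seed=seed,
        schedule=sched,
        acceptance=float(acceptance),
        displacement=float(disp),
        r=r,
        rho=rho,
        rho_se=rho_se,
        psi=psi,
        psi_se=psi_se,
        block_rho=brho,
        energy_drift=float(drift),
        meta={
            "counts": dict(config.counts),
            "n_particles": config.n_particles,
            "alpha_over_l": ew.alpha_over_l,
            "nmax2": ew.nmax2,
            "u_final": float(u_run[0]),
        },
    )
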