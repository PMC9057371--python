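"""Numba-compiled inner loops of the canonical Monte Carlo engine.

Positions live in a cubic box [0, L)^3 with the macroion fixed at the
centre as particle 0 (a point charge Z_M with a hard core of diameter 2R,
which by Gauss's law is exactly equivalent to the uniformly charged
surface outside R).  Electrostatics use Ewald summation with conducting
(tin-foil) boundary conditions; energies are in k_BT, charges in e,
lengths in nm, with the Coulomb coupling carried by the Bjerrum length.

The RNG is a single deterministic xorshift64* stream whose 64-bit state is
threaded through every kernel; runs are bit-reproducible given the seed.
"""

from __future__ import annotations

import math

import numpy as np
from numba import njit

_U64 = np.uint64
_MASK = _U64(0xFFFFFFFFFFFFFFFF)


@njit(cache=False)
def rng_uniform(state):
    """xorshift64* uniform in [0, 1) with 53-bit resolution."""
    x = state[0]
    x ^= x >> _U64(12)
    x ^= (x << _U64(25)) & _MASK
    x ^= x >> _U64(27)
    state[0] = x
    y = (x * _U64(0x2545F4914F6CDD1D)) & _MASK
    return (y >> _U64(11)) * (1.0 / 9007199254740992.0)


@njit(cache=False)
def seed_state(seed):
    """SplitMix64 scramble of a small integer seed into a nonzero state."""
    z = (_U64(seed) + _U64(0x9E3779B97F4A7C15)) & _MASK
    z = ((z ^ (z >> _U64(30))) * _U64(0xBF58476D1CE4E5B9)) & _MASK
    z = ((z ^ (z >> _U64(27))) * _U64(0x94D049BB133111EB)) & _MASK
    z = z ^ (z >> _U64(31))
    if z == _U64(0):
        z = _U64(0x9E3779B97F4A7C15)
    out = np.empty(1, dtype=np.uint64)
    out[0] = z
    return out


@njit(cache=False)
def min_image(d, L):
    return d - L * math.floor(d / L + 0.5)


@njit(cache=False)
def total_real_energy(pos, q, sig, L, alpha, lambda_b, nshell):
    """Real-space Ewald sum (+ overlap flag).

    ``nshell = 0``: minimum image with spherical cutoff L/2.
    ``nshell >= 1``: explicit image shells out to +-nshell boxes (used for
    high-accuracy energies and splitting-parameter invariance checks).
    """
    n = pos.shape[0]
    rcut = 0.5 * L
    u = 0.0
    overlap = False
    for i in range(n):
        for j in range(i + 1, n):
            dx = min_image(pos[j, 0] - pos[i, 0], L)
            dy = min_image(pos[j, 1] - pos[i, 1], L)
            dz = min_image(pos[j, 2] - pos[i, 2], L)
            contact = 0.5 * (sig[i] + sig[j])
            if nshell == 0:
                r2 = dx * dx + dy * dy + dz * dz
                r = math.sqrt(r2)
                if r < contact:
                    overlap = True
                if q[i] != 0.0 and q[j] != 0.0 and r < rcut and r > 0.0:
                    u += lambda_b * q[i] * q[j] * math.erfc(alpha * r) / r
            else:
                for mx in range(-nshell, nshell + 1):
                    for my in range(-nshell, nshell + 1):
                        for mz in range(-nshell, nshell + 1):
                            rx = dx + mx * L
                            ry = dy + my * L
                            rz = dz + mz * L
                            r = math.sqrt(rx * rx + ry * ry + rz * rz)
                            if mx == 0 and my == 0 and mz == 0 and r < contact:
                                overlap = True
                            if q[i] != 0.0 and q[j] != 0.0 and r > 0.0:
                                u += lambda_b * q[i] * q[j] * math.erfc(alpha * r) / r
        if nshell > 0 and q[i] != 0.0:
            # self-interaction with own periodic images
            for mx in range(-nshell, nshell + 1):
                for my in range(-nshell, nshell + 1):
                    for mz in range(-nshell, nshell + 1):
                        if mx == 0 and my == 0 and mz == 0:
                            continue
                        r = L * math.sqrt(float(mx * mx + my * my + mz * mz))
                        u += 0.5 * lambda_b * q[i] * q[i] * math.erfc(alpha * r) / r
    return u, overlap


@njit(cache=False)
def structure_factor(pos, q, kx, ky, kz):
    nk = kx.shape[0]
    n = pos.shape[0]
    sre = np.zeros(nk)
    sim = np.zeros(nk)
    for m in range(nk):
        a = 0.0
        b = 0.0
        for i in range(n):
            if q[i] == 0.0:
                continue
            ph = kx[m] * pos[i, 0] + ky[m] * pos[i, 1] + kz[m] * pos[i, 2]
            a += q[i] * math.cos(ph)
            b += q[i] * math.sin(ph)
        sre[m] = a
        sim[m] = b
    return sre, sim


@njit(cache=False)
def recip_energy(sre, sim, wk):
    u = 0.0
    for m in range(wk.shape[0]):
        u += wk[m] * (sre[m] * sre[m] + sim[m] * sim[m])
    return u


@njit(cache=False)
def self_energy(q, alpha, lambda_b):
    s = 0.0
    for i in range(q.shape[0]):
        s += q[i] * q[i]
    return -lambda_b * alpha / math.sqrt(math.pi) * s


@njit(cache=False)
def sweep(
    pos,
    q,
    sig,
    mobile,
    L,
    alpha,
    lambda_b,
    kx,
    ky,
    kz,
    wk,
    sre,
    sim,
    disp,
    state,
    u_run,
):
    """One Metropolis sweep: one attempted translation per mobile particle.

    Returns the number of accepted moves; updates positions, the reciprocal
    structure factor and the running energy in place.  Hard overlaps reject
    unconditionally (infinite-energy contract).
    """
    n = pos.shape[0]
    nk = wk.shape[0]
    rcut = 0.5 * L
    accepted = 0
    dsre = np.empty(nk)
    dsim = np.empty(nk)
    for i in range(n):
        if not mobile[i]:
            continue
        xo, yo, zo = pos[i, 0], pos[i, 1], pos[i, 2]
        xn = (xo + disp * (2.0 * rng_uniform(state) - 1.0)) % L
        yn = (yo + disp * (2.0 * rng_uniform(state) - 1.0)) % L
        zn = (zo + disp * (2.0 * rng_uniform(state) - 1.0)) % L
        du_real = 0.0
        overlap = False
        qi = q[i]
        for j in range(n):
            if j == i:
                continue
            contact = 0.5 * (sig[i] + sig[j])
            dx = min_image(pos[j, 0] - xn, L)
            dy = min_image(pos[j, 1] - yn, L)
            dz = min_image(pos[j, 2] - zn, L)
            rn = math.sqrt(dx * dx + dy * dy + dz * dz)
            if rn < contact:
                overlap = True
                break
            qq = qi * q[j]
            if qq != 0.0:
                if rn < rcut:
                    du_real += lambda_b * qq * math.erfc(alpha * rn) / rn
                dx = min_image(pos[j, 0] - xo, L)
                dy = min_image(pos[j, 1] - yo, L)
                dz = min_image(pos[j, 2] - zo, L)
                ro = math.sqrt(dx * dx + dy * dy + dz * dz)
                if ro < rcut:
                    du_real -= lambda_b * qq * math.erfc(alpha * ro) / ro
        if overlap:
            continue
        du = du_real
        if qi != 0.0 and nk > 0:
            du_recip = 0.0
            for m in range(nk):
                pho = kx[m] * xo + ky[m] * yo + kz[m] * zo
                phn = kx[m] * xn + ky[m] * yn + kz[m] * zn
                dre = qi * (math.cos(phn) - math.cos(pho))
                dim = qi * (math.sin(phn) - math.sin(pho))
                dsre[m] = dre
                dsim[m] = dim
                du_recip += wk[m] * (
                    dre * (2.0 * sre[m] + dre) + dim * (2.0 * sim[m] + dim)
                )
            du += du_recip
        if du <= 0.0 or rng_uniform(state) < math.exp(-du):
            pos[i, 0], pos[i, 1], pos[i, 2] = xn, yn, zn
            if qi != 0.0 and nk > 0:
                for m in range(nk):
                    sre[m] += dsre[m]
                    sim[m] += dsim[m]
            u_run[0] += du
            accepted += 1
    return accepted


@njit(cache=False)
def bin_counts(pos, species, L, bin_width, nbins, counts):
    """Accumulate per-species counts into spherical shells around the centre."""
    c = 0.5 * L
    n = pos.shape[0]
    for i in range(n):
        sp = species[i]
        if sp < 0:
            continue
        dx = min_image(pos[i, 0] - c, L)
        dy = min_image(pos[i, 1] - c, L)
        dz = min_image(pos[i, 2] - c, L)
        r = math.sqrt(dx * dx + dy * dy + dz * dz)
        k = int(r / bin_width)
        if k < nbins:
            counts[sp, k] += 1.0


@njit(cache=False)
def insert_random(pos, sig, n_start, n_insert, sig_new, L, state, max_attempts):
    """Sequential random insertion with overlap rejection.

    Inserts ``n_insert`` particles of diameter ``sig_new`` starting at row
    ``n_start``; returns the number successfully placed.
    """
    placed = 0
    for _ in range(n_insert * max_attempts):
        if placed == n_insert:
            break
        x = L * rng_uniform(state)
        y = L * rng_uniform(state)
        z = L * rng_uniform(state)
        ok = True
        for j in range(n_start + placed):
            contact = 0.5 * (sig_new + sig[j])
            dx = min_image(pos[j, 0] - x, L)
            dy = min_image(pos[j, 1] - y, L)
            dz = min_image(pos[j, 2] - z, L)
            if dx * dx + dy * dy + dz * dz < contact * contact:
                ok = False
                break
        if ok:
            idx = n_start + placed
            pos[idx, 0], pos[idx, 1], pos[idx, 2] = x, y, z
            sig[idx] = sig_new
            placed += 1
    return placed


@njit(cache=False)
def pair_histogram(pos, sig, L, r_lo, dr, nbins, hist):
    """Distance histogram over all mobile pairs (for contact-value extrapolation)."""
    n = pos.shape[0]
    for i in range(n):
        for j in range(i + 1, n):
            dx = min_image(pos[j, 0] - pos[i, 0], L)
            dy = min_image(pos[j, 1] - pos[i, 1], L)
            dz = min_image(pos[j, 2] - pos[i, 2], L)
            r = math.sqrt(dx * dx + dy * dy + dz * dz)
            k = int((r - r_lo) / dr)
            if 0 <= k < nbins:
                hist[k] += 1.0
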