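# Methods

`spmedl` computes the ionic and solvent structure of the spherical electric
double layer (SDL) around a single charged colloidal sphere in the *solvent
primitive model* (SPM): small ions are charged hard spheres, the solvent is
an explicit neutral hard sphere *and* a uniform dielectric continuum of
permittivity ε, and the macroion is a rigid sphere of radius R carrying a
uniform surface charge density Q (valence Z_M = 4πR²Q/e). Two independent
engines solve the same model — a classical density functional theory (DFT)
and a canonical Metropolis Monte Carlo (MC) simulation — plus a point-ion
Poisson–Boltzmann reference (URMGC). Everything runs in reduced units:
lengths in nm, energies in k_BT, charges in e; the Coulomb coupling is the
Bjerrum length λ_B = e²/(4πε₀ε k_BT) (0.714 nm for water at 298 K).

## The model

Pair interactions are additive hard cores plus bare Coulomb,
u_ab(r) = ∞ for r < (σ_a+σ_b)/2, λ_B z_a z_b / r otherwise; the macroion
acts as a hard wall at R + σ_a/2 plus λ_B Z_M z_a / r. The working
electrolyte is the asymmetric four-component mixture Mg²⁺ : Na⁺ : Cl⁻ :
solvent with diameter ratio 1 : 1.25 : 2 : 1.5 on σ = 0.2125 nm, NaCl and
MgCl₂ at a 2:1 concentration ratio, and solvent at 27.75 M in the common
("base") condition — a reduced surface density chosen because explicit
bulk-water solvent counts are prohibitive at high salt; at 0.1 M salt the
registry also carries the full 55.55 M variant. Image charges, hydration,
dispersion and any position dependence of ε are outside the model.

## Density functional theory

The equilibrium profiles satisfy

    ρ_a(r) = ρ⁰_a exp{ −z_a ψ(r) + [c¹ʰˢ_a(r) − c¹ʰˢ_a(bulk)]
                                 + [c¹ᵉˡ_a(r) − c¹ᵉˡ_a(bulk)] },

with hard cutoffs at each species' distance of closest approach.

**Mean electrostatic potential.** ψ (in k_BT/e) is generated by the
macroion and the full ionic charge density q(r) = Σ z_a ρ_a(r):

    ψ(r) = λ_B Z_M/r + 4πλ_B [ (1/r)∫_R^r s² q ds + ∫_r^{r_max} s q ds ],

pinned to ψ(r_max) = 0. This two-term Gauss-law form does not assume
global electroneutrality, so it is valid at every Picard iterate; at
convergence it coincides with the compact single-integral form that does.
ψ is recomputed from the densities at every iteration, never iterated
independently.

**Hard-sphere correlations (WDA).** The nonuniform one-particle direct
correlation function (DCF) is the uniform-fluid function evaluated at
smoothed densities, c¹ʰˢ_a(r) = c̃¹ʰˢ_a({ρ̄ᵃ_b(r)}), with one weighted
density per (target, source) species pair,

    ρ̄ᵃ_b(r) = ∫ ρ_b(r′) w_ab(|r−r′|; D) d³r′,
    w_ab(s; D) = c̃²ʰˢ_ab(s; D) / (∂c̃¹ʰˢ_a/∂ρ_b)(D).

Both c̃¹ʰˢ and c̃²ʰˢ derive from a single scaled-particle/PY-compressibility
excess free-energy density (the fundamental-measure form evaluated in the
uniform limit), which makes the identity ∂c̃¹_a/∂ρ_b = ∫c̃²_ab d³s exact:
the weights integrate to one analytically, and uniform profiles are an
exact fixed point (the discrete operators are additionally row-normalized
so this holds to rounding level on any grid). The kernel density argument
D is the bulk vector by default (`wda_mode="bulk_weights"`, position-
independent kernels, precompiled convolution matrices); the full
self-consistent prescription, D = ρ̄ᵃ(r) closed by an inner fixed point per
radius, is available as `wda_mode="self_consistent"`. The two agree to
first order in the density modulation; at the packing fractions studied
here the bulk-weight mode is the default because it is an order of
magnitude cheaper and numerically robust.

**Electrostatic correlations (MSA perturbation).** The residual is linear
in the density deviation,

    c¹ᵉˡ_a(r) − c¹ᵉˡ_a(bulk) = Σ_b ∫ Δc²ᵉˡ_ab(|r−r′|) [ρ_b(r′) − ρ⁰_b] d³r′,

where Δc²ᵉˡ_ab(s) = c²ᵉˡ_ab(s) + λ_B z_a z_b/s is the *short-range* part of
the bulk MSA electrostatic DCF. The Coulomb tail of the full kernel is
exactly the ionic mean field already carried by ψ; convolving it again
would double-count it (and provably breaks bulk recovery at r_max). The
bulk kernels come from the mean spherical approximation of the asymmetric
mixture: outside contact the closure fixes c²ᵉˡ = −λ_B z_a z_b/s exactly;
inside the core the kernels are obtained by solving the multicomponent
Ornstein–Zernike equations with the MSA closure numerically (sine-transform
grid, long-range part renormalized with an erf/erfc split, Picard-converged
to 1e-9). Blum's analytic solution for the screening parameter Γ —
fixed point of 4Γ² = 4πλ_B Σ ρ_i X_i², X_i = [z_i − (π/2Δ)σ_i²P_n]/(1+Γσ_i)
— is solved alongside (damped iteration from the exact bound κ/2) and
validated against the equal-diameter closed form Γ = [√(1+2κσ)−1]/(2σ);
the numeric kernels are validated against the equal-diameter
(Waisman–Lebowitz) closed form. A cheap analytic kernel mode
(`el_kernel_mode="wl"`, the equal-diameter form evaluated at each pair's
contact distance) serves for dilute/point-ion work where the inside-core
region carries negligible weight. The neutral solvent enters the MSA only
through the packing terms (`msa_include_solvent`, default on). Note the
MSA electrostatic DCF is *discontinuous* at contact (the restricted-case
jump is (1−B)²λ_B z_i z_j/σ with B = Γσ/(1+Γσ)); the package asserts the
jump rather than continuity.

**Numerics.** Uniform radial grid from R to r_max with defaults
h = σ_min/40 and r_max = R + max(10/κ, 8σ_max); convolutions are reduced to
one-dimensional operators (2π/r)∫dr′ r′f(r′)[J(r+r′) − J(|r−r′|)] with
J(x) = ∫₀ˣ sK(s)ds and precompiled into dense matrices, so an iteration is
a handful of matrix-vector products. The Picard update mixes the
*Boltzmann exponent* (log-density), not the density: transient contact
spikes then stay multiplicative and the hard-sphere feedback engages before
they can run away (density-space mixing demonstrably diverges at the base
condition, η ≈ 0.34, κ ≈ 5.2 nm⁻¹, Z_M = 18). Mixing starts at 0.05,
doubles after 200 non-rising steps (cap 0.4) and halves on residual growth;
convergence is max_a,r |Δρ|/ρ⁰_a < 1e-7. Transiently over-packed weighted
densities are rescaled onto a 0.95 packing shell (composition preserved)
before the equation of state is evaluated. Initialization is Boltzmann in
the bare Debye–Hückel potential. The base condition converges in ~10³
iterations (≈ 650 grid nodes, a few seconds; operator assembly including
the bulk OZ solve takes ~20 s).

## Monte Carlo

Canonical (N,V,T) Metropolis sampling of a cubic periodic cell with the
macroion fixed at the centre, represented as a point charge Z_M with a hard
radius R (by Gauss's law exactly equivalent to the uniformly charged
surface). Particle counts are round(ρ⁰_a L³) with the neutrality correction
(including the integer Z_M) absorbed by the monovalent counterion.
Configurations start from random sequential insertion (largest species
first). Electrostatics use Ewald summation with conducting boundary
conditions; the sampling convention is minimum-image real space (α = 6/L,
erfc(3) truncation) plus a reciprocal sum to |n|² ≤ 42; high-accuracy
energy evaluations expand real-space image shells until erfc is negligible,
making the total invariant under the splitting parameter to better than
1e-6 (and recovering the rock-salt Madelung constant to 1e-9). Per-move
energy differences update a running total and the reciprocal structure
factor incrementally; neutral-solvent moves skip electrostatics entirely.
The displacement is tuned during equilibration into a 35–50% acceptance
window and then frozen. Densities are accumulated in spherical shells
(default width σ_min/10, exact shell volumes) over ≥10 production blocks;
standard errors come from the block scatter; the MEP is computed from the
binned charge density with the same quadrature as the DFT. The RNG is a
single xorshift64* stream seeded through SplitMix64; runs are
bit-reproducible given the seed. All kernels are numba-compiled.

Cell-size rule: L ≥ 2(R + 4 Debye lengths). This is enforced as a warning,
and it matters: in smaller cells the ionic profiles acquire systematic
percent-tens offsets from overlapping periodic-image double layers (the
short-ranged solvent profile stays clean — a useful diagnostic).

Because the cell holds integer particle numbers, the reservoir it realizes
differs from the nominal concentrations by rounding (significant at desk
scale, e.g. 21 Na⁺ in a 7 nm cell); DFT↔MC comparisons therefore run the
DFT at the realized concentrations: counts minus the Z_M neutralizing
excess, divided by the macroion-free volume, re-neutralized exactly.

## URMGC reference

The unequal-radius modified Gouy–Chapman equation — nonlinear
Poisson–Boltzmann for point ions that keeps only the species-specific
Stern exclusions θ(r − R − σ_a/2), solvent omitted entirely — is solved
with a damped Newton method on the finite-difference system in u = rψ
(tridiagonal Jacobian, line search, Picard fallback), with the Gauss-law
surface condition ψ′(R) = −λ_B Z_M/R² and ψ(r_max) = 0, to residual 1e-10.
Its completely monotonic profiles are the structureless baseline against
which the correlation effects (layering, overcharging, charge reversal)
are judged.

## Observables

* **Integrated charge** P(r) = Z_M + 4πΣ_a z_a ∫_R^r s²ρ_a ds — the net
  charge inside radius r, macroion included, so P(R) = Z_M and P(r_max)→0
  by electroneutrality. This inclusion convention is the only one under
  which "P(r)Z_M < 0 marks charge reversal" and "ΔZ_M = max P − Z_M > 0
  marks amplification" are simultaneously coherent; an ionic-only accessor
  is provided as well. Charge-reversal/amplification flags carry a 1e-6
  relative guard band so quadrature noise around P = 0 cannot raise them.
* **Capacitive compactness** τ_c, from 1/τ_c = 1/R − ψ₀/(λ_B Z_M) with
  ψ₀ = ψ(R): the radius of the ideal spherical-capacitor counter-charge
  shell reproducing the surface potential. τ_c → R means perfect screening
  at contact; an unscreened macroion gives τ_c = +∞ (flagged). ψ₀ is read
  at the surface by default (`psi0_at="contact"` reads it at the innermost
  closest approach instead). Under this diagnostic the explicit solvent
  *reduces* τ_c at the base condition: packing forces more counter-charge
  into contact (ΔZ_M grows strongly at the same time), lowering ψ₀ and
  pulling the equivalent capacitor radius inward.

## What the tests do and do not show

The synthetic inputs (analytic profile sets, rock-salt cells, hard-sphere
fluids, the dilute point-ion limit) exercise exact closed-form oracles; the
cross-engine comparison runs the scaled-down condition R = 1 nm, Z_M = 8,
0.1 M NaCl + 0.05 M MgCl₂, solvent 5 M, L = 7 nm, ~1100 particles,
21k sweeps — small enough for a laptop-scale test run, with MC error bars
that are correspondingly larger than a production study would carry. The
engines agreeing there validates the shared model and both numerical
treatments at moderate coupling and packing; it does not by itself certify
the DFT's approximations (WDA + MSA perturbation) at the strongest
couplings (|Q| = 0.408 C m⁻², C_S = 55.55 M), where the paper-scale
comparison would need hours of sampling. Qualitative orderings at the base
condition (URMGC monotone vs DFT layering and charge reversal; solvent
raising ΔZ_M and lowering τ_c) are asserted as inequalities, not values.

## Known limitations

* The WDA self-consistent mode is an O(N²) per-radius inner iteration —
  correct but slow; it is tested on coarse grids only.
* The numeric OZ/MSA kernels inherit sine-transform grid error near
  contact (~0.5% against the restricted closed form at default resolution).
* Picard with exponent mixing is robust but not accelerated (no
  Anderson/DIIS); the stiffest fixtures take a few thousand iterations.
* Canonical MC at desk scale carries integer-count reservoir distortion;
  the realized-concentration matching above is the supported comparison
  route.
* No free-energy evaluation: the variational functional enters only
  through its stationarity condition.
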