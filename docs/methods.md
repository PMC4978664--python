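# Methods

## Model

The package studies a single-species logistic population with distributed
habitat and indirect feedback control,

    N_t = d1 ΔN + r N (1 − (a1 N + a2 N_τ)/K − c u),
    u_t = d2 Δu + b N_τ − a u,

on Ω = (0, lπ) with homogeneous Neumann boundaries (a closed habitat) and
nonnegative continuous history data on [−τ, 0].  The instantaneous
self-limitation weight `a1` and the delayed weight `a2` split the usual
logistic crowding term; the control `u` integrates the delayed population at
rate `b`, decays at rate `a`, and suppresses growth through `c`.  All ten
constants are strictly positive.  The kinetics are *exactly quadratic* in
`(N, N_τ, u)`, which the normal-form machinery exploits (no cubic Taylor
terms exist).

Basic structure: the equilibria are `E0 = (0,0)` and
`E* = (aK/(a(a1+a2)+bcK)) · (1, b/a)`.  `E0` is always unstable
(`λ = r > 0` for the homogeneous mode).  Comparison arguments give the
ultimate bounds `limsup N ≤ K/a1`, `limsup u ≤ bK/(a a1)`; the package
exposes these as checkable predicates and the simulator asserts them at run
time.  `a a1 > a a2 + b c K` is a sufficient (not necessary) permanence
condition; its failure asserts nothing.

## Characteristic analysis

Fourier expansion in the Neumann eigenfunctions `cos(nx/l)` reduces the
linearization at `E*` to one transcendental equation per mode,

    λ² + A_n λ + B_n + e^{−λτ} (C λ + D_n) = 0.

At `τ = 0` Routh–Hurwitz holds for every mode (`A_n + C > 0`,
`B_n + D_n > 0`), so the undelayed system is stable and diffusion alone
cannot destabilize (no Turing instability).  Purely imaginary roots `iω`
require `ω⁴ + P_n ω² + Q_n = 0` with `P_n = A_n² − 2B_n − C²` and
`Q_n = B_n² − D_n²`.  `P_n` is computed from the coefficient values, never
from re-expanded algebraic displays: re-derivations of `P_n` in the
literature of this model drop an `a²` term, and only the coefficient-level
value reproduces the reference frequency `ω0 = 0.348266`.

When `Q_n < 0` the quadratic has exactly one admissible root and mode `n`
destabilizes at

    τ_0^(n) = (1/ω_n) arccos[ ((D_n − A_n C)ω_n² − B_n D_n) / (C²ω_n² + D_n²) ],

with branches `τ_j^(n) = τ_0^(n) + 2πj/ω_n`.  The principal arccos branch is
valid because `A_n D_n − B_n C > 0` forces `sin ω_n τ > 0`; the code checks
both this and the characteristic residual (`< 1e−9`) at every returned
point.  `N0` is the largest `n` with `Q_n < 0`; for `a1 ≥ a2` the sign is
monotone in `n²/l²`, allowing an early stop in the scan (default bound
`n_max = 200`; a diagnostic is raised if the sign has not stabilized).
Floating-point ties `|Q_n| ≤ 1e−12` count as "no Hopf" with a warning.

Transversality is evaluated from the closed-form inverse derivative; its
real part reduces to `(ω⁴ + D_n² − B_n²)/((Cω²)² + (D_n ω)²) > 0`, so roots
always cross rightward and each `τ_j^(n)` is a genuine Hopf point.  The
implementation cross-checks the closed form against the evaluated complex
expression at every call, and the test suite additionally against numerical
root tracking and a brute-force grid+Newton search for imaginary-axis
crossings on random parameter sets.

### The two coupling conventions

The true Jacobian entry of the control in the population equation is
`−r c N*`.  The analysis chain traditionally used for this model carries it
as `−c N*`, i.e. without the growth-rate factor (and books the `n²/l²` cross
terms of `B_n`, `D_n` with `d1` where the determinant gives `d2`).  Both
conventions are implemented:

* `reduced` (default): display-faithful.  Reproduces the shipped reference
  values (`ω0 = 0.348266`, `τ0 = 5.81966`, `N0 = 0`).
* `exact`: determinant of the true Jacobian.  For the reference preset it
  gives `ω0 = 0.259712`, `τ0 = 8.602256`.

The two coincide at `r = 1`; the reference preset has `r = 0.6`, where they
differ.  The nonlinear simulator integrates the actual PDE, whose onset
matches `exact` (verified: the simulated switch lies between `0.95 τ0` and
`1.05 τ0` of the exact value).  Every test that confronts theory with
simulation therefore uses `exact`; the reference tables and the acceptance
pipeline use `reduced`.  Both conventions yield the same qualitative
picture — a unique destabilizable mode band, delay-induced supercritical
Hopf bifurcation, stable homogeneous cycles above onset.

## Center-manifold normal form

At a Hopf point `(ω*, τ*)` of mode `n` the critical eigenspace is spanned by
`q(θ) = (1, ξ)ᵀ e^{iω*θ}` and its conjugate, with
`ξ = b e^{−iω*τ*}/(iω* + a + d2 n²/l²)`.  The projection functional is
`M·(1, η)` with the *row* eigenvector component
`η = −cpl/(iω* + a + d2 n²/l²)` (`cpl` the coupling entry of the chosen
convention) and the pairing normalization

    M = [1 + ξη + τ* e^{−iω*τ*} (bη − (r a2/K) N*)]^{−1}.

Time is left unscaled; the reduced equation is
`ż = iω* z + g20 z²/2 + g11 z z̄ + g02 z̄²/2 + g21 z² z̄/2 + …` with the
first eigenvector component pinned to 1.  The quadratic projections follow
from the exact Taylor coefficients `(−r a1/K, −r a2/K, −r c)`; the
second-order manifold blocks solve `Δ(2iω*) E1 = F20` and `Δ(0) E2 = F11`
with the characteristic matrix `Δ(λ)`, and

    W20(θ) = (i g20/ω*) q(θ) + (i ḡ02/3ω*) q̄(θ) + E1 e^{2iω*θ},
    W11(θ) = (−i g11/ω*) q(θ) + (i ḡ11/ω*) q̄(θ) + E2,
    c1(0)  = (i/2ω*)(g20 g11 − 2|g11|² − |g02|²/3) + g21/2,

with `g21` assembled from the `z²z̄` coefficient of the quadratic kinetics
evaluated on `φ = qz + q̄z̄ + W20 z²/2 + W11 z z̄`.  The indices are
`μ2 = −Re c1/Re λ′(τ*)`, `β2 = 2 Re c1`,
`T2 = −(Im c1 + μ2 Im λ′)/(ω* τ*)`; supercritical iff `μ2 > 0`, orbitally
stable iff `β2 < 0`, period increasing iff `T2 > 0`.

Validation.  The chain is delicate — conjugation and normalization slips
change `c1` silently — so it is pinned three independent ways:

1. On Wright's equation `x′ = −α x(t−1)(1+x)` at `α = π/2` the same recipe
   reproduces the classical value
   `Re c1 = −2π(3π−2)/(10(4+π²)) ≈ −0.33636` exactly.
2. A Chebyshev pseudospectral discretization of the delay system (48+1
   nodes per component) with the finite-dimensional projection/solve
   reduction reproduces `c1` to ~1e−12 on both conventions and on random
   Hopf-regime parameter sets (test suite).
3. Dynamically: at `τ = τ0 + 0.2` (exact convention) the simulated cycle's
   peak-to-trough amplitude matches `4 sqrt(Re λ′ · Δτ / (−Re c1))` to a few
   percent, and the measured period sits within 5% of `2π/ω0`.

For the reference preset the chain gives
`c1(0) = −0.418685 − 1.781683i` (reduced convention, mode 0, branch 0):
supercritical, orbitally stable, period increasing.  A note on `g02`: with
the eigenvector phase pinned by `q₁(0) = 1`, the direct projection gives
`g02 = conj(g20) · M²/|M|²` — equal to `conj(g20)` in modulus (which is all
that enters `c1`) but not in phase unless `M` is real.

Only the homogeneous mode `n = 0` is validated.  For `n ≥ 1` the quadratic
projections vanish identically (the spatial average of `cos³` is zero) and
the cubic assembly applies the `cos⁴` average `3/4`; these results carry
`validated=False` and are excluded from the acceptance pipeline.

## Simulator

Method of lines: `M` equally spaced nodes on `[0, lπ]` (default 101),
second-order Laplacian with mirror ghost nodes for the no-flux condition,
fixed-step explicit RK4 on reaction plus diffusion.  The step is fitted so
that (i) `τ/dt` is an exact integer — the delayed field is then an exact
ring-buffer index, no interpolation — and (ii) `dt ≤ h²/(2 max(d1,d2))`,
inside the explicit stability region with margin.  The delayed field is
frozen across the four RK stages of a step; this is an `O(dt)` consistency
error in the delayed argument only and is invisible at the default steps
(halving `dt` moves measured periods by `< 1%`, tested).  There is no
randomness anywhere in the simulator.

History data default to the constant pair `(N, u)(x, 0) = (0.5, 0.9)` held
on `[−τ, 0]` — the natural reading when only the `t = 0` values are
prescribed.  Blow-up (any field above ten times its dissipative bound) and
NaNs raise immediately; nonnegativity and the dissipative bounds are
asserted by the tests for every run.

Oscillation diagnostics probe the node nearest the domain midpoint over the
last 30% of the run (peak detection with 10% prominence): `steady` means
peak-to-trough below `1e−3` in field units; `periodic` needs at least three
peaks with period dispersion under 10%; everything else, including windows
shorter than two periods, is `undetermined`.

Problem sizes in the shipped tests are chosen for desk-scale runtimes:
spatially resolved runs use `M = 101` (convergence below onset) or `M = 41`
(classification far above onset, where the attractor is spatially
homogeneous), and onset-adjacent runs exploit the Neumann symmetry — a
spatially constant history stays exactly constant — to run on `M = 5`
nodes with `dt = 0.01`.  Far above onset the cycles are relaxation-like
(period ≈ `2.5 τ` at `τ = 130`), so horizons scale with the delay.

## What the defaults do and do not show

The worked examples use one parameter point; the random-parameter property
tests sample log-uniform boxes `[0.1, 3]^10` restricted to the Hopf regime
`a2 ≤ a1 < a2 + bcK/(ar)`.  Passing tests demonstrate internal consistency
of the analysis chain and its agreement with the integrated PDE for this
model family; they say nothing about parameter ranges with `a1 < a2` (two
admissible frequencies, stability switching sequences), about non-constant
diffusion, higher space dimensions, or non-quadratic kinetics, none of
which are implemented.  The delay-sweep classification is a probe-point
diagnostic, not a proof of spatial homogeneity of the attractor.

## Known limitations

* `n ≥ 1` normal forms are structurally implemented but unvalidated.
* The `reduced` convention is internally consistent as an analysis chain
  but is not the linearization of the simulated PDE when `r ≠ 1`; mixing
  conventions across modules is the caller's responsibility (the package
  defaults never mix them silently).
* Degenerate Hopf points (`Re c1 = 0`) are classified by sign without an
  unfolding; no continuation of root branches or global bifurcation
  structure is attempted.
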