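# Methods

## Model and assumptions

The package treats steady, incompressible flow of a pseudoplastic nanofluid
in a two-dimensional symmetric channel whose walls carry a ciliated carpet,
in the frame travelling with the metachronal wave.  The cilia are not
resolved individually: the envelope model replaces them by a material
surface h(x) = 1 + ε·cos(2πx) whose tips move axially with
u_h(x) = −1 − 2αδε·cos(2πx) in the wave frame.  The governing equations are
the long-wavelength (δ → 0), low-Reynolds lubrication reduction, so
pressure is uniform across the gap and the momentum balance collapses to a
single fourth-order ODE in y at each station x:

    ψ'''' − ζ ((ψ'')³)'' = 0,
    ψ(0) = ψ''(0) = 0,   ψ(h) = q,   ψ'(h) = u_h,

with ζ the relaxation measure of the constitutive law and q the
wall-streamline flux.  Energy and nanoparticle-concentration equations
(Prandtl Pr, Brownian Nb, thermophoresis Nt, dissipation coefficient Ec)
close the thermal problem with θ, σ = 0 at the centreline and 1 at the wall.

Everything is dimensionless; no SI-unit parameterisation is offered.
The model is steady in the wave frame, strictly two-dimensional, and says
nothing about cilia sublayer mechanics.

## Parameters

| name  | meaning                                  | default | notes |
|-------|------------------------------------------|---------|-------|
| zeta  | relaxation measure ζ = λ₁² − μ₁²          | 0.01    | perturbation parameter; ζ=0 Newtonian |
| eps   | wall amplitude ratio ε                    | 0.15    | must be < 1 so h > 0 |
| alpha | cilia-tip path eccentricity α             | 0.2     | |
| delta | wave number δ = a/λ                       | 0.01    | enters u_h and the transverse velocity |
| F     | wave-frame flow rate (wall ψ = F/2)       | 0.1     | |
| Q     | mean flow rate for sweeps                 | unset   | mapped to F, see below |
| Pr    | Prandtl number                            | 2       | |
| Nb    | Brownian-motion parameter                 | 0.8     | must be > 0 (Nt/Nb appears) |
| Nt    | thermophoresis parameter                  | 1       | |
| Ec    | dissipation coefficient multiplying Pr    | 1       | its formal definition is left free |
| F0,F1 | order split of F in dp/dx                 | F, 0    | the O(ζ) flux correction vanishes at the wall |

Defaults are the parameter set of the published velocity/stream-function
comparison (thermal values from the published profile figures).

## Convention switches

The published formulation leaves several choices ambiguous; each is an
explicit toggle on `Conventions`, never a silent assumption:

* **wall**: `scaled` (h = 1 + ε·cos 2πx, default) vs `verbatim`
  (h = 1 + cos 2πx as literally printed).  The printed form contradicts the
  captions (which all list ε) and the table y-grids; `scaled` is the only
  consistent reading.
* **tip**: `printed` (u_h = −1 − 2αδε cos 2πx) vs `two_pi`
  (−1 − 2παδε cos 2πx, the common envelope-model variant).
* **flux**: `half` (wall streamline ψ(h) = F/2, the printed boundary
  condition, default) vs `full` (ψ(h) = F).
* **series**: `derived` (default) vs `printed`, see next section.
* **q_mapping**: `identity` (F = Q, default) vs `shift` (F = Q − 1).  The
  conventional wave-frame shift *inverts* the reported δ-trend of the
  pressure rise at the published sweep parameters, while the identity
  reading reproduces all four qualitative trends (Δp_λ increasing in ζ,
  decreasing in δ; F_λ decreasing in ζ and in ε); the identity mapping is
  therefore the default, with the shift available.

`compare_tables`/`scan_conventions` score every combination against the
published table columns and report the best match rather than asserting one.

## The perturbation series: derived vs printed

The series is computed symbolically-by-construction from the first integral
ψ'' − ζ(ψ'')³ = A·y (the centreline symmetry kills the integration
constant): order by order, w₀ = A₀y, w₁ = A₁y + w₀³, w₂ = A₂y + 3w₀²w₁,
each ψₙ recovered by double integration with ψₙ(h) = ψₙ'(h) = 0 for n ≥ 1.
This yields exact polynomial coefficients (plain linear algebra, no
truncation) and the pressure-gradient coefficients A₀, A₁, A₂ for free.

The published closed forms are reproduced by this derivation only in part:

* the printed O(ζ⁰) term and the printed O(ζ) pressure-gradient
  coefficient correspond to wall flux q = F/2, consistent with the printed
  boundary condition;
* the printed O(ζ) stream-function term corresponds to q = F (it equals the
  derived term exactly upon substituting q = F) — a factor-of-two misprint
  in the flux;
* the printed O(ζ²) term scales as (h·u_h − F)⁹, whereas the structure of
  the expansion forces (h·u_h − q)⁵ at second order; it cannot be produced
  by any flux reading and is taken to be an editorial error.

The `derived` series (default) is therefore the package's reference
solution; `series="printed"` evaluates the published expressions verbatim
for comparison.  With the derived series the velocity gap against the
independent numerical solver at the published table point is 2.51×10⁻⁴ —
essentially identical to the published Difference column (max 2.54×10⁻⁴),
which indicates the published tables were themselves computed from the
correct (unprinted) expansion.  The stream-function gap at the same point
is 7.1×10⁻⁵, the genuine third-order truncation remainder at ζ = 0.01;
the published Table-2 difference column (max 5.7×10⁻⁵) is slightly
smaller than any reconstruction we can produce, consistent with the
caption's missing ζ.

## Thermal solution

Integrating the concentration equation twice and applying its boundary
values gives the exact reduction

    σ = −(Nt/Nb)·θ + c·y,     c = (1 + Nt/Nb)/h,

so Nbσ' + Ntθ' = (Nb+Nt)/h is a known constant and the energy equation is
*linear* with constant decay rate k = Pr·(Nb+Nt)/h — at every perturbation
order and in the full numerical problem.  Each temperature order is then an
exponential plus a polynomial particular solution,

    θₙ = Dₙ − (Cₙ/k)·e^{−ky} + Pₙ(y),

with Pₙ obtained by a triangular solve for the polynomial forcing
(−Pr·Ec·(ψ₀'')² at order 0, −2Pr·Ec·ψ₀''ψ₁'' at order 1) and (Cₙ, Dₙ)
fixed by the two temperature boundary values.  The published
γ₁…γ₄ / δ₁…δ₄ constants map onto this structure (γ₂ = c is the
concentration slope, γ₃/γ₄ and δ₃/δ₄ the amplitude/offset pairs; the
boundary conditions force γ₁ = δ₁ = δ₂ = 0 — the rank of the BC system
leaves no independent first-order slope).  The published templates are
also available (`thermal="printed"`); note they solve the energy equation
with Ec in place of Pr·Ec (a dropped Prandtl factor) and carry a
(F − h·u_h)⁶ dissipation power where the expansion structure gives fourth
powers, so they deviate from the numerical solution when Pr ≠ 1.

A consequence worth stating: with Ec = 0 and Nt = 0 the temperature profile
is *not* linear — σ' = 1/h makes θ'' + (Pr·Nb/h)θ' = 0, whose solution is
the saturating exponential (1 − e^{−ky})/(1 − e^{−kh}).  The conduction
line y/h is recovered only as Pr·Nb → 0; it serves as the solver's initial
guess, not as a solution.

## Numerical solvers

* **Momentum.** The cubic w − ζw³ = A·y is inverted pointwise on the
  Newtonian-continuous branch by the trigonometric root
  w = (2/√(3ζ))·sin(arcsin(r)/3), r = (3√(3ζ)/2)·A·y; beyond the fold
  |r| > 1 (shear demand outside the monotone range of the constitutive law)
  the solver raises a branch-loss error instead of switching branches.
  Because w depends on y alone, ψ'(0) enters the remaining boundary
  conditions linearly and is eliminated, reducing the two-parameter shoot
  to one bracketed scalar equation in A, solved by Brent iteration
  (xtol 10⁻¹⁴).  Profiles are assembled by cumulative Simpson integration
  on the fixed grid (default n = 2001; BC residuals ≤ 10⁻¹⁰; halving the
  step changes velocities by < 10⁻⁹; results are bitwise stable across
  runs).  A collocation solve of the fourth-order form
  ψ''''(1 − 3ζψ''²) = 6ζψ''ψ'''² (scipy `solve_bvp`, tol 10⁻¹⁰, Newtonian
  closed form as initial mesh) is the independent cross-check.
  Note the fold bound: at ζ = 0.05 several of the published sweep
  parameter sets demand |A|·h beyond 2/(3√(3ζ)), where the pseudoplastic
  branch ceases to exist; the perturbation formulas remain evaluable there
  (and are what the sweeps integrate) but the numerical oracle correctly
  refuses.
* **Thermal.** A damped-Newton shoot on (θ'(0), c) with residuals
  (θ(h) − 1, σ(h) − 1), conduction initial guess, tolerance 10⁻¹⁰, at most
  100 iterations; the integrating-factor kernel is written with exponents
  shifted by h so nothing overflows.  Because the system is linear given c,
  convergence takes one or two steps.

## Derived quantities

* **Transverse velocity**: v = −δ·∫₀^y (∂u/∂x) dy′, the constant fixed to
  zero by centreline symmetry; ∂u/∂x by central differences (step 10⁻⁵),
  the integral by 64-node Gauss–Legendre (the integrand is polynomial in y,
  so this is exact to rounding).  The δ factor restores the scaled
  continuity δ·u_x + v_y = 0 implied by v = −δ·ψ_x; the published
  expression omits it.
* **Pressure rise / friction**: Δp_λ and F_λ by 64-node Gauss–Legendre over
  one wavelength of the series dp/dx (optionally of the numerical A);
  doubling the node count changes results by < 10⁻⁹.
* **Trapping**: ψ is sampled on x ∈ [0, 2] (two wavelengths so loops
  straddling a period are seen whole), y ∈ [−h_max, h_max] with the odd
  mirror and wall clamping, on a 241×241 grid.  Closed contours are
  extracted by marching squares at 20 levels spanning [0, max(F/2, ψ̂)]
  (ψ̂ the grid maximum; endpoints excluded).  Levels up to F/2 alone
  contain no closed loops at the published figure parameters — all closed
  streamlines lie between the separatrix value F/2 and the interior
  maximum — hence the upper end of the schedule.  A contour counts as a
  trapped loop if it closes on itself, stays strictly inside the wall,
  encloses area > 10⁻⁵ and is centred in x ∈ [0.5, 1.5).  Counts and the
  largest enclosed area are stable under grid doubling (area shifts
  < 0.1 %).

## What the checks do and do not show

All validation is internal to the stated model: the series is checked
against an independent solver of the same reduced equations, structural
identities (affine σ + (Nt/Nb)θ, boundary values, continuity) are verified
to 10⁻⁸, and the qualitative parameter trends reported for the published
sweeps are confirmed as orderings.  The published tables' absolute values
are not reproduced by any convention combination (best deviation ~10⁻²,
reported by `scan_conventions`); since the package does reproduce the
published *difference* magnitudes almost exactly, the discrepancy points at
an unstated parameter or normalisation in the original tables rather than
at either solver.  Nothing here tests the physical fidelity of the envelope
model itself, the lubrication reduction, or three-dimensional/unsteady
effects; figure appearance is not matched, only content.

## Problem sizes

Default sizes — momentum grid n = 2001, thermal grid inherited from the
momentum solve, trapping grid 241×241 with 20 levels, quadrature 64 nodes,
convergence study over ζ ∈ {10⁻³, 2·10⁻³, 4·10⁻³} — were chosen so that
every reported quantity is converged well past its stated tolerance; the
full test suite and the acceptance script each run in seconds.
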