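# Methods

## Model and assumptions

The package solves the axisymmetric, unidirectional flow of an
incompressible Brinkman-type fluid (blood) carrying a dilute suspension
of magnetic particles in a rigid circular tube, with convective heat and
mass transfer. The constitutive assumptions are linear: bulk Brinkman
drag `β₁ f`, Lorentz damping `M f` from a strong transverse field (the
induced field is neglected), Stokes drag coupling between the phases, and
Boussinesq-type buoyancy `Gr Θ + Gm Φ` with wall temperature/concentration
at least the ambient values. Memory is introduced by replacing every time
derivative with a Caputo derivative of order `α ∈ (0,1]`; `α = 1` recovers
the classical local-in-time model.

Scales: `ξ = r/r₀`, `τ = νt/r₀²`, velocities by the wall speed `u₀`,
temperature and concentration by their wall–ambient differences. The
dimensionless groups then read `M = σB₀²r₀²/μ`, `β₁ = βr₀²/ν`,
`Pc = KNr₀²/μ`, `Pr = μc_p/k`, `Sc = ν/D`,
`Gr = g r₀² β_T (T_w−T_∞)/(u₀ν)`, `Gm = g r₀² β_C (C_w−C_∞)/(u₀ν)`.

Two conventions required a decision because source presentations of this
model are internally inconsistent:

* **Combined damping.** Both the Lorentz and Brinkman terms oppose the
  motion, so the default is `M0 = M + β₁`. The alternative difference
  convention (`m0_convention="difference"`, `M0 = M − β₁`) is provided for
  reproducibility of presentations that print it; it anti-damps the flow
  whenever `β₁ > M` and the validator warns about it.
* **Particle relaxation rate.** The particle momentum balance is taken as
  `D^α g = (f−g)/Pm` — rate `1/Pm`, so that heavier particles respond more
  slowly — which is the only convention consistent with the convolution
  solution `g = (1/Pm)F_α(−1/Pm,τ)*f` and the wall response
  `g(1,τ) = 1 − E_α(−τ^α/Pm)` (classically `1 − e^{−bτ}` with `b = 1/Pm`).
  The physical mapping is therefore `Pm = mν/(Kr₀²) = 1/b`.

## Exact solutions

After Laplace (`τ → ℓ`) and finite Hankel (`ξ → ε_n`, the positive zeros
of `J0`) transforms, each scalar mode is
`(J1(ε_n)/ε_n)[1/ℓ − ℓ^{α−1}/(ℓ^α + a_n)]` with `a_n = ε_n²/Pr` (or
`/Sc`), inverting to `1 − E_α(−a_n τ^α)`. The velocity mode is a rational
function of `y = ℓ^α`,

```
fH = {ε J1/ℓ + F0(ℓ) J1/ε + Gr(...) + Gm(...)} (y+Υ2)/((y+Υ3)(y+Υ4)),
```

with `Υ2 = 1/Pm`, `Υ0 = ε² + M0 + Pc + 1/Pm`, `Υ1 = (ε² + M0)/Pm` and
`Υ3,Υ4` the roots of `x² − Υ0x + Υ1`. The discriminant equals
`(ε²+M0−1/Pm)² + Pc² + 2Pc(ε²+M0+1/Pm) > 0`, so the roots are real and
distinct except in the measure-zero case `Pc = 0, ε²+M0 = 1/Pm`, which
raises a dedicated `DegenerateModeError` (the numerical-inversion path
still applies there).

The seven-term time-domain brace per mode,

```
1 + N1 R(−Υ3) + N2 R(−Υ4) + N3 cos*F(−Υ3) + N4 cos*F(−Υ4) + N5 R(−a1) + N6 R(−a2),
```

uses weights computed by exact residue algebra of the rational image —
never transcribed constants. With `c3 = (Υ2−Υ3)/(Υ4−Υ3)`,
`c4 = (Υ2−Υ4)/(Υ3−Υ4)`, `d`-residues of `(y+Υ2)/((y+a)(y+Υ3)(y+Υ4))` and
`S = ε² + A0 + Gr + Gm`:

```
N1 = −(S c3 + Υ3(Gr d3¹ + Gm d3²))   N2 = −(S c4 + Υ4(Gr d4¹ + Gm d4²))
N3 = −A1 c3                          N4 = −A1 c4
N5 = −Gr a1 d1¹                      N6 = −Gm a2 d1²
```

Correctness of the reconstruction is enforced structurally, not assumed:
the recombined partial fractions must equal the directly-evaluated image
at random complex frequencies (≤1e−8 relative), and the image must
satisfy the transformed momentum balance identically (residual ≤1e−10).

The wall value is carried exactly by the `1 − 2Σ(...)` lifting: every
`J0(ε_n)` vanishes at `ξ = 1` (enforced exactly in floating point), so
boundary rows are exact and the series represents only the deviation.

## Special functions

All kernels reduce to the two-parameter Mittag-Leffler function on the
negative half-line, `E_{α,β}(−x)`, evaluated by a three-regime scheme:

* power series for `x ≤ 11.5^α` (cancellation grows like `e^{x^{1/α}}`;
  the cap limits the loss to ~5 digits);
* algebraic asymptotics `Σ_k (−1)^{k+1} x^{−k}/Γ(β−αk)` for `x ≥ 30`,
  truncated at the smallest term (reciprocal-gamma poles contribute exact
  zeros and are skipped by the truncation rule);
* de Hoog Bromwich inversion of `s^{α−β}/(s^α+x)` at `t = 1` in the
  middle band.

At `α = 1` with integer `β` the exponential closed forms are exact. The
scheme was validated against `erfcx` closed forms and 30-digit mpmath
references; worst observed relative error ~1e−8 (middle band, `α → 1`),
typically ≤1e−12.

`R_{q,v}(−a,t) = t^{q+v−1}E_{q,q+v}(−at^q)` and
`F_q(−a,t) = t^{q−1}E_{q,q}(−at^q)` follow directly. In the solution
formulas `R_{α,−1}(−a,τ)` denotes `L⁻¹{ℓ⁻¹/(ℓ^α+a)} = (1−E_α(−aτ^α))/a` —
the bounded, vanishing-at-zero member that reproduces the classical
`(1−e^{−aτ})/a` limit. The oscillatory convolution is summed exactly:
`cos(ωτ)*F_α(−b,τ) = Σ_m (−ω²)^m τ^{2m+α} E_{α,α+2m+1}(−bτ^α)`, with the
term count set by `ωτ_max` (absolutely convergent; ~25 terms at `ωτ ≤ 4`).

The classical (`α = 1`) velocity uses
`cos(ωτ)*e^{−bτ} = (b cos ωτ + ω sin ωτ − b e^{−bτ})/(b²+ω²)`: note the
**plus** sign in `b²+ω²` and the decaying exponentials — the forms forced
by the transform pair (some printed presentations carry sign typos here).

### Singular-kernel convolution

`g = (1/Pm)F_α(−1/Pm,τ)*f` has an integrable `τ^{α−1}` kernel singularity.
Product integration handles it exactly for piecewise-linear `f`:
integrating by parts against the exact antiderivatives
`K(u) = 1 − E_α(−au^α)` and `∫K = u(1 − E_{α,2}(−au^α))` leaves only
slope sums, with the impulsive wall start entering through the jump value
`f(ξ,0⁺)`. A step input is reproduced to machine precision for every `α`.

### Numerical inverse Laplace transform

The independent inversion route defaults to the de Hoog–Knight–Stokes
accelerated Fourier series (each time inverted on its own contour scale;
~1e−9 relative on smooth images), with fixed-Talbot (~1e−8) and
Gaver–Stehfest (~1e−4, smooth images only) selectable. Images built on
`ℓ^α` carry a branch cut on the negative axis; de Hoog and Talbot handle
it, which is why de Hoog is the default.

## Finite-difference oracle

The L1 scheme (`b_j = (j+1)^{1−α} − j^{1−α}`) with implicit second-order
central differencing of the radial Laplacian, axis regularity via the
symmetry stencil `4(u₁−u₀)/Δr²`, and the fluid–particle drag coupling
eliminated exactly per step (the particle update is a scalar linear
relation in the new fluid value — `g` has no spatial derivatives — so
substituting it keeps the fluid solve tridiagonal and the scheme
unconditionally stable with no lag error). `g` is stepped from its own
fractional relaxation equation, never from the convolution, so the FD
route is genuinely independent of the analytic particle solution.

## Verification protocol and parameter choices

* **Study defaults** (fixed by the graphical analysis of the problem):
  `Pr = 22.64` and `Sc = 1.9e4` from the blood properties, `Gr = 320`,
  `A0 = A1 = 0.5`, `ω = 5π/8` (so the quoted phase `ωτ = 5π/8` holds at
  `τ = 1`), all remaining groups 0.5 (`Pm = 0.8` in the memory-order
  sweeps), `α = 0.5` unless swept.
* **Comparison metric**: sup norm relative to each field's own magnitude
  scale — at `Gr = 320` the velocity is O(10²), so absolute tolerances
  would silently rescale with the forcing.
* **Series truncation**: 80 Hankel modes for field evaluation (40 for
  sweeps). Interior Fourier–Bessel error decays like O(1/N) pointwise for
  the impulsive start; at `τ = 0` the representation carries a documented
  ripple (~0.08 at 80 modes for `ξ ≤ 0.9`) because the initial data are
  incompatible with the instantaneous wall values.
* **FD cross-validation** uses `n_r = 96`, `n_t = 1024` on `τ ∈ [0,1]`,
  comparing at `τ ∈ {0.25, 0.5, 0.75, 1}` and `ξ ≤ 0.9`; all four fields
  agree with the series to ≤1e−3 relative for `α ∈ {0.5, 1}`. The
  concentration comparison runs at `Sc = 10`: at the physical
  `Sc = 1.9e4` the solutal boundary layer (width ~`√(τ/Sc)` ≈ 0.007 at
  `τ = 1`) is unresolvable on any uniform desk-scale grid and the series
  needs O(√Sc) modes, so the comparison would measure resolution, not
  correctness. All other groups stay at the study defaults.

## Known limitations

* **L1 start-up order.** The impulsive wall data make the solution behave
  like `t^α` near `t = 0`, where the L1 scheme degrades from its smooth
  -solution order `2−α` to ~first order; measured self-convergence on the
  temperature field is ~1.05 at `α = 0.5`. The `2−α` rate is verified
  separately on a manufactured smooth-solution fractional ODE. No graded
  meshes are provided.
* **Parameter trends.** Sweeps reproduce the expected strict decrease of
  the centerline velocities in `M`, `β₁`, `Pc` and `Pm`, and the
  short/long-time ordering reversal across `τ ≈ 1` when varying `α`. The
  solutal Grashof number `Gm`, however, multiplies the non-negative
  buoyancy source `Gm·Φ` with `Φ ∈ [0,1]`, and the linear parabolic
  system's resolvent is positivity-preserving, so the model's velocity is
  strictly *increasing* in `Gm` (by ~1e−5 per unit `Gm` at the physical
  `Sc`, where `Φ ≈ 0` in the interior). A claimed decrease with `Gm`
  cannot be produced by this model under the stated buoyancy convention;
  the trend suite reports the measured direction.
* **Degenerate modes.** The repeated-root branch (`Υ3 = Υ4`) and pole
  collisions (`a_i` equal to `Υ3` or `Υ4` to ~1e−9) raise errors rather
  than switching to confluent formulas; the numerical-inversion path
  covers those parameter points.
* The Mittag-Leffler evaluator covers real arguments (plus the principal
  branch on the Bromwich contour internally); general complex arguments
  and matrix arguments are out of scope, as are wall elasticity,
  non-axisymmetric flow and particle back-reaction beyond linear drag.
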