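# Methods

## The characteristic equation and its geometry

All stability questions reduce to the location of the roots of
Δ(λ) = λ − α₁ − (α₂ + α₃λ)e^{−λ}. The neutral term α₃λe^{−λ} reflects the
delayed-derivative character of the linearized renewal equation; for
|α₃| < 1 every root with Re λ ≥ 0 satisfies
|λ| ≤ (|α₁| + |α₂|)/(1 − |α₃|), which is what makes a complete numerical
treatment possible: every search and every contour below is confined to a
disk of that radius plus one. For |α₃| > 1 there are infinitely many right
half-plane roots and the package refuses the region operations (evaluation
of Δ itself is unrestricted).

Critical roots organize the (α₁, α₂) plane: λ = 0 occurs on
α₁ + α₂ = 0 (simple, double at the corner (1 − α₃, α₃ − 1) where
additionally α₂ = α₃ − 1, triple only in the degenerate limit α₃ = −1),
and ±iω occurs exactly at (c₁(ω, α₃), c₂(ω, α₃)). The stability region is
encoded as the open set

    {α₁ < 1 − α₃,  φ(α₁) < α₂ < −α₁},

where φ parameterizes the ω ∈ [0, π) critical curve by α₁ — legitimate
because ∂c₁/∂ω < 0 throughout. This membership rule is the package's
geometric oracle; the argument-principle counter is its independent
cross-check, and the test suite drives grids of thousands of points
through both.

## Numerical procedures

**Root counting.** The winding number of Δ is tracked along the boundary
of {Re λ ≥ margin} ∩ {|λ| ≤ bound + 1} (default margin 1e−8). The contour
is sampled adaptively: segments are bisected until every consecutive phase
increment is below π/2, so the summed principal-branch increments give an
exact integer winding without quadrature of Δ′/Δ. If Δ comes within 1e−9
(relative) of zero on the contour, the flat segment is nudged to
margin/2, margin/4, … (roots between the nudged contour and the margin are
re-classified as marginal); after six nudges a ContourError is raised.
Axis roots are sought separately from seeds on the imaginary axis and
reported as marginal when |Re λ| ≤ margin.

**Root location.** Damped Newton iteration (step capped at 1, 50
iterations, |Δ| < 1e−12·scale acceptance) from a 0.25-spaced seed grid,
deduplicated at 1e−6. Near a multiple root plain Newton stalls ~1e−6
away, so candidates with |Δ′| < 1e−4 are re-polished with the modified
step m·Δ/Δ′ for m = 2, 3 and flagged with the multiplicity whose
derivative signature (|Δ^{(j)}| < 1e−8 for j < m) they satisfy. The search
window is [re_min, bound + 1] × [0, im_max]; the default im_max = bound + 1
is exhaustive for the right half-plane but not for Re λ < 0, where roots
extend arbitrarily high — callers chasing left-plane roots widen it.

**Scalar solves.** One-dimensional roots (φ(α₁), the sign-change frequency
of ∂c₂/∂ω, the Hopf frequency, θ_crit, the steady state Ē) are bracketed
by the monotonicity facts stated with each operation and solved with
`scipy.optimize.brentq` (a bracketing method) at 1e−12/1e−13 in the
variable; Ē uses plain bisection on R₀ − 1 to 1e−12. The sign-change
detector for ∂c₂/∂ω is deliberately numerical (a 4096-point sample of
h(ω, α₃) = α₃(sin ω cos ω − ω) + ω cos ω − sin ω followed by bracketing)
rather than an α₃ ≥ −1/2 short-circuit, so the −1/2 threshold is a
measured outcome, not an input.

**Curve sampling.** ω grids are refined until consecutive α₁ steps are
below a cap (default 0.25) wherever the curve is inside a window (default
|α₁| ≤ 50); poles at ω = mπ are clipped at distance 1e−6 by default. The
clip is a parameter because two uses pull in opposite directions: the far
tail of the curve (needed to observe the α₃ → −1 limit set) requires
~1e−9, while within ~clip of a pole the quarter-plane inequalities
α₂ ≷ ±|α₁| hold by margins smaller than double-precision rounding on
coordinates of size π/clip.

## The cell model

Parameters: death rate μ ≥ 0 (time is scaled so the proliferation delay
is 1, so μ is per proliferation time; a nontrivial steady state needs
2e^{−μ} > 1, i.e. μ < ln 2 ≈ 0.693); consumption weight θ ∈ [0, 1]
(θ : 1 − θ weighs proliferating vs quiescent consumption; θ ≥ 1/2 is the
biologically sensible half); and the responses β₁(E) ∈ [0, 1), G(E) > 0 on
the scaled environment E ∈ (0, 1].

The response families are constant, increasing Hill
v·Eⁿ/(Eⁿ + hⁿ) (evaluated through (h/E)ⁿ in log space so exponents in the
hundreds neither overflow nor lose the derivative), and clamped linear.
The model never pins the shape of β₁ or G — only μ, β₁(Ē) and Ē enter the
reference setting — so fixtures are built by calibration: the Hill level v
is chosen so that G(Ē) equals the value (1 − α₃)μ/(2e^{−μ} − 1) forced by
R₀(Ē) = 1, with half-saturation at Ē; the Hill exponent then sets the
slope G′(Ē) = nG(Ē)/(2Ē) without moving Ē. "Steep" and "shallow" fixtures
differ only in that exponent (100 vs 1 at the reference setting μ = 0.5,
β₁ ≡ 0.5, Ē = 0.5, where the critical slope separating the existence of a
critical consumption weight is ≈ 66).

The uniqueness hypothesis β₁′(μ + G) + G′(1 − β₁) > 0 is checked on a
1001-point grid rather than symbolically. Strictly positive steep Hill
derivatives underflow to exactly 0 near the ends of [0, 1], so the grid
surrogate rejects only genuine violations: a negative value anywhere, or a
derivative identically zero across (0, 1).

Distinct error types separate the three failure regimes: extinction
(R₀(1) ≤ 1), unbounded growth (R₀(0) ≥ 1), and hypothesis failure. The
2×2 characteristic matrix of the (p, Q) linearization is provided
independently of the scalar reduction; only coincidence of zero sets is
asserted (the proportionality factor between the two is not used
anywhere), with the removable singularity at λ = −μ filled by the limit
of (1 − e^{−z})/z.

## Simulator

The scaled system is integrated by the method of steps on a uniform grid
with N points per unit delay (default 256), locked to integer times so the
discontinuities the difference-equation part propagates land on nodes; no
smoothing is applied. The history integral ∫₀¹ p(t − a)e^{−μa} da uses the
composite trapezoidal rule on the stored grid; its a → 0 endpoint couples
E(tₙ) to p(tₙ), which is resolved by fixed-point iteration on E
(tolerance 1e−12, 50 iterations, 0.5 damping when an update exceeds 0.5).
Q advances by an implicit trapezoidal step, which is linear in Q(tₙ) and
solved exactly. The scheme is first-order at the breakpoints and
second-order between them; the discrete steady state therefore sits
O(h²) ≈ 3e−7 from the exact one at N = 256.

Dominant modes are measured on the *difference* between a perturbed and an
unperturbed run (this subtracts the O(h²) offset, dropping the noise floor
to ~1e−12): positive peaks are located and quadratically refined, the rate
is the slope of log amplitude over the peaks and the frequency is 2π over
the mean spacing. The estimator is accurate when the dominant root is
well-separated; fits therefore start after a transient (≈15 time units for
stable fixtures) so faster-decaying secondary modes die out first, and
growth fits use small kicks (1e−6 relative) and stop before nonlinear
saturation (the unstable limit cycle has a visibly shifted frequency, which
is exactly why the linear window matters).

## What the fixtures do and do not emulate

Fixtures are exact instances of the scaled model, not data: passing tests
demonstrate internal consistency of the analysis (geometry ↔ root counts ↔
linearization ↔ nonlinear simulation) at calibrated parameter points, not
agreement with measured cell populations. Real systems have distributed
cell-cycle durations, non-quasi-static resource dynamics, and unknown
response shapes; none of those enter here. The problem sizes used
throughout (41×41 classification grids, 100-model random sweeps,
simulations to t = 35–45 at N = 256, boundary curves of a few hundred
points) were chosen as the smallest that exercise every code path at the
stated tolerances.

## Known limitations

- Region operations require |α₃| < 1; for |α₃| ≥ 1 only finite-window
  illustrations are possible (the limiting line arrangements are tested at
  |α₃| = 1 − 1e−5).
- `find_roots` is exhaustive only on its stated window; left of the
  imaginary axis the root chains continue beyond any finite im_max.
- The peak-based mode estimator needs ≥ 4 oscillation peaks and a
  separated dominant root; deep inside the stable region, where several
  modes decay at comparable rates, its frequency estimate degrades (the
  rate fit is more robust).
- The mapped stability boundary and the first-harmonic image share a θ
  asymptote as the response slope grows without bound; "strictly inside"
  statements about the instability region are made on the charted window.
- No continuation of periodic orbits past the Hopf boundary, and no
  treatment of the well-posedness theory of the neutral system; the
  simulator is validated against the linear predictions only.
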