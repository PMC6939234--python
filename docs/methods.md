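# Methods

`blanketmech` studies stochastic systems whose stationary density factors
across a *Markov blanket*: a set of states b = (s, a) (sensory and active)
that renders internal states μ and external states η conditionally
independent,

    p(η, μ | b) = p(η | b) p(μ | b).

The package provides an exactly solvable reference class — linear drift with
a Gaussian non-equilibrium steady state (NESS) — plus the machinery to
verify, numerically and symbolically, the claims one can make about such
systems: that internal dynamics implement variational inference, that the
blanket induces a dual information geometry, and that both connect to
path-level thermodynamics.

## The model class

A system is (Π, Q, Γ, partition):

- **Π** (units: state⁻²) — symmetric positive-definite precision of the
  zero-mean Gaussian NESS, with the blanket zero block Π[η, μ] = 0.
- **Q** — constant skew-symmetric solenoidal operator, block-diagonal over
  the coarse partition (η, b, μ), so the *rates of change* of internal and
  external states are also uncoupled. State-dependent Q is out of scope.
- **Γ** (units: state²·time⁻¹) — diagonal, strictly positive fluctuation
  amplitude; the Langevin noise has covariance 2Γδ(τ−t).

The drift is the Helmholtz-decomposed stationary flow
f(x) = (Q − Γ)∇ℑ(x) with surprise ℑ(x) = −ln p(x) = ½xᵀΠx + ½ln((2π)ⁿ/|Π|);
for this class f(x) = A x with A = (Q − Γ)Π. Stationarity is algebraic:

    A Π⁻¹ + Π⁻¹ Aᵀ + 2Γ = (Q − Γ) + (Qᵀ − Γ) = −2Γ + 2Γ = 0,

and A is automatically Hurwitz (its spectrum equals that of
Π^{1/2}(Q − Γ)Π^{1/2}, whose symmetric part is negative definite). The
surprise carries its full Gaussian normalization so free energies and KL
divergences are absolute; every identity we test is stated as a difference
in which the normalization cancels.

Nonlinear surprise functions are supported through a contract type
(surprise, gradient, optional Laplacian); the constructor verifies the
gradient against central finite differences at seeded random points
(tolerance 1e-5 relative). They are used by the simulator and the path
functionals only (gradient-descent case), not by the geometry or mechanics
layers, which rely on Gaussian conditioning.

## Strict validation and the synchronization map: a structural tension

Two validation levels exist. "Blanket" systems satisfy only Π[η, μ] = 0 —
the literal conditional-independence condition. "Strict" systems
additionally satisfy Π[a, η] = 0 and Π[s, μ] = 0, encoding the directed
reading of the blanket: active states are not influenced by external
states, sensory states not by internal states.

These two extra zero blocks have a consequence that is easy to miss: the
conditional mode maps become

    η(b) = −Π[η,η]⁻¹ Π[η,b] b   with zero *active* columns,
    μ(b) = −Π[μ,μ]⁻¹ Π[μ,b] b   with zero *sensory* columns,

so μ(b) depends only on a while η(b) depends only on s. The map b ↦ μ(b) is
then never injective when n_s, n_a ≥ 1, and no function σ with
σ(μ(b)) = η(b) can exist (the same obstruction reappears, merely rotated,
if strictness is instead imposed on the drift rows A[a, η] and A[s, μ] with
a blanket-wide Q block). `sync_map` therefore raises a rank error on
generic strict systems — this is asserted as a tested property, not
papered over — and all synchronization-dependent functionality (Laplace
beliefs, free-energy flows, relaxations) is exercised on blanket-level
systems, where K_μ is generically full rank. Strictness remains available
and is the right setting for the stationarity and conditional-independence
checks, where no σ is needed.

## Geometry

Conditional modes are conditional means (they coincide for Gaussians, and
positive-definite Π makes the maximum unique). Because Π[η, μ] = 0,
conditioning η on (s, a, μ) reduces to conditioning on b, so the
conditional precision of η|b is simply Π[η, η], constant in b.

The synchronization map is assembled from the affine mode maps:
σ = K_η K_μ⁺ with the Moore–Penrose pseudoinverse (cut-off 1e-10 on
relative singular values). On the mode manifold σ(μ(b)) = η(b) exactly;
off it, σ acts through the least-squares projection the pseudoinverse
implies — a documented contract, matching the use of pseudoinverses in the
flow construction below.

The Laplace belief of an internal state is q_μ(η) = N(σ(μ), Π[η,η]⁻¹). In
this linear-Gaussian class the Laplace construction is exact:
q_{μ(b)} = p(η|b) identically, which the tests assert at machine precision.

Fisher metrics are computed *numerically* as the central-difference Hessian
of KL[q_θ ‖ q_{θ+u}] at u = 0 (step 1e-4·(1+|θ_i|) per coordinate,
symmetrized after assembly); closed forms (inverse covariance for
fixed-covariance Gaussians, p(1−p) for the Bernoulli logit family) live in
the test suite as independent oracles. The two KL directions agree at zero
displacement within the finite-difference tolerance. Information length sums
√(dθ·g(θ_mid)·dθ) over path segments, subdividing until the total changes
by less than 1e-8. The parametrization λ of the density over internal
states is not canonically fixed by the theory; we use the mean
parametrization of p(μ|b) with frozen covariance, for which g_λ = Π[μ, μ].
The second metric pulls beliefs over η back through σ:
g_μ = J_σᵀ Π[η,η] J_σ.

## Mechanics

Variational free energy is computed by two independent routes and asserted
equal: F = ℑ(b) + KL[q_μ ‖ p(η|b)] (exact Gaussian KL), and
F = E_q[ℑ(η, b)] + E_q[ln q_μ(η)] via closed-form Gaussian expectations of
the quadratic joint surprise. F ≥ ℑ(b) always, with equality exactly at
μ = μ(b).

The internal-mode flow is μ̇ = −Γ_σσ ∇_μF with
Γ_σσ = J⁻ Γ[η,η] (J⁻)ᵀ, J = ∇_μσ. The symmetrized assembly (with the
transpose on the second factor) is required for Γ_σσ to be symmetric PSD
and hence for the flow to be a well-defined gradient flow; it reduces to
the scalar form in one dimension. The two gradient routes — chain rule
through the joint surprise, and the gradient of F — coincide exactly here
because the curvature terms of F are constant in μ; both are computed and
compared. The solenoidal-bearing intermediate (pushing the external flow
(Q_ηη − Γ_ηη)∇_ηℑ through J⁻) is kept as `internal_flow_via_external` for
the consistency check; it reproduces the direct flow when Q_ηη = 0 and J is
square invertible. The final flow retains only the Γ term.

Active states descend the same free energy:
ȧ = (Q_aa − Γ_aa)∇_a ℑ(σ(μ), b) = (Q_aa − Γ_aa)∇_a F(μ, b), with Q_aa the
active sub-block of the blanket Q block. Prediction errors are the
quadratic-form regrouping of the joint surprise: ε_η = σ(μ) − 0 against the
marginal precision of η, and ε_b = b − E[b | η = σ(μ)] against the
conditional precision of b — their weighted squares reassemble
ℑ(σ(μ), b) up to its constant.

Mode relaxation integrates the flow with explicit Euler after a stability
pre-check step < 2/λ_max(Γ_σσ H), H = JᵀΠ[η,η]J; for the quadratic F this
bound is exact and guarantees monotone non-increase of F, which is asserted
at every accepted step.

## Simulation

Euler–Maruyama with seeded `numpy` generators; trajectories are
byte-reproducible given (seed, dt, n_steps, x0). A divergence guard
(‖x‖_∞ > 1e6) reports the offending step — linear systems are Hurwitz, so
blow-up signals a mis-specified nonlinear surprise or an excessive step.
Ensembles draw initial conditions from the exact stationary density
(Cholesky of Π⁻¹); members carry seeds derived deterministically from
(seed, index). `ness_samples` integrates a large batch of short runs in
vectorized form and returns the i.i.d. endpoint samples used by the
conditional-independence test; for the default step (dt = 0.002, 250
steps) the analytic stationary covariance of the discrete scheme — the
solution of the corresponding discrete Lyapunov equation — retains the
blanket zero block exactly, so the test's z-scores are pure sampling noise.
Standard errors for pooled trajectory moments use the integrated
autocorrelation time with the initial-positive-sequence truncation;
precision-matrix checks on ensembles use member-wise estimates, whose
cross-member scatter gives honest errors despite serial correlation.

## Thermodynamics

Path functionals require isotropic (scalar) Γ — with a matrix Γ the 1/(4Γ)
and 1/Γ weights are ambiguous — and Γ is then read as k_BT for unit
conversions. Discretization is midpoint (Stratonovich) throughout:
forward-difference velocities, drift and divergence at segment midpoints.
Two exactness properties of this scheme are worth recording, because they
shape the tests:

1. action(reverse) − action(forward) = q/Γ holds *exactly* at the discrete
   level (the even terms share midpoints and cancel), for any system.
2. For quadratic surprise the midpoint sum Σ Δx·∇ℑ(x_mid) telescopes
   exactly, so q = −Γ·Δℑ to machine precision on any stored path of a
   linear gradient (Q = 0) system.

The genuine O(dt) behaviour of the second identity is therefore
demonstrated on a quartic-surprise gradient system, where halving dt on a
stored path shrinks the residual by ≈4 (the path is smooth, so the
midpoint rule is second order there); on stochastic paths the residual is
a random O(dt) quantity whose single-realization ratios fluctuate widely,
which is why the convergence assertion uses the deterministic path.

Time reversal is plain path reversal; Q is not flipped (no odd-parity
bookkeeping), so the reversal-asymmetry functional is the standard total
entropy production σ = q/Γ + Δℑ — for linear systems exactly
(1/Γ)ΣΔx·QΠx_mid, the housekeeping contribution of the circulation. The
fluctuation estimator averages g(S†)·e^{−σ} over a NESS-initialized
ensemble with jackknife standard errors and max-shifted exponentials; with
g ≡ 1 this targets the integral fluctuation theorem E[e^{−σ}] = 1. Path
probabilities include the initial-state surprise (fixed convention), which
is what makes σ the total — rather than merely the path-wise —
entropy production.

The free-energy/heat relation along a deterministic mode relaxation,
q = −Γ·ΔF = −Γ·Δℑ(σ(μ), b), holds exactly here because F and the joint
surprise differ by a constant in μ; both routes are computed independently
and compared.

### Expected free energy

The discrete model realizes the predictive "trajectory" at a single future
step: a steady-state joint table p(η, π) over finite outcome sets, a
predictive density q(π) and conditional beliefs q(η|π). By exact
enumeration:

    G        = E_q[ℑ(η, π) + ln q(η|π)],
    risk     = E_{q(π)} KL[q(η|π) ‖ p(η)],
    ambiguity = E_q H[p(π|η)],
    bound    = H[q(π)].

G ≥ H[q(π)] always (Gibbs' inequality), with equality when q matches the
steady state. The risk + ambiguity decomposition, however, is an identity
only when q(π|η) = p(π|η): the exact relation is
G = risk + E_{q(η)}[CE(q(π|η), p(π|η))], where CE is cross-entropy, and
the gap G − (risk + ambiguity) can take either sign for mismatched beliefs
(e.g. p(π|η) = (0.6, 0.4) against a degenerate q(π|η) gives a negative
gap). The package computes all terms, reports the gap, and asserts it is
exactly zero on matched constructions rather than claiming a sign in
general. Zero-probability cells follow the 0·ln 0 = 0 convention;
multi-step horizons are an extension point, not implemented.

## Synthetic fixtures

The affine-conditional dataset draws a scalar blanket state from a standard
normal and generates 2-D internal and external states from conditional
bivariate normals whose means are affine in b (defaults: slopes of order
one half) and whose covariances are modulated affinely through their
Cholesky factors (base factors ≈ 0.3·I, modulation ≈ 0.05 per unit b). A
literal affine map on the covariance itself loses positive definiteness at
finite |b|, so the modulation acts on the factor and each realized factor
is validated (diagonal > 1e-6, i.e. the family has not degenerated); with
the default parameters a violation requires |b| ≈ 6, a ~1e-9 event per
sample. The conditional-mean pairs lie on a 1-D affine manifold —
the statistical-manifold picture the construction is meant to make visible
— which the tests verify by an affine fit with residual below 1e-8.

Random systems are drawn project-then-repair: a Wishart-style precision has
its forbidden blocks zeroed, then ridge is added until the smallest
eigenvalue clears 0.05; Q is random skew within each coarse block and Γ
random in [0.5, 1.5] (optionally isotropic). Every draw passes the public
validator, which a 100-seed sweep asserts for both validation levels.

## Problem sizes and tolerances in the verification suites

The shipped suites use dimensions (2, 1, 1, 2) (6 states) for system-level
checks; 100 systems for stationarity; 10 systems × 100 blanket draws for
synchronization; 10⁵ endpoint samples for conditional independence
(z-threshold 3); 10⁴ paths of 1000 steps at dt = 1e-3 for the fluctuation
theorem (Q = 0.6 circulation, ≈17 s total for the full battery on one
core); 50 random tables for the expected-free-energy enumeration.
Machine-precision identities are asserted at 1e-10, finite-difference
comparisons at 1e-6 (gradients) and 1e-4 relative (Hessians), Monte-Carlo
statements at 3 standard errors. The Monte-Carlo suites carry the
irreducible false-alarm rate of a 3-SE test (≈1% over the handful of
entries examined).

## What the fixtures do and do not show

All quantitative claims are verified in the linear-Gaussian class, where
Laplace is exact, mode flows are exactly gradient flows and the heat
identities close exactly. Passing tests therefore demonstrate internal
consistency of the formalism and correctness of the implementation — not
that any empirical system satisfies these conditions. For nonlinear
surprise the mode-flow/population-dynamics correspondence is approximate
and is not asserted; only the simulator and path functionals accept
nonlinear systems. Degenerate (rank-deficient) precisions, state-dependent
Q or Γ, anisotropic-Γ thermodynamics and multi-step predictive horizons
are out of scope.
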