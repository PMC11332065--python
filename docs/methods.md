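# Methods

This note documents the model this package implements, the numerical
choices behind the solver, what the synthetic decision processes do and
do not emulate, and the design decisions taken where the problem was
genuinely open.

## The control problem

A two-alternative decision maker holds Gaussian value beliefs
N(μᵢ(t), σᵢ(t)).  Investing `z = κ·t` resources increases belief
precision linearly (`1/σᵢ = 1/σᵢ⁰ + βz`) and perturbs the belief modes
with variance `γz`.  Confidence is mapped from the belief moments by

    P_c(Δμ, σ₁, σ₂) = s(π·|Δμ| / √(3(σ₁+σ₂))),

the variance-matched logistic approximation to the Gaussian CDF
Φ(|Δμ|/√(σ₁+σ₂)).  The controller maximizes `R·P_c − α·zᵛ`, realized at
the moment it stops.

**Parameters.**  All in utility units unless noted.

| symbol | meaning | default | notes |
|---|---|---|---|
| R | decision importance (weight on confidence) | 1 | trades exactly against α |
| α | unitary effort cost | 0.2 | cost of spending the full budget |
| ν | cost power (dimensionless) | 0.5 | ν>1 makes late effort comparatively costly |
| β | type-1 efficacy (precision / resource) | 1 | |
| γ | type-2 efficacy (mode variance / resource) | 4 | γ=0 freezes the mode difference |
| κ | effort intensity (resource / step) | 1/100 | horizon T = round(1/κ) |
| μ⁰, σ⁰ | prior belief moments per option | 0, 1 | |

The defaults are the canonical regime used throughout the simulation
studies.

## Approximations in the forecast (and their true accuracy)

Two closed-form approximations propagate through every prospective
quantity:

1. **Sigmoid ↔ Gaussian CDF.**  sup|s(πx/√3) − Φ(x)| = 0.0227, attained
   near x ≈ 0.68.  Confidence values are therefore accurate to ±0.023.
2. **Folded-normal mean.**  The anticipated absolute mode gap
   E|Δμ(z)| uses the folded-normal mean with the sigmoid substituted
   for Φ.  The substitution contributes an error up to
   ≈ 2·0.023·|Δμ⁰|; it vanishes for symmetric priors (Δμ⁰ = 0).  A side
   effect is that the *approximate* forecast can dip slightly below
   |Δμ⁰| at small z (the exact folded mean never does), and expected
   confidence can dip below the prior by a comparable amount for
   strongly asymmetric priors.

The expected-confidence forecast treats the confidence argument
x = πλ|Δμ|, λ = 1/√(3(σ₁(z)+σ₂(z))), as Gaussian with the forecast
moments and applies E[s(x)] ≈ s(E[x]/√(1 + ½·Var[x]^¾)).  The π factor
enters both the mean and the variance term; this reproduces the
current-confidence mapping exactly at z = 0 and agrees with a 10⁶-draw
Monte-Carlo average within 0.01 (the variance-power denominator is used
as a fitted heuristic; it is not derived from first principles).

## The stopping solver

* **State.**  Δμ discretized on a uniform symmetric grid centered on
  Δμ⁰, spanning ±6·√(2γκT) (513 points by default).  The span keeps the
  mass escaping the grid below 10⁻⁶; γ = 0 degenerates to a single
  deterministic state.
* **Kernel.**  Row i of the transition matrix integrates
  N(gridᵢ, 2γκ) over grid cells (outer cells absorb the tails), built
  from one CDF vector via the Toeplitz structure of a uniform grid.
  Cell integration is exact even when the step sd is below the cell
  width (a warning suggests a finer grid); rows are renormalized to
  sum to 1 within 10⁻¹⁰.
* **Recursion.**  Stop value S(x,t) = benefit(x,t) − α(κt)ᵛ;
  continuation value C(x,t) is a deterministic matrix–vector
  expectation of the optimal value one step ahead; stopping is forced
  at T; ties stop.  Benefits are pluggable: `R·P_c` (the standard
  controller, with an overridable variance schedule for ideal
  controllers) or `R·E[chosen value] = R(μ̄⁰ + |Δμ|/2)` (the
  `max(value)` variant, insensitive to β).
* **Thresholds.**  The critical Δμ*(t) is found by linear interpolation
  of the sign change of S − C along |Δμ|; no sign change is flagged
  explicitly (`continue_everywhere` / `stop_everywhere`) rather than
  extrapolated, and multiple crossings — never observed for α>0, γ>0 —
  would be flagged, not hidden.  ω*(t) evaluates the benefit at the
  interpolated critical point; ω*_P(t) = (ω*(t)+α(κt)ᵛ)/R is computed
  as benefit/R directly so the terminal value is exactly ½.  Threshold
  extraction assumes symmetric priors (Δμ⁰ = 0), which holds in every
  shipped study; the underlying state-wise rule is general.
* **Convergence.**  Doubling the grid from 513 to 1025 points moves the
  confidence threshold by < 10⁻³ (sup norm) at the default parameters.

Stop rules threshold confidence at integer steps (no interpolation in
t).  Thresholding the net benefit against ω* and confidence against
ω*_P are algebraically identical; both forms are exported
(JSON, full float precision, bit-exact round trip).

## Synthetic decision processes

The generators *are* the study conditions; their defaults are the
canonical regimes of the simulation studies.

* **Generic** — the controller's own working model: zero-drift Gaussian
  random walk on the modes (step variance γκ per option), deterministic
  precision growth.  No ground-truth value exists, so
  choice-consistency statistics are undefined here.
* **Bayesian value denoising** — hidden values V ~ N(μ₀, σ₀) emit noisy
  signals y(t) = V + ε, ε ~ N(0, Σ); beliefs are the exact Bayesian
  posterior.  Calibration: β = 1/(κΣ) (exact), γ = the time-average of
  E[δ̃(t)²]/(κt) (an approximation: the true mode-change rate decays
  with t, so the process is *not* stationary — precisely the model
  misspecification the framework claims robustness to).  Defaults:
  σ₀ = 10, Σ = 100, κ = 1/100 with costs R=1, α=0.1, ν=2.
* **Progressive attribute integration** — option value is Σ wₖxₖ,
  xₖ ~ N(ηₖ, ςₖ) per option; one uniformly random disclosure order per
  trial (shared by both options) reveals one attribute per step, so
  κ = 1/k and σ(T) = 0 exactly.  Calibration: γ = σ₀ = Σ wₖ²ςₖ (exact;
  the permutation-averaged squared mode change is (t/k)·σ₀ = γz),
  β = the harmonic-mean precision-growth rate over t = 1..k−1 (the
  horizon is excluded: full disclosure has infinite precision).
  Defaults: k = 20, η = ς = w = 1 with costs R=1, α=3, ν=4.

Calibration quality: the agnostic forecast tracks the simulated mean
confidence of the true processes with opposite-signed errors early and
late in the trial — sup error ≈ 0.07, mean ≈ 0.02 under the default
regimes.  Passing tests therefore show the controller is *robustly
close* to, not identical with, the true-process statistics.

What the generators do **not** emulate: cross-option correlations
(options are simulated independently), non-stationary effort intensity,
trial-to-trial learning of efficacies, lapses/attention effects, and
any empirical response-time noise — so agreement with these simulations
does not by itself establish agreement with behavioral data.

## Ideal policies

* **Denoising**: the true Δμ transition kernel is time-varying Gaussian
  with step variance 2(σ(t−1)−σ(t)) (the martingale increments of the
  posterior mean; they telescope to 2(σ₀−σ(T))).  The ideal rule is the
  same backward induction under this kernel; the variance schedule
  needs no correction because β = 1/(κΣ) reproduces it exactly.
* **Attributes**: the sufficient state is (disclosed attribute set,
  Δμ): conditional on the set, the remaining variance is known and the
  next disclosure is uniform over the complement.  Exact backward
  induction over attribute subsets (bitmasks; k ≤ 16 enforced —
  2ᵏ states) yields one critical |Δμ| per subset.  With homogeneous
  attributes the subset matters only through its size and the rule
  provably collapses onto a one-dimensional time-indexed threshold;
  this collapse is verified exactly in the tests.

## Experiment harness

Policies under comparison always share trajectories (paired
comparison), which removes between-path Monte-Carlo variance from
policy contrasts.  Random-setting sweeps draw α, β, γ log-uniformly
(α ∈ [0.05, 1], β, γ ∈ [0.5, 8]) and ν uniformly in [0.25, 2] with
R = 1 and κ = 1/100 fixed (R is redundant with α); the ranges are
package defaults, documented and overridable.  The difficulty sweep
varies β ∈ {2..8} with every other decision parameter — including the
prior variance — at 4 (κ stays 1/100, μ⁰ = 0).  "High/low-confidence"
trials split at the median confidence at stopping.  Logistic
choice-vs-value regressions use iteratively reweighted least squares;
under (quasi-)separation the slope is capped at ±50 and flagged.  No
multiple-testing correction is applied: the signature statistics are
qualitative sign checks, not inferential claims.

## Known limitations

* Continuous-time and infinite-horizon formulations are out of scope;
  the solver is strictly finite-horizon with integer steps.
* The heterogeneous-attribute ideal policy is exponential in k
  (rejected above k = 16).
* The sigmoid-based approximations bound achievable accuracy at the
  levels quantified above; in particular sub-0.02 agreement with exact
  Gaussian quantities is not attainable by construction.
* Fitting the controller's parameters to empirical data (likelihoods
  for response times or confidence reports) is deliberately not
  provided.
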