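# Methods

## Observer models

Both observers act on a scalar decision variable *D* = *E* + *I*. On
signal-A trials *E* ~ N(0, σ_E²); on signal-B trials *E* ~ N(μ_E, σ_E²);
*I* ~ N(0, σ_I²) independently, redrawn on every presentation. Signals are
equiprobable. Two derived quantities parameterize everything:
d′_D = μ_E/√(σ_E² + σ_I²) (signal-to-noise ratio of *D*) and ρ = σ_I/σ_E
(internal-to-external noise ratio). With equal priors the posterior is a
logistic in *d*:

    P(A|d) = expit(−μ_E (d − μ_E/2) / (σ_E² + σ_I²)).

The VPPM rule responds A with probability P(A|d); the MAP rule responds A
iff *d* ≤ μ_E/2. The criterion comparison, rather than a posterior
comparison, is used in code because it extends continuously to μ_E = 0,
where the posterior is flat at 0.5 but the criterion rule still produces
the perfectly-repeatable behaviour the closed forms describe. The
measure-zero tie *d* = μ_E/2 responds A. Responses are coded A↔0, B↔1
wherever an integer coding is needed.

In a two-pass pair the external sample is drawn once and shared; internal
samples are fresh on each pass. Signals are assigned by a fair Bernoulli
draw per pair, not forced balance.

## Closed-form two-pass probabilities

Working in units of the total SD of *D*, write f(u) = expit(−d′(u − d′/2))
for the posterior of the correct response on a signal-A trial. For the
matching observer

    p_C  = E[f(U)],  U ~ N(0,1)
    p_CC = E_u[ m(u)² ],  p_II = E_u[ (1 − m(u))² ],  m(u) = E_v[ f(u+v) ]

with u the shared (external) part, SD 1/√(1+ρ²), and v the internal part,
SD 1/√(1+ρ⁻²). p_A = p_CC + p_II. Default evaluation is nested adaptive
quadrature (scipy `quad`, absolute tolerance 1e-10, integrals truncated at
±10 effective SDs of each Gaussian weight); a tensor Gauss–Hermite grid
(201 nodes per axis) is available as `method="tensor"`. The test suite
gates numerical stability: doubling the truncation range and halving the
tolerance must move results by < 1e-6.

For the unbiased MAP observer p_C = Φ(d′/2), and the two passes form a
bivariate normal pair with correlation c = 1/(1+ρ²), so

    p_CC = Φ₂(d′/2, d′/2; c),   p_II = Φ₂(−d′/2, −d′/2; c),

evaluated exactly via Owen's T (Φ₂(h,h;c) = Φ(h) − 2·T(h, √((1−c)/(1+c)))).
The equivalent single-integral quadrature forms are retained as
`method="quad"` and agree with the closed form to ~1e-9 in the tests;
the closed form is the default because it is exact, vectorizes, and makes
the bootstrap fast.

Limits: ρ below 1e-6 or above 1e6 is routed to the analytic ρ→0 / ρ→∞
expressions to avoid overflow in the (1+ρ⁻²) terms. ρ→0 gives p_A = 1 for
MAP and the degenerate-inner-integral form for the matcher; ρ→∞ gives
independent passes, p_A = p_C² + (1−p_C)².

## Apparent-noise inversion

Observed (p̂_C, p̂_A) are inverted by minimizing
(p̂_C − p_C(d′,ρ))² + (p̂_A − p_A(d′,ρ))² against the MAP closed forms.
Implementation: a cached coarse grid (d′ on [0,6] in 61 steps; ρ = 0 plus
60 log-spaced values on [0.05, 20]; ties broken toward the smallest ρ)
seeds a bounded Nelder–Mead refinement (xatol 1e-9). On the feasible
interior the residual is ~0 (two equations, two unknowns) and the
round-trip identity holds to better than 1e-3 over d′ ∈ [0, 2.6] ×
ρ ∈ {0, 1, 2}.

Feasibility: independent passes at accuracy p agree with probability
p² + (1−p)², so inputs below that parabola admit no finite ρ; they are
reported as ρ̃ = +∞ with `feasible=False` (serialized as the literal
"inf"). Inputs on the parabola — including chance performance with chance
agreement, (0.5, 0.5) — are feasible boundary cases with ρ̃ = +∞. Inputs
with p̂_C < 0.5 are reflected to 1 − p̂_C with a warning (unbiased-observer
assumption); d′ is never extrapolated below 0.

The bootstrap resamples n_correct ~ Bin(n_trials, p̂_C) and
n_consistent ~ Bin(n_pairs, p̂_A) independently (their joint structure is
not modelled; see Limitations), 10,000 replicates by default, and reports
percentile 2.5/97.5 bounds computed as order statistics so that infinite
replicates sort to the upper end without arithmetic on infinities.
Replicates are inverted by a vectorized profile solve — d′ = 2Φ⁻¹(p̂_C)
exactly, then monotone bisection in the pass correlation c — which is
equivalent to the full minimization on the feasible region and ~10³×
faster. Estimates whose upper 95% bound exceeds twice the point estimate
are flagged `discarded`; infinite estimates are always discarded.

## Efficiency

Efficiency is η = (d′/d′_ideal)². The matcher is analyzed in its best case
(σ_I = 0, decision variable carries all task information), so
d′_ideal = d′_D and its apparent sensitivity is 2Φ⁻¹(p_C) with p_C from the
performance integral. `vppm_efficiency_at_pc` root-solves the monotone
performance integral by Brent's method on d′ ∈ [1e-4, 12] (unique root;
residual < 1e-6 enforced). Efficiency is carried as a fraction; the
presentation layer converts to percent. Note that the computed best-case
efficiency at 75% correct is 53.5%, commonly quoted rounded as "around
50%".

## Synthetic experiments

The generator works at the decision-variable level; no stimulus rendering.
Contrast maps to sensitivity by linear transduction d′_D(c) = k·c with
σ_E = 1 and gain k = 1 by default — the minimal bridge between a
staircased signal magnitude and the decision-variable model.

**Staircase.** 1-up 2-down: one step up after each error, one step down
after two consecutive correct responses; asymptote at p = 1/√2 ≈ 70.7%
correct. Steps are multiplicative with default factor 10^0.1 (2 dB),
starting at the contrast giving d′ = 2. The step size is config-exposed:
the emulated protocols specify only the convergence target, and 2 dB steps
make the pooled long design concentrate ≥100 repeated pairs on 4–6
contrast levels, the structure those protocols report. Contrast is tracked
as an integer index on the step ladder so revisited levels are
bit-identical (exact per-level pooling).

**Long design (exp1).** 33 blocks × 300 trials. Trials 1–150 staircased;
trials 151–200 replay trials 101–150 verbatim (same signal, contrast and
external sample; fresh internal noise; staircase frozen); trials 201–300
resume the staircase, whose state carries across blocks. Yields 9,900
trials and 1,650 repeated pairs per session.

**Short design (exp2).** 100 staircased trials; a Weibull psychometric
function p(c) = 0.5 + 0.5(1 − exp(−(c/α)^β)) (guess 0.5, no lapse) is fit
to them by maximizing the Bernoulli likelihood over log-parameterized
(α, β) with Nelder–Mead; the fit is bounded (log α within ±2 nats of the
observed contrast range, β ∈ [0.2, 32]) because staircase-concentrated
data leave the slope weakly identified and the unbounded ML fit can
diverge toward β → 0. The fitted function is inverted for the 65%- and
80%-correct contrasts, and trials 101–500 use those two contrasts in
random order (uniform draw per trial), organized as four 100-trial
two-pass blocks (second 50 trials replay the first 50): 500 trials, 200
pairs, ~100 per level.

## Statistical pipeline

Per-contrast pooling counts agreement over pairs and correctness over the
two-pass trials at that level by default; a switch pools unrepeated
staircase trials at the same contrast into the correctness denominator.
Long-design analysis regresses ρ̃ on p̂_C by unweighted OLS across retained
conditions; slope CIs come from re-estimating parametrically resampled
counts (10,000 replicates; pair-resampling available by flag). Short-design
analysis forms each observer's ρ̃_low/ρ̃_high and compares it with the
ratio predicted by the matching model's apparent-noise curve at the
observer's own two performance levels; observers with an infinite ρ̃ are
excluded. Sign tests are exact binomial, one-sided in the predicted
direction by default (configurable). Plot exports clip ratios at 4.0 for
visibility; statistics always use unclipped values.

## Problem sizes and checks in the test suite

Monte-Carlo/closed-form agreement is checked at 10⁵ pairs per cell over
d′ ∈ {0, 0.65, 1.3, 2.6} × ρ ∈ {0, 1, 2} within 3 binomial SEs (SE bounded
by √(0.25/n)). Cohort-level end-to-end checks run 21 synthetic
short-design observers per cohort with 2,000-replicate bootstraps: a
noiseless matching cohort must reject constant ρ (one-sided Wilcoxon
signed-rank on log(ρ̃_low/ρ̃_high), chosen over per-observer sign flags for
power at 100 pairs/level), and a MAP cohort must fall mostly below the
matching prediction. The staircase target is checked over 10⁴ post-burn-in
trials.

## What the generator does and does not emulate

It reproduces the trial logistics that make the analyses well-posed:
staircase adaptation, verbatim replay with fresh internal noise, threshold
selection, block structure and sample sizes. It does not model stimulus
rendering, spatial uncertainty, lapses, learning, fatigue, or response
bias — human data can violate the unbiased, stationary,
additive-Gaussian-noise assumptions in ways these synthetic observers
cannot. Passing cohort tests therefore validates the pipeline's inferential
machinery, not the empirical claim about human observers.

## Known limitations

- The inversion assumes an unbiased observer with stationary additive
  Gaussian internal noise; it is the definition of the apparent ratio, not
  a fit of alternative noise models.
- Bootstrap resampling of correct and consistent counts is independent,
  which ignores their (positive) sampling covariance and is mildly
  conservative for CI width.
- Near the feasibility parabola the objective flattens in ρ, so ρ̃
  estimates just above the boundary have very wide CIs; the discard rule
  exists precisely to flag these.
- The exact one-sided binomial p for 17 successes in 21 is 0.0036;
  stricter published bounds for that configuration are not reproduced by
  a standard exact sign test.
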