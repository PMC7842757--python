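# Methods

## Task and stimulus model

Each block has `n_trials` trials (default 220, the block length the
analyses assume).  Stimuli live in natural-log frequency units relative to
the 1 kHz median: `s_i = ln(f_i / 1000)`.  A trial is parameterised by the
pair mean `m = (s1 + s2)/2` and half-difference `d = (s1 − s2)/2`; the
generator draws `m ~ U(−0.2, 0.2)` and, on possible trials,
`d ~ U(−0.0905, 0.0905)`, giving a uniform parallelogram of pairs in the
log f1 × log f2 plane.  Exactly 25% of trials are impossible (`d = 0`,
f1 = f2 bit-identically), at uniformly shuffled positions.  We fix the
impossible count exactly rather than Bernoulli-sampling per trial so block
composition is deterministic and testable.  Impossible-trial means within
5·10⁻⁷ of 0 are redrawn so "below/above 1 kHz" is always defined; the
excluded interval is negligible (width 10⁻⁶ of a 0.4-wide range).

Feedback on possible trials is always veridical.  On impossible trials the
rewarded response is pre-drawn per protocol from the side-dependent
probability that "f1 > f2" is correct: control (0.5, 0.5), enhance/suppress
"f1 > f2" (0.9, 0.9)/(0.1, 0.1), enhance/suppress contraction
(0.9, 0.1)/(0.1, 0.9), where the pair denotes (below, above) the median.

The exclusion screen mirrors a chance-performance criterion: within each
half of the block (110 trials by default), correct responses among the
*possible* trials are tested against 0.5 with an exact two-sided binomial
test; a block is kept only if both halves reject at α = 0.05.  Two-sided
testing is the deliberate choice: at 82 possible trials per half it yields
a minimal passing count of 51/82 ≈ 62%, whereas a one-sided test would
pass at a lower count.

## The Perceptron observer

Internal representations are `r1 = s1 + n` with `n ~ N(0, σ²)` and
`r2 = s2`: all noise is loaded on the remembered first tone.  The response
is `A = Θ(a·r1 − r2 − b)`.  Θ(0) is undefined in the usual step-function
convention; we resolve ties to `A = 0`, a measure-zero event whenever
σ > 0, so that simulation and probability calculations are deterministic.
The choice probability is

    P(A = 1 | s1, s2) = Φ((a·s1 − s2 − b) / (|a|·σ)),

degenerating to the step value when σ = 0 or a = 0.  Noise on the second
stimulus is not modelled; the decision rule extends directly (the decision
variable stays Gaussian) and the extension point is `_prob_one`, but the
asymmetric form is the model under study.

Bayesian shrinkage motivates `a < 1`: with prior `s1 ~ N(0, Σ²)` the
posterior mean of s1 given r1 is `r1 / (1 + σ²/Σ²)` with variance
`(1/σ² + 1/Σ²)⁻¹`, so comparing the posterior mean with s2 is a Perceptron
with `a = 1/(1 + σ²/Σ²)`, `b = 0`.  The task's actual s1 marginal is a
uniform–uniform convolution, not Gaussian; the Gaussian closed form is
kept as an analytic oracle (its Σ², when compared against task-matched
quantities, is the computed marginal variance 0.2²/3 + 0.0905²/3), while
all protocol optima are found numerically under the true task
distribution.

## Expected reward and its optimisation

The expected feedback rate of an (a, b, σ) observer is
`0.75·E_possible[P(correct)] + 0.25·E_impossible[P(rewarded)]`.  Both
expectations are evaluated **exactly**: the double integral of a normal
CDF over a rectangle has a closed form via the iterated antiderivatives
G1(u) = uΦ(u) + φ(u) and G2(u) = ((u² + 1)Φ(u) + uφ(u))/2, applied
separately on the d > 0 and d < 0 halves (where the veridically correct
response flips) and on the m < 0 and m > 0 halves of impossible trials
(where the reward contingency flips).  This is preferred over fixed-order
quadrature because it is cheaper and keeps full accuracy as σ → 0, where
the integrand approaches a step.  At σ = 0 exactly, the response is a step
function and the integral is computed exactly in m (interval clipping) with
a 2000-point midpoint rule per half-range of d (the remaining integrand is
piecewise linear; the rule resolves reward differences of order 10⁻⁴
between candidate weights near a = 1).  A seeded Monte-Carlo estimator
cross-checks the analytic values in the tests.

`optimize_params` maximises expected reward over a ∈ [−0.5, 2],
b ∈ [−0.3, 0.3] with a deterministic coarse-to-fine search: a 25×25 grid
per stage, re-centred on the maximiser with a box of 3 grid steps, until
both box widths fall below 10⁻³.  There is no randomness, so optima are
bit-reproducible.  Negative a stays inside the box because
bias-suppressing feedback pushes a* above 1 and hypothetical protocols
could push it below 0.  Under the control protocol the reward surface is
exactly symmetric in b (the analytic integrals preserve the task's
symmetry), so the returned b* is 0 to machine precision.

Quadrant accuracies (the f1 × f2 plane split at 1 kHz) use a 400×400
midpoint grid; in the straddling quadrants the a = b = 0 observer is
correct with probability exactly 1 at every grid node, so the reported
100% is exact, not a sampling statement.

## Synthetic observers

Static observers apply fixed (a, b, σ) per trial.  Criterion-adaptive
observers update after every trial,

    b ← b − η·(2·feedback − 1)·(2·response − 1),

so a rewarded response lowers (raises) the criterion when the response was
"f1 > f2" ("f1 < f2"), making rewarded responses more likely.  This
delta rule is deliberately the simplest reward-following criterion
learner — it is pipeline machinery for generating realistic choice-bias
dynamics, not part of the optimality analysis, and the contraction weight
a never adapts (that fixed-weight assumption is exactly the hypothesis the
bias analyses probe).  The default η = 0.02 log-units per trial produces
clear divergence between opposing choice-bias protocols within tens of
trials while keeping criterion drift under unbiased feedback modest; under
symmetric feedback the rule has zero expected drift.

Cohorts draw per-observer σ from a configurable distribution; the default
stand-in for an unavailable empirical population is log-normal with median
0.08 log-units and log-SD 0.5, spanning roughly 0.03–0.2.  Per-observer
block and noise seeds derive from `SeedSequence((master_seed, index))` and
are recorded in a ground-truth manifest for recovery tests.

What the generator does *not* emulate: lapses and attention drift,
learning of the weight a, sequential dependencies beyond the criterion
rule, audio-level effects, and any empirical σ distribution.  Passing
tests therefore establish internal consistency of the method — parameter
and model recovery under the model's own assumptions, and the direction of
protocol effects — not claims about any particular human data set.

## Model fitting

Both candidate models are one-parameter Bernoulli choice models in σ.
The psychometric model fixes (a, b) = (1, 0); the optimal-Perceptron model
sets (a, b) to the protocol-specific optimum for each candidate σ.  For
fitting, (a*, b*)(σ) is precomputed on the 201-point log-spaced search
grid σ ∈ [10⁻³, 1] and linearly interpolated in log σ during refinement;
a* varies smoothly, so interpolation error is far below the likelihood's
resolution.  The likelihood includes impossible trials (they contribute
log 0.5 under the psychometric model but carry contraction information
under the Perceptron); a flag restricts to possible trials.  Probabilities
are clipped to [10⁻⁹, 1 − 10⁻⁹] to keep deterministic predictions finite.
The σ estimate is the grid maximiser refined by bounded scalar
minimisation between its neighbours; boundary maximisers (e.g. effectively
noiseless data) and all-identical-response blocks are flagged
non-converged.  Model comparison reports ΔLL per trial per observer and an
exact two-sided sign test over observers, with ties given half weight in
the favouring fraction and dropped from the test.

## Bias analyses

Frequency regions are terciles of the design range of m
(boundary ±0.2/3); the source figures define regions only graphically, so
terciles are a declared convention.  Psychometric curves use possible
trials only, 9 equal-width Δ bins over ±0.181, and cross-observer
averaging of per-observer proportions with cross-observer SEM — never
trial pooling.  Curve evaluation "at f1 = f2" uses a two-parameter
cumulative-normal ML fit (deterministic grid + refinement, like the σ
fits); degenerate all-0/all-1 data are flagged and fall back to the
empirical proportion.  Contraction magnitude is the region-I minus
region-III fitted value at Δ = 0, cross-validated by the same contrast
computed from the non-overlapping impossible trials.  Choice-bias time
courses average impossible-trial response rates in windows of 20 trials
(11 points per 220-trial block).

Group differences use the one-sided Wilcoxon rank-sum test: exact by full
enumeration of rank assignments (with midranks, so ties are handled
exactly) for group sizes up to 10, and the tie-corrected normal
approximation above that; the exact path serves as the oracle for the
approximate path in the tests.  For the five-protocol
feedback-insensitivity check of fixed-weight cohorts, the test suite
asserts the key bias+ vs bias− contrast (one-sided rank-sum, n = 34 per
group) plus a bound on the spread of group means, rather than ten pairwise
tests whose family-wise false-alarm rate under the very null being
asserted would approach 40%.

## Problem sizes and reproducibility

Simulated checks use 220-trial blocks and cohorts of 20–40 observers
(34 per group for the protocol-insensitivity check), with 10 000–20 000
trial draws for distributional checks — sizes at which every targeted
effect is separated from its standard error by a comfortable factor while
the whole suite runs in about a minute.  All randomness flows through
numpy `SeedSequence`s derived from explicit seeds; repeated runs are
bit-identical, and `scripts/acceptance.py --seed N` threads its seed
through every stochastic input.

## Known limitations

* The optimal-Perceptron fit interpolates (a*, b*) between grid σ values;
  exact per-call optimisation is available through `optimize_params`.
* The exact rank-sum path is combinatorial and restricted to groups of
  ≤ 10; larger groups rely on the asymptotic approximation, which degrades
  (|Δp| up to ~0.06 in adversarially tie-heavy 5-vs-5 samples) though it
  stays within 0.02 for continuous data.
* `fit_sigmoid` assumes a symmetric cumulative normal without lapse rate;
  strongly asymmetric or lapse-contaminated data will bias its midpoint.
* The criterion delta rule is one of many plausible learners; conclusions
  drawn from adaptive cohorts are directional, not quantitative.
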