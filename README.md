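# tonebias

Ideal-observer (Perceptron) modelling of **contraction bias** and **choice
bias** in two-tone delayed frequency discrimination, with a full synthetic
pipeline: block generation with protocol-controlled feedback, simulated
observer cohorts, maximum-likelihood model fitting, and the bias analyses
that dissociate feedback-sensitive from feedback-insensitive biases.

## The problem

In a delayed comparison trial an observer hears two pure tones, f1 then f2,
and reports which had the higher pitch.  Two biases shape behaviour beyond
sensory resolution:

* **choice bias** — a stationary preference for one response (a lateral
  shift of the psychometric curve);
* **contraction bias** — the remembered first tone is pulled toward the
  centre of the stimulus distribution, so responses depend on *where* the
  pair sits relative to the 1 kHz median, not only on the frequency
  difference.

Both map onto the two parameters of a linear discriminator acting on noisy
internal representations.  With stimuli in natural-log units relative to
1 kHz (`s_i = ln(f_i / 1000)`):

```
r1 = s1 + n,  n ~ N(0, σ²)        (the remembered tone is noisy)
r2 = s2                            (the just-heard tone is not)
A  = Θ(a·r1 − r2 − b)              (report "f1 > f2" iff A = 1)
```

The weight `a` sets the slope of the indifference line in the
log f1 × log f2 plane — `a < 1` *is* contraction bias — and the criterion
`b` sets its offset — choice bias.  Bayesian shrinkage of the noisy `r1`
toward the prior mean makes underweighting rational: for a Gaussian prior
`s1 ~ N(0, Σ²)` the accuracy-maximising weight is `a = 1/(1 + σ²/Σ²)`,
which equals 1 only at σ = 0.  The *optimal Perceptron* for a given noise
level σ and feedback protocol is the (a, b) pair maximising the expected
"correct" feedback rate under the task's stimulus statistics; it is a
one-parameter model of behaviour, directly comparable to the classical
one-parameter psychometric curve (`a = 1, b = 0`).

Blocks contain 220 trials: 75% "possible" trials (pair mean uniform on
±0.2, half-difference uniform on ±0.0905 log-units, veridical feedback)
and 25% "impossible" trials (f1 = f2) on which feedback follows one of
five protocols (unbiased; enhance/suppress the "f1 > f2" response;
enhance/suppress contraction-congruent responses).  Synthetic observers —
static, or with a reward-following delta rule on the criterion b — stand
in for a human cohort, so every analysis runs offline at desk scale.

## Worked example

```python
from tonebias import (generate_block, simulate_static_observer, ObserverSpec,
                      PerceptronParams, fit_sigma, optimize_params,
                      contraction_magnitude)

opt = optimize_params(sigma=0.1, protocol="control")
print(f"optimal Perceptron at sigma=0.10: a*={opt.a:.3f}, b*={opt.b:.3f}, "
      f"expected reward={opt.expected_reward:.3f}")

block = generate_block("control", n_trials=220, seed=1)
observer = ObserverSpec("static", PerceptronParams(a=opt.a, b=opt.b, sigma=0.1), seed=2)
log = simulate_static_observer(observer, block)

fit_p = fit_sigma("optimal_perceptron", log)
fit_c = fit_sigma("psychometric", log)
print(f"ML noise estimate, Perceptron model:   sigma_hat={fit_p.sigma_hat:.3f}  logL={fit_p.loglik:.1f}")
print(f"ML noise estimate, psychometric model: sigma_hat={fit_c.sigma_hat:.3f}  logL={fit_c.loglik:.1f}")
print(f"delta LL per trial (Perceptron - psychometric): {(fit_p.loglik - fit_c.loglik)/220:+.4f}")

bias = contraction_magnitude([log])
print(f"contraction magnitude (region I vs III at f1=f2): {bias.contraction_magnitude:.3f}")
```

Output:

```
optimal Perceptron at sigma=0.10: a*=0.737, b*=0.000, expected reward=0.727
ML noise estimate, Perceptron model:   sigma_hat=0.094  logL=-104.7
ML noise estimate, psychometric model: sigma_hat=0.092  logL=-111.5
delta LL per trial (Perceptron - psychometric): +0.0308
contraction magnitude (region I vs III at f1=f2): 0.416
```

Reading the numbers: under unbiased feedback the reward-maximising
criterion is b* = 0 while the optimal weight at σ = 0.1 drops to
a* ≈ 0.74, i.e. the optimal observer *should* show contraction bias.  The
simulated observer's noise level is recovered near its true value of 0.10
by both models, but the Perceptron model fits the same 220 choices better
(positive ΔLL per trial) because it also captures the contraction bias —
the ~0.42 gap between the low- and high-frequency psychometric curves at
f1 = f2.

A full simulate → fit → analyze → report run (all five feedback protocols,
trial logs, fit tables, bias tables, figures and a JSON summary):

```
tonebias run --seed 0 --n-observers 12 --out runs/demo
```

## Layout

```
src/tonebias/
  protocols.py    stimulus blocks, feedback protocols, exclusion screen, CSV IO
  perceptron.py   the model: decisions, response probabilities, Bayesian
                  shrinkage, exact expected-reward integrals, (a, b) optimiser
  observers.py    static and criterion-adaptive synthetic observers, cohorts
  fitting.py      ML estimation of sigma, per-observer model comparison
  analysis.py     psychometric curves, contraction magnitude, time courses,
                  rank-sum group tests
  benchmarks.py   the reference quantities reported by scripts/acceptance.py
  pipeline.py     end-to-end orchestration with reproducible seeding
  figures.py      figure regeneration (every figure ships with its table)
  cli.py          `tonebias` command-line entry point
```

See `docs/methods.md` for the model, numerical choices and limitations.
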