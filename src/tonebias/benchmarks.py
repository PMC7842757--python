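"""Reference quantities of the model and task, recomputed from scratch.

These are the headline numbers a fresh run of the package should
reproduce: the noise-free optimal contraction weight, the optimal
criterion under unbiased feedback, the performance of the
second-stimulus-only Perceptron in the straddling quadrants, the
impossible-trial rate of generated blocks, and the chance-performance
exclusion threshold.
"""

from __future__ import annotations

import numpy as np

from .perceptron import optimize_params, possible_accuracy
from .protocols import (
    D_HALF_RANGE,
    M_HALF_RANGE,
    generate_block,
    minimal_passing_fraction,
)

__all__ = [
    "optimal_weight_noise_free",
    "max_abs_optimal_b",
    "straddling_accuracy_percent",
    "impossible_trial_percent",
    "exclusion_threshold_percent",
]


def optimal_weight_noise_free(
    a_min: float = 0.5, a_max: float = 1.5, step: float = 1e-3
) -> float:
    """argmax over a of noise-free accuracy on possible trials (b = 0).

    Grid search with the stated step; expected accuracy is evaluated by
    exact integration over the stimulus rectangle.  Only a = 1 classifies
    every pair correctly, so the argmax is 1 for any sigma = 0 task.
    """
    n = int(round((a_max - a_min) / step)) + 1
    a = a_min + step * np.arange(n)
    acc = possible_accuracy(a, 0.0, 0.0)
    return float(round(a[int(np.argmax(acc))], 3))


def max_abs_optimal_b(
    sigmas: tuple[float, ...] = (0.05, 0.1, 0.2), protocol: str = "control"
) -> tuple[float, dict[float, tuple[float, float]]]:
    """Largest-magnitude optimal criterion b* across noise levels.

    Runs the joint (a, b) optimisation per sigma; under unbiased feedback
    with stimuli measured relative to the distribution median the optimum
    is b = 0 at every sigma.  Returns (signed b* of largest magnitude,
    {sigma: (a*, b*)}).
    """
    per_sigma = {}
    worst = 0.0
    for s in sigmas:
        res = optimize_params(s, protocol)
        per_sigma[s] = (res.a, res.b)
        if abs(res.b) > abs(worst):
            worst = res.b
    return float(worst), per_sigma


def straddling_accuracy_percent(
    n_trials: int = 20_000, seed: int = 0
) -> tuple[float, int]:
    """Percent correct of the a = b = 0 Perceptron on straddling trials.

    Draws possible trials, classifies each from the second stimulus only
    (report "f1>f2" iff f2 < 1 kHz), and scores the trials where exactly
    one frequency exceeds 1 kHz.  Returns (percent, straddling count).
    """
    rng = np.random.default_rng(seed)
    m = rng.uniform(-M_HALF_RANGE, M_HALF_RANGE, n_trials)
    d = rng.uniform(-D_HALF_RANGE, D_HALF_RANGE, n_trials)
    s1, s2 = m + d, m - d
    resp = s2 < 0
    correct = resp == (d > 0)
    straddle = (s1 > 0) != (s2 > 0)
    n = int(straddle.sum())
    return float(100.0 * correct[straddle].mean()), n


def impossible_trial_percent(n_trials: int = 220, seed: int = 0) -> float:
    """Percent of impossible trials in a generated block (exactly 25)."""
    block = generate_block("control", n_trials, seed)
    frac = np.mean([t.stimulus.is_impossible for t in block.trials])
    return float(100.0 * frac)


def exclusion_threshold_percent(n_possible: int = 82, alpha: float = 0.05) -> float:
    """Minimal passing percent-correct of the exclusion screen."""
    _, frac = minimal_passing_fraction(n_possible, alpha)
    return float(100.0 * frac)
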