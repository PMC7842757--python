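"""Maximum-likelihood fitting of the single-parameter choice models.

Both candidate models are one-parameter Bernoulli choice models indexed by
the internal-noise SD sigma:

* ``optimal_perceptron`` — (a, b) are the reward-maximising values for that
  sigma under the stated feedback protocol, so the model predicts a
  contraction bias that grows with sigma;
* ``psychometric`` — (a, b) = (1, 0): choice probability depends only on
  the log-frequency difference (the classical psychometric curve).

sigma is estimated by a deterministic log-spaced grid scan followed by
bounded 1-D refinement; models are compared per observer by the difference
in log-likelihood per trial and an exact sign test over observers.
"""

from __future__ import annotations

from dataclasses import dataclass
from functools import lru_cache

import numpy as np
from scipy import optimize, stats

from .perceptron import _prob_one, optimize_params
from .protocols import TrialLog, get_protocol

__all__ = [
    "MODELS",
    "SIGMA_GRID",
    "FitResult",
    "ModelComparison",
    "model_weights",
    "choice_loglik",
    "fit_sigma",
    "compare_models",
]

MODELS = ("optimal_perceptron", "psychometric")
#: sigma search grid: 201 log-spaced points on [1e-3, 1] (log-frequency units)
SIGMA_GRID = np.logspace(-3.0, 0.0, 201)
_EPS = 1e-9


@dataclass(frozen=True)
class FitResult:
    model: str
    sigma_hat: float
    loglik: float
    n_trials_used: int
    converged: bool
    observer_id: "str | None" = None


@dataclass(frozen=True)
class ModelComparison:
    """Per-observer log-likelihood contrast (Perceptron minus psychometric)."""

    dll_per_trial: np.ndarray
    fraction_favoring_perceptron: float
    p_value: float
    n_ties: int
    all_tied: bool


@lru_cache(maxsize=None)
def _weights_table(protocol: str) -> tuple[np.ndarray, np.ndarray]:
    """(a*, b*) of the optimal Perceptron on SIGMA_GRID, warm-started."""
    a_tab = np.empty_like(SIGMA_GRID)
    b_tab = np.empty_like(SIGMA_GRID)
    init = None
    for i, sigma in enumerate(SIGMA_GRID):
        res = optimize_params(float(sigma), protocol, init=init)
        a_tab[i], b_tab[i] = res.a, res.b
        init = (res.a, res.b)
    return a_tab, b_tab


def model_weights(model: str, sigma: float, protocol: str = "control") -> tuple[float, float]:
    """(a, b) implied by a model at a given sigma.

    The optimal-Perceptron weights are interpolated (in log sigma) from a
    precomputed table over the search grid, which keeps the likelihood a
    smooth, cheap function of sigma during refinement.
    """
    if model == "psychometric":
        return 1.0, 0.0
    if model != "optimal_perceptron":
        raise ValueError(f"unknown model {model!r}; choose from {MODELS}")
    proto = get_protocol(protocol)
    a_tab, b_tab = _weights_table(proto.name)
    logs = np.log(np.clip(sigma, SIGMA_GRID[0], SIGMA_GRID[-1]))
    a = float(np.interp(logs, np.log(SIGMA_GRID), a_tab))
    b = float(np.interp(logs, np.log(SIGMA_GRID), b_tab))
    return a, b


def _trial_arrays(log: TrialLog, possible_only: bool):
    frame = log.to_frame()
    if not log.has_responses:
        raise ValueError("choice log-likelihood requires responses on every trial")
    if possible_only:
        frame = frame[~frame["is_impossible"]]
    if frame.empty:
        raise ValueError("no trials left to fit")
    return (
        frame["s1"].to_numpy(),
        frame["s2"].to_numpy(),
        frame["response"].to_numpy().astype(int),
    )


def _loglik_core(model, sigma, s1, s2, resp, protocol) -> float:
    a, b = model_weights(model, sigma, protocol)
    p1 = _prob_one(a, b, sigma, s1, s2)
    p = np.where(resp == 1, p1, 1.0 - p1)
    return float(np.sum(np.log(np.clip(p, _EPS, 1.0 - _EPS))))


def choice_loglik(
    model: str,
    sigma: float,
    log: TrialLog,
    protocol: str = "control",
    possible_only: bool = False,
) -> float:
    """Total Bernoulli log-likelihood of the observed responses.

    Both possible and impossible trials contribute (impossible trials are
    uninformative under the psychometric model, where they give log 0.5
    each, but carry contraction-bias information under the Perceptron).
    Probabilities are clipped to [1e-9, 1 - 1e-9] before logging.
    """
    if sigma <= 0:
        raise ValueError("sigma must be positive")
    s1, s2, resp = _trial_arrays(log, possible_only)
    return _loglik_core(model, sigma, s1, s2, resp, protocol)


def fit_sigma(
    model: str,
    log: TrialLog,
    protocol: str = "control",
    possible_only: bool = False,
) -> FitResult:
    """ML estimate of sigma for one observer under one model.

    Scans the 201-point log-spaced grid, then refines between the
    neighbours of the grid maximiser with bounded scalar minimisation.
    A maximiser on the grid boundary (e.g. effectively noiseless data) is
    flagged ``converged=False``, as are blocks with all-identical responses.
    """
    s1, s2, resp = _trial_arrays(log, possible_only)
    degenerate = bool(np.all(resp == resp[0]))

    lls = np.array(
        [_loglik_core(model, float(s), s1, s2, resp, protocol) for s in SIGMA_GRID]
    )
    i = int(np.argmax(lls))
    n_used = len(resp)
    if i in (0, len(SIGMA_GRID) - 1):
        return FitResult(model, float(SIGMA_GRID[i]), float(lls[i]), n_used, False,
                         log.observer_id)

    res = optimize.minimize_scalar(
        lambda s: -_loglik_core(model, float(s), s1, s2, resp, protocol),
        bounds=(SIGMA_GRID[i - 1], SIGMA_GRID[i + 1]),
        method="bounded",
        options={"xatol": 1e-6},
    )
    sigma_hat, ll = float(res.x), float(-res.fun)
    if lls[i] > ll:  # refinement should never lose to the grid point
        sigma_hat, ll = float(SIGMA_GRID[i]), float(lls[i])
    return FitResult(model, sigma_hat, ll, n_used, not degenerate, log.observer_id)


def compare_models(
    fits_perceptron: list[FitResult], fits_psychometric: list[FitResult]
) -> ModelComparison:
    """Per-observer ΔLL/trial (Perceptron minus psychometric) and sign test.

    Requires fits on identical trial sets per observer.  Ties contribute
    half weight to the favouring fraction and are dropped from the exact
    two-sided sign (binomial) test.
    """
    if len(fits_perceptron) != len(fits_psychometric):
        raise ValueError("paired fit lists must have equal length")
    dll = []
    for fp, fc in zip(fits_perceptron, fits_psychometric):
        if fp.n_trials_used != fc.n_trials_used:
            raise ValueError(
                f"observer {fp.observer_id}: trial counts differ "
                f"({fp.n_trials_used} vs {fc.n_trials_used})"
            )
        if fp.observer_id != fc.observer_id:
            raise ValueError("paired fits must be aligned by observer")
        dll.append((fp.loglik - fc.loglik) / fp.n_trials_used)
    dll = np.asarray(dll)
    n_pos = int(np.sum(dll > 0))
    n_neg = int(np.sum(dll < 0))
    n_tie = len(dll) - n_pos - n_neg
    fraction = (n_pos + 0.5 * n_tie) / len(dll)
    if n_pos + n_neg == 0:
        return ModelComparison(dll, fraction, 1.0, n_tie, True)
    p = stats.binomtest(n_pos, n_pos + n_neg, 0.5).pvalue
    return ModelComparison(dll, fraction, float(p), n_tie, False)
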