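"""Synthetic observers: simulated cohorts standing in for a human cohort.

Two observer kinds are provided.  A *static* observer applies a fixed
Perceptron (a, b, sigma) to every trial.  A *criterion-adaptive* observer
keeps a and sigma fixed but nudges its decision criterion b after every
trial with a reward-following delta rule,

    b <- b - eta * (2*feedback - 1) * (2*response - 1)

so rewarded responses become more likely and punished ones less likely.
The adaptive rule is deliberate plumbing for generating realistic choice
dynamics — the claim it embodies is that only the criterion (choice bias),
never the contraction weight a, adapts to feedback.
"""

from __future__ import annotations

from dataclasses import dataclass, field

import numpy as np
import pandas as pd

from .fitting import model_weights
from .perceptron import PerceptronParams
from .protocols import TrialLog, generate_block, get_protocol

__all__ = [
    "ObserverSpec",
    "CohortSpec",
    "simulate_static_observer",
    "simulate_adaptive_observer",
    "simulate_cohort",
    "sample_sigmas",
]

#: default stand-in for the (unavailable) population distribution of
#: representation-noise levels: log-normal, median 0.08 log-units
DEFAULT_SIGMA_DISTRIBUTION = {"name": "lognormal", "median": 0.08, "sigma_log": 0.5}


@dataclass(frozen=True)
class ObserverSpec:
    """One simulated observer: kind, Perceptron parameters, learning rate."""

    kind: str  # "static" or "adaptive_b"
    params: PerceptronParams
    learning_rate: float = 0.0
    seed: int = 0

    def __post_init__(self) -> None:
        if self.kind not in ("static", "adaptive_b"):
            raise ValueError("kind must be 'static' or 'adaptive_b'")
        if self.learning_rate < 0:
            raise ValueError("learning_rate must be non-negative")


@dataclass(frozen=True)
class CohortSpec:
    """A cohort of observers sharing a protocol and a sigma distribution.

    ``a_policy`` is either a fixed contraction weight (float) or the string
    "optimal", in which case each observer uses the (a, b) that maximise
    expected reward for its own sigma under the cohort's protocol.
    """

    n_observers: int
    protocol: str
    observer_kind: str = "static"
    sigma_distribution: dict = field(
        default_factory=lambda: dict(DEFAULT_SIGMA_DISTRIBUTION)
    )
    a_policy: "float | str" = 1.0
    b0: float = 0.0
    learning_rate: float = 0.0
    n_trials: int = 220
    master_seed: int = 0

    def __post_init__(self) -> None:
        if self.n_observers < 1:
            raise ValueError("n_observers must be >= 1")
        get_protocol(self.protocol)
        if isinstance(self.a_policy, str) and self.a_policy != "optimal":
            raise ValueError("a_policy must be a number or 'optimal'")


def _simulate(
    params: PerceptronParams,
    learning_rate: float,
    log: TrialLog,
    rng: np.random.Generator,
    return_trajectory: bool = False,
):
    """Shared simulation core: static behaviour is learning_rate = 0."""
    frame = log.to_frame()
    s1 = frame["s1"].to_numpy()
    s2 = frame["s2"].to_numpy()
    d = frame["d"].to_numpy()
    impossible = frame["is_impossible"].to_numpy().astype(bool)
    draws = frame["rewarded_response_draw"].to_numpy()
    n = len(log)
    noise = rng.normal(0.0, params.sigma, n) if params.sigma > 0 else np.zeros(n)

    a, b = params.a, params.b
    responses = np.empty(n, dtype=int)
    feedback = np.empty(n, dtype=int)
    b_traj = np.empty(n + 1)
    b_traj[0] = b
    for i in range(n):
        h = a * (s1[i] + noise[i]) - s2[i] - b
        resp = int(h > 0)
        if impossible[i]:
            fb = int(resp == int(draws[i]))
        else:
            fb = int(resp == int(d[i] > 0))
        responses[i] = resp
        feedback[i] = fb
        if learning_rate > 0:
            b = b - learning_rate * (2 * fb - 1) * (2 * resp - 1)
        b_traj[i + 1] = b
    out = log.with_responses(responses, feedback)
    return (out, b_traj) if return_trajectory else out


def simulate_static_observer(spec: ObserverSpec, log: TrialLog) -> TrialLog:
    """Run a fixed-parameter observer through a generated block.

    Per trial the noisy representation r1 = s1 + n is formed, the linear
    threshold rule applied, and feedback assigned per the block's protocol.
    Seeded and bit-reproducible.
    """
    if spec.kind != "static":
        raise ValueError("spec.kind must be 'static'")
    rng = np.random.default_rng(spec.seed)
    return _simulate(spec.params, 0.0, log, rng)


def simulate_adaptive_observer(
    spec: ObserverSpec,
    protocol: "str | None" = None,
    n_trials: int = 220,
    seed: "int | None" = None,
    log: "TrialLog | None" = None,
    return_trajectory: bool = False,
):
    """Run a criterion-adaptive observer (delta rule on b; a, sigma fixed).

    Either pass a pre-generated ``log`` or a (protocol, n_trials, seed)
    triple to generate one.  With learning_rate = 0 the output is identical
    to the static observer with the same spec seed on the same block.
    """
    if spec.kind != "adaptive_b":
        raise ValueError("spec.kind must be 'adaptive_b'")
    if log is None:
        if protocol is None:
            raise ValueError("either a log or a protocol must be given")
        log = generate_block(protocol, n_trials, seed)
    rng = np.random.default_rng(spec.seed)
    return _simulate(
        spec.params, spec.learning_rate, log, rng, return_trajectory=return_trajectory
    )


def sample_sigmas(
    distribution: dict, n: int, rng: np.random.Generator
) -> np.ndarray:
    """Draw per-observer noise SDs from a named distribution spec."""
    if "name" not in distribution:
        raise ValueError("sigma distribution spec needs a 'name'")
    name = distribution["name"]
    if name == "fixed":
        value = float(distribution["value"])
        if value <= 0:
            raise ValueError("fixed sigma must be positive")
        return np.full(n, value)
    if name == "lognormal":
        median = float(distribution["median"])
        sigma_log = float(distribution["sigma_log"])
        if median <= 0 or sigma_log < 0:
            raise ValueError("lognormal needs median > 0 and sigma_log >= 0")
        return median * np.exp(sigma_log * rng.standard_normal(n))
    if name == "loguniform":
        low, high = float(distribution["low"]), float(distribution["high"])
        if not 0 < low <= high:
            raise ValueError("loguniform needs 0 < low <= high")
        return np.exp(rng.uniform(np.log(low), np.log(high), n))
    if name == "cycle":
        values = np.asarray(distribution["values"], dtype=float)
        if np.any(values <= 0):
            raise ValueError("cycle values must be positive")
        return values[np.arange(n) % len(values)]
    raise ValueError(f"unknown sigma distribution {name!r}")


def _child_seeds(master_seed: int, index: int) -> tuple[int, int]:
    state = np.random.SeedSequence((master_seed, index)).generate_state(2)
    return int(state[0] % 2**31), int(state[1] % 2**31)


def simulate_cohort(cohort: CohortSpec) -> tuple[list[TrialLog], pd.DataFrame]:
    """Simulate a cohort; returns the trial logs and a ground-truth manifest.

    Per-observer seeds derive deterministically from the master seed; the
    manifest records every observer's true parameters for recovery tests.
    """
    sigma_rng = np.random.default_rng(np.random.SeedSequence((cohort.master_seed, 1 << 20)))
    sigmas = sample_sigmas(cohort.sigma_distribution, cohort.n_observers, sigma_rng)
    if np.any(sigmas <= 0):
        raise ValueError("sampled sigma must be positive")

    logs: list[TrialLog] = []
    rows = []
    for i, sigma in enumerate(sigmas):
        block_seed, obs_seed = _child_seeds(cohort.master_seed, i)
        if cohort.a_policy == "optimal":
            a, b0 = model_weights("optimal_perceptron", float(sigma), cohort.protocol)
        else:
            a, b0 = float(cohort.a_policy), cohort.b0
        params = PerceptronParams(a=a, b=b0, sigma=float(sigma))
        observer_id = f"obs{i:03d}"
        block = generate_block(
            cohort.protocol, cohort.n_trials, block_seed, observer_id=observer_id
        )
        spec = ObserverSpec(
            kind=cohort.observer_kind,
            params=params,
            learning_rate=cohort.learning_rate,
            seed=obs_seed,
        )
        if cohort.observer_kind == "static":
            log = simulate_static_observer(spec, block)
        else:
            log = simulate_adaptive_observer(spec, log=block)
        logs.append(log)
        rows.append(
            {
                "observer_id": observer_id,
                "kind": cohort.observer_kind,
                "protocol": cohort.protocol,
                "true_a": a,
                "true_b0": b0,
                "true_sigma": float(sigma),
                "learning_rate": cohort.learning_rate,
                "seed": obs_seed,
                "block_seed": block_seed,
            }
        )
    return logs, pd.DataFrame(rows)
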