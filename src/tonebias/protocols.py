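"""Experiment machinery for the two-tone delayed comparison task.

A block consists of trials in which two pure tones are presented in sequence
and the observer reports which had the higher pitch.  Frequencies are drawn
so that, in natural-log units relative to the 1 kHz median, the pair mean
``m = (s1 + s2)/2`` is uniform on ±0.2 and the half-difference
``d = (s1 - s2)/2`` is uniform on ±0.0905.  A quarter of the trials are
"impossible" (f1 = f2 exactly); on those, which response earns "correct"
feedback is drawn according to the active feedback protocol, keyed on
whether the pair sits below or above the 1 kHz median.

This module generates blocks, delivers feedback, applies the
chance-performance exclusion rule, and reads/writes trial-log CSV files.
"""

from __future__ import annotations

import math
from dataclasses import dataclass, field, replace
from pathlib import Path

import numpy as np
import pandas as pd
from scipy import stats

__all__ = [
    "BASE_FREQ_HZ",
    "M_HALF_RANGE",
    "D_HALF_RANGE",
    "IMPOSSIBLE_FRACTION",
    "StimulusPair",
    "FeedbackProtocol",
    "PROTOCOLS",
    "get_protocol",
    "TrialRecord",
    "TrialLog",
    "generate_block",
    "assign_feedback",
    "ExclusionResult",
    "exclusion_test",
    "minimal_passing_fraction",
    "write_trial_log",
    "read_trial_log",
]

BASE_FREQ_HZ = 1000.0
#: half-range of the uniform distribution of the pair mean m (log units)
M_HALF_RANGE = 0.2
#: half-range of the uniform distribution of the half-difference d (log units)
D_HALF_RANGE = 0.0905
#: fraction of trials with f1 = f2
IMPOSSIBLE_FRACTION = 0.25
# impossible-trial means this close to the median are redrawn so that the
# below/above-1kHz side of the pair is always defined
_M_GAP = 5e-7

_CSV_COLUMNS = [
    "observer_id",
    "protocol",
    "trial_index",
    "f1_hz",
    "f2_hz",
    "is_impossible",
    "rewarded_response_draw",
    "response",
    "feedback",
]


@dataclass(frozen=True)
class StimulusPair:
    """One trial's tone pair, stored as (mean, half-difference) in log units.

    ``m`` and ``d`` are primary so that the identities ``s1 = m + d`` and
    ``s2 = m - d`` hold exactly, and impossible trials (d = 0) have
    bit-identical frequencies.
    """

    m: float
    d: float

    def __post_init__(self) -> None:
        if not (math.isfinite(self.m) and math.isfinite(self.d)):
            raise ValueError("stimulus coordinates must be finite")

    @property
    def s1(self) -> float:
        return self.m + self.d

    @property
    def s2(self) -> float:
        return self.m - self.d

    @property
    def f1(self) -> float:
        return BASE_FREQ_HZ * math.exp(self.s1)

    @property
    def f2(self) -> float:
        return BASE_FREQ_HZ * math.exp(self.s2)

    @property
    def is_impossible(self) -> bool:
        return self.d == 0.0

    @classmethod
    def from_frequencies(cls, f1: float, f2: float) -> "StimulusPair":
        if not (f1 > 0 and f2 > 0):
            raise ValueError("frequencies must be positive")
        if f1 == f2:
            return cls(m=math.log(f1 / BASE_FREQ_HZ), d=0.0)
        s1 = math.log(f1 / BASE_FREQ_HZ)
        s2 = math.log(f2 / BASE_FREQ_HZ)
        return cls(m=0.5 * (s1 + s2), d=0.5 * (s1 - s2))


@dataclass(frozen=True)
class FeedbackProtocol:
    """Reward contingency for impossible trials.

    ``p_reward_f1gt_low`` (``_high``) is the probability that the response
    "f1 > f2" is the rewarded one when f1 = f2 lies below (above) 1 kHz.
    Feedback on possible trials is always veridical.
    """

    name: str
    p_reward_f1gt_low: float
    p_reward_f1gt_high: float

    def __post_init__(self) -> None:
        for p in (self.p_reward_f1gt_low, self.p_reward_f1gt_high):
            if not 0.0 <= p <= 1.0:
                raise ValueError("reward probabilities must lie in [0, 1]")


PROTOCOLS: dict[str, FeedbackProtocol] = {
    "control": FeedbackProtocol("control", 0.5, 0.5),
    "enhance_f1gt": FeedbackProtocol("enhance_f1gt", 0.9, 0.9),
    "suppress_f1gt": FeedbackProtocol("suppress_f1gt", 0.1, 0.1),
    "enhance_contraction": FeedbackProtocol("enhance_contraction", 0.9, 0.1),
    "suppress_contraction": FeedbackProtocol("suppress_contraction", 0.1, 0.9),
}


def get_protocol(protocol: "str | FeedbackProtocol") -> FeedbackProtocol:
    """Resolve a protocol name (or pass a protocol through), with validation."""
    if isinstance(protocol, FeedbackProtocol):
        return protocol
    try:
        return PROTOCOLS[protocol]
    except KeyError:
        raise ValueError(
            f"unknown protocol {protocol!r}; valid names are "
            f"{sorted(PROTOCOLS)}"
        ) from None


@dataclass
class TrialRecord:
    """A single trial: stimulus, and (once simulated) response and feedback."""

    index: int
    stimulus: StimulusPair
    response: "int | None" = None
    feedback: "int | None" = None
    #: pre-drawn rewarded response for impossible trials (None for possible)
    rewarded_response_draw: "int | None" = None


@dataclass
class TrialLog:
    """An ordered block of trials for one observer under one protocol."""

    protocol: str
    observer_id: str = "obs0"
    seed: "int | None" = None
    trials: list[TrialRecord] = field(default_factory=list)

    def __len__(self) -> int:
        return len(self.trials)

    def __iter__(self):
        return iter(self.trials)

    @property
    def has_responses(self) -> bool:
        return all(t.response is not None for t in self.trials)

    def to_frame(self) -> pd.DataFrame:
        """Tabular view of the block (one row per trial, NaN for absent)."""
        rows = []
        for t in self.trials:
            s = t.stimulus
            rows.append(
                {
                    "trial_index": t.index,
                    "m": s.m,
                    "d": s.d,
                    "s1": s.s1,
                    "s2": s.s2,
                    "f1_hz": s.f1,
                    "f2_hz": s.f2,
                    "is_impossible": s.is_impossible,
                    "rewarded_response_draw": (
                        np.nan
                        if t.rewarded_response_draw is None
                        else t.rewarded_response_draw
                    ),
                    "response": np.nan if t.response is None else t.response,
                    "feedback": np.nan if t.feedback is None else t.feedback,
                }
            )
        return pd.DataFrame(rows)

    def with_responses(
        self, responses: np.ndarray, feedback: np.ndarray
    ) -> "TrialLog":
        """Copy of the log with per-trial responses and feedback filled in."""
        if len(responses) != len(self.trials) or len(feedback) != len(self.trials):
            raise ValueError("response/feedback arrays must match the trial count")
        trials = [
            replace(t, response=int(r), feedback=int(f))
            for t, r, f in zip(self.trials, responses, feedback)
        ]
        return TrialLog(self.protocol, self.observer_id, self.seed, trials)


def generate_block(
    protocol: "str | FeedbackProtocol",
    n_trials: int = 220,
    seed: "int | None" = None,
    observer_id: str = "obs0",
) -> TrialLog:
    """Generate one block of stimuli (responses absent).

    Exactly ``round(0.25 * n_trials)`` trials are impossible, at uniformly
    shuffled positions.  The rewarded response on each impossible trial is
    pre-drawn from the protocol's contingency based on the side of the 1 kHz
    median.  Identical ``(protocol, n_trials, seed)`` give identical blocks.
    """
    proto = get_protocol(protocol)
    if not isinstance(n_trials, (int, np.integer)) or n_trials <= 0:
        raise ValueError("n_trials must be a positive integer")
    if n_trials % 4 != 0:
        raise ValueError(
            f"n_trials={n_trials} must be divisible by 4 so the 75/25 "
            "possible/impossible split is exact"
        )
    rng = np.random.default_rng(seed)
    n_impossible = round(IMPOSSIBLE_FRACTION * n_trials)
    flags = np.zeros(n_trials, dtype=bool)
    flags[:n_impossible] = True
    flags = flags[rng.permutation(n_trials)]

    trials: list[TrialRecord] = []
    for i, impossible in enumerate(flags, start=1):
        if impossible:
            m = rng.uniform(-M_HALF_RANGE, M_HALF_RANGE)
            while abs(m) < _M_GAP:
                m = rng.uniform(-M_HALF_RANGE, M_HALF_RANGE)
            p_f1gt = proto.p_reward_f1gt_low if m < 0 else proto.p_reward_f1gt_high
            draw = 1 if rng.random() < p_f1gt else 0
            trials.append(
                TrialRecord(i, StimulusPair(m=m, d=0.0), rewarded_response_draw=draw)
            )
        else:
            m = rng.uniform(-M_HALF_RANGE, M_HALF_RANGE)
            d = rng.uniform(-D_HALF_RANGE, D_HALF_RANGE)
            while d == 0.0:
                d = rng.uniform(-D_HALF_RANGE, D_HALF_RANGE)
            trials.append(TrialRecord(i, StimulusPair(m=m, d=d)))
    return TrialLog(proto.name, observer_id, None if seed is None else int(seed), trials)


def assign_feedback(
    protocol: "str | FeedbackProtocol", trial: TrialRecord, response: int
) -> int:
    """Feedback (1 = "correct" face) for a response on one trial.

    Possible trials are scored veridically; impossible trials against the
    pre-drawn rewarded response.
    """
    get_protocol(protocol)  # validates the name
    if response not in (0, 1):
        raise ValueError("response must be 0 or 1")
    stim = trial.stimulus
    if not stim.is_impossible:
        return int(response == int(stim.d > 0))
    if stim.m == 0.0:
        raise ValueError(
            "impossible trial with m = 0 exactly: the below/above-median side "
            "is undefined (the generator never produces this)"
        )
    if trial.rewarded_response_draw is None:
        raise ValueError("impossible trial lacks a rewarded_response_draw")
    return int(response == trial.rewarded_response_draw)


@dataclass(frozen=True)
class ExclusionResult:
    """Outcome of the chance-performance screen on one block."""

    decision: str  # "keep" or "exclude"
    p_first: float
    p_second: float
    n_possible: tuple[int, int]
    n_correct: tuple[int, int]


def exclusion_test(log: TrialLog, alpha: float = 0.05) -> ExclusionResult:
    """Screen a block for above-chance performance in both halves.

    Counts correct responses among the possible trials of each half of the
    block and runs an exact two-sided binomial test against chance (p = 0.5).
    The block is kept only if both halves differ significantly from chance.
    """
    if not log.has_responses:
        raise ValueError("exclusion_test requires responses for every trial")
    n = len(log)
    halves = (log.trials[: n // 2], log.trials[n // 2 :])
    ps, ns, ks = [], [], []
    for half in halves:
        possible = [t for t in half if not t.stimulus.is_impossible]
        if not possible:
            raise ValueError("a half-block contains no possible trials")
        k = sum(int(t.response == int(t.stimulus.d > 0)) for t in possible)
        ps.append(stats.binomtest(k, len(possible), 0.5).pvalue)
        ns.append(len(possible))
        ks.append(k)
    decision = "keep" if all(p < alpha for p in ps) else "exclude"
    return ExclusionResult(decision, ps[0], ps[1], (ns[0], ns[1]), (ks[0], ks[1]))


def minimal_passing_fraction(
    n_possible: int, alpha: float = 0.05
) -> tuple[int, float]:
    """Smallest correct count (and fraction) that passes the exclusion screen.

    Returns the minimal k >= n/2 with a two-sided exact binomial p-value
    below ``alpha`` for ``n_possible`` trials at chance 0.5.
    """
    if n_possible <= 0:
        raise ValueError("n_possible must be positive")
    for k in range(math.ceil(n_possible / 2), n_possible + 1):
        if stats.binomtest(k, n_possible, 0.5).pvalue < alpha:
            return k, k / n_possible
    raise ValueError("no passing count exists at this alpha")


def write_trial_log(log: TrialLog, path: "str | Path") -> None:
    """Write a block to CSV in the fixed trial-log dialect.

    Frequencies are written with shortest round-trip precision (>= 12
    significant digits); absent responses/feedback become empty cells.
    """
    rows = []
    for t in log.trials:
        s = t.stimulus
        rows.append(
            {
                "observer_id": log.observer_id,
                "protocol": log.protocol,
                "trial_index": t.index,
                "f1_hz": s.f1,
                "f2_hz": s.f2,
                "is_impossible": int(s.is_impossible),
                "rewarded_response_draw": (
                    np.nan if t.rewarded_response_draw is None else t.rewarded_response_draw
                ),
                "response": np.nan if t.response is None else t.response,
                "feedback": np.nan if t.feedback is None else t.feedback,
            }
        )
    pd.DataFrame(rows, columns=_CSV_COLUMNS).to_csv(path, index=False)


def _opt_int(value, allowed: tuple[int, ...], row: int, name: str) -> "int | None":
    if pd.isna(value):
        return None
    v = float(value)
    if v not in [float(x) for x in allowed]:
        raise ValueError(f"row {row}: {name}={value!r} not in {allowed} or empty")
    return int(v)


def read_trial_log(path: "str | Path") -> TrialLog:
    """Read a trial-log CSV back into a :class:`TrialLog`.

    Validates columns, numeric frequencies, binary flags and contiguous
    1-based trial indices, reporting the first offending data row.  The CSV
    dialect does not carry the generator seed, so ``seed`` is ``None``.
    """
    df = pd.read_csv(path)
    missing = [c for c in _CSV_COLUMNS if c not in df.columns]
    if missing:
        raise ValueError(f"trial log {path} is missing columns {missing}")
    if df.empty:
        raise ValueError(f"trial log {path} contains no trials")
    if df["observer_id"].nunique() != 1 or df["protocol"].nunique() != 1:
        raise ValueError("a trial log must contain a single observer and protocol")

    protocol = str(df["protocol"].iloc[0])
    get_protocol(protocol)
    observer_id = str(df["observer_id"].iloc[0])

    trials: list[TrialRecord] = []
    for pos, (_, row) in enumerate(df.iterrows(), start=1):
        idx = row["trial_index"]
        if pd.isna(idx) or float(idx) != pos:
            raise ValueError(
                f"row {pos}: trial_index {idx!r} breaks the contiguous 1..N order"
            )
        f1, f2 = row["f1_hz"], row["f2_hz"]
        for name, f in (("f1_hz", f1), ("f2_hz", f2)):
            if pd.isna(pd.to_numeric(f, errors="coerce")) or float(f) <= 0:
                raise ValueError(f"row {pos}: non-numeric or non-positive {name}={f!r}")
        impossible = _opt_int(row["is_impossible"], (0, 1), pos, "is_impossible")
        if impossible is None:
            raise ValueError(f"row {pos}: is_impossible must be 0 or 1")
        f1v, f2v = float(f1), float(f2)
        # tolerate last-ulp parser differences; frequencies are guaranteed
        # to round-trip at >= 12 significant digits, not bit-exactly
        same = abs(f1v - f2v) <= 1e-9 * f1v
        if bool(impossible) != same:
            raise ValueError(
                f"row {pos}: is_impossible={impossible} inconsistent with "
                f"f1={f1!r}, f2={f2!r}"
            )
        if impossible:
            stim = StimulusPair(m=math.log(f1v / BASE_FREQ_HZ), d=0.0)
        else:
            stim = StimulusPair.from_frequencies(f1v, f2v)
        trials.append(
            TrialRecord(
                index=pos,
                stimulus=stim,
                response=_opt_int(row["response"], (0, 1), pos, "response"),
                feedback=_opt_int(row["feedback"], (0, 1), pos, "feedback"),
                rewarded_response_draw=_opt_int(
                    row["rewarded_response_draw"], (0, 1), pos, "rewarded_response_draw"
                ),
            )
        )
    return TrialLog(protocol, observer_id, None, trials)
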