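"""Descriptive bias statistics: psychometric curves, contraction magnitude,
choice-bias time courses, and group comparisons.

Contraction bias is read out by splitting trials into three frequency
regions by the pair mean m (terciles of its design range): in the low
region the remembered first tone is pulled up toward the distribution
centre, shifting the psychometric curve left; in the high region it is
pulled down, shifting the curve right.  The bias magnitude is the vertical
distance between the low- and high-region curves evaluated at zero
frequency difference, with the impossible-trial response fractions as an
independent cross-check.  Cross-observer aggregation always averages
per-observer proportions (never pools trials) and reports the
cross-observer SEM.
"""

from __future__ import annotations

import itertools
from dataclasses import dataclass

import numpy as np
from scipy import stats
from scipy.special import ndtr

from .perceptron import PerceptronParams, _prob_one
from .protocols import D_HALF_RANGE, M_HALF_RANGE, StimulusPair, TrialLog

__all__ = [
    "REGION_BOUNDARY",
    "assign_region",
    "PsychometricCurve",
    "psychometric_curve",
    "SigmoidFit",
    "fit_sigmoid",
    "BiasSummary",
    "contraction_magnitude",
    "Timecourse",
    "choice_bias_timecourse",
    "group_difference_test",
    "expected_curve",
    "model_contraction_magnitude",
]

#: tercile boundary of the design range of m; regions are
#: I: m < -boundary, II: |m| <= boundary, III: m > boundary
REGION_BOUNDARY = M_HALF_RANGE / 3.0
_DELTA_RANGE = 2.0 * D_HALF_RANGE  # full range of s1 - s2 on possible trials


def assign_region(trial: "StimulusPair | float") -> str:
    """Frequency region of a trial: "I" (low), "II" (middle), "III" (high)."""
    m = trial.m if isinstance(trial, StimulusPair) else float(trial)
    if m < -REGION_BOUNDARY:
        return "I"
    if m > REGION_BOUNDARY:
        return "III"
    return "II"


def _region_mask(m: np.ndarray, region: str) -> np.ndarray:
    if region == "all":
        return np.ones_like(m, dtype=bool)
    if region == "I":
        return m < -REGION_BOUNDARY
    if region == "III":
        return m > REGION_BOUNDARY
    if region == "II":
        return (m >= -REGION_BOUNDARY) & (m <= REGION_BOUNDARY)
    raise ValueError(f"unknown region {region!r}")


@dataclass(frozen=True)
class PsychometricCurve:
    """Binned choice proportions vs Δ = s1 - s2 (possible trials only)."""

    region: str
    bin_centers: np.ndarray
    proportion: np.ndarray  # cross-observer mean of per-observer proportions
    sem: np.ndarray  # cross-observer SEM
    n_trials: np.ndarray  # pooled trial count per bin
    n_observers: np.ndarray  # observers contributing to each bin
    empty: bool = False


def _as_logs(logs: "TrialLog | list[TrialLog]") -> list[TrialLog]:
    return [logs] if isinstance(logs, TrialLog) else list(logs)


def psychometric_curve(
    logs: "TrialLog | list[TrialLog]",
    region: str = "all",
    n_bins: int = 9,
) -> PsychometricCurve:
    """Psychometric curve for one frequency region, aggregated over observers.

    Possible trials are binned by Δ = s1 - s2 into ``n_bins`` equal-width
    bins spanning the design range ±0.181; the curve is the cross-observer
    mean of per-observer response-1 proportions.
    """
    logs = _as_logs(logs)
    edges = np.linspace(-_DELTA_RANGE, _DELTA_RANGE, n_bins + 1)
    centers = 0.5 * (edges[:-1] + edges[1:])
    props = np.full((len(logs), n_bins), np.nan)
    counts = np.zeros(n_bins, dtype=int)
    for i, log in enumerate(logs):
        frame = log.to_frame()
        if frame["response"].isna().any():
            raise ValueError("psychometric_curve requires responses")
        sel = (~frame["is_impossible"]) & _region_mask(frame["m"].to_numpy(), region)
        delta = (frame["s1"] - frame["s2"]).to_numpy()[sel.to_numpy()]
        resp = frame["response"].to_numpy()[sel.to_numpy()].astype(int)
        which = np.clip(np.digitize(delta, edges) - 1, 0, n_bins - 1)
        for j in range(n_bins):
            mask = which == j
            if mask.any():
                props[i, j] = resp[mask].mean()
                counts[j] += int(mask.sum())
    n_obs = np.sum(~np.isnan(props), axis=0)
    if counts.sum() == 0:
        return PsychometricCurve(
            region, centers, np.full(n_bins, np.nan), np.full(n_bins, np.nan),
            counts, n_obs, empty=True,
        )
    with np.errstate(invalid="ignore"):
        mean = np.nanmean(props, axis=0)
        sd = np.nanstd(props, axis=0, ddof=1)
    sem = np.where(n_obs > 1, sd / np.sqrt(np.maximum(n_obs, 1)), np.nan)
    return PsychometricCurve(region, centers, mean, sem, counts, n_obs)


@dataclass(frozen=True)
class SigmoidFit:
    """Two-parameter cumulative-normal fit P(Δ) = Phi((Δ - midpoint)/slope)."""

    midpoint: float
    slope: float
    value_at_zero: float
    degenerate: bool = False


def fit_sigmoid(deltas: np.ndarray, responses: np.ndarray) -> SigmoidFit:
    """ML cumulative-normal fit to raw Bernoulli trials.

    Deterministic coarse-to-fine grid search over (midpoint, log slope).
    Degenerate data (all responses identical) are flagged and the value at
    Δ = 0 falls back to the empirical proportion.
    """
    deltas = np.asarray(deltas, dtype=float)
    responses = np.asarray(responses, dtype=int)
    if deltas.shape != responses.shape or deltas.size == 0:
        raise ValueError("deltas and responses must be equal-length, non-empty")
    if np.all(responses == responses[0]):
        return SigmoidFit(np.nan, np.nan, float(responses.mean()), degenerate=True)

    lo_mu, hi_mu = -0.25, 0.25
    lo_ls, hi_ls = np.log(1e-3), np.log(1.0)
    grid = 41
    best_mu, best_s = 0.0, 0.1
    for _ in range(5):
        mus = np.linspace(lo_mu, hi_mu, grid)
        lss = np.linspace(lo_ls, hi_ls, grid)
        MU, LS = np.meshgrid(mus, lss, indexing="ij")
        z = (deltas[None, :] - MU.ravel()[:, None]) / np.exp(LS.ravel())[:, None]
        p = np.clip(ndtr(z), 1e-9, 1 - 1e-9)
        ll = np.where(responses[None, :] == 1, np.log(p), np.log1p(-p)).sum(axis=1)
        k = int(np.argmax(ll))
        best_mu, best_ls = float(MU.ravel()[k]), float(LS.ravel()[k])
        step_mu = (hi_mu - lo_mu) / (grid - 1)
        step_ls = (hi_ls - lo_ls) / (grid - 1)
        lo_mu, hi_mu = best_mu - 1.5 * step_mu, best_mu + 1.5 * step_mu
        lo_ls, hi_ls = best_ls - 1.5 * step_ls, best_ls + 1.5 * step_ls
    best_s = float(np.exp(best_ls))
    return SigmoidFit(best_mu, best_s, float(ndtr(-best_mu / best_s)))


def _region_trials(logs: list[TrialLog], region: str, impossible: bool):
    deltas, resp = [], []
    for log in logs:
        frame = log.to_frame()
        sel = (frame["is_impossible"] == impossible) & _region_mask(
            frame["m"].to_numpy(), region
        )
        deltas.append((frame["s1"] - frame["s2"]).to_numpy()[sel.to_numpy()])
        resp.append(frame["response"].to_numpy()[sel.to_numpy()])
    deltas = np.concatenate(deltas)
    resp = np.concatenate(resp)
    if np.any(np.isnan(resp)):
        raise ValueError("responses required for bias analysis")
    return deltas, resp.astype(int)


@dataclass(frozen=True)
class BiasSummary:
    """Contraction-bias magnitude and choice-bias readouts for a cohort."""

    contraction_magnitude: float  # P_I(Δ=0) - P_III(Δ=0) from fitted curves
    impossible_contrast: float  # same contrast from impossible-trial fractions
    choice_bias: float  # midpoint of the region-II curve (log units)
    degenerate: bool = False


def _one_bias_summary(logs: list[TrialLog]) -> BiasSummary:
    fits = {}
    for region in ("I", "III"):
        deltas, resp = _region_trials(logs, region, impossible=False)
        if deltas.size == 0:
            raise ValueError(f"region {region} contains no possible trials")
        fits[region] = fit_sigmoid(deltas, resp)
    magnitude = fits["I"].value_at_zero - fits["III"].value_at_zero

    imp = {}
    for region in ("I", "III"):
        _, resp = _region_trials(logs, region, impossible=True)
        imp[region] = float(resp.mean()) if resp.size else np.nan
    contrast = imp["I"] - imp["III"]

    deltas2, resp2 = _region_trials(logs, "II", impossible=False)
    mid_fit = fit_sigmoid(deltas2, resp2) if deltas2.size else SigmoidFit(
        np.nan, np.nan, np.nan, True
    )
    return BiasSummary(
        contraction_magnitude=float(magnitude),
        impossible_contrast=float(contrast),
        choice_bias=float(mid_fit.midpoint),
        degenerate=any(f.degenerate for f in (*fits.values(), mid_fit)),
    )


def contraction_magnitude(
    logs: "TrialLog | list[TrialLog]", per_observer: bool = False
):
    """Contraction-bias magnitude from region-I vs region-III curves.

    Fits cumulative-normal curves to the possible trials of the extreme
    frequency regions, evaluates both at Δ = 0 and returns the difference
    (positive = contraction), alongside the impossible-trial fraction
    contrast computed from non-overlapping trials.  With ``per_observer``
    a list of single-observer summaries is returned instead of one pooled
    summary.
    """
    logs = _as_logs(logs)
    if per_observer:
        return [_one_bias_summary([log]) for log in logs]
    return _one_bias_summary(logs)


@dataclass(frozen=True)
class Timecourse:
    """Windowed impossible-trial choice rate, averaged across observers."""

    window: int
    trial_mid: np.ndarray  # centre trial index of each window
    mean: np.ndarray
    sem: np.ndarray
    n_observers: np.ndarray


def choice_bias_timecourse(
    logs: "TrialLog | list[TrialLog]", window: int = 20
) -> Timecourse:
    """Mean P("f1>f2") on impossible trials per window of trials.

    A 220-trial block with the default 20-trial window yields 11 points
    (about five impossible trials each).  Observers with no impossible
    trials in a window are omitted from that point.
    """
    logs = _as_logs(logs)
    n = len(logs[0])
    if any(len(log) != n for log in logs):
        raise ValueError("all logs must have the same number of trials")
    if n % window != 0:
        raise ValueError(f"window {window} must divide the trial count {n}")
    n_win = n // window
    rates = np.full((len(logs), n_win), np.nan)
    for i, log in enumerate(logs):
        frame = log.to_frame()
        if frame["response"].isna().any():
            raise ValueError("choice_bias_timecourse requires responses")
        imp = frame["is_impossible"].to_numpy()
        resp = frame["response"].to_numpy()
        for w in range(n_win):
            sel = slice(w * window, (w + 1) * window)
            mask = imp[sel]
            if mask.any():
                rates[i, w] = resp[sel][mask].mean()
    n_obs = np.sum(~np.isnan(rates), axis=0)
    with np.errstate(invalid="ignore"):
        mean = np.nanmean(rates, axis=0)
        sd = np.nanstd(rates, axis=0, ddof=1)
    sem = np.where(n_obs > 1, sd / np.sqrt(np.maximum(n_obs, 1)), np.nan)
    mid = window * (np.arange(n_win) + 0.5)
    return Timecourse(window, mid, mean, sem, n_obs)


def _ranksum_exact(a: np.ndarray, b: np.ndarray, alternative: str) -> float:
    """Exact rank-sum p-value by full enumeration of rank assignments.

    Uses midranks, so ties are handled exactly; feasible for group sizes
    up to 10 (C(20,10) = 184756 assignments).
    """
    pooled = np.concatenate([a, b])
    ranks = stats.rankdata(pooled)
    n_a = len(a)
    w_obs = ranks[:n_a].sum()
    total = 0
    count = 0
    tol = 1e-9
    for combo in itertools.combinations(range(len(pooled)), n_a):
        w = ranks[list(combo)].sum()
        total += 1
        if alternative == "less":
            count += w <= w_obs + tol
        else:
            count += w >= w_obs - tol
    return count / total


def group_difference_test(
    values_a, values_b, alternative: str = "less", force_exact: "bool | None" = None
) -> float:
    """One-sided Wilcoxon rank-sum p-value for a group difference.

    ``alternative="less"`` tests whether group A tends to be smaller than
    group B.  Group sizes up to 10 use exact enumeration of the rank-sum
    null (with midranks); larger groups use the tie-corrected normal
    approximation.  ``force_exact`` overrides the automatic choice.
    """
    a = np.asarray(values_a, dtype=float)
    b = np.asarray(values_b, dtype=float)
    if a.size < 2 or b.size < 2:
        raise ValueError("each group needs at least 2 values")
    if alternative not in ("less", "greater"):
        raise ValueError("alternative must be 'less' or 'greater'")
    exact = (a.size <= 10 and b.size <= 10) if force_exact is None else force_exact
    if exact:
        if a.size > 10 or b.size > 10:
            raise ValueError("exact enumeration supports group sizes <= 10")
        return float(_ranksum_exact(a, b, alternative))
    return float(
        stats.mannwhitneyu(a, b, alternative=alternative, method="asymptotic").pvalue
    )


# ---------------------------------------------------------------------------
# model-predicted analogues (expected curves of a Perceptron, no simulation)
# ---------------------------------------------------------------------------

def expected_curve(
    params: PerceptronParams, region: str = "all", n_bins: int = 9, n_grid: int = 400
) -> tuple[np.ndarray, np.ndarray]:
    """Model-expected psychometric curve: mean response probability per
    Δ bin, averaged over the possible-trial stimulus distribution within
    the region.  Returns (bin centers, probabilities)."""
    edges = np.linspace(-_DELTA_RANGE, _DELTA_RANGE, n_bins + 1)
    centers = 0.5 * (edges[:-1] + edges[1:])
    m = (np.arange(n_grid) + 0.5) / n_grid * 2 * M_HALF_RANGE - M_HALF_RANGE
    m = m[_region_mask(m, region)]
    probs = np.empty(n_bins)
    for j in range(n_bins):
        d = np.linspace(edges[j] / 2, edges[j + 1] / 2, 21)[:, None]
        s1 = m[None, :] + d
        s2 = m[None, :] - d
        probs[j] = _prob_one(params.a, params.b, params.sigma, s1, s2).mean()
    return centers, probs


def model_contraction_magnitude(params: PerceptronParams, n_grid: int = 2000) -> float:
    """Expected contraction magnitude of a Perceptron: the difference in
    P("f1>f2") at f1 = f2 between the low and high frequency regions."""
    m = (np.arange(n_grid) + 0.5) / n_grid * 2 * M_HALF_RANGE - M_HALF_RANGE
    p1 = _prob_one(params.a, params.b, params.sigma, m, m)
    low = p1[m < -REGION_BOUNDARY].mean()
    high = p1[m > REGION_BOUNDARY].mean()
    return float(low - high)
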