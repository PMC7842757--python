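"""Noisy-representation Perceptron model of delayed two-tone discrimination.

The observer holds internal representations ``r1 = s1 + n`` (the remembered
first tone, corrupted by Gaussian noise n ~ N(0, sigma^2)) and ``r2 = s2``
(the just-heard second tone), with stimuli measured in natural-log units
relative to the 1 kHz median.  The response is a linear threshold:

    A = step(h),   h = a * r1 - r2 - b

``a`` weights the remembered stimulus (a < 1 produces contraction bias: the
indifference line in the log f1 x log f2 plane has slope a) and ``b`` is the
decision criterion (choice bias: a parallel shift of that line).

Underweighting the noisy first representation is Bayes-rational: with a
Gaussian prior s1 ~ N(0, Sigma^2) the posterior mean of s1 given r1 is
``r1 / (1 + sigma^2/Sigma^2)``, so the accuracy-maximising weight is
``a = 1 / (1 + sigma^2/Sigma^2)`` and b = 0.  Under the task's actual
uniform stimulus distribution the optimum has no closed form; this module
evaluates the expected feedback rate of any (a, b, sigma) Perceptron under
any feedback protocol by exact integration, and locates the optimum by a
deterministic coarse-to-fine grid search.
"""

from __future__ import annotations

import math
from dataclasses import dataclass

import numpy as np
from scipy.special import ndtr

from .protocols import (
    D_HALF_RANGE,
    M_HALF_RANGE,
    BASE_FREQ_HZ,
    FeedbackProtocol,
    get_protocol,
)

__all__ = [
    "PerceptronParams",
    "InternalRepresentation",
    "DecisionOutcome",
    "PriorSpec",
    "PosteriorBelief",
    "task_s1_variance",
    "task_prior",
    "decide",
    "response_probability",
    "posterior_s1",
    "optimal_a_gaussian",
    "possible_accuracy",
    "impossible_reward",
    "expected_reward",
    "expected_reward_mc",
    "OptimalPerceptron",
    "optimize_params",
    "quadrant_accuracy",
    "response_surface",
    "indifference_line",
]

_SQRT_2PI = math.sqrt(2.0 * math.pi)
# number of midpoints per half-range of d used by the noiseless (step
# function) integration path; the m-integral there is exact
_NOISELESS_D_POINTS = 2000


@dataclass(frozen=True)
class PerceptronParams:
    """Perceptron parameters: first-stimulus weight, criterion, noise SD."""

    a: float
    b: float
    sigma: float

    def __post_init__(self) -> None:
        if not (math.isfinite(self.a) and math.isfinite(self.b)):
            raise ValueError("a and b must be finite")
        if not (math.isfinite(self.sigma) and self.sigma >= 0):
            raise ValueError("sigma must be finite and non-negative")


@dataclass(frozen=True)
class InternalRepresentation:
    """Internal representations of the two tones; r2 is noiseless."""

    r1: float
    r2: float


@dataclass(frozen=True)
class DecisionOutcome:
    """Decision variable h and the binary action A (1 = report "f1>f2")."""

    h: float
    A: int


@dataclass(frozen=True)
class PriorSpec:
    """Prior over s1: its SD, and whether it stands for the Gaussian
    idealisation or the task's uniform-uniform marginal."""

    sigma_prior: float
    family: str = "gaussian"

    def __post_init__(self) -> None:
        if not self.sigma_prior > 0:
            raise ValueError("sigma_prior must be positive")
        if self.family not in ("gaussian", "task_uniform"):
            raise ValueError("family must be 'gaussian' or 'task_uniform'")


@dataclass(frozen=True)
class PosteriorBelief:
    """Gaussian posterior over s1 given the noisy representation r1."""

    mu: float
    rho2: float


def task_s1_variance() -> float:
    """Variance of the generator's s1 marginal (m and d independent uniforms)."""
    return (M_HALF_RANGE**2 + D_HALF_RANGE**2) / 3.0


def task_prior() -> PriorSpec:
    """PriorSpec whose SD matches the task's s1 marginal."""
    return PriorSpec(math.sqrt(task_s1_variance()), family="task_uniform")


def decide(params: PerceptronParams, rep: InternalRepresentation) -> DecisionOutcome:
    """Apply the linear threshold rule; ties (h = 0) resolve to A = 0."""
    if not (math.isfinite(rep.r1) and math.isfinite(rep.r2)):
        raise ValueError("representations must be finite")
    h = params.a * rep.r1 - rep.r2 - params.b
    return DecisionOutcome(h=h, A=int(h > 0))


def _prob_one(a, b, sigma, s1, s2):
    """P(report "f1>f2") for arbitrary broadcastable array arguments.

    h is normal with mean a*s1 - s2 - b and SD |a|*sigma; degenerate cases
    (sigma = 0 or a = 0) give the deterministic step value with ties -> 0.
    """
    a = np.asarray(a, dtype=float)
    mean = a * np.asarray(s1, dtype=float) - np.asarray(s2, dtype=float) - b
    scale = np.abs(a) * sigma
    mean, scale = np.broadcast_arrays(mean, np.broadcast_to(scale, mean.shape))
    out = np.where(mean > 0, 1.0, 0.0)
    noisy = scale > 0
    if np.any(noisy):
        out = np.where(noisy, ndtr(np.divide(mean, scale, where=noisy,
                                             out=np.zeros_like(mean))), out)
    return out


def response_probability(params: PerceptronParams, s1, s2):
    """Probability of reporting "f1>f2" for stimuli in relative log units."""
    res = _prob_one(params.a, params.b, params.sigma, s1, s2)
    if np.ndim(s1) == 0 and np.ndim(s2) == 0:
        return float(res)
    return res


def posterior_s1(r1: float, sigma: float, prior: PriorSpec) -> PosteriorBelief:
    """Gaussian posterior over s1 given r1 (sigma = 0 collapses onto r1)."""
    if sigma < 0:
        raise ValueError("sigma must be non-negative")
    S2 = prior.sigma_prior**2
    if sigma**2 == 0:  # includes subnormal sigma whose square underflows
        return PosteriorBelief(mu=r1, rho2=0.0)
    mu = r1 / (1.0 + sigma**2 / S2)
    rho2 = 1.0 / (1.0 / sigma**2 + 1.0 / S2)
    return PosteriorBelief(mu=mu, rho2=rho2)


def optimal_a_gaussian(sigma: float, prior: PriorSpec) -> float:
    """Accuracy-maximising weight under the Gaussian prior: the shrinkage
    factor 1 / (1 + sigma^2 / Sigma^2).  Strictly decreasing in sigma."""
    if sigma < 0:
        raise ValueError("sigma must be non-negative")
    return 1.0 / (1.0 + sigma**2 / prior.sigma_prior**2)


# ---------------------------------------------------------------------------
# exact integrals of the normal CDF over the stimulus rectangles
# ---------------------------------------------------------------------------

def _phi(u):
    return np.exp(-0.5 * u * u) / _SQRT_2PI


def _g1(u):
    """Antiderivative of the standard normal CDF."""
    return u * ndtr(u) + _phi(u)


def _g2(u):
    """Second antiderivative of the standard normal CDF."""
    return 0.5 * ((u * u + 1.0) * ndtr(u) + u * _phi(u))


def _int_ndtr_line(alpha, c, x0: float, x1: float):
    """Integral of Phi(alpha*x + c) over [x0, x1], vectorised in alpha, c."""
    alpha = np.asarray(alpha, dtype=float)
    c = np.broadcast_to(np.asarray(c, dtype=float), alpha.shape)
    out = np.empty_like(alpha)
    nz = alpha != 0
    a_nz = alpha[nz]
    out[nz] = (_g1(a_nz * x1 + c[nz]) - _g1(a_nz * x0 + c[nz])) / a_nz
    out[~nz] = (x1 - x0) * ndtr(c[~nz])
    return out


def _int_ndtr_rect(alpha, beta, c, m0: float, m1: float, d0: float, d1: float):
    """Integral of Phi(alpha*m + beta*d + c) over [m0,m1] x [d0,d1]."""
    alpha, beta, c = np.broadcast_arrays(
        np.asarray(alpha, dtype=float),
        np.asarray(beta, dtype=float),
        np.asarray(c, dtype=float),
    )
    out = np.empty_like(alpha)
    both = (alpha != 0) & (beta != 0)
    if np.any(both):
        al, be, cc = alpha[both], beta[both], c[both]
        out[both] = (
            _g2(al * m1 + be * d1 + cc)
            - _g2(al * m0 + be * d1 + cc)
            - _g2(al * m1 + be * d0 + cc)
            + _g2(al * m0 + be * d0 + cc)
        ) / (al * be)
    only_b = (alpha == 0) & (beta != 0)
    if np.any(only_b):
        be, cc = beta[only_b], c[only_b]
        out[only_b] = (m1 - m0) * (_g1(be * d1 + cc) - _g1(be * d0 + cc)) / be
    only_a = (alpha != 0) & (beta == 0)
    if np.any(only_a):
        al, cc = alpha[only_a], c[only_a]
        out[only_a] = (d1 - d0) * (_g1(al * m1 + cc) - _g1(al * m0 + cc)) / al
    neither = (alpha == 0) & (beta == 0)
    if np.any(neither):
        out[neither] = (m1 - m0) * (d1 - d0) * ndtr(c[neither])
    return out


def _clip_len(x, width: float):
    return np.clip(x, 0.0, width)


def _possible_accuracy_deterministic(a, b):
    """Fraction correct on possible trials for a noise-free response rule.

    The response is the step function of (a-1)m + (a+1)d - b.  For each
    fixed d the correct-response set in m is an interval whose length is
    computed exactly; the d-integral uses a fine midpoint grid on each half
    (the integrand is piecewise linear with a few kinks).
    """
    a = np.atleast_1d(np.asarray(a, dtype=float))
    b = np.broadcast_to(np.atleast_1d(np.asarray(b, dtype=float)), a.shape)
    nd = _NOISELESS_D_POINTS
    dpos = (np.arange(nd) + 0.5) * (D_HALF_RANGE / nd)
    w = D_HALF_RANGE / nd
    M, D = M_HALF_RANGE, D_HALF_RANGE

    acc = np.empty_like(a)
    one = a == 1.0
    if np.any(one):
        bb = b[one][:, None]
        l_pos = 2 * M * (2.0 * dpos[None, :] > bb)
        # d < 0: correct means A = 0, i.e. -2*dpos - b <= 0
        l_neg = 2 * M * (bb >= -2.0 * dpos[None, :])
        acc[one] = (l_pos.sum(axis=1) + l_neg.sum(axis=1)) * w / (2 * M * 2 * D)
    gen = ~one
    if np.any(gen):
        ag = a[gen][:, None]
        bg = b[gen][:, None]
        up = ag > 1.0
        # d > 0: correct set is {A=1}
        mstar = (bg - (ag + 1.0) * dpos[None, :]) / (ag - 1.0)
        l_pos = np.where(up, _clip_len(M - mstar, 2 * M), _clip_len(mstar + M, 2 * M))
        # d < 0: correct set is the complement of {A=1}
        mstar2 = (bg + (ag + 1.0) * dpos[None, :]) / (ag - 1.0)
        l_a1 = np.where(up, _clip_len(M - mstar2, 2 * M), _clip_len(mstar2 + M, 2 * M))
        l_neg = 2 * M - l_a1
        acc[gen] = (l_pos.sum(axis=1) + l_neg.sum(axis=1)) * w / (2 * M * 2 * D)
    return acc


def possible_accuracy(a, b, sigma: float):
    """Expected fraction of veridically-correct responses on possible trials.

    Integrates the response probability against m ~ U(-0.2, 0.2),
    d ~ U(-0.0905, 0.0905) analytically (the double integral of the normal
    CDF over a rectangle has a closed form).  Accepts arrays of (a, b).
    """
    scalar = np.ndim(a) == 0 and np.ndim(b) == 0
    a = np.atleast_1d(np.asarray(a, dtype=float))
    b = np.broadcast_to(np.atleast_1d(np.asarray(b, dtype=float)), a.shape).copy()
    M, D = M_HALF_RANGE, D_HALF_RANGE
    area_half = 2 * M * D
    acc = np.empty_like(a)

    scale = np.abs(a) * sigma
    det = scale == 0
    if np.any(det):
        acc[det] = _possible_accuracy_deterministic(a[det], b[det])
    noisy = ~det
    if np.any(noisy):
        an, bn, sc = a[noisy], b[noisy], scale[noisy]
        alpha = (an - 1.0) / sc
        beta = (an + 1.0) / sc
        c = -bn / sc
        # P(A=1) integrated over the d>0 half (where A=1 is correct) ...
        i_pos = _int_ndtr_rect(alpha, beta, c, -M, M, 0.0, D)
        # ... and over the d<0 half (where A=0 is correct)
        i_neg = _int_ndtr_rect(alpha, beta, c, -M, M, -D, 0.0)
        acc[noisy] = (i_pos + (area_half - i_neg)) / (2.0 * area_half)
    return float(acc[0]) if scalar else acc


def impossible_reward(a, b, sigma: float, protocol: "str | FeedbackProtocol"):
    """Expected feedback rate on impossible trials (f1 = f2 = e^m kHz).

    The response probability P1(m) = P(A=1 | s1=s2=m) is integrated exactly
    over each half of m ~ U(-0.2, 0.2); the protocol rewards response 1
    with probability p_low below the median and p_high above it.
    """
    proto = get_protocol(protocol)
    scalar = np.ndim(a) == 0 and np.ndim(b) == 0
    a = np.atleast_1d(np.asarray(a, dtype=float))
    b = np.broadcast_to(np.atleast_1d(np.asarray(b, dtype=float)), a.shape).copy()
    M = M_HALF_RANGE

    int_low = np.empty_like(a)   # integral of P1 over [-M, 0]
    int_high = np.empty_like(a)  # integral of P1 over [0, M]
    scale = np.abs(a) * sigma
    det = scale == 0
    if np.any(det):
        ad, bd = a[det], b[det]
        lo = np.empty_like(ad)
        hi = np.empty_like(ad)
        one = ad == 1.0
        # a=1: P1 = step(-b), constant in m
        lo[one] = M * (bd[one] < 0)
        hi[one] = M * (bd[one] < 0)
        gen = ~one
        if np.any(gen):
            mstar = bd[gen] / (ad[gen] - 1.0)
            up = ad[gen] > 1.0  # response 1 where m > mstar
            lo[gen] = np.where(up, _clip_len(-mstar, M), _clip_len(mstar + M, M))
            hi[gen] = np.where(up, _clip_len(M - mstar, M), _clip_len(mstar, M))
        int_low[det], int_high[det] = lo, hi
    noisy = ~det
    if np.any(noisy):
        alpha = (a[noisy] - 1.0) / scale[noisy]
        c = -b[noisy] / scale[noisy]
        int_low[noisy] = _int_ndtr_line(alpha, c, -M, 0.0)
        int_high[noisy] = _int_ndtr_line(alpha, c, 0.0, M)

    p_lo, p_hi = proto.p_reward_f1gt_low, proto.p_reward_f1gt_high
    mean_low = (1.0 - p_lo) + (2.0 * p_lo - 1.0) * int_low / M
    mean_high = (1.0 - p_hi) + (2.0 * p_hi - 1.0) * int_high / M
    res = 0.5 * (mean_low + mean_high)
    return float(res[0]) if scalar else res


def expected_reward(a, b, sigma: float, protocol: "str | FeedbackProtocol"):
    """Expected feedback rate over the whole block: 75% possible trials
    scored veridically plus 25% impossible trials scored per protocol."""
    return 0.75 * possible_accuracy(a, b, sigma) + 0.25 * impossible_reward(
        a, b, sigma, protocol
    )


def expected_reward_mc(
    a: float,
    b: float,
    sigma: float,
    protocol: "str | FeedbackProtocol",
    n_samples: int = 100_000,
    seed: int = 0,
) -> tuple[float, float]:
    """Monte-Carlo cross-check of :func:`expected_reward`.

    Returns (estimate, standard error).  Stimuli and noise are sampled; the
    reward is taken in expectation given the realised response, which keeps
    the estimator unbiased while reducing variance.
    """
    proto = get_protocol(protocol)
    rng = np.random.default_rng(seed)
    n_imp = n_samples // 4
    n_pos = n_samples - n_imp

    m = rng.uniform(-M_HALF_RANGE, M_HALF_RANGE, n_pos)
    d = rng.uniform(-D_HALF_RANGE, D_HALF_RANGE, n_pos)
    noise = rng.normal(0.0, sigma, n_pos) if sigma > 0 else np.zeros(n_pos)
    h = a * (m + d + noise) - (m - d) - b
    resp = h > 0
    reward_pos = (resp == (d > 0)).astype(float)

    mi = rng.uniform(-M_HALF_RANGE, M_HALF_RANGE, n_imp)
    noise_i = rng.normal(0.0, sigma, n_imp) if sigma > 0 else np.zeros(n_imp)
    hi = a * (mi + noise_i) - mi - b
    resp_i = hi > 0
    p1 = np.where(mi < 0, proto.p_reward_f1gt_low, proto.p_reward_f1gt_high)
    reward_imp = np.where(resp_i, p1, 1.0 - p1)

    rewards = np.concatenate([reward_pos, reward_imp])
    est = float(rewards.mean())
    se = float(rewards.std(ddof=1) / math.sqrt(n_samples))
    return est, se


@dataclass(frozen=True)
class OptimalPerceptron:
    """Result of the (a, b) optimisation for one (sigma, protocol)."""

    a: float
    b: float
    expected_reward: float


def optimize_params(
    sigma: float,
    protocol: "str | FeedbackProtocol",
    a_bounds: tuple[float, float] = (-0.5, 2.0),
    b_bounds: tuple[float, float] = (-0.3, 0.3),
    grid: int = 25,
    tol: float = 1e-3,
    init: "tuple[float, float] | None" = None,
) -> OptimalPerceptron:
    """Maximise expected reward over (a, b) by coarse-to-fine grid search.

    Deterministic: each stage evaluates an odd grid over the current box and
    re-centres a box of width 3 grid steps on the maximiser, until both box
    widths fall below ``tol``.  ``init`` (warm start) restricts the first
    box to a neighbourhood of a known good point.
    """
    proto = get_protocol(protocol)
    if sigma < 0:
        raise ValueError("sigma must be non-negative")
    lo_a, hi_a = a_bounds
    lo_b, hi_b = b_bounds
    if init is not None:
        a0, b0 = init
        lo_a, hi_a = max(a_bounds[0], a0 - 0.15), min(a_bounds[1], a0 + 0.15)
        lo_b, hi_b = max(b_bounds[0], b0 - 0.15), min(b_bounds[1], b0 + 0.15)

    best = None
    for _ in range(60):
        av = np.linspace(lo_a, hi_a, grid)
        bv = np.linspace(lo_b, hi_b, grid)
        A, B = np.meshgrid(av, bv, indexing="ij")
        R = expected_reward(A.ravel(), B.ravel(), sigma, proto)
        k = int(np.argmax(R))
        a_star, b_star, r_star = float(A.ravel()[k]), float(B.ravel()[k]), float(R[k])
        best = OptimalPerceptron(a_star, b_star, r_star)
        if max(hi_a - lo_a, hi_b - lo_b) < tol:
            break
        step_a = (hi_a - lo_a) / (grid - 1)
        step_b = (hi_b - lo_b) / (grid - 1)
        lo_a = max(a_bounds[0], a_star - 1.5 * step_a)
        hi_a = min(a_bounds[1], a_star + 1.5 * step_a)
        lo_b = max(b_bounds[0], b_star - 1.5 * step_b)
        hi_b = min(b_bounds[1], b_star + 1.5 * step_b)
    return best


def quadrant_accuracy(
    params: PerceptronParams, n_grid: int = 400
) -> dict[str, float]:
    """Fraction correct in each quadrant of the f1 x f2 plane (split at 1 kHz).

    Keys are "<f1 side>_<f2 side>" with sides "low"/"high"; the straddling
    quadrants are low_high and high_low.  Accuracy integrates the response
    probability over the possible-trial distribution restricted to the
    quadrant (midpoint rule); quadrants with zero stimulus mass get NaN.
    """
    m = (np.arange(n_grid) + 0.5) / n_grid * 2 * M_HALF_RANGE - M_HALF_RANGE
    d = (np.arange(n_grid) + 0.5) / n_grid * 2 * D_HALF_RANGE - D_HALF_RANGE
    Mg, Dg = np.meshgrid(m, d, indexing="ij")
    s1, s2 = Mg + Dg, Mg - Dg
    p1 = _prob_one(params.a, params.b, params.sigma, s1, s2)
    p_correct = np.where(Dg > 0, p1, 1.0 - p1)

    out: dict[str, float] = {}
    for key, mask in {
        "low_low": (s1 < 0) & (s2 < 0),
        "low_high": (s1 < 0) & (s2 > 0),
        "high_low": (s1 > 0) & (s2 < 0),
        "high_high": (s1 > 0) & (s2 > 0),
    }.items():
        n = int(mask.sum())
        out[key] = float(p_correct[mask].mean()) if n else float("nan")
    return out


def response_surface(
    params: PerceptronParams, f1_grid: np.ndarray, f2_grid: np.ndarray
) -> np.ndarray:
    """Matrix of P("f1>f2") with entry [i, j] for (f1_grid[i], f2_grid[j])."""
    f1 = np.asarray(f1_grid, dtype=float)
    f2 = np.asarray(f2_grid, dtype=float)
    if np.any(f1 <= 0) or np.any(f2 <= 0):
        raise ValueError("frequencies must be positive")
    s1 = np.log(f1 / BASE_FREQ_HZ)[:, None]
    s2 = np.log(f2 / BASE_FREQ_HZ)[None, :]
    return _prob_one(params.a, params.b, params.sigma, s1, s2)


def indifference_line(params: PerceptronParams) -> tuple[float, float]:
    """(slope, intercept) of the indifference line s2 = a*s1 - b in the
    (log f1, log f2) plane relative to 1 kHz."""
    return params.a, -params.b
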