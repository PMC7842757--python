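"""The linear-discriminator model: decisions, response probabilities,
Bayesian shrinkage, expected reward and its optimisation."""

import math

import numpy as np
import pytest
from hypothesis import given, settings
from hypothesis import strategies as st
from scipy.special import ndtr

from tonebias.perceptron import (
    DecisionOutcome,
    InternalRepresentation,
    PerceptronParams,
    PriorSpec,
    decide,
    expected_reward,
    expected_reward_mc,
    impossible_reward,
    indifference_line,
    optimal_a_gaussian,
    optimize_params,
    posterior_s1,
    possible_accuracy,
    quadrant_accuracy,
    response_probability,
    response_surface,
    task_prior,
    task_s1_variance,
)
from tonebias.protocols import D_HALF_RANGE, M_HALF_RANGE


@pytest.mark.parametrize(
    "params,rep,expected_A",
    [
        (PerceptronParams(1, 0, 0), InternalRepresentation(0.1, 0.0), 1),
        (PerceptronParams(1, 0.2, 0), InternalRepresentation(0.1, 0.0), 0),
        # a = 0: the first representation is ignored entirely
        (PerceptronParams(0, 0, 0), InternalRepresentation(0.5, -0.05), 1),
        (PerceptronParams(0, 0, 0), InternalRepresentation(-0.5, -0.05), 1),
    ],
)
def test_decide_examples(params, rep, expected_A):
    out = decide(params, rep)
    assert isinstance(out, DecisionOutcome)
    assert out.A == expected_A
    assert out.h == pytest.approx(params.a * rep.r1 - rep.r2 - params.b)


def test_decide_tie_resolves_to_zero():
    assert decide(PerceptronParams(1, 0, 0), InternalRepresentation(0.0, 0.0)).A == 0


def test_response_probability_values():
    # symmetric noise at equal stimuli
    assert response_probability(PerceptronParams(1, 0, 0.1), 0.03, 0.03) == 0.5
    # one-sigma separation: standard normal upper tail at -1
    expected = 0.5 * (1 + math.erf(1 / math.sqrt(2)))
    assert response_probability(PerceptronParams(1, 0, 0.1), 0.1, 0.0) == pytest.approx(
        expected, abs=1e-12
    )
    # deterministic on the second stimulus when a = 0
    assert response_probability(PerceptronParams(0, 0, 0.3), 0.1, 0.05) == 0.0
    assert response_probability(PerceptronParams(0, 0, 0.3), 0.1, -0.05) == 1.0


@settings(max_examples=50, deadline=None, derandomize=True)
@given(
    a=st.floats(0.05, 2.0),
    b=st.floats(-0.2, 0.2),
    sigma=st.floats(0.01, 0.5),
    s=st.floats(-0.25, 0.25),
)
def test_response_probability_monotone_in_stimuli(a, b, sigma, s):
    """For a > 0: non-decreasing in s1, non-increasing in s2."""
    params = PerceptronParams(a, b, sigma)
    grid = np.linspace(-0.3, 0.3, 21)
    p_s1 = np.array([response_probability(params, x, s) for x in grid])
    p_s2 = np.array([response_probability(params, s, x) for x in grid])
    assert np.all(np.diff(p_s1) >= -1e-12)
    assert np.all(np.diff(p_s2) <= 1e-12)
    assert np.all((p_s1 >= 0) & (p_s1 <= 1))


def test_posterior_examples():
    prior = PriorSpec(0.1)
    post = posterior_s1(0.1, 0.1, prior)  # equal precisions halve the estimate
    assert post.mu == pytest.approx(0.05)
    assert post.rho2 == pytest.approx(0.005)
    post0 = posterior_s1(0.07, 0.0, prior)
    assert (post0.mu, post0.rho2) == (0.07, 0.0)
    post_inf = posterior_s1(0.1, 10.0, prior)
    assert abs(post_inf.mu) < 1e-4


@settings(max_examples=50, deadline=None, derandomize=True)
@given(r1=st.floats(-0.5, 0.5), sigma=st.floats(0.0, 1.0), Sigma=st.floats(0.01, 1.0))
def test_posterior_shrinkage_invariants(r1, sigma, Sigma):
    post = posterior_s1(r1, sigma, PriorSpec(Sigma))
    assert post.rho2 <= min(sigma**2, Sigma**2) + 1e-15
    lo, hi = sorted((0.0, r1))
    assert lo - 1e-12 <= post.mu <= hi + 1e-12


def test_optimal_a_gaussian_values():
    prior = PriorSpec(0.1)
    assert optimal_a_gaussian(0.0, prior) == 1.0
    assert optimal_a_gaussian(0.1, prior) == pytest.approx(0.5)
    assert optimal_a_gaussian(0.2, prior) == pytest.approx(0.2)
    sigmas = np.linspace(0, 1, 20)
    values = [optimal_a_gaussian(s, prior) for s in sigmas]
    assert np.all(np.diff(values) < 0)


def test_task_prior_variance_is_uniform_convolution():
    assert task_s1_variance() == pytest.approx(
        (M_HALF_RANGE**2 + D_HALF_RANGE**2) / 3.0
    )
    assert task_prior().sigma_prior == pytest.approx(math.sqrt(task_s1_variance()))


def _accuracy_quadrature_oracle(a, b, sigma, n=1500):
    """Independent midpoint-rule check of the possible-trial accuracy."""
    m = (np.arange(n) + 0.5) / n * 2 * M_HALF_RANGE - M_HALF_RANGE
    d = (np.arange(n) + 0.5) / n * 2 * D_HALF_RANGE - D_HALF_RANGE
    M, D = np.meshgrid(m, d, indexing="ij")
    mean = a * (M + D) - (M - D) - b
    scale = abs(a) * sigma
    p1 = ndtr(mean / scale) if scale > 0 else (mean > 0).astype(float)
    return float(np.where(D > 0, p1, 1 - p1).mean())


@pytest.mark.parametrize(
    "a,b,sigma",
    [(0.7, 0.05, 0.1), (1.0, 0.0, 0.05), (-0.3, 0.1, 0.2), (1.3, -0.1, 0.02),
     (0.5, 0.0, 0.0), (0.0, 0.02, 0.1)],
)
def test_possible_accuracy_matches_quadrature_oracle(a, b, sigma):
    assert possible_accuracy(a, b, sigma) == pytest.approx(
        _accuracy_quadrature_oracle(a, b, sigma), abs=2e-4
    )


def test_expected_reward_examples():
    # noiseless veridical observer: perfect on possible, coin-flip on impossible
    assert expected_reward(1.0, 0.0, 0.0, "control") == pytest.approx(0.875, abs=1e-12)
    # ignoring the first tone still beats chance
    for sigma in (0.0, 0.1, 0.5):
        assert expected_reward(0.0, 0.0, sigma, "control") > 0.5


def test_expected_reward_symmetric_in_criterion_under_control():
    for a, sigma in [(0.8, 0.1), (1.2, 0.05), (0.5, 0.2)]:
        for b in (0.02, 0.1, 0.25):
            assert expected_reward(a, b, sigma, "control") == pytest.approx(
                expected_reward(a, -b, sigma, "control"), abs=1e-12
            )


def test_expected_reward_monte_carlo_agreement():
    for proto in ("control", "enhance_contraction"):
        est, se = expected_reward_mc(0.7, 0.05, 0.1, proto, n_samples=100_000, seed=9)
        assert abs(est - expected_reward(0.7, 0.05, 0.1, proto)) < 3 * se


def test_impossible_reward_control_is_half_for_any_observer():
    # unbiased reward draws make the impossible-trial rate exactly 1/2 when
    # the observer's own response distribution is symmetric (b = 0, a = 1),
    # and still 1/2 in expectation over reward draws for any fixed response
    assert impossible_reward(1.0, 0.0, 0.1, "control") == pytest.approx(0.5)
    assert impossible_reward(0.3, 0.2, 0.4, "control") == pytest.approx(0.5)


def test_optimize_noise_free_control():
    res = optimize_params(0.0, "control")
    assert res.a == pytest.approx(1.0, abs=2e-3)
    assert res.b == pytest.approx(0.0, abs=1e-3)
    assert res.expected_reward == pytest.approx(0.875, abs=1e-6)


def test_optimize_control_b_zero_and_a_decreasing():
    a_stars = []
    for sigma in (0.05, 0.1, 0.2):
        res = optimize_params(sigma, "control")
        assert abs(res.b) < 5e-3
        assert 0.0 < res.a <= 1.0
        a_stars.append(res.a)
    assert a_stars[0] > a_stars[1] > a_stars[2]


def test_optimize_a_approaches_one_for_small_noise():
    assert optimize_params(0.01, "control").a == pytest.approx(1.0, abs=0.02)


def test_optimize_protocol_ordering_at_sigma_01():
    a_sup = optimize_params(0.1, "suppress_contraction").a
    a_ctrl = optimize_params(0.1, "control").a
    a_enh = optimize_params(0.1, "enhance_contraction").a
    assert a_sup > a_ctrl > a_enh


def test_optimize_choice_protocols_shift_criterion():
    b_enh = optimize_params(0.1, "enhance_f1gt").b
    b_sup = optimize_params(0.1, "suppress_f1gt").b
    # rewarding "f1>f2" lowers the criterion (more response 1), and vice versa
    assert b_enh < -5e-3 < 5e-3 < b_sup
    assert b_enh == pytest.approx(-b_sup, abs=1e-3)


def test_quadrant_accuracy():
    q0 = quadrant_accuracy(PerceptronParams(0, 0, 0.1))
    assert q0["low_high"] == 1.0 and q0["high_low"] == 1.0
    assert q0["low_low"] == pytest.approx(0.5, abs=0.01)
    assert q0["high_high"] == pytest.approx(0.5, abs=0.01)
    q1 = quadrant_accuracy(PerceptronParams(1, 0, 0.0))
    assert all(v == 1.0 for v in q1.values())


def test_response_surface_shape_and_indifference_line():
    params = PerceptronParams(0.75, 0.02, 0.1)
    f = 1000.0 * np.exp(np.linspace(-0.25, 0.25, 41))
    P = response_surface(params, f, f)
    assert P.shape == (41, 41)
    # increasing in f1 (rows), decreasing in f2 (columns)
    assert np.all(np.diff(P, axis=0) >= -1e-12)
    assert np.all(np.diff(P, axis=1) <= 1e-12)
    # points on s2 = a*s1 - b are at indifference
    slope, intercept = indifference_line(params)
    assert (slope, intercept) == (0.75, -0.02)
    for s1 in (-0.1, 0.0, 0.1):
        s2 = slope * s1 + intercept
        assert response_probability(params, s1, s2) == pytest.approx(0.5, abs=1e-12)


def test_parameter_validation():
    with pytest.raises(ValueError):
        PerceptronParams(1.0, 0.0, -0.1)
    with pytest.raises(ValueError):
        PerceptronParams(math.nan, 0.0, 0.1)
    with pytest.raises(ValueError):
        PriorSpec(0.0)
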