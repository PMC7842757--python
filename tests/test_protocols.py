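"""Block generation, feedback delivery, exclusion screen, and trial-log IO."""

import math

import numpy as np
import pytest
from hypothesis import given, settings
from hypothesis import strategies as st
from scipy import stats

from tonebias.protocols import (
    D_HALF_RANGE,
    M_HALF_RANGE,
    StimulusPair,
    TrialRecord,
    TrialLog,
    assign_feedback,
    exclusion_test,
    generate_block,
    get_protocol,
    minimal_passing_fraction,
    read_trial_log,
    write_trial_log,
)
from tests.conftest import make_static_log


@pytest.mark.parametrize("n_trials,expected_impossible", [(4, 1), (220, 55), (1000, 250)])
def test_block_counts_and_bounds(n_trials, expected_impossible):
    block = generate_block("control", n_trials, seed=7)
    frame = block.to_frame()
    assert int(frame["is_impossible"].sum()) == expected_impossible
    f_low = 1000.0 * math.exp(-(M_HALF_RANGE + D_HALF_RANGE))
    f_high = 1000.0 * math.exp(M_HALF_RANGE + D_HALF_RANGE)
    assert frame[["f1_hz", "f2_hz"]].to_numpy().min() >= f_low
    assert frame[["f1_hz", "f2_hz"]].to_numpy().max() <= f_high
    assert np.all(np.abs(frame["m"]) <= M_HALF_RANGE)
    possible = frame[~frame["is_impossible"]]
    assert np.all(np.abs(possible["d"]) <= D_HALF_RANGE)
    assert np.all(possible["d"] != 0.0)
    impossible = frame[frame["is_impossible"]]
    # f1 = f2 must be bit-exact on impossible trials
    assert np.all(impossible["f1_hz"].to_numpy() == impossible["f2_hz"].to_numpy())
    assert np.all(impossible["d"] == 0.0)


def test_stimulus_identities_exact(control_block):
    for t in control_block.trials:
        s = t.stimulus
        assert s.s1 == s.m + s.d
        assert s.s2 == s.m - s.d
        assert s.is_impossible == (s.d == 0.0)


def test_block_determinism():
    a = generate_block("enhance_contraction", 220, seed=42)
    b = generate_block("enhance_contraction", 220, seed=42)
    assert a.to_frame().equals(b.to_frame())


def test_block_validation_errors():
    with pytest.raises(ValueError, match="divisible by 4"):
        generate_block("control", 10, seed=0)
    with pytest.raises(ValueError, match="positive"):
        generate_block("control", -4, seed=0)
    with pytest.raises(ValueError, match="unknown protocol"):
        generate_block("nonexistent", 220, seed=0)


def test_stimulus_marginals(big_control_block):
    """Empirical means of m and d sit within 3 SE of zero, ranges respected."""
    frame = big_control_block.to_frame()
    possible = frame[~frame["is_impossible"]]
    n = len(possible)
    se_m = (M_HALF_RANGE / math.sqrt(3.0)) / math.sqrt(n)
    se_d = (D_HALF_RANGE / math.sqrt(3.0)) / math.sqrt(n)
    assert abs(possible["m"].mean()) < 3 * se_m
    assert abs(possible["d"].mean()) < 3 * se_d


def test_feedback_possible_trials_veridical():
    trial = TrialRecord(1, StimulusPair(m=0.0, d=0.05))  # s1 > s2
    assert assign_feedback("control", trial, 1) == 1
    assert assign_feedback("control", trial, 0) == 0


def test_feedback_impossible_follows_draw_and_rejects_m_zero():
    trial = TrialRecord(1, StimulusPair(m=-0.1, d=0.0), rewarded_response_draw=1)
    assert assign_feedback("enhance_contraction", trial, 1) == 1
    assert assign_feedback("enhance_contraction", trial, 0) == 0
    degenerate = TrialRecord(1, StimulusPair(m=0.0, d=0.0), rewarded_response_draw=1)
    with pytest.raises(ValueError, match="m = 0"):
        assign_feedback("control", degenerate, 1)
    with pytest.raises(ValueError, match="response"):
        assign_feedback("control", trial, 2)


def test_control_reward_rate_is_half(big_control_block):
    """Under unbiased feedback any fixed response earns reward half the time."""
    frame = big_control_block.to_frame()
    draws = frame.loc[frame["is_impossible"], "rewarded_response_draw"].to_numpy()
    n = len(draws)
    assert abs(draws.mean() - 0.5) < 3 * math.sqrt(0.25 / n)


def test_contraction_protocol_draw_probabilities():
    """Rewarded-response draws follow Table-style side-dependent probabilities."""
    block = generate_block("enhance_contraction", 20_000, seed=5)
    frame = block.to_frame()
    imp = frame[frame["is_impossible"]]
    low = imp.loc[imp["m"] < 0, "rewarded_response_draw"].to_numpy()
    high = imp.loc[imp["m"] > 0, "rewarded_response_draw"].to_numpy()
    assert abs(low.mean() - 0.9) < 3 * math.sqrt(0.09 / len(low))
    assert abs(high.mean() - 0.1) < 3 * math.sqrt(0.09 / len(high))


def _binom_two_sided_oracle(k: int, n: int) -> float:
    """Two-sided exact binomial p by direct enumeration of the pmf."""
    pmf = np.array([math.comb(n, i) * 0.5**n for i in range(n + 1)])
    return float(pmf[pmf <= pmf[k] * (1 + 1e-12)].sum())


@pytest.mark.parametrize("n", [5, 17, 40, 82, 100])
def test_exact_binomial_matches_enumeration(n):
    for k in range(0, n + 1, max(1, n // 7)):
        assert stats.binomtest(k, n, 0.5).pvalue == pytest.approx(
            _binom_two_sided_oracle(k, n), abs=1e-12
        )


def _block_with_accuracy(n_per_half_correct):
    """Possible-only synthetic block: 20 trials/half, given correct counts."""
    trials = []
    idx = 1
    for n_correct in n_per_half_correct:
        for i in range(20):
            stim = StimulusPair(m=0.0, d=0.05)
            resp = 1 if i < n_correct else 0
            trials.append(
                TrialRecord(idx, stim, response=resp,
                            feedback=assign_feedback("control", TrialRecord(idx, stim), resp))
            )
            idx += 1
    return TrialLog("control", "obs0", None, trials)


def test_exclusion_decisions():
    assert exclusion_test(_block_with_accuracy([20, 20])).decision == "keep"
    res = exclusion_test(_block_with_accuracy([10, 20]))
    assert res.decision == "exclude"
    assert res.p_first == pytest.approx(1.0)


def test_exclusion_requires_responses(control_block):
    with pytest.raises(ValueError, match="responses"):
        exclusion_test(control_block)


def test_minimal_passing_fraction_rounds_to_62_percent():
    k, frac = minimal_passing_fraction(82, alpha=0.05)
    assert k == 51
    assert round(100 * frac) == 62
    # one-sided would pass at a lower count, so sidedness matters
    assert stats.binomtest(k - 1, 82, 0.5).pvalue >= 0.05


def test_trial_log_roundtrip(tmp_path):
    log = make_static_log(protocol="suppress_contraction", sigma=0.1, a=0.8,
                          block_seed=3, obs_seed=4)
    path = tmp_path / "log.csv"
    write_trial_log(log, path)
    back = read_trial_log(path)
    assert back.protocol == log.protocol
    assert back.observer_id == log.observer_id
    for t0, t1 in zip(log.trials, back.trials):
        assert t1.index == t0.index
        assert t1.response == t0.response
        assert t1.feedback == t0.feedback
        assert t1.rewarded_response_draw == t0.rewarded_response_draw
        assert t1.stimulus.f1 == pytest.approx(t0.stimulus.f1, rel=1e-12)
        assert t1.stimulus.f2 == pytest.approx(t0.stimulus.f2, rel=1e-12)
        assert t1.stimulus.is_impossible == t0.stimulus.is_impossible


def test_roundtrip_without_responses(tmp_path, control_block):
    path = tmp_path / "block.csv"
    write_trial_log(control_block, path)
    back = read_trial_log(path)
    assert all(t.response is None and t.feedback is None for t in back.trials)


def test_read_validation_errors(tmp_path, control_block):
    path = tmp_path / "log.csv"
    write_trial_log(control_block, path)
    text = path.read_text().splitlines()

    # missing column
    broken = "\n".join(line.rsplit(",", 1)[0] for line in text)
    p = tmp_path / "missing.csv"
    p.write_text(broken + "\n")
    with pytest.raises(ValueError, match="missing columns"):
        read_trial_log(p)

    # non-numeric frequency on a specific row
    rows = list(text)
    parts = rows[3].split(",")
    parts[3] = "oops"
    rows[3] = ",".join(parts)
    p2 = tmp_path / "badfreq.csv"
    p2.write_text("\n".join(rows) + "\n")
    with pytest.raises(ValueError, match="row 3"):
        read_trial_log(p2)

    # response outside {0, 1}
    rows = list(text)
    parts = rows[5].split(",")
    parts[7] = "2"
    rows[5] = ",".join(parts)
    p3 = tmp_path / "badresp.csv"
    p3.write_text("\n".join(rows) + "\n")
    with pytest.raises(ValueError, match="row 5"):
        read_trial_log(p3)

    # dropped row breaks the contiguous index
    rows = list(text)
    del rows[10]
    p4 = tmp_path / "gap.csv"
    p4.write_text("\n".join(rows) + "\n")
    with pytest.raises(ValueError, match="trial_index"):
        read_trial_log(p4)


@settings(max_examples=25, deadline=None, derandomize=True)
@given(seed=st.integers(min_value=0, max_value=2**31 - 1))
def test_generator_invariants_over_seeds(seed):
    block = generate_block("control", 8, seed=seed)
    frame = block.to_frame()
    assert int(frame["is_impossible"].sum()) == 2
    assert list(frame["trial_index"]) == list(range(1, 9))
    for t in block.trials:
        s = t.stimulus
        assert s.s1 == s.m + s.d and s.s2 == s.m - s.d
        if s.is_impossible:
            assert t.rewarded_response_draw in (0, 1)
            assert s.m != 0.0
        else:
            assert t.rewarded_response_draw is None


def test_get_protocol_table_values():
    assert get_protocol("control").p_reward_f1gt_low == 0.5
    assert get_protocol("enhance_f1gt").p_reward_f1gt_high == 0.9
    p = get_protocol("suppress_contraction")
    assert (p.p_reward_f1gt_low, p.p_reward_f1gt_high) == (0.1, 0.9)
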