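"""Sequence constraints, press detection, and behavioral statistics."""

import itertools

import numpy as np
import pytest
from hypothesis import given, settings
from hypothesis import strategies as st

from seqmvpa import seqtask
from seqmvpa.seqtask import (
    ForceTrace,
    IncompleteTrialError,
    PressEvent,
    SequenceSet,
    all_valid_sequences,
    detect_presses,
    generate_sequence_pool,
    is_valid_sequence,
    movement_time,
    sequence_specific_test,
    split_pool,
    transition_overlap,
    transitions,
)


def brute_force_valid_count() -> int:
    """Independent enumeration: scan every window of 4 for a +/-1 staircase."""
    count = 0
    for p in itertools.permutations([1, 2, 3, 4, 5]):
        ok = True
        for i in range(2):
            w = p[i : i + 4]
            if w in (tuple(range(w[0], w[0] + 4)), tuple(range(w[0], w[0] - 4, -1))):
                ok = False
        count += ok
    return count


class TestSequenceValidity:
    def test_enumeration_matches_brute_force(self):
        n = brute_force_valid_count()
        assert len(all_valid_sequences()) == n
        assert n == 114  # frozen from the enumeration oracle

    @pytest.mark.parametrize(
        "seq,expected",
        [
            ((3, 2, 5, 1, 4), True),  # example trial sequence
            ((1, 2, 3, 4, 5), False),  # full ascending run
            ((5, 4, 3, 2, 1), False),  # full descending run
            ((1, 2, 3, 5, 4), True),  # ascending run of only 3
            ((2, 3, 4, 5, 1), False),  # ascending run of 4 at start
            ((1, 5, 4, 3, 2), False),  # descending run of 4 at end
            ((1, 2, 3, 4), False),  # not a permutation of 1..5
            ((1, 1, 2, 3, 4), False),
        ],
    )
    def test_run_constraint(self, seq, expected):
        assert is_valid_sequence(seq) is expected

    def test_every_sequence_has_4_transitions_and_5_digits(self):
        for s in all_valid_sequences():
            assert len(transitions(s)) == 4
            assert len(set(s)) == 5


class TestPoolGeneration:
    def test_pool_is_distinct_and_valid(self):
        pool = generate_sequence_pool(12, rng_seed=0)
        assert len(pool) == 12
        assert len(set(pool.sequences)) == 12

    def test_infeasible_request_raises(self):
        with pytest.raises(ValueError, match="114"):
            generate_sequence_pool(115, rng_seed=0)

    def test_seed_determinism(self):
        a = generate_sequence_pool(12, rng_seed=7)
        b = generate_sequence_pool(12, rng_seed=7)
        assert a.sequences == b.sequences

    def test_draws_cover_the_valid_set(self):
        # over many draws every valid sequence should appear (uniformity smoke)
        seen = set()
        for seed in range(300):
            seen.update(generate_sequence_pool(12, rng_seed=seed).sequences)
        assert seen == set(all_valid_sequences())

    def test_split_is_a_partition(self):
        pool = generate_sequence_pool(12, rng_seed=1)
        groups = split_pool(pool, 3, rng_seed=2)
        assert [len(g) for g in groups] == [4, 4, 4]
        union = [s for g in groups for s in g]
        assert sorted(union) == sorted(pool.sequences)

    def test_split_identity_and_determinism(self):
        pool = generate_sequence_pool(4, rng_seed=3)
        (only,) = split_pool(pool, 1, rng_seed=0)
        assert sorted(only.sequences) == sorted(pool.sequences)
        g1 = split_pool(pool, 2, rng_seed=9)
        g2 = split_pool(pool, 2, rng_seed=9)
        assert [a.sequences for a in g1] == [a.sequences for a in g2]

    def test_split_indivisible_raises(self):
        pool = generate_sequence_pool(10, rng_seed=0)
        with pytest.raises(ValueError):
            split_pool(pool, 3, rng_seed=0)


class TestTransitionOverlap:
    def test_identical_sets_share_everything(self):
        s = SequenceSet(((1, 3, 5, 2, 4), (2, 4, 1, 3, 5)))
        assert transition_overlap(s, s) == 100.0

    def test_hand_enumerated_half_overlap(self):
        ref = SequenceSet(((1, 3, 5, 2, 4),))
        probe = SequenceSet(((1, 3, 5, 4, 2),))
        # shared: 1->3, 3->5; not shared: 5->4, 4->2
        assert transition_overlap(ref, probe) == 50.0

    def test_empty_set_raises(self):
        s = SequenceSet(((1, 3, 5, 2, 4),))
        with pytest.raises(ValueError):
            transition_overlap(SequenceSet(()), s)

    @settings(max_examples=50, derandomize=True)
    @given(st.integers(0, 10_000), st.integers(0, 10_000))
    def test_overlap_bounded(self, seed_a, seed_b):
        a = generate_sequence_pool(4, rng_seed=seed_a)
        b = generate_sequence_pool(4, rng_seed=seed_b)
        assert 0.0 <= transition_overlap(a, b) <= 100.0


def trace_from_onsets(onsets_s, fingers, fs=200.0, press_n=3.0, width_s=0.15):
    """Build a clean force trace with one bump per requested press."""
    t_end = max(onsets_s) + 0.5
    t = np.arange(0, t_end, 1.0 / fs)
    f = np.zeros((t.size, 5))
    for onset, finger in zip(onsets_s, fingers):
        mask = (t >= onset) & (t < onset + width_s)
        f[mask, finger - 1] = press_n
    return ForceTrace(t, f)


class TestPressDetection:
    def test_single_ramp_triggers_at_threshold(self):
        t = np.arange(0, 1.0, 0.005)
        f = np.zeros((t.size, 5))
        f[:, 1] = 5.0 * t  # reaches 2.5 N at t=0.5
        events = detect_presses(ForceTrace(t, f))
        assert len(events) == 1
        assert events[0].finger == 2
        assert events[0].onset == pytest.approx(0.5, abs=0.005)

    def test_other_finger_above_22_blocks_press(self):
        t = np.arange(0, 1.0, 0.005)
        f = np.zeros((t.size, 5))
        f[:, 1] = 3.0  # finger 2 pressing throughout
        f[t < 0.5, 2] = 2.3  # finger 3 held above 2.2 N for first half
        events = detect_presses(ForceTrace(t, f))
        assert [e.finger for e in events] == [2]
        assert events[0].onset >= 0.5

    def test_tie_at_exactly_2_2_blocks(self):
        t = np.arange(0, 0.1, 0.005)
        f = np.zeros((t.size, 5))
        f[:, 0] = 3.0
        f[:, 4] = 2.2  # exactly at the interference threshold
        assert detect_presses(ForceTrace(t, f)) == []

    def test_round_trip_recovers_onsets(self):
        onsets = [0.10, 0.35, 0.60, 0.85, 1.10]
        fingers = [3, 2, 5, 1, 4]
        events = detect_presses(trace_from_onsets(onsets, fingers))
        assert [e.finger for e in events] == fingers
        assert np.allclose([e.onset for e in events], onsets, atol=1e-9)

    def test_subthreshold_noise_leaves_events_unchanged(self, rng):
        onsets = [0.1, 0.3, 0.5, 0.7, 0.9]
        fingers = [1, 4, 2, 5, 3]
        clean = trace_from_onsets(onsets, fingers)
        noisy = ForceTrace(
            clean.time, clean.forces + rng.uniform(0, 0.09, clean.forces.shape)
        )
        assert detect_presses(clean) == detect_presses(noisy)

    def test_empty_trace_raises(self):
        with pytest.raises(ValueError):
            detect_presses(ForceTrace(np.array([]), np.empty((0, 5))))

    def test_refractory_until_release(self):
        # force stays above 2.2 N between two peaks -> only one press
        t = np.arange(0, 1.0, 0.005)
        f = np.zeros((t.size, 5))
        f[:, 0] = 2.3
        f[(t >= 0.1) & (t < 0.2), 0] = 3.0
        f[(t >= 0.5) & (t < 0.6), 0] = 3.0
        assert len(detect_presses(ForceTrace(t, f))) == 1


class TestMovementTime:
    def test_onset_to_onset(self):
        presses = [PressEvent(i + 1, 0.1 * i) for i in range(5)]
        assert movement_time(presses) == pytest.approx(400.0)

    def test_degenerate_zero(self):
        presses = [PressEvent(i + 1, 1.0) for i in range(5)]
        assert movement_time(presses) == 0.0

    def test_incomplete_trial(self):
        with pytest.raises(IncompleteTrialError):
            movement_time([PressEvent(1, 0.0)] * 4)

    def test_round_trip_mt(self):
        onsets = [0.2, 0.45, 0.62, 0.95, 1.40]
        events = detect_presses(trace_from_onsets(onsets, [1, 2, 3, 4, 5]))
        assert movement_time(events) == pytest.approx(1200.0, abs=1.0)


class TestSequenceSpecificTest:
    def test_zero_post_difference(self):
        pre = np.array([10.0, -5.0, 3.0, 8.0])
        intercept, t, p = sequence_specific_test(pre, np.zeros(4))
        assert intercept == pytest.approx(0.0)
        assert t == pytest.approx(0.0)

    def test_matches_closed_form_ols(self, rng):
        x = rng.normal(0, 50, 20)
        y = 100 + 0.4 * x + rng.normal(0, 30, 20)
        intercept, t, p = sequence_specific_test(x, y)
        # closed-form simple regression oracle
        xb, yb = x.mean(), y.mean()
        slope = np.sum((x - xb) * (y - yb)) / np.sum((x - xb) ** 2)
        a = yb - slope * xb
        resid = y - a - slope * x
        s2 = np.sum(resid**2) / (len(x) - 2)
        se_a = np.sqrt(s2 * (1 / len(x) + xb**2 / np.sum((x - xb) ** 2)))
        assert intercept == pytest.approx(a, rel=1e-10)
        assert t == pytest.approx(a / se_a, rel=1e-10)

    def test_recovers_injected_advantage(self, rng):
        # 237 ms advantage at zero pre-test difference, small noise
        pre = rng.normal(0, 40, 16)
        post = 237.0 + 0.3 * pre + rng.normal(0, 30, 16)
        intercept, t, p = sequence_specific_test(pre, post)
        assert intercept == pytest.approx(237.0, abs=30.0)
        assert p < 0.001

    def test_too_few_subjects(self):
        with pytest.raises(ValueError):
            sequence_specific_test(np.array([1.0, 2.0]), np.array([1.0, 2.0]))


def test_behavioral_table_round_trip(tmp_path, rng):
    import seqmvpa as sm

    sched = sm.make_schedule(n_runs=2, rng_seed=0)
    rec = sm.simulate_behavior(sched, [1200, 1250, 1300, 1350], rng_seed=1)
    path = tmp_path / "behavior.tsv"
    seqtask.write_behavioral_table(rec, path)
    back = seqtask.read_behavioral_table(path)
    assert len(back) == len(rec)
    assert back["error"].dtype == bool
    np.testing.assert_allclose(back["MT_ms"], rec["MT_ms"])
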