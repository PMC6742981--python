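"""Learning-measure unit and property tests against brute-force oracles."""

import numpy as np
import pytest
from hypothesis import given, settings, strategies as st

from revlearn import (
    compute_phase_metrics,
    find_change_point,
    flexibility_score,
    max_consecutive_incorrect,
    regress_score,
    role_map_for,
    split_pre_post,
    trials_to_criterion,
)
from revlearn.learning_metrics import NOT_REACHED

from oracles import (
    change_point_oracle,
    fs_oracle,
    maxci_oracle,
    regress_oracle,
    ttc_oracle,
)


def random_sequences(n_seqs, rng):
    for _ in range(n_seqs):
        n = int(rng.integers(10, 401))
        p = float(rng.uniform(0.2, 0.95))
        yield (rng.random(n) < p).astype(int).tolist()


class TestTrialsToCriterion:
    def test_all_correct_reaches_at_window_end(self):
        assert trials_to_criterion([1] * 20) == 20
        assert trials_to_criterion([1] * 50) == 20

    def test_alternating_never_reaches(self):
        assert trials_to_criterion([1, 0] * 50) is NOT_REACHED

    def test_short_sequence_not_reached(self):
        assert trials_to_criterion([]) is NOT_REACHED
        assert trials_to_criterion([1] * 19) is NOT_REACHED

    def test_window_never_spans_sessions(self):
        # 10 correct at the end of session 1 plus 10 at the start of session
        # 2 do not form a criterion window; 20 within session 2 do
        correct = [1] * 10 + [1] * 20
        sessions = [1] * 10 + [2] * 20
        assert trials_to_criterion(correct, sessions) == 30

    def test_matches_exhaustive_scan_with_sessions(self):
        rng = np.random.default_rng(11)
        for _ in range(300):
            n = int(rng.integers(10, 300))
            correct = (rng.random(n) < rng.uniform(0.5, 0.95)).astype(int).tolist()
            sessions = np.sort(rng.integers(1, 4, size=n)).tolist()
            assert trials_to_criterion(correct, sessions) == ttc_oracle(
                correct, sessions
            )


class TestChangePoint:
    def test_all_correct_is_degenerate(self):
        res = find_change_point([1] * 10)
        assert res.degenerate and res.cp_index == 1
        assert np.allclose(res.deviation, 0.0)

    def test_step_sequence(self):
        # deviation maximal where the flat segment ends; that trial is
        # designated the first POST trial
        res = find_change_point([0, 0, 0, 1, 1, 1])
        assert res.cp_index == 3 and not res.degenerate

    def test_too_short_raises(self):
        with pytest.raises(ValueError):
            find_change_point([1])

    def test_matches_oracle_on_random_sequences(self):
        rng = np.random.default_rng(12)
        for seq in random_sequences(300, rng):
            res = find_change_point(seq)
            cp, devs, degen = change_point_oracle(seq)
            assert res.cp_index == cp
            assert res.degenerate == degen
            assert np.allclose(res.deviation, devs)

    @pytest.mark.parametrize("k,m", [(3, 3), (10, 30), (25, 5)])
    def test_planted_step_located_exactly(self, k, m):
        # k flat trials then m perfect trials: deviation peaks at the end
        # of the flat segment, trial k
        res = find_change_point([0] * k + [1] * m)
        assert res.cp_index == k

    def test_immediate_learning_is_degenerate(self):
        # a single flat trial then perfect: the curve tracks the chord from
        # trial 1, so there is no positive deviation
        res = find_change_point([0] + [1] * 50)
        assert res.degenerate and res.cp_index == 1

    def test_ties_resolve_to_earliest_trial(self):
        # symmetric valley: deviation equal at both shoulders
        res = find_change_point([0, 1, 0, 1, 1, 0, 1])
        tied = np.flatnonzero(
            np.isclose(res.deviation, res.deviation.max())
        )
        assert res.cp_index == tied[0] + 1


class TestFlexibilityScore:
    def test_deterministic_win_stay_lose_shift(self):
        # alternating W/L: every post-loss trial correct, every post-win too
        fs, p_ls, p_ws = flexibility_score([1, 1, 1, 0, 1, 1, 0, 1])
        assert p_ws is not None and p_ls == 1.0

    def test_all_correct_has_no_lose_component(self):
        fs, p_ls, p_ws = flexibility_score([1] * 10)
        assert p_ls is None and fs is None and p_ws == 1.0

    def test_counted_example(self):
        # losses at 1,4,5,8 -> followers 1,0,1,1 (3/4 correct);
        # wins at 2,3,6,7 -> followers 1,0,1,0 (2/4 correct)
        seq = [0, 1, 1, 0, 0, 1, 1, 0, 1]
        fs, p_ls, p_ws = flexibility_score(seq)
        assert p_ls == pytest.approx(3 / 4)
        assert p_ws == pytest.approx(1 / 2)
        assert fs == pytest.approx(1 / 4)

    @given(st.lists(st.integers(0, 1), min_size=2, max_size=200))
    @settings(max_examples=200, deadline=None)
    def test_matches_oracle_and_bounded(self, seq):
        fs, p_ls, p_ws = flexibility_score(seq)
        ofs, opls, opws = fs_oracle(seq)
        assert fs == ofs and p_ls == opls and p_ws == opws
        if fs is not None:
            assert -1.0 <= fs <= 1.0

    def test_antisymmetric_under_component_swap(self):
        fs, p_ls, p_ws = flexibility_score([0, 1, 1, 0, 0, 1, 0, 0, 1, 1])
        assert fs == pytest.approx(-(p_ws - p_ls))


class TestMaxci:
    @pytest.mark.parametrize(
        "seq,expected",
        [
            ([1] * 8, 0),
            ([], 0),
            ([0] * 7, 7),
            ([0, 1, 0, 0, 0, 1, 0, 0], 3),
        ],
    )
    def test_known_values(self, seq, expected):
        assert max_consecutive_incorrect(seq) == expected

    @given(st.lists(st.integers(0, 1), max_size=300))
    @settings(max_examples=200, deadline=None)
    def test_matches_oracle(self, seq):
        assert max_consecutive_incorrect(seq) == maxci_oracle(seq)


class TestRegressScore:
    def test_monotone_improvement_scores_zero(self):
        assert regress_score([0] * 5 + [1] * 10) == 0.0

    def test_hand_computed_step_down(self):
        # accuracy drops from the first to the second block of 5 then
        # recovers; oracle-evaluated sliding sum frozen here
        seq = [1, 1, 1, 1, 1, 0, 0, 0, 0, 0, 1, 1, 1, 1, 1]
        assert regress_score(seq) == pytest.approx(regress_oracle(seq))
        assert regress_score(seq) > 0

    def test_short_sequence_absent(self):
        assert regress_score([1, 0] * 4) is None

    @given(st.lists(st.integers(0, 1), min_size=10, max_size=300))
    @settings(max_examples=200, deadline=None)
    def test_matches_oracle(self, seq):
        assert regress_score(seq) == pytest.approx(regress_oracle(seq))

    def test_nonoverlapping_variant_on_block_structure(self):
        # block accuracies 1.0, 0.0, 1.0 -> one decline of 1.0 over 15 trials
        seq = [1] * 5 + [0] * 5 + [1] * 5
        assert regress_score(seq, sliding=False) == pytest.approx(1.0 / 15)


class TestSplitAndPhaseMetrics:
    def test_split_conserves_counts(self, hand_series):
        series, profile = hand_series
        pm = compute_phase_metrics(series, role_map_for(profile))
        assert pm.pre.n_trials + pm.post.n_trials == pm.trials_to_criterion

    def test_degenerate_cp_gives_empty_pre(self):
        res = find_change_point([1, 1, 1, 1])
        pre, post = split_pre_post([], res)
        assert pre == [] and post == []

    def test_phase_metrics_flags_non_criterion(self, hand_series):
        series, profile = hand_series
        short = type(series)(
            subject_id=series.subject_id,
            phase=series.phase,
            trials=series.trials[:12],
        )
        pm = compute_phase_metrics(short, role_map_for(profile))
        assert not pm.reached_criterion
        assert pm.trials_to_criterion is None
        assert pm.pre.n_trials + pm.post.n_trials == 11  # one omission dropped
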