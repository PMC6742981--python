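"""Trial-table and event-log I/O: round trips, validation, reconstruction."""

import pytest

from revlearn import (
    Choice,
    Outcome,
    Phase,
    PhaseSeries,
    Side,
    TrialRecord,
    parse_event_log,
    read_trial_table,
    write_trial_table,
)
from revlearn.trial_model import EventLogError, SchemaError, ValidationError


def _record(**overrides):
    base = dict(
        subject_id="s1",
        phase=Phase.ACQ,
        session_index=1,
        trial_index=1,
        correct_side=Side.LEFT,
        choice=Choice.LEFT,
        outcome=Outcome.REWARDED,
        trial_initiation_latency=5.0,
        target_response_latency=2.0,
        reward_retrieval_latency=1.0,
    )
    base.update(overrides)
    return TrialRecord(**base)


class TestRecordValidation:
    def test_valid_record_passes(self):
        _record().validate()

    @pytest.mark.parametrize(
        "overrides",
        [
            # retrieval latency on an unrewarded trial
            dict(choice=Choice.RIGHT, outcome=Outcome.UNREWARDED,
                 reward_retrieval_latency=1.0),
            # rewarded outcome without matching side
            dict(choice=Choice.RIGHT, outcome=Outcome.REWARDED),
            # omission with a response latency
            dict(choice=Choice.OMISSION, outcome=Outcome.UNREWARDED,
                 reward_retrieval_latency=None),
            # response latency outside the 30-s window
            dict(target_response_latency=31.0),
            dict(premature_left=-1),
        ],
    )
    def test_invariant_violations_raise(self, overrides):
        with pytest.raises(ValidationError):
            _record(**overrides).validate()

    def test_series_requires_contiguous_indices(self):
        series = PhaseSeries(
            "s1", Phase.ACQ, [_record(trial_index=1), _record(trial_index=3)]
        )
        with pytest.raises(ValidationError, match="trial_index"):
            series.validate()


class TestTrialTableRoundTrip:
    def test_empty_cohort_writes_header_only(self, tmp_path):
        path = tmp_path / "t.csv"
        write_trial_table([], path)
        assert path.read_text().count("\n") == 1

    def test_same_input_identical_bytes(self, tmp_path, small_cohort):
        series = [small_cohort[0].acq, small_cohort[0].rev]
        p1, p2 = tmp_path / "a.csv", tmp_path / "b.csv"
        write_trial_table(series, p1)
        write_trial_table(series, p2)
        assert p1.read_bytes() == p2.read_bytes()

    def test_round_trip_identity_on_simulated_cohort(self, tmp_path, small_cohort):
        series = [x for s in small_cohort for x in (s.acq, s.rev)]
        profiles = {s.profile.subject_id: s.profile for s in small_cohort}
        path = tmp_path / "cohort.csv"
        write_trial_table(series, path, profiles)
        back, back_profiles = read_trial_table(path)
        by_key = {(s.subject_id, s.phase): s for s in back}
        for s in series:
            got = by_key[(s.subject_id, s.phase)]
            assert got.trials == s.trials
        assert back_profiles == profiles

    def test_invalid_retrieval_latency_reported_with_row(self, tmp_path, hand_series):
        series, profile = hand_series
        path = tmp_path / "bad.csv"
        write_trial_table([series], path, {profile.subject_id: profile})
        lines = path.read_text().splitlines()
        # plant a retrieval latency on an unrewarded row (first error trial)
        cols = lines[0].split(",")
        i_out = cols.index("outcome")
        i_ret = cols.index("reward_retrieval_latency_s")
        for k, line in enumerate(lines[1:], start=2):
            vals = line.split(",")
            if vals[i_out] == "UNREWARDED" and vals[i_ret] == "":
                vals[i_ret] = "1.25"
                lines[k - 1] = ",".join(vals)
                break
        path.write_text("\n".join(lines) + "\n")
        with pytest.raises(ValidationError, match=rf"row {k}"):
            read_trial_table(path)

    def test_wrong_header_is_schema_error(self, tmp_path):
        path = tmp_path / "bad.csv"
        path.write_text("subject,phase\n")
        with pytest.raises(SchemaError):
            read_trial_table(path)


class TestEventLogParsing:
    def test_hand_written_single_trial(self, tmp_path):
        # init poke 2 s after trial start, targets on after a 0.1-s hold,
        # left poke 1.5 s later, pellet, magazine entry 0.8 s after that
        log = "\n".join(
            [
                "0.0000\tSESSION_START\ts1|ACQ|1|LEFT",
                "0.0000\tITI_END\t",
                "0.0000\tTRIAL_ARMED\t",
                "2.0000\tOBS_POKE_START\t",
                "2.1000\tTARGETS_ON\t",
                "3.6000\tTARGET_POKE\tLEFT",
                "3.6000\tPELLET\t",
                "4.4000\tMAG_ENTRY\t",
                "7.4000\tITI_END\t",
                "7.4000\tSESSION_END\t",
            ]
        )
        path = tmp_path / "one.log"
        path.write_text(log + "\n")
        [series] = parse_event_log(path)
        [t] = series.trials
        assert t.outcome is Outcome.REWARDED
        assert t.trial_initiation_latency == pytest.approx(2.0)
        assert t.target_response_latency == pytest.approx(1.5)
        assert t.reward_retrieval_latency == pytest.approx(0.8)
        assert t.eor == 0 and t.orto == 0

    def test_center_poke_during_targets_counts_as_eor(self, tmp_path):
        log = "\n".join(
            [
                "0.0000\tSESSION_START\ts1|ACQ|1|LEFT",
                "0.0000\tITI_END\t",
                "1.0000\tOBS_POKE_START\t",
                "1.1000\tTARGETS_ON\t",
                "1.5000\tOBS_POKE_START\t",
                "2.0000\tTARGET_POKE\tRIGHT",
                "9.0000\tITI_END\t",
                "9.0000\tSESSION_END\t",
            ]
        )
        path = tmp_path / "eor.log"
        path.write_text(log + "\n")
        [series] = parse_event_log(path)
        assert series.trials[0].eor == 1
        assert series.trials[0].outcome is Outcome.UNREWARDED

    def test_out_of_order_timestamps_rejected(self, tmp_path):
        log = "\n".join(
            [
                "0.0000\tSESSION_START\ts1|ACQ|1|LEFT",
                "5.0000\tITI_END\t",
                "2.0000\tOBS_POKE_START\t",
            ]
        )
        path = tmp_path / "ooo.log"
        path.write_text(log + "\n")
        with pytest.raises(EventLogError, match="out-of-order"):
            parse_event_log(path)

    def test_pellet_without_choice_rejected(self, tmp_path):
        log = "\n".join(
            [
                "0.0000\tSESSION_START\ts1|ACQ|1|LEFT",
                "0.0000\tITI_END\t",
                "1.0000\tOBS_POKE_START\t",
                "1.1000\tTARGETS_ON\t",
                "1.2000\tPELLET\t",
                "5.0000\tITI_END\t",
                "5.0000\tSESSION_END\t",
            ]
        )
        path = tmp_path / "bad.log"
        path.write_text(log + "\n")
        with pytest.raises(EventLogError, match="PELLET"):
            parse_event_log(path)

    def test_simulator_log_reconstructs_simulator_trials(self, tmp_path, small_cohort):
        # cross-representation identity for several subjects
        for sim in small_cohort[:4]:
            path = tmp_path / f"{sim.profile.subject_id}.log"
            path.write_text(sim.event_log)
            parsed = {(s.phase): s for s in parse_event_log(path)}
            assert parsed[Phase.ACQ].trials == sim.acq.trials
            assert parsed[Phase.REV].trials == sim.rev.trials
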