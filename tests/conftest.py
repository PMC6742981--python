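"""Shared fixtures: a hand-built 30-trial phase and small simulated cohorts."""

from __future__ import annotations

import pytest

from revlearn import (
    AgentParams,
    Choice,
    Outcome,
    Phase,
    PhaseSeries,
    SexModel,
    Side,
    SubjectProfile,
    TaskConfig,
    TrialRecord,
    simulate_cohort,
)

# correctness of the 28 response trials of the hand-built reversal phase
HAND_CORRECT = [0, 1, 1, 1, 1, 0, 0, 0, 0, 1, 0, 1, 1, 0, 1, 1, 1, 1, 1, 1,
                1, 1, 1, 1, 1, 1, 1, 1]
# 1-based positions of the two omission trials within the 30-trial list
HAND_OMISSIONS = (6, 21)


def build_hand_series() -> tuple[PhaseSeries, SubjectProfile]:
    """30 trials (28 responses + 2 omissions) of one reversal phase.

    Field values follow simple positional rules so every aggregate is
    reproducible with pencil and paper: initiation latency 10 + position,
    target-response latency 1 + 0.1 * position, retrieval latency 1.5,
    premature left/right flags on positions divisible by 3/4, one extraneous
    observing response on odd positions, an observing timeout on positions
    divisible by 5.  The rewarded side is LEFT; the subject acquired on
    RIGHT, so role C_ACQ = RIGHT and C_REV = LEFT.
    """
    profile = SubjectProfile(
        subject_id="F1",
        sex_model=SexModel.TS,
        x_dose="2X",
        gdx="SHAM",
        assigned_acq_side=Side.RIGHT,
    )
    trials = []
    r = 0
    for pos in range(1, 31):
        if pos in HAND_OMISSIONS:
            choice, outcome = Choice.OMISSION, Outcome.UNREWARDED
            resp_lat = None
        else:
            ok = HAND_CORRECT[r]
            r += 1
            choice = Choice.LEFT if ok else Choice.RIGHT
            outcome = Outcome.REWARDED if ok else Outcome.UNREWARDED
            resp_lat = round(1.0 + 0.1 * pos, 3)
        trials.append(
            TrialRecord(
                subject_id="F1",
                phase=Phase.REV,
                session_index=1,
                trial_index=pos,
                correct_side=Side.LEFT,
                choice=choice,
                outcome=outcome,
                trial_initiation_latency=float(10 + pos),
                target_response_latency=resp_lat,
                reward_retrieval_latency=1.5 if outcome is Outcome.REWARDED else None,
                premature_left=1 if pos % 3 == 0 else 0,
                premature_right=1 if pos % 4 == 0 else 0,
                eor=pos % 2,
                orto=1 if pos % 5 == 0 else 0,
            )
        )
    series = PhaseSeries(subject_id="F1", phase=Phase.REV, trials=trials)
    series.validate()
    return series, profile


@pytest.fixture
def hand_series():
    return build_hand_series()


@pytest.fixture(scope="session")
def small_cohort():
    """Two subjects per group, short sessions, fixed master seed."""
    task = TaskConfig(trials_per_session=80, max_sessions_per_phase=10)
    return simulate_cohort(2, task, master_seed=7)
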