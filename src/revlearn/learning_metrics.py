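"""Scalar behavioral measures on a reversal-learning phase.

The measures quantify distinct facets of two-choice discrimination learning:

* **trials to criterion** — response trials until accuracy first reaches a
  sliding-window criterion (default 80% correct over 20 consecutive response
  trials, the window never spanning a session boundary);
* **change point (CP)** — the trial of maximum linear deviation between the
  cumulative correct-response curve and the chord joining its endpoints,
  bisecting the phase into PRE and POST fractions;
* **FS** — flexibility-stability score, p(Lose-Shift) − p(Win-Stay): the
  difference between accuracy after unrewarded and after rewarded trials;
* **MAXCI** — maximum run of consecutive incorrect responses, an operational
  index of perseveration;
* **Regress Score** — normalized sum of accuracy *declines* between the
  prior-5-trial and next-5-trial windows as a one-trial-step moving window
  slides over the phase, an index of regressive (non-perseverative) errors.

Omission trials are excluded from all choice-sequence measures but retained
for the per-trial omission rate; see :func:`compute_phase_metrics`.
"""

from __future__ import annotations


from dataclasses import dataclass
from typing import Sequence

import numpy as np

from .trial_model import Choice, Outcome, PhaseSeries, Side, TrialRecord

__all__ = [
    "NOT_REACHED",
    "ChangePointResult",
    "SplitMetrics",
    "PhaseMetrics",
    "trials_to_criterion",
    "find_change_point",
    "flexibility_score",
    "max_consecutive_incorrect",
    "regress_score",
    "split_pre_post",
    "compute_phase_metrics",
]

NOT_REACHED = None  # sentinel returned by trials_to_criterion


def trials_to_criterion(
    correct: Sequence[int],
    session_ids: Sequence[int] | None = None,
    window: int = 20,
    accuracy: float = 0.80,
) -> int | None:
    """Index (1-based, in response trials) of the trial completing the first
    criterion window, or ``NOT_REACHED`` (None).

    ``correct`` is the 0/1 correctness sequence of *response* trials
    (omissions excluded by the caller).  A window qualifies when ``window``
    consecutive response trials all lie within one session and their mean
    correctness is >= ``accuracy``.  The criterion-completing trial (last
    trial of the qualifying window) is counted.
    """
    n = len(correct)
    if n < window:
        return NOT_REACHED
    if session_ids is None:
        session_ids = [1] * n
    if len(session_ids) != n:
        raise ValueError("session_ids must align with correct")
    run = 0  # running sum over the current in-session window
    for i in range(n):
        if i > 0 and session_ids[i] != session_ids[i - 1]:
            run = 0
            start = i  # first index of the current session
        if i == 0:
            start = 0
        run += correct[i]
        if i - start + 1 > window:
            run -= correct[i - window]
        if i - start + 1 >= window and run >= accuracy * window - 1e-12:
            return i + 1
    return NOT_REACHED


@dataclass
class ChangePointResult:
    """Change point of a learning curve.

    ``cp_index`` is the 1-based response-trial index of the first POST trial
    (the trial at which the linear deviation is maximal; earliest on ties).
    ``deviation`` holds the per-trial deviation d(t) = chord(t) − cumulative(t).
    ``degenerate`` flags curves whose deviation never rises above zero (e.g.,
    all-correct sequences); then ``cp_index`` is 1 and the whole phase is POST.
    """

    cp_index: int
    deviation: np.ndarray
    degenerate: bool


def find_change_point(correct: Sequence[int]) -> ChangePointResult:
    """Locate the trial of maximal linear deviation of the cumulative curve.

    The cumulative correct-response curve C(t) is compared against the
    straight line L(t) through its first and last points; the deviation
    d(t) = L(t) − C(t) is positive where the curve sags below the chord, as
    acquisition curves do before the learning step.  The argmax of d (1-based,
    earliest on ties) is the first POST trial.
    """
    n = len(correct)
    if n < 2:
        raise ValueError("change point requires at least 2 response trials")
    c = np.cumsum(np.asarray(correct, dtype=float))
    t = np.arange(1, n + 1, dtype=float)
    chord = c[0] + (c[-1] - c[0]) * (t - 1.0) / (n - 1.0)
    deviation = chord - c
    max_d = float(deviation.max())
    if max_d <= 1e-12:
        return ChangePointResult(cp_index=1, deviation=deviation, degenerate=True)
    # earliest trial on ties, robust to float noise in the chord
    cp_index = int(np.flatnonzero(deviation >= max_d - 1e-9)[0]) + 1
    return ChangePointResult(cp_index=cp_index, deviation=deviation, degenerate=False)


def flexibility_score(
    correct: Sequence[int],
) -> tuple[float | None, float | None, float | None]:
    """(FS, p_lose_shift, p_win_stay) on a response-trial correctness sequence.

    p(Lose-Shift) is the fraction of trials immediately following an
    unrewarded trial that are correct; p(Win-Stay) the analogue after
    rewarded trials; FS is their difference.  A component with an empty
    denominator is None, and then FS is None ("absence is a value") —
    downstream summaries drop absent FS rather than imputing 0.
    """
    n = len(correct)
    lose_n = lose_k = win_n = win_k = 0
    for i in range(1, n):
        if correct[i - 1]:
            win_n += 1
            win_k += correct[i]
        else:
            lose_n += 1
            lose_k += correct[i]
    p_ls = lose_k / lose_n if lose_n else None
    p_ws = win_k / win_n if win_n else None
    fs = (p_ls - p_ws) if (p_ls is not None and p_ws is not None) else None
    return fs, p_ls, p_ws


def max_consecutive_incorrect(correct: Sequence[int]) -> int:
    """MAXCI: length of the longest run of incorrect response trials."""
    best = run = 0
    for c in correct:
        run = 0 if c else run + 1
        best = max(best, run)
    return best


def regress_score(
    correct: Sequence[int],
    block: int = 5,
    sliding: bool = True,
) -> float | None:
    """Normalized sum of accuracy declines between adjacent trial blocks.

    With the default one-trial-step moving window, every position ``i`` with a
    full prior block (trials i−block+1..i) and next block (i+1..i+block) is
    visited; where next-block accuracy falls below prior-block accuracy the
    (positive) decline is accumulated.  The sum of declines, in proportion
    units, is divided by the total number of response trials.  Returns None
    for sequences shorter than two blocks.

    ``sliding=False`` uses non-overlapping consecutive blocks instead, an
    alternative reading of block stepping kept for sensitivity analysis.
    """
    n = len(correct)
    if n < 2 * block:
        return None
    arr = np.asarray(correct, dtype=float)
    total = 0.0
    if sliding:
        for i in range(block, n - block + 1):
            prior = arr[i - block : i].mean()
            nxt = arr[i : i + block].mean()
            if nxt < prior:
                total += prior - nxt
    else:
        k = n // block
        for j in range(1, k):
            prior = arr[(j - 1) * block : j * block].mean()
            nxt = arr[j * block : (j + 1) * block].mean()
            if nxt < prior:
                total += prior - nxt
    return total / n


def split_pre_post(
    series_trials: Sequence[TrialRecord],
    cp: ChangePointResult,
) -> tuple[list[TrialRecord], list[TrialRecord]]:
    """Partition trials (omissions included) at the change point.

    ``cp`` was computed on the response trials of ``series_trials``; the
    cp-th response trial is the first POST trial, and omission trials fall
    into whichever side of that boundary they occupy positionally.  A
    degenerate CP yields an empty PRE.
    """
    resp_seen = 0
    boundary = 0  # positional index of the first POST trial
    for pos, t in enumerate(series_trials):
        if t.is_response:
            resp_seen += 1
            if resp_seen == cp.cp_index:
                boundary = pos
                break
    else:
        boundary = len(series_trials)
    return list(series_trials[:boundary]), list(series_trials[boundary:])


def _mean(values: list[float]) -> float | None:
    return float(np.mean(values)) if values else None


@dataclass
class SplitMetrics:
    """Per-trial rates and mean latencies within one PRE/POST fraction.

    Rates are per response trial, except ``omissions_per_trial`` which is per
    presented trial (omission trials are non-response).  Premature rates and
    target-response latencies are keyed by side role: C_ACQ is the physical
    side rewarded in acquisition, C_REV its opposite.
    """

    n_trials: int  # response trials
    n_presented: int  # response + omission trials
    errors_per_trial: float | None
    fs: float | None
    p_lose_shift: float | None
    p_win_stay: float | None
    premature_per_trial: dict[str, float | None]  # by side role
    init_latency_mean: float | None
    init_latency_after_win: float | None
    init_latency_after_loss: float | None
    n_after_win: int
    n_after_loss: int
    target_latency_mean: dict[str, float | None]  # by side role of the poked side
    retrieval_latency_mean: float | None
    eor_per_trial: float | None
    orto_per_trial: float | None
    omissions_per_trial: float | None


@dataclass
class PhaseMetrics:
    """All scalar measures for one subject x phase."""

    subject_id: str
    phase: str
    trials_to_criterion: int | None
    reached_criterion: bool
    cp_index: int
    cp_degenerate: bool
    maxci: int
    regress: float | None
    pre: SplitMetrics
    post: SplitMetrics


def _split_metrics(
    trials: Sequence[TrialRecord],
    role_map: dict[str, Side],
    prior_outcomes: Sequence[Outcome | None],
) -> SplitMetrics:
    """Aggregate one PRE/POST fraction.

    ``prior_outcomes`` aligns with ``trials`` and gives each trial's
    preceding-trial outcome within the full phase (None for the phase's
    first trial), so initiation latencies at the split boundary still
    condition on the true prior trial.
    """
    resp = [t for t in trials if t.is_response]
    n_resp = len(resp)
    n_pres = len(trials)
    correct = [1 if t.outcome is Outcome.REWARDED else 0 for t in resp]
    fs, p_ls, p_ws = flexibility_score(correct) if n_resp >= 2 else (None, None, None)

    role_of_side = {side.value: role for role, side in role_map.items()}
    premature = {
        role: (
            _mean(
                [
                    (t.premature_left if side is Side.LEFT else t.premature_right)
                    for t in resp
                ]
            )
        )
        for role, side in role_map.items()
    }
    init_all = [t.trial_initiation_latency for t in trials]
    init_win = [
        t.trial_initiation_latency
        for t, po in zip(trials, prior_outcomes)
        if po is Outcome.REWARDED
    ]
    init_loss = [
        t.trial_initiation_latency
        for t, po in zip(trials, prior_outcomes)
        if po is Outcome.UNREWARDED
    ]
    target_lat: dict[str, list[float]] = {role: [] for role in role_map}
    for t in resp:
        role = role_of_side[t.choice.value]
        if t.target_response_latency is not None:
            target_lat[role].append(t.target_response_latency)
    retrieval = [
        t.reward_retrieval_latency
        for t in resp
        if t.reward_retrieval_latency is not None
    ]
    return SplitMetrics(
        n_trials=n_resp,
        n_presented=n_pres,
        errors_per_trial=_mean([1 - c for c in correct]) if n_resp else None,
        fs=fs,
        p_lose_shift=p_ls,
        p_win_stay=p_ws,
        premature_per_trial=premature if n_resp else {r: None for r in role_map},
        init_latency_mean=_mean(init_all),
        init_latency_after_win=_mean(init_win),
        init_latency_after_loss=_mean(init_loss),
        n_after_win=len(init_win),
        n_after_loss=len(init_loss),
        target_latency_mean={r: _mean(v) for r, v in target_lat.items()},
        retrieval_latency_mean=_mean(retrieval),
        eor_per_trial=_mean([float(t.eor) for t in resp]) if n_resp else None,
        orto_per_trial=_mean([float(t.orto) for t in resp]) if n_resp else None,
        omissions_per_trial=(
            sum(1 for t in trials if not t.is_response) / n_pres if n_pres else None
        ),
    )


def compute_phase_metrics(
    series: PhaseSeries,
    role_map: dict[str, Side],
    window: int = 20,
    accuracy: float = 0.80,
    regress_block: int = 5,
    regress_sliding: bool = True,
) -> PhaseMetrics:
    """Compute every phase-level measure for one subject x phase.

    The phase is truncated at the criterion-completing trial, so the PRE and
    POST response-trial counts sum to trials-to-criterion; series that never
    reached criterion are analyzed over all available trials and flagged.
    Choice-sequence measures (criterion, CP, FS, MAXCI, regress) use response
    trials only; omission trials contribute to the per-presented-trial
    omission rate and their premature/EOR/ORTO counts are folded into the
    fraction containing them.
    """
    resp = series.response_trials()
    correct = [1 if t.outcome is Outcome.REWARDED else 0 for t in resp]
    sessions = [t.session_index for t in resp]
    ttc = trials_to_criterion(correct, sessions, window=window, accuracy=accuracy)
    reached = ttc is not NOT_REACHED
    n_used = ttc if reached else len(correct)

    # truncate the full trial list at the criterion response trial
    if reached:
        resp_seen = 0
        cut = len(series.trials)
        for pos, t in enumerate(series.trials):
            if t.is_response:
                resp_seen += 1
                if resp_seen == n_used:
                    cut = pos + 1
                    break
        trials_used = series.trials[:cut]
    else:
        trials_used = list(series.trials)
    correct_used = correct[:n_used]

    if len(correct_used) >= 2:
        cp = find_change_point(correct_used)
    else:
        cp = ChangePointResult(
            cp_index=1, deviation=np.zeros(len(correct_used)), degenerate=True
        )
    pre_trials, post_trials = split_pre_post(trials_used, cp)

    prior: list[Outcome | None] = [None]
    for t in trials_used[:-1]:
        prior.append(t.outcome)
    pre_prior = prior[: len(pre_trials)]
    post_prior = prior[len(pre_trials) :]

    return PhaseMetrics(
        subject_id=series.subject_id,
        phase=series.phase.value,
        trials_to_criterion=ttc if reached else None,
        reached_criterion=reached,
        cp_index=cp.cp_index,
        cp_degenerate=cp.degenerate,
        maxci=max_consecutive_incorrect(correct_used),
        regress=regress_score(
            correct_used, block=regress_block, sliding=regress_sliding
        ),
        pre=_split_metrics(pre_trials, role_map, pre_prior),
        post=_split_metrics(post_trials, role_map, post_prior),
    )
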