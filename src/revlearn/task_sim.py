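"""Generative simulator of the observing-response reversal-learning task.

The task: each trial the animal initiates by nose-poking the lit center
aperture and sustaining the poke for a short required holding duration (RHD,
in centiseconds); a failed hold triggers a 2-s observing timeout (ORTO) and
another attempt.  A successful hold lights the two flanking target apertures;
a poke into the currently rewarded side delivers a pellet, a poke into the
other side triggers a 5-s timeout, and no poke within 30 s is an omission
(5-s timeout).  A 3-s inter-trial interval separates trials.  Acquisition
(ACQ) runs in daily sessions until the 80%/20-trial sliding criterion is
met; reversal (REV) then swaps the rewarded side with contingencies
otherwise unchanged.

The choice agent is a two-armed softmax Q-learner with
``Q(chosen) += alpha * (r - Q(chosen))`` plus three behavioral biases:

* ``perseveration_weight`` (kappa) — a softmax bonus proportional to a
  reinforcement-habit trace of each side, grown by rewards on that side at
  rate ``habit_rate`` and decayed by nonreward at the much slower
  ``habit_decay`` (habits resist extinction).  At reversal the trace still
  points at the old rule, so kappa produces the initial perseverative bout
  whose length MAXCI measures.
* ``alternation_bias`` — rodents' innate tendency to visit the side not
  chosen on the previous trial.  Early in learning it makes accuracy after
  losses exceed accuracy after wins (positive FS before the change point:
  alternating is correct after an error, incorrect after a win) and it
  slows acquisition realistically.
* ``lose_shift_bias`` — an additional one-trial bonus away from the
  previous choice after nonreward (outcome-dependent exploration on top of
  plain alternation).

Both exploration biases are gated by ``1 - max(habit)``: as the reinforced
response becomes habitual the animal stops alternating and stops shifting
after single losses, reproducing the documented strategy change from
lose-shift early in a phase to win-stay late in it.
* an outcome-coupled inattentive state: a reward re-engages the animal,
  while after nonreward it disengages with probability ``lapse`` (and a
  disengaged animal stays so with probability ``lapse_persistence``).
  Disengaged responding is habitual — mostly a repeat of the previous
  choice (``lapse_habit``), occasionally random.  Errors therefore arrive
  in self-sustaining bouts, so once the discrimination is learned,
  accuracy after an error is well below accuracy after a reward — FS turns
  negative after the change point, while early in learning the lose-shift
  bias keeps it positive.

After the criterion is reached the running session is completed before the
phase ends (the reversal starts the next day), so the learned response is
overtrained well past criterion exactly as daily testing produces; the
analysis-side truncation at the criterion trial is unaffected.

Omissions, premature responses (over-dispersed counts, split across sides by
the agent's current side preference), extraneous observing responses,
observing failures, and outcome-dependent log-normal latencies (initiation
slower after rewarded trials) are drawn per :class:`AgentParams`.  Every
draw comes from one seeded generator, so a run is fully reproducible and the
emitted event log and trial table describe identical trials.
"""

from __future__ import annotations

import math
from dataclasses import dataclass, field, replace

import numpy as np
import yaml

from .learning_metrics import trials_to_criterion
from .trial_model import (
    Choice,
    Outcome,
    Phase,
    PhaseSeries,
    SexModel,
    Side,
    SubjectProfile,
    TrialRecord,
)

__all__ = [
    "TaskConfig",
    "AgentParams",
    "SimulatedSubject",
    "simulate_subject",
    "simulate_cohort",
    "load_cohort_config",
    "GROUPS",
]

#: the eight between-subject cells: sex model x X dose x gonadal status
GROUPS = [
    (sm, xd, gd)
    for sm in (SexModel.KS, SexModel.TS)
    for xd in ("1X", "2X")
    for gd in ("GDX", "SHAM")
]


@dataclass(frozen=True)
class TaskConfig:
    """Task contingencies and session structure.

    Durations are seconds except ``rhd_values_csec`` (centiseconds, as the
    holding requirement is specified).  ``trials_per_session`` stands in for
    the ~1-h daily session; ``max_sessions_per_phase`` guards against
    non-learners running forever.
    """

    rhd_values_csec: tuple[int, ...] = (1, 10, 20)
    obs_timeout_s: float = 2.0
    incorrect_timeout_s: float = 5.0
    omission_window_s: float = 30.0
    iti_s: float = 3.0
    criterion_accuracy: float = 0.80
    criterion_window: int = 20
    max_sessions_per_phase: int = 20
    trials_per_session: int = 120

    def __post_init__(self) -> None:
        if not (0 < self.criterion_accuracy <= 1):
            raise ValueError("criterion_accuracy must lie in (0, 1]")
        if self.criterion_window < 1:
            raise ValueError("criterion_window must be >= 1")


@dataclass(frozen=True)
class AgentParams:
    """Generative parameters of a simulated subject.

    Latency means are arithmetic means of log-normal draws (sigma is the
    log-scale dispersion), so configured means are directly comparable with
    aggregated cell means.  ``mu_init_win``/``mu_init_lose`` are the
    initiation-latency means after rewarded/unrewarded trials; defaults take
    the ordering and magnitudes typical of food-restricted mice, which
    initiate sooner after going unrewarded.  ``p_premature_per_trial`` is the
    mean of an over-dispersed (gamma-Poisson) count.
    """

    learn_rate: float = 0.03
    inv_temp: float = 3.0
    perseveration_weight: float = 1.0
    habit_rate: float = 0.12
    habit_decay: float = 0.02
    lapse: float = 0.20
    lapse_persistence: float = 0.70
    lapse_habit: float = 0.90
    alternation_bias: float = 1.4
    lose_shift_bias: float = 0.4
    win_stay_bias: float = 2.2
    p_premature_per_trial: float = 0.8
    premature_dispersion: float = 1.0
    p_obs_fail: float = 0.15
    p_omission: float = 0.03
    eor_rate: float = 0.3
    mu_init_win: float = 29.5
    mu_init_lose: float = 12.0
    sigma_init: float = 0.55
    mu_resp: float = 4.0
    resp_value_gain: float = 0.5
    sigma_resp: float = 0.40
    mu_retr: float = 1.5
    sigma_retr: float = 0.35
    q_init: tuple[float, float] | None = None  # (left, right); default 0.5 each
    rng_seed: int = 0

    def __post_init__(self) -> None:
        if not (0 <= self.learn_rate <= 1):
            raise ValueError("learn_rate must lie in [0, 1]")
        if self.inv_temp < 0 or self.perseveration_weight < 0:
            raise ValueError("inv_temp and perseveration_weight must be >= 0")
        for name in ("lapse", "lapse_persistence", "p_omission"):
            v = getattr(self, name)
            if not (0 <= v < 1):
                raise ValueError(f"{name} must lie in [0, 1)")
        if not (0 <= self.p_obs_fail < 1):
            raise ValueError("p_obs_fail must lie in [0, 1)")
        if min(self.mu_init_win, self.mu_init_lose, self.mu_resp, self.mu_retr) <= 0:
            raise ValueError("latency means must be positive")


@dataclass
class SimulatedSubject:
    profile: SubjectProfile
    acq: PhaseSeries
    rev: PhaseSeries
    event_log: str  # tab-delimited text, one event per line


def _lognormal_mean(rng: np.random.Generator, mean: float, sigma: float) -> float:
    """Log-normal draw with arithmetic mean ``mean``."""
    mu = math.log(mean) - 0.5 * sigma * sigma
    return float(rng.lognormal(mu, sigma))


def _neg_binomial(rng: np.random.Generator, mean: float, dispersion: float) -> int:
    """Gamma-Poisson mixture: variance = mean + mean^2 / dispersion."""
    if mean <= 0:
        return 0
    lam = rng.gamma(dispersion, mean / dispersion)
    return int(rng.poisson(lam))


class _EventWriter:
    def __init__(self) -> None:
        self.lines: list[str] = []

    def emit(self, ts: float, code: str, detail: str = "") -> None:
        self.lines.append(f"{ts:.4f}\t{code}\t{detail}")

    def text(self) -> str:
        return "\n".join(self.lines) + "\n"


_SIDES = (Side.LEFT, Side.RIGHT)


class _Agent:
    """Mutable agent state shared across both phases of a subject."""

    def __init__(self, params: AgentParams, rng: np.random.Generator) -> None:
        self.p = params
        self.rng = rng
        if params.q_init is not None:
            self.q = {Side.LEFT: params.q_init[0], Side.RIGHT: params.q_init[1]}
        else:
            self.q = {Side.LEFT: 0.5, Side.RIGHT: 0.5}
        self.prev_choice: Side | None = None
        self.prev_outcome: Outcome | None = None
        self.habit = {Side.LEFT: 0.0, Side.RIGHT: 0.0}
        self.lapsed = False

    def step_attention(self) -> None:
        # reward re-engages; nonreward lets disengagement start or persist
        if self.prev_outcome is Outcome.REWARDED:
            self.lapsed = False
        else:
            p_stay = self.p.lapse_persistence if self.lapsed else self.p.lapse
            self.lapsed = bool(self.rng.random() < p_stay)

    def choose(self) -> Side:
        if self.lapsed:
            # inattentive responding is habitual: mostly repeat the last
            # choice, otherwise poke at random
            if self.prev_choice is not None and self.rng.random() < self.p.lapse_habit:
                return self.prev_choice
            return _SIDES[int(self.rng.random() < 0.5)]
        p = self.p
        # strategy shift: exploration (alternation, lose-shift) fades as the
        # habit consolidates, while win-stay grows with it
        h_max = max(self.habit.values())
        explore = 1.0 - h_max
        logits = {}
        for s in _SIDES:
            z = p.inv_temp * self.q[s] + p.perseveration_weight * self.habit[s]
            if self.prev_choice is not None:
                if s is not self.prev_choice:
                    z += p.alternation_bias * explore
                if self.prev_outcome is Outcome.UNREWARDED and s is not self.prev_choice:
                    z += p.lose_shift_bias * explore
                if self.prev_outcome is Outcome.REWARDED and s is self.prev_choice:
                    # stay-after-reward strength tracks the habit of the
                    # response just made, not the strongest habit overall:
                    # a win on a newly rewarded side earns no stay bonus yet
                    z += p.win_stay_bias * self.habit[self.prev_choice]
            logits[s] = z
        zmax = max(logits.values())
        w = {s: math.exp(z - zmax) for s, z in logits.items()}
        total = w[Side.LEFT] + w[Side.RIGHT]
        return Side.LEFT if self.rng.random() < w[Side.LEFT] / total else Side.RIGHT

    def p_left_preference(self) -> float:
        """Softmax probability of the left side from values alone; used to
        apportion premature pokes across apertures."""
        d = self.p.inv_temp * (self.q[Side.LEFT] - self.q[Side.RIGHT])
        d += self.p.perseveration_weight * (
            self.habit[Side.LEFT] - self.habit[Side.RIGHT]
        )
        return 1.0 / (1.0 + math.exp(-d))

    def update(self, choice: Side, rewarded: bool) -> None:
        r = 1.0 if rewarded else 0.0
        self.q[choice] += self.p.learn_rate * (r - self.q[choice])
        # reinforcement-habit trace: grown by reward on the chosen side,
        # decayed only slowly by nonreward there (habits resist extinction);
        # the unchosen side is untouched
        if rewarded:
            self.habit[choice] += self.p.habit_rate * (1.0 - self.habit[choice])
        else:
            self.habit[choice] -= self.p.habit_decay * self.habit[choice]
        self.prev_choice = choice
        self.prev_outcome = Outcome.REWARDED if rewarded else Outcome.UNREWARDED

    def register_omission(self) -> None:
        # no choice was made; prior-outcome context becomes "unrewarded"
        self.prev_outcome = Outcome.UNREWARDED


def _simulate_phase(
    profile: SubjectProfile,
    phase: Phase,
    correct_side: Side,
    task: TaskConfig,
    agent: _Agent,
    writer: _EventWriter,
    clock: float,
) -> tuple[PhaseSeries, float]:
    rng = agent.rng
    p = agent.p
    trials: list[TrialRecord] = []
    correct_seq: list[int] = []
    session_seq: list[int] = []
    reached = False
    trial_index = 0

    for session in range(1, task.max_sessions_per_phase + 1):
        writer.emit(
            clock,
            "SESSION_START",
            f"{profile.subject_id}|{phase.value}|{session}|{correct_side.value}",
        )
        for _ in range(task.trials_per_session):
            trial_index += 1
            iti_end = clock
            writer.emit(iti_end, "ITI_END")
            writer.emit(iti_end, "TRIAL_ARMED")

            # outcome-dependent initiation latency
            if agent.prev_outcome is Outcome.REWARDED:
                mu_init = p.mu_init_win
            elif agent.prev_outcome is Outcome.UNREWARDED:
                mu_init = p.mu_init_lose
            else:
                mu_init = math.sqrt(p.mu_init_win * p.mu_init_lose)
            init_lat = round(_lognormal_mean(rng, mu_init, p.sigma_init), 3)

            # premature pokes before target onset, split by side preference
            n_premature = _neg_binomial(
                rng, p.p_premature_per_trial, p.premature_dispersion
            )
            p_left = agent.p_left_preference()
            prem_left = int(rng.binomial(n_premature, p_left))
            prem_right = n_premature - prem_left
            prem_times = sorted(
                round(float(x), 3)
                for x in rng.uniform(0.0, max(init_lat, 0.001), size=n_premature)
            )
            prem_sides = [Side.LEFT] * prem_left + [Side.RIGHT] * prem_right
            rng.shuffle(prem_sides)  # type: ignore[arg-type]
            for dt, s in zip(prem_times, prem_sides):
                writer.emit(iti_end + dt, "TARGET_POKE", s.value)

            first_obs = iti_end + init_lat
            writer.emit(first_obs, "OBS_POKE_START")
            # observing failures: geometric number of 2-s timeouts before success
            orto = 0
            t = first_obs
            rhd_s = float(rng.choice(task.rhd_values_csec)) / 100.0
            while rng.random() < p.p_obs_fail:
                orto += 1
                t += round(rhd_s * float(rng.uniform(0.2, 0.9)), 3)
                writer.emit(t, "OBS_FAIL_TIMEOUT")
                t += task.obs_timeout_s + round(
                    _lognormal_mean(rng, 1.0, 0.3), 3
                )
                writer.emit(t, "OBS_POKE_START")
            targets_on = round(t + rhd_s, 3)
            writer.emit(targets_on, "TARGETS_ON")

            agent.step_attention()
            omitted = rng.random() < p.p_omission
            eor = int(rng.poisson(p.eor_rate))

            if omitted:
                for k in range(eor):
                    writer.emit(
                        targets_on
                        + round(
                            task.omission_window_s * (k + 1) / (eor + 1), 3
                        ),
                        "OBS_POKE_START",
                    )
                om_ts = targets_on + task.omission_window_s
                writer.emit(om_ts, "OMISSION")
                writer.emit(om_ts, "TIMEOUT_ON")
                writer.emit(om_ts + task.incorrect_timeout_s, "TIMEOUT_OFF")
                clock = om_ts + task.incorrect_timeout_s + task.iti_s
                agent.register_omission()
                trials.append(
                    TrialRecord(
                        subject_id=profile.subject_id,
                        phase=phase,
                        session_index=session,
                        trial_index=trial_index,
                        correct_side=correct_side,
                        choice=Choice.OMISSION,
                        outcome=Outcome.UNREWARDED,
                        trial_initiation_latency=init_lat,
                        target_response_latency=None,
                        reward_retrieval_latency=None,
                        premature_left=prem_left,
                        premature_right=prem_right,
                        eor=eor,
                        orto=orto,
                    )
                )
                continue

            choice = agent.choose()
            rewarded = choice is correct_side
            # faster responding as the value gap grows
            gap = abs(agent.q[Side.LEFT] - agent.q[Side.RIGHT])
            mu_resp = p.mu_resp * (1.0 - p.resp_value_gain * gap)
            resp_lat = round(
                min(
                    max(_lognormal_mean(rng, max(mu_resp, 0.2), p.sigma_resp), 0.05),
                    task.omission_window_s - 0.001,
                ),
                3,
            )
            choice_ts = targets_on + resp_lat
            for k in range(eor):
                writer.emit(
                    targets_on + round(resp_lat * (k + 1) / (eor + 1), 3),
                    "OBS_POKE_START",
                )
            writer.emit(choice_ts, "TARGET_POKE", choice.value)

            retr_lat: float | None = None
            if rewarded:
                writer.emit(choice_ts, "PELLET")
                retr_lat = round(_lognormal_mean(rng, p.mu_retr, p.sigma_retr), 3)
                writer.emit(choice_ts + retr_lat, "MAG_ENTRY")
                clock = choice_ts + retr_lat + task.iti_s
            else:
                writer.emit(choice_ts, "TIMEOUT_ON")
                writer.emit(choice_ts + task.incorrect_timeout_s, "TIMEOUT_OFF")
                clock = choice_ts + task.incorrect_timeout_s + task.iti_s

            agent.update(choice, rewarded)
            trials.append(
                TrialRecord(
                    subject_id=profile.subject_id,
                    phase=phase,
                    session_index=session,
                    trial_index=trial_index,
                    correct_side=correct_side,
                    choice=Choice(choice.value),
                    outcome=Outcome.REWARDED if rewarded else Outcome.UNREWARDED,
                    trial_initiation_latency=init_lat,
                    target_response_latency=resp_lat,
                    reward_retrieval_latency=retr_lat,
                    premature_left=prem_left,
                    premature_right=prem_right,
                    eor=eor,
                    orto=orto,
                )
            )
            correct_seq.append(1 if rewarded else 0)
            session_seq.append(session)
            # criterion checked with the same routine the analysis uses,
            # applied to the newest window only (first qualifying window and
            # first qualifying tail are the same event); the session then
            # runs to completion — the phase switch happens the next day
            w = task.criterion_window
            if (
                not reached
                and len(correct_seq) >= w
                and trials_to_criterion(
                    correct_seq[-w:],
                    session_seq[-w:],
                    window=w,
                    accuracy=task.criterion_accuracy,
                )
                is not None
            ):
                reached = True
        writer.emit(clock, "ITI_END")  # closes the session's last trial
        writer.emit(clock, "SESSION_END")
        clock += 60.0  # gap between daily sessions (log time is arbitrary)
        if reached:
            break

    series = PhaseSeries(
        subject_id=profile.subject_id,
        phase=phase,
        trials=trials,
        reached_criterion=reached,
    )
    return series, clock


def simulate_subject(
    profile: SubjectProfile,
    task: TaskConfig | None = None,
    agent: AgentParams | None = None,
) -> SimulatedSubject:
    """Run one subject through acquisition then reversal.

    Acquisition runs until the sliding criterion (or the session guard, in
    which case the series is flagged ``reached_criterion=False`` and reversal
    still follows); reversal starts a fresh session with the rewarded side
    swapped and contingencies unchanged.  Q-values, reinforcement history and
    the attention state carry across the phase boundary — that carry-over is
    what makes reversal hard.  Fully reproducible given ``rng_seed``.
    """
    task = task or TaskConfig()
    agent_params = agent or AgentParams()
    rng = np.random.default_rng(agent_params.rng_seed)
    ag = _Agent(agent_params, rng)
    writer = _EventWriter()
    acq, clock = _simulate_phase(
        profile, Phase.ACQ, profile.assigned_acq_side, task, ag, writer, 0.0
    )
    rev, _ = _simulate_phase(
        profile,
        Phase.REV,
        profile.assigned_acq_side.opposite,
        task,
        ag,
        writer,
        clock,
    )
    return SimulatedSubject(
        profile=profile, acq=acq, rev=rev, event_log=writer.text()
    )


def simulate_cohort(
    n_per_group: int,
    task: TaskConfig | None = None,
    agent_by_group: dict[tuple[SexModel, str, str], AgentParams] | None = None,
    master_seed: int = 0,
) -> list[SimulatedSubject]:
    """Simulate a counterbalanced cohort over the eight subject groups.

    Within every group the acquisition side alternates LEFT/RIGHT (counts
    differ by at most one).  Per-subject seeds derive deterministically from
    ``master_seed`` via :class:`numpy.random.SeedSequence`, so cohorts are
    reproducible and subjects statistically independent.
    """
    if n_per_group < 1:
        raise ValueError("n_per_group must be >= 1")
    task = task or TaskConfig()
    agent_by_group = agent_by_group or {}
    ss = np.random.SeedSequence(master_seed)
    child_seeds = ss.generate_state(len(GROUPS) * n_per_group) % (2**31)
    out: list[SimulatedSubject] = []
    k = 0
    for sm, xd, gd in GROUPS:
        base = agent_by_group.get((sm, xd, gd), AgentParams())
        for i in range(n_per_group):
            sid = f"{sm.value}-{xd}-{gd}-{i + 1:03d}"
            profile = SubjectProfile(
                subject_id=sid,
                sex_model=sm,
                x_dose=xd,
                gdx=gd,
                assigned_acq_side=_SIDES[i % 2],
            )
            params = replace(base, rng_seed=int(child_seeds[k]))
            out.append(simulate_subject(profile, task, params))
            k += 1
    return out


# ---------------------------------------------------------------------------
# configuration files

_TASK_KEYS = set(TaskConfig.__dataclass_fields__)
_AGENT_KEYS = set(AgentParams.__dataclass_fields__)


def load_cohort_config(path):
    """Load a cohort specification from a YAML file.

    Schema::

        n_per_group: 10
        master_seed: 17
        task: {criterion_window: 20, trials_per_session: 120, ...}
        agent_defaults: {learn_rate: 0.25, ...}
        agent_overrides:            # optional per-group deltas
          KS/2X/SHAM: {perseveration_weight: 2.0}

    Returns ``(n_per_group, master_seed, TaskConfig, agent_by_group)``.
    """
    with open(path, "r", encoding="utf-8") as fh:
        cfg = yaml.safe_load(fh) or {}
    n = int(cfg.get("n_per_group", 1))
    seed = int(cfg.get("master_seed", 0))
    task_kwargs = cfg.get("task", {}) or {}
    unknown = set(task_kwargs) - _TASK_KEYS
    if unknown:
        raise ValueError(f"unknown task keys: {sorted(unknown)}")
    if "rhd_values_csec" in task_kwargs:
        task_kwargs["rhd_values_csec"] = tuple(task_kwargs["rhd_values_csec"])
    task = TaskConfig(**task_kwargs)
    defaults = cfg.get("agent_defaults", {}) or {}
    unknown = set(defaults) - _AGENT_KEYS
    if unknown:
        raise ValueError(f"unknown agent keys: {sorted(unknown)}")
    base = AgentParams(**defaults)
    agent_by_group: dict[tuple[SexModel, str, str], AgentParams] = {}
    for key, deltas in (cfg.get("agent_overrides", {}) or {}).items():
        sm_s, xd, gd = key.split("/")
        unknown = set(deltas) - _AGENT_KEYS
        if unknown:
            raise ValueError(f"unknown agent keys in {key}: {sorted(unknown)}")
        agent_by_group[(SexModel(sm_s), xd, gd)] = replace(base, **deltas)
    for g in GROUPS:
        agent_by_group.setdefault(g, base)
    return n, seed, task, agent_by_group
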