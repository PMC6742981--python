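"""Trial-level data model and I/O for the two-choice reversal-learning task.

A subject runs an acquisition (ACQ) phase with one target aperture rewarded,
then a reversal (REV) phase with the contingency swapped.  Every completed
trial — including omission trials, on which no target response occurred — is
one :class:`TrialRecord`.  Records are grouped per subject x phase into a
:class:`PhaseSeries`.

Two on-disk representations are supported:

* a tidy comma-delimited *trial table* (one row per trial, fixed column
  order, empty string for absent values), written/read by
  :func:`write_trial_table` / :func:`read_trial_table`;
* a tab-delimited timestamped *event log* (``timestamp<TAB>code<TAB>detail``)
  mirroring the chamber events (observing pokes, target lights, pellet
  delivery, magazine entries, timeouts), reconstructed into trial records by
  :func:`parse_event_log`.
"""

from __future__ import annotations


from dataclasses import dataclass, field
from enum import Enum
from typing import Iterable

__all__ = [
    "Phase",
    "Side",
    "Choice",
    "Outcome",
    "SexModel",
    "TrialRecord",
    "SubjectProfile",
    "PhaseSeries",
    "SchemaError",
    "ValidationError",
    "EventLogError",
    "TRIAL_TABLE_COLUMNS",
    "read_trial_table",
    "write_trial_table",
    "parse_event_log",
    "role_map_for",
]


class Phase(str, Enum):
    ACQ = "ACQ"
    REV = "REV"


class Side(str, Enum):
    LEFT = "LEFT"
    RIGHT = "RIGHT"

    @property
    def opposite(self) -> "Side":
        return Side.RIGHT if self is Side.LEFT else Side.LEFT


class Choice(str, Enum):
    LEFT = "LEFT"
    RIGHT = "RIGHT"
    OMISSION = "OMISSION"


class Outcome(str, Enum):
    REWARDED = "REWARDED"
    UNREWARDED = "UNREWARDED"


class SexModel(str, Enum):
    """Which sex-chromosome comparison a subject belongs to.

    KS: gonadal males, XY (1X) vs XXY (2X).  TS: gonadal females,
    XO (1X) vs XX (2X).
    """

    KS = "KS"
    TS = "TS"


class SchemaError(ValueError):
    """Trial-table header does not match the column contract."""


class ValidationError(ValueError):
    """A record violates a trial-level invariant; message names the rule."""


class EventLogError(ValueError):
    """Event log is malformed (ordering, codes, or impossible sequences)."""


@dataclass(frozen=True)
class TrialRecord:
    """One completed trial.

    Latencies are in seconds.  ``trial_initiation_latency`` runs from the end
    of the inter-trial interval to the first observing poke (whether or not
    that poke satisfied the holding requirement).  ``target_response_latency``
    runs from target onset to the first target poke and is absent on omission
    trials.  ``reward_retrieval_latency`` runs from pellet delivery to the
    first magazine entry and is present exactly on rewarded trials.

    ``premature_left``/``premature_right`` count pokes into the (unlit) target
    apertures before target presentation; ``eor`` counts extraneous center
    pokes while the targets are lit; ``orto`` counts observing-response
    timeouts (failures to sustain the center hold) on this trial.
    """

    subject_id: str
    phase: Phase
    session_index: int
    trial_index: int
    correct_side: Side
    choice: Choice
    outcome: Outcome
    trial_initiation_latency: float
    target_response_latency: float | None
    reward_retrieval_latency: float | None
    premature_left: int = 0
    premature_right: int = 0
    eor: int = 0
    orto: int = 0

    @property
    def is_response(self) -> bool:
        return self.choice is not Choice.OMISSION

    def validate(self) -> None:
        """Raise :class:`ValidationError` naming the first violated rule."""
        if self.session_index < 1:
            raise ValidationError("session_index must be >= 1")
        if self.trial_index < 1:
            raise ValidationError("trial_index must be >= 1")
        rewarded = self.outcome is Outcome.REWARDED
        if rewarded != (
            self.choice is not Choice.OMISSION
            and self.choice.value == self.correct_side.value
        ):
            raise ValidationError(
                "outcome must be REWARDED iff choice equals correct_side "
                "and is not an omission"
            )
        if (self.reward_retrieval_latency is not None) != rewarded:
            raise ValidationError(
                "reward_retrieval_latency must be present iff outcome is REWARDED"
            )
        if self.choice is Choice.OMISSION and self.target_response_latency is not None:
            raise ValidationError(
                "target_response_latency must be absent on omission trials"
            )
        if self.choice is not Choice.OMISSION:
            if self.target_response_latency is None:
                raise ValidationError(
                    "target_response_latency required on response trials"
                )
            if not 0 <= self.target_response_latency <= 30:
                raise ValidationError("target_response_latency must lie in [0, 30] s")
        if self.trial_initiation_latency < 0:
            raise ValidationError("trial_initiation_latency must be >= 0")
        if self.reward_retrieval_latency is not None and self.reward_retrieval_latency < 0:
            raise ValidationError("reward_retrieval_latency must be >= 0")
        for name in ("premature_left", "premature_right", "eor", "orto"):
            if getattr(self, name) < 0:
                raise ValidationError(f"{name} must be a non-negative count")


@dataclass(frozen=True)
class SubjectProfile:
    """Between-subject factors: sex model, X dose, gonadal status, and which
    physical side was rewarded during acquisition."""

    subject_id: str
    sex_model: SexModel
    x_dose: str  # "1X" | "2X"
    gdx: str  # "GDX" | "SHAM"
    assigned_acq_side: Side

    def __post_init__(self) -> None:
        if self.x_dose not in ("1X", "2X"):
            raise ValidationError("x_dose must be '1X' or '2X'")
        if self.gdx not in ("GDX", "SHAM"):
            raise ValidationError("gdx must be 'GDX' or 'SHAM'")

    @property
    def genotype(self) -> str:
        table = {
            (SexModel.KS, "1X"): "XY",
            (SexModel.KS, "2X"): "XXY",
            (SexModel.TS, "1X"): "XO",
            (SexModel.TS, "2X"): "XX",
        }
        return table[(self.sex_model, self.x_dose)]


def role_map_for(profile: SubjectProfile) -> dict[str, Side]:
    """Physical sides for the analysis roles C_ACQ (correct-in-acquisition)
    and C_REV (correct-in-reversal)."""
    return {
        "C_ACQ": profile.assigned_acq_side,
        "C_REV": profile.assigned_acq_side.opposite,
    }


@dataclass
class PhaseSeries:
    """Ordered trials of one subject in one phase, with session structure."""

    subject_id: str
    phase: Phase
    trials: list[TrialRecord] = field(default_factory=list)
    reached_criterion: bool = True

    @property
    def session_boundaries(self) -> list[int]:
        """Trial indices (1-based) at which a new session starts."""
        bounds: list[int] = []
        prev = None
        for t in self.trials:
            if t.session_index != prev:
                bounds.append(t.trial_index)
                prev = t.session_index
        return bounds

    @property
    def correct_side(self) -> Side:
        return self.trials[0].correct_side

    def response_trials(self) -> list[TrialRecord]:
        return [t for t in self.trials if t.is_response]

    def validate(self) -> None:
        if not self.trials:
            raise ValidationError("PhaseSeries must contain at least one trial")
        side = self.trials[0].correct_side
        prev_session = 0
        for i, t in enumerate(self.trials, start=1):
            t.validate()
            if t.subject_id != self.subject_id or t.phase != self.phase:
                raise ValidationError(
                    "trial subject/phase must match the series key"
                )
            if t.trial_index != i:
                raise ValidationError(
                    "trial_index must increase by exactly 1 from 1"
                )
            if t.correct_side != side:
                raise ValidationError(
                    "correct_side must be constant within a phase"
                )
            if t.session_index < prev_session:
                raise ValidationError("session_index must be non-decreasing")
            prev_session = t.session_index


TRIAL_TABLE_COLUMNS = [
    "subject_id",
    "sex_model",
    "x_dose",
    "gdx",
    "phase",
    "session_index",
    "trial_index",
    "correct_side",
    "choice",
    "outcome",
    "trial_initiation_latency_s",
    "target_response_latency_s",
    "reward_retrieval_latency_s",
    "premature_left",
    "premature_right",
    "eor",
    "orto",
]


def _fmt_latency(x: float | None) -> str:
    return "" if x is None else f"{x:.3f}"


def write_trial_table(
    series: Iterable[PhaseSeries],
    path,
    profiles: dict[str, SubjectProfile] | None = None,
) -> None:
    """Write a tidy trial table (UTF-8 CSV, fixed column order).

    Latencies are printed with three decimals so output is byte-stable for a
    fixed input.  ``profiles`` supplies the subject-factor columns; when a
    subject has no profile those columns are left empty.
    """
    profiles = profiles or {}
    lines = [",".join(TRIAL_TABLE_COLUMNS)]
    for s in series:
        prof = profiles.get(s.subject_id)
        for t in s.trials:
            row = [
                t.subject_id,
                prof.sex_model.value if prof else "",
                prof.x_dose if prof else "",
                prof.gdx if prof else "",
                t.phase.value,
                str(t.session_index),
                str(t.trial_index),
                t.correct_side.value,
                t.choice.value,
                t.outcome.value,
                _fmt_latency(t.trial_initiation_latency),
                _fmt_latency(t.target_response_latency),
                _fmt_latency(t.reward_retrieval_latency),
                str(t.premature_left),
                str(t.premature_right),
                str(t.eor),
                str(t.orto),
            ]
            lines.append(",".join(row))
    with open(path, "w", encoding="utf-8", newline="\n") as fh:
        fh.write("\n".join(lines) + "\n")


def _parse_optional_float(text: str, row: int, col: str) -> float | None:
    if text == "":
        return None
    try:
        return float(text)
    except ValueError as exc:
        raise ValidationError(f"row {row}: column {col} is not a number") from exc


def read_trial_table(path) -> tuple[list[PhaseSeries], dict[str, SubjectProfile]]:
    """Read a trial table into per-subject x phase series.

    Returns ``(series_list, profiles)``; ``profiles`` only contains subjects
    whose factor columns were populated.  All record and series invariants
    are validated; violations are reported with the offending row number.
    """
    with open(path, "r", encoding="utf-8") as fh:
        header = fh.readline().rstrip("\n")
        if header.split(",") != TRIAL_TABLE_COLUMNS:
            raise SchemaError(
                "trial table header does not match the expected columns: "
                f"expected {TRIAL_TABLE_COLUMNS}"
            )
        grouped: dict[tuple[str, Phase], list[TrialRecord]] = {}
        profiles: dict[str, SubjectProfile] = {}
        acq_sides: dict[str, str] = {}
        for row_no, line in enumerate(fh, start=2):
            line = line.rstrip("\n")
            if not line:
                continue
            vals = line.split(",")
            if len(vals) != len(TRIAL_TABLE_COLUMNS):
                raise SchemaError(f"row {row_no}: wrong number of fields")
            rec = dict(zip(TRIAL_TABLE_COLUMNS, vals))
            try:
                record = TrialRecord(
                    subject_id=rec["subject_id"],
                    phase=Phase(rec["phase"]),
                    session_index=int(rec["session_index"]),
                    trial_index=int(rec["trial_index"]),
                    correct_side=Side(rec["correct_side"]),
                    choice=Choice(rec["choice"]),
                    outcome=Outcome(rec["outcome"]),
                    trial_initiation_latency=float(
                        rec["trial_initiation_latency_s"]
                    ),
                    target_response_latency=_parse_optional_float(
                        rec["target_response_latency_s"], row_no,
                        "target_response_latency_s",
                    ),
                    reward_retrieval_latency=_parse_optional_float(
                        rec["reward_retrieval_latency_s"], row_no,
                        "reward_retrieval_latency_s",
                    ),
                    premature_left=int(rec["premature_left"]),
                    premature_right=int(rec["premature_right"]),
                    eor=int(rec["eor"]),
                    orto=int(rec["orto"]),
                )
                record.validate()
            except (ValueError, KeyError) as exc:
                if isinstance(exc, ValidationError):
                    raise ValidationError(f"row {row_no}: {exc}") from None
                raise ValidationError(f"row {row_no}: {exc}") from exc
            grouped.setdefault((record.subject_id, record.phase), []).append(record)
            if rec["sex_model"] and record.subject_id not in profiles:
                if rec["phase"] == "ACQ":
                    acq_side = Side(rec["correct_side"])
                else:
                    acq_side = Side(rec["correct_side"]).opposite
                profiles[record.subject_id] = SubjectProfile(
                    subject_id=record.subject_id,
                    sex_model=SexModel(rec["sex_model"]),
                    x_dose=rec["x_dose"],
                    gdx=rec["gdx"],
                    assigned_acq_side=acq_side,
                )
    out: list[PhaseSeries] = []
    for (sid, phase), trials in grouped.items():
        series = PhaseSeries(subject_id=sid, phase=phase, trials=trials)
        series.validate()
        out.append(series)
    # a subject's rewarded side must flip exactly once between ACQ and REV
    by_subject: dict[str, dict[Phase, PhaseSeries]] = {}
    for s in out:
        by_subject.setdefault(s.subject_id, {})[s.phase] = s
    for sid, phases in by_subject.items():
        if Phase.ACQ in phases and Phase.REV in phases:
            if phases[Phase.ACQ].correct_side == phases[Phase.REV].correct_side:
                raise ValidationError(
                    f"subject {sid}: correct_side must flip between ACQ and REV"
                )
    return out, profiles


# ---------------------------------------------------------------------------
# event-log parsing

_EVENT_CODES = {
    "SESSION_START",
    "TRIAL_ARMED",
    "OBS_POKE_START",
    "OBS_FAIL_TIMEOUT",
    "TARGETS_ON",
    "TARGET_POKE",
    "PELLET",
    "MAG_ENTRY",
    "TIMEOUT_ON",
    "TIMEOUT_OFF",
    "ITI_END",
    "OMISSION",
    "SESSION_END",
}


def parse_event_log(
    path,
    count_timeout_prematures: bool = True,
) -> list[PhaseSeries]:
    """Reconstruct trial records from a timestamped chamber event log.

    Latencies are timestamp differences rounded to the millisecond.  A target
    poke while the target apertures are unlit is a premature response
    (``count_timeout_prematures`` controls whether pokes during punishment
    timeouts count as well); a center poke while the targets are lit is an
    extraneous observing response; each ``OBS_FAIL_TIMEOUT`` is one
    observing-response timeout.

    The log must be time-ordered within each session; a ``PELLET`` without a
    preceding correct target poke is an error.
    """
    sessions: list[tuple[str, Phase, int, str, list[tuple[float, str, str]]]] = []
    current: list[tuple[float, str, str]] | None = None
    meta: tuple[str, Phase, int, str] | None = None
    with open(path, "r", encoding="utf-8") as fh:
        for line_no, line in enumerate(fh, start=1):
            line = line.rstrip("\n")
            if not line:
                continue
            parts = line.split("\t")
            if len(parts) != 3:
                raise EventLogError(f"line {line_no}: expected 3 tab-separated fields")
            ts_text, code, detail = parts
            try:
                ts = float(ts_text)
            except ValueError as exc:
                raise EventLogError(f"line {line_no}: bad timestamp") from exc
            if code not in _EVENT_CODES:
                raise EventLogError(f"line {line_no}: unknown event code {code!r}")
            if code == "SESSION_START":
                # detail: subject_id|phase|session_index|correct_side
                sid, phase_s, sess_s, side_s = detail.split("|")
                meta = (sid, Phase(phase_s), int(sess_s), side_s)
                current = []
            elif code == "SESSION_END":
                if meta is None or current is None:
                    raise EventLogError(f"line {line_no}: SESSION_END without start")
                sessions.append((*meta, current))
                meta, current = None, None
            else:
                if current is None:
                    raise EventLogError(
                        f"line {line_no}: event outside SESSION_START/SESSION_END"
                    )
                if current and ts < current[-1][0]:
                    raise EventLogError(
                        f"line {line_no}: out-of-order timestamp {ts}"
                    )
                current.append((ts, code, detail))
    if meta is not None:
        raise EventLogError("unterminated session (missing SESSION_END)")

    grouped: dict[tuple[str, Phase], list[TrialRecord]] = {}
    trial_counter: dict[tuple[str, Phase], int] = {}
    for sid, phase, session_index, side_s, events in sessions:
        correct_side = Side(side_s)
        key = (sid, phase)
        recs = grouped.setdefault(key, [])
        state = _TrialState(count_timeout_prematures)
        for ts, code, detail in events:
            rec = state.feed(ts, code, detail)
            if rec is not None:
                trial_counter[key] = trial_counter.get(key, 0) + 1
                recs.append(
                    rec.build(
                        subject_id=sid,
                        phase=phase,
                        session_index=session_index,
                        trial_index=trial_counter[key],
                        correct_side=correct_side,
                    )
                )
        if state.has_open_content():
            raise EventLogError(
                f"session {session_index} of {sid}/{phase.value} ends mid-trial"
            )
    out = []
    for (sid, phase), trials in grouped.items():
        series = PhaseSeries(subject_id=sid, phase=phase, trials=trials)
        series.validate()
        out.append(series)
    out.sort(key=lambda s: (s.subject_id, s.phase.value))
    return out


def _round_ms(x: float) -> float:
    return round(x, 3)


@dataclass
class _PendingTrial:
    iti_end: float
    first_obs: float | None = None
    targets_on: float | None = None
    choice: Choice | None = None
    choice_ts: float | None = None
    pellet_ts: float | None = None
    mag_ts: float | None = None
    premature_left: int = 0
    premature_right: int = 0
    eor: int = 0
    orto: int = 0

    def build(self, subject_id, phase, session_index, trial_index, correct_side):
        rewarded = (
            self.choice is not None
            and self.choice is not Choice.OMISSION
            and self.choice.value == correct_side.value
        )
        return TrialRecord(
            subject_id=subject_id,
            phase=phase,
            session_index=session_index,
            trial_index=trial_index,
            correct_side=correct_side,
            choice=self.choice if self.choice is not None else Choice.OMISSION,
            outcome=Outcome.REWARDED if rewarded else Outcome.UNREWARDED,
            trial_initiation_latency=_round_ms(self.first_obs - self.iti_end),
            target_response_latency=(
                None
                if self.choice is Choice.OMISSION
                else _round_ms(self.choice_ts - self.targets_on)
            ),
            reward_retrieval_latency=(
                _round_ms(self.mag_ts - self.pellet_ts) if rewarded else None
            ),
            premature_left=self.premature_left,
            premature_right=self.premature_right,
            eor=self.eor,
            orto=self.orto,
        )


class _TrialState:
    """Event-driven reconstruction of one trial at a time."""

    def __init__(self, count_timeout_prematures: bool) -> None:
        self.count_timeout_prematures = count_timeout_prematures
        self.trial: _PendingTrial | None = None
        self.targets_lit = False
        self.in_timeout = False

    @property
    def in_trial(self) -> bool:
        return self.trial is not None

    def has_open_content(self) -> bool:
        """True when a trial is mid-flight at session end (the ITI_END that
        closes the last trial legitimately leaves an empty pending slot)."""
        t = self.trial
        return t is not None and (t.first_obs is not None or t.choice is not None)

    def feed(self, ts: float, code: str, detail: str) -> _PendingTrial | None:
        """Consume one event; return the finished trial on ITI_END."""
        t = self.trial
        if code == "ITI_END":
            if t is None:  # arms the first trial of the session
                self.trial = _PendingTrial(iti_end=ts)
                return None
            done, self.trial = t, _PendingTrial(iti_end=ts)
            if done.first_obs is None and done.choice is None:
                raise EventLogError("trial closed with no events")
            return done
        if t is None:
            raise EventLogError(f"event {code} before first ITI_END")
        if code == "TRIAL_ARMED":
            pass
        elif code == "OBS_POKE_START":
            if self.targets_lit:
                t.eor += 1
            elif t.first_obs is None:
                t.first_obs = ts
        elif code == "OBS_FAIL_TIMEOUT":
            t.orto += 1
        elif code == "TARGETS_ON":
            self.targets_lit = True
            t.targets_on = ts
        elif code == "TARGET_POKE":
            side = Choice(detail)
            if self.targets_lit and t.choice is None:
                t.choice = side
                t.choice_ts = ts
                self.targets_lit = False
            elif not self.targets_lit:
                if self.in_timeout and not self.count_timeout_prematures:
                    return None
                if side is Choice.LEFT:
                    t.premature_left += 1
                else:
                    t.premature_right += 1
        elif code == "PELLET":
            if t.choice is None or t.choice is Choice.OMISSION:
                raise EventLogError("PELLET without a preceding target choice")
            t.pellet_ts = ts
        elif code == "MAG_ENTRY":
            if t.pellet_ts is not None and t.mag_ts is None:
                t.mag_ts = ts
        elif code == "TIMEOUT_ON":
            self.in_timeout = True
        elif code == "TIMEOUT_OFF":
            self.in_timeout = False
        elif code == "OMISSION":
            t.choice = Choice.OMISSION
            self.targets_lit = False
        return None
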