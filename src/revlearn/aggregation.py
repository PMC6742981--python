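"""Long-format analysis tables crossing subject and within-subject factors.

The study design crosses the between-subject factors (X dose: 1X vs 2X;
gonadal status: GDX vs SHAM) with the within-subject factors phase
(ACQ/REV), change-point fraction (PRE/POST), side role (C_ACQ/C_REV) and
prior-trial outcome, with a measure-specific factor structure.  Male (KS:
XY vs XXY) and female (TS: XX vs XO) cohorts are analyzed separately and
never pooled, so :func:`build_long_table` returns one table per sex model.

The table is lossless reshaping of :class:`~revlearn.learning_metrics.PhaseMetrics`
values — no transformation is applied here (display transforms such as
log10(y+1) for premature counts belong to plotting, not the data layer) —
and its schema is what a generalized-estimating-equations routine in any
statistics environment consumes directly.
"""

from __future__ import annotations

from typing import Iterable, Mapping

import numpy as np
import pandas as pd

from .learning_metrics import PhaseMetrics, SplitMetrics
from .trial_model import SubjectProfile

__all__ = [
    "ANALYSIS_CELL_COLUMNS",
    "MEASURE_FACTORS",
    "build_long_table",
    "summarize_cells",
]

ANALYSIS_CELL_COLUMNS = [
    "subject_id",
    "sex_model",
    "x_dose",
    "gdx",
    "phase",
    "cp_split",
    "side_role",
    "prior_outcome",
    "measure_name",
    "value",
]

#: factor structure per measure: which within-subject factors are crossed.
#: cp: PRE/POST split; side: C_ACQ/C_REV role; prior: prior-trial outcome.
MEASURE_FACTORS: Mapping[str, tuple[bool, bool, bool]] = {
    # measure -> (cp, side, prior)
    "trials": (True, False, False),
    "error_rate": (True, False, False),
    "fs": (True, False, False),
    "maxci": (False, False, False),
    "regress": (False, False, False),
    "premature_rate": (True, True, False),
    "target_latency": (True, True, False),
    "init_latency": (False, False, True),
    "retrieval_latency": (True, False, False),
    "orto_rate": (True, False, False),
    "eor_rate": (True, False, False),
    "omission_rate": (True, False, False),
}


def _split_value(split: SplitMetrics, measure: str, side_role: str | None):
    if measure == "trials":
        return split.n_trials
    if measure == "error_rate":
        return split.errors_per_trial
    if measure == "fs":
        return split.fs
    if measure == "premature_rate":
        return split.premature_per_trial.get(side_role)
    if measure == "target_latency":
        return split.target_latency_mean.get(side_role)
    if measure == "retrieval_latency":
        return split.retrieval_latency_mean
    if measure == "orto_rate":
        return split.orto_per_trial
    if measure == "eor_rate":
        return split.eor_per_trial
    if measure == "omission_rate":
        return split.omissions_per_trial
    raise KeyError(measure)


def _rows_for_phase(
    prof: SubjectProfile, pm: PhaseMetrics | None
) -> Iterable[dict]:
    base = {
        "subject_id": prof.subject_id,
        "sex_model": prof.sex_model.value,
        "x_dose": prof.x_dose,
        "gdx": prof.gdx,
    }
    for measure, (by_cp, by_side, by_prior) in MEASURE_FACTORS.items():
        cp_levels = ["PRE", "POST"] if by_cp else ["NA"]
        side_levels = ["C_ACQ", "C_REV"] if by_side else ["NA"]
        prior_levels = ["REWARDED", "UNREWARDED"] if by_prior else ["NA"]
        for cp in cp_levels:
            for side in side_levels:
                for prior in prior_levels:
                    value = None
                    if pm is not None:
                        if measure == "maxci":
                            value = pm.maxci
                        elif measure == "regress":
                            value = pm.regress
                        elif measure == "init_latency":
                            # phase-level mean conditioned on prior outcome
                            value = _prior_weighted_mean(pm, prior)
                        else:
                            split = pm.pre if cp == "PRE" else pm.post
                            value = _split_value(
                                split, measure, side if side != "NA" else None
                            )
                    yield {
                        **base,
                        "phase": pm.phase if pm is not None else "NA",
                        "cp_split": cp,
                        "side_role": side,
                        "prior_outcome": prior,
                        "measure_name": measure,
                        "value": np.nan if value is None else float(value),
                    }


def _prior_weighted_mean(pm: PhaseMetrics, prior: str) -> float | None:
    """Phase-level initiation-latency mean for one prior-trial outcome,
    recombining the PRE/POST fractions without re-touching trial data."""
    attr = (
        "init_latency_after_win" if prior == "REWARDED" else "init_latency_after_loss"
    )
    count_attr = "n_after_win" if prior == "REWARDED" else "n_after_loss"
    total_w = 0.0
    total = 0.0
    for split in (pm.pre, pm.post):
        v = getattr(split, attr)
        w = getattr(split, count_attr)
        if v is not None and w:
            total += v * w
            total_w += w
    return total / total_w if total_w else None


def build_long_table(
    metrics: Mapping[str, Mapping[str, PhaseMetrics]],
    profiles: Mapping[str, SubjectProfile],
) -> dict[str, pd.DataFrame]:
    """One tidy analysis table per sex model.

    ``metrics`` maps subject_id -> {"ACQ": PhaseMetrics, "REV": PhaseMetrics};
    a subject missing a phase still gets rows, with absent values.  Returns
    ``{"KS": DataFrame, "TS": DataFrame}`` (a key is present only when that
    cohort has subjects); X-dose levels never mix across sex models — XY/XXY
    live only in the KS table, XX/XO only in the TS table.
    """
    per_model: dict[str, list[dict]] = {}
    for sid, prof in profiles.items():
        rows = per_model.setdefault(prof.sex_model.value, [])
        subject_metrics = metrics.get(sid, {})
        for phase in ("ACQ", "REV"):
            pm = subject_metrics.get(phase)
            if pm is None:
                for row in _rows_for_phase(prof, None):
                    row["phase"] = phase
                    rows.append(row)
            else:
                rows.extend(_rows_for_phase(prof, pm))
    out = {}
    for model, rows in per_model.items():
        df = pd.DataFrame(rows, columns=ANALYSIS_CELL_COLUMNS)
        df = df.sort_values(
            ["measure_name", "subject_id", "phase", "cp_split", "side_role",
             "prior_outcome"],
            kind="mergesort",
        ).reset_index(drop=True)
        out[model] = df
    return out


def summarize_cells(table: pd.DataFrame) -> pd.DataFrame:
    """Per-cell mean, SD and n over non-absent values.

    Cells are measure x group (x_dose, gdx) x within-subject factors.  SD is
    the ddof=1 standard deviation and absent for singleton cells; ordering is
    deterministic.
    """
    keys = [
        "measure_name",
        "sex_model",
        "x_dose",
        "gdx",
        "phase",
        "cp_split",
        "side_role",
        "prior_outcome",
    ]
    grouped = table.dropna(subset=["value"]).groupby(keys, sort=True)["value"]
    out = grouped.agg(mean="mean", sd=lambda v: v.std(ddof=1), n="count")
    return out.reset_index()
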