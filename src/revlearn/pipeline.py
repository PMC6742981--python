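"""Cohort-level convenience layer tying the stages together.

``analyze_cohort`` maps per-subject phase series to :class:`PhaseMetrics`;
``metrics_table`` flattens them to the one-row-per-subject x phase x split
CSV schema; the long-format builders live in :mod:`revlearn.aggregation`.
"""

from __future__ import annotations

from typing import Iterable, Mapping

import numpy as np
import pandas as pd

from .learning_metrics import PhaseMetrics, SplitMetrics, compute_phase_metrics
from .trial_model import PhaseSeries, SubjectProfile, role_map_for

__all__ = ["analyze_cohort", "metrics_table", "metrics_per_subject_phase"]


def analyze_cohort(
    series: Iterable[PhaseSeries],
    profiles: Mapping[str, SubjectProfile],
    **metric_kwargs,
) -> dict[str, dict[str, PhaseMetrics]]:
    """subject_id -> phase name -> PhaseMetrics for every series with a
    profile (side roles need the acquisition side assignment)."""
    out: dict[str, dict[str, PhaseMetrics]] = {}
    for s in series:
        prof = profiles.get(s.subject_id)
        if prof is None:
            raise KeyError(f"no profile for subject {s.subject_id}")
        pm = compute_phase_metrics(s, role_map_for(prof), **metric_kwargs)
        out.setdefault(s.subject_id, {})[s.phase.value] = pm
    return out


def _split_row(sm: SplitMetrics) -> dict:
    row = {
        "n_trials": sm.n_trials,
        "n_presented": sm.n_presented,
        "errors_per_trial": sm.errors_per_trial,
        "fs": sm.fs,
        "p_lose_shift": sm.p_lose_shift,
        "p_win_stay": sm.p_win_stay,
        "init_latency_mean": sm.init_latency_mean,
        "init_latency_after_win": sm.init_latency_after_win,
        "init_latency_after_loss": sm.init_latency_after_loss,
        "retrieval_latency_mean": sm.retrieval_latency_mean,
        "eor_per_trial": sm.eor_per_trial,
        "orto_per_trial": sm.orto_per_trial,
        "omissions_per_trial": sm.omissions_per_trial,
    }
    for role in ("C_ACQ", "C_REV"):
        row[f"premature_per_trial_{role}"] = sm.premature_per_trial.get(role)
        row[f"target_latency_{role}"] = sm.target_latency_mean.get(role)
    return row


def metrics_table(
    metrics: Mapping[str, Mapping[str, PhaseMetrics]],
    profiles: Mapping[str, SubjectProfile] | None = None,
) -> pd.DataFrame:
    """Flatten metrics to one row per subject x phase x split (PRE/POST).

    Whole-phase scalars (trials to criterion, CP index, MAXCI, regress score)
    repeat on both split rows.  Absent values become NaN.
    """
    profiles = profiles or {}
    rows = []
    for sid in sorted(metrics):
        prof = profiles.get(sid)
        for phase in ("ACQ", "REV"):
            pm = metrics[sid].get(phase)
            if pm is None:
                continue
            for split_name, sm in (("PRE", pm.pre), ("POST", pm.post)):
                row = {
                    "subject_id": sid,
                    "sex_model": prof.sex_model.value if prof else "",
                    "x_dose": prof.x_dose if prof else "",
                    "gdx": prof.gdx if prof else "",
                    "phase": phase,
                    "cp_split": split_name,
                    "trials_to_criterion": pm.trials_to_criterion,
                    "reached_criterion": pm.reached_criterion,
                    "cp_index": pm.cp_index,
                    "cp_degenerate": pm.cp_degenerate,
                    "maxci": pm.maxci,
                    "regress": pm.regress,
                }
                row.update(_split_row(sm))
                rows.append(row)
    df = pd.DataFrame(rows)
    return df.replace({None: np.nan})


def metrics_per_subject_phase(
    metrics: Mapping[str, Mapping[str, PhaseMetrics]],
    profiles: Mapping[str, SubjectProfile],
    phase: str = "REV",
) -> pd.DataFrame:
    """One row per subject with the error measures of one phase, for the
    measure-correlation analysis (MAXCI vs regress vs trials)."""
    rows = []
    for sid, per_phase in sorted(metrics.items()):
        pm = per_phase.get(phase)
        if pm is None:
            continue
        prof = profiles[sid]
        rows.append(
            {
                "subject_id": sid,
                "sex_model": prof.sex_model.value,
                "x_dose": prof.x_dose,
                "gdx": prof.gdx,
                "maxci": pm.maxci,
                "regress": pm.regress,
                "trials": pm.trials_to_criterion,
            }
        )
    return pd.DataFrame(rows)
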