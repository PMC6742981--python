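"""Pre-model statistics: transformation selection, Bonferroni, correlations.

Omnibus model fitting (GEE with robust covariance) is deliberately left to
standard statistical tooling; this module prepares its inputs.  For each
measure a link/transformation is chosen by normality testing of candidate
transforms (identity, log, square root) — the candidate whose transformed
sample looks most normal wins; count-like measures that no transform
normalizes are recommended a gamma/log-link instead.  Post hoc families are
corrected with Bonferroni.  The perseverative (MAXCI) and regressive error
measures are checked for independence via per-group correlations.
"""

from __future__ import annotations

import json
from dataclasses import dataclass

import numpy as np
import pandas as pd
from scipy import stats
from statsmodels.stats.diagnostic import lilliefors

__all__ = [
    "TransformChoice",
    "select_transformation",
    "bonferroni_adjust",
    "correlate_measures",
    "export_gee",
    "DEFAULT_PAIRS",
]

_CANDIDATES = ("identity", "log", "sqrt")


@dataclass
class TransformChoice:
    """Outcome of transformation selection for one measure.

    ``ks_stat``/``ks_p`` hold the normality-test statistic and p-value per
    candidate; ``chosen`` has the maximal p unless all candidates reject at
    0.05 on non-negative right-skewed data, in which case ``gamma_log`` is
    recommended (the data are then treated as gamma-distributed with a log
    link rather than transformed to normality).  ``shifted`` records whether
    log/sqrt were applied to ``x + 1`` because zeros were present.
    """

    measure_name: str
    ks_stat: dict[str, float]
    ks_p: dict[str, float]
    chosen: str
    shifted: bool


def _transform(x: np.ndarray, name: str, shift: bool) -> np.ndarray:
    y = x + 1.0 if shift and name in ("log", "sqrt") else x
    if name == "log":
        return np.log(y)
    if name == "sqrt":
        return np.sqrt(y)
    return y


def select_transformation(
    values,
    measure_name: str = "",
    alpha: float = 0.05,
    exact_ks: bool = False,
) -> TransformChoice:
    """Choose identity/log/sqrt by normality of the transformed sample.

    Normality is tested with the Lilliefors-corrected Kolmogorov–Smirnov
    test (parameters estimated from the data); ``exact_ks=True`` instead
    standardizes by the sample moments and runs a plain one-sample KS against
    N(0,1).  When zeros are present, log and sqrt are applied to ``x + 1``.
    Negative values restrict candidates to the identity.  If every candidate
    rejects at ``alpha`` and the data are non-negative and right-skewed,
    ``gamma_log`` is recommended.

    Raises ``ValueError`` for constant samples (no distribution to test) and
    for samples with fewer than 8 finite values.
    """
    x = np.asarray(values, dtype=float)
    x = x[np.isfinite(x)]
    if x.size < 8:
        raise ValueError("need at least 8 finite values")
    if np.ptp(x) == 0:
        raise ValueError("constant sample: no distribution to test")
    shift = bool((x == 0).any())
    candidates = _CANDIDATES if x.min() >= 0 else ("identity",)
    ks_stat: dict[str, float] = {}
    ks_p: dict[str, float] = {}
    for name in candidates:
        y = _transform(x, name, shift)
        if np.ptp(y) == 0:
            continue
        if exact_ks:
            z = (y - y.mean()) / y.std(ddof=1)
            stat, p = stats.kstest(z, "norm")
        else:
            stat, p = lilliefors(y, dist="norm")
        ks_stat[name] = float(stat)
        ks_p[name] = float(p)
    chosen = max(ks_p, key=ks_p.get)
    if all(p < alpha for p in ks_p.values()) and x.min() >= 0:
        if stats.skew(x) > 0:
            chosen = "gamma_log"
    return TransformChoice(
        measure_name=measure_name,
        ks_stat=ks_stat,
        ks_p=ks_p,
        chosen=chosen,
        shifted=shift,
    )


def bonferroni_adjust(p_values, m: int | None = None) -> list[float]:
    """Bonferroni-adjusted p-values: ``min(1, p * m)`` elementwise.

    ``m`` defaults to the family size ``len(p_values)`` and must not be
    smaller than it.
    """
    p = list(p_values)
    if m is None:
        m = len(p)
    if m < len(p):
        raise ValueError("family size m must be >= number of p-values")
    for v in p:
        if not 0 <= v <= 1:
            raise ValueError("p-values must lie in [0, 1]")
    return [min(1.0, v * m) for v in p]


DEFAULT_PAIRS = (
    ("maxci", "regress"),
    ("maxci", "trials"),
    ("regress", "trials"),
)


def correlate_measures(
    per_subject: pd.DataFrame,
    pairs=DEFAULT_PAIRS,
    grouping=("sex_model", "x_dose", "gdx"),
    method: str = "pearson",
    min_n: int = 4,
) -> pd.DataFrame:
    """Pairwise measure correlations split by subject group.

    ``per_subject`` has one row per subject with the measure columns plus the
    grouping columns (measures already collapsed over phase or taken within
    one phase, the caller's choice).  Returns one row per group x pair with
    the coefficient and two-sided p; groups with fewer than ``min_n``
    complete observations get NaN and a reason.  ``method`` is ``pearson``
    (product-moment, default) or ``spearman``.
    """
    if method not in ("pearson", "spearman"):
        raise ValueError("method must be 'pearson' or 'spearman'")
    corr = stats.pearsonr if method == "pearson" else stats.spearmanr
    rows = []
    for keys, grp in per_subject.groupby(list(grouping), sort=True):
        if not isinstance(keys, tuple):
            keys = (keys,)
        for a, b in pairs:
            sub = grp[[a, b]].dropna()
            row = dict(zip(grouping, keys))
            row.update({"measure_a": a, "measure_b": b, "n": len(sub)})
            if len(sub) < min_n:
                row.update(r=np.nan, p=np.nan, note=f"n < {min_n}")
            elif sub[a].nunique() < 2 or sub[b].nunique() < 2:
                row.update(r=np.nan, p=np.nan, note="constant measure")
            else:
                res = corr(sub[a].to_numpy(), sub[b].to_numpy())
                row.update(r=float(res.statistic), p=float(res.pvalue), note="")
            rows.append(row)
    return pd.DataFrame(rows)


def export_gee(
    table: pd.DataFrame,
    transforms: dict[str, TransformChoice],
    table_path,
    sidecar_path,
) -> None:
    """Write the long analysis table plus a JSON sidecar naming, per measure,
    the link/transform a GEE routine should use (values in the table itself
    stay untransformed)."""
    table.to_csv(table_path, index=False)
    meta = {
        name: {
            "link": tc.chosen,
            "shifted_plus_1": tc.shifted,
            "ks_p": tc.ks_p,
        }
        for name, tc in transforms.items()
    }
    with open(sidecar_path, "w", encoding="utf-8") as fh:
        json.dump(meta, fh, indent=2, sort_keys=True)
        fh.write("\n")
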