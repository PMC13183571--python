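"""Patient versus healthy-control comparison of gait metrics.

Independent-samples t-tests per metric x condition on subject-level
values (mean of the two walks).  The unequal-variance (Welch) form is
the default because the patient and control groups differ in size and
plausibly in spread; the pooled-variance Student form is available by
switch.  Shapiro-Wilk normality flags are attached per group.
"""

from __future__ import annotations

import math
from dataclasses import dataclass
from typing import Sequence

import numpy as np
import pandas as pd
from scipy import stats

from .gait_metrics import METRICS, shapiro_normality

VARIANTS = ("welch", "student")


@dataclass
class GroupComparison:
    metric: str
    condition: str
    n_patients: int
    n_controls: int
    mean_patients: float
    mean_controls: float
    mean_diff: float  # patients - controls
    t_stat: float
    p: float
    variant: str
    patients_normal_p: float
    controls_normal_p: float


def compare_groups(
    patient_values: Sequence[float],
    control_values: Sequence[float],
    variant: str = "welch",
    metric: str = "",
    condition: str = "",
) -> GroupComparison:
    """Two-sided independent-samples t-test of patients vs controls."""
    if variant not in VARIANTS:
        raise ValueError(f"variant must be one of {VARIANTS}, got '{variant}'")
    pat = np.asarray(patient_values, dtype=float)
    con = np.asarray(control_values, dtype=float)
    pat = pat[~np.isnan(pat)]
    con = con[~np.isnan(con)]
    if len(pat) < 3 or len(con) < 3:
        raise ValueError(
            f"each group needs n >= 3, got {len(pat)} patients / {len(con)} controls"
        )
    if np.ptp(pat) == 0 and np.ptp(con) == 0:
        raise ValueError("degenerate: zero variance in both groups")
    t, p = stats.ttest_ind(pat, con, equal_var=(variant == "student"))

    def normal_p(values: np.ndarray) -> float:
        try:
            _, sp = shapiro_normality(values)
            return sp
        except ValueError:
            return math.nan

    return GroupComparison(
        metric=metric,
        condition=condition,
        n_patients=len(pat),
        n_controls=len(con),
        mean_patients=float(pat.mean()),
        mean_controls=float(con.mean()),
        mean_diff=float(pat.mean() - con.mean()),
        t_stat=float(t),
        p=float(p),
        variant=variant,
        patients_normal_p=normal_p(pat),
        controls_normal_p=normal_p(con),
    )


def comparison_table(
    patient_means: pd.DataFrame,
    control_means: pd.DataFrame,
    variant: str = "welch",
    alpha: float = 0.05,
) -> pd.DataFrame:
    """Per metric x condition comparison of two long-format subject-mean tables.

    Adds the sign of the patient-control difference and a significance
    flag, the ingredients of a summary matrix of gait alterations.
    """
    rows = []
    conditions = sorted(set(patient_means["condition"]) & set(control_means["condition"]))
    for condition in conditions:
        for metric in METRICS:
            pat = patient_means.query("condition == @condition and metric == @metric")["value"]
            con = control_means.query("condition == @condition and metric == @metric")["value"]
            res = compare_groups(pat, con, variant=variant, metric=metric, condition=condition)
            rows.append(
                {
                    "condition": condition,
                    "metric": metric,
                    "n_patients": res.n_patients,
                    "n_controls": res.n_controls,
                    "mean_patients": res.mean_patients,
                    "mean_controls": res.mean_controls,
                    "mean_diff": res.mean_diff,
                    "t_stat": res.t_stat,
                    "p": res.p,
                    "direction": int(np.sign(res.mean_diff)),
                    "significant": bool(res.p < alpha),
                    "patients_normal_p": res.patients_normal_p,
                    "controls_normal_p": res.controls_normal_p,
                }
            )
    return pd.DataFrame(rows)
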