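"""Minimal detectable change and minimal clinically important difference.

For every metric x condition the pipeline reports:

* SEM and MDC95 — ``SEM = SD * sqrt(1 - ICC)``,
  ``MDC95 = 1.96 * sqrt(2) * SEM`` — the smallest change exceeding
  measurement error at 95 % confidence.
* Distribution-based MCIDs — small/medium/large effect sizes (0.2,
  0.5, 0.8) times the cohort SD.
* Anchor-based MCIDs — the unstandardized slope B of the metric on a
  clinical anchor, times that anchor's established MCID, reported only
  when the metric-anchor Pearson correlation clears |r| > 0.3.
* A triangulated MCID — the mean of the medium-effect
  distribution-based estimate and the available anchor-based estimates.

Estimates are signed by the metric's direction of clinical improvement
(positive for velocity, stride length and swing phase; negative for
stride time, double support, variability, asymmetry and base-of-support
metrics), and anchors whose own improvement is a decrease (FES-I) enter
with a negative anchor change so that B x delta-anchor carries the
correct metric direction.
"""

from __future__ import annotations

import math
from dataclasses import dataclass, field
from decimal import ROUND_HALF_UP, Decimal
from typing import Mapping, Sequence

import numpy as np
import pandas as pd
from scipy import stats

from .gait_metrics import DOMAINS, IMPROVEMENT_SIGN, METRICS
from .reliability import ReliabilityResult

EFFECT_SIZES = {"small": 0.2, "medium": 0.5, "large": 0.8}
#: Minimum |Pearson r| for an anchor to qualify for a metric.
CORRELATION_GATE = 0.3
#: Minimum paired complete cases for an anchor regression.
MIN_ANCHOR_PAIRS = 10


@dataclass(frozen=True)
class AnchorSpec:
    """A clinical anchor with its established meaningful-change threshold."""

    name: str
    anchor_mcid: float  # points, magnitude
    improvement_direction: str  # "increase" or "decrease"
    column: str  # column in the anchor table

    def __post_init__(self) -> None:
        if self.anchor_mcid <= 0:
            raise ValueError("anchor_mcid must be > 0")
        if self.improvement_direction not in ("increase", "decrease"):
            raise ValueError("improvement_direction must be 'increase' or 'decrease'")

    @property
    def signed_change(self) -> float:
        """The anchor change representing clinical improvement, signed."""
        return self.anchor_mcid if self.improvement_direction == "increase" else -self.anchor_mcid


#: FGA improves by increasing (+4 points is meaningful), FES-I by
#: decreasing (-8 points), PCS-12 by increasing (+10 points).
DEFAULT_ANCHORS = (
    AnchorSpec("FGA", 4.0, "increase", "fga"),
    AnchorSpec("FES_I", 8.0, "decrease", "fes_i"),
    AnchorSpec("PCS12", 10.0, "increase", "pcs12"),
)


@dataclass
class AnchorResult:
    """Anchor regression outcome for one metric x condition x anchor."""

    anchor: str
    n: int
    r: float
    b: float
    estimate: float | None  # None when gated out or not estimable
    reason: str = ""


@dataclass
class MCIDEstimate:
    """All change thresholds for one metric x condition."""

    metric: str
    condition: str
    sign: int  # improvement direction of the metric
    sd: float
    icc: float
    sem: float
    mdc95: float  # magnitude
    dist_small: float
    dist_medium: float
    dist_large: float
    anchors: dict[str, AnchorResult] = field(default_factory=dict)
    triangulated: float | None = None
    n_triangulated: int = 0
    below_mdc: bool = False


def round_half_away(x: float, ndigits: int = 2) -> float:
    """Decimal rounding with ties away from zero (report convention)."""
    if x is None or (isinstance(x, float) and math.isnan(x)):
        return math.nan
    q = Decimal(1).scaleb(-ndigits)
    return float(Decimal(repr(float(x))).quantize(q, rounding=ROUND_HALF_UP))


def sem_mdc(sd: float, icc: float) -> tuple[float, float]:
    """Standard error of measurement and MDC95 from cohort SD and ICC.

    ``SEM = SD * sqrt(1 - ICC)``; ``MDC95 = 1.96 * sqrt(2) * SEM``.
    """
    if sd <= 0:
        raise ValueError(f"sd must be > 0, got {sd}")
    if icc > 1:
        raise ValueError(f"icc must be <= 1, got {icc}")
    sem = sd * math.sqrt(1.0 - icc)
    mdc95 = 1.96 * math.sqrt(2.0) * sem
    return sem, mdc95


def distribution_mcid(sd: float, effect_size: float) -> float:
    """Distribution-based MCID magnitude: effect size times cohort SD."""
    if sd <= 0:
        raise ValueError(f"sd must be > 0, got {sd}")
    if effect_size <= 0:
        raise ValueError(f"effect_size must be > 0, got {effect_size}")
    return effect_size * sd


def anchor_mcid(
    metric_values: Sequence[float],
    anchor_values: Sequence[float],
    anchor: AnchorSpec,
    min_pairs: int = MIN_ANCHOR_PAIRS,
    r_gate: float = CORRELATION_GATE,
) -> AnchorResult:
    """Anchor-based MCID for one metric: B x (signed anchor MCID).

    The estimate is absent (None) when fewer than ``min_pairs`` complete
    pairs exist, the anchor is constant, or |r| does not exceed
    ``r_gate``.
    """
    x = np.asarray(anchor_values, dtype=float)
    y = np.asarray(metric_values, dtype=float)
    ok = ~(np.isnan(x) | np.isnan(y))
    x, y = x[ok], y[ok]
    n = len(x)
    if n < min_pairs:
        return AnchorResult(anchor.name, n, math.nan, math.nan, None, reason="too_few_pairs")
    if np.ptp(x) == 0 or np.ptp(y) == 0:
        return AnchorResult(
            anchor.name, n, math.nan, math.nan, None, reason="degenerate_variance"
        )
    r, _ = stats.pearsonr(x, y)
    fit = stats.linregress(x, y)
    b = float(fit.slope)
    if abs(r) <= r_gate:
        return AnchorResult(anchor.name, n, float(r), b, None, reason="below_correlation_gate")
    return AnchorResult(anchor.name, n, float(r), b, b * anchor.signed_change)


def triangulate(
    dist_medium: float | None, anchor_estimates: Sequence[float | None]
) -> tuple[float | None, int]:
    """Mean of the available members of {medium-effect distribution
    estimate, anchor-based estimates}; (None, 0) when nothing is available."""
    members = [
        v
        for v in (dist_medium, *anchor_estimates)
        if v is not None and not (isinstance(v, float) and math.isnan(v))
    ]
    if not members:
        return None, 0
    return float(np.mean(members)), len(members)


def build_mcid_table(
    subject_means: pd.DataFrame,
    anchors: pd.DataFrame,
    reliability: Mapping[tuple[str, str], ReliabilityResult],
    cohort_sd: Mapping[tuple[str, str], float],
    anchor_specs: Sequence[AnchorSpec] = DEFAULT_ANCHORS,
) -> list[MCIDEstimate]:
    """Assemble the MDC / MCID estimates for every metric x condition.

    ``subject_means`` is long (subject_id, condition, metric, value)
    holding each subject's mean over the two walks, after outlier
    removal; ``cohort_sd`` maps (condition, metric) to the cohort SD
    pooled over both walks of the condition (the SD feeding both SEM/MDC
    and the distribution-based estimates); ``anchors`` is one row per
    subject.  A row is flagged ``below_mdc`` when the triangulated value
    or any contributing MCID does not exceed the MDC95.
    """
    estimates: list[MCIDEstimate] = []
    anchors = anchors.set_index("subject_id") if "subject_id" in anchors.columns else anchors
    for (condition, metric), rel in reliability.items():
        sd = cohort_sd[(condition, metric)]
        sign = IMPROVEMENT_SIGN[metric]
        sem, mdc95 = sem_mdc(sd, rel.icc)
        est = MCIDEstimate(
            metric=metric,
            condition=condition,
            sign=sign,
            sd=sd,
            icc=rel.icc,
            sem=sem,
            mdc95=mdc95,
            dist_small=sign * distribution_mcid(sd, EFFECT_SIZES["small"]),
            dist_medium=sign * distribution_mcid(sd, EFFECT_SIZES["medium"]),
            dist_large=sign * distribution_mcid(sd, EFFECT_SIZES["large"]),
        )
        cell = subject_means[
            (subject_means["condition"] == condition) & (subject_means["metric"] == metric)
        ].set_index("subject_id")["value"]
        for spec in anchor_specs:
            joined = pd.concat([cell, anchors[spec.column]], axis=1, join="inner").dropna()
            est.anchors[spec.name] = anchor_mcid(
                joined["value"].to_numpy(), joined[spec.column].to_numpy(), spec
            )
        est.triangulated, est.n_triangulated = triangulate(
            est.dist_medium, [a.estimate for a in est.anchors.values()]
        )
        components = [est.triangulated] + [
            a.estimate for a in est.anchors.values() if a.estimate is not None
        ]
        est.below_mdc = any(
            c is not None and abs(c) <= est.mdc95 for c in components
        )
        estimates.append(est)
    return estimates


def mcid_table_frame(
    estimates: Sequence[MCIDEstimate],
    anchor_specs: Sequence[AnchorSpec] = DEFAULT_ANCHORS,
    ndigits: int | None = 2,
) -> pd.DataFrame:
    """Render MCID estimates as the report table (signed values).

    MDC95 and the distribution/anchor/triangulated estimates carry the
    sign of the metric's improvement direction.  ``ndigits=None``
    disables rounding.
    """

    def fmt(v: float | None) -> float:
        if v is None:
            return math.nan
        return round_half_away(v, ndigits) if ndigits is not None else float(v)

    rows = []
    for e in estimates:
        row = {
            "condition": e.condition,
            "domain": DOMAINS[e.metric],
            "metric": e.metric,
            "mdc": fmt(e.sign * e.mdc95),
            "dist_small": fmt(e.dist_small),
            "dist_medium": fmt(e.dist_medium),
            "dist_large": fmt(e.dist_large),
        }
        for spec in anchor_specs:
            a = e.anchors.get(spec.name)
            row[spec.name] = fmt(a.estimate if a else None)
            row[f"{spec.name}_r"] = fmt(a.r if a else None)
        row["triangulated"] = fmt(e.triangulated)
        row["n_estimates"] = e.n_triangulated
        row["below_mdc"] = e.below_mdc
        rows.append(row)
    df = pd.DataFrame(rows)
    order = {m: i for i, m in enumerate(METRICS)}
    return df.sort_values(
        ["condition", "metric"], key=lambda s: s.map(order) if s.name == "metric" else s
    ).reset_index(drop=True)
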