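"""Spatiotemporal gait metrics from pooled walkway walks.

Thirteen metrics in five domains are computed per walk:

* pace: gait velocity (cm/s), stride length (cm), stride time (s)
* phase: swing and double-support phase (% of gait cycle)
* variability: coefficient of variation (CV, %) of stride length,
  stride time and swing phase
* asymmetry: left-right asymmetry (%) of stride length, stride time and
  swing phase
* postural control: mean (cm) and CV (%) of base of support

A gait cycle (stride) runs between two successive contacts of the same
foot within one trial; strides never span the pooled-trial boundary.
The walk's progression axis is re-estimated as the principal axis of all
heel positions, so the nominal walkway orientation need not be exact.
"""

from __future__ import annotations

import math
import warnings
from dataclasses import dataclass
from typing import Sequence

import numpy as np
import pandas as pd
from scipy import stats

from .walkway_io import Foot, Walk

#: Canonical metric order (Table rows run in this order).
METRICS = (
    "vel",
    "slen",
    "stime",
    "swing",
    "dsupp",
    "slen_CV",
    "stime_CV",
    "swing_CV",
    "slen_ASYM",
    "stime_ASYM",
    "swing_ASYM",
    "swidth",
    "swidth_CV",
)

#: Gait domain of each metric.
DOMAINS = {
    "vel": "pace",
    "slen": "pace",
    "stime": "pace",
    "swing": "phase",
    "dsupp": "phase",
    "slen_CV": "variability",
    "stime_CV": "variability",
    "swing_CV": "variability",
    "slen_ASYM": "asymmetry",
    "stime_ASYM": "asymmetry",
    "swing_ASYM": "asymmetry",
    "swidth": "postural_control",
    "swidth_CV": "postural_control",
}

#: Direction of clinical improvement: +1 if larger is better (faster
#: gait, longer strides, longer swing), -1 if smaller is better (shorter
#: stride time, less double support, lower variability/asymmetry,
#: narrower base of support).
IMPROVEMENT_SIGN = {
    "vel": 1,
    "slen": 1,
    "stime": -1,
    "swing": 1,
    "dsupp": -1,
    "slen_CV": -1,
    "stime_CV": -1,
    "swing_CV": -1,
    "slen_ASYM": -1,
    "stime_ASYM": -1,
    "swing_ASYM": -1,
    "swidth": -1,
    "swidth_CV": -1,
}

#: Hard floor of strides per foot for variability/asymmetry estimates.
MIN_STRIDES_PER_FOOT = 4
#: Commonly recommended minimum cycle count for stable CV estimates.
RECOMMENDED_MIN_CYCLES = 15


class InsufficientDataError(ValueError):
    """A walk does not contain enough footfalls for stride segmentation."""


@dataclass(frozen=True)
class StrideRecord:
    """One complete same-foot gait cycle within a trial."""

    foot: Foot
    trial_index: int
    stride_time: float  # s, same-foot contact interval (= cycle_time)
    stride_length: float  # cm, heel displacement along progression axis
    swing_time: float  # s, lift to next same-foot contact
    cycle_time: float  # s
    double_support_time: float | None  # s; None when the opposite stride is incomplete
    base_of_support: float | None  # cm, at the stride's initial contact

    @property
    def swing_pct(self) -> float:
        return 100.0 * self.swing_time / self.cycle_time

    @property
    def dsupp_pct(self) -> float | None:
        if self.double_support_time is None:
            return None
        return 100.0 * self.double_support_time / self.cycle_time


@dataclass
class GaitMetricSet:
    """The 13 named metric values for one walk (NaN = not estimable)."""

    subject_id: str
    condition: str
    walk: int  # 1-based walk index within the condition
    n_strides: int
    vel: float
    slen: float
    stime: float
    swing: float
    dsupp: float
    slen_CV: float
    stime_CV: float
    swing_CV: float
    slen_ASYM: float
    stime_ASYM: float
    swing_ASYM: float
    swidth: float
    swidth_CV: float

    def values(self) -> dict[str, float]:
        return {m: getattr(self, m) for m in METRICS}


def _progression_frame(walk: Walk) -> tuple[np.ndarray, np.ndarray]:
    """Unit progression axis and its lateral normal from heel positions.

    Principal axis of the heel point cloud after centering each
    (trial, foot) group separately: per-group centering makes the
    estimate invariant to the lateral offset between the two feet and
    to the spatial reset between the pooled trials, which would
    otherwise tilt the axis.
    """
    groups: dict[tuple[int, Foot], list[list[float]]] = {}
    for e in walk.events:
        groups.setdefault((e.trial_index, e.foot), []).append([e.heel_x, e.heel_y])
    residuals = []
    for pts in groups.values():
        arr = np.asarray(pts)
        residuals.append(arr - arr.mean(axis=0))
    centered = np.vstack(residuals)
    cov = centered.T @ centered
    _, vecs = np.linalg.eigh(cov)
    u = vecs[:, -1]  # principal axis = progression
    v = np.array([-u[1], u[0]])
    return u, v


def _project(events: Sequence, axis: np.ndarray) -> np.ndarray:
    pts = np.array([[e.heel_x, e.heel_y] for e in events])
    return pts @ axis


def segment_strides(walk: Walk) -> list[StrideRecord]:
    """Segment a walk into complete same-foot gait cycles.

    Double support of a cycle is the part of the cycle during which both
    feet are on the ground.  For an alternating footfall pattern it
    equals ``cycle_time - swing(own) - swing(opposite)``, where the
    opposite swing belongs to the opposite-foot stride initiated inside
    the cycle; this temporal identity is used directly, which keeps the
    estimate well defined even when the left-right contact phase
    wanders.  Base of support is the lateral heel distance to the
    opposite foot's line of progression within the same trial.
    """
    for trial in walk.trial_pair:
        for foot in Foot:
            if len(walk.events_of(trial, foot)) < 3:
                raise InsufficientDataError(
                    f"walk {walk.subject_id}/{walk.condition.value}/trials "
                    f"{walk.trial_pair}: fewer than 3 {foot.value}-foot events "
                    f"in trial {trial}"
                )
    u, v = _progression_frame(walk)

    strides: list[StrideRecord] = []
    for trial in walk.trial_pair:
        per_foot = {foot: walk.events_of(trial, foot) for foot in Foot}
        proj = {foot: _project(per_foot[foot], u) for foot in Foot}
        lat = {foot: _project(per_foot[foot], v) for foot in Foot}
        mean_lat = {foot: float(np.mean(lat[foot])) for foot in Foot}

        # swing time of the stride starting at each contact (None for the last)
        swing_at: dict[Foot, list[float | None]] = {}
        for foot in Foot:
            evs = per_foot[foot]
            swing_at[foot] = [
                evs[i + 1].contact_time - evs[i].lift_time for i in range(len(evs) - 1)
            ] + [None]

        for foot in Foot:
            other = Foot.RIGHT if foot is Foot.LEFT else Foot.LEFT
            evs = per_foot[foot]
            opp = per_foot[other]
            for i in range(len(evs) - 1):
                t0, t1 = evs[i].contact_time, evs[i + 1].contact_time
                cycle = t1 - t0
                swing = swing_at[foot][i]
                # opposite-foot stride initiated within this cycle
                opp_swing: float | None = None
                for j, oe in enumerate(opp):
                    if t0 <= oe.contact_time < t1 and swing_at[other][j] is not None:
                        opp_swing = swing_at[other][j]
                        break
                ds = cycle - swing - opp_swing if opp_swing is not None else None
                strides.append(
                    StrideRecord(
                        foot=foot,
                        trial_index=trial,
                        stride_time=cycle,
                        stride_length=abs(proj[foot][i + 1] - proj[foot][i]),
                        swing_time=swing,
                        cycle_time=cycle,
                        double_support_time=ds,
                        base_of_support=abs(lat[foot][i] - mean_lat[other]),
                    )
                )
    return strides


def base_of_support_values(walk: Walk) -> np.ndarray:
    """Per-step base of support: lateral heel distance of every footfall
    to the opposite foot's line of progression in the same trial."""
    u, v = _progression_frame(walk)
    out: list[float] = []
    for trial in walk.trial_pair:
        per_foot = {foot: walk.events_of(trial, foot) for foot in Foot}
        lat = {foot: _project(per_foot[foot], v) for foot in Foot}
        mean_lat = {foot: float(np.mean(lat[foot])) for foot in Foot}
        for foot in Foot:
            other = Foot.RIGHT if foot is Foot.LEFT else Foot.LEFT
            out.extend(np.abs(lat[foot] - mean_lat[other]))
    return np.asarray(out)


def _cv(values: np.ndarray) -> float:
    if len(values) < 2:
        return math.nan
    m = float(np.mean(values))
    if m == 0:
        return math.nan
    return 100.0 * float(np.std(values, ddof=1)) / m


def _asymmetry(left: np.ndarray, right: np.ndarray, formula: str) -> float:
    ml, mr = float(np.mean(left)), float(np.mean(right))
    if formula == "symmetry_index":
        mid = 0.5 * (ml + mr)
        if mid == 0:
            return math.nan
        return 100.0 * abs(ml - mr) / mid
    if formula == "log_ratio":
        if ml <= 0 or mr <= 0:
            return math.nan
        return 100.0 * abs(math.log(ml / mr))
    raise ValueError(f"unknown asymmetry formula '{formula}'")


def compute_metrics(
    strides: Sequence[StrideRecord],
    walk: Walk,
    asym_formula: str = "symmetry_index",
) -> GaitMetricSet:
    """Compute the 13 spatiotemporal metrics for one walk.

    Velocity is progression distance over ambulation time computed per
    trial and combined weighted by trial duration (the pooled walk
    contains a spatial reset between trials, so a naive end-to-end
    displacement would be wrong).  Phase metrics are expressed as a
    percentage of each stride's cycle time and then averaged.  CVs pool
    the strides of both feet; asymmetry is the absolute symmetry index
    ``100*|mean_L - mean_R| / (0.5*(mean_L + mean_R))`` by default, with
    a log-ratio alternative behind the ``asym_formula`` switch.

    Variability and asymmetry entries require at least
    ``MIN_STRIDES_PER_FOOT`` strides per foot; below that they are
    returned as NaN (missing, never zero).
    """
    if not strides:
        raise InsufficientDataError(f"walk {walk.subject_id}: no strides")
    u, _ = _progression_frame(walk)

    # velocity: per-trial distance / time, combined over trials
    total_dist = 0.0
    total_time = 0.0
    for trial in walk.trial_pair:
        evs = sorted(
            (e for e in walk.events if e.trial_index == trial),
            key=lambda e: e.contact_time,
        )
        proj = _project(evs, u)
        dist = abs(proj[-1] - proj[0])
        time = evs[-1].contact_time - evs[0].contact_time
        total_dist += dist
        total_time += time
    vel = total_dist / total_time

    stime_v = np.array([s.stride_time for s in strides])
    slen_v = np.array([s.stride_length for s in strides])
    swing_v = np.array([s.swing_pct for s in strides])
    dsupp_v = np.array([s.dsupp_pct for s in strides if s.dsupp_pct is not None])
    bos_v = base_of_support_values(walk)

    n_per_foot = {f: sum(1 for s in strides if s.foot is f) for f in Foot}
    enough = all(n >= MIN_STRIDES_PER_FOOT for n in n_per_foot.values())
    if len(strides) < RECOMMENDED_MIN_CYCLES:
        warnings.warn(
            f"walk {walk.subject_id}/{walk.condition.value}: {len(strides)} gait "
            f"cycles, below the recommended minimum of {RECOMMENDED_MIN_CYCLES} "
            "for stable variability/asymmetry estimates",
            stacklevel=2,
        )

    def per_foot(attr) -> dict[Foot, np.ndarray]:
        return {
            f: np.array([attr(s) for s in strides if s.foot is f]) for f in Foot
        }

    if enough:
        slen_f = per_foot(lambda s: s.stride_length)
        stime_f = per_foot(lambda s: s.stride_time)
        swing_f = per_foot(lambda s: s.swing_pct)
        cvs = {
            "slen_CV": _cv(slen_v),
            "stime_CV": _cv(stime_v),
            "swing_CV": _cv(swing_v),
            "swidth_CV": _cv(bos_v),
        }
        asyms = {
            "slen_ASYM": _asymmetry(slen_f[Foot.LEFT], slen_f[Foot.RIGHT], asym_formula),
            "stime_ASYM": _asymmetry(stime_f[Foot.LEFT], stime_f[Foot.RIGHT], asym_formula),
            "swing_ASYM": _asymmetry(swing_f[Foot.LEFT], swing_f[Foot.RIGHT], asym_formula),
        }
    else:
        cvs = {k: math.nan for k in ("slen_CV", "stime_CV", "swing_CV", "swidth_CV")}
        asyms = {k: math.nan for k in ("slen_ASYM", "stime_ASYM", "swing_ASYM")}

    return GaitMetricSet(
        subject_id=walk.subject_id,
        condition=walk.condition.value,
        walk=1 if walk.trial_pair[0] == 1 else 2,
        n_strides=len(strides),
        vel=vel,
        slen=float(np.mean(slen_v)),
        stime=float(np.mean(stime_v)),
        swing=float(np.mean(swing_v)),
        dsupp=float(np.mean(dsupp_v)) if len(dsupp_v) else math.nan,
        slen_CV=cvs["slen_CV"],
        stime_CV=cvs["stime_CV"],
        swing_CV=cvs["swing_CV"],
        slen_ASYM=asyms["slen_ASYM"],
        stime_ASYM=asyms["stime_ASYM"],
        swing_ASYM=asyms["swing_ASYM"],
        swidth=float(np.mean(bos_v)),
        swidth_CV=cvs["swidth_CV"],
    )


def metric_sets_to_long(metric_sets: Sequence[GaitMetricSet]) -> pd.DataFrame:
    """Long-format table: one row per subject x condition x walk x metric."""
    rows = []
    for ms in metric_sets:
        for metric, value in ms.values().items():
            rows.append(
                {
                    "subject_id": ms.subject_id,
                    "condition": ms.condition,
                    "walk": ms.walk,
                    "metric": metric,
                    "value": value,
                }
            )
    return pd.DataFrame(rows, columns=["subject_id", "condition", "walk", "metric", "value"])


@dataclass
class OutlierReport:
    removed_subjects: list[str]
    n_subjects: int
    fraction_removed: float


def remove_outliers(
    pairs: pd.DataFrame, threshold: float = 3.0
) -> tuple[pd.DataFrame, OutlierReport]:
    """Pairwise outlier removal for one metric x condition.

    ``pairs`` is indexed by subject with one column per walk.  A
    subject's pair is dropped when either walk value lies beyond
    ``mean +/- threshold * SD`` of the cohort for that walk; both walks
    of the subject are excluded together (removal is per metric x
    condition only).
    """
    if len(pairs) < 3:
        raise ValueError("outlier removal requires at least 3 subjects")
    values = pairs.to_numpy(dtype=float)
    mean = np.nanmean(values, axis=0)
    sd = np.nanstd(values, axis=0, ddof=1)
    with np.errstate(invalid="ignore"):
        out = np.abs(values - mean) > threshold * sd
    mask = out.any(axis=1)
    removed = [str(s) for s in pairs.index[mask]]
    report = OutlierReport(
        removed_subjects=removed,
        n_subjects=len(pairs),
        fraction_removed=float(mask.mean()),
    )
    return pairs.loc[~mask], report


def shapiro_normality(values: Sequence[float]) -> tuple[float, float]:
    """Shapiro-Wilk test of normality; requires n >= 3 and non-constant input."""
    arr = np.asarray(values, dtype=float)
    arr = arr[~np.isnan(arr)]
    if len(arr) < 3:
        raise ValueError(f"Shapiro-Wilk requires n >= 3, got {len(arr)}")
    if np.ptp(arr) == 0:
        raise ValueError("Shapiro-Wilk is undefined for a constant sample")
    stat, p = stats.shapiro(arr)
    return float(stat), float(p)
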