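"""Seeded synthetic cohorts of footfall streams and gait metrics.

Two layers of generation, matching the two layers of the analysis:

* :func:`simulate_metric_cohort` draws per-subject, per-walk metric
  values under an explicit variance decomposition: for a metric with
  population SD ``sigma`` and target test-retest ICC ``rho``, subject
  true values have variance ``rho * sigma**2`` and walk-level noise has
  variance ``(1 - rho) * sigma**2``, so the expected ICC(3,1) of the two
  walks equals ``rho``.  Clinical anchor scores are linear in a latent
  standard-normal mobility factor shared with the gait metrics, which
  makes metric-anchor correlations controllable.

* :func:`synthesize_step_stream` renders a target metric set as an
  event-level footfall stream (two trials) whose extracted metrics
  reproduce the targets.  Per-cycle stride times, stride lengths and
  swing fractions are drawn per foot and affinely standardized so the
  realized per-foot means and the pooled sample SD equal the targets
  exactly ("moment matching"); left/right mean offsets realize the
  asymmetry targets and lateral heel noise realizes the base-of-support
  CV.  Gait velocity and double-support phase are structural properties
  of any footfall stream (``vel ~ slen / stime`` and
  ``dsupp ~ 100 - 2 * swing``) and therefore emerge from the other
  targets rather than being set independently; the stream is rejected
  when the requested values conflict with these identities.

:func:`simulate_full_study` composes the two into an on-disk dataset
(footfall + anchor tables plus a ground-truth file) that the full
pipeline can consume end to end.  All randomness flows from the seed in
the spec; there is no hidden global state.
"""

from __future__ import annotations

import math
from dataclasses import dataclass, field, replace
from pathlib import Path
from typing import Mapping, Sequence

import numpy as np
import pandas as pd

from .gait_metrics import IMPROVEMENT_SIGN, METRICS
from .walkway_io import (
    AnchorRecord,
    Condition,
    Foot,
    FootfallEvent,
    write_anchors,
    write_footfalls,
)


class InfeasibleTargetError(ValueError):
    """A target metric combination cannot be realized by a footfall stream."""


#: Default population calibration for a chronic-vestibulopathy cohort:
#: per condition and metric, (population mean, population SD, target
#: test-retest ICC of two pooled walks).
POPULATION_DEFAULTS: dict[str, dict[str, tuple[float, float, float]]] = {
    "PWS": {
        "vel": (98.27, 21.27, 0.98),
        "slen": (112.52, 20.49, 0.99),
        "stime": (1.16, 0.09, 0.92),
        "swing": (36.45, 1.94, 0.95),
        "dsupp": (26.96, 4.04, 0.97),
        "slen_CV": (3.49, 1.49, 0.65),
        "stime_CV": (3.17, 1.28, 0.60),
        "swing_CV": (5.61, 2.74, 0.83),
        "slen_ASYM": (0.71, 0.30, 0.32),
        "stime_ASYM": (0.91, 0.52, 0.51),
        "swing_ASYM": (3.81, 2.26, 0.55),
        "swidth": (11.48, 3.67, 0.94),
        "swidth_CV": (23.80, 13.82, 0.75),
    },
    "SWS": {
        "vel": (53.29, 10.68, 0.86),
        "slen": (83.83, 13.09, 0.93),
        "stime": (1.61, 0.23, 0.95),
        "swing": (31.79, 2.14, 0.86),
        "dsupp": (36.27, 4.15, 0.86),
        "slen_CV": (5.44, 2.08, 0.47),
        "stime_CV": (4.94, 2.01, 0.66),
        "swing_CV": (11.66, 4.92, 0.81),
        "slen_ASYM": (0.90, 0.52, 0.65),
        "stime_ASYM": (0.71, 0.43, 0.34),
        "swing_ASYM": (6.65, 4.56, 0.64),
        "swidth": (13.50, 4.32, 0.97),
        "swidth_CV": (18.92, 13.29, 0.89),
    },
    "EC": {
        "vel": (73.14, 18.43, 0.88),
        "slen": (84.75, 18.73, 0.92),
        "stime": (1.18, 0.13, 0.91),
        "swing": (34.27, 2.96, 0.90),
        "dsupp": (31.52, 6.15, 0.94),
        "slen_CV": (9.96, 3.72, 0.53),
        "stime_CV": (6.96, 2.84, 0.76),
        "swing_CV": (14.53, 5.39, 0.80),
        "slen_ASYM": (1.49, 0.81, 0.16),
        "stime_ASYM": (1.26, 0.94, 0.78),
        "swing_ASYM": (7.18, 5.48, 0.66),
        "swidth": (14.94, 5.16, 0.92),
        "swidth_CV": (27.04, 15.39, 0.87),
    },
}

#: Mean / SD of gait cycles per pooled walk, by condition.
CYCLE_COUNT_DEFAULTS: dict[str, tuple[float, float]] = {
    "PWS": (21.8, 4.5),
    "SWS": (29.2, 4.8),
    "EC": (30.4, 8.5),
}


@dataclass(frozen=True)
class AnchorModel:
    """Linear model of one anchor score on the latent mobility factor."""

    intercept: float
    slope: float  # per unit latent mobility (higher latent = better mobility)
    resid_sd: float
    lo: float | None = None
    hi: float | None = None
    integer: bool = False


#: Default anchor models.  Slopes are signed so that better latent
#: mobility raises FGA and PCS-12 and lowers FES-I; residual SDs put the
#: default metric-anchor correlations around |r| = 0.4-0.6, above the
#: |r| > 0.3 gate of the anchor-based MCID analysis.
ANCHOR_MODEL_DEFAULTS: dict[str, AnchorModel] = {
    "fga": AnchorModel(22.0, 4.0, 3.0, lo=0, hi=30, integer=True),
    "fes_i": AnchorModel(36.0, -8.0, 6.0, lo=16, hi=64, integer=True),
    "pcs12": AnchorModel(38.0, 6.0, 4.5),
    "mcs12": AnchorModel(50.0, 0.0, 8.0),
}


def _validate_params(params: Mapping[str, Mapping[str, tuple[float, float, float]]]) -> None:
    for cond, metrics in params.items():
        for metric, (mean, sd, icc) in metrics.items():
            if sd <= 0:
                raise ValueError(f"{cond}/{metric}: SD must be > 0, got {sd}")
            if not 0.0 <= icc <= 1.0:
                raise ValueError(f"{cond}/{metric}: target ICC must be in [0, 1], got {icc}")
            del mean


@dataclass
class CohortSpec:
    """Configuration of a synthetic cohort.

    ``metric_params`` maps condition -> metric -> (mean, SD, target ICC).
    ``latent_loading`` is the share of between-subject variation that
    loads on the common mobility factor (it bounds the achievable
    metric-anchor correlations).
    """

    n_subjects: int = 60
    conditions: tuple[str, ...] = ("PWS", "SWS", "EC")
    metric_params: dict[str, dict[str, tuple[float, float, float]]] = field(
        default_factory=lambda: {c: dict(m) for c, m in POPULATION_DEFAULTS.items()}
    )
    anchor_model: dict[str, AnchorModel] = field(
        default_factory=lambda: dict(ANCHOR_MODEL_DEFAULTS)
    )
    latent_loading: float = 0.75
    n_cycles_target: dict[str, tuple[float, float]] = field(
        default_factory=lambda: dict(CYCLE_COUNT_DEFAULTS)
    )
    subject_prefix: str = "P"
    seed: int = 0

    def __post_init__(self) -> None:
        if self.n_subjects < 1:
            raise ValueError("n_subjects must be >= 1")
        unknown = set(self.conditions) - {c.value for c in Condition}
        if unknown:
            raise ValueError(f"unknown conditions: {sorted(unknown)}")
        if not 0.0 <= self.latent_loading <= 1.0:
            raise ValueError("latent_loading must be in [0, 1]")
        _validate_params(self.metric_params)

    def with_icc(self, icc: float) -> "CohortSpec":
        """Copy of the spec with every metric's target ICC replaced."""
        params = {
            c: {m: (mu, sd, icc) for m, (mu, sd, _) in ms.items()}
            for c, ms in self.metric_params.items()
        }
        return replace(self, metric_params=params)


@dataclass
class CohortSample:
    """Output of :func:`simulate_metric_cohort`."""

    metrics: pd.DataFrame  # long: subject_id, condition, walk, metric, value
    anchors: list[AnchorRecord]
    subjects: pd.DataFrame  # subject_id, latent mobility factor
    true_values: pd.DataFrame  # long: subject_id, condition, metric, true value


def _subject_ids(spec: CohortSpec) -> list[str]:
    width = max(3, len(str(spec.n_subjects)))
    return [f"{spec.subject_prefix}{i + 1:0{width}d}" for i in range(spec.n_subjects)]


def _simulate_metric_cohort(spec: CohortSpec, rng: np.random.Generator) -> CohortSample:
    n = spec.n_subjects
    lam = spec.latent_loading
    ids = _subject_ids(spec)
    z = rng.standard_normal(n)  # latent mobility, higher = better

    metric_frames = []
    true_frames = []
    for cond in spec.conditions:
        for metric in METRICS:
            mean, sd, icc = spec.metric_params[cond][metric]
            sign = IMPROVEMENT_SIGN[metric]
            eta = rng.standard_normal(n)
            subject_effect = lam * sign * z + math.sqrt(1.0 - lam**2) * eta
            true = mean + sd * math.sqrt(icc) * subject_effect
            noise = rng.standard_normal((n, 2)) * sd * math.sqrt(1.0 - icc)
            walks = true[:, None] + noise
            true_frames.append(
                pd.DataFrame(
                    {"subject_id": ids, "condition": cond, "metric": metric, "value": true}
                )
            )
            metric_frames.append(
                pd.DataFrame(
                    {
                        "subject_id": np.repeat(ids, 2),
                        "condition": cond,
                        "walk": np.tile([1, 2], n),
                        "metric": metric,
                        "value": walks.ravel(),
                    }
                )
            )
    metrics_df = pd.concat(metric_frames, ignore_index=True)
    true_df = pd.concat(true_frames, ignore_index=True)

    anchors = []
    anchor_draws = {
        name: model.intercept + model.slope * z + model.resid_sd * rng.standard_normal(n)
        for name, model in spec.anchor_model.items()
    }
    for i, sid in enumerate(ids):
        scored: dict[str, float] = {}
        for name, model in spec.anchor_model.items():
            v = anchor_draws[name][i]
            if model.lo is not None:
                v = min(max(v, model.lo), model.hi)
            scored[name] = round(v) if model.integer else v
        anchors.append(
            AnchorRecord(
                subject_id=sid,
                fga=int(scored["fga"]),
                fes_i=int(scored["fes_i"]),
                pcs12=float(scored["pcs12"]),
                mcs12=float(scored["mcs12"]),
            )
        )

    return CohortSample(
        metrics=metrics_df,
        anchors=anchors,
        subjects=pd.DataFrame({"subject_id": ids, "mobility_factor": z}),
        true_values=true_df,
    )


def simulate_metric_cohort(spec: CohortSpec) -> CohortSample:
    """Draw per-subject, per-condition, per-walk metric values and anchors."""
    return _simulate_metric_cohort(spec, np.random.default_rng(spec.seed))


# ---------------------------------------------------------------------------
# step-event synthesis


def _standardized(rng: np.random.Generator, m: int) -> np.ndarray:
    """m standard-normal draws rescaled to sample mean 0 and sample SD 1 (ddof=1)."""
    if m == 1:
        return np.zeros(1)
    z = rng.standard_normal(m)
    z = z - z.mean()
    sd = z.std(ddof=1)
    if sd == 0:  # pragma: no cover - measure-zero event
        return np.zeros(m)
    return z / sd


def _draw_pooled(
    rng: np.random.Generator,
    m_left: int,
    m_right: int,
    mean: float,
    cv_pct: float,
    asym_pct: float,
    what: str,
) -> tuple[np.ndarray, np.ndarray]:
    """Per-foot samples whose per-foot means, pooled sample SD (ddof=1) and
    symmetry index match the targets exactly."""
    if mean <= 0:
        raise InfeasibleTargetError(f"{what}: mean must be > 0, got {mean}")
    if cv_pct < 0 or asym_pct < 0:
        raise InfeasibleTargetError(f"{what}: CV and asymmetry targets must be >= 0")
    d = asym_pct / 100.0 * mean
    mu_l, mu_r = mean + d / 2.0, mean - d / 2.0
    pooled_sd = cv_pct / 100.0 * mean
    n = m_left + m_right
    grand = (m_left * mu_l + m_right * mu_r) / n
    between = m_left * (mu_l - grand) ** 2 + m_right * (mu_r - grand) ** 2
    s2 = ((n - 1) * pooled_sd**2 - between) / (n - 2)
    if s2 < -1e-9:
        raise InfeasibleTargetError(
            f"{what}: CV target {cv_pct}% is below the spread implied by the "
            f"asymmetry target {asym_pct}%"
        )
    s = math.sqrt(max(s2, 0.0))
    left = mu_l + s * _standardized(rng, m_left)
    right = mu_r + s * _standardized(rng, m_right)
    return left, right


def _split_counts(n_cycles: int) -> dict[tuple[int, Foot], int]:
    """Distribute n_cycles strides over (trial, foot) cells as evenly as possible."""
    q, r = divmod(n_cycles, 4)
    cells = [(1, Foot.LEFT), (1, Foot.RIGHT), (2, Foot.LEFT), (2, Foot.RIGHT)]
    return {cell: q + (1 if i < r else 0) for i, cell in enumerate(cells)}


def synthesize_step_stream(
    target: Mapping[str, float],
    n_cycles: int,
    rng: np.random.Generator | int,
    subject_id: str = "S1",
    condition: Condition | str = Condition.PWS,
    trial_pair: tuple[int, int] = (1, 2),
    dsupp_tol: float = 3.0,
    vel_tol: float = 0.05,
) -> list[FootfallEvent]:
    """Render a target metric set as a two-trial footfall event stream.

    ``n_cycles`` counts complete gait cycles over both feet and both
    trials, matching ``Walk.n_cycles``.  Raises
    :class:`InfeasibleTargetError` when the targets are not realizable
    by a walking footfall pattern (swing >= 50 %, a double-support or
    velocity target in conflict with the structural identities, or an
    asymmetry larger than the variability that has to carry it).
    """
    if isinstance(rng, (int, np.integer)):
        rng = np.random.default_rng(int(rng))
    condition = Condition(condition)
    t = {m: float(target[m]) for m in METRICS}
    if n_cycles < 8:
        raise InfeasibleTargetError("n_cycles must be >= 8 (>= 2 strides per foot and trial)")
    if not 0.0 < t["swing"] < 50.0:
        raise InfeasibleTargetError(
            f"swing target {t['swing']}% is not walkable (double support would be negative)"
        )
    implied_dsupp = 100.0 - 2.0 * t["swing"]
    if abs(t["dsupp"] - implied_dsupp) > dsupp_tol:
        raise InfeasibleTargetError(
            f"dsupp target {t['dsupp']}% conflicts with swing target "
            f"{t['swing']}% (implied dsupp {implied_dsupp:.2f}%)"
        )
    implied_vel = t["slen"] / t["stime"]
    if abs(t["vel"] - implied_vel) > vel_tol * implied_vel:
        raise InfeasibleTargetError(
            f"velocity target {t['vel']} conflicts with stride length/time "
            f"(implied {implied_vel:.2f} cm/s)"
        )

    counts = _split_counts(n_cycles)
    m_l = counts[(1, Foot.LEFT)] + counts[(2, Foot.LEFT)]
    m_r = counts[(1, Foot.RIGHT)] + counts[(2, Foot.RIGHT)]

    stime_l, stime_r = _draw_pooled(
        rng, m_l, m_r, t["stime"], t["stime_CV"], t["stime_ASYM"], "stride time"
    )
    slen_l, slen_r = _draw_pooled(
        rng, m_l, m_r, t["slen"], t["slen_CV"], t["slen_ASYM"], "stride length"
    )
    swing_l, swing_r = _draw_pooled(
        rng, m_l, m_r, t["swing"], t["swing_CV"], t["swing_ASYM"], "swing phase"
    )
    for name, arrs in (("stride time", (stime_l, stime_r)), ("stride length", (slen_l, slen_r))):
        if min(a.min() for a in arrs) <= 0:
            raise InfeasibleTargetError(f"{name}: drawn values reach zero; CV target too large")
    for arr in (swing_l, swing_r):
        if arr.min() <= 2.0 or arr.max() >= 98.0:
            raise InfeasibleTargetError("swing phase draws leave (2, 98)% — CV target too large")

    width = t["swidth"]
    if width <= 0:
        raise InfeasibleTargetError("base-of-support mean must be > 0")
    n_events = n_cycles + 4  # one extra contact per (trial, foot) cell
    sw_sd2 = (n_events - 1) / (n_events - 4) * (t["swidth_CV"] / 100.0 * width) ** 2
    sw_sd = math.sqrt(sw_sd2)

    stride_seq = {Foot.LEFT: (stime_l, slen_l, swing_l), Foot.RIGHT: (stime_r, slen_r, swing_r)}
    offset = {Foot.LEFT: 0, Foot.RIGHT: 1}  # half-cycle phase/space lead of the right foot
    lateral_sign = {Foot.LEFT: +1.0, Foot.RIGHT: -1.0}

    events: list[FootfallEvent] = []
    taken = {Foot.LEFT: 0, Foot.RIGHT: 0}
    for trial_i, trial in enumerate(trial_pair):
        trial_key = trial_i + 1  # 1 or 2 within this walk
        slices = {}
        for foot in Foot:
            m = counts[(trial_key, foot)]
            lo = taken[foot]
            times, lengths, swings = stride_seq[foot]
            slices[foot] = (times[lo : lo + m], lengths[lo : lo + m], swings[lo : lo + m])
            taken[foot] += m
        t_first_left = slices[Foot.LEFT][0][0]
        x_first_left = slices[Foot.LEFT][1][0]
        for foot in Foot:
            times, lengths, swings = slices[foot]
            m = len(times)
            contacts = np.concatenate([[0.0], np.cumsum(times)])
            positions = np.concatenate([[0.0], np.cumsum(lengths)])
            if offset[foot]:
                contacts = contacts + 0.5 * t_first_left
                positions = positions + 0.5 * x_first_left
            lat_noise = sw_sd * _standardized(rng, m + 1)
            lateral = lateral_sign[foot] * width / 2.0 + lat_noise
            stance = np.empty(m + 1)
            stance[:m] = (1.0 - swings / 100.0) * times
            stance[m] = (1.0 - swings.mean() / 100.0) * times.mean()
            for i in range(m + 1):
                events.append(
                    FootfallEvent(
                        subject_id=subject_id,
                        condition=condition,
                        trial_index=trial,
                        foot=foot,
                        contact_time=float(contacts[i]),
                        lift_time=float(contacts[i] + stance[i]),
                        heel_x=float(positions[i]),
                        heel_y=float(lateral[i]),
                    )
                )
    events.sort(key=lambda e: (e.trial_index, e.contact_time, e.foot.value))
    return events


# ---------------------------------------------------------------------------
# full study


@dataclass
class StudyDataset:
    """On-disk synthetic study plus its ground truth."""

    footfalls_path: Path
    anchors_path: Path
    truth_path: Path
    cohort: CohortSample
    walk_targets: pd.DataFrame  # subject_id, condition, walk, metric, requested, effective
    n_events: int


def _feasible_targets(raw: Mapping[str, float], n_cycles: int) -> dict[str, float]:
    """Clamp a drawn walk-level metric vector into the step-realizable region.

    Normal draws occasionally leave the physical domain (negative CV,
    asymmetry exceeding the variability that must carry it, swing out of
    range); the clamps are rare-event guards, not recalibrations.
    """
    t = dict(raw)
    t["swing"] = float(np.clip(t["swing"], 15.0, 48.0))
    t["stime"] = max(t["stime"], 0.3)
    t["slen"] = max(t["slen"], 20.0)
    t["swidth"] = max(t["swidth"], 2.0)
    for cv in ("slen_CV", "stime_CV", "swing_CV", "swidth_CV"):
        t[cv] = max(t[cv], 0.05)
    n = n_cycles  # pooled stride count; asymmetry feasibility scales with it
    cap = 1.8 * math.sqrt((n - 1) / n)
    for asym, cv in (
        ("slen_ASYM", "slen_CV"),
        ("stime_ASYM", "stime_CV"),
        ("swing_ASYM", "swing_CV"),
    ):
        t[asym] = float(np.clip(t[asym], 0.0, cap * t[cv]))
    # structural identities of a footfall stream
    t["vel"] = t["slen"] / t["stime"]
    t["dsupp"] = 100.0 - 2.0 * t["swing"]
    return t


def simulate_full_study(
    spec: CohortSpec,
    outdir: str | Path,
    trial_pairs: tuple[tuple[int, int], tuple[int, int]] = ((1, 2), (3, 4)),
) -> StudyDataset:
    """Simulate a complete study and write it to ``outdir``.

    Deterministic for a fixed ``spec.seed``: running twice produces
    byte-identical files.
    """
    outdir = Path(outdir)
    outdir.mkdir(parents=True, exist_ok=True)
    rng = np.random.default_rng(spec.seed)
    cohort = _simulate_metric_cohort(spec, rng)

    walks = cohort.metrics.pivot_table(
        index=["subject_id", "condition", "walk"], columns="metric", values="value"
    )
    events: list[FootfallEvent] = []
    target_rows = []
    for sid in cohort.subjects["subject_id"]:
        for cond in spec.conditions:
            mean_cycles, sd_cycles = spec.n_cycles_target[cond]
            for walk_idx, pair in zip((1, 2), trial_pairs):
                requested = walks.loc[(sid, cond, walk_idx)].to_dict()
                n_cycles = int(np.clip(round(rng.normal(mean_cycles, sd_cycles)), 12, 80))
                effective = _feasible_targets(requested, n_cycles)
                events.extend(
                    synthesize_step_stream(
                        effective,
                        n_cycles=n_cycles,
                        rng=rng,
                        subject_id=sid,
                        condition=cond,
                        trial_pair=pair,
                    )
                )
                for metric in METRICS:
                    target_rows.append(
                        {
                            "subject_id": sid,
                            "condition": cond,
                            "walk": walk_idx,
                            "metric": metric,
                            "requested": requested[metric],
                            "effective": effective[metric],
                        }
                    )

    walk_targets = pd.DataFrame(target_rows)
    footfalls_path = outdir / "footfalls.csv"
    anchors_path = outdir / "anchors.csv"
    truth_path = outdir / "synthetic_walk_targets.csv"
    write_footfalls(events, footfalls_path)
    write_anchors(cohort.anchors, anchors_path)
    walk_targets.to_csv(truth_path, index=False)
    return StudyDataset(
        footfalls_path=footfalls_path,
        anchors_path=anchors_path,
        truth_path=truth_path,
        cohort=cohort,
        walk_targets=walk_targets,
        n_events=len(events),
    )


def control_spec(
    base: CohortSpec | None = None,
    n_subjects: int = 30,
    seed: int = 1,
) -> CohortSpec:
    """Cohort spec for a healthy control group.

    Applies normative shifts to the patient calibration: faster and
    longer strides, less variability and asymmetry, narrower base of
    support.  Used by the patient-vs-control comparison stage.
    """
    base = base or CohortSpec()
    scale = {
        "vel": 1.18,
        "slen": 1.12,
        "stime": 0.95,
        "swing": 1.04,
        "slen_CV": 0.55,
        "stime_CV": 0.55,
        "swing_CV": 0.55,
        "slen_ASYM": 0.6,
        "stime_ASYM": 0.6,
        "swing_ASYM": 0.55,
        "swidth": 0.78,
        "swidth_CV": 0.7,
    }
    params: dict[str, dict[str, tuple[float, float, float]]] = {}
    for cond, metrics in base.metric_params.items():
        params[cond] = {}
        for metric, (mean, sd, icc) in metrics.items():
            if metric == "dsupp":
                # derived from swing so the calibration stays walkable
                new_mean = 100.0 - 2.0 * metrics["swing"][0] * scale["swing"]
            elif metric == "vel":
                new_mean = (
                    metrics["slen"][0] * scale["slen"] / (metrics["stime"][0] * scale["stime"])
                )
            else:
                new_mean = mean * scale[metric]
            params[cond][metric] = (new_mean, sd * 0.8, icc)
    return replace(
        base,
        n_subjects=n_subjects,
        metric_params=params,
        subject_prefix="C",
        seed=seed,
    )


def walk_pairs_wide(metrics_long: pd.DataFrame, condition: str, metric: str) -> pd.DataFrame:
    """Pivot the long metric table into a subjects x walks matrix for one
    metric and condition (columns ``walk1``, ``walk2``)."""
    sub = metrics_long[
        (metrics_long["condition"] == condition) & (metrics_long["metric"] == metric)
    ]
    wide = sub.pivot_table(index="subject_id", columns="walk", values="value")
    wide.columns = [f"walk{int(c)}" for c in wide.columns]
    return wide
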