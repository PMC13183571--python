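"""Stride segmentation, the 13 metrics, outlier rule and normality test."""

from __future__ import annotations

import warnings

import numpy as np
import pandas as pd
import pytest
from hypothesis import given, settings
from hypothesis import strategies as st

from vestgait.gait_metrics import (
    InsufficientDataError,
    compute_metrics,
    remove_outliers,
    segment_strides,
    shapiro_normality,
)
from vestgait.synthetic_gait import synthesize_step_stream
from vestgait.walkway_io import Condition, Foot, FootfallEvent, Walk, pool_trials


def _event(trial, foot, contact, lift, x, y, subject="S1"):
    return FootfallEvent(
        subject_id=subject,
        condition=Condition.PWS,
        trial_index=trial,
        foot=Foot(foot),
        contact_time=contact,
        lift_time=lift,
        heel_x=x,
        heel_y=y,
    )


def _regular_walk(stride_time=1.0, stride_length=100.0, swing_frac=0.36, n_contacts=5):
    """Perfectly regular symmetric gait, two identical trials."""
    events = []
    stance = (1 - swing_frac) * stride_time
    for trial in (1, 2):
        for i in range(n_contacts):
            t = i * stride_time
            x = i * stride_length
            events.append(_event(trial, "left", t, t + stance, x, 5.0))
            events.append(
                _event(trial, "right", t + stride_time / 2, t + stride_time / 2 + stance,
                       x + stride_length / 2, -5.0)
            )
    return Walk(subject_id="S1", condition=Condition.PWS, trial_pair=(1, 2), events=events)


def test_hand_computable_stride_segmentation():
    """Alternating contacts at 0.5 s spacing with lift at contact+0.64 s:
    stride times 1.0 s and swing times 0.36 s on both feet."""
    events = []
    for trial in (1, 2):
        for i, (foot, t) in enumerate(
            [("left", 0.0), ("right", 0.5), ("left", 1.0), ("right", 1.5),
             ("left", 2.0), ("right", 2.5)]
        ):
            events.append(_event(trial, foot, t, t + 0.64, 50.0 * i, 6.0 if foot == "left" else -6.0))
    walk = Walk(subject_id="S1", condition=Condition.PWS, trial_pair=(1, 2), events=events)
    strides = segment_strides(walk)
    left = [s for s in strides if s.foot is Foot.LEFT]
    assert [s.stride_time for s in left] == [1.0, 1.0, 1.0, 1.0]
    for s in strides:
        assert s.swing_time == pytest.approx(0.36)
        assert s.swing_pct == pytest.approx(36.0)
        if s.double_support_time is not None:
            # both feet down: cycle - 2 * swing
            assert s.double_support_time == pytest.approx(1.0 - 0.72)


def test_regular_gait_has_zero_variability_and_asymmetry():
    walk = _regular_walk(n_contacts=6)
    with warnings.catch_warnings():
        warnings.simplefilter("ignore")
        ms = compute_metrics(segment_strides(walk), walk)
    assert ms.vel == pytest.approx(100.0)
    assert ms.slen == pytest.approx(100.0)
    assert ms.stime == pytest.approx(1.0)
    assert ms.swing == pytest.approx(36.0)
    assert ms.dsupp == pytest.approx(28.0)
    assert ms.swidth == pytest.approx(10.0)
    for m in ("slen_CV", "stime_CV", "swing_CV", "swidth_CV",
              "slen_ASYM", "stime_ASYM", "swing_ASYM"):
        assert getattr(ms, m) == pytest.approx(0.0, abs=1e-10)


def test_two_foot_toy_asymmetry():
    """Left stride lengths alternate 100/102, right 98/100: mean stride
    length 100 cm and symmetry-index asymmetry 2.0 %."""
    events = []
    for trial in (1, 2):
        xl, xr = 0.0, 50.0
        for i in range(5):
            t = float(i)
            events.append(_event(trial, "left", t, t + 0.64, xl, 6.0))
            events.append(_event(trial, "right", t + 0.5, t + 1.14, xr, -6.0))
            xl += 100.0 if i % 2 == 0 else 102.0
            xr += 98.0 if i % 2 == 0 else 100.0
    walk = Walk(subject_id="S1", condition=Condition.PWS, trial_pair=(1, 2), events=events)
    with warnings.catch_warnings():
        warnings.simplefilter("ignore")
        ms = compute_metrics(segment_strides(walk), walk)
    assert ms.slen == pytest.approx(100.0)
    assert ms.slen_ASYM == pytest.approx(2.0)
    assert ms.stime_ASYM == pytest.approx(0.0, abs=1e-10)


def _scaled(walk: Walk, c: float) -> Walk:
    events = [
        FootfallEvent(
            subject_id=e.subject_id,
            condition=e.condition,
            trial_index=e.trial_index,
            foot=e.foot,
            contact_time=e.contact_time,
            lift_time=e.lift_time,
            heel_x=c * e.heel_x,
            heel_y=c * e.heel_y,
        )
        for e in walk.events
    ]
    return Walk(walk.subject_id, walk.condition, walk.trial_pair, events)


@pytest.fixture(scope="module")
def stochastic_walk(pws_targets):
    events = synthesize_step_stream(pws_targets, n_cycles=40, rng=11)
    return pool_trials(events, (1, 2))


@settings(max_examples=20, deadline=None)
@given(c=st.floats(min_value=0.2, max_value=5.0))
def test_scale_equivariance(c):
    from vestgait.synthetic_gait import POPULATION_DEFAULTS

    targets = {m: v[0] for m, v in POPULATION_DEFAULTS["PWS"].items()}
    events = synthesize_step_stream(targets, n_cycles=40, rng=11)
    walk = pool_trials(events, (1, 2))
    with warnings.catch_warnings():
        warnings.simplefilter("ignore")
        base = compute_metrics(segment_strides(walk), walk)
        scaled_walk = _scaled(walk, c)
        scaled = compute_metrics(segment_strides(scaled_walk), scaled_walk)
    for m in ("vel", "slen", "swidth"):
        assert getattr(scaled, m) == pytest.approx(c * getattr(base, m), rel=1e-9)
    for m in ("stime", "swing", "dsupp", "slen_CV", "stime_CV", "swing_CV",
              "swidth_CV", "slen_ASYM", "stime_ASYM", "swing_ASYM"):
        assert getattr(scaled, m) == pytest.approx(getattr(base, m), rel=1e-7, abs=1e-9)


def test_direction_reversal_and_foot_swap_invariance(stochastic_walk):
    walk = stochastic_walk
    reversed_events = [
        FootfallEvent(
            subject_id=e.subject_id, condition=e.condition, trial_index=e.trial_index,
            foot=e.foot, contact_time=e.contact_time, lift_time=e.lift_time,
            heel_x=-e.heel_x, heel_y=e.heel_y,
        )
        for e in walk.events
    ]
    swapped_events = [
        FootfallEvent(
            subject_id=e.subject_id, condition=e.condition, trial_index=e.trial_index,
            foot=Foot.RIGHT if e.foot is Foot.LEFT else Foot.LEFT,
            contact_time=e.contact_time, lift_time=e.lift_time,
            heel_x=e.heel_x, heel_y=e.heel_y,
        )
        for e in walk.events
    ]
    with warnings.catch_warnings():
        warnings.simplefilter("ignore")
        base = compute_metrics(segment_strides(walk), walk)
        for variant_events in (reversed_events, swapped_events):
            vw = Walk(walk.subject_id, walk.condition, walk.trial_pair, variant_events)
            vm = compute_metrics(segment_strides(vw), vw)
            for m in ("slen_CV", "stime_CV", "swing_CV", "swidth_CV",
                      "slen_ASYM", "stime_ASYM", "swing_ASYM"):
                assert getattr(vm, m) == pytest.approx(getattr(base, m), rel=1e-9, abs=1e-12)


def test_too_few_events_raises():
    walk = _regular_walk(n_contacts=2)
    with pytest.raises(InsufficientDataError, match="S1"):
        segment_strides(walk)


def test_few_strides_flags_variability_missing():
    walk = _regular_walk(n_contacts=3)  # 2 strides per foot per trial = 4 total, 2/foot/trial
    with warnings.catch_warnings():
        warnings.simplefilter("ignore")
        strides = segment_strides(walk)
        # keep only 3 strides per foot: below the per-foot floor of 4
        per_foot = {Foot.LEFT: 0, Foot.RIGHT: 0}
        kept = []
        for s in strides:
            if per_foot[s.foot] < 3:
                kept.append(s)
                per_foot[s.foot] += 1
        ms = compute_metrics(kept, walk)
    assert np.isnan(ms.slen_CV) and np.isnan(ms.swing_ASYM)
    assert not np.isnan(ms.vel)  # pace metrics still reported


def test_outlier_rule_no_removal_within_one_sd():
    rng = np.random.default_rng(0)
    base = rng.uniform(-1, 1, 60)
    pairs = pd.DataFrame({"walk1": base, "walk2": base * 0.9}, index=[f"P{i}" for i in range(60)])
    kept, rep = remove_outliers(pairs)
    assert len(kept) == 60 and rep.fraction_removed == 0.0


def test_outlier_rule_removes_planted_pair_only():
    rng = np.random.default_rng(1)
    v1 = rng.normal(100, 10, 60)
    v2 = v1 + rng.normal(0, 2, 60)
    v1[17] = v1.mean() + 5 * v1.std(ddof=1)  # plant in walk 1 only
    pairs = pd.DataFrame({"walk1": v1, "walk2": v2}, index=[f"P{i:03d}" for i in range(60)])
    kept, rep = remove_outliers(pairs)
    assert rep.removed_subjects == ["P017"]
    assert len(kept) == 59
    assert "P017" not in kept.index  # both walks of the subject gone together


def test_shapiro_size_and_power():
    rng = np.random.default_rng(42)
    normal_ok = sum(shapiro_normality(rng.normal(size=500))[1] > 0.01 for _ in range(100))
    assert normal_ok >= 98
    expo_reject = sum(shapiro_normality(rng.exponential(size=500))[1] < 0.01 for _ in range(100))
    assert expo_reject >= 99


def test_shapiro_degenerate_inputs():
    with pytest.raises(ValueError):
        shapiro_normality([1.0, 1.0])
    with pytest.raises(ValueError, match="constant"):
        shapiro_normality([2.0] * 50)
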