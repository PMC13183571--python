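"""SEM/MDC95, distribution- and anchor-based MCIDs, triangulation."""

from __future__ import annotations

import math

import numpy as np
import pandas as pd
import pytest
from hypothesis import given, settings
from hypothesis import strategies as st

from vestgait.change_metrics import (
    DEFAULT_ANCHORS,
    AnchorSpec,
    anchor_mcid,
    build_mcid_table,
    distribution_mcid,
    mcid_table_frame,
    round_half_away,
    sem_mdc,
    triangulate,
)
from vestgait.reliability import ReliabilityResult

FGA = DEFAULT_ANCHORS[0]
FES_I = DEFAULT_ANCHORS[1]


def test_sem_mdc_limits():
    sem, mdc = sem_mdc(10.0, 1.0)
    assert sem == 0.0 and mdc == 0.0
    sem, mdc = sem_mdc(1.0, 0.0)
    assert mdc == pytest.approx(1.96 * math.sqrt(2))
    with pytest.raises(ValueError):
        sem_mdc(10.0, 1.2)
    with pytest.raises(ValueError):
        sem_mdc(0.0, 0.5)


def test_mdc_decreases_in_icc():
    mdcs = [sem_mdc(21.27, icc)[1] for icc in np.linspace(0, 1, 21)]
    assert all(a > b for a, b in zip(mdcs, mdcs[1:]))
    # an unrounded ICC near 0.992 puts the velocity MDC near 5.3 cm/s
    assert sem_mdc(21.27, 0.992)[1] == pytest.approx(5.3, abs=0.05)


def test_distribution_mcid_is_effect_size_times_sd():
    assert distribution_mcid(21.27, 0.5) == pytest.approx(10.635)
    assert distribution_mcid(4.04, 0.8) == pytest.approx(3.232)
    with pytest.raises(ValueError):
        distribution_mcid(0.0, 0.5)


def test_anchor_mcid_exact_slope():
    """A metric that is exactly 2 cm/s per FGA point triangulates the
    textbook anchor computation: 2.0 x 4 = 8.0 cm/s."""
    rng = np.random.default_rng(0)
    fga = rng.integers(5, 29, size=60).astype(float)
    vel = 30.0 + 2.0 * fga
    res = anchor_mcid(vel, fga, FGA)
    assert res.b == pytest.approx(2.0)
    assert res.estimate == pytest.approx(8.0)
    assert res.r == pytest.approx(1.0)


def test_anchor_mcid_orientation_for_decreasing_anchor():
    """FES-I improves by decreasing, so a negative slope of velocity on
    FES-I still yields a positive velocity MCID."""
    rng = np.random.default_rng(1)
    fes = rng.uniform(16, 64, 200)
    vel = 120.0 - 1.5 * fes + rng.normal(0, 5, 200)
    res = anchor_mcid(vel, fes, FES_I)
    assert res.b < 0
    assert res.estimate is not None and res.estimate > 0
    assert res.estimate == pytest.approx(-res.b * 8.0)


def test_anchor_mcid_absent_cases():
    rng = np.random.default_rng(2)
    # constant anchor
    res = anchor_mcid(rng.normal(size=50), np.full(50, 20.0), FGA)
    assert res.estimate is None and res.reason == "degenerate_variance"
    # too few pairs
    res = anchor_mcid(rng.normal(size=5), rng.normal(size=5), FGA)
    assert res.estimate is None and res.reason == "too_few_pairs"
    # below the |r| > 0.3 gate
    res = anchor_mcid(rng.normal(size=500), rng.normal(size=500), FGA)
    assert abs(res.r) < 0.3
    assert res.estimate is None and res.reason == "below_correlation_gate"


def test_anchor_mcid_parameter_recovery():
    """A planted slope with r ~ 0.5 is recovered within 5 % at n = 2000
    (averaged over replicates to keep Monte-Carlo error well below the
    tolerance)."""
    rng = np.random.default_rng(3)
    b_true = 2.5
    estimates = []
    for _ in range(10):
        fga = rng.uniform(5, 29, 2000)
        noise_sd = b_true * np.std(fga) * math.sqrt(1 / 0.5**2 - 1)
        vel = 40.0 + b_true * fga + rng.normal(0, noise_sd, 2000)
        res = anchor_mcid(vel, fga, FGA)
        assert 0.4 < abs(res.r) < 0.6
        estimates.append(res.estimate)
    assert np.mean(estimates) == pytest.approx(b_true * 4.0, rel=0.05)


def test_anchor_mcid_equivariance():
    rng = np.random.default_rng(4)
    fga = rng.uniform(5, 29, 300)
    vel = 40.0 + 2.0 * fga + rng.normal(0, 10, 300)
    base = anchor_mcid(vel, fga, FGA)
    scaled_metric = anchor_mcid(3.0 * vel, fga, FGA)
    assert scaled_metric.estimate == pytest.approx(3.0 * base.estimate, rel=1e-9)
    rescaled_anchor = anchor_mcid(vel, 10.0 * fga, AnchorSpec("FGA", 40.0, "increase", "fga"))
    assert rescaled_anchor.estimate == pytest.approx(base.estimate, rel=1e-9)


def test_triangulate_basics():
    value, n = triangulate(5.0, [])
    assert value == 5.0 and n == 1
    value, n = triangulate(None, [3.0])
    assert value == 3.0 and n == 1
    value, n = triangulate(None, [None, None])
    assert value is None and n == 0


@settings(max_examples=50, deadline=None)
@given(
    st.lists(st.floats(min_value=-50, max_value=50), min_size=1, max_size=4),
    st.randoms(use_true_random=False),
)
def test_triangulate_permutation_invariant_and_bounded(values, rnd):
    shuffled = list(values)
    rnd.shuffle(shuffled)
    a, na = triangulate(values[0], values[1:])
    b, nb = triangulate(shuffled[0], shuffled[1:])
    assert na == nb == len(values)
    assert a == pytest.approx(b, abs=1e-9)
    assert min(values) - 1e-9 <= a <= max(values) + 1e-9


def test_rounding_half_away_from_zero():
    assert round_half_away(10.635, 2) == 10.64
    assert round_half_away(4.305, 2) == 4.31
    assert round_half_away(-1.745, 2) == -1.75
    assert round_half_away(2.77186, 4) == 2.7719


def _fake_reliability(metric, condition, icc):
    return ReliabilityResult(
        metric=metric, condition=condition, n=60, k=2, form="absolute_agreement",
        icc=icc, ci_low=icc - 0.05, ci_high=icc + 0.02, f_stat=50.0, p=1e-10,
        band="excellent", ms_rows=1.0, ms_cols=0.0, ms_error=0.01,
    )


def test_build_mcid_table_flags_low_reliability_rows():
    """A high-ICC pace metric keeps its MCIDs above the MDC; a low-ICC
    asymmetry metric is flagged below the detectable-change floor."""
    rng = np.random.default_rng(8)
    sids = [f"P{i:03d}" for i in range(60)]
    fga = rng.integers(8, 29, 60).astype(float)
    rows = []
    for metric, scale in (("vel", 2.0), ("slen_ASYM", -0.02)):
        vals = 50.0 + scale * fga + rng.normal(0, 4 if metric == "vel" else 0.15, 60)
        rows += [
            {"subject_id": s, "condition": "PWS", "metric": metric, "value": v}
            for s, v in zip(sids, vals)
        ]
    means = pd.DataFrame(rows)
    anchors = pd.DataFrame(
        {"subject_id": sids, "fga": fga, "fes_i": 30.0, "pcs12": 40.0, "mcs12": 50.0}
    )
    rel = {
        ("PWS", "vel"): _fake_reliability("vel", "PWS", 0.98),
        ("PWS", "slen_ASYM"): _fake_reliability("slen_ASYM", "PWS", 0.30),
    }
    sds = {("PWS", "vel"): 8.0, ("PWS", "slen_ASYM"): 0.3}
    estimates = build_mcid_table(means, anchors, rel, sds, anchor_specs=(FGA,))
    by_metric = {e.metric: e for e in estimates}
    assert not by_metric["vel"].below_mdc
    assert by_metric["slen_ASYM"].below_mdc
    # signed reporting: improvement negative for asymmetry, positive for velocity
    frame = mcid_table_frame(estimates, anchor_specs=(FGA,))
    row_vel = frame[frame.metric == "vel"].iloc[0]
    row_asym = frame[frame.metric == "slen_ASYM"].iloc[0]
    assert row_vel["dist_medium"] > 0 and row_vel["FGA"] > 0
    assert row_asym["dist_medium"] < 0 and row_asym["mdc"] < 0


def test_pipeline_mcid_table_shape_and_signs(pipeline):
    _, paths = pipeline
    mcid = pd.read_csv(paths["mcid"])
    assert len(mcid) == 13 * 3
    positive = {"vel", "slen", "swing"}
    for _, row in mcid.iterrows():
        expected = 1 if row["metric"] in positive else -1
        assert np.sign(row["dist_medium"]) == expected
        if not np.isnan(row["triangulated"]):
            assert np.sign(row["triangulated"]) == expected
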