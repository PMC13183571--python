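"""Shared fixtures: a simulated study and one full pipeline run."""

from __future__ import annotations

import warnings

import pytest

from vestgait.report import RunConfig, run_pipeline
from vestgait.synthetic_gait import POPULATION_DEFAULTS, CohortSpec, simulate_full_study


@pytest.fixture(scope="session")
def pws_targets() -> dict[str, float]:
    """Population means of the preferred-speed calibration (used as
    walk-level targets for step synthesis)."""
    return {m: v[0] for m, v in POPULATION_DEFAULTS["PWS"].items()}


@pytest.fixture(scope="session")
def small_study(tmp_path_factory):
    """A small single-condition synthetic study on disk (12 subjects, PWS)."""
    spec = CohortSpec(n_subjects=12, conditions=("PWS",), seed=3)
    outdir = tmp_path_factory.mktemp("small_study")
    with warnings.catch_warnings():
        warnings.simplefilter("ignore")
        dataset = simulate_full_study(spec, outdir)
    return spec, dataset


@pytest.fixture(scope="session")
def pipeline(tmp_path_factory):
    """One full default pipeline run (60 patients + 30 controls, 3 conditions)."""
    outdir = tmp_path_factory.mktemp("pipeline")
    config = RunConfig(outdir=outdir, seed=0)
    paths = run_pipeline(config)
    return config, paths
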