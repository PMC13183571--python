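"""Pipeline orchestration: simulate/extract -> reliability -> MCID -> comparison.

``run_pipeline`` drives the full analysis and writes four result
surfaces to the output directory:

* ``metrics.csv`` — long-format per-walk metric values
* ``reliability.csv`` — per condition x metric: n, mean, SD, ICC with
  95 % CI, F, p, interpretation band
* ``mcid.csv`` — per condition x metric: MDC95, distribution-based
  small/medium/large, anchor-based (FGA, FES-I, PCS-12), triangulated
  MCID and the below-MDC flag
* ``comparison.csv`` — patients vs controls per condition x metric
* ``manifest.json`` — every switch, per-stage subject counts and the
  outlier-removal log, so each table is recomputable from the
  intermediate files.
"""

from __future__ import annotations

import hashlib
import json
import warnings
from dataclasses import asdict, dataclass, field
from pathlib import Path

import pandas as pd

from . import __version__
from .change_metrics import (
    DEFAULT_ANCHORS,
    AnchorSpec,
    build_mcid_table,
    mcid_table_frame,
)
from .gait_metrics import (
    METRICS,
    compute_metrics,
    metric_sets_to_long,
    remove_outliers,
    segment_strides,
)
from .group_compare import comparison_table
from .reliability import ReliabilityResult, estimate_reliability, reliability_table
from .synthetic_gait import CohortSpec, control_spec, simulate_full_study
from .walkway_io import (
    anchors_to_frame,
    group_walks,
    read_anchors,
    read_footfalls,
    write_metrics,
)


@dataclass
class RunConfig:
    """All switches of one pipeline run."""

    outdir: Path = Path("results/run")
    # input: either paths to an existing dataset ...
    footfalls: Path | None = None
    anchors: Path | None = None
    control_footfalls: Path | None = None
    # ... or a synthetic study simulated on the fly
    synthetic: bool = True
    n_subjects: int = 60
    n_controls: int = 30
    conditions: tuple[str, ...] = ("PWS", "SWS", "EC")
    seed: int = 0
    # analysis switches
    icc_form: str = "absolute_agreement"
    t_variant: str = "welch"
    asym_formula: str = "symmetry_index"
    outlier_sd: float = 3.0
    anchor_specs: tuple[AnchorSpec, ...] = tuple(DEFAULT_ANCHORS)
    round_digits: int = 2

    def __post_init__(self) -> None:
        self.outdir = Path(self.outdir)
        if self.icc_form not in ("consistency", "absolute_agreement"):
            raise ValueError(f"unknown icc_form '{self.icc_form}'")
        if self.t_variant not in ("welch", "student"):
            raise ValueError(f"unknown t_variant '{self.t_variant}'")
        if self.asym_formula not in ("symmetry_index", "log_ratio"):
            raise ValueError(f"unknown asym_formula '{self.asym_formula}'")
        if self.outlier_sd <= 0:
            raise ValueError("outlier_sd must be > 0")


def extract_metrics_table(
    footfalls_path: str | Path, asym_formula: str = "symmetry_index"
) -> pd.DataFrame:
    """Footfall file -> long per-walk metric table (the extract stage)."""
    events = read_footfalls(footfalls_path)
    walks = group_walks(events)
    metric_sets = []
    with warnings.catch_warnings():
        warnings.simplefilter("ignore")  # short-walk advisories are summarized in the manifest
        for walk in walks:
            strides = segment_strides(walk)
            metric_sets.append(compute_metrics(strides, walk, asym_formula=asym_formula))
    return metric_sets_to_long(metric_sets)


def filtered_pairs(
    metrics_long: pd.DataFrame, outlier_sd: float = 3.0
) -> tuple[dict[tuple[str, str], pd.DataFrame], dict[str, dict]]:
    """Outlier-filtered subjects x walks matrices per condition x metric.

    Returns the matrices and a removal log {condition/metric: {removed,
    fraction}} implementing the pairwise +/- ``outlier_sd`` SD rule.
    """
    cells: dict[tuple[str, str], pd.DataFrame] = {}
    log: dict[str, dict] = {}
    for condition in sorted(metrics_long["condition"].unique()):
        for metric in METRICS:
            sub = metrics_long[
                (metrics_long["condition"] == condition) & (metrics_long["metric"] == metric)
            ]
            wide = sub.pivot_table(index="subject_id", columns="walk", values="value")
            wide = wide.rename(columns={c: f"walk{int(c)}" for c in wide.columns})
            kept, rep = remove_outliers(wide, threshold=outlier_sd)
            cells[(condition, metric)] = kept
            log[f"{condition}/{metric}"] = {
                "removed_subjects": rep.removed_subjects,
                "fraction_removed": rep.fraction_removed,
            }
    return cells, log


def subject_mean_table(cells: dict[tuple[str, str], pd.DataFrame]) -> pd.DataFrame:
    """Per-subject mean of the two walks, long format (post outlier removal)."""
    rows = []
    for (condition, metric), pairs in cells.items():
        means = pairs.mean(axis=1)
        for sid, v in means.items():
            rows.append(
                {"subject_id": str(sid), "condition": condition, "metric": metric, "value": v}
            )
    return pd.DataFrame(rows)


def pooled_sd(cells: dict[tuple[str, str], pd.DataFrame]) -> dict[tuple[str, str], float]:
    """Cohort SD pooled over the two walks of each condition x metric cell."""
    return {
        key: float(pd.concat([pairs[c] for c in pairs.columns]).std(ddof=1))
        for key, pairs in cells.items()
    }


def reliability_results(
    cells: dict[tuple[str, str], pd.DataFrame], form: str
) -> dict[tuple[str, str], ReliabilityResult]:
    return {
        (condition, metric): estimate_reliability(
            pairs.to_numpy(), form=form, metric=metric, condition=condition
        )
        for (condition, metric), pairs in cells.items()
    }


def run_pipeline(config: RunConfig) -> dict[str, Path]:
    """Run every stage and write the result surfaces; returns output paths."""
    out = config.outdir
    out.mkdir(parents=True, exist_ok=True)

    if config.synthetic:
        data_dir = out / "data"
        spec = CohortSpec(
            n_subjects=config.n_subjects, conditions=config.conditions, seed=config.seed
        )
        study = simulate_full_study(spec, data_dir / "patients")
        ctl = simulate_full_study(
            control_spec(spec, n_subjects=config.n_controls, seed=config.seed + 1),
            data_dir / "controls",
        )
        footfalls, anchors_path = study.footfalls_path, study.anchors_path
        control_footfalls = ctl.footfalls_path
    else:
        if config.footfalls is None or config.anchors is None:
            raise ValueError("non-synthetic runs need footfalls and anchors paths")
        footfalls, anchors_path = config.footfalls, config.anchors
        control_footfalls = config.control_footfalls

    metrics_long = extract_metrics_table(footfalls, asym_formula=config.asym_formula)
    metrics_path = out / "metrics.csv"
    write_metrics(metrics_long, metrics_path)

    cells, removal_log = filtered_pairs(metrics_long, outlier_sd=config.outlier_sd)
    rel = reliability_results(cells, form=config.icc_form)
    rel_df = reliability_table(cells, form=config.icc_form)
    rel_path = out / "reliability.csv"
    rel_df.to_csv(rel_path, index=False)

    anchors_df = anchors_to_frame(read_anchors(anchors_path))
    means = subject_mean_table(cells)
    estimates = build_mcid_table(
        means, anchors_df, rel, pooled_sd(cells), anchor_specs=config.anchor_specs
    )
    mcid_df = mcid_table_frame(
        estimates, anchor_specs=config.anchor_specs, ndigits=config.round_digits
    )
    mcid_path = out / "mcid.csv"
    mcid_df.to_csv(mcid_path, index=False)

    paths = {
        "metrics": metrics_path,
        "reliability": rel_path,
        "mcid": mcid_path,
    }

    if control_footfalls is not None:
        ctl_long = extract_metrics_table(control_footfalls, asym_formula=config.asym_formula)
        ctl_cells, _ = filtered_pairs(ctl_long, outlier_sd=config.outlier_sd)
        cmp_df = comparison_table(
            means, subject_mean_table(ctl_cells), variant=config.t_variant
        )
        cmp_path = out / "comparison.csv"
        cmp_df.to_csv(cmp_path, index=False)
        paths["comparison"] = cmp_path

    cfg = asdict(config)
    cfg = {k: (str(v) if isinstance(v, Path) else v) for k, v in cfg.items()}
    cfg["anchor_specs"] = [asdict(a) for a in config.anchor_specs]
    manifest = {
        "package_version": __version__,
        "config": cfg,
        "config_hash": hashlib.sha256(
            json.dumps(cfg, sort_keys=True, default=str).encode()
        ).hexdigest(),
        "n_walks": int(metrics_long.groupby(["subject_id", "condition"]).ngroups),
        "subjects_per_cell": {
            f"{c}/{m}": int(len(pairs)) for (c, m), pairs in cells.items()
        },
        "outlier_removal": removal_log,
        "mean_removal_fraction": float(
            pd.Series([v["fraction_removed"] for v in removal_log.values()]).mean()
        ),
    }
    manifest_path = out / "manifest.json"
    manifest_path.write_text(json.dumps(manifest, indent=2, sort_keys=True))
    paths["manifest"] = manifest_path
    return paths
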