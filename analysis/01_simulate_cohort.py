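#!/usr/bin/env python
"""Simulate the study cohorts.

Emits a 60-patient cohort (three walking conditions, four walkway trials
per condition pooled into two walks) plus a 30-subject healthy control
group, as footfall event tables with clinical anchor scores and the
generator's ground truth, under results/data/.
"""

import argparse
from pathlib import Path

from vestgait.synthetic_gait import CohortSpec, control_spec, simulate_full_study


def main() -> None:
    ap = argparse.ArgumentParser(description=__doc__)
    ap.add_argument("--seed", type=int, default=0)
    ap.add_argument("--outdir", type=Path, default=Path("results/data"))
    args = ap.parse_args()

    patients = CohortSpec(n_subjects=60, seed=args.seed)
    pat = simulate_full_study(patients, args.outdir / "patients")
    ctl = simulate_full_study(
        control_spec(patients, n_subjects=30, seed=args.seed + 1), args.outdir / "controls"
    )
    print(f"patients: {pat.n_events} footfall events -> {pat.footfalls_path}")
    print(f"controls: {ctl.n_events} footfall events -> {ctl.footfalls_path}")
    print(f"anchor scores for {len(pat.cohort.anchors)} patients -> {pat.anchors_path}")


if __name__ == "__main__":
    main()
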