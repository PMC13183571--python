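#!/usr/bin/env python
"""Patients versus healthy controls, per metric and condition.

Welch t-tests on subject-level values (mean of the two walks after
outlier removal) produce the sign + significance summary matrix of the
sensory-ataxic gait pattern.
"""

import argparse
from pathlib import Path

from vestgait.group_compare import comparison_table
from vestgait.report import filtered_pairs, subject_mean_table
from vestgait.walkway_io import read_metrics


def main() -> None:
    ap = argparse.ArgumentParser(description=__doc__)
    ap.add_argument("--patients", type=Path, default=Path("results/metrics_patients.csv"))
    ap.add_argument("--controls", type=Path, default=Path("results/metrics_controls.csv"))
    ap.add_argument("--out", type=Path, default=Path("results/comparison.csv"))
    ap.add_argument("--variant", default="welch", choices=("welch", "student"))
    args = ap.parse_args()

    pat, _ = filtered_pairs(read_metrics(args.patients))
    con, _ = filtered_pairs(read_metrics(args.controls))
    table = comparison_table(
        subject_mean_table(pat), subject_mean_table(con), variant=args.variant
    )
    table.to_csv(args.out, index=False)

    for cond, sub in table.groupby("condition"):
        sig = sub[sub["significant"]]
        print(f"{cond}: {len(sig)}/{len(sub)} metrics differ from controls at p < 0.05")
    print(f"comparison matrix -> {args.out}")


if __name__ == "__main__":
    main()
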