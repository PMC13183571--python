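#!/usr/bin/env python
"""Test-retest reliability of the 13 gait metrics across the two walks.

Applies the pairwise +/-3 SD outlier rule, then estimates the
single-measure absolute-agreement ICC with 95 % CI, F test and
interpretation band per metric and walking condition.
"""

import argparse
from pathlib import Path

from vestgait.reliability import reliability_table
from vestgait.report import filtered_pairs
from vestgait.walkway_io import read_metrics


def main() -> None:
    ap = argparse.ArgumentParser(description=__doc__)
    ap.add_argument("--metrics", type=Path, default=Path("results/metrics_patients.csv"))
    ap.add_argument("--out", type=Path, default=Path("results/reliability.csv"))
    ap.add_argument("--icc-form", default="absolute_agreement")
    args = ap.parse_args()

    cells, log = filtered_pairs(read_metrics(args.metrics))
    table = reliability_table(cells, form=args.icc_form)
    table.to_csv(args.out, index=False)

    removed = sum(len(v["removed_subjects"]) for v in log.values())
    print(f"outlier rule removed {removed} subject-pairs across "
          f"{len(log)} metric x condition cells")
    for cond, sub in table.groupby("condition"):
        bands = sub["band"].value_counts().to_dict()
        print(f"{cond}: bands {bands}")
    print(f"reliability table -> {args.out}")


if __name__ == "__main__":
    main()
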