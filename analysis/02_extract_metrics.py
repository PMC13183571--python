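#!/usr/bin/env python
"""Extract the 13 spatiotemporal gait metrics from the footfall streams.

Pools trial pairs (1,2) and (3,4) into two walks per subject and
condition, segments strides, and writes one long-format metric table per
cohort under results/.
"""

import argparse
from pathlib import Path

from vestgait.report import extract_metrics_table
from vestgait.walkway_io import write_metrics


def main() -> None:
    ap = argparse.ArgumentParser(description=__doc__)
    ap.add_argument("--datadir", type=Path, default=Path("results/data"))
    ap.add_argument("--outdir", type=Path, default=Path("results"))
    args = ap.parse_args()

    for cohort in ("patients", "controls"):
        table = extract_metrics_table(args.datadir / cohort / "footfalls.csv")
        out = args.outdir / f"metrics_{cohort}.csv"
        write_metrics(table, out)
        n_walks = table.groupby(["subject_id", "condition", "walk"]).ngroups
        print(f"{cohort}: {n_walks} walks x 13 metrics -> {out}")


if __name__ == "__main__":
    main()
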