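#!/usr/bin/env python
"""Group comparisons on the per-animal aggregated morphometry.

Aggregates the per-cell table to per-animal means (scene ≙ animal), runs
unpaired t-tests on the PVH-P16 diet contrast and the ARH age contrast,
and writes the summary (means ± SEM, percent change, p, stars) to
results/group_comparisons.csv.
"""

from pathlib import Path

import pandas as pd

from gliamorph.stats import aggregate, report, two_group_test

ROOT = Path(__file__).resolve().parents[1]

CONTRASTS = [
    # (metric, condition_a, condition_b, label)
    ("total_process_length", "pvh_p16_ncd", "pvh_p16_mhfd", "PVH P16: MHFD-L vs NCD"),
    ("sholl_auc", "pvh_p16_ncd", "pvh_p16_mhfd", "PVH P16: MHFD-L vs NCD"),
    ("total_process_length", "arh_p16_ncd", "arh_p30_ncd", "ARH NCD: P30 vs P16"),
]


def main() -> None:
    src = ROOT / "results" / "morphometry_per_cell.csv"
    per_cell = pd.read_csv(src)
    long = per_cell.melt(
        id_vars=["condition", "animal_id", "cell_id"],
        value_vars=["total_process_length", "sholl_auc", "cell_volume", "territory_volume"],
        var_name="metric", value_name="value",
    )
    long["animal_id"] = long["condition"] + "/" + long["animal_id"]

    comparisons = []
    for metric, ca, cb, label in CONTRASTS:
        sub = long[long.condition.isin([ca, cb]) & (long.metric == metric)].copy()
        sub["group"] = sub["condition"]
        per_animal = aggregate(sub.rename(columns={"group": "diet"}))
        try:
            res = two_group_test(per_animal, metric, "diet", levels=(ca, cb))
        except ValueError as exc:
            print(f"{label} [{metric}]: skipped ({exc})")
            continue
        res.metric = f"{metric} ({label})"
        comparisons.append(res)
        print(
            f"{label} [{metric}]: {res.percent_change:+.0f}%  "
            f"t={res.statistic:.2f}, p={res.p:.2g} {res.note}"
        )

    if comparisons:
        rep = report(comparisons)
        out = ROOT / "results" / "group_comparisons.csv"
        rep.to_csv(out, index=False)
        print(f"\nwrote {out}")


if __name__ == "__main__":
    main()
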