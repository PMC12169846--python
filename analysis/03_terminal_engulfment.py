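#!/usr/bin/env python
"""Detect AgRP terminal puncta and quantify microglial engulfment and CD68.

For every simulated scene: LoG spot detection at 0.8 µm, classification of
each punctum as free / contact (≤1 µm from a microglial surface) /
engulfed (>0.5 µm inside), and intracellular CD68 volume per cell.  Writes
per-scene summaries to results/engulfment_per_scene.csv and reports the
recovered BST terminal-density age contrast.
"""

from pathlib import Path

import numpy as np
import pandas as pd

from gliamorph.engulfment import cd68_volume, classify_spots, detect_spots, summarize_engulfment
from gliamorph.io import read_ground_truth, read_ome_tiff
from gliamorph.morphometry import segment_microglia

ROOT = Path(__file__).resolve().parents[1]
CONDITIONS = ("pvh_p16_ncd", "pvh_p16_mhfd", "arh_p16_ncd", "arh_p30_ncd",
              "bst_p16", "bst_p30")


def main() -> None:
    rows = []
    for cond in CONDITIONS:
        d = ROOT / "scratch" / "scenes" / cond
        if not d.exists():
            continue
        for img_path in sorted(d.glob("*.ome.tif")):
            vol = read_ome_tiff(img_path)
            gt = read_ground_truth(
                img_path.with_name(img_path.name.replace(".ome.tif", ".truth.json"))
            )
            spots = detect_spots(vol, spot_diameter=0.8)
            labels, _ = segment_microglia(vol)
            classified = classify_spots(spots, labels, vol.voxel_size)
            cd68 = cd68_volume(vol, labels)
            s = summarize_engulfment(classified, cd68, vol.roi_volume_um3)
            rows.append(
                dict(condition=cond, animal_id=img_path.stem.replace(".ome", ""),
                     n_spots=s.n_spots_total, n_contact=s.n_contact,
                     n_engulfed=s.n_engulfed,
                     terminal_density=s.terminal_density,
                     engulfed_fraction=s.engulfed_fraction,
                     cd68_volume_per_cell=s.cd68_volume_per_cell,
                     true_n_spots=len(gt.spot_centers),
                     true_engulfed_fraction=float(np.mean(gt.spot_labels == "engulfed"))
                     if len(gt.spot_labels) else 0.0)
            )
    table = pd.DataFrame(rows)
    out = ROOT / "results" / "engulfment_per_scene.csv"
    out.parent.mkdir(exist_ok=True)
    table.to_csv(out, index=False)
    print(f"wrote {len(table)} scenes -> {out}\n")
    print(table.groupby("condition")[
        ["terminal_density", "engulfed_fraction", "cd68_volume_per_cell"]
    ].mean().round(3).to_string())
    bst = table[table.condition.str.startswith("bst")]
    if set(bst.condition) == {"bst_p16", "bst_p30"}:
        dens = bst.groupby("condition")["terminal_density"].mean()
        print(
            f"\nBST terminal density P30 vs P16: "
            f"{100 * (dens['bst_p30'] / dens['bst_p16'] - 1):+.0f}% (embedded +61%)"
        )


if __name__ == "__main__":
    main()
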