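"""Simulation-recovery experiments: render condition pairs and re-measure
the embedded contrasts with the full measurement chain.

A "scene" plays the role of one animal's imaged ROI: per-scene means over
cells correspond to the per-animal means the study plots, and group percent
changes are computed on those scene means.  Condition pairs within a
contrast share per-scene seed substreams (common random numbers), mirroring
a paired simulation design.
"""

from __future__ import annotations

from dataclasses import dataclass

import numpy as np
import pandas as pd

from .engulfment import detect_spots, terminal_density
from .morphometry import measure_scene
from .render import ScenePreset, render_scene

# scaled-down study geometry: 64×80×80 µm ROIs at 0.4 µm isotropic voxels for
# morphometry scenes, 40×56×56 µm for terminal-density scenes
MORPHO_SHAPE = (160, 200, 200)
SPOT_SHAPE = (100, 140, 140)
VOXEL_SIZE = (0.4, 0.4, 0.4)


def scene_seed(master_seed: int, k: int) -> int:
    """Per-scene substream seed; fixed arithmetic so scene k is reproducible
    in isolation and shared across the two conditions of a paired contrast."""
    return int(np.random.SeedSequence([int(master_seed), int(k)]).generate_state(1)[0] & 0x7FFFFFFF)


def measure_morphology_scenes(
    preset: ScenePreset,
    n_scenes: int,
    master_seed: int,
    roi_shape=MORPHO_SHAPE,
    voxel_size=VOXEL_SIZE,
    sholl_step: float = 1.0,
) -> pd.DataFrame:
    """Render ``n_scenes`` and measure every segmented cell.

    Returns a tidy per-cell table (scene, cell_id, total_process_length,
    sholl_auc, sholl_max, cell_volume, territory_volume) plus per-scene
    ground-truth columns for recovery checks.
    """
    rows = []
    for k in range(n_scenes):
        s = scene_seed(master_seed, k)
        vol, gt = render_scene(preset, roi_shape, voxel_size, seed=s)
        metrics, _, _, _ = measure_scene(vol, sholl_step=sholl_step)
        true_mean = float(np.mean(gt.true_total_length_per_cell)) if gt.n_cells else np.nan
        for m in metrics:
            rows.append(
                dict(
                    preset=preset.name,
                    scene=k,
                    cell_id=m.cell_id,
                    total_process_length=m.total_process_length,
                    sholl_auc=m.sholl.summary_auc,
                    sholl_max=m.sholl.summary_max,
                    cell_volume=m.cell_volume,
                    territory_volume=m.territory_volume,
                    n_true_cells=gt.n_cells,
                    true_scene_mean_length=true_mean,
                )
            )
    return pd.DataFrame(rows)


def percent_change_of_scene_means(
    table_a: pd.DataFrame, table_b: pd.DataFrame, metric: str
) -> float:
    """100 × (mean_B − mean_A) / mean_A on per-scene means (scene = animal)."""
    a = table_a.groupby("scene")[metric].mean()
    b = table_b.groupby("scene")[metric].mean()
    return float(100.0 * (b.mean() - a.mean()) / a.mean())


@dataclass
class ContrastRecovery:
    metric: str
    percent_change: float
    n_scenes: int
    n_cells_a: int
    n_cells_b: int


def recover_morphology_contrast(
    preset_a: ScenePreset,
    preset_b: ScenePreset,
    metric: str,
    n_scenes: int = 8,
    master_seed: int = 1,
    **kw,
) -> ContrastRecovery:
    """Full-pipeline percent change (B vs A) of a per-cell morphology metric."""
    ta = measure_morphology_scenes(preset_a, n_scenes, master_seed, **kw)
    tb = measure_morphology_scenes(preset_b, n_scenes, master_seed, **kw)
    return ContrastRecovery(
        metric=metric,
        percent_change=percent_change_of_scene_means(ta, tb, metric),
        n_scenes=n_scenes,
        n_cells_a=len(ta),
        n_cells_b=len(tb),
    )


def measure_terminal_density_scenes(
    preset: ScenePreset,
    n_scenes: int,
    master_seed: int,
    roi_shape=SPOT_SHAPE,
    voxel_size=VOXEL_SIZE,
    spot_diameter: float = 0.8,
) -> pd.DataFrame:
    """LoG-detect terminals per scene and report densities (per 1000 µm³)."""
    rows = []
    for k in range(n_scenes):
        s = scene_seed(master_seed, k)
        vol, gt = render_scene(preset, roi_shape, voxel_size, seed=s)
        spots = detect_spots(vol, spot_diameter=spot_diameter)
        rows.append(
            dict(
                preset=preset.name,
                scene=k,
                n_detected=len(spots),
                n_true=len(gt.spot_centers),
                density=terminal_density(spots, vol.roi_volume_um3),
                true_density=terminal_density(len(gt.spot_centers), vol.roi_volume_um3),
            )
        )
    return pd.DataFrame(rows)


def recover_terminal_density_contrast(
    preset_a: ScenePreset,
    preset_b: ScenePreset,
    n_scenes: int = 8,
    master_seed: int = 1,
    **kw,
) -> ContrastRecovery:
    ta = measure_terminal_density_scenes(preset_a, n_scenes, master_seed, **kw)
    tb = measure_terminal_density_scenes(preset_b, n_scenes, master_seed, **kw)
    pc = float(100.0 * (tb["density"].mean() - ta["density"].mean()) / ta["density"].mean())
    return ContrastRecovery(
        metric="terminal_density",
        percent_change=pc,
        n_scenes=n_scenes,
        n_cells_a=int(ta["n_detected"].sum()),
        n_cells_b=int(tb["n_detected"].sum()),
    )
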