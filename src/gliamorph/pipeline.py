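"""End-to-end pipeline driver: simulate → morpho → spots → interact → stats.

Each stage writes its artifacts under the run's output directory and is
recorded in a manifest (inputs, parameter hash, software version, per-stage
outputs).  The manifest contains no timestamps, so a rerun with the same
configuration and seed reproduces it bit-identically; a failed stage leaves
partial outputs in place with the manifest marking where the run stopped.
"""

from __future__ import annotations

import hashlib
import json
import logging
import time
from pathlib import Path

import numpy as np
import pandas as pd
import tifffile

from . import __version__
from .config import RunConfig
from .engulfment import cd68_volume, classify_spots, detect_spots, summarize_engulfment, terminal_density
from .experiments import scene_seed
from .io import read_ome_tiff, write_ground_truth, write_ome_tiff, write_swc
from .morphometry import measure_scene
from .presets import default_presets
from .render import render_scene

log = logging.getLogger(__name__)


def run_pipeline(config: RunConfig) -> tuple[int, dict]:
    """Execute all stages; returns (exit status, manifest dict)."""
    out = Path(config.out_dir)
    out.mkdir(parents=True, exist_ok=True)
    manifest: dict = {
        "version": __version__,
        "config_hash": config.config_hash(),
        "parameters": {k: v for k, v in config.canonical_dict().items() if k != "out_dir"},
        "stages": [],
    }
    status = 0
    stages = [
        ("simulate", _stage_simulate),
        ("morpho", _stage_morpho),
        ("spots", _stage_spots),
        ("interact", _stage_interact),
        ("stats", _stage_stats),
    ]
    state: dict = {}
    for name, fn in stages:
        t0 = time.perf_counter()
        try:
            outputs = fn(config, out, state)
            log.info("stage %s finished in %.1fs", name, time.perf_counter() - t0)
            manifest["stages"].append({"name": name, "status": "ok", "outputs": sorted(outputs)})
        except Exception as exc:  # noqa: BLE001 - report any stage failure
            log.error("stage %s failed: %s", name, exc)
            manifest["stages"].append({"name": name, "status": "failed", "error": str(exc)})
            status = 1
            break
    (out / "manifest.json").write_text(json.dumps(manifest, indent=2, sort_keys=True))
    return status, manifest


def manifest_hash(manifest: dict) -> str:
    return hashlib.sha256(
        json.dumps(manifest, sort_keys=True, separators=(",", ":")).encode()
    ).hexdigest()


# ---------------------------------------------------------------------------
# stages
# ---------------------------------------------------------------------------

def _scene_paths(out: Path, k: int) -> tuple[Path, Path]:
    d = out / "scenes"
    return d / f"scene_{k:03d}.ome.tif", d / f"scene_{k:03d}.truth.json"


def _stage_simulate(config: RunConfig, out: Path, state: dict) -> list[str]:
    outputs = []
    volumes = []
    if config.input_dir is not None:
        paths = sorted(Path(config.input_dir).glob("*.ome.tif"))
        if not paths:
            raise FileNotFoundError(f"no .ome.tif volumes under {config.input_dir}")
        for p in paths:
            volumes.append(read_ome_tiff(p))
            outputs.append(str(p))
    else:
        preset = default_presets()[config.preset]
        (out / "scenes").mkdir(exist_ok=True)
        for k in range(config.n_scenes):
            vol, gt = render_scene(
                preset, config.roi_shape, config.voxel_size, seed=scene_seed(config.seed, k)
            )
            p_img, p_gt = _scene_paths(out, k)
            write_ome_tiff(p_img, vol)
            write_ground_truth(p_gt, gt)
            volumes.append(vol)
            outputs += [str(p_img.relative_to(out)), str(p_gt.relative_to(out))]
    state["volumes"] = volumes
    return outputs


def _stage_morpho(config: RunConfig, out: Path, state: dict) -> list[str]:
    rows = []
    labels_all = []
    skel_dir = out / "skeletons"
    skel_dir.mkdir(exist_ok=True)
    outputs = []
    for k, vol in enumerate(state["volumes"]):
        metrics, skels, labels, info = measure_scene(
            vol,
            channel=config.channel_map["microglia"],
            sholl_step=config.sholl_step,
            min_cell_volume=config.min_cell_volume,
        )
        labels_all.append(labels)
        lab_path = skel_dir / f"scene_{k:03d}.labels.tif"
        tifffile.imwrite(str(lab_path), labels.astype(np.int16))
        outputs.append(str(lab_path.relative_to(out)))
        for m, s in zip(metrics, skels):
            swc = skel_dir / f"scene_{k:03d}_cell_{m.cell_id:03d}.swc"
            write_swc(swc, s)
            outputs.append(str(swc.relative_to(out)))
            rows.append(
                dict(
                    animal_id=f"scene_{k:03d}",
                    cell_id=m.cell_id,
                    total_process_length=m.total_process_length,
                    cell_volume=m.cell_volume,
                    territory_volume=m.territory_volume,
                    sholl_auc=m.sholl.summary_auc,
                    sholl_max=m.sholl.summary_max,
                )
            )
    table = pd.DataFrame(rows)
    path = out / "morphometry_per_cell.csv"
    table.to_csv(path, index=False)
    state["morpho_table"] = table
    state["labels"] = labels_all
    return outputs + [str(path.relative_to(out))]


def _stage_spots(config: RunConfig, out: Path, state: dict) -> list[str]:
    all_spots = []
    for vol in state["volumes"]:
        all_spots.append(
            detect_spots(
                vol,
                channel=config.channel_map["terminals"],
                spot_diameter=config.spot_diameter,
            )
        )
    state["spots"] = all_spots
    rows = []
    for k, s in enumerate(all_spots):
        for (z, y, x), r in zip(s.centroids, s.peak_response):
            rows.append(dict(animal_id=f"scene_{k:03d}", x=x, y=y, z=z, response=r))
    path = out / "spots_detected.csv"
    pd.DataFrame(rows).to_csv(path, index=False)
    return [str(path.relative_to(out))]


def _stage_interact(config: RunConfig, out: Path, state: dict) -> list[str]:
    rows, summaries = [], []
    for k, (vol, spots, labels) in enumerate(
        zip(state["volumes"], state["spots"], state["labels"])
    ):
        classified = classify_spots(
            spots,
            labels,
            vol.voxel_size,
            contact_max=config.contact_threshold,
            internal_min=config.internalization_threshold,
        )
        cd68 = cd68_volume(vol, labels, channel=config.channel_map["cd68"])
        summary = summarize_engulfment(classified, cd68, vol.roi_volume_um3)
        summaries.append(
            dict(animal_id=f"scene_{k:03d}", **summary.__dict__)
        )
        for i in range(len(classified)):
            z, y, x = classified.centroids[i]
            rows.append(
                dict(
                    animal_id=f"scene_{k:03d}", x=x, y=y, z=z,
                    response=classified.peak_response[i],
                    signed_distance=classified.signed_distance[i],
                    label=classified.label[i],
                    owner=int(classified.owner_cell_id[i]),
                )
            )
    p1 = out / "spots_classified.csv"
    pd.DataFrame(rows).to_csv(p1, index=False)
    p2 = out / "engulfment_summary.json"
    p2.write_text(json.dumps(summaries, indent=2))
    state["engulfment"] = summaries
    return [str(p1.relative_to(out)), str(p2.relative_to(out))]


def _stage_stats(config: RunConfig, out: Path, state: dict) -> list[str]:
    from .stats import aggregate

    per_cell = state["morpho_table"].melt(
        id_vars=["animal_id", "cell_id"], var_name="metric", value_name="value"
    )
    table = aggregate(per_cell) if len(per_cell) else pd.DataFrame(
        columns=["animal_id", "metric", "value", "n_cells"]
    )
    eng = pd.DataFrame(state["engulfment"])
    if len(eng):
        eng_long = eng.melt(id_vars=["animal_id"], var_name="metric", value_name="value")
        eng_long["n_cells"] = np.nan
        table = pd.concat([table, eng_long], ignore_index=True)
    p1 = out / "group_table.csv"
    table.to_csv(p1, index=False)
    summary = (
        table.groupby("metric")["value"]
        .agg(["mean", "sem", "count"])
        .reset_index()
        .to_dict(orient="records")
    )
    p2 = out / "stats_summary.json"
    p2.write_text(json.dumps(summary, indent=2, default=float))
    return [str(p1.relative_to(out)), str(p2.relative_to(out))]
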