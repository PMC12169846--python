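"""Segmentation, skeletonization and density against analytic fixtures and
generator ground truth."""

import numpy as np
import pytest

from gliamorph.morphometry import (
    cell_density,
    measure_scene,
    segment_microglia,
    skeletonize_cell,
)
from gliamorph.render import rasterize_skeleton, render_scene
from gliamorph.types import VolumeImage


def make_volume(mask, voxel_size=(0.2, 0.2, 0.2), amplitude=1.0, bg=0.02):
    data = np.zeros((4,) + mask.shape, dtype=np.float32)
    data[0] = mask.astype(np.float32) * amplitude + bg
    return VolumeImage(data=data, voxel_size=voxel_size)


def cylinder_mask(shape, voxel_size, length_um, radius_um, axis=1):
    vs = np.asarray(voxel_size)
    center = np.asarray(shape) * vs / 2
    zz, yy, xx = np.meshgrid(*[(np.arange(n) + 0.5) * v for n, v in zip(shape, vs)],
                             indexing="ij")
    pts = np.stack([zz, yy, xx], axis=-1) - center
    along = pts[..., axis]
    perp = np.sqrt(np.sum(np.delete(pts, axis, axis=-1) ** 2, axis=-1))
    return (np.abs(along) <= length_um / 2) & (perp <= radius_um)


# ---------------------------------------------------------------------------
# segmentation
# ---------------------------------------------------------------------------

def test_single_cell_segmentation_covers_ground_truth(single_cell_scene):
    vol, gt = single_cell_scene
    labels, info = segment_microglia(vol)
    assert labels.max() == 1
    gt_mask = gt.cell_labels > 0
    covered = np.logical_and(labels > 0, gt_mask).sum() / gt_mask.sum()
    assert covered >= 0.95


def test_blank_volume_yields_no_cells():
    rng = np.random.default_rng(0)
    data = np.full((4, 40, 60, 60), 0.03, dtype=np.float32)
    data += rng.normal(0, 0.01, data.shape).astype(np.float32)
    vol = VolumeImage(data=data, voxel_size=(0.4, 0.4, 0.4))
    labels, info = segment_microglia(vol)
    assert labels.max() == 0


def test_two_distant_cells_not_merged(presets):
    """Two cells with well-separated somas give two labels."""
    from gliamorph.growth import grow_cell

    p = presets["pvh_p16_ncd"].morphology
    vs = (0.4, 0.4, 0.4)
    shape = (100, 110, 230)
    labels_gt = np.zeros(shape, dtype=np.int16)
    cache = {}
    s1 = grow_cell(p, 21, cell_id=1, origin=(20.0, 22.0, 24.0))
    s2 = grow_cell(p, 22, cell_id=2, origin=(20.0, 22.0, 68.0))
    rasterize_skeleton(labels_gt, s1, vs, 1, cache)
    rasterize_skeleton(labels_gt, s2, vs, 2, cache)
    vol = make_volume(labels_gt > 0, voxel_size=vs)
    labels, _ = segment_microglia(vol)
    assert labels.max() == 2
    # each soma falls in a distinct label
    ids = {labels[tuple(np.round(np.array(c) / 0.4 - 0.5).astype(int))] for c in
           ((20.0, 22.0, 24.0), (20.0, 22.0, 68.0))}
    assert ids == {1, 2}


# ---------------------------------------------------------------------------
# skeletonization
# ---------------------------------------------------------------------------

def test_cylinder_total_length():
    """A straight 20 µm tube of radius 0.5 µm skeletonizes to 19–21 µm."""
    vs = (0.2, 0.2, 0.2)
    mask = cylinder_mask((40, 130, 40), vs, 20.0, 0.5)
    skel = skeletonize_cell(mask, vs)
    assert 19.0 <= skel.total_length() <= 21.0


def test_sphere_only_gives_trivial_skeleton():
    vs = (0.2, 0.2, 0.2)
    zz, yy, xx = np.meshgrid(*[(np.arange(40) + 0.5) * 0.2 - 4 for _ in range(3)],
                             indexing="ij")
    mask = zz**2 + yy**2 + xx**2 <= 3.0**2
    skel = skeletonize_cell(mask, vs)
    assert skel.total_length(exclude_radius=getattr(skel, "soma_radius_estimate", 0.0)) < 2.0


def test_rendered_tree_length_within_10_percent(single_cell_scene):
    vol, gt = single_cell_scene
    metrics, skels, labels, _ = measure_scene(vol)
    assert len(metrics) == 1
    measured = metrics[0].total_process_length
    true = gt.true_total_length_per_cell[0]
    assert measured == pytest.approx(true, rel=0.10)


def test_noise_does_not_inflate_length(presets):
    """Monotone degradation: realistic noise must not increase the measured
    total length beyond the spur-pruning tolerance (1 µm)."""
    p_clean = presets["pvh_p16_ncd"].replace(photon_scale=0.0, read_noise_sd=1e-4)
    p_noisy = presets["pvh_p16_ncd"]
    out = {}
    for name, p in (("clean", p_clean), ("noisy", p_noisy)):
        vol, _ = render_scene(p, (96, 120, 120), (0.4, 0.4, 0.4), seed=42, n_cells=1)
        metrics, _, _, _ = measure_scene(vol)
        out[name] = metrics[0].total_process_length
    assert out["noisy"] <= out["clean"] + 1.0


# ---------------------------------------------------------------------------
# density
# ---------------------------------------------------------------------------

def test_density_unit_conversion():
    assert cell_density(5, 1e6) == pytest.approx(5000.0)
    assert cell_density(0, 1e6) == 0.0
    with pytest.raises(ValueError):
        cell_density(1, 0.0)


def test_density_recovery_from_scenes(presets):
    """Mean recovered microglial density across 8 scenes within 15% of the
    preset value."""
    p = presets["pvh_p16_ncd"]
    from gliamorph.experiments import scene_seed

    n_rec, vol_tot = 0, 0.0
    for k in range(8):
        vol, gt = render_scene(p, (80, 110, 110), (0.4, 0.4, 0.4),
                               seed=scene_seed(3, k))
        labels, _ = segment_microglia(vol)
        n_rec += labels.max()
        vol_tot += vol.roi_volume_um3
    recovered = cell_density(n_rec, vol_tot)
    assert recovered == pytest.approx(p.cell_density, rel=0.15)
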