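"""Engulfment classification: threshold fixtures, partition/monotonicity
properties, an exhaustive distance oracle, and CD68 volumes."""

import numpy as np
import pytest
from scipy import ndimage

from gliamorph.engulfment import (
    cd68_volume,
    classify_spots,
    detect_spots,
    summarize_engulfment,
    terminal_density,
)
from gliamorph.types import SpotSet, VolumeImage


VS_FINE = (0.1, 0.1, 0.1)


@pytest.fixture(scope="module")
def sphere_labels():
    """A single spherical 'cell' of radius 5 µm on a fine 0.1 µm grid."""
    shape = (160, 160, 160)
    center = np.array([8.0, 8.0, 8.0])
    grids = [(np.arange(n) + 0.5) * v for n, v in zip(shape, VS_FINE)]
    zz, yy, xx = np.meshgrid(*grids, indexing="ij")
    mask = (zz - center[0]) ** 2 + (yy - center[1]) ** 2 + (xx - center[2]) ** 2 <= 25.0
    return mask.astype(np.int16), center


def spots_at(points):
    pts = np.asarray(points, dtype=float)
    return SpotSet(centroids=pts, diameter=0.8, peak_response=np.ones(len(pts)))


def test_threshold_examples(sphere_labels):
    """0.9 µm outside → contact; 0.6 µm inside → engulfed; 1.5 µm outside →
    free; 0.3 µm inside (shallow interior) → contact."""
    labels, c = sphere_labels
    pts = [c + (0, 0, 5.9), c + (0, 0, 4.4), c + (0, 0, 6.5), c + (0, 0, 4.7)]
    out = classify_spots(spots_at(pts), labels, VS_FINE)
    assert list(out.label) == ["contact", "engulfed", "free", "contact"]
    assert out.owner_cell_id[0] == 1 and out.owner_cell_id[1] == 1
    assert out.owner_cell_id[2] == -1


def test_no_cells_all_free():
    labels = np.zeros((20, 20, 20), dtype=np.int16)
    out = classify_spots(spots_at([(1.0, 1.0, 1.0)]), labels, (0.4, 0.4, 0.4))
    assert list(out.label) == ["free"]


def test_edge_to_surface_toggle(sphere_labels):
    """Edge-to-surface distance is centre distance minus the spot radius."""
    labels, c = sphere_labels
    p = [c + (0, 0, 6.2)]  # centre 1.2 outside: free by centre, contact by edge
    by_center = classify_spots(spots_at(p), labels, VS_FINE)
    by_edge = classify_spots(spots_at(p), labels, VS_FINE, edge_to_surface=True)
    assert by_center.label[0] == "free"
    assert by_edge.label[0] == "contact"


def test_partition_and_monotonicity(noisy_scene):
    """Labels partition every detected spot; tightening either threshold
    shrinks the corresponding class monotonically."""
    vol, gt = noisy_scene
    spots = detect_spots(vol)
    out = classify_spots(spots, gt.cell_labels, vol.voxel_size)
    counts = out.counts()
    assert counts["free"] + counts["contact"] + counts["engulfed"] == counts["total"]

    tight = classify_spots(spots, gt.cell_labels, vol.voxel_size, contact_max=0.0)
    # contact set with threshold 0 is a subset of the default contact set
    default_contact = set(map(tuple, out.centroids[out.label == "contact"]))
    tight_contact = set(map(tuple, tight.centroids[tight.label == "contact"]))
    assert tight_contact <= default_contact

    deeper = classify_spots(spots, gt.cell_labels, vol.voxel_size, internal_min=1.0)
    deep_eng = set(map(tuple, deeper.centroids[deeper.label == "engulfed"]))
    default_eng = set(map(tuple, out.centroids[out.label == "engulfed"]))
    assert deep_eng <= default_eng


def test_labels_match_exhaustive_distance_oracle(noisy_scene):
    """Exact point-to-surface-voxel distances reproduce the labels for spots
    farther than half a voxel diagonal from either threshold."""
    vol, gt = noisy_scene
    labels = gt.cell_labels
    vs = np.array(vol.voxel_size)
    half_diag = 0.5 * float(np.linalg.norm(vs))
    rng = np.random.default_rng(0)
    dims = np.array(labels.shape) * vs
    pts = rng.uniform(1.0, dims - 1.0, size=(150, 3))
    out = classify_spots(spots_at(pts), labels, vs)

    mask = labels > 0
    eroded = ndimage.binary_erosion(mask, structure=np.ones((3, 3, 3), bool))
    surface = np.argwhere(mask & ~eroded)
    surface_um = (surface + 0.5) * vs
    for p, lab in zip(pts, out.label):
        d = float(np.min(np.linalg.norm(surface_um - p, axis=1)))
        vox = tuple(np.clip(np.round(p / vs - 0.5).astype(int), 0, np.array(labels.shape) - 1))
        signed = -d if mask[vox] else d
        if min(abs(signed + 0.5), abs(signed - 1.0)) <= half_diag:
            continue  # too close to a threshold for the half-voxel convention
        expected = "engulfed" if signed < -0.5 else ("contact" if signed <= 1.0 else "free")
        assert lab == expected, f"point {p}: {lab} vs oracle {expected} (d={signed:.3f})"


def test_anisotropic_distances_match_isotropic_resampling(sphere_labels):
    """Signed distances on an anisotropic grid agree with the isotropic ones
    within half a voxel diagonal."""
    labels_fine, c = sphere_labels
    # every 3rd z-slice starting at 1 keeps voxel centres aligned with the
    # (i + 0.5) * voxel_size convention at 0.3 µm z spacing
    coarse = labels_fine[1::3]
    vs_aniso = (0.3, 0.1, 0.1)
    rng = np.random.default_rng(1)
    pts = c + rng.uniform(-6.5, 6.5, size=(40, 3))
    out_iso = classify_spots(spots_at(pts), labels_fine, VS_FINE)
    out_aniso = classify_spots(spots_at(pts), coarse, vs_aniso)
    half_diag = 0.5 * float(np.linalg.norm(vs_aniso))
    assert np.all(
        np.abs(out_iso.signed_distance - out_aniso.signed_distance) <= half_diag + 1e-6
    )


def test_end_to_end_engulfed_fraction_recovery(noisy_scene, presets):
    """Detected-and-classified engulfed fraction within ±0.05 absolute of the
    preset ground-truth fraction at preset SNR."""
    vol, gt = noisy_scene
    spots = detect_spots(vol)
    out = classify_spots(spots, gt.cell_labels, vol.voxel_size)
    counts = out.counts()
    frac = counts["engulfed"] / counts["total"]
    assert frac == pytest.approx(presets["pvh_p16_ncd"].engulfed_fraction, abs=0.05)


# ---------------------------------------------------------------------------
# CD68
# ---------------------------------------------------------------------------

def ball_mask(shape, vs, center, radius):
    grids = [(np.arange(n) + 0.5) * v for n, v in zip(shape, vs)]
    zz, yy, xx = np.meshgrid(*grids, indexing="ij")
    return (zz - center[0]) ** 2 + (yy - center[1]) ** 2 + (xx - center[2]) ** 2 <= radius**2


def test_cd68_blob_inside_cell_recovers_volume():
    vs = (0.1, 0.1, 0.1)
    shape = (120, 120, 120)
    cell = ball_mask(shape, vs, (6, 6, 6), 4.0).astype(np.int16)
    r = (3.0 * 4.0 / (4 * np.pi)) ** (1 / 3)  # 4 µm³ sphere
    cd = ball_mask(shape, vs, (6, 6, 6), r)
    data = np.zeros((4,) + shape, dtype=np.float32)
    data[2] = cd * 1.0 + 0.01
    vol = VolumeImage(data=data, voxel_size=vs)
    out = cd68_volume(vol, cell)
    surface_bound = float(4 * np.pi * r**2 * np.linalg.norm(vs))
    assert out[1] == pytest.approx(4.0, abs=surface_bound)


def test_cd68_blob_outside_cells_counts_zero():
    vs = (0.1, 0.1, 0.1)
    shape = (120, 120, 120)
    cell = ball_mask(shape, vs, (3.5, 3.5, 3.5), 2.5).astype(np.int16)
    cd = ball_mask(shape, vs, (9, 9, 9), 1.0)
    data = np.zeros((4,) + shape, dtype=np.float32)
    data[2] = cd * 1.0 + 0.01
    vol = VolumeImage(data=data, voxel_size=vs)
    out = cd68_volume(vol, cell)
    assert out[1] == 0.0


def test_cd68_recovery_from_scenes(presets):
    """Mean recovered intracellular CD68 within 15% of the preset value."""
    from gliamorph.experiments import scene_seed
    from gliamorph.render import render_scene

    p = presets["pvh_p16_ncd"]
    vols = []
    for k in range(4):
        vol, gt = render_scene(p, (96, 120, 120), (0.4, 0.4, 0.4),
                               seed=scene_seed(17, k), n_cells=1)
        vols += list(cd68_volume(vol, gt.cell_labels).values())
    assert np.mean(vols) == pytest.approx(p.cd68_volume_per_cell, rel=0.15)


# ---------------------------------------------------------------------------
# densities
# ---------------------------------------------------------------------------

def test_terminal_density_arithmetic():
    assert terminal_density(10, 1000.0) == pytest.approx(10.0)
    assert terminal_density(spots_at(np.zeros((0, 3))), 500.0) == 0.0
    with pytest.raises(ValueError):
        terminal_density(5, 0.0)


def test_summary_counts_consistent(noisy_scene):
    vol, gt = noisy_scene
    spots = detect_spots(vol)
    out = classify_spots(spots, gt.cell_labels, vol.voxel_size)
    summary = summarize_engulfment(out, {1: 10.0}, vol.roi_volume_um3)
    assert summary.n_contact + summary.n_engulfed <= summary.n_spots_total
    assert summary.terminal_density >= summary.engulfed_density >= 0
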