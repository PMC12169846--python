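"""Scene generator: determinism, label soundness, mass conservation, anisotropy."""

import numpy as np
import pytest

from gliamorph.grid import sample_field, signed_distance_field
from gliamorph.growth import MorphologyParams
from gliamorph.render import ScenePreset, render_scene


def test_preset_invariants_enforced():
    with pytest.raises(ValueError):
        ScenePreset(name="bad", contact_fraction=0.7, engulfed_fraction=0.5)
    with pytest.raises(ValueError):
        ScenePreset(name="bad", spot_diameter=0.0)


def test_roi_too_small_for_soma_raises():
    with pytest.raises(ValueError, match="too small"):
        render_scene(ScenePreset(name="p"), (8, 8, 8), (0.4, 0.4, 0.4), seed=0)


def test_deterministic_rendering(presets):
    p = presets["pvh_p16_ncd"]
    v1, g1 = render_scene(p, (64, 96, 96), (0.4, 0.4, 0.4), seed=5, n_cells=1)
    v2, g2 = render_scene(p, (64, 96, 96), (0.4, 0.4, 0.4), seed=5, n_cells=1)
    assert np.array_equal(v1.data, v2.data)
    assert np.array_equal(g1.spot_centers, g2.spot_centers)
    assert np.array_equal(g1.skeletons[0].nodes, g2.skeletons[0].nodes)


def test_noiseless_single_process_ridge_traces_polyline():
    """With noise off and a single straight process, the intensity ridge of
    the microglia channel follows the ground-truth polyline within a voxel."""
    morph = MorphologyParams(
        n_primary_processes=1, branch_probability=0.0, tortuosity=0.0,
        segment_length_mean=8.0,
    )
    preset = ScenePreset(
        name="one", morphology=morph, spot_density=0.0, cd68_volume_per_cell=0.0,
        photon_scale=0.0, read_noise_sd=0.0, soma_margin=12.0,
    )
    vol, gt = render_scene(preset, (70, 70, 70), (0.4, 0.4, 0.4), seed=2, n_cells=1)
    skel = gt.skeletons[0]
    ch = vol.channel("microglia")
    vs = np.array(vol.voxel_size)
    # sample along the polyline away from the soma: local max within 1 voxel
    soma = skel.soma_center
    for node in skel.nodes[1:]:
        if np.linalg.norm(node - soma) < skel.radii[skel.soma_index] + 1.0:
            continue
        idx = np.round(node / vs - 0.5).astype(int)
        if np.any(idx < 1) or np.any(idx >= np.array(ch.shape) - 1):
            continue
        neigh = ch[idx[0]-1:idx[0]+2, idx[1]-1:idx[1]+2, idx[2]-1:idx[2]+2]
        assert neigh.max() > 0.5 * ch.max()


def test_spot_density_zero_gives_background_only(quiet_preset):
    p = quiet_preset.replace(spot_density=0.0)
    vol, gt = render_scene(p, (48, 72, 72), (0.4, 0.4, 0.4), seed=3, n_cells=1)
    assert len(gt.spot_centers) == 0
    # pre-noise terminal channel is flat background
    assert np.allclose(vol.channel("terminals"), vol.channel("terminals").flat[0])


def test_ground_truth_labels_sound(noisy_scene):
    """Recomputing signed distances from spot centres to the cell masks
    reproduces the stored free/contact/engulfed label for every spot."""
    vol, gt = noisy_scene
    field = signed_distance_field(gt.cell_labels > 0, vol.voxel_size)
    d = sample_field(field, gt.spot_centers, vol.voxel_size)
    for dist, lab in zip(d, gt.spot_labels):
        if lab == "engulfed":
            assert dist < -0.5
        elif lab == "contact":
            assert -0.5 <= dist <= 1.0
        else:
            assert dist > 1.0


def test_engulfed_and_contact_spots_have_owners(noisy_scene):
    _, gt = noisy_scene
    labelled = gt.spot_labels != "free"
    assert np.all(gt.spot_owner[labelled] > 0)
    assert np.all(gt.spot_owner[~labelled] == -1)


def test_mass_conservation_pre_noise(presets):
    """Integrated pre-noise terminal signal is proportional to spot count
    within 1% (free spots only, so no blob is clipped by a cell margin)."""
    base = presets["bst_p16"].replace(
        photon_scale=0.0, read_noise_sd=0.0, cell_density=0.0,
        contact_fraction=0.0, engulfed_fraction=0.0,
    )
    sums, counts = [], []
    for dens in (0.8, 1.6):
        vol, gt = render_scene(base.replace(spot_density=dens), (64, 96, 96),
                               (0.4, 0.4, 0.4), seed=9, n_cells=0)
        ch = vol.channel("terminals")
        sums.append(float(ch.sum() - ch.flat[0] * ch.size))  # subtract background
        counts.append(len(gt.spot_centers))
    per_spot = [s / c for s, c in zip(sums, counts)]
    assert per_spot[0] == pytest.approx(per_spot[1], rel=0.01)


def test_anisotropy_preserves_ground_truth_geometry(presets):
    """Doubling the z voxel size while halving the z extent leaves the
    ground-truth µm geometry (skeletons, somas, lengths) unchanged."""
    p = presets["pvh_p16_ncd"]
    _, g1 = render_scene(p, (160, 96, 96), (0.2, 0.4, 0.4), seed=13, n_cells=1)
    _, g2 = render_scene(p, (80, 96, 96), (0.4, 0.4, 0.4), seed=13, n_cells=1)
    assert np.allclose(g1.soma_centers, g2.soma_centers)
    assert np.allclose(g1.skeletons[0].nodes, g2.skeletons[0].nodes)
    assert np.allclose(g1.true_total_length_per_cell, g2.true_total_length_per_cell)


def test_cells_not_emitted_when_count_zero(quiet_preset):
    vol, gt = render_scene(quiet_preset, (48, 72, 72), (0.4, 0.4, 0.4), seed=1, n_cells=0)
    assert gt.n_cells == 0
    assert not (gt.cell_labels > 0).any()
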