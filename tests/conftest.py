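"""Shared fixtures: calibrated presets and rendered scenes reused across tests."""

from __future__ import annotations

import numpy as np
import pytest

from gliamorph.presets import default_presets
from gliamorph.render import ScenePreset, render_scene


@pytest.fixture(scope="session")
def presets():
    return default_presets()


@pytest.fixture(scope="session")
def quiet_preset(presets):
    """PVH-P16 NCD preset with noise disabled (pre-noise rendering checks)."""
    return presets["pvh_p16_ncd"].replace(photon_scale=0.0, read_noise_sd=0.0)


@pytest.fixture(scope="session")
def single_cell_scene(presets):
    """One noiseless cell in a 38×48×48 µm ROI with its ground truth."""
    preset = presets["pvh_p16_ncd"].replace(photon_scale=0.0, read_noise_sd=1e-4)
    vol, gt = render_scene(preset, (96, 120, 120), (0.4, 0.4, 0.4), seed=42, n_cells=1)
    return vol, gt


@pytest.fixture(scope="session")
def noisy_scene(presets):
    """A default-noise two-cell scene used by segmentation/classification tests."""
    vol, gt = render_scene(
        presets["pvh_p16_ncd"], (120, 160, 160), (0.4, 0.4, 0.4), seed=7, n_cells=2
    )
    return vol, gt


@pytest.fixture(scope="session")
def bst_scene(presets):
    """BST P16 terminal-density scene (~200 puncta at preset SNR)."""
    vol, gt = render_scene(presets["bst_p16"], (100, 140, 140), (0.4, 0.4, 0.4), seed=11)
    return vol, gt


def random_tree(seed: int):
    """A random grown skeleton for geometry oracles."""
    from gliamorph.growth import MorphologyParams, grow_cell

    rng = np.random.default_rng(seed)
    params = MorphologyParams(
        n_primary_processes=int(rng.integers(2, 7)),
        segment_length_mean=float(rng.uniform(4, 10)),
        branch_probability=float(rng.uniform(0.2, 1.0)),
        max_branch_order=int(rng.integers(1, 4)),
        tortuosity=float(rng.uniform(0.0, 0.8)),
    )
    return grow_cell(params, seed)
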