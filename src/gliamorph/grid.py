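"""Voxel-grid geometry helpers: µm ↔ index mapping and signed distance fields."""

from __future__ import annotations

import numpy as np
from scipy import ndimage


def um_to_index(points_um: np.ndarray, voxel_size) -> np.ndarray:
    """Continuous (fractional) voxel index of physical points.

    The voxel centre convention is ``x_um = (i + 0.5) * voxel_size`` so the
    fractional index is ``x / vs - 0.5``.
    """
    vs = np.asarray(voxel_size, dtype=float)
    return np.asarray(points_um, dtype=float) / vs - 0.5


def index_to_um(indices, voxel_size) -> np.ndarray:
    vs = np.asarray(voxel_size, dtype=float)
    return (np.asarray(indices, dtype=float) + 0.5) * vs


def nearest_voxel(points_um: np.ndarray, voxel_size, shape=None) -> np.ndarray:
    idx = np.rint(um_to_index(points_um, voxel_size)).astype(int)
    if shape is not None:
        idx = np.clip(idx, 0, np.asarray(shape) - 1)
    return idx


def signed_distance_field(mask: np.ndarray, voxel_size) -> np.ndarray:
    """Signed Euclidean distance (µm) to the mask surface on the voxel grid.

    Positive outside the mask, negative inside; computed with anisotropic
    sampling so distances are physical.  The zero level sits between the last
    inside and first outside voxel centres (half-voxel surface convention);
    the same field is used by the generator when it places labelled spots and
    by the classifier, so labels are self-consistent by construction.
    """
    mask = np.asarray(mask, dtype=bool)
    if not mask.any():
        return np.full(mask.shape, np.inf, dtype=np.float32)
    sampling = tuple(float(v) for v in voxel_size)
    d_out = ndimage.distance_transform_edt(~mask, sampling=sampling)
    d_in = ndimage.distance_transform_edt(mask, sampling=sampling)
    return (d_out - d_in).astype(np.float32)


def sample_field(field: np.ndarray, points_um: np.ndarray, voxel_size) -> np.ndarray:
    """Trilinear interpolation of a scalar voxel field at physical points."""
    pts = np.atleast_2d(np.asarray(points_um, dtype=float))
    coords = um_to_index(pts, voxel_size).T
    return ndimage.map_coordinates(
        np.asarray(field, dtype=float), coords, order=1, mode="nearest"
    )


def ball_offsets(radius_um: float, voxel_size) -> np.ndarray:
    """Integer voxel offsets whose centres lie within ``radius_um`` (anisotropic)."""
    vs = np.asarray(voxel_size, dtype=float)
    half = np.ceil(radius_um / vs).astype(int)
    rng = [np.arange(-h, h + 1) for h in half]
    zz, yy, xx = np.meshgrid(*rng, indexing="ij")
    d2 = (zz * vs[0]) ** 2 + (yy * vs[1]) ** 2 + (xx * vs[2]) ** 2
    keep = d2 <= radius_um**2
    return np.stack([zz[keep], yy[keep], xx[keep]], axis=1)
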