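"""Synthetic multichannel confocal volume renderer.

Scenes emulate a laser-scanning confocal stack through labelled tissue:
tube-rendered microglial skeletons (Iba1-like channel), AgRP terminal puncta
as Gaussian blobs of configurable FWHM, intracellular CD68 blobs, a nuclear
counterstain, anisotropic Gaussian PSF blur, and Poisson photon noise plus
additive Gaussian read noise.  Every rendered scene carries full ground
truth (skeletons, per-cell lengths and volumes, spot positions with
free/contact/engulfed labels, CD68 blob volumes).

Spot labels follow the distance rules used downstream: a spot centre more
than 0.5 µm inside a cell surface is engulfed, within 1 µm outside (or
shallowly inside) is a contact, beyond that free.  The generator places
engulfed spots at interior depth > 0.6 µm and keeps a margin around both
thresholds so labels are unambiguous under the half-voxel surface
convention.
"""

from __future__ import annotations

import logging
from dataclasses import dataclass, field, replace

import numpy as np
from scipy import ndimage

from .grid import ball_offsets, nearest_voxel, sample_field, um_to_index
from .growth import MorphologyParams, grow_cell
from .types import GroundTruth, VolumeImage

log = logging.getLogger(__name__)

CHANNELS = ("microglia", "terminals", "cd68", "nuclei")
_AMPLITUDE = 1.0
_BACKGROUND = 0.03
_NUCLEUS_RADIUS = 2.2          # µm, microglial nuclei at soma centres
_BG_NUCLEI_PER_MM3 = 30000.0   # cosmetic non-microglial nuclei
_SPOT_EDGE_MARGIN = 1.25       # µm, keeps puncta blobs inside the ROI
_FIELD_PAD = 2.0               # µm, bounding-box pad for distance fields

# placement margins around the classification thresholds (µm); see module docstring
_ENGULF_PLACE_DEPTH = 0.8
_ENGULF_VERIFY_DEPTH = 0.65
_CONTACT_BAND = (-0.40, 0.90)
_FREE_MIN = 1.30


@dataclass(frozen=True)
class ScenePreset:
    """One simulated experimental condition.

    ``cell_density`` is cells/mm³, ``spot_density`` puncta per 1000 µm³.
    ``contact_fraction``/``engulfed_fraction`` set the ground-truth share of
    puncta placed in contact with / internalized by microglia.
    """

    name: str
    morphology: MorphologyParams = field(default_factory=MorphologyParams)
    cell_density: float = 4000.0
    spot_density: float = 1.0
    spot_diameter: float = 0.8
    contact_fraction: float = 0.15
    engulfed_fraction: float = 0.08
    cd68_volume_per_cell: float = 25.0
    photon_scale: float = 60.0
    read_noise_sd: float = 0.01
    psf_sigma: tuple[float, float, float] = (0.35, 0.12, 0.12)
    soma_margin: float = 18.0
    min_soma_separation: float = 20.0
    spot_min_separation: float = 1.1

    def __post_init__(self) -> None:
        if self.spot_diameter <= 0:
            raise ValueError("spot_diameter must be > 0")
        if self.contact_fraction < 0 or self.engulfed_fraction < 0:
            raise ValueError("spot fractions must be >= 0")
        if self.contact_fraction + self.engulfed_fraction > 1.0 + 1e-12:
            raise ValueError("engulfed_fraction + contact_fraction must be <= 1")
        for name in ("cell_density", "spot_density", "cd68_volume_per_cell"):
            if getattr(self, name) < 0:
                raise ValueError(f"{name} must be >= 0")

    def replace(self, **kw) -> "ScenePreset":
        return replace(self, **kw)


def _rng(seed: int, *key: int) -> np.random.Generator:
    return np.random.Generator(np.random.PCG64(np.random.SeedSequence([int(seed), *key])))


def _cell_seed(seed: int, j: int) -> int:
    return int(np.random.SeedSequence([int(seed), 100 + j]).generate_state(1)[0] & 0x7FFFFFFF)


class _SignedField:
    """Signed distance to the microglial surface, computed on a padded crop."""

    def __init__(self, mask: np.ndarray, voxel_size, labels: np.ndarray | None = None):
        self.voxel_size = np.asarray(voxel_size, dtype=float)
        self.empty = not mask.any()
        if self.empty:
            return
        obj = ndimage.find_objects(mask.astype(np.int8))[0]
        pad = np.ceil(_FIELD_PAD / self.voxel_size).astype(int)
        self.slices = tuple(
            slice(max(0, s.start - p), min(n, s.stop + p))
            for s, p, n in zip(obj, pad, mask.shape)
        )
        crop = mask[self.slices]
        sampling = tuple(self.voxel_size)
        d_out = ndimage.distance_transform_edt(~crop, sampling=sampling)
        d_in = ndimage.distance_transform_edt(crop, sampling=sampling)
        self.field = (d_out - d_in).astype(np.float32)
        self.origin = np.array([s.start for s in self.slices]) * self.voxel_size
        self.owner = None
        if labels is not None:
            idx = ndimage.distance_transform_edt(
                ~crop, sampling=sampling, return_distances=False, return_indices=True
            )
            self.owner = labels[self.slices][tuple(idx)]

    def __call__(self, points_um: np.ndarray) -> np.ndarray:
        pts = np.atleast_2d(np.asarray(points_um, dtype=float))
        if self.empty:
            return np.full(len(pts), np.inf)
        local = pts - self.origin
        shape_um = np.array(self.field.shape) * self.voxel_size
        inside = np.all((local >= 0) & (local < shape_um), axis=1)
        out = np.full(len(pts), 2.0 * _FREE_MIN)
        if inside.any():
            out[inside] = sample_field(self.field, local[inside], self.voxel_size)
        return out

    def owner_at(self, point_um: np.ndarray) -> int:
        if self.empty or self.owner is None:
            return -1
        local = np.asarray(point_um, dtype=float) - self.origin
        idx = nearest_voxel(local, self.voxel_size, self.owner.shape)
        return int(self.owner[tuple(idx)])


# ---------------------------------------------------------------------------
# rasterization
# ---------------------------------------------------------------------------

def _stamp_ball(arr, center_um, radius_um, voxel_size, value, offsets_cache, only_empty=False):
    vs = np.asarray(voxel_size)
    key = round(float(radius_um) / 0.05)
    offs = offsets_cache.get(key)
    if offs is None:
        offs = ball_offsets(max(key * 0.05, 0.5 * min(vs)), vs)
        offsets_cache[key] = offs
    idx = nearest_voxel(center_um, vs) + offs
    ok = np.all((idx >= 0) & (idx < np.array(arr.shape)), axis=1)
    idx = idx[ok]
    if only_empty:
        flat = arr[idx[:, 0], idx[:, 1], idx[:, 2]]
        idx = idx[flat == 0]
    arr[idx[:, 0], idx[:, 1], idx[:, 2]] = value


def rasterize_skeleton(labels: np.ndarray, skel, voxel_size, cell_value: int, offsets_cache) -> None:
    """Stamp tube + soma of one skeleton into a label volume (first id wins)."""
    vs = np.asarray(voxel_size, dtype=float)
    spacing = 0.5 * float(min(vs))
    _stamp_ball(labels, skel.soma_center, skel.radii[skel.soma_index], vs, cell_value,
                offsets_cache, only_empty=True)
    for a, b in skel.edges:
        p, q = skel.nodes[a], skel.nodes[b]
        r = float(min(skel.radii[a], skel.radii[b]))
        L = float(np.linalg.norm(q - p))
        n = max(1, int(np.ceil(L / spacing)))
        for t in np.linspace(0.0, 1.0, n + 1):
            _stamp_ball(labels, p + t * (q - p), r, vs, cell_value, offsets_cache,
                        only_empty=True)


def _clipped_process_length(skel, dims_um) -> float:
    """Total process length inside the ROI box (soma-incident edges excluded)."""
    lo = np.zeros(3)
    hi = np.asarray(dims_um, dtype=float)
    total = 0.0
    for a, b in skel.edges:
        if a == skel.soma_index or b == skel.soma_index:
            continue
        p, q = skel.nodes[a], skel.nodes[b]
        total += _seg_box_overlap(p, q, lo, hi)
    return float(total)


def _seg_box_overlap(p, q, lo, hi) -> float:
    """Length of the part of segment pq inside the axis box [lo, hi]."""
    d = q - p
    L = float(np.linalg.norm(d))
    if L == 0:
        return 0.0
    t0, t1 = 0.0, 1.0
    for ax in range(3):
        if abs(d[ax]) < 1e-12:
            if not (lo[ax] <= p[ax] <= hi[ax]):
                return 0.0
            continue
        ta = (lo[ax] - p[ax]) / d[ax]
        tb = (hi[ax] - p[ax]) / d[ax]
        ta, tb = min(ta, tb), max(ta, tb)
        t0, t1 = max(t0, ta), min(t1, tb)
    return L * max(0.0, t1 - t0)


def _gaussian_blob(channel, center_um, sigma_um, voxel_size, amplitude=_AMPLITUDE):
    """Additive anisotropically-sampled Gaussian blob (window at ±3.5σ)."""
    vs = np.asarray(voxel_size)
    half = np.ceil(3.5 * sigma_um / vs).astype(int)
    c_idx = um_to_index(center_um, vs)
    lo = np.maximum(0, np.floor(c_idx - half).astype(int))
    hi = np.minimum(np.array(channel.shape), np.ceil(c_idx + half).astype(int) + 1)
    if np.any(lo >= hi):
        return
    grids = [ (np.arange(l, h) + 0.5) * v for l, h, v in zip(lo, hi, vs) ]
    zz = ((grids[0] - center_um[0]) / sigma_um) ** 2
    yy = ((grids[1] - center_um[1]) / sigma_um) ** 2
    xx = ((grids[2] - center_um[2]) / sigma_um) ** 2
    blob = amplitude * np.exp(-0.5 * (zz[:, None, None] + yy[None, :, None] + xx[None, None, :]))
    channel[lo[0]:hi[0], lo[1]:hi[1], lo[2]:hi[2]] += blob


# ---------------------------------------------------------------------------
# scene assembly
# ---------------------------------------------------------------------------

def render_scene(
    preset: ScenePreset,
    roi_shape: tuple[int, int, int],
    voxel_size: tuple[float, float, float] = (0.4, 0.4, 0.4),
    seed: int = 0,
    n_cells: int | None = None,
) -> tuple[VolumeImage, GroundTruth]:
    """Render one scene; bit-deterministic given all arguments.

    ``n_cells`` overrides the density-derived cell count (None → stochastic
    rounding of ``cell_density × ROI volume``).  Cells whose soma cannot be
    placed inside the ROI margin are not emitted.  Raises ``ValueError`` if
    the ROI cannot contain a single soma.
    """
    shape = tuple(int(s) for s in roi_shape)
    vs = np.asarray(voxel_size, dtype=float)
    if len(shape) != 3 or any(s <= 0 for s in shape) or np.any(vs <= 0):
        raise ValueError("roi_shape and voxel_size must be positive")
    dims_um = np.array(shape) * vs
    roi_volume = float(np.prod(dims_um))
    morph = preset.morphology

    if np.any(dims_um < 2 * (morph.soma_radius + 0.5)):
        raise ValueError(
            f"ROI {tuple(np.round(dims_um, 1))} µm is too small to contain a soma "
            f"of radius {morph.soma_radius} µm"
        )
    margin = np.minimum(preset.soma_margin, 0.45 * dims_um)
    margin = np.maximum(margin, morph.soma_radius + 0.5)

    rng_place = _rng(seed, 1)
    if n_cells is None:
        lam = preset.cell_density * roi_volume / 1e9
        n_cells = int(np.floor(lam)) + int(rng_place.uniform() < (lam - np.floor(lam)))

    # soma placement with minimum separation (rejection)
    somas = []
    for _ in range(n_cells):
        for _try in range(200):
            p = rng_place.uniform(margin, dims_um - margin)
            if all(np.linalg.norm(p - q) >= preset.min_soma_separation for q in somas):
                somas.append(p)
                break
        else:
            log.warning("could not place all somas (placed %d of %d)", len(somas), n_cells)
            break
    n_cells = len(somas)

    skeletons = []
    labels = np.zeros(shape, dtype=np.int16)
    cache: dict = {}
    for j, soma in enumerate(somas):
        skel = grow_cell(morph, _cell_seed(seed, j), cell_id=j + 1, origin=soma)
        skeletons.append(skel)
        rasterize_skeleton(labels, skel, vs, j + 1, cache)

    mask = labels > 0
    counts = np.bincount(labels.ravel(), minlength=n_cells + 1)[1:]
    true_volumes = counts.astype(float) * float(np.prod(vs))
    true_lengths = np.array([_clipped_process_length(s, dims_um) for s in skeletons])

    sdf = _SignedField(mask, vs, labels=labels)

    # --- spots ------------------------------------------------------------
    rng_spots = _rng(seed, 2)
    n_spots = int(round(preset.spot_density * roi_volume / 1000.0))
    n_eng = int(round(preset.engulfed_fraction * n_spots)) if n_cells else 0
    n_con = int(round(preset.contact_fraction * n_spots)) if n_cells else 0
    spot_centers, spot_labels, spot_owner = _place_spots(
        rng_spots, preset, skeletons, sdf, dims_um, n_spots, n_eng, n_con
    )

    # --- cd68 blobs --------------------------------------------------------
    rng_cd = _rng(seed, 3)
    cd_centers, cd_vols, cd_cell = _place_cd68(rng_cd, preset, skeletons, sdf, labels, vs)

    # --- channels ----------------------------------------------------------
    data = np.zeros((4,) + shape, dtype=np.float32)
    data[0] = mask.astype(np.float32) * _AMPLITUDE

    sigma_spot = preset.spot_diameter / 2.355  # FWHM -> σ
    for p in spot_centers:
        _gaussian_blob(data[1], p, sigma_spot, vs)

    for c, v in zip(cd_centers, cd_vols):
        r = (3.0 * v / (4.0 * np.pi)) ** (1.0 / 3.0)
        tmp = np.zeros(shape, dtype=np.int8)
        _stamp_ball(tmp, c, r, vs, 1, cache)
        data[2] += tmp.astype(np.float32) * _AMPLITUDE

    rng_nuc = _rng(seed, 4)
    nuc = np.zeros(shape, dtype=np.int8)
    for soma in somas:
        _stamp_ball(nuc, soma, _NUCLEUS_RADIUS, vs, 1, cache)
    n_bg = int(round(_BG_NUCLEI_PER_MM3 * roi_volume / 1e9))
    for _ in range(n_bg):
        c = rng_nuc.uniform(3.0, dims_um - 3.0)
        _stamp_ball(nuc, c, float(rng_nuc.uniform(1.8, 2.6)), vs, 1, cache)
    data[3] = nuc.astype(np.float32) * _AMPLITUDE

    sigma_vox = np.asarray(preset.psf_sigma) / vs
    for ch in range(4):
        if data[ch].any():
            data[ch] = ndimage.gaussian_filter(data[ch], sigma=sigma_vox)
        data[ch] += _BACKGROUND

    rng_noise = _rng(seed, 5)
    if preset.photon_scale > 0:
        data = rng_noise.poisson(data * preset.photon_scale).astype(np.float32) / preset.photon_scale
    if preset.read_noise_sd > 0:
        data += rng_noise.normal(0.0, preset.read_noise_sd, size=data.shape).astype(np.float32)

    volume = VolumeImage(data=data, voxel_size=tuple(vs), channel_names=CHANNELS)
    gt = GroundTruth(
        skeletons=skeletons,
        true_total_length_per_cell=true_lengths,
        true_cell_volumes=true_volumes,
        soma_centers=np.asarray(somas).reshape(-1, 3),
        spot_centers=spot_centers,
        spot_labels=spot_labels,
        spot_owner=spot_owner,
        cd68_centers=cd_centers,
        cd68_volumes=cd_vols,
        cd68_cell=cd_cell,
        cell_labels=labels,
        roi_volume_um3=roi_volume,
    )
    return volume, gt


def _place_spots(rng, preset, skeletons, sdf, dims_um, n_spots, n_eng, n_con):
    """Rejection-sample spot centres per class, with minimum separation.

    Proposals are continuous µm points (soma-ball interiors for engulfed,
    skeleton-node neighbourhoods for contacts, uniform for free) accepted
    against the signed-distance field with a margin inside each label band.
    """
    accepted: list[np.ndarray] = []
    labels: list[str] = []
    owners: list[int] = []
    min_sep = preset.spot_min_separation

    def far_enough(p):
        if not accepted:
            return True
        arr = np.asarray(accepted)
        return bool(np.min(np.sum((arr - p) ** 2, axis=1)) >= min_sep**2)

    def in_margin(p):
        return np.all(p >= _SPOT_EDGE_MARGIN) and np.all(p <= dims_um - _SPOT_EDGE_MARGIN)

    n_free = max(0, n_spots - n_eng - n_con)

    for _ in range(n_eng):
        for _try in range(400):
            skel = skeletons[rng.integers(len(skeletons))]
            u = rng.standard_normal(3)
            u /= np.linalg.norm(u)
            r = (skel.radii[skel.soma_index] - _ENGULF_PLACE_DEPTH) * rng.uniform() ** (1 / 3)
            p = skel.soma_center + u * max(r, 0.0)
            if in_margin(p) and far_enough(p) and sdf(p)[0] <= -_ENGULF_PLACE_DEPTH:
                accepted.append(p)
                labels.append("engulfed")
                owners.append(int(skel.cell_id))
                break
        else:
            log.warning("could not place all engulfed spots")
            break

    for _ in range(n_con):
        for _try in range(400):
            skel = skeletons[rng.integers(len(skeletons))]
            node = int(rng.integers(skel.n_nodes))
            u = rng.standard_normal(3)
            u /= np.linalg.norm(u)
            p = skel.nodes[node] + u * (skel.radii[node] + rng.uniform(0.0, 0.9))
            if not (in_margin(p) and far_enough(p)):
                continue
            v = sdf(p)[0]
            if _CONTACT_BAND[0] <= v <= _CONTACT_BAND[1]:
                accepted.append(p)
                labels.append("contact")
                owners.append(sdf.owner_at(p))
                break
        else:
            log.warning("could not place all contact spots")
            break

    for _ in range(n_free):
        for _try in range(400):
            p = rng.uniform(_SPOT_EDGE_MARGIN, dims_um - _SPOT_EDGE_MARGIN)
            if far_enough(p) and sdf(p)[0] >= _FREE_MIN:
                accepted.append(p)
                labels.append("free")
                owners.append(-1)
                break
        else:
            log.warning("could not place all free spots")
            break

    centers = np.asarray(accepted, dtype=float).reshape(-1, 3)
    return centers, np.asarray(labels, dtype=object), np.asarray(owners, dtype=int)


def _place_cd68(rng, preset, skeletons, sdf, labels_vol, vs):
    """Place intracellular CD68 blobs totalling ``cd68_volume_per_cell`` per cell."""
    centers, vols, owners = [], [], []
    target = preset.cd68_volume_per_cell
    if target <= 0 or not skeletons:
        return (np.zeros((0, 3)), np.zeros(0), np.zeros(0, dtype=int))
    for skel in skeletons:
        n_blobs = max(1, int(round(target / 12.0)))
        v_blob = target / n_blobs
        r = (3.0 * v_blob / (4.0 * np.pi)) ** (1.0 / 3.0)
        placed = 0
        for _try in range(400):
            if placed >= n_blobs:
                break
            u = rng.standard_normal(3)
            u /= np.linalg.norm(u)
            rad = max(skel.radii[skel.soma_index] - r - 0.2, 0.0) * rng.uniform() ** (1 / 3)
            p = skel.soma_center + u * rad
            if sdf(p)[0] <= -(r * 0.8):
                centers.append(p)
                vols.append(v_blob)
                owners.append(int(skel.cell_id))
                placed += 1
        if placed < n_blobs:
            log.warning("cell %d: placed %d of %d CD68 blobs", skel.cell_id, placed, n_blobs)
    return (
        np.asarray(centers, dtype=float).reshape(-1, 3),
        np.asarray(vols, dtype=float),
        np.asarray(owners, dtype=int),
    )
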