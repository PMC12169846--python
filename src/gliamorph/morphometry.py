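"""Per-cell microglial morphometry.

Implements the measurement chain applied to the microglia channel of a
confocal stack: threshold-based segmentation with marker-controlled
splitting of touching cells, 3D thinning to a skeleton graph, exact
segment–sphere Sholl analysis, convex-hull territory, and cell density.
"""

from __future__ import annotations

import logging
from typing import NamedTuple, Optional

import networkx as nx
import numpy as np
from scipy import ndimage
from skimage.feature import peak_local_max
from skimage.filters import threshold_otsu
from skimage.morphology import skeletonize
from skimage.segmentation import watershed

from .grid import index_to_um
from .types import (CellMorphometrics, CellSkeleton, ShollProfile, VolumeImage,
                    _segment_length_outside_ball)

log = logging.getLogger(__name__)

_26 = [
    (dz, dy, dx)
    for dz in (-1, 0, 1)
    for dy in (-1, 0, 1)
    for dx in (-1, 0, 1)
    if (dz, dy, dx) > (0, 0, 0)  # 13 positive half-space offsets
]


# ---------------------------------------------------------------------------
# segmentation
# ---------------------------------------------------------------------------

def segment_microglia(
    volume: VolumeImage,
    channel="microglia",
    min_cell_volume: float = 30.0,
    threshold: Optional[float] = None,
    exclude_boundary: bool = False,
    min_soma_radius: float = 1.5,
    min_soma_separation: float = 8.0,
) -> tuple[np.ndarray, dict]:
    """Label individual microglia in ``channel``.

    The channel is thresholded (Otsu within the ROI unless ``threshold`` is
    given), cleaned of objects below ``min_cell_volume`` µm³, and split into
    cells by marker-controlled watershed on the interior distance transform:
    soma markers are distance-map peaks deeper than ``min_soma_radius`` µm.
    Components without any soma marker are dropped as debris.  Returns
    ``(labels, info)`` where labels is an int32 volume (0 = background) and
    info counts dropped components.  An empty segmentation is returned (with
    a warning) rather than raised.
    """
    img = np.asarray(volume.channel(channel), dtype=float)
    if threshold is None:
        # Otsu, floored above the background noise: with sparse foreground the
        # Otsu split can land inside the (Poisson-skewed) background mode and
        # flood the mask.  Median/MAD estimate the background robustly because
        # foreground occupies a small volume fraction.
        med = float(np.median(img))
        mad = float(np.median(np.abs(img - med)))
        floor = med + 8.0 * 1.4826 * mad
        threshold = max(float(threshold_otsu(img)), floor)
    mask = img > threshold

    mask = ndimage.binary_closing(mask, structure=np.ones((3, 3, 3), bool))

    voxvol = volume.voxel_volume
    min_vox = max(1, int(round(min_cell_volume / voxvol)))
    comp, n_comp = ndimage.label(mask, structure=np.ones((3, 3, 3), int))
    sizes = np.bincount(comp.ravel())
    small = np.flatnonzero(sizes < min_vox)
    n_small = int(np.sum(small > 0))
    mask &= ~np.isin(comp, small[small > 0])

    info = {
        "threshold": threshold,
        "n_dropped_small": n_small,
        "n_dropped_no_soma": 0,
        "n_dropped_boundary": 0,
    }
    if not mask.any():
        log.warning("segment_microglia: empty segmentation")
        return np.zeros(volume.shape, dtype=np.int32), info

    edt = ndimage.distance_transform_edt(mask, sampling=volume.voxel_size)
    min_dist_vox = max(1, int(round(min_soma_separation / max(volume.voxel_size))))
    peaks = peak_local_max(
        edt, min_distance=min_dist_vox, threshold_abs=min_soma_radius, labels=mask
    )
    markers = np.zeros(mask.shape, dtype=np.int32)
    for i, p in enumerate(peaks, start=1):
        markers[tuple(p)] = i
    if markers.max() == 0:
        log.warning("segment_microglia: no soma-scale components found")
        info["n_dropped_no_soma"] = int(ndimage.label(mask)[1])
        return np.zeros(volume.shape, dtype=np.int32), info

    labels = watershed(-edt, markers, mask=mask).astype(np.int32)

    # debris: mask voxels not reached by any marker's watershed basin
    comp, _ = ndimage.label(mask, structure=np.ones((3, 3, 3), int))
    reached = np.unique(comp[labels > 0])
    info["n_dropped_no_soma"] = int(len(np.setdiff1d(np.unique(comp), np.append(reached, 0))))

    if exclude_boundary:
        border = np.zeros(mask.shape, bool)
        for ax in range(3):
            sl = [slice(None)] * 3
            for edge in (0, -1):
                sl[ax] = edge
                border[tuple(sl)] = True
        touching = np.unique(labels[border & (labels > 0)])
        info["n_dropped_boundary"] = int(len(touching))
        labels[np.isin(labels, touching)] = 0

    # compact label ids
    ids = np.unique(labels)
    ids = ids[ids > 0]
    remap = np.zeros(labels.max() + 1, dtype=np.int32)
    remap[ids] = np.arange(1, len(ids) + 1)
    return remap[labels], info


# ---------------------------------------------------------------------------
# skeletonization
# ---------------------------------------------------------------------------

def skeletonize_cell(
    mask: np.ndarray,
    voxel_size,
    intensity: Optional[np.ndarray] = None,
    prune_um: float = 1.0,
    cell_id: int = 0,
    origin_um=(0.0, 0.0, 0.0),
) -> CellSkeleton:
    """3D-thin a cell mask and convert the voxel skeleton to a µm tree.

    The thinned voxels are linked over 26-connectivity with physical edge
    lengths, reduced to a minimum spanning tree (thinning occasionally leaves
    small cycles), and spurs shorter than ``prune_um`` are removed.  The soma
    node is the skeleton voxel nearest the maximum of the interior distance
    map; node radii are the distance-map values.  A mask that thins to
    nothing yields a single-node skeleton at the distance-map maximum.

    ``origin_um`` shifts reported coordinates (useful when ``mask`` is a crop
    of a larger volume).
    """
    mask = np.asarray(mask, dtype=bool)
    vs = np.asarray(voxel_size, dtype=float)
    origin_um = np.asarray(origin_um, dtype=float)
    edt = ndimage.distance_transform_edt(mask, sampling=tuple(vs))
    soma_vox = np.unravel_index(int(np.argmax(edt)), mask.shape)
    soma_radius = float(edt[soma_vox])

    skel_vox = skeletonize(mask)
    if not skel_vox.any() and mask.sum() > 8:
        # 3D thinning can delete symmetric even-width objects outright; a 2³
        # dilation flips the width parity (centreline shift ≤ half a voxel)
        skel_vox = skeletonize(
            ndimage.binary_dilation(mask, structure=np.ones((2, 2, 2), bool))
        )
    coords = np.argwhere(skel_vox)
    if len(coords) == 0:
        coords = np.array([soma_vox])

    pts = index_to_um(coords, vs) + origin_um
    node_radii = edt[tuple(coords.T)]

    key = {tuple(c): i for i, c in enumerate(map(tuple, coords))}
    G = nx.Graph()
    G.add_nodes_from(range(len(coords)))
    for (dz, dy, dx) in _26:
        shifted = coords + (dz, dy, dx)
        w = float(np.linalg.norm(np.array([dz, dy, dx]) * vs))
        for i, c in enumerate(map(tuple, shifted)):
            j = key.get(c)
            if j is not None:
                G.add_edge(i, j, weight=w)

    # keep the component containing the soma voxel
    soma_pt = index_to_um(np.array(soma_vox), vs) + origin_um
    d2 = np.sum((pts - soma_pt) ** 2, axis=1)
    soma_node = int(np.argmin(d2))
    comp = nx.node_connected_component(G, soma_node)
    if len(comp) < G.number_of_nodes():
        G = G.subgraph(comp).copy()

    T = nx.minimum_spanning_tree(G, weight="weight")
    _prune_spurs(T, soma_node, prune_um)

    # Process length is measured on the lightly relaxed voxel path (one
    # Laplacian pass removes grid roughness without straightening genuine
    # curvature); Sholl and territory use the fully relaxed coordinates,
    # where residual zigzag would otherwise bias crossing counts.
    pts = _smooth_tree(T, pts, soma_node, n_iter=1)
    raw_length = 0.0
    soma_pt_raw = pts[soma_node]
    for a, b in T.edges:
        raw_length += _segment_length_outside_ball(
            pts[a], pts[b], soma_pt_raw, soma_radius
        )
    pts = _smooth_tree(T, pts, soma_node, n_iter=2)

    keep = sorted(T.nodes)
    relabel = {n: i for i, n in enumerate(keep)}
    nodes = pts[keep]
    radii = node_radii[keep]
    edges = np.array([(relabel[a], relabel[b]) for a, b in T.edges], dtype=int).reshape(-1, 2)
    skel = CellSkeleton(
        cell_id=cell_id,
        nodes=nodes,
        radii=radii,
        edges=edges,
        soma_index=relabel[soma_node],
        mask=mask,
        voxel_size=tuple(vs),
    )
    skel.soma_radius_estimate = soma_radius
    skel.raw_process_length = float(raw_length)
    return skel


def _smooth_tree(
    T: nx.Graph, pts: np.ndarray, soma_node: int, lam: float = 0.5, n_iter: int = 3
) -> np.ndarray:
    """Laplacian smoothing of node coordinates along the tree.

    Voxel skeletons zigzag at the grid scale, which inflates Sholl crossing
    counts (each grazing pass of a sphere can pick up spurious re-crossings);
    a few relaxation passes remove the zigzag without moving the centreline.
    The soma node and leaves stay fixed so path extents are preserved.
    """
    pts = pts.copy()
    fixed = {soma_node} | {n for n in T.nodes if T.degree(n) == 1}
    free = [n for n in T.nodes if n not in fixed]
    nbrs = {n: list(T.neighbors(n)) for n in free}
    for _ in range(n_iter):
        new = pts.copy()
        for n in free:
            new[n] = (1 - lam) * pts[n] + lam * np.mean(pts[nbrs[n]], axis=0)
        pts = new
    return pts


def _prune_spurs(T: nx.Graph, soma_node: int, prune_um: float, max_passes: int = 4) -> None:
    """Iteratively remove leaf chains shorter than ``prune_um`` (in place)."""
    for _ in range(max_passes):
        removed = False
        leaves = [n for n in T.nodes if T.degree(n) == 1 and n != soma_node]
        for leaf in leaves:
            if leaf not in T:
                continue
            chain = [leaf]
            length = 0.0
            cur, prev = leaf, None
            while True:
                nbrs = [n for n in T.neighbors(cur) if n != prev]
                if len(nbrs) != 1:
                    break
                nxt = nbrs[0]
                length += T.edges[cur, nxt]["weight"]
                if T.degree(nxt) > 2 or nxt == soma_node:
                    break
                chain.append(nxt)
                prev, cur = cur, nxt
                if length >= prune_um:
                    break
            if length < prune_um:
                T.remove_nodes_from(chain)
                removed = True
        if not removed:
            break


# ---------------------------------------------------------------------------
# Sholl analysis
# ---------------------------------------------------------------------------

def sholl(
    skeleton: CellSkeleton,
    radius_step: float = 1.0,
    radii: Optional[np.ndarray] = None,
) -> ShollProfile:
    """Exact 3D Sholl profile of a skeleton tree.

    For each concentric sphere of radius ``r = k * radius_step`` about the
    soma centre, counts transversal crossings of tree edges through the
    sphere by solving the segment–sphere quadratic on every edge (half-open
    parameter interval ``[0, 1)`` so shared endpoints are not double
    counted).  Tangencies do not count as crossings.
    """
    if radius_step <= 0:
        raise ValueError("radius_step must be > 0")
    c = skeleton.soma_center
    if radii is None:
        if skeleton.n_nodes <= 1:
            radii = np.array([radius_step])
        else:
            rmax = float(np.max(np.linalg.norm(skeleton.nodes - c, axis=1)))
            kmax = max(1, int(np.ceil(rmax / radius_step)))
            radii = radius_step * np.arange(1, kmax + 1)
    radii = np.asarray(radii, dtype=float)

    if len(skeleton.edges) == 0:
        return ShollProfile(radii=radii, intersections=np.zeros(len(radii), int))

    P = skeleton.nodes[skeleton.edges[:, 0]] - c
    Q = skeleton.nodes[skeleton.edges[:, 1]] - c
    D = Q - P
    a = np.einsum("ij,ij->i", D, D)
    b = 2.0 * np.einsum("ij,ij->i", P, D)
    p2 = np.einsum("ij,ij->i", P, P)
    ok = a > 0  # ignore zero-length edges

    counts = np.zeros(len(radii), dtype=int)
    for k, r in enumerate(radii):
        c0 = p2 - r * r
        disc = b * b - 4 * a * c0
        cross = ok & (disc > 0)
        if not cross.any():
            continue
        sq = np.sqrt(disc[cross])
        aa, bb = a[cross], b[cross]
        t0 = (-bb - sq) / (2 * aa)
        t1 = (-bb + sq) / (2 * aa)
        n = ((t0 >= 0) & (t0 < 1)).astype(int) + ((t1 >= 0) & (t1 < 1)).astype(int)
        counts[k] = int(n.sum())
    return ShollProfile(radii=radii, intersections=counts)


# ---------------------------------------------------------------------------
# territory and density
# ---------------------------------------------------------------------------

class TerritoryResult(NamedTuple):
    volume: float       # µm³
    degenerate: bool


def territory(skeleton: CellSkeleton) -> TerritoryResult:
    """Convex-hull volume of the skeleton nodes (the cell's tissue territory).

    Coplanar or collinear node sets are degenerate: volume 0 with the flag set.
    """
    pts = skeleton.nodes
    if len(pts) < 4:
        return TerritoryResult(0.0, True)
    centered = pts - pts.mean(axis=0)
    if np.linalg.matrix_rank(centered, tol=1e-9) < 3:
        return TerritoryResult(0.0, True)
    from scipy.spatial import ConvexHull, QhullError

    try:
        hull = ConvexHull(pts)
    except QhullError:
        return TerritoryResult(0.0, True)
    return TerritoryResult(float(hull.volume), False)


def cell_density(n_cells: int, roi_volume_um3: float) -> float:
    """Cells per mm³ given an ROI volume in µm³."""
    if roi_volume_um3 <= 0:
        raise ValueError("roi_volume_um3 must be > 0")
    return float(n_cells) / roi_volume_um3 * 1e9


# ---------------------------------------------------------------------------
# per-scene driver
# ---------------------------------------------------------------------------

def measure_cell(skeleton: CellSkeleton, voxel_volume: float, sholl_step: float = 1.0) -> CellMorphometrics:
    soma_r = getattr(skeleton, "soma_radius_estimate", 0.0)
    length = getattr(skeleton, "raw_process_length", None)
    if length is None:
        length = skeleton.total_length(exclude_radius=soma_r)
    vol = float(np.count_nonzero(skeleton.mask)) * voxel_volume if skeleton.mask is not None else 0.0
    terr = territory(skeleton)
    prof = sholl(skeleton, radius_step=sholl_step)
    return CellMorphometrics(
        cell_id=skeleton.cell_id,
        total_process_length=length,
        cell_volume=vol,
        territory_volume=terr.volume,
        territory_degenerate=terr.degenerate,
        sholl=prof,
    )


def measure_scene(
    volume: VolumeImage,
    channel="microglia",
    sholl_step: float = 1.0,
    min_cell_volume: float = 30.0,
    threshold: Optional[float] = None,
    pad_um: float = 2.0,
) -> tuple[list[CellMorphometrics], list[CellSkeleton], np.ndarray, dict]:
    """Segment a scene and measure every cell.

    Returns (metrics, skeletons, label volume, segmentation info).  Each cell
    is skeletonized on a padded bounding-box crop for speed.
    """
    labels, info = segment_microglia(
        volume, channel=channel, min_cell_volume=min_cell_volume, threshold=threshold
    )
    vs = np.asarray(volume.voxel_size)
    pad = np.maximum(1, np.ceil(pad_um / vs).astype(int))
    metrics: list[CellMorphometrics] = []
    skeletons: list[CellSkeleton] = []
    objects = ndimage.find_objects(labels)
    for cid, sl in enumerate(objects, start=1):
        if sl is None:
            continue
        sl_pad = tuple(
            slice(max(0, s.start - p), min(n, s.stop + p))
            for s, p, n in zip(sl, pad, labels.shape)
        )
        crop = labels[sl_pad] == cid
        origin = index_to_um([s.start for s in sl_pad], vs) - 0.5 * vs
        skel = skeletonize_cell(crop, vs, cell_id=cid, origin_um=origin)
        skeletons.append(skel)
        metrics.append(measure_cell(skel, volume.voxel_volume, sholl_step=sholl_step))
    return metrics, skeletons, labels, info
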