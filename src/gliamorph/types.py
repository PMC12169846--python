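"""Core in-memory containers shared across the pipeline.

Conventions
-----------
All physical coordinates are micrometres in ``(z, y, x)`` axis order.  Voxel
indices are 0-based and the centre of voxel ``i`` sits at ``(i + 0.5) *
voxel_size``, which keeps sub-voxel geometry unambiguous when volumes are
anisotropic.
"""

from __future__ import annotations

from dataclasses import dataclass, field
from typing import Optional, Sequence

import numpy as np

SPOT_LABELS = ("free", "contact", "engulfed")


@dataclass
class VolumeImage:
    """A multichannel 3D intensity grid with physical voxel size.

    ``data`` has shape ``(C, Z, Y, X)``; ``voxel_size`` is ``(dz, dy, dx)``
    in µm.  ``channel_names`` maps semantic channels (microglia, terminals,
    cd68, nuclei) to indices in ``data``.
    """

    data: np.ndarray
    voxel_size: tuple[float, float, float]
    channel_names: tuple[str, ...] = ("microglia", "terminals", "cd68", "nuclei")

    def __post_init__(self) -> None:
        self.data = np.asarray(self.data)
        if self.data.ndim != 4:
            raise ValueError("VolumeImage.data must be 4D (C, Z, Y, X)")
        vs = tuple(float(v) for v in self.voxel_size)
        if len(vs) != 3 or any(v <= 0 for v in vs):
            raise ValueError("voxel_size must be three positive values (z, y, x)")
        self.voxel_size = vs

    @property
    def n_channels(self) -> int:
        return self.data.shape[0]

    @property
    def shape(self) -> tuple[int, int, int]:
        return self.data.shape[1:]

    @property
    def voxel_volume(self) -> float:
        dz, dy, dx = self.voxel_size
        return dz * dy * dx

    @property
    def roi_volume_um3(self) -> float:
        return self.voxel_volume * int(np.prod(self.shape))

    def channel(self, name_or_index) -> np.ndarray:
        if isinstance(name_or_index, str):
            try:
                name_or_index = self.channel_names.index(name_or_index)
            except ValueError as exc:
                raise KeyError(f"unknown channel {name_or_index!r}") from exc
        if not 0 <= int(name_or_index) < self.n_channels:
            raise IndexError(f"channel index {name_or_index} out of range")
        return self.data[int(name_or_index)]


@dataclass
class CellSkeleton:
    """Rooted spatial tree for one microglial cell.

    ``nodes`` are µm coordinates ``(N, 3)``, ``radii`` local tube radii in µm,
    ``edges`` index pairs into ``nodes``.  ``soma_index`` points at the root
    node; the soma centre is therefore always a node.  ``mask`` optionally
    carries the binary voxel mask the skeleton was extracted from.
    """

    cell_id: int
    nodes: np.ndarray
    radii: np.ndarray
    edges: np.ndarray
    soma_index: int = 0
    mask: Optional[np.ndarray] = None
    voxel_size: Optional[tuple[float, float, float]] = None

    def __post_init__(self) -> None:
        self.nodes = np.atleast_2d(np.asarray(self.nodes, dtype=float))
        self.radii = np.asarray(self.radii, dtype=float)
        self.edges = np.asarray(self.edges, dtype=int).reshape(-1, 2)

    @property
    def soma_center(self) -> np.ndarray:
        return self.nodes[self.soma_index]

    @property
    def n_nodes(self) -> int:
        return self.nodes.shape[0]

    def edge_lengths(self) -> np.ndarray:
        if len(self.edges) == 0:
            return np.zeros(0)
        d = self.nodes[self.edges[:, 0]] - self.nodes[self.edges[:, 1]]
        return np.linalg.norm(d, axis=1)

    def total_length(self, exclude_radius: float = 0.0) -> float:
        """Sum of edge lengths, optionally excluding the part of every edge
        that lies inside a ball of ``exclude_radius`` around the soma centre
        (used to report process length without the soma body)."""
        if len(self.edges) == 0:
            return 0.0
        if exclude_radius <= 0:
            return float(self.edge_lengths().sum())
        c = self.soma_center
        total = 0.0
        for a, b in self.edges:
            total += _segment_length_outside_ball(self.nodes[a], self.nodes[b], c, exclude_radius)
        return float(total)


def _segment_length_outside_ball(p: np.ndarray, q: np.ndarray, c: np.ndarray, r: float) -> float:
    """Length of segment pq lying outside the ball of radius r at c (exact)."""
    d = q - p
    L = float(np.linalg.norm(d))
    if L == 0.0:
        return 0.0
    # solve ||p + t d - c||^2 = r^2 for t
    f = p - c
    a = L * L
    b = 2.0 * float(f @ d)
    cc = float(f @ f) - r * r
    disc = b * b - 4 * a * cc
    if disc <= 0:
        # no (or tangent) intersection: fully inside or fully outside
        return 0.0 if cc < 0 else L
    sq = np.sqrt(disc)
    t0 = (-b - sq) / (2 * a)
    t1 = (-b + sq) / (2 * a)
    lo = max(0.0, min(t0, t1))
    hi = min(1.0, max(t0, t1))
    inside = max(0.0, hi - lo)
    return L * (1.0 - inside)


@dataclass
class ShollProfile:
    """Intersection counts of a cell's processes with concentric spheres."""

    radii: np.ndarray
    intersections: np.ndarray

    def __post_init__(self) -> None:
        self.radii = np.asarray(self.radii, dtype=float)
        self.intersections = np.asarray(self.intersections, dtype=int)
        if np.any(np.diff(self.radii) <= 0):
            raise ValueError("Sholl radii must be strictly increasing")

    @property
    def summary_auc(self) -> float:
        """Trapezoidal area under the intersection profile (µm·crossings)."""
        if len(self.radii) < 2:
            return 0.0
        return float(np.trapezoid(self.intersections, self.radii))

    @property
    def summary_max(self) -> int:
        return int(self.intersections.max()) if len(self.intersections) else 0


@dataclass
class CellMorphometrics:
    cell_id: int
    total_process_length: float  # µm
    cell_volume: float           # µm³ (mask voxels × voxel volume; soma included)
    territory_volume: float      # µm³ (convex hull of skeleton nodes)
    territory_degenerate: bool
    sholl: ShollProfile


@dataclass
class SpotSet:
    """Detected terminal puncta with optional engulfment classification.

    ``signed_distance`` is the µm distance from each centroid to the nearest
    microglial surface, negative inside a cell.  ``label`` is one of
    free/contact/engulfed once :func:`classify_spots` has run, else "".
    """

    centroids: np.ndarray                 # (M, 3) µm, (z, y, x)
    diameter: float
    peak_response: np.ndarray
    signed_distance: np.ndarray = field(default=None)  # type: ignore[assignment]
    label: np.ndarray = field(default=None)            # type: ignore[assignment]
    owner_cell_id: np.ndarray = field(default=None)    # type: ignore[assignment]

    def __post_init__(self) -> None:
        self.centroids = np.asarray(self.centroids, dtype=float).reshape(-1, 3)
        m = len(self.centroids)
        self.peak_response = np.asarray(self.peak_response, dtype=float).reshape(m)
        if self.signed_distance is None:
            self.signed_distance = np.full(m, np.nan)
        if self.label is None:
            self.label = np.array([""] * m, dtype=object)
        if self.owner_cell_id is None:
            self.owner_cell_id = np.full(m, -1, dtype=int)

    def __len__(self) -> int:
        return len(self.centroids)

    def counts(self) -> dict[str, int]:
        out = {k: int(np.sum(self.label == k)) for k in SPOT_LABELS}
        out["total"] = len(self)
        return out


@dataclass
class GroundTruth:
    """Everything the generator knows about a rendered scene."""

    skeletons: list[CellSkeleton]
    true_total_length_per_cell: np.ndarray   # µm, clipped to the ROI
    true_cell_volumes: np.ndarray            # µm³ from the rendered masks
    soma_centers: np.ndarray                 # (n_cells, 3) µm
    spot_centers: np.ndarray                 # (M, 3) µm
    spot_labels: np.ndarray                  # free | contact | engulfed
    spot_owner: np.ndarray                   # cell index, -1 for free
    cd68_centers: np.ndarray                 # (K, 3) µm
    cd68_volumes: np.ndarray                 # µm³ per blob
    cd68_cell: np.ndarray                    # owning cell index per blob
    cell_labels: Optional[np.ndarray] = None  # int16 label volume (0 = background)
    roi_volume_um3: float = 0.0

    @property
    def n_cells(self) -> int:
        return len(self.skeletons)

    def to_json_dict(self) -> dict:
        """JSON-serializable sidecar (label volume excluded, stored as TIFF)."""
        return {
            "n_cells": self.n_cells,
            "roi_volume_um3": self.roi_volume_um3,
            "true_total_length_per_cell": np.asarray(self.true_total_length_per_cell).tolist(),
            "true_cell_volumes": np.asarray(self.true_cell_volumes).tolist(),
            "soma_centers": np.asarray(self.soma_centers).tolist(),
            "spot_centers": np.asarray(self.spot_centers).tolist(),
            "spot_labels": list(map(str, self.spot_labels)),
            "spot_owner": np.asarray(self.spot_owner).tolist(),
            "cd68_centers": np.asarray(self.cd68_centers).tolist(),
            "cd68_volumes": np.asarray(self.cd68_volumes).tolist(),
            "cd68_cell": np.asarray(self.cd68_cell).tolist(),
            "skeletons": [
                {
                    "cell_id": s.cell_id,
                    "nodes": s.nodes.tolist(),
                    "radii": s.radii.tolist(),
                    "edges": s.edges.tolist(),
                    "soma_index": s.soma_index,
                }
                for s in self.skeletons
            ],
        }

    @classmethod
    def from_json_dict(cls, d: dict) -> "GroundTruth":
        skels = [
            CellSkeleton(
                cell_id=s["cell_id"],
                nodes=np.asarray(s["nodes"], dtype=float),
                radii=np.asarray(s["radii"], dtype=float),
                edges=np.asarray(s["edges"], dtype=int),
                soma_index=s["soma_index"],
            )
            for s in d["skeletons"]
        ]
        return cls(
            skeletons=skels,
            true_total_length_per_cell=np.asarray(d["true_total_length_per_cell"], dtype=float),
            true_cell_volumes=np.asarray(d["true_cell_volumes"], dtype=float),
            soma_centers=np.asarray(d["soma_centers"], dtype=float).reshape(-1, 3),
            spot_centers=np.asarray(d["spot_centers"], dtype=float).reshape(-1, 3),
            spot_labels=np.asarray(d["spot_labels"], dtype=object),
            spot_owner=np.asarray(d["spot_owner"], dtype=int),
            cd68_centers=np.asarray(d["cd68_centers"], dtype=float).reshape(-1, 3),
            cd68_volumes=np.asarray(d["cd68_volumes"], dtype=float),
            cd68_cell=np.asarray(d["cd68_cell"], dtype=int),
            roi_volume_um3=float(d["roi_volume_um3"]),
        )
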