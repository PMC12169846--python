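"""File formats: OME-TIFF volumes, SWC skeletons, JSON ground truth, CSV tables."""

from __future__ import annotations

import json
from pathlib import Path

import numpy as np
import tifffile

from .types import CellSkeleton, GroundTruth, VolumeImage


def write_ome_tiff(path, volume: VolumeImage) -> None:
    """Write a 4-channel volume as OME-TIFF with voxel size in the metadata."""
    dz, dy, dx = volume.voxel_size
    tifffile.imwrite(
        str(path),
        volume.data.astype(np.float32),
        ome=True,
        metadata={
            "axes": "CZYX",
            "PhysicalSizeZ": dz,
            "PhysicalSizeY": dy,
            "PhysicalSizeX": dx,
            "PhysicalSizeZUnit": "µm",
            "PhysicalSizeYUnit": "µm",
            "PhysicalSizeXUnit": "µm",
            "Channel": {"Name": list(volume.channel_names)},
        },
    )


def read_ome_tiff(path) -> VolumeImage:
    """Read an OME-TIFF written by :func:`write_ome_tiff` (or compatible)."""
    with tifffile.TiffFile(str(path)) as tif:
        series = tif.series[0]
        data = series.asarray()
        axes = series.axes
        vs = [1.0, 1.0, 1.0]
        names = None
        if tif.ome_metadata:
            import re

            xml = tif.ome_metadata
            for i, key in enumerate(("PhysicalSizeZ", "PhysicalSizeY", "PhysicalSizeX")):
                m = re.search(rf'{key}="([0-9.eE+-]+)"', xml)
                if m:
                    vs[i] = float(m.group(1))
            names = tuple(re.findall(r'<Channel[^>]*Name="([^"]+)"', xml)) or None
    # normalize axis order to (C, Z, Y, X)
    if axes == "ZCYX":
        data = np.moveaxis(data, 1, 0)
    elif axes == "ZYX":
        data = data[None]
    elif axes != "CZYX":
        data = data.reshape((-1,) + data.shape[-3:])
    kwargs = {"channel_names": names} if names and len(names) == data.shape[0] else {}
    return VolumeImage(data=data, voxel_size=tuple(vs), **kwargs)


def write_ground_truth(path, gt: GroundTruth) -> None:
    Path(path).write_text(json.dumps(gt.to_json_dict()))


def read_ground_truth(path) -> GroundTruth:
    return GroundTruth.from_json_dict(json.loads(Path(path).read_text()))


def write_swc(path, skeleton: CellSkeleton) -> None:
    """Write a skeleton as SWC (index, type, x, y, z, radius, parent; µm).

    SWC stores x y z; our arrays are (z, y, x), so columns are reversed on
    write.  Node type 1 marks the soma, 3 the processes.
    """
    import networkx as nx

    G = nx.Graph()
    G.add_nodes_from(range(skeleton.n_nodes))
    G.add_edges_from(map(tuple, skeleton.edges))
    order = list(nx.bfs_tree(G, skeleton.soma_index)) if skeleton.n_nodes > 1 else [skeleton.soma_index]
    parent = {skeleton.soma_index: -1}
    for u, v in nx.bfs_edges(G, skeleton.soma_index):
        parent[v] = u
    swc_id = {n: i + 1 for i, n in enumerate(order)}
    lines = []
    for n in order:
        z, y, x = skeleton.nodes[n]
        t = 1 if n == skeleton.soma_index else 3
        par = parent.get(n, -1)
        lines.append(
            f"{swc_id[n]} {t} {x:.4f} {y:.4f} {z:.4f} {skeleton.radii[n]:.4f} "
            f"{swc_id[par] if par != -1 else -1}"
        )
    Path(path).write_text("\n".join(lines) + "\n")


def read_swc(path) -> CellSkeleton:
    nodes, radii, parents, types = [], [], [], []
    for line in Path(path).read_text().splitlines():
        line = line.strip()
        if not line or line.startswith("#"):
            continue
        i, t, x, y, z, r, par = line.split()
        nodes.append((float(z), float(y), float(x)))
        radii.append(float(r))
        types.append(int(t))
        parents.append(int(par))
    edges = [(p - 1, i) for i, p in enumerate(parents) if p != -1]
    soma = types.index(1) if 1 in types else 0
    return CellSkeleton(
        cell_id=0,
        nodes=np.asarray(nodes),
        radii=np.asarray(radii),
        edges=np.asarray(edges, dtype=int).reshape(-1, 2),
        soma_index=soma,
    )
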