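"""Centerline probability maps.

The tracing stage works on a scalar probability map that peaks on the airway
centerline and decays with distance from it.  Given a traced centerline tree,
the map is built by (1) rasterizing the tree onto the voxel grid and (2)
applying a Gaussian kernel to the anisotropy-aware Euclidean distance
transform:

    p(v) = exp(-D(v)^2 / (2 sigma^2))

where D(v) is the distance in mm from the center of voxel v to the nearest
rasterized centerline voxel.  This gives p = 1 exactly on the centerline and
a strict monotone decay with distance, which is the property the tracer's
geodesic speed relies on.
"""

from __future__ import annotations

import numpy as np
from scipy import ndimage

from .grid import ImageGrid, ScalarVolume
from .tree import AirwayTree, resample_edges

__all__ = ["rasterize_centerline", "centerline_probability"]


def rasterize_centerline(tree: AirwayTree, grid: ImageGrid) -> np.ndarray:
    """Voxel indices (N, 3) covered by the centerline.

    Every parent-child edge is sampled at half the minimum spacing or finer
    and each sample mapped to its nearest voxel, so the per-edge voxel chain
    is 26-connected.  Nodes outside the grid are an error.
    """
    if not tree.nodes:
        raise ValueError("tree has no nodes")
    node_idx = grid.round_to_voxel(tree.positions())
    inside = grid.contains_index(node_idx)
    if not np.all(inside):
        bad = np.flatnonzero(~inside)[0]
        nid = sorted(tree.nodes)[bad]
        raise ValueError(
            f"node {nid} at {tree.nodes[nid].position} lies outside the grid "
            f"(dims {grid.dims}, spacing {grid.spacing}, origin {grid.origin})"
        )
    step = 0.5 * min(grid.spacing)
    points, _ = resample_edges(tree, step)
    idx = grid.round_to_voxel(points)
    # interior samples of in-bounds edges stay in bounds (the grid box is convex)
    return np.unique(idx, axis=0)


def centerline_probability(
    tree: AirwayTree, grid: ImageGrid, sigma: float = 1.0
) -> ScalarVolume:
    """Gaussian-of-distance probability map of the centerline (values in [0, 1])."""
    if sigma <= 0:
        raise ValueError(f"sigma must be > 0, got {sigma}")
    idx = rasterize_centerline(tree, grid)
    mask = np.zeros(grid.dims, dtype=bool)
    mask[idx[:, 0], idx[:, 1], idx[:, 2]] = True
    dist_mm = ndimage.distance_transform_edt(~mask, sampling=grid.spacing)
    prob = np.exp(-(dist_mm**2) / (2.0 * sigma**2))
    return ScalarVolume(grid, prob)
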