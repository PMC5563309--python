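"""Spatial selection of streamlines: octree box queries and slab filtering.

A tractogram's points are static and known up front, so the octree is
built once, top-down, instead of by incremental insertion.  A box query
returns every streamline with at least one point inside the (closed)
box; the slab filter keeps the individual segments whose axis interval
overlaps a slice of given thickness, mirroring what a 2D slice view
clips and displays.
"""

from __future__ import annotations

from dataclasses import dataclass

import numpy as np

from .io_formats import Tractogram
from .tracking import SeedBox

__all__ = ["Box", "Octree", "build_octree", "select_by_box", "slab_filter"]

# an axis-aligned selection box is the same object as a seed box
Box = SeedBox

_AXES = {"x": 0, "y": 1, "z": 2}


class _Node:
    __slots__ = ("low", "high", "children", "point_idx")

    def __init__(self, low: np.ndarray, high: np.ndarray):
        self.low = low
        self.high = high
        self.children: list["_Node"] | None = None
        self.point_idx: np.ndarray | None = None   # leaf payload


@dataclass
class Octree:
    """Static octree over every point of a tractogram.

    Leaves hold indices into flat ``points`` / ``streamline_ids`` arrays,
    so that a query touches contiguous numpy slices rather than Python
    point objects.
    """

    root: _Node
    points: np.ndarray           # (n_points, 3)
    streamline_ids: np.ndarray   # (n_points,)
    leaf_capacity: int
    max_depth: int

    @property
    def n_points(self) -> int:
        return len(self.points)


def _build(
    points: np.ndarray,
    idx: np.ndarray,
    low: np.ndarray,
    high: np.ndarray,
    leaf_capacity: int,
    depth_left: int,
) -> _Node:
    node = _Node(low, high)
    if len(idx) <= leaf_capacity or depth_left == 0:
        node.point_idx = idx
        return node
    mid = 0.5 * (low + high)
    pts = points[idx]
    octant = (
        (pts[:, 0] > mid[0]).astype(np.uint8)
        | ((pts[:, 1] > mid[1]).astype(np.uint8) << 1)
        | ((pts[:, 2] > mid[2]).astype(np.uint8) << 2)
    )
    children = []
    for code in range(8):
        sub = idx[octant == code]
        lo = low.copy()
        hi = mid.copy()
        for ax in range(3):
            if code >> ax & 1:
                lo[ax], hi[ax] = mid[ax], high[ax]
        children.append(_build(points, sub, lo, hi, leaf_capacity, depth_left - 1))
    node.children = children
    return node


def build_octree(
    t: Tractogram, leaf_capacity: int = 64, max_depth: int = 8
) -> Octree:
    """Index every streamline point; bounds are the tight bounding box of
    all points, padded by 1e-6 mm."""
    if len(t) == 0:
        raise ValueError("cannot index an empty tractogram")
    points = np.vstack(t.streamlines)
    sids = np.concatenate(
        [np.full(len(s), i, dtype=np.intp) for i, s in enumerate(t.streamlines)]
    )
    pad = 1e-6
    low = points.min(axis=0) - pad
    high = points.max(axis=0) + pad
    root = _build(
        points, np.arange(len(points), dtype=np.intp), low, high,
        leaf_capacity, max_depth,
    )
    return Octree(root, points, sids, leaf_capacity, max_depth)


def select_by_box(tree: Octree, box: Box) -> set[int]:
    """Ids of all streamlines with >= 1 point inside the closed box."""
    blo, bhi = box.low, box.high
    found: set[int] = set()
    stack = [tree.root]
    while stack:
        node = stack.pop()
        if np.any(node.low > bhi) or np.any(node.high < blo):
            continue
        if node.children is not None:
            stack.extend(node.children)
            continue
        idx = node.point_idx
        if idx is None or len(idx) == 0:
            continue
        pts = tree.points[idx]
        inside = np.all((pts >= blo) & (pts <= bhi), axis=1)
        if inside.any():
            found.update(np.unique(tree.streamline_ids[idx[inside]]).tolist())
    return found


def slab_filter(
    t: Tractogram, axis: str, slice_center: float, thickness: float
) -> list[tuple[int, int]]:
    """Segments intersecting a slab perpendicular to ``axis``.

    A segment ``(p_i, p_{i+1})`` is kept iff its coordinate interval on
    the axis overlaps ``[slice_center - thickness/2, slice_center +
    thickness/2]`` — interval overlap, not endpoint membership, so thin
    slabs still catch segments that pierce them.  Returns
    ``(streamline_id, segment_index)`` pairs.
    """
    if thickness <= 0:
        raise ValueError("thickness must be > 0")
    try:
        ax = _AXES[axis]
    except KeyError:
        raise ValueError(f"axis must be one of x/y/z, got {axis!r}") from None
    lo = slice_center - thickness / 2.0
    hi = slice_center + thickness / 2.0
    out: list[tuple[int, int]] = []
    for sid, s in enumerate(t.streamlines):
        a = s[:-1, ax]
        b = s[1:, ax]
        keep = (np.maximum(a, b) >= lo) & (np.minimum(a, b) <= hi)
        out.extend((sid, int(seg)) for seg in np.flatnonzero(keep))
    return out
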