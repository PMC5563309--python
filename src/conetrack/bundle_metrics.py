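"""Voxel density maps and (weighted) Dice overlap between bundles.

Two bundles are compared on a common voxel grid.  Each streamline
increments a voxel's count at most once, whatever the number of its
points falling there; the weighted Dice then scores density-weighted
overlap:

    wDice(A, B) = sum_{v in A&B} (rho_A(v) + rho_B(v))
                  -----------------------------------
                  sum_{v in A} rho_A(v) + sum_{v in B} rho_B(v)

where A, B are the nonzero-voxel supports and rho the visit counts.  It
is symmetric, lives in [0, 1], and reduces to the classical binary Dice
when every nonzero count is 1.
"""

from __future__ import annotations

import warnings
from dataclasses import dataclass

import numpy as np

from .io_formats import ScalarVolume, Tractogram, world_to_voxel

__all__ = ["DensityMap", "density_map", "weighted_dice", "binary_dice"]


@dataclass
class DensityMap:
    """Per-voxel count of distinct streamlines visiting each voxel."""

    counts: np.ndarray
    affine: np.ndarray
    n_out_of_grid: int = 0   # points that fell outside the grid (ignored)

    def __post_init__(self) -> None:
        self.counts = np.asarray(self.counts)
        if self.counts.ndim != 3:
            raise ValueError("density map must be 3D")
        if np.any(self.counts < 0):
            raise ValueError("negative counts")

    def as_scalar_volume(self) -> ScalarVolume:
        return ScalarVolume(self.counts.astype(float), self.affine)


def density_map(
    t: Tractogram,
    shape: tuple[int, int, int],
    affine: np.ndarray | None = None,
) -> DensityMap:
    """Rasterize a tractogram into per-voxel visit counts.

    Voxel membership comes from walking each streamline's points (each
    point is binned to its nearest-center voxel and deduplicated per
    streamline).  This is exact as long as the tracking step does not
    exceed the voxel size; a warning is emitted otherwise since steps
    longer than a voxel can skip voxels entirely.
    """
    if affine is None:
        affine = t.affine
    shape = tuple(int(s) for s in shape)
    if min(shape) < 1:
        raise ValueError("degenerate grid")
    min_voxel = float(np.min(np.linalg.norm(np.asarray(affine)[:3, :3], axis=0)))
    counts = np.zeros(shape, dtype=np.int64)
    out_of_grid = 0
    warned = False
    for s in t.streamlines:
        if len(s) == 0:
            continue
        if not warned and len(s) > 1:
            max_step = float(np.max(np.linalg.norm(np.diff(s, axis=0), axis=1)))
            if max_step > min_voxel * (1 + 1e-9):
                warnings.warn(
                    f"streamline step ({max_step:.3g} mm) exceeds voxel size "
                    f"({min_voxel:.3g} mm); density map may skip voxels",
                    stacklevel=2,
                )
                warned = True
        vox = np.rint(world_to_voxel(s, affine)).astype(np.intp)
        inside = np.all((vox >= 0) & (vox < np.asarray(shape)), axis=1)
        out_of_grid += int(np.count_nonzero(~inside))
        vox = np.unique(vox[inside], axis=0)
        counts[vox[:, 0], vox[:, 1], vox[:, 2]] += 1
    return DensityMap(counts, np.asarray(affine, float), n_out_of_grid=out_of_grid)


def _check_same_grid(a: DensityMap, b: DensityMap) -> None:
    if a.counts.shape != b.counts.shape:
        raise ValueError("density maps live on different grids")
    if not np.allclose(a.affine, b.affine, atol=1e-6):
        raise ValueError("density maps have different affines")


def weighted_dice(a: DensityMap, b: DensityMap) -> float:
    """Density-weighted Dice overlap in [0, 1]."""
    _check_same_grid(a, b)
    ca = a.counts.astype(float)
    cb = b.counts.astype(float)
    overlap = (ca > 0) & (cb > 0)
    denom = ca.sum() + cb.sum()
    if denom == 0:
        warnings.warn("both density maps are empty; Dice defined as 0", stacklevel=2)
        return 0.0
    return float((ca[overlap].sum() + cb[overlap].sum()) / denom)


def binary_dice(a: DensityMap, b: DensityMap) -> float:
    """Classical Dice coefficient on the nonzero-voxel supports."""
    _check_same_grid(a, b)
    sa = a.counts > 0
    sb = b.counts > 0
    denom = int(sa.sum()) + int(sb.sum())
    if denom == 0:
        warnings.warn("both density maps are empty; Dice defined as 0", stacklevel=2)
        return 0.0
    return float(2.0 * np.count_nonzero(sa & sb) / denom)
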