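"""Reading and writing of the on-disk artifacts used throughout the toolkit.

Four kinds of objects live on disk:

* scalar anatomy volumes (T1, FA, GFA, ...)        -> 3D NIfTI-1
* spherical-harmonic fODF volumes                  -> 4D NIfTI-1, last axis
  holds ``(lmax+1)(lmax+2)/2`` real symmetric-SH coefficients
* peak fields, up to 5 directions per voxel, optionally with an
  uncertainty half-angle alpha per peak             -> 4D NIfTI-1, last axis
  15 (``x1 y1 z1 ... x5 y5 z5``) or 20 (``x1 y1 z1 a1 ...``)
* streamline bundles                               -> TrackVis ``.trk``

Coordinate conventions (fixed for the whole package):

* voxel indices are 0-based and a voxel's *center* sits at integer
  continuous-voxel coordinates; "the voxel containing point p" is the
  element-wise *rounding* of ``world_to_voxel(p)``;
* streamline points are world-mm RAS coordinates;
* peak directions are expressed along world-RAS axes;
* alpha is stored in radians on disk (the CLI talks degrees).
"""

from __future__ import annotations

import json
from dataclasses import dataclass, field
from pathlib import Path

import nibabel as nib
import numpy as np
from nibabel.streamlines import TrkFile
from nibabel.streamlines.header import Field
from nibabel.streamlines.tractogram import Tractogram as _NibTractogram

__all__ = [
    "MAX_PEAKS",
    "ScalarVolume",
    "ShVolume",
    "PeakField",
    "Tractogram",
    "world_to_voxel",
    "voxel_to_world",
    "voxel_of",
    "lmax_from_ncoeffs",
    "n_sh_coeffs",
    "read_scalar_volume",
    "write_scalar_volume",
    "read_sh_volume",
    "write_sh_volume",
    "read_peaks",
    "write_peaks",
    "read_tractogram",
    "write_tractogram",
]

#: maximum number of stored directions per voxel
MAX_PEAKS = 5


# ----------------------------------------------------------------------------
# affine helpers
# ----------------------------------------------------------------------------

def _as_affine(affine: np.ndarray) -> np.ndarray:
    a = np.asarray(affine, dtype=float)
    if a.shape != (4, 4):
        raise ValueError(f"affine must be 4x4, got {a.shape}")
    if abs(np.linalg.det(a[:3, :3])) < 1e-12:
        raise ValueError("affine is singular")
    return a


def world_to_voxel(points: np.ndarray, affine: np.ndarray) -> np.ndarray:
    """Map world-mm point(s) to continuous voxel coordinates."""
    a = _as_affine(affine)
    inv = np.linalg.inv(a)
    p = np.asarray(points, dtype=float)
    return p @ inv[:3, :3].T + inv[:3, 3]


def voxel_to_world(indices: np.ndarray, affine: np.ndarray) -> np.ndarray:
    """Map (continuous) voxel coordinates to world mm."""
    a = _as_affine(affine)
    p = np.asarray(indices, dtype=float)
    return p @ a[:3, :3].T + a[:3, 3]


def voxel_of(points: np.ndarray, affine: np.ndarray) -> np.ndarray:
    """Integer voxel index containing each world point (nearest-center)."""
    return np.rint(world_to_voxel(points, affine)).astype(np.intp)


def n_sh_coeffs(lmax: int) -> int:
    """Number of real symmetric (even-degree) SH coefficients up to ``lmax``."""
    if lmax < 0 or lmax % 2:
        raise ValueError(f"lmax must be even and >= 0, got {lmax}")
    return (lmax + 1) * (lmax + 2) // 2


def lmax_from_ncoeffs(n: int) -> int:
    """Inverse of :func:`n_sh_coeffs`; raises if ``n`` is not a valid count."""
    lmax = int(round((-3 + np.sqrt(1 + 8 * n)) / 2))
    if lmax < 0 or lmax % 2 or n_sh_coeffs(lmax) != n:
        raise ValueError(f"{n} is not a symmetric-SH coefficient count")
    return lmax


# ----------------------------------------------------------------------------
# in-memory containers
# ----------------------------------------------------------------------------

@dataclass
class ScalarVolume:
    """A 3D scalar map (FA, GFA, T1, ...) plus its voxel-to-world affine."""

    data: np.ndarray
    affine: np.ndarray

    def __post_init__(self) -> None:
        self.data = np.asarray(self.data, dtype=float)
        self.affine = _as_affine(self.affine)
        if self.data.ndim != 3:
            raise ValueError(f"scalar volume must be 3D, got {self.data.ndim}D")
        if min(self.data.shape) < 1:
            raise ValueError("empty volume")
        if not np.all(np.isfinite(self.data)):
            raise ValueError("scalar volume contains non-finite values")


@dataclass
class ShVolume:
    """A 4D volume of real symmetric spherical-harmonic coefficients."""

    data: np.ndarray
    lmax: int
    affine: np.ndarray

    def __post_init__(self) -> None:
        self.data = np.asarray(self.data, dtype=float)
        self.affine = _as_affine(self.affine)
        if self.data.ndim != 4:
            raise ValueError("SH volume must be 4D")
        if self.data.shape[-1] != n_sh_coeffs(self.lmax):
            raise ValueError(
                f"last axis {self.data.shape[-1]} does not match lmax={self.lmax}"
            )


@dataclass
class PeakField:
    """Per-voxel fODF peak directions, optionally with uncertainty angles.

    ``data`` has shape ``(X, Y, Z, 15)`` (directions only) or
    ``(X, Y, Z, 20)`` (direction triplets interleaved with alpha, in
    radians).  Unused slots are all-zero; a zero direction means "no peak".
    """

    data: np.ndarray
    affine: np.ndarray
    has_alpha: bool

    def __post_init__(self) -> None:
        self.data = np.asarray(self.data, dtype=float)
        self.affine = _as_affine(self.affine)
        if self.data.ndim != 4:
            raise ValueError("peak field must be 4D")
        expected = MAX_PEAKS * (4 if self.has_alpha else 3)
        if self.data.shape[-1] != expected:
            raise ValueError(
                f"last axis {self.data.shape[-1]} inconsistent with "
                f"has_alpha={self.has_alpha}"
            )

    @classmethod
    def from_arrays(
        cls,
        directions: np.ndarray,
        alphas: np.ndarray | None,
        affine: np.ndarray,
    ) -> "PeakField":
        """Build from ``(X,Y,Z,5,3)`` directions and optional ``(X,Y,Z,5)`` alphas."""
        directions = np.asarray(directions, dtype=float)
        if directions.ndim != 5 or directions.shape[3:] != (MAX_PEAKS, 3):
            raise ValueError("directions must have shape (X, Y, Z, 5, 3)")
        shape = directions.shape[:3]
        if alphas is None:
            data = directions.reshape(shape + (MAX_PEAKS * 3,))
            return cls(data, affine, has_alpha=False)
        alphas = np.asarray(alphas, dtype=float)
        if alphas.shape != shape + (MAX_PEAKS,):
            raise ValueError("alphas must have shape (X, Y, Z, 5)")
        data = np.concatenate([directions, alphas[..., None]], axis=-1)
        return cls(data.reshape(shape + (MAX_PEAKS * 4,)), affine, has_alpha=True)

    @property
    def grid_shape(self) -> tuple[int, int, int]:
        return self.data.shape[:3]

    def directions(self) -> np.ndarray:
        """View of shape ``(X, Y, Z, 5, 3)``."""
        w = 4 if self.has_alpha else 3
        return self.data.reshape(self.grid_shape + (MAX_PEAKS, w))[..., :3]

    def alphas(self) -> np.ndarray:
        """Array of shape ``(X, Y, Z, 5)``; zeros when alpha is absent."""
        if not self.has_alpha:
            return np.zeros(self.grid_shape + (MAX_PEAKS,))
        return self.data.reshape(self.grid_shape + (MAX_PEAKS, 4))[..., 3]

    def peak_counts(self) -> np.ndarray:
        """Number of nonzero peaks per voxel."""
        norms = np.linalg.norm(self.directions(), axis=-1)
        return (norms > 0).sum(axis=-1)

    def peaks_at(self, i: int, j: int, k: int) -> tuple[np.ndarray, np.ndarray]:
        """Nonzero (directions, alphas) at one voxel."""
        dirs = self.directions()[i, j, k]
        keep = np.linalg.norm(dirs, axis=-1) > 0
        return dirs[keep], self.alphas()[i, j, k][keep]


@dataclass
class Tractogram:
    """A bundle of streamlines in world-mm plus its reference grid.

    ``provenance`` is a free-text record of the parameters that produced
    the bundle; it survives a save/load round-trip.
    """

    streamlines: list[np.ndarray]
    affine: np.ndarray
    provenance: str = ""
    grid_shape: tuple[int, int, int] = (1, 1, 1)

    def __post_init__(self) -> None:
        self.affine = _as_affine(self.affine)
        self.streamlines = [np.asarray(s, dtype=float) for s in self.streamlines]
        for s in self.streamlines:
            if s.ndim != 2 or s.shape[1] != 3:
                raise ValueError("each streamline must be an (N, 3) array")
            if not np.all(np.isfinite(s)):
                raise ValueError("streamline contains non-finite points")

    def __len__(self) -> int:
        return len(self.streamlines)


# ----------------------------------------------------------------------------
# NIfTI readers / writers
# ----------------------------------------------------------------------------

def read_scalar_volume(path: str | Path) -> ScalarVolume:
    """Load a 3D scalar NIfTI volume.

    Raises ``ValueError`` on 4D input — use :func:`read_sh_volume` or
    :func:`read_peaks` for those.
    """
    img = nib.load(str(path))
    data = np.asarray(img.dataobj, dtype=float)
    if data.ndim == 4 and data.shape[-1] == 1:
        data = data[..., 0]
    if data.ndim != 3:
        raise ValueError(
            f"{path}: expected a 3D volume, got {data.ndim}D "
            "(SH and peak volumes have dedicated readers)"
        )
    return ScalarVolume(data, img.affine)


def write_scalar_volume(vol: ScalarVolume, path: str | Path) -> None:
    nib.save(nib.Nifti1Image(vol.data, vol.affine), str(path))


def read_sh_volume(path: str | Path) -> ShVolume:
    """Load a 4D symmetric-SH coefficient volume; lmax is inferred."""
    img = nib.load(str(path))
    data = np.asarray(img.dataobj, dtype=float)
    if data.ndim != 4:
        raise ValueError(f"{path}: expected a 4D SH volume, got {data.ndim}D")
    lmax = lmax_from_ncoeffs(data.shape[-1])
    return ShVolume(data, lmax, img.affine)


def write_sh_volume(vol: ShVolume, path: str | Path) -> None:
    nib.save(nib.Nifti1Image(vol.data, vol.affine), str(path))


def read_peaks(path: str | Path) -> PeakField:
    """Load a peaks NIfTI; last axis must be 15 (no alpha) or 20 (with alpha).

    Directions whose norm deviates from 1 by more than 1e-3 are
    renormalized (exact zeros, i.e. empty slots, are preserved); peak
    files in the wild often carry a magnitude on each vector while only
    the direction matters for tracking.
    """
    img = nib.load(str(path))
    data = np.asarray(img.dataobj, dtype=float)
    if data.ndim != 4 or data.shape[-1] not in (3 * MAX_PEAKS, 4 * MAX_PEAKS):
        raise ValueError(
            f"{path}: peaks volume must be 4D with last axis 15 or 20, "
            f"got shape {data.shape}"
        )
    has_alpha = data.shape[-1] == 4 * MAX_PEAKS
    field = PeakField(data, img.affine, has_alpha=has_alpha)
    dirs = field.directions()
    norms = np.linalg.norm(dirs, axis=-1)
    bad = (norms > 0) & (np.abs(norms - 1.0) > 1e-3)
    if np.any(bad):
        dirs[bad] /= norms[bad][..., None]
    return field


def write_peaks(field: PeakField, path: str | Path) -> None:
    nib.save(nib.Nifti1Image(field.data, field.affine), str(path))


# ----------------------------------------------------------------------------
# TrackVis
# ----------------------------------------------------------------------------

def _provenance_sidecar(path: str | Path) -> Path:
    return Path(str(path) + ".json")


def write_tractogram(t: Tractogram, path: str | Path) -> None:
    """Save to TrackVis ``.trk`` (points in world mm / RASMM).

    The free-text provenance record is written to a ``.trk.json`` sidecar
    (the fixed-size TrackVis header has no room for it).
    """
    for s in t.streamlines:
        if len(s) < 2:
            raise ValueError("cannot write a streamline with fewer than 2 points")
    voxel_sizes = np.linalg.norm(t.affine[:3, :3], axis=0)
    header = {
        Field.VOXEL_TO_RASMM: t.affine.astype(np.float32),
        Field.VOXEL_SIZES: voxel_sizes.astype(np.float32),
        Field.DIMENSIONS: np.asarray(t.grid_shape, dtype=np.int16),
        Field.VOXEL_ORDER: b"RAS",
    }
    nib_t = _NibTractogram(t.streamlines, affine_to_rasmm=np.eye(4))
    TrkFile(nib_t, header=header).save(str(path))
    meta = {"provenance": t.provenance}
    _provenance_sidecar(path).write_text(json.dumps(meta, indent=1))


def read_tractogram(path: str | Path) -> Tractogram:
    """Load a TrackVis ``.trk`` bundle; points come back in world mm."""
    trk = TrkFile.load(str(path), lazy_load=False)
    streamlines = [np.asarray(s, dtype=float) for s in trk.tractogram.streamlines]
    affine = np.asarray(trk.header[Field.VOXEL_TO_RASMM], dtype=float)
    shape = tuple(int(d) for d in trk.header[Field.DIMENSIONS])
    provenance = ""
    sidecar = _provenance_sidecar(path)
    if sidecar.exists():
        provenance = json.loads(sidecar.read_text()).get("provenance", "")
    return Tractogram(streamlines, affine, provenance=provenance, grid_shape=shape)
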