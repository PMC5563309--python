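"""Spherical-harmonic fODFs on a tessellated sphere: evaluation, peak
finding, and FWHM-fraction uncertainty angles.

The fiber ODF in each voxel is an antipodally symmetric spherical
function represented by real, even-degree spherical harmonics.  To turn
it into tracking directions it is sampled on a symmetric tessellated
sphere; local maxima over the mesh adjacency are the peaks, and each
peak's uncertainty half-angle alpha is the angular distance at which the
function first falls below a chosen fraction ``k`` of the peak value
(``k = 0.5`` gives the literal FWHM half-width).
"""

from __future__ import annotations

import heapq
from dataclasses import dataclass, field

import numpy as np
from scipy.special import sph_harm_y

from .io_formats import (
    MAX_PEAKS,
    PeakField,
    ScalarVolume,
    ShVolume,
    n_sh_coeffs,
)

__all__ = [
    "SphereMesh",
    "SphericalFunction",
    "PeakExtractionParams",
    "make_icosphere",
    "sh_basis_matrix",
    "evaluate_fodf",
    "sf_to_sh",
    "find_peaks_on_sphere",
    "uncertainty_angle",
    "peaks_from_sh_volume",
]


# ----------------------------------------------------------------------------
# mesh
# ----------------------------------------------------------------------------

@dataclass
class SphereMesh:
    """Tessellated unit sphere with adjacency and antipodal pairing."""

    vertices: np.ndarray            # (n, 3), unit norm
    faces: np.ndarray               # (m, 3) int
    neighbors: list[np.ndarray]     # per-vertex neighbor indices
    antipode: np.ndarray            # (n,) int, index of -v for each v
    max_edge_angle: float           # radians, longest mesh edge as an arc

    # padded neighbor table for vectorized local-max tests; padding repeats
    # the first neighbor so a strict '>' comparison stays meaningful
    _nbr_pad: np.ndarray = field(repr=False, default=None)

    def __post_init__(self) -> None:
        if self._nbr_pad is None:
            deg = max(len(nb) for nb in self.neighbors)
            pad = np.empty((len(self.vertices), deg), dtype=np.intp)
            for i, nb in enumerate(self.neighbors):
                pad[i, : len(nb)] = nb
                pad[i, len(nb):] = nb[0]
            self._nbr_pad = pad

    @property
    def n_vertices(self) -> int:
        return len(self.vertices)


_ICO_T = (1.0 + np.sqrt(5.0)) / 2.0
_ICO_VERTS = np.array(
    [
        (-1, _ICO_T, 0), (1, _ICO_T, 0), (-1, -_ICO_T, 0), (1, -_ICO_T, 0),
        (0, -1, _ICO_T), (0, 1, _ICO_T), (0, -1, -_ICO_T), (0, 1, -_ICO_T),
        (_ICO_T, 0, -1), (_ICO_T, 0, 1), (-_ICO_T, 0, -1), (-_ICO_T, 0, 1),
    ],
    dtype=float,
)
_ICO_FACES = np.array(
    [
        (0, 11, 5), (0, 5, 1), (0, 1, 7), (0, 7, 10), (0, 10, 11),
        (1, 5, 9), (5, 11, 4), (11, 10, 2), (10, 7, 6), (7, 1, 8),
        (3, 9, 4), (3, 4, 2), (3, 2, 6), (3, 6, 8), (3, 8, 9),
        (4, 9, 5), (2, 4, 11), (6, 2, 10), (8, 6, 7), (9, 8, 1),
    ],
    dtype=np.intp,
)


def make_icosphere(subdivisions: int) -> SphereMesh:
    """Subdivided icosahedron with ``10 * 4**s + 2`` vertices.

    The icosahedron's vertex and face sets are centrally symmetric, and
    midpoint subdivision preserves that, so every vertex has its exact
    antipode in the mesh.
    """
    if subdivisions < 0:
        raise ValueError("subdivisions must be >= 0")
    verts = _ICO_VERTS / np.linalg.norm(_ICO_VERTS, axis=1, keepdims=True)
    verts = [tuple(v) for v in verts]
    faces = [tuple(f) for f in _ICO_FACES]

    for _ in range(subdivisions):
        midpoint_cache: dict[tuple[int, int], int] = {}

        def midpoint(i: int, j: int) -> int:
            key = (i, j) if i < j else (j, i)
            idx = midpoint_cache.get(key)
            if idx is None:
                m = np.asarray(verts[i]) + np.asarray(verts[j])
                m /= np.linalg.norm(m)
                idx = len(verts)
                verts.append(tuple(m))
                midpoint_cache[key] = idx
            return idx

        new_faces = []
        for a, b, c in faces:
            ab, bc, ca = midpoint(a, b), midpoint(b, c), midpoint(c, a)
            new_faces += [(a, ab, ca), (b, bc, ab), (c, ca, bc), (ab, bc, ca)]
        faces = new_faces

    vertices = np.asarray(verts, dtype=float)
    vertices /= np.linalg.norm(vertices, axis=1, keepdims=True)
    faces = np.asarray(faces, dtype=np.intp)

    n = len(vertices)
    nbr_sets: list[set[int]] = [set() for _ in range(n)]
    for a, b, c in faces:
        nbr_sets[a].update((b, c))
        nbr_sets[b].update((a, c))
        nbr_sets[c].update((a, b))
    neighbors = [np.array(sorted(s), dtype=np.intp) for s in nbr_sets]

    # antipodal pairing by nearest vertex to -v
    dots = vertices @ (-vertices.T)
    antipode = np.argmax(dots, axis=1).astype(np.intp)
    if not np.allclose(vertices[antipode], -vertices, atol=1e-6):
        raise RuntimeError("mesh lost its antipodal symmetry")

    edge_cos = 1.0
    for a, b, c in faces:
        for i, j in ((a, b), (b, c), (c, a)):
            edge_cos = min(edge_cos, float(vertices[i] @ vertices[j]))
    max_edge_angle = float(np.arccos(np.clip(edge_cos, -1.0, 1.0)))

    return SphereMesh(vertices, faces, neighbors, antipode, max_edge_angle)


# ----------------------------------------------------------------------------
# SH basis
# ----------------------------------------------------------------------------

def sh_basis_matrix(mesh: SphereMesh | np.ndarray, lmax: int) -> np.ndarray:
    """Real symmetric SH design matrix, one row per mesh vertex.

    Even degrees only (fODFs are antipodally symmetric); column order is
    ``(l, m)`` for ``l = 0, 2, ..., lmax`` and ``m = -l..l``, with
    ``m < 0`` mapping to ``sqrt(2) Im(Y_l^{|m|})``, ``m = 0`` to the real
    ``Y_l^0`` and ``m > 0`` to ``sqrt(2) Re(Y_l^m)``.  Rows of antipodal
    vertices are identical because all degrees are even.
    """
    if lmax < 0 or lmax % 2:
        raise ValueError(f"lmax must be even and >= 0, got {lmax}")
    verts = mesh.vertices if isinstance(mesh, SphereMesh) else np.asarray(mesh, float)
    theta = np.arccos(np.clip(verts[:, 2], -1.0, 1.0))     # polar
    phi = np.arctan2(verts[:, 1], verts[:, 0])             # azimuth
    cols = []
    for l in range(0, lmax + 1, 2):
        for m in range(-l, l + 1):
            y = sph_harm_y(l, abs(m), theta, phi)
            if m < 0:
                cols.append(np.sqrt(2.0) * y.imag)
            elif m == 0:
                cols.append(y.real)
            else:
                cols.append(np.sqrt(2.0) * y.real)
    return np.column_stack(cols)


@dataclass
class SphericalFunction:
    """Values of a spherical function at each mesh vertex."""

    values: np.ndarray
    mesh: SphereMesh

    def __post_init__(self) -> None:
        self.values = np.asarray(self.values, dtype=float)
        if self.values.shape != (self.mesh.n_vertices,):
            raise ValueError("one value per mesh vertex required")
        if not np.all(np.isfinite(self.values)):
            raise ValueError("non-finite spherical function")


def evaluate_fodf(
    coeffs: np.ndarray, mesh: SphereMesh, basis: np.ndarray | None = None
) -> SphericalFunction:
    """Evaluate SH coefficients on the mesh (``values = B @ coeffs``)."""
    coeffs = np.asarray(coeffs, dtype=float)
    if basis is None:
        lmax = _lmax_of(coeffs.shape[-1])
        basis = sh_basis_matrix(mesh, lmax)
    if coeffs.shape[-1] != basis.shape[1]:
        raise ValueError("coefficient length does not match basis")
    return SphericalFunction(basis @ coeffs, mesh)


def _lmax_of(ncoef: int) -> int:
    from .io_formats import lmax_from_ncoeffs

    return lmax_from_ncoeffs(ncoef)


def sf_to_sh(
    f: SphericalFunction | np.ndarray,
    mesh: SphereMesh | None = None,
    lmax: int = 8,
    basis: np.ndarray | None = None,
) -> np.ndarray:
    """Least-squares SH fit of a sampled spherical function.

    Exact (to round-off) for functions band-limited at ``lmax``; used by
    the phantom generator to author fODF volumes.
    """
    if isinstance(f, SphericalFunction):
        values, mesh = f.values, f.mesh
    else:
        values = np.asarray(f, dtype=float)
        if mesh is None:
            raise ValueError("mesh required when passing raw values")
    if basis is None:
        basis = sh_basis_matrix(mesh, lmax)
    if basis.shape[0] < basis.shape[1]:
        raise ValueError(
            f"underdetermined fit: {basis.shape[0]} vertices for "
            f"{basis.shape[1]} coefficients"
        )
    coeffs, *_ = np.linalg.lstsq(basis, values, rcond=None)
    return coeffs


# ----------------------------------------------------------------------------
# peak finding
# ----------------------------------------------------------------------------

@dataclass
class PeakExtractionParams:
    """Knobs of per-voxel peak extraction.

    ``fwhm_fraction`` is the fraction of the peak value at which the
    uncertainty angle is measured (1.0 degenerates to alpha = 0 on any
    strictly peaked function's nearest neighbor... practically the
    deterministic limit; 0.35 is the conventional permissive setting).
    """

    relative_threshold: float = 0.5
    min_separation_angle: float = 25.0   # degrees
    max_peaks: int = MAX_PEAKS
    fwhm_fraction: float = 0.35

    def __post_init__(self) -> None:
        if not 0.0 < self.relative_threshold < 1.0:
            raise ValueError("relative_threshold must be in (0, 1)")
        if not 0.0 < self.fwhm_fraction <= 1.0:
            raise ValueError("fwhm_fraction must be in (0, 1]")
        if not 1 <= self.max_peaks <= MAX_PEAKS:
            raise ValueError(f"max_peaks must be in [1, {MAX_PEAKS}]")


def _local_maxima(values: np.ndarray, mesh: SphereMesh) -> np.ndarray:
    """Indices of strict local maxima over the mesh adjacency."""
    nbr_max = values[mesh._nbr_pad].max(axis=1)
    return np.flatnonzero(values > nbr_max)


def find_peaks_on_sphere(
    f: SphericalFunction, params: PeakExtractionParams | None = None
) -> list[tuple[np.ndarray, float, int]]:
    """Peaks of a spherical function: ``(direction, value, vertex_index)``.

    Strict local maxima only (a flat/isotropic function yields no peaks),
    deduplicated over antipodes, thresholded at
    ``relative_threshold * max``, sorted by descending value, and greedily
    pruned so that surviving peaks are at least ``min_separation_angle``
    apart (axial angle, i.e. sign-insensitive).
    """
    if params is None:
        params = PeakExtractionParams()
    values, mesh = f.values, f.mesh
    vmax = float(values.max())
    if vmax <= 0.0:
        return []
    cand = _local_maxima(values, mesh)
    # keep one representative of each antipodal pair
    cand = np.unique(np.minimum(cand, mesh.antipode[cand]))
    cand = cand[values[cand] >= params.relative_threshold * vmax]
    order = np.argsort(values[cand], kind="stable")[::-1]
    cand = cand[order]

    min_sep_cos = np.cos(np.deg2rad(params.min_separation_angle))
    accepted: list[int] = []
    for idx in cand:
        v = mesh.vertices[idx]
        ok = all(
            abs(float(v @ mesh.vertices[a])) < min_sep_cos for a in accepted
        )
        if ok:
            accepted.append(int(idx))
        if len(accepted) == params.max_peaks:
            break
    return [(mesh.vertices[i].copy(), float(values[i]), i) for i in accepted]


def uncertainty_angle(
    f: SphericalFunction, peak_vertex: int, k: float
) -> float:
    """Uncertainty half-angle alpha (radians) of one peak.

    Starting from the peak vertex, mesh vertices are visited in order of
    increasing angular distance from the peak (best-first over the
    adjacency); alpha is the angular distance of the first vertex whose
    value drops below ``k`` times the peak value.  If nothing within 90
    degrees drops below the fraction, alpha is capped at pi/2 (the cone
    degrades to a hemisphere).
    """
    if not 0.0 < k <= 1.0:
        raise ValueError("fraction k must be in (0, 1]")
    values, mesh = f.values, f.mesh
    pv = float(values[peak_vertex])
    threshold = k * pv
    pdir = mesh.vertices[peak_vertex]
    cap = np.pi / 2

    visited = {int(peak_vertex)}
    heap: list[tuple[float, int]] = []
    for nb in mesh.neighbors[peak_vertex]:
        ang = float(np.arccos(np.clip(pdir @ mesh.vertices[nb], -1.0, 1.0)))
        heapq.heappush(heap, (ang, int(nb)))
        visited.add(int(nb))
    while heap:
        ang, idx = heapq.heappop(heap)
        if ang > cap:
            return cap
        if values[idx] < threshold:
            return ang
        for nb in mesh.neighbors[idx]:
            nb = int(nb)
            if nb not in visited:
                visited.add(nb)
                a = float(np.arccos(np.clip(pdir @ mesh.vertices[nb], -1.0, 1.0)))
                heapq.heappush(heap, (a, nb))
    return cap


# ----------------------------------------------------------------------------
# whole-volume extraction
# ----------------------------------------------------------------------------

def peaks_from_sh_volume(
    vol: ShVolume,
    mesh: SphereMesh,
    params: PeakExtractionParams | None = None,
    mask: ScalarVolume | None = None,
    mask_threshold: float = 0.0,
) -> PeakField:
    """Extract up-to-5 peaks plus alpha per voxel from an SH fODF volume.

    Voxels outside the mask (value < ``mask_threshold``) come out
    all-zero.  The returned field always carries alpha
    (``has_alpha=True``), measured at ``params.fwhm_fraction``.
    """
    if params is None:
        params = PeakExtractionParams()
    shape = vol.data.shape[:3]
    if mask is not None and mask.data.shape != shape:
        raise ValueError(
            f"mask shape {mask.data.shape} does not match SH volume {shape}"
        )
    basis = sh_basis_matrix(mesh, vol.lmax)
    dirs = np.zeros(shape + (MAX_PEAKS, 3))
    alphas = np.zeros(shape + (MAX_PEAKS,))

    if mask is not None:
        voxels = np.argwhere(mask.data >= mask_threshold)
    else:
        voxels = np.argwhere(np.ones(shape, dtype=bool))
    if len(voxels) == 0:
        return PeakField.from_arrays(dirs, alphas, vol.affine)

    coeffs = vol.data[voxels[:, 0], voxels[:, 1], voxels[:, 2]]
    chunk = 512
    for start in range(0, len(voxels), chunk):
        block = coeffs[start:start + chunk] @ basis.T
        for row, (i, j, k) in zip(block, voxels[start:start + chunk]):
            sf = SphericalFunction(row, mesh)
            found = find_peaks_on_sphere(sf, params)
            for slot, (d, _, vidx) in enumerate(found):
                dirs[i, j, k, slot] = d
                alphas[i, j, k, slot] = uncertainty_angle(
                    sf, vidx, params.fwhm_fraction
                )
    return PeakField.from_arrays(dirs, alphas, vol.affine)
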