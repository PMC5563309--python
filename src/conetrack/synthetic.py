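"""Synthetic tractography phantoms with analytic ground truth.

Each phantom is a tube-shaped fiber bundle (straight, curved, or two
straight bundles crossing) embedded in a cubic volume: it provides the
same artifacts a real diffusion dataset would — an FA-like scalar map, a
peak field with uncertainty angles, an SH fODF volume, and ground-truth
centerline streamlines — so the whole pipeline is testable end to end
without any acquisition.

The single-fiber kernel is Gaussian in angle,
``K(theta) = exp(-theta^2 / (2 sigma^2))`` with ``theta`` the (axial)
angle to the local fiber tangent.  That choice makes the
fraction-crossing angle analytic:

    alpha(k) = sigma * sqrt(2 ln(1/k))

which is the closed-form oracle used to validate the mesh-traversal
uncertainty extraction (``k = 0.5`` recovers the literal FWHM
half-width ``1.1774 sigma``).  Crossing voxels hold the *unnormalized
sum* of the two arms' kernels, so their peak values differ from the
single-fiber case on purpose — that exercises the relative threshold of
peak extraction.
"""

from __future__ import annotations

from dataclasses import dataclass

import numpy as np

from .io_formats import MAX_PEAKS, PeakField, ScalarVolume, ShVolume, n_sh_coeffs
from .sphere_fodf import SphereMesh, make_icosphere, sh_basis_matrix

__all__ = ["PhantomSpec", "Phantom", "make_phantom", "analytic_alpha"]


def analytic_alpha(sigma: float, k: float) -> float:
    """Angle (same unit as ``sigma``) at which a Gaussian angular profile
    of width ``sigma`` falls to fraction ``k`` of its maximum.

    ``k = 1`` returns 0 (the degenerate, deterministic cone).
    """
    if not 0.0 < k <= 1.0:
        raise ValueError("fraction k must be in (0, 1]")
    if k == 1.0:
        return 0.0
    return float(sigma * np.sqrt(2.0 * np.log(1.0 / k)))


@dataclass
class PhantomSpec:
    """Phantom configuration.

    Defaults mirror a desk-scale analog of a typical single-subject
    grid: 40^3 voxels at 1.72 mm isotropic, white-matter-like FA 0.8
    inside the bundle over a 0.05 background, a 20-degree single-fiber
    kernel, and uncertainty angles measured at the 35% fraction.
    """

    shape: tuple[int, int, int] = (40, 40, 40)
    voxel_size: float = 1.72            # mm, isotropic
    geometry: str = "straight"          # straight | curved | crossing
    fa_inside: float = 0.8
    fa_outside: float = 0.05
    kernel_sigma: float = 20.0          # degrees
    crossing_angle: float = 90.0        # degrees, between the two arms
    curve_radius: float = 20.0          # mm
    half_width: float = 8.6             # mm, bundle tube half-width
    fwhm_fraction: float = 0.35         # k at which stored alphas are computed
    lmax: int = 8
    rng_seed: int = 0

    def __post_init__(self) -> None:
        if self.geometry not in ("straight", "curved", "crossing"):
            raise ValueError(f"unknown geometry {self.geometry!r}")
        if not self.fa_inside > self.fa_outside:
            raise ValueError("fa_inside must exceed fa_outside")
        if self.kernel_sigma <= 0:
            raise ValueError("kernel_sigma must be > 0")
        if self.half_width <= 0 or self.voxel_size <= 0:
            raise ValueError("half_width and voxel_size must be > 0")
        if not 0.0 < self.fwhm_fraction <= 1.0:
            raise ValueError("fwhm_fraction must be in (0, 1]")


@dataclass
class Phantom:
    """Everything a phantom provides; ``truth`` are centerline polylines."""

    scalar: ScalarVolume
    peaks: PeakField
    sh: ShVolume
    truth: list[np.ndarray]
    arm_masks: list[np.ndarray]
    spec: PhantomSpec

    @property
    def mask(self) -> np.ndarray:
        m = np.zeros(self.scalar.data.shape, dtype=bool)
        for am in self.arm_masks:
            m |= am
        return m

    def center(self) -> np.ndarray:
        return (np.asarray(self.spec.shape, float) - 1) / 2 * self.spec.voxel_size

    def seed_center(self) -> np.ndarray:
        """Midpoint of the first ground-truth centerline — a point that is
        guaranteed to lie on the bundle, suitable as a seed-box center."""
        line = self.truth[0]
        return line[len(line) // 2].copy()


def _voxel_centers(shape: tuple[int, int, int], voxel: float) -> np.ndarray:
    grids = np.meshgrid(*[np.arange(s) * voxel for s in shape], indexing="ij")
    return np.stack(grids, axis=-1)   # (X, Y, Z, 3) world mm


def _kernel(dirs: np.ndarray, verts: np.ndarray, sigma_rad: float) -> np.ndarray:
    """Axially symmetric Gaussian angular kernel, (n_vox, n_verts)."""
    cos = np.clip(np.abs(dirs @ verts.T), 0.0, 1.0)
    theta = np.arccos(cos)
    return np.exp(-(theta ** 2) / (2.0 * sigma_rad ** 2))


def _polyline(points_fn, t0: float, t1: float, step: float = 0.5) -> np.ndarray:
    n = max(2, int(np.floor((t1 - t0) / step)) + 1)
    ts = t0 + np.arange(n) * step
    return np.asarray([points_fn(t) for t in ts])


def make_phantom(spec: PhantomSpec, mesh: SphereMesh | None = None) -> Phantom:
    """Build the phantom described by ``spec``.

    Raises ``ValueError`` when the geometry does not fit the volume
    (e.g. the curved tube would leave the grid).
    """
    if mesh is None:
        mesh = make_icosphere(3)
    if mesh.n_vertices < n_sh_coeffs(spec.lmax):
        raise ValueError("mesh too coarse for the requested lmax")
    shape = tuple(int(s) for s in spec.shape)
    vs = spec.voxel_size
    affine = np.diag([vs, vs, vs, 1.0])
    centers = _voxel_centers(shape, vs)
    c = (np.asarray(shape, float) - 1) / 2 * vs
    hw = spec.half_width
    lo_bound = -vs / 2
    hi_bound = (np.asarray(shape, float) - 0.5) * vs
    extent_x = (shape[0] - 1) * vs

    # each arm: (mask bool grid, per-voxel tangents (n_in, 3), truth polyline)
    arms: list[tuple[np.ndarray, np.ndarray, np.ndarray]] = []

    if spec.geometry in ("straight", "crossing"):
        u1 = np.array([1.0, 0.0, 0.0])
        rel = centers - c
        d1 = rel - (rel @ u1)[..., None] * u1
        m1 = np.linalg.norm(d1, axis=-1) <= hw
        truth1 = _polyline(lambda t: c + (t - c[0]) * u1, 0.0, extent_x)
        arms.append((m1, np.tile(u1, (int(m1.sum()), 1)), truth1))
        if spec.geometry == "crossing":
            g = np.deg2rad(spec.crossing_angle)
            u2 = np.array([np.cos(g), np.sin(g), 0.0])
            d2 = rel - (rel @ u2)[..., None] * u2
            m2 = np.linalg.norm(d2, axis=-1) <= hw
            # clip the second centerline to the volume
            ts = []
            for ax in range(3):
                if abs(u2[ax]) > 1e-12:
                    ts.append(sorted(
                        [(lo_bound - c[ax]) / u2[ax], (hi_bound[ax] - c[ax]) / u2[ax]]
                    ))
            t0 = max(t[0] for t in ts)
            t1 = min(t[1] for t in ts)
            truth2 = _polyline(lambda t: c + t * u2, t0, t1)
            arms.append((m2, np.tile(u2, (int(m2.sum()), 1)), truth2))
    else:  # curved: circular arc of radius R in the xy plane
        R = spec.curve_radius
        arc_center = c + np.array([0.0, -R / 2.0, 0.0])
        half_span = np.pi / 4   # arc spans +/- 45 degrees about +y
        phis = np.linspace(-half_span, half_span, 256)
        arc_pts = arc_center[None, :] + R * np.stack(
            [np.sin(phis), np.cos(phis), np.zeros_like(phis)], axis=-1
        )
        if np.any(arc_pts - hw < lo_bound) or np.any(arc_pts + hw > hi_bound):
            raise ValueError("curved bundle does not fit inside the volume")
        rel = centers - arc_center
        r_xy = np.hypot(rel[..., 0], rel[..., 1])
        phi = np.arctan2(rel[..., 0], rel[..., 1])   # 0 at +y
        in_span = np.abs(phi) <= half_span
        dist_arc = np.hypot(r_xy - R, rel[..., 2])
        end_a = arc_center + R * np.array([np.sin(-half_span), np.cos(half_span), 0.0])
        end_b = arc_center + R * np.array([np.sin(half_span), np.cos(half_span), 0.0])
        dist_ends = np.minimum(
            np.linalg.norm(centers - end_a, axis=-1),
            np.linalg.norm(centers - end_b, axis=-1),
        )
        dist = np.where(in_span, dist_arc, dist_ends)
        m1 = dist <= hw
        phin = phi[m1]
        tangents = np.stack(
            [np.cos(phin), -np.sin(phin), np.zeros_like(phin)], axis=-1
        )
        truth1 = _polyline(
            lambda t: arc_center
            + R * np.array([np.sin(t / R), np.cos(t / R), 0.0]),
            -half_span * R,
            half_span * R,
        )
        arms.append((m1, tangents, truth1))

    # scalar map
    union = np.zeros(shape, dtype=bool)
    for m, _, _ in arms:
        union |= m
    fa = np.where(union, spec.fa_inside, spec.fa_outside)
    scalar = ScalarVolume(fa, affine)

    # peaks with analytic alpha
    sigma_rad = np.deg2rad(spec.kernel_sigma)
    alpha = min(
        np.deg2rad(analytic_alpha(spec.kernel_sigma, spec.fwhm_fraction)),
        np.pi / 2,
    )
    dirs5 = np.zeros(shape + (MAX_PEAKS, 3))
    alphas5 = np.zeros(shape + (MAX_PEAKS,))
    slot = np.zeros(shape, dtype=np.intp)
    for m, tangents, _ in arms:
        ii = np.nonzero(m)
        s = slot[ii]
        dirs5[ii[0], ii[1], ii[2], s] = tangents
        alphas5[ii[0], ii[1], ii[2], s] = alpha
        slot[ii] += 1
    peaks = PeakField.from_arrays(dirs5, alphas5, affine)

    # SH fODF volume (sum of per-arm kernels; SH fit is linear so the
    # coefficients of the sum are the sum of per-arm fits)
    basis = sh_basis_matrix(mesh, spec.lmax)
    proj = np.linalg.pinv(basis)      # (n_coef, n_verts)
    sh_data = np.zeros(shape + (n_sh_coeffs(spec.lmax),))
    for m, tangents, _ in arms:
        vals = _kernel(tangents, mesh.vertices, sigma_rad)
        sh_data[m] += vals @ proj.T
    sh = ShVolume(sh_data, spec.lmax, affine)

    truth = [t for _, _, t in arms]
    arm_masks = [m for m, _, _ in arms]
    return Phantom(scalar, peaks, sh, truth, arm_masks, spec)
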