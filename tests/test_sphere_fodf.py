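import numpy as np
import pytest

from conetrack import (
    PeakExtractionParams,
    ScalarVolume,
    ShVolume,
    SphericalFunction,
    evaluate_fodf,
    find_peaks_on_sphere,
    make_icosphere,
    peaks_from_sh_volume,
    sf_to_sh,
    sh_basis_matrix,
    uncertainty_angle,
)

Y00 = 1.0 / (2.0 * np.sqrt(np.pi))


def gaussian_profile(mesh, direction, sigma_deg):
    """Axially symmetric Gaussian-in-angle profile around ``direction``."""
    cos = np.clip(np.abs(mesh.vertices @ np.asarray(direction, float)), 0, 1)
    theta = np.arccos(cos)
    return np.exp(-(theta ** 2) / (2 * np.deg2rad(sigma_deg) ** 2))


class TestIcosphere:
    @pytest.mark.parametrize("s,n", [(0, 12), (1, 42), (2, 162), (3, 642)])
    def test_vertex_count(self, s, n):
        assert make_icosphere(s).n_vertices == n

    def test_negative_subdivisions_rejected(self):
        with pytest.raises(ValueError):
            make_icosphere(-1)

    def test_construction_invariants(self, mesh):
        norms = np.linalg.norm(mesh.vertices, axis=1)
        np.testing.assert_allclose(norms, 1.0, atol=1e-9)
        # antipodal symmetry
        np.testing.assert_allclose(
            mesh.vertices[mesh.antipode], -mesh.vertices, atol=1e-6
        )
        # adjacency is symmetric
        for i, nbrs in enumerate(mesh.neighbors):
            for j in nbrs:
                assert i in mesh.neighbors[j]
        # every face references valid vertices, consistent outward winding
        v = mesh.vertices[mesh.faces]
        centroid_dot = np.einsum(
            "fi,fi->f",
            np.cross(v[:, 1] - v[:, 0], v[:, 2] - v[:, 0]),
            v.mean(axis=1),
        )
        assert np.all(centroid_dot > 0)


class TestShBasis:
    def test_lmax0_is_constant_y00(self, mesh):
        b = sh_basis_matrix(mesh, 0)
        assert b.shape == (mesh.n_vertices, 1)
        np.testing.assert_allclose(b[:, 0], Y00, atol=1e-12)

    def test_lmax8_has_45_columns_and_antipodal_rows(self, mesh):
        b = sh_basis_matrix(mesh, 8)
        assert b.shape == (mesh.n_vertices, 45)
        np.testing.assert_allclose(b[mesh.antipode], b, atol=1e-9)

    def test_odd_lmax_rejected(self, mesh):
        with pytest.raises(ValueError):
            sh_basis_matrix(mesh, 3)

    def test_orthonormal_under_mesh_quadrature(self):
        # quadrature weights = 1/3 of each vertex's adjacent face area
        # (a plain uniform vertex sum is biased by the 12 valence-5 vertices)
        fine = make_icosphere(4)
        v = fine.vertices[fine.faces]
        areas = 0.5 * np.linalg.norm(
            np.cross(v[:, 1] - v[:, 0], v[:, 2] - v[:, 0]), axis=1
        )
        w = np.zeros(fine.n_vertices)
        for f, a in zip(fine.faces, areas):
            w[f] += a / 3
        w *= 4 * np.pi / w.sum()
        b = sh_basis_matrix(fine, 8)
        gram = (b * w[:, None]).T @ b
        np.testing.assert_allclose(gram, np.eye(b.shape[1]), atol=0.02)


class TestEvaluate:
    def test_isotropic_coefficients_give_constant(self, mesh):
        coeffs = np.zeros(45)
        coeffs[0] = 2.5
        f = evaluate_fodf(coeffs, mesh)
        np.testing.assert_allclose(f.values, 2.5 * Y00, atol=1e-12)

    def test_linearity(self, mesh):
        rng = np.random.default_rng(3)
        a, b = rng.normal(size=45), rng.normal(size=45)
        fa = evaluate_fodf(a, mesh).values
        fb = evaluate_fodf(b, mesh).values
        fab = evaluate_fodf(a + b, mesh).values
        np.testing.assert_allclose(fab, fa + fb, atol=1e-12)

    def test_length_mismatch_rejected(self, mesh):
        with pytest.raises(ValueError):
            evaluate_fodf(np.zeros(44), mesh)

    def test_single_fiber_max_near_truth(self, mesh):
        truth = np.array([1.0, 2.0, 0.5])
        truth /= np.linalg.norm(truth)
        coeffs = sf_to_sh(gaussian_profile(mesh, truth, 25), mesh, lmax=8)
        f = evaluate_fodf(coeffs, mesh)
        best = mesh.vertices[np.argmax(f.values)]
        angle = np.arccos(np.clip(abs(best @ truth), 0, 1))
        assert angle <= mesh.max_edge_angle


class TestSfToSh:
    def test_bandlimited_roundtrip_exact(self, mesh):
        rng = np.random.default_rng(7)
        coeffs = rng.normal(size=45)
        values = evaluate_fodf(coeffs, mesh).values
        back = sf_to_sh(values, mesh, lmax=8)
        np.testing.assert_allclose(back, coeffs, atol=1e-9)
        np.testing.assert_allclose(
            evaluate_fodf(back, mesh).values, values, atol=1e-6
        )

    def test_constant_projects_to_degree_zero_only(self, mesh):
        coeffs = sf_to_sh(np.full(mesh.n_vertices, 3.0), mesh, lmax=8)
        np.testing.assert_allclose(coeffs[0], 3.0 / Y00, rtol=1e-9)
        assert np.all(np.abs(coeffs[1:]) < 1e-9)

    def test_underdetermined_rejected(self):
        coarse = make_icosphere(0)   # 12 vertices < 45 coefficients
        with pytest.raises(ValueError, match="underdetermined"):
            sf_to_sh(np.ones(12), coarse, lmax=8)


def brute_force_peaks(values, mesh, params):
    """Independent oracle: per-vertex neighbor scan + greedy suppression."""
    vmax = values.max()
    if vmax <= 0:
        return []
    maxima = []
    for i in range(mesh.n_vertices):
        if all(values[i] > values[j] for j in mesh.neighbors[i]):
            maxima.append(i)
    maxima = sorted({min(i, int(mesh.antipode[i])) for i in maxima})
    maxima = [i for i in maxima if values[i] >= params.relative_threshold * vmax]
    maxima.sort(key=lambda i: -values[i])
    sep = np.cos(np.deg2rad(params.min_separation_angle))
    kept = []
    for i in maxima:
        if all(
            abs(mesh.vertices[i] @ mesh.vertices[j]) < sep for j in kept
        ):
            kept.append(i)
        if len(kept) == params.max_peaks:
            break
    return kept


class TestFindPeaks:
    def test_isotropic_yields_no_peaks(self, mesh):
        f = SphericalFunction(np.full(mesh.n_vertices, 1.0), mesh)
        assert find_peaks_on_sphere(f) == []

    def test_two_fibers_at_90_degrees(self, mesh):
        vals = gaussian_profile(mesh, [1, 0, 0], 20) + gaussian_profile(
            mesh, [0, 1, 0], 20
        )
        found = find_peaks_on_sphere(SphericalFunction(vals, mesh))
        assert len(found) == 2
        errs = []
        for d, _, _ in found:
            err = min(
                np.arccos(np.clip(abs(d @ np.array(t)), 0, 1))
                for t in ([1, 0, 0], [0, 1, 0])
            )
            errs.append(err)
        assert max(errs) <= mesh.max_edge_angle

    def test_max_peaks_honored_on_five_lobes(self, mesh):
        # 6 well-separated axes; max_peaks=5 must cap the output
        ico = make_icosphere(0).vertices
        axes = [a for a in ico if a[np.argmax(np.abs(a))] > 0][:6]
        vals = sum(gaussian_profile(mesh, a, 8) for a in axes)
        params = PeakExtractionParams(
            relative_threshold=0.1, min_separation_angle=15.0, max_peaks=5
        )
        found = find_peaks_on_sphere(SphericalFunction(vals, mesh), params)
        assert len(found) == 5

    @pytest.mark.parametrize("seed", range(8))
    def test_matches_brute_force_oracle(self, mesh, seed):
        rng = np.random.default_rng(seed)
        coeffs = rng.normal(size=45)
        values = evaluate_fodf(coeffs, mesh).values
        params = PeakExtractionParams(
            relative_threshold=0.3, min_separation_angle=20.0
        )
        got = [i for _, _, i in
               find_peaks_on_sphere(SphericalFunction(values, mesh), params)]
        assert got == brute_force_peaks(values, mesh, params)


class TestUncertaintyAngle:
    def test_gaussian_profile_matches_closed_form(self, mesh):
        sigma = 20.0
        f = SphericalFunction(gaussian_profile(mesh, [0, 0, 1], sigma), mesh)
        peak = int(np.argmax(f.values))
        for k in (0.95, 0.75, 0.5, 0.35, 0.15):
            alpha = uncertainty_angle(f, peak, k)
            expect = np.deg2rad(sigma * np.sqrt(2 * np.log(1 / k)))
            assert abs(alpha - expect) <= mesh.max_edge_angle

    def test_monotone_non_increasing_in_fraction(self, mesh):
        f = SphericalFunction(gaussian_profile(mesh, [1, 0, 0], 15), mesh)
        peak = int(np.argmax(f.values))
        ks = np.linspace(0.05, 1.0, 20)
        alphas = [uncertainty_angle(f, peak, k) for k in ks]
        assert all(a2 <= a1 + 1e-12 for a1, a2 in zip(alphas, alphas[1:]))

    def test_constant_function_caps_at_half_pi(self, mesh):
        f = SphericalFunction(np.ones(mesh.n_vertices), mesh)
        assert uncertainty_angle(f, 0, 0.5) == pytest.approx(np.pi / 2)

    def test_fraction_one_returns_nearest_neighbor_angle(self, mesh):
        f = SphericalFunction(gaussian_profile(mesh, [0, 0, 1], 30), mesh)
        peak = int(np.argmax(f.values))
        alpha = uncertainty_angle(f, peak, 1.0)
        nbr_angles = [
            np.arccos(np.clip(mesh.vertices[peak] @ mesh.vertices[j], -1, 1))
            for j in mesh.neighbors[peak]
        ]
        assert alpha == pytest.approx(min(nbr_angles), abs=1e-12)

    def test_bad_fraction_rejected(self, mesh):
        f = SphericalFunction(np.ones(mesh.n_vertices), mesh)
        with pytest.raises(ValueError):
            uncertainty_angle(f, 0, 0.0)


class TestVolumeExtraction:
    def _crop(self, phantom, xlo, xhi):
        sh = phantom.sh
        return (
            ShVolume(sh.data[xlo:xhi], sh.lmax, sh.affine),
            ScalarVolume(phantom.scalar.data[xlo:xhi], phantom.scalar.affine),
        )

    def test_single_fiber_volume_recovers_direction(self, mesh, straight_phantom):
        sh, mask = self._crop(straight_phantom, 18, 21)
        fld = peaks_from_sh_volume(sh, mesh, mask=mask, mask_threshold=0.1)
        inside = straight_phantom.mask[18:21]
        counts = fld.peak_counts()
        assert np.all(counts[inside] == 1)
        assert np.all(counts[~inside] == 0)
        dirs = fld.directions()[inside][:, 0]
        err = np.arccos(np.clip(np.abs(dirs @ np.array([1.0, 0, 0])), 0, 1))
        assert err.max() <= mesh.max_edge_angle

    def test_alpha_nested_with_fraction(self, mesh, straight_phantom):
        sh, mask = self._crop(straight_phantom, 19, 20)
        tight = peaks_from_sh_volume(
            sh, mesh, PeakExtractionParams(fwhm_fraction=0.95),
            mask=mask, mask_threshold=0.1,
        )
        loose = peaks_from_sh_volume(
            sh, mesh, PeakExtractionParams(fwhm_fraction=0.35),
            mask=mask, mask_threshold=0.1,
        )
        inside = straight_phantom.mask[19:20]
        a_tight = tight.alphas()[inside][:, 0]
        a_loose = loose.alphas()[inside][:, 0]
        assert np.all(a_tight <= a_loose + 1e-12)
        assert np.all(a_tight > 0)

    def test_empty_mask_gives_all_zero_field(self, mesh, straight_phantom):
        sh, _ = self._crop(straight_phantom, 19, 20)
        empty = ScalarVolume(np.zeros(sh.data.shape[:3]), sh.affine)
        fld = peaks_from_sh_volume(sh, mesh, mask=empty, mask_threshold=0.5)
        assert np.all(fld.data == 0)

    def test_shape_mismatch_rejected(self, mesh, straight_phantom):
        sh, _ = self._crop(straight_phantom, 19, 20)
        bad_mask = ScalarVolume(np.ones((2, 2, 2)), sh.affine)
        with pytest.raises(ValueError, match="mask shape"):
            peaks_from_sh_volume(sh, mesh, mask=bad_mask)
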