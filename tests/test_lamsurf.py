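"""Surface geometry: meshes, equi-volume depths, sampling, smoothing, registration."""

import numpy as np
import pytest
from scipy.optimize import brentq

from lamconn.lamsurf import (
    LaminarDataset,
    LaminarMesh,
    RegistrationMap,
    SurfaceMesh,
    apply_registration,
    build_depth_surfaces,
    equivolume_depth_fraction,
    icosahedron,
    icosphere,
    refine_mesh,
    sample_volume_to_surface,
    smooth_within_depth,
)


class TestMeshBasics:
    def test_icosahedron_counts(self):
        m = icosahedron()
        assert m.n_vertices == 12 and m.n_triangles == 20
        assert len(m.edges()) == 30

    def test_refine_counts_one_iteration(self):
        m = refine_mesh(icosahedron(), 1)
        assert m.n_vertices == 42 and m.n_triangles == 80

    def test_refine_counts_two_iterations(self):
        m = refine_mesh(icosahedron(), 2)
        assert m.n_triangles == 20 * 4**2  # 320

    def test_refine_zero_identity(self):
        m0 = icosahedron()
        m1 = refine_mesh(m0, 0)
        np.testing.assert_array_equal(m1.vertices, m0.vertices)
        np.testing.assert_array_equal(m1.triangles, m0.triangles)

    def test_prolongation_interpolates_linear(self):
        m0 = icosahedron()
        m1, P = refine_mesh(m0, 1, return_prolongation=True)
        f0 = m0.vertices[:, 0]  # linear field: x-coordinate
        f1 = P @ f0
        np.testing.assert_allclose(f1, m1.vertices[:, 0], atol=1e-12)

    def test_vertex_areas_sum_to_surface_area(self):
        m = icosphere(3, radius=10.0)
        assert m.vertex_areas().sum() == pytest.approx(m.triangle_areas().sum())
        # icosphere area approaches the sphere area from below
        assert m.triangle_areas().sum() == pytest.approx(4 * np.pi * 100, rel=0.02)

    def test_validate_rejects_degenerate(self):
        verts = np.array([[0, 0, 0], [1, 0, 0], [1, 0, 0]], dtype=float)
        tris = np.array([[0, 1, 2]])
        with pytest.raises(ValueError):
            SurfaceMesh(verts, tris).validate()


class TestEquivolume:
    def test_boundaries(self):
        assert equivolume_depth_fraction(1.0, 2.0, 0.0) == 0.0
        assert equivolume_depth_fraction(1.0, 2.0, 1.0) == 1.0

    def test_equidistant_limit(self):
        a = np.linspace(0.1, 0.9, 9)
        np.testing.assert_allclose(equivolume_depth_fraction(3.0, 3.0, a), a)

    def test_worked_example(self):
        # a_w=1, a_p=2, alpha=0.5 -> rho = sqrt(2.5) - 1
        rho = equivolume_depth_fraction(1.0, 2.0, 0.5)
        assert rho == pytest.approx(np.sqrt(2.5) - 1.0, abs=1e-12)
        assert rho == pytest.approx(0.58114, abs=1e-5)

    def test_matches_numeric_root(self):
        # independent oracle: numeric root of the cumulative-volume equation
        # integral_0^rho (a_w + (a_p - a_w) s) ds = alpha * (a_w + a_p) / 2
        for a_w in (0.5, 1.0, 2.0, 7.3):
            for a_p in (0.6, 1.5, 3.0, 9.1):
                for alpha in (0.1, 0.25, 0.5, 0.75, 0.9):
                    def vol(rho):
                        return (
                            a_w * rho
                            + 0.5 * (a_p - a_w) * rho**2
                            - alpha * (a_w + a_p) / 2.0
                        )

                    rho_num = brentq(vol, 0.0, 1.0, xtol=1e-14)
                    rho_ana = equivolume_depth_fraction(a_w, a_p, alpha)
                    assert abs(rho_ana - rho_num) < 1e-10

    def test_strictly_increasing_in_alpha(self):
        alphas = np.linspace(0, 1, 50)
        rho = equivolume_depth_fraction(1.0, 4.0, alphas)
        assert np.all(np.diff(rho) > 0)

    def test_invalid_inputs(self):
        with pytest.raises(ValueError):
            equivolume_depth_fraction(-1.0, 2.0, 0.5)
        with pytest.raises(ValueError):
            equivolume_depth_fraction(1.0, 2.0, 1.5)


class TestBuildDepthSurfaces:
    def test_concentric_spheres_monotone_inside(self):
        white = icosphere(2, 10.0)
        pial = SurfaceMesh(white.vertices * 1.25, white.triangles)  # radius 12.5
        lm = build_depth_surfaces(white, pial, n_depths=2)
        r = np.linalg.norm(lm.coords, axis=2)  # (V, 2)
        assert np.all(r > 10.0) and np.all(r < 12.5)
        assert np.all(r[:, 1] > r[:, 0])

    def test_equal_area_limit_equidistant(self):
        # pial = translated white surface: identical one-ring areas, so the
        # equi-volume rule reduces to equidistant spacing at bin centers
        white = icosphere(1, 10.0)
        pial = SurfaceMesh(white.vertices + np.array([0.0, 0.0, 2.0]), white.triangles)
        D = 4
        lm = build_depth_surfaces(white, pial, n_depths=D)
        frac = (lm.coords[:, :, 2] - white.vertices[:, 2:3]) / 2.0
        expected = (np.arange(D) + 0.5) / D
        np.testing.assert_allclose(frac, np.broadcast_to(expected, frac.shape), atol=1e-9)

    def test_sphere_pair_matches_closed_form(self):
        # per-vertex rho within 2% of the scalar rule with analytic area
        # ratio a_p / a_w = (R_p / R_w)^2
        Rw, Rp = 10.0, 12.5
        white = icosphere(3, Rw)
        pial = SurfaceMesh(white.vertices * (Rp / Rw), white.triangles)
        D = 6
        lm = build_depth_surfaces(white, pial, n_depths=D)
        r = np.linalg.norm(lm.coords, axis=2)
        rho_mesh = (r - Rw) / (Rp - Rw)
        alphas = (np.arange(D) + 0.5) / D
        rho_exact = equivolume_depth_fraction(Rw**2, Rp**2, alphas)
        err = np.abs(rho_mesh - rho_exact[None, :]) / rho_exact[None, :]
        assert err.max() < 0.02

    def test_shell_volumes_equal(self):
        # quadratic-area model: the volume between consecutive depths is equal
        a_w, a_p = 1.3, 3.7
        D = 18
        alphas = np.concatenate([[0.0], (np.arange(D) + 0.5) / D, [1.0]])
        rho = equivolume_depth_fraction(a_w, a_p, alphas)

        def cumvol(r):
            return a_w * r + 0.5 * (a_p - a_w) * r**2

        vols = np.diff(cumvol(rho))
        inner = vols[1:-1]  # shells between bin centers are all 1/D of total
        assert np.max(np.abs(inner - inner[0])) / inner[0] < 1e-9

    def test_topology_mismatch_rejected(self):
        white = icosphere(1, 10.0)
        pial = icosphere(2, 12.0)
        with pytest.raises(ValueError):
            build_depth_surfaces(white, pial)


def _flat_lmesh(nx=5, spacing=1.0, n_depths=3):
    """A tiny laminar 'mesh' of grid points for sampling tests."""
    xs = np.arange(nx) * spacing
    pts = np.array([[x, y, 0.0] for x in xs for y in xs])
    tris = []
    for i in range(nx - 1):
        for j in range(nx - 1):
            a = i * nx + j
            tris += [[a, a + 1, a + nx], [a + 1, a + nx + 1, a + nx]]
    base = SurfaceMesh(pts, np.array(tris))
    coords = np.stack([pts + [0, 0, d] for d in range(n_depths)], axis=1)
    return LaminarMesh(base=base, coords=coords, depth_fractions=np.linspace(0, 1, n_depths))


class TestSampling:
    def test_constant_volume(self):
        lm = _flat_lmesh()
        vol = np.full((8, 8, 8), 3.5)
        ds = sample_volume_to_surface(vol, np.eye(4), lm)
        np.testing.assert_allclose(ds.values, 3.5)

    def test_linear_field_exact(self):
        lm = _flat_lmesh(spacing=0.7)
        shape = (10, 10, 10)
        aff = np.eye(4) * 0.5
        aff[3, 3] = 1.0
        ii, jj, kk = np.meshgrid(*[np.arange(s) for s in shape], indexing="ij")
        vol = 0.5 * ii  # f(x, y, z) = x in mm
        ds = sample_volume_to_surface(vol.astype(float), aff, lm)
        expect = lm.coords[..., 0]
        np.testing.assert_allclose(ds.values, expect, atol=1e-12)

    def test_upsample5_snaps_to_fine_lattice(self):
        lm = _flat_lmesh(spacing=1.0)
        shape = (8, 8, 8)
        ii = np.meshgrid(*[np.arange(s) for s in shape], indexing="ij")[0].astype(float)
        tri = sample_volume_to_surface(ii, np.eye(4), lm, mode="trilinear")
        up = sample_volume_to_surface(ii, np.eye(4), lm, mode="upsample5_nearest")
        # vertices exactly at voxel centers: both modes give the voxel value
        np.testing.assert_allclose(up.values, tri.values, atol=1e-12)

    def test_outside_points_missing(self):
        lm = _flat_lmesh(spacing=10.0)  # many points beyond the 4^3 grid
        vol = np.ones((4, 4, 4))
        with pytest.warns(UserWarning, match="outside"):
            ds = sample_volume_to_surface(vol, np.eye(4), lm)
        assert ds.n_missing > 0
        assert np.isnan(ds.values).sum() == ds.n_missing

    def test_nan_aware_near_mask_edge(self):
        # a NaN voxel adjacent to the sample point is dropped and the
        # remaining corner weights renormalized, not propagated
        lm = _flat_lmesh(spacing=0.5)
        lm.coords = lm.coords + np.array([0.3, 0.0, 0.0])  # off the NaN plane
        vol = np.full((8, 8, 8), 2.0)
        vol[0, :, :] = np.nan
        ds = sample_volume_to_surface(vol, np.eye(4), lm)
        assert np.isfinite(ds.values).all()
        np.testing.assert_allclose(ds.values, 2.0)

    def test_unknown_mode(self):
        lm = _flat_lmesh()
        with pytest.raises(ValueError):
            sample_volume_to_surface(np.ones((4, 4, 4)), np.eye(4), lm, mode="cubic")


def _sphere_lmesh(subdiv=3, radius=20.0, n_depths=2):
    base = icosphere(subdiv, radius)
    coords = np.repeat(base.vertices[:, None, :], n_depths, axis=1)
    return LaminarMesh(
        base=base, coords=coords, depth_fractions=np.linspace(0, 1, n_depths)
    )


class TestSmoothing:
    def test_fwhm_zero_identity(self, rng):
        lm = _sphere_lmesh()
        vals = rng.standard_normal((lm.n_vertices, lm.n_depths, 4))
        out = smooth_within_depth(LaminarDataset(vals, lm), fwhm=0.0)
        np.testing.assert_array_equal(out.values, vals)

    def test_constant_field_unchanged(self):
        lm = _sphere_lmesh()
        vals = np.full((lm.n_vertices, lm.n_depths, 2), 1.25)
        out = smooth_within_depth(LaminarDataset(vals, lm), fwhm=3.0)
        np.testing.assert_allclose(out.values, 1.25, atol=1e-12)

    def test_depths_never_mix(self, rng):
        lm = _sphere_lmesh(n_depths=3)
        vals = np.zeros((lm.n_vertices, 3, 1))
        vals[:, 1, 0] = rng.standard_normal(lm.n_vertices)
        out = smooth_within_depth(LaminarDataset(vals, lm), fwhm=3.0)
        assert np.all(out.values[:, 0] == 0) and np.all(out.values[:, 2] == 0)

    def test_mass_preserving(self, rng):
        lm = _sphere_lmesh()
        vals = rng.standard_normal((lm.n_vertices, lm.n_depths, 1))
        out = smooth_within_depth(LaminarDataset(vals, lm), fwhm=3.0)
        # uniform-degree closed mesh: neighbour averaging preserves the mean
        before = vals.mean()
        after = out.values.mean()
        assert abs(after - before) <= 0.005 * max(abs(before), vals.std())

    def test_delta_fwhm_calibration(self):
        # delta at one vertex on a fine sphere: the spread's measured width
        # (per-axis standard deviation of the kernel mass over geodesic
        # distance, converted to FWHM) within 25% of the target 3 mm
        fwhm = 3.0
        lm = _sphere_lmesh(subdiv=4, radius=20.0, n_depths=1)
        V = lm.n_vertices
        src = 0
        vals = np.zeros((V, 1, 1))
        vals[src] = 1.0
        out = smooth_within_depth(LaminarDataset(vals, lm), fwhm=fwhm)
        v = out.values[:, 0, 0]
        p0 = lm.base.vertices[src] / np.linalg.norm(lm.base.vertices[src])
        pv = lm.base.vertices / np.linalg.norm(lm.base.vertices, axis=1, keepdims=True)
        geo = 20.0 * np.arccos(np.clip(pv @ p0, -1, 1))
        # 2D isotropic kernel: per-axis variance = half the radial variance
        var_axis = 0.5 * np.sum(v * geo**2) / np.sum(v)
        measured_fwhm = 2.3548 * np.sqrt(var_axis)
        assert abs(measured_fwhm - fwhm) / fwhm < 0.25

    def test_negative_fwhm(self):
        lm = _sphere_lmesh()
        with pytest.raises(ValueError):
            smooth_within_depth(LaminarDataset(np.zeros((lm.n_vertices, 2, 1)), lm), -1)


class TestRegistration:
    def test_identity(self, rng):
        lm = _sphere_lmesh(subdiv=1)
        vals = rng.standard_normal((lm.n_vertices, 2, 3))
        out = apply_registration(RegistrationMap.identity(lm.n_vertices), LaminarDataset(vals, lm))
        np.testing.assert_array_equal(out.values, vals)

    def test_permutation_preserves_profiles(self, rng):
        lm = _sphere_lmesh(subdiv=1)
        V = lm.n_vertices
        perm = rng.permutation(V)
        vals = rng.standard_normal((V, 2, 3))
        out = apply_registration(RegistrationMap.from_permutation(perm), LaminarDataset(vals, lm))
        np.testing.assert_array_equal(out.values, vals[perm])

    def test_depth_block_diagonality_exact(self, rng):
        lm = _sphere_lmesh(subdiv=1, n_depths=4)
        V = lm.n_vertices
        rm = RegistrationMap.from_permutation(rng.permutation(V))
        vals = rng.standard_normal((V, 4, 2))
        base = apply_registration(rm, LaminarDataset(vals, lm)).values
        pert = vals.copy()
        pert[:, 2, :] += rng.standard_normal((V, 2))
        out = apply_registration(rm, LaminarDataset(pert, lm)).values
        changed = np.any(out != base, axis=(0, 2))
        assert changed.tolist() == [False, False, True, False]

    def test_unnormalized_weights_renormalized_with_warning(self):
        from scipy import sparse

        M = sparse.csr_matrix(np.array([[2.0, 0.0], [0.0, 4.0]]))
        with pytest.warns(UserWarning, match="renormaliz"):
            rm = RegistrationMap(M)
        rs = np.asarray(rm.matrix.sum(axis=1)).ravel()
        np.testing.assert_allclose(rs, 1.0)

    def test_negative_weights_rejected(self):
        from scipy import sparse

        M = sparse.csr_matrix(np.array([[1.5, -0.5], [0.0, 1.0]]))
        with pytest.raises(ValueError):
            RegistrationMap(M)

    def test_constant_per_depth_preserved(self):
        lm = _sphere_lmesh(subdiv=1, n_depths=3)
        V = lm.n_vertices
        vals = np.zeros((V, 3, 1))
        vals[:, 0] = 1.0
        vals[:, 1] = 2.0
        vals[:, 2] = 3.0
        rm = RegistrationMap.from_permutation(np.random.default_rng(2).permutation(V))
        out = apply_registration(rm, LaminarDataset(vals, lm)).values
        np.testing.assert_allclose(out, vals)
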