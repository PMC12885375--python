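import numpy as np
import pytest
from scipy import stats

from swmprof.geometry_io import ScalarVolume, SurfaceMap, TriangleMesh, make_grid_mesh
from swmprof.profiling import (
    IntensityProfileMatrix,
    RegistrationError,
    compute_moments,
    regress_out_curvature,
    repair_outliers_tukey,
    sample_volume_to_stack,
    smooth_profiles,
    smooth_surface_map,
    tukey_fences,
)


def _affine_volume(shape=(12, 12, 12), h=0.5):
    """f(x, y, z) = 2x + 3y - z + 4 on voxel centres."""
    aff = np.diag([h, h, h, 1.0])
    aff[:3, 3] = h / 2
    idx = np.indices(shape).astype(float)
    world = np.stack(
        [idx[0] * h + h / 2, idx[1] * h + h / 2, idx[2] * h + h / 2]
    )
    data = 2 * world[0] + 3 * world[1] - world[2] + 4
    return ScalarVolume(data=data, affine=aff)


class TestTrilinearSampling:
    def test_exact_for_affine_volume(self, invivo_slab_stack, slab):
        vol = _affine_volume(slab.seg.labels.shape, h=0.5)
        profiles = sample_volume_to_stack(invivo_slab_stack, vol)
        for k, mesh in enumerate(invivo_slab_stack.meshes):
            expected = (
                2 * mesh.vertices[:, 0] + 3 * mesh.vertices[:, 1] - mesh.vertices[:, 2] + 4
            )
            valid = profiles.valid[k]
            np.testing.assert_allclose(profiles.values[k][valid], expected[valid], rtol=1e-12)

    def test_voxel_center_returns_voxel_value(self):
        rng = np.random.default_rng(0)
        vol = ScalarVolume(data=rng.normal(size=(6, 6, 6)), affine=np.eye(4))
        from swmprof.laplace_swm import SurfaceStack

        mesh = TriangleMesh(
            vertices=np.array([[2.0, 3.0, 4.0], [1.0, 1.0, 1.0], [5.0, 5.0, 5.0]]),
            faces=np.array([[0, 1, 2]]),
        )
        stack = SurfaceStack(
            meshes=[mesh],
            depths=[0.0],
            valid=np.ones((1, 3), dtype=bool),
            arc_lengths=np.zeros((1, 3)),
        )
        profiles = sample_volume_to_stack(stack, vol)
        assert profiles.values[0, 0] == pytest.approx(vol.data[2, 3, 4], rel=1e-12)

    def test_slab_depth_rows_recover_spacing(self, slab, invivo_slab_stack):
        vol = ScalarVolume(data=slab.depth.copy(), affine=slab.seg.affine)
        profiles = sample_volume_to_stack(invivo_slab_stack, vol)
        step = invivo_slab_stack.provenance["step_size"]
        for k in range(1, 16):
            row = profiles.values[k][profiles.valid[k]]
            assert abs(np.mean(row) - 0.2 * k) <= step

    def test_outside_positions_nan(self):
        vol = ScalarVolume(data=np.ones((4, 4, 4)), affine=np.eye(4))
        from swmprof.laplace_swm import SurfaceStack

        mesh = TriangleMesh(
            vertices=np.array([[50.0, 50.0, 50.0], [1, 1, 1], [2, 2, 2]], dtype=float),
            faces=np.array([[0, 1, 2]]),
        )
        stack = SurfaceStack(
            meshes=[mesh], depths=[0.0], valid=np.ones((1, 3), dtype=bool),
            arc_lengths=np.zeros((1, 3)),
        )
        profiles = sample_volume_to_stack(stack, vol)
        assert np.isnan(profiles.values[0, 0])
        assert not profiles.valid[0, 0]

    def test_affine_mismatch_rejected(self, invivo_slab_stack):
        bad_aff = np.diag([0.7, 0.7, 0.7, 1.0])
        vol = ScalarVolume(data=np.ones((8, 8, 8)), affine=bad_aff)
        with pytest.raises(RegistrationError):
            sample_volume_to_stack(invivo_slab_stack, vol)


class TestTukeyRepair:
    def _line_mesh(self, n):
        verts = np.column_stack([np.arange(n, dtype=float), np.zeros(n), np.zeros(n)])
        faces = np.array([[i, i + 1, (i + 2) % n] for i in range(n - 2)])
        return TriangleMesh(vertices=verts, faces=faces)

    def test_fences_type7(self):
        lo, hi = tukey_fences(np.array([1.0, 2, 3, 4, 100]))
        # type-7 quartiles: Q1=2, Q3=4 -> fences [-1, 7]
        assert (lo, hi) == (-1.0, 7.0)
        assert 100 > hi  # the documented outlier is flagged

    def test_outlier_replaced_nonoutliers_untouched(self):
        mesh = self._line_mesh(5)
        out = repair_outliers_tukey(np.array([1.0, 2, 3, 4, 100]), mesh)
        assert out.values[4] != 100
        np.testing.assert_array_equal(out.values[:4], [1, 2, 3, 4])

    def test_constant_region_nothing_flagged(self):
        mesh = self._line_mesh(6)
        vals = np.full(6, 3.14)
        out = repair_outliers_tukey(vals, mesh)
        np.testing.assert_array_equal(out.values, vals)

    def test_neighbour_mean_replacement(self):
        # chain 0-1-2; value at 1 is an outlier, neighbours are 2 and 4
        verts = np.array([[0, 0, 0], [1, 0, 0], [2, 0, 0], [1, 1, 0]], dtype=float)
        faces = np.array([[0, 1, 3], [1, 2, 3]])
        mesh = TriangleMesh(vertices=verts, faces=faces)
        vals = np.array([2.0, 1000.0, 4.0, 3.0])
        out = repair_outliers_tukey(vals, mesh)
        assert out.values[1] == pytest.approx((2.0 + 4.0 + 3.0) / 3.0)

    def test_degenerate_region_rejected(self):
        # fences computed from the region itself can never flag everything
        # (half the data lies within the IQR), so the degenerate error path
        # is a region without finite values
        mesh = self._line_mesh(5)
        region = np.zeros(5, dtype=bool)
        region[:2] = True
        vals = np.array([np.nan, np.nan, 1.0, 2.0, 3.0])
        with pytest.raises(ValueError):
            repair_outliers_tukey(vals, mesh, region_mask=region)
        with pytest.raises(ValueError):
            repair_outliers_tukey(vals, mesh, region_mask=np.zeros(5, dtype=bool))


class TestMoments:
    def test_symmetric_triplet(self):
        table = compute_moments(np.array([[1.0, 2.0, 3.0, 2.0]]))
        row = table.iloc[0]
        assert row["mean"] == pytest.approx(2.0)
        assert row["skewness"] == pytest.approx(0.0)

    def test_matches_brute_force_oracle(self):
        rng = np.random.default_rng(3)
        values = rng.gamma(2.0, size=(6, 200))
        table = compute_moments(values)
        for i in range(6):
            x = values[i]
            n = len(x)
            mean = sum(x) / n
            m2 = sum((v - mean) ** 2 for v in x) / n
            m3 = sum((v - mean) ** 3 for v in x) / n
            m4 = sum((v - mean) ** 4 for v in x) / n
            sd = (sum((v - mean) ** 2 for v in x) / (n - 1)) ** 0.5
            assert table["mean"][i] == pytest.approx(mean, abs=1e-12)
            assert table["sd"][i] == pytest.approx(sd, abs=1e-12)
            assert table["skewness"][i] == pytest.approx(m3 / m2**1.5, abs=1e-12)
            assert table["kurtosis"][i] == pytest.approx(m4 / m2**2 - 3, abs=1e-12)

    def test_matches_scipy_conventions(self):
        rng = np.random.default_rng(4)
        x = rng.normal(size=(1, 500))
        table = compute_moments(x)
        assert table["skewness"][0] == pytest.approx(stats.skew(x[0]), abs=1e-12)
        assert table["kurtosis"][0] == pytest.approx(stats.kurtosis(x[0]), abs=1e-12)

    def test_normal_excess_kurtosis_near_zero(self):
        rng = np.random.default_rng(11)
        x = rng.standard_normal(size=(1, 100_000))
        table = compute_moments(x)
        assert abs(table["kurtosis"][0]) < 0.05

    def test_few_valid_vertices_nan(self):
        values = np.full((1, 10), np.nan)
        values[0, :3] = [1.0, 2.0, 3.0]
        table = compute_moments(values)
        assert np.isnan(table["mean"][0])
        assert table["n_valid"][0] == 3

    def test_zero_variance_warns(self):
        with pytest.warns(UserWarning, match="zero variance"):
            table = compute_moments(np.ones((1, 10)))
        assert np.isnan(table["skewness"][0])
        assert table["sd"][0] == 0.0


class TestSmoothing:
    def test_constant_map_fixed_point(self, icosphere3):
        vals = np.full(icosphere3.n_vertices, 2.5)
        out = smooth_surface_map(vals, icosphere3, iterations=5)
        np.testing.assert_array_equal(out.values, vals)

    def test_single_impulse_one_step(self, torus_mesh):
        # degree-6 vertex: centre -> (1-0.5)*1 + 0.5*0 = 0.5;
        # each neighbour -> 0.5 * (1/6)
        vals = np.zeros(torus_mesh.n_vertices)
        vals[0] = 1.0
        out = smooth_surface_map(vals, torus_mesh, iterations=1, relaxation=0.5)
        assert out.values[0] == pytest.approx(0.5)
        from swmprof.geometry_io import vertex_adjacency

        for nb in vertex_adjacency(torus_mesh)[0]:
            assert out.values[nb] == pytest.approx(0.5 / 6.0)

    def test_mean_preserved_on_regular_mesh(self, torus_mesh):
        rng = np.random.default_rng(0)
        vals = rng.normal(size=torus_mesh.n_vertices)
        out = smooth_surface_map(vals, torus_mesh, iterations=5)
        assert out.values.mean() == pytest.approx(vals.mean(), abs=1e-9)

    def test_variance_strictly_decreases(self, icosphere3):
        rng = np.random.default_rng(1)
        v = rng.normal(size=icosphere3.n_vertices)
        prev = np.var(v)
        for _ in range(4):
            v = smooth_surface_map(v, icosphere3, iterations=1).values
            assert np.var(v) < prev
            prev = np.var(v)

    def test_non_expansive_max_norm(self, icosphere3):
        rng = np.random.default_rng(2)
        vals = rng.normal(size=icosphere3.n_vertices)
        out = smooth_surface_map(vals, icosphere3, iterations=3)
        assert np.abs(out.values).max() <= np.abs(vals).max() + 1e-12

    def test_nan_vertices_stay_nan_and_are_excluded(self, icosphere3):
        vals = np.ones(icosphere3.n_vertices)
        vals[0] = np.nan
        out = smooth_surface_map(vals, icosphere3, iterations=2)
        assert np.isnan(out.values[0])
        np.testing.assert_allclose(out.values[1:], 1.0)

    def test_profile_rows_smoothed_independently(self, icosphere3):
        rng = np.random.default_rng(3)
        values = rng.normal(size=(4, icosphere3.n_vertices))
        pm = IntensityProfileMatrix(values=values, depths=np.arange(4.0))
        sm = smooth_profiles(pm, icosphere3, iterations=2)
        for k in range(4):
            row = smooth_surface_map(values[k], icosphere3, iterations=2).values
            np.testing.assert_array_equal(sm.values[k], row)


class TestCurvatureRegression:
    def _profiles(self, values):
        return IntensityProfileMatrix(values=values, depths=np.arange(values.shape[0], dtype=float))

    def test_perfect_fit_leaves_intercept(self):
        curv = np.linspace(-1, 1, 50)
        values = (2.0 * curv + 5.0)[None, :]
        out, table = regress_out_curvature(self._profiles(values), curv)
        np.testing.assert_allclose(out.values[0], 5.0, atol=1e-10)
        assert table["slope"][0] == pytest.approx(2.0)

    def test_orthogonal_curvature_identity(self):
        rng = np.random.default_rng(0)
        curv = np.tile([1.0, -1.0], 50)
        intensity = np.tile([3.0, 3.0], 50) + rng.normal(0, 1e-12, 100)
        values = intensity[None, :]
        out, table = regress_out_curvature(self._profiles(values), curv)
        np.testing.assert_allclose(out.values[0], values[0], atol=1e-9)

    def test_removes_planted_curvature_effect(self):
        rng = np.random.default_rng(5)
        curv = rng.normal(size=2000)
        depth_effect = 1.7
        intensity = depth_effect + 0.8 * curv + rng.normal(0, 0.1, size=2000)
        out, _ = regress_out_curvature(self._profiles(intensity[None, :]), curv)
        rho = stats.spearmanr(out.values[0], curv).statistic
        assert abs(rho) < 0.05

    def test_constant_curvature_warns_identity(self):
        values = np.arange(20.0)[None, :]
        with pytest.warns(UserWarning, match="constant curvature"):
            out, _ = regress_out_curvature(self._profiles(values), np.ones(20))
        np.testing.assert_array_equal(out.values, values)

    def test_mean_level_preserved(self):
        rng = np.random.default_rng(6)
        curv = rng.normal(size=300)
        intensity = 4.0 + 0.5 * curv + rng.normal(0, 0.2, 300)
        out, _ = regress_out_curvature(self._profiles(intensity[None, :]), curv)
        assert out.values[0].mean() == pytest.approx(intensity.mean(), abs=0.05)


class TestProfileMatrix:
    def test_drop_shallowest(self):
        pm = IntensityProfileMatrix(values=np.arange(12.0).reshape(3, 4), depths=[-0.5, 0.0, 0.5])
        out = pm.drop_shallowest()
        assert out.n_depths == 2
        np.testing.assert_array_equal(out.depths, [0.0, 0.5])

    def test_depths_must_increase(self):
        with pytest.raises(ValueError):
            IntensityProfileMatrix(values=np.zeros((2, 3)), depths=[1.0, 0.5])
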