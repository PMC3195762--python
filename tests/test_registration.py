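"""Shape normalization: kernels, transforms, warping, SSD registration."""

import numpy as np
import pytest
from scipy import ndimage

from gndpca import registration as R
from gndpca.synthetic import CohortSpec, make_template, sample_volume
from gndpca.volume import Volume

SMALL_SHAPE = (48, 48, 24)
SMALL_SPACING = (1.25, 1.25, 2.5)


@pytest.fixture(scope="module")
def template():
    return make_template(SMALL_SHAPE, SMALL_SPACING)


@pytest.fixture(scope="module")
def textured():
    spec = CohortSpec(shape=SMALL_SHAPE, shape_deform_sd=0.0, noise_sd=0.0, seed=3)
    return sample_volume(spec, 0)


class TestKernel:
    def test_knot_values(self):
        assert R.bspline_kernel(0.0) == pytest.approx(2.0 / 3.0)
        assert R.bspline_kernel(1.0) == pytest.approx(1.0 / 6.0)
        assert R.bspline_kernel(-1.0) == pytest.approx(1.0 / 6.0)
        assert R.bspline_kernel(2.0) == 0.0
        assert R.bspline_kernel(-2.5) == 0.0

    def test_partition_of_unity_and_symmetry(self, rng):
        a = rng.uniform(-3, 3, size=1000)
        shifts = np.arange(-4, 5)
        total = R.bspline_kernel(a[:, None] - shifts[None, :]).sum(axis=1)
        assert np.abs(total - 1.0).max() < 1e-12
        assert np.allclose(R.bspline_kernel(a), R.bspline_kernel(-a))
        assert np.all(R.bspline_kernel(a) >= 0)


class TestRigid:
    def test_identity(self, rng):
        p = rng.standard_normal((10, 3))
        params = R.RigidParams()
        assert np.allclose(R.rigid_apply(p, params), p)

    def test_quarter_turn_about_z(self):
        center = np.array([10.0, 20.0, 5.0])
        params = R.RigidParams(theta=[0, 0, np.pi / 2], t=[0, 0, 0], center=center)
        moved = R.rigid_apply(center + [3.0, 0, 0], params)
        assert np.allclose(moved, center + [0, 3.0, 0], atol=1e-12)

    def test_inverse_roundtrip(self, rng):
        params = R.RigidParams(theta=[0.3, -0.2, 0.5], t=[4.0, -1.0, 2.5],
                               center=[8.0, 8.0, 8.0])
        p = rng.standard_normal((20, 3)) * 10
        q = R.rigid_apply(p, params)
        back = R.rigid_apply(q, R.rigid_inverse(params))
        assert np.abs(back - p).max() < 1e-10


class TestFFD:
    def test_zero_and_constant_coefficients(self, template, rng):
        grid = R.make_lattice(template, (5, 5, 3))
        pts = template.origin + rng.uniform(0.1, 0.9, (50, 3)) * template.extent
        assert np.abs(R.ffd_displacement(pts, grid)).max() == 0.0
        grid.coeffs[...] = np.array([1.5, -2.0, 0.7])
        disp = R.ffd_displacement(pts, grid)
        assert np.abs(disp - [1.5, -2.0, 0.7]).max() < 1e-12

    def test_single_control_point_peak(self, template):
        grid = R.make_lattice(template, (5, 5, 3))
        grid.coeffs[3, 3, 2] = [1.0, 0.0, 0.0]
        phi = grid.origin + np.array([3, 3, 2]) * grid.rho
        disp = R.ffd_displacement(phi, grid)
        assert disp[0] == pytest.approx((2.0 / 3.0) ** 3)
        assert abs(disp[0] - 8.0 / 27.0) < 1e-12

    def test_outside_support_errors_or_zero(self, template):
        grid = R.make_lattice(template, (4, 4, 3))
        far = template.origin - 10 * template.spacing
        with pytest.raises(ValueError, match="outside"):
            R.ffd_displacement(far, grid)
        assert np.allclose(R.ffd_displacement(far, grid, outside="zero"), 0.0)

    def test_dense_field_matches_pointwise(self, template, rng):
        grid = R.make_lattice(template, (4, 4, 3))
        grid.coeffs[...] = rng.standard_normal(grid.coeffs.shape)
        weights = R._weight_matrices(template, grid)
        dense = R._dense_displacement(weights, grid.coeffs)
        idx = rng.integers(0, np.array(SMALL_SHAPE), size=(20, 3))
        pts = template.voxel_to_physical(idx)
        pointwise = R.ffd_displacement(pts, grid)
        assert np.abs(dense[idx[:, 0], idx[:, 1], idx[:, 2]] - pointwise).max() < 1e-10

    def test_dense_adjoint_is_true_adjoint(self, template, rng):
        grid = R.make_lattice(template, (4, 4, 3))
        weights = R._weight_matrices(template, grid)
        coeffs = rng.standard_normal(grid.coeffs.shape)
        fld = rng.standard_normal(SMALL_SHAPE + (3,))
        lhs = np.sum(R._dense_displacement(weights, coeffs) * fld)
        rhs = np.sum(coeffs * R._dense_adjoint(weights, fld))
        assert lhs == pytest.approx(rhs, rel=1e-10)


class TestComposite:
    def test_identity_and_pure_parts(self, template, rng):
        p = template.center + rng.uniform(-5, 5, (10, 3))
        grid = R.make_lattice(template, (4, 4, 3))
        t_id = R.CompositeTransform(rigid=R.RigidParams(), ffd=grid)
        assert np.allclose(R.composite_apply(p, t_id), p)
        grid.coeffs[...] = np.array([0.5, 0.5, -0.5])
        assert np.allclose(
            R.composite_apply(p, R.CompositeTransform(ffd=grid)), p + [0.5, 0.5, -0.5]
        )
        rp = R.RigidParams(theta=[0.1, 0, 0], t=[1, 2, 3], center=template.center)
        assert np.allclose(
            R.composite_apply(p, R.CompositeTransform(rigid=rp)), R.rigid_apply(p, rp)
        )

    def test_serialization_roundtrip(self, template, tmp_path, rng):
        grid = R.make_lattice(template, (4, 4, 3))
        grid.coeffs[...] = rng.standard_normal(grid.coeffs.shape)
        t = R.CompositeTransform(
            rigid=R.RigidParams(theta=[0.1, 0.2, -0.1], t=[1, 2, 3], center=template.center),
            ffd=grid,
        )
        path = tmp_path / "transform.json"
        R.save_transform(t, path)
        loaded = R.load_transform(path)
        p = template.center + rng.uniform(-8, 8, (5, 3))
        assert np.allclose(R.composite_apply(p, loaded), R.composite_apply(p, t))


class TestWarp:
    def test_identity_transform_preserves_volume(self, textured):
        w = R.warp(textured, R.CompositeTransform(), textured)
        assert np.allclose(w.data, textured.data)

    def test_integer_translation_shifts(self, textured):
        # shifting sampling by +2 voxels in x == content moves to lower x
        params = R.RigidParams(t=[2 * textured.spacing[0], 0, 0])
        w = R.warp(textured, R.CompositeTransform(rigid=params), textured)
        assert np.allclose(w.data[:-2], textured.data[2:], atol=1e-10)
        assert np.allclose(w.data[-2:], 0.0)

    def test_constant_volume_interior(self, template, rng):
        const = template.like(np.full(SMALL_SHAPE, 7.0))
        grid = R.make_lattice(template, (4, 4, 3))
        grid.coeffs[...] = rng.standard_normal(grid.coeffs.shape) * 1.0
        w = R.warp(const, R.CompositeTransform(ffd=grid), template)
        interior = w.data[4:-4, 4:-4, 4:-4]
        assert np.abs(interior - 7.0).max() < 1e-10


class TestRegistration:
    def test_self_registration_near_identity(self, textured):
        params = R.register_rigid(textured, textured)
        assert np.linalg.norm(params.theta) < 1e-3
        assert np.all(np.abs(params.t / textured.spacing) < 0.1)

    def test_known_translation_recovered(self, textured):
        true = R.RigidParams(t=np.array([3.0, -2.0, 1.0]) * textured.spacing)
        fixed = R.warp(textured, R.CompositeTransform(rigid=true), textured)
        rec = R.register_rigid(textured, fixed)
        assert np.all(np.abs((rec.t - true.t) / textured.spacing) < 0.5)

    def test_known_rotation_recovered(self, textured):
        true = R.RigidParams(theta=[0, 0, np.deg2rad(5.0)],
                             center=textured.center)
        fixed = R.warp(textured, R.CompositeTransform(rigid=true), textured)
        rec = R.register_rigid(textured, fixed)
        assert abs(np.rad2deg(rec.theta[2] - true.theta[2])) < 0.5

    def test_constant_volume_rejected(self, template):
        const = template.like(np.zeros(SMALL_SHAPE))
        with pytest.raises(ValueError, match="constant"):
            R.register_rigid(const, template)

    def test_bspline_self_registration(self, textured):
        grid = R.register_bspline(textured, textured, (4, 4, 3))
        assert grid.meta["final_ssd"] <= grid.meta["initial_ssd"]
        assert grid.meta["final_ssd"] < 1e-8 * max(grid.meta["initial_ssd"], 1.0)

    def test_known_ffd_recovered(self, textured, rng):
        true = R.make_lattice(textured, (4, 4, 3))
        true.coeffs[...] = rng.standard_normal(true.coeffs.shape) * textured.spacing
        fixed = R.warp(textured, R.CompositeTransform(ffd=true), textured)
        rec = R.register_bspline(textured, fixed, (4, 4, 3))
        assert rec.meta["final_ssd"] <= rec.meta["initial_ssd"]
        weights = R._weight_matrices(textured, true)
        d_true = R._dense_displacement(weights, true.coeffs)
        d_rec = R._dense_displacement(R._weight_matrices(textured, rec), rec.coeffs)
        fg = textured.data > 1.0
        err_vox = (d_rec - d_true)[fg] / textured.spacing
        rms = float(np.sqrt(np.mean(np.sum(err_vox**2, axis=1))))
        assert rms < 0.5

    def test_normalize_to_overlap(self, template):
        spec = CohortSpec(shape=SMALL_SHAPE, seed=5)
        moving = sample_volume(spec, 1)
        warped, transform = R.normalize_to(moving, template, (6, 6, 3))
        wm = warped.data > 1.0
        tm = template.data > 1.0
        dice = 2.0 * np.sum(wm & tm) / (np.sum(wm) + np.sum(tm))
        assert dice >= 0.95
        assert transform.ffd is not None and transform.rigid is not None

    def test_ssd_never_increases(self, template, textured):
        grid = R.register_bspline(
            textured, template, (4, 4, 3),
            R.RegistrationConfig(bspline_max_iter=5),
        )
        assert grid.meta["final_ssd"] <= grid.meta["initial_ssd"]
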