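import numpy as np
import numpy.testing as npt
import pytest

from axdt.forward_model import (
    AXDTOperator,
    Geometry,
    ProjectionStack,
    SphericalHarmonicsField,
    WeightModel,
    forward_darkfield,
    line_backproject,
    line_project,
    load_field,
    load_projections,
    save_field,
    save_projections,
    weight_coeffs,
    weight_coeffs_batch,
)
from axdt.geometry import Pose, euler_rotation
from axdt.schemes import design_Z, legacy_W, sensitivity_from_alpha
from axdt.sphere import SHBasis, sh_eval

from conftest import random_unit_vectors


def small_scheme(hemi, N=2):
    from axdt.sphere import DirectionSet
    return design_Z(DirectionSet(hemi.points[:4]), sensitivity_from_alpha(45), N)


class TestWeightModel:
    def test_maximal_along_sensitivity_zero_along_beam(self, model):
        s = np.array([0.0, 1.0, 0.0])
        t = np.array([0.0, 0.0, 1.0])
        assert model(s[None], s, t)[0] == pytest.approx(1.0)
        assert model(t[None], s, t)[0] == pytest.approx(0.0)

    def test_coefficients_reproduce_the_function(self, model, rng):
        s = np.array([0.6, 0.8, 0.0])
        t = np.array([0.0, 0.0, 1.0])
        c = weight_coeffs(model, s, t)
        q = random_unit_vectors(rng, 50)
        npt.assert_allclose(sh_eval(model.basis, q) @ c, model(q, s, t),
                            atol=1e-12)

    def test_isotropic_coefficient_rotation_invariant(self, model, rng):
        h00 = []
        for _ in range(50):
            s = random_unit_vectors(rng, 1)[0]
            helper = random_unit_vectors(rng, 1)[0]
            t = np.cross(s, helper)
            t /= np.linalg.norm(t)
            h00.append(weight_coeffs(model, s, t)[0])
        npt.assert_allclose(h00, h00[0], atol=1e-12)

    def test_rejects_non_orthogonal_pair(self, model):
        with pytest.raises(ValueError):
            weight_coeffs(model, [0, 1, 0], [0, 1, 0])

    def test_rejects_unknown_form(self):
        with pytest.raises(ValueError):
            WeightModel(form="nope")


class TestLineProjector:
    def test_uniform_volume_axis_aligned_path_length(self, desk_geometry):
        vol = np.ones(desk_geometry.vol_shape)
        img = line_project(vol, np.eye(3), desk_geometry)
        center = img[24, 24]
        assert center == pytest.approx(32.0, rel=0.02)

    def test_zero_volume_projects_to_zero(self, desk_geometry):
        img = line_project(np.zeros(desk_geometry.vol_shape),
                           euler_rotation(Pose(10, 20, 30)), desk_geometry)
        npt.assert_array_equal(img, 0.0)

    def test_adjoint_dot_product_identity(self, desk_geometry, rng):
        for pose in [Pose(0, 0, 0), Pose(33, 55, -70), Pose(-40, 90, 12)]:
            R = euler_rotation(pose)
            v = rng.normal(size=desk_geometry.vol_shape)
            w = rng.normal(size=desk_geometry.det_shape)
            lhs = float((line_project(v, R, desk_geometry) * w).sum())
            rhs = float((v * line_backproject(w, R, desk_geometry)).sum())
            assert abs(lhs - rhs) / abs(lhs) < 1e-10

    def test_linearity(self, desk_geometry, rng):
        R = euler_rotation(Pose(15, 40, 60))
        a = rng.normal(size=desk_geometry.vol_shape)
        b = rng.normal(size=desk_geometry.vol_shape)
        npt.assert_allclose(
            line_project(a + 2.5 * b, R, desk_geometry),
            line_project(a, R, desk_geometry)
            + 2.5 * line_project(b, R, desk_geometry),
            atol=1e-9,
        )


class TestFullOperator:
    def test_adjoint_dot_product(self, hemi, model, desk_geometry, rng):
        op = AXDTOperator(small_scheme(hemi), model, desk_geometry)
        x = rng.normal(size=op.domain_shape)
        y = rng.normal(size=op.range_shape)
        lhs = float((op.apply(x) * y).sum())
        rhs = float((x * op.adjoint(y)).sum())
        assert abs(lhs - rhs) / abs(lhs) < 1e-8

    def test_linearity(self, hemi, model, desk_geometry, rng):
        op = AXDTOperator(small_scheme(hemi), model, desk_geometry)
        a = rng.normal(size=op.domain_shape)
        b = rng.normal(size=op.domain_shape)
        npt.assert_allclose(op.apply(a - 3.0 * b),
                            op.apply(a) - 3.0 * op.apply(b), atol=1e-9)

    def test_single_coefficient_reduces_to_weighted_projection(
            self, hemi, model, desk_geometry, rng):
        scheme = small_scheme(hemi, N=1)
        op = AXDTOperator(scheme, model, desk_geometry)
        j = 3
        x = np.zeros(op.domain_shape)
        x[..., j] = rng.normal(size=desk_geometry.vol_shape)
        p = op.apply(x)
        R = scheme.rotations()[0]
        expected = op.H[0, j] * line_project(x[..., j], R, desk_geometry)
        npt.assert_allclose(p[0], expected, atol=1e-12)

    def test_matches_literal_sum_over_coefficients(
            self, hemi, model, desk_geometry, rng):
        """Cross-check the operator against the measurement equation spelled
        out term by term: p = (1/4pi) sum_km h_km * P eta_km."""
        scheme = small_scheme(hemi, N=2)
        field = SphericalHarmonicsField(
            rng.normal(size=desk_geometry.vol_shape + (15,)))
        stack = forward_darkfield(field, scheme, model, desk_geometry)
        rots = scheme.rotations()
        svecs = rots @ scheme.S
        tvecs = rots @ scheme.T
        H = weight_coeffs_batch(model, svecs, tvecs)
        for i in range(len(scheme)):
            p_literal = np.zeros(desk_geometry.det_shape)
            for j in range(15):
                p_literal += H[i, j] * line_project(field.coeffs[..., j],
                                                    rots[i], desk_geometry)
            p_literal /= 4.0 * np.pi
            npt.assert_allclose(stack.p[i], p_literal, atol=1e-10)


class TestForwardDarkfield:
    def test_zero_field_gives_unit_transmission(self, hemi, model,
                                                desk_geometry):
        field = SphericalHarmonicsField(
            np.zeros(desk_geometry.vol_shape + (15,)))
        stack = forward_darkfield(field, small_scheme(hemi), model,
                                  desk_geometry)
        npt.assert_array_equal(stack.d, 1.0)

    def test_isotropic_field_ignores_grating_orientation(self, hemi,
                                                         desk_geometry):
        """For a purely isotropic field the signal depends on the pose only
        through the path length, not through the sensitivity direction."""
        coeffs = np.zeros(desk_geometry.vol_shape + (15,))
        coeffs[..., 0] = 0.3
        field = SphericalHarmonicsField(coeffs)
        from axdt.schemes import base_scheme
        pA = forward_darkfield(field, base_scheme(0, 0, 4, S=[0, 1, 0]),
                               geometry=desk_geometry).p
        pB = forward_darkfield(field, base_scheme(0, 0, 4, S=[1, 0, 0]),
                               geometry=desk_geometry).p
        npt.assert_allclose(pA, pB, atol=1e-10)

    def test_log_domain_linearity(self, hemi, model, desk_geometry, rng):
        coeffs = np.abs(rng.normal(size=desk_geometry.vol_shape + (15,)))
        scheme = small_scheme(hemi)
        p1 = forward_darkfield(SphericalHarmonicsField(coeffs), scheme,
                               model, desk_geometry).p
        p2 = forward_darkfield(SphericalHarmonicsField(2 * coeffs), scheme,
                               model, desk_geometry).p
        npt.assert_allclose(p2, 2 * p1, atol=1e-9)

    def test_nonnegative_field_transmission_in_unit_interval(
            self, hemi, model, desk_geometry):
        from axdt.phantom import build_phantom, weldline_phantom
        field, _ = build_phantom(weldline_phantom())
        stack = forward_darkfield(field, small_scheme(hemi), model,
                                  desk_geometry)
        assert stack.d.min() > 0.0
        assert stack.d.max() <= 1.0
        npt.assert_allclose(stack.p, -np.log(stack.d), atol=1e-12)


class TestIO:
    def test_projection_round_trip(self, hemi, model, desk_geometry,
                                   tmp_path, rng):
        scheme = small_scheme(hemi)
        field = SphericalHarmonicsField(
            np.abs(rng.normal(size=desk_geometry.vol_shape + (15,))))
        stack = forward_darkfield(field, scheme, model, desk_geometry)
        save_projections(tmp_path / "proj.h5", stack)
        back = load_projections(tmp_path / "proj.h5")
        npt.assert_allclose(back.p, stack.p)
        npt.assert_allclose(back.scheme.poses, scheme.poses)
        assert back.geometry == desk_geometry

    def test_field_round_trip_h5_and_nifti(self, tmp_path, rng):
        field = SphericalHarmonicsField(rng.normal(size=(6, 5, 4, 15)),
                                        spacing=2.0)
        for name in ["field.h5", "field.nii"]:
            save_field(tmp_path / name, field)
            back = load_field(tmp_path / name)
            npt.assert_allclose(back.coeffs, field.coeffs, atol=1e-12)
            assert back.spacing == pytest.approx(2.0)
            assert back.basis.K == 4
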