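import numpy as np
import numpy.testing as npt
import pytest

from axdt.forward_model import SphericalHarmonicsField
from axdt.metrics import (
    OrientationField,
    coverage_surrogate,
    experimental_metric,
    extract_orientations,
)
from axdt.phantom import build_phantom, weldline_phantom, FiberRegion, PhantomSpec
from axdt.schemes import (
    SetupLimits,
    design_Z,
    legacy_W,
    sensitivity_from_alpha,
    truncate_scheme,
)
from axdt.sphere import fibonacci_hemisphere

from conftest import random_unit_vectors


def uniform_orientations(rng, shape):
    v = random_unit_vectors(rng, int(np.prod(shape)))
    return OrientationField(v.reshape(shape + (3,)), np.ones(shape, bool))


class TestOrientationField:
    def test_rejects_non_unit_vectors(self):
        with pytest.raises(ValueError):
            OrientationField(np.full((2, 2, 2, 3), 0.4), np.ones((2, 2, 2), bool))

    def test_masked_voxels_unconstrained(self):
        v = np.zeros((2, 2, 2, 3))
        mask = np.zeros((2, 2, 2), bool)
        OrientationField(v, mask)  # no error


class TestExtractOrientations:
    def test_single_fiber_structure_mode_recovers_axis(self):
        f = np.array([0.0, 0.6, 0.8])
        spec = PhantomSpec(shape=(4, 4, 4), regions=(
            FiberRegion((0, 0, 0), (4, 4, 4), tuple(f)),))
        field, truth = build_phantom(spec)
        ori = extract_orientations(field, mode="structure")
        dots = np.abs(ori.vectors.reshape(-1, 3) @ f)
        ang = np.degrees(np.arccos(np.clip(dots, 0, 1)))
        assert ang.max() < 5.0

    def test_scattering_mode_orthogonal_to_fiber(self):
        f = np.array([0.0, 0.0, 1.0])
        spec = PhantomSpec(shape=(3, 3, 3), regions=(
            FiberRegion((0, 0, 0), (3, 3, 3), tuple(f)),))
        field, _ = build_phantom(spec)
        ori = extract_orientations(field, mode="scattering")
        dots = np.abs(ori.vectors.reshape(-1, 3) @ f)
        ang = np.degrees(np.arccos(np.clip(dots, 0, 1)))
        assert ang.min() > 85.0

    def test_isotropic_voxels_masked_undefined(self):
        coeffs = np.zeros((3, 3, 3, 15))
        coeffs[..., 0] = 1.0
        ori = extract_orientations(SphericalHarmonicsField(coeffs))
        assert not ori.mask.any()

    def test_rejects_empty_grid(self):
        coeffs = np.zeros((2, 2, 2, 15))
        from axdt.sphere import DirectionSet
        with pytest.raises(ValueError):
            extract_orientations(SphericalHarmonicsField(coeffs),
                                 DirectionSet(np.empty((0, 3))))

    def test_rejects_unknown_mode(self):
        coeffs = np.zeros((2, 2, 2, 15))
        with pytest.raises(ValueError):
            extract_orientations(SphericalHarmonicsField(coeffs), mode="best")


class TestExperimentalMetric:
    def test_self_comparison_is_one(self, rng):
        X = uniform_orientations(rng, (5, 5, 5))
        assert experimental_metric(X, X) == pytest.approx(1.0)

    def test_orthogonal_fields_score_zero(self):
        shape = (4, 4, 4)
        a = np.zeros(shape + (3,)); a[..., 0] = 1.0
        b = np.zeros(shape + (3,)); b[..., 1] = 1.0
        mask = np.ones(shape, bool)
        em = experimental_metric(OrientationField(a, mask),
                                 OrientationField(b, mask))
        assert em == pytest.approx(0.0)

    def test_random_against_fixed_averages_one_half(self, rng):
        shape = (22, 22, 22)  # > 10^4 voxels
        X = uniform_orientations(rng, shape)
        ref = np.zeros(shape + (3,)); ref[..., 2] = 1.0
        em = experimental_metric(X, OrientationField(ref, np.ones(shape, bool)))
        assert em == pytest.approx(0.5, abs=0.02)

    def test_symmetric_and_sign_invariant(self, rng):
        X = uniform_orientations(rng, (4, 4, 4))
        Y = uniform_orientations(rng, (4, 4, 4))
        assert experimental_metric(X, Y) == pytest.approx(
            experimental_metric(Y, X))
        flipped = OrientationField(-Y.vectors, Y.mask)
        assert experimental_metric(X, flipped) == pytest.approx(
            experimental_metric(X, Y))

    def test_empty_roi_rejected(self, rng):
        X = uniform_orientations(rng, (2, 2, 2))
        with pytest.raises(ValueError):
            experimental_metric(X, X, roi=np.zeros((2, 2, 2), bool))


class TestCoverageSurrogate:
    def test_single_pose_touches_one_sector(self, hemi):
        from axdt.schemes import base_scheme
        cm = coverage_surrogate(base_scheme(0, 0, 1), hemi, n_sectors=18)
        assert 0 < cm <= 1.0 / (28 * 18) + 1e-12

    def test_truncation_reduces_coverage(self, hemi):
        Z = design_Z(hemi, sensitivity_from_alpha(45), 20)
        Zt = truncate_scheme(Z, SetupLimits(40.0))
        assert coverage_surrogate(Z, hemi) > coverage_surrogate(Zt, hemi)

    def test_monotone_under_adding_poses(self, hemi):
        Z = design_Z(hemi, sensitivity_from_alpha(45), 8)
        import dataclasses
        half = dataclasses.replace(Z, poses=Z.poses[::2], targets=None)
        assert coverage_surrogate(Z, hemi) >= coverage_surrogate(half, hemi)

    def test_ranking_of_truncated_schemes(self, hemi):
        """Diagonal gratings cover at least as well as the alternatives."""
        lim = SetupLimits(40.0)
        N = 20
        cms = {}
        for name, alpha in [("D", 45.0), ("H", 90.0), ("V", 0.0)]:
            Z = truncate_scheme(design_Z(hemi, sensitivity_from_alpha(alpha), N), lim)
            cms[name] = coverage_surrogate(Z, hemi)
        cms["W"] = coverage_surrogate(legacy_W(N), hemi)
        assert cms["D"] >= cms["H"]
        assert cms["D"] >= cms["V"]
        assert cms["D"] >= cms["W"]

    def test_rejects_empty_scheme(self, hemi):
        from axdt.schemes import AcquisitionScheme
        empty = legacy_W(1)
        import dataclasses
        with pytest.raises(ValueError):
            coverage_surrogate(
                dataclasses.replace(empty, poses=np.empty((0, 3))), hemi)


class TestOrientationIO:
    def test_nifti_round_trip(self, tmp_path, rng):
        X = uniform_orientations(rng, (4, 5, 6))
        X.mask[0, 0, :] = False
        X.vectors[0, 0, :] = 0.0
        from axdt.metrics import load_orientations, save_orientations
        save_orientations(tmp_path / "ori.nii", X)
        back = load_orientations(tmp_path / "ori.nii")
        np.testing.assert_array_equal(back.mask, X.mask)
        np.testing.assert_allclose(back.vectors[back.mask],
                                   X.vectors[X.mask], atol=1e-7)

    def test_csv_lists_defined_voxels(self, tmp_path, rng):
        import pandas as pd
        from axdt.metrics import save_orientations
        X = uniform_orientations(rng, (3, 3, 3))
        X.mask[1, 1, 1] = False
        X.vectors[1, 1, 1] = 0.0
        save_orientations(tmp_path / "ori.csv", X)
        df = pd.read_csv(tmp_path / "ori.csv")
        assert len(df) == 26
        assert list(df.columns) == ["i", "j", "k", "ux", "uy", "uz"]
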