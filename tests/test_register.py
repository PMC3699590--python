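"""Registration engines, warping and displacement-field algebra."""
import numpy as np
import pytest

from popatlas.register import (
    AffineTransform,
    DisplacementField,
    RegConfig,
    average_fields,
    chain_resample,
    compose_fields,
    mean_displacement,
    mutual_information,
    register_affine_mi,
    register_elastic,
    warp_volume,
)
from popatlas.synthpop import SynthParams, make_phantom, random_deformation
from popatlas.volio import Volume

from conftest import sinusoidal_field


class TestMutualInformation:
    def test_self_information_equals_entropy(self, phantom32):
        vol, _ = phantom32
        bins = 32
        mi = mutual_information(vol, vol, bins)
        hist, _ = np.histogram(vol.data.ravel(), bins=bins)
        p = hist / hist.sum()
        p = p[p > 0]
        entropy = -(p * np.log2(p)).sum()
        assert mi == pytest.approx(entropy, rel=1e-10)

    def test_symmetry(self, phantom32):
        vol, _ = phantom32
        rng = np.random.default_rng(0)
        other = Volume(rng.normal(size=vol.shape))
        assert mutual_information(vol, other) == pytest.approx(
            mutual_information(other, vol), abs=1e-12
        )

    def test_independent_noise_near_zero(self):
        rng = np.random.default_rng(42)
        a = Volume(rng.normal(size=(48, 48, 48)))
        b = Volume(rng.normal(size=(48, 48, 48)))
        assert 0.0 <= mutual_information(a, b, 32) < 0.05

    def test_shape_mismatch_raises(self):
        with pytest.raises(ValueError):
            mutual_information(Volume(np.zeros((4, 4, 4))), Volume(np.zeros((5, 4, 4))))


class TestAffineTransform:
    def test_singular_matrix_rejected(self):
        with pytest.raises(ValueError):
            AffineTransform(np.zeros((3, 3)), np.zeros(3))

    def test_json_round_trip(self, tmp_path):
        t = AffineTransform(np.diag([1.0, 2.0, 0.5]), [1.0, -2.0, 3.0])
        t.to_json(tmp_path / "t.json")
        back = AffineTransform.from_json(tmp_path / "t.json")
        np.testing.assert_allclose(back.matrix, t.matrix)
        np.testing.assert_allclose(back.translation, t.translation)

    def test_inverse_composes_to_identity(self):
        t = AffineTransform(np.diag([1.1, 0.9, 1.0]), [2.0, 0.0, -1.0])
        pts = np.random.default_rng(0).normal(size=(10, 3))
        np.testing.assert_allclose(t.inverse().apply(t.apply(pts)), pts, atol=1e-12)


class TestAffineMI:
    def test_self_registration_near_identity(self, noisy_phantom32):
        vol, _ = noisy_phantom32
        t = register_affine_mi(vol, vol, RegConfig())
        assert np.abs(t.matrix - np.eye(3)).max() < 1e-2
        assert np.abs(t.translation).max() < 1e-2

    def test_translation_recovery(self, noisy_phantom32):
        from scipy import ndimage

        vol, _ = noisy_phantom32
        shift = np.array([3.0, -2.0, 1.0])
        moving = Volume(ndimage.shift(vol.data.astype(float), -shift, order=1))
        t = register_affine_mi(vol, moving, RegConfig())
        np.testing.assert_allclose(t.translation, -shift, atol=0.5)

    def test_multimodal_monotone_remap(self, noisy_phantom32):
        from scipy import ndimage

        vol, _ = noisy_phantom32
        remapped = np.sqrt(vol.data - vol.data.min() + 1.0)  # monotone nonlinearity
        moving = Volume(ndimage.shift(remapped, (-2.0, 0.0, 0.0), order=1))
        t = register_affine_mi(vol, moving, RegConfig())
        np.testing.assert_allclose(t.translation, [-2.0, 0.0, 0.0], atol=0.5)


class TestElastic:
    def test_identity_pair_gives_zero_field(self, phantom32):
        vol, _ = phantom32
        d = register_elastic(vol, vol, RegConfig())
        assert mean_displacement(d) < 0.1

    def test_recovers_smooth_sinusoidal_field(self, phantom48):
        vol, lab = phantom48
        truth = sinusoidal_field(vol.shape, amplitude=2.0, wavelength=48.0)
        moving_is_base = warp_volume(vol, truth)
        d = register_elastic(Volume(moving_is_base.data), vol, RegConfig())
        err = np.sqrt(((d.vectors - truth.vectors) ** 2).sum(-1))
        fg = lab.labels > 0
        assert err[fg].mean() < 0.5

    def test_correlation_never_decreases(self, phantom48):
        vol, _ = phantom48
        truth = random_deformation(vol.shape, 2.0, 6.0, 7)
        fixed = warp_volume(vol, truth)
        d = register_elastic(Volume(fixed.data), vol, RegConfig())
        before = np.corrcoef(fixed.data.ravel(), vol.data.ravel())[0, 1]
        after = np.corrcoef(
            fixed.data.ravel(), warp_volume(vol, d).data.ravel()
        )[0, 1]
        assert after >= before

    def test_flat_image_warns_zero_field(self):
        flat = Volume(np.zeros((24, 24, 24)))
        with pytest.warns(UserWarning):
            d = register_elastic(flat, flat, RegConfig())
        np.testing.assert_array_equal(d.vectors, 0.0)

    def test_shape_mismatch_raises(self, phantom32):
        vol, _ = phantom32
        with pytest.raises(ValueError):
            register_elastic(vol, Volume(np.zeros((8, 8, 8))), RegConfig())


class TestWarp:
    def test_zero_field_identity_both_modes(self, phantom32):
        vol, _ = phantom32
        zero = DisplacementField.zero(vol.shape)
        for interp in ("trilinear", "nearest"):
            out = warp_volume(vol, zero, interp=interp)
            np.testing.assert_array_equal(out.data, vol.data)

    def test_subvoxel_shift_of_linear_ramp_is_exact(self):
        shape = (12, 12, 12)
        idx = np.indices(shape).astype(float)
        ramp = Volume(2.0 * idx[0] + 0.5)
        d = DisplacementField(np.zeros(shape + (3,)) + [1.5, 0, 0])
        out = warp_volume(ramp, d)
        expected = 2.0 * (idx[0] + 1.5) + 0.5
        interior = (slice(0, 10), slice(None), slice(None))
        np.testing.assert_allclose(out.data[interior], expected[interior], atol=1e-12)

    def test_integer_translation_nearest_preserves_labels(self, tiny_regions):
        from popatlas.volio import LabelMap

        rng = np.random.default_rng(0)
        labels = rng.integers(0, 4, size=(12, 12, 12)).astype(np.int32)
        vol = Volume(labels)
        d = DisplacementField(np.zeros((12, 12, 12, 3)) + [2, 0, 0])
        out = warp_volume(vol, d, interp="nearest")
        np.testing.assert_array_equal(out.data[:10], labels[2:])

    def test_unknown_interp_raises(self, phantom32):
        vol, _ = phantom32
        with pytest.raises(ValueError):
            warp_volume(vol, DisplacementField.zero(vol.shape), interp="cubic")


class TestFieldAlgebra:
    def test_mean_displacement_cases(self):
        zero = DisplacementField.zero((4, 4, 4))
        assert mean_displacement(zero) == 0.0
        const = DisplacementField(np.zeros((4, 4, 4, 3)) + [3.0, 4.0, 0.0])
        assert mean_displacement(const) == pytest.approx(5.0)

    def test_mean_displacement_matches_naive_loop(self):
        rng = np.random.default_rng(11)
        vec = rng.normal(size=(6, 5, 4, 3))
        d = DisplacementField(vec)
        total = 0.0
        for i in range(6):
            for j in range(5):
                for k in range(4):
                    total += np.linalg.norm(vec[i, j, k])
        assert mean_displacement(d) == pytest.approx(total / (6 * 5 * 4), rel=1e-12)

    def test_mean_displacement_empty_mask_raises(self):
        with pytest.raises(ValueError):
            mean_displacement(DisplacementField.zero((4, 4, 4)), np.zeros((4, 4, 4), bool))

    def test_average_fields_cases(self):
        rng = np.random.default_rng(2)
        f = DisplacementField(rng.normal(size=(4, 4, 4, 3)))
        neg = DisplacementField(-f.vectors)
        np.testing.assert_allclose(average_fields([f, neg]).vectors, 0.0, atol=1e-15)
        np.testing.assert_array_equal(average_fields([f]).vectors, f.vectors)

    def test_average_fields_matches_naive_mean(self):
        rng = np.random.default_rng(5)
        fields = [DisplacementField(rng.normal(size=(4, 4, 4, 3))) for _ in range(3)]
        got = average_fields(fields).vectors
        expected = (fields[0].vectors + fields[1].vectors + fields[2].vectors) / 3
        np.testing.assert_allclose(got, expected, atol=1e-15)

    def test_average_fields_errors(self):
        with pytest.raises(ValueError):
            average_fields([])
        with pytest.raises(ValueError):
            average_fields(
                [DisplacementField.zero((4, 4, 4)), DisplacementField.zero((5, 4, 4))]
            )

    def test_compose_constant_fields_add(self):
        shape = (10, 10, 10)
        a = DisplacementField(np.zeros(shape + (3,)) + [1.0, -2.0, 0.5])
        b = DisplacementField(np.zeros(shape + (3,)) + [0.5, 1.0, 0.0])
        out = compose_fields(a, b).vectors
        # interior voxels see a + b exactly; near the border the inner field
        # is sampled out of bounds (zero fill)
        interior = (slice(2, 8),) * 3
        expected = np.broadcast_to([1.5, -1.0, 0.5], (6, 6, 6, 3))
        np.testing.assert_allclose(out[interior], expected, atol=1e-12)

    def test_compose_linear_inner_field_is_exact(self):
        # trilinear sampling reproduces an affine-in-x field exactly
        shape = (10, 10, 10)
        idx = np.indices(shape).astype(float)
        inner = np.zeros(shape + (3,))
        inner[..., 1] = 0.25 * idx[0]
        outer = DisplacementField(np.zeros(shape + (3,)) + [1.0, 0.0, 0.0])
        out = compose_fields(outer, DisplacementField(inner)).vectors
        expected_y = 0.25 * (idx[0] + 1.0)
        interior = (slice(0, 8), slice(None), slice(None))
        np.testing.assert_allclose(out[..., 1][interior], expected_y[interior], atol=1e-12)
        np.testing.assert_allclose(out[..., 0][interior], 1.0)

    def test_chain_resample_affine_only_matches_warp(self, phantom32):
        vol, _ = phantom32
        t = AffineTransform(np.eye(3), [1.0, 0.0, -2.0])
        a = chain_resample(vol.data, affine=t, order=1)
        b = warp_volume(vol, t).data
        np.testing.assert_allclose(a, b, atol=1e-10)
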