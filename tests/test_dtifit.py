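"""Tensor estimation: reorientation, OLS fit, eigenanalysis, FA/MD."""
import numpy as np
import pytest

from popatlas.dtifit import (
    DWISet,
    TensorImage,
    eigen_decompose,
    fa,
    fa_color,
    fit_tensor,
    md,
    predict_signals,
    read_bvals_bvecs,
    reorient_bvecs,
    write_bvals_bvecs,
)
from popatlas.synthpop import fibonacci_directions
from popatlas.volio import Volume


def _dwiset_from_tensor(D, bvecs, bval=1000.0, s0=100.0, shape=(3, 3, 3)):
    signals = []
    for g in bvecs:
        s = s0 * np.exp(-bval * g @ D @ g)
        signals.append(Volume(np.full(shape, s)))
    b0 = Volume(np.full(shape, s0))
    return DWISet(b0, signals, np.full(len(bvecs), bval), bvecs)


class TestReorient:
    def test_identity_unchanged(self):
        g = fibonacci_directions(12)
        np.testing.assert_allclose(reorient_bvecs(g, np.eye(3)), g, atol=1e-12)

    def test_rotation_about_z(self):
        Rz = np.array([[0.0, -1.0, 0.0], [1.0, 0.0, 0.0], [0.0, 0.0, 1.0]])
        out = reorient_bvecs(np.array([[1.0, 0.0, 0.0]]), Rz)
        np.testing.assert_allclose(out, [[0.0, 1.0, 0.0]], atol=1e-12)

    def test_pure_scaling_leaves_directions(self):
        # polar decomposition of a positive diagonal is the identity rotation
        A = np.diag([1.2, 0.9, 1.0])
        g = fibonacci_directions(10)
        np.testing.assert_allclose(reorient_bvecs(g, A), g, atol=1e-12)
        # cross-check R against an SVD-based polar decomposition
        u, _, vt = np.linalg.svd(A)
        np.testing.assert_allclose(u @ vt, np.eye(3), atol=1e-12)

    def test_preserves_pairwise_angles(self):
        rng = np.random.default_rng(3)
        A = rng.normal(size=(3, 3)) + 3 * np.eye(3)
        g = fibonacci_directions(8)
        out = reorient_bvecs(g, A)
        np.testing.assert_allclose(out @ out.T, g @ g.T, atol=1e-9)

    def test_singular_affine_raises(self):
        with pytest.raises(ValueError):
            reorient_bvecs(fibonacci_directions(6), np.zeros((3, 3)))


class TestFitTensor:
    def test_recovers_known_tensor(self):
        D = np.diag([1.7e-3, 0.3e-3, 0.3e-3])
        bvecs = fibonacci_directions(12)
        dwi = _dwiset_from_tensor(D, bvecs)
        t = fit_tensor(dwi, np.ones((3, 3, 3), bool))
        assert t.mask.all()
        got = t.full_tensors()[1, 1, 1]
        np.testing.assert_allclose(got, D, atol=1e-8)

    def test_equal_signals_give_zero_tensor(self):
        bvecs = fibonacci_directions(8)
        dwi = _dwiset_from_tensor(np.zeros((3, 3)), bvecs)
        t = fit_tensor(dwi, np.ones((3, 3, 3), bool))
        np.testing.assert_allclose(t.components, 0.0, atol=1e-12)

    def test_outside_mask_zero_and_unfit(self):
        bvecs = fibonacci_directions(8)
        dwi = _dwiset_from_tensor(np.diag([1e-3] * 3), bvecs)
        mask = np.zeros((3, 3, 3), bool)
        mask[1, 1, 1] = True
        t = fit_tensor(dwi, mask)
        assert t.mask[1, 1, 1]
        assert not t.mask[0, 0, 0]
        np.testing.assert_array_equal(t.components[0, 0, 0], np.zeros(6))

    def test_dropped_nonpositive_measurements(self):
        D = np.diag([1.2e-3, 0.4e-3, 0.4e-3])
        bvecs = fibonacci_directions(10)
        dwi = _dwiset_from_tensor(D, bvecs)
        # corrupt three measurements at one voxel: fit should drop them
        for j in range(3):
            dwi.weighted[j].data[1, 1, 1] = 0.0
        t = fit_tensor(dwi, np.ones((3, 3, 3), bool))
        assert t.mask[1, 1, 1]
        np.testing.assert_allclose(t.full_tensors()[1, 1, 1], D, atol=1e-8)

    def test_too_few_directions_raises(self):
        bvecs = fibonacci_directions(5)
        dwi = _dwiset_from_tensor(np.diag([1e-3] * 3), bvecs)
        with pytest.raises(ValueError):
            fit_tensor(dwi, np.ones((3, 3, 3), bool))

    def test_forward_model_round_trip(self):
        D = np.array(
            [[1.5e-3, 2e-4, 1e-4], [2e-4, 0.8e-3, 5e-5], [1e-4, 5e-5, 0.5e-3]]
        )
        bvecs = fibonacci_directions(15)
        dwi = _dwiset_from_tensor(D, bvecs)
        t = fit_tensor(dwi, np.ones((3, 3, 3), bool))
        pred = predict_signals(t, dwi.bvals, dwi.bvecs, 100.0)
        obs = np.stack([v.data for v in dwi.weighted])
        np.testing.assert_allclose(pred, obs, atol=1e-8)


def char_poly_roots(T):
    """Eigenvalues as roots of the characteristic polynomial."""
    c2 = -np.trace(T)
    c1 = 0.5 * (np.trace(T) ** 2 - np.trace(T @ T))
    c0 = -np.linalg.det(T)
    roots = np.roots([1.0, c2, c1, c0])
    return np.sort(roots.real)[::-1]


class TestEigen:
    def _single(self, T):
        comps = np.array(
            [T[0, 0], T[1, 1], T[2, 2], T[0, 1], T[0, 2], T[1, 2]]
        ).reshape(1, 1, 1, 6)
        return TensorImage(comps, np.ones((1, 1, 1), bool))

    def test_diagonal(self):
        evals, e1, degen = eigen_decompose(self._single(np.diag([3.0, 2.0, 1.0])))
        np.testing.assert_allclose(evals[0, 0, 0], [3, 2, 1])
        np.testing.assert_allclose(e1[0, 0, 0], [1, 0, 0], atol=1e-12)
        assert not degen[0, 0, 0]

    def test_isotropic_flagged_degenerate(self):
        evals, _, degen = eigen_decompose(self._single(np.eye(3)))
        np.testing.assert_allclose(evals[0, 0, 0], [1, 1, 1])
        assert degen[0, 0, 0]

    @pytest.mark.parametrize("seed", [0, 1, 2])
    def test_matches_characteristic_polynomial(self, seed):
        rng = np.random.default_rng(seed)
        M = rng.normal(size=(3, 3))
        T = (M + M.T) / 2
        evals, e1, _ = eigen_decompose(self._single(T))
        np.testing.assert_allclose(evals[0, 0, 0], char_poly_roots(T), atol=1e-9)
        v = e1[0, 0, 0]
        assert np.linalg.norm(v) == pytest.approx(1.0)
        np.testing.assert_allclose(T @ v, evals[0, 0, 0, 0] * v, atol=1e-9)


class TestScalars:
    @pytest.mark.parametrize(
        "lam,expected_fa,expected_md",
        [
            ((1, 1, 1), 0.0, 1.0),
            ((1, 0, 0), 1.0, 1 / 3),
            ((2, 1, 1), 1 / np.sqrt(6), 4 / 3),
        ],
    )
    def test_closed_forms(self, lam, expected_fa, expected_md):
        assert fa(np.array(lam, float)) == pytest.approx(expected_fa, abs=1e-12)
        assert md(np.array(lam, float)) == pytest.approx(expected_md, abs=1e-12)

    def test_zero_tensor_fa_is_zero(self):
        assert fa(np.zeros(3)) == 0.0

    @pytest.mark.parametrize("seed", [0, 4])
    def test_fa_invariant_to_permutation_and_scale(self, seed):
        rng = np.random.default_rng(seed)
        lam = rng.uniform(0.1, 2.0, 3)
        ref = fa(lam)
        for perm in [(1, 0, 2), (2, 1, 0), (0, 2, 1)]:
            assert fa(lam[list(perm)]) == pytest.approx(ref, rel=1e-12)
        assert fa(3.7 * lam) == pytest.approx(ref, rel=1e-12)

    def test_fa_color_cases(self):
        rgb = fa_color(np.array(1.0), np.array([1.0, 0.0, 0.0]))
        np.testing.assert_allclose(rgb, [1, 0, 0])
        rgb = fa_color(np.array(0.0), np.array([0.3, 0.5, 0.8]))
        np.testing.assert_allclose(rgb, [0, 0, 0])
        e = np.ones(3) / np.sqrt(3)
        rgb = fa_color(np.array(0.5), e)
        np.testing.assert_allclose(rgb, 0.5 / np.sqrt(3), rtol=1e-12)


class TestGradientIO:
    def test_fsl_round_trip(self, tmp_path):
        bvals = np.array([0.0, 1000, 1000, 2000])
        bvecs = np.vstack([[0, 0, 0], fibonacci_directions(3)])
        write_bvals_bvecs(bvals, bvecs, tmp_path / "bvals", tmp_path / "bvecs")
        bv, gv = read_bvals_bvecs(tmp_path / "bvals", tmp_path / "bvecs")
        np.testing.assert_allclose(bv, bvals)
        np.testing.assert_allclose(gv, bvecs, atol=1e-8)
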