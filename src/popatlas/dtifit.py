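"""Diffusion-tensor estimation and derived scalar maps.

Implements the standard single-tensor pipeline: ordinary least squares on
the log-linearized monoexponential model

    ln(S_j / S0) = -b_j g_j^T D g_j,

per-voxel eigenanalysis, fractional anisotropy (FA), mean diffusivity (MD)
and direction-encoded FA-color maps.  Gradient tables follow the FSL text
convention (one row of b-values; bvecs as three rows, one per axis).
Gradient directions are re-expressed after affine alignment by applying the
rotation component of the transform (polar decomposition).
"""
from __future__ import annotations

from dataclasses import dataclass

import numpy as np
from scipy.linalg import polar

from .register import AffineTransform
from .volio import Volume

__all__ = [
    "DWISet",
    "TensorImage",
    "read_bvals_bvecs",
    "write_bvals_bvecs",
    "reorient_bvecs",
    "fit_tensor",
    "eigen_decompose",
    "fa",
    "md",
    "fa_color",
    "predict_signals",
]

# component order for the 6-vector tensor representation
TENSOR_COMPONENTS = ("Dxx", "Dyy", "Dzz", "Dxy", "Dxz", "Dyz")


@dataclass
class DWISet:
    """A diffusion-weighted acquisition: baseline + weighted volumes.

    ``bvals`` are in s/mm^2 and ``bvecs`` are unit gradient directions,
    one row per weighted volume.
    """

    b0: Volume
    weighted: list
    bvals: np.ndarray
    bvecs: np.ndarray

    def __post_init__(self):
        self.bvals = np.asarray(self.bvals, dtype=float).ravel()
        self.bvecs = np.asarray(self.bvecs, dtype=float).reshape(-1, 3)
        n = len(self.weighted)
        if not (len(self.bvals) == len(self.bvecs) == n):
            raise ValueError(
                f"inconsistent DWI set: {n} volumes, {len(self.bvals)} bvals, "
                f"{len(self.bvecs)} bvecs"
            )
        norms = np.linalg.norm(self.bvecs, axis=1)
        if np.any(np.abs(norms - 1.0) > 1e-6):
            raise ValueError("bvecs must be unit vectors (within 1e-6)")
        if self.b0.data.min() < 0:
            raise ValueError("b0 volume must be non-negative")
        shapes = {v.shape for v in self.weighted} | {self.b0.shape}
        if len(shapes) != 1:
            raise ValueError(f"volume shapes differ: {shapes}")


@dataclass
class TensorImage:
    """Per-voxel symmetric tensors as 6 components (mm^2/s) plus fit mask.

    Component order is Dxx, Dyy, Dzz, Dxy, Dxz, Dyz.  Values are zero
    outside the fitted mask.
    """

    components: np.ndarray
    mask: np.ndarray

    def __post_init__(self):
        self.components = np.asarray(self.components, dtype=float)
        self.mask = np.asarray(self.mask, dtype=bool)
        if self.components.ndim != 4 or self.components.shape[-1] != 6:
            raise ValueError("components must have shape (X, Y, Z, 6)")
        if self.mask.shape != self.components.shape[:3]:
            raise ValueError("mask shape mismatch")
        if not np.all(np.isfinite(self.components[self.mask])):
            raise ValueError("non-finite tensor components inside mask")

    def full_tensors(self) -> np.ndarray:
        """Expand to an (X, Y, Z, 3, 3) array of symmetric matrices."""
        c = self.components
        t = np.empty(c.shape[:3] + (3, 3))
        t[..., 0, 0] = c[..., 0]
        t[..., 1, 1] = c[..., 1]
        t[..., 2, 2] = c[..., 2]
        t[..., 0, 1] = t[..., 1, 0] = c[..., 3]
        t[..., 0, 2] = t[..., 2, 0] = c[..., 4]
        t[..., 1, 2] = t[..., 2, 1] = c[..., 5]
        return t


def read_bvals_bvecs(bval_path, bvec_path):
    """Read FSL-style gradient tables -> (bvals (N,), bvecs (N, 3))."""
    bvals = np.loadtxt(bval_path).ravel()
    bvecs = np.loadtxt(bvec_path)
    if bvecs.shape[0] == 3 and bvecs.shape != (3, 3):
        bvecs = bvecs.T
    elif bvecs.ndim == 1:
        bvecs = bvecs.reshape(1, 3)
    if bvecs.shape != (len(bvals), 3):
        raise ValueError(
            f"bvals ({len(bvals)}) and bvecs ({bvecs.shape}) are inconsistent"
        )
    return bvals, bvecs


def write_bvals_bvecs(bvals, bvecs, bval_path, bvec_path) -> None:
    np.savetxt(bval_path, np.asarray(bvals).reshape(1, -1), fmt="%.6g")
    np.savetxt(bvec_path, np.asarray(bvecs).T, fmt="%.9g")


def reorient_bvecs(bvecs: np.ndarray, affine) -> np.ndarray:
    """Rotate gradient directions to follow an affine realignment.

    Only the rotation component matters for directions: the affine is split
    by polar decomposition A = R S (R orthogonal, S symmetric positive
    definite) and R is applied; pure scalings and shears therefore leave the
    directions unchanged up to renormalization.
    """
    A = affine.matrix if isinstance(affine, AffineTransform) else np.asarray(affine, float)
    A = A.reshape(3, 3)
    if abs(np.linalg.det(A)) <= 1e-12:
        raise ValueError("affine matrix is singular")
    R, _ = polar(A)  # A = R @ S
    out = np.asarray(bvecs, dtype=float).reshape(-1, 3) @ R.T
    norms = np.linalg.norm(out, axis=1)
    nz = norms > 0
    out[nz] /= norms[nz, None]
    return out


def _design_matrix(bvals, bvecs) -> np.ndarray:
    g = np.asarray(bvecs, float)
    b = np.asarray(bvals, float)
    return np.column_stack(
        [
            b * g[:, 0] ** 2,
            b * g[:, 1] ** 2,
            b * g[:, 2] ** 2,
            2 * b * g[:, 0] * g[:, 1],
            2 * b * g[:, 0] * g[:, 2],
            2 * b * g[:, 1] * g[:, 2],
        ]
    )


def fit_tensor(dwi: DWISet, mask: np.ndarray) -> TensorImage:
    """Ordinary least-squares tensor fit inside a binary mask.

    Voxels where individual measurements are non-positive have those
    measurements dropped; the fit proceeds when at least 6 usable,
    non-collinear directions remain, otherwise the voxel is flagged unfit
    (excluded from the output mask) rather than raising.
    """
    mask = np.asarray(mask, dtype=bool)
    B = _design_matrix(dwi.bvals, dwi.bvecs)
    if np.linalg.matrix_rank(B) < 6:
        raise ValueError("need >= 6 non-collinear gradient directions")
    shape = dwi.b0.shape
    if mask.shape != shape:
        raise ValueError("mask shape mismatch")
    S = np.stack([np.asarray(v.data, float) for v in dwi.weighted])  # (N, X, Y, Z)
    s0 = np.asarray(dwi.b0.data, float)

    comps = np.zeros(shape + (6,))
    fit_mask = np.zeros(shape, dtype=bool)
    vox = np.argwhere(mask & (s0 > 0))
    if len(vox) == 0:
        return TensorImage(comps, fit_mask)
    idx = tuple(vox.T)
    sig = S[(slice(None),) + idx]  # (N, V)
    s0v = s0[idx]
    usable = sig > 0
    clean = usable.all(axis=0)

    pinvB = np.linalg.pinv(B)
    if clean.any():
        y = -np.log(sig[:, clean] / s0v[clean])
        d = pinvB @ y  # (6, Vc)
        comps[tuple(vox[clean].T)] = d.T
        fm = fit_mask[idx]
        fm[clean] = True
        fit_mask[idx] = fm
    # voxels with dropped measurements: per-voxel reduced solve
    for j in np.nonzero(~clean)[0]:
        rows = usable[:, j]
        if rows.sum() < 6:
            continue
        Bj = B[rows]
        if np.linalg.matrix_rank(Bj) < 6:
            continue
        y = -np.log(sig[rows, j] / s0v[j])
        d, *_ = np.linalg.lstsq(Bj, y, rcond=None)
        comps[tuple(vox[j])] = d
        fit_mask[tuple(vox[j])] = True
    comps[~fit_mask] = 0.0
    return TensorImage(comps, fit_mask)


def eigen_decompose(t: TensorImage):
    """Per-voxel eigenanalysis.

    Returns
    -------
    evals : (X, Y, Z, 3) eigenvalues, descending.
    e1 : (X, Y, Z, 3) principal eigenvector, unit norm, sign fixed so the
        first component of magnitude > 1e-12 is non-negative.
    degenerate : bool mask where lambda1 - lambda2 < 1e-12 * ||lambda||
        (e1 should not be interpreted there).
    """
    full = t.full_tensors()
    w, v = np.linalg.eigh(full)  # ascending
    evals = w[..., ::-1]
    e1 = v[..., :, 2]  # eigenvector of the largest eigenvalue
    # deterministic sign: first non-negligible component made non-negative
    tol = 1e-12
    sgn = np.where(
        np.abs(e1[..., 0]) > tol,
        np.sign(e1[..., 0]),
        np.where(
            np.abs(e1[..., 1]) > tol,
            np.sign(e1[..., 1]),
            np.where(np.abs(e1[..., 2]) > tol, np.sign(e1[..., 2]), 1.0),
        ),
    )
    e1 = e1 * sgn[..., None]
    norm = np.linalg.norm(evals, axis=-1)
    degenerate = (evals[..., 0] - evals[..., 1]) < 1e-12 * np.maximum(norm, 1e-300)
    return evals, e1, degenerate


def fa(evals) -> np.ndarray:
    """Fractional anisotropy: sqrt(3/2) ||lambda - mean|| / ||lambda||.

    Accepts a length-3 sequence or an (..., 3) array; defined as 0 where
    ``||lambda|| = 0``.
    """
    lam = np.asarray(evals, dtype=float)
    scalar = lam.ndim == 1
    lam = np.atleast_2d(lam)
    mean = lam.mean(axis=-1, keepdims=True)
    num = np.linalg.norm(lam - mean, axis=-1)
    den = np.linalg.norm(lam, axis=-1)
    out = np.where(den > 0, np.sqrt(1.5) * num / np.maximum(den, 1e-300), 0.0)
    return float(out[0]) if scalar else out.reshape(np.asarray(evals).shape[:-1])


def md(evals) -> np.ndarray:
    """Mean diffusivity: (lambda1 + lambda2 + lambda3) / 3."""
    lam = np.asarray(evals, dtype=float)
    out = lam.mean(axis=-1)
    return float(out) if out.ndim == 0 else out


def fa_color(fa_vol: np.ndarray, e1: np.ndarray) -> np.ndarray:
    """Direction-encoded color map: RGB = FA * (|e1x|, |e1y|, |e1z|)."""
    f = np.asarray(fa_vol, dtype=float)
    rgb = f[..., None] * np.abs(np.asarray(e1, dtype=float))
    return np.clip(rgb, 0.0, 1.0)


def predict_signals(tensor: TensorImage, bvals, bvecs, s0) -> np.ndarray:
    """Forward monoexponential model: S_j = S0 exp(-b_j g_j^T D g_j).

    Returns an (N, X, Y, Z) array; zero outside the tensor mask.
    """
    B = _design_matrix(bvals, bvecs)  # (N, 6)
    expo = np.tensordot(tensor.components, B, axes=([-1], [1]))  # (X, Y, Z, N)
    s = np.asarray(s0, dtype=float) * np.exp(-np.moveaxis(expo, -1, 0))
    s[:, ~tensor.mask] = 0.0
    return s
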