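"""Image registration and displacement-field algebra.

Two registration engines are provided:

* :func:`register_affine_mi` — 12-parameter affine alignment by maximizing
  histogram mutual information, for multimodal pairs (e.g. T1 against the
  diffusion baseline), optimized coarse-to-fine with a derivative-free
  (Powell) search.
* :func:`register_elastic` — dense non-rigid alignment by multiresolution
  block matching: integer-offset search maximizing the Pearson correlation
  of small blocks, scattered and Gaussian-smoothed into a displacement
  field, composed across pyramid levels.

Conventions
-----------
All transforms act in 0-based voxel coordinates of the fixed grid and use
the pull-back convention: the warped image at voxel ``x`` samples the moving
image at ``x + d(x)`` (fields) or ``A x + t`` (affines).  The elastic engine
searches integer block offsets and gains subvoxel accuracy from parabolic
refinement of the correlation peak plus Gaussian field smoothing.
"""
from __future__ import annotations

import itertools
import json
import warnings
from dataclasses import dataclass, field as dc_field

import numpy as np
from scipy import ndimage, optimize

from .volio import Volume

__all__ = [
    "AffineTransform",
    "DisplacementField",
    "RegConfig",
    "mutual_information",
    "register_affine_mi",
    "register_elastic",
    "warp_volume",
    "chain_resample",
    "compose_fields",
    "mean_displacement",
    "average_fields",
]


@dataclass
class AffineTransform:
    """Affine map ``x -> matrix @ x + translation`` in voxel coordinates.

    Under the pull-back convention, resampling a moving image through this
    transform brings it into the fixed grid.
    """

    matrix: np.ndarray
    translation: np.ndarray
    converged: bool = True

    def __post_init__(self):
        self.matrix = np.asarray(self.matrix, dtype=float).reshape(3, 3)
        self.translation = np.asarray(self.translation, dtype=float).reshape(3)
        if abs(np.linalg.det(self.matrix)) <= 1e-12:
            raise ValueError("affine matrix is singular")

    @classmethod
    def identity(cls) -> "AffineTransform":
        return cls(np.eye(3), np.zeros(3))

    def apply(self, points: np.ndarray) -> np.ndarray:
        """Apply to an (..., 3) array of voxel coordinates."""
        pts = np.asarray(points, dtype=float)
        return pts @ self.matrix.T + self.translation

    def inverse(self) -> "AffineTransform":
        inv = np.linalg.inv(self.matrix)
        return AffineTransform(inv, -inv @ self.translation, self.converged)

    def to_json(self, path=None):
        obj = {
            "matrix": [float(x) for x in self.matrix.ravel()],
            "translation": [float(x) for x in self.translation],
            "space": "voxel",
        }
        if path is None:
            return obj
        with open(path, "w") as fh:
            json.dump(obj, fh, indent=2)

    @classmethod
    def from_json(cls, obj_or_path) -> "AffineTransform":
        if isinstance(obj_or_path, (str, bytes)) or hasattr(obj_or_path, "__fspath__"):
            with open(obj_or_path) as fh:
                obj = json.load(fh)
        else:
            obj = obj_or_path
        return cls(np.array(obj["matrix"]).reshape(3, 3), np.array(obj["translation"]))


@dataclass
class DisplacementField:
    """Dense per-voxel displacement, shape (X, Y, Z, 3), voxel units.

    Pull-back convention: ``warped(x) = moving(x + d(x))`` on the fixed grid.
    """

    vectors: np.ndarray

    def __post_init__(self):
        self.vectors = np.asarray(self.vectors, dtype=float)
        if self.vectors.ndim != 4 or self.vectors.shape[-1] != 3:
            raise ValueError(
                f"field must have shape (X, Y, Z, 3), got {self.vectors.shape}"
            )
        if not np.all(np.isfinite(self.vectors)):
            raise ValueError("displacement field contains non-finite values")

    @property
    def shape(self):
        return self.vectors.shape[:3]

    def magnitude(self) -> np.ndarray:
        """Per-voxel Euclidean norm of the displacement."""
        return np.sqrt((self.vectors**2).sum(-1))

    @classmethod
    def zero(cls, shape) -> "DisplacementField":
        return cls(np.zeros(tuple(shape) + (3,)))


@dataclass
class RegConfig:
    """Tuning knobs shared by both registration engines.

    ``min_block_variance=None`` means the gate is set at run time to
    1e-6 x (intensity range of the fixed image)^2.
    """

    pyramid_levels: int = 3
    block_size: int = 5
    block_spacing: int = 3
    search_radius: int = 3
    smoothing_sigma: float = 3.0
    min_block_variance: float | None = None
    iterations_per_level: int = 2
    mi_bins: int = 32
    seed: int = 0

    def __post_init__(self):
        if self.pyramid_levels < 1:
            raise ValueError("pyramid_levels must be >= 1")
        for name in ("block_size", "block_spacing", "search_radius", "iterations_per_level"):
            if getattr(self, name) < 1:
                raise ValueError(f"{name} must be positive")
        if self.smoothing_sigma <= 0:
            raise ValueError("smoothing_sigma must be positive")
        if self.mi_bins < 2:
            raise ValueError("mi_bins must be >= 2")


# ---------------------------------------------------------------------------
# similarity metrics
# ---------------------------------------------------------------------------

def _mi_arrays(a: np.ndarray, b: np.ndarray, bins: int) -> float:
    h, _, _ = np.histogram2d(a.ravel(), b.ravel(), bins=bins)
    p = h / h.sum()
    px = p.sum(axis=1)
    py = p.sum(axis=0)
    outer = px[:, None] * py[None, :]
    nz = p > 0
    mi = float(np.sum(p[nz] * np.log2(p[nz] / outer[nz])))
    return max(mi, 0.0)


def mutual_information(a: Volume, b: Volume, bins: int = 32) -> float:
    """Mutual information (bits) of the joint `bins` x `bins` histogram."""
    if a.shape != b.shape:
        raise ValueError(f"shape mismatch: {a.shape} vs {b.shape}")
    if bins < 2:
        raise ValueError("bins must be >= 2")
    return _mi_arrays(np.asarray(a.data, float), np.asarray(b.data, float), bins)


# ---------------------------------------------------------------------------
# pyramid helpers
# ---------------------------------------------------------------------------

def _downsample(a: np.ndarray, factor: int) -> np.ndarray:
    if factor == 1:
        return a
    sm = ndimage.gaussian_filter(a, sigma=factor / 2.0, mode="nearest")
    out_shape = tuple(max(1, int(np.ceil(s / factor))) for s in a.shape)
    zoom = [o / s for o, s in zip(out_shape, a.shape)]
    return ndimage.zoom(sm, zoom, order=1, mode="nearest")


def _resize_field(field: np.ndarray, new_shape) -> np.ndarray:
    """Resample a (X,Y,Z,3) field to a new grid, rescaling the vectors."""
    old_shape = field.shape[:3]
    if tuple(old_shape) == tuple(new_shape):
        return field
    zoom = [n / o for n, o in zip(new_shape, old_shape)]
    out = np.empty(tuple(new_shape) + (3,), dtype=field.dtype)
    for c in range(3):
        out[..., c] = ndimage.zoom(field[..., c], zoom, order=1, mode="nearest") * zoom[c]
    return out


# ---------------------------------------------------------------------------
# warping
# ---------------------------------------------------------------------------

_ORDERS = {"trilinear": 1, "nearest": 0}


def _warp_arr(arr: np.ndarray, field: np.ndarray, order: int, cval: float) -> np.ndarray:
    coords = np.indices(field.shape[:3], dtype=np.float64)
    coords = coords + np.moveaxis(field, -1, 0)
    return ndimage.map_coordinates(arr, coords, order=order, mode="constant", cval=cval)


def warp_volume(v: Volume, t, interp: str = "trilinear", fill: float = 0.0) -> Volume:
    """Resample a volume through a transform (pull-back).

    ``t`` is a :class:`DisplacementField` or :class:`AffineTransform`.
    Out-of-bounds samples take the ``fill`` value.
    """
    if interp not in _ORDERS:
        raise ValueError(f"unknown interpolation mode {interp!r}")
    order = _ORDERS[interp]
    arr = np.asarray(v.data)
    if isinstance(t, DisplacementField):
        out = _warp_arr(arr, t.vectors, order=order, cval=fill)
    elif isinstance(t, AffineTransform):
        out = ndimage.affine_transform(
            arr, t.matrix, offset=t.translation, order=order, mode="constant", cval=fill
        )
    else:
        raise TypeError(f"unsupported transform type {type(t).__name__}")
    return Volume(out, v.spacing, v.origin)


def chain_resample(
    arr: np.ndarray,
    affine: AffineTransform | None = None,
    field: DisplacementField | None = None,
    order: int = 1,
    cval: float = 0.0,
    shape=None,
) -> np.ndarray:
    """Resample through elastic-then-affine in one interpolation pass.

    Output at voxel ``x`` samples ``arr`` at ``A (x + d(x)) + t``, the
    composition produced by affine pre-alignment followed by elastic
    refinement.  Either stage may be None.
    """
    if field is not None:
        base = field.vectors.shape[:3]
    elif shape is not None:
        base = tuple(shape)
    else:
        base = arr.shape
    coords = np.indices(base, dtype=np.float64)
    if field is not None:
        coords = coords + np.moveaxis(field.vectors, -1, 0)
    if affine is not None:
        pts = np.moveaxis(coords, 0, -1)
        pts = pts @ affine.matrix.T + affine.translation
        coords = np.moveaxis(pts, -1, 0)
    return ndimage.map_coordinates(arr, coords, order=order, mode="constant", cval=cval)


def compose_fields(d_first: DisplacementField, d_second: DisplacementField) -> DisplacementField:
    """Compose two pull-back fields: warp by ``d_first``, then resample the
    result through ``d_second``.

    ``out(x) = d_first(x) + d_second(x + d_first(x))``, i.e. the total field
    of ``warp(warp(m, d_second), d_first)``.
    """
    if d_first.shape != d_second.shape:
        raise ValueError("field shapes differ")
    f1 = d_first.vectors
    out = f1.copy()
    for c in range(3):
        out[..., c] += _warp_arr(d_second.vectors[..., c], f1, order=1, cval=0.0)
    return DisplacementField(out)


def mean_displacement(d: DisplacementField, mask: np.ndarray | None = None) -> float:
    """Mean Euclidean displacement magnitude over (masked) voxels."""
    mag = d.magnitude()
    if mask is not None:
        mask = np.asarray(mask, bool)
        if not mask.any():
            raise ValueError("empty mask")
        mag = mag[mask]
    return float(mag.mean())


def average_fields(fields) -> DisplacementField:
    """Voxelwise arithmetic mean of displacement fields."""
    fields = list(fields)
    if not fields:
        raise ValueError("empty field list")
    shapes = {f.shape for f in fields}
    if len(shapes) != 1:
        raise ValueError(f"field shapes differ: {shapes}")
    return DisplacementField(np.mean([f.vectors for f in fields], axis=0))


# ---------------------------------------------------------------------------
# affine registration by mutual information
# ---------------------------------------------------------------------------

def _params_to_affine(p: np.ndarray):
    t = p[:3]
    rx, ry, rz = p[3:6]
    s = np.exp(p[6:9])
    hxy, hxz, hyz = p[9:12]
    cx, sx = np.cos(rx), np.sin(rx)
    cy, sy = np.cos(ry), np.sin(ry)
    cz, sz = np.cos(rz), np.sin(rz)
    Rx = np.array([[1, 0, 0], [0, cx, -sx], [0, sx, cx]])
    Ry = np.array([[cy, 0, sy], [0, 1, 0], [-sy, 0, cy]])
    Rz = np.array([[cz, -sz, 0], [sz, cz, 0], [0, 0, 1]])
    H = np.array([[1, hxy, hxz], [0, 1, hyz], [0, 0, 1]])
    A = Rz @ Ry @ Rx @ H @ np.diag(s)
    return A, t


def register_affine_mi(fixed: Volume, moving: Volume, cfg: RegConfig | None = None) -> AffineTransform:
    """Estimate the 12-parameter affine maximizing mutual information.

    The search is run coarse-to-fine over a Gaussian pyramid with a Powell
    (derivative-free) optimizer; the MI objective is non-smooth under
    histogram binning, so no gradients are used.  The returned transform
    resamples ``moving`` onto the fixed grid.  If the optimizer reports
    non-convergence at the finest level, the best-so-far transform is
    returned with ``converged=False`` and a warning.
    """
    cfg = cfg or RegConfig()
    f = np.asarray(fixed.data, dtype=np.float32)
    m = np.asarray(moving.data, dtype=np.float32)
    params = np.zeros(12)
    # Powell search directions scaled to each parameter's natural step.
    scales = np.array([2.0] * 3 + [0.1] * 3 + [0.05] * 3 + [0.05] * 3)
    cf_full = (np.array(f.shape) - 1) / 2.0
    cm_full = (np.array(m.shape) - 1) / 2.0
    mfill = float(m.min())
    converged = True
    for level in range(cfg.pyramid_levels - 1, -1, -1):
        factor = 2**level
        fl = _downsample(f, factor)
        ml = _downsample(m, factor)
        cf = (np.array(fl.shape) - 1) / 2.0
        cm = (np.array(ml.shape) - 1) / 2.0

        def neg_mi(p):
            A, t = _params_to_affine(p)
            offset = cm + t / factor - A @ cf
            w = ndimage.affine_transform(
                ml, A, offset=offset, order=1, mode="constant", cval=mfill
            )
            return -_mi_arrays(fl, w, cfg.mi_bins)

        res = optimize.minimize(
            neg_mi,
            params,
            method="Powell",
            options={
                "direc": np.diag(scales),
                "xtol": 1e-3,
                "ftol": 1e-5,
                "maxiter": 20,
            },
        )
        params = res.x
        if level == 0 and not res.success:
            converged = False
            warnings.warn("affine MI optimizer did not converge; returning best-so-far")
    A, t = _params_to_affine(params)
    translation = cm_full + t - A @ cf_full
    out = AffineTransform(A, translation)
    out.converged = converged
    return out


# ---------------------------------------------------------------------------
# elastic registration by block matching
# ---------------------------------------------------------------------------

def _shift(a: np.ndarray, o) -> np.ndarray:
    """out(x) = a(x + o), zero-filled outside."""
    out = np.zeros_like(a)
    src, dst = [], []
    for s, oi in zip(a.shape, o):
        lo = max(0, -oi)
        hi = min(s, s - oi)
        if hi <= lo:
            return out
        dst.append(slice(lo, hi))
        src.append(slice(lo + oi, hi + oi))
    out[tuple(dst)] = a[tuple(src)]
    return out


def _subvoxel_refine(best: np.ndarray, best_r: np.ndarray, r_all: np.ndarray, sr: int):
    """Parabolic refinement of the per-block correlation peak.

    Along each axis a 1-D parabola is fitted through the correlation at the
    winning offset and its two axis neighbours; the vertex gives a subvoxel
    correction, clipped to half a voxel.  Blocks whose peak sits on the
    search border, or whose neighbourhood is not locally concave, keep their
    integer offset.
    """
    out = best.astype(np.float32)
    vshape = best_r.shape
    bidx = np.indices(vshape)
    centered = best + sr  # indices into r_all's offset axes
    for axis in range(3):
        interior = (centered[..., axis] > 0) & (centered[..., axis] < 2 * sr)
        lo = np.clip(centered[..., axis] - 1, 0, 2 * sr)
        hi = np.clip(centered[..., axis] + 1, 0, 2 * sr)
        off_idx = [centered[..., 0], centered[..., 1], centered[..., 2]]
        off_lo = list(off_idx)
        off_hi = list(off_idx)
        off_lo[axis] = lo
        off_hi[axis] = hi
        r_lo = r_all[tuple(off_lo) + tuple(bidx)]
        r_hi = r_all[tuple(off_hi) + tuple(bidx)]
        r0 = best_r
        curv = r_lo - 2 * r0 + r_hi
        # refine only genuinely peaked, imperfect maxima: plateaus
        # (aperture problem, flat blocks) have noise vertices, and an
        # already-perfect match (identical images) must stay put
        ok = interior & (curv < -5e-3) & (r_lo > -1.0) & (r_hi > -1.0)
        ok &= r0 < 1.0 - 1e-6
        delta = np.where(ok, 0.5 * (r_lo - r_hi) / np.where(ok, curv, 1.0), 0.0)
        out[..., axis] += np.clip(delta, -0.5, 0.5)
    return out


def _block_match_field(f: np.ndarray, w: np.ndarray, cfg: RegConfig, minvar: float, refine: bool = True):
    """One block-matching sweep: dense smoothed increment field on f's grid.

    Blocks of ``block_size``^3 are placed every ``block_spacing`` voxels;
    blocks whose fixed-image variance falls below ``minvar`` are excluded.
    For each remaining block the integer offset within ``search_radius``
    maximizing the Pearson correlation against ``w`` is kept (ties favour
    the smaller displacement), and the per-block offsets are scattered and
    Gaussian-smoothed into a dense field by normalized convolution, each
    block weighted by its best correlation.
    """
    bs, sp, sr = cfg.block_size, cfg.block_spacing, cfg.search_radius
    # float64 throughout: the E[x^2]-E[x]^2 variance form cancels badly in
    # float32 for near-flat blocks, producing spurious correlations > 1
    f = np.asarray(f, dtype=np.float64)
    w = np.asarray(w, dtype=np.float64)
    margin = bs // 2 + sr
    axes = [np.arange(margin, s - margin, sp) for s in f.shape]
    if any(len(ax) == 0 for ax in axes):
        return np.zeros(f.shape + (3,), dtype=np.float32), False

    def uf(x):
        return ndimage.uniform_filter(x, size=bs, mode="constant")

    grid = np.ix_(*axes)
    Ef = uf(f)
    Eff = uf(f * f)
    mf = Ef[grid]
    vf = Eff[grid] - mf * mf
    valid = vf >= minvar
    if not valid.any():
        warnings.warn("all blocks below variance threshold; zero increment")
        return np.zeros(f.shape + (3,), dtype=np.float32), False

    Em = uf(w)
    Emm = uf(w * w)
    vshape = valid.shape
    best_r = np.full(vshape, -np.inf, dtype=np.float64)
    best = np.zeros(vshape + (3,), dtype=np.int32)
    n_off = 2 * sr + 1
    r_all = np.full((n_off, n_off, n_off) + vshape, -1.0, dtype=np.float64)
    offsets = sorted(
        itertools.product(range(-sr, sr + 1), repeat=3),
        key=lambda o: (o[0] ** 2 + o[1] ** 2 + o[2] ** 2, o),
    )
    for o in offsets:
        ws = _shift(w, o)
        cross = uf(f * ws)[grid]
        mm = _shift(Em, o)[grid]
        vm = _shift(Emm, o)[grid] - mm * mm
        cov = cross - mf * mm
        denom = np.sqrt(np.maximum(vf, 0.0) * np.maximum(vm, 0.0))
        # correlation against a (near-)constant moving block is undefined;
        # gate it with the same variance threshold as the fixed blocks
        r = np.where(vm >= minvar, cov / np.maximum(denom, 1e-30), -1.0)
        r_all[o[0] + sr, o[1] + sr, o[2] + sr] = r
        # Parsimony margin: offsets are visited by ascending norm and a
        # larger displacement must improve the correlation by a real margin
        # to win.  Guards against the aperture problem — a block on a flat
        # boundary between homogeneous regions correlates near-perfectly at
        # many offsets along the boundary — and against rounding noise on
        # near-identical images.
        upd = r > best_r + 5e-3
        if upd.any():
            best_r[upd] = r[upd]
            best[upd] = o

    if refine:
        best = _subvoxel_refine(best, best_r, r_all, sr)
    best = best.astype(np.float32)
    best[~valid] = 0.0
    # scatter block offsets weighted by match quality: confidently matched
    # blocks dominate the smoothed field, poorly correlated ones fade out
    quality = np.clip(best_r, 0.0, 1.0).astype(np.float32)
    quality[~valid] = 0.0
    num = np.zeros(f.shape + (3,), dtype=np.float32)
    den = np.zeros(f.shape, dtype=np.float32)
    cx, cy, cz = np.meshgrid(*axes, indexing="ij")
    num[cx, cy, cz] = best * quality[..., None]
    den[cx, cy, cz] = quality
    sig = cfg.smoothing_sigma
    for c in range(3):
        num[..., c] = ndimage.gaussian_filter(num[..., c], sig, mode="constant")
    den = ndimage.gaussian_filter(den, sig, mode="constant")
    out = np.zeros_like(num)
    nz = den > 1e-8
    for c in range(3):
        out[..., c][nz] = num[..., c][nz] / den[nz]
    return out, True


def register_elastic(fixed: Volume, moving: Volume, cfg: RegConfig | None = None) -> DisplacementField:
    """Multiresolution block-matching elastic registration.

    Returns a dense displacement field on the fixed grid such that
    ``warp_volume(moving, field)`` aligns with ``fixed``.  Requires equal
    shapes (apply affine pre-alignment first for grossly misaligned pairs).
    """
    cfg = cfg or RegConfig()
    if fixed.shape != moving.shape:
        raise ValueError(f"shape mismatch: {fixed.shape} vs {moving.shape}")
    f0 = np.asarray(fixed.data, dtype=np.float32)
    m0 = np.asarray(moving.data, dtype=np.float32)
    rng = float(f0.max() - f0.min())
    minvar = cfg.min_block_variance if cfg.min_block_variance is not None else 1e-6 * rng * rng
    minvar = max(minvar, 1e-12)  # a constant image must fail the gate
    acc = None
    matched_any = False
    for level in range(cfg.pyramid_levels - 1, -1, -1):
        factor = 2**level
        fl = _downsample(f0, factor)
        ml = _downsample(m0, factor)
        if acc is None:
            acc = np.zeros(fl.shape + (3,), dtype=np.float32)
        else:
            acc = _resize_field(acc, fl.shape)
        for it in range(cfg.iterations_per_level):
            warped = _warp_arr(ml, acc, order=1, cval=0.0).astype(np.float32)
            # subvoxel refinement only on the last sweep of the finest
            # level: its small parabola bias must not compound across the
            # pyramid (coarse-level deltas would be upscaled)
            refine = level == 0 and it == cfg.iterations_per_level - 1
            inc, ok = _block_match_field(fl, warped, cfg, minvar, refine=refine)
            matched_any = matched_any or ok
            if not ok:
                continue
            acc = compose_fields(
                DisplacementField(inc), DisplacementField(acc)
            ).vectors.astype(np.float32)
    if not matched_any:
        warnings.warn("no block passed the variance gate at any level; zero field")
    return DisplacementField(acc.astype(np.float64))
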