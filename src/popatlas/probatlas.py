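"""Probabilistic atlas construction and atlas-based segmentation.

At each template voxel x the probability of region r is the fraction of
subjects whose propagated label there is r:

    p_r(x) = |{i : L_i(x) = r}| / N.

Since every subject contributes exactly one vote per voxel (out-of-field
samples count as background), the probabilities including background sum to
1 exactly and each value is a multiple of 1/N.

Segmentation of a new volume registers the template to it (affine, then
elastic block matching), carries every probability map across with
trilinear interpolation — which preserves the partial-volume robustness of
the probabilistic representation, unlike warping a discrete label map —
and assigns each voxel to the most probable region (background competes;
ties go to the smallest id).
"""
from __future__ import annotations

import json
import warnings
from dataclasses import dataclass
from pathlib import Path

import numpy as np

from .register import (
    RegConfig,
    chain_resample,
    register_affine_mi,
    register_elastic,
    warp_volume,
)
from .template import TemplateModel
from .volio import LabelMap, RegionTable, Volume, read_volume, write_volume

__all__ = [
    "ProbAtlas",
    "build_probability_maps",
    "max_label_map",
    "segment",
    "save_atlas",
    "load_atlas",
]


@dataclass
class ProbAtlas:
    """Template volume plus one probability map per region.

    ``probabilities`` has shape (R, X, Y, Z) with regions ordered by
    ascending ``region_ids``; the implicit background probability is
    ``1 - probabilities.sum(0)``.
    """

    template: Volume
    probabilities: np.ndarray
    region_ids: np.ndarray
    n_subjects: int
    regions: RegionTable

    def __post_init__(self):
        self.probabilities = np.asarray(self.probabilities, dtype=float)
        self.region_ids = np.asarray(self.region_ids, dtype=int)
        if self.probabilities.ndim != 4:
            raise ValueError("probabilities must have shape (R, X, Y, Z)")
        if len(self.region_ids) != self.probabilities.shape[0]:
            raise ValueError("one probability map per region id required")
        if self.probabilities.shape[1:] != self.template.shape:
            raise ValueError("probability maps must live on the template grid")
        # tolerance covers float32 round trips through the NIfTI store
        if self.probabilities.min() < -1e-6 or self.probabilities.max() > 1 + 1e-6:
            raise ValueError("probabilities must lie in [0, 1]")
        total = self.probabilities.sum(axis=0)
        if total.max() > 1 + 1e-6:
            raise ValueError("region probabilities exceed 1 at some voxel")

    def background(self) -> np.ndarray:
        return 1.0 - self.probabilities.sum(axis=0)


def build_probability_maps(tm: TemplateModel, labelmaps) -> ProbAtlas:
    """Per-region probability maps on the template grid.

    Each subject's label map is carried to the template by nearest-neighbor
    resampling through the stored template->subject field (the pull-back
    sample at ``x + d_i(x)`` is exactly the propagation required — no field
    inversion is involved).  Out-of-field samples count as background.
    """
    labelmaps = list(labelmaps)
    n = len(labelmaps)
    if n == 0:
        raise ValueError("no label maps given")
    if len(tm.subject_fields) != n:
        raise ValueError(
            f"template stores {len(tm.subject_fields)} subject fields "
            f"but {n} label maps were given"
        )
    regions = labelmaps[0].regions
    ids = regions.ids
    shape = tm.volume.shape
    counts = np.zeros((len(ids), ) + shape, dtype=np.int32)
    for lm, field in zip(labelmaps, tm.subject_fields):
        if field.shape != shape:
            raise ValueError("stored field does not match the template grid")
        warped = chain_resample(lm.labels, field=field, order=0, cval=0)
        for k, r in enumerate(ids):
            counts[k] += warped == r
    probs = counts.astype(float) / n
    return ProbAtlas(tm.volume, probs, ids, n, regions)


def _argmax_labels(prob_stack: np.ndarray, background: np.ndarray, ids: np.ndarray) -> np.ndarray:
    """Argmax over [background, regions...]; first maximum wins, so ties go
    to the smallest id (background = 0 first)."""
    stacked = np.concatenate([background[None], prob_stack], axis=0)
    winner = np.argmax(stacked, axis=0)
    lut = np.concatenate([[0], ids]).astype(np.int32)
    return lut[winner]


def max_label_map(atlas: ProbAtlas) -> LabelMap:
    """Most-probable-region label map on the template grid."""
    labels = _argmax_labels(atlas.probabilities, atlas.background(), atlas.region_ids)
    return LabelMap(labels, atlas.regions, atlas.template.spacing, atlas.template.origin)


def segment(new_volume: Volume, atlas: ProbAtlas, cfg: RegConfig | None = None):
    """Atlas-based parcellation of a new volume.

    Registers the template to the new volume (affine MI, then elastic block
    matching), warps every probability map with trilinear interpolation and
    labels each voxel with the most probable region.  If the affine stage
    fails to converge the elastic stage still runs on the best-so-far
    alignment (warned); a hard elastic failure falls back to affine-only.

    Returns
    -------
    labels : LabelMap on the new volume's grid.
    maxprob : Volume holding the winning probability per voxel.
    """
    cfg = cfg or RegConfig()
    affine = register_affine_mi(new_volume, atlas.template, cfg)
    try:
        template_aff = warp_volume(atlas.template, affine)
        field = register_elastic(new_volume, template_aff, cfg)
    except Exception as err:  # registration failure: affine-only fallback
        warnings.warn(f"elastic stage failed ({err}); affine-only segmentation")
        field = None
    warped = np.stack(
        [
            chain_resample(p, affine=affine, field=field, order=1, cval=0.0,
                           shape=new_volume.shape)
            for p in atlas.probabilities
        ]
    )
    bg = chain_resample(
        atlas.background(), affine=affine, field=field, order=1, cval=1.0,
        shape=new_volume.shape,
    )
    labels = _argmax_labels(warped, bg, atlas.region_ids)
    maxprob = np.concatenate([bg[None], warped], axis=0).max(axis=0)
    lm = LabelMap(labels, atlas.regions, new_volume.spacing, new_volume.origin)
    return lm, new_volume.like(maxprob)


def save_atlas(atlas: ProbAtlas, out_dir) -> Path:
    """Persist an atlas: template NIfTI, 4-D probability NIfTI (region axis
    ordered by region id), region TSV and a JSON manifest."""
    import nibabel as nib

    out = Path(out_dir)
    out.mkdir(parents=True, exist_ok=True)
    write_volume(atlas.template, out / "template.nii")
    aff = np.diag(list(atlas.template.spacing) + [1.0])
    aff[:3, 3] = atlas.template.origin
    prob4d = np.moveaxis(atlas.probabilities, 0, -1).astype(np.float32)
    img = nib.Nifti1Image(prob4d, aff)
    img.set_data_dtype(np.float32)
    nib.save(img, str(out / "probabilities.nii"))
    atlas.regions.to_tsv(out / "regions.tsv")
    meta = {
        "n_subjects": int(atlas.n_subjects),
        "region_ids": [int(r) for r in atlas.region_ids],
    }
    (out / "atlas.json").write_text(json.dumps(meta, indent=2))
    return out


def load_atlas(atlas_dir) -> ProbAtlas:
    import nibabel as nib

    d = Path(atlas_dir)
    template = read_volume(d / "template.nii")
    img = nib.load(str(d / "probabilities.nii"))
    prob4d = np.asarray(img.dataobj, dtype=float)
    probs = np.moveaxis(prob4d, -1, 0)
    regions = RegionTable.from_tsv(d / "regions.tsv")
    meta = json.loads((d / "atlas.json").read_text())
    return ProbAtlas(
        template, probs, np.array(meta["region_ids"]), int(meta["n_subjects"]), regions
    )
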