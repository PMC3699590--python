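"""Label propagation and most-frequent-label fusion.

The delineation bootstrap: a new subject inherits a starting parcellation
by elastically registering each already-labeled subject to it, propagating
their label maps with nearest-neighbor warping, and fusing the propagated
maps by per-voxel majority vote.  Ties go to the smallest region id and
background (0) participates as a vote, so fusion is fully deterministic.
"""
from __future__ import annotations

import numpy as np

from .register import (
    AffineTransform,
    DisplacementField,
    RegConfig,
    chain_resample,
    register_affine_mi,
    register_elastic,
    warp_volume,
)
from .volio import LabelMap, Volume

__all__ = ["propagate_labels", "majority_vote", "bootstrap_initialization"]


def propagate_labels(labels: LabelMap, t) -> LabelMap:
    """Warp a label map with nearest-neighbor interpolation.

    ``t`` is a DisplacementField or AffineTransform targeting the new grid.
    Out-of-field samples become background; no new labels can appear.
    """
    if isinstance(t, DisplacementField) and t.shape != labels.shape:
        # fields live on the target grid; shapes must agree for the pull-back
        raise ValueError(f"grid mismatch: field {t.shape} vs labels {labels.shape}")
    vol = Volume(labels.labels, labels.spacing, labels.origin)
    warped = warp_volume(vol, t, interp="nearest", fill=0)
    return LabelMap(warped.data.astype(np.int32), labels.regions, labels.spacing, labels.origin)


def majority_vote(maps) -> LabelMap:
    """Per-voxel most frequent label over a list of equally shaped maps.

    Background counts as a vote; ties are broken by the smallest region id
    (background first).
    """
    maps = list(maps)
    if not maps:
        raise ValueError("empty list of label maps")
    shapes = {m.shape for m in maps}
    if len(shapes) != 1:
        raise ValueError(f"label map shapes differ: {shapes}")
    stack = np.stack([m.labels for m in maps])  # (k, X, Y, Z)
    labels = np.unique(stack)
    out = np.zeros(maps[0].shape, dtype=np.int32)
    best = np.full(maps[0].shape, -1, dtype=np.int32)
    for lab in labels:  # ascending: ties keep the smallest id
        count = (stack == lab).sum(axis=0).astype(np.int32)
        upd = count > best
        out[upd] = lab
        best[upd] = count[upd]
    return maps[0].like(out)


def _propagate_prior(
    new_subject: Volume,
    prior_volume: Volume,
    prior_labels: LabelMap,
    cfg: RegConfig,
    affine_first: bool,
) -> LabelMap:
    """Carry one prior's labels onto the new subject's grid."""
    affine = None
    moving = prior_volume
    if affine_first:
        affine = register_affine_mi(new_subject, prior_volume, cfg)
        moving = warp_volume(prior_volume, affine)
    field = register_elastic(new_subject, moving, cfg)
    warped = chain_resample(
        prior_labels.labels, affine=affine, field=field, order=0, cval=0
    )
    return LabelMap(
        warped.astype(np.int32),
        prior_labels.regions,
        new_subject.spacing,
        new_subject.origin,
    )


def bootstrap_initialization(
    new_subject: Volume,
    priors,
    cfg: RegConfig | None = None,
    affine_first: bool = True,
) -> LabelMap:
    """Initial parcellation of an unlabeled subject from labeled priors.

    Each prior ``(volume, label_map)`` is registered to the new subject
    (optionally affine-first, then elastic), its labels are propagated with
    nearest-neighbor warping, and the propagated maps are fused by
    :func:`majority_vote`.  This is exactly the composition of those
    operations, so it can be cross-checked piecewise.
    """
    priors = list(priors)
    if not priors:
        raise ValueError("at least one labeled prior is required")
    cfg = cfg or RegConfig()
    propagated = [
        _propagate_prior(new_subject, vol, lab, cfg, affine_first)
        for vol, lab in priors
    ]
    return majority_vote(propagated)
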