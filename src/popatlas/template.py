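"""Average-shape / average-intensity population template construction.

The template is built in three stages:

1. *Reference selection* — every candidate is elastically registered to all
   other subjects; the subject whose fields have the smallest average mean
   displacement (the most "normal" anatomy) seeds the iteration.
2. *Mean shape* — the current template is registered to every subject, the
   resulting displacement fields are averaged, and the template is warped
   by the mean field; iteration stops when the mean displacement of the
   average field drops below a tolerance (convergence typically takes only
   a few iterations).
3. *Mean intensity* — every subject is registered and resampled onto the
   shape template; the template intensity at each voxel is the mean of the
   per-subject values after discarding outliers beyond 2 sample standard
   deviations of the voxel mean (a single pass; guards against noise and
   misregistration).

The final per-subject fields (template grid -> subject) are retained in the
model so the probabilistic atlas can be built without re-registration.
"""
from __future__ import annotations

from dataclasses import dataclass, field as dc_field

import numpy as np

from .register import (
    DisplacementField,
    RegConfig,
    average_fields,
    compose_fields,
    mean_displacement,
    register_elastic,
    warp_volume,
)
from .volio import Volume

__all__ = [
    "TemplateModel",
    "select_reference",
    "pairwise_mean_displacement",
    "build_mean_shape",
    "trimmed_mean",
    "build_mean_intensity",
    "build_template",
]


@dataclass
class TemplateModel:
    """Population template plus the transforms that produced it."""

    volume: Volume
    subject_fields: list
    iterations_run: int
    converged: bool
    history: list = dc_field(default_factory=list)

    def __post_init__(self):
        if not np.all(np.isfinite(self.volume.data)):
            raise ValueError("template volume contains non-finite values")


def pairwise_mean_displacement(volumes, cfg: RegConfig | None = None) -> np.ndarray:
    """Matrix M[i, j] = mean displacement of register_elastic(i, j), i != j.

    Row i collects the effort of matching every other subject onto
    candidate i; the diagonal is 0.
    """
    volumes = list(volumes)
    n = len(volumes)
    cfg = cfg or RegConfig()
    M = np.zeros((n, n))
    for i in range(n):
        for j in range(n):
            if i == j:
                continue
            field = register_elastic(volumes[i], volumes[j], cfg)
            M[i, j] = mean_displacement(field)
    return M


def select_reference(volumes, cfg: RegConfig | None = None) -> int:
    """Index of the subject requiring the minimum transformation to match
    all others (ties -> smallest index)."""
    volumes = list(volumes)
    if len(volumes) < 2:
        raise ValueError("need at least 2 volumes to select a reference")
    M = pairwise_mean_displacement(volumes, cfg)
    n = len(volumes)
    scores = M.sum(axis=1) / (n - 1)
    return int(np.argmin(scores))  # argmin returns the first (smallest) index


def build_mean_shape(
    volumes,
    ref_index: int,
    cfg: RegConfig | None = None,
    tol: float = 0.1,
    max_iter: int = 10,
    mean_field_mode: str = "inverse",
):
    """Iterative average-shape template.

    Each iteration registers the current template to every subject (fields
    map template grid -> subject under the pull-back convention) and
    averages the fields.  With ``mean_field_mode="inverse"`` (default) the
    template is warped by the first-order inverse of the mean field (its
    negation), which moves it toward the population mean shape; a shifted-
    copies argument shows the mean field itself points the other way, so
    ``"forward"`` (warping by the mean field directly) is kept only for
    comparison and diverges in general.

    Returns ``(shape_template, history, converged)`` where ``history`` holds
    the mean displacement of the average field at each iteration.
    """
    if mean_field_mode not in ("inverse", "forward"):
        raise ValueError(f"unknown mean_field_mode {mean_field_mode!r}")
    volumes = list(volumes)
    if not 0 <= ref_index < len(volumes):
        raise ValueError("invalid reference index")
    cfg = cfg or RegConfig()
    tmpl = Volume(
        np.array(volumes[ref_index].data, dtype=float),
        volumes[ref_index].spacing,
        volumes[ref_index].origin,
    )
    reference = tmpl
    total = DisplacementField.zero(reference.shape)
    history: list[float] = []
    converged = False
    for _ in range(max_iter):
        fields = [register_elastic(tmpl, v, cfg) for v in volumes]
        mean_field = average_fields(fields)
        disp = mean_displacement(mean_field)
        history.append(disp)
        if disp < tol:
            converged = True
            break
        if mean_field_mode == "inverse":
            update = DisplacementField(-mean_field.vectors)
        else:
            update = mean_field
        # accumulate updates and resample the original reference once per
        # iteration, so interpolation blur does not compound across passes
        total = compose_fields(update, total)
        tmpl = warp_volume(reference, total)
    return tmpl, history, converged


def trimmed_mean(samples: np.ndarray, nsd: float = 2.0, side: str = "two"):
    """Mean over axis 0 after discarding values beyond ``nsd`` sample SDs.

    A single pass: mean and sample standard deviation (ddof=1) are computed
    once and values with ``|x - mean| > nsd * sd`` (or ``x - mean > nsd *
    sd`` for ``side="upper"``) are excluded.  Where the SD is zero all
    values are kept.  With n >= 2 at least one value always survives
    (asserted), since the squared deviations sum to (n-1) sd^2.
    """
    x = np.asarray(samples, dtype=float)
    n = x.shape[0]
    mean = x.mean(axis=0)
    if n < 2:
        return mean
    sd = x.std(axis=0, ddof=1)
    dev = x - mean
    if side == "two":
        excl = np.abs(dev) > nsd * sd
    elif side == "upper":
        excl = dev > nsd * sd
    else:
        raise ValueError(f"unknown trim side {side!r}")
    excl &= sd > 0
    counts = (~excl).sum(axis=0)
    assert counts.min() >= 1, "trimming excluded every sample at a voxel"
    return np.where(excl, 0.0, x).sum(axis=0) / counts


def build_mean_intensity(
    volumes,
    shape_template: Volume,
    cfg: RegConfig | None = None,
    trim_nsd: float = 2.0,
    trim_side: str = "two",
) -> TemplateModel:
    """Average-intensity model on the mean-shape grid.

    Registers every subject to the shape template, resamples, and takes the
    2-SD trimmed mean per voxel.  The registration fields (template grid ->
    subject) are stored on the returned model.
    """
    volumes = list(volumes)
    cfg = cfg or RegConfig()
    fields = [register_elastic(shape_template, v, cfg) for v in volumes]
    warped = np.stack(
        [warp_volume(v, f).data for v, f in zip(volumes, fields)], axis=0
    )
    intensity = trimmed_mean(warped, nsd=trim_nsd, side=trim_side)
    vol = Volume(intensity, shape_template.spacing, shape_template.origin)
    return TemplateModel(vol, fields, iterations_run=0, converged=True)


def build_template(
    volumes,
    cfg: RegConfig | None = None,
    tol: float = 0.1,
    max_iter: int = 10,
    ref_cfg: RegConfig | None = None,
    trim_nsd: float = 2.0,
    trim_side: str = "two",
) -> TemplateModel:
    """Full template construction: reference selection, mean shape, mean
    intensity.

    ``ref_cfg`` optionally uses a cheaper registration configuration for the
    O(n^2) reference-selection stage; it only needs to rank candidates.
    Deterministic given fixed inputs and configuration.
    """
    volumes = list(volumes)
    if len(volumes) < 2:
        raise ValueError("need at least 2 volumes")
    cfg = cfg or RegConfig()
    ref = select_reference(volumes, ref_cfg or cfg)
    shape_tmpl, history, converged = build_mean_shape(
        volumes, ref, cfg, tol=tol, max_iter=max_iter
    )
    model = build_mean_intensity(
        volumes, shape_tmpl, cfg, trim_nsd=trim_nsd, trim_side=trim_side
    )
    model.iterations_run = len(history)
    model.converged = converged
    model.history = history
    return model
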