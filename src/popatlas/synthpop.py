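"""Synthetic population generator for desk-scale pipeline testing.

Real atlas construction starts from T1 and diffusion MRI of ten adult
rabbit brains.  This module emulates those inputs: a parametric labeled
phantom (an ellipsoidal "brain" partitioned into compact regions placed at
group-appropriate depths — cortical near the surface, white matter
mid-depth, deep gray centrally), per-subject anatomical variability as
smooth random deformations, T1-like intensities with per-region means and
noise, and optionally diffusion-weighted signals with per-region FA/MD
targets.  Region defaults (volume fraction, relative T1 intensity, FA and
relative MD, with their across-subject SDs) come from the published
characterization of the 35 merged rabbit brain structures; the default
phantom uses a 12-region subset so that desk-scale grids keep every region
well above 100 voxels.

Every output is deterministic given the seed, and every subject carries its
generating deformation field and label map, so registration endpoint error
and segmentation Dice can be scored against exact ground truth.
"""
from __future__ import annotations

from dataclasses import dataclass, field as dc_field, replace

import numpy as np

from .dtifit import DWISet
from .register import DisplacementField, warp_volume
from .volio import LabelMap, RegionTable, Volume

__all__ = [
    "RegionSpec",
    "SynthParams",
    "SynthSubject",
    "REGION_STATS",
    "default_region_table",
    "default_region_specs",
    "make_phantom",
    "random_deformation",
    "synth_population",
    "synth_dwi",
    "fibonacci_directions",
]

# Published per-structure statistics (35 merged regions): volume % of brain,
# relative T1 intensity, FA, relative MD — each as (mean, sd) across the ten
# study subjects.  `bilateral` marks structures delineated separately on the
# left and right (25 of 35, giving the 60-entry full table).
# name: (group, bilateral, vol%, vol_sd, T1, T1_sd, FA, FA_sd, MD, MD_sd)
REGION_STATS = {
    "Frontal cortex": ("cortical", True, 7.89, 0.65, 0.93, 0.05, 0.18, 0.06, 1.00, 0.20),
    "Medial frontal cortex": ("cortical", True, 2.45, 0.09, 0.94, 0.08, 0.18, 0.04, 1.07, 0.09),
    "Cingulate cortex": ("cortical", True, 2.86, 0.30, 0.83, 0.06, 0.15, 0.04, 1.08, 0.06),
    "Piriform cortex": ("cortical", True, 3.77, 0.19, 0.87, 0.04, 0.19, 0.04, 1.03, 0.14),
    "Entorhinal cortex": ("cortical", True, 1.40, 0.09, 0.75, 0.05, 0.15, 0.02, 1.15, 0.12),
    "Parietal cortex": ("cortical", True, 5.59, 0.40, 0.86, 0.02, 0.16, 0.03, 1.07, 0.06),
    "Occipital cortex": ("cortical", True, 3.35, 0.23, 0.80, 0.03, 0.15, 0.04, 1.16, 0.11),
    "Insular cortex": ("cortical", True, 0.66, 0.08, 0.86, 0.07, 0.21, 0.07, 1.06, 0.17),
    "Temporal cortex": ("cortical", True, 5.92, 0.24, 0.82, 0.04, 0.13, 0.02, 1.08, 0.05),
    "External capsule": ("white_matter", True, 0.43, 0.04, 0.95, 0.08, 0.28, 0.03, 1.07, 0.06),
    "Internal capsule": ("white_matter", True, 1.49, 0.09, 1.28, 0.07, 0.35, 0.05, 0.97, 0.08),
    "Corpus callosum": ("white_matter", False, 0.70, 0.09, 1.15, 0.03, 0.24, 0.04, 1.04, 0.09),
    "Anterior commissure": ("white_matter", False, 0.13, 0.02, 1.30, 0.05, 0.27, 0.04, 0.96, 0.09),
    "Periventricular WM": ("white_matter", True, 0.65, 0.03, 1.16, 0.06, 0.26, 0.04, 1.04, 0.07),
    "Subcortical WM": ("white_matter", True, 2.82, 0.33, 1.04, 0.03, 0.21, 0.03, 1.04, 0.06),
    "Corona radiata": ("white_matter", True, 1.59, 0.13, 1.17, 0.05, 0.23, 0.06, 1.06, 0.09),
    "Fimbria of hippocampus": ("white_matter", True, 0.39, 0.06, 1.22, 0.05, 0.31, 0.14, 1.01, 0.08),
    "Fornix": ("white_matter", False, 0.07, 0.01, 1.28, 0.04, 0.22, 0.03, 0.92, 0.08),
    "Claustrum": ("deep_gray", True, 0.17, 0.02, 0.99, 0.06, 0.32, 0.08, 1.01, 0.10),
    "Caudate nucleus": ("deep_gray", True, 1.43, 0.11, 1.08, 0.03, 0.23, 0.05, 1.07, 0.05),
    "Thalamus": ("deep_gray", True, 6.86, 0.39, 1.21, 0.05, 0.23, 0.02, 0.97, 0.03),
    "Hippocampus": ("deep_gray", True, 9.39, 0.32, 0.92, 0.02, 0.19, 0.02, 1.07, 0.03),
    "Amygdala": ("deep_gray", True, 1.26, 0.11, 0.98, 0.03, 0.21, 0.06, 1.00, 0.04),
    "Hypothalamus": ("deep_gray", False, 0.67, 0.08, 1.09, 0.04, 0.20, 0.04, 0.96, 0.13),
    "Lenticular nucleus": ("deep_gray", True, 0.69, 0.07, 1.18, 0.05, 0.30, 0.07, 1.03, 0.12),
    "Olfactory bulb": ("deep_gray", True, 1.59, 0.41, 0.76, 0.05, 0.12, 0.06, 0.61, 0.03),
    "Cerebellar hemispheres": ("other", True, 6.47, 0.82, 0.85, 0.02, 0.11, 0.03, 0.95, 0.13),
    "Vermis": ("other", False, 8.08, 0.57, 1.02, 0.04, 0.14, 0.01, 0.92, 0.10),
    "Basal forebrain": ("other", True, 1.65, 0.16, 1.13, 0.03, 0.26, 0.04, 0.95, 0.07),
    "Forebrain": ("other", True, 0.23, 0.02, 1.19, 0.03, 0.28, 0.05, 0.94, 0.11),
    "Diencephalon": ("other", False, 0.17, 0.03, 1.11, 0.11, 0.18, 0.05, 1.15, 0.45),
    "Mesencephalon": ("other", False, 8.17, 0.54, 1.14, 0.03, 0.19, 0.01, 0.96, 0.05),
    "Pons": ("other", False, 5.94, 0.33, 1.25, 0.06, 0.22, 0.01, 0.98, 0.11),
    "Medulla oblongata": ("other", False, 4.13, 0.53, 1.17, 0.05, 0.18, 0.03, 0.78, 0.08),
    "Septum": ("other", False, 0.88, 0.06, 1.07, 0.03, 0.23, 0.02, 1.02, 0.06),
}

# 12-region subset used by the default phantom: spans all four groups and
# keeps every region comfortably above 100 voxels on a 48^3 grid.
PHANTOM_STRUCTURES = (
    "Frontal cortex",
    "Parietal cortex",
    "Temporal cortex",
    "Occipital cortex",
    "Internal capsule",
    "Corpus callosum",
    "Corona radiata",
    "Caudate nucleus",
    "Thalamus",
    "Hippocampus",
    "Vermis",
    "Mesencephalon",
)

# reference absolute MD (mm^2/s) corresponding to a relative MD of 1.0 in
# fixed tissue; relative MD targets are scaled by this when simulating DWI
MD_REFERENCE = 0.7e-3


@dataclass
class RegionSpec:
    """Target properties of one phantom region."""

    region_id: int
    name: str
    group: str
    volume_fraction: float  # fraction of the brain mask
    t1_mean: float  # relative T1 intensity (brain average = 1)
    t1_sd: float  # voxel noise SD, relative units
    fa: float
    md: float  # relative MD (brain average = 1)


@dataclass
class SynthParams:
    """Study-condition parameters of the synthetic population.

    Defaults emulate the source study: ten subjects, smooth inter-subject
    deformations of 2-voxel amplitude, per-region T1 noise at the published
    across-subject SDs.
    """

    grid_shape: tuple = (48, 48, 48)
    region_specs: list = dc_field(default_factory=lambda: default_region_specs())
    deform_amplitude: float = 2.0
    deform_smoothness: float = 6.0
    n_subjects: int = 10
    intensity_scale: float = 100.0
    noise_scale: float = 1.0
    seed: int = 0

    def __post_init__(self):
        if len(self.grid_shape) != 3 or min(self.grid_shape) < 8:
            raise ValueError("grid_shape must be 3 axes of at least 8 voxels")
        total = sum(s.volume_fraction for s in self.region_specs)
        if total > 1 + 1e-9:
            raise ValueError(f"region volume fractions sum to {total:.3f} > 1")
        if self.deform_amplitude < 0:
            raise ValueError("deform_amplitude must be >= 0")
        if self.deform_smoothness <= 0:
            raise ValueError("deform_smoothness must be > 0")
        if self.n_subjects < 1:
            raise ValueError("n_subjects must be >= 1")

    @property
    def n_regions(self) -> int:
        return len(self.region_specs)


@dataclass
class SynthSubject:
    """One simulated subject with its generating ground truth."""

    volume: Volume
    labels: LabelMap
    field: DisplacementField


def default_region_table() -> RegionTable:
    """Rabbit-like full region catalogue: 60 entries (25 bilateral pairs
    plus 10 midline structures) that merge to 35."""
    rows = []
    next_id = 1
    for name, (group, bilateral, *_rest) in REGION_STATS.items():
        if bilateral:
            rows.append((next_id, name, group, "left"))
            rows.append((next_id + 1, name, group, "right"))
            next_id += 2
        else:
            rows.append((next_id, name, group, "midline"))
            next_id += 1
    return RegionTable.from_rows(rows)


def default_region_specs(structures=PHANTOM_STRUCTURES) -> list:
    """Phantom region specs from the published statistics.

    Volume fractions of the selected structures are renormalized to tile
    the brain mask completely (their published values are fractions of the
    whole brain, most of which the subset does not cover).
    """
    total = sum(REGION_STATS[n][2] for n in structures)
    specs = []
    for i, name in enumerate(structures):
        group, _bilat, vol, _vsd, t1, t1_sd, fa, _fasd, md_rel, _mdsd = REGION_STATS[name]
        specs.append(
            RegionSpec(
                region_id=i + 1,
                name=name,
                group=group,
                volume_fraction=vol / total,
                t1_mean=t1,
                t1_sd=t1_sd,
                fa=fa,
                md=md_rel,
            )
        )
    return specs


def fibonacci_directions(n: int) -> np.ndarray:
    """n roughly uniformly spread unit vectors (golden-spiral hemisphere
    construction, mirrored), deterministic."""
    i = np.arange(n, dtype=float)
    golden = (1 + 5**0.5) / 2
    z = 1 - (2 * i + 1) / n
    theta = 2 * np.pi * i / golden
    r = np.sqrt(np.maximum(0.0, 1 - z * z))
    v = np.column_stack([r * np.cos(theta), r * np.sin(theta), z])
    return v / np.linalg.norm(v, axis=1, keepdims=True)


# depth of each group's seed points, as a fraction of the brain radius
_GROUP_RADIUS = {"cortical": 0.78, "white_matter": 0.50, "deep_gray": 0.22, "other": 0.60}


def make_phantom(p: SynthParams):
    """Deterministic base anatomy: labeled ellipsoidal brain phantom.

    The brain is an ellipsoid filling ~80% of each grid axis.  Region
    shapes come from an additively weighted (power-diagram) partition of
    the brain voxels around group-depth seed points; the weights are
    iteratively adjusted so each region's voxel count matches its target
    volume fraction.  Intensities are per-region relative T1 means times
    ``intensity_scale``, plus Gaussian noise with the per-region SD (scaled
    by ``noise_scale``); background is exactly 0.

    Returns ``(Volume, LabelMap)``.  Raises if the requested fractions
    cannot be realized on the grid (offending regions listed).
    """
    shape = tuple(int(s) for s in p.grid_shape)
    semi = np.array([0.40 * s for s in shape])
    center = (np.array(shape) - 1) / 2.0
    idx = np.indices(shape).reshape(3, -1).T.astype(float)
    rho2 = (((idx - center) / semi) ** 2).sum(axis=1)
    inside = rho2 <= 1.0
    pts = idx[inside]
    k_brain = len(pts)
    specs = list(p.region_specs)
    n_r = len(specs)
    if n_r == 0:
        raise ValueError("no region specs")

    dirs = fibonacci_directions(max(n_r, 3))[:n_r]
    seeds = np.array(
        [center + _GROUP_RADIUS[s.group] * dirs[i] * semi for i, s in enumerate(specs)]
    )
    d2 = ((pts[:, None, :] - seeds[None, :, :]) ** 2).sum(axis=-1)  # (K, R)

    frac = np.array([s.volume_fraction for s in specs], dtype=float)
    targets = frac / frac.sum() * k_brain if frac.sum() > 0 else frac
    # unassigned share (fractions summing below 1) stays background: model
    # it as a virtual region seeded at the boundary shell
    leftover = 1.0 - min(frac.sum(), 1.0)
    has_bg = leftover > 1e-6
    if has_bg:
        targets = np.append(frac * k_brain, leftover * k_brain)
        d2 = np.column_stack([d2, (1.0 - np.sqrt(rho2[inside])) ** 2 * semi.max() ** 2])

    w = np.zeros(d2.shape[1])
    scale = float(np.median(d2))
    assign = np.zeros(k_brain, dtype=int)
    for _ in range(200):
        assign = np.argmin(d2 - w[None, :], axis=1)
        counts = np.bincount(assign, minlength=len(w)).astype(float)
        rel_err = np.abs(counts - targets) / np.maximum(targets, 1.0)
        if rel_err.max() < 0.02:
            break
        w += 0.8 * scale * (targets - counts) / k_brain

    counts = np.bincount(assign, minlength=len(w)).astype(float)
    rel_err = np.abs(counts[:n_r] - targets[:n_r]) / np.maximum(targets[:n_r], 1.0)
    bad = [specs[i].name for i in np.nonzero(rel_err > 0.2)[0]]
    if bad:
        raise ValueError(f"could not pack regions into the grid: {bad}")

    labels = np.zeros(shape, dtype=np.int32)
    ids = np.array([s.region_id for s in specs] + ([0] if has_bg else []), dtype=np.int32)
    flat = np.zeros(shape, dtype=np.int32).ravel()
    flat[np.flatnonzero(inside)] = ids[assign]
    labels = flat.reshape(shape)

    rng = np.random.default_rng(p.seed)
    t1 = np.zeros(shape, dtype=float)
    for s in specs:
        sel = labels == s.region_id
        vals = s.t1_mean * p.intensity_scale
        if p.noise_scale > 0 and s.t1_sd > 0:
            vals = vals + rng.normal(
                0.0, s.t1_sd * p.intensity_scale * p.noise_scale, size=int(sel.sum())
            )
        t1[sel] = vals

    regions = RegionTable.from_rows(
        [(s.region_id, s.name, s.group, "midline") for s in specs]
    )
    return Volume(t1), LabelMap(labels, regions)


def random_deformation(shape, amplitude: float, smoothness: float, seed) -> DisplacementField:
    """Smooth random displacement field with exact peak amplitude.

    Gaussian-smoothed white noise per component, rescaled so the maximum
    voxel displacement norm equals ``amplitude``.  Amplitudes below the
    smoothness scale keep the warp fold-free in practice.
    """
    from scipy.ndimage import gaussian_filter

    if amplitude < 0:
        raise ValueError("amplitude must be >= 0")
    shape = tuple(int(s) for s in shape)
    rng = np.random.default_rng(seed)
    raw = rng.standard_normal(shape + (3,))
    if amplitude == 0:
        return DisplacementField(np.zeros(shape + (3,)))
    for c in range(3):
        raw[..., c] = gaussian_filter(raw[..., c], sigma=smoothness, mode="nearest")
    norms = np.sqrt((raw**2).sum(-1))
    peak = norms.max()
    if peak > 0:
        raw *= amplitude / peak
    return DisplacementField(raw)


def synth_population(p: SynthParams):
    """Simulated study population: each subject is the base phantom warped
    by its own smooth random field, with fresh per-region noise.

    Returns a list of :class:`SynthSubject`; the generating field and the
    warped ground-truth label map of each subject are retained.
    """
    base_vol, base_lab = make_phantom(replace(p, noise_scale=0.0))
    ss = np.random.SeedSequence(p.seed)
    children = ss.spawn(2 * p.n_subjects)
    sd_lut = np.zeros(int(base_lab.regions.ids.max()) + 1)
    for s in p.region_specs:
        sd_lut[s.region_id] = s.t1_sd * p.intensity_scale * p.noise_scale
    subjects = []
    for i in range(p.n_subjects):
        field = random_deformation(
            p.grid_shape, p.deform_amplitude, p.deform_smoothness, children[2 * i]
        )
        vol = warp_volume(base_vol, field)
        labels = base_lab.like(
            warp_volume(
                Volume(base_lab.labels, base_lab.spacing, base_lab.origin),
                field,
                interp="nearest",
            ).data.astype(np.int32)
        )
        noise_rng = np.random.default_rng(children[2 * i + 1])
        data = vol.data.copy()
        sds = sd_lut[labels.labels]
        noisy = sds > 0
        data[noisy] += noise_rng.normal(0.0, 1.0, size=int(noisy.sum())) * sds[noisy]
        subjects.append(SynthSubject(Volume(data), labels, field))
    return subjects


def _lambdas_from_fa_md(fa_target: float, md_abs: float):
    """Eigenvalues of a cylindrically symmetric tensor (l2 = l3) with the
    given FA and absolute MD; unique feasible solution for FA < 1."""
    if fa_target < 0 or fa_target >= 1:
        raise ValueError(f"FA target must be in [0, 1), got {fa_target}")
    T = 3.0 * md_abs
    if fa_target == 0:
        return md_abs, md_abs, md_abs
    a2 = fa_target**2
    A = 1.5 * a2 - 2.25
    B = (1.5 - a2) * T
    C = (0.5 * a2 - 0.25) * T**2
    disc = B * B - 4 * A * C
    roots = [(-B + np.sqrt(disc)) / (2 * A), (-B - np.sqrt(disc)) / (2 * A)]
    lam1 = next(r for r in roots if T / 3 < r <= T + 1e-12)
    lam2 = (T - lam1) / 2.0
    return lam1, lam2, lam2


def synth_dwi(
    labels: LabelMap,
    p: SynthParams,
    bvecs: np.ndarray | None = None,
    bval: float = 3000.0,
    s0: float = 100.0,
    noise_sd: float = 0.0,
    seed: int = 0,
) -> DWISet:
    """Diffusion-weighted signals from per-region target tensors.

    Each region gets a cylindrically symmetric tensor whose trace matches
    3 x (relative MD x MD_REFERENCE) and whose anisotropy solves the FA
    target in closed form; the principal axis is fixed per region.  Signals
    follow the monoexponential model with optional additive Gaussian noise.
    """
    if bvecs is None:
        bvecs = fibonacci_directions(30)
    bvecs = np.asarray(bvecs, dtype=float)
    if len(bvecs) < 6:
        raise ValueError("need at least 6 gradient directions")
    specs = {s.region_id: s for s in p.region_specs}
    ids = sorted(specs)
    axes = fibonacci_directions(max(len(ids), 3))
    # per-region attenuation for each direction
    att = np.ones((int(max(ids)) + 1, len(bvecs)))
    for k, rid in enumerate(ids):
        s = specs[rid]
        lam1, lam2, _ = _lambdas_from_fa_md(s.fa, s.md * MD_REFERENCE)
        u = axes[k]
        D = (lam1 - lam2) * np.outer(u, u) + lam2 * np.eye(3)
        quad = np.einsum("ni,ij,nj->n", bvecs, D, bvecs)
        att[rid] = np.exp(-bval * quad)
    lab = labels.labels
    brain = lab > 0
    rng = np.random.default_rng(seed)
    weighted = []
    for j in range(len(bvecs)):
        sig = np.where(brain, s0 * att[lab, j], 0.0)
        if noise_sd > 0:
            sig[brain] += rng.normal(0.0, noise_sd, size=int(brain.sum()))
        weighted.append(Volume(sig, labels.spacing, labels.origin))
    b0 = Volume(np.where(brain, float(s0), 0.0), labels.spacing, labels.origin)
    return DWISet(b0, weighted, np.full(len(bvecs), float(bval)), bvecs)
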