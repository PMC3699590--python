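# Methods

This note documents the models and algorithms implemented in `popatlas`,
the parameters that matter, the design choices made where the design was
genuinely open, and what the synthetic test suite does and does not show
about real data.

## Coordinate conventions

All geometry lives in 0-based voxel coordinates of the fixed image's grid;
millimetre spacing and origin are header metadata only.  Every transform is
pull-back: the resampled image at voxel `x` samples the moving image at
`x + d(x)` (displacement fields) or `A x + t` (affines), so "a field
mapping the template into subject i" is precisely the object that resamples
subject i onto the template grid.  This choice makes label propagation to
the template a direct warp with the stored field — no numerical field
inversion anywhere in the pipeline.

## Brain masking

Otsu thresholding over a 256-bin histogram of `[min, max]`; the threshold
maximizes between-class variance, ties resolve to the lowest candidate, and
the mask is `v >= t` (the brain is brighter than the background in the
acquisitions this pipeline models; the polarity is a flag).  Empty-bin
plateaus make exact ties common, hence the explicit tie rule.

## Diffusion tensor estimation

Ordinary least squares on `ln(S_j/S0) = -b_j g_j' D g_j` — the reproducible
baseline, with no weighting or positivity constraint; negative eigenvalues
are possible in principle and are not clipped.  Voxels with non-positive
measurements keep the fit if ≥ 6 usable non-collinear directions remain,
otherwise they are flagged unfit rather than raising.  Eigenvalues are
sorted descending; the principal eigenvector's sign is fixed (first
non-negligible component non-negative) and voxels with
`λ1 − λ2 < 1e-12·‖λ‖` are flagged degenerate so the direction is not
interpreted there.  FA is `sqrt(3/2)·‖λ − mean(λ)‖/‖λ‖` (0 for the zero
tensor), MD the eigenvalue mean, and the color map `FA·(|e1x|,|e1y|,|e1z|)`.
Gradient directions follow an affine realignment through the rotation
factor of the polar decomposition `A = R S`; scalings and shears leave unit
directions unchanged, which the tests check explicitly.

## Affine registration by mutual information

MI is computed in bits from a `bins × bins` joint histogram (default 32
bins).  The 12 parameters (translation, rotation, log-scale, shear) are
optimized by a Powell search per pyramid level, coarse to fine, with search
directions scaled to each parameter's natural step; MI under histogram
binning is not differentiable, so no gradients are used.  On noiseless
piecewise-constant images the empirical MI optimum can sit a fraction of a
voxel off true alignment (the known interpolation artifact of
histogram MI); with realistic intensity noise the bias disappears, and the
self-alignment error on the noisy synthetic phantom is ~0.002 voxel.

## Elastic registration by block matching

Per pyramid level (default 3 levels, 2 sweeps each): blocks of 5³ voxels
every 3 voxels; each block with fixed-image variance above a gate (default
`1e-6 × intensity-range²`, floored at 1e-12) searches integer offsets
within a radius of 3 for the maximum Pearson correlation against the
current warped moving image.  Numerical details that proved essential:

* **Variance gating of both blocks.** Correlation against a near-constant
  *moving* block is undefined; without gating it, denominator underflow
  produced correlations ≫ 1 from pure round-off.  Both block variances must
  clear the gate, computed in float64 (the `E[x²] − E[x]²` form cancels
  catastrophically in float32).
* **Parsimony margin.** Offsets are visited in order of increasing norm and
  a larger offset must beat the incumbent correlation by 5e-3.  This
  resolves the aperture problem — a block on a flat boundary between
  homogeneous regions correlates near-perfectly at many offsets along the
  boundary — in favour of the smallest displacement.
* **Subvoxel refinement.** After the integer search, a 1-D parabola per
  axis through the correlation at the peak and its neighbours yields a
  subvoxel correction (clipped to ±0.5 voxel).  It runs only on the final
  sweep of the finest level — its small bias must not be upscaled through
  the pyramid — and only for peaks that are genuinely curved
  (curvature < −5e-3) and imperfect (r < 1 − 1e-6), so identical images
  yield an exactly zero field.
* **Field regularization.** Per-block offsets are scattered at block
  centres, weighted by their correlation, and turned into a dense field by
  normalized convolution with a Gaussian (σ = 3 voxels).  σ = 3 measurably
  beat σ = 2 in every validation scenario because it propagates
  well-determined interior estimates across the aperture-limited brain
  surface.
* **Composition.** Increments estimated against the warped moving image
  compose as `d_total(x) = e(x) + d_acc(x + e(x))` (warp by the increment,
  then resample through the accumulated field).

On the synthetic suite the engine recovers a 2-voxel-amplitude smooth
random field with ~0.07 voxel mean foreground endpoint error and a
2-voxel sinusoidal field (typical displacement ~1.7 voxel) with ~0.45.
The residual error concentrates within ~4 voxels of the brain surface,
where the tangential component of motion along the smooth phantom boundary
is fundamentally unobservable from intensity; real cortex, with folds and
texture, is more informative there.

## Average template

1. **Reference selection.**  Every candidate is registered to every other
   subject; the candidate whose fields have the smallest average mean
   displacement wins (ties → lowest index).  Ranking is insensitive to
   registration effort, so the O(n²) stage accepts a cheaper configuration
   (`ref_cfg`, typically one sweep per level).
2. **Mean shape.**  The template is registered to every subject, the fields
   averaged, and the template warped by the *inverse* of the mean field
   (first-order inverse: the negated field).  Warping by the mean field
   directly moves the template away from the population mean — a
   shifted-copies argument shows the mean pull-back field points from the
   template toward itself as seen from the subjects — and diverges in
   practice, so the forward variant exists only behind
   `mean_field_mode="forward"` for comparison.  Updates accumulate by
   composition and the original reference is resampled once per iteration,
   so interpolation blur does not compound.  Iteration stops when the mean
   displacement of the average field drops below `tol` (default 0.1 voxel,
   `max_iter` 10).  On noisy populations the mean displacement plateaus at
   the registration noise floor (~0.3–0.4 voxel over the full grid,
   dominated by background extrapolation) rather than reaching `tol`; the
   template is stable by then, and the end-to-end workflows cap the
   iteration at 4 as their standard problem size.
3. **Mean intensity.**  Every subject is registered and resampled onto the
   shape template; the per-voxel mean excludes values deviating from the
   voxel mean by more than 2 *sample* standard deviations (ddof = 1, one
   pass, two-sided by default with an upper-only flag).  At least one value
   always survives, since the squared deviations sum to `(n−1)s²`.  Note
   that a single extreme outlier among n = 10 deviates by
   `s·(n−1)/√n ≈ 2.85 s` and is therefore always trimmed — the rule behaves
   as intended on exactly the contamination it targets.  The registration
   fields from this stage (template → subject) are stored for atlas
   building.

## Probabilistic atlas and parcellation

Subject label maps are carried to the template by nearest-neighbour
resampling through the stored fields; `p_r(x)` is the fraction of subjects
voting `r` at `x`.  Out-of-field samples count as background votes, so the
probabilities including background sum to exactly 1 and live on the `1/N`
lattice.  The most-probable-label map takes the per-voxel argmax with
background competing; ties go to the smallest id (background = 0 first).

Segmentation of a new volume registers the template to it (affine MI, then
block matching), carries each probability map across with *trilinear*
interpolation in a single resampling pass (`p(A(x + d(x)) + t)`), and
labels each voxel with the most probable region.  Warping probabilities
rather than discrete labels preserves the partial-volume robustness of the
probabilistic representation.  A hard elastic failure degrades to
affine-only with a warning.

## Evaluation

Per-region Dice uses the conventions: 1 if the region is empty in both
maps, 0 if empty in exactly one.  The global matching index is
label-aggregated Dice `2 Σ_r |A_r∩B_r| / Σ_r (|A_r|+|B_r|)` over
non-background regions (background would inflate agreement); the
unweighted per-region mean is available as a variant for sensitivity
analysis.  Confusion matrices are row-normalized percentages with
background as an explicit row/column; empty reference regions yield an
all-zero row.  `merge_bilateral` pools left/right entries of the same
structure (60 catalogue entries → 35 structures); unpaired lateral entries
warn and pass through.

## Synthetic population generator

The generator emulates the study inputs: ten subjects, one T1-like channel,
optional DWI, with per-region targets (volume fraction, relative T1
intensity and its SD, FA, relative MD) taken from the published
characterization of 35 rabbit brain structures.  The default phantom uses a
12-structure subset spanning all four region groups, with fractions
renormalized to tile the brain mask, so that every region stays well above
100 voxels on a 48³ grid; the full 60-entry lateralized catalogue is also
provided for structural tests.

The phantom is an ellipsoid (~80% of each grid axis) partitioned by an
additively weighted nearest-seed rule: seeds sit at group-appropriate
depths (cortical near the surface, white matter mid-depth, deep gray
central) and the additive weights are iterated until every region's voxel
count is within 2% of target (packing failures raise, naming the offending
regions).  Intensities are per-region relative-T1 means × a global scale
(default 100) plus Gaussian noise at the per-region SDs; the background is
exactly zero.  Subjects are the noiseless base warped by independent
Gaussian-smoothed white-noise fields rescaled to an exact peak amplitude
(default 2 voxels, smoothness 6 — fold-free: the Jacobian stays positive),
with fresh noise added after warping.  DWI signals come from cylindrically
symmetric per-region tensors whose eigenvalues solve the FA/MD targets in
closed form (relative MD × 0.7 × 10⁻³ mm²/s, a typical fixed-tissue scale),
through the monoexponential model.

What the phantom does *not* emulate: bias fields, Rician noise statistics,
partial-volume smoothing at boundaries, anatomically realistic shapes, and
surface texture.  Consequences for interpreting green tests: registration
accuracy at the smooth synthetic brain surface *understates* what textured
real anatomy allows (aperture problem), while the perfectly reproducible
noise "fingerprint" shared between a base and its warped copies makes
interior matching somewhat easier than between two real subjects.  Dice
values near 1 on the synthetic suite demonstrate the pipeline's internal
consistency at these deformation scales, not expected accuracy on real
rabbit brains, where agreement comparable to inter-observer variability is
the realistic ceiling.

## Problem sizes

The test suite and `scripts/acceptance.py` run the full pipeline at
48³ voxels, ten subjects, twelve regions, 2-voxel deformations — the
package's standard desk-scale configuration; unit tests use 16³–32³
variants of the same generator.  All stages are deterministic given the
configuration and a single top-level seed.

## Known limitations

* No diffeomorphic guarantee or inverse consistency in the elastic engine;
  large or folding deformations are out of scope.
* The affine MI optimizer is a local search; grossly misaligned volumes
  need a better initialization than identity.
* The first-order field inverse (negation) used in template iteration is
  accurate only for small, smooth mean fields — exactly the regime the
  iteration operates in after the first pass.
* Label fusion is unweighted majority vote; intensity-informed or
  STAPLE-style fusion is deliberately not implemented.
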