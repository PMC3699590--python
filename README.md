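# popatlas

Population MRI atlas construction and atlas-based brain parcellation.

Small-animal neuroimaging studies often lack a digital brain atlas for the
species under study, forcing manual delineation of every region of
interest.  `popatlas` implements the full pipeline for building such an
atlas from a set of individually labeled 3-D volumes — developed around the
use case of a T1/diffusion MRI atlas of the New Zealand rabbit brain — and
for using it to parcellate new volumes automatically:

* **Multimodal alignment** — affine registration by mutual-information
  maximization (for T1 vs. diffusion baselines), with gradient-direction
  reorientation by the rotation component (polar decomposition) of the
  transform, followed by log-linear least-squares diffusion-tensor
  estimation, FA/MD and direction-encoded color maps.
* **Delineation bootstrap** — propagation of existing parcellations to a
  new subject by elastic registration and per-voxel most-frequent-label
  fusion, giving each subject a starting parcellation.
* **Average template** — the subject requiring the minimum transformation
  to match all others seeds an iterative average-shape template
  (register, average the displacement fields, apply the inverse mean
  transformation, repeat until the mean displacement falls below a
  threshold); intensities are averaged with 2-standard-deviation trimming.
* **Probabilistic atlas** — per-region probability maps on the template,
  `p_r(x) = |{i : L_i(x) = r}| / N`, and a most-probable-label map.
* **Automatic parcellation** — template-to-subject registration (affine,
  then multiresolution block matching on the correlation coefficient),
  trilinear warping of the probability maps and per-voxel maximum
  probability labeling.
* **Evaluation** — per-region Dice `DC_r = 2|A_r ∩ B_r|/(|A_r|+|B_r|)`,
  a label-aggregated global matching index, and row-normalized confusion
  matrices.

Because real atlas-grade MRI is large and rarely redistributable, the
package ships a first-class synthetic-population generator
(`popatlas.synthpop`): a parametric labeled brain phantom whose region
volumes, relative T1 intensities, FA and MD follow published statistics of
35 rabbit brain structures, deformed per subject by smooth random fields
with known ground truth.  Every pipeline stage is testable end to end
against that ground truth.

## Worked example

```python
import numpy as np
from popatlas.register import RegConfig
from popatlas.synthpop import SynthParams, synth_population
from popatlas.template import build_template
from popatlas.probatlas import build_probability_maps, segment
from popatlas.evalseg import evaluate

subjects = synth_population(SynthParams(grid_shape=(32, 32, 32), n_subjects=6, seed=15))
train, held = subjects[:5], subjects[5]

tm = build_template([s.volume for s in train], RegConfig(), max_iter=4,
                    ref_cfg=RegConfig(iterations_per_level=1))
atlas = build_probability_maps(tm, [s.labels for s in train])
auto, maxprob = segment(held.volume, atlas, RegConfig())
report = evaluate(held.labels, auto)
print(f"global matching index: {report.global_index:.4f}")
```

prints

```
global matching index: 0.9987
```

meaning that, aggregated over all regions, 99.9% of region voxels agree
between the automatic parcellation of the held-out subject and its ground
truth (1.0 is perfect overlap; the per-region Dice values and the confusion
matrix in `report` break this down by structure).  The scripts in
`examples/` walk through each capability — simulation, tensor fitting,
registration recovery, atlas construction and evaluation — printing and
explaining the numbers they compute.

A thin CLI mirrors the pipeline for shell use:

```sh
popatlas simulate --out pop/ --n-subjects 10 --grid 48 --seed 1
popatlas build    --config build.yaml --out atlas/
popatlas segment  --atlas atlas/ --volume new_t1.nii --reference truth.nii --out seg/
```

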