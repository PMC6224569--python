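# ctmorph

Atlas-based segmentation and comparative 3-D morphometrics for micro-CT
volumes of small teleost fish (medaka, zebrafish).

Whole-body micro-CT of contrast-stained adult fish yields quantitative
volumes in which every organ is visible — but analysing cohorts by manual
segmentation takes hours per specimen.  `ctmorph` automates the analysis:
each new scan is aligned to a labelled reference atlas, the atlas labels
are propagated organ by organ through multi-resolution registration, and
the resulting segmentations feed comparative morphometrics (organ volumes,
surfaces, positions, inter-eye distance, cross-section shape profiles,
shape probability maps and surface distance maps) that can resolve
strain-level anatomical differences.  A synthetic fish-phantom generator
with exact ground-truth labels makes the entire pipeline testable without
scan data.

## Method

Segmentation proceeds in five steps:

1. **Whole-body alignment.**  The body mask (Otsu threshold, morphological
   closing, largest component, cavity filling) is aligned to the atlas:
   a three-point similarity initialisation — both eye lenses, found among
   below-threshold regions by Wadell sphericity
   `psi = pi^(1/3) (6V)^(2/3) / A` and volume self-similarity
   `|V_i - V_j|/(V_i + V_j)`, plus a tail point — followed by
   multi-resolution rigid, affine and diffeomorphic (demons) registration
   minimising the mean squared intensity difference over a Gaussian
   pyramid.
2. **Bounding boxes.**  Each atlas organ label is mapped through the chain
   and enclosed in an axis-aligned box with a 10% margin.
3. **Organ registration.**  The intensity sub-volumes inside each box are
   re-registered with an organ-level schedule.
4. **Label propagation.**  The atlas organ label is warped into the
   specimen box by nearest-neighbour resampling.
5. **Refinement and assembly.**  Largest component, radius-1 morphology and
   hole filling per organ; per-organ results are assembled into one label
   map with deterministic conflict resolution.

Morphometric parameters are normalised to the specimen's total volume
(`V/V_tot`, `A/V_tot^(2/3)`, `L/V_tot^(1/3)`), making comparisons
independent of absolute body size.  Cohort shape analysis averages aligned
binary organ masks into probability maps, thresholds them at 60% for
consensus shapes, and quantifies divergence by surface distance maps and
the Dice coefficient `2|A∩B|/(|A|+|B|)`.  See `docs/methods.md` for the
full model description, parameter defaults and estimator validation.

## Worked example

Segment five synthetic specimens — seeded deformations of a phantom atlas
(rotation up to 3°, scale ±3%, translation up to 4 voxels, a smooth local
field up to 8 voxels, 2% noise) — and score them against ground truth:

```python
import numpy as np
from ctmorph.phantom import (PhantomSpec, DeformationSpec, phantom_atlas,
                             apply_known_deformation, derive_seed)
from ctmorph.pipeline import PipelineConfig, run_segmentation
from ctmorph.shape import dice_coefficient

spec = PhantomSpec()                       # 160 x 96 x 96 voxels
atlas = phantom_atlas(spec)                # clean reference + truth labels
specimens = []
for k in range(1, 6):
    d = DeformationSpec(rot_max_deg=3, scale_range=(0.97, 1.03),
                        trans_max_vox=4, local_max_vox=8,
                        local_sigma_vox=16, seed=derive_seed(1, k))
    vol, truth, _ = apply_known_deformation(
        atlas.reference, atlas.labels, d, noise_sd=spec.noise_sd)
    specimens.append((vol, truth))

config = PipelineConfig(atlas=atlas, organs=[1, 2, 3, 4])  # lenses, brain, cord
run = run_segmentation(config, [v for v, _ in specimens])
for (v, truth), (sid, seg) in zip(specimens, run.results.items()):
    dice = {o: dice_coefficient(seg.labels.data == o, truth.data == o)
            for o in config.organs}
    print(sid, {k: round(d, 3) for k, d in dice.items()})
```

Output (seed hierarchy rooted at 1):

```
specimen_000 {1: 0.978, 2: 0.975, 3: 0.979, 4: 0.949}
specimen_001 {1: 0.959, 2: 0.977, 3: 0.987, 4: 0.957}
specimen_002 {1: 0.966, 2: 0.95, 3: 0.979, 4: 0.98}
specimen_003 {1: 0.991, 2: 0.982, 3: 0.988, 4: 0.984}
specimen_004 {1: 0.987, 2: 0.966, 3: 0.982, 4: 0.979}
```

Every propagated organ label overlaps its ground truth at Dice 0.95–0.99,
i.e. the automated segmentation recovers the deformed anatomy to within a
fraction of a voxel at the boundary.  The same objects drive the cohort
comparison (`run_comparison`), which reports group cross-section profiles,
the head-region contrast, per-organ normalised volume statistics and
consensus-shape distances.

A `ctmorph` command-line interface wraps the same functionality
(`ctmorph phantom`, `mask`, `landmarks`, `register`, `segment`, `morpho`,
`profile`, `dice`, `run`, `compare`); see `ctmorph --help`.

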