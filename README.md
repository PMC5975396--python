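# shapeseg

Statistical shape-model segmentation of 3-D organ images, implemented as a
ladder of three methods that use increasingly rich shape knowledge:

1. **Single-atlas propagation** — a reference image with a known segmentation
   is registered to the target (similarity alignment + cubic B-spline
   free-form deformation, driven by SSD or mutual information) and its mask
   is propagated through the recovered transform.
2. **Active Shape Models (ASM)** — a point distribution model
   (`x = x̄ + P b`, Procrustes-aligned landmarks, PCA modes with |b_i| ≤ 3√λ_i)
   is fitted iteratively at three image resolutions, moving each landmark
   along its surface normal to the best-scoring candidate: minimal
   Mahalanobis distance of the normalized derivative profile to the trained
   mean (*classic*), or best agreement of per-point kNN inside/outside
   classifications with the ideal half-inside/half-outside pattern
   (*optimal features*).
3. **Gaussian Process Morphable Models (GPMM)** — shapes are a reference
   surface plus a deformation field `u ~ GP(μ, k)` in low-rank
   Karhunen–Loève form `u = μ + Σ α_i √λ_i φ_i` (dense eigendecomposition or
   Nyström approximation for analytic kernels; Gram-factorized empirical
   mean/covariance learned from example shapes). Segmentation draws
   whole-shape candidates from the deformation distribution and keeps the
   one whose boundary profiles best match the appearance model.

Results are quantified with DICE overlap (%), symmetric mean surface
distance (mm) and Hausdorff distance (mm). Because real annotated CT
cohorts cannot ship with a package, a seeded phantom generator produces
CT-like liver phantoms (lobed ellipsoid deformed by a known GP, distinct
interior/exterior intensities, partial-volume smoothing, additive noise)
with exact ground-truth masks, meshes and correspondences, so every claim
the package makes is reproducible from scratch.

The three segmentation methods are scikit-learn-style estimators
(`fit`/`predict`/`get_params`); I/O covers MetaImage (.mhd/.mha), NIfTI
(.nii/.nii.gz), PLY and legacy-VTK meshes, CSV/JSON reports.

## Worked example

```python
import numpy as np
from shapeseg import GPMMSegmenter, SingleAtlasSegmenter, evaluate_case
from shapeseg.phantom import PhantomSpec, generate_cohort, split_train_test

cohort = generate_cohort(PhantomSpec(), 20, seed=0)   # 64^3 voxels, 2 mm
train, test = split_train_test(cohort, 10, seed=0)

gpmm = GPMMSegmenter(seed=0).fit([c.image for c in train],
                                 [c.mesh for c in train])
atlas = SingleAtlasSegmenter(metric="mi").fit([c.image for c in train],
                                              [c.mask for c in train])

case = test[0]
for name, seg in [("gpmm", gpmm), ("atlas-mi", atlas)]:
    rep = evaluate_case(seg.predict(case.image), case.mask, case_id=case.case_id)
    print(f"{name:9s} DICE {rep.dice_percent:5.2f}%  "
          f"MSD {rep.msd_mm:.2f} mm  H {rep.hausdorff_mm:.2f} mm")
```

prints (seed 0, first test case):

```
gpmm      DICE 99.12%  MSD 0.19 mm  H 2.00 mm
atlas-mi  DICE 95.84%  MSD 0.81 mm  H 2.83 mm
```

i.e. on this case the learned deformation model places the boundary within
a fifth of a voxel on average, while plain atlas registration leaves a
residual of almost half a voxel — the gap the shape-model ladder is designed
to show.

The same comparison over a whole cohort, including both ASM variants, the
GPMM vertex-count ladder, and an intensity-remap robustness probe of the
two atlas similarity measures, runs from the command line:

```bash
shapeseg experiment --config config.yaml --out results/
```

writing per-case and mean rows of all three measures to
`results/report.csv` (see `shapeseg --help` for the `synth`, `train`,
`segment` and `evaluate` subcommands).

## Layout

| module | contents |
| --- | --- |
| `shapeseg.core` | `Volume`/`LabelMask`/`SurfaceMesh`, format I/O, voxel↔surface conversion |
| `shapeseg.registration` | B-spline FFD, similarity transform, SSD/MI costs, both optimizers |
| `shapeseg.atlas` | atlas propagation, `SingleAtlasSegmenter` |
| `shapeseg.pdm` | Procrustes alignment, PCA point-distribution models |
| `shapeseg.profiles` | gray-level profile statistics, optimal-feature kNN models |
| `shapeseg.asm` | ASM search steps and fitting, `ActiveShapeModelSegmenter` |
| `shapeseg.gpmm` | kernels, low-rank GPs, Nyström, correspondence, `GPMMSegmenter` |
| `shapeseg.metrics` | DICE, mean surface distance, Hausdorff, case reports |
| `shapeseg.phantom` | seeded phantom cohorts with exact ground truth |
| `shapeseg.experiment` / `shapeseg.cli` | experiment orchestration and CLI |

See `docs/methods.md` for the models, their assumptions, parameter defaults
and known limitations.
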