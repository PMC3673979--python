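# infuseg

Semi-automated segmentation of convection-enhanced delivery (CED) infusions
on T1-weighted MRI.

In CED, drug is pumped directly into brain parenchyma and a co-infused
gadolinium contrast agent makes the infusate appear hyperintense on
intra-operative T1 FLASH images. The clinically interesting quantity is the
distribution volume **Vd** — how far the infusate has spread — and its ratio
**Vd/Vi** to the pump-reported infusion volume **Vi**. Manual delineation of
the infusate is slow and disagrees heavily between operators, because the
infusion edge is a sloped intensity "shoulder" rather than a sharp boundary.
`infuseg` replaces manual tracing with a reproducible procedure that needs
only a rough operator-drawn 3D bounding box around the infusion.

## Method

1. **Normalization.** Voxel intensities are mapped affinely to `[0, 1]` over
   the whole scan: `x' = (x − min) / (max − min)`.
2. **Two-class Gaussian mixture.** Intensities inside the bounding box are
   modelled as

   `p(x) = (1 − α) N(x; μ₀, σ₀) + α N(x; μ₁, σ₁)`

   with background class (μ₀, σ₀), foreground (infusate) class (μ₁, σ₁) and
   mixing proportion α. The five parameters are fitted by
   Expectation-Maximization from starting values μ₀ = 0.2, σ₀ = 0.2,
   μ₁ = 0.8, σ₁ = 0.2, α = 0.5, iterating until the relative change of the
   negative log-likelihood falls below 0.1%.
3. **Classification.** Each boxed voxel is assigned to the class with the
   higher posterior probability: foreground iff
   `α N(x; μ₁, σ₁) > (1 − α) N(x; μ₀, σ₀)`. Everything outside the box is
   background.
4. **Morphological refinement.** 3D binary closing then opening with a
   spheroidal structuring element 5 × 5 × 3 voxels wide removes holes in the
   infusate and isolated bright voxels; optionally only the largest
   26-connected component is kept.
5. **Metrics.** Vd (µL, from voxel count × voxel volume), Vd/Vi, and the
   inter-operator coefficient of variance
   `CoV = 100 · sd(volumes) / mean(volumes)` (sample standard deviation).

A synthetic-phantom generator produces T1-FLASH-like volumes — a
hyperintense quasi-ellipsoidal infusate with a blurred shoulder over a
heterogeneous darker background, plus noise and bright border distractors —
with exact ground truth, so the whole pipeline is testable without imaging
data.

## Worked example

Generate a phantom and segment it:

```sh
$ infuseg phantom --seed 5 --out ph
{
  "files": ["ph/phantom_image.nii", "ph/phantom_truth.nii"],
  "truth_volume_ul": 368.48,
  "suggested_box": {"lo": [20, 20, 8], "hi": [44, 44, 24]}
}

$ infuseg segment --input ph/phantom_image.nii --box 19 19 7 45 44 25 \
    --vi-ul 150 --out-mask mask.nii --out-report report.json
{
  "vd_ul": 370.93,
  "voxel_count": 757,
  "vi_ul": 150.0,
  "vd_vi": 2.47,
  "iterations": 9,
  "converged": true,
  "alpha": 0.0679,
  "mu0": 0.2762, "sigma0": 0.0597,
  "mu1": 0.7440, "sigma1": 0.1138,
  ...
}
```

EM converged in 9 iterations to a dark background class (mean 0.28) and a
bright infusate class (mean 0.74); the segmented distribution volume of
370.9 µL is within 0.7% of the phantom's 368.5 µL ground truth, and
Vd/Vi = 2.47 says the infusate spread over ~2.5× the infused volume.
`infuseg segment` also accepts a DICOM series directory as `--input`, and
`infuseg batch --config batch.json` runs many datasets and appends cohort
Vd/CoV summaries.

The same pipeline is available as a library:

```python
from infuseg import PhantomSpec, generate_phantom, default_box, segment_infusion

res = generate_phantom(PhantomSpec(seed=5))
mask, report = segment_infusion(res.grid, default_box(res))
print(report.vd_ul, res.truth_volume_ul)
```

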