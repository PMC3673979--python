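# Methods

## Model and procedure

The segmentation treats the intensity histogram inside an operator-defined
bounding box as a two-component univariate Gaussian mixture: a darker
background class N(μ₀, σ₀²) and a brighter infusate class N(μ₁, σ₁²) mixed
with foreground proportion α. The model deliberately carries no spatial
prior — spatial coherence is restored afterwards by binary morphology —
and assumes each class is intensity-homogeneous, which real brain
backgrounds only approximate (deep grey, white matter and CSF differ);
that approximation is the main driver of the residual sensitivity of the
result to the box contents.

The procedure, in order:

1. Min–max normalization of the whole scan to [0, 1]. Whole-scan rather
   than within-box normalization keeps the fitted parameters comparable
   across boxes; within-box normalization is available as
   `RunConfig(normalize_within_box=True)`.
2. EM fit of (α, μ₀, σ₀, μ₁, σ₁) on the boxed voxels from the fixed
   starting values (0.5, 0.2, 0.2, 0.8, 0.2). The E-step computes the
   posterior foreground responsibility of each voxel; the M-step updates
   mixing weight, weighted means and population (maximum-likelihood)
   weighted variances.
3. Posterior (Bayes-rule) classification of the boxed voxels; ties go to
   background, so a degenerate decision never inflates Vd. A raw
   likelihood-ratio mode (`posterior=False`) is available; the posterior
   rule is the default because the mixture semantics of "more probably
   foreground" include the class priors.
4. 3D closing, then opening, with a 5×5×3 spheroidal element; closing
   first fills interior holes before opening removes isolated voxels, so
   large contiguous infusate regions survive unchanged. Optionally
   (default on) only the largest 26-connected component is kept.
5. Vd = foreground voxel count × voxel volume (mm³ = µL); Vd/Vi when the
   pump volume is supplied.

## Convergence and numerical choices

* **Stopping rule.** Model fit is monitored through the negative
  log-likelihood; iteration stops when its relative change between
  successive iterations drops below 0.1% (`tol=1e-3`). The fit quality
  criterion and the stopping criterion are therefore the same quantity. A
  500-iteration cap guards against non-termination and is flagged as
  `converged=False`.
* **Log-space densities.** All density evaluations, responsibilities and
  the NLL are computed via log-sum-exp, so intensities far from both
  components cannot underflow into a 0/0 responsibility.
* **Variance floor and α clamp.** σ ≥ 1e-4 (normalized units) and
  α ∈ [1e-6, 1−1e-6] prevent the singular likelihood spikes a
  floor-less EM can reach when a component collapses onto one value. A
  component absorbing (almost) everything is reported as `collapsed=True`
  and, at the pipeline level, yields an empty mask rather than an
  exception — the right answer for a box containing only background.
* **Label order.** EM does not order components; after convergence the
  brighter component is relabelled foreground (μ₁ ≥ μ₀, α flipped with it).
* **Element semantics.** "5 × 5 × 3 voxels wide" is read as full widths,
  giving semi-axes (2, 2, 1) and membership
  (di/2)² + (dj/2)² + (dk/1)² ≤ 1. At 0.7 mm in-plane / 1 mm slices the
  element is roughly isotropic in millimetres. Borders are treated as
  background padding, so a mask touching the array edge is not spuriously
  retained by closing.
* **Coordinates.** 0-based voxel indices and half-open boxes [lo, hi),
  which make the box voxel count exactly ∏(hi − lo). Non-finite voxels
  are rejected at load time.

## Tunable parameters

| parameter | default | units | role |
|---|---|---|---|
| `tol` | 1e-3 | relative NLL change | EM stopping threshold (0.1%) |
| `max_iter` | 500 | iterations | EM cap |
| `element_widths` | (5, 5, 3) | voxels | spheroidal element full widths |
| `keep_largest` | on | — | retain only the largest 26-connected component |
| `normalize_within_box` | off | — | normalization scope |
| `posterior` | on | — | posterior vs raw-likelihood classification |

## The phantom generator

`PhantomSpec` renders a quasi-ellipsoidal hyperintense infusate
(default semi-axes 5 × 4.5 × 4 mm, foreground mean 0.75) over a darker
background (mean 0.25) on a 64 × 64 × 32 grid at 0.7 × 0.7 × 1 mm spacing,
then blurs the edge with a Gaussian of σ = 0.5 mm — a point-spread-scale
shoulder, FWHM comparable to the in-plane voxel — and adds white Gaussian
noise (σ = 0.05). The background is made heterogeneous by a smooth random
field (amplitude 0.03, correlation length 3 mm), and three bright
distractor blobs near the volume border emulate fat-like structures that
the bounding box exists to exclude. `generate_study` jitters semi-axes
(±20%), centre (±2 voxels) and noise (±20%) across subjects.

The infusate region itself is a voxelized ellipsoid regularized by an
element-scale spheroidal opening. A raw voxelized ellipsoid carries
single-voxel staircase jaggies that no physical infusion front has and
that any element-scale opening necessarily shaves; regularizing the truth
region at the voxel scale makes "the pipeline recovers the noiseless
phantom exactly" a meaningful statement about the method rather than
about discretization artifacts. The regularized region stays within one
voxel-shell of the analytic ellipsoid volume (521.4 vs 523.6 µL for a
5 mm sphere).

Ground truth is the pre-blur region: the shoulder is modelled as a
property of imaging, so the measured volume-recovery error quantifies how
the classifier places the boundary on the shoulder — exactly the decision
human operators disagree on.

What the phantom does **not** model: MR signal physics (TE/TR/flip-angle),
spatially varying coil sensitivity, zipper or flow artifacts, partial
infusate filling of sulci, or anatomically structured backgrounds.
Passing phantom tests therefore demonstrates correctness of the
normalization → EM → classification → morphology chain and its robustness
to noise, shoulder ambiguity and box choice, not clinical accuracy on
real acquisitions.

## Problem sizes

The test suite and the acceptance script run at desk scale by choice:
phantoms of 64 × 64 × 32 voxels (boxes of ~10⁴ voxels entering EM),
a 14-subject synthetic cohort with four bounding boxes per subject, EM
parameter-recovery checks on 10⁵ samples, and brute-force morphology
oracles on masks up to 25³. Cohort-level human results (inter-operator
CoV of 4 operators over 14 animal datasets) require the original images
and operators and are represented instead by the worked per-example CoV
computations and by phantom-cohort analogues.

## Known limitations

* One background class: strongly multi-modal backgrounds inside the box
  (e.g. box spanning CSF and white matter) violate the model and can pull
  the decision boundary; tighter boxes mitigate this.
* The automated result still depends weakly on the box (the phantom
  cohort shows a few-percent volume change when the box margin doubles),
  matching the weak box-size dependence seen in practice.
* No pre-infusion baseline subtraction, brain extraction, bias-field
  correction, registration or resampling; inputs are assumed de-identified
  single-series volumes with uniform slice spacing.
* Masks are written as NIfTI-1, not DICOM-SEG.
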