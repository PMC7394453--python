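# Methods

## The problem

Single-shot EPI — the workhorse readout for diffusion MRI — accumulates
phase slowly along the phase-encoding (PE) axis, so magnetic-field
inhomogeneity near air–tissue interfaces displaces signal along that axis.
A voxel sitting at off-resonance `f` Hz in an acquisition with total
readout time `T` seconds appears shifted by

    Δ = polarity · f · T   (voxels)

along the PE axis. Where the shift field compresses voxels the signal
*piles up* (bright bands); where it stretches them the signal rarefies.
Standard correction (topup) estimates the field from a pair of
opposite-polarity ("blip-up / blip-down") b0 images — but many archival
and clinical datasets have only a single blip and no field map.

This package implements a synthesis route to correction: a 3D U-Net takes
the (undistorted) T1w image and the distorted b0 and synthesizes an
undistorted b0 with diffusion contrast. Declaring that synthetic volume to
have readout time 0 ("infinite PE bandwidth", i.e. free of susceptibility
displacement) turns the single-blip problem back into a two-image field
estimation problem.

## Pipeline

1. **Preprocess** (`preprocess`): T1 intensities on the 0–150 convention
   map affinely to [-1, 1] (values above 150 clip at +1; the convention
   only defines the 0–150 range, and bounded network inputs are worth the
   truncation). b0 intensities map 0 → -1 and the 99th percentile of the
   *distorted* b0 → +1, without upper clipping — min/max scaling is
   unstable under pileup, while the 99th percentile reliably lands on CSF,
   the brightest b0 tissue. The same percentile value scales the paired
   undistorted b0 so both live on one scale. Volumes are resampled to a
   2.5 mm isotropic working grid with recorded, invertible transforms;
   the intersection of resampling-validity masks is the loss mask.
   When truth and distorted b0 come from different acquisitions, a global
   median-ratio gain match aligns their scales first.
2. **Synthesize** (`unet`, `synthesis`): a 3D U-Net (2 input channels,
   1 output channel; instance normalization and leaky ReLU after every
   convolution) is trained with 5-fold cross-validation partitioned by
   subject. Single-blip sessions use the masked MSE to the truth b0.
   Dual-blip sessions pass both blips through the same network and
   minimize `(MSE₁ + MSE₂)/2 + MSE(out₁, out₂)` — a bias term plus a
   Siamese variance term (opposite distortions of the same anatomy must
   synthesize to the same volume). Optimization is Adam, lr 1e-4, betas
   (0.9, 0.999), weight decay 1e-5, batch size 1 (hence instance norm),
   for 100 epochs at full scale; each fold keeps the weights from its
   minimum-validation-MSE epoch, and inference averages the five
   networks' outputs voxelwise.
3. **Correct** (`field`): the distorted b0 is smoothed slightly to match
   the synthesis's smoothness (the synthesis inherits interpolation
   smoothing from the working-grid round trip; the kernel width is found
   by bisection on a Laplacian-energy statistic, search range 0–1.5
   voxels). The displacement field minimizing

       Σ_mask [pushforward(b0_synth; d) − b0_d]² + λ Σ ‖∇d‖²

   is found by damped Gauss–Newton (matrix-free conjugate-gradient inner
   solves, backtracking line search, so each level's cost trace is
   non-increasing) over a coarse-to-fine pyramid along the PE axis
   (factors 4, 2, 1). The distorted b0 is then pulled back through the
   estimated shift with Jacobian modulation `1 + ∂d/∂i` (clamped below at
   0.05), which redistributes piled-up signal. A two-row topup-style
   acquisition-parameters file (dummy positive readout; readout exactly 0
   for the synthetic volume) is emitted so the same correction can be
   reproduced with the external tool where it is installed.

The estimator is a deliberate surrogate for topup: voxelwise field with
first-order smoothness instead of a B-spline basis, SSD data term only,
no movement parameters. It is simple enough to verify against the
simulator's ground truth, and the forward (splatting) and inverse
(interpolating) warps are adjoint discretizations, which gives an
independent consistency check between simulation and correction.

## Regularization: two profiles

λ has normalized-intensity² units (both images are scaled by the
distorted b0's 99th percentile before the cost is formed).

* **Exact reference** (`FieldEstimationConfig()` default, λ = 0.02): the
  L-curve of data residual against field roughness, measured on
  simulated subjects with the truth b0 as reference, has its corner near
  0.02 — below it roughness grows with almost no data gain, above it the
  data term degrades quickly.
* **Learned reference** (`correct_subject` default, λ = 1.0): a
  synthesized b0 carries contrast model error, and at the oracle corner
  the voxelwise field happily "explains" those intensity errors as
  displacement — on validation subjects this *increased* the error to
  truth and degraded T1 alignment. Sweeping λ on validation subjects
  (never the held-out test set) shows stiff priors (λ ≈ 1) recover the
  bulk geometric shift while ignoring contrast mismatch. This mirrors
  topup practice, whose spline basis plus heavy regularization encode the
  same prior.

Neither value is tuned per subject.

## The phantom simulator

Clinical training corpora are replaced by a parametric head phantom so
every stage is testable at desk scale:

* nested ellipsoidal shells (white core, gray, CSF, skull/scalp) with
  smoothly perturbed radii and a ventricle-like central CSF pocket;
  T1 contrast white > gray > CSF, b0 contrast CSF brightest — so both
  normalization conventions are exercised;
* a susceptibility field built from correlated Gaussian noise
  (correlation length 6 voxels, amplitude ±50 Hz by default), plus
  high-amplitude Gaussian hotspots near the anterior-inferior mask
  boundary emulating sinus/ear-canal interfaces; the smooth component is
  scaled to keep `1 + ∂Δ/∂i ≥ 0.05` at the nominal readout (invertible
  almost everywhere, as in real heads) while hotspots may violate it and
  create genuine pileup; the field tapers continuously to zero over ~2
  voxels inside the mask edge and is exactly zero outside;
* distortion applied as a mass-preserving 1D splatting pushforward, so
  every PE line of a distorted blip sums exactly to its undistorted
  counterpart; dual-blip sessions reuse one truth volume with negated
  shifts;
* Gaussian tissue noise added in the phantom (shared by truth and
  blips); an optional post-distortion acquisition-noise term exists but
  defaults to 0 so the conservation identity holds exactly;
* per-subject parameter spread (field amplitude, noise ±30%) and
  deterministic per-subject seeds derived from one master seed.

The paper-scale magnitude of clinical distortions is not publicly
stated; ±50 Hz (2.5 voxels at 50 ms readout) is a simulator choice
exposed in configuration, not asserted as cohort-faithful.

What the phantom does **not** emulate: realistic cortical folding and
anatomy, eddy-current and motion effects, through-plane distortion,
multi-coil/bias-field intensity artifacts, k-space/Bloch physics, or
inter-modality misregistration (volumes are generated co-registered, so
the real-data bias-correction and registration prerequisites are out of
scope here). Passing tests therefore demonstrate the correctness and
internal consistency of the machinery — the forward model, the losses,
the estimator — under known ground truth, not clinical-grade accuracy.

## Desk-scale study sizes

NumPy training on one CPU sets the study sizes the tests and the
reproduction script use, chosen once:

* end-to-end study: 30 subjects (alternating single/dual blip) on 16³
  phantoms, reduced network (levels 2, base 8 channels), 20 epochs,
  5-fold; 5 subjects withheld. The optimizer settings are the full-scale
  ones. At 400 Adam steps per fold the synthesis is far from converged
  (validation curves are still descending at epoch 20, and every fold
  selects the last epoch); the study measures that the machinery learns
  and that the learned synthesis already supports beneficial correction,
  not a converged model.
* field recovery: 20 subjects at 48³ (the working-grid resolution),
  smooth hotspot-free fields, oracle (truth-b0) reference — this bounds
  what any learned synthesis can achieve through the same estimator.
* mutual information: 64 equal-width bins in nats by default; 32 bins on
  16³ phantoms (the histogram needs ≥10 voxels per bin); the evaluation
  mask is the head mask.

## Numerical choices

* All volumes are float32 on load; the network runs float32, the field
  estimator float64.
* Splat positions are clamped to line ends (no mass loss); the Jacobian
  of the clamped splat is zeroed where clamping is active.
* Gauss–Newton damping: Levenberg term 1e-3·max(a)², CG from a zero
  start (≤40 iterations), backtracking halves the step up to 10 times
  and stops the level when no decrease is found; level convergence at
  relative cost decrease < 1e-7.
* Ties in the minimum-validation epoch resolve to the earlier epoch
  (`argmin`).
* Smoothness-matching returns σ = 0 whenever the input is already at
  least as smooth as the reference.
* Instance-norm ε = 1e-5; He initialization with the leaky-slope
  correction; the per-fold seed is `base_seed + fold_index`.

## Known limitations

* The estimator's voxelwise field with a membrane prior under-resolves
  field curvature inside uniform tissue (no data support), the dominant
  term in the ~0.15-voxel oracle RMSE.
* Jacobian modulation amplifies errors of rough estimated fields; the
  stiff correction profile mitigates but does not remove this.
* The dual-blip difference loss is implemented exactly but its benefit
  is not separately quantified at desk scale.
* Correction quality with a learned reference depends strongly on
  synthesis contrast fidelity; at the desk training budget the synthesis
  is deliberately undertrained (see above).
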