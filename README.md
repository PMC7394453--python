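# b0synth

Susceptibility distortion correction for diffusion MRI **without reverse
phase-encoding scans or field maps**, via deep synthesis of an
undistorted b0.

## The problem

Single-shot EPI, the standard diffusion-MRI readout, displaces signal
along the phase-encoding (PE) axis wherever the static field is
inhomogeneous: a voxel at off-resonance `f` Hz with total readout time
`T` s appears shifted by `Δ = polarity · f · T` voxels, with signal
pileup where the shift field compresses voxels. State-of-the-art
correction (FSL topup) needs a pair of opposite-polarity ("blip-up /
blip-down") b0 acquisitions — which legacy, clinical and many archival
datasets simply do not have.

`b0synth` targets exactly those datasets. Given only a distorted b0 and
an undistorted T1w anatomical image, a 3D U-Net synthesizes a
distortion-free b0 with diffusion contrast. Treating that synthetic
volume as an acquisition with readout time 0 (infinite PE bandwidth, so
zero susceptibility displacement) reduces the single-blip problem to a
standard two-image field estimation, solved here by a built-in
Gauss–Newton estimator — or by topup itself, via the emitted two-row
acquisition-parameters file.

Intended users: diffusion-MRI methods researchers and pipeline builders
who need distortion correction for single-PE data, and anyone studying
synthesis-based correction under controlled (simulated) ground truth.

## Method at a glance

* **Inputs** (working grid, 2.5 mm isotropic): T1 normalized from the
  0–150 convention to [-1, 1]; b0 scaled so that [0, p99 of the
  *distorted* b0] maps to [-1, 1] (no upper clipping — pileup may exceed
  +1), the same p99 applied to the paired truth b0.
* **Network**: 3D U-Net, 2 input channels → 1 output channel, instance
  norm + leaky ReLU after every convolution.
* **Loss** (masked to voxels where resampling is valid): single-blip
  sessions, `MSE(b0_synth, b0_u)`; dual-blip sessions,
  `(MSE₁ + MSE₂)/2 + MSE(b0_synth₁, b0_synth₂)` — a truth (bias) term
  plus a Siamese difference (variance) term.
* **Training**: Adam (lr 1e-4, betas 0.9/0.999, weight decay 1e-5,
  batch size 1), 5-fold cross-validation split by subject, minimum-
  validation-epoch model per fold; inference averages the 5 networks.
* **Correction**: displacement `d` along the PE axis minimizes
  `Σ‖pushforward(b0_synth; d) − b0_d‖² + λ‖∇d‖²` (damped Gauss–Newton,
  coarse-to-fine); the distorted b0 is pulled back through `d` with
  Jacobian intensity modulation to undo pileup.
* **Simulator**: parametric head phantoms (nested tissue shells, T1 and
  b0 contrast orderings, ±50 Hz smooth fields with pileup hotspots,
  mass-preserving forward warping) replace clinical corpora so every
  stage runs against known ground truth. See `docs/methods.md`.

Everything — including the 3D U-Net and its Adam training loop — runs on
NumPy/SciPy; no GPU or deep-learning framework is required.

## Worked example

Correction with a known-good reference (the simulator's truth b0), which
isolates the field-estimation stage:

```python
from b0synth import (PhantomParams, simulate_subject, correct_subject,
                     FieldEstimationConfig, field_to_displacement,
                     mutual_information, masked_mse)
import numpy as np

params = PhantomParams(grid=(48, 48, 48), seed=7, n_hotspots=0)
s = simulate_subject(params, pe_axis=1, readout=0.05, n_blips=1)
b0_d, pe = s.b0_d_blips[0]

# exact-reference estimation profile: the reference here is the true b0,
# so the stiff learned-reference default is unnecessary
result = correct_subject(b0_d, s.b0_u, pe, FieldEstimationConfig())
mask = s.mask.data
d_true = field_to_displacement(s.truth_field, pe)
m = mask > 0
rmse = np.sqrt(np.mean((result.field.shift[m] - d_true.shift[m]) ** 2))

print(f"shift RMSE vs truth: {rmse:.3f} voxels")
print(f"MI(b0, T1): {mutual_information(b0_d, s.t1, mask):.3f} distorted"
      f" -> {mutual_information(result.corrected, s.t1, mask):.3f} corrected")
print(f"MSE to truth b0: {masked_mse(b0_d, s.b0_u, mask):.0f}"
      f" -> {masked_mse(result.corrected, s.b0_u, mask):.0f}")
```

prints

```
shift RMSE vs truth: 0.177 voxels
MI(b0, T1): 0.934 distorted -> 1.123 corrected
MSE to truth b0: 17726 -> 4660
```

The estimated field tracks the simulated truth to better than a fifth of
a voxel; the corrected b0 is geometrically closer to the T1 (higher
mutual information) and its intensities move most of the way back to the
truth volume (74% MSE reduction here).

The full learned pipeline runs from the shell:

```bash
b0synth simulate --n-subjects 30 --grid 16 --blips mixed --seed 0 --out cohort/
b0synth train --data cohort/ --epochs 20 --folds 5 --out models/
b0synth preprocess --t1 cohort/sub-000/t1.nii.gz \
    --b0 cohort/sub-000/b0_d_blip1.nii.gz --out prep/
b0synth synthesize --t1 prep/t1_norm.nii.gz --b0 prep/b0_d_norm.nii.gz \
    --models models/ --out b0_synth.nii.gz
b0synth correct --b0 cohort/sub-000/b0_d_blip1.nii.gz \
    --synth b0_synth.nii.gz --pe-axis y --readout 0.05 --out corrected/
b0synth evaluate --cohort cohort/ --out report.csv
```

`correct` also writes `acqparams.txt` — the two-row topup table (dummy
positive readout, then readout exactly 0 for the synthetic volume) — so
the identical correction can be reproduced with FSL topup where it is
available.

## Scope

The package corrects susceptibility distortion of b0 volumes only: no
eddy-current or motion modeling (run FSL eddy downstream), no 4D DWI
handling, no DICOM/BIDS tooling, and the real-data prerequisites
(bias-field correction, template registration) are assumed done upstream
— the simulator emits pre-aligned volumes.
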