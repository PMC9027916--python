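# Methods

## Problem and model

Radiographic confirmation of endotracheal-tube (ETT) placement asks
whether the tube tip sits at a safe distance above the tracheal carina
and below the level of the clavicular heads.  `ettloc` implements this
as two coupled components:

1. **A two-stage landmark detector.**  Four anatomical key points —
   tube end, carina, left and right clavicular heads — are regressed as
   2-D heatmaps.  Each training target is an unnormalized Gaussian
   surface `exp(−‖p − c‖² / (2σ²))` with σ = 10 px at the working
   resolution, peak 1 at the landmark pixel.  The same encoder–decoder
   network is trained twice: stage 1 sees the whole image resized to the
   working resolution; stage 2 sees a window cropped around the four
   landmarks and resampled to the same resolution, giving it a finer
   effective pixel pitch.  At inference the stage-1 argmax decodes the
   coarse landmarks, those landmarks define the crop, and the stage-2
   argmax (mapped back through the crop transform) replaces the tube-end
   and carina estimates; the clavicular heads keep their stage-1
   positions.  Decoding is the plain per-channel argmax with row-major
   first-maximum tie-breaking — no sub-pixel refinement — so the decoder
   is exactly invertible against the encoder on integer landmarks.

2. **A distance-rule appropriateness engine.**  From the landmarks, in
   the native pixel frame: the tube-to-carina distance
   `(y_carina − y_tube) · spacing_y` (mm, positive = tip above carina)
   and the tube-to-clavicle distance `(y_tube − y_mid) · spacing_y`
   relative to the mean of the two clavicular heads (≥ 0 = tip below the
   midpoint).  A placement is adequate under a rule set
   `(L, U, clavicle)` iff `L ≤ d < U` (closed-below/open-above, matching
   the convention the thresholds are quoted in) and, when the clavicle
   clause is active, tube-to-clavicle ≥ threshold.  The **ensemble
   score** averages the binary calls of all 11 × 16 × 11 = 1936
   combinations of L ∈ {20..30}, U ∈ {55..70} and clavicle threshold
   ∈ {−5..5} mm; because the clauses act independently on the two
   distances, the implementation computes the passing count as a product
   of per-axis counts, which equals the brute-force triple loop exactly
   (tested).  The ensemble score is the quantity swept for ROC analysis;
   the reported operating point maximizes the Youden index
   J = sensitivity + specificity − 1 with ties broken toward higher
   sensitivity.

### Distance convention

Vertical (craniocaudal) rather than Euclidean distances are the default:
the clavicle rule's "below the midpoint" semantics is inherently signed,
and a tube at or past the carina must fail the lower bound, which an
unsigned distance cannot express.  A Euclidean mode
(`distances(..., euclidean=True)`) exists for sensitivity analysis.
Vertical separations always use the y-axis pixel spacing, so anisotropic
detectors are handled exactly.

## Network and optimization

The decoder is fixed: three blocks of (2× bilinear upsampling → 3×3
convolution → batch normalization → ReLU → SCSE), a bilinear resize to
the input resolution, a 1×1 convolution to four channels, and a sigmoid
so predictions live in [0, 1] like the targets.  SCSE combines a channel
gate (global average pool → bottleneck → sigmoid) and a spatial gate
(1×1 convolution → sigmoid) by adding the two recalibrated maps; the
module also admits a max-combination variant, and the additive form was
chosen as the more common one.  No skip connections are used.  Two
encoders are available: a **small topology** (3×3 stem plus four
stride-2 conv-BN-ReLU blocks, ~74 k parameters at the default width)
used for all desk-scale experiments, and the DenseNet-121 connectivity
(blocks 6/12/24/16, growth 32, 0.5-compression transitions) for
full-scale use.  No pretrained weights are bundled; `pretrained=True`
raises.

Everything runs on a small reverse-mode autodiff engine written in
numpy (`ettloc.nn.autograd`): convolution as im2col + GEMM, bilinear
resizing as separable interpolation matrices, batch normalization with
running statistics, max/average pooling.  Each op's gradient is verified
against central finite differences in the test suite.  The engine is
single-threaded and deterministic, which makes the reproducibility
contract (same seed ⇒ identical loss history) exact rather than
approximate.

Optimization: Adam, batch 8, per-pixel L1 loss between predicted and
target surfaces (binary cross-entropy on the sigmoid outputs is
available by config flag).  The default learning rate is 1e-4, the
setting appropriate to long schedules (hundreds of epochs) with a large
pretrained encoder.  The desk-scale study (`ettloc.experiments`) trains
the small topology from scratch for ≤ 60 epochs and uses 3e-3, chosen
once from short calibration runs as the largest rate that converges
smoothly at this width.

**Augmentation.**  One affine per sample: uniform field-of-view scale in
[0.90, 1.25] (0.90 = zoom-in, implemented as magnification 1/s about the
image centre) followed by rotation in ±45°, applied identically to
pixels and landmarks.  If any landmark leaves the frame the draw is
retried up to 10 times, then the untransformed sample is used, so
augmentation can never produce invalid targets.

**Stage-2 crop.**  Axis-aligned bounding box of the four points expanded
by 25 % of its side per side, grown to a 64-px minimum side, clipped to
the image, and rounded to integer pixels so the resampling grid and the
coordinate transform share exact geometry.  During training the crop
comes from the annotated points; stage-1 predictions are used only at
inference.  The margin keeps the tube and carina inside the window when
stage 1 errs by several millimetres.  A single joint window serves all
four points (per-point windows would quadruple stage-2 cost for no
benefit on the two points stage 2 actually refines).

## Phantom generator

Real annotated radiographs of this kind are not publicly deposited, so
the package ships a synthetic phantom population with exactly known
ground truth.  Each phantom is a stylized frontal chest image: two dark
elliptical lung fields, a brighter mediastinal band, a tracheal stripe
bifurcating at the carina, two clavicular arcs whose medial endpoints are
the landmarks, a radio-opaque tube line ending exactly at the tube-end
landmark, and additive Gaussian noise (σ = 0.03 intensity).  Defaults:
128×128 px at 0.8 mm/px (so the 20–55 mm adequacy band spans 25–69 px),
abnormal fraction 1/3 (a 2:1 normal:abnormal case mix), tube-to-carina
sampled uniformly inside the band for normal cases.  Abnormal cases are
stratified in equal thirds across the three clinically distinct failure
modes — tube too deep (d < 18 mm), too shallow (d > 58 mm), and within
the band but above the clavicular midpoint (rendered with a raised
clavicle line) — so both the carina and the clavicle clauses are
exercised.  Every generated label is recomputed from the sampled
coordinates through the same rule engine at generation time; an
infeasible band/geometry combination raises instead of silently
producing inconsistent labels.

What the phantoms deliberately do **not** model: projection physics,
ribs and scapulae, patient rotation, exposure variation, and annotation
noise.  Passing the desk-scale study therefore demonstrates that the
pipeline recovers landmark geometry and that the rules/ensemble/ROC
machinery is correct — not that the detector generalizes to hospital
radiographs, which would require real annotated data and the full-scale
encoder.

## The desk-scale study

`ettloc.experiments.run_desk_study` (also the body of
`scripts/acceptance.py`) generates 200 training and 50 held-out test
phantoms, trains both stages of the small topology for 50 epochs, and
reports: per-landmark mean absolute error (mm and px, native frame),
stage-1 vs stage-2 tube/carina error, sensitivity/specificity of the
(20–55 mm + clavicle ≥ 0) rule on the true and on the predicted
keypoints, and the ensemble-score AUC with its Youden operating point.
The problem sizes were chosen so the whole study completes in minutes on
one CPU; a single integer seed drives phantom sampling (the test
population uses a derived stream), initialization, shuffling and
augmentation.

## Numerical choices and edge cases

- Min-max intensity normalization; a constant image maps to all zeros.
- Gaussian targets are centred on the nearest integer pixel so each
  channel's maximum is exactly the peak value and encode→decode is the
  identity on integer landmarks; the ≤ 0.5 px quantization is negligible
  against σ = 10 px and the detector's own error.
- DICOM `ImagerPixelSpacing` is preferred over `PixelSpacing` (projection
  radiography convention); both are (row, column) ordered and converted
  to the package's (x, y) convention.  A missing spacing is an error,
  never a default.
- Non-square images are stretched anisotropically to the working size;
  the per-axis factors are recorded in the frame transform and all mm
  quantities are computed in the native frame, so the stretch cannot
  distort distances.
- A completely flat predicted channel decodes (with a warning) to the
  first pixel; a flat stage-1 output skips refinement and flags the
  result as stage-1-only.
- ROC thresholds sweep the distinct scores plus a +∞ sentinel
  (score ≥ threshold ⇒ positive), so (0,0) is always on the curve;
  trapezoidal AUC over tied-score blocks equals the ½-tie Mann–Whitney
  pair count, which matters because the ensemble score takes at most
  1937 distinct values and ties are the norm.
- Sensitivity (specificity) is reported as not applicable when the test
  set has no positives (negatives).

## Known limitations

- The autodiff engine is CPU-only and single-threaded; the DenseNet-121
  topology is functional but impractically slow to train here, and no
  ImageNet initialization is available for it.
- The argmax decoder quantizes to the working grid; sub-pixel accuracy
  is limited to the crop-zoom factor of stage 2 by design.
- Phantom realism is intentionally low (see above); reported error
  statistics characterize the method on phantoms, not clinical accuracy.
- No confidence intervals on AUC or sensitivity/specificity are
  computed.
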