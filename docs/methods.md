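# Methods

## Problem and pipeline

A CT scanner images trays of 30 chicken eggs (5 rows × 6 columns) as 89
transverse slices of 512 × 512 voxels: 333 mm field of view (so 0.650390625
mm in-plane voxel side), 3 mm slice thickness, intensities in [0, 1600].
Each egg is isolated by preprocessing into a 40 × 140 × 90 volume
(depth × height × width), segmented into background/shell/yolk/albumen/air
cell, and measured. The pipeline is: phantom or scanner data → tray
splitting → per-egg cropping and padding → intensity normalization →
two-stage network training → segmentation → voxel-counting morphometry →
agreement statistics.

## Preprocessing

Rows are contiguous bands of slices whose content exceeds 10% of the volume
maximum (for masks: any non-zero code); a tray must yield exactly the
expected number of bands. Each egg is located in-plane by connected
components of the row's through-depth projection, cropped to a 140 × 90
window centered on the egg (clamped to bounds), and padded with constant
background slices to 40 deep, split floor(gap/2) in front and ceil(gap/2)
behind. The deterministic floor/ceil rule realizes "similar amounts front
and back" reproducibly. Masks travel through the identical recorded
geometry (row interval, crop origin, padding), so image/mask alignment
cannot drift. Normalization maps [0, 1600] linearly onto [0, 255] with
clipping; it runs after the geometric steps. Padding background is 0, the
normalized value of air.

## Phantom model

An egg is a prolate spheroid with semi-axes `a` (long) and `b` (short),
modulated by a linear taper: a point at signed long-axis fraction
`u = y/a ∈ (−1, 1)` is inside when its squared radial distance is at most
`b²(1−u²)(1 − τ·max(u, 0))`, with asymmetry `τ ∈ [0, 1)`. The taper acts
only on the sharp half, so the maximal width is exactly `2b` and the length
exactly `2a`; the blunt pole hosts a spherical-cap air cell of given depth
carved from the interior, the yolk is a centered sphere, the shell is the
shell-thickness erosion band of the outer surface, and albumen fills the
rest. Regions are nested, and a voxel takes the class of its center, so
labels are unambiguous. Intensities are class means (defaults: background 0,
shell 1400, albumen 900, yolk 700, air cell 50 — invented values; only the
ordering matters to tests) plus seeded Gaussian noise (default sd 30),
clipped to [0, 1600].

Egg-to-egg variation draws `2a` from 55–62 mm, `2b` from 42–46.4 mm, shell
thickness 1.0–2.0 mm (the mask-scale thickness: annotated shells are ~2
voxels thick, not the ~0.37 mm micrometer value), yolk radius 13–16 mm, air
cell depth 4–8 mm, taper 0.15–0.35 — matching the size range of the
reference test eggs. Trays place eggs with the long axis in-plane, so a row
spans roughly 12–15 (occasionally 16) slices of 3 mm.

What the phantom does **not** model: CT physics (beam hardening,
reconstruction filters, partial-volume blur at boundaries), intra-class
texture, shell-thickness variation around the egg, chalazae, and eggs
touching each other. Passing phantom tests therefore demonstrates the
correctness of the geometry, bookkeeping, training mechanics and
measurement arithmetic — not segmentation accuracy on real scans.

## Networks

Both architectures run on a small numpy layer library with explicit
backpropagation (`eggct.nn`): convolution is computed as a sum over kernel
offsets (contiguous block copy + BLAS matmul each), transposed convolutions
use kernel = stride (each input voxel paints a disjoint block), pooling is
2×2×2 max. All tensors are float32.

* **U-Net 3D** — `n_stages` encoder stages (two 3×3×3 convolutions + ReLU,
  then 2×2×2 max-pool; channels double per stage), a two-convolution
  bottleneck (optional channel dropout, rate 0.1), and a mirrored decoder
  (2× up-convolution, skip concatenation, two convolutions), closed by a
  1×1×1 scoring layer. Convolutions use "same" padding so skips concatenate
  without cropping. Upsampling is a learned transposed convolution by
  default, switchable to nearest-neighbor repetition (whose backward is
  exact 2×2×2 sum pooling); nearest-neighbor is also the variant that is
  strictly translation-consistent on constant inputs, a learned
  up-convolution being consistent only modulo its stride-2 phase.
* **FCN-16 3D** — a VGG-style downsampling path of seven blocks (blocks
  1–2: two convolutions + pool; 3–5: three convolutions + pool; 6–7: one
  convolution each, with optional channel dropout), then 1×1×1 score layers
  on block 7 (stride 32) and on the pool-4 skip (stride 16), fused after a
  2× transposed convolution and restored to full resolution by a 16×
  transposed convolution.

Inputs are zero-padded internally to the nearest pooling-compatible size
and outputs cropped back. Channel widths are configurable: 64 base channels
corresponds to the reference design; 8–16 is the desk scale used by the
tests. The original description gives no channel counts, no padding rule
and no head internals; those are design choices here. Dropout placement is
ambiguous in the source protocol (a table assigns 0.1 to the U-Net and none
to the FCN; the architecture text puts dropout in FCN blocks 6–7), so both
placements exist behind separate flags, defaulting to the table's reading.

The **measurement head** consumes the final decoder feature map (U-Net: the
last decoder block's output; FCN: the fused stride-16 score map) via global
average pooling followed by two dense layers (hidden width 32) emitting
(thickness, height, width) in mm. Head parameters are a group disjoint from
the backbone.

## Training

Stage 1 trains all parameters with voxel-wise cross-entropy under Adam,
logging accuracy, macro F1, kappa, MCC and loss for train and validation
every epoch and retaining the best-validation checkpoint. Stage 2 freezes
the backbone structurally: the backbone runs once per sample in eval mode,
the pooled head features are cached, and only head parameters are ever
given to the optimizer — so backbone weights are bit-identical afterwards
by construction, and verified by checksum in tests. Reference
hyperparameters (learning rate 1e-4 U-Net / 1e-5 FCN, 1000 epochs, batch 25
/ 15, stage-2 rate 1e-5 for 80 / 1000 epochs) are defaults in
`TrainConfig`; desk-scale phantom runs instead use learning rate 1e-3 with
batch 2 for 50 epochs, because at 8 base channels the large reference batch
leaves too few optimizer steps to converge in 50 epochs. Whole eggs are fed
as single volumes; no patch sampling, no early stopping, no class
weighting (a weighting hook exists since shell and air cell are small
classes). Joint single-stage training of both losses is implemented behind
`train_joint` only to document that it underperforms the two-stage
protocol; it is not part of the pipeline.

The 80/10/10 split takes floor(n·0.1) samples for validation and test and
the remainder for training (122 → 98/12/12), deterministically from a seed.
Note the reference test set prints 11 eggs where 122 × 10% rounds to 12;
the discrepancy is in the source tables and is left as printed.

## Measurement conventions

The measurement slice is the one maximizing non-background voxel count,
ties broken toward the center. Measurement lines are fixed **midway along
the egg's extent** on each in-plane axis, not at the content centroid: a
tapered ovoid's centroid sits off the equator and a centroid line would
under-measure the width by up to a voxel. Heights and widths are then
integer multiples of the voxel side and thicknesses quarter-multiples
(means of four integer runs) — exactly the grid every mask-derived value in
the reference tables lies on. Thickness uses in-plane spacing only, since
3 mm slices are far coarser than the 0.65 mm in-plane side. Height counts
all four egg classes, so the air cell counts toward the silhouette.

Mask-derived shell thickness (~1.3–1.9 mm) and micrometer thickness
(~0.29–0.40 mm) are different quantities — annotated shells are about two
voxels thick, an approximation rather than ground truth — and both are
carried side by side without reconciliation.

## Evaluation

All segmentation metrics derive from the 5-class voxel confusion matrix:
accuracy; macro F1 (over classes present in the truth — macro because it
exposes small-class failure, consistent with reported FCN test F1 of ~0.63
alongside ~0.98 accuracy); Cohen's kappa `(po − pe)/(1 − pe)` with `pe`
from the marginals; the multiclass Matthews correlation in its covariance
form. Background is included in the global metrics; per-class
precision/recall are reported for the four egg classes. An independent
cross-check against scikit-learn runs in the test suite.

Agreement statistics pool all (egg, measure) pairs for the per-model
scalar — only pooling reproduces the published 95.39%/8.37% pattern —
and also report per-measure values. Success summaries use the population
standard deviation (ddof = 0), which is what reproduces the printed
"± sd" figures. The t-test is paired and two-sided, per measure.

The U-Net reference table is internally inconsistent: recomputing its
success percentages from its own printed columns gives a pooled 108.20%,
not the printed 107.03% (nor the 101.65% quoted in the running text). The
implementation follows the definitions; the regression test asserts the
recomputed value. The FCN table is self-consistent.

## Desk-scale validation studies

Real scans and GPU-scale training are unavailable, so `eggct.validation`
defines the substitute studies the acceptance checks run:

* **Segmentation**: 20 noiseless phantoms at a coarsened calibration
  (matrix 170, ~1.96 mm in-plane; one egg on a 21 × 37 × 29 grid), 8-base-
  channel 2-stage U-Net, 50 epochs — held-out voxel accuracy ≥ 0.95 for a
  majority of 3 seeds. Observed: ~0.95–0.99 depending on seed; a run takes
  a few minutes on one CPU.
* **Morphometry**: 20 phantoms at the full 512-matrix calibration;
  voxel-counting on ground-truth masks recovers height and width within one
  voxel side and shell thickness within one voxel.
* **Freeze contract**: largest backbone parameter change across stage 2 is
  exactly 0.

## Numerical choices and edge cases

* Calibration derivations are exact float arithmetic (333/512 is a dyadic
  rational, so 0.650390625 is exact). The voxel volume is `side² × dz` by
  definition; note the printed reference value 1.269023798 mm³ differs from
  the exact product 1.269023895 mm³ in the 8th significant digit (an
  arithmetic slip in the source), so agreement is asserted to 7 digits.
* Degenerate phantom geometry: zero shell thickness yields a shell-free
  egg; the yolk must clear the inner shell surface (checked by numeric
  minimization over the polar angle) and the air-cell plane.
* Measurement errors: an empty slice/mask, a line crossing no egg voxels,
  or fewer than four shell crossings raise with counts in the message.
* Cross-entropy clamps log arguments at 1e-12; Adam uses the standard
  bias-corrected moments (β = 0.9/0.999, ε = 1e-8).
* Determinism: every stochastic component (phantom sampling, noise, splits,
  weight init, batch order, dropout) takes an explicit seed; the pipeline
  fans one global seed out to per-stage seeds, and re-running a
  configuration reproduces measurement CSVs bit-identically on the same
  platform.

## Known limitations

* The phantom's sharp class boundaries make segmentation intensity-driven;
  real-scan difficulty (partial volume, noise correlation, annotation
  error) is not represented, so phantom accuracies do not transfer.
* Transposed-convolution decoders show stride-phase (checkerboard) patterns
  at initialization; the nearest-neighbor decoder avoids them at some cost
  in expressiveness.
* The FCN head reads a 5-channel fused score map, a much narrower feature
  than the U-Net head's decoder block; head capacity is deliberately small.
* `split_row_into_eggs` assumes well-separated eggs (true for phantom
  trays); touching eggs in real scans would need manual centers.
* DICOM support covers single-frame CT series with standard spacing tags;
  compressed transfer syntaxes depend on the installed pydicom handlers.
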