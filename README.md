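# eggct

Non-destructive egg morphometry from 3D computed-tomography volumes.

Egg quality assessment — shell thickness, height, width, and the volumes of
shell, yolk, albumen and air cell — traditionally requires calipers,
micrometers and breaking the egg. `eggct` implements the alternative: trays
of eggs are CT-scanned, each egg volume is segmented into five classes
(background, shell, yolk, albumen, air cell) by a 3D U-Net or a 3D FCN-16,
and the morphometric measurements are read off the segmentation by
calibrated voxel counting, or predicted directly by a small regression head
attached to the frozen segmentation backbone.

Because no public CT egg dataset exists, the package ships a phantom
generator that emulates the acquisition — 5 × 6 egg trays, 89 transverse
slices of 512 × 512 voxels, 3 mm slice thickness, 333 mm field of view,
intensities in [0, 1600] — with exact voxel-level ground truth, so every
stage runs and is tested offline.

## The measurements

With field of view `F` (mm) and reconstruction matrix `M`, the in-plane
voxel side is `s = F/M` (333/512 = 0.650390625 mm) and the voxel volume
`s² × dz` with `dz` the slice thickness. On the segmented volume:

* **height / width** — on the slice with the most egg content, the count of
  non-background voxels along the vertical (resp. horizontal) line fixed
  midway along the egg's extent, times `s`;
* **shell thickness** — the mean length of the four shell-class runs where
  those two lines cross the egg boundary, times `s`;
* **class volumes** — per-class voxel count times the voxel volume;
* **equation volume** — the classical allometric estimate
  `V = (0.6057 − 0.0018·W) · L · W²` from caliper length `L` and width `W`.

Training is two-stage: stage 1 fits all network parameters with voxel-wise
cross-entropy; stage 2 freezes the backbone and fits only a small head
(global average pooling + two dense layers) with MSE against reference
(thickness, height, width) triplets.

Agreement between estimates and references is summarized by MAE, RMSE,
MAPE, a paired two-sided t-test, and the per-egg *success percentage*
(estimate/reference × 100); segmentation quality by voxel accuracy, macro
F1, Cohen's kappa and the multiclass Matthews correlation.

## Worked example

Reproduce the voxel-counting arithmetic on the bundled 11-egg reference
test set:

```python
>>> from eggct import make_calibration
>>> from eggct.reference import load_reference_class_voxels, load_reference_measurements
>>> from eggct.evaluate import measurement_metrics
>>> cal = make_calibration(333, 512, 3)
>>> cal.voxel_side_mm
0.650390625
>>> df = load_reference_class_voxels("fcn")
>>> round(df["estimated_voxels"].sum() * cal.voxel_volume_mm3 / 11 / 1000, 2)
53.88
>>> fcn = load_reference_measurements("fcn")
>>> rep = measurement_metrics(fcn.rename(columns={
...     "output_estimate_mm": "estimate", "physical_mm": "reference"})
...     [["measure", "estimate", "reference"]])
>>> round(rep.success_mean["pooled"], 2), round(rep.success_mean["height"], 2)
(95.39, 100.21)
```

53.88 cm³ is the mean total egg volume estimated by counting the FCN's
predicted class voxels over the test set, and the FCN's direct
measurement head agrees with the physical references at 95.39% pooled
success (100.21% for height alone).

Run the full synthetic pipeline (phantoms → preprocessing → two-stage
training → segmentation → measurement → evaluation) from the shell:

```sh
eggct run --seed 1 --out run1          # ~2 min on one CPU
eggct phantom --tray --seed 7 --out tray7   # one 89x512x512 tray + truth
```

`run1/report.json` then contains the held-out segmentation metrics and the
measurement success summaries; `run1/measurements.csv` the per-egg table.

## Layout

| module | role |
| --- | --- |
| `eggct.volume_io` | DICOM series / NIfTI / PNG-stack readers and writers |
| `eggct.preprocess` | calibration, tray→row→egg splitting, padding, cropping, normalization |
| `eggct.phantom` | synthetic egg and tray generation with ground truth |
| `eggct.nn` | numpy conv-net layers with explicit backprop |
| `eggct.nets` | 3D U-Net, 3D FCN-16, measurement head |
| `eggct.training` | 80/10/10 split, stage-1/stage-2 protocols |
| `eggct.morphometrics` | voxel-counting measurements, volume equation |
| `eggct.evaluate` | segmentation metrics, agreement statistics, report tables |
| `eggct.validation` | desk-scale phantom studies |
| `eggct.cli` / `eggct.pipeline` | `eggct` command and end-to-end runs |

See `docs/methods.md` for the model, assumptions and numerical choices.
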