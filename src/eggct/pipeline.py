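"""End-to-end reproducible pipeline on synthetic phantoms:
generate -> preprocess -> split -> train (two stages) -> segment -> measure
-> evaluate.

Every stage draws its seed deterministically from one global seed, and every
artifact directory gets a ``config.json`` stamped with the configuration and
its hash, so re-running the same configuration reproduces the deterministic
artifacts bit-identically.
"""

from __future__ import annotations

import dataclasses
import hashlib
import json
import logging
from dataclasses import dataclass, field
from pathlib import Path

import numpy as np
import pandas as pd

from . import phantom, training
from .evaluate import build_report_tables, measurement_metrics, segmentation_metrics
from .morphometrics import measure_egg
from .nets import NetConfig, build_fcn3d, build_unet3d
from .preprocess import Calibration, make_calibration, normalize_intensity
from .training import SplitSpec, TrainConfig, segment, split_dataset, train_stage1, train_stage2
from .volume_io import CTVolume

log = logging.getLogger("eggct")


@dataclass
class PipelineConfig:
    """Configuration for one pipeline run; unknown keys are rejected."""

    seed: int = 0
    out_dir: str = "eggct_run"
    arch: str = "unet3d"  # or "fcn3d"
    n_eggs: int = 12
    noise_sd: float = 0.0
    fov_mm: float = 333.0
    matrix: int = 256  # 1.3 mm in-plane: desk-scale phantom resolution
    slice_thickness_mm: float = 3.0
    net: NetConfig = field(default_factory=lambda: NetConfig(base_channels=8, n_stages=2))
    train: TrainConfig = field(default_factory=lambda: TrainConfig(
        learning_rate=1e-3, epochs=30, batch_size=4,
        learning_rate_stage2=1e-2, epochs_stage2=200))
    split: SplitSpec = field(default_factory=SplitSpec)
    log_level: str = "INFO"

    @classmethod
    def from_dict(cls, raw: dict) -> "PipelineConfig":
        raw = dict(raw)
        kwargs = {}
        for sub, subcls in (("net", NetConfig), ("train", TrainConfig), ("split", SplitSpec)):
            if sub in raw:
                section = raw.pop(sub)
                known = {f.name for f in dataclasses.fields(subcls)}
                bad = set(section) - known
                if bad:
                    raise ValueError(f"unknown key(s) in '{sub}' section: {sorted(bad)}")
                kwargs[sub] = subcls(**section)
        known = {f.name for f in dataclasses.fields(cls)}
        bad = set(raw) - known
        if bad:
            raise ValueError(f"unknown configuration key(s): {sorted(bad)}")
        return cls(**raw, **kwargs)

    def to_dict(self) -> dict:
        d = dataclasses.asdict(self)
        d["train"]["class_weights"] = None
        return d

    @property
    def calibration(self) -> Calibration:
        return make_calibration(self.fov_mm, self.matrix, self.slice_thickness_mm)


def _stage_seeds(seed: int) -> dict[str, int]:
    rng = np.random.default_rng(seed)
    return {k: int(rng.integers(0, 2**31 - 1))
            for k in ("phantom", "split", "net", "train")}


def run_pipeline(config: PipelineConfig) -> Path:
    """Execute the full phantom pipeline; returns the artifact directory."""
    logging.basicConfig(level=config.log_level)
    out = Path(config.out_dir)
    out.mkdir(parents=True, exist_ok=True)
    seeds = _stage_seeds(config.seed)
    cal = config.calibration

    cfg_json = json.dumps(config.to_dict(), sort_keys=True, default=str)
    stamp = {"config": json.loads(cfg_json),
             "config_hash": hashlib.sha256(cfg_json.encode()).hexdigest(),
             "seed": config.seed}
    (out / "config.json").write_text(json.dumps(stamp, indent=2))

    log.info("generating %d phantom eggs", config.n_eggs)
    rng = np.random.default_rng(seeds["phantom"])
    all_params = [phantom.sample_params(rng, noise_sd=config.noise_sd)
                  for _ in range(config.n_eggs)]
    # one common odd-sized grid holding the largest egg of the batch
    dz, dy, dx = cal.spacing
    bmax = max(p.semi_axis_short for p in all_params)
    amax = max(p.semi_axis_long for p in all_params)
    need = [int(np.ceil(2 * bmax / dz)) + 5,
            int(np.ceil(2 * amax / dy)) + 7,
            int(np.ceil(2 * bmax / dx)) + 7]
    grid = tuple(n + (n % 2 == 0) for n in need)
    eggs = []
    for p in all_params:
        ct, labels, gt = phantom.generate_egg(p, cal, grid_shape=grid)
        ct = normalize_intensity(ct)
        eggs.append((ct, labels, gt))
    phantom.write_ground_truth_csv(out / "ground_truth.csv", [g for _, _, g in eggs])

    spec = SplitSpec(seed=seeds["split"])
    train_set, val_set, test_set = split_dataset(eggs, spec)
    if not test_set:
        raise ValueError(
            f"n_eggs={config.n_eggs} leaves an empty test split at "
            f"fractions {spec.fractions}; use at least 10 eggs")
    log.info("split: %d train / %d val / %d test", len(train_set), len(val_set), len(test_set))

    builder = build_unet3d if config.arch == "unet3d" else build_fcn3d
    model = builder(config.net, seed=seeds["net"])
    tcfg = dataclasses.replace(config.train, seed=seeds["train"])

    log.info("stage 1: segmentation training (%d epochs)", tcfg.epochs)
    res1 = train_stage1(model, [(c, l) for c, l, _ in train_set],
                        [(c, l) for c, l, _ in val_set], tcfg)
    res1.history.to_csv(out / "stage1_history.csv", index=False)

    log.info("stage 2: measurement head training (%d epochs)", tcfg.epochs_stage2)
    res2 = train_stage2(model, [(c, (g.thickness_mm, g.height_mm, g.width_mm))
                                for c, _, g in train_set], tcfg)
    res2.history.to_csv(out / "stage2_history.csv", index=False)
    model.save(out / "model.npz")

    log.info("segmenting and measuring %d held-out eggs", len(test_set))
    rows = []
    seg_reports = []
    for i, (ct, labels, gt) in enumerate(test_set):
        pred = segment(model, ct)
        seg_reports.append(segmentation_metrics(pred, labels))
        ref = measure_egg(labels, cal, source="mask")
        est = measure_egg(pred, cal, source="voxel-estimate")
        _, head_out = model.forward_with_head(
            np.asarray(ct.intensities, dtype=np.float32)[None, None] / 255.0, train=False)
        t_hat, h_hat, w_hat = (float(v) for v in head_out[0])
        for measure, mask_v, vox_v, phys_v, out_v in (
                ("thickness", ref.thickness_mm, est.thickness_mm, gt.thickness_mm, t_hat),
                ("height", ref.height_mm, est.height_mm, gt.height_mm, h_hat),
                ("width", ref.width_mm, est.width_mm, gt.width_mm, w_hat)):
            rows.append({"egg": i, "measure": measure, "mask_mm": mask_v,
                         "voxel_estimate_mm": vox_v, "physical_mm": phys_v,
                         "output_estimate_mm": out_v})
    records = pd.DataFrame(rows)
    table, summary = build_report_tables(records)
    table.to_csv(out / "measurements.csv", index=False)
    summary.to_csv(out / "measurement_summary.csv", index=False)

    agg = {
        "segmentation": {
            "mean_accuracy": float(np.mean([r.accuracy for r in seg_reports])),
            "mean_macro_f1": float(np.mean([r.macro_f1 for r in seg_reports])),
            "mean_kappa": float(np.mean([r.kappa for r in seg_reports])),
            "mean_mcc": float(np.mean([r.mcc for r in seg_reports])),
        },
        "voxel_measurement": measurement_metrics(
            records.rename(columns={"voxel_estimate_mm": "estimate",
                                    "mask_mm": "reference"})).success_mean,
        "head_measurement": measurement_metrics(
            records.rename(columns={"output_estimate_mm": "estimate",
                                    "physical_mm": "reference"})).success_mean,
    }
    (out / "report.json").write_text(json.dumps(agg, indent=2))
    log.info("pipeline complete: %s", out)
    return out
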