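"""Segmentation and measurement-agreement statistics.

Segmentation quality is summarized from the 5-class voxel confusion matrix:
overall accuracy, macro F1, Cohen's kappa ((po - pe) / (1 - pe) with pe from
the marginals), the multiclass Matthews correlation coefficient, and
per-class precision/recall for the four egg classes.

Measurement agreement between estimates and references uses MAE, RMSE, MAPE,
the per-egg success percentage (estimate / reference x 100), and a paired
two-sided t-test per measurement type.  Summary success percentages are
reported as mean +/- population standard deviation, matching how such tables
are conventionally printed.
"""

from __future__ import annotations

from dataclasses import dataclass, field

import numpy as np
import pandas as pd
from scipy import stats

from .volume_io import LabelVolume

EGG_CLASSES = (1, 2, 3, 4)


@dataclass
class SegmentationReport:
    accuracy: float
    macro_f1: float
    kappa: float
    mcc: float
    precision: dict[int, float]
    recall: dict[int, float]
    confusion: np.ndarray  # (n_classes, n_classes), rows = truth

    def to_dict(self) -> dict:
        return {
            "accuracy": self.accuracy, "macro_f1": self.macro_f1,
            "kappa": self.kappa, "mcc": self.mcc,
            "precision": {str(k): v for k, v in self.precision.items()},
            "recall": {str(k): v for k, v in self.recall.items()},
            "confusion": self.confusion.tolist(),
        }


def confusion_matrix(truth: np.ndarray, pred: np.ndarray, n_classes: int = 5) -> np.ndarray:
    truth = np.asarray(truth).ravel().astype(np.int64)
    pred = np.asarray(pred).ravel().astype(np.int64)
    if truth.shape != pred.shape:
        raise ValueError("prediction and truth have different sizes")
    return np.bincount(truth * n_classes + pred,
                       minlength=n_classes * n_classes).reshape(n_classes, n_classes)


def metrics_from_confusion(cm: np.ndarray) -> dict:
    """Accuracy, macro F1, kappa and multiclass MCC from a confusion matrix."""
    cm = np.asarray(cm, dtype=np.float64)
    total = cm.sum()
    if total == 0:
        raise ValueError("empty confusion matrix")
    diag = np.diag(cm)
    truth_marg = cm.sum(axis=1)
    pred_marg = cm.sum(axis=0)

    accuracy = diag.sum() / total

    with np.errstate(divide="ignore", invalid="ignore"):
        precision = np.where(pred_marg > 0, diag / pred_marg, 0.0)
        recall = np.where(truth_marg > 0, diag / truth_marg, 0.0)
        denom = precision + recall
        f1 = np.where(denom > 0, 2 * precision * recall / denom, 0.0)
    # macro-average over classes actually present in the truth
    present = truth_marg > 0
    macro_f1 = float(f1[present].mean())

    pe = float((truth_marg * pred_marg).sum()) / total**2
    kappa = (accuracy - pe) / (1 - pe) if pe < 1 else 1.0

    # multiclass MCC (correlation form over the confusion matrix)
    c = diag.sum()
    s2 = total**2
    cov_tp = c * total - float((truth_marg * pred_marg).sum())
    var_t = s2 - float((truth_marg**2).sum())
    var_p = s2 - float((pred_marg**2).sum())
    mcc = cov_tp / np.sqrt(var_t * var_p) if var_t > 0 and var_p > 0 else 1.0

    return {"accuracy": float(accuracy), "macro_f1": macro_f1,
            "kappa": float(kappa), "mcc": float(mcc),
            "precision": precision, "recall": recall}


def segmentation_metrics(pred: LabelVolume | np.ndarray,
                         truth: LabelVolume | np.ndarray,
                         n_classes: int = 5) -> SegmentationReport:
    p = pred.codes if isinstance(pred, LabelVolume) else np.asarray(pred)
    t = truth.codes if isinstance(truth, LabelVolume) else np.asarray(truth)
    if p.shape != t.shape:
        raise ValueError(f"shape mismatch: pred {p.shape} vs truth {t.shape}")
    cm = confusion_matrix(t, p, n_classes)
    m = metrics_from_confusion(cm)
    return SegmentationReport(
        accuracy=m["accuracy"], macro_f1=m["macro_f1"], kappa=m["kappa"],
        mcc=m["mcc"],
        precision={c: float(m["precision"][c]) for c in EGG_CLASSES if c < n_classes},
        recall={c: float(m["recall"][c]) for c in EGG_CLASSES if c < n_classes},
        confusion=cm,
    )


@dataclass
class MeasurementReport:
    mae: dict[str, float]
    rmse: dict[str, float]
    mape: dict[str, float]
    success_pct: dict[str, np.ndarray] = field(repr=False)
    success_mean: dict[str, float] = field(default_factory=dict)
    success_sd: dict[str, float] = field(default_factory=dict)
    t_stat: dict[str, float] = field(default_factory=dict)
    p_value: dict[str, float] = field(default_factory=dict)

    @property
    def pooled_success_mean(self) -> float:
        return self.success_mean["pooled"]


def measurement_metrics(estimates: pd.DataFrame | dict,
                        references: pd.DataFrame | dict | None = None) -> MeasurementReport:
    """Agreement statistics between paired estimates and references.

    Accepts either two mappings ``measure -> vector`` (equal-length, paired)
    or a single tidy DataFrame with columns (measure, estimate, reference).
    Pooled statistics aggregate every (egg, measure) pair, which is how the
    per-model scalar summaries are defined.
    """
    if references is None:
        df = estimates
        groups = {m: (g["estimate"].to_numpy(float), g["reference"].to_numpy(float))
                  for m, g in df.groupby("measure", sort=False)}
    else:
        groups = {m: (np.asarray(estimates[m], float), np.asarray(references[m], float))
                  for m in estimates}

    mae, rmse, mape = {}, {}, {}
    success, smean, ssd, tstat, pval = {}, {}, {}, {}, {}
    all_e, all_r = [], []
    for m, (e, r) in groups.items():
        if e.shape != r.shape:
            raise ValueError(f"{m}: estimate/reference vectors differ in length")
        if np.any(r == 0):
            raise ValueError(f"{m}: zero reference value; MAPE/success undefined")
        all_e.append(e)
        all_r.append(r)
        d = e - r
        mae[m] = float(np.abs(d).mean())
        rmse[m] = float(np.sqrt((d**2).mean()))
        mape[m] = float((np.abs(d) / np.abs(r)).mean() * 100)
        success[m] = e / r * 100
        smean[m] = float(success[m].mean())
        ssd[m] = float(success[m].std(ddof=0))
        if e.size >= 2:
            t = stats.ttest_rel(e, r)
            tstat[m], pval[m] = float(t.statistic), float(t.pvalue)

    e = np.concatenate(all_e)
    r = np.concatenate(all_r)
    d = e - r
    mae["pooled"] = float(np.abs(d).mean())
    rmse["pooled"] = float(np.sqrt((d**2).mean()))
    mape["pooled"] = float((np.abs(d) / np.abs(r)).mean() * 100)
    success["pooled"] = e / r * 100
    smean["pooled"] = float(success["pooled"].mean())
    ssd["pooled"] = float(success["pooled"].std(ddof=0))

    return MeasurementReport(mae=mae, rmse=rmse, mape=mape, success_pct=success,
                             success_mean=smean, success_sd=ssd,
                             t_stat=tstat, p_value=pval)


REPORT_COLUMNS = ["egg", "measure", "mask_mm", "voxel_estimate_mm",
                  "success_voxel_pct", "physical_mm", "output_estimate_mm",
                  "success_output_pct"]


def build_report_tables(records: pd.DataFrame) -> tuple[pd.DataFrame, pd.DataFrame]:
    """Build the per-egg measurement table and its mean +/- sd summary.

    ``records`` must carry columns (egg, measure, mask_mm, voxel_estimate_mm,
    physical_mm, output_estimate_mm).  Success columns are recomputed from
    the value columns: voxel-estimate vs mask, output-estimate vs physical.
    Returns ``(per_egg_table, summary_table)``; the summary also contains a
    pooled row whose output-success mean is the per-model scalar.
    """
    needed = {"egg", "measure", "mask_mm", "voxel_estimate_mm",
              "physical_mm", "output_estimate_mm"}
    missing = needed - set(records.columns)
    if missing:
        raise ValueError(f"records table missing column(s): {sorted(missing)}")

    table = records.copy()
    table["success_voxel_pct"] = table["voxel_estimate_mm"] / table["mask_mm"] * 100
    table["success_output_pct"] = table["output_estimate_mm"] / table["physical_mm"] * 100
    table = table[REPORT_COLUMNS]

    rows = []
    for m, g in table.groupby("measure", sort=False):
        rows.append({
            "measure": m,
            "success_voxel_mean": g["success_voxel_pct"].mean(),
            "success_voxel_sd": g["success_voxel_pct"].std(ddof=0),
            "success_output_mean": g["success_output_pct"].mean(),
            "success_output_sd": g["success_output_pct"].std(ddof=0),
        })
    rows.append({
        "measure": "pooled",
        "success_voxel_mean": table["success_voxel_pct"].mean(),
        "success_voxel_sd": table["success_voxel_pct"].std(ddof=0),
        "success_output_mean": table["success_output_pct"].mean(),
        "success_output_sd": table["success_output_pct"].std(ddof=0),
    })
    return table, pd.DataFrame(rows)
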