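"""Bundled reference tables for an 11-egg CT test set.

Two small CSVs ship with the package as the worked example and as inputs to
regression checks:

``reference_measurements.csv`` — per-egg thickness/height/width, four ways:
measured on the labeled mask by voxel counting, estimated by voxel counting
on each model's predicted mask, measured physically (caliper/micrometer),
and estimated directly by each model's regression head.  Note the physical
micrometer shell thickness (~0.37 mm) and the mask-derived thickness
(~1.6 mm, limited by the ~0.65 mm voxel side) are different quantities; both
are carried without reconciliation.

``reference_class_voxels.csv`` — test-set totals of true and estimated
voxels per class with mean per-class precision/recall, for the
voxel-counting volume computation.
"""

from __future__ import annotations

from importlib import resources

import pandas as pd

EQUATION_VOLUME_CM3 = 63.51  # mean egg volume from the width/length equation


def _read(name: str) -> pd.DataFrame:
    with resources.files("eggct.data").joinpath(name).open("r") as fh:
        return pd.read_csv(fh)


def load_reference_measurements(model: str | None = None) -> pd.DataFrame:
    """Tidy per-egg measurement table; ``model`` filters to 'unet' or 'fcn'."""
    df = _read("reference_measurements.csv")
    if model is not None:
        if model not in set(df["model"]):
            raise ValueError(f"unknown model {model!r}")
        df = df[df["model"] == model].reset_index(drop=True)
    return df


def load_reference_class_voxels(model: str | None = None) -> pd.DataFrame:
    df = _read("reference_class_voxels.csv")
    if model is not None:
        if model not in set(df["model"]):
            raise ValueError(f"unknown model {model!r}")
        df = df[df["model"] == model].reset_index(drop=True)
    return df
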