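"""Voxel-counting morphometry on segmentation masks.

Given a labeled egg volume and the scanner calibration, this module measures
height, width, and shell thickness on an intermediate slice, converts
per-class voxel counts to volumes, and evaluates the empirical egg-volume
equation V = (0.6057 - 0.0018 W) * L * W^2 (L = length/height, W = width,
all in mm).

Measurement procedure: on the slice with the most egg content, fix the
point midway along each in-plane axis of the egg's extent; the height is
the count of non-background voxels along the vertical line through that
column times the voxel side, the width likewise along the horizontal line
through that row.  (The midway point, not the content centroid, is used:
an egg tapers toward its sharp pole, so the centroid row sits off the
equator and would systematically under-measure the width.)  Shell
thickness is the mean length of the four shell-class runs where those two
lines cross the egg boundary.  Heights and widths are therefore integer
multiples of the voxel side, and thicknesses quarter-multiples.
"""

from __future__ import annotations

from dataclasses import dataclass, field

import numpy as np

from .preprocess import Calibration
from .volume_io import LabelVolume

SHELL = 1


@dataclass
class MeasurementRecord:
    """Morphometric measurements for one egg, in mm and mm^3."""

    thickness_mm: float
    height_mm: float
    width_mm: float
    class_volumes_mm3: dict[int, float] = field(default_factory=dict)
    equation_volume_mm3: float | None = None
    source: str = "mask"  # mask | voxel-estimate | head-estimate | physical

    def __post_init__(self) -> None:
        for v in (self.thickness_mm, self.height_mm, self.width_mm):
            if v < 0:
                raise ValueError("measurements must be non-negative")


def select_measurement_slice(label: LabelVolume) -> int:
    """Depth index of the slice with the most non-background voxels.

    Ties break toward the central slice, making the choice robust to eggs
    off-center in depth.
    """
    counts = (label.codes != 0).sum(axis=(1, 2))
    best = int(counts.max())
    if best == 0:
        raise ValueError("label volume contains no non-background voxels")
    candidates = np.flatnonzero(counts == best)
    center = (label.shape[0] - 1) / 2
    return int(candidates[np.argmin(np.abs(candidates - center))])


def _midway_lines(sl: np.ndarray) -> tuple[int, int]:
    """(row, column) midway along each axis of the egg's in-plane extent."""
    ys, xs = np.nonzero(sl != 0)
    if ys.size == 0:
        raise ValueError("slice contains no non-background voxels")
    return (int(round((ys.min() + ys.max()) / 2)),
            int(round((xs.min() + xs.max()) / 2)))


def measure_height(sl: np.ndarray, calibration: Calibration) -> float:
    """Egg height: non-background voxels along the vertical line at the
    midway column, times the voxel side."""
    _, col = _midway_lines(sl)
    n = int((sl[:, col] != 0).sum())
    if n == 0:
        raise ValueError("measurement line crosses no egg voxels")
    return n * calibration.voxel_side_mm


def measure_width(sl: np.ndarray, calibration: Calibration) -> float:
    """Egg width: the mirror of :func:`measure_height` on the midway row."""
    row, _ = _midway_lines(sl)
    n = int((sl[row, :] != 0).sum())
    if n == 0:
        raise ValueError("measurement line crosses no egg voxels")
    return n * calibration.voxel_side_mm


def _shell_runs(line: np.ndarray) -> list[int]:
    """Lengths of contiguous shell-class runs along one measurement line."""
    is_shell = np.concatenate(([0], (line == SHELL).astype(int), [0]))
    d = np.diff(is_shell)
    starts, stops = np.flatnonzero(d == 1), np.flatnonzero(d == -1)
    return (stops - starts).tolist()


def measure_thickness(sl: np.ndarray, calibration: Calibration) -> float:
    """Shell thickness: mean of the four shell runs where the midway
    vertical and horizontal lines cross the egg boundary."""
    row, col = _midway_lines(sl)
    runs = _shell_runs(sl[:, col]) + _shell_runs(sl[row, :])
    if len(runs) < 4:
        raise ValueError(f"found {len(runs)} shell crossings, need at least 4")
    return float(np.mean(runs)) * calibration.voxel_side_mm


def class_volumes(label: LabelVolume, calibration: Calibration,
                  n_classes: int = 5) -> dict[int, float]:
    """Exact per-class volume: voxel count times the calibrated voxel volume."""
    counts = np.bincount(label.codes.ravel().astype(np.int64), minlength=n_classes)
    return {c: int(counts[c]) * calibration.voxel_volume_mm3 for c in range(n_classes)}


def equation_volume(length_mm: float, width_mm: float) -> float:
    """Empirical egg volume V = (0.6057 - 0.0018 W) * L * W^2 in mm^3."""
    if length_mm <= 0 or width_mm <= 0:
        raise ValueError("length and width must be positive")
    if width_mm >= 0.6057 / 0.0018:
        raise ValueError("width too large: volume coefficient would be non-positive")
    return (0.6057 - 0.0018 * width_mm) * length_mm * width_mm ** 2


def measure_egg(label: LabelVolume, calibration: Calibration,
                source: str = "mask") -> MeasurementRecord:
    """Full voxel-counting measurement of one segmented egg."""
    idx = select_measurement_slice(label)
    sl = label.codes[idx]
    height = measure_height(sl, calibration)
    width = measure_width(sl, calibration)
    thickness = measure_thickness(sl, calibration)
    vols = class_volumes(label, calibration)
    return MeasurementRecord(
        thickness_mm=thickness, height_mm=height, width_mm=width,
        class_volumes_mm3=vols,
        equation_volume_mm3=equation_volume(height, width),
        source=source,
    )
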