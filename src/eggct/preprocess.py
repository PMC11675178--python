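"""Tray-to-egg preprocessing: row splitting, depth padding, in-plane cropping,
intensity normalization, and the voxel calibration that converts counts to mm.

A scanned tray holds 5 rows of 6 eggs and arrives as an 89 x 512 x 512 volume;
each egg leaves this module as a 40 x 140 x 90 volume.  CT volumes and their
paired masks are transformed with the same recorded geometry so alignment
cannot drift.
"""

from __future__ import annotations

from dataclasses import dataclass, asdict

import numpy as np
from scipy import ndimage

from .volume_io import CTVolume, LabelVolume

TARGET_DEPTH = 40
TARGET_HEIGHT = 140
TARGET_WIDTH = 90


@dataclass(frozen=True)
class Calibration:
    """Scanner geometry: field of view, reconstruction matrix, slice thickness.

    The in-plane voxel side is ``fov_mm / matrix`` (333 mm / 512 =
    0.650390625 mm by default) and the voxel volume is side^2 x slice
    thickness.
    """

    fov_mm: float = 333.0
    matrix: int = 512
    slice_thickness_mm: float = 3.0

    @property
    def voxel_side_mm(self) -> float:
        return self.fov_mm / self.matrix

    @property
    def voxel_volume_mm3(self) -> float:
        return self.voxel_side_mm * self.voxel_side_mm * self.slice_thickness_mm

    @property
    def spacing(self) -> tuple[float, float, float]:
        return (self.slice_thickness_mm, self.voxel_side_mm, self.voxel_side_mm)


def make_calibration(fov_mm: float = 333.0, matrix: int = 512,
                     slice_thickness_mm: float = 3.0) -> Calibration:
    if fov_mm <= 0 or matrix <= 0 or slice_thickness_mm <= 0:
        raise ValueError("fov_mm, matrix and slice_thickness_mm must all be positive")
    return Calibration(float(fov_mm), int(matrix), float(slice_thickness_mm))


@dataclass
class GeometryTransform:
    """Record of the geometry applied to one egg, reusable on a paired mask."""

    row_interval: tuple[int, int]  # [start, stop) slice indices in the tray
    crop_origin: tuple[int, int]  # (y0, x0) of the 140x90 window in the tray
    pad_front: int
    pad_back: int

    def to_dict(self) -> dict:
        return asdict(self)


def normalize_intensity(vol: CTVolume, in_max: float = 1600.0) -> CTVolume:
    """Linearly map [0, in_max] -> [0, 255], clipping out-of-range values."""
    if in_max <= 0:
        raise ValueError("in_max must be positive")
    scaled = 255.0 * np.clip(vol.intensities, 0.0, in_max) / in_max
    return CTVolume(scaled.astype(np.float32), vol.spacing)


def _content_mask(vol: CTVolume | LabelVolume, threshold_frac: float) -> np.ndarray:
    if isinstance(vol, LabelVolume):
        return vol.codes != 0
    data = vol.intensities
    return data > threshold_frac * float(data.max())


def occupied_depth_bands(vol: CTVolume | LabelVolume,
                         threshold_frac: float = 0.1) -> list[tuple[int, int]]:
    """Contiguous [start, stop) intervals of slices containing content."""
    occ = _content_mask(vol, threshold_frac).any(axis=(1, 2))
    bands: list[tuple[int, int]] = []
    start = None
    for i, flag in enumerate(occ):
        if flag and start is None:
            start = i
        elif not flag and start is not None:
            bands.append((start, i))
            start = None
    if start is not None:
        bands.append((start, len(occ)))
    return bands


def _subvolume(vol: CTVolume | LabelVolume, sl) -> CTVolume | LabelVolume:
    if isinstance(vol, LabelVolume):
        return LabelVolume(vol.codes[sl], vol.spacing, vol.class_map)
    return CTVolume(vol.intensities[sl], vol.spacing)


def split_tray_into_rows(tray: CTVolume | LabelVolume, n_rows: int = 5,
                         threshold_frac: float = 0.1):
    """Split a tray along depth into its rows of eggs.

    Returns ``(rows, intervals)`` where each interval is the [start, stop)
    depth band of occupied slices for that row.
    """
    depth = tray.shape[0]
    if depth < n_rows:
        raise ValueError(f"tray depth {depth} < n_rows {n_rows}")
    bands = occupied_depth_bands(tray, threshold_frac)
    if len(bands) != n_rows:
        raise ValueError(
            f"detected {len(bands)} occupied depth bands, expected {n_rows} rows"
        )
    rows = [_subvolume(tray, np.s_[b0:b1]) for b0, b1 in bands]
    return rows, bands


def pad_depth(vol: CTVolume | LabelVolume, target: int = TARGET_DEPTH,
              background_value: float = 0.0):
    """Pad with constant background slices front and back to ``target`` slices.

    The gap is split floor(gap/2) in front, ceil(gap/2) behind; original
    slices are unmodified.  Returns ``(padded, pad_front, pad_back)``.
    """
    depth = vol.shape[0]
    if depth > target:
        raise ValueError(f"input depth {depth} exceeds target {target}; refusing to truncate")
    gap = target - depth
    front, back = gap // 2, gap - gap // 2
    pad = ((front, back), (0, 0), (0, 0))
    if isinstance(vol, LabelVolume):
        codes = np.pad(vol.codes, pad, constant_values=int(background_value))
        return LabelVolume(codes, vol.spacing, vol.class_map), front, back
    data = np.pad(vol.intensities, pad, constant_values=background_value)
    return CTVolume(data, vol.spacing), front, back


def crop_to_egg(vol: CTVolume | LabelVolume, height: int = TARGET_HEIGHT,
                width: int = TARGET_WIDTH, threshold_frac: float = 0.1,
                center: tuple[float, float] | None = None):
    """Crop in-plane to a ``height x width`` window centered on the content
    centroid (clamped to image bounds).  Returns ``(cropped, (y0, x0))``.
    """
    d, h, w = vol.shape
    mask = _content_mask(vol, threshold_frac)
    flat = mask.any(axis=0)
    if center is None:
        if not flat.any():
            raise ValueError("no content found to center the crop on")
        ys, xs = np.nonzero(flat)
        ext_y = ys.max() - ys.min() + 1
        ext_x = xs.max() - xs.min() + 1
        if ext_y > height or ext_x > width:
            raise ValueError(
                f"content extent ({ext_y} x {ext_x}) exceeds crop window ({height} x {width})"
            )
        cy, cx = float(ys.mean()), float(xs.mean())
    else:
        cy, cx = center
    y0 = int(round(cy)) - height // 2
    x0 = int(round(cx)) - width // 2
    y0 = min(max(y0, 0), max(h - height, 0))
    x0 = min(max(x0, 0), max(w - width, 0))
    if h < height or w < width:
        raise ValueError(f"volume in-plane shape ({h} x {w}) smaller than crop window")
    sl = np.s_[:, y0:y0 + height, x0:x0 + width]
    return _subvolume(vol, sl), (y0, x0)


def split_row_into_eggs(row: CTVolume | LabelVolume, n_cols: int = 6,
                        threshold_frac: float = 0.1) -> list[tuple[float, float]]:
    """Locate the eggs in one row via in-plane connected components.

    Returns the (y, x) centroid of each egg, sorted left to right.  Intended
    for well-separated phantom trays; arbitrary real scans may need manual
    centers.
    """
    flat = _content_mask(row, threshold_frac).any(axis=0)
    labeled, n = ndimage.label(flat)
    if n != n_cols:
        raise ValueError(f"found {n} in-plane components, expected {n_cols} eggs")
    centroids = ndimage.center_of_mass(flat, labeled, range(1, n + 1))
    return sorted(((float(cy), float(cx)) for cy, cx in centroids), key=lambda c: c[1])


def preprocess_tray(
    tray_ct: CTVolume,
    tray_mask: LabelVolume | None = None,
    n_rows: int = 5,
    n_cols: int = 6,
    normalize: bool = False,
    threshold_frac: float = 0.1,
):
    """Run the full tray -> per-egg pipeline: split rows, locate eggs, crop
    140 x 90, pad depth to 40 (and optionally normalize intensities).

    Returns a list of ``(egg_ct, egg_mask_or_None, GeometryTransform)``, row
    by row, left to right.  The mask, when given, goes through the identical
    recorded geometry.
    """
    ct_rows, bands = split_tray_into_rows(tray_ct, n_rows, threshold_frac)
    mask_rows = None
    if tray_mask is not None:
        if tray_mask.shape != tray_ct.shape:
            raise ValueError("tray mask shape differs from tray CT shape")
        mask_rows = [_subvolume(tray_mask, np.s_[b0:b1]) for b0, b1 in bands]

    out = []
    for r, (ct_row, band) in enumerate(zip(ct_rows, bands)):
        centers = split_row_into_eggs(ct_row, n_cols, threshold_frac)
        for cy, cx in centers:
            egg_ct, origin = crop_to_egg(ct_row, threshold_frac=threshold_frac,
                                         center=(cy, cx))
            egg_ct, front, back = pad_depth(egg_ct)
            if normalize:
                egg_ct = normalize_intensity(egg_ct)
            tr = GeometryTransform(band, origin, front, back)
            egg_mask = None
            if mask_rows is not None:
                y0, x0 = origin
                sl = np.s_[:, y0:y0 + TARGET_HEIGHT, x0:x0 + TARGET_WIDTH]
                egg_mask = _subvolume(mask_rows[r], sl)
                egg_mask, _, _ = pad_depth(egg_mask)
            out.append((egg_ct, egg_mask, tr))
    return out
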