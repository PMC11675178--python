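"""Read and write the volume and mask formats the pipeline touches.

All volumes use the canonical axis order ``(depth, height, width)`` with
0-based voxel indexing; DICOM rows/columns map to (height, width).  Readers
never rescale intensities.
"""

from __future__ import annotations

import os
from dataclasses import dataclass, field
from pathlib import Path

import nibabel as nib
import numpy as np
import pydicom
from PIL import Image

#: canonical class codes for the five-class egg segmentation problem
CLASS_NAMES: dict[int, str] = {
    0: "background",
    1: "shell",
    2: "yolk",
    3: "albumen",
    4: "air_cell",
}

#: default RGB palette for PNG slice-stack masks: green albumen, yellow yolk,
#: purple air cell, blue shell, black background.  Exact-match only; the
#: annotation tool's true RGB values are configurable via ``palette=``.
DEFAULT_PALETTE: dict[tuple[int, int, int], int] = {
    (0, 0, 0): 0,
    (0, 0, 255): 1,
    (255, 255, 0): 2,
    (0, 255, 0): 3,
    (128, 0, 128): 4,
}


@dataclass
class CTVolume:
    """A 3D scalar CT image with per-axis voxel spacing in mm."""

    intensities: np.ndarray  # (depth, height, width)
    spacing: tuple[float, float, float]  # (dz, dy, dx) mm

    def __post_init__(self) -> None:
        self.intensities = np.asarray(self.intensities)
        if self.intensities.ndim != 3 or self.intensities.size == 0:
            raise ValueError("CTVolume requires a non-empty 3D grid")
        if any(s <= 0 for s in self.spacing):
            raise ValueError(f"spacing must be strictly positive, got {self.spacing}")
        self.spacing = tuple(float(s) for s in self.spacing)

    @property
    def shape(self) -> tuple[int, int, int]:
        return self.intensities.shape

    @property
    def intensity_range(self) -> tuple[float, float]:
        return float(self.intensities.min()), float(self.intensities.max())


@dataclass
class LabelVolume:
    """Integer class codes on the same grid as a paired :class:`CTVolume`."""

    codes: np.ndarray  # (depth, height, width), small ints
    spacing: tuple[float, float, float] = (1.0, 1.0, 1.0)
    class_map: dict[int, str] = field(default_factory=lambda: dict(CLASS_NAMES))

    def __post_init__(self) -> None:
        self.codes = np.asarray(self.codes)
        if self.codes.ndim != 3 or self.codes.size == 0:
            raise ValueError("LabelVolume requires a non-empty 3D grid")
        present = set(np.unique(self.codes).tolist())
        unknown = present - set(self.class_map)
        if unknown:
            raise ValueError(f"codes not in class_map: {sorted(unknown)}")
        self.spacing = tuple(float(s) for s in self.spacing)

    @property
    def shape(self) -> tuple[int, int, int]:
        return self.codes.shape


def _affine(spacing: tuple[float, float, float]) -> np.ndarray:
    dz, dy, dx = spacing
    return np.diag([dz, dy, dx, 1.0])


def write_volume(path: str | os.PathLike, vol: CTVolume) -> None:
    """Write a CT volume as NIfTI, spacing encoded in the affine."""
    img = nib.Nifti1Image(np.asarray(vol.intensities, dtype=np.float32), _affine(vol.spacing))
    nib.save(img, str(path))


def read_volume(path: str | os.PathLike) -> CTVolume:
    img = nib.load(str(path))
    data = np.asarray(img.get_fdata(), dtype=np.float32)
    zooms = img.header.get_zooms()[:3]
    return CTVolume(data, tuple(float(z) for z in zooms))


def write_mask(path: str | os.PathLike, label: LabelVolume) -> None:
    """Write a label volume as NIfTI (uint8, lossless round-trip)."""
    if label.codes.max(initial=0) > 255 or label.codes.min(initial=0) < 0:
        raise ValueError("label codes must fit in 8 bits")
    img = nib.Nifti1Image(np.asarray(label.codes, dtype=np.uint8), _affine(label.spacing))
    nib.save(img, str(path))


def read_mask(
    path: str | os.PathLike,
    class_map: dict[int, str] | None = None,
) -> LabelVolume:
    """Read a NIfTI label volume; unknown codes are an error, not background."""
    cmap = dict(CLASS_NAMES) if class_map is None else dict(class_map)
    img = nib.load(str(path))
    codes = np.asanyarray(img.dataobj).astype(np.uint8)
    zooms = img.header.get_zooms()[:3]
    unknown = sorted(set(np.unique(codes).tolist()) - set(cmap))
    if unknown:
        raise ValueError(f"mask contains codes not in class_map: {unknown}")
    return LabelVolume(codes, tuple(float(z) for z in zooms), cmap)


def read_png_mask_stack(
    directory: str | os.PathLike,
    palette: dict[tuple[int, int, int], int] | None = None,
    spacing: tuple[float, float, float] = (1.0, 1.0, 1.0),
) -> LabelVolume:
    """Read a directory of RGB PNG slices into a label volume.

    Slices are ordered by sorted filename.  Every pixel must match one
    palette color exactly; unmatched colors raise with the offending RGB
    triples rather than silently becoming background.
    """
    pal = DEFAULT_PALETTE if palette is None else palette
    paths = sorted(Path(directory).glob("*.png"))
    if not paths:
        raise FileNotFoundError(f"no PNG slices found in {directory}")
    slices = []
    for p in paths:
        rgb = np.asarray(Image.open(p).convert("RGB"), dtype=np.uint8)
        # pack RGB into a single int for exact vectorized matching
        packed = (rgb[..., 0].astype(np.int64) << 16) | (rgb[..., 1].astype(np.int64) << 8) | rgb[..., 2]
        codes = np.full(packed.shape, -1, dtype=np.int64)
        for (r, g, b), code in pal.items():
            codes[packed == ((r << 16) | (g << 8) | b)] = code
        if (codes < 0).any():
            bad = np.unique(packed[codes < 0])
            triples = [((v >> 16) & 255, (v >> 8) & 255, v & 255) for v in bad.tolist()]
            raise ValueError(f"{p.name}: pixel colors not in palette: {triples}")
        slices.append(codes.astype(np.uint8))
    return LabelVolume(np.stack(slices, axis=0), spacing)


def read_dicom_series(directory: str | os.PathLike) -> CTVolume:
    """Read one DICOM series (e.g. Siemens IMA dialect) into a CT volume.

    Slices are sorted by position along the scan axis (fallback: instance
    number); depth spacing comes from successive slice positions, falling
    back to SpacingBetweenSlices then the declared SliceThickness.
    """
    paths = sorted(
        p for p in Path(directory).iterdir()
        if p.suffix.lower() in {".dcm", ".ima"} or p.suffix == ""
    )
    datasets = []
    for p in paths:
        try:
            datasets.append(pydicom.dcmread(str(p)))
        except (pydicom.errors.InvalidDicomError, IsADirectoryError):
            continue
    if not datasets:
        raise FileNotFoundError(f"no DICOM slices found in {directory}")

    uids = {getattr(ds, "SeriesInstanceUID", None) for ds in datasets}
    if len(uids) > 1:
        raise ValueError(f"directory mixes {len(uids)} DICOM series")
    shapes = {(int(ds.Rows), int(ds.Columns)) for ds in datasets}
    if len(shapes) > 1:
        raise ValueError(f"inconsistent slice shapes in series: {sorted(shapes)}")

    def sort_key(ds):
        if hasattr(ds, "ImagePositionPatient"):
            return float(ds.ImagePositionPatient[2])
        if hasattr(ds, "InstanceNumber"):
            return float(ds.InstanceNumber)
        raise ValueError("slices carry neither ImagePositionPatient nor InstanceNumber")

    datasets.sort(key=sort_key)
    first = datasets[0]
    if not hasattr(first, "PixelSpacing"):
        raise ValueError("missing spacing tag: PixelSpacing")
    dy, dx = (float(v) for v in first.PixelSpacing)

    if len(datasets) > 1 and all(hasattr(ds, "ImagePositionPatient") for ds in datasets):
        zs = [float(ds.ImagePositionPatient[2]) for ds in datasets]
        dz = float(np.median(np.diff(zs)))
    elif hasattr(first, "SpacingBetweenSlices"):
        dz = float(first.SpacingBetweenSlices)
    elif hasattr(first, "SliceThickness"):
        dz = float(first.SliceThickness)
    else:
        raise ValueError("missing spacing tag: SliceThickness")

    stack = np.stack([ds.pixel_array.astype(np.float32) for ds in datasets], axis=0)
    return CTVolume(stack, (abs(dz), dy, dx))
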