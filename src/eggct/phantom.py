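"""Synthetic egg CT phantoms with exact ground truth.

The generator emulates the acquisition this tool targets: trays of 5 x 6
chicken eggs imaged as 89 transverse slices of 512 x 512 voxels, 3 mm slice
thickness, 333 mm field of view, intensities in [0, 1600].  Each egg is an
ovoid — a prolate spheroid whose radius is tapered linearly toward the sharp
pole — with a concentric shell of constant thickness, a spherical yolk, and a
spherical-cap air cell carved from the albumen at the blunt pole.

A voxel belongs to a class if its center lies inside the class region; the
regions are nested, so ties cannot occur.  Ground-truth voxel counts are
taken from the emitted label volume (exact by construction) and physical
dimensions from the generating parameters.
"""

from __future__ import annotations

import csv
from dataclasses import dataclass, field, replace
from pathlib import Path

import numpy as np

from .preprocess import Calibration
from .volume_io import CTVolume, LabelVolume, CLASS_NAMES

INTENSITY_MAX = 1600.0

#: default class mean intensities; only the ordering shell > interior > air
#: cell is relied on downstream.
DEFAULT_INTENSITIES: dict[int, float] = {0: 0.0, 1: 1400.0, 2: 700.0, 3: 900.0, 4: 50.0}


@dataclass
class PhantomParams:
    """Geometry and appearance of one synthetic egg.

    Lengths in mm.  ``asymmetry`` in [0, 1) tapers the ovoid toward the
    sharp pole; the blunt pole (where the air cell sits) keeps the pure
    spheroid profile, so the maximal width is exactly 2 x semi_axis_short.
    """

    semi_axis_long: float = 29.6
    semi_axis_short: float = 22.1
    shell_thickness: float = 1.3
    yolk_radius: float = 15.0
    air_cell_depth: float = 6.0
    asymmetry: float = 0.25
    class_intensities: dict[int, float] = field(
        default_factory=lambda: dict(DEFAULT_INTENSITIES))
    noise_sd: float = 30.0
    seed: int = 0

    def validate(self) -> None:
        a, b, t = self.semi_axis_long, self.semi_axis_short, self.shell_thickness
        if not (0 <= t < b):
            raise ValueError(f"shell_thickness must be in [0, semi_axis_short), got {t}")
        if a < b:
            raise ValueError("semi_axis_long must be >= semi_axis_short")
        if not (0 <= self.asymmetry < 1):
            raise ValueError("asymmetry must be in [0, 1)")
        for code, mu in self.class_intensities.items():
            if not (0 <= mu <= INTENSITY_MAX):
                raise ValueError(
                    f"class {code} mean intensity {mu} outside [0, {INTENSITY_MAX:g}]")
        if self.yolk_radius > 0 and self.yolk_radius >= self._inner_clearance():
            raise ValueError("yolk sphere does not fit inside the inner shell surface")
        if self.air_cell_depth > 0 and self.yolk_radius > 0:
            if (a - t) - self.air_cell_depth <= self.yolk_radius:
                raise ValueError("air cell cap would intersect the yolk sphere")

    def _inner_clearance(self) -> float:
        """Distance from the egg center to the nearest point of the inner
        shell surface (numeric minimization over the polar angle)."""
        a, b = self.semi_axis_long - self.shell_thickness, \
            self.semi_axis_short - self.shell_thickness
        u = np.linspace(-0.999, 0.999, 2001)
        r2 = b * b * (1 - u * u) * (1 - self.asymmetry * np.clip(u, 0, None))
        d = np.sqrt((a * u) ** 2 + r2)
        return float(d.min())


@dataclass
class GroundTruth:
    """Analytic dimensions plus exact voxel counts for one phantom egg."""

    height_mm: float
    width_mm: float
    thickness_mm: float
    voxel_counts: dict[int, int]
    voxel_volume_mm3: float

    @property
    def volumes_mm3(self) -> dict[int, float]:
        return {c: n * self.voxel_volume_mm3 for c, n in self.voxel_counts.items()}


def _inside_ovoid(y: np.ndarray, rho2: np.ndarray, a: float, b: float,
                  asym: float) -> np.ndarray:
    """Mask of points inside the tapered spheroid.

    ``y`` is the signed long-axis coordinate (sharp pole at +y), ``rho2`` the
    squared radial distance from the axis.  Radius profile:
    r(u)^2 = b^2 (1 - u^2)(1 - asym * max(u, 0)) for u = y/a in (-1, 1).
    """
    if a <= 0 or b <= 0:
        return np.zeros(y.shape, dtype=bool)
    u = y / a
    taper = 1.0 - asym * np.clip(u, 0.0, None)
    return (np.abs(u) < 1.0) & (rho2 <= b * b * (1 - u * u) * taper)


def rasterize_egg(params: PhantomParams, spacing: tuple[float, float, float],
                  grid_shape: tuple[int, int, int],
                  center_vox: tuple[float, float, float]) -> np.ndarray:
    """Rasterize one egg into a label grid (voxel-center inclusion rule).

    The long axis runs along the in-plane height axis (axis 1); the sharp
    pole points toward +height.  ``center_vox`` is in voxel units.
    """
    dz, dy, dx = spacing
    nd, nh, nw = grid_shape
    cz, cy, cx = center_vox
    z = (np.arange(nd) - cz)[:, None, None] * dz
    y = (np.arange(nh) - cy)[None, :, None] * dy
    x = (np.arange(nw) - cx)[None, None, :] * dx
    rho2 = z * z + x * x

    a, b = params.semi_axis_long, params.semi_axis_short
    t = params.shell_thickness
    outer = _inside_ovoid(y, rho2, a, b, params.asymmetry)
    inner = _inside_ovoid(y, rho2, a - t, b - t, params.asymmetry)

    labels = np.zeros(grid_shape, dtype=np.uint8)
    labels[outer & ~inner] = 1  # shell
    interior = outer & inner

    r2_full = rho2 + y * y
    yolk = interior & (r2_full <= params.yolk_radius ** 2)
    # blunt pole is at -y; the air cell is the cap of the interior below the
    # plane air_cell_depth above the inner pole
    air_plane = -(a - t) + params.air_cell_depth
    air = interior & (y <= air_plane) & ~yolk
    labels[interior] = 3  # albumen
    labels[yolk] = 2
    labels[air] = 4
    return labels


def _check_fit(params: PhantomParams, spacing, grid_shape, center_vox) -> None:
    names = "depth height width".split()
    half_extent_mm = (params.semi_axis_short, params.semi_axis_long,
                      params.semi_axis_short)
    for ax in range(3):
        lo = center_vox[ax] - half_extent_mm[ax] / spacing[ax]
        hi = center_vox[ax] + half_extent_mm[ax] / spacing[ax]
        if lo < 1 or hi > grid_shape[ax] - 2:
            raise ValueError(
                f"egg overflows grid along {names[ax]} axis: needs voxels "
                f"[{lo:.1f}, {hi:.1f}] in a grid of {grid_shape[ax]}")


def generate_egg(
    params: PhantomParams,
    calibration: Calibration,
    grid_shape: tuple[int, int, int] | None = None,
    center_vox: tuple[float, float, float] | None = None,
) -> tuple[CTVolume, LabelVolume, GroundTruth]:
    """Generate one synthetic egg: CT volume, label volume, ground truth.

    By default the grid is sized to hold the ovoid plus margin and the egg is
    centered on it (on a voxel center along every axis of odd size), so the
    central slice passes through the true equator.
    """
    params.validate()
    spacing = calibration.spacing
    if grid_shape is None:
        need = [int(np.ceil(2 * params.semi_axis_short / spacing[0])) + 5,
                int(np.ceil(2 * params.semi_axis_long / spacing[1])) + 7,
                int(np.ceil(2 * params.semi_axis_short / spacing[2])) + 7]
        grid_shape = tuple(n + (n % 2 == 0) for n in need)  # odd => centered
    if center_vox is None:
        center_vox = tuple((n - 1) / 2 for n in grid_shape)
    _check_fit(params, spacing, grid_shape, center_vox)

    labels = rasterize_egg(params, spacing, grid_shape, center_vox)
    rng = np.random.default_rng(params.seed)
    means = np.zeros(5, dtype=np.float64)
    for code, mu in params.class_intensities.items():
        means[code] = mu
    ct = means[labels]
    if params.noise_sd > 0:
        ct = ct + rng.normal(0.0, params.noise_sd, size=labels.shape)
    ct = np.clip(ct, 0.0, INTENSITY_MAX).astype(np.float32)

    counts = np.bincount(labels.ravel(), minlength=5)
    gt = GroundTruth(
        height_mm=2 * params.semi_axis_long,
        width_mm=2 * params.semi_axis_short,
        thickness_mm=params.shell_thickness,
        voxel_counts={c: int(counts[c]) for c in range(5)},
        voxel_volume_mm3=calibration.voxel_volume_mm3,
    )
    return CTVolume(ct, spacing), LabelVolume(labels, spacing, dict(CLASS_NAMES)), gt


def sample_params(rng: np.random.Generator, **overrides) -> PhantomParams:
    """Draw egg-to-egg variation matching the size range of real test eggs
    (heights ~55-62 mm, widths ~42-46 mm, mask shell thickness ~1-2 mm)."""
    p = PhantomParams(
        semi_axis_long=rng.uniform(27.5, 31.0),
        semi_axis_short=rng.uniform(21.0, 23.2),
        shell_thickness=rng.uniform(1.0, 2.0),
        yolk_radius=rng.uniform(13.0, 16.0),
        air_cell_depth=rng.uniform(4.0, 8.0),
        asymmetry=rng.uniform(0.15, 0.35),
        seed=int(rng.integers(0, 2**31 - 1)),
    )
    return replace(p, **overrides)


def generate_tray(
    n_rows: int = 5,
    n_cols: int = 6,
    params: list[PhantomParams] | None = None,
    calibration: Calibration | None = None,
    depth: int = 89,
    seed: int = 0,
    noise_sd: float | None = None,
) -> tuple[CTVolume, LabelVolume, list[GroundTruth], list[tuple]]:
    """Generate a full tray: ``n_rows x n_cols`` eggs on an
    ``depth x matrix x matrix`` grid (89 x 512 x 512 by default).

    Eggs lie with their long axis in-plane, so each row of eggs occupies a
    band of roughly 12-15 slices in depth.  Returns the CT volume, label
    volume, per-egg ground truths, and per-egg bounding boxes
    ``(z0, z1, y0, y1, x0, x1)``.  Overlapping eggs raise an error naming
    the colliding indices.
    """
    calibration = calibration or Calibration()
    rng = np.random.default_rng(seed)
    n_eggs = n_rows * n_cols
    if params is None:
        kw = {} if noise_sd is None else {"noise_sd": noise_sd}
        params = [sample_params(rng, **kw) for _ in range(n_eggs)]
    if len(params) != n_eggs:
        raise ValueError(f"need {n_eggs} parameter sets, got {len(params)}")

    dz, dy, dx = calibration.spacing
    m = calibration.matrix
    shape = (depth, m, m)
    ct = np.zeros(shape, dtype=np.float32)
    labels = np.zeros(shape, dtype=np.uint8)
    owner = np.full(shape, -1, dtype=np.int16)  # which egg claimed each voxel
    gts: list[GroundTruth] = []
    bboxes: list[tuple] = []

    for r in range(n_rows):
        for c in range(n_cols):
            i = r * n_cols + c
            p = params[i]
            p.validate()
            cz = (r + 0.5) * depth / n_rows
            cy = m / 2
            cx = (c + 0.5) * m / n_cols
            # exact half-extents in voxel units; bounding boxes get a one-voxel
            # margin but are clamped to the grid (true overflow checked first)
            hz = p.semi_axis_short / dz
            hy = p.semi_axis_long / dy
            hx = p.semi_axis_short / dx
            for cc, hh, nn, ax in ((cz, hz, depth, "depth"), (cy, hy, m, "height"),
                                   (cx, hx, m, "width")):
                if cc - hh < 0 or cc + hh > nn:
                    raise ValueError(f"egg {i} overflows the tray grid along {ax}")
            z0, z1 = max(0, int(np.floor(cz - hz - 1))), min(depth, int(np.ceil(cz + hz + 1)) + 1)
            y0, y1 = max(0, int(np.floor(cy - hy - 1))), min(m, int(np.ceil(cy + hy + 1)) + 1)
            x0, x1 = max(0, int(np.floor(cx - hx - 1))), min(m, int(np.ceil(cx + hx + 1)) + 1)
            local_shape = (z1 - z0, y1 - y0, x1 - x0)
            local_center = (cz - z0, cy - y0, cx - x0)
            local = rasterize_egg(p, calibration.spacing, local_shape, local_center)
            target = labels[z0:z1, y0:y1, x0:x1]
            owner_t = owner[z0:z1, y0:y1, x0:x1]
            clash = (owner_t >= 0) & (local != 0)
            if clash.any():
                prior = sorted({int(v) for v in np.unique(owner_t[clash])})
                raise ValueError(f"egg {i} overlaps egg(s) {prior}")
            target[local != 0] = local[local != 0]
            owner_t[local != 0] = i

            means = np.zeros(5)
            for code, mu in p.class_intensities.items():
                means[code] = mu
            patch = means[local]
            if p.noise_sd > 0:
                egg_rng = np.random.default_rng(p.seed)
                patch = patch + egg_rng.normal(0, p.noise_sd, local.shape) * (local != 0)
            ct_target = ct[z0:z1, y0:y1, x0:x1]
            ct_target[local != 0] = np.clip(patch, 0, INTENSITY_MAX)[local != 0]

            counts = np.bincount(local.ravel(), minlength=5)
            gts.append(GroundTruth(2 * p.semi_axis_long, 2 * p.semi_axis_short,
                                   p.shell_thickness,
                                   {k: int(counts[k]) for k in range(1, 5)} | {0: 0},
                                   calibration.voxel_volume_mm3))
            bboxes.append((z0, z1, y0, y1, x0, x1))

    ctvol = CTVolume(ct, calibration.spacing)
    labvol = LabelVolume(labels, calibration.spacing, dict(CLASS_NAMES))
    return ctvol, labvol, gts, bboxes


def write_ground_truth_csv(path, gts: list[GroundTruth]) -> None:
    with open(path, "w", newline="") as fh:
        w = csv.writer(fh)
        w.writerow(["egg_id", "height_mm", "width_mm", "thickness_mm",
                    "shell_vox", "yolk_vox", "albumen_vox", "aircell_vox"])
        for i, g in enumerate(gts):
            w.writerow([i, f"{g.height_mm:.4f}", f"{g.width_mm:.4f}",
                        f"{g.thickness_mm:.4f}", g.voxel_counts[1],
                        g.voxel_counts[2], g.voxel_counts[3], g.voxel_counts[4]])
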