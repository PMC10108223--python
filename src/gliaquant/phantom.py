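"""Synthetic radial-glia phantoms with exact ground truth.

These generators replace microscopy downloads as the test bed: vertical glial
stalks with somata, lateral branches and basal endfeet, plus configurable
degradation (PSF blur, exponential z-decay, Poisson and Gaussian noise).

Ground truth is derived from the *voxelized* geometry (primitives rasterized
at pixel centers), so mask-level quantities are exactly testable; skeleton
quantities (length, junction/endpoint counts) come from the analytic
construction.

Geometry convention: rows (y) are the apicobasal axis with the basal side
(endfeet) at low row indices, matching the standardized subregion frame.
"""

from __future__ import annotations

import math
from dataclasses import dataclass, field
from typing import Sequence

import numpy as np

from .deconvolve import PsfParams, theoretical_psf
from .segment import BinaryMask
from .volume_io import OvalRoi, VolumetricImage

__all__ = [
    "PhantomSpec",
    "GroundTruth",
    "generate_glia_phantom",
    "degrade_stack",
    "generate_quality_phantom",
    "make_cylinder_mask",
    "make_y_mask",
    "make_torus_mask",
]


@dataclass
class PhantomSpec:
    shape: tuple[int, int, int] = (10, 200, 120)  # (z, y, x)
    voxel_size: tuple[float, float, float] = (0.5, 0.5, 1.0)  # (dx, dy, dz) um
    n_cells: int = 2
    stalk_radius_um: float = 1.5
    soma_center_row_frac: float = 0.7
    soma_radii_um: tuple[float, float] = (2.5, 3.5)  # (lateral, along-axis)
    endfoot_rows_frac: float = 0.08
    endfoot_radius_um: float = 3.0
    #: (row_frac_lo, row_frac_hi, branches_per_cell, branch_length_um)
    branch_zones: list[tuple[float, float, int, float]] = field(
        default_factory=lambda: [(0.35, 0.55, 2, 6.0)])
    branch_radius_um: float = 1.0
    row_margin_frac: float = 0.05
    foreground: float = 200.0
    background: float = 10.0
    noise_gaussian_sd: float = 0.0
    noise_poisson: bool = False
    z_decay_tau_um: float = math.inf
    psf_blur: PsfParams | None = None
    bit_range: tuple[float, float] = (0.0, 255.0)
    seed: int = 0

    def __post_init__(self) -> None:
        for frac in (self.soma_center_row_frac, self.endfoot_rows_frac,
                     self.row_margin_frac):
            if not (0.0 <= frac <= 1.0):
                raise ValueError("row fractions must lie in [0, 1]")
        for lo, hi, n, length in self.branch_zones:
            if not (0.0 <= lo < hi <= 1.0) or n < 0 or length < 0:
                raise ValueError(f"bad branch zone {(lo, hi, n, length)}")
        if min(self.stalk_radius_um, self.endfoot_radius_um,
               self.branch_radius_um) <= 0:
            raise ValueError("radii must be positive")


@dataclass
class GroundTruth:
    mask: BinaryMask
    volume_um3: float
    height_um: float
    skeleton_length_um: float
    n_junctions: int
    n_endpoints: int
    n_cells: int
    per_cell: list[dict] = field(default_factory=list)


def _grid_um(shape, voxel_size):
    nz, ny, nx = shape
    dx, dy, dz = voxel_size
    z = np.arange(nz) * dz
    y = np.arange(ny) * dy
    x = np.arange(nx) * dx
    return np.meshgrid(z, y, x, indexing="ij")


def _tube(grid, p0, p1, radius_um) -> np.ndarray:
    """Voxels within ``radius_um`` of the segment p0-p1 (all in (z,y,x) um)."""
    Z, Y, X = grid
    p0 = np.asarray(p0, dtype=np.float64)
    v = np.asarray(p1, dtype=np.float64) - p0
    vv = float(v @ v)
    if vv == 0:
        d2 = (Z - p0[0]) ** 2 + (Y - p0[1]) ** 2 + (X - p0[2]) ** 2
        return d2 <= radius_um**2
    t = ((Z - p0[0]) * v[0] + (Y - p0[1]) * v[1] + (X - p0[2]) * v[2]) / vv
    t = np.clip(t, 0.0, 1.0)
    d2 = ((Z - (p0[0] + t * v[0])) ** 2 + (Y - (p0[1] + t * v[1])) ** 2
          + (X - (p0[2] + t * v[2])) ** 2)
    return d2 <= radius_um**2


def generate_glia_phantom(spec: PhantomSpec) -> tuple[VolumetricImage, GroundTruth]:
    """Rasterize the phantom and compute its ground truth.

    The returned image is the clean intensity-coded mask (foreground /
    background levels) before any degradation; apply :func:`degrade_stack`
    for noise, decay and blur.
    """
    nz, ny, nx = spec.shape
    dx, dy, dz = spec.voxel_size
    grid = _grid_um(spec.shape, spec.voxel_size)
    extent = ((nz - 1) * dz, (ny - 1) * dy, (nx - 1) * dx)

    y0 = spec.row_margin_frac * extent[1]          # basal end of the stalk (um)
    y1 = (1.0 - spec.row_margin_frac) * extent[1]  # apical end (um)
    zc = extent[0] / 2.0
    xs = [(i + 1) * extent[2] / (spec.n_cells + 1) for i in range(spec.n_cells)]

    fg = np.zeros(spec.shape, dtype=bool)
    per_cell = []
    total_length = 0.0
    n_junctions = 0
    n_endpoints = 0

    for ci, xc in enumerate(xs):
        _check_bounds(xc, spec.stalk_radius_um, extent[2], "stalk (x)")
        fg |= _tube(grid, (zc, y0, xc), (zc, y1, xc), spec.stalk_radius_um)

        # soma: ellipsoid on the stalk
        y_soma = y0 + spec.soma_center_row_frac * (y1 - y0)
        rl, ra = spec.soma_radii_um
        Z, Y, X = grid
        fg |= (((Z - zc) / rl) ** 2 + ((Y - y_soma) / ra) ** 2
               + ((X - xc) / rl) ** 2) <= 1.0
        _check_bounds(xc, rl, extent[2], "soma (x)")

        # basal endfoot: cone widening toward row 0
        foot_h = spec.endfoot_rows_frac * (y1 - y0)
        if foot_h > 0:
            frac = np.clip((Y - y0) / foot_h, 0.0, 1.0)
            r_of_y = spec.endfoot_radius_um + (
                spec.stalk_radius_um - spec.endfoot_radius_um) * frac
            in_rows = (Y >= y0) & (Y <= y0 + foot_h)
            lateral2 = (Z - zc) ** 2 + (X - xc) ** 2
            fg |= in_rows & (lateral2 <= r_of_y**2)
            _check_bounds(xc, spec.endfoot_radius_um, extent[2], "endfoot (x)")

        # lateral branches, evenly spaced in each declared zone, alternating side
        cell_branches = 0
        for zi, (lo, hi, n_br, blen) in enumerate(spec.branch_zones):
            if n_br == 0:
                continue
            rows = np.linspace(y0 + lo * (y1 - y0), y0 + hi * (y1 - y0),
                               n_br + 2)[1:-1]
            for bi, yb in enumerate(rows):
                sign = 1 if (bi + zi + ci) % 2 == 0 else -1
                x_end = xc + sign * blen
                if not (0.0 <= x_end <= extent[2]):
                    raise ValueError(
                        f"branch (cell {ci}, zone {zi}) exceeds image bounds: "
                        f"x_end={x_end:.2f} um of {extent[2]:.2f} um")
                fg |= _tube(grid, (zc, yb, xc), (zc, yb, x_end),
                            spec.branch_radius_um)
                cell_branches += 1
                total_length += blen
        stalk_len = y1 - y0
        total_length += stalk_len
        n_junctions += cell_branches
        n_endpoints += 2 + cell_branches
        per_cell.append({"x_um": xc, "stalk_length_um": stalk_len,
                         "n_branches": cell_branches})

    mask = BinaryMask(fg.astype(np.uint8), spec.voxel_size,
                      provenance={"generator": "glia_phantom", "seed": spec.seed})
    intensity = np.where(fg, spec.foreground, spec.background).astype(np.float64)
    image = VolumetricImage(intensity, spec.voxel_size, name=f"phantom_s{spec.seed}",
                            bit_depth="float")
    truth = GroundTruth(
        mask=mask,
        volume_um3=float(fg.sum()) * dx * dy * dz,
        height_um=float(y1 - y0),
        skeleton_length_um=float(total_length),
        n_junctions=n_junctions,
        n_endpoints=n_endpoints,
        n_cells=spec.n_cells,
        per_cell=per_cell,
    )
    return image, truth


def _check_bounds(center: float, radius: float, extent: float, what: str) -> None:
    if center - radius < 0 or center + radius > extent:
        raise ValueError(f"{what} primitive exceeds image bounds")


def degrade_stack(image: VolumetricImage, spec: PhantomSpec) -> VolumetricImage:
    """Apply, in order: PSF blur, z-decay, Poisson resampling, Gaussian noise, clip."""
    rng = np.random.default_rng(spec.seed)
    data = image.voxels.astype(np.float64).copy()

    if spec.psf_blur is not None:
        from scipy.signal import fftconvolve

        psf = theoretical_psf(spec.psf_blur).voxels
        data = fftconvolve(data, psf, mode="same")
        np.clip(data, 0.0, None, out=data)

    if math.isfinite(spec.z_decay_tau_um):
        dz = image.voxel_size[2]
        decay = np.exp(-np.arange(data.shape[0]) * dz / spec.z_decay_tau_um)
        data *= decay[:, None, None]

    if spec.noise_poisson:
        data = rng.poisson(np.clip(data, 0.0, None)).astype(np.float64)

    if spec.noise_gaussian_sd > 0:
        data += rng.normal(0.0, spec.noise_gaussian_sd, size=data.shape)

    lo, hi = spec.bit_range
    np.clip(data, lo, hi, out=data)
    return image.with_voxels(data, bit_depth="float")


def generate_quality_phantom(
    mu_s: float, mu_ns: float, sigma_bg: float, seed: int = 0,
    shape: tuple[int, int, int] = (3, 96, 96),
    voxel_size: tuple[float, float, float] = (0.5, 0.5, 1.0),
) -> tuple[VolumetricImage, dict[str, OvalRoi]]:
    """Three planted patches (signal / non-signal / background) with matching ROIs.

    The whole field is background-distributed; the signal and non-signal
    patches override it. With ``sigma_bg == 0`` the field is noiseless, so ROI
    statistics yield zero standard deviation and CNR is undefined downstream.
    """
    rng = np.random.default_rng(seed)
    nz, ny, nx = shape
    if sigma_bg > 0:
        data = rng.normal(mu_ns, sigma_bg, size=shape)
    else:
        data = np.full(shape, float(mu_ns))
    zmid = nz // 2

    patch_r = min(ny, nx) // 6
    centers = {
        "signal": (nx // 4, ny // 4),
        "nonSignal": (3 * nx // 4, ny // 4),
        "background": (nx // 2, 3 * ny // 4),
    }
    means = {"signal": mu_s, "nonSignal": mu_ns, "background": mu_ns}
    yy, xx = np.mgrid[0:ny, 0:nx]
    for key, (cx, cy) in centers.items():
        inside = ((xx - cx) ** 2 + (yy - cy) ** 2) <= patch_r**2
        if sigma_bg > 0:
            data[zmid][inside] = rng.normal(means[key], sigma_bg,
                                            size=int(inside.sum()))
        else:
            data[zmid][inside] = means[key]
    np.clip(data, 0.0, None, out=data)

    rois = {key: OvalRoi(center=c, radii=(patch_r * 0.8, patch_r * 0.8),
                         slice_index=zmid)
            for key, c in centers.items()}
    img = VolumetricImage(data, voxel_size, name=f"quality_phantom_s{seed}",
                          bit_depth="float")
    return img, rois


# ---------------------------------------------------------------------------
# Simple geometric masks for oracle tests
# ---------------------------------------------------------------------------

def make_cylinder_mask(
    shape: tuple[int, int, int],
    voxel_size: tuple[float, float, float],
    radius_um: float,
    height_um: float | None = None,
    axis: str = "y",
) -> BinaryMask:
    """A digitized solid flat-capped cylinder along an axis, centred in the volume."""
    grid = _grid_um(shape, voxel_size)
    nz, ny, nx = shape
    dx, dy, dz = voxel_size
    extent = ((nz - 1) * dz, (ny - 1) * dy, (nx - 1) * dx)
    center = [e / 2 for e in extent]
    ax = {"z": 0, "y": 1, "x": 2}[axis]
    half = (extent[ax] / 2) if height_um is None else height_um / 2
    lateral = [grid[i] - center[i] for i in range(3) if i != ax]
    within_r = (lateral[0] ** 2 + lateral[1] ** 2) <= radius_um**2
    # half-open slab: exactly height/voxel_pitch voxel layers along the axis
    along = grid[ax] - center[ax]
    within_h = (along > -half) & (along <= half)
    return BinaryMask((within_r & within_h).astype(np.uint8), voxel_size,
                      provenance={"generator": "cylinder", "radius_um": radius_um,
                                  "height_um": (2 * half)})


def make_y_mask(
    shape: tuple[int, int, int] = (9, 80, 80),
    voxel_size: tuple[float, float, float] = (0.5, 0.5, 0.5),
    radius_um: float = 1.5,
) -> BinaryMask:
    """A Y-shaped tube: vertical trunk splitting into two 45° arms (1 triple point)."""
    grid = _grid_um(shape, voxel_size)
    nz, ny, nx = shape
    dx, dy, dz = voxel_size
    extent = ((nz - 1) * dz, (ny - 1) * dy, (nx - 1) * dx)
    zc, xc = extent[0] / 2, extent[2] / 2
    y_base, y_split, y_top = 0.1 * extent[1], 0.5 * extent[1], 0.9 * extent[1]
    arm_dx = (y_top - y_split)  # 45 degrees in the y-x plane
    fg = _tube(grid, (zc, y_base, xc), (zc, y_split, xc), radius_um)
    fg |= _tube(grid, (zc, y_split, xc), (zc, y_top, xc - arm_dx), radius_um)
    fg |= _tube(grid, (zc, y_split, xc), (zc, y_top, xc + arm_dx), radius_um)
    return BinaryMask(fg.astype(np.uint8), voxel_size,
                      provenance={"generator": "y_tube"})


def make_torus_mask(
    shape: tuple[int, int, int] = (15, 64, 64),
    voxel_size: tuple[float, float, float] = (0.5, 0.5, 0.5),
    major_radius_um: float = 9.0,
    minor_radius_um: float = 2.0,
) -> BinaryMask:
    """A solid torus in the y-x plane (skeleton should be a single cycle)."""
    Z, Y, X = _grid_um(shape, voxel_size)
    nz, ny, nx = shape
    dx, dy, dz = voxel_size
    zc, yc, xc = ((nz - 1) * dz / 2, (ny - 1) * dy / 2, (nx - 1) * dx / 2)
    ring = np.sqrt((Y - yc) ** 2 + (X - xc) ** 2)
    d2 = (ring - major_radius_um) ** 2 + (Z - zc) ** 2
    return BinaryMask((d2 <= minor_radius_um**2).astype(np.uint8), voxel_size,
                      provenance={"generator": "torus"})
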