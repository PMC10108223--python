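"""Apicobasal zonation: collapse a standardized stack to a 1D intensity profile."""

from __future__ import annotations

import warnings
from dataclasses import dataclass
from pathlib import Path
from typing import Sequence

import numpy as np
import pandas as pd

from .segment import BinaryMask
from .volume_io import VolumetricImage

__all__ = [
    "ZonationProfile",
    "apicobasal_profile",
    "normalize_profile",
    "measure_heights",
    "export_zonation",
]


@dataclass
class ZonationProfile:
    """Mean intensity per apicobasal row (row 0 = basal by convention)."""

    values: np.ndarray
    spacing_um: float
    orientation: str = "basal_to_apical"
    name: str = "profile"
    normalized_length: int | None = None

    def __post_init__(self) -> None:
        self.values = np.asarray(self.values, dtype=np.float64)
        if self.values.ndim != 1 or len(self.values) < 1:
            raise ValueError("profile must be a non-empty 1D vector")
        if self.spacing_um <= 0:
            raise ValueError("spacing must be positive")
        if self.orientation not in ("basal_to_apical", "apical_to_basal"):
            raise ValueError(f"bad orientation {self.orientation!r}")

    def flipped(self) -> "ZonationProfile":
        other = ("apical_to_basal" if self.orientation == "basal_to_apical"
                 else "basal_to_apical")
        return ZonationProfile(self.values[::-1].copy(), self.spacing_um,
                               orientation=other, name=self.name,
                               normalized_length=self.normalized_length)


def _voxels_of(obj: VolumetricImage | BinaryMask | np.ndarray) -> tuple[np.ndarray, float, str]:
    if isinstance(obj, VolumetricImage):
        return obj.voxels, obj.voxel_size[1], obj.name
    if isinstance(obj, BinaryMask):
        return obj.voxels, obj.voxel_size[1], "mask"
    arr = np.asarray(obj)
    return arr, 1.0, "array"


def apicobasal_profile(obj: VolumetricImage | BinaryMask | np.ndarray) -> ZonationProfile:
    """Full 3D → 1D collapse: ``values[y] = mean over all (z, x) at row y``.

    Works identically on intensity stacks, binary masks (giving per-row
    foreground fraction) and skeleton grids.
    """
    vox, dy, name = _voxels_of(obj)
    if vox.ndim != 3:
        raise ValueError("expected a 3D (z,y,x) grid")
    values = vox.astype(np.float64).mean(axis=(0, 2))
    return ZonationProfile(values, dy, name=name)


def normalize_profile(profile: ZonationProfile, target_rows: int) -> ZonationProfile:
    """Linearly resample to exactly ``target_rows`` values, endpoint to endpoint."""
    if target_rows < 2:
        raise ValueError("target_rows must be >= 2")
    n = len(profile.values)
    if n < 2:
        raise ValueError("cannot resample a length-1 profile")
    src = np.linspace(0.0, 1.0, n)
    dst = np.linspace(0.0, 1.0, target_rows)
    values = np.interp(dst, src, profile.values)
    spacing = profile.spacing_um * (n - 1) / (target_rows - 1)
    return ZonationProfile(values, spacing, orientation=profile.orientation,
                           name=profile.name, normalized_length=target_rows)


def measure_heights(
    obj: VolumetricImage | BinaryMask, sigma_um: float = 0.0
) -> tuple[float, float]:
    """Image height and radial cell extent along the apicobasal (row) axis.

    Returns ``(image_height_um, cell_height_um)`` where image height is
    ``rows * dy`` (tissue height is that minus the sigma extension chosen at
    subregion time) and cell height is the row extent of mask foreground.
    For intensity input the cell height covers rows with any nonzero voxel.
    """
    vox, dy, _ = _voxels_of(obj)
    image_height = vox.shape[1] * dy
    rows = np.flatnonzero(vox.astype(bool).any(axis=(0, 2)))
    if rows.size == 0:
        warnings.warn("empty mask: cell height reported as 0", stacklevel=2)
        cell_height = 0.0
    else:
        cell_height = float((rows.max() - rows.min() + 1) * dy)
    _ = sigma_um  # retained in the results table, not subtracted here
    return float(image_height), cell_height


def tissue_height(image_height_um: float, sigma_um: float) -> float:
    """Tissue (retina) height = image height minus the sigma extension."""
    return image_height_um - sigma_um


def export_zonation(
    profiles: Sequence[ZonationProfile],
    out_dir: str | Path,
    sigma_um: float = 0.0,
    heights: Sequence[tuple[float, float]] | None = None,
) -> dict[str, Path]:
    """Write ``ZonationToolProfiles.csv``, ``ZonationResults.csv`` and per-profile
    colormap strips into a ``ZonationTool`` folder.

    Profiles of unequal length are written with trailing empty cells (the
    intended use is comparing possibly unequal stacks before normalization).
    """
    if len(profiles) == 0:
        raise ValueError("need at least one profile")
    out = Path(out_dir) / "ZonationTool"
    out.mkdir(parents=True, exist_ok=True)

    lengths = {len(p.values) for p in profiles}
    if len(lengths) > 1:
        warnings.warn("profiles differ in length; padding CSV rows with empty cells",
                      stacklevel=2)
    cols = {}
    for i, p in enumerate(profiles):
        name = p.name if p.name not in cols else f"{p.name}_{i}"
        cols[name] = pd.Series(p.values)
    profiles_csv = out / "ZonationToolProfiles.csv"
    pd.DataFrame(cols).to_csv(profiles_csv, index=False)

    rows = []
    for i, p in enumerate(profiles):
        ih, ch = heights[i] if heights is not None else (
            len(p.values) * p.spacing_um, float("nan"))
        rows.append({"image": p.name, "orientation": p.orientation,
                     "image_height_um": ih,
                     "tissue_height_um": tissue_height(ih, sigma_um),
                     "cell_height_um": ch})
    results_csv = out / "ZonationResults.csv"
    pd.DataFrame(rows).to_csv(results_csv, index=False)

    strip_paths = []
    for i, p in enumerate(profiles):
        strip_paths.append(_write_strip(p, out / f"strip_{i:02d}_{p.name}.png"))
    return {"profiles": profiles_csv, "results": results_csv,
            "strips": strip_paths[0].parent}


def _write_strip(profile: ZonationProfile, path: Path, width_px: int = 24) -> Path:
    """Render the profile as a vertical heat strip (fire-like LUT)."""
    import matplotlib

    matplotlib.use("Agg", force=False)
    import matplotlib.pyplot as plt

    v = profile.values
    vmax = v.max() if v.max() > 0 else 1.0
    strip = np.tile((v / vmax)[:, None], (1, width_px))
    cmap = plt.get_cmap("inferno")  # closest stock analogue of the 'fire' LUT
    rgb = (cmap(strip)[..., :3] * 255).astype(np.uint8)
    plt.imsave(path, rgb)
    return path
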