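"""Calibrated volumetric TIFF I/O, ROI annotations, and basic stack reshaping.

Axis convention used throughout the package: arrays are indexed ``(z, y, x)``
and the physical voxel size is carried as ``(dx, dy, dz)`` in micrometres.
"""

from __future__ import annotations

import json
import struct
import warnings
import zipfile
from dataclasses import dataclass, field
from pathlib import Path
from typing import Sequence

import numpy as np
import tifffile

__all__ = [
    "VolumetricImage",
    "LineRoi",
    "OvalRoi",
    "CalibrationWarning",
    "read_stack",
    "write_stack",
    "max_projection",
    "split_channels",
    "convert_8bit",
    "read_roi_archive",
    "write_roi_archive",
    "pair_rois_with_images",
]

MAX_CHANNELS = 4


class CalibrationWarning(UserWarning):
    """Raised when voxel calibration is missing and a default is substituted."""


def _infer_bit_depth(arr: np.ndarray) -> str:
    if arr.dtype == np.uint8:
        return "8"
    if arr.dtype == np.uint16:
        return "16"
    return "float"


@dataclass
class VolumetricImage:
    """A calibrated 3D intensity stack, optionally multi-channel.

    Parameters
    ----------
    voxels:
        Primary (first) channel, shape ``(z, y, x)``.
    voxel_size:
        Physical voxel extents ``(dx, dy, dz)`` in micrometres.
    channels:
        All channels (including the first) when the stack is multi-channel,
        otherwise ``None``.
    bit_depth:
        One of ``{"8", "16", "float"}``.
    name:
        Source identifier (usually the file stem).
    calibration_certain:
        ``False`` when the calibration was defaulted rather than read or
        supplied; downstream µm-scaled outputs would then be meaningless.
    """

    voxels: np.ndarray
    voxel_size: tuple[float, float, float]
    channels: list[np.ndarray] | None = None
    bit_depth: str = ""
    name: str = "stack"
    calibration_certain: bool = True

    def __post_init__(self) -> None:
        self.voxels = np.asarray(self.voxels)
        if self.voxels.ndim != 3:
            raise ValueError(f"voxels must be 3D (z,y,x), got {self.voxels.ndim}D")
        dx, dy, dz = self.voxel_size
        if not (dx > 0 and dy > 0 and dz > 0):
            raise ValueError(f"voxel_size must be positive, got {self.voxel_size}")
        if not self.bit_depth:
            self.bit_depth = _infer_bit_depth(self.voxels)
        if self.bit_depth in ("8", "16") and self.voxels.size and self.voxels.min() < 0:
            raise ValueError("integer-depth stacks must be non-negative")
        if self.channels is not None:
            shapes = {c.shape for c in self.channels}
            if len(shapes) != 1:
                raise ValueError(f"channel grids differ in shape: {sorted(shapes)}")
            if next(iter(shapes)) != self.voxels.shape:
                raise ValueError("channel shape differs from primary voxel grid")

    # -- convenience -------------------------------------------------------
    @property
    def shape(self) -> tuple[int, int, int]:
        return self.voxels.shape

    @property
    def n_channels(self) -> int:
        return 1 if self.channels is None else len(self.channels)

    def channel_arrays(self) -> list[np.ndarray]:
        return [self.voxels] if self.channels is None else list(self.channels)

    def with_voxels(self, voxels: np.ndarray, **overrides) -> "VolumetricImage":
        """Copy of this image with a new single-channel voxel grid."""
        kw = dict(
            voxel_size=self.voxel_size,
            bit_depth=_infer_bit_depth(np.asarray(voxels)),
            name=self.name,
            calibration_certain=self.calibration_certain,
        )
        kw.update(overrides)
        return VolumetricImage(np.asarray(voxels), **kw)

    @property
    def voxel_volume_um3(self) -> float:
        dx, dy, dz = self.voxel_size
        return dx * dy * dz


@dataclass
class LineRoi:
    """A straight line annotation: start = inner/basal, end = outer/apical."""

    start: tuple[float, float]  # (x, y) px
    end: tuple[float, float]  # (x, y) px
    slice_index: int | None = None
    image_name: str = ""

    def __post_init__(self) -> None:
        if self.length_px() <= 0:
            raise ValueError("line ROI must have positive length")

    def length_px(self) -> float:
        return float(np.hypot(self.end[0] - self.start[0], self.end[1] - self.start[1]))

    def length_um(self, voxel_size: Sequence[float]) -> float:
        dx, dy = voxel_size[0], voxel_size[1]
        return float(
            np.hypot((self.end[0] - self.start[0]) * dx, (self.end[1] - self.start[1]) * dy)
        )


@dataclass
class OvalRoi:
    """An elliptical annotation on a single slice."""

    center: tuple[float, float]  # (x, y) px
    radii: tuple[float, float]  # (rx, ry) px
    slice_index: int = 0

    def __post_init__(self) -> None:
        if not (self.radii[0] > 0 and self.radii[1] > 0):
            raise ValueError("oval radii must be positive")


# ---------------------------------------------------------------------------
# TIFF stack I/O
# ---------------------------------------------------------------------------

def read_stack(
    path: str | Path,
    voxel_size: tuple[float, float, float] | None = None,
) -> VolumetricImage:
    """Read a TIFF z-stack with its voxel calibration.

    Calibration is taken from the TIFF resolution tags plus ImageJ ``spacing``
    metadata when present; otherwise from the explicit ``voxel_size`` override.
    If neither is available a 1 µm default is substituted with a
    :class:`CalibrationWarning` and the image flagged, since wrong voxel
    dimensions silently corrupt every µm-scaled measurement downstream.
    """
    path = Path(path)
    if not path.exists():
        raise FileNotFoundError(f"file not found: {path}")
    with tifffile.TiffFile(str(path)) as tif:
        series = tif.series[0]
        data = series.asarray()
        axes = series.axes
        meta_size = _calibration_from_tiff(tif)
    data, channels = _normalize_axes(data, axes)

    certain = True
    if voxel_size is not None:
        size = tuple(float(v) for v in voxel_size)
    elif meta_size is not None:
        size = meta_size
    else:
        warnings.warn(
            f"{path.name}: no voxel calibration in TIFF and no override given; "
            "defaulting to 1.0 um — quantification in um will be meaningless",
            CalibrationWarning,
            stacklevel=2,
        )
        size = (1.0, 1.0, 1.0)
        certain = False

    return VolumetricImage(
        voxels=data,
        voxel_size=size,  # type: ignore[arg-type]
        channels=channels,
        name=path.stem,
        calibration_certain=certain,
    )


def _calibration_from_tiff(tif: tifffile.TiffFile) -> tuple[float, float, float] | None:
    page = tif.pages[0]
    xres = page.tags.get("XResolution")
    yres = page.tags.get("YResolution")
    if xres is None or yres is None:
        return None
    def _inv(tag) -> float | None:
        num, den = tag.value
        if num == 0:
            return None
        return den / num
    dx = _inv(xres)
    dy = _inv(yres)
    if dx is None or dy is None:
        return None
    has_spacing = bool(tif.imagej_metadata and "spacing" in tif.imagej_metadata)
    unit_tag = page.tags.get("ResolutionUnit")
    unit_none = unit_tag is None or int(unit_tag.value) == 1  # RESUNIT.NONE
    if dx == 1.0 and dy == 1.0 and unit_none and not has_spacing:
        return None  # writer-default placeholder, not a real calibration
    dz = float(tif.imagej_metadata["spacing"]) if has_spacing else 1.0
    return (float(dx), float(dy), dz)


def _normalize_axes(data: np.ndarray, axes: str) -> tuple[np.ndarray, list[np.ndarray] | None]:
    """Coerce tifffile output to (z,y,x) [+ channel list]."""
    if data.ndim == 2:
        data = data[None]
        axes = "Z" + axes[-2:] if len(axes) >= 2 else "ZYX"
    if data.ndim == 3:
        return data, None
    if data.ndim == 4:
        c_axis = axes.find("C") if "C" in axes else 1
        data = np.moveaxis(data, c_axis, 0)
        chans = [np.ascontiguousarray(data[i]) for i in range(data.shape[0])]
        if len(chans) > MAX_CHANNELS:
            raise ValueError(f"unsupported channel count {len(chans)} (max {MAX_CHANNELS})")
        return chans[0], chans
    raise ValueError(f"unsupported TIFF dimensionality {data.ndim}")


def write_stack(image: VolumetricImage, path: str | Path) -> Path:
    """Write a stack as an ImageJ-compatible calibrated TIFF (lossless)."""
    path = Path(path)
    path.parent.mkdir(parents=True, exist_ok=True)
    dx, dy, dz = image.voxel_size
    arrs = image.channel_arrays()
    if image.channels is not None:
        data = np.stack(arrs, axis=1)  # (z, c, y, x)
        axes = "ZCYX"
    else:
        data = image.voxels
        axes = "ZYX"
    if data.dtype not in (np.uint8, np.uint16, np.float32):
        data = data.astype(np.float32)
    tifffile.imwrite(
        str(path),
        data,
        imagej=True,
        resolution=(1.0 / dx, 1.0 / dy),
        metadata={"spacing": dz, "unit": "um", "axes": axes},
    )
    return path


# ---------------------------------------------------------------------------
# Stack reshaping
# ---------------------------------------------------------------------------

def max_projection(image: VolumetricImage) -> VolumetricImage:
    """Maximum intensity projection over z, per channel; named ``MAX_…``."""
    if image.shape[0] < 1:
        raise ValueError("stack must contain at least one slice")
    name = image.name if image.name.startswith("MAX_") else f"MAX_{image.name}"
    if image.channels is not None:
        mips = [c.max(axis=0)[None] for c in image.channels]
        return VolumetricImage(
            mips[0], image.voxel_size, channels=mips, name=name,
            calibration_certain=image.calibration_certain,
        )
    return image.with_voxels(image.voxels.max(axis=0)[None], name=name,
                             bit_depth=image.bit_depth)


def split_channels(
    image: VolumetricImage, out_dir: str | Path | None = None
) -> list[VolumetricImage]:
    """Split a multi-channel stack into single-channel images named ``XC-name``.

    With ``out_dir`` set, each channel is additionally written to its own
    ``XCDir`` folder (``1CDir`` … ``4CDir``).
    """
    n = image.n_channels
    if n > MAX_CHANNELS:
        raise ValueError(f"unsupported channel count {n} (supported: 1-{MAX_CHANNELS})")
    out: list[VolumetricImage] = []
    for i, arr in enumerate(image.channel_arrays(), start=1):
        sub = VolumetricImage(
            arr, image.voxel_size, name=f"{i}C-{image.name}",
            calibration_certain=image.calibration_certain,
        )
        if out_dir is not None:
            d = Path(out_dir) / f"{i}CDir"
            d.mkdir(parents=True, exist_ok=True)
            write_stack(sub, d / f"{sub.name}.tif")
        out.append(sub)
    return out


def convert_8bit(image: VolumetricImage) -> VolumetricImage:
    """Linearly rescale the whole stack's ``[min, max]`` to ``[0, 255]``.

    Rounding is round-half-up; a constant stack maps to all zeros.
    """
    out_channels = []
    for arr in image.channel_arrays():
        a = arr.astype(np.float64)
        lo, hi = a.min(), a.max()
        if hi == lo:
            out_channels.append(np.zeros(arr.shape, dtype=np.uint8))
        else:
            scaled = np.floor(255.0 * (a - lo) / (hi - lo) + 0.5)
            out_channels.append(np.clip(scaled, 0, 255).astype(np.uint8))
    if image.channels is not None:
        return VolumetricImage(
            out_channels[0], image.voxel_size, channels=out_channels,
            name=image.name, calibration_certain=image.calibration_certain,
        )
    return image.with_voxels(out_channels[0], bit_depth="8")


# ---------------------------------------------------------------------------
# ROI archives — ImageJ binary dialect (.zip of .roi) and a JSON equivalent
# ---------------------------------------------------------------------------

_ROI_MAGIC = b"Iout"
_ROI_VERSION = 228
_TYPE_OVAL = 2
_TYPE_LINE = 3
_HEADER_SIZE = 64


def _encode_roi(roi: LineRoi | OvalRoi) -> bytes:
    buf = bytearray(_HEADER_SIZE)
    buf[0:4] = _ROI_MAGIC
    struct.pack_into(">h", buf, 4, _ROI_VERSION)
    position = 0
    if isinstance(roi, LineRoi):
        buf[6] = _TYPE_LINE
        x1, y1 = roi.start
        x2, y2 = roi.end
        top, left = int(min(y1, y2)), int(min(x1, x2))
        bottom, right = int(max(y1, y2)), int(max(x1, x2))
        struct.pack_into(">4h", buf, 8, top, left, bottom, right)
        struct.pack_into(">4f", buf, 18, x1, y1, x2, y2)
        if roi.slice_index is not None:
            position = roi.slice_index + 1  # ImageJ positions are 1-based
    else:
        buf[6] = _TYPE_OVAL
        cx, cy = roi.center
        rx, ry = roi.radii
        top, left = int(round(cy - ry)), int(round(cx - rx))
        bottom, right = int(round(cy + ry)), int(round(cx + rx))
        struct.pack_into(">4h", buf, 8, top, left, bottom, right)
        position = roi.slice_index + 1
    struct.pack_into(">i", buf, 56, position)
    return bytes(buf)


def _decode_roi(raw: bytes, name: str = "") -> LineRoi | OvalRoi:
    if raw[0:4] != _ROI_MAGIC:
        raise ValueError(f"unreadable ROI entry {name!r}: bad magic")
    roi_type = raw[6]
    top, left, bottom, right = struct.unpack_from(">4h", raw, 8)
    position = struct.unpack_from(">i", raw, 56)[0]
    slice_index = position - 1 if position > 0 else None
    if roi_type == _TYPE_LINE:
        x1, y1, x2, y2 = struct.unpack_from(">4f", raw, 18)
        return LineRoi(start=(x1, y1), end=(x2, y2), slice_index=slice_index,
                       image_name=name)
    if roi_type == _TYPE_OVAL:
        cx = (left + right) / 2.0
        cy = (top + bottom) / 2.0
        rx = (right - left) / 2.0
        ry = (bottom - top) / 2.0
        return OvalRoi(center=(cx, cy), radii=(rx, ry),
                       slice_index=slice_index if slice_index is not None else 0)
    raise ValueError(f"unreadable ROI entry {name!r}: unsupported type {roi_type}")


def write_roi_archive(rois: Sequence[LineRoi | OvalRoi], path: str | Path) -> Path:
    """Write ROIs to either a ``.zip`` of ImageJ ``.roi`` records or a JSON file."""
    path = Path(path)
    path.parent.mkdir(parents=True, exist_ok=True)
    if path.suffix.lower() == ".json":
        payload = []
        for roi in rois:
            if isinstance(roi, LineRoi):
                payload.append({"type": "line", "start": list(roi.start),
                                "end": list(roi.end), "slice": roi.slice_index,
                                "image": roi.image_name})
            else:
                payload.append({"type": "oval", "center": list(roi.center),
                                "radii": list(roi.radii), "slice": roi.slice_index})
        path.write_text(json.dumps(payload, indent=2))
        return path
    with zipfile.ZipFile(path, "w") as zf:
        for i, roi in enumerate(rois):
            zf.writestr(f"{i + 1:04d}.roi", _encode_roi(roi))
    return path


def read_roi_archive(path: str | Path) -> list[LineRoi | OvalRoi]:
    """Read a ``RoiSetLine.zip``-style archive or the JSON dialect, order preserved."""
    path = Path(path)
    if not path.exists():
        raise FileNotFoundError(
            f"ROI archive not found: {path} (expected a file such as 'RoiSetLine.zip' "
            "in the same folder as the input TIFFs)"
        )
    if path.suffix.lower() == ".json":
        out: list[LineRoi | OvalRoi] = []
        for rec in json.loads(path.read_text()):
            if rec["type"] == "line":
                out.append(LineRoi(start=tuple(rec["start"]), end=tuple(rec["end"]),
                                   slice_index=rec.get("slice"),
                                   image_name=rec.get("image", "")))
            elif rec["type"] == "oval":
                out.append(OvalRoi(center=tuple(rec["center"]),
                                   radii=tuple(rec["radii"]),
                                   slice_index=rec.get("slice") or 0))
            else:
                raise ValueError(f"unreadable ROI record of type {rec['type']!r}")
        return out
    with zipfile.ZipFile(path) as zf:
        return [_decode_roi(zf.read(n), n) for n in zf.namelist()
                if n.lower().endswith(".roi")]


def pair_rois_with_images(
    rois: Sequence[LineRoi | OvalRoi], tiff_paths: Sequence[str | Path]
) -> list[tuple[Path, LineRoi | OvalRoi]]:
    """Pair ROI *i* with the *i*-th TIFF in lexicographic filename order.

    Errors on a count mismatch instead of guessing — manual open-order pairing
    is not reproducible headlessly.
    """
    paths = sorted(Path(p) for p in tiff_paths)
    if len(rois) != len(paths):
        raise ValueError(
            f"ROI count ({len(rois)}) does not match TIFF count ({len(paths)}); "
            "each image needs exactly one ROI, in filename order"
        )
    return list(zip(paths, rois))
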