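"""Theoretical PSF generation and Richardson-Lucy deconvolution.

The PSF follows the scalar paraxial (Born-Wolf) diffraction model: at focus
the lateral intensity is the squared Airy pattern ``[2 J1(v)/v]**2`` with
``v = 2*pi*NA*r/lambda``; defocus enters through the paraxial pupil integral

    h(r, z) = | 2 * int_0^1 J0(v*rho) * exp(i*u*rho**2/2) * rho d_rho |**2

with ``u = 2*pi*NA**2*z/(n*lambda)``. This approximates the plugin-based
diffraction model used by the upstream workflow; the exact defocus model of
that plugin is undocumented.
"""

from __future__ import annotations

from dataclasses import dataclass
from pathlib import Path

import numpy as np
from scipy.signal import fftconvolve
from scipy.special import j0

from .volume_io import VolumetricImage, read_stack

__all__ = ["PsfParams", "theoretical_psf", "richardson_lucy", "load_psf"]

#: Typical emission wavelengths (nm) for common fluorophores.
EMISSION_NM = {"GFP": 510.0, "dsRed": 586.0}


@dataclass
class PsfParams:
    emission_wavelength_nm: float
    numerical_aperture: float
    refractive_index: float = 1.33
    voxel_size: tuple[float, float, float] = (0.05, 0.05, 0.19)
    shape: tuple[int, int, int] = (15, 31, 31)  # (z, y, x), odd so the peak centres

    def __post_init__(self) -> None:
        if not (0 < self.numerical_aperture < self.refractive_index):
            raise ValueError(
                f"need 0 < NA ({self.numerical_aperture}) < refractive index "
                f"({self.refractive_index})")
        if not (300.0 < self.emission_wavelength_nm < 800.0):
            raise ValueError("emission wavelength must be in (300, 800) nm")
        if any(s % 2 == 0 or s < 1 for s in self.shape):
            raise ValueError(f"PSF extents must be odd, got {self.shape}")


def theoretical_psf(params: PsfParams, n_rho: int = 128) -> VolumetricImage:
    """Sample the paraxial diffraction PSF on the voxel grid, normalized to sum 1."""
    nz, ny, nx = params.shape
    dx, dy, dz = params.voxel_size
    lam_um = params.emission_wavelength_nm / 1000.0
    na = params.numerical_aperture

    z = (np.arange(nz) - nz // 2) * dz
    y = (np.arange(ny) - ny // 2) * dy
    x = (np.arange(nx) - nx // 2) * dx
    r = np.hypot(y[:, None], x[None, :])  # um, (ny, nx)

    v = 2.0 * np.pi * na * r / lam_um
    u = 2.0 * np.pi * na**2 * z / (params.refractive_index * lam_um)

    rho = np.linspace(0.0, 1.0, n_rho)
    bessel = j0(v[..., None] * rho)  # (ny, nx, n_rho)
    psf = np.empty((nz, ny, nx), dtype=np.float64)
    for k, uk in enumerate(u):
        phase = np.exp(0.5j * uk * rho**2) * rho
        integral = 2.0 * np.trapezoid(bessel * phase, rho, axis=-1)
        psf[k] = np.abs(integral) ** 2
    psf /= psf.sum()
    return VolumetricImage(psf, params.voxel_size, name="PSF", bit_depth="float")


def load_psf(path: str | Path) -> VolumetricImage:
    """Read a user-provided PSF TIFF and renormalize it to sum 1."""
    img = read_stack(path)
    data = img.voxels.astype(np.float64)
    total = data.sum()
    if total <= 0:
        raise ValueError(f"PSF at {path} has non-positive total intensity")
    return img.with_voxels(data / total, bit_depth="float")


def richardson_lucy(
    image: VolumetricImage, psf: VolumetricImage, iterations: int = 1
) -> VolumetricImage:
    """Richardson-Lucy deconvolution (default 1 iteration, as in the protocol).

    Uses reflective padding by half the PSF extent to avoid ringing at the
    crop borders of subregion outputs. Output is non-negative and the same
    shape as the input.
    """
    if iterations < 0:
        raise ValueError("iterations must be >= 0")
    kernel = np.asarray(psf.voxels, dtype=np.float64)
    ksum = kernel.sum()
    if ksum <= 0:
        raise ValueError("PSF must have positive total intensity")
    kernel = kernel / ksum
    data = np.asarray(image.voxels, dtype=np.float64)
    if np.any(data < 0):
        raise ValueError("image must be non-negative for Richardson-Lucy")
    if iterations == 0:
        return image.with_voxels(data, bit_depth="float")
    if any(k > 2 * s + 1 for k, s in zip(kernel.shape, data.shape)):
        raise ValueError(
            f"PSF shape {kernel.shape} too large for image shape {data.shape}")

    pad = [min(k // 2, s) for k, s in zip(kernel.shape, data.shape)]
    padded = np.pad(data, [(p, p) for p in pad], mode="reflect")
    kernel_mirror = kernel[::-1, ::-1, ::-1]

    estimate = padded.copy()  # observed image as the initial estimate
    eps = 1e-12
    for _ in range(iterations):
        blurred = fftconvolve(estimate, kernel, mode="same")
        ratio = padded / np.maximum(blurred, eps)
        estimate *= fftconvolve(ratio, kernel_mirror, mode="same")
        np.clip(estimate, 0.0, None, out=estimate)

    sl = tuple(slice(p, p + s) for p, s in zip(pad, data.shape))
    return image.with_voxels(estimate[sl], bit_depth="float")
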