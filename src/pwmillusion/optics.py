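"""Fourier-optical defocus simulation and pixel/degree unit conversions.

The eye viewing a screen at distance ``d`` with pixel pitch ``p`` sees one
degree of visual angle spanning ``2 d tan(0.5°)/p`` pixels.  Dioptric
defocus of ``D`` diopters with pupil radius ``r`` adds a wavefront error
``W(ρ) = D ρ² / 2`` (meters) to an otherwise aberration-free circular
pupil; the incoherent point-spread function is the squared magnitude of the
Fourier transform of the generalized pupil function.  Defocus 0 yields the
diffraction-limited (Airy) pattern.

Bangerter occlusion foils have no published optical model; they are
approximated here by an equivalent Gaussian blur of configurable angular
width (:func:`foil_psf`).
"""

from __future__ import annotations

import math
from dataclasses import dataclass

import numpy as np
from scipy import signal

__all__ = [
    "ViewingGeometry",
    "DefocusSpec",
    "PSFKernel",
    "px_per_degree",
    "cpd_of_pattern",
    "f_px_of_cpd",
    "defocus_psf",
    "foil_psf",
    "apply_blur",
]


@dataclass(frozen=True)
class ViewingGeometry:
    """Viewing distance and screen pixel pitch, both in centimeters."""

    distance_cm: float
    pixel_pitch_cm: float

    def __post_init__(self) -> None:
        if not self.distance_cm > 0:
            raise ValueError("distance_cm must be positive")
        if not self.pixel_pitch_cm > 0:
            raise ValueError("pixel_pitch_cm must be positive")

    @property
    def px_per_degree(self) -> float:
        return 2.0 * self.distance_cm * math.tan(math.radians(0.5)) / self.pixel_pitch_cm

    @property
    def degrees_per_px(self) -> float:
        return 1.0 / self.px_per_degree


#: The experiment's geometry: 300 cm viewing distance, 0.025 cm pixel pitch
#: (21" CRT at 1200x1600).
EXPERIMENT_GEOMETRY = ViewingGeometry(distance_cm=300.0, pixel_pitch_cm=0.025)


@dataclass(frozen=True)
class DefocusSpec:
    """Dioptric defocus with pupil diameter and wavelength.

    Defaults (4 mm pupil, 555 nm) are this package's choices for a photopic
    observer, not measured values.
    """

    defocus_d: float = 1.0
    pupil_diameter_mm: float = 4.0
    wavelength_nm: float = 555.0

    def __post_init__(self) -> None:
        if self.defocus_d < 0:
            raise ValueError("defocus_d must be >= 0")
        if not self.pupil_diameter_mm > 0:
            raise ValueError("pupil_diameter_mm must be positive")
        if not self.wavelength_nm > 0:
            raise ValueError("wavelength_nm must be positive")


@dataclass(frozen=True)
class PSFKernel:
    """Nonnegative 2-D kernel normalized to unit sum."""

    values: np.ndarray

    def __post_init__(self) -> None:
        arr = np.asarray(self.values, dtype=float)
        if arr.ndim != 2 or arr.size == 0:
            raise ValueError("PSFKernel requires a non-empty 2-D array")
        if arr.min() < 0:
            raise ValueError("PSFKernel entries must be nonnegative")
        total = arr.sum()
        if not math.isfinite(total) or total <= 0:
            raise ValueError("PSFKernel must have positive finite mass")
        object.__setattr__(self, "values", arr / total)

    @property
    def support_px(self) -> int:
        return max(self.values.shape)

    def width_px(self, energy: float = 0.5) -> int:
        """Diameter (px) of the smallest centered square window containing
        the given fraction of the kernel's mass — a ringing-robust width."""
        return 2 * _tail_radius(self.values, keep=energy) + 1


def px_per_degree(geom: ViewingGeometry) -> float:
    """Pixels subtending one degree of visual angle."""
    return geom.px_per_degree


def cpd_of_pattern(f_px: float, geom: ViewingGeometry) -> float:
    """Convert a pattern frequency in cycles/pixel to cycles/degree."""
    if not f_px > 0:
        raise ValueError("f_px must be positive")
    return f_px * geom.px_per_degree


def f_px_of_cpd(sf_cpd: float, geom: ViewingGeometry) -> float:
    """Convert cycles/degree back to cycles/pixel (inverse of
    :func:`cpd_of_pattern`)."""
    if not sf_cpd > 0:
        raise ValueError("sf_cpd must be positive")
    return sf_cpd / geom.px_per_degree


def defocus_psf(spec: DefocusSpec, geom: ViewingGeometry,
                max_support_px: int | None = None,
                grid_size: int = 1024) -> PSFKernel:
    """Point-spread function of a defocused circular pupil, sampled on the
    image pixel grid.

    The pupil plane is sampled so that the FFT of the generalized pupil
    lands exactly on the image's angular pixel spacing: with N samples of
    spacing dξ, the PSF sample spacing is λ/(N dξ) radians, which is set
    equal to one screen pixel's angular subtense.

    Parameters
    ----------
    spec : DefocusSpec
    geom : ViewingGeometry
    max_support_px : int, optional
        If given and the trimmed kernel would exceed this size (e.g. the
        image size), an error is raised with guidance.
    grid_size : int
        Pupil-plane FFT size; must comfortably contain the pupil.
    """
    lam = spec.wavelength_nm * 1e-9
    r_pupil = spec.pupil_diameter_mm * 1e-3 / 2.0
    dtheta = math.radians(geom.degrees_per_px)  # radians per screen pixel
    n = grid_size
    # oversample the angular grid so the pupil fits the FFT grid with a
    # margin of 2.5x, then bin the fine PSF into screen pixels
    oversample = max(1, math.ceil(5.0 * r_pupil * dtheta / lam))
    if oversample % 2 == 0:
        oversample += 1  # odd factor keeps the binning centered on the peak
    dtheta_f = dtheta / oversample
    dxi = lam / (n * dtheta_f)  # pupil-plane sample spacing (m)
    if r_pupil / dxi > n / 2 - 2:
        raise ValueError(
            f"pupil does not fit the pupil-plane grid (radius {r_pupil / dxi:.0f} "
            f"samples vs grid {n}); increase grid_size")
    coords = (np.arange(n) - n // 2) * dxi
    xx, yy = np.meshgrid(coords, coords)
    rho2 = xx * xx + yy * yy
    aperture = rho2 <= r_pupil * r_pupil
    # defocus wavefront W = D * rho^2 / 2 (meters), phase = 2 pi W / lambda
    w = spec.defocus_d * rho2 / 2.0
    pupil = aperture * np.exp(1j * 2.0 * np.pi * w / lam)
    psf_f = np.abs(np.fft.fftshift(np.fft.fft2(np.fft.ifftshift(pupil)))) ** 2
    if oversample > 1:
        psf = _bin_radial(psf_f, oversample)
    else:
        psf = psf_f
    psf /= psf.sum()
    n_c = psf.shape[0]
    # trim to the support holding 99% of the mass (Airy tails decay too
    # slowly for a stricter criterion); renormalization restores unit sum
    half = _tail_radius(psf, keep=0.99)
    half = min(half, n_c // 2 - 1)
    c = n_c // 2
    kernel = psf[c - half:c + half + 1, c - half:c + half + 1]
    if max_support_px is not None and 2 * half + 1 > max_support_px:
        raise ValueError(
            f"PSF support {2 * half + 1} px exceeds the allowed {max_support_px} px; "
            "reduce defocus, view from closer, or use a larger image")
    return PSFKernel(kernel)


def _bin_radial(psf: np.ndarray, k: int) -> np.ndarray:
    """Integrate a finely sampled centered PSF into kxk blocks so the
    result is sampled at the coarse (screen-pixel) spacing, keeping the
    peak centered on a sample."""
    n = psf.shape[0]
    c = n // 2
    m = (c - k // 2) // k  # coarse half-width that stays inside the grid
    lo = c - k // 2 - m * k
    size = 2 * m + 1
    crop = psf[lo:lo + size * k, lo:lo + size * k]
    return crop.reshape(size, k, size, k).sum(axis=(1, 3))


def _tail_radius(psf: np.ndarray, keep: float) -> int:
    """Smallest half-width of a centered square window containing ``keep``
    of the PSF mass."""
    n = psf.shape[0]
    c = n // 2
    cum = 0.0
    target = keep * psf.sum()
    for half in range(1, c):
        cum = psf[c - half:c + half + 1, c - half:c + half + 1].sum()
        if cum >= target:
            return half
    return c - 1


def foil_psf(sigma_deg: float, geom: ViewingGeometry,
             truncate: float = 4.0) -> PSFKernel:
    """Gaussian stand-in for a Bangerter occlusion foil of angular width
    ``sigma_deg`` (degrees).  An approximation: real foils scatter light in
    a way no simple kernel captures."""
    if not sigma_deg > 0:
        raise ValueError("sigma_deg must be positive")
    sigma_px = sigma_deg * geom.px_per_degree
    half = max(1, int(math.ceil(truncate * sigma_px)))
    ax = np.arange(-half, half + 1)
    g = np.exp(-0.5 * (ax / sigma_px) ** 2)
    return PSFKernel(np.outer(g, g))


def apply_blur(image, psf: PSFKernel) -> np.ndarray:
    """Convolve an image with a normalized PSF using reflective boundaries.

    Uses FFT convolution on a reflect-padded copy, so large defocus kernels
    stay fast.
    """
    arr = image.values if hasattr(image, "values") else np.asarray(image, float)
    if arr.ndim != 2:
        raise ValueError("apply_blur expects a 2-D image")
    k = psf.values
    if k.shape[0] > 4 * arr.shape[0] or k.shape[1] > 4 * arr.shape[1]:
        raise ValueError(
            f"PSF support {k.shape} far exceeds image {arr.shape}; "
            "trim the kernel or use a larger image")
    py, px = k.shape[0] // 2, k.shape[1] // 2
    padded = _reflect_pad(arr, py, px)
    out = signal.fftconvolve(padded, k, mode="same")
    return out[py:py + arr.shape[0], px:px + arr.shape[1]]


def _reflect_pad(arr: np.ndarray, py: int, px: int) -> np.ndarray:
    """Reflect-pad by any amount (numpy limits one pass to size - 1)."""
    while py or px:
        sy = min(py, arr.shape[0] - 1)
        sx = min(px, arr.shape[1] - 1)
        arr = np.pad(arr, ((sy, sy), (sx, sx)), mode="reflect")
        py, px = py - sy, px - sx
    return arr
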