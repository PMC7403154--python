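"""Pulse-width-modulated zigzag halftone generator.

A hidden figure is encoded in a binary line pattern by modulating the duty
cycle of a triangular carrier: where the source silhouette is present the
lines of the zigzag pattern are drawn slightly thicker (duty ``d_on``) than
where it is absent (duty ``d_off``).  At carrier frequencies the eye cannot
resolve, local duty translates into local mean luminance and the figure
becomes visible — the "panda illusion" principle of PWM halftoning.

Conventions
-----------
* ``SourceImage`` values live in [0, 1] with **1 = figure / signal present**
  (the black parts of a silhouette).  This is the polarity under which the
  figure regions come out with thickened lines when ``d_on > d_off``.
  Luminance-coded inputs (white background = 1) must be inverted first; see
  :func:`pwmillusion.imageio.read_source_image`.
* Rendered output is binary with **0 = line ink (black), 1 = background**.
* The carrier is evaluated at pixel centers ``(col + 0.5, row + 0.5)`` in a
  0-based, top-left-origin frame with x = column and y = row.
"""

from __future__ import annotations

import math
import warnings
from dataclasses import dataclass

import numpy as np
from scipy import ndimage

__all__ = [
    "SourceImage",
    "HalftoneParams",
    "HalftoneImage",
    "FIG_PARAMS",
    "heaviside",
    "triangle",
    "carrier",
    "render",
    "demodulate_lowpass",
]

_TAN_TOL = 1e-12


@dataclass(frozen=True)
class SourceImage:
    """Signal map S(x, y) with values in [0, 1]; 1 marks the figure."""

    values: np.ndarray

    def __post_init__(self) -> None:
        arr = np.asarray(self.values, dtype=float)
        if arr.ndim != 2 or arr.size == 0:
            raise ValueError("SourceImage requires a non-empty 2-D array")
        if not np.all(np.isfinite(arr)):
            raise ValueError("SourceImage values must be finite")
        if arr.min() < 0.0 or arr.max() > 1.0:
            warnings.warn("SourceImage values outside [0, 1]; clipping", stacklevel=3)
            arr = np.clip(arr, 0.0, 1.0)
        object.__setattr__(self, "values", arr)

    @property
    def height(self) -> int:
        return self.values.shape[0]

    @property
    def width(self) -> int:
        return self.values.shape[1]

    @classmethod
    def constant(cls, s: float, shape: tuple[int, int]) -> "SourceImage":
        return cls(np.full(shape, float(s)))


@dataclass(frozen=True)
class HalftoneParams:
    """Generator parameters of the zigzag carrier.

    Parameters
    ----------
    f : float
        Carrier frequency in cycles per pixel (> 0).
    alpha : float
        Zigzag angle in radians, in (0, π); the zigzag segment slope is
        dx/dy = cot(alpha), so π/2 gives vertically aligned rows and π/4 a
        45° zigzag.  Angles with tan(alpha) = 0 are singular and rejected.
    r_hw : float
        Height/width ratio of one zigzag tile (> 0); the phase-shift term is
        periodic in y with period ``r_hw / f``.
    d_on : float
        Line duty cycle where the signal is present, in (0, 1).
    d_off : float
        Line duty cycle where the signal is absent, in (0, 1).
    """

    f: float
    alpha: float
    r_hw: float
    d_on: float
    d_off: float

    def __post_init__(self) -> None:
        if not (self.f > 0 and math.isfinite(self.f)):
            raise ValueError(f"carrier frequency must be positive, got {self.f}")
        if not (0 < self.alpha < math.pi):
            raise ValueError(f"alpha must lie in (0, pi), got {self.alpha}")
        if abs(math.tan(self.alpha)) < _TAN_TOL:
            raise ValueError(f"alpha={self.alpha} is singular: tan(alpha) = 0")
        if not self.r_hw > 0:
            raise ValueError(f"tile aspect r_hw must be positive, got {self.r_hw}")
        for name in ("d_on", "d_off"):
            d = getattr(self, name)
            if not (0 < d < 1):
                raise ValueError(f"{name} must lie in (0, 1), got {d}")
        if self.d_on == self.d_off:
            raise ValueError("degenerate duty cycles: d_on must differ from d_off")

    @classmethod
    def with_degrees(cls, f: float, alpha_degrees: float, r_hw: float,
                     d_on: float, d_off: float) -> "HalftoneParams":
        """Construct with the zigzag angle given in degrees."""
        return cls(f=f, alpha=math.radians(alpha_degrees), r_hw=r_hw,
                   d_on=d_on, d_off=d_off)


#: Reference parameter set of the published demonstration figure
#: (f = 0.05 px^-1, d_on = 0.6, d_off = 0.5, r_hw = 4).  Angle conventions
#: quoted for this parameter set are mutually inconsistent (and the formula
#: is singular at tan(alpha) = 0); this package uses a 45 deg zigzag, which
#: changes none of the duty or spectral properties.
FIG_PARAMS = HalftoneParams(f=0.05, alpha=math.pi / 4, r_hw=4.0,
                            d_on=0.6, d_off=0.5)


@dataclass(frozen=True)
class HalftoneImage:
    """Binary rendered pattern; 0 = line ink (black), 1 = background (white)."""

    values: np.ndarray

    def __post_init__(self) -> None:
        arr = np.asarray(self.values, dtype=float)
        if arr.ndim != 2 or arr.size == 0:
            raise ValueError("HalftoneImage requires a non-empty 2-D array")
        if not np.isin(arr, (0.0, 1.0)).all():
            raise ValueError("HalftoneImage must be strictly binary {0, 1}")
        object.__setattr__(self, "values", arr)

    @property
    def ink_fraction(self) -> float:
        """Fraction of black (line) pixels."""
        return float(np.mean(self.values == 0.0))


def heaviside(n):
    """Step function: 0 for n < 0, 1 for n >= 0 (the convention used here
    assigns 1 at exactly zero)."""
    n = np.asarray(n, dtype=float)
    if not np.all(np.isfinite(n)):
        raise ValueError("heaviside requires finite input")
    out = np.where(n < 0, 0.0, 1.0)
    return out if out.ndim else float(out)


def triangle(x, y, f: float, alpha: float, r_hw: float):
    """Triangular carrier in [0, 1], periodic in x with period 1/f.

    The y-dependent phase shift tilts successive rows into a zigzag whose
    tile height is ``r_hw / f`` pixels; within one half tile the x-offset
    grows linearly with y at slope cot(alpha).
    """
    if not f > 0:
        raise ValueError("f must be positive")
    if not r_hw > 0:
        raise ValueError("r_hw must be positive")
    t = math.tan(alpha)
    if abs(t) < _TAN_TOL:
        raise ValueError(f"alpha={alpha} is singular: tan(alpha) = 0")
    x = np.asarray(x, dtype=float)
    y = np.asarray(y, dtype=float)
    shift = r_hw * (np.pi - 2.0 * np.arcsin(np.cos(2.0 * np.pi * f * y / r_hw))) \
        / (4.0 * np.pi * f * t)
    val = np.arcsin(np.sin(2.0 * np.pi * f * (x - shift))) / np.pi + 0.5
    return val if val.ndim else float(val)


def carrier(x, y, params: HalftoneParams):
    """Triangular carrier rescaled so that it crosses 0 at duty ``d_off`` and
    1 at duty ``d_on``."""
    tri = triangle(x, y, params.f, params.alpha, params.r_hw)
    return (tri - params.d_off) / (params.d_on - params.d_off)


def render(source: SourceImage, params: HalftoneParams,
           invert_source: bool = False) -> HalftoneImage:
    """Render the PWM halftone: I(x, y) = step(carrier(x, y) − S(x, y)).

    A pixel is ink (0) where the scaled carrier falls below the local signal
    level, so the local ink duty fraction approaches
    ``d_off + S · (d_on − d_off)`` as resolution grows.

    Parameters
    ----------
    source : SourceImage
        Signal map; pass ``invert_source=True`` for luminance-coded inputs
        where the figure is dark (0) on a light (1) background.
    params : HalftoneParams
        Carrier parameters.
    """
    s = source.values
    if invert_source:
        s = 1.0 - s
    h, w = s.shape
    if params.f * w < 2:
        raise ValueError(
            f"image width {w} px fits fewer than two carrier periods at f={params.f}")
    # pixel centers, x = column, y = row, top-left origin
    yy, xx = np.mgrid[0:h, 0:w]
    c = carrier(xx + 0.5, yy + 0.5, params)
    return HalftoneImage(heaviside(c - s))


def demodulate_lowpass(image, cutoff: float, *, filter_type: str = "gaussian",
                       pitch: float = 1.0) -> np.ndarray:
    """Low-pass filter an image, the textbook way to demodulate a PWM signal.

    Parameters
    ----------
    image : HalftoneImage or 2-D array
        Input; a binary rendered pattern or any real-valued image.
    cutoff : float
        Cut-off frequency in cycles per unit of ``pitch`` (cycles/px when
        pitch is 1).  Must be positive.
    filter_type : {"gaussian", "ideal"}
        ``gaussian`` uses a spatial Gaussian with σ = 1/(2π·cutoff);
        ``ideal`` zeroes all spectral components beyond ``cutoff``
        (radially).  Both preserve the mean (DC gain 1).
    pitch : float
        Physical size of a pixel in the units ``cutoff`` is expressed in
        (e.g. degrees per pixel when cutoff is in cpd).
    """
    if not cutoff > 0:
        raise ValueError("cutoff must be positive")
    arr = image.values if isinstance(image, HalftoneImage) else np.asarray(image, float)
    cutoff_px = cutoff * pitch  # cycles per pixel
    if filter_type == "gaussian":
        sigma = 1.0 / (2.0 * np.pi * cutoff_px)
        return ndimage.gaussian_filter(arr, sigma=sigma, mode="reflect")
    if filter_type == "ideal":
        fy = np.fft.fftfreq(arr.shape[0])
        fx = np.fft.fftfreq(arr.shape[1])
        rho = np.hypot(*np.meshgrid(fy, fx, indexing="ij"))
        spec = np.fft.fft2(arr)
        spec[rho > cutoff_px] = 0.0
        return np.fft.ifft2(spec).real
    raise ValueError(f"unknown filter_type {filter_type!r}")
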