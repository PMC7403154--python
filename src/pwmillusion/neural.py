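"""Neural demodulation mechanisms: Ricco summation, spatial-frequency
channels, and the oriented difference-of-Gaussians (ODOG) brightness model.

Each mechanism maps a stimulus image to a real-valued response image.  All
three act, to first order, as low-pass operations on a fine zigzag carrier
and therefore increase the separability of the figure (duty ``d_on``) from
the background (duty ``d_off``).
"""

from __future__ import annotations

import math
import warnings
from dataclasses import dataclass

import numpy as np
from scipy import signal

from .optics import ViewingGeometry

__all__ = [
    "ChannelBank",
    "OdogParams",
    "DEFAULT_CHANNEL_EDGES_CPD",
    "ricco_summation",
    "channel_decompose",
    "odog_response",
]

#: Default spatial-frequency band edges (cpd) of the six-channel
#: decomposition; adjacent edges share boundaries and the edge ratio is
#: close to a constant factor of ~2.77.
DEFAULT_CHANNEL_EDGES_CPD = (0.03, 0.08, 0.22, 0.61, 1.72, 4.82, 13.49)


def _disc_kernel(diameter_px: float) -> np.ndarray:
    r = diameter_px / 2.0
    half = int(math.ceil(r))
    ax = np.arange(-half, half + 1)
    xx, yy = np.meshgrid(ax, ax)
    disc = (xx * xx + yy * yy <= r * r).astype(float)
    return disc / disc.sum()


def ricco_summation(image, diameter_arcmin: float,
                    geom: ViewingGeometry) -> np.ndarray:
    """Sum luminance over a uniform disc of the given angular diameter.

    Ricco's area — roughly 10 arcmin across in the photopic fovea — is the
    region over which the visual system pools luminance; pooling over an
    area wider than one carrier period converts duty cycle into mean level.
    The disc kernel is normalized to DC gain 1, so the image mean is
    preserved.
    """
    if not diameter_arcmin > 0:
        raise ValueError("diameter_arcmin must be positive")
    arr = image.values if hasattr(image, "values") else np.asarray(image, float)
    diameter_px = diameter_arcmin / 60.0 * geom.px_per_degree
    if diameter_px < 1.0:
        warnings.warn(
            f"Ricco disc ({diameter_px:.2f} px) smaller than one pixel; "
            "returning the input unchanged", stacklevel=2)
        return arr.copy()
    kernel = _disc_kernel(diameter_px)
    py, px = kernel.shape[0] // 2, kernel.shape[1] // 2
    padded = np.pad(arr, ((py, py), (px, px)), mode="reflect")
    out = signal.fftconvolve(padded, kernel, mode="same")
    return out[py:py + arr.shape[0], px:px + arr.shape[1]]


@dataclass(frozen=True)
class ChannelBank:
    """Bank of radial log-Gaussian band-pass filters.

    ``edges_cpd`` are the shared band boundaries in cycles/degree.  Filters
    are log-Gaussian annuli in the frequency domain, renormalized so the
    bank forms a partition of unity inside the covered passband: there the
    band images plus the DC component sum back to the original exactly,
    while frequencies outside the passband roll off smoothly.
    """

    edges_cpd: tuple = DEFAULT_CHANNEL_EDGES_CPD

    def __post_init__(self) -> None:
        edges = tuple(float(e) for e in self.edges_cpd)
        if len(edges) < 2:
            raise ValueError("ChannelBank needs at least two edges (one band)")
        if any(e <= 0 for e in edges) or any(
                b <= a for a, b in zip(edges, edges[1:])):
            raise ValueError("edges must be positive and strictly increasing")
        object.__setattr__(self, "edges_cpd", edges)

    @property
    def n_bands(self) -> int:
        return len(self.edges_cpd) - 1

    @property
    def centers_cpd(self) -> tuple:
        return tuple(math.sqrt(a * b)
                     for a, b in zip(self.edges_cpd, self.edges_cpd[1:]))

    @classmethod
    def geometric(cls, f_min: float, f_max: float, n_bands: int) -> "ChannelBank":
        """Bank of ``n_bands`` geometrically spaced bands covering
        [f_min, f_max] cpd."""
        edges = np.geomspace(f_min, f_max, n_bands + 1)
        return cls(tuple(edges))

    def weights(self, freq_cpd: np.ndarray) -> list[np.ndarray]:
        """Spectral weights of each band at the given radial frequencies
        (cpd).

        Inside the covered passband [first edge, last edge] the weights form
        a partition of unity, so the bands sum back to the original there;
        outside they roll off with the log-Gaussian tails of the outermost
        bands.  Zero frequency gets weight 0 in every band (the DC residual
        carries it).
        """
        logf = np.full_like(freq_cpd, -np.inf)
        pos = freq_cpd > 0
        logf[pos] = np.log(freq_cpd[pos])
        gs = []
        sigmas = []
        for lo, hi in zip(self.edges_cpd, self.edges_cpd[1:]):
            center = 0.5 * (math.log(lo) + math.log(hi))
            # half-amplitude at the band edges
            sigma = 0.5 * (math.log(hi) - math.log(lo)) / math.sqrt(2 * math.log(2))
            sigmas.append(sigma)
            g = np.zeros_like(freq_cpd)
            g[pos] = np.exp(-0.5 * ((logf[pos] - center) / sigma) ** 2)
            gs.append(g)
        total = np.sum(gs, axis=0)
        total[total == 0] = 1.0
        # envelope: 1 inside the passband, outermost-band tails outside
        env = np.ones_like(freq_cpd)
        log_lo, log_hi = math.log(self.edges_cpd[0]), math.log(self.edges_cpd[-1])
        below = pos & (logf < log_lo)
        above = pos & (logf > log_hi)
        # tails at a quarter of the band width, so out-of-band leakage stays small
        env[below] = np.exp(-0.5 * ((logf[below] - log_lo) / (0.25 * sigmas[0])) ** 2)
        env[above] = np.exp(-0.5 * ((logf[above] - log_hi) / (0.25 * sigmas[-1])) ** 2)
        env[~pos] = 0.0
        return [g / total * env for g in gs]


def channel_decompose(image, bank: ChannelBank,
                      geom: ViewingGeometry) -> list[np.ndarray]:
    """Split an image into the bank's spatial-frequency bands.

    Returns one real-valued image per band.  Inside the bank's passband the
    filters sum to one, so ``sum(bands) + image.mean()`` reconstructs the
    original exactly there (spectral components outside the passband are
    attenuated).
    """
    arr = image.values if hasattr(image, "values") else np.asarray(image, float)
    if arr.ndim != 2:
        raise ValueError("channel_decompose expects a 2-D image")
    lowest_period_px = geom.px_per_degree / bank.edges_cpd[0]
    if max(arr.shape) < lowest_period_px:
        warnings.warn(
            f"image ({max(arr.shape)} px) is smaller than one period of the "
            f"lowest band ({lowest_period_px:.0f} px); low bands are poorly "
            "resolved", stacklevel=2)
    fy = np.fft.fftfreq(arr.shape[0]) * geom.px_per_degree
    fx = np.fft.fftfreq(arr.shape[1]) * geom.px_per_degree
    rho = np.hypot(*np.meshgrid(fy, fx, indexing="ij"))
    spec = np.fft.fft2(arr)
    bands = []
    for w in bank.weights(rho):
        bands.append(np.fft.ifft2(spec * w).real)
    return bands


@dataclass(frozen=True)
class OdogParams:
    """Constants of the oriented difference-of-Gaussians model.

    Six orientations and seven octave-spaced scales by default; the surround
    Gaussian is elongated 2:1 along the filter orientation and twice the
    center width across it; scale weights grow as f^0.1; each orientation's
    multiscale sum is normalized by its own RMS energy before the
    orientations are summed.
    """

    n_orientations: int = 6
    center_freqs_cpd: tuple = tuple(6.5 / 2 ** k for k in range(6, -1, -1))
    surround_center_ratio: float = 2.0
    surround_elongation: float = 2.0
    weight_exponent: float = 0.1
    orientation_offset_rad: float = 0.0

    def __post_init__(self) -> None:
        if self.n_orientations < 2:
            raise ValueError("need at least 2 orientations")
        freqs = tuple(float(f) for f in self.center_freqs_cpd)
        if any(b <= a for a, b in zip(freqs, freqs[1:])):
            raise ValueError("center_freqs_cpd must be ascending")
        object.__setattr__(self, "center_freqs_cpd", freqs)

    @property
    def orientations_rad(self) -> tuple:
        return tuple(self.orientation_offset_rad + k * math.pi / self.n_orientations
                     for k in range(self.n_orientations))


def _odog_filter_spectrum(fy: np.ndarray, fx: np.ndarray, theta: float,
                          f_c_px: float, params: OdogParams) -> np.ndarray:
    """Frequency response of one oriented DoG (unit DC-free balance).

    Built in the Fourier domain: a Gaussian with space constant
    σ_c = 1/(2π f_c) for the center, and a surround of width
    ``surround_center_ratio``·σ_c across the orientation, additionally
    elongated by ``surround_elongation`` along it.  Both lobes have unit
    volume, so the difference has exactly zero DC response.
    """
    # rotate frequency coordinates into the filter frame
    u = fx * math.cos(theta) + fy * math.sin(theta)   # along orientation
    v = -fx * math.sin(theta) + fy * math.cos(theta)  # across orientation
    sigma_c = 1.0 / (2.0 * math.pi * f_c_px)
    sigma_s = params.surround_center_ratio * sigma_c
    sigma_s_along = params.surround_elongation * sigma_s
    two_pi2 = 2.0 * math.pi ** 2
    center = np.exp(-two_pi2 * sigma_c ** 2 * (u ** 2 + v ** 2))
    surround = np.exp(-two_pi2 * (sigma_s_along ** 2 * u ** 2 + sigma_s ** 2 * v ** 2))
    return center - surround


def odog_response(image, params: OdogParams,
                  geom: ViewingGeometry) -> np.ndarray:
    """ODOG model response: oriented DoG outputs summed across scales per
    orientation, RMS-normalized per orientation, then summed across
    orientations.  The output has zero mean; a constant input maps to an
    all-zero response.
    """
    arr = image.values if hasattr(image, "values") else np.asarray(image, float)
    if arr.ndim != 2:
        raise ValueError("odog_response expects a 2-D image")
    if float(np.ptp(arr)) == 0.0:
        return np.zeros_like(arr, dtype=float)
    fy = np.fft.fftfreq(arr.shape[0])
    fx = np.fft.fftfreq(arr.shape[1])
    fyy, fxx = np.meshgrid(fy, fx, indexing="ij")
    spec = np.fft.fft2(arr)
    weights = np.array([f ** params.weight_exponent
                        for f in params.center_freqs_cpd])
    out = np.zeros_like(arr, dtype=float)
    for theta in params.orientations_rad:
        resp_spec = np.zeros_like(spec)
        for w, f_cpd in zip(weights, params.center_freqs_cpd):
            f_px = f_cpd / geom.px_per_degree
            resp_spec += w * _odog_filter_spectrum(fyy, fxx, theta, f_px, params)
        orient = np.fft.ifft2(spec * resp_spec).real
        rms = float(np.sqrt(np.mean(orient ** 2)))
        if rms > 0:
            out += orient / rms
    return out - out.mean()
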