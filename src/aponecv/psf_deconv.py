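"""Diffraction PSF generation and iterative image deconvolution.

The imaging model is a diffraction-limited wide-field system: a point
source images as an Airy pattern, I(r) = [2 J1(v) / v]^2 with
v = 2*pi*NA*r*dx / lambda, where NA is the numerical aperture, lambda the
emission wavelength and dx the pixel spacing.  Lateral resolution follows
the Rayleigh criterion, 0.61*lambda/NA.

Deconvolution is non-negative Richardson-Lucy with an optional
Wiener/Tikhonov damping factor, iterated until a maximum count or until
the relative L2 change of the estimate between iterations falls below a
termination threshold.  Processing is entirely 2-D: channel images are
single planes and any 3-D PSF is reduced by average-intensity projection
before use (``lowpass_z`` is accepted for config compatibility and
ignored).
"""

from __future__ import annotations

from dataclasses import dataclass, field

import numpy as np
from scipy.signal import fftconvolve
from scipy.special import j1

__all__ = [
    "OpticsParams",
    "DeconvSettings",
    "rayleigh_resolution_px",
    "generate_psf",
    "zproject_average",
    "deconvolve",
]

#: Pixel spacing used when none is calibrated, in nm/px.  The default is
#: a 6.5 um camera pixel behind the validated 10x objective (650 nm/px in
#: the sample plane), the common sCMOS geometry.  This is a calibration
#: placeholder: the correct value depends on the acquiring system and
#: should always be supplied with real data.
DEFAULT_PIXEL_SPACING_NM = 650.0


@dataclass(frozen=True)
class OpticsParams:
    """Optical configuration of one fluorescence channel.

    wavelength is the laser line in nm (488 for the green 6-CF channel,
    561 for the red AnnCy3 channel); the validated objective is a 10x
    0.3 NA air lens (refractive index 1.0).
    """

    wavelength: float
    numerical_aperture: float = 0.3
    refractive_index: float = 1.0
    pixel_spacing: float = DEFAULT_PIXEL_SPACING_NM  # nm per pixel
    psf_size: int = 63  # pixels, square, odd

    def __post_init__(self) -> None:
        if not (0 < self.numerical_aperture < self.refractive_index <= 2):
            raise ValueError("need 0 < NA < refractive index <= 2")
        if not (300 <= self.wavelength <= 800):
            raise ValueError("wavelength must be in [300, 800] nm")
        if self.pixel_spacing <= 0:
            raise ValueError("pixel_spacing must be positive")


@dataclass(frozen=True)
class DeconvSettings:
    """Iterative deconvolution settings.

    Defaults follow the validated run configuration: no Wiener
    regularisation (gamma 0), unit low-pass, at most 10 iterations,
    stopping early when the estimate changes by less than 1% in relative
    L2 norm between iterations.
    """

    wiener_gamma: float = 0.0
    lowpass_xy: float = 1.0
    lowpass_z: float = 1.0  # accepted and ignored in 2-D processing
    max_iterations: int = 10
    termination_change: float = 0.010

    def __post_init__(self) -> None:
        if self.max_iterations < 1:
            raise ValueError("max_iterations must be >= 1")
        if not (0 <= self.termination_change < 1):
            raise ValueError("termination_change must be in [0, 1)")


def rayleigh_resolution_px(optics: OpticsParams) -> float:
    """Lateral Rayleigh resolution in pixels: 0.61*lambda/NA / pixel_spacing."""
    return 0.61 * optics.wavelength / optics.numerical_aperture / optics.pixel_spacing


def generate_psf(optics: OpticsParams) -> np.ndarray:
    """In-focus diffraction-limited intensity PSF sampled on the pixel grid.

    Returns a square float array of odd side ``optics.psf_size`` whose
    pixels sum to 1.  The pattern is the Airy intensity [2 J1(v)/v]^2; the
    centre pixel (v = 0) takes the limit value 1 before normalisation.
    """
    size = optics.psf_size
    if size % 2 == 0:
        raise ValueError("psf_size must be odd")
    if size < 15:
        raise ValueError("psf_size must be >= 15 to contain the Airy core")
    half = size // 2
    y, x = np.mgrid[-half: half + 1, -half: half + 1]
    r = np.hypot(x, y) * optics.pixel_spacing
    v = 2.0 * np.pi * optics.numerical_aperture * r / optics.wavelength
    out = np.ones_like(v)
    nz = v > 0
    out[nz] = (2.0 * j1(v[nz]) / v[nz]) ** 2
    return out / out.sum()


def zproject_average(stack) -> np.ndarray:
    """Average-intensity z-projection: pixelwise mean across planes."""
    planes = [np.asarray(p, float) for p in stack]
    if not planes:
        raise ValueError("empty stack")
    shape = planes[0].shape
    if any(p.shape != shape for p in planes):
        raise ValueError("stack planes must share one shape")
    return np.mean(planes, axis=0)


def _convolve_same(img: np.ndarray, kernel: np.ndarray) -> np.ndarray:
    """'same'-size convolution with edge-replicated padding (flux-friendly)."""
    ph, pw = kernel.shape[0] // 2, kernel.shape[1] // 2
    padded = np.pad(img, ((ph, ph), (pw, pw)), mode="edge")
    return fftconvolve(padded, kernel, mode="valid")


def deconvolve(img: np.ndarray, psf: np.ndarray,
               settings: DeconvSettings = DeconvSettings(),
               full_output: bool = False):
    """Non-negative Richardson-Lucy deconvolution.

    The estimate starts at the observed image and is updated
    multiplicatively, x <- x * (K^T (*) (y / (K (*) x))); when
    ``wiener_gamma`` > 0 the update is damped by 1/(1 + gamma).
    Iteration stops at ``settings.max_iterations`` or as soon as
    ||x_k - x_{k-1}|| / ||x_{k-1}|| < ``settings.termination_change``.
    The output is clipped to the input's bit range and returned in the
    input dtype.

    With ``full_output=True`` returns ``(image, n_iterations)``.
    """
    arr = np.asarray(img)
    psf = np.asarray(psf, float)
    if psf.shape[0] > arr.shape[0] or psf.shape[1] > arr.shape[1]:
        raise ValueError("PSF must not be larger than the image")
    if not np.isclose(psf.sum(), 1.0, atol=1e-6):
        raise ValueError("PSF must be normalised to unit sum")

    y = arr.astype(float)
    psf_flip = psf[::-1, ::-1]
    eps = 1e-12
    x = y.copy()
    n_iter = 0
    for _ in range(settings.max_iterations):
        blurred = _convolve_same(x, psf)
        ratio = y / np.maximum(blurred, eps)
        update = _convolve_same(ratio, psf_flip)
        x_new = x * update
        if settings.wiener_gamma > 0:
            x_new = x + (x_new - x) / (1.0 + settings.wiener_gamma)
        x_new = np.clip(x_new, 0, None)
        n_iter += 1
        denom = np.linalg.norm(x)
        change = np.linalg.norm(x_new - x) / denom if denom > 0 else 0.0
        x = x_new
        if change < settings.termination_change:
            break

    if np.issubdtype(arr.dtype, np.integer):
        limit = float(np.iinfo(arr.dtype).max)
        out = np.round(np.clip(x, 0, limit)).astype(arr.dtype)
    else:
        out = x
    if full_output:
        return out, n_iter
    return out
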