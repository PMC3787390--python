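"""PSF models, convolution and Poisson noise for simulated STED/confocal images.

The effective lateral point spread function is modeled as a radially symmetric
Lorentzian (STED) or Gaussian (confocal), parameterized by its full width at
half maximum.  The Lorentzian has heavy tails, so the rendered kernel is
truncated at a configurable support radius and renormalized to unit sum.
"""

from __future__ import annotations

from dataclasses import dataclass
from typing import Optional

import numpy as np
from scipy.signal import fftconvolve

from .errors import InvalidSpecError, ShapeMismatchError
from .structures import Image2D

__all__ = ["PSFSpec", "NoiseParams", "make_psf", "image_structure"]

_LN2 = np.log(2.0)


@dataclass(frozen=True)
class PSFSpec:
    """Point-spread-function model.

    ``fwhm`` is the full width at half maximum in nm.  ``support_radius`` is
    the truncation radius of the rendered kernel (defaults to 4 FWHM, and must
    be at least 3 FWHM so the truncated Lorentzian still carries its tails).
    """

    model: str = "lorentzian"
    fwhm: float = 80.0
    support_radius: Optional[float] = None

    def __post_init__(self) -> None:
        if self.model not in ("lorentzian", "gaussian"):
            raise InvalidSpecError(f"unknown PSF model {self.model!r}")
        if self.fwhm <= 0:
            raise InvalidSpecError("fwhm must be > 0")
        if self.support_radius is not None and self.support_radius < 3 * self.fwhm:
            raise InvalidSpecError("support_radius must be >= 3 * fwhm")

    @property
    def support(self) -> float:
        return self.support_radius if self.support_radius is not None else 4.0 * self.fwhm


@dataclass(frozen=True)
class NoiseParams:
    """Poisson detection model.

    ``signal_scale`` converts one unit of projected label intensity into
    expected detector counts; ``background_rate`` is the expected count per
    pixel from autofluorescence / stray light.  Both feed a single Poisson
    draw per pixel (shot noise on signal plus background).
    """

    signal_scale: float = 50.0
    background_rate: float = 5.0
    rng_seed: Optional[int] = None

    def __post_init__(self) -> None:
        if self.signal_scale < 0:
            raise InvalidSpecError("signal_scale must be >= 0")
        if self.background_rate < 0:
            raise InvalidSpecError("background_rate must be >= 0")


def psf_profile(model: str, r: np.ndarray, fwhm: float) -> np.ndarray:
    """Unnormalized radial profile with the given FWHM, evaluated at r (nm)."""
    r = np.asarray(r, dtype=float)
    if model == "lorentzian":
        return 1.0 / (1.0 + (2.0 * r / fwhm) ** 2)
    if model == "gaussian":
        return np.exp(-4.0 * _LN2 * (r / fwhm) ** 2)
    raise InvalidSpecError(f"unknown PSF model {model!r}")


def make_psf(spec: PSFSpec, pixel_size: float) -> Image2D:
    """Render the PSF as an odd-sized, unit-sum 2D kernel.

    The kernel covers +/- ``spec.support`` nm; values are the radial profile
    evaluated at pixel centers, then normalized so the truncated kernel sums
    to exactly 1.
    """
    if pixel_size <= 0:
        raise InvalidSpecError("pixel_size must be > 0")
    r_px = int(np.ceil(spec.support / pixel_size))
    offsets = (np.arange(2 * r_px + 1) - r_px) * pixel_size
    dx, dy = np.meshgrid(offsets, offsets, indexing="ij")
    r = np.sqrt(dx * dx + dy * dy)
    kernel = psf_profile(spec.model, r, spec.fwhm)
    kernel /= kernel.sum()
    return Image2D(kernel, pixel_size)


def image_structure(
    img: Image2D,
    psf: PSFSpec,
    noise: Optional[NoiseParams] = None,
    rng: Optional[np.random.Generator] = None,
) -> Image2D:
    """Blur a projected label density with the PSF; optionally add Poisson noise.

    Noise-free output is the zero-padded convolution ``img (*) kernel``.  With
    ``noise``, each pixel is a Poisson draw with mean
    ``signal_scale * conv + background_rate``; the draw is seeded from
    ``noise.rng_seed`` unless an explicit generator is passed.
    """
    if img.values.ndim != 2:
        raise ShapeMismatchError("image_structure expects a 2D image")
    kernel = make_psf(psf, img.pixel_size)
    conv = fftconvolve(np.asarray(img.values, dtype=np.float64), kernel.values, mode="same")
    np.clip(conv, 0.0, None, out=conv)  # FFT round-off can go slightly negative
    if noise is None:
        return Image2D(conv, img.pixel_size)
    expected = noise.signal_scale * conv + noise.background_rate
    if rng is None:
        rng = np.random.default_rng(noise.rng_seed)
    counts = rng.poisson(expected).astype(np.float64)
    return Image2D(counts, img.pixel_size)
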