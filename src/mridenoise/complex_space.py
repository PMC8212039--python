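"""K-space <-> complex-image transforms, noise injection and sigma estimation.

MRI raw data live in k-space (the 2-D spatial-frequency domain); the
complex image is its inverse Fourier transform.  Thermal acquisition noise
is i.i.d. complex Gaussian in k-space and — under a *unitary* transform —
remains i.i.d. complex Gaussian with the same per-channel variance in the
complex image, which is why both denoisers in this package operate on the
real/imaginary channel pair rather than on Rician-corrupted magnitudes.

All transforms here use the orthonormal FFT with the zero-frequency
component at the array centre, so total power (Parseval) and noise
variance are preserved between domains.
"""

from __future__ import annotations

from dataclasses import dataclass, field, replace

import numpy as np
from scipy.optimize import brentq

__all__ = [
    "ComplexImage",
    "KSpaceSlice",
    "NoiseModel",
    "InvalidDataError",
    "ParameterError",
    "DimensionError",
    "kspace_to_image",
    "image_to_kspace",
    "add_gaussian_noise",
    "apply_scale",
    "center_crop",
    "zero_pad_square",
    "estimate_sigma_background",
    "magnitude",
    "to_channels",
    "from_channels",
]


class InvalidDataError(ValueError):
    """Raised when an array contains NaN/inf or has an unusable shape."""


class ParameterError(ValueError):
    """Raised for out-of-range scalar parameters (sigma, scale, fractions)."""


class DimensionError(ValueError):
    """Raised when requested sizes are incompatible with the data."""


def _check_finite_2d(data: np.ndarray, what: str) -> np.ndarray:
    arr = np.asarray(data)
    if arr.ndim != 2:
        raise InvalidDataError(f"{what} must be 2-D, got shape {arr.shape}")
    if not np.all(np.isfinite(arr.view(np.float64) if arr.dtype.kind == "c" else arr)):
        raise InvalidDataError(f"{what} contains non-finite values")
    return np.asarray(arr, dtype=np.complex128)


@dataclass
class ComplexImage:
    """A 2-D complex-valued slice in image space.

    ``scale_applied`` records the multiplicative factor already applied to
    ``data`` relative to raw acquisition units (1.0 = raw).  Both training
    protocols rescale their inputs, and keeping the factor on the image
    lets a denoiser's output be mapped back to raw units.
    """

    data: np.ndarray
    scale_applied: float = 1.0

    def __post_init__(self):
        self.data = _check_finite_2d(self.data, "ComplexImage.data")
        if self.data.shape[0] < 8 or self.data.shape[1] < 8:
            raise InvalidDataError(
                f"ComplexImage must be at least 8x8, got {self.data.shape}"
            )
        if not self.scale_applied > 0:
            raise ParameterError("scale_applied must be positive")

    @property
    def height(self) -> int:
        return self.data.shape[0]

    @property
    def width(self) -> int:
        return self.data.shape[1]


@dataclass
class KSpaceSlice:
    """The 2-D spatial-frequency dual of a :class:`ComplexImage`."""

    data: np.ndarray

    def __post_init__(self):
        self.data = _check_finite_2d(self.data, "KSpaceSlice.data")

    @property
    def height(self) -> int:
        return self.data.shape[0]

    @property
    def width(self) -> int:
        return self.data.shape[1]


@dataclass
class NoiseModel:
    """Additive i.i.d. complex Gaussian noise: y = x + n.

    ``sigma`` is the standard deviation of *each* of the real and imaginary
    channels, in the units of the image it is applied to.
    """

    sigma: float
    seed: int = field(default=0)

    def __post_init__(self):
        if self.sigma < 0:
            raise ParameterError("sigma must be non-negative")


# -- Fourier pair ---------------------------------------------------------


def kspace_to_image(k: KSpaceSlice) -> ComplexImage:
    """Centered, orthonormal inverse 2-D FFT (k-space -> complex image)."""
    img = np.fft.fftshift(np.fft.ifft2(np.fft.ifftshift(k.data), norm="ortho"))
    return ComplexImage(img)


def image_to_kspace(img: ComplexImage) -> KSpaceSlice:
    """Centered, orthonormal forward 2-D FFT (complex image -> k-space)."""
    k = np.fft.fftshift(np.fft.fft2(np.fft.ifftshift(img.data), norm="ortho"))
    return KSpaceSlice(k)


# -- noise, scaling, geometry ---------------------------------------------


def add_gaussian_noise(img: ComplexImage, noise: NoiseModel) -> ComplexImage:
    """Add independent N(0, sigma^2) noise to each channel of every pixel."""
    if noise.sigma == 0:
        return replace(img, data=img.data.copy())
    rng = np.random.default_rng(noise.seed)
    n = rng.normal(0.0, noise.sigma, size=img.data.shape) + 1j * rng.normal(
        0.0, noise.sigma, size=img.data.shape
    )
    return replace(img, data=img.data + n)


def apply_scale(img: ComplexImage, factor: float) -> ComplexImage:
    """Multiply the image by ``factor`` and record it in ``scale_applied``."""
    if not factor > 0:
        raise ParameterError("scale factor must be positive")
    return ComplexImage(img.data * factor, scale_applied=img.scale_applied * factor)


def center_crop(img: ComplexImage, size: int) -> ComplexImage:
    """Centered size x size window; odd remainders drop the high-index side."""
    if size > img.height or size > img.width:
        raise DimensionError(
            f"crop size {size} exceeds image dimensions {img.data.shape}"
        )
    r0 = (img.height - size) // 2
    c0 = (img.width - size) // 2
    return replace(img, data=img.data[r0 : r0 + size, c0 : c0 + size].copy())


def zero_pad_square(k: KSpaceSlice) -> KSpaceSlice:
    """Zero-pad the smaller k-space dimension symmetrically to a square.

    Odd total padding puts the extra row/column on the high-index side.
    Zeros carry no energy, so total power is unchanged.
    """
    h, w = k.data.shape
    n = max(h, w)
    dh, dw = n - h, n - w
    padded = np.pad(k.data, [(dh // 2, dh - dh // 2), (dw // 2, dw - dw // 2)])
    return KSpaceSlice(padded)


def magnitude(img: ComplexImage) -> np.ndarray:
    """Per-pixel modulus (the conventional magnitude MRI)."""
    return np.abs(img.data)


# -- background sigma estimation ------------------------------------------


def _g(u: float) -> float:
    # E[m^2 | m <= t] / t^2 for Rayleigh magnitudes, with u = t^2 / (2 sigma^2);
    # decreasing from 1/2 (u -> 0) to 0 (u -> inf).
    return 1.0 / u - 1.0 / np.expm1(u)


def _solve_truncated_sigma(mean_m2: float, t: float) -> float:
    """Solve E[m^2 | m<=t] = mean_m2 for sigma under a Rayleigh tail model."""
    r = mean_m2 / (t * t)
    if r >= _g(1e-6):
        # threshold deep inside the noise bulk: sigma is only lower-bounded;
        # return the threshold itself so an iterative caller widens its net
        return float(t)
    if r <= _g(500.0):  # truncation irrelevant (t >> sigma)
        return np.sqrt(mean_m2 / 2.0)
    u = brentq(lambda v: _g(v) - r, 1e-6, 500.0)
    return float(t / np.sqrt(2.0 * u))


def estimate_sigma_background(img: ComplexImage, background_fraction: float = 0.1) -> float:
    """Estimate the per-channel noise standard deviation from background pixels.

    MRI slices contain large zero-signal regions, where the magnitude of
    pure complex Gaussian noise is Rayleigh(sigma).  The lowest
    ``background_fraction`` of pixels by magnitude seeds the estimate, but
    a plain standard deviation over that subset is biased low — selecting
    the lower tail of a Rayleigh truncates it — so sigma is recovered by
    matching the observed mean squared magnitude to the truncated-Rayleigh
    conditional mean, then refined on all pixels below 2*sigma (a wider,
    better-conditioned truncation that still avoids tissue).
    """
    if not 0 < background_fraction < 0.5:
        raise ParameterError("background_fraction must lie in (0, 0.5)")
    m = np.abs(img.data).ravel()
    k = max(int(round(background_fraction * m.size)), 8)
    sel = np.partition(m, k - 1)[:k]
    t = float(sel.max())
    if t == 0.0:
        return 0.0
    sigma = _solve_truncated_sigma(float(np.mean(sel**2)), t)
    for _ in range(8):  # refinement: threshold scales with the estimate
        thr = 2.0 * sigma
        below = m[m <= thr]
        if below.size < 50 or sigma == 0.0:
            break
        new = _solve_truncated_sigma(float(np.mean(below**2)), thr)
        if abs(new - sigma) <= 1e-6 * sigma:
            sigma = new
            break
        sigma = new
    return float(sigma)


# -- channel packing (network I/O) ----------------------------------------


def to_channels(img: ComplexImage) -> np.ndarray:
    """Pack a complex image as a (2, H, W) float array (real, imaginary)."""
    return np.stack([img.data.real, img.data.imag]).astype(np.float64)


def from_channels(arr: np.ndarray, scale_applied: float = 1.0) -> ComplexImage:
    """Inverse of :func:`to_channels`."""
    if arr.ndim != 3 or arr.shape[0] != 2:
        raise InvalidDataError(f"expected (2, H, W) array, got {arr.shape}")
    return ComplexImage(arr[0] + 1j * arr[1], scale_applied=scale_applied)
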