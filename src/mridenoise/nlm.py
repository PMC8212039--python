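"""Non-local means baseline.

NLM replaces each pixel by a weighted average of the centre pixels of all
patches inside a search window, weighting by patch similarity:
w = exp(-max(d^2 - 2 sigma^2, 0) / h^2), with d^2 the mean squared patch
difference and the 2 sigma^2 subtraction compensating the noise floor of
the distance.  The filtering strength h is dimensionless and is resolved
against the noise amplitude (h_abs = h * sigma, the convention under
which a single value like h = 0.71 transfers across datasets whose raw
magnitudes differ by orders of magnitude); when no sigma is available the
fallback resolves h against the image range instead.  The patch-space
averaging itself is delegated to ``skimage.restoration.denoise_nl_means``
(slow mode, which implements exactly this weighting).
"""

from __future__ import annotations

from dataclasses import dataclass, replace

import numpy as np
from skimage.restoration import denoise_nl_means

from .complex_space import ComplexImage, DimensionError, InvalidDataError, ParameterError

__all__ = ["NlmParams", "nlm_denoise", "nlm_denoise_complex"]


@dataclass
class NlmParams:
    """Filtering strength and patch geometry (defaults: h=0.71, 5x5, distance 6)."""

    h: float = 0.71
    patch_size: int = 5
    patch_distance: int = 6

    def __post_init__(self):
        if not self.h > 0:
            raise ParameterError("h must be positive")
        if self.patch_size < 3 or self.patch_size % 2 == 0:
            raise ParameterError("patch_size must be odd and >= 3")
        if self.patch_distance < 1:
            raise ParameterError("patch_distance must be >= 1")


def _nlm_channel(x: np.ndarray, params: NlmParams, sigma: float | None) -> np.ndarray:
    lo, hi = float(x.min()), float(x.max())
    if hi == lo:  # constant images are a fixed point
        return x.copy()
    if sigma == 0:
        # h resolves against sigma, and the h -> 0 limit of the weights is
        # a delta at the centre patch: nothing to average away
        return x.copy()
    if sigma is not None and sigma > 0:
        return denoise_nl_means(
            x,
            h=params.h * float(sigma),
            sigma=float(sigma),
            patch_size=params.patch_size,
            patch_distance=params.patch_distance,
            fast_mode=False,
            preserve_range=True,
        )
    # sigma-free fallback: h relative to the normalised [0, 1] range
    xn = (x - lo) / (hi - lo)
    out = denoise_nl_means(
        xn,
        h=params.h,
        patch_size=params.patch_size,
        patch_distance=params.patch_distance,
        fast_mode=False,
        preserve_range=True,
    )
    return out * (hi - lo) + lo


def nlm_denoise(img: np.ndarray, params: NlmParams, sigma: float | None = None) -> np.ndarray:
    """Denoise a 2-D magnitude image.

    ``sigma`` (same units as ``img``) enables the variance-compensated
    weights; ``None`` disables the compensation.
    """
    arr = np.asarray(img, dtype=np.float64)
    if arr.ndim != 2:
        raise InvalidDataError("nlm_denoise expects a 2-D array")
    if not np.all(np.isfinite(arr)):
        raise InvalidDataError("input contains non-finite values")
    if np.any(arr < 0):
        raise InvalidDataError("magnitude input must be non-negative")
    if min(arr.shape) < params.patch_size:
        raise DimensionError(
            f"image {arr.shape} smaller than patch size {params.patch_size}"
        )
    return _nlm_channel(arr, params, sigma)


def nlm_denoise_complex(
    img: ComplexImage, params: NlmParams, sigma: float | None = None
) -> ComplexImage:
    """Apply NLM independently to the real and imaginary channels."""
    if min(img.data.shape) < params.patch_size:
        raise DimensionError(
            f"image {img.data.shape} smaller than patch size {params.patch_size}"
        )
    re = _nlm_channel(img.data.real.copy(), params, sigma)
    im = _nlm_channel(img.data.imag.copy(), params, sigma)
    return replace(img, data=re + 1j * im)
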