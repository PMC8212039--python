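"""Image quality measures: MSE, PSNR and SSIM.

SSIM follows the standard luminance/contrast/structure decomposition

    SSIM(x, y) = l(x,y)^alpha * c(x,y)^beta * s(x,y)^gamma

computed over a sliding Gaussian-weighted window; with alpha = beta =
gamma = 1 and C3 = C2/2 it collapses algebraically to the familiar
two-factor form, and that simplified path is the default.  Local
statistics use population (ddof=0) moments, matching the common
reference implementations.
"""

from __future__ import annotations

from dataclasses import dataclass

import numpy as np
from scipy.signal import convolve2d

__all__ = ["MetricsRecord", "mse", "psnr", "ssim"]


@dataclass
class MetricsRecord:
    """One row of a quantitative comparison table."""

    method: str
    sigma: float
    mse: float
    psnr: float
    ssim: float

    def __post_init__(self):
        if self.mse < 0:
            raise ValueError("mse must be non-negative")
        if self.ssim > 1 + 1e-12:
            raise ValueError("ssim cannot exceed 1")


def _pair(i1, i2):
    a = np.asarray(i1, dtype=np.float64)
    b = np.asarray(i2, dtype=np.float64)
    if a.shape != b.shape:
        raise ValueError(f"shape mismatch: {a.shape} vs {b.shape}")
    return a, b


def mse(i1, i2) -> float:
    """Mean squared error sum((I1-I2)^2) / (M*N)."""
    a, b = _pair(i1, i2)
    return float(np.mean((a - b) ** 2))


def psnr(i1, i2, max_value: float) -> float:
    """10 log10(MAX^2 / MSE) in dB; identical images give +inf."""
    err = mse(i1, i2)
    if err == 0:
        return float("inf")
    return float(10.0 * np.log10(max_value**2 / err))


def _gaussian_window(size: int, sigma: float) -> np.ndarray:
    r = np.arange(size) - (size - 1) / 2.0
    g = np.exp(-(r**2) / (2 * sigma**2))
    k = np.outer(g, g)
    return k / k.sum()


def ssim(
    i1,
    i2,
    data_range: float | None = None,
    window: int = 7,
    window_sigma: float = 1.5,
    C1: float | None = None,
    C2: float | None = None,
    C3: float | None = None,
    alpha: float = 1.0,
    beta: float = 1.0,
    gamma: float = 1.0,
) -> float:
    """Mean structural similarity over sliding Gaussian windows.

    With the defaults (alpha=beta=gamma=1, C3=C2/2) the simplified
    two-factor index is evaluated; any other exponents or C3 switch to
    the general three-term product.  C1, C2 default to (0.01*R)^2 and
    (0.03*R)^2 with R the data range (max over both images if not given).
    """
    a, b = _pair(i1, i2)
    if window % 2 == 0:
        raise ValueError("window size must be odd")
    if data_range is None:
        data_range = float(max(a.max(), b.max()) - min(a.min(), b.min()))
        if data_range == 0:
            data_range = 1.0
    if C1 is None:
        C1 = (0.01 * data_range) ** 2
    if C2 is None:
        C2 = (0.03 * data_range) ** 2
    simplified = alpha == 1.0 and beta == 1.0 and gamma == 1.0 and C3 is None
    if C3 is None:
        C3 = C2 / 2.0

    w = _gaussian_window(window, window_sigma)
    conv = lambda x: convolve2d(x, w, mode="valid")
    mu1, mu2 = conv(a), conv(b)
    s11 = np.maximum(conv(a * a) - mu1**2, 0.0)
    s22 = np.maximum(conv(b * b) - mu2**2, 0.0)
    s12 = conv(a * b) - mu1 * mu2

    if simplified:
        idx = ((2 * mu1 * mu2 + C1) * (2 * s12 + C2)) / (
            (mu1**2 + mu2**2 + C1) * (s11 + s22 + C2)
        )
    else:
        sd1, sd2 = np.sqrt(s11), np.sqrt(s22)
        lum = (2 * mu1 * mu2 + C1) / (mu1**2 + mu2**2 + C1)
        con = (2 * sd1 * sd2 + C2) / (s11 + s22 + C2)
        stru = (s12 + C3) / (sd1 * sd2 + C3)
        # negative structure terms keep their sign under fractional exponents
        idx = (
            np.sign(lum) * np.abs(lum) ** alpha
            * np.sign(con) * np.abs(con) ** beta
            * np.sign(stru) * np.abs(stru) ** gamma
        )
    return float(idx.mean())
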