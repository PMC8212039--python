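"""Internal helpers to move between ComplexImage lists and (N,2,H,W) arrays."""

from __future__ import annotations

from typing import Sequence

import numpy as np

from .complex_space import ComplexImage, to_channels


def as_batch(images) -> np.ndarray:
    """Coerce ComplexImage / sequence / array into a (N, 2, H, W) float batch."""
    if isinstance(images, ComplexImage):
        return to_channels(images)[None]
    if isinstance(images, np.ndarray):
        if images.ndim == 3 and images.shape[0] == 2:
            return images[None].astype(np.float64)
        if images.ndim == 4 and images.shape[1] == 2:
            return images.astype(np.float64)
        raise ValueError(f"expected (N,2,H,W) or (2,H,W) array, got {images.shape}")
    if isinstance(images, Sequence) and len(images) > 0:
        return np.stack([to_channels(im) for im in images])
    raise ValueError("empty or unrecognized image batch")


def batch_scale(images) -> float:
    """The common scale_applied of a batch (1.0 for bare arrays)."""
    if isinstance(images, ComplexImage):
        return images.scale_applied
    if isinstance(images, Sequence) and images and isinstance(images[0], ComplexImage):
        scales = {im.scale_applied for im in images}
        if len(scales) > 1:
            raise ValueError("training images carry inconsistent scale_applied")
        return scales.pop()
    return 1.0
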