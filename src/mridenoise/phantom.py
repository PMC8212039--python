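"""Synthetic complex-valued MRI phantoms with known ground truth.

Real single-coil knee acquisitions and simulated brain volumes are both
license- or web-gated, so this module generates stand-ins that reproduce
the features the denoisers actually exercise: piecewise-smooth anatomy
built from nested, randomly-perturbed ellipses (Shepp-Logan style), a
smooth non-constant spatial phase (so the complex channels genuinely carry
independent information), and an exactly-zero background region outside
the head ellipse (which is what background sigma estimation relies on).
Phantoms are noise-free by construction and serve as ground truth.
"""

from __future__ import annotations

import hashlib
import json
from dataclasses import asdict, dataclass, field
from pathlib import Path

import numpy as np
from scipy.ndimage import gaussian_filter

from .complex_space import ComplexImage
from .io import write_complex_volume

__all__ = ["PhantomSpec", "generate_phantom_slice", "generate_dataset"]


@dataclass
class PhantomSpec:
    """Parameters of the synthetic anatomy.

    Defaults follow the brain-protocol geometry: 192x192 slices and tissue
    intensities spanning 400-2000 arbitrary signal units, so that additive
    complex Gaussian noise with sigma in {50, 100, 200} produces visibly
    low / medium / high corruption.
    """

    size: int = 192
    n_slices: int = 4
    n_subjects: int = 16
    tissue_count: int = 4
    intensity_range: tuple[float, float] = (400.0, 2000.0)
    phase_smoothness: float = 0.08  # low-pass cutoff, fraction of Nyquist
    background_margin: float = 0.2  # fraction of pixels guaranteed zero
    seed: int = 0

    def __post_init__(self):
        if self.size < 32:
            raise ValueError("size must be >= 32")
        if self.tissue_count < 2:
            raise ValueError("tissue_count must be >= 2")
        if not 0 < self.background_margin < 0.5:
            raise ValueError("background_margin must lie in (0, 0.5)")


def _ellipse_mask(h, w, cy, cx, ay, ax, theta):
    yy, xx = np.mgrid[0:h, 0:w]
    y = yy - cy
    x = xx - cx
    ct, st = np.cos(theta), np.sin(theta)
    yr = y * ct - x * st
    xr = y * st + x * ct
    return (yr / ay) ** 2 + (xr / ax) ** 2 <= 1.0


def _subject_rng(spec: PhantomSpec, subject: int, slice_index: int | None = None):
    key = (spec.seed, 7919 + subject) if slice_index is None else (
        spec.seed,
        7919 + subject,
        104729 + slice_index,
    )
    return np.random.default_rng(np.random.SeedSequence(key))


def generate_phantom_slice(
    spec: PhantomSpec, subject: int, slice_index: int, width: int | None = None
) -> ComplexImage:
    """Deterministic phantom slice for (seed, subject, slice).

    ``width`` overrides the horizontal size to emit a rectangular slice
    (useful for exercising k-space zero padding); by default slices are
    square with side ``spec.size``.
    """
    if not 0 <= subject < spec.n_subjects:
        raise IndexError(f"subject {subject} out of range [0, {spec.n_subjects})")
    if not 0 <= slice_index < spec.n_slices:
        raise IndexError(f"slice {slice_index} out of range [0, {spec.n_slices})")
    h = spec.size
    w = int(width) if width is not None else spec.size
    half = min(h, w) / 2.0

    rng_sub = _subject_rng(spec, subject)
    # head ellipse sized so its area can never exceed 1 - background_margin
    fa_cap = min(0.45, 0.95 * np.sqrt((1.0 - spec.background_margin) / np.pi))
    fa = fa_cap * rng_sub.uniform(0.92, 1.0)
    fb = fa * rng_sub.uniform(0.80, 0.90)
    theta = rng_sub.uniform(-0.26, 0.26)
    cy = h / 2.0 + rng_sub.uniform(-0.02, 0.02) * h
    cx = w / 2.0 + rng_sub.uniform(-0.02, 0.02) * w

    lo, hi = spec.intensity_range
    levels = np.linspace(lo, hi, spec.tissue_count)
    levels = np.clip(levels * rng_sub.uniform(0.97, 1.03, size=levels.shape), lo, hi)

    # through-slice profile: the head shrinks toward the volume ends
    if spec.n_slices > 1:
        z = 2.0 * slice_index / (spec.n_slices - 1) - 1.0
    else:
        z = 0.0
    profile = np.sqrt(max(0.35, 1.0 - 0.6 * z * z))
    ay = fa * 2 * half * profile
    ax = fb * 2 * half * profile

    rng_slc = _subject_rng(spec, subject, slice_index)
    head = _ellipse_mask(h, w, cy, cx, ay, ax, theta)
    mag = np.zeros((h, w))
    mag[head] = levels[0]
    # nested interior tissues, shrinking toward the centre
    for i in range(1, spec.tissue_count):
        shrink = 1.0 - i / (spec.tissue_count + 0.5)
        jit = rng_slc.uniform(0.9, 1.05)
        m = _ellipse_mask(
            h,
            w,
            cy + rng_slc.uniform(-0.03, 0.03) * ay,
            cx + rng_slc.uniform(-0.03, 0.03) * ax,
            ay * shrink * jit,
            ax * shrink * jit,
            theta + rng_slc.uniform(-0.15, 0.15),
        )
        mag[m & head] = levels[i]
    # two small lesion-like inclusions reusing existing tissue intensities
    for _ in range(2):
        m = _ellipse_mask(
            h,
            w,
            cy + rng_slc.uniform(-0.4, 0.4) * ay,
            cx + rng_slc.uniform(-0.4, 0.4) * ax,
            max(2.0, 0.08 * ay * rng_slc.uniform(0.5, 1.5)),
            max(2.0, 0.08 * ax * rng_slc.uniform(0.5, 1.5)),
            rng_slc.uniform(-np.pi, np.pi),
        )
        mag[m & head] = levels[int(rng_slc.integers(0, spec.tissue_count))]

    # soften interior boundaries, keep the background exactly zero
    mag = gaussian_filter(mag, 0.8)
    mag[~head] = 0.0

    # band-limited random phase field (peak ~ pi/2)
    noise = rng_slc.normal(size=(h, w))
    fy = np.fft.fftfreq(h)[:, None]
    fx = np.fft.fftfreq(w)[None, :]
    keep = np.sqrt(fy**2 + fx**2) <= 0.5 * spec.phase_smoothness
    fld = np.real(np.fft.ifft2(np.fft.fft2(noise) * keep))
    peak = np.abs(fld).max()
    phase = (np.pi / 2.0) * fld / peak if peak > 0 else np.zeros_like(fld)

    return ComplexImage(mag * np.exp(1j * phase))


def generate_dataset(spec: PhantomSpec, out_path, n_train: int | None = None) -> dict:
    """Write one HDF5 volume per subject plus a train/test manifest.

    By default the split mirrors the 12-train / 4-test convention
    (3:1 for other subject counts).  Returns the manifest dict; a JSON
    copy is written next to the volumes.
    """
    out = Path(out_path)
    out.mkdir(parents=True, exist_ok=True)
    if n_train is None:
        n_train = max(1, int(round(0.75 * spec.n_subjects)))
    if not 0 < n_train <= spec.n_subjects:
        raise ValueError("n_train out of range")
    subjects = []
    for s in range(spec.n_subjects):
        vol = np.stack(
            [generate_phantom_slice(spec, s, z).data for z in range(spec.n_slices)]
        )
        fname = f"subject_{s:02d}.h5"
        write_complex_volume(out / fname, vol, dataset="image")
        subjects.append(
            {
                "subject": s,
                "file": fname,
                "split": "train" if s < n_train else "test",
                "sha256": hashlib.sha256(np.ascontiguousarray(vol).tobytes()).hexdigest(),
            }
        )
    manifest = {
        "spec": asdict(spec),
        "n_train": n_train,
        "n_test": spec.n_subjects - n_train,
        "subjects": subjects,
    }
    with open(out / "manifest.json", "w") as fh:
        json.dump(manifest, fh, indent=2)
    return manifest
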