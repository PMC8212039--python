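"""Denoiser model container and single-file checkpoints.

A :class:`DenoiserModel` bundles a network with the bookkeeping its
predictions depend on: the serializable architecture descriptor, the input
scale factor the weights were trained under (both training protocols
rescale their data, and applying a model at the wrong scale silently
breaks it), and the noise level it was trained for.

Checkpoints are single ``.npz`` archives: a JSON architecture descriptor,
the ordered weight arrays, and the scalar metadata.  Architectures
register a rebuild function under their descriptor ``kind`` so that
loading dispatches without import cycles.
"""

from __future__ import annotations

import json
import warnings
from dataclasses import dataclass, field
from typing import Callable

import numpy as np

__all__ = ["DenoiserModel", "save_checkpoint", "load_checkpoint", "register_architecture"]

_REGISTRY: dict[str, Callable[[dict], object]] = {}


def register_architecture(kind: str):
    """Class decorator hook: register a descriptor->network rebuild function."""

    def deco(fn):
        _REGISTRY[kind] = fn
        return fn

    return deco


@dataclass
class DenoiserModel:
    """Trained (or untrained) denoiser = network + descriptor + scale context."""

    net: object
    architecture: dict
    train_scale: float = 1.0
    sigma_trained: float = 0.0
    train_stats: dict = field(default_factory=dict)

    def __post_init__(self):
        if not self.train_scale > 0:
            raise ValueError("train_scale must be positive")

    def params(self):
        return self.net.params()

    def check_input_scale(self, scaled_magnitude_median: float) -> None:
        """Warn when an input looks ~100x off the training magnitude scale."""
        ref = self.train_stats.get("median_magnitude")
        if not ref or ref <= 0 or scaled_magnitude_median <= 0:
            return
        ratio = scaled_magnitude_median / ref
        if ratio > 100 or ratio < 0.01:
            warnings.warn(
                f"input magnitude is {ratio:.3g}x the training scale; "
                "did you pass raw-unit data to a scale-trained model?",
                RuntimeWarning,
                stacklevel=3,
            )


def save_checkpoint(model: DenoiserModel, path) -> None:
    arrays = {f"w{i:03d}": p.data for i, p in enumerate(model.params())}
    np.savez(
        path,
        descriptor=json.dumps(model.architecture),
        train_scale=model.train_scale,
        sigma_trained=model.sigma_trained,
        train_stats=json.dumps(model.train_stats),
        **arrays,
    )


def load_checkpoint(path) -> DenoiserModel:
    with np.load(path, allow_pickle=False) as npz:
        descriptor = json.loads(str(npz["descriptor"]))
        kind = descriptor.get("kind")
        if kind not in _REGISTRY:
            raise ValueError(f"unknown architecture kind {kind!r} in checkpoint")
        net = _REGISTRY[kind](descriptor)
        weights = [npz[k] for k in sorted(k for k in npz.files if k.startswith("w"))]
        params = net.params()
        if len(weights) != len(params):
            raise ValueError("checkpoint weight count does not match architecture")
        for p, w in zip(params, weights):
            if p.data.shape != w.shape:
                raise ValueError("checkpoint weight shape mismatch")
            p.data = np.array(w, dtype=np.float64)
        return DenoiserModel(
            net=net,
            architecture=descriptor,
            train_scale=float(npz["train_scale"]),
            sigma_trained=float(npz["sigma_trained"]),
            train_stats=json.loads(str(npz["train_stats"])),
        )
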