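"""Convolutional layers and the Adam optimizer used by both denoisers."""

from __future__ import annotations

import numpy as np

from .autograd import Tensor, conv2d, pad2d

__all__ = ["Conv2dLayer", "Adam"]


class Conv2dLayer:
    """2-D convolution with He-normal init and a named padding policy.

    pad:
      - ``"same"``    zero padding keeping H, W (odd kernels);
      - ``"causal"``  pad top by k-1 and left/right by k//2 only — the
        output at row r then depends on input rows <= r, the building
        block of the half-plane (blindspot) branches;
      - ``"none"``    valid convolution (used for 1x1 fusion layers).
    """

    def __init__(
        self,
        in_channels: int,
        out_channels: int,
        kernel_size: int,
        rng: np.random.Generator,
        pad: str = "same",
    ):
        if pad not in ("same", "causal", "none"):
            raise ValueError(f"unknown padding policy {pad!r}")
        k = int(kernel_size)
        std = np.sqrt(2.0 / (in_channels * k * k))
        self.weight = Tensor(
            rng.normal(0.0, std, size=(out_channels, in_channels, k, k)),
            requires_grad=True,
        )
        self.bias = Tensor(np.zeros(out_channels), requires_grad=True)
        self.pad = pad
        self.kernel_size = k

    def __call__(self, x: Tensor) -> Tensor:
        k = self.kernel_size
        if self.pad == "same":
            x = pad2d(x, k // 2, k // 2, k // 2, k // 2, mode="zero")
        elif self.pad == "causal":
            x = pad2d(x, k - 1, 0, k // 2, k // 2, mode="zero")
        return conv2d(x, self.weight, self.bias)

    def params(self) -> list[Tensor]:
        return [self.weight, self.bias]


class Adam:
    """Adam with a mutable learning rate (for reduce-on-plateau schedules)."""

    def __init__(self, params: list[Tensor], lr: float, betas=(0.9, 0.999), eps: float = 1e-8):
        self.params = list(params)
        self.lr = float(lr)
        self.b1, self.b2 = betas
        self.eps = eps
        self.t = 0
        self.m = [np.zeros_like(p.data) for p in self.params]
        self.v = [np.zeros_like(p.data) for p in self.params]

    def zero_grad(self) -> None:
        for p in self.params:
            p.zero_grad()

    def step(self) -> None:
        self.t += 1
        for i, p in enumerate(self.params):
            g = p.grad
            if g is None:
                continue
            self.m[i] = self.b1 * self.m[i] + (1 - self.b1) * g
            self.v[i] = self.b2 * self.v[i] + (1 - self.b2) * g * g
            mhat = self.m[i] / (1 - self.b1**self.t)
            vhat = self.v[i] / (1 - self.b2**self.t)
            p.data -= self.lr * mhat / (np.sqrt(vhat) + self.eps)
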