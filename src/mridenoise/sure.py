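"""U-Net denoiser trained with the Monte-Carlo SURE loss.

Stein's unbiased risk estimator turns the supervised MSE of a Gaussian
denoising problem into a quantity computable from the *noisy* data alone:

    (1/M) sum_j [ ||y_j - h(y_j)||^2  -  K sigma^2  +  2 sigma^2 div h(y_j) ]

is, in expectation, the true risk (1/M) sum_j ||h(y_j) - x_j||^2 up to a
constant, where K is the number of real scalars per sample (2 per complex
pixel) and sigma the known per-channel noise level.  The divergence is
intractable for a deep network and is replaced by a Monte-Carlo
finite-difference probe with a fresh standard-normal field n~ per sample:

    div h(y) ~= (1/eps) n~ . [ h(y + eps n~) - h(y) ]

Minimising this estimator trains the U-Net without any clean targets.
"""

from __future__ import annotations

from dataclasses import dataclass, replace
from typing import Callable

import numpy as np

from ._batching import as_batch, batch_scale
from .complex_space import ComplexImage, ParameterError, from_channels, to_channels
from .models import DenoiserModel, register_architecture
from .nn import Adam, Conv2dLayer, Tensor, cat, leaky_relu, maxpool2x2, pad2d, upsample2x

__all__ = [
    "SureConfig",
    "SureUNet",
    "build_sure_unet",
    "mse_supervised",
    "mc_sure_loss",
    "train_sure",
    "denoise_sure",
]


@dataclass
class SureConfig:
    """Training protocol for the SURE U-Net.

    Defaults are the full-scale protocol (depth-5 U-Net, 48 feature maps,
    kernel 3, batches of 10 for 300 epochs, Adam at 3e-4); desk-scale runs
    shrink depth/features/epochs.  ``epsilon`` is the Monte-Carlo
    perturbation magnitude *relative* to the batch peak magnitude; the
    absolute step is resolved per batch.  ``sigma`` is the known noise
    standard deviation in the (scaled) units of the training data.
    """

    depth: int = 5
    kernel_size: int = 3
    base_features: int = 48
    batch_size: int = 10
    epochs: int = 300
    learning_rate: float = 3e-4
    epsilon: float = 1e-3
    sigma: float = 0.0
    seed: int = 0

    def __post_init__(self):
        if self.depth < 1:
            raise ParameterError("depth must be >= 1")
        if not self.epsilon > 0:
            raise ParameterError("epsilon must be positive")
        if self.sigma < 0:
            raise ParameterError("sigma must be non-negative")


class SureUNet:
    """Two-channel U-Net: LeakyReLU after every convolution except the last.

    ``depth`` downsampling levels (max-pool 2x2, features doubling per
    level), nearest-neighbour upsampling with a convolution, skip
    connections by channel concatenation, and a linear 1x1 output layer.
    Inputs whose sides are not divisible by 2^depth are reflect-padded and
    the output cropped back.
    """

    def __init__(self, depth: int, kernel_size: int, base_features: int,
                 rng: np.random.Generator, alpha: float = 0.1):
        self.depth = depth
        self.alpha = alpha
        k = kernel_size
        self.enc: list[tuple[Conv2dLayer, Conv2dLayer]] = []
        cin, f = 2, base_features
        for _ in range(depth):
            self.enc.append((Conv2dLayer(cin, f, k, rng), Conv2dLayer(f, f, k, rng)))
            cin, f = f, f * 2
        self.mid = (Conv2dLayer(cin, f, k, rng), Conv2dLayer(f, f, k, rng))
        self.dec: list[tuple[Conv2dLayer, Conv2dLayer, Conv2dLayer]] = []
        fcur = f
        for lev in reversed(range(depth)):
            fskip = base_features * 2**lev
            self.dec.append(
                (
                    Conv2dLayer(fcur, fskip, k, rng),       # after upsampling
                    Conv2dLayer(2 * fskip, fskip, k, rng),  # after skip concat
                    Conv2dLayer(fskip, fskip, k, rng),
                )
            )
            fcur = fskip
        self.out = Conv2dLayer(base_features, 2, 1, rng, pad="none")
        self.descriptor = {
            "kind": "sure_unet",
            "depth": depth,
            "kernel_size": kernel_size,
            "base_features": base_features,
            "alpha": alpha,
            "skip": "concat",
            "down": "maxpool2x2",
            "up": "nearest+conv",
        }

    def params(self) -> list[Tensor]:
        ps: list[Tensor] = []
        for c1, c2 in self.enc:
            ps += c1.params() + c2.params()
        ps += self.mid[0].params() + self.mid[1].params()
        for u, c1, c2 in self.dec:
            ps += u.params() + c1.params() + c2.params()
        ps += self.out.params()
        return ps

    def forward(self, x: Tensor) -> Tensor:
        n, c, h, w = x.shape
        m = 2**self.depth
        ph, pw = (-h) % m, (-w) % m
        if ph or pw:
            x = pad2d(x, ph // 2, ph - ph // 2, pw // 2, pw - pw // 2, mode="reflect")
        a = self.alpha
        skips = []
        for c1, c2 in self.enc:
            x = leaky_relu(c1(x), a)
            x = leaky_relu(c2(x), a)
            skips.append(x)
            x = maxpool2x2(x)
        x = leaky_relu(self.mid[0](x), a)
        x = leaky_relu(self.mid[1](x), a)
        for (up, c1, c2), skip in zip(self.dec, reversed(skips)):
            x = leaky_relu(up(upsample2x(x)), a)
            x = cat([x, skip], axis=1)
            x = leaky_relu(c1(x), a)
            x = leaky_relu(c2(x), a)
        x = self.out(x)  # linear output layer
        if ph or pw:
            x = x[:, :, ph // 2 : ph // 2 + h, pw // 2 : pw // 2 + w]
        return x

    def apply(self, arr: np.ndarray) -> np.ndarray:
        """Forward pass on a bare (N,2,H,W) array, no gradient tape."""
        return self.forward(Tensor(arr)).data


@register_architecture("sure_unet")
def _rebuild_sure_unet(desc: dict) -> SureUNet:
    return SureUNet(
        desc["depth"],
        desc["kernel_size"],
        desc["base_features"],
        np.random.default_rng(0),
        alpha=desc.get("alpha", 0.1),
    )


def build_sure_unet(cfg: SureConfig) -> DenoiserModel:
    """Untrained paper-architecture U-Net wrapped in a DenoiserModel."""
    net = SureUNet(
        cfg.depth, cfg.kernel_size, cfg.base_features, np.random.default_rng(cfg.seed)
    )
    return DenoiserModel(net=net, architecture=net.descriptor, sigma_trained=cfg.sigma)


# -- losses ----------------------------------------------------------------


def mse_supervised(pred, truth) -> float:
    """Oracle batch loss (1/M) sum_j ||pred_j - truth_j||^2 (tests only).

    The norm sums squared differences over both channels and all pixels of
    a sample; the mean runs over the batch.
    """
    p, t = as_batch(pred), as_batch(truth)
    if p.shape != t.shape:
        raise ValueError(f"shape mismatch: {p.shape} vs {t.shape}")
    return float(((p - t) ** 2).sum() / p.shape[0])


def _resolve_forward(model) -> Callable[[np.ndarray], np.ndarray]:
    if isinstance(model, DenoiserModel):
        return model.net.apply
    if callable(model):
        return model
    raise TypeError("model must be a DenoiserModel or a callable array -> array")


def mc_sure_loss(model, y, sigma: float, epsilon: float, seed: int = 0) -> float:
    """Monte-Carlo SURE estimate of the denoising risk of ``model`` on ``y``.

    ``epsilon`` is the absolute perturbation step in the units of ``y``;
    one standard-normal probe field is drawn per sample.  ``model`` may be
    a DenoiserModel or any callable mapping (N,2,H,W) -> (N,2,H,W).
    """
    if sigma < 0:
        raise ParameterError("sigma must be non-negative")
    if not epsilon > 0:
        raise ParameterError("epsilon must be positive (divergence probe undefined)")
    h = _resolve_forward(model)
    yb = as_batch(y)
    m = yb.shape[0]
    k = yb[0].size  # real scalars per sample: 2 per complex pixel
    probe = np.random.default_rng(seed).normal(size=yb.shape)
    hy = h(yb)
    hyp = h(yb + epsilon * probe)
    residual = ((yb - hy) ** 2).sum() / m
    divergence = (probe * (hyp - hy)).sum() / (epsilon * m)
    return float(residual - k * sigma**2 + 2.0 * sigma**2 * divergence)


def _sure_loss_tensor(net, yb: np.ndarray, sigma: float, eps: float,
                      probe: np.ndarray) -> Tensor:
    # Differentiable twin of mc_sure_loss for the training loop.
    m = yb.shape[0]
    k = yb[0].size
    hy = net.forward(Tensor(yb))
    hyp = net.forward(Tensor(yb + eps * probe))
    residual = ((Tensor(yb) - hy) ** 2).sum() * (1.0 / m)
    divergence = (Tensor(probe) * (hyp - hy)).sum() * (1.0 / (eps * m))
    return residual + (-(k * sigma**2)) + (2.0 * sigma**2) * divergence


# -- training / inference --------------------------------------------------


def train_sure(model: DenoiserModel, train_images, cfg: SureConfig):
    """Minimise the MC-SURE loss with Adam; returns (model, per-epoch losses).

    ``train_images`` must already be scaled per protocol (their
    ``scale_applied`` is recorded on the model for inference bookkeeping).
    """
    yb_all = as_batch(train_images)
    model.train_scale = batch_scale(train_images)
    model.sigma_trained = cfg.sigma
    model.train_stats = {
        "median_magnitude": float(
            np.median(np.hypot(yb_all[:, 0], yb_all[:, 1]))
        )
    }
    history: list[float] = []
    if cfg.epochs == 0:
        return model, history
    rng = np.random.default_rng(cfg.seed + 1)
    opt = Adam(model.params(), lr=cfg.learning_rate)
    n = yb_all.shape[0]
    for _ in range(cfg.epochs):
        order = rng.permutation(n)
        epoch_losses = []
        for start in range(0, n, cfg.batch_size):
            yb = yb_all[order[start : start + cfg.batch_size]]
            peak = np.abs(yb).max()
            eps = cfg.epsilon * (peak if peak > 0 else 1.0)
            probe = rng.normal(size=yb.shape)
            opt.zero_grad()
            loss = _sure_loss_tensor(model.net, yb, cfg.sigma, eps, probe)
            if not np.isfinite(loss.data):
                raise RuntimeError(
                    "non-finite MC-SURE loss; the usual cause is an input "
                    "scale factor inconsistent with sigma"
                )
            loss.backward()
            opt.step()
            epoch_losses.append(loss.item())
        history.append(float(np.mean(epoch_losses)))
    return model, history


def denoise_sure(model: DenoiserModel, y: ComplexImage) -> ComplexImage:
    """Single forward pass; scale handled via the model's training scale."""
    factor = model.train_scale / y.scale_applied
    arr = to_channels(y) * factor
    model.check_input_scale(float(np.median(np.hypot(arr[0], arr[1]))))
    out = model.net.apply(arr[None])[0] / factor
    return from_channels(out, scale_applied=y.scale_applied)
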