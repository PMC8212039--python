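"""Blindspot network with Bayesian posterior-mean inference.

A blindspot network predicts each pixel from its surroundings while being
architecturally unable to see the pixel itself.  Trained on noisy data
alone, its natural target is a per-pixel Gaussian *prior* p(x | context):
a mean and a variance per channel.  Because the observation model is also
Gaussian (y = x + n, n ~ N(0, sigma^2) per channel), the posterior over
the clean value is conjugate and its mean has the closed form

    E[x | y, context] = (mu sigma^2 + y var) / (var + sigma^2),

which re-admits the centre pixel at test time — the information the
architecture had to discard during training.

The half-plane construction: one shared stack of "causal" convolutions
(receptive field limited to rows <= r) is applied to the four 90-degree
rotations of the input; a one-pixel downward shift then excludes the
centre row, the branches are counter-rotated and fused with 1x1
convolutions into the mean and variance heads.  The union of four strict
half-planes is everything except the centre pixel.
"""

from __future__ import annotations

from dataclasses import dataclass

import numpy as np

from ._batching import as_batch, batch_scale
from .complex_space import ComplexImage, ParameterError, from_channels, to_channels
from .models import DenoiserModel, register_architecture
from .nn import Adam, Conv2dLayer, Tensor, cat, leaky_relu, log, pad2d, rot90, softplus

__all__ = [
    "BlindspotConfig",
    "GaussianPrior",
    "BlindspotNet",
    "build_blindspot_net",
    "blindspot_train_loss",
    "posterior_mean",
    "train_blindspot",
    "denoise_blindspot",
    "predict_prior",
]

VAR_FLOOR = 1e-8  # scaled units^2; keeps the posterior-mean division finite


@dataclass
class BlindspotConfig:
    """Training protocol for the blindspot network.

    Defaults mirror the full-scale protocol: 5 convolution layers per
    branch, kernel 3, 48 feature maps, batches of 5 for 300 epochs, Adam
    at 3e-4 with the learning rate halved when the validation loss has
    not decreased for ``lr_patience`` epochs.
    """

    depth: int = 5
    kernel_size: int = 3
    base_features: int = 48
    batch_size: int = 5
    epochs: int = 300
    learning_rate: float = 3e-4
    lr_patience: int = 10
    lr_factor: float = 0.5
    sigma: float = 0.0
    seed: int = 0

    def __post_init__(self):
        if self.depth < 1:
            raise ParameterError("depth must be >= 1")
        if self.lr_patience < 1:
            raise ParameterError("lr_patience must be >= 1")
        if self.sigma < 0:
            raise ParameterError("sigma must be non-negative")


@dataclass
class GaussianPrior:
    """Per-pixel Gaussian prior: mean and per-channel variance, (2, H, W)."""

    mu: np.ndarray
    var: np.ndarray

    def __post_init__(self):
        self.mu = np.asarray(self.mu, dtype=np.float64)
        self.var = np.asarray(self.var, dtype=np.float64)
        if self.mu.shape != self.var.shape:
            raise ValueError("mu and var must share a shape")
        if not np.all(self.var > 0):
            raise ValueError("prior variance must be positive everywhere")


class BlindspotNet:
    """Four rotated half-plane branches with shared weights, 1x1 fusion heads.

    Branch convolutions use LeakyReLU; the two 1x1 fusion layers and the
    output map are linear.  The variance head passes through a softplus
    (plus a small floor) to stay positive.
    """

    def __init__(self, depth: int, kernel_size: int, base_features: int,
                 rng: np.random.Generator, alpha: float = 0.1):
        self.depth = depth
        self.alpha = alpha
        k = kernel_size
        self.branch: list[Conv2dLayer] = []
        cin = 2
        for _ in range(depth):
            self.branch.append(Conv2dLayer(cin, base_features, k, rng, pad="causal"))
            cin = base_features
        self.fuse1 = Conv2dLayer(4 * base_features, 2 * base_features, 1, rng, pad="none")
        self.fuse2 = Conv2dLayer(2 * base_features, 4, 1, rng, pad="none")
        self.descriptor = {
            "kind": "blindspot",
            "depth": depth,
            "kernel_size": kernel_size,
            "base_features": base_features,
            "alpha": alpha,
            "branches": "4x rotated shared causal stack, shift 1, linear 1x1 fusion",
            "var_floor": VAR_FLOOR,
        }

    def params(self) -> list[Tensor]:
        ps: list[Tensor] = []
        for c in self.branch:
            ps += c.params()
        return ps + self.fuse1.params() + self.fuse2.params()

    def _run_branch(self, x: Tensor) -> Tensor:
        for conv in self.branch:
            x = leaky_relu(conv(x), self.alpha)
        # shift down one pixel: row r now only sees rows < r
        x = pad2d(x, 1, 0, 0, 0)
        return x[:, :, :-1, :]

    def forward(self, x: Tensor) -> tuple[Tensor, Tensor]:
        outs = []
        for r in range(4):
            b = self._run_branch(rot90(x, r))
            outs.append(rot90(b, -r))
        fused = self.fuse2(self.fuse1(cat(outs, axis=1)))
        mu = fused[:, 0:2]
        var = softplus(fused[:, 2:4]) + VAR_FLOOR
        return mu, var

    def apply(self, arr: np.ndarray) -> tuple[np.ndarray, np.ndarray]:
        mu, var = self.forward(Tensor(arr))
        return mu.data, var.data


@register_architecture("blindspot")
def _rebuild_blindspot(desc: dict) -> BlindspotNet:
    return BlindspotNet(
        desc["depth"],
        desc["kernel_size"],
        desc["base_features"],
        np.random.default_rng(0),
        alpha=desc.get("alpha", 0.1),
    )


def build_blindspot_net(cfg: BlindspotConfig) -> DenoiserModel:
    net = BlindspotNet(
        cfg.depth, cfg.kernel_size, cfg.base_features, np.random.default_rng(cfg.seed)
    )
    return DenoiserModel(net=net, architecture=net.descriptor, sigma_trained=cfg.sigma)


# -- loss and inference ----------------------------------------------------


def blindspot_train_loss(prior: GaussianPrior, y: ComplexImage | np.ndarray,
                         sigma: float) -> float:
    """Negative log-likelihood of y under the predictive marginal N(mu, var+sigma^2).

    Per pixel and channel (constants dropped):
        1/2 log(var + sigma^2) + (y - mu)^2 / (2 (var + sigma^2)).
    """
    if sigma < 0:
        raise ParameterError("sigma must be non-negative")
    yc = to_channels(y) if isinstance(y, ComplexImage) else np.asarray(y, dtype=np.float64)
    if yc.shape != prior.mu.shape:
        raise ValueError(f"shape mismatch: y {yc.shape} vs prior {prior.mu.shape}")
    v = prior.var + sigma**2
    return float(np.mean(0.5 * np.log(v) + (yc - prior.mu) ** 2 / (2.0 * v)))


def _nll_tensor(mu: Tensor, var: Tensor, yb: np.ndarray, sigma: float) -> Tensor:
    v = var + sigma**2
    return (0.5 * log(v) + (Tensor(yb) - mu) ** 2 * (0.5 * v**-1.0)).mean()


def posterior_mean(prior: GaussianPrior, y: ComplexImage, sigma: float) -> ComplexImage:
    """Conjugate-Gaussian posterior mean (mu sigma^2 + y var) / (var + sigma^2).

    sigma = 0 returns y exactly; var -> 0 returns mu (the network fully
    trusted).  The result always lies between mu and y channel-wise.
    """
    if sigma < 0:
        raise ParameterError("sigma must be non-negative")
    yc = to_channels(y)
    if sigma == 0:  # no-noise limit: the observation is trusted exactly
        return from_channels(yc, scale_applied=y.scale_applied)
    post = (prior.mu * sigma**2 + yc * prior.var) / (prior.var + sigma**2)
    return from_channels(post, scale_applied=y.scale_applied)


def predict_prior(model: DenoiserModel, y: ComplexImage) -> GaussianPrior:
    """Network forward pass on one image; prior is in the model's scaled units."""
    factor = model.train_scale / y.scale_applied
    arr = to_channels(y) * factor
    model.check_input_scale(float(np.median(np.hypot(arr[0], arr[1]))))
    mu, var = model.net.apply(arr[None])
    return GaussianPrior(mu[0], var[0])


# -- training --------------------------------------------------------------


def train_blindspot(model: DenoiserModel, train_images, cfg: BlindspotConfig,
                    validation_images=None):
    """Minimise the blindspot NLL; LR is halved on validation plateaus.

    Without an explicit validation set, the last sixth of the training
    images (at least one) is held out to drive the schedule.  Returns
    (model, history) with per-epoch train/validation losses and the LR.
    """
    yb_all = as_batch(train_images)
    model.train_scale = batch_scale(train_images)
    model.sigma_trained = cfg.sigma
    model.train_stats = {
        "median_magnitude": float(np.median(np.hypot(yb_all[:, 0], yb_all[:, 1])))
    }
    if validation_images is None:
        n_val = max(1, yb_all.shape[0] // 6)
        if yb_all.shape[0] <= n_val:
            raise ValueError("need at least two training images to hold out validation")
        vb, yb_all = yb_all[-n_val:], yb_all[:-n_val]
    else:
        vb = as_batch(validation_images)

    history = {"train_loss": [], "val_loss": [], "lr": []}
    if cfg.epochs == 0:
        return model, history
    rng = np.random.default_rng(cfg.seed + 1)
    opt = Adam(model.params(), lr=cfg.learning_rate)
    best_val = np.inf
    since_best = 0
    n = yb_all.shape[0]
    for _ in range(cfg.epochs):
        order = rng.permutation(n)
        epoch_losses = []
        for start in range(0, n, cfg.batch_size):
            yb = yb_all[order[start : start + cfg.batch_size]]
            opt.zero_grad()
            mu, var = model.net.forward(Tensor(yb))
            loss = _nll_tensor(mu, var, yb, cfg.sigma)
            if not np.isfinite(loss.data):
                raise RuntimeError("non-finite blindspot loss; check scale and sigma")
            loss.backward()
            opt.step()
            epoch_losses.append(loss.item())
        mu_v, var_v = model.net.apply(vb)
        val = float(
            np.mean(
                0.5 * np.log(var_v + cfg.sigma**2)
                + (vb - mu_v) ** 2 / (2.0 * (var_v + cfg.sigma**2))
            )
        )
        history["train_loss"].append(float(np.mean(epoch_losses)))
        history["val_loss"].append(val)
        history["lr"].append(opt.lr)
        if val < best_val - 1e-12:
            best_val = val
            since_best = 0
        else:
            since_best += 1
            if since_best >= cfg.lr_patience:
                opt.lr *= cfg.lr_factor
                since_best = 0
    return model, history


def denoise_blindspot(model: DenoiserModel, y: ComplexImage, sigma: float) -> ComplexImage:
    """Prior prediction followed by posterior-mean fusion with the centre pixel.

    ``sigma`` is given in the units of ``y`` (e.g. from
    :func:`~mridenoise.complex_space.estimate_sigma_background`) and is
    converted to the model's training scale internally.
    """
    factor = model.train_scale / y.scale_applied
    prior = predict_prior(model, y)
    y_scaled = ComplexImage(y.data * factor, scale_applied=y.scale_applied * factor)
    post = posterior_mean(prior, y_scaled, sigma * factor)
    return from_channels(to_channels(post) / factor, scale_applied=y.scale_applied)
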