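"""Fully dense U-Net (FD-UNet) and the three learned reconstruction pipelines.

The network is a U-Net whose contracting and expanding paths use densely
connected convolutional blocks: inside a block every 3 x 3 convolution sees
the concatenation of the block input and all previous layer outputs, adding
``growth rate`` feature maps per layer; a 1 x 1 convolution then compresses
the concatenation before the resolution changes.  The growth rate doubles with
each downsampling level from its initial value k1; the compressed feature
count follows f1 at the first level.  Defaults are k1 = 16 and f1 = 128 with
4 levels of 4 dense layers each; the desk-scale preset shrinks these so the
whole pipeline trains in minutes on one CPU core.

Three input pipelines share the architecture:

* Post-DL: input is a time-reversal reconstruction (1 channel); the network is
  trained with residual learning (its output is added to the input), so it
  learns the artifact map.
* Pixel-DL: input is the H x W x N pixel-interpolated volume (N channels, one
  per sensor); direct mapping to the image.
* mDirect-DL: input is the raw sinogram resampled to image dimensions
  (1 channel); direct mapping.
"""

from __future__ import annotations

import copy
from dataclasses import dataclass, field, replace

import numpy as np

from paxel.nn.autograd import Tensor, add, concat, maxpool2x2, mse_loss, relu
from paxel.nn.layers import Adam, BatchNorm2d, Conv2d, ConvTranspose2x2, Module
from paxel.interp import PixelInterpolatedVolume

__all__ = [
    "FDUNetSpec",
    "TrainConfig",
    "TrainedModel",
    "build_fdunet",
    "train",
    "predict_postdl",
    "predict_pixeldl",
    "predict_mdirect",
]

APPROACHES = ("postdl", "pixeldl", "mdirectdl")


@dataclass(frozen=True)
class FDUNetSpec:
    """Architecture hyperparameters.

    in_channels is 1 for Post-DL/mDirect-DL and the sensor count for Pixel-DL;
    growth_rate_init (k1) and features_init (f1) set the dense-block growth
    and compressed width at the top level, both doubling per level.
    """

    in_channels: int = 1
    growth_rate_init: int = 16
    features_init: int = 128
    levels: int = 4
    dense_layers_per_block: int = 4
    out_channels: int = 1
    residual: bool = False

    def __post_init__(self) -> None:
        if self.in_channels < 1 or self.out_channels < 1:
            raise ValueError("channel counts must be >= 1")
        if self.levels < 1 or self.dense_layers_per_block < 1:
            raise ValueError("levels and dense_layers_per_block must be >= 1")

    @classmethod
    def desk(cls, in_channels: int = 1, residual: bool = False) -> "FDUNetSpec":
        """Small CPU-friendly variant used by the desk-scale experiments."""
        return cls(in_channels=in_channels, growth_rate_init=4, features_init=16,
                   levels=2, dense_layers_per_block=2, residual=residual)


@dataclass(frozen=True)
class TrainConfig:
    """Training protocol: Adam on mean squared error.

    Full-scale defaults follow the reference protocol (learning rate 1e-4,
    batches of three images, 40 epochs); the desk preset caps the run for CPU
    experiments.
    """

    learning_rate: float = 1e-4
    batch_size: int = 3
    epochs: int = 40
    seed: int = 0
    scale_preset: str = "full"

    def __post_init__(self) -> None:
        if self.batch_size < 1 or self.epochs < 1:
            raise ValueError("batch_size and epochs must be >= 1")
        if self.scale_preset not in ("full", "desk"):
            raise ValueError("scale_preset must be 'full' or 'desk'")

    @classmethod
    def desk(cls, epochs: int = 10, learning_rate: float = 1e-3, seed: int = 0) -> "TrainConfig":
        return cls(learning_rate=learning_rate, batch_size=3, epochs=epochs,
                   seed=seed, scale_preset="desk")


class _DenseBlock(Module):
    def __init__(self, in_ch: int, growth: int, n_layers: int, rng: np.random.Generator):
        self.bns: list[BatchNorm2d] = []
        self.convs: list[Conv2d] = []
        ch = in_ch
        for _ in range(n_layers):
            self.bns.append(BatchNorm2d(ch))
            self.convs.append(Conv2d(ch, growth, 3, rng))
            ch += growth
        self.out_channels = ch

    def __call__(self, x: Tensor) -> Tensor:
        feats = [x]
        for bn, conv in zip(self.bns, self.convs):
            h = concat(feats) if len(feats) > 1 else feats[0]
            feats.append(conv(relu(bn(h))))
        return concat(feats)


class _Compress(Module):
    """BN-ReLU-1x1 convolution channel compression."""

    def __init__(self, in_ch: int, out_ch: int, rng: np.random.Generator):
        self.bn = BatchNorm2d(in_ch)
        self.conv = Conv2d(in_ch, out_ch, 1, rng)

    def __call__(self, x: Tensor) -> Tensor:
        return self.conv(relu(self.bn(x)))


class FDUNet(Module):
    def __init__(self, spec: FDUNetSpec, seed: int = 0):
        rng = np.random.default_rng(seed)
        self.spec = spec
        k1, f1, L, nd = (spec.growth_rate_init, spec.features_init,
                         spec.levels, spec.dense_layers_per_block)

        # plain stem convolution so the first BN-ReLU never acts on the raw
        # input (pixel-interpolated pressures are bipolar)
        stem_ch = max(f1 // 2, spec.in_channels)
        self.stem = Conv2d(spec.in_channels, stem_ch, 3, rng)

        self.down_blocks: list[_DenseBlock] = []
        self.down_compress: list[_Compress] = []
        ch = stem_ch
        feats = []
        for i in range(L):
            blk = _DenseBlock(ch, k1 * 2 ** i, nd, rng)
            comp = _Compress(blk.out_channels, f1 * 2 ** i, rng)
            self.down_blocks.append(blk)
            self.down_compress.append(comp)
            feats.append(f1 * 2 ** i)
            ch = f1 * 2 ** i

        self.bottom_block = _DenseBlock(ch, k1 * 2 ** L, nd, rng)
        self.bottom_compress = _Compress(self.bottom_block.out_channels, f1 * 2 ** L, rng)
        ch = f1 * 2 ** L

        self.up_convs: list[ConvTranspose2x2] = []
        self.up_blocks: list[_DenseBlock] = []
        self.up_compress: list[_Compress] = []
        for i in range(L - 1, -1, -1):
            fi = f1 * 2 ** i
            self.up_convs.append(ConvTranspose2x2(ch, fi, rng))
            blk = _DenseBlock(2 * fi, k1 * 2 ** i, nd, rng)
            self.up_blocks.append(blk)
            self.up_compress.append(_Compress(blk.out_channels, fi, rng))
            ch = fi

        self.head = Conv2d(ch, spec.out_channels, 1, rng)

    def __call__(self, x: Tensor) -> Tensor:
        skips = []
        h = self.stem(x)
        for blk, comp in zip(self.down_blocks, self.down_compress):
            h = comp(blk(h))
            skips.append(h)
            h = maxpool2x2(h)
        h = self.bottom_compress(self.bottom_block(h))
        for up, blk, comp, skip in zip(self.up_convs, self.up_blocks,
                                       self.up_compress, reversed(skips)):
            h = up(h)
            h = comp(blk(concat([skip, h])))
        out = self.head(h)
        if self.spec.residual:
            out = add(out, x)
        return out


@dataclass
class TrainedModel:
    """FD-UNet with its spec, approach tag and training provenance."""

    spec: FDUNetSpec
    net: FDUNet
    approach: str
    seed: int
    loss_history: list[float] = field(default_factory=list)
    train_config: TrainConfig | None = None

    def n_parameters(self) -> int:
        return sum(p.data.size for p in self.net.parameters())


def build_fdunet(spec: FDUNetSpec, seed: int = 0, approach: str = "pixeldl") -> TrainedModel:
    """Untrained FD-UNet with deterministic seeded initialization.

    Post-DL requires single-channel input with residual learning; the other
    approaches use direct mapping.
    """
    if approach not in APPROACHES:
        raise ValueError(f"approach must be one of {APPROACHES}")
    if approach in ("postdl", "mdirectdl") and spec.in_channels != 1:
        raise ValueError(f"{approach} requires in_channels=1, got {spec.in_channels}")
    if approach == "postdl" and not spec.residual:
        spec = replace(spec, residual=True)
    net = FDUNet(spec, seed=seed)
    return TrainedModel(spec=spec, net=net, approach=approach, seed=seed)


def _check_batch(model: TrainedModel, inputs: np.ndarray) -> np.ndarray:
    inputs = np.asarray(inputs, dtype=np.float32)
    if inputs.ndim != 4 or inputs.shape[1] != model.spec.in_channels:
        raise ValueError(
            f"inputs must be (n, {model.spec.in_channels}, H, W); got {inputs.shape}")
    h, w = inputs.shape[2:]
    if h % 2 ** model.spec.levels or w % 2 ** model.spec.levels:
        raise ValueError("spatial dims must be divisible by 2**levels")
    return inputs


def train(model: TrainedModel, inputs: np.ndarray, targets: np.ndarray,
          cfg: TrainConfig | None = None, log=None) -> TrainedModel:
    """Minimize MSE with Adam; deterministic for a fixed seed and data order.

    inputs: (n, C, H, W); targets: (n, H, W) or (n, 1, H, W) ground truths in
    [0, 1].  Per-epoch mean loss is appended to ``model.loss_history``.  If the
    loss turns non-finite, the parameters roll back to the end of the last
    finite epoch and a numeric failure is raised.
    """
    cfg = cfg or TrainConfig()
    inputs = _check_batch(model, inputs)
    targets = np.asarray(targets, dtype=np.float32)
    if targets.ndim == 3:
        targets = targets[:, None]
    if targets.shape[0] != inputs.shape[0] or targets.shape[2:] != inputs.shape[2:]:
        raise ValueError("targets must pair with inputs and share spatial dims")

    rng = np.random.default_rng(cfg.seed)
    net = model.net
    net.train()
    opt = Adam(net.parameters(), lr=cfg.learning_rate)
    n = inputs.shape[0]
    checkpoint = [p.data.copy() for p in net.parameters()]
    for epoch in range(cfg.epochs):
        order = rng.permutation(n)
        losses = []
        for start in range(0, n, cfg.batch_size):
            idx = order[start:start + cfg.batch_size]
            x = Tensor(inputs[idx])
            out = net(x)
            loss = mse_loss(out, targets[idx])
            if not np.isfinite(loss.data):
                for p, saved in zip(net.parameters(), checkpoint):
                    p.data = saved
                raise ArithmeticError(
                    f"training loss became non-finite in epoch {epoch}; "
                    "parameters rolled back to the last finite epoch")
            opt.zero_grad()
            loss.backward()
            opt.step()
            losses.append(float(loss.data))
        model.loss_history.append(float(np.mean(losses)))
        checkpoint = [p.data.copy() for p in net.parameters()]
        if log is not None:
            log(epoch, model.loss_history[-1])
    net.eval()
    model.train_config = cfg
    return model


def _predict(model: TrainedModel, batch: np.ndarray) -> np.ndarray:
    model.net.eval()
    out = model.net(Tensor(batch)).data[:, 0]
    out = np.clip(out, 0.0, None).astype(np.float64)
    imgs = np.empty_like(out)
    for i, im in enumerate(out):
        m = im.max()
        imgs[i] = im / m if m > 0 else im
    return imgs


def predict_postdl(model: TrainedModel, tr_image: np.ndarray) -> np.ndarray:
    """Artifact-removal pass over a time-reversal image (residual learning)."""
    if model.approach != "postdl":
        raise ValueError(f"model approach is {model.approach!r}, not 'postdl'")
    x = np.asarray(tr_image, dtype=np.float32)[None, None]
    return _predict(model, x)[0]


def predict_pixeldl(model: TrainedModel, volume: PixelInterpolatedVolume | np.ndarray) -> np.ndarray:
    """Direct reconstruction from the H x W x N pixel-interpolated volume."""
    if model.approach != "pixeldl":
        raise ValueError(f"model approach is {model.approach!r}, not 'pixeldl'")
    vol = volume.volume if isinstance(volume, PixelInterpolatedVolume) else np.asarray(volume)
    if vol.ndim != 3 or vol.shape[2] != model.spec.in_channels:
        raise ValueError(
            f"volume must be H x W x {model.spec.in_channels}; got {vol.shape}")
    x = vol.transpose(2, 0, 1)[None].astype(np.float32)
    return _predict(model, x)[0]


def predict_mdirect(model: TrainedModel, resampled: np.ndarray) -> np.ndarray:
    """Direct reconstruction from image-sized resampled sensor data."""
    if model.approach != "mdirectdl":
        raise ValueError(f"model approach is {model.approach!r}, not 'mdirectdl'")
    resampled = np.asarray(resampled, dtype=np.float32)
    if resampled.ndim != 2:
        raise ValueError(f"resampled input must be 2D; got {resampled.shape}")
    return _predict(model, resampled[None, None])[0]
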