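"""Principal and refinement segmentation networks.

The principal network is a 3D encoder-decoder with strided-convolution
downsampling, a multi-scale residual (Res2) bottleneck, attention-gated
skip connections, and a deep-supervision head at half resolution.
Residual units appear only in the bottleneck; all nonlinearities are
ReLU.  The refinement network is a lighter attention U-Net that takes
the image concatenated with the principal network's class probabilities.
"""

from __future__ import annotations

from dataclasses import dataclass
from typing import List, Optional, Tuple

import numpy as np

from .autodiff import Tensor, add, concat, relu, softmax_channels, upsample_nearest
from .layers import (AttentionGate, Conv3d, ConvBlock, InstanceNorm, Module,
                     Res2Block)

__all__ = ["NetworkConfig", "PrincipalNet", "RefinementNet",
           "build_principal", "build_refinement"]


@dataclass(frozen=True)
class NetworkConfig:
    """Shared hyperparameters for both networks."""

    in_channels: int = 1
    num_classes: int = 10
    base_width: int = 8
    depth: int = 3                   # number of strided downsamplings
    res2_scale: int = 4
    deep_supervision: bool = True
    aux_loss_weight: float = 0.4
    seed: int = 0

    def __post_init__(self) -> None:
        if self.depth < 2:
            raise ValueError("depth must be >= 2")
        if self.base_width < self.res2_scale:
            raise ValueError("base width must be >= res2 scale")


def _check_divisible(shape: Tuple[int, ...], depth: int) -> None:
    for n in shape:
        if n % (2 ** depth):
            raise ValueError(
                f"spatial shape {shape} not divisible by 2^{depth}")


class PrincipalNet(Module):
    """Attention U-Net with Res2 bottleneck and deep supervision."""

    def __init__(self, cfg: NetworkConfig):
        rng = np.random.default_rng(cfg.seed)
        self.cfg = cfg
        w = cfg.base_width
        widths = [w * 2 ** i for i in range(cfg.depth)]
        bottleneck_w = w * 2 ** cfg.depth

        self.enc = [ConvBlock(cfg.in_channels, widths[0], rng)]
        self.downs: List[Conv3d] = []
        self.down_norms: List[InstanceNorm] = []
        for i in range(cfg.depth):
            nxt = widths[i + 1] if i + 1 < cfg.depth else bottleneck_w
            self.downs.append(Conv3d(widths[i], nxt, 3, stride=2, rng=rng))
            self.down_norms.append(InstanceNorm(nxt))
            if i + 1 < cfg.depth:
                self.enc.append(ConvBlock(nxt, nxt, rng))
        self.bottleneck = Res2Block(bottleneck_w, cfg.res2_scale, rng)

        self.gates: List[AttentionGate] = []
        self.dec: List[ConvBlock] = []
        up_w = bottleneck_w
        for i in reversed(range(cfg.depth)):
            self.gates.append(AttentionGate(widths[i], up_w,
                                            max(widths[i] // 2, 1), rng))
            self.dec.append(ConvBlock(up_w + widths[i], widths[i], rng))
            up_w = widths[i]
        self.head = Conv3d(widths[0], cfg.num_classes, 1, rng=rng)
        self.aux_head = (Conv3d(widths[1], cfg.num_classes, 1, rng=rng)
                         if cfg.deep_supervision else None)

    def __call__(self, x: Tensor) -> Tuple[Tensor, Optional[Tensor]]:
        """Return (main scores, aux scores at 1/2 resolution or None)."""
        _check_divisible(x.data.shape[1:], self.cfg.depth)
        skips = []
        h = self.enc[0](x)
        for i in range(self.cfg.depth):
            skips.append(h)
            h = relu(self.down_norms[i](self.downs[i](h)))
            if i + 1 < self.cfg.depth:
                h = self.enc[i + 1](h)
        h = self.bottleneck(h)

        aux = None
        for j, i in enumerate(reversed(range(self.cfg.depth))):
            h = upsample_nearest(h)
            gated = self.gates[j](skips[i], h)
            h = self.dec[j](concat([h, gated]))
            if self.aux_head is not None and i == 1:
                aux = self.aux_head(h)
        return self.head(h), aux

    def predict_probs(self, image: np.ndarray) -> np.ndarray:
        """Class probabilities (num_classes, D, H, W) for one image."""
        x = Tensor(image[None] if image.ndim == 3 else image)
        scores, _ = self(x)
        return softmax_channels(scores).data


class RefinementNet(Module):
    """Lightweight attention U-Net refining an initial segmentation.

    Input channels = image (1) + class probabilities of the initial
    segmentation (num_classes).
    """

    def __init__(self, cfg: NetworkConfig):
        if cfg.in_channels != 1 + cfg.num_classes:
            raise ValueError(
                f"refinement expects {1 + cfg.num_classes} input channels "
                f"(image + class probabilities), got {cfg.in_channels}")
        rng = np.random.default_rng(cfg.seed + 1)
        self.cfg = cfg
        w = cfg.base_width
        widths = [w * 2 ** i for i in range(cfg.depth)]
        bottleneck_w = w * 2 ** cfg.depth

        self.stem = ConvBlock(cfg.in_channels, widths[0], rng)
        self.downs = []
        self.down_norms = []
        for i in range(cfg.depth):
            nxt = widths[i + 1] if i + 1 < cfg.depth else bottleneck_w
            self.downs.append(Conv3d(widths[i], nxt, 3, stride=2, rng=rng))
            self.down_norms.append(InstanceNorm(nxt))
        self.gates = []
        self.dec = []
        up_w = bottleneck_w
        for i in reversed(range(cfg.depth)):
            self.gates.append(AttentionGate(widths[i], up_w,
                                            max(widths[i] // 2, 1), rng))
            self.dec.append(ConvBlock(up_w + widths[i], widths[i], rng))
            up_w = widths[i]
        self.head = Conv3d(widths[0], cfg.num_classes, 1, rng=rng)

    def __call__(self, x: Tensor) -> Tensor:
        if x.data.shape[0] != self.cfg.in_channels:
            raise ValueError(
                f"expected {self.cfg.in_channels} channels, got {x.data.shape[0]}")
        _check_divisible(x.data.shape[1:], self.cfg.depth)
        skips = []
        h = self.stem(x)
        for i in range(self.cfg.depth):
            skips.append(h)
            h = relu(self.down_norms[i](self.downs[i](h)))
        for j, i in enumerate(reversed(range(self.cfg.depth))):
            h = upsample_nearest(h)
            gated = self.gates[j](skips[i], h)
            h = self.dec[j](concat([h, gated]))
        return self.head(h)

    def predict_probs(self, image: np.ndarray, probs: np.ndarray) -> np.ndarray:
        x = Tensor(np.concatenate([image[None], probs], axis=0))
        return softmax_channels(self(x)).data


def build_principal(cfg: NetworkConfig) -> PrincipalNet:
    return PrincipalNet(cfg)


def build_refinement(cfg: NetworkConfig) -> RefinementNet:
    return RefinementNet(cfg)
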