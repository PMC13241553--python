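"""Network building blocks: convolutions, attention gates, Res2 bottleneck."""

from __future__ import annotations

from typing import Dict, List

import numpy as np

from .autodiff import (Tensor, add, concat, conv3d, instance_norm, mul, relu,
                       sigmoid, upsample_nearest)

__all__ = ["Module", "Conv3d", "InstanceNorm", "ConvBlock", "AttentionGate",
           "Res2Block"]


class Module:
    """Base class: children discovered by attribute inspection."""

    def parameters(self) -> List[Tensor]:
        params: List[Tensor] = []
        for value in vars(self).values():
            if isinstance(value, Tensor) and value.requires_grad:
                params.append(value)
            elif isinstance(value, Module):
                params.extend(value.parameters())
            elif isinstance(value, (list, tuple)):
                for item in value:
                    if isinstance(item, Module):
                        params.extend(item.parameters())
        return params

    def num_parameters(self) -> int:
        return sum(int(np.prod(p.data.shape)) for p in self.parameters())

    def state_dict(self) -> Dict[str, np.ndarray]:
        return {f"p{i}": p.data.copy() for i, p in enumerate(self.parameters())}

    def load_state_dict(self, state: Dict[str, np.ndarray]) -> None:
        params = self.parameters()
        if len(state) != len(params):
            raise ValueError(
                f"checkpoint has {len(state)} arrays, model expects {len(params)}")
        for i, p in enumerate(params):
            arr = np.asarray(state[f"p{i}"], dtype=np.float32)
            if arr.shape != p.data.shape:
                raise ValueError(
                    f"parameter {i}: checkpoint shape {arr.shape} != "
                    f"model shape {p.data.shape}")
            p.data = arr


class Conv3d(Module):
    """3D convolution with He-normal init and optional bias."""

    def __init__(self, cin: int, cout: int, k: int = 3, stride: int = 1,
                 pad: int | None = None, rng: np.random.Generator | None = None):
        rng = rng or np.random.default_rng(0)
        fan_in = cin * k ** 3
        scale = np.sqrt(2.0 / fan_in)
        self.w = Tensor(rng.normal(0.0, scale, size=(cout, cin, k, k, k)),
                        requires_grad=True)
        self.b = Tensor(np.zeros(cout), requires_grad=True)
        self.stride = stride
        self.pad = k // 2 if pad is None else pad

    def __call__(self, x: Tensor) -> Tensor:
        return conv3d(x, self.w, self.b, stride=self.stride, pad=self.pad)


class InstanceNorm(Module):
    """Learnable per-channel normalization over spatial dimensions."""

    def __init__(self, channels: int):
        self.gamma = Tensor(np.ones(channels), requires_grad=True)
        self.beta = Tensor(np.zeros(channels), requires_grad=True)

    def __call__(self, x: Tensor) -> Tensor:
        return instance_norm(x, self.gamma, self.beta)


class ConvBlock(Module):
    """Conv3x3 + InstanceNorm + ReLU (no residual; residual units live in
    the bottleneck)."""

    def __init__(self, cin: int, cout: int, rng):
        self.conv = Conv3d(cin, cout, 3, rng=rng)
        self.norm = InstanceNorm(cout)

    def __call__(self, x: Tensor) -> Tensor:
        return relu(self.norm(self.conv(x)))


class AttentionGate(Module):
    """Additive attention on a skip connection, gated by the decoder.

    att = sigmoid(psi(relu(Wg g + Wx x))); output = x * att, with att a
    single channel broadcast over the skip features.
    """

    def __init__(self, c_skip: int, c_gate: int, c_inter: int, rng):
        self.wx = Conv3d(c_skip, c_inter, 1, rng=rng)
        self.wg = Conv3d(c_gate, c_inter, 1, rng=rng)
        self.psi = Conv3d(c_inter, 1, 1, rng=rng)
        # start with gates mostly open so gradients reach the encoder early
        self.psi.b.data[:] = 2.0

    def __call__(self, x: Tensor, g: Tensor) -> Tensor:
        att = sigmoid(self.psi(relu(add(self.wx(x), self.wg(g)))))
        return mul(x, att)


class Res2Block(Module):
    """Residual bottleneck with hierarchical multi-scale convolutions.

    Channels are reduced by a 1x1 conv, split into ``scale`` groups; the
    first group passes through, each later group is convolved after
    adding the previous group's output (cascade), widening the receptive
    field.  Groups are re-fused by a 1x1 conv and added to the input.
    """

    def __init__(self, channels: int, scale: int, rng):
        if channels % scale:
            raise ValueError(f"channels {channels} not divisible by scale {scale}")
        self.scale = scale
        width = channels // scale
        self.reduce = Conv3d(channels, channels, 1, rng=rng)
        self.reduce_norm = InstanceNorm(channels)
        self.convs = [Conv3d(width, width, 3, rng=rng)
                      for _ in range(scale - 1)]
        self.fuse = Conv3d(channels, channels, 1, rng=rng)
        self.width = width

    def __call__(self, x: Tensor) -> Tensor:
        h = relu(self.reduce_norm(self.reduce(x)))
        splits = _split_channels(h, self.scale)
        outs = [splits[0]]
        prev = splits[0]
        for i in range(1, self.scale):
            y = relu(self.convs[i - 1](add(splits[i], prev)))
            outs.append(y)
            prev = y
        fused = self.fuse(concat(outs))
        return relu(add(fused, x))


def _split_channels(x: Tensor, n: int) -> List[Tensor]:
    c = x.data.shape[0] // n
    pieces = []
    for i in range(n):
        sl = slice(i * c, (i + 1) * c)
        piece_data = x.data[sl]

        def backward(g, sl=sl, x=x):
            if x.requires_grad:
                full = np.zeros_like(x.data)
                full[sl] = g
                x.accumulate(full)

        pieces.append(Tensor(piece_data, (x,), backward))
    return pieces
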