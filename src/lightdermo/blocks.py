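"""Reusable blocks of the ShuffleNet-Light architecture.

The network composes four ideas: (1) *channel shuffle*, a fixed permutation
interleaving channels across groups so information mixes between grouped
convolutions; (2) *depthwise separable convolution*, a per-channel k x k
spatial convolution followed by a 1 x 1 pointwise convolution, cutting the
dense-convolution parameter cost k*k*Cin*Cout down to k*k*Cin + Cin*Cout;
(3) *squeeze-and-excitation* channel attention, which pools each channel to a
scalar, passes the channel descriptor through a two-layer bottleneck
(GELU inside, sigmoid gate last) and rescales every channel by its gate in
(0, 1); and (4) the composite *shuffle unit* that splits the channels in two
even halves, transforms one half and re-interleaves the concatenation.
"""

from __future__ import annotations

from dataclasses import dataclass

import numpy as np

from . import nn
from ._tensor import Tensor, concat, gelu, sigmoid, take_channels

__all__ = [
    "ConvSpec",
    "DepthwiseSeparableConv",
    "SEBlock",
    "ShuffleUnit",
    "channel_shuffle",
    "conv_param_count",
    "shuffle_permutation",
]


def shuffle_permutation(channels: int, groups: int) -> np.ndarray:
    """Channel-shuffle index map: reshape to (G, N), transpose, flatten.

    Output channel j takes input channel (j mod G) * N + j // G, N = C / G.
    """
    if channels % groups:
        raise ValueError(
            f"channel count C={channels} is not divisible by groups G={groups}"
        )
    n = channels // groups
    return np.arange(channels).reshape(groups, n).T.reshape(-1)


def channel_shuffle(x, groups: int):
    """Apply the shuffle permutation along the channel axis of (B, C, H, W).

    Pure reindexing — channel contents are untouched.  Accepts either a
    plain ndarray or an autograd :class:`Tensor` (the permutation is
    differentiable by inverse reindexing).
    """
    channels = x.shape[1]
    perm = shuffle_permutation(channels, groups)
    if isinstance(x, Tensor):
        return take_channels(x, perm)
    return np.asarray(x)[:, perm]


@dataclass(frozen=True)
class ConvSpec:
    """Static description of one convolution, for parameter accounting."""

    kernel_w: int
    kernel_h: int
    in_channels: int
    out_channels: int
    groups: int = 1
    stride: int = 1
    has_bias: bool = False

    def __post_init__(self):
        if self.kernel_w < 1 or self.kernel_h < 1:
            raise ValueError("kernel dimensions must be >= 1")
        if self.in_channels % self.groups:
            raise ValueError(
                f"in_channels {self.in_channels} not divisible by groups {self.groups}"
            )


def conv_param_count(spec: ConvSpec) -> int:
    """Trainable-weight count of a convolution (normalization excluded).

    kernel_w * kernel_h * (in/groups) * out, plus ``out`` biases when biased;
    the depthwise case (groups == in == out) collapses to k*k*C.
    """
    count = spec.kernel_w * spec.kernel_h * (spec.in_channels // spec.groups) * spec.out_channels
    if spec.has_bias:
        count += spec.out_channels
    return int(count)


class DepthwiseSeparableConv(nn.Module):
    """k x k depthwise convolution followed by a 1 x 1 pointwise convolution.

    Biasless; trainable parameters = k*k*C + C*out_channels.
    """

    def __init__(self, in_channels, out_channels, kernel_size=3, padding=None, rng=None):
        super().__init__()
        if padding is None:
            padding = kernel_size // 2
        self.depthwise = nn.Conv2d(
            in_channels, in_channels, kernel_size,
            padding=padding, groups=in_channels, rng=rng,
        )
        self.pointwise = nn.Conv2d(in_channels, out_channels, 1, rng=rng)

    def forward(self, x):
        return self.pointwise(self.depthwise(x))


class SEBlock(nn.Module):
    """Squeeze-and-excitation channel attention.

    Squeeze: global average pool to one scalar per channel.  Excitation:
    FC(C -> max(1, C // r)) -> GELU -> FC(-> C) -> sigmoid, giving a gate in
    (0, 1) per channel.  Scale: multiply each input channel by its gate.
    """

    def __init__(self, channels: int, reduction: int = 16, rng=None):
        super().__init__()
        self.channels = channels
        self.reduction = reduction
        bottleneck = max(1, channels // reduction)
        self.fc1 = nn.Linear(channels, bottleneck, rng=rng)
        self.fc2 = nn.Linear(bottleneck, channels, rng=rng)

    def forward(self, x):
        if x.shape[1] != self.channels:
            raise ValueError(
                f"SE block built for {self.channels} channels, got {x.shape[1]}"
            )
        squeezed = x.mean(axis=(2, 3))  # (B, C)
        gate = sigmoid(self.fc2(gelu(self.fc1(squeezed))))
        b, c = gate.shape
        return x * gate.reshape(b, c, 1, 1)


class ShuffleUnit(nn.Module):
    """Even channel split; identity half + transform half; concat; shuffle.

    The transform half applies 1x1 conv + BN + ReLU, 3x3 depthwise conv + BN,
    1x1 conv + BN + final activation (GELU by default).  Concatenating the
    halves restores the input width, and a group-2 channel shuffle interleaves
    them so the identity half participates in the next unit's transform.
    Stride is always 1 — downsampling is done by pooling between stages.
    """

    def __init__(self, width: int, use_shuffle: bool = True, activation: str = "gelu",
                 rng=None):
        super().__init__()
        if width % 2:
            raise ValueError(f"shuffle unit width must be even, got {width}")
        self.width = width
        self.use_shuffle = use_shuffle
        half = width // 2
        self.pw1 = nn.Conv2d(half, half, 1, rng=rng)
        self.bn1 = nn.BatchNorm2d(half)
        self.dw = nn.Conv2d(half, half, 3, padding=1, groups=half, rng=rng)
        self.bn2 = nn.BatchNorm2d(half)
        self.pw2 = nn.Conv2d(half, half, 1, rng=rng)
        self.bn3 = nn.BatchNorm2d(half)
        self.act = nn.Activation(activation)
        self._relu = nn.Activation("relu")

    def forward(self, x):
        if x.shape[1] != self.width:
            raise ValueError(f"unit width {self.width}, input has {x.shape[1]} channels")
        half = self.width // 2
        idx = np.arange(self.width)
        identity = take_channels(x, idx[:half]) if isinstance(x, Tensor) else x[:, :half]
        branch = take_channels(x, idx[half:]) if isinstance(x, Tensor) else x[:, half:]
        branch = self._relu(self.bn1(self.pw1(branch)))
        branch = self.bn2(self.dw(branch))
        branch = self.act(self.bn3(self.pw2(branch)))
        out = concat([identity, branch], axis=1)
        if self.use_shuffle:
            out = channel_shuffle(out, 2)
        return out
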