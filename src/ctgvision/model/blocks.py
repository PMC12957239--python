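"""Building blocks: depthwise-separable conv, squeeze-excitation, MBConv, CBAM.

MBConv (mobile inverted bottleneck) expands channels with a 1x1 convolution,
applies a depthwise spatial convolution, recalibrates channels with a
squeeze-and-excitation (SE) gate, projects back with a 1x1 convolution, and
adds the inverted residual Y = X + F(X) when the spatial size and channel
count are preserved.

CBAM (convolutional block attention module) refines a feature map serially:
a channel map Mc = sigma(MLP(AvgPool(F)) + MLP(MaxPool(F))) picks *what* to
emphasize, then a spatial map Ms = sigma(conv7x7([AvgPool; MaxPool] over
channels)) picks *where*: F'' = Ms (x) (Mc (x) F).  Both maps are sigmoid
outputs, so refinement never increases an activation's magnitude.
"""

from __future__ import annotations

from dataclasses import dataclass

import numpy as np

from . import autograd as ag
from .autograd import Tensor
from .layers import (BatchNorm2d, Conv2d, DepthwiseConv2d, Linear, Module,
                     Parameter)


@dataclass
class StageConfig:
    """One backbone stage of repeated MBConv blocks."""

    block_type: str  # "MBConv1" or "MBConv6"
    kernel: int
    stride: int
    out_channels: int
    repeats: int
    expansion: int
    se_reduction: int = 4

    def __post_init__(self) -> None:
        expected = 1 if self.block_type == "MBConv1" else 6
        if self.expansion != expected:
            raise ValueError(
                f"{self.block_type} requires expansion {expected}")
        if self.kernel % 2 == 0:
            raise ValueError("kernel must be odd")


class DepthwiseSeparable(Module):
    """Depthwise spatial convolution followed by a 1x1 pointwise projection.

    Parameter count (no bias): C_in * k^2 + C_in * C_out.
    """

    def __init__(self, in_channels: int, out_channels: int, kernel: int,
                 stride: int = 1, bias: bool = True,
                 rng: np.random.Generator | None = None):
        super().__init__()
        rng = rng or np.random.default_rng(0)
        self.depthwise = DepthwiseConv2d(in_channels, kernel, stride,
                                         bias=bias, rng=rng)
        self.pointwise = Conv2d(in_channels, out_channels, 1, bias=bias,
                                rng=rng)

    def forward(self, x: Tensor) -> Tensor:
        return self.pointwise(self.depthwise(x))


def depthwise_separable(x: Tensor, depthwise_weight: np.ndarray,
                        pointwise_weight: np.ndarray,
                        stride: int = 1) -> Tensor:
    """Functional depthwise-separable convolution with explicit weights.

    ``depthwise_weight`` has shape (C, k, k) with odd k; ``pointwise_weight``
    has shape (C_out, C, 1, 1).
    """
    k = depthwise_weight.shape[-1]
    if k % 2 == 0:
        raise ValueError("kernel size must be odd")
    dw = ag.depthwise_conv2d(x, Tensor(depthwise_weight), None, stride, k // 2)
    return ag.conv2d(dw, Tensor(pointwise_weight), None, 1, 0)


class SqueezeExcite(Module):
    """SE channel gate: Mc = sigma(W2 . ReLU(W1 . GAP(F))), applied
    multiplicatively to F."""

    def __init__(self, channels: int, hidden: int,
                 rng: np.random.Generator | None = None):
        super().__init__()
        if hidden < 1:
            raise ValueError("SE hidden width must be >= 1 "
                             "(reduction too large for the channel count)")
        self.fc1 = Linear(channels, hidden, rng=rng)
        self.fc2 = Linear(hidden, channels, rng=rng)

    def gate(self, x: Tensor) -> Tensor:
        """Channel weights in (0,1), shape (N, C)."""
        z = ag.global_avg_pool(x)
        return ag.sigmoid(self.fc2(ag.relu(self.fc1(z))))

    def forward(self, x: Tensor) -> Tensor:
        n, c = x.shape[0], x.shape[1]
        return x * self.gate(x).reshape(n, c, 1, 1)


def se_gate(F: Tensor, reduction: int,
            rng: np.random.Generator | None = None,
            module: SqueezeExcite | None = None) -> Tensor:
    """Squeeze-and-excitation channel weights for a feature map.

    The hidden width is floor(C / reduction); a reduction so large that the
    hidden width would be zero is rejected.
    """
    c = F.shape[1]
    if module is None:
        module = SqueezeExcite(c, c // reduction, rng=rng)
    return module.gate(F)


class MBConv(Module):
    """Mobile inverted bottleneck block with SE recalibration.

    The skip connection Y = X + F(X) is applied iff stride == 1 and the input
    and output channel counts match.  SE hidden width follows the B0
    convention: max(1, C_in // se_reduction) computed on the *input* channels,
    with the gate acting on the expanded tensor.
    """

    def __init__(self, in_channels: int, out_channels: int, kernel: int,
                 stride: int = 1, expansion: int = 6, se_reduction: int = 4,
                 rng: np.random.Generator | None = None):
        super().__init__()
        rng = rng or np.random.default_rng(0)
        mid = in_channels * expansion
        self.use_skip = stride == 1 and in_channels == out_channels
        self.expand = None
        if expansion != 1:
            self.expand = Conv2d(in_channels, mid, 1, bias=False, rng=rng)
            self.expand_bn = BatchNorm2d(mid)
        self.depthwise = DepthwiseConv2d(mid, kernel, stride, bias=False,
                                         rng=rng)
        self.dw_bn = BatchNorm2d(mid)
        self.se = SqueezeExcite(mid, max(1, in_channels // se_reduction),
                                rng=rng)
        self.project = Conv2d(mid, out_channels, 1, bias=False, rng=rng)
        self.project_bn = BatchNorm2d(out_channels)

    def residual_branch(self, x: Tensor) -> Tensor:
        """F(X): the transformation inside the block, without the skip."""
        h = x
        if self.expand is not None:
            h = ag.silu(self.expand_bn(self.expand(h)))
        h = ag.silu(self.dw_bn(self.depthwise(h)))
        h = self.se(h)
        return self.project_bn(self.project(h))

    def forward(self, x: Tensor) -> Tensor:
        f = self.residual_branch(x)
        return x + f if self.use_skip else f


class ChannelAttention(Module):
    """CBAM channel module: shared two-layer MLP over average- and
    max-pooled descriptors, summed before the sigmoid."""

    def __init__(self, channels: int, reduction: int = 16,
                 rng: np.random.Generator | None = None):
        super().__init__()
        hidden = channels // reduction
        if hidden < 1:
            raise ValueError("reduction too large for the channel count")
        rng = rng or np.random.default_rng(0)
        self.fc1 = Linear(channels, hidden, rng=rng)
        self.fc2 = Linear(hidden, channels, rng=rng)

    def _mlp(self, z: Tensor) -> Tensor:
        return self.fc2(ag.relu(self.fc1(z)))

    def forward(self, F: Tensor) -> Tensor:
        """Channel map Mc, shape (N, C, 1, 1), entries in (0,1)."""
        n, c = F.shape[0], F.shape[1]
        avg = F.mean(axis=(2, 3))
        mx = F.max(axis=(2, 3))
        mc = ag.sigmoid(self._mlp(avg) + self._mlp(mx))
        return mc.reshape(n, c, 1, 1)


class SpatialAttention(Module):
    """CBAM spatial module: 7x7 convolution over the concatenated
    channel-wise average and max maps."""

    def __init__(self, kernel: int = 7, rng: np.random.Generator | None = None):
        super().__init__()
        self.conv = Conv2d(2, 1, kernel, padding=kernel // 2, bias=True,
                           rng=rng or np.random.default_rng(0))

    def forward(self, F: Tensor) -> Tensor:
        """Spatial map Ms, shape (N, 1, H, W), entries in (0,1)."""
        if F.shape[2] < 1 or F.shape[3] < 1:
            raise ValueError("spatial dimensions must be >= 1")
        avg = F.mean(axis=1, keepdims=True)
        mx = F.max(axis=1, keepdims=True)
        return ag.sigmoid(self.conv(ag.concat([avg, mx], axis=1)))


class CBAM(Module):
    """Serial channel-then-spatial attention: F'' = Ms (x) (Mc (x) F)."""

    def __init__(self, channels: int, reduction: int = 16,
                 spatial_kernel: int = 7,
                 rng: np.random.Generator | None = None):
        super().__init__()
        rng = rng or np.random.default_rng(0)
        self.channel = ChannelAttention(channels, reduction, rng=rng)
        self.spatial = SpatialAttention(spatial_kernel, rng=rng)

    def forward(self, F: Tensor) -> Tensor:
        f_prime = F * self.channel(F)
        return f_prime * self.spatial(f_prime)


def cbam_channel(F: Tensor, reduction: int = 16,
                 module: ChannelAttention | None = None,
                 rng: np.random.Generator | None = None) -> Tensor:
    """Channel attention map Mc of shape (N, C, 1, 1)."""
    if module is None:
        module = ChannelAttention(F.shape[1], reduction, rng=rng)
    return module(F)


def cbam_spatial(F_prime: Tensor,
                 module: SpatialAttention | None = None,
                 rng: np.random.Generator | None = None) -> Tensor:
    """Spatial attention map Ms of shape (N, 1, H, W)."""
    if module is None:
        module = SpatialAttention(rng=rng)
    return module(F_prime)


def cbam_apply(F: Tensor, module: CBAM | None = None,
               reduction: int = 16,
               rng: np.random.Generator | None = None) -> Tensor:
    """Two-stage CBAM refinement of a feature map.

    Without an explicit module the reduction is capped at the channel count
    so small feature maps stay valid.
    """
    if module is None:
        module = CBAM(F.shape[1], reduction=min(reduction, F.shape[1]),
                      rng=rng)
    return module(F)
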