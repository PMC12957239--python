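"""CBAM-augmented EfficientNet-B0 classifier for CTG chart inputs.

The backbone follows the canonical B0 schedule: a 3x3 stride-2 stem
(3 -> 32 channels, BN + SiLU), seven MBConv stages with widths
16/24/40/80/112/192/320, repeats 1/2/2/3/3/4/1, kernels 3/3/5/3/5/5/3 and
strides 1/2/2/2/1/2/1, landing at a 320 x 7 x 7 feature map for a 224 x 224
input.  A CBAM block refines that final feature, which is then globally
average-pooled and classified by a fully connected layer (Reassuring vs.
Non-Reassuring).  The canonical 320 -> 1280 1x1 head convolution is off by
default and available behind ``include_top_conv``.

Compound scaling (depth d = alpha^phi, width w = beta^phi, resolution
r = gamma^phi) is exposed both as the standalone :func:`compound_scale` and
as ``width_mult`` / ``depth_mult`` knobs on :func:`build_network`, which is
how the package instantiates CPU-sized variants for smoke experiments.
"""

from __future__ import annotations

import math

import numpy as np

from . import autograd as ag
from .autograd import Tensor
from .blocks import CBAM, MBConv, StageConfig
from .layers import BatchNorm2d, Conv2d, Dropout, Linear, Module

#: Canonical EfficientNet-B0 stage schedule.
B0_STAGES = [
    StageConfig("MBConv1", kernel=3, stride=1, out_channels=16, repeats=1,
                expansion=1),
    StageConfig("MBConv6", kernel=3, stride=2, out_channels=24, repeats=2,
                expansion=6),
    StageConfig("MBConv6", kernel=5, stride=2, out_channels=40, repeats=2,
                expansion=6),
    StageConfig("MBConv6", kernel=3, stride=2, out_channels=80, repeats=3,
                expansion=6),
    StageConfig("MBConv6", kernel=5, stride=1, out_channels=112, repeats=3,
                expansion=6),
    StageConfig("MBConv6", kernel=5, stride=2, out_channels=192, repeats=4,
                expansion=6),
    StageConfig("MBConv6", kernel=3, stride=1, out_channels=320, repeats=1,
                expansion=6),
]

STEM_CHANNELS = 32
TOP_CHANNELS = 1280


def compound_scale(alpha: float, beta: float, gamma: float,
                   phi: float) -> tuple[float, float, float]:
    """Compound scaling coefficients (d, w, r) = (alpha^phi, beta^phi,
    gamma^phi) for network depth, width and input resolution."""
    if alpha <= 0 or beta <= 0 or gamma <= 0:
        raise ValueError("scaling bases must be positive")
    return (alpha ** phi, beta ** phi, gamma ** phi)


def make_divisible(value: float, divisor: int = 8) -> int:
    """Round a scaled channel count to the nearest multiple of ``divisor``
    without dropping more than 10% (the standard width-scaling rule)."""
    new = max(divisor, int(value + divisor / 2) // divisor * divisor)
    if new < 0.9 * value:
        new += divisor
    return new


def scale_stages(stages: list, width_mult: float = 1.0,
                 depth_mult: float = 1.0, divisor: int = 8) -> list:
    scaled = []
    for s in stages:
        scaled.append(StageConfig(
            s.block_type, s.kernel, s.stride,
            make_divisible(s.out_channels * width_mult, divisor),
            max(1, math.ceil(s.repeats * depth_mult)),
            s.expansion, s.se_reduction))
    return scaled


class CbamEfficientNet(Module):
    """EfficientNet-B0 backbone with a CBAM block on its final feature map."""

    def __init__(self, num_classes: int = 2, width_mult: float = 1.0,
                 depth_mult: float = 1.0, input_size: int = 224,
                 include_top_conv: bool = False, dropout: float = 0.2,
                 cbam_reduction: int = 16, seed: int = 0):
        super().__init__()
        rng = np.random.default_rng(seed)
        self.input_size = input_size
        self.stages_cfg = scale_stages(B0_STAGES, width_mult, depth_mult)
        stem_ch = make_divisible(STEM_CHANNELS * width_mult)

        self.stem = Conv2d(3, stem_ch, 3, stride=2, bias=False, rng=rng)
        self.stem_bn = BatchNorm2d(stem_ch)

        self.stages = []
        c_in = stem_ch
        for cfg in self.stages_cfg:
            blocks = []
            for rep in range(cfg.repeats):
                blocks.append(MBConv(
                    c_in, cfg.out_channels, cfg.kernel,
                    stride=cfg.stride if rep == 0 else 1,
                    expansion=cfg.expansion,
                    se_reduction=cfg.se_reduction, rng=rng))
                c_in = cfg.out_channels
            self.stages.append(blocks)

        self.feature_channels = c_in
        self.top_conv = None
        if include_top_conv:
            top_ch = make_divisible(TOP_CHANNELS * width_mult)
            self.top_conv = Conv2d(c_in, top_ch, 1, bias=False, rng=rng)
            self.top_bn = BatchNorm2d(top_ch)
            head_ch = top_ch
        else:
            head_ch = c_in

        reduction = min(cbam_reduction, c_in)
        self.cbam = CBAM(c_in, reduction=reduction, rng=rng)
        self.dropout = Dropout(dropout, seed=seed + 1)
        self.fc = Linear(head_ch, num_classes, rng=rng)

    def _check_input(self, x: Tensor) -> None:
        if x.ndim != 4 or x.shape[1] != 3:
            raise ValueError("input must be (N, 3, H, W)")
        if x.shape[2] != self.input_size or x.shape[3] != self.input_size:
            raise ValueError(
                f"expected {self.input_size}x{self.input_size} input, got "
                f"{x.shape[2]}x{x.shape[3]}")

    def forward_features(self, x: Tensor) -> dict:
        """Forward pass returning tapped intermediate features.

        Taps: ``input`` (the raw tensor), ``stage3``/``stage6`` backbone
        outputs, ``final`` (pre-CBAM feature map), ``refined`` (post-CBAM),
        and ``pooled`` (post-CBAM globally pooled vector).
        """
        self._check_input(x)
        taps = {"input": x}
        h = ag.silu(self.stem_bn(self.stem(x)))
        for i, blocks in enumerate(self.stages, start=1):
            for block in blocks:
                h = block(h)
            if i in (3, 6):
                taps[f"stage{i}"] = h
        taps["final"] = h
        h = self.cbam(h)
        taps["refined"] = h
        if self.top_conv is not None:
            h = ag.silu(self.top_bn(self.top_conv(h)))
        pooled = ag.global_avg_pool(h)
        taps["pooled"] = pooled
        return taps

    def forward(self, x: Tensor) -> Tensor:
        pooled = self.forward_features(x)["pooled"]
        return self.fc(self.dropout(pooled))

    def describe(self) -> list:
        """Stage-by-stage shape ladder for the configured input size."""
        size = self.input_size // 2
        rows = [("stem", self.stem.weight.shape[0], size, size)]
        for i, cfg in enumerate(self.stages_cfg, start=1):
            size = math.ceil(size / cfg.stride)
            rows.append((f"stage{i}:{cfg.block_type}x{cfg.repeats}",
                         cfg.out_channels, size, size))
        rows.append(("cbam", self.feature_channels, size, size))
        rows.append(("pooled", self.fc.weight.shape[0], 1, 1))
        return rows


def build_network(num_classes: int = 2, width_mult: float = 1.0,
                  depth_mult: float = 1.0, input_size: int = 224,
                  include_top_conv: bool = False, dropout: float = 0.2,
                  seed: int = 0) -> CbamEfficientNet:
    """Construct the CBAM-augmented EfficientNet with seeded random init."""
    return CbamEfficientNet(num_classes=num_classes, width_mult=width_mult,
                            depth_mult=depth_mult, input_size=input_size,
                            include_top_conv=include_top_conv,
                            dropout=dropout, seed=seed)
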