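"""Encoder backbones producing a five-level feature pyramid.

Every encoder exposes ``forward(x) -> [F1..F5]`` with feature maps at
strides 2, 4, 8, 16, 32 relative to the input.  Channel schedules:

* plain:            (w, 2w, 4w, 8w, 16w) for base width w
* efficientnet_b0:  (16, 24, 40, 112, 320) — MBConv stages with
  squeeze-and-excitation, taps at the stride boundaries of the B0 schedule
* xception:         (64, 128, 256, 728, 2048) — entry-flow taps, the
  728-wide middle flow, and the exit flow

Encoders are built from a seeded RNG; no pretrained weights are required
(an externally saved state dict can be loaded onto the built model).
"""

from __future__ import annotations

import numpy as np

from .. import nn
from ..nn import functional as F
from ..nn.tensor import Tensor

__all__ = [
    "PlainEncoder",
    "EfficientNetB0Encoder",
    "XceptionEncoder",
    "ENCODER_CHANNELS",
]


class ConvBNAct(nn.Module):
    def __init__(self, cin, cout, k, rng, stride=1, act="relu", groups=1, use_bn=True):
        super().__init__()
        self.conv = nn.Conv2d(
            cin, cout, k, rng, stride=stride, padding=k // 2, groups=groups,
            bias=not use_bn,
        )
        self.bn = nn.BatchNorm2d(cout) if use_bn else nn.Identity()
        self.act = nn.make_activation(act) if act else nn.Identity()

    def forward(self, x):
        return self.act(self.bn(self.conv(x)))


class PlainEncoder(nn.Module):
    """Doubling-channel convolutional encoder (the U-Net contracting path)."""

    def __init__(self, in_channels, base_width, rng, act="relu", use_bn=True):
        super().__init__()
        self.channels = tuple(base_width * 2**i for i in range(5))
        self.levels = nn.ModuleList()
        cin = in_channels
        for cout in self.channels:
            self.levels.append(
                nn.Sequential(
                    [
                        nn.MaxPool2x(),
                        ConvBNAct(cin, cout, 3, rng, act=act, use_bn=use_bn),
                        ConvBNAct(cout, cout, 3, rng, act=act, use_bn=use_bn),
                    ]
                )
            )
            cin = cout

    def forward(self, x: Tensor) -> list[Tensor]:
        feats = []
        for level in self.levels:
            x = level(x)
            feats.append(x)
        return feats


class SqueezeExcite(nn.Module):
    """Channel attention: global pool -> bottleneck MLP -> sigmoid gate."""

    def __init__(self, channels, squeezed, rng, act="relu"):
        super().__init__()
        self.reduce = nn.Conv2d(channels, squeezed, 1, rng, bias=True)
        self.act = nn.make_activation(act)
        self.expand = nn.Conv2d(squeezed, channels, 1, rng, bias=True)

    def forward(self, x):
        s = F.global_avg_pool(x)
        s = self.expand(self.act(self.reduce(s))).sigmoid()
        return x * s


class MBConv(nn.Module):
    """Inverted-bottleneck depthwise block (MobileNetV2/EfficientNet unit)."""

    def __init__(self, cin, cout, k, stride, expand, rng, act="swish"):
        super().__init__()
        mid = cin * expand
        self.expand_conv = (
            ConvBNAct(cin, mid, 1, rng, act=act) if expand != 1 else nn.Identity()
        )
        self.dw = ConvBNAct(mid, mid, k, rng, stride=stride, act=act, groups=mid)
        self.se = SqueezeExcite(mid, max(1, cin // 4), rng, act=act)
        self.project = ConvBNAct(mid, cout, 1, rng, act=None)
        self.residual = stride == 1 and cin == cout

    def forward(self, x):
        out = self.project(self.se(self.dw(self.expand_conv(x))))
        return out + x if self.residual else out


# (expand, channels, repeats, first-stride, kernel) for each B0 stage
_B0_STAGES = [
    (1, 16, 1, 1, 3),
    (6, 24, 2, 2, 3),
    (6, 40, 2, 2, 5),
    (6, 80, 3, 2, 3),
    (6, 112, 3, 1, 5),
    (6, 192, 4, 2, 5),
    (6, 320, 1, 1, 3),
]


class EfficientNetB0Encoder(nn.Module):
    """EfficientNet-B0 trunk; taps after stages 1, 2, 3, 5 and 7."""

    channels = (16, 24, 40, 112, 320)
    _tap_after = {0, 1, 2, 4, 6}

    def __init__(self, in_channels, rng, act="swish"):
        super().__init__()
        self.stem = ConvBNAct(in_channels, 32, 3, rng, stride=2, act=act)
        self.stages = nn.ModuleList()
        cin = 32
        for expand, cout, repeats, stride, k in _B0_STAGES:
            blocks = nn.Sequential(
                [
                    MBConv(
                        cin if r == 0 else cout,
                        cout,
                        k,
                        stride if r == 0 else 1,
                        expand,
                        rng,
                        act=act,
                    )
                    for r in range(repeats)
                ]
            )
            self.stages.append(blocks)
            cin = cout

    def forward(self, x: Tensor) -> list[Tensor]:
        x = self.stem(x)
        feats = []
        for i, stage in enumerate(self.stages):
            x = stage(x)
            if i in self._tap_after:
                feats.append(x)
        return feats


class SeparableConv(nn.Module):
    """Depthwise 3x3 + pointwise 1x1, each batch-normalised."""

    def __init__(self, cin, cout, rng, act="relu", final_act=True):
        super().__init__()
        self.dw = ConvBNAct(cin, cin, 3, rng, act=None, groups=cin)
        self.pw = ConvBNAct(cin, cout, 1, rng, act=act if final_act else None)

    def forward(self, x):
        return self.pw(self.dw(x))


class XceptionBlock(nn.Module):
    """Two/three separable convs with a strided 1x1 residual shortcut."""

    def __init__(self, cin, cout, rng, act="relu", downsample=True, repeats=2):
        super().__init__()
        self.convs = nn.Sequential(
            [
                SeparableConv(cin if r == 0 else cout, cout, rng, act=act)
                for r in range(repeats)
            ]
        )
        self.pool = nn.MaxPool2x() if downsample else nn.Identity()
        if downsample or cin != cout:
            self.skip = nn.Conv2d(cin, cout, 1, rng, stride=2 if downsample else 1,
                                  bias=False)
            self.skip_bn = nn.BatchNorm2d(cout)
        else:
            self.skip = None

    def forward(self, x):
        out = self.pool(self.convs(x))
        if self.skip is not None:
            return out + self.skip_bn(self.skip(x))
        return out + x


class XceptionEncoder(nn.Module):
    """Xception trunk: entry flow, 8-block middle flow, exit flow."""

    channels = (64, 128, 256, 728, 2048)

    def __init__(self, in_channels, rng, act="relu"):
        super().__init__()
        self.stem = nn.Sequential(
            [
                ConvBNAct(in_channels, 32, 3, rng, stride=2, act=act),
                ConvBNAct(32, 64, 3, rng, act=act),
            ]
        )
        self.entry2 = XceptionBlock(64, 128, rng, act=act)
        self.entry3 = XceptionBlock(128, 256, rng, act=act)
        self.entry4 = XceptionBlock(256, 728, rng, act=act)
        self.middle = nn.Sequential(
            [
                XceptionBlock(728, 728, rng, act=act, downsample=False, repeats=3)
                for _ in range(8)
            ]
        )
        self.exit_block = XceptionBlock(728, 1024, rng, act=act)
        self.exit_tail = nn.Sequential(
            [
                SeparableConv(1024, 1536, rng, act=act),
                SeparableConv(1536, 2048, rng, act=act),
            ]
        )

    def forward(self, x: Tensor) -> list[Tensor]:
        f1 = self.stem(x)
        f2 = self.entry2(f1)
        f3 = self.entry3(f2)
        f4 = self.middle(self.entry4(f3))
        f5 = self.exit_tail(self.exit_block(f4))
        return [f1, f2, f3, f4, f5]


ENCODER_CHANNELS = {
    "efficientnet_b0": EfficientNetB0Encoder.channels,
    "xception": XceptionEncoder.channels,
}
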