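"""Decoders: classic U-Net, dense UNet++, and the pruned ("improved") UNet++.

The UNet++ decoder is a triangular grid of nodes X(i, j): row i lives at the
resolution of encoder level i, column j counts refinement steps.  X(i, 0)
are the encoder taps.  For j >= 1:

* **dense** wiring — X(i, j) receives *all* same-row predecessors
  X(i, 0..j-1) plus the 2x-upsampled X(i+1, j-1);
* **improved** wiring — only the immediate predecessor X(i, j-1) plus the
  upsampled X(i+1, j-1).  Pruning the dense skips shrinks every node's input
  and hence the parameter count, while keeping the deep-to-shallow gradient
  path.

Each node is [conv3x3 -> (BN) -> activation] x 2 followed by spatial
dropout; upsampling inside the UNet++ grid is bilinear.  The classic U-Net
decoder uses kernel-2 stride-2 transposed convolutions instead.
"""

from __future__ import annotations

from .. import nn
from ..nn import functional as F
from ..nn.tensor import Tensor
from .encoders import ConvBNAct

__all__ = ["UNetDecoder", "UNetPPDecoder"]


class NodeBlock(nn.Module):
    """[conv3x3 -> BN -> act] x 2 + spatial dropout — one decoder node."""

    def __init__(self, cin, cout, rng, act="relu", use_bn=True, dropout=0.0):
        super().__init__()
        self.block = nn.Sequential(
            [
                ConvBNAct(cin, cout, 3, rng, act=act, use_bn=use_bn),
                ConvBNAct(cout, cout, 3, rng, act=act, use_bn=use_bn),
                nn.Dropout2d(dropout),
            ]
        )

    def forward(self, x):
        return self.block(x)


class UNetDecoder(nn.Module):
    """Classic expanding path: transposed-conv up, concat skip, double conv."""

    def __init__(self, enc_channels, widths, rng, act="relu", use_bn=True,
                 dropout=0.0, out_channels=1):
        super().__init__()
        self.ups = nn.ModuleList()
        self.nodes = nn.ModuleList()
        cin = enc_channels[4]
        for i in range(3, -1, -1):
            self.ups.append(nn.ConvTranspose2x(cin, widths[i], rng))
            self.nodes.append(
                NodeBlock(widths[i] + enc_channels[i], widths[i], rng, act,
                          use_bn, dropout)
            )
            cin = widths[i]
        self.final_up = nn.ConvTranspose2x(widths[0], widths[0], rng)
        self.head = nn.Conv2d(widths[0], out_channels, 1, rng, bias=True)

    def forward(self, feats: list[Tensor]) -> list[Tensor]:
        x = feats[4]
        for step, (up, node) in enumerate(zip(self.ups, self.nodes)):
            skip = feats[3 - step]
            x = node(F.concat_channels([skip, up(x)]))
        return [self.head(self.final_up(x))]


class UNetPPDecoder(nn.Module):
    """Nested-grid decoder, dense or pruned wiring, optional deep supervision."""

    def __init__(self, enc_channels, widths, rng, dense, act="relu", use_bn=True,
                 dropout=0.0, out_channels=1, deep_supervision=False):
        super().__init__()
        self.dense = dense
        self.deep_supervision = deep_supervision
        self.nodes = nn.ModuleList()  # flat, indexed via self._index
        self._index: dict[tuple[int, int], int] = {}
        ch = {(i, 0): enc_channels[i] for i in range(5)}
        for j in range(1, 5):
            for i in range(0, 5 - j):
                if dense:
                    cin = sum(ch[(i, m)] for m in range(j)) + ch[(i + 1, j - 1)]
                else:
                    cin = ch[(i, j - 1)] + ch[(i + 1, j - 1)]
                self._index[(i, j)] = len(self.nodes)
                self.nodes.append(NodeBlock(cin, widths[i], rng, act, use_bn, dropout))
                ch[(i, j)] = widths[i]
        n_heads = 4 if deep_supervision else 1
        self.heads = nn.ModuleList(
            [nn.Conv2d(widths[0], out_channels, 1, rng, bias=True)
             for _ in range(n_heads)]
        )

    def node_in_channels(self, i: int, j: int, enc_channels, widths) -> int:
        """Input channel count of node X(i, j) under this wiring."""
        ch0 = enc_channels[i]
        up = widths[i + 1] if j > 1 else enc_channels[i + 1]
        if self.dense:
            return ch0 + (j - 1) * widths[i] + up
        return (widths[i] if j > 1 else ch0) + up

    def forward(self, feats: list[Tensor]) -> list[Tensor]:
        x: dict[tuple[int, int], Tensor] = {(i, 0): feats[i] for i in range(5)}
        for j in range(1, 5):
            for i in range(0, 5 - j):
                below = F.upsample_bilinear2x(x[(i + 1, j - 1)])
                if self.dense:
                    inputs = [x[(i, m)] for m in range(j)] + [below]
                else:
                    inputs = [x[(i, j - 1)], below]
                x[(i, j)] = self.nodes[self._index[(i, j)]](
                    F.concat_channels(inputs)
                )
        if self.deep_supervision:
            return [head(x[(0, j)]) for j, head in zip(range(1, 5), self.heads)]
        return [self.heads[0](x[(0, 4)])]
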