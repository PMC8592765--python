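"""Model zoo: declarative specs, builders, and parameter counting.

``ModelSpec`` describes an architecture instance (encoder, decoder wiring,
widths, activation, regularisation); ``build_model`` turns it into a
runnable :class:`SegmentationModel` deterministically from a seed.  The
pinned ``EFFICIENT_UNETPP`` configuration is the package's headline model:
EfficientNet-B0 encoder, pruned-skip UNet++ decoder, widths
(16, 32, 64, 128, 256), batch norm, ReLU, single head.
"""

from __future__ import annotations

from dataclasses import dataclass

import numpy as np

from .. import nn
from ..errors import ConfigError, ValidationError
from ..nn import functional as F
from ..nn.tensor import Tensor
from .decoders import UNetDecoder, UNetPPDecoder
from .encoders import (
    ENCODER_CHANNELS,
    EfficientNetB0Encoder,
    PlainEncoder,
    XceptionEncoder,
)

__all__ = [
    "ModelSpec",
    "FeaturePyramid",
    "SegmentationModel",
    "build_model",
    "encoder_features",
    "count_trainable_parameters",
    "EFFICIENT_UNETPP",
    "XCEPTION_UNETPP",
]

_ARCHITECTURES = ("unet", "unetpp_dense", "unetpp_improved")
_ENCODERS = ("plain", "efficientnet_b0", "xception")


@dataclass(frozen=True)
class ModelSpec:
    architecture: str = "unetpp_improved"
    encoder: str = "efficientnet_b0"
    encoder_pretrained: bool = False
    decoder_widths: tuple[int, ...] = (16, 32, 64, 128, 256)  # shallow -> deep
    base_width: int = 32  # plain encoder only
    activation: str = "relu"
    dropout_rate: float = 0.2
    batch_norm: bool = True
    deep_supervision: bool = False
    in_channels: int = 3
    out_channels: int = 1

    def __post_init__(self):
        if self.architecture not in _ARCHITECTURES:
            raise ConfigError(
                f"unknown architecture {self.architecture!r}; choose from {_ARCHITECTURES}"
            )
        if self.encoder not in _ENCODERS:
            raise ConfigError(
                f"unknown encoder {self.encoder!r}; choose from {_ENCODERS}"
            )
        if self.activation not in nn.ACTIVATIONS:
            raise ConfigError(
                f"unknown activation {self.activation!r}; choose from {sorted(nn.ACTIVATIONS)}"
            )
        if len(self.decoder_widths) != 5 or any(w <= 0 for w in self.decoder_widths):
            raise ConfigError(
                f"decoder_widths must be 5 positive integers, got {self.decoder_widths}"
            )
        if not 0.0 <= self.dropout_rate < 1.0:
            raise ConfigError(f"dropout_rate must be in [0, 1), got {self.dropout_rate}")
        if self.base_width < 1 or self.in_channels < 1 or self.out_channels < 1:
            raise ConfigError("widths and channel counts must be positive")


@dataclass
class FeaturePyramid:
    """Five feature maps at strides 2..32 with their channel counts."""

    features: list[np.ndarray]
    channels: tuple[int, ...]
    strides: tuple[int, ...] = (2, 4, 8, 16, 32)

    def __post_init__(self):
        if len(self.features) != 5:
            raise ValidationError("a feature pyramid has exactly five levels")
        for a, b in zip(self.features, self.features[1:]):
            if a.shape[2] != 2 * b.shape[2] or a.shape[3] != 2 * b.shape[3]:
                raise ValidationError(
                    f"spatial dims must halve per level, got {a.shape} -> {b.shape}"
                )


class SegmentationModel(nn.Module):
    """Encoder + decoder; maps (N, C, H, W) inputs to same-size logits.

    The sigmoid is applied only at prediction time (``predict_proba``),
    never inside the forward map.
    """

    def __init__(self, spec: ModelSpec, encoder, decoder, logits_at_input_res: bool):
        super().__init__()
        self.spec = spec
        self.encoder = encoder
        self.decoder = decoder
        self._full_res = logits_at_input_res

    def _check_input(self, x: Tensor):
        n, c, h, w = x.shape
        if c != self.spec.in_channels:
            raise ValidationError(
                f"expected {self.spec.in_channels} input channels, got {c}"
            )
        if h % 32 or w % 32:
            raise ValidationError(
                f"input spatial dims must be multiples of 32 (encoder stride "
                f"budget), got {h}x{w}"
            )

    def forward_heads(self, x: Tensor) -> list[Tensor]:
        self._check_input(x)
        heads = self.decoder(self.encoder(x))
        if not self._full_res:
            heads = [F.upsample_bilinear2x(h) for h in heads]
        return heads

    def forward(self, x: Tensor) -> Tensor:
        return self.forward_heads(x)[-1]

    def predict_proba(self, images: np.ndarray) -> np.ndarray:
        """Eval-mode forward + sigmoid on a (N, C, H, W) float batch."""
        was_training = self.training
        self.eval()
        try:
            logits = self.forward(Tensor(np.asarray(images, np.float32)))
        finally:
            self.train(was_training)
        return 1.0 / (1.0 + np.exp(-np.clip(logits.data, -60.0, 60.0)))


def build_model(spec: ModelSpec, seed: int = 0) -> SegmentationModel:
    """Deterministically instantiate the model described by ``spec``."""
    rng = np.random.default_rng([seed, 0x5E6])
    act = spec.activation
    if spec.encoder == "plain":
        encoder = PlainEncoder(
            spec.in_channels, spec.base_width, rng, act=act, use_bn=spec.batch_norm
        )
        enc_channels = encoder.channels
    elif spec.encoder == "efficientnet_b0":
        encoder = EfficientNetB0Encoder(spec.in_channels, rng, act=act)
        enc_channels = encoder.channels
    else:
        encoder = XceptionEncoder(spec.in_channels, rng, act=act)
        enc_channels = encoder.channels

    if spec.architecture == "unet":
        decoder = UNetDecoder(
            enc_channels,
            spec.decoder_widths,
            rng,
            act=act,
            use_bn=spec.batch_norm,
            dropout=spec.dropout_rate,
            out_channels=spec.out_channels,
        )
        full_res = True
    else:
        decoder = UNetPPDecoder(
            enc_channels,
            spec.decoder_widths,
            rng,
            dense=spec.architecture == "unetpp_dense",
            act=act,
            use_bn=spec.batch_norm,
            dropout=spec.dropout_rate,
            out_channels=spec.out_channels,
            deep_supervision=spec.deep_supervision,
        )
        full_res = False
    return SegmentationModel(spec, encoder, decoder, full_res)


def encoder_features(model: SegmentationModel, batch: np.ndarray) -> FeaturePyramid:
    """Run the encoder alone and return the five-level pyramid."""
    x = Tensor(np.asarray(batch, np.float32))
    model._check_input(x)
    feats = [f.data for f in model.encoder(x)]
    return FeaturePyramid(feats, tuple(f.shape[1] for f in feats))


def count_trainable_parameters(model: nn.Module) -> int:
    """Total element count over all trainable tensors (conv weights, biases,
    batch-norm affine pairs); running statistics are buffers and excluded."""
    return int(sum(p.data.size for p in model.parameters()))


# Pinned headline configurations
EFFICIENT_UNETPP = ModelSpec(
    architecture="unetpp_improved",
    encoder="efficientnet_b0",
    decoder_widths=(16, 32, 64, 128, 256),
)
XCEPTION_UNETPP = ModelSpec(
    architecture="unetpp_improved",
    encoder="xception",
    decoder_widths=(16, 32, 64, 128, 256),
)
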