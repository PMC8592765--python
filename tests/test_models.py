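"""Architecture contracts: shapes, pyramids, wiring arithmetic, param counts."""

import dataclasses

import numpy as np
import pytest

from dermseg import nn
from dermseg.errors import ConfigError, ValidationError
from dermseg.models import (
    EFFICIENT_UNETPP,
    ModelSpec,
    build_model,
    count_trainable_parameters,
    encoder_features,
)
from dermseg.nn.tensor import Tensor

SMALL_WIDTHS = (8, 16, 24, 32, 48)


def _small_spec(arch, encoder, **kw):
    return ModelSpec(
        architecture=arch,
        encoder=encoder,
        decoder_widths=SMALL_WIDTHS,
        base_width=8,
        dropout_rate=0.0,
        **kw,
    )


class TestShapeContracts:
    @pytest.mark.parametrize("arch", ["unet", "unetpp_dense", "unetpp_improved"])
    @pytest.mark.parametrize("encoder", ["plain", "efficientnet_b0"])
    @pytest.mark.parametrize("size", [64, 96])
    def test_output_matches_input_resolution(self, arch, encoder, size):
        model = build_model(_small_spec(arch, encoder), seed=0).eval()
        x = Tensor(np.zeros((1, 3, size, size), np.float32))
        assert model(x).shape == (1, 1, size, size)

    def test_xception_shape_contract(self):
        model = build_model(_small_spec("unetpp_improved", "xception"), seed=0).eval()
        x = Tensor(np.zeros((1, 3, 64, 64), np.float32))
        assert model(x).shape == (1, 1, 64, 64)

    def test_non_multiple_of_32_rejected(self):
        model = build_model(_small_spec("unet", "plain"), seed=0)
        with pytest.raises(ValidationError, match="32"):
            model(Tensor(np.zeros((1, 3, 50, 50), np.float32)))

    def test_rectangular_input_supported(self):
        model = build_model(_small_spec("unetpp_improved", "plain"), seed=0).eval()
        x = Tensor(np.zeros((1, 3, 64, 96), np.float32))
        assert model(x).shape == (1, 1, 64, 96)


class TestFeaturePyramid:
    def test_b0_strides_and_channels_at_256(self):
        model = build_model(_small_spec("unetpp_improved", "efficientnet_b0"), seed=0).eval()
        fp = encoder_features(model, np.zeros((1, 3, 256, 256), np.float32))
        assert fp.channels == (16, 24, 40, 112, 320)
        assert [f.shape[2] for f in fp.features] == [128, 64, 32, 16, 8]
        assert fp.strides == (2, 4, 8, 16, 32)

    def test_plain_encoder_doubling_rule(self):
        model = build_model(_small_spec("unet", "plain"), seed=0).eval()
        fp = encoder_features(model, np.zeros((1, 3, 64, 64), np.float32))
        assert fp.channels == (8, 16, 32, 64, 128)

    def test_xception_channels(self):
        model = build_model(_small_spec("unet", "xception"), seed=0).eval()
        fp = encoder_features(model, np.zeros((1, 3, 64, 64), np.float32))
        assert fp.channels == (64, 128, 256, 728, 2048)


class TestDecoderWiring:
    def test_node_input_channel_arithmetic(self):
        """X(0,4): dense concatenates all four same-row predecessors, the
        pruned decoder only the immediate one (enc tap w0=16 here equals the
        row width, matching the 4*w0 + up vs w0 + up accounting)."""
        dense = build_model(EFFICIENT_UNETPP_DENSE, seed=0).decoder
        improved = build_model(EFFICIENT_UNETPP, seed=0).decoder
        enc, w = (16, 24, 40, 112, 320), EFFICIENT_UNETPP.decoder_widths
        assert dense.node_in_channels(0, 4, enc, w) == 4 * 16 + w[1]
        assert improved.node_in_channels(0, 4, enc, w) == 16 + w[1]

    def test_first_column_identical_between_wirings(self):
        enc, w = (16, 24, 40, 112, 320), SMALL_WIDTHS
        dense = build_model(_small_spec("unetpp_dense", "efficientnet_b0"), seed=0).decoder
        improved = build_model(_small_spec("unetpp_improved", "efficientnet_b0"), seed=0).decoder
        for i in range(4):
            assert dense.node_in_channels(i, 1, enc, w) == improved.node_in_channels(i, 1, enc, w)

    def test_deep_supervision_heads_and_loss_heads(self):
        spec = dataclasses.replace(
            _small_spec("unetpp_improved", "plain"), deep_supervision=True
        )
        model = build_model(spec, seed=0).eval()
        heads = model.forward_heads(Tensor(np.zeros((1, 3, 64, 64), np.float32)))
        assert len(heads) == 4
        assert all(h.shape == (1, 1, 64, 64) for h in heads)


class TestParameterCounting:
    def test_lone_conv_and_batchnorm_counts(self, rng):
        conv = nn.Conv2d(3, 8, 3, rng, bias=True)
        assert count_trainable_parameters(conv) == 3 * 8 * 9 + 8 == 224
        bn = nn.BatchNorm2d(8)
        assert count_trainable_parameters(bn) == 16  # scale + shift per channel

    def test_running_stats_are_not_trainable(self):
        bn = nn.BatchNorm2d(4)
        names = [n for n, _ in bn.named_parameters()]
        assert set(names) == {"gamma", "beta"}

    def test_improved_strictly_below_dense_at_equal_spec(self):
        for encoder in ("plain", "efficientnet_b0"):
            n_dense = count_trainable_parameters(
                build_model(_small_spec("unetpp_dense", encoder), seed=0)
            )
            n_improved = count_trainable_parameters(
                build_model(_small_spec("unetpp_improved", encoder), seed=0)
            )
            assert n_improved < n_dense

    def test_count_invariant_to_input_size(self):
        model = build_model(_small_spec("unetpp_improved", "plain"), seed=0).eval()
        n0 = count_trainable_parameters(model)
        model(Tensor(np.zeros((1, 3, 64, 64), np.float32)))
        model(Tensor(np.zeros((1, 3, 128, 128), np.float32)))
        assert count_trainable_parameters(model) == n0


class TestForwardSemantics:
    def test_eval_forward_deterministic(self, rng):
        model = build_model(_small_spec("unetpp_improved", "efficientnet_b0"), seed=0).eval()
        x = Tensor(rng.normal(0, 1, (1, 3, 64, 64)).astype(np.float32))
        np.testing.assert_array_equal(model(x).data, model(x).data)

    def test_same_seed_same_weights(self):
        spec = _small_spec("unet", "plain")
        a, b = build_model(spec, seed=3), build_model(spec, seed=3)
        for (na, pa), (nb, pb) in zip(a.named_parameters(), b.named_parameters()):
            assert na == nb
            np.testing.assert_array_equal(pa.data, pb.data)
        c = build_model(spec, seed=4)
        assert any(
            not np.array_equal(pa.data, pc.data)
            for (_, pa), (_, pc) in zip(a.named_parameters(), c.named_parameters())
        )

    def test_predict_proba_in_unit_interval(self, rng):
        model = build_model(_small_spec("unetpp_improved", "plain"), seed=0)
        p = model.predict_proba(rng.normal(0, 1, (2, 3, 64, 64)))
        assert p.shape == (2, 1, 64, 64)
        assert p.min() >= 0.0 and p.max() <= 1.0

    def test_single_step_decreases_loss_on_fixed_batch(self, rng, small_samples):
        """Gradient flow smoke property: one small Adam step reduces the
        combined loss on the same batch."""
        from dermseg.losses import LossWeights, combined_loss_t
        from dermseg.training import _to_batch

        model = build_model(_small_spec("unetpp_improved", "plain"), seed=1)
        model.train()
        x, y = _to_batch(small_samples[:2])
        opt = nn.Adam(model.parameters(), lr=1e-3)
        loss0 = combined_loss_t(model.forward(Tensor(x)).sigmoid(), y, LossWeights())
        opt.zero_grad()
        loss0.backward()
        opt.step()
        loss1 = combined_loss_t(model.forward(Tensor(x)).sigmoid(), y, LossWeights())
        assert loss1.item() < loss0.item()


class TestSpecValidation:
    def test_unknown_enums_rejected(self):
        with pytest.raises(ConfigError):
            ModelSpec(architecture="segnet")
        with pytest.raises(ConfigError):
            ModelSpec(encoder="resnet50")
        with pytest.raises(ConfigError):
            ModelSpec(activation="selu")

    def test_activation_set_is_complete(self):
        assert set(nn.ACTIVATIONS) == {"relu", "prelu", "gelu", "swish", "mish"}

    @pytest.mark.parametrize("act", ["relu", "prelu", "gelu", "swish", "mish"])
    def test_every_activation_builds_and_runs(self, act):
        spec = dataclasses.replace(_small_spec("unetpp_improved", "plain"), activation=act)
        model = build_model(spec, seed=0).eval()
        out = model(Tensor(np.zeros((1, 3, 64, 64), np.float32)))
        assert out.shape == (1, 1, 64, 64)


EFFICIENT_UNETPP_DENSE = dataclasses.replace(
    EFFICIENT_UNETPP, architecture="unetpp_dense"
)
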