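"""Trainable-parameter accounting across the model zoo.

Pruning the dense UNet++ skips shrinks every decoder node's input, so the
improved decoder is strictly smaller than the dense one at identical widths.
"""

from dermseg import EFFICIENT_UNETPP, XCEPTION_UNETPP, ModelSpec, build_model
from dermseg.models import count_trainable_parameters

specs = {
    "U-Net (plain encoder)": ModelSpec(architecture="unet", encoder="plain"),
    "UNet++ dense (B0)": ModelSpec(architecture="unetpp_dense", encoder="efficientnet_b0"),
    "EfficientUNet++ (pruned)": EFFICIENT_UNETPP,
    "XceptionUNet++ (pruned)": XCEPTION_UNETPP,
}
for name, spec in specs.items():
    print(f"{name:26s} {count_trainable_parameters(build_model(spec, seed=0)):>12,}")
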