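"""The normalisation chain and the joint image/mask augmentation policy.

Gray-world colour constancy equalises the RGB channel means (correcting the
dermoscope's illumination cast); augmentation applies geometry to image and
mask together while photometric jitter touches only the image.
"""

import numpy as np

from dermseg import AugmentPolicy, augment_sample, generate_sample, gray_world_normalize
from dermseg.synthetic import SyntheticConfig

sample = generate_sample(SyntheticConfig(seed=3), np.random.default_rng(3))
before = sample.image.mean(axis=(0, 1))
after = gray_world_normalize(sample.image).mean(axis=(0, 1))
print("channel means before gray-world:", np.round(before, 2))
print("channel means after  gray-world:", np.round(after, 2), "(all equal)")

policy = AugmentPolicy(crop_size=32)
out = augment_sample(sample, policy, np.random.default_rng(5))
print(f"augmented: {sample.shape} -> {out.shape}, mask still binary:",
      sorted(int(v) for v in np.unique(out.mask)))
print(f"lesion fraction before {sample.mask.mean():.3f}, after {out.mask.mean():.3f}")
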