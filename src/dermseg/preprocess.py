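"""Image normalisation and joint image/mask augmentation.

The normalisation chain applied before the network is:

1. gray-world colour constancy (each channel rescaled to the common mean,
   correcting the varying illumination of dermoscopes),
2. geometric resize / augmentation,
3. subtraction of the ImageNet channel means (transfer-learning convention),
4. scaling to unit range.

Augmentation applies every *geometric* operation (scale, rotation, flips,
crop) with identical parameters to image and mask — the mask is resampled
nearest-neighbour so it stays binary — while *photometric* operations
(brightness/contrast, CLAHE, HSV shifts) touch the image only.  Random crop
is the one augmentation also applied to validation images.
"""

from __future__ import annotations

from dataclasses import dataclass, replace

import numpy as np
from scipy import ndimage
from skimage import color, exposure

from .data import DermoscopySample
from .errors import ConfigError, DegenerateInputError, ValidationError

__all__ = [
    "IMAGENET_MEANS",
    "AugmentPolicy",
    "gray_world_normalize",
    "subtract_channel_means",
    "normalize_for_network",
    "augment_sample",
    "resize_pair",
]

# Published ImageNet RGB channel means on the 0-255 scale.
IMAGENET_MEANS = (123.68, 116.779, 103.939)


def gray_world_normalize(image: np.ndarray) -> np.ndarray:
    """Gray-world colour constancy on a (H, W, 3) image, 0-255 scale.

    Channel c is scaled by ``mean_of_channel_means / mean_c`` so all channel
    means become equal; the result is clipped to [0, 255].
    """
    image = np.asarray(image, dtype=np.float64)
    if image.ndim != 3 or image.shape[2] != 3:
        raise ValidationError(f"expected (H, W, 3) image, got {image.shape}")
    mu = image.mean(axis=(0, 1))
    if np.any(mu <= 0):
        raise DegenerateInputError(
            f"gray-world undefined: channel means {tuple(mu)} must be positive"
        )
    gains = mu.mean() / mu
    return np.clip(image * gains[None, None, :], 0.0, 255.0)


def subtract_channel_means(
    image: np.ndarray, means: tuple[float, float, float] = IMAGENET_MEANS
) -> np.ndarray:
    """Subtract per-channel means; output may be negative (no clipping)."""
    image = np.asarray(image, dtype=np.float64)
    if image.ndim != 3 or image.shape[2] != 3:
        raise ValidationError(f"expected (H, W, 3) image, got {image.shape}")
    return image - np.asarray(means, dtype=np.float64)[None, None, :]


def normalize_for_network(
    image: np.ndarray, means: tuple[float, float, float] = IMAGENET_MEANS
) -> np.ndarray:
    """Mean subtraction followed by scaling to unit range (divide by 255)."""
    return subtract_channel_means(image, means) / 255.0


@dataclass(frozen=True)
class AugmentPolicy:
    """Enable flags and ranges for the seven-operation augmentation policy.

    Defaults are conventional dermoscopy-augmentation magnitudes; every field
    is configurable.  ``crop_size=None`` disables cropping.
    """

    enable_scale: bool = True
    scale_range: tuple[float, float] = (0.9, 1.1)
    enable_rotation: bool = True
    rotation_range: tuple[float, float] = (-30.0, 30.0)
    hflip_prob: float = 0.5
    vflip_prob: float = 0.5
    enable_brightness_contrast: bool = True
    brightness_range: tuple[float, float] = (-0.2, 0.2)
    contrast_range: tuple[float, float] = (-0.2, 0.2)
    clahe_prob: float = 0.25
    clahe_clip_limit: float = 0.01
    crop_size: int | None = None
    apply_to_validation: bool = True  # crop only
    enable_hsv: bool = True
    hue_range: tuple[float, float] = (-10.0, 10.0)
    sat_range: tuple[float, float] = (-10.0, 10.0)
    value_range: tuple[float, float] = (-10.0, 10.0)

    def __post_init__(self):
        for name in ("hflip_prob", "vflip_prob", "clahe_prob"):
            p = getattr(self, name)
            if not 0.0 <= p <= 1.0:
                raise ConfigError(f"{name} must be in [0, 1], got {p}")
        for name in (
            "scale_range",
            "rotation_range",
            "brightness_range",
            "contrast_range",
            "hue_range",
            "sat_range",
            "value_range",
        ):
            lo, hi = getattr(self, name)
            if lo > hi:
                raise ConfigError(f"{name} must be ordered (lo <= hi), got ({lo}, {hi})")
        if self.crop_size is not None and self.crop_size < 32:
            raise ConfigError(f"crop_size must be >= 32, got {self.crop_size}")

    def for_validation(self) -> "AugmentPolicy":
        """The validation-time policy: everything off except (optionally) crop."""
        return replace(
            self,
            enable_scale=False,
            enable_rotation=False,
            hflip_prob=0.0,
            vflip_prob=0.0,
            enable_brightness_contrast=False,
            clahe_prob=0.0,
            enable_hsv=False,
            crop_size=self.crop_size if self.apply_to_validation else None,
        )

    @staticmethod
    def disabled() -> "AugmentPolicy":
        return AugmentPolicy(
            enable_scale=False,
            enable_rotation=False,
            hflip_prob=0.0,
            vflip_prob=0.0,
            enable_brightness_contrast=False,
            clahe_prob=0.0,
            crop_size=None,
            enable_hsv=False,
        )


def _affine_pair(
    image: np.ndarray, mask: np.ndarray, scale: float, angle_deg: float
) -> tuple[np.ndarray, np.ndarray]:
    """Rotate-and-scale image (bilinear) and mask (nearest) about the centre."""
    theta = np.deg2rad(angle_deg)
    rot = np.array(
        [[np.cos(theta), -np.sin(theta)], [np.sin(theta), np.cos(theta)]]
    )
    m = rot / scale  # output->input mapping
    h, w = mask.shape
    centre = np.array([(h - 1) / 2.0, (w - 1) / 2.0])
    offset = centre - m @ centre
    warped = np.stack(
        [
            ndimage.affine_transform(
                image[:, :, c], m, offset=offset, order=1, mode="reflect"
            )
            for c in range(3)
        ],
        axis=2,
    )
    warped_mask = ndimage.affine_transform(
        mask, m, offset=offset, order=0, mode="constant", cval=0
    )
    return warped.astype(np.float32), warped_mask.astype(np.uint8)


def _apply_clahe(image: np.ndarray, clip_limit: float) -> np.ndarray:
    eq = exposure.equalize_adapthist(
        np.clip(image, 0, 255).astype(np.uint8), clip_limit=clip_limit
    )
    return (eq * 255.0).astype(np.float32)


def _apply_hsv(image: np.ndarray, dh: float, ds: float, dv: float) -> np.ndarray:
    hsv = color.rgb2hsv(np.clip(image, 0, 255) / 255.0)
    hsv[:, :, 0] = (hsv[:, :, 0] + dh / 255.0) % 1.0
    hsv[:, :, 1] = np.clip(hsv[:, :, 1] + ds / 255.0, 0.0, 1.0)
    hsv[:, :, 2] = np.clip(hsv[:, :, 2] + dv / 255.0, 0.0, 1.0)
    return (color.hsv2rgb(hsv) * 255.0).astype(np.float32)


def augment_sample(
    sample: DermoscopySample, policy: AugmentPolicy, rng: np.random.Generator
) -> DermoscopySample:
    """Apply the stochastic policy jointly to image and mask.

    Geometric order: scale -> rotation -> flips -> crop; photometric
    (image-only) order: brightness/contrast -> CLAHE -> HSV.
    """
    image, mask = sample.image, sample.mask
    h, w = mask.shape
    if policy.crop_size is not None and policy.crop_size > min(h, w):
        raise ValidationError(
            f"crop_size {policy.crop_size} exceeds sample size {h}x{w}"
        )

    scale = rng.uniform(*policy.scale_range) if policy.enable_scale else 1.0
    angle = rng.uniform(*policy.rotation_range) if policy.enable_rotation else 0.0
    if scale != 1.0 or angle != 0.0:
        image, mask = _affine_pair(image, mask, scale, angle)

    if policy.hflip_prob and rng.random() < policy.hflip_prob:
        image, mask = image[:, ::-1], mask[:, ::-1]
    if policy.vflip_prob and rng.random() < policy.vflip_prob:
        image, mask = image[::-1, :], mask[::-1, :]

    if policy.crop_size is not None:
        ch = cw = policy.crop_size
        top = int(rng.integers(0, mask.shape[0] - ch + 1))
        left = int(rng.integers(0, mask.shape[1] - cw + 1))
        image = image[top : top + ch, left : left + cw]
        mask = mask[top : top + ch, left : left + cw]

    if policy.enable_brightness_contrast:
        b = rng.uniform(*policy.brightness_range)
        c = rng.uniform(*policy.contrast_range)
        mean = image.mean()
        image = np.clip(mean + (image - mean) * (1.0 + c) + 255.0 * b, 0, 255)
    if policy.clahe_prob and rng.random() < policy.clahe_prob:
        image = _apply_clahe(image, policy.clahe_clip_limit)
    if policy.enable_hsv:
        dh = rng.uniform(*policy.hue_range)
        ds = rng.uniform(*policy.sat_range)
        dv = rng.uniform(*policy.value_range)
        image = _apply_hsv(image, dh, ds, dv)

    return DermoscopySample(
        sample.sample_id,
        np.ascontiguousarray(image, dtype=np.float32),
        np.ascontiguousarray(mask),
        sample.source,
    )


def resize_pair(
    sample: DermoscopySample, target: tuple[int, int]
) -> DermoscopySample:
    """Resize to ``target`` (H, W): bilinear image, nearest mask.

    Target dims must be multiples of 32 — the encoders downsample five times,
    so any other size cannot flow through the network.
    """
    th, tw = target
    if th % 32 or tw % 32 or th < 32 or tw < 32:
        raise ValidationError(
            f"target dims must be multiples of 32 (encoder stride budget), got {target}"
        )
    if (th, tw) == sample.shape:
        return sample
    h, w = sample.shape
    zoom_img = (th / h, tw / w, 1.0)
    image = ndimage.zoom(sample.image, zoom_img, order=1, mode="reflect")
    # nearest-neighbour via coordinate lookup keeps the mask binary
    rows = np.clip(np.round(np.arange(th) * h / th).astype(int), 0, h - 1)
    cols = np.clip(np.round(np.arange(tw) * w / tw).astype(int), 0, w - 1)
    mask = sample.mask[np.ix_(rows, cols)]
    image = image[:th, :tw]  # guard against zoom rounding
    return DermoscopySample(sample.sample_id, image, mask, sample.source)
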