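"""Seeded generator of dermoscopy-like image/mask pairs.

Each sample is a darker, irregular, star-convex lesion blob on a skin-tone
background with Gaussian texture noise, an optional linear illumination
gradient and optional thin dark hair arcs (drawn on the image only — never
in the mask).  The lesion boundary is an ellipse whose radius is modulated
by a low-order random harmonic series; the mask is the exact blob indicator,
and rejection sampling guarantees the mask area fraction falls inside the
configured range.

The generator emulates the gross photometric structure of dermoscopic
imagery (lesion darker than skin, irregular border, hair occlusion, uneven
illumination); it does not attempt photorealism.
"""

from __future__ import annotations

from dataclasses import dataclass
from pathlib import Path

import numpy as np
from scipy import ndimage

from .data import DermoscopySample, write_sample
from .errors import ConfigError

__all__ = ["SyntheticConfig", "generate_sample", "generate_samples", "generate_dataset"]


@dataclass(frozen=True)
class SyntheticConfig:
    n_samples: int = 10
    size: tuple[int, int] = (64, 64)
    lesion_area_range: tuple[float, float] = (0.1, 0.35)
    boundary_irregularity: float = 0.15
    lesion_contrast: float = 0.45
    hair_probability: float = 0.3
    illumination_gradient: float = 0.15
    noise_sd: float = 5.0
    seed: int = 0

    def __post_init__(self):
        lo, hi = self.lesion_area_range
        if not 0.0 < lo < hi < 1.0:
            raise ConfigError(
                f"lesion_area_range must satisfy 0 < lo < hi < 1, got ({lo}, {hi})"
            )
        h, w = self.size
        if h % 32 or w % 32 or h < 32 or w < 32:
            raise ConfigError(f"size must be multiples of 32, got {self.size}")
        if not 0.0 <= self.hair_probability <= 1.0:
            raise ConfigError(f"hair_probability must be in [0, 1]")
        if not 0.0 < self.lesion_contrast <= 1.0:
            raise ConfigError(f"lesion_contrast must be in (0, 1]")
        if self.boundary_irregularity < 0 or self.illumination_gradient < 0:
            raise ConfigError("irregularity and illumination gradient must be >= 0")
        if self.noise_sd < 0:
            raise ConfigError("noise_sd must be >= 0")
        if self.n_samples < 1:
            raise ConfigError("n_samples must be >= 1")


def _blob_mask(
    shape: tuple[int, int],
    rng: np.random.Generator,
    area_range: tuple[float, float],
    irregularity: float,
) -> np.ndarray:
    """Star-convex lesion indicator with area fraction inside `area_range`."""
    h, w = shape
    yy, xx = np.mgrid[0:h, 0:w].astype(np.float64)
    for _ in range(200):
        target = rng.uniform(*area_range)
        aspect = rng.uniform(0.7, 1.3)
        theta0 = rng.uniform(0, np.pi)
        cy = h / 2 + rng.uniform(-0.1, 0.1) * h
        cx = w / 2 + rng.uniform(-0.1, 0.1) * w
        # ellipse with area target*h*w: semi-axes a = r*aspect, b = r/aspect
        r0 = np.sqrt(target * h * w / np.pi)
        # harmonic radial perturbation, zero-mean over angle
        ks = np.arange(2, 7)
        amps = rng.normal(0.0, 1.0, size=ks.size) / ks
        phases = rng.uniform(0, 2 * np.pi, size=ks.size)
        dy, dx = yy - cy, xx - cx
        ry = dy * np.cos(theta0) - dx * np.sin(theta0)
        rx = dy * np.sin(theta0) + dx * np.cos(theta0)
        rad = np.hypot(rx / aspect, ry * aspect)
        ang = np.arctan2(ry * aspect, rx / aspect)
        pert = np.zeros_like(ang)
        if irregularity > 0:
            for k, a, p in zip(ks, amps, phases):
                pert += a * np.cos(k * ang + p)
            pert *= irregularity
        mask = (rad <= r0 * (1.0 + pert)).astype(np.uint8)
        frac = mask.mean()
        if area_range[0] <= frac <= area_range[1]:
            return mask
    raise ConfigError(
        f"could not draw a lesion with area fraction in {area_range} "
        f"on a {h}x{w} canvas (irregularity {irregularity})"
    )


def _hair_arcs(shape: tuple[int, int], rng: np.random.Generator) -> np.ndarray:
    """Boolean raster of a few thin arcs (quadratic Bezier curves)."""
    h, w = shape
    canvas = np.zeros(shape, dtype=bool)
    for _ in range(int(rng.integers(1, 4))):
        p0 = rng.uniform([0, 0], [h - 1, w - 1])
        p2 = rng.uniform([0, 0], [h - 1, w - 1])
        p1 = (p0 + p2) / 2 + rng.uniform(-0.3, 0.3, 2) * [h, w]
        t = np.linspace(0.0, 1.0, 4 * max(h, w))[:, None]
        pts = (1 - t) ** 2 * p0 + 2 * t * (1 - t) * p1 + t**2 * p2
        rr = np.clip(np.round(pts[:, 0]).astype(int), 0, h - 1)
        cc = np.clip(np.round(pts[:, 1]).astype(int), 0, w - 1)
        canvas[rr, cc] = True
    return ndimage.binary_dilation(canvas)


def generate_sample(
    config: SyntheticConfig, rng: np.random.Generator, sample_id: str = "synthetic"
) -> DermoscopySample:
    """Draw one image/mask pair from the generator's distribution."""
    h, w = config.size
    mask = _blob_mask((h, w), rng, config.lesion_area_range, config.boundary_irregularity)

    # skin-tone base with a mild red-dominant cast
    base = np.array(
        [rng.uniform(190, 230), rng.uniform(145, 185), rng.uniform(120, 160)],
        dtype=np.float64,
    )
    image = np.broadcast_to(base, (h, w, 3)).copy()

    # lesion fill: darkened base with smooth internal texture
    lesion_color = base * (1.0 - config.lesion_contrast)
    texture = ndimage.gaussian_filter(rng.normal(0.0, 1.0, (h, w)), 3.0)
    texture = 12.0 * texture / (np.abs(texture).max() + 1e-9)
    inside = mask.astype(bool)
    image[inside] = lesion_color + texture[inside, None]

    if config.illumination_gradient > 0:
        phi = rng.uniform(0, 2 * np.pi)
        ramp = (
            np.cos(phi) * (np.arange(h)[:, None] / max(h - 1, 1) - 0.5)
            + np.sin(phi) * (np.arange(w)[None, :] / max(w - 1, 1) - 0.5)
        )
        image *= (1.0 + config.illumination_gradient * ramp)[:, :, None]

    if config.noise_sd > 0:
        image += rng.normal(0.0, config.noise_sd, (h, w, 3))

    if config.hair_probability and rng.random() < config.hair_probability:
        hair = _hair_arcs((h, w), rng)
        image[hair] = rng.uniform(20, 60)  # dark hair shafts, image only

    image = ndimage.gaussian_filter(image, (0.7, 0.7, 0.0))
    image = np.clip(image, 0.0, 255.0).astype(np.float32)
    return DermoscopySample(sample_id, image, mask, source="synthetic")


def _substream(seed: int, index: int) -> np.random.Generator:
    # counter-derived substream: reproducible regardless of generation order
    return np.random.default_rng([seed, index])


def generate_samples(config: SyntheticConfig) -> list[DermoscopySample]:
    """Generate ``config.n_samples`` in-memory samples, one substream each."""
    return [
        generate_sample(config, _substream(config.seed, i), f"SYN_{i:05d}")
        for i in range(config.n_samples)
    ]


def generate_dataset(
    config: SyntheticConfig,
    layout: str,
    out_dir: str | Path,
    overwrite: bool = False,
) -> list[str]:
    """Write a synthetic dataset in the chosen dialect; returns sample ids.

    Refuses a non-empty output directory unless ``overwrite`` is set.  A
    ``manifest.tsv`` (sample_id, layout) is written alongside the rasters.
    """
    out_dir = Path(out_dir)
    if out_dir.exists() and any(out_dir.iterdir()) and not overwrite:
        raise FileExistsError(
            f"{out_dir} is not empty; pass overwrite=True to replace it"
        )
    out_dir.mkdir(parents=True, exist_ok=True)
    ids = []
    for sample in generate_samples(config):
        write_sample(sample, out_dir, layout)
        ids.append(sample.sample_id)
    with (out_dir / "manifest.tsv").open("w") as fh:
        fh.write("sample_id\tlayout\n")
        for sid in ids:
            fh.write(f"{sid}\t{layout}\n")
    return ids
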