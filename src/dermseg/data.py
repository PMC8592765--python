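"""Domain types and dataset I/O for dermoscopic image / lesion-mask pairs.

Two on-disk dialects are supported:

* **ISIC-style** — flat directory of ``<id>.jpg|png`` images with sibling
  ``<id>_segmentation.png`` masks.
* **PH2-style** — one directory per case holding a dermoscopic image and a
  ``*_lesion`` mask raster (BMP dialect supported); nested per-case
  subdirectories, as in the original distribution, are searched recursively.

Masks are binarised at ingest with the rule ``value > 127 -> 1`` (tolerant of
anti-aliased or JPEG-fringed boundaries); images stay on the 0-255 scale —
normalisation is an explicit preprocessing step, never an I/O side effect.
"""

from __future__ import annotations

from dataclasses import dataclass, field
from pathlib import Path

import numpy as np
from PIL import Image

from .errors import ValidationError

__all__ = [
    "DermoscopySample",
    "DatasetSplit",
    "read_isic_pair",
    "read_ph2_case",
    "read_dataset",
    "write_sample",
    "write_manifest",
    "read_manifest",
    "split_dataset",
    "kfold_split",
]

MASK_THRESHOLD = 127
_SOURCES = ("isic", "ph2", "synthetic")
_RASTER_SUFFIXES = {".png", ".jpg", ".jpeg", ".bmp"}


@dataclass
class DermoscopySample:
    """One RGB dermoscopic image with its aligned binary lesion mask.

    image: (H, W, 3) float, 0-255 scale at ingest. mask: (H, W) uint8 in {0,1}.
    """

    sample_id: str
    image: np.ndarray
    mask: np.ndarray
    source: str = "synthetic"

    def __post_init__(self):
        self.image = np.asarray(self.image, dtype=np.float32)
        self.mask = np.asarray(self.mask)
        if self.source not in _SOURCES:
            raise ValidationError(f"unknown source {self.source!r}; expected one of {_SOURCES}")
        if self.image.ndim != 3 or self.image.shape[2] != 3:
            raise ValidationError(f"image must be (H, W, 3), got {self.image.shape}")
        if self.mask.ndim != 2:
            raise ValidationError(f"mask must be (H, W), got {self.mask.shape}")
        if self.image.shape[:2] != self.mask.shape:
            raise ValidationError(
                f"image/mask shape mismatch: image {self.image.shape[:2]} vs mask {self.mask.shape}"
            )
        h, w = self.mask.shape
        if h < 32 or w < 32:
            raise ValidationError(f"images must be at least 32x32, got {h}x{w}")
        if not np.isin(self.mask, (0, 1)).all():
            raise ValidationError("mask values must be exactly 0 or 1")
        self.mask = self.mask.astype(np.uint8)

    @property
    def shape(self) -> tuple[int, int]:
        return self.mask.shape


def _load_raster(path: Path) -> np.ndarray:
    if not path.exists():
        raise FileNotFoundError(f"no such file: {path}")
    with Image.open(path) as im:
        return np.asarray(im)


def _collapse_mask(raw: np.ndarray, path: Path) -> np.ndarray:
    """Accept single-channel masks, or multi-channel ones whose channels agree."""
    if raw.ndim == 3:
        if raw.shape[2] == 4:  # drop an alpha plane if fully opaque
            raw = raw[:, :, :3]
        if not (raw == raw[:, :, :1]).all():
            raise ValidationError(
                f"mask {path} has {raw.shape[2]} disagreeing channels; cannot collapse"
            )
        raw = raw[:, :, 0]
    elif raw.ndim != 2:
        raise ValidationError(f"mask {path} has unsupported shape {raw.shape}")
    return (raw > MASK_THRESHOLD).astype(np.uint8)


def _load_image_rgb(path: Path) -> np.ndarray:
    raw = _load_raster(path)
    if raw.ndim == 2:  # grayscale dermoscopic image: replicate
        raw = np.repeat(raw[:, :, None], 3, axis=2)
    if raw.shape[2] == 4:
        raw = raw[:, :, :3]
    return raw.astype(np.float32)


def read_isic_pair(image_path: str | Path, mask_path: str | Path) -> DermoscopySample:
    """Read an ISIC-style image + ``*_segmentation`` mask pair."""
    image_path, mask_path = Path(image_path), Path(mask_path)
    image = _load_image_rgb(image_path)
    mask = _collapse_mask(_load_raster(mask_path), mask_path)
    if image.shape[:2] != mask.shape:
        raise ValidationError(
            f"image {image_path.name} is {image.shape[:2]} but mask "
            f"{mask_path.name} is {mask.shape}"
        )
    return DermoscopySample(image_path.stem, image, mask, source="isic")


def read_ph2_case(case_dir: str | Path) -> DermoscopySample:
    """Read a PH2-style case directory (one image, one ``*_lesion`` mask)."""
    case_dir = Path(case_dir)
    if not case_dir.is_dir():
        raise FileNotFoundError(f"no such directory: {case_dir}")
    rasters = sorted(
        p for p in case_dir.rglob("*") if p.suffix.lower() in _RASTER_SUFFIXES
    )
    masks = [p for p in rasters if "_lesion" in p.stem]
    images = [p for p in rasters if "_lesion" not in p.stem]
    if len(masks) != 1 or len(images) != 1:
        raise ValidationError(
            f"case {case_dir} is ambiguous: found {len(images)} image(s) "
            f"{[p.name for p in images]} and {len(masks)} mask(s) "
            f"{[p.name for p in masks]}; expected exactly one of each"
        )
    image = _load_image_rgb(images[0])
    mask = _collapse_mask(_load_raster(masks[0]), masks[0])
    if image.shape[:2] != mask.shape:
        raise ValidationError(
            f"image {images[0].name} is {image.shape[:2]} but mask "
            f"{masks[0].name} is {mask.shape}"
        )
    return DermoscopySample(case_dir.name, image, mask, source="ph2")


def read_dataset(root: str | Path, layout: str) -> list[DermoscopySample]:
    """Read every sample under `root` in the given dialect (isic | ph2)."""
    root = Path(root)
    samples: list[DermoscopySample] = []
    if layout == "isic":
        for mask_path in sorted(root.glob("*_segmentation.png")):
            stem = mask_path.name[: -len("_segmentation.png")]
            candidates = [
                root / f"{stem}{ext}" for ext in (".png", ".jpg", ".jpeg")
            ]
            image_path = next((p for p in candidates if p.exists()), None)
            if image_path is None:
                raise FileNotFoundError(f"no image found for mask {mask_path}")
            samples.append(read_isic_pair(image_path, mask_path))
    elif layout == "ph2":
        for case_dir in sorted(p for p in root.iterdir() if p.is_dir()):
            samples.append(read_ph2_case(case_dir))
    else:
        raise ValidationError(f"unknown layout {layout!r}; expected 'isic' or 'ph2'")
    return samples


def write_sample(sample: DermoscopySample, out_dir: str | Path, layout: str) -> None:
    """Write one sample in the chosen dialect.

    Images are written as PNG so that read-back is bit-exact; the ISIC naming
    convention (``<id>.png`` + ``<id>_segmentation.png``) is kept.
    """
    out_dir = Path(out_dir)
    img = np.clip(np.rint(sample.image), 0, 255).astype(np.uint8)
    msk = (sample.mask * 255).astype(np.uint8)
    if layout == "isic":
        out_dir.mkdir(parents=True, exist_ok=True)
        Image.fromarray(img).save(out_dir / f"{sample.sample_id}.png")
        Image.fromarray(msk).save(out_dir / f"{sample.sample_id}_segmentation.png")
    elif layout == "ph2":
        case = out_dir / sample.sample_id
        case.mkdir(parents=True, exist_ok=True)
        Image.fromarray(img).save(case / f"{sample.sample_id}.bmp")
        Image.fromarray(msk).save(case / f"{sample.sample_id}_lesion.bmp")
    else:
        raise ValidationError(f"unknown layout {layout!r}; expected 'isic' or 'ph2'")


@dataclass
class DatasetSplit:
    """Disjoint train/validation/test partition of sample ids."""

    train: list[str] = field(default_factory=list)
    validation: list[str] = field(default_factory=list)
    test: list[str] = field(default_factory=list)

    def __post_init__(self):
        groups = (set(self.train), set(self.validation), set(self.test))
        n = len(self.train) + len(self.validation) + len(self.test)
        if len(groups[0] | groups[1] | groups[2]) != n:
            raise ValidationError("split subsets must be pairwise disjoint")

    @property
    def all_ids(self) -> set[str]:
        return set(self.train) | set(self.validation) | set(self.test)


def split_dataset(
    ids: list[str], fractions: tuple[float, float, float], seed: int
) -> DatasetSplit:
    """Random train/validation/test split.

    Subset sizes are the rounded fractions of ``len(ids)``; the rounding
    remainder goes to the training set.  Deterministic for a fixed seed.
    """
    ids = list(ids)
    if len(ids) < 3:
        raise ValidationError(f"need at least 3 ids to split, got {len(ids)}")
    if len(set(ids)) != len(ids):
        raise ValidationError("duplicate sample ids")
    f_train, f_val, f_test = fractions
    if min(fractions) < 0:
        raise ValidationError(f"fractions must be non-negative, got {fractions}")
    if abs(sum(fractions) - 1.0) > 1e-9:
        raise ValidationError(f"fractions must sum to 1, got {sum(fractions)}")
    n = len(ids)
    n_val = int(round(f_val * n))
    n_test = int(round(f_test * n))
    n_train = n - n_val - n_test  # remainder to the largest bucket
    if n_train < 0:
        raise ValidationError("rounded validation+test exceed the dataset size")
    order = np.random.default_rng(seed).permutation(n)
    shuffled = [ids[i] for i in order]
    return DatasetSplit(
        train=shuffled[:n_train],
        validation=shuffled[n_train : n_train + n_val],
        test=shuffled[n_train + n_val :],
    )


def kfold_split(
    ids: list[str], k: int, seed: int
) -> list[tuple[list[str], list[str]]]:
    """k-fold cross-validation pairs; fold sizes differ by at most one."""
    ids = list(ids)
    if k < 2:
        raise ValidationError(f"k must be >= 2, got {k}")
    if k > len(ids):
        raise ValidationError(f"k={k} exceeds the number of ids ({len(ids)})")
    order = np.random.default_rng(seed).permutation(len(ids))
    shuffled = [ids[i] for i in order]
    folds = [list(f) for f in np.array_split(np.array(shuffled, dtype=object), k)]
    pairs = []
    for i, fold in enumerate(folds):
        val = [str(x) for x in fold]
        train = [str(x) for j, f in enumerate(folds) if j != i for x in f]
        pairs.append((train, val))
    return pairs


def write_manifest(split: DatasetSplit, path: str | Path) -> None:
    """Plain-text split manifest: one ``sample_id<TAB>subset`` row per sample."""
    path = Path(path)
    with path.open("w") as fh:
        fh.write("sample_id\tsubset\n")
        for subset in ("train", "validation", "test"):
            for sid in getattr(split, subset):
                fh.write(f"{sid}\t{subset}\n")


def read_manifest(path: str | Path) -> DatasetSplit:
    split = {"train": [], "validation": [], "test": []}
    with Path(path).open() as fh:
        header = fh.readline()
        if header.split() != ["sample_id", "subset"]:
            raise ValidationError(f"unrecognised manifest header: {header!r}")
        for line in fh:
            sid, subset = line.split()
            if subset not in split:
                raise ValidationError(f"unknown subset {subset!r} in manifest")
            split[subset].append(sid)
    return DatasetSplit(**split)
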