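"""Slide tiling, patch extraction, and color augmentation.

High-resolution slide images are segmented into fixed 1360x1024 tiles;
each tile yields ten randomly placed square training patches together
with their horizontal and vertical reflections (a 30x augmentation), and
fifteen deterministic test patches (center + four corners, each with
both reflections). Color augmentation is power-law gamma correction,
out = round(255*(in/255)^gamma) per channel with gamma drawn uniformly
from a configurable range, optionally followed by CLAHE on luminance.
"""

from __future__ import annotations

import logging
import warnings
from dataclasses import dataclass, replace
from pathlib import Path
from typing import Iterable, Literal, Sequence

import imageio.v3 as iio
import numpy as np
from skimage import exposure
from skimage.color import rgb2ycbcr, ycbcr2rgb

logger = logging.getLogger(__name__)

Reflection = Literal["none", "horizontal", "vertical"]
REFLECTIONS: tuple[Reflection, ...] = ("none", "horizontal", "vertical")


class PatchSizeError(ValueError):
    """Image too small for the requested patch size."""


@dataclass
class RgbImage:
    """8-bit H x W x 3 raster with a provenance identifier."""

    pixels: np.ndarray
    source_id: str
    offset: tuple[int, int] = (0, 0)  # (row, col) of this raster in its parent

    def __post_init__(self) -> None:
        px = np.asarray(self.pixels)
        if px.ndim != 3 or px.shape[2] != 3 or px.shape[0] < 1 or px.shape[1] < 1:
            raise ValueError(f"expected H x W x 3 RGB array, got shape {px.shape}")
        if px.dtype != np.uint8:
            raise ValueError(f"expected uint8 pixels, got {px.dtype}")
        self.pixels = px

    @property
    def shape(self) -> tuple[int, int]:
        return self.pixels.shape[0], self.pixels.shape[1]

    @classmethod
    def load(cls, path: str | Path, source_id: str | None = None) -> "RgbImage":
        px = iio.imread(path)
        if px.ndim == 2:
            px = np.stack([px] * 3, axis=-1)
        if px.shape[2] == 4:
            px = px[:, :, :3]
        return cls(px.astype(np.uint8), source_id or Path(path).stem)

    def save(self, path: str | Path) -> None:
        iio.imwrite(path, self.pixels)


@dataclass
class Patch:
    """Square crop with its source offset and reflection flag."""

    pixels: np.ndarray
    source_id: str
    offset: tuple[int, int]
    reflection: Reflection = "none"
    gamma: float | None = None

    @property
    def size(self) -> int:
        return self.pixels.shape[0]


@dataclass(frozen=True)
class AugmentationConfig:
    n_train_patches: int = 10
    patch_size: int = 1000
    gamma_range: tuple[float, float] = (0.5, 2.0)
    clahe_enabled: bool = False
    include_reflections: bool = True
    seed: int = 0

    def __post_init__(self) -> None:
        lo, hi = self.gamma_range
        if lo <= 0 or hi <= 0 or hi < lo:
            raise ValueError(f"gamma_range must be positive and ordered: {self.gamma_range}")
        if self.n_train_patches < 1 or self.patch_size < 1:
            raise ValueError("n_train_patches and patch_size must be >= 1")


def tile_slide(
    image: RgbImage, tile_height: int = 1024, tile_width: int = 1360
) -> list[RgbImage]:
    """Cut a slide image into a non-overlapping grid of fixed-size tiles.

    Tiles are returned in row-major order, each carrying its (row, col)
    offset in the source. Partial border strips are discarded; an image
    smaller than one tile yields an empty list with a warning logged.
    """
    h, w = image.shape
    n_rows, n_cols = h // tile_height, w // tile_width
    if n_rows == 0 or n_cols == 0:
        logger.warning(
            "image %s (%dx%d) smaller than one %dx%d tile; no tiles produced",
            image.source_id, h, w, tile_height, tile_width,
        )
        return []
    tiles = []
    for i in range(n_rows):
        for j in range(n_cols):
            r, c = i * tile_height, j * tile_width
            tiles.append(
                RgbImage(
                    image.pixels[r : r + tile_height, c : c + tile_width].copy(),
                    source_id=f"{image.source_id}#t{i}_{j}",
                    offset=(r, c),
                )
            )
    return tiles


def _reflect(px: np.ndarray, reflection: Reflection) -> np.ndarray:
    if reflection == "horizontal":  # flip left-right
        return px[:, ::-1]
    if reflection == "vertical":  # flip up-down
        return px[::-1, :]
    return px


def _crop(image: RgbImage, offset: tuple[int, int], size: int) -> np.ndarray:
    r, c = offset
    return image.pixels[r : r + size, c : c + size]


def _check_fits(image: RgbImage, size: int) -> None:
    h, w = image.shape
    if h < size or w < size:
        raise PatchSizeError(
            f"image {image.source_id} of shape {h}x{w} cannot hold a {size}x{size} patch"
        )


def sample_training_patches(
    image: RgbImage, cfg: AugmentationConfig, rng: np.random.Generator | None = None
) -> list[Patch]:
    """Randomly place ``n_train_patches`` base patches and emit each with
    its horizontal and vertical reflections (3 x n_train_patches total).

    Offsets are uniform over all valid top-left positions; the draw is
    seeded (``cfg.seed``) unless an external generator is supplied.
    """
    _check_fits(image, cfg.patch_size)
    if rng is None:
        rng = np.random.default_rng(cfg.seed)
    h, w = image.shape
    out: list[Patch] = []
    reflections = REFLECTIONS if cfg.include_reflections else ("none",)
    for _ in range(cfg.n_train_patches):
        r = int(rng.integers(0, h - cfg.patch_size + 1))
        c = int(rng.integers(0, w - cfg.patch_size + 1))
        base = _crop(image, (r, c), cfg.patch_size)
        for refl in reflections:
            out.append(
                Patch(_reflect(base, refl).copy(), image.source_id, (r, c), refl)
            )
    return out


def extract_test_patches(image: RgbImage, patch_size: int = 1000) -> list[Patch]:
    """Deterministic 15-patch test cover: center + 4 corners, each with
    horizontal and vertical reflections."""
    _check_fits(image, patch_size)
    h, w = image.shape
    rmax, cmax = h - patch_size, w - patch_size
    base_offsets = [
        (0, 0),
        (0, cmax),
        (rmax, 0),
        (rmax, cmax),
        (rmax // 2, cmax // 2),
    ]
    out = []
    for off in base_offsets:
        base = _crop(image, off, patch_size)
        for refl in REFLECTIONS:
            out.append(Patch(_reflect(base, refl).copy(), image.source_id, off, refl))
    return out


def gamma_correct(pixels: np.ndarray, gamma: float) -> np.ndarray:
    """Power-law intensity transform out = round(255*(in/255)^gamma)."""
    if gamma <= 0:
        raise ValueError(f"gamma must be positive, got {gamma}")
    lut = np.rint(255.0 * (np.arange(256) / 255.0) ** gamma).astype(np.uint8)
    return lut[pixels]


def _clahe_luminance(pixels: np.ndarray) -> np.ndarray:
    """CLAHE applied to the luma channel only, chroma preserved."""
    ycbcr = rgb2ycbcr(pixels)
    y = ycbcr[:, :, 0]
    # skimage luma is in [16, 235]
    y01 = np.clip((y - 16.0) / 219.0, 0.0, 1.0)
    with warnings.catch_warnings():
        warnings.simplefilter("ignore")
        eq = exposure.equalize_adapthist(y01)
    ycbcr[:, :, 0] = eq * 219.0 + 16.0
    rgb = ycbcr2rgb(ycbcr)
    return np.clip(np.rint(rgb * 255.0), 0, 255).astype(np.uint8)


def color_augment(
    patch: Patch,
    cfg: AugmentationConfig,
    rng: np.random.Generator | None = None,
    gamma: float | None = None,
) -> Patch:
    """Apply gamma correction (random from ``cfg.gamma_range`` unless an
    explicit gamma is passed) and, if enabled, CLAHE on luminance."""
    if gamma is None:
        if rng is None:
            rng = np.random.default_rng(cfg.seed)
        gamma = float(rng.uniform(*cfg.gamma_range))
    px = gamma_correct(patch.pixels, gamma)
    if cfg.clahe_enabled:
        px = _clahe_luminance(px)
    return replace(patch, pixels=px, gamma=gamma)


def augment_training_set(
    images: Iterable[RgbImage], cfg: AugmentationConfig
) -> list[Patch]:
    """Full training augmentation: random patches + reflections + per-patch
    gamma. One seeded stream drives the whole pass for reproducibility."""
    rng = np.random.default_rng(cfg.seed)
    out: list[Patch] = []
    for image in images:
        for patch in sample_training_patches(image, cfg, rng=rng):
            out.append(color_augment(patch, cfg, rng=rng))
    return out


def write_patch_archive(patches: Sequence[Patch], out_dir: str | Path) -> Path:
    """Store patches as PNGs plus a tab-separated index; returns index path."""
    out_dir = Path(out_dir)
    out_dir.mkdir(parents=True, exist_ok=True)
    lines = ["\t".join(["file", "source_id", "row", "col", "reflection", "gamma"])]
    for k, p in enumerate(patches):
        name = f"patch_{k:06d}.png"
        iio.imwrite(out_dir / name, p.pixels)
        g = "" if p.gamma is None else f"{p.gamma:.6g}"
        lines.append(
            "\t".join([name, p.source_id, str(p.offset[0]), str(p.offset[1]), p.reflection, g])
        )
    index = out_dir / "index.tsv"
    index.write_text("\n".join(lines) + "\n")
    return index
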