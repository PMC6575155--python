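"""Highest-activation traceback: from layer-4 feature maps to source pixels.

For each feature map the single highest activation on the final
convolution grid is located and projected back through the network's
receptive-field geometry to a box of source pixels; a fixed-size square
segment (default side 142) centered on that box is cropped from the
source image. Ranking the per-image peaks across a set of images gives
top-k galleries of the tissue structures that drive each filter.

The receptive-field recurrence accumulates kernel extents and pooling
strides layer by layer (convolutions keep stride 1 with same-size zero
padding; pooling stride equals the pooling window). For the default
architecture a conv4 unit has a theoretical field of 164 pixels and
adjacent units are 40 source pixels apart; the cropped segment side is
an independent, configurable artifact size.
"""

from __future__ import annotations

import logging
import warnings
from dataclasses import dataclass
from pathlib import Path
from typing import Sequence

import imageio.v3 as iio
import numpy as np

from .cnn import NetworkConfig, TrainedModel, layer_activations
from .imgprep import RgbImage

logger = logging.getLogger(__name__)

DEFAULT_SEGMENT_SIDE = 142


@dataclass(frozen=True)
class ActivationPeak:
    feature_map_index: int
    grid_position: tuple[int, int]  # (row, col) on the final conv grid
    value: float


@dataclass(frozen=True)
class ReceptiveField:
    """Receptive-field geometry of one unit: size (pixels), stride between
    adjacent units (pixels), and the source-pixel center of unit (0, 0)."""

    size: int
    stride: int
    center0: float


@dataclass
class SegmentRecord:
    pixels: np.ndarray
    source_id: str
    center: tuple[int, int]  # source-pixel coordinates (row, col)
    value: float
    feature_map_index: int
    box: tuple[int, int, int, int]  # crop (top, left, bottom, right), half-open
    clipped: bool = False


def receptive_field_geometry(
    config: NetworkConfig, layer: str = "conv4"
) -> ReceptiveField:
    """Accumulate (size, stride, first-center) through conv/pool layers.

    ``layer`` may be any conv/pool name; the recurrence is
    size += (k - 1) * jump; jump *= stride; center += ((k - 1) / 2 - pad) * jump_prev.
    """
    if layer not in config.layer_names():
        raise ValueError(
            f"unknown layer {layer!r}; valid: {', '.join(config.layer_names())}"
        )
    size, jump, center = 1, 1, 0.0
    for i, (k, pw) in enumerate(zip(config.conv_kernels, config.pool_windows)):
        # convolution: stride 1, zero pad k//2 (same size)
        size += (k - 1) * jump
        center += ((k - 1) / 2 - k // 2) * jump  # zero for odd k
        if layer == f"conv{i+1}":
            return ReceptiveField(size=size, stride=jump, center0=center)
        # max pooling: window pw, stride pw, no padding
        size += (pw - 1) * jump
        center += ((pw - 1) / 2) * jump
        jump *= pw
        if layer == f"pool{i+1}":
            return ReceptiveField(size=size, stride=jump, center0=center)
    raise AssertionError("unreachable")


def receptive_field_box(
    config: NetworkConfig,
    grid_position: tuple[int, int],
    layer: str = "conv4",
) -> tuple[tuple[int, int, int, int], bool]:
    """Source-pixel box (top, left, bottom, right; half-open) feeding one
    grid unit, clipped to image bounds; second element flags clipping."""
    geom = receptive_field_geometry(config, layer)
    n_layer = int(layer[-1])
    grid_side = config.input_size
    for i in range(n_layer - (0 if layer.startswith("pool") else 1)):
        grid_side //= config.pool_windows[i]
    r, c = grid_position
    if not (0 <= r < grid_side and 0 <= c < grid_side):
        raise ValueError(
            f"grid position {grid_position} outside {grid_side}x{grid_side} "
            f"grid of layer {layer}"
        )
    cy = geom.center0 + r * geom.stride
    cx = geom.center0 + c * geom.stride
    half = (geom.size - 1) / 2
    top, bottom = int(np.floor(cy - half)), int(np.floor(cy + half)) + 1
    left, right = int(np.floor(cx - half)), int(np.floor(cx + half)) + 1
    s = config.input_size
    clipped = top < 0 or left < 0 or bottom > s or right > s
    return (max(top, 0), max(left, 0), min(bottom, s), min(right, s)), clipped


def locate_peak(
    model: TrainedModel, image, feature_map_index: int, layer: str | None = None
) -> ActivationPeak:
    """Argmax of one feature map over the final convolution grid; ties are
    broken by the smallest row-major index."""
    n_maps = model.config.conv_feature_maps[-1]
    if not (0 <= feature_map_index < n_maps):
        raise ValueError(
            f"feature map index {feature_map_index} outside [0, {n_maps - 1}]"
        )
    layer = layer or f"conv{len(model.config.conv_feature_maps)}"
    grid = layer_activations(model, image, layer)[:, :, feature_map_index]
    flat_idx = int(np.argmax(grid))  # first maximum in row-major order
    r, c = divmod(flat_idx, grid.shape[1])
    return ActivationPeak(
        feature_map_index=feature_map_index,
        grid_position=(r, c),
        value=float(grid[r, c]),
    )


def _clamped_crop(
    image: RgbImage, center: tuple[float, float], side: int
) -> tuple[np.ndarray, tuple[int, int, int, int], bool]:
    """Square crop of exactly ``side`` pixels centered as close to
    ``center`` as the image bounds allow (window shifted inward at borders)."""
    h, w = image.shape
    side_r = min(side, h)
    side_c = min(side, w)
    top = int(round(center[0] - side_r / 2))
    left = int(round(center[1] - side_c / 2))
    t0, l0 = top, left
    top = min(max(top, 0), h - side_r)
    left = min(max(left, 0), w - side_c)
    clipped = (top, left) != (t0, l0) or side_r != side or side_c != side
    box = (top, left, top + side_r, left + side_c)
    return image.pixels[box[0] : box[2], box[1] : box[3]].copy(), box, clipped


def extract_segment(
    model: TrainedModel,
    image: RgbImage,
    peak: ActivationPeak,
    segment_side: int = DEFAULT_SEGMENT_SIDE,
) -> SegmentRecord:
    """Crop the fixed-size segment centered on the peak's traced
    receptive-field center."""
    geom = receptive_field_geometry(
        model.config, f"conv{len(model.config.conv_feature_maps)}"
    )
    r, c = peak.grid_position
    cy = geom.center0 + r * geom.stride
    cx = geom.center0 + c * geom.stride
    pixels, box, clipped = _clamped_crop(image, (cy, cx), segment_side)
    return SegmentRecord(
        pixels=pixels,
        source_id=image.source_id,
        center=(int(round(cy)), int(round(cx))),
        value=peak.value,
        feature_map_index=peak.feature_map_index,
        box=box,
        clipped=clipped,
    )


def top_k_segments(
    model: TrainedModel,
    images: Sequence[RgbImage],
    feature_map_index: int,
    k: int = 9,
    segment_side: int = DEFAULT_SEGMENT_SIDE,
) -> list[SegmentRecord]:
    """The k highest per-image peaks of one feature map across an image
    set, as traced segments in non-increasing activation order."""
    if k < 1:
        raise ValueError(f"k must be >= 1, got {k}")
    if len(images) == 0:
        raise ValueError("need at least one image")
    peaks = [(locate_peak(model, im, feature_map_index), im) for im in images]
    if k > len(peaks):
        warnings.warn(
            f"requested k={k} segments but only {len(peaks)} images available; "
            "returning all",
            stacklevel=2,
        )
        k = len(peaks)
    # stable sort keeps earlier images first at exact ties
    order = sorted(range(len(peaks)), key=lambda i: -peaks[i][0].value)[:k]
    return [
        extract_segment(model, peaks[i][1], peaks[i][0], segment_side) for i in order
    ]


def export_gallery(
    segments: Sequence[SegmentRecord], out_dir: str | Path, map_index: int
) -> Path:
    """Write one gallery grid PNG plus a tab-separated index; returns the
    index path."""
    out_dir = Path(out_dir)
    out_dir.mkdir(parents=True, exist_ok=True)
    if segments:
        side = max(max(s.pixels.shape[0], s.pixels.shape[1]) for s in segments)
        cols = int(np.ceil(np.sqrt(len(segments))))
        rows = int(np.ceil(len(segments) / cols))
        grid = np.full((rows * side, cols * side, 3), 255, dtype=np.uint8)
        for i, seg in enumerate(segments):
            r, c = divmod(i, cols)
            hh, ww = seg.pixels.shape[:2]
            grid[r * side : r * side + hh, c * side : c * side + ww] = seg.pixels
        iio.imwrite(out_dir / f"map_{map_index:02d}.png", grid)
    lines = ["map\trank\tsource\tcenter_row\tcenter_col\tvalue"]
    for rank, seg in enumerate(segments):
        lines.append(
            f"{map_index}\t{rank}\t{seg.source_id}\t{seg.center[0]}"
            f"\t{seg.center[1]}\t{seg.value:.6g}"
        )
    index = out_dir / f"map_{map_index:02d}.tsv"
    index.write_text("\n".join(lines) + "\n")
    return index
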