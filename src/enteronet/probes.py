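"""Analytically constructed probe networks and probe images.

A probe model carries hand-set weights whose response is known in closed
form: feature map 0 integrates local darkness (it peaks over dark
blobs), map 1 is a center-surround contrast detector, and every deeper
layer passes channels through unchanged so the final-layer peak sits
above the first-layer response. Probe models make traceback and
activation-statistics behavior verifiable without training.
"""

from __future__ import annotations

import numpy as np

from .cnn import NetworkConfig, TrainedModel, build_model
from .imgprep import RgbImage


def make_probe_model(input_size: int = 200) -> TrainedModel:
    """Two-map probe network: darkness detector + contrast detector."""
    cfg = NetworkConfig(
        conv_feature_maps=(2, 2, 2, 2),
        conv_kernels=(5, 5, 5, 3),
        pool_windows=(2, 4, 5, 5),
        fc_width=4,
        dropout_p=0.0,
        input_size=input_size,
    )
    model = build_model(cfg, init_seed=0)
    c1 = model.convs[0]
    c1.weight[:] = 0
    c1.bias[:] = 0
    # map 0: mean darkness of the 5x5 window, shifted so background is off
    c1.weight[0, :, :, :] = -1.0 / 75.0
    c1.bias[0] = 0.55
    # map 1: center-surround contrast on the green channel
    c1.weight[1, 1, :, :] = -1.0 / 24.0
    c1.weight[1, 1, 2, 2] = 1.0
    c1.bias[1] = 0.0
    for conv in model.convs[1:]:
        conv.weight[:] = 0
        conv.bias[:] = 0
        k = conv.weight.shape[2]
        for ch in range(conv.weight.shape[0]):
            conv.weight[ch, ch, k // 2, k // 2] = 1.0
    return model


def blank_image_with_blob(
    rng: np.random.Generator,
    size: int,
    blob_radius: int = 12,
    margin: int = 20,
) -> tuple[RgbImage, tuple[int, int, int, int]]:
    """Bright image with one dark disc at a random position.

    Returns the image and the blob bounding box (top, left, bottom,
    right; half-open) for localization checks.
    """
    px = np.full((size, size, 3), 220, dtype=np.uint8)
    cy = int(rng.integers(margin, size - margin))
    cx = int(rng.integers(margin, size - margin))
    yy, xx = np.mgrid[0:size, 0:size]
    mask = (yy - cy) ** 2 + (xx - cx) ** 2 <= blob_radius**2
    px[mask] = (40, 30, 60)
    bbox = (cy - blob_radius, cx - blob_radius, cy + blob_radius + 1, cx + blob_radius + 1)
    return RgbImage(px, source_id=f"blob_{cy}_{cx}"), bbox
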