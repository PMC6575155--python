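"""Canonical configurations: the full-size architecture and a desk-scale
variant for synthetic-cohort experiments.

The full-size network is the published architecture (16/32/32/32 maps,
5/5/5/3 kernels, 2/4/5/5 pools, 1024-wide fully connected layer,
1000x1000 input). The desk-scale variant keeps the same depth, kernel
sizes and pooling schedule but narrows the feature maps and shrinks the
input to 200x200 — one pooling period — so a complete case-preserving
10-fold cross-validation trains in minutes on one CPU. At 200x200 the
final convolution grid is 1x1, i.e. the classifier head sees one global
maximum per map; the desk-scale synthetic textures therefore separate
classes through local appearance (blob shape and ridge strength), which
a maximum can see, rather than through blob counts, which it cannot.
"""

from __future__ import annotations

from .cnn import NetworkConfig, TrainingConfig
from .imgprep import AugmentationConfig
from .synthgen import ClassTexture, SyntheticCohortSpec


def full_size_network() -> NetworkConfig:
    return NetworkConfig()


#: desk-scale class textures: well separated in blob shape/density and
#: ridge amplitude so that the cohort is separable by design
DESK_TEXTURES = {
    "control": ClassTexture(
        blob_density=150.0, blob_eccentricity=0.10, ridge_amplitude=40.0,
        blob_radius=3.5, ridge_period=30.0, noise_sd=2.0,
    ),
    "CD": ClassTexture(
        blob_density=300.0, blob_eccentricity=0.50, ridge_amplitude=12.0,
        blob_radius=6.0, ridge_period=30.0, noise_sd=2.0,
    ),
    "EE": ClassTexture(
        blob_density=600.0, blob_eccentricity=0.85, ridge_amplitude=2.0,
        blob_radius=9.0, ridge_period=30.0, noise_sd=2.0,
    ),
}


def desk_scale_cohort_spec(seed: int = 0, **overrides) -> SyntheticCohortSpec:
    """30 cases (10 per class), 5 images each, 200x200 pixels."""
    kw = dict(
        n_cases_per_class=10,
        images_per_case=5,
        image_height=200,
        image_width=200,
        class_texture_params=dict(DESK_TEXTURES),
        seed=seed,
    )
    kw.update(overrides)
    return SyntheticCohortSpec(**kw)


def desk_scale_network(**overrides) -> NetworkConfig:
    kw = dict(
        conv_feature_maps=(4, 8, 8, 16),
        conv_kernels=(5, 5, 5, 3),
        pool_windows=(2, 4, 5, 5),
        fc_width=32,
        dropout_p=0.25,
        input_size=200,
    )
    kw.update(overrides)
    return NetworkConfig(**kw)


def desk_scale_training(seed: int = 0, **overrides) -> TrainingConfig:
    kw = dict(epochs=20, batch_size=8, learning_rate=3e-3, seed=seed)
    kw.update(overrides)
    return TrainingConfig(**kw)


def desk_scale_augmentation(seed: int = 0, **overrides) -> AugmentationConfig:
    """One full-frame patch per 200x200 image, no reflections or gamma:
    the augmentation machinery is exercised but adds no training cost."""
    kw = dict(
        n_train_patches=1,
        patch_size=200,
        gamma_range=(1.0, 1.0),
        include_reflections=False,
        seed=seed,
    )
    kw.update(overrides)
    return AugmentationConfig(**kw)
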