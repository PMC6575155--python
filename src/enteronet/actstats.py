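"""Per-filter class-activation statistics.

Each image contributes one observation per feature map: the maximum
rectified activation of that map on the final convolution grid. For a
target class, a one-sided Welch (unequal-variance) two-sample t test
asks, filter by filter, whether the target class's activations are
higher than those of the pooled other classes — a proxy for the
prevalence of the tissue pattern that the filter responds to. Holm
step-down adjusted p values are reported alongside the raw ones.

The observational unit is the image (not the patch) to limit
pseudo-replication; a patch-level mode is available and logged loudly.
"""

from __future__ import annotations

import logging
from dataclasses import dataclass
from pathlib import Path
from typing import Sequence

import numpy as np
from scipy import stats
from statsmodels.stats.multitest import multipletests

from .cnn import CLASS_ORDER, TrainedModel, layer_activations

logger = logging.getLogger(__name__)


@dataclass(frozen=True)
class FilterActivationSample:
    """Per-image maxima: one value per feature map at the final conv layer."""

    image_id: str
    class_label: str
    values: np.ndarray

    def __post_init__(self) -> None:
        v = np.asarray(self.values, dtype=float)
        if v.ndim != 1:
            raise ValueError("values must be a 1-d vector of per-map maxima")
        if np.any(v < 0):
            raise ValueError("rectified activations cannot be negative")
        object.__setattr__(self, "values", v)


@dataclass(frozen=True)
class TTestResult:
    feature_map_index: int
    t: float
    df: float
    p: float  # one-sided, H1: target > rest
    n_target: int
    n_rest: int
    p_adjusted: float | None = None


def collect_max_activations(
    model: TrainedModel,
    images_with_labels: Sequence[tuple],
    unit: str = "image",
) -> list[FilterActivationSample]:
    """Per-map maxima of the final convolution grid, one sample per image.

    ``images_with_labels`` is a sequence of (image, class_label); images
    may be RgbImage, Patch or arrays sized to the model input.
    """
    if len(images_with_labels) == 0:
        raise ValueError("need at least one labeled image")
    if unit != "image":
        logger.warning(
            "collect_max_activations running at unit=%r: patch-level samples "
            "pseudo-replicate cases and inflate test power", unit,
        )
    layer = f"conv{len(model.config.conv_feature_maps)}"
    out = []
    for i, (image, label) in enumerate(images_with_labels):
        grid = layer_activations(model, image, layer)
        image_id = getattr(image, "source_id", f"image_{i}")
        out.append(
            FilterActivationSample(
                image_id=image_id,
                class_label=label,
                values=grid.max(axis=(0, 1)),
            )
        )
    return out


def welch_one_sided(
    target: np.ndarray, rest: np.ndarray
) -> tuple[float, float, float]:
    """Welch two-sample t, Welch–Satterthwaite df, and one-sided p for
    H1: mean(target) > mean(rest)."""
    target = np.asarray(target, dtype=float)
    rest = np.asarray(rest, dtype=float)
    res = stats.ttest_ind(target, rest, equal_var=False, alternative="greater")
    return float(res.statistic), float(res.df), float(res.pvalue)


def per_filter_class_test(
    samples: Sequence[FilterActivationSample],
    target_class: str,
    adjust: str = "holm",
) -> list[TTestResult]:
    """One Welch test per feature map of target class vs pooled others."""
    if target_class not in CLASS_ORDER:
        raise ValueError(f"unknown class {target_class!r}; expected one of {CLASS_ORDER}")
    tgt = np.stack([s.values for s in samples if s.class_label == target_class]) \
        if any(s.class_label == target_class for s in samples) else np.empty((0, 0))
    rest = np.stack([s.values for s in samples if s.class_label != target_class]) \
        if any(s.class_label != target_class for s in samples) else np.empty((0, 0))
    if tgt.shape[0] < 2:
        raise ValueError(
            f"target group {target_class!r} has {tgt.shape[0]} samples; need >= 2"
        )
    if rest.shape[0] < 2:
        raise ValueError(
            f"pooled complement of {target_class!r} has {rest.shape[0]} samples; need >= 2"
        )
    n_maps = tgt.shape[1]
    results = []
    for j in range(n_maps):
        t, df, p = welch_one_sided(tgt[:, j], rest[:, j])
        results.append(
            TTestResult(
                feature_map_index=j, t=t, df=df, p=p,
                n_target=tgt.shape[0], n_rest=rest.shape[0],
            )
        )
    if adjust is not None:
        raw = np.array([r.p for r in results])
        _, adj, _, _ = multipletests(raw, method=adjust)
        results = [
            TTestResult(
                feature_map_index=r.feature_map_index, t=r.t, df=r.df, p=r.p,
                n_target=r.n_target, n_rest=r.n_rest, p_adjusted=float(a),
            )
            for r, a in zip(results, adj)
        ]
    return results


def pairwise_class_tests(
    samples: Sequence[FilterActivationSample],
    target_class: str,
    other_class: str,
) -> list[TTestResult]:
    """Pairwise variant: target class vs one named other class."""
    kept = [s for s in samples if s.class_label in (target_class, other_class)]
    return per_filter_class_test(kept, target_class)


def write_test_table(results: Sequence[TTestResult], path: str | Path) -> None:
    lines = ["map\tt\tdf\tp\tp_holm\tn_target\tn_rest"]
    for r in results:
        adj = "" if r.p_adjusted is None else f"{r.p_adjusted:.6g}"
        lines.append(
            f"{r.feature_map_index}\t{r.t:.6g}\t{r.df:.6g}\t{r.p:.6g}"
            f"\t{adj}\t{r.n_target}\t{r.n_rest}"
        )
    Path(path).write_text("\n".join(lines) + "\n")
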