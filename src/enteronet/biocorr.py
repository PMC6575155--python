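"""Biomarker <-> biopsy-feature correlation via sparse linear models.

Each case (biopsy) is summarized by the per-feature-map maxima of its
CNN activations — the max, over all the case's images, of each image's
final-layer grid maximum — together with the traced source segment that
produced each maximum. One lasso regression per feature map then maps
the case's noninvasive biomarker panel to that activation value. At
prediction time, negative linear estimates are clamped to zero (ReLU
activations are nonnegative, so a negative estimate carries no signal);
estimated activations are scored by mean squared error against the CNN's
actual activations, and reconstructed visually by matching each
estimate to the training segment with the nearest stored activation.

A random-forest importance ranking with backward elimination maps out
how the cross-validated error evolves as the least informative markers
are dropped.
"""

from __future__ import annotations

import logging
from dataclasses import dataclass, field
from pathlib import Path
from typing import Sequence

import numpy as np
import pandas as pd
from sklearn.ensemble import RandomForestRegressor
from sklearn.inspection import permutation_importance
from sklearn.linear_model import Lasso, LassoCV
from sklearn.model_selection import KFold

from .cnn import TrainedModel
from .imgprep import RgbImage
from .synthgen import BiomarkerTable, CohortManifest
from .traceviz import (
    DEFAULT_SEGMENT_SIDE,
    SegmentRecord,
    extract_segment,
    locate_peak,
)

logger = logging.getLogger(__name__)

__all__ = [
    "ActivationTargetMatrix",
    "LassoModelSet",
    "ReconstructionResult",
    "build_activation_targets",
    "fit_lasso_set",
    "predict_activations",
    "evaluate_activation_mse",
    "cross_validate_lasso",
    "match_segments",
    "importance_elimination_curve",
]


@dataclass
class ActivationTargetMatrix:
    """Case x feature-map activation maxima plus the traced segments.

    ``values`` is a DataFrame (rows case ids, one column per map);
    ``segments[(case_id, map)]`` holds the SegmentRecord of the image
    position that realized the case maximum.
    """

    values: pd.DataFrame
    segments: dict[tuple[str, int], SegmentRecord] = field(default_factory=dict)

    @property
    def n_maps(self) -> int:
        return self.values.shape[1]

    @property
    def case_ids(self) -> list[str]:
        return list(self.values.index)


def build_activation_targets(
    model: TrainedModel,
    manifest: CohortManifest,
    segment_side: int = DEFAULT_SEGMENT_SIDE,
) -> ActivationTargetMatrix:
    """Case-level activation maxima over all the case's images, with the
    argmax segment traced for each (case, map)."""
    n_maps = model.config.conv_feature_maps[-1]
    rows = {}
    segments: dict[tuple[str, int], SegmentRecord] = {}
    for rec in manifest.records:
        if not rec.image_paths:
            raise ValueError(f"case {rec.case_id} has no images")
        best = np.full(n_maps, -np.inf)
        for rel in rec.image_paths:
            image = RgbImage.load(
                manifest.resolve(rel), source_id=f"{rec.case_id}/{Path(rel).stem}"
            )
            for j in range(n_maps):
                peak = locate_peak(model, image, j)
                if peak.value > best[j]:
                    best[j] = peak.value
                    segments[(rec.case_id, j)] = extract_segment(
                        model, image, peak, segment_side
                    )
        rows[rec.case_id] = best
    values = pd.DataFrame.from_dict(
        rows, orient="index", columns=[f"map_{j}" for j in range(n_maps)]
    )
    values.index.name = "case_id"
    return ActivationTargetMatrix(values=values, segments=segments)


@dataclass
class LassoModelSet:
    """One sparse linear model per feature map, sharing marker order and
    the training-set standardization of the markers."""

    marker_names: list[str]
    coefficients: np.ndarray  # (n_maps, n_markers), on standardized markers
    intercepts: np.ndarray  # (n_maps,)
    penalties: np.ndarray  # (n_maps,)
    marker_mean: np.ndarray
    marker_scale: np.ndarray

    @property
    def n_maps(self) -> int:
        return len(self.intercepts)


def _align(markers: BiomarkerTable, targets: ActivationTargetMatrix):
    shared = [c for c in targets.case_ids if c in set(markers.case_ids)]
    if not shared:
        raise ValueError("no overlapping case ids between markers and targets")
    x = markers.data.loc[shared]
    if x.isna().any().any():
        na_cols = list(x.columns[x.isna().any()])
        raise ValueError(
            f"biomarker table has missing values in columns {na_cols}; "
            "impute or drop explicitly before fitting"
        )
    return x.to_numpy(dtype=float), targets.values.loc[shared].to_numpy(dtype=float), shared


def fit_lasso_set(
    markers: BiomarkerTable,
    targets: ActivationTargetMatrix,
    cv: int = 5,
    seed: int = 0,
    alpha: float | None = None,
) -> LassoModelSet:
    """Fit one lasso per feature map on standardized markers.

    The penalty is selected per map by inner ``cv``-fold cross-validation
    unless ``alpha`` fixes it. Standardization statistics come from the
    training cases only and are stored on the model set.
    """
    x, y, shared = _align(markers, targets)
    if len(shared) < 3:
        raise ValueError(f"need at least 3 shared cases, got {len(shared)}")
    mean = x.mean(axis=0)
    scale = x.std(axis=0, ddof=0)
    scale[scale == 0] = 1.0
    xs = (x - mean) / scale
    n_maps = y.shape[1]
    coefs = np.zeros((n_maps, x.shape[1]))
    intercepts = np.zeros(n_maps)
    penalties = np.zeros(n_maps)
    for j in range(n_maps):
        if alpha is not None:
            mdl = Lasso(alpha=alpha, max_iter=50_000)
        else:
            mdl = LassoCV(
                cv=KFold(cv, shuffle=True, random_state=seed),
                alphas=60,
                max_iter=50_000,
                random_state=seed,
            )
        mdl.fit(xs, y[:, j])
        coefs[j] = mdl.coef_
        intercepts[j] = mdl.intercept_
        penalties[j] = mdl.alpha_ if alpha is None else alpha
    return LassoModelSet(
        marker_names=list(markers.marker_names),
        coefficients=coefs,
        intercepts=intercepts,
        penalties=penalties,
        marker_mean=mean,
        marker_scale=scale,
    )


def predict_activations(
    models: LassoModelSet,
    marker_row: pd.Series | dict,
    clamp_negative: bool = True,
) -> np.ndarray:
    """Per-map linear estimates for one case's marker panel.

    Negative raw estimates are clamped to zero by default (activations
    are nonnegative); ``clamp_negative=False`` returns raw estimates so
    a caller may instead drop them from scoring.
    """
    if isinstance(marker_row, dict):
        marker_row = pd.Series(marker_row)
    missing = [m for m in models.marker_names if m not in marker_row.index]
    if missing:
        raise ValueError(f"marker_row lacks marker(s): {', '.join(missing)}")
    x = marker_row[models.marker_names].to_numpy(dtype=float)
    xs = (x - models.marker_mean) / models.marker_scale
    est = models.coefficients @ xs + models.intercepts
    if clamp_negative:
        est = np.maximum(est, 0.0)
    return est


def evaluate_activation_mse(
    estimated: np.ndarray, actual: np.ndarray
) -> tuple[np.ndarray, float]:
    """Per-case MSE (mean over maps of squared differences) and its mean.

    ``estimated`` and ``actual`` are (n_cases, n_maps) arrays aligned by
    case.
    """
    estimated = np.atleast_2d(np.asarray(estimated, dtype=float))
    actual = np.atleast_2d(np.asarray(actual, dtype=float))
    if estimated.shape != actual.shape:
        raise ValueError(
            f"shape mismatch: estimated {estimated.shape} vs actual {actual.shape}"
        )
    per_case = np.mean((estimated - actual) ** 2, axis=1)
    return per_case, float(per_case.mean())


def cross_validate_lasso(
    markers: BiomarkerTable,
    targets: ActivationTargetMatrix,
    k: int = 10,
    seed: int = 0,
    standardize_targets: bool = False,
    marker_subset: Sequence[str] | None = None,
) -> dict:
    """K-fold cross-validation of the lasso set over cases.

    Returns mean MSE across held-out cases, the variance of per-fold MSE,
    and per-fold values. ``standardize_targets`` reports the error on
    unit-variance activation scale instead of the raw scale.
    """
    if marker_subset is not None:
        markers = BiomarkerTable(markers.data[list(marker_subset)])
    x_all, y_all, shared = _align(markers, targets)
    n = len(shared)
    k = min(k, n)
    if k < 2:
        raise ValueError("need at least 2 folds / cases")
    if standardize_targets:
        sd = y_all.std(axis=0, ddof=0)
        sd[sd == 0] = 1.0
        y_all = y_all / sd
    kf = KFold(n_splits=k, shuffle=True, random_state=seed)
    frame = markers.data.loc[shared]
    fold_mses = []
    for train_idx, test_idx in kf.split(np.arange(n)):
        tr_cases = [shared[i] for i in train_idx]
        te_cases = [shared[i] for i in test_idx]
        sub_targets = ActivationTargetMatrix(
            values=pd.DataFrame(
                y_all[train_idx], index=tr_cases, columns=targets.values.columns
            )
        )
        model_set = fit_lasso_set(
            BiomarkerTable(frame.loc[tr_cases]), sub_targets, seed=seed
        )
        est = np.stack(
            [predict_activations(model_set, frame.loc[c]) for c in te_cases]
        )
        _, mse = evaluate_activation_mse(est, y_all[test_idx])
        fold_mses.append(mse)
    fold_mses = np.array(fold_mses)
    return {
        "mean_mse": float(fold_mses.mean()),
        "fold_mse_variance": float(fold_mses.var(ddof=1)) if k > 1 else 0.0,
        "fold_mses": fold_mses.tolist(),
    }


@dataclass
class ReconstructionResult:
    """Per-map nearest-segment reconstruction of one case."""

    estimates: np.ndarray
    matched: list[SegmentRecord]
    differences: np.ndarray
    order: np.ndarray  # map indices sorted by ascending difference
    mse: float


def match_segments(
    estimates: np.ndarray,
    library: dict[tuple[str, int], SegmentRecord],
) -> ReconstructionResult:
    """Match each estimated activation to the training segment with the
    nearest stored activation value (ties: earliest library insertion)."""
    estimates = np.asarray(estimates, dtype=float)
    n_maps = len(estimates)
    matched: list[SegmentRecord] = []
    diffs = np.zeros(n_maps)
    for j in range(n_maps):
        candidates = [s for (cid, m), s in library.items() if m == j]
        if not candidates:
            raise ValueError(f"segment library empty for feature map {j}")
        best = min(candidates, key=lambda s: abs(s.value - estimates[j]))
        matched.append(best)
        diffs[j] = abs(best.value - estimates[j])
    order = np.argsort(diffs, kind="stable")
    actual = np.array([m.value for m in matched])
    mse = float(np.mean((estimates - actual) ** 2))
    return ReconstructionResult(
        estimates=estimates, matched=matched, differences=diffs, order=order, mse=mse
    )


def rank_marker_importance(
    markers: BiomarkerTable,
    targets: ActivationTargetMatrix,
    n_trees: int = 500,
    seed: int = 0,
) -> pd.Series:
    """Random-forest permutation importance of each marker for predicting
    the activation matrix (averaged over feature maps)."""
    x, y, _ = _align(markers, targets)
    rf = RandomForestRegressor(n_estimators=n_trees, random_state=seed, n_jobs=1)
    rf.fit(x, y.ravel() if y.shape[1] == 1 else y)
    imp = permutation_importance(
        rf, x, y, n_repeats=5, random_state=seed, n_jobs=1
    )
    return pd.Series(imp.importances_mean, index=markers.marker_names).sort_values(
        ascending=False
    )


def importance_elimination_curve(
    markers: BiomarkerTable,
    targets: ActivationTargetMatrix,
    k: int = 10,
    n_trees: int = 500,
    seed: int = 0,
) -> dict:
    """Backward elimination guided by random-forest importance.

    Starting from the full marker set, the least important marker is
    removed and the lasso set re-cross-validated at every step, down to
    one marker. Returns the MSE curve (one point per subset size, largest
    first), the removal order, and the argmin subset.
    """
    current = list(markers.marker_names)
    if len(current) < 1:
        raise ValueError("need at least one marker")
    if len(current) == 1:
        logger.warning("single marker: elimination curve has length 1")
    curve = []
    subsets = []
    while current:
        cv = cross_validate_lasso(
            markers, targets, k=k, seed=seed, marker_subset=current
        )
        curve.append(cv["mean_mse"])
        subsets.append(list(current))
        if len(current) == 1:
            break
        imp = rank_marker_importance(
            BiomarkerTable(markers.data[current]), targets, n_trees=n_trees, seed=seed
        )
        least = imp.index[-1]
        logger.info(
            "eliminating %r (importance %.4g); %d markers remain",
            least, imp.iloc[-1], len(current) - 1,
        )
        current.remove(least)
    best = int(np.argmin(curve))
    return {
        "subset_sizes": [len(s) for s in subsets],
        "mse_curve": curve,
        "subsets": subsets,
        "best_subset": subsets[best],
        "best_mse": curve[best],
    }
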