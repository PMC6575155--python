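"""Case-preserving cross-validation and aggregate evaluation metrics.

Folds are split at the case (patient) level so that no case's images
ever appear in both the training and testing side of a fold — the
leakage control that matters most when several images derive from one
biopsy. Accuracy is reported per image (each image classified
individually from its 15-test-patch mean probabilities) and per case
(after averaging image-level probabilities within a case). The
false-negative rate is the fraction of diseased cases (CD or EE)
predicted as control.
"""

from __future__ import annotations

import dataclasses
import logging
from dataclasses import dataclass, field
from pathlib import Path
from typing import Sequence

import numpy as np
from sklearn.model_selection import StratifiedKFold

from .cnn import (
    CLASS_ORDER,
    NetworkConfig,
    TrainingConfig,
    build_model,
    predict_case,
    predict_image,
    train_model,
)
from .imgprep import AugmentationConfig, RgbImage, augment_training_set
from .synthgen import CohortManifest

logger = logging.getLogger(__name__)


@dataclass
class FoldAssignment:
    k: int
    assignment: dict[str, int]  # case_id -> fold index
    seed: int = 0

    def fold_cases(self, fold: int) -> list[str]:
        return [c for c, f in self.assignment.items() if f == fold]

    def save(self, path: str | Path) -> None:
        lines = ["case_id\tfold"] + [
            f"{c}\t{f}" for c, f in sorted(self.assignment.items())
        ]
        Path(path).write_text("\n".join(lines) + "\n")

    @classmethod
    def load(cls, path: str | Path) -> "FoldAssignment":
        lines = Path(path).read_text().splitlines()[1:]
        assignment = {}
        for line in lines:
            case_id, fold = line.split("\t")
            assignment[case_id] = int(fold)
        return cls(k=max(assignment.values()) + 1, assignment=assignment)


@dataclass
class ConfusionMatrix:
    """3x3 count grid; rows true class, columns predicted, order
    (control, CD, EE)."""

    counts: np.ndarray = field(
        default_factory=lambda: np.zeros((3, 3), dtype=np.int64)
    )

    def add(self, true_label: str, pred_label: str) -> None:
        self.counts[CLASS_ORDER.index(true_label), CLASS_ORDER.index(pred_label)] += 1

    @property
    def total(self) -> int:
        return int(self.counts.sum())

    @property
    def accuracy(self) -> float:
        return float(np.trace(self.counts)) / self.total

    def false_negative_rate(self, over_all: bool = False) -> float:
        """Diseased (CD, EE) predicted control, over diseased cases.

        With ``over_all=True`` the denominator is all cases instead.
        """
        ctrl = CLASS_ORDER.index("control")
        diseased_rows = [i for i in range(len(CLASS_ORDER)) if i != ctrl]
        fn = int(self.counts[diseased_rows, ctrl].sum())
        denom = self.total if over_all else int(self.counts[diseased_rows, :].sum())
        return fn / denom if denom else 0.0

    def __add__(self, other: "ConfusionMatrix") -> "ConfusionMatrix":
        return ConfusionMatrix(self.counts + other.counts)


@dataclass
class EvaluationReport:
    per_image_accuracy: float
    per_case_accuracy: float
    false_negative_rate: float
    confusion: ConfusionMatrix  # case level
    image_confusion: ConfusionMatrix
    per_fold: list[dict] = field(default_factory=list)

    def summary(self) -> str:
        lines = [
            f"per-image accuracy: {self.per_image_accuracy:.4f}",
            f"per-case accuracy:  {self.per_case_accuracy:.4f}",
            f"false-negative rate (diseased -> control): {self.false_negative_rate:.4f}",
            "case confusion (rows true, cols predicted; control, CD, EE):",
        ]
        for row in self.confusion.counts:
            lines.append("  " + "\t".join(str(v) for v in row))
        return "\n".join(lines)


def make_case_preserving_folds(
    manifest: CohortManifest, k: int = 10, seed: int = 0
) -> FoldAssignment:
    """Class-stratified partition of cases into k folds.

    Every case lands in exactly one fold; within each class the fold
    sizes differ by at most one. Requires at least k cases per class.
    """
    labels = manifest.classes()
    for cls_label in set(labels):
        n_cls = labels.count(cls_label)
        if n_cls < k:
            raise ValueError(
                f"class {cls_label!r} has {n_cls} cases, fewer than k={k} folds"
            )
    case_ids = manifest.case_ids
    skf = StratifiedKFold(n_splits=k, shuffle=True, random_state=seed)
    assignment: dict[str, int] = {}
    for fold, (_, test_idx) in enumerate(skf.split(case_ids, labels)):
        for i in test_idx:
            assignment[case_ids[i]] = fold
    return FoldAssignment(k=k, assignment=assignment, seed=seed)


def aggregate_metrics(
    true_labels: Sequence[str],
    predicted_labels: Sequence[str],
    fn_over_all: bool = False,
) -> tuple[ConfusionMatrix, float, float]:
    """Confusion counts, accuracy (= trace/total), and false-negative rate."""
    if len(true_labels) != len(predicted_labels):
        raise ValueError("label sequences must have equal length")
    cm = ConfusionMatrix()
    for t, p in zip(true_labels, predicted_labels):
        if t not in CLASS_ORDER or p not in CLASS_ORDER:
            raise ValueError(f"label outside class set {CLASS_ORDER}: ({t!r}, {p!r})")
        cm.add(t, p)
    return cm, cm.accuracy, cm.false_negative_rate(over_all=fn_over_all)


def _load_case_images(manifest: CohortManifest, case_id: str) -> list[RgbImage]:
    rec = next(r for r in manifest.records if r.case_id == case_id)
    return [
        RgbImage.load(manifest.resolve(p), source_id=f"{case_id}/{Path(p).stem}")
        for p in rec.image_paths
    ]


def _train_fold_model(
    manifest: CohortManifest,
    train_cases: Sequence[str],
    ncfg: NetworkConfig,
    tcfg: TrainingConfig,
    acfg: AugmentationConfig,
    fold_seed: int,
):
    labels_by_case = {r.case_id: r.class_label for r in manifest.records}
    images, labels = [], []
    for cid in train_cases:
        for img in _load_case_images(manifest, cid):
            images.append(img)
            labels.append(labels_by_case[cid])
    aug = dataclasses.replace(acfg, seed=fold_seed)
    patches = augment_training_set(images, aug)
    # patch count per image is fixed, so labels repeat in image order
    per_image = len(patches) // len(images)
    patch_labels = [l for l in labels for _ in range(per_image)]
    model = build_model(ncfg, init_seed=fold_seed)
    train_model(
        model, patches, patch_labels, dataclasses.replace(tcfg, seed=fold_seed)
    )
    return model


def run_cross_validation(
    manifest: CohortManifest,
    folds: FoldAssignment,
    ncfg: NetworkConfig,
    tcfg: TrainingConfig,
    acfg: AugmentationConfig,
) -> EvaluationReport:
    """Train one model per fold on the train-side cases' augmented patches
    and classify the held-out fold's images and cases; aggregate over folds.
    """
    labels_by_case = {r.case_id: r.class_label for r in manifest.records}
    image_cm = ConfusionMatrix()
    case_cm = ConfusionMatrix()
    per_fold = []
    for fold in range(folds.k):
        test_cases = folds.fold_cases(fold)
        train_cases = [c for c in manifest.case_ids if c not in set(test_cases)]
        train_classes = {labels_by_case[c] for c in train_cases}
        missing = set(CLASS_ORDER) - train_classes
        if missing:
            raise ValueError(
                f"fold {fold}: training side lacks class(es) {sorted(missing)}"
            )
        fold_seed = tcfg.seed + 1009 * fold
        model = _train_fold_model(manifest, train_cases, ncfg, tcfg, acfg, fold_seed)
        fold_image_cm = ConfusionMatrix()
        fold_case_cm = ConfusionMatrix()
        for cid in test_cases:
            images = _load_case_images(manifest, cid)
            true = labels_by_case[cid]
            for img in images:
                fold_image_cm.add(true, predict_image(model, img).argmax_label())
            _, case_label = predict_case(model, images)
            fold_case_cm.add(true, case_label)
        logger.info(
            "fold %d: image acc %.3f, case acc %.3f",
            fold, fold_image_cm.accuracy, fold_case_cm.accuracy,
        )
        image_cm = image_cm + fold_image_cm
        case_cm = case_cm + fold_case_cm
        per_fold.append(
            {
                "fold": fold,
                "per_image_accuracy": fold_image_cm.accuracy,
                "per_case_accuracy": fold_case_cm.accuracy,
                "n_cases": len(test_cases),
            }
        )
    return EvaluationReport(
        per_image_accuracy=image_cm.accuracy,
        per_case_accuracy=case_cm.accuracy,
        false_negative_rate=case_cm.false_negative_rate(),
        confusion=case_cm,
        image_confusion=image_cm,
        per_fold=per_fold,
    )


def cross_site_transfer(
    site_a: CohortManifest,
    site_b: CohortManifest,
    shared_other_classes: CohortManifest,
    ncfg: NetworkConfig,
    tcfg: TrainingConfig,
    acfg: AugmentationConfig,
    allocation_fraction: float = 0.5,
    seed: int = 0,
    subset_ids: Sequence[str] | None = None,
) -> dict:
    """Leave-one-case-out site-transfer protocol.

    ``site_a`` holds the target-class cases of the training site and
    ``site_b`` the same class from the held-out site; control/CD cases
    from ``shared_other_classes`` are randomly allocated (a seeded
    fraction) to each model. For each of the n site-A cases a model is
    trained with that case removed and evaluated on every site-B case.
    Returns a table of per-image and per-case accuracies (2 rows x n
    models) plus, when ``subset_ids`` names site-A cases, one extra model
    trained on that subset only.
    """
    n = len(site_a.records)
    if n < 2:
        raise ValueError(f"need at least 2 site-A cases, got {n}")
    rng = np.random.default_rng(seed)
    other_ids = shared_other_classes.case_ids
    b_labels = [r.class_label for r in site_b.records]

    def _evaluate(model) -> tuple[float, float]:
        img_true, img_pred, case_true, case_pred = [], [], [], []
        for rec in site_b.records:
            images = _load_case_images(site_b, rec.case_id)
            for img in images:
                img_true.append(rec.class_label)
                img_pred.append(predict_image(model, img).argmax_label())
            _, label = predict_case(model, images)
            case_true.append(rec.class_label)
            case_pred.append(label)
        img_acc = float(np.mean([t == p for t, p in zip(img_true, img_pred)]))
        case_acc = float(np.mean([t == p for t, p in zip(case_true, case_pred)]))
        return img_acc, case_acc

    def _train(a_cases: list[str], model_seed: int):
        # allocate within each class so no class disappears from training
        alloc: list[str] = []
        by_class: dict[str, list[str]] = {}
        for r in shared_other_classes.records:
            by_class.setdefault(r.class_label, []).append(r.case_id)
        for ids in by_class.values():
            n_alloc = max(1, int(round(allocation_fraction * len(ids))))
            alloc.extend(rng.choice(ids, size=n_alloc, replace=False))
        logger.info("transfer model (seed %d): allocated others %s", model_seed, alloc)
        merged = CohortManifest(
            records=[r for r in site_a.records if r.case_id in set(a_cases)]
            + [r for r in shared_other_classes.records if r.case_id in set(alloc)],
            root=site_a.root,
        )
        return _train_fold_model(
            merged, merged.case_ids, ncfg, tcfg, acfg, model_seed
        )

    per_image, per_case = [], []
    for i, rec in enumerate(site_a.records):
        a_cases = [r.case_id for r in site_a.records if r.case_id != rec.case_id]
        model = _train(a_cases, seed + 211 * (i + 1))
        img_acc, case_acc = _evaluate(model)
        per_image.append(img_acc)
        per_case.append(case_acc)

    result = {
        "removed_case": [r.case_id for r in site_a.records],
        "per_image_accuracy": per_image,
        "per_case_accuracy": per_case,
    }
    if subset_ids is not None:
        model = _train(list(subset_ids), seed + 97)
        img_acc, case_acc = _evaluate(model)
        result["subset_model"] = {
            "cases": list(subset_ids),
            "per_image_accuracy": img_acc,
            "per_case_accuracy": case_acc,
        }
    return result


def write_report(report: EvaluationReport, out_dir: str | Path) -> None:
    out_dir = Path(out_dir)
    out_dir.mkdir(parents=True, exist_ok=True)
    (out_dir / "summary.txt").write_text(report.summary() + "\n")
    lines = ["fold\tper_image_accuracy\tper_case_accuracy\tn_cases"]
    for row in report.per_fold:
        lines.append(
            f"{row['fold']}\t{row['per_image_accuracy']:.6f}"
            f"\t{row['per_case_accuracy']:.6f}\t{row['n_cases']}"
        )
    (out_dir / "folds.tsv").write_text("\n".join(lines) + "\n")
    np.savetxt(
        out_dir / "case_confusion.tsv", report.confusion.counts, fmt="%d", delimiter="\t"
    )
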