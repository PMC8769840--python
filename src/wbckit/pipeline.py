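"""End-to-end orchestration: segment, crop, featurize, classify, report.

The full run segments every input smear, scores each mask against its
manual reference when one is available, trains the convolutional
feature extractor on labeled single-cell crops, fuses its penultimate
activations with pooled local descriptors, and evaluates the
sparse-representation classifier by stratified cross-validation.  All
randomness flows from the configuration seed, so a rerun with the same
config produces byte-identical report bodies; the config hash is
recorded in every report.
"""

from __future__ import annotations

import logging
from dataclasses import dataclass, field
from pathlib import Path

import numpy as np
import pandas as pd
from skimage.measure import label, regionprops
from skimage.transform import resize
from sklearn.model_selection import StratifiedKFold

from . import __version__
from . import cnn as cnn_mod
from . import metrics as metrics_mod
from . import sift as sift_mod
from .classifier import Hyperparams, WTPTSSRClassifier, fuse_features
from .config import PipelineConfig
from .io import read_image, read_mask, write_mask
from .segmentation import segment_nucleus
from .synthdata import CellClassSpec, make_cell_crops

logger = logging.getLogger(__name__)

__all__ = [
    "RunReport",
    "crop_cells",
    "featurize_crops",
    "cross_validate",
    "run_pipeline",
]


@dataclass
class RunReport:
    """Everything one pipeline run produced."""

    metrics: pd.DataFrame              # one row per evaluated image
    confusion: np.ndarray | None       # classes x classes, rows = true
    accuracy: float | None
    predictions: pd.DataFrame | None   # per-crop class predictions
    version: str = __version__
    config_hash: str = ""

    def write(self, out_dir) -> None:
        out = Path(out_dir)
        out.mkdir(parents=True, exist_ok=True)
        self.metrics.to_csv(out / "segmentation_metrics.csv", index=False)
        if self.confusion is not None:
            pd.DataFrame(self.confusion).to_csv(out / "confusion_matrix.csv")
        if self.predictions is not None:
            self.predictions.to_csv(out / "predictions.csv", index=False)
        summary = pd.DataFrame(
            [
                {
                    "version": self.version,
                    "config_hash": self.config_hash,
                    "n_images": len(self.metrics),
                    "cv_accuracy": self.accuracy,
                }
            ]
        )
        summary.to_csv(out / "summary.csv", index=False)


def crop_cells(img, mask, size: int = 64) -> list:
    """One centered, resized crop per connected nucleus component.

    The square window is centered on the component centroid with side
    1.4x the larger bounding-box dimension; regions outside the image
    are zero-padded, so border-touching cells are kept.  Crops are
    resized to ``size x size`` by bilinear interpolation.
    """
    img = np.asarray(img)
    mask = np.asarray(mask, dtype=bool)
    lab = label(mask, connectivity=2)
    crops = []
    for region in regionprops(lab):
        cy, cx = region.centroid
        r0, c0, r1, c1 = region.bbox
        side = max(r1 - r0, c1 - c0)
        half = max(4, int(np.ceil(side * 1.4 / 2)))
        window = np.zeros((2 * half, 2 * half, img.shape[2]), dtype=float)
        ylo, yhi = int(round(cy)) - half, int(round(cy)) + half
        xlo, xhi = int(round(cx)) - half, int(round(cx)) + half
        sy, sx = max(ylo, 0), max(xlo, 0)
        ey, ex = min(yhi, img.shape[0]), min(xhi, img.shape[1])
        window[sy - ylo : ey - ylo, sx - xlo : ex - xlo] = img[sy:ey, sx:ex]
        crop = resize(window, (size, size), order=1, preserve_range=True,
                      anti_aliasing=True)
        crops.append(np.clip(np.round(crop), 0, 255).astype(np.uint8))
    return crops


def crop_to_input(crop) -> np.ndarray:
    """Crop image to network input: channels-first, scaled and centered.

    Centering the [0, 1] intensities at zero keeps early SGD steps
    well-conditioned (the pale smear background otherwise biases every
    activation the same way).
    """
    return np.moveaxis(np.asarray(crop, dtype=float) / 255.0 - 0.5, -1, 0)


def featurize_crops(crops, params, cfg: PipelineConfig) -> np.ndarray:
    """Fused CNN + pooled-descriptor feature vector for each crop.

    The CNN block and the pooled-descriptor block are L2-normalized
    separately before fusion so that neither modality dominates the
    classifier's column normalization (raw CNN activations are an
    order of magnitude larger than pooled unit descriptors).

    Returns an m x n matrix with one column per crop (the dictionary
    layout the classifier expects).
    """
    cols = []
    for crop in crops:
        feat = cnn_mod.forward(crop_to_input(crop), params, cfg.cnn, mode="features")
        pairs = sift_mod.extract(crop, cfg.sift)
        descs = np.asarray([d for _, d in pairs])
        fused = fuse_features(feat, descs)
        for block in (fused[: feat.size], fused[feat.size :]):
            norm = np.linalg.norm(block)
            if norm > 0:
                block /= norm
        cols.append(fused)
    return np.stack(cols, axis=1)


def cross_validate(
    features: np.ndarray,
    labels,
    hp: Hyperparams,
    folds: int = 5,
    seed: int = 0,
    n_classes: int = 5,
):
    """Stratified k-fold evaluation of the WTPTSSR classifier.

    Returns ``(confusion, accuracy, fold_accuracies)`` with confusion
    rows indexed by true class and columns by predicted class.
    """
    labels = np.asarray(labels)
    skf = StratifiedKFold(n_splits=folds, shuffle=True, random_state=seed)
    confusion = np.zeros((n_classes, n_classes), dtype=int)
    fold_acc = []
    for train_idx, test_idx in skf.split(features.T, labels):
        clf = WTPTSSRClassifier(hp)
        clf.fit(features[:, train_idx], labels[train_idx])
        pred = clf.predict(features[:, test_idx])
        truth = labels[test_idx]
        for t, p in zip(truth, pred):
            confusion[int(t), int(p)] += 1
        fold_acc.append(float(np.mean(pred == truth)))
    accuracy = float(np.trace(confusion) / confusion.sum())
    return confusion, accuracy, fold_acc


def _find_pairs(image_dir: Path):
    """img_XXX.png / mask_XXX.png pairs; mask may be absent."""
    pairs = []
    for img_path in sorted(image_dir.glob("img_*.png")):
        mask_path = image_dir / img_path.name.replace("img_", "mask_")
        pairs.append((img_path, mask_path if mask_path.exists() else None))
    if not pairs:
        for img_path in sorted(image_dir.glob("*.png")):
            if not img_path.name.startswith("mask"):
                pairs.append((img_path, None))
    return pairs


def run_pipeline(
    image_dir, cfg: PipelineConfig | None = None, out_dir=None
) -> RunReport:
    """Full pipeline over a directory of smear images.

    Each image is segmented and, when a paired manual mask exists,
    scored with the five segmentation criteria.  The classifier branch
    trains the CNN on ``cfg.train_crops_per_class`` labeled synthetic
    cell crops per class, evaluates fused features by stratified
    cross-validation, and classifies the nuclei cropped from the input
    smears with the trained model.  Per-image failures are logged and
    skipped.
    """
    if cfg is None:
        cfg = PipelineConfig()
    image_dir = Path(image_dir)
    rows = []
    all_crops: list = []
    crop_sources: list = []
    for img_path, mask_path in _find_pairs(image_dir):
        try:
            img = read_image(img_path)
            auto = segment_nucleus(img, cfg.segmentation)
            if out_dir is not None:
                out = Path(out_dir)
                out.mkdir(parents=True, exist_ok=True)
                write_mask(out / f"seg_{img_path.name}", auto)
            row = {"filename": img_path.name}
            if mask_path is not None:
                manual = read_mask(mask_path)
                report = metrics_mod.evaluate_pair(
                    auto, manual, rde_variant=cfg.rde_variant
                )
                row.update(report.as_dict())
            rows.append(row)
            crops = crop_cells(img, auto, cfg.crop_size)
            all_crops.extend(crops)
            crop_sources.extend([img_path.name] * len(crops))
        except Exception:
            logger.exception("image %s failed; skipped", img_path.name)
    metrics_df = pd.DataFrame(rows)

    confusion = accuracy = predictions = None
    if cfg.train_crops_per_class > 0:
        spec = CellClassSpec(crop_size=cfg.crop_size)
        crops, labels = make_cell_crops(
            spec, n_per_class=cfg.train_crops_per_class, seed=cfg.seed
        )
        X = np.stack([crop_to_input(c) for c in crops])
        params, _ = cnn_mod.train(X, labels, cfg.cnn)
        feats = featurize_crops(list(crops), params, cfg)
        confusion, accuracy, _ = cross_validate(
            feats, labels, cfg.classifier, folds=cfg.folds, seed=cfg.seed
        )
        if all_crops:
            clf = WTPTSSRClassifier(cfg.classifier).fit(feats, labels)
            test_feats = featurize_crops(all_crops, params, cfg)
            preds = clf.predict(test_feats)
            predictions = pd.DataFrame(
                {"source": crop_sources, "predicted_class": preds}
            )
    report = RunReport(
        metrics=metrics_df,
        confusion=confusion,
        accuracy=accuracy,
        predictions=predictions,
        config_hash=cfg.config_hash(),
    )
    if out_dir is not None:
        report.write(out_dir)
    return report
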