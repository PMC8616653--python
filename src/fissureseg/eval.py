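"""Confusion-matrix metrics, model evaluation, overlays, and the ablation harness.

Metric definitions follow the fully-convolutional-segmentation standard:
pixel accuracy (PA) is the trace of the confusion matrix over its total,
per-class IoU is TP / (TP + FP + FN), and MIoU is the mean of the
defined per-class IoUs. Dataset-level scores accumulate a single
confusion matrix over all images rather than averaging per-image scores;
classes absent from both prediction and truth are excluded from the mean
(per-image averaging is available as an option).
"""

from __future__ import annotations

from dataclasses import dataclass, field
from typing import Callable, List, Optional, Sequence, Tuple

import numpy as np
import pandas as pd

from ._nn import Module
from ._nn.autodiff import Tensor
from .data_io import Sample
from .train import TrainConfig, pixel_loss, preprocess_batch, train_model

__all__ = [
    "ConfusionMatrix",
    "MetricsReport",
    "confusion",
    "accumulate",
    "pixel_accuracy",
    "per_class_iou",
    "miou",
    "evaluate",
    "overlay",
    "compare_configs",
]

ConfusionMatrix = np.ndarray  # (C, C) ints; rows = true class, cols = predicted


@dataclass
class MetricsReport:
    pixel_accuracy: float
    per_class_iou: List[float]  # nan where the class union is empty
    miou: float
    mean_loss: float
    n_images: int

    def to_dict(self):
        return {
            "pixel_accuracy": self.pixel_accuracy,
            "per_class_iou": list(self.per_class_iou),
            "miou": self.miou,
            "mean_loss": self.mean_loss,
            "n_images": self.n_images,
        }


def confusion(pred_mask: np.ndarray, true_mask: np.ndarray, num_classes: int) -> ConfusionMatrix:
    """counts[i, j] = number of pixels with true class i predicted as j."""
    pred = np.asarray(pred_mask)
    true = np.asarray(true_mask)
    if pred.shape != true.shape:
        raise ValueError(f"shape mismatch: pred {pred.shape} vs true {true.shape}")
    if pred.min() < 0 or pred.max() >= num_classes or true.min() < 0 or true.max() >= num_classes:
        raise ValueError(f"labels must lie in [0, {num_classes})")
    flat = num_classes * true.astype(np.int64).ravel() + pred.astype(np.int64).ravel()
    return np.bincount(flat, minlength=num_classes**2).reshape(num_classes, num_classes)


def accumulate(*matrices: ConfusionMatrix) -> ConfusionMatrix:
    """Elementwise sum; equals the confusion of the concatenated images."""
    return np.sum(matrices, axis=0)


def _check_cm(cm):
    cm = np.asarray(cm)
    if cm.ndim != 2 or cm.shape[0] != cm.shape[1]:
        raise ValueError(f"confusion matrix must be square, got {cm.shape}")
    if cm.sum() == 0:
        raise ValueError("confusion matrix is empty (zero total)")
    return cm


def pixel_accuracy(cm: ConfusionMatrix) -> float:
    cm = _check_cm(cm)
    return float(np.trace(cm) / cm.sum())


def per_class_iou(cm: ConfusionMatrix) -> np.ndarray:
    """IoU_c = cm[c,c] / (row_c + col_c - cm[c,c]); nan where the union is 0."""
    cm = _check_cm(cm).astype(np.float64)
    tp = np.diag(cm)
    union = cm.sum(axis=1) + cm.sum(axis=0) - tp
    with np.errstate(invalid="ignore", divide="ignore"):
        iou = np.where(union > 0, tp / np.where(union > 0, union, 1.0), np.nan)
    return iou


def miou(cm: ConfusionMatrix) -> float:
    """Mean of the defined per-class IoUs; errors if every union is empty."""
    iou = per_class_iou(cm)
    defined = ~np.isnan(iou)
    if not defined.any():
        raise ValueError("MIoU undefined: every class has zero union")
    return float(iou[defined].mean())


def _predict_scores(model, images: np.ndarray, batch_size: int = 8):
    model.eval()
    outs = []
    for start in range(0, len(images), batch_size):
        out = model(Tensor(np.ascontiguousarray(images[start : start + batch_size])))
        outs.append(out.data)
    return np.concatenate(outs, axis=0)


def evaluate(
    model,
    samples: Sequence[Sample],
    config: TrainConfig,
    num_classes: Optional[int] = None,
    per_image: bool = False,
) -> MetricsReport:
    """Dataset-level metrics on one accumulated confusion matrix.

    ``model`` may be a network module or any callable mapping a
    ``(N, C, H, W)`` image array to a ``(N, H, W)`` label array (useful for
    oracle predictors in tests). ``per_image=True`` switches MIoU/PA to the
    mean of per-image scores instead of the accumulated-matrix standard.
    """
    if len(samples) == 0:
        raise ValueError("cannot evaluate on an empty sample list")
    if any(s.mask is None for s in samples):
        raise ValueError("evaluation requires labeled samples")
    images, masks = preprocess_batch(samples, config.input_size)
    if isinstance(model, Module):
        scores = _predict_scores(model, images)
        preds = scores.argmax(axis=1).astype(np.uint8)
        losses = [pixel_loss(scores[i], masks[i], config.class_weights) for i in range(len(samples))]
    else:
        preds = np.asarray(model(images))
        scores = None
        losses = [float("nan")] * len(samples)
    c = num_classes if num_classes is not None else int(max(preds.max(), masks.max())) + 1
    cms = [confusion(preds[i], masks[i], c) for i in range(len(samples))]
    if per_image:
        pas = [pixel_accuracy(cm) for cm in cms]
        mious = [miou(cm) for cm in cms]
        total = accumulate(*cms)
        return MetricsReport(
            float(np.mean(pas)),
            list(per_class_iou(total)),
            float(np.mean(mious)),
            float(np.mean(losses)),
            len(samples),
        )
    total = accumulate(*cms)
    return MetricsReport(
        pixel_accuracy(total),
        list(per_class_iou(total)),
        miou(total),
        float(np.mean(losses)),
        len(samples),
    )


def overlay(image: np.ndarray, mask: np.ndarray, color=(255, 0, 0), alpha: float = 0.5) -> np.ndarray:
    """Blend `color` over mask-positive pixels: out = (1-a)*image + a*color."""
    if not 0.0 <= alpha <= 1.0:
        raise ValueError("alpha must be in [0, 1]")
    image = np.asarray(image, dtype=np.float64)
    mask = np.asarray(mask) != 0
    out = image.copy()
    out[mask] = (1.0 - alpha) * image[mask] + alpha * np.asarray(color, dtype=np.float64)
    return np.clip(np.round(out), 0, 255).astype(np.uint8)


def compare_configs(
    config_grid,
    dataset_spec,
    train_config: TrainConfig,
    n_seeds: int = 1,
    train_fraction: float = 0.7,
) -> pd.DataFrame:
    """Ablation harness: train each model config on identical data and seeds.

    Parameters
    ----------
    config_grid : sequence of (name, ModelConfig)
    dataset_spec : (SyntheticParams, n_samples, data_seed) — the shared
        synthetic benchmark every configuration is trained and scored on.
    n_seeds : number of training/init seeds; the table reports mean and sd
        of PA, loss (x100, as conventionally printed), and MIoU over them.

    Returns a DataFrame with one row per configuration.
    """
    from .data_io import split_dataset
    from .net import build_improved_unet
    from .synthetic import generate_dataset

    params, n_samples, data_seed = dataset_spec
    samples = generate_dataset(params, n_samples, data_seed)
    ids = list(range(len(samples)))
    split = split_dataset(ids, train_fraction, data_seed)
    train_set = [samples[i] for i in split.train_ids]
    held_out = [samples[i] for i in split.held_out_ids]

    rows = []
    for name, mconfig in config_grid:
        pas, losses, mious = [], [], []
        for s in range(n_seeds):
            seed = train_config.seed + s
            model = build_improved_unet(mconfig, seed=seed)
            cfg = TrainConfig(
                learning_rate=train_config.learning_rate,
                batch_size=train_config.batch_size,
                beta1=train_config.beta1,
                beta2=train_config.beta2,
                input_size=train_config.input_size,
                epochs=train_config.epochs,
                lr_decay=train_config.lr_decay,
                seed=seed,
                class_weights=train_config.class_weights,
            )
            model, _ = train_model(model, train_set, held_out, cfg)
            report = evaluate(model, held_out, cfg, num_classes=mconfig.num_classes)
            pas.append(report.pixel_accuracy)
            losses.append(report.mean_loss)
            mious.append(report.miou)
        rows.append(
            {
                "model": name,
                "pa_mean": float(np.mean(pas)),
                "pa_sd": float(np.std(pas)),
                "loss_pct_mean": float(np.mean(losses)) * 100.0,
                "loss_pct_sd": float(np.std(losses)) * 100.0,
                "miou_mean": float(np.mean(mious)),
                "miou_sd": float(np.std(mious)),
                "n_seeds": n_seeds,
            }
        )
    return pd.DataFrame(rows)
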