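"""scikit-learn style estimator facade over the segmentation pipeline."""

from __future__ import annotations

from typing import Optional, Sequence, Tuple

import numpy as np
from sklearn.base import BaseEstimator

from .data_io import Sample, split_dataset
from .eval import evaluate
from .net import ModelConfig, build_improved_unet
from .train import TrainConfig, preprocess_batch, train_model

__all__ = ["FissureSegmenter", "desk_model_config", "desk_train_config"]


def desk_model_config(**overrides) -> ModelConfig:
    """The CPU-trainable improved U-Net used throughout tests and examples:
    small GoogLeNet-style encoder, dense GCN k=7, BR on, 64x64 input."""
    kw = dict(
        encoder="googlenet",
        use_gcn=True,
        gcn_kernel_size=7,
        gcn_variant="dense",
        use_br=True,
        num_classes=2,
        base_channels=16,
        input_size=(64, 64),
    )
    kw.update(overrides)
    return ModelConfig(**kw)


def desk_train_config(**overrides) -> TrainConfig:
    """Desk-scale training regime: lr 1e-3 from scratch, batch 4, 20 epochs,
    crack class upweighted 8x to counter the ~6% positive-pixel fraction."""
    kw = dict(
        learning_rate=1e-3,
        batch_size=4,
        beta1=0.9,
        input_size=(64, 64),
        epochs=20,
        lr_decay=0.98,
        seed=0,
        class_weights=(1.0, 8.0),
    )
    kw.update(overrides)
    return TrainConfig(**kw)


class FissureSegmenter(BaseEstimator):
    """Per-pixel fissure classifier with the sklearn fit/predict contract.

    Wraps model construction (:func:`build_improved_unet`) and the training
    loop (:func:`train_model`). ``X`` is an ``(n, H, W, 3)`` uint8 image
    stack, ``y`` an ``(n, H, W)`` integer label stack; ``predict`` returns
    ``(n, H, W)`` labels and ``score`` the held-in MIoU.

    Parameters mirror ``ModelConfig`` + ``TrainConfig``; fitted state lives
    in ``model_`` and ``history_``.
    """

    def __init__(
        self,
        encoder="googlenet",
        use_gcn=True,
        gcn_kernel_size=7,
        gcn_variant="dense",
        use_br=True,
        num_classes=2,
        base_channels=16,
        input_size=(64, 64),
        upsample="deconv",
        fusion="add",
        learning_rate=1e-3,
        batch_size=4,
        beta1=0.9,
        epochs=20,
        lr_decay=0.98,
        class_weights=(1.0, 8.0),
        validation_fraction=0.2,
        seed=0,
    ):
        self.encoder = encoder
        self.use_gcn = use_gcn
        self.gcn_kernel_size = gcn_kernel_size
        self.gcn_variant = gcn_variant
        self.use_br = use_br
        self.num_classes = num_classes
        self.base_channels = base_channels
        self.input_size = input_size
        self.upsample = upsample
        self.fusion = fusion
        self.learning_rate = learning_rate
        self.batch_size = batch_size
        self.beta1 = beta1
        self.epochs = epochs
        self.lr_decay = lr_decay
        self.class_weights = class_weights
        self.validation_fraction = validation_fraction
        self.seed = seed

    def _model_config(self) -> ModelConfig:
        return ModelConfig(
            encoder=self.encoder,
            use_gcn=self.use_gcn,
            gcn_kernel_size=self.gcn_kernel_size,
            gcn_variant=self.gcn_variant,
            use_br=self.use_br,
            num_classes=self.num_classes,
            base_channels=self.base_channels,
            input_size=tuple(self.input_size),
            upsample=self.upsample,
            fusion=self.fusion,
        )

    def _train_config(self) -> TrainConfig:
        return TrainConfig(
            learning_rate=self.learning_rate,
            batch_size=self.batch_size,
            beta1=self.beta1,
            input_size=tuple(self.input_size),
            epochs=self.epochs,
            lr_decay=self.lr_decay,
            seed=self.seed,
            class_weights=self.class_weights,
        )

    @staticmethod
    def _to_samples(X, y=None):
        X = np.asarray(X)
        if X.ndim != 4 or X.shape[3] != 3:
            raise ValueError(f"X must be (n, H, W, 3), got {X.shape}")
        masks = [None] * len(X)
        if y is not None:
            y = np.asarray(y)
            if y.shape != X.shape[:3]:
                raise ValueError(f"y shape {y.shape} != X spatial shape {X.shape[:3]}")
            masks = list(y)
        return [Sample(img, m, identifier=str(i)) for i, (img, m) in enumerate(zip(X, masks))]

    def fit(self, X, y):
        samples = self._to_samples(X, y)
        if self.validation_fraction > 0 and len(samples) >= 5:
            split = split_dataset(
                list(range(len(samples))), 1.0 - self.validation_fraction, self.seed
            )
            train_set = [samples[i] for i in split.train_ids]
            val_set = [samples[i] for i in split.held_out_ids]
        else:
            train_set, val_set = samples, []
        model = build_improved_unet(self._model_config(), seed=self.seed)
        model, history = train_model(model, train_set, val_set, self._train_config())
        self.model_ = model
        self.history_ = history
        self.classes_ = np.arange(self.num_classes)
        return self

    def predict(self, X):
        self._check_fitted()
        samples = self._to_samples(X)
        images, _ = preprocess_batch(samples, tuple(self.input_size))
        from .net import predict as net_predict

        return net_predict(self.model_, images)

    def score(self, X, y):
        """Dataset-level MIoU of predictions against `y`."""
        self._check_fitted()
        samples = self._to_samples(X, y)
        report = evaluate(self.model_, samples, self._train_config(), num_classes=self.num_classes)
        return report.miou

    def _check_fitted(self):
        if not hasattr(self, "model_"):
            raise RuntimeError("this FissureSegmenter instance is not fitted yet")
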