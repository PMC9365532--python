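"""Scikit-learn style estimator wrapping the segmentation network.

``TumorSegmenter`` exposes the full pipeline — network construction,
training with the combined Dice/BCE/edge loss, best-validation-DSC model
selection — behind the familiar ``fit`` / ``predict`` contract, so it
composes with sklearn model selection and pipelines.  ``X`` is a stack of
grayscale slices ``(n, H, W)`` with intensities in [0, 1]; ``y`` the
matching binary masks.
"""

from __future__ import annotations

import numpy as np
from sklearn.base import BaseEstimator

from .exchange import ExchangeConfig
from .fusion import FusionConfig
from .model import ModelConfig, SegmentationNet
from .train import TrainConfig, train_model

__all__ = ["TumorSegmenter"]


class _ArraySample:
    __slots__ = ("image", "mask", "slice_id")

    def __init__(self, image, mask, slice_id):
        self.image = image
        self.mask = mask
        self.slice_id = slice_id


class TumorSegmenter(BaseEstimator):
    """Residual-fusion tumor segmenter with an sklearn interface.

    Parameters mirror the network and optimizer configuration; see
    :class:`~osteoseg.model.ModelConfig` and
    :class:`~osteoseg.train.TrainConfig`.  ``validation_fraction`` carves a
    validation subset from the end of ``X`` for best-epoch selection (set 0
    to keep every sample for training).

    Attributes (after ``fit``)
    --------------------------
    model_ : SegmentationNet
        The trained network (best validation DSC parameters).
    history_ : pandas.DataFrame
        Per-epoch loss and validation DSC.
    n_parameters_ : int
        Trainable parameter count.
    """

    def __init__(self, base_channels: int = 8, dropout_p: float = 0.2,
                 shape_flow: bool = True, fusion_layers: int = 4,
                 pairing: str = "all_pairs", residual_scale: float = 0.4,
                 lr: float = 1e-4, epochs: int = 200, batch_size: int = 8,
                 max_steps: int | None = None,
                 loss_weights: tuple = (1.0, 1.0, 0.5),
                 validation_fraction: float = 0.2, seed: int = 0):
        self.base_channels = base_channels
        self.dropout_p = dropout_p
        self.shape_flow = shape_flow
        self.fusion_layers = fusion_layers
        self.pairing = pairing
        self.residual_scale = residual_scale
        self.lr = lr
        self.epochs = epochs
        self.batch_size = batch_size
        self.max_steps = max_steps
        self.loss_weights = loss_weights
        self.validation_fraction = validation_fraction
        self.seed = seed

    # -- helpers ----------------------------------------------------------
    def _validate_arrays(self, X, y=None):
        X = np.asarray(X, dtype=float)
        if X.ndim == 2:
            X = X[None]
        if X.ndim != 3:
            raise ValueError(f"X must be (n, H, W), got shape {X.shape}")
        if not np.all(np.isfinite(X)):
            raise ValueError("X contains non-finite values")
        if y is None:
            return X, None
        y = np.asarray(y)
        if y.shape != X.shape:
            raise ValueError(f"y shape {y.shape} must match X shape {X.shape}")
        if not np.all(np.isin(np.unique(y), (0, 1))):
            raise ValueError("y must be binary masks")
        return X, y.astype(np.uint8)

    def _model_config(self, input_size) -> ModelConfig:
        return ModelConfig(
            base_channels=self.base_channels,
            input_size=input_size,
            dropout_p=self.dropout_p,
            shape_flow_enabled=self.shape_flow,
            fusion=FusionConfig(
                n_layers=self.fusion_layers,
                pairing=self.pairing,
                exchange=ExchangeConfig(residual_scale=self.residual_scale),
            ),
            seed=self.seed,
        )

    # -- sklearn API ------------------------------------------------------
    def fit(self, X, y):
        X, y = self._validate_arrays(X, y)
        if y is None:
            raise ValueError("fit requires masks y")
        n, h, w = X.shape
        if h % 16 or w % 16:
            raise ValueError(f"training slices must have dims divisible by 16, got {h}x{w}")
        samples = [_ArraySample(X[i], y[i], f"s{i:05d}") for i in range(n)]
        n_val = int(round(self.validation_fraction * n))
        train_samples = samples[: n - n_val] if n_val else samples
        val_samples = samples[n - n_val:] if n_val else []
        if not train_samples:
            raise ValueError("validation_fraction leaves no training samples")

        model = SegmentationNet(self._model_config((h, w)))
        tcfg = TrainConfig(lr=self.lr, epochs=self.epochs,
                           batch_size=self.batch_size, seed=self.seed,
                           loss_weights=tuple(self.loss_weights),
                           max_steps=self.max_steps)
        model, history = train_model(model, train_samples, val_samples, tcfg)
        self.model_ = model.eval()
        self.history_ = history
        self.n_parameters_ = model.n_parameters()
        return self

    def predict_proba(self, X) -> np.ndarray:
        self._check_fitted()
        X, _ = self._validate_arrays(X)
        return self.model_.predict_proba(X, batch_size=self.batch_size)

    def predict(self, X) -> np.ndarray:
        self._check_fitted()
        X, _ = self._validate_arrays(X)
        return self.model_.predict(X, batch_size=self.batch_size)

    def score(self, X, y) -> float:
        """Mean per-slice Dice similarity coefficient."""
        from .metrics import metrics_from_masks

        X, y = self._validate_arrays(X, y)
        preds = self.predict(X)
        return float(np.mean([metrics_from_masks(p, t).dsc
                              for p, t in zip(preds, y)]))

    def _check_fitted(self):
        if not hasattr(self, "model_"):
            raise AttributeError("this TumorSegmenter is not fitted yet; call fit")
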