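"""scikit-learn-style estimator facade over the U-net.

``UNetSegmenter`` is a per-pixel classifier: ``X`` is a stack of grayscale
patches ``(n, s, s)`` with values in [0, 255] and ``y`` a stack of integer
class maps of the same shape (255 = unlabeled, excluded from loss and
score).  It follows the sklearn estimator contract — constructor stores
hyperparameters untouched, ``fit`` validates input and sets trailing-
underscore attributes, ``get_params``/``set_params`` work with
``sklearn.base.clone`` and model selection.
"""

from __future__ import annotations

import numpy as np
from sklearn.base import BaseEstimator

from .unet import UNet, UNetConfig, build_unet
from .training import TrainConfig, train, evaluate


class UNetSegmenter(BaseEstimator):
    """2D semantic segmentation with a small U-net.

    Parameters mirror :class:`UNetConfig` and :class:`TrainConfig`; set
    ``pretrained`` to a :class:`UNet` (or a path to an ``.onnx`` / ``.npz``
    model) to start from existing weights, which together with
    ``mode="continuous" | "freeze_last" | "freeze_encoder" | "leaky_freeze"
    | "episodic"`` gives the transfer-learning behaviours.

    Attributes set by :meth:`fit`:

    - ``model_``: the trained :class:`UNet`
    - ``history_``: per-epoch train/validation learning curves
    - ``classes_``: the class indices ``0..n_classes-1``
    - ``n_classes_``: number of classes
    """

    def __init__(
        self,
        depth: int = 2,
        base_channels: int = 8,
        n_classes: int = 2,
        epochs: int = 10,
        batch_size: int = 8,
        lr: float = 0.05,
        momentum: float = 0.9,
        mode: str = "scratch",
        leaky_factor: float = 0.1,
        episodic_ratio: tuple[int, int] = (1, 1),
        class_weights=None,
        validation_fraction: float = 0.1,
        pretrained=None,
        random_state: int = 0,
    ):
        self.depth = depth
        self.base_channels = base_channels
        self.n_classes = n_classes
        self.epochs = epochs
        self.batch_size = batch_size
        self.lr = lr
        self.momentum = momentum
        self.mode = mode
        self.leaky_factor = leaky_factor
        self.episodic_ratio = episodic_ratio
        self.class_weights = class_weights
        self.validation_fraction = validation_fraction
        self.pretrained = pretrained
        self.random_state = random_state

    # -- helpers ----------------------------------------------------------
    def _validate_X(self, X: np.ndarray, fitted: bool = False) -> np.ndarray:
        X = np.asarray(X)
        if X.ndim == 2:
            X = X[None]
        if X.ndim != 3:
            raise ValueError(f"X must be (n, s, s) grayscale patches, got shape {X.shape}")
        s_h, s_w = X.shape[1:]
        if s_h % 128 or s_w % 128 or s_h == 0 or s_w == 0:
            raise ValueError(
                f"patch sides must be positive multiples of 128, got {(s_h, s_w)}"
            )
        return X

    def _resolve_model(self) -> UNet:
        if self.pretrained is None:
            cfg = UNetConfig(
                depth=self.depth,
                base_channels=self.base_channels,
                n_classes=self.n_classes,
            )
            return build_unet(cfg, np.random.default_rng(self.random_state))
        if isinstance(self.pretrained, UNet):
            return self.pretrained.copy()
        path = str(self.pretrained)
        if path.endswith(".onnx"):
            from ..onnx_io import import_model

            return import_model(path)
        return UNet.load_npz(path)

    # -- sklearn API ------------------------------------------------------
    def fit(self, X, y, memory=None):
        """Train on patches X (n,s,s) and class maps y (n,s,s).

        ``memory`` is the (X, y) episodic-memory dataset for
        ``mode="episodic"``.
        """
        X = self._validate_X(X)
        y = np.asarray(y)
        if y.shape != X.shape:
            raise ValueError(f"y shape {y.shape} does not match X shape {X.shape}")
        model = self._resolve_model()
        if model.config.n_classes != self.n_classes:
            raise ValueError(
                f"pretrained model has n_classes={model.config.n_classes}, "
                f"estimator expects {self.n_classes}"
            )
        rng = np.random.default_rng(self.random_state)
        n = len(X)
        n_val = int(round(self.validation_fraction * n)) if n > 1 else 0
        perm = rng.permutation(n)
        val_idx, train_idx = perm[:n_val], perm[n_val:]
        cfg = TrainConfig(
            epochs=self.epochs,
            batch_size=self.batch_size,
            lr=self.lr,
            momentum=self.momentum,
            mode=self.mode,
            leaky_factor=self.leaky_factor,
            episodic_ratio=tuple(self.episodic_ratio),
            class_weights=self.class_weights,
            rng_seed=self.random_state,
        )
        val = (X[val_idx], y[val_idx]) if n_val else None
        self.history_ = train(model, (X[train_idx], y[train_idx]), val, cfg, memory)
        self.model_ = model
        self.n_classes_ = self.n_classes
        self.classes_ = np.arange(self.n_classes)
        return self

    def _check_fitted(self):
        if not hasattr(self, "model_"):
            raise AttributeError("UNetSegmenter is not fitted yet; call fit first")

    def predict_proba(self, X) -> np.ndarray:
        """Per-pixel class probabilities, shape (n, s, s, n_classes)."""
        self._check_fitted()
        X = self._validate_X(X, fitted=True)
        out = []
        for i in range(0, len(X), max(self.batch_size, 1)):
            xb = X[i : i + self.batch_size].astype(np.float32) / 255.0
            out.append(self.model_.forward(xb))
        return np.moveaxis(np.concatenate(out), 1, -1)

    def predict(self, X) -> np.ndarray:
        """Per-pixel class map, shape (n, s, s); ties go to the lower index."""
        return self.predict_proba(X).argmax(axis=-1)

    def score(self, X, y) -> float:
        """Mean pixel accuracy, ignoring unlabeled (255) pixels."""
        self._check_fitted()
        X = self._validate_X(X)
        _, acc = evaluate(self.model_, X, np.asarray(y), batch_size=self.batch_size)
        return acc
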