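"""scikit-learn style estimators wrapping the network builders and training
loops, so the classifier composes with sklearn pipelines and model selection.

``OnsetTimeClassifier`` is the user-facing model: ``fit(X, y)`` on
``(N, 2, X, Y, Z)`` standardized volume pairs, ``predict_proba`` for
continuous mismatch scores, ``predict`` for thresholded calls.  Defaults are
the desk-scale G-CNN used throughout the package's own experiments; the
clinical-scale five-stage architecture is one config away
(``stages=5, channels=(8, 16, 32, 64, 128), input_pool=None``).
"""

from __future__ import annotations

import numpy as np
from sklearn.base import BaseEstimator, ClassifierMixin, TransformerMixin
from sklearn.utils.validation import check_is_fitted

from .model import (
    EncoderConfig,
    build_ae_regularized,
    build_cae,
    build_classifier,
)
from .training import TrainConfig, predict_scores, pretrain_cae, train_classifier


def _as_volumes(X) -> np.ndarray:
    X = np.asarray(X, dtype=np.float32)
    if X.ndim != 5 or X.shape[1] != 2:
        raise ValueError(f"expected (N, 2, X, Y, Z) volume pairs, got {X.shape}")
    return X


class OnsetTimeClassifier(ClassifierMixin, BaseEstimator):
    """Dichotomized stroke onset-time classifier (<= 4.5 h vs > 4.5 h).

    Parameters mirror :class:`~flairmatch.model.EncoderConfig` and
    :class:`~flairmatch.training.TrainConfig`.  ``equivariant`` switches
    between the plain CNN baseline and the D4h G-CNN; ``alpha < 1`` enables
    autoencoder regularization (joint reconstruction loss);
    ``init='pretrained'`` loads encoder weights from a CAE checkpoint state
    dict passed as ``encoder_state``.
    """

    def __init__(self, equivariant: bool = True, stages: int = 2,
                 channels: tuple[int, ...] = (6, 12),
                 kernel_size: tuple[int, int, int] = (3, 3, 3),
                 input_pool: tuple[int, int, int] | None = (8, 8, 4),
                 fc: tuple[int, int] = (16, 8), dropout: float = 0.0,
                 orientation_pool: str = "max", conv_bias_init: float = -0.5,
                 mismatch_init: bool = True,
                 bottleneck: int = 16, alpha: float = 1.0,
                 init: str = "random", encoder_state: dict | None = None,
                 lr: float = 0.01, momentum: float = 0.9, nesterov: bool = True,
                 epochs: int = 40, batch_size: int = 5,
                 class_weighted: bool = True, patience: int | None = None,
                 threshold: float = 0.5, random_state: int = 0):
        self.equivariant = equivariant
        self.stages = stages
        self.channels = channels
        self.kernel_size = kernel_size
        self.input_pool = input_pool
        self.fc = fc
        self.dropout = dropout
        self.orientation_pool = orientation_pool
        self.conv_bias_init = conv_bias_init
        self.mismatch_init = mismatch_init
        self.bottleneck = bottleneck
        self.alpha = alpha
        self.init = init
        self.encoder_state = encoder_state
        self.lr = lr
        self.momentum = momentum
        self.nesterov = nesterov
        self.epochs = epochs
        self.batch_size = batch_size
        self.class_weighted = class_weighted
        self.patience = patience
        self.threshold = threshold
        self.random_state = random_state

    def _encoder_config(self) -> EncoderConfig:
        return EncoderConfig(
            stages=self.stages, channels=tuple(self.channels),
            kernel_size=tuple(self.kernel_size), equivariant=self.equivariant,
            dropout=self.dropout, fc=tuple(self.fc), bottleneck=self.bottleneck,
            input_pool=None if self.input_pool is None else tuple(self.input_pool),
            orientation_pool=self.orientation_pool,
            conv_bias_init=self.conv_bias_init, mismatch_init=self.mismatch_init)

    def _train_config(self) -> TrainConfig:
        return TrainConfig(lr=self.lr, momentum=self.momentum, nesterov=self.nesterov,
                           epochs=self.epochs, batch_size=self.batch_size,
                           alpha=self.alpha, class_weighted=self.class_weighted,
                           patience=self.patience)

    def fit(self, X, y, X_val=None, y_val=None):
        X = _as_volumes(X)
        y = np.asarray(y).astype(int)
        self.classes_ = np.unique(y)
        cfg = self._encoder_config()
        shape = X.shape[2:]
        if self.alpha < 1.0:
            self.net_ = build_ae_regularized(
                cfg, shape, seed=self.random_state, init=self.init,
                checkpoint=self.encoder_state)
        else:
            self.net_ = build_classifier(cfg, shape, seed=self.random_state)
            if self.init == "pretrained":
                from .model import load_encoder
                if self.encoder_state is None:
                    raise ValueError("init='pretrained' requires encoder_state")
                load_encoder(self.net_, self.encoder_state)
        self.history_ = train_classifier(
            self.net_, X, y, self._train_config(),
            X_val=X_val, y_val=y_val, seed=self.random_state)
        return self

    def predict_proba(self, X):
        check_is_fitted(self, "net_")
        p1 = predict_scores(self.net_, _as_volumes(X), batch_size=self.batch_size)
        return np.column_stack([1.0 - p1, p1])

    def decision_function(self, X):
        return self.predict_proba(X)[:, 1]

    def predict(self, X):
        return (self.predict_proba(X)[:, 1] >= self.threshold).astype(int)


class ConvAutoencoderPretrainer(TransformerMixin, BaseEstimator):
    """Unsupervised CAE pre-training on labeled + unlabeled volume pairs.

    ``fit(X)`` trains the reconstruction task; the fitted ``encoder_state_``
    plugs into :class:`OnsetTimeClassifier` via ``init='pretrained'``.
    ``transform`` returns reconstructions (useful for inspecting what the
    encoder has learned to keep).
    """

    def __init__(self, equivariant: bool = True, stages: int = 2,
                 channels: tuple[int, ...] = (6, 12),
                 kernel_size: tuple[int, int, int] = (3, 3, 3),
                 input_pool: tuple[int, int, int] | None = (8, 8, 4),
                 bottleneck: int = 16, orientation_pool: str = "max",
                 conv_bias_init: float = -0.5,
                 lr: float = 0.01, momentum: float = 0.9, nesterov: bool = True,
                 epochs: int = 20, batch_size: int = 5, random_state: int = 0):
        self.equivariant = equivariant
        self.stages = stages
        self.channels = channels
        self.kernel_size = kernel_size
        self.input_pool = input_pool
        self.bottleneck = bottleneck
        self.orientation_pool = orientation_pool
        self.conv_bias_init = conv_bias_init
        self.lr = lr
        self.momentum = momentum
        self.nesterov = nesterov
        self.epochs = epochs
        self.batch_size = batch_size
        self.random_state = random_state

    def fit(self, X, y=None):
        X = _as_volumes(X)
        cfg = EncoderConfig(
            stages=self.stages, channels=tuple(self.channels),
            kernel_size=tuple(self.kernel_size), equivariant=self.equivariant,
            dropout=0.0, fc=(8, 4), bottleneck=self.bottleneck,
            input_pool=None if self.input_pool is None else tuple(self.input_pool),
            orientation_pool=self.orientation_pool,
            conv_bias_init=self.conv_bias_init)
        self.net_ = build_cae(cfg, X.shape[2:], seed=self.random_state)
        tc = TrainConfig(lr=self.lr, momentum=self.momentum, nesterov=self.nesterov,
                         epochs=self.epochs, batch_size=self.batch_size,
                         class_weighted=False)
        self.history_ = pretrain_cae(self.net_, X, tc, seed=self.random_state)
        self.encoder_state_ = self.net_.state_dict()
        return self

    def transform(self, X):
        check_is_fitted(self, "net_")
        X = _as_volumes(X)
        out = []
        for i in range(0, X.shape[0], self.batch_size):
            out.append(self.net_.forward(X[i:i + self.batch_size], train=False))
        return np.concatenate(out)
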