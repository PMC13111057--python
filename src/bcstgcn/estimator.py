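"""Scikit-learn style estimator wrapping the BCST-GCN backbone.

``BCSTGCNClassifier`` follows the sklearn contract: all constructor
arguments are stored verbatim, ``fit`` learns from (N, 3, T, 17) skeleton
tensors and sets trailing-underscore attributes, and the class composes with
``sklearn.base.clone`` and model-selection utilities.
"""

from __future__ import annotations

import numpy as np
from sklearn.base import BaseEstimator, ClassifierMixin
from sklearn.utils.validation import check_is_fitted

from .network import BCSTGCN, default_config, prune_layers
from .training import TrainConfig, predict as _predict, train as _train


class BCSTGCNClassifier(BaseEstimator, ClassifierMixin):
    """Spatiotemporal graph convolutional behavior classifier.

    Parameters
    ----------
    channels : per-layer output channel plan.
    stride_layers : 1-based layer positions with temporal stride 2.
    pruned_layers : 1-based width-preserving layers removed from the stack.
    use_bc : enable the global/local self-attention (BC) module.
    c_lambda : global-attention threshold; None keeps above-uniform (1/V) links.
    epochs, batch_size, lr, momentum, weight_decay, dropout, lr_steps,
    lr_gamma : SGD recipe (defaults follow the published configuration).
    random_state : seed for initialization, batching and dropout.

    Attributes
    ----------
    classes_ : ndarray of class labels seen in ``fit``.
    model_ : the trained backbone.
    history_ : per-epoch training records.
    n_parameters_ : trainable-parameter count of ``model_``.
    """

    def __init__(self, channels=(64, 64, 64, 64, 128, 128, 128, 256, 256, 256),
                 stride_layers=(5, 8), pruned_layers=(), use_bc=True,
                 c_lambda=None, leaky_slope=0.2, temporal_kernel=9,
                 partition_strategy="spatial-configuration",
                 epochs=100, batch_size=64, lr=0.1, momentum=0.9,
                 weight_decay=5e-4, dropout=0.5, lr_steps=(40, 80),
                 lr_gamma=0.1, random_state=0):
        self.channels = channels
        self.stride_layers = stride_layers
        self.pruned_layers = pruned_layers
        self.use_bc = use_bc
        self.c_lambda = c_lambda
        self.leaky_slope = leaky_slope
        self.temporal_kernel = temporal_kernel
        self.partition_strategy = partition_strategy
        self.epochs = epochs
        self.batch_size = batch_size
        self.lr = lr
        self.momentum = momentum
        self.weight_decay = weight_decay
        self.dropout = dropout
        self.lr_steps = lr_steps
        self.lr_gamma = lr_gamma
        self.random_state = random_state

    def _build_config(self, n_classes: int):
        cfg = default_config(channels=tuple(self.channels),
                             stride_layers=tuple(self.stride_layers),
                             use_bc=self.use_bc, dropout=self.dropout,
                             seed=self.random_state,
                             temporal_kernel=self.temporal_kernel,
                             num_classes=n_classes,
                             partition_strategy=self.partition_strategy,
                             c_lambda=self.c_lambda,
                             leaky_slope=self.leaky_slope)
        if self.pruned_layers:
            cfg = prune_layers(cfg, self.pruned_layers)
        return cfg

    @staticmethod
    def _validate_X(X):
        X = np.asarray(X, dtype=float)
        if X.ndim != 4 or X.shape[1] != 3:
            raise ValueError("X must have shape (N, 3, T, V)")
        if not np.isfinite(X).all():
            raise ValueError("X contains non-finite values")
        return X

    def fit(self, X, y, X_val=None, y_val=None):
        """Train on skeleton tensors X (N, 3, T, 17) and labels y."""
        X = self._validate_X(X)
        y = np.asarray(y)
        if y.shape[0] != X.shape[0]:
            raise ValueError("X and y length mismatch")
        self.classes_, y_idx = np.unique(y, return_inverse=True)
        from .network import count_parameters

        cfg = self._build_config(n_classes=len(self.classes_))
        model = BCSTGCN(cfg)
        tc = TrainConfig(batch_size=self.batch_size, epochs=self.epochs,
                         lr=self.lr, momentum=self.momentum,
                         weight_decay=self.weight_decay,
                         seed=self.random_state,
                         lr_steps=tuple(self.lr_steps),
                         lr_gamma=self.lr_gamma)
        val = None
        if X_val is not None and y_val is not None:
            lut = {c: i for i, c in enumerate(self.classes_)}
            val = (self._validate_X(X_val),
                   np.array([lut[v] for v in np.asarray(y_val)]))
        model, history = _train(model, (X, y_idx), val_seqs=val, config=tc)
        self.model_ = model
        self.history_ = history
        self.n_parameters_ = count_parameters(model)
        return self

    def decision_function(self, X):
        check_is_fitted(self, "model_")
        X = self._validate_X(X)
        out = []
        for start in range(0, X.shape[0], self.batch_size):
            out.append(self.model_.predict_logits(X[start:start + self.batch_size]))
        return np.concatenate(out)

    def predict_proba(self, X):
        z = self.decision_function(X)
        z = z - z.max(axis=1, keepdims=True)
        p = np.exp(z)
        return p / p.sum(axis=1, keepdims=True)

    def predict(self, X):
        check_is_fitted(self, "model_")
        X = self._validate_X(X)
        return self.classes_[_predict(self.model_, X, self.batch_size)]
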