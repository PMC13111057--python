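"""Minibatch SGD training loop and the three-arm ablation driver.

Optimization follows the published recipe: SGD with momentum 0.9, initial
learning rate 0.1, weight decay 5e-4, batch size 64, cross-entropy loss,
dropout 0.5 per unit.  The learning rate decays by 10x at configurable
epochs (40 and 80 by default).  Training is deterministic for a fixed seed
when numpy runs single-threaded.
"""

from __future__ import annotations

from dataclasses import dataclass

import numpy as np
import pandas as pd

from . import autodiff as ad
from .metrics import evaluate
from .network import (BCSTGCN, count_parameters, default_config,
                      prune_layers)


@dataclass(frozen=True)
class TrainConfig:
    batch_size: int = 64
    epochs: int = 100
    lr: float = 0.1
    momentum: float = 0.9
    weight_decay: float = 5e-4
    seed: int = 0
    lr_steps: tuple[int, ...] = (40, 80)
    lr_gamma: float = 0.1

    def __post_init__(self):
        if min(self.batch_size, self.epochs) < 1 or self.lr < 0:
            raise ValueError("batch_size, epochs must be >= 1 and lr >= 0")
        if list(self.lr_steps) != sorted(set(self.lr_steps)):
            raise ValueError("lr_steps must be strictly increasing")


class SGD:
    """SGD with classical momentum and decoupled-in-gradient weight decay:
    v <- momentum*v + grad + wd*w;  w <- w - lr*v."""

    def __init__(self, params, lr: float, momentum: float = 0.9,
                 weight_decay: float = 0.0):
        self.params = list(params)
        self.lr = lr
        self.momentum = momentum
        self.weight_decay = weight_decay
        self.velocity = [np.zeros_like(p.data) for p in self.params]

    def step(self):
        for p, v in zip(self.params, self.velocity):
            g = p.grad if p.grad is not None else np.zeros_like(p.data)
            g = g + self.weight_decay * p.data
            v *= self.momentum
            v += g
            p.data = p.data - self.lr * v

    def zero_grad(self):
        for p in self.params:
            p.zero_grad()


def _as_arrays(seqs, class_order):
    """Stack SkeletonSequences (or (X, y) arrays) into (N,3,T,V) + labels."""
    if isinstance(seqs, tuple) and len(seqs) == 2:
        X, y = seqs
        return np.asarray(X, dtype=float), np.asarray(y, dtype=int)
    X = np.stack([s.data for s in seqs])
    lut = {lab: i for i, lab in enumerate(class_order)}
    try:
        y = np.array([lut[s.label] for s in seqs], dtype=int)
    except KeyError as exc:
        raise ValueError(f"label {exc.args[0]!r} outside class set "
                         f"{tuple(class_order)}") from exc
    return X, y


def train(model: BCSTGCN, train_seqs, val_seqs=None,
          config: TrainConfig = TrainConfig(),
          class_order=("feeding", "walking", "lying", "sitting"),
          verbose: bool = False):
    """Train in place; returns (model, history).

    ``history`` is a list of per-epoch dicts with train loss/accuracy and,
    when a validation set is given, validation accuracy.
    """
    X, y = _as_arrays(train_seqs, class_order)
    if X.shape[0] == 0:
        raise ValueError("empty training set")
    if y.max() >= model.config.num_classes:
        raise ValueError("label outside the configured class set")
    val = _as_arrays(val_seqs, class_order) if val_seqs is not None else None

    rng = np.random.default_rng(config.seed)
    model.dropout_rng = np.random.default_rng(config.seed + 1)
    opt = SGD(model.parameters(), lr=config.lr, momentum=config.momentum,
              weight_decay=config.weight_decay)
    history = []
    n = X.shape[0]
    for epoch in range(config.epochs):
        decay = sum(1 for s in config.lr_steps if epoch >= s)
        opt.lr = config.lr * (config.lr_gamma ** decay)
        model.set_training(True)
        perm = rng.permutation(n)
        losses, correct = [], 0
        for start in range(0, n, config.batch_size):
            idx = perm[start:start + config.batch_size]
            logits = model.forward(X[idx])
            loss = ad.cross_entropy(logits, y[idx])
            opt.zero_grad()
            loss.backward()
            opt.step()
            losses.append(float(loss.data))
            correct += int((logits.data.argmax(axis=1) == y[idx]).sum())
        record = {"epoch": epoch,
                  "lr": opt.lr,
                  "train_loss": float(np.mean(losses)),
                  "train_accuracy": correct / n}
        if val is not None:
            pred = predict(model, val[0])
            record["val_accuracy"] = float((pred == val[1]).mean())
        history.append(record)
        if verbose:
            print("  ".join(f"{k}={v:.4f}" if isinstance(v, float) else f"{k}={v}"
                            for k, v in record.items()))
    return model, history


def predict(model: BCSTGCN, X: np.ndarray, batch_size: int = 64) -> np.ndarray:
    """Eval-mode class predictions; argmax ties break toward the lowest
    class index (numpy argmax convention)."""
    out = []
    for start in range(0, X.shape[0], batch_size):
        logits = model.predict_logits(X[start:start + batch_size])
        out.append(logits.argmax(axis=1))
    return np.concatenate(out) if out else np.empty(0, dtype=int)


ABLATION_ARMS = ("baseline", "+BC", "+BC+prune")


def ablation_run(train_seqs, test_seqs, base_channels=(16, 32),
                 stride_layers=(2,), prune_set=None,
                 config: TrainConfig = TrainConfig(epochs=20),
                 class_order=("feeding", "walking", "lying", "sitting"),
                 arms=ABLATION_ARMS, verbose: bool = False) -> pd.DataFrame:
    """Train the three ablation arms on shared data/seed and report
    accuracy / precision / recall per arm (plus parameter counts).

    Arms: plain ST-GCN baseline; + the BC attention module; + BC with the
    width-preserving layers pruned.  All arms share the data, seed and
    schedule so differences are attributable to the architecture axis.
    """
    rows = []
    Xte, yte = _as_arrays(test_seqs, class_order)
    for arm in arms:
        use_bc = arm != "baseline"
        channels = list(base_channels)
        cfg = default_config(channels=tuple(channels),
                             stride_layers=tuple(stride_layers),
                             use_bc=use_bc, seed=config.seed)
        if arm == "+BC+prune":
            drop = prune_set
            if drop is None:
                drop = [i for i, spec in enumerate(cfg.layers, start=1)
                        if spec.in_channels == spec.out_channels
                        and spec.temporal_stride == 1][-1:]
            cfg = prune_layers(cfg, drop)
        model = BCSTGCN(cfg)
        model, _ = train(model, train_seqs, config=config,
                         class_order=class_order, verbose=verbose)
        pred = predict(model, Xte)
        report = evaluate(yte, pred, labels=class_order)
        rows.append({"model": arm,
                     "accuracy": report.accuracy,
                     "precision": report.precision,
                     "recall": report.recall,
                     "parameters": count_parameters(model)})
    return pd.DataFrame(rows).set_index("model")
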