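"""Scikit-learn style estimator wrapping the numpy UNet.

``UNetSegmenter`` follows the sklearn estimator contract: constructor
arguments are hyperparameters stored verbatim, ``fit`` learns from a
stack of preprocessed tensors and label maps, fitted state lives in
trailing-underscore attributes, and ``get_params``/``set_params`` come
from :class:`sklearn.base.BaseEstimator`, so the segmenter composes with
sklearn model selection.

Training minimises the class-weighted cross-entropy + soft-Dice mix with
Adam.  Validation is split at the pullback level: frames of one pullback
never appear on both sides (a hard error, not a warning, guards this),
because adjacent frames of a pullback are nearly identical and would
leak.  The checkpoint kept is the epoch with the best validation mean
plaque-class soft Dice.
"""

from __future__ import annotations

import json
from dataclasses import dataclass, field
from typing import Dict, List, Optional, Sequence, Tuple

import numpy as np
from sklearn.base import BaseEstimator

from octcalc.phantom import PLAQUE_CLASSES
from octcalc.segnet.nn import (
    NetConfig,
    UNet,
    combined_loss,
    soft_dice_per_class,
)


@dataclass(frozen=True)
class TrainConfig:
    """Optimization hyperparameters for the segmenter."""

    epochs: int = 20
    batch_size: int = 4
    learning_rate: float = 1e-3
    ce_dice_mix: float = 0.5
    plaque_weight: float = 5.0
    loss_weights: Optional[Tuple[float, ...]] = None
    seed: int = 0
    checkpoint_metric: str = "plaque_dice"
    validation_fraction: float = 0.25

    def __post_init__(self) -> None:
        if not 0.0 <= self.ce_dice_mix <= 1.0:
            raise ValueError("ce_dice_mix must lie in [0, 1]")
        if self.epochs < 1 or self.batch_size < 1:
            raise ValueError("epochs and batch_size must be >= 1")


class _Adam:
    """Adaptive-moment optimizer over a dict of parameter arrays."""

    def __init__(self, params: Dict[str, np.ndarray], lr: float):
        self.lr = lr
        self.b1, self.b2, self.eps = 0.9, 0.999, 1e-8
        self.t = 0
        self.m = {k: np.zeros_like(v) for k, v in params.items()}
        self.v = {k: np.zeros_like(v) for k, v in params.items()}

    def step(self, params: Dict[str, np.ndarray], grads: Dict[str, np.ndarray]):
        self.t += 1
        bc1 = 1.0 - self.b1**self.t
        bc2 = 1.0 - self.b2**self.t
        for k, g in grads.items():
            g = g.astype(np.float32)
            self.m[k] = self.b1 * self.m[k] + (1 - self.b1) * g
            self.v[k] = self.b2 * self.v[k] + (1 - self.b2) * g * g
            params[k] -= self.lr * (self.m[k] / bc1) / (
                np.sqrt(self.v[k] / bc2) + self.eps
            )


def _group_split(
    n: int,
    groups: Optional[Sequence],
    validation_fraction: float,
    rng: np.random.Generator,
) -> Tuple[np.ndarray, np.ndarray]:
    """Index split that keeps every group entirely on one side."""
    if groups is None:
        groups = np.arange(n)
    groups = np.asarray(groups)
    uniq = np.unique(groups)
    if uniq.size < 2:
        raise ValueError("need at least two pullbacks/groups to split")
    perm = rng.permutation(uniq)
    n_val = max(1, int(round(validation_fraction * uniq.size)))
    n_val = min(n_val, uniq.size - 1)
    val_groups = set(perm[:n_val].tolist())
    val_mask = np.array([g in val_groups for g in groups])
    return np.nonzero(~val_mask)[0], np.nonzero(val_mask)[0]


def check_no_leakage(groups_train: Sequence, groups_val: Sequence) -> None:
    """Raise if any pullback contributes frames to both splits."""
    overlap = set(np.asarray(groups_train).tolist()) & set(
        np.asarray(groups_val).tolist()
    )
    if overlap:
        raise ValueError(
            f"pullbacks present in both train and validation splits: {sorted(overlap)}"
        )


class UNetSegmenter(BaseEstimator):
    """Per-pixel 10-class segmenter for preprocessed polar OCT tensors.

    Parameters mirror :class:`NetConfig` and :class:`TrainConfig`.  By
    default the three plaque classes (calcium, lipid, fibrous) share one
    equal, elevated loss weight; all other classes weigh 1.

    Attributes set by :meth:`fit`: ``net_`` (the trained network),
    ``history_`` (one dict per epoch), ``best_epoch_``, ``n_params_``,
    ``classes_``.
    """

    def __init__(
        self,
        in_channels: int = 2,
        n_classes: int = 10,
        base_filters: int = 16,
        depth: int = 4,
        dropout_rate: float = 0.1,
        epochs: int = 20,
        batch_size: int = 4,
        learning_rate: float = 1e-3,
        ce_dice_mix: float = 0.5,
        plaque_weight: float = 5.0,
        loss_weights: Optional[Sequence[float]] = None,
        validation_fraction: float = 0.25,
        checkpoint_metric: str = "plaque_dice",
        plaque_classes: Sequence[int] = PLAQUE_CLASSES,
        seed: int = 0,
    ):
        self.in_channels = in_channels
        self.n_classes = n_classes
        self.base_filters = base_filters
        self.depth = depth
        self.dropout_rate = dropout_rate
        self.epochs = epochs
        self.batch_size = batch_size
        self.learning_rate = learning_rate
        self.ce_dice_mix = ce_dice_mix
        self.plaque_weight = plaque_weight
        self.loss_weights = loss_weights
        self.validation_fraction = validation_fraction
        self.checkpoint_metric = checkpoint_metric
        self.plaque_classes = plaque_classes
        self.seed = seed

    # ------------------------------------------------------------------
    def _net_config(self) -> NetConfig:
        return NetConfig(
            in_channels=self.in_channels,
            n_classes=self.n_classes,
            base_filters=self.base_filters,
            depth=self.depth,
            dropout_rate=self.dropout_rate,
        )

    def _class_weights(self) -> np.ndarray:
        if self.loss_weights is not None:
            w = np.asarray(self.loss_weights, dtype=np.float64)
            if w.shape != (self.n_classes,):
                raise ValueError("loss_weights must have one entry per class")
            return w
        w = np.ones(self.n_classes)
        w[list(self.plaque_classes)] = self.plaque_weight
        return w

    def fit(
        self,
        X,
        y,
        groups: Optional[Sequence] = None,
        X_val=None,
        y_val=None,
        groups_val: Optional[Sequence] = None,
    ):
        """Train on tensors ``X`` (N, C, H, W) and label maps ``y`` (N, H, W).

        ``groups`` carries the pullback id of each frame; the validation
        split is made at that level.  An explicit validation set may be
        passed instead, in which case overlapping pullback ids raise.
        """
        X = np.asarray(X, dtype=np.float32)
        y = np.asarray(y)
        if X.ndim != 4 or y.ndim != 3 or X.shape[0] != y.shape[0]:
            raise ValueError("X must be (N, C, H, W) with matching y (N, H, W)")
        if X.shape[0] == 0:
            raise ValueError("empty training set")
        rng = np.random.default_rng(self.seed)

        if X_val is not None:
            if groups is not None or groups_val is not None:
                check_no_leakage(
                    groups if groups is not None else [],
                    groups_val if groups_val is not None else [],
                )
            X_tr, y_tr = X, y
            X_va = np.asarray(X_val, dtype=np.float32)
            y_va = np.asarray(y_val)
        else:
            tr, va = _group_split(X.shape[0], groups, self.validation_fraction, rng)
            if groups is not None:
                check_no_leakage(np.asarray(groups)[tr], np.asarray(groups)[va])
            X_tr, y_tr, X_va, y_va = X[tr], y[tr], X[va], y[va]
        if X_tr.shape[0] == 0 or X_va.shape[0] == 0:
            raise ValueError("empty train or validation split")

        cfg = self._net_config()
        net = UNet(cfg, np.random.default_rng(self.seed))
        opt = _Adam(net.params, self.learning_rate)
        weights = self._class_weights()
        plaque = list(self.plaque_classes)

        self.history_: List[Dict] = []
        best_metric, best_params, best_epoch = -np.inf, None, -1
        n_tr = X_tr.shape[0]
        for epoch in range(self.epochs):
            order = rng.permutation(n_tr)
            ep_loss, n_batches = 0.0, 0
            for s in range(0, n_tr, self.batch_size):
                idx = order[s : s + self.batch_size]
                probs = net.forward(X_tr[idx], train=True, rng=rng)
                loss, dlogits = combined_loss(
                    probs,
                    y_tr[idx],
                    class_weights=weights,
                    ce_dice_mix=self.ce_dice_mix,
                    return_grad=True,
                )
                grads = net.backward(dlogits)
                opt.step(net.params, grads)
                ep_loss += loss
                n_batches += 1
            val_loss, val_dice = self._validate(net, X_va, y_va, weights, plaque)
            row = {
                "epoch": epoch,
                "train_loss": ep_loss / max(1, n_batches),
                "val_loss": val_loss,
                "val_plaque_dice": val_dice,
            }
            self.history_.append(row)
            metric = val_dice if self.checkpoint_metric == "plaque_dice" else -val_loss
            if metric > best_metric:
                best_metric = metric
                best_epoch = epoch
                best_params = {k: v.copy() for k, v in net.params.items()}

        if best_params is not None:
            net.params = best_params
        self.net_ = net
        self.best_epoch_ = best_epoch
        self.n_params_ = net.n_parameters
        self.classes_ = np.arange(self.n_classes)
        return self

    def _validate(self, net, X_va, y_va, weights, plaque) -> Tuple[float, float]:
        losses, dices = [], []
        for s in range(0, X_va.shape[0], self.batch_size):
            xb = X_va[s : s + self.batch_size]
            yb = y_va[s : s + self.batch_size]
            probs = net.forward(xb, train=False)
            losses.append(
                combined_loss(probs, yb, class_weights=weights, ce_dice_mix=self.ce_dice_mix)
            )
            dices.append(soft_dice_per_class(probs, yb)[plaque].mean())
        return float(np.mean(losses)), float(np.mean(dices))

    # ------------------------------------------------------------------
    def predict_proba(self, X) -> np.ndarray:
        """Per-pixel class probabilities, ``(N, n_classes, H, W)``."""
        self._check_fitted()
        X = np.asarray(X, dtype=np.float32)
        if X.ndim == 3:
            X = X[None]
        out = []
        for s in range(0, X.shape[0], max(1, self.batch_size)):
            out.append(self.net_.forward(X[s : s + self.batch_size], train=False))
        return np.concatenate(out, axis=0)

    def predict(self, X) -> np.ndarray:
        """Per-pixel class labels, ``(N, H, W)``."""
        return self.predict_proba(X).argmax(axis=1)

    def _check_fitted(self):
        if not hasattr(self, "net_"):
            raise RuntimeError("UNetSegmenter is not fitted; call fit() first")

    # ------------------------------------------------------------------
    def save(self, path: str) -> None:
        """Serialize weights + configuration to an .npz checkpoint."""
        self._check_fitted()
        meta = json.dumps(
            {
                "params": {
                    k: v for k, v in self.get_params().items() if k != "loss_weights"
                }
                | {
                    "loss_weights": None
                    if self.loss_weights is None
                    else list(self.loss_weights),
                    "plaque_classes": list(self.plaque_classes),
                },
                "best_epoch": self.best_epoch_,
            }
        )
        np.savez(path, __meta__=np.frombuffer(meta.encode(), dtype=np.uint8), **self.net_.params)

    @classmethod
    def load(cls, path: str) -> "UNetSegmenter":
        with np.load(path) as data:
            meta = json.loads(bytes(data["__meta__"]).decode())
            weights = {k: data[k] for k in data.files if k != "__meta__"}
        est = cls(**{k: (tuple(v) if isinstance(v, list) else v) for k, v in meta["params"].items()})
        net = UNet(est._net_config(), np.random.default_rng(est.seed))
        net.params = {k: np.asarray(v, dtype=np.float32) for k, v in weights.items()}
        est.net_ = net
        est.best_epoch_ = meta["best_epoch"]
        est.n_params_ = net.n_parameters
        est.classes_ = np.arange(est.n_classes)
        return est
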