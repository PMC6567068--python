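"""Training protocol for the deep classifiers.

Class-weighted softmax cross-entropy minimized with Adam; learning rate
starts at 1e-3 and is cut by a factor of 2^(1/3) after every 100 epochs
without a validation-accuracy improvement, floored at 1e-4.  Convolution
kernels are He-initialized.  Validation accuracy is monitored on the test
split of each repeat (the optimistic-monitoring convention of the works this
protocol follows).

Two presets are used throughout: ``full`` (2000 epochs, 25 repeated splits)
and ``desk`` (300 epochs, 5 repeats) for CPU-scale runs.  Training stops
early once validation accuracy has saturated at 1.0 for a stretch of epochs
(nothing the plateau schedule monitors can improve after that), which on the
separable synthetic libraries cuts most runs far below the epoch cap without
affecting the monitored optimum.
"""

from __future__ import annotations

from dataclasses import dataclass, field, replace

import numpy as np
import pandas as pd

from ..dataset import ScanDataset
from ..splits import ClassWeights, SplitPlan, compute_class_weights, stratified_split
from .layers import F32, weighted_cross_entropy
from .models import CELL_GRID, DeepClassifier, FCNConfig, LSTMConfig, build_model

__all__ = [
    "TrainConfig",
    "TrainingDiverged",
    "lr_schedule_step",
    "train",
    "sweep",
    "desk_config",
    "full_config",
]

LR_FACTOR = 2.0 ** (1.0 / 3.0)


@dataclass(frozen=True)
class TrainConfig:
    epochs: int = 2000
    batch_size: int = 128
    lr_init: float = 1e-3
    lr_final: float = 1e-4
    lr_factor: float = LR_FACTOR
    patience: int = 100
    use_class_weights: bool = True
    #: stop once validation accuracy has been 1.0 for this many epochs (0 = never)
    saturation_patience: int = 15
    seed: int = 0

    def __post_init__(self) -> None:
        if self.lr_final > self.lr_init:
            raise ValueError("lr_final must not exceed lr_init")
        if self.patience < 1:
            raise ValueError("patience must be >= 1")
        if self.epochs < 1 or self.batch_size < 1:
            raise ValueError("epochs and batch_size must be >= 1")


def desk_config(**overrides) -> TrainConfig:
    """CPU-scale preset: 300-epoch cap."""
    return replace(TrainConfig(epochs=300), **overrides)


def full_config(**overrides) -> TrainConfig:
    """Study-scale preset: 2000-epoch cap."""
    return replace(TrainConfig(epochs=2000), **overrides)


def acceptance_scale_config(**overrides) -> TrainConfig:
    """Single-CPU scale used by the test suite and acceptance script.

    Batch size 4 — the smallest value of the batch-size refinement grid —
    maximizes optimizer updates per epoch, and the epoch cap keeps one
    training run in the minutes range on plain NumPy; saturation early
    stopping usually ends runs sooner.
    """
    return replace(TrainConfig(epochs=80, batch_size=4, saturation_patience=8), **overrides)


def lr_schedule_step(current_lr: float, epochs_since_improvement: int, cfg: TrainConfig) -> float:
    """Plateau decay: divide by 2^(1/3) at each full patience window, floor at lr_final."""
    if current_lr <= 0:
        raise ValueError("learning rate must be positive")
    if epochs_since_improvement > 0 and epochs_since_improvement % cfg.patience == 0:
        return max(cfg.lr_final, current_lr / cfg.lr_factor)
    return current_lr


class TrainingDiverged(RuntimeError):
    """Raised when the loss becomes non-finite; carries the history so far."""

    def __init__(self, message: str, history: pd.DataFrame) -> None:
        super().__init__(message)
        self.history = history


class _Adam:
    def __init__(self, model: DeepClassifier, beta1=0.9, beta2=0.999, eps=1e-7) -> None:
        self.beta1, self.beta2, self.eps = beta1, beta2, eps
        self.t = 0
        self.state: list[tuple[dict, str, np.ndarray, np.ndarray]] = []
        for layer in model.layers():
            for name, p in layer.params.items():
                self.state.append((layer, name, np.zeros_like(p), np.zeros_like(p)))

    def step(self, lr: float) -> None:
        self.t += 1
        b1, b2 = self.beta1, self.beta2
        corr = np.sqrt(1 - b2**self.t) / (1 - b1**self.t)
        for layer, name, m, v in self.state:
            g = layer.grads.get(name)
            if g is None:
                continue
            m *= b1
            m += (1 - b1) * g
            v *= b2
            v += (1 - b2) * (g * g)
            layer.params[name] -= (lr * corr) * m / (np.sqrt(v) + self.eps)


def _accuracy(model: DeepClassifier, x: np.ndarray, y: np.ndarray, batch: int) -> float:
    correct = 0
    for i in range(0, x.shape[0], batch):
        logits = model.forward(x[i : i + batch], train=False)
        correct += int(np.sum(np.argmax(logits, axis=1) == y[i : i + batch]))
    return correct / x.shape[0]


def train(
    model: DeepClassifier,
    train_ds: ScanDataset,
    val_ds: ScanDataset,
    cfg: TrainConfig,
    class_weights: ClassWeights | None = None,
) -> DeepClassifier:
    """Fit ``model`` in place and attach its training history.

    Deterministic for a fixed ``cfg.seed`` (all shuffling and dropout draw
    from one seeded generator).  Raises :class:`TrainingDiverged` on a
    non-finite loss.
    """
    if train_ds.class_names != val_ds.class_names or train_ds.scheme != val_ds.scheme:
        raise ValueError("train and validation sets must share one class scheme")
    model.class_names = list(train_ds.class_names)

    x = train_ds.currents.astype(F32)
    y = train_ds.y_indices()
    xv = val_ds.currents.astype(F32)
    yv = val_ds.y_indices()
    if cfg.use_class_weights:
        cw = class_weights or compute_class_weights(train_ds)
        w = cw.per_scan(train_ds.labels)
    else:
        w = np.ones(len(train_ds))

    rng = np.random.default_rng([cfg.seed, 0x747261696E])
    for layer in model.rnn_layers:
        if hasattr(layer, "rng"):
            layer.rng = rng  # dropout draws from the training stream
    opt = _Adam(model)
    lr = cfg.lr_init
    best_val, since_improve, saturated = -1.0, 0, 0
    hist: dict[str, list] = {"epoch": [], "loss": [], "val_accuracy": [], "lr": []}

    n = x.shape[0]
    for epoch in range(cfg.epochs):
        order = rng.permutation(n)
        losses, weights_sum = 0.0, 0.0
        for i in range(0, n, cfg.batch_size):
            idx = order[i : i + cfg.batch_size]
            logits = model.forward(x[idx], train=True)
            loss, dlogits = weighted_cross_entropy(logits, y[idx], w[idx])
            bw = float(np.sum(w[idx]))
            losses += loss * bw
            weights_sum += bw
            model.backward(dlogits)
            opt.step(lr)
        epoch_loss = losses / weights_sum
        val_acc = _accuracy(model, xv, yv, cfg.batch_size)
        hist["epoch"].append(epoch)
        hist["loss"].append(epoch_loss)
        hist["val_accuracy"].append(val_acc)
        hist["lr"].append(lr)
        if not np.isfinite(epoch_loss):
            raise TrainingDiverged(
                f"non-finite loss at epoch {epoch}", pd.DataFrame(hist)
            )
        if val_acc > best_val + 1e-12:
            best_val, since_improve = val_acc, 0
        else:
            since_improve += 1
        lr = lr_schedule_step(lr, since_improve, cfg)
        saturated = saturated + 1 if val_acc >= 1.0 else 0
        if cfg.saturation_patience and saturated >= cfg.saturation_patience:
            break

    model.history = pd.DataFrame(hist)
    model.train_config = cfg
    return model


def fit_deep(
    kind: str,
    train_ds: ScanDataset,
    val_ds: ScanDataset,
    cfg: TrainConfig,
    fcn_cfg: FCNConfig | None = None,
    lstm_cfg: LSTMConfig | None = None,
) -> DeepClassifier:
    """Build + train in one call (the entry the evaluation loop uses)."""
    model = build_model(
        kind,
        n_classes=len(train_ds.class_names),
        length=train_ds.n_points,
        fcn_cfg=fcn_cfg,
        lstm_cfg=lstm_cfg,
        seed=cfg.seed,
    )
    return train(model, train_ds, val_ds, cfg)


def sweep(
    kind: str,
    ds: ScanDataset,
    cells_grid: tuple[int, ...] = CELL_GRID[::-1],
    batch_grid: tuple[int, ...] | None = None,
    n_repeats: int = 5,
    cfg: TrainConfig | None = None,
    plan: SplitPlan | None = None,
) -> pd.DataFrame:
    """Cell-number / batch-size refinement sweep.

    For every grid setting, trains on ``n_repeats`` stratified splits and
    records the micro-average ROC-AUC on each test split; the caller picks
    the setting with the highest median.  Returns the long-form table with
    one row per (setting, repeat).
    """
    from ..metrics import roc_auc  # local import: metrics depends on nothing here

    cfg = cfg or desk_config(epochs=500)
    plan = plan or SplitPlan.for_scheme(ds.scheme, n_repeats=n_repeats, seed=cfg.seed)
    settings: list[tuple[str, int]] = [("cells", c) for c in cells_grid]
    if batch_grid:
        settings += [("batch_size", b) for b in batch_grid]
    rows = []
    for param, value in settings:
        for rep in range(n_repeats):
            tr, te = stratified_split(ds, plan, rep)
            run_cfg = replace(cfg, seed=plan.repeat_seed(rep) % (2**31))
            drop = 0.0 if kind == "lstm" else 0.8  # standalone LSTM runs dropout-free
            if param == "batch_size":
                run_cfg = replace(run_cfg, batch_size=value)
                lstm_cfg = LSTMConfig(dropout=drop)
            else:
                lstm_cfg = LSTMConfig(cells=value, dropout=drop)
            model = fit_deep(kind, tr, te, run_cfg, lstm_cfg=lstm_cfg)
            proba = model.predict_proba(te)
            auc = roc_auc(te.y_indices(), proba, average="micro", n_classes=len(ds.class_names))
            rows.append(
                {"model": kind, "parameter": param, "value": value, "repeat": rep,
                 "micro_roc_auc": auc}
            )
    return pd.DataFrame(rows)


def best_setting(sweep_table: pd.DataFrame, parameter: str) -> int:
    """Setting value with the highest median micro ROC-AUC in a sweep table."""
    sub = sweep_table[sweep_table["parameter"] == parameter]
    med = sub.groupby("value")["micro_roc_auc"].median()
    return int(med.idxmax())
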