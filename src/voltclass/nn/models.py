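"""The four deep voltammogram classifiers: FCN, LSTM, LSTM-FCN, ALSTM-FCN.

The convolutional branch is the fixed stack used throughout the study —
three stride-1 blocks (conv -> batch norm -> ReLU) with 128, 256 and 128
filters and kernels 8, 5 and 3, closed by global average pooling.  The
recurrent branch consumes the dimension-shuffled trace (one time step of L
features), optionally gated by softmax input attention, followed by 80%
dropout.  Hybrids concatenate both branches before the softmax head.
"""

from __future__ import annotations

from dataclasses import dataclass, field

import numpy as np

from ..dataset import ScanDataset
from .layers import (
    F32,
    BatchNorm1D,
    Conv1DSame,
    Dense,
    Dropout,
    GlobalAvgPool,
    InputAttention,
    Layer,
    ReLU,
    ShuffledLSTM,
    softmax,
)

__all__ = ["FCNConfig", "LSTMConfig", "DeepClassifier", "build_model", "MODEL_KINDS"]

MODEL_KINDS = ("lstm", "fcn", "lstm_fcn", "alstm_fcn")

CELL_GRID = (4, 8, 16, 32, 64, 128)


@dataclass(frozen=True)
class FCNConfig:
    filters: tuple[int, int, int] = (128, 256, 128)
    kernel_sizes: tuple[int, int, int] = (8, 5, 3)

    def __post_init__(self) -> None:
        if len(self.filters) != 3 or len(self.kernel_sizes) != 3:
            raise ValueError("the convolutional branch has exactly three blocks")


@dataclass(frozen=True)
class LSTMConfig:
    cells: int = 8
    dimension_shuffle: bool = True
    dropout: float = 0.8

    def __post_init__(self) -> None:
        if self.cells < 1:
            raise ValueError("cells must be >= 1")
        if not (0.0 <= self.dropout < 1.0):
            raise ValueError("dropout must be in [0, 1)")


class DeepClassifier:
    """One of the four architectures, with explicit forward/backward.

    Exposes everything downstream analysis needs: class-probability
    prediction, the final-convolution feature maps and the softmax weights
    attached to the convolutional branch (for class activation maps), and
    the input-attention weights for the attention variant.
    """

    def __init__(
        self,
        kind: str,
        n_classes: int,
        length: int,
        fcn_cfg: FCNConfig,
        lstm_cfg: LSTMConfig,
        rng: np.random.Generator,
    ) -> None:
        if kind not in MODEL_KINDS:
            raise ValueError(f"unknown model kind {kind!r}; choose from {MODEL_KINDS}")
        if n_classes < 2:
            raise ValueError("need at least 2 classes")
        self.kind = kind
        self.n_classes = n_classes
        self.length = length
        self.fcn_cfg, self.lstm_cfg = fcn_cfg, lstm_cfg
        self.class_names: list[str] = []

        self.fcn_layers: list[Layer] = []
        self.rnn_layers: list[Layer] = []
        head_dim = 0
        if kind in ("fcn", "lstm_fcn", "alstm_fcn"):
            if length < max(fcn_cfg.kernel_sizes):
                raise ValueError("trace shorter than the largest convolution kernel")
            c_in = 1
            for f, k in zip(fcn_cfg.filters, fcn_cfg.kernel_sizes):
                self.fcn_layers += [Conv1DSame(c_in, f, k, rng), BatchNorm1D(f), ReLU()]
                c_in = f
            self.gap = GlobalAvgPool()
            head_dim += fcn_cfg.filters[-1]
        if kind in ("lstm", "lstm_fcn", "alstm_fcn"):
            if kind == "alstm_fcn":
                self.rnn_layers.append(InputAttention(length, rng))
            self.rnn_layers.append(ShuffledLSTM(length, lstm_cfg.cells, rng))
            self.rnn_layers.append(Dropout(lstm_cfg.dropout, rng))
            head_dim += lstm_cfg.cells
        self.head = Dense(head_dim, n_classes, rng)

    # -- plumbing ----------------------------------------------------------
    def layers(self) -> list[Layer]:
        out = list(self.fcn_layers)
        if self.fcn_layers:
            out.append(self.gap)
        out += self.rnn_layers
        out.append(self.head)
        return out

    @property
    def gap_dim(self) -> int:
        """Feature dimension handed from GAP to the head (0 if no FCN branch)."""
        return self.fcn_cfg.filters[-1] if self.fcn_layers else 0

    # -- forward / backward ------------------------------------------------
    def forward(self, x: np.ndarray, train: bool) -> np.ndarray:
        """Logits for a (batch, length) float32 current matrix."""
        feats = []
        if self.fcn_layers:
            h = x[:, :, None]
            for layer in self.fcn_layers:
                h = layer.forward(h, train)
            self._fmaps = h  # (batch, length, 128): final conv block activations
            feats.append(self.gap.forward(h, train))
        if self.rnn_layers:
            h = x
            for layer in self.rnn_layers:
                h = layer.forward(h, train)
            feats.append(h)
        self._split = feats[0].shape[1] if len(feats) == 2 else None
        return self.head.forward(np.concatenate(feats, axis=1) if len(feats) > 1 else feats[0], train)

    def backward(self, dlogits: np.ndarray) -> None:
        dz = self.head.backward(dlogits)
        if self._split is not None:
            d_fcn, d_rnn = dz[:, : self._split], dz[:, self._split :]
        elif self.fcn_layers:
            d_fcn, d_rnn = dz, None
        else:
            d_fcn, d_rnn = None, dz
        if d_rnn is not None:
            h = np.ascontiguousarray(d_rnn)
            for layer in reversed(self.rnn_layers):
                h = layer.backward(h)
        if d_fcn is not None:
            h = self.gap.backward(np.ascontiguousarray(d_fcn))
            for layer in reversed(self.fcn_layers):
                h = layer.backward(h)

    # -- inference-side API ------------------------------------------------
    def _check(self, ds: ScanDataset) -> np.ndarray:
        if ds.n_points != self.length:
            raise ValueError(
                f"scan length {ds.n_points} does not match the model ({self.length})"
            )
        return ds.currents.astype(F32)

    def predict_proba(self, ds: ScanDataset, batch: int = 128) -> np.ndarray:
        x = self._check(ds)
        out = [
            softmax(self.forward(x[i : i + batch], train=False).astype(np.float64))
            for i in range(0, x.shape[0], batch)
        ]
        return np.concatenate(out, axis=0)

    def predict(self, ds: ScanDataset) -> np.ndarray:
        idx = np.argmax(self.predict_proba(ds), axis=1)
        return np.array([self.class_names[i] for i in idx], dtype=object)

    def feature_maps(self, ds: ScanDataset, batch: int = 128) -> np.ndarray:
        """Final convolutional feature maps, shape (n, length, last_filters)."""
        if not self.fcn_layers:
            raise ValueError(f"model kind {self.kind!r} has no convolutional branch")
        x = self._check(ds)
        maps = []
        for i in range(0, x.shape[0], batch):
            h = x[i : i + batch, :, None]
            for layer in self.fcn_layers:
                h = layer.forward(h, train=False)
            maps.append(h)
        return np.concatenate(maps, axis=0)

    def fcn_head_weights(self) -> np.ndarray:
        """Softmax weights attached to the FCN branch: (last_filters, n_classes)."""
        if not self.fcn_layers:
            raise ValueError(f"model kind {self.kind!r} has no convolutional branch")
        return np.asarray(self.head.params["W"][: self.gap_dim])

    def attention_weights(self, ds: ScanDataset) -> np.ndarray:
        """Input-attention weights per scan (attention variant only)."""
        att = next((l for l in self.rnn_layers if isinstance(l, InputAttention)), None)
        if att is None:
            raise ValueError(f"model kind {self.kind!r} has no attention gate")
        self.predict_proba(ds)
        return att.last_attention


    # -- persistence -------------------------------------------------------
    def save(self, path) -> None:
        """Serialize architecture config, weights and class order to one .npz."""
        import json

        meta = {
            "format_version": 1,
            "kind": self.kind,
            "n_classes": self.n_classes,
            "length": self.length,
            "filters": list(self.fcn_cfg.filters),
            "kernel_sizes": list(self.fcn_cfg.kernel_sizes),
            "cells": self.lstm_cfg.cells,
            "dropout": self.lstm_cfg.dropout,
            "class_names": self.class_names,
        }
        arrays: dict[str, np.ndarray] = {}
        for li, layer in enumerate(self.layers()):
            for name, p in layer.params.items():
                arrays[f"p_{li}_{name}"] = p
            if isinstance(layer, BatchNorm1D):
                arrays[f"s_{li}_running_mean"] = layer.running_mean
                arrays[f"s_{li}_running_var"] = layer.running_var
        np.savez(path, meta=np.frombuffer(json.dumps(meta).encode(), dtype=np.uint8), **arrays)

    @classmethod
    def load(cls, path) -> "DeepClassifier":
        import json

        with np.load(path) as z:
            meta = json.loads(bytes(z["meta"]).decode())
            if meta.get("format_version") != 1:
                raise ValueError("unsupported model bundle format")
            model = build_model(
                meta["kind"],
                meta["n_classes"],
                meta["length"],
                FCNConfig(tuple(meta["filters"]), tuple(meta["kernel_sizes"])),
                LSTMConfig(cells=meta["cells"], dropout=meta["dropout"]),
            )
            model.class_names = list(meta["class_names"])
            for li, layer in enumerate(model.layers()):
                for name in layer.params:
                    layer.params[name] = z[f"p_{li}_{name}"]
                if isinstance(layer, BatchNorm1D):
                    layer.running_mean = z[f"s_{li}_running_mean"]
                    layer.running_var = z[f"s_{li}_running_var"]
        return model


def build_model(
    kind: str,
    n_classes: int,
    length: int,
    fcn_cfg: FCNConfig | None = None,
    lstm_cfg: LSTMConfig | None = None,
    seed: int = 0,
) -> DeepClassifier:
    """Construct an untrained classifier with seeded initialization.

    The standalone LSTM runs without dropout (it is isolated from the hybrid
    architecture, where the 80% dropout guards the concatenated head); the
    hybrids keep the 0.8 default unless overridden.
    """
    rng = np.random.default_rng([seed, 0x6D6F64])
    if lstm_cfg is None:
        # 64 cells for the standalone LSTM (the cell-number sweep's choice on
        # the synthetic seawater libraries); hybrids default to 8 cells.
        lstm_cfg = LSTMConfig(cells=64, dropout=0.0) if kind == "lstm" else LSTMConfig()
    return DeepClassifier(
        kind=kind,
        n_classes=n_classes,
        length=length,
        fcn_cfg=fcn_cfg or FCNConfig(),
        lstm_cfg=lstm_cfg,
        rng=rng,
    )
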