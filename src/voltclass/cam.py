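"""Class activation maps for the convolutional voltammogram classifiers.

The CAM for class ``c`` is the weighted sum of the final convolutional
feature maps, ``CAM(t) = sum_k w_{k,c} A_k(t)``, where ``w`` are the softmax
weights attached to the GAP features of the convolutional branch (hybrid
models ignore the recurrent branch's weights).  Maps are linearly resampled
to the input length (the stride-1 stack already matches it) and min-max
normalized to [0, 1]; a constant raw map normalizes to all zeros.

The CAM-guided truncation experiment retrains a model on traces trimmed to
the activation-dense window and compares confusion matrices and accuracies
against the full-length run.
"""

from __future__ import annotations

from dataclasses import dataclass

import numpy as np
import pandas as pd

from .dataset import ScanDataset, Voltammogram, truncate_dataset
from .metrics import confusion
from .nn.models import DeepClassifier
from .nn.training import TrainConfig, fit_deep
from .splits import SplitPlan, stratified_split

__all__ = ["CAMResult", "compute_cam", "normalize_cam", "cam_guided_truncation", "TruncationReport"]


@dataclass(frozen=True)
class CAMResult:
    activations: np.ndarray  # length n_points, in [0, 1]
    target_class: str
    sample_id: str

    @property
    def argmax(self) -> int:
        return int(np.argmax(self.activations))


def normalize_cam(raw: np.ndarray) -> np.ndarray:
    """Min-max normalize a raw activation map; constant maps become zeros."""
    lo, hi = float(raw.min()), float(raw.max())
    if hi - lo < 1e-12:
        return np.zeros_like(raw, dtype=float)
    return (raw - lo) / (hi - lo)


def _resample(raw: np.ndarray, length: int) -> np.ndarray:
    if raw.size == length:
        return raw
    src = np.linspace(0.0, 1.0, raw.size)
    dst = np.linspace(0.0, 1.0, length)
    return np.interp(dst, src, raw)


def compute_cam(model: DeepClassifier, scan: Voltammogram, target_class: str) -> CAMResult:
    """Class activation map of one scan for one target class."""
    if not getattr(model, "fcn_layers", None):
        raise ValueError(
            f"model kind {getattr(model, 'kind', '?')!r} has no convolutional branch; "
            "CAMs require an FCN-containing model"
        )
    names = list(model.class_names)
    if target_class not in names:
        raise ValueError(f"unknown class {target_class!r}")
    ds = ScanDataset(
        currents=scan.currents[None, :],
        labels=[scan.label],
        scheme="custom",
        class_names=[scan.label],
        grid=scan.grid,
        sample_ids=[scan.sample_id],
    )
    fmaps = model.feature_maps(ds)[0]  # (length, n_filters)
    w_c = model.fcn_head_weights()[:, names.index(target_class)]
    raw = fmaps @ w_c
    cam = normalize_cam(_resample(raw.astype(float), scan.grid.n_points))
    return CAMResult(activations=cam, target_class=target_class, sample_id=scan.sample_id)


def cam_table(model: DeepClassifier, scan: Voltammogram, target_class: str) -> pd.DataFrame:
    """CAM export: index, potential, current and activation per sample point."""
    cam = compute_cam(model, scan, target_class)
    return pd.DataFrame(
        {
            "index": np.arange(scan.grid.n_points),
            "potential_V": scan.grid.potentials(),
            "current": scan.currents,
            "activation": cam.activations,
        }
    )


@dataclass
class TruncationReport:
    """Paired full-length vs truncated retraining results on one split."""

    full_confusion: np.ndarray
    truncated_confusion: np.ndarray
    full_accuracy: float
    truncated_accuracy: float
    class_names: list[str]
    truncated_length: int

    @property
    def accuracy_drop(self) -> float:
        return self.full_accuracy - self.truncated_accuracy


def cam_guided_truncation(
    ds: ScanDataset,
    model_kind: str,
    cfg: TrainConfig,
    drop_head: int = 502,
    drop_tail: int = 100,
    plan: SplitPlan | None = None,
    repeat_index: int = 0,
    lstm_cfg=None,
) -> tuple[ScanDataset, TruncationReport]:
    """Truncate, retrain, and compare against the full-length model.

    The canonical experiment trims the 1002-point seawater traces to the
    400-point anodic stripping window (drop 502 head / 100 tail samples)
    that the class activation maps highlight, then retrains the designated
    model on the same stratified split and reports paired confusion
    matrices and test accuracies.
    """
    plan = plan or SplitPlan.for_scheme(ds.scheme, n_repeats=1, seed=cfg.seed)
    truncated = truncate_dataset(ds, drop_head, drop_tail)
    tr_full, te_full = stratified_split(ds, plan, repeat_index)
    tr_cut, te_cut = stratified_split(truncated, plan, repeat_index)

    K = len(ds.class_names)
    results = {}
    for tag, (tr, te) in (("full", (tr_full, te_full)), ("truncated", (tr_cut, te_cut))):
        model = fit_deep(model_kind, tr, te, cfg, lstm_cfg=lstm_cfg)
        proba = model.predict_proba(te)
        y = te.y_indices()
        results[tag] = (
            confusion(y, proba, n_classes=K),
            float(np.mean(np.argmax(proba, axis=1) == y)),
        )
    report = TruncationReport(
        full_confusion=results["full"][0],
        truncated_confusion=results["truncated"][0],
        full_accuracy=results["full"][1],
        truncated_accuracy=results["truncated"][1],
        class_names=list(ds.class_names),
        truncated_length=truncated.n_points,
    )
    return truncated, report
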