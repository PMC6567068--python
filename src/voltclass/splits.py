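"""Repeated stratified train/test splitting and class weighting.

The evaluation protocol uses randomized, stratified, shuffled train/test
splits (70:30 for the seawater and 3-class explosives schemes, 50:50 for the
11-class explosives scheme), repeated 25 times, with rare-event class
weighting: class ``c`` gets weight ``N / (K * n_c)`` so every class carries
equal effective mass in the loss regardless of its sample count.
"""

from __future__ import annotations

from dataclasses import dataclass, field

import numpy as np
from sklearn.model_selection import StratifiedShuffleSplit

from .dataset import ScanDataset

__all__ = ["SplitPlan", "ClassWeights", "stratified_split", "compute_class_weights"]

#: train fraction per label scheme
TRAIN_FRACTIONS = {"4-SW": 0.7, "11-SW": 0.7, "3-EXP": 0.7, "11-EXP": 0.5}


@dataclass(frozen=True)
class SplitPlan:
    train_fraction: float = 0.7
    n_repeats: int = 25
    seed: int = 0

    def __post_init__(self) -> None:
        if not (0.0 < self.train_fraction < 1.0):
            raise ValueError("train_fraction must be in (0, 1)")
        if self.n_repeats < 1:
            raise ValueError("n_repeats must be >= 1")

    @classmethod
    def for_scheme(cls, scheme: str, n_repeats: int = 25, seed: int = 0) -> "SplitPlan":
        return cls(
            train_fraction=TRAIN_FRACTIONS.get(scheme, 0.7),
            n_repeats=n_repeats,
            seed=seed,
        )

    def repeat_seed(self, repeat_index: int) -> int:
        """Derived seed for one repeat, reproducible in isolation."""
        if not (0 <= repeat_index < self.n_repeats):
            raise ValueError(f"repeat_index {repeat_index} outside 0..{self.n_repeats - 1}")
        ss = np.random.SeedSequence([self.seed, repeat_index])
        return int(ss.generate_state(1)[0] % (2**31))


@dataclass(frozen=True)
class ClassWeights:
    weights: dict[str, float]

    def __post_init__(self) -> None:
        if any(w <= 0 for w in self.weights.values()):
            raise ValueError("class weights must be positive")

    def per_scan(self, labels) -> np.ndarray:
        return np.array([self.weights[str(l)] for l in labels], dtype=float)


def stratified_split(
    ds: ScanDataset, plan: SplitPlan, repeat_index: int = 0
) -> tuple[ScanDataset, ScanDataset]:
    """One stratified shuffled train/test split of a dataset.

    Per class, the train fraction is within one scan of
    ``plan.train_fraction``; train and test are disjoint and exhaustive.
    Deterministic in ``(plan.seed, repeat_index)``.
    """
    counts = ds.class_counts()
    thin = [c for c, n in counts.items() if n < 2]
    if thin:
        raise ValueError(f"classes with < 2 scans cannot be split: {thin}")
    splitter = StratifiedShuffleSplit(
        n_splits=1,
        train_size=plan.train_fraction,
        random_state=plan.repeat_seed(repeat_index),
    )
    y = ds.y_indices()
    train_idx, test_idx = next(splitter.split(np.zeros((len(ds), 1)), y))
    return ds.subset(np.sort(train_idx)), ds.subset(np.sort(test_idx))


def compute_class_weights(train: ScanDataset) -> ClassWeights:
    """Inverse-frequency weights ``w_c = N / (K * n_c)`` over the training set.

    Sum over scans of their class weight equals N, and each class contributes
    N/K in total — the rare-event correction that keeps minority classes
    (e.g. 4 BPA scans vs 80 blanks) from being ignored by the loss.
    """
    if len(train) == 0:
        raise ValueError("empty training set")
    counts = {c: n for c, n in train.class_counts().items() if n > 0}
    if not counts:
        raise ValueError("no populated classes")
    N = len(train)
    K = len(counts)
    return ClassWeights({c: N / (K * n) for c, n in counts.items()})
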