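"""Non-deep baseline classifiers: 1NN-DTW, PCA-SVM and LDA.

The nearest-neighbour dynamic-time-warping classifier is written from scratch
(banded dynamic programme, Sakoe-Chiba window of 10 samples by default); the
two projection baselines wrap scikit-learn (3 principal components + RBF SVM,
and a 3-discriminant LDA using its native Bayes classification rule).
"""

from __future__ import annotations

from dataclasses import dataclass

import numpy as np
from numba import njit
from sklearn.decomposition import PCA
from sklearn.discriminant_analysis import LinearDiscriminantAnalysis
from sklearn.pipeline import Pipeline
from sklearn.svm import SVC

from .dataset import ScanDataset, Voltammogram

__all__ = [
    "DTWParams",
    "ProjectionParams",
    "dtw_distance",
    "dtw_distance_bruteforce",
    "OneNNDTW",
    "knn1_dtw_predict",
    "SklearnClassifier",
    "fit_pca_svm",
    "fit_lda",
]


@dataclass(frozen=True)
class DTWParams:
    """Sakoe-Chiba-banded DTW settings; k is fixed to 1 (nearest neighbour)."""

    window: int = 10
    local_cost: str = "absolute"
    k: int = 1

    def __post_init__(self) -> None:
        if self.window < 0:
            raise ValueError("window must be >= 0")
        if self.local_cost not in ("absolute", "squared"):
            raise ValueError("local_cost must be 'absolute' or 'squared'")
        if self.k != 1:
            raise ValueError("only k=1 is supported")


@dataclass(frozen=True)
class ProjectionParams:
    n_components: int = 3

    def __post_init__(self) -> None:
        if self.n_components < 1:
            raise ValueError("n_components must be >= 1")


@njit(cache=True)
def _dtw_band(a, b, window, squared):  # pragma: no cover - jitted
    n = a.shape[0]
    m = b.shape[0]
    w = max(window, abs(n - m))
    inf = np.inf
    prev = np.full(m + 1, inf)
    curr = np.full(m + 1, inf)
    prev[0] = 0.0
    for i in range(1, n + 1):
        lo = max(1, i - w)
        hi = min(m, i + w)
        curr[:] = inf
        for j in range(lo, hi + 1):
            d = a[i - 1] - b[j - 1]
            c = d * d if squared else abs(d)
            best = prev[j - 1]
            if prev[j] < best:
                best = prev[j]
            if curr[j - 1] < best:
                best = curr[j - 1]
            curr[j] = c + best
        prev, curr = curr, prev
    return prev[m]


def dtw_distance(a: np.ndarray, b: np.ndarray, params: DTWParams = DTWParams()) -> float:
    """Banded DTW distance between two equal-length current traces.

    Standard recurrence ``D(i,j) = cost(a_i, b_j) + min(D(i-1,j), D(i,j-1),
    D(i-1,j-1))`` restricted to ``|i - j| <= window``.  With window 0 this
    degenerates to the pointwise L1 (or squared-L2) distance.
    """
    a = np.ascontiguousarray(a, dtype=np.float64)
    b = np.ascontiguousarray(b, dtype=np.float64)
    if a.size == 0 or b.size == 0:
        raise ValueError("empty trace")
    return float(_dtw_band(a, b, params.window, params.local_cost == "squared"))


def dtw_distance_bruteforce(
    a: np.ndarray, b: np.ndarray, params: DTWParams = DTWParams()
) -> float:
    """Reference DTW by explicit enumeration of all monotone warping paths.

    Exponential; only usable for tiny traces.  Kept as the independent check
    on the dynamic programme.
    """
    a = np.asarray(a, dtype=float)
    b = np.asarray(b, dtype=float)
    if a.size == 0 or b.size == 0:
        raise ValueError("empty trace")
    squared = params.local_cost == "squared"
    w = max(params.window, abs(a.size - b.size))

    def cost(i: int, j: int) -> float:
        d = a[i] - b[j]
        return d * d if squared else abs(d)

    best = [np.inf]

    def walk(i: int, j: int, acc: float) -> None:
        if abs(i - j) > w:
            return
        acc += cost(i, j)
        if acc >= best[0]:
            return
        if i == a.size - 1 and j == b.size - 1:
            best[0] = acc
            return
        if i + 1 < a.size:
            walk(i + 1, j, acc)
        if j + 1 < b.size:
            walk(i, j + 1, acc)
        if i + 1 < a.size and j + 1 < b.size:
            walk(i + 1, j + 1, acc)

    walk(0, 0, 0.0)
    return float(best[0])


class OneNNDTW:
    """1-nearest-neighbour classifier under banded DTW distance.

    Ties (equidistant neighbours) resolve to the earliest training index, so
    predictions are deterministic.  ``predict_proba`` is the one-hot of the
    nearest neighbour's class — the classifier has no native probability.
    """

    def __init__(self, params: DTWParams = DTWParams()) -> None:
        self.params = params
        self._train: ScanDataset | None = None

    def fit(self, train: ScanDataset) -> "OneNNDTW":
        if len(train) == 0:
            raise ValueError("empty training set")
        self._train = train
        return self

    @property
    def class_names(self) -> list[str]:
        return self._train.class_names

    def _nearest(self, trace: np.ndarray) -> int:
        tr = self._train
        best_i, best_d = 0, np.inf
        for i in range(len(tr)):
            d = dtw_distance(tr.currents[i], trace, self.params)
            if d < best_d:  # strict: keeps the earliest index on ties
                best_i, best_d = i, d
        return best_i

    def predict(self, ds: ScanDataset) -> np.ndarray:
        return np.array(
            [str(self._train.labels[self._nearest(t)]) for t in ds.currents], dtype=object
        )

    def predict_proba(self, ds: ScanDataset) -> np.ndarray:
        lut = {c: k for k, c in enumerate(self._train.class_names)}
        proba = np.zeros((len(ds), len(lut)))
        for r, lbl in enumerate(self.predict(ds)):
            proba[r, lut[lbl]] = 1.0
        return proba


def knn1_dtw_predict(
    train: ScanDataset, query: Voltammogram, params: DTWParams = DTWParams()
) -> str:
    """Label of the training scan nearest to ``query`` under banded DTW."""
    model = OneNNDTW(params).fit(train)
    return str(train.labels[model._nearest(np.asarray(query.currents))])


class SklearnClassifier:
    """Thin adapter giving sklearn pipelines the ScanDataset interface."""

    def __init__(self, pipeline: Pipeline) -> None:
        self.pipeline = pipeline
        self.class_names: list[str] = []

    def fit(self, train: ScanDataset) -> "SklearnClassifier":
        self.class_names = train.class_names
        self.pipeline.fit(train.currents, train.y_indices())
        return self

    def predict_proba(self, ds: ScanDataset) -> np.ndarray:
        raw = self.pipeline.predict_proba(ds.currents)
        # expand to all classes (some may be absent from a small training split)
        proba = np.zeros((len(ds), len(self.class_names)))
        proba[:, np.asarray(self.pipeline.classes_, dtype=int)] = raw
        return proba

    def predict(self, ds: ScanDataset) -> np.ndarray:
        idx = np.argmax(self.predict_proba(ds), axis=1)
        return np.array([self.class_names[i] for i in idx], dtype=object)


def fit_pca_svm(
    train: ScanDataset,
    params: ProjectionParams = ProjectionParams(),
    seed: int = 0,
) -> SklearnClassifier:
    """3-component PCA followed by an RBF SVM with probability outputs."""
    if len(train.class_counts()) < 2:
        raise ValueError("need at least 2 classes")
    if len(train) <= params.n_components:
        raise ValueError("fewer scans than projection components")
    pipe = Pipeline(
        [
            ("pca", PCA(n_components=params.n_components, random_state=seed)),
            ("svm", SVC(kernel="rbf", probability=True, random_state=seed)),
        ]
    )
    return SklearnClassifier(pipe).fit(train)


def fit_lda(
    train: ScanDataset, params: ProjectionParams = ProjectionParams()
) -> SklearnClassifier:
    """LDA with a 3-discriminant subspace; classification uses the full rule.

    The component cap limits the embedding dimension only — the Bayes-rule
    classifier over all classes is otherwise ill-posed with 3 components.
    """
    n_classes = len([c for c, n in train.class_counts().items() if n > 0])
    if n_classes < 2:
        raise ValueError("need at least 2 classes")
    n_comp = min(params.n_components, n_classes - 1)
    pipe = Pipeline([("lda", LinearDiscriminantAnalysis(n_components=n_comp))])
    return SklearnClassifier(pipe).fit(train)
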