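"""DTW distance (vs. brute-force path enumeration), 1NN-DTW, PCA-SVM, LDA."""

import itertools

import numpy as np
import pytest
from hypothesis import given, settings
from hypothesis import strategies as st

import voltclass as vc
from voltclass.classical import (
    DTWParams,
    OneNNDTW,
    ProjectionParams,
    dtw_distance,
    dtw_distance_bruteforce,
    fit_lda,
    fit_pca_svm,
    knn1_dtw_predict,
)
from voltclass.dataset import ScanDataset
from voltclass.grid import PotentialGrid


class TestDTWDistance:
    def test_identity_is_zero(self):
        x = np.array([0.3, -1.2, 4.0, 0.0])
        assert dtw_distance(x, x) == 0.0

    def test_worked_example(self):
        # brute-force enumeration over all monotone warping paths gives 1.0
        a = np.array([0.0, 1.0, 2.0])
        b = np.array([0.0, 2.0, 2.0])
        assert dtw_distance(a, b) == pytest.approx(1.0)
        assert dtw_distance_bruteforce(a, b) == pytest.approx(1.0)

    def test_window_zero_collapses_to_l1(self):
        rng = np.random.default_rng(0)
        a, b = rng.normal(size=12), rng.normal(size=12)
        d = dtw_distance(a, b, DTWParams(window=0))
        assert d == pytest.approx(np.abs(a - b).sum())

    def test_empty_trace_rejected(self):
        with pytest.raises(ValueError):
            dtw_distance(np.array([]), np.array([1.0]))

    def test_exhaustive_oracle_equivalence_short(self):
        """Banded DP equals brute force on every pair of length<=3 traces over {0,1,2}."""
        alphabet = (0.0, 1.0, 2.0)
        traces = [
            np.array(t, dtype=float)
            for L in (1, 2, 3)
            for t in itertools.product(alphabet, repeat=L)
        ]
        params = DTWParams(window=10)
        for a in traces:
            for b in traces:
                assert dtw_distance(a, b, params) == pytest.approx(
                    dtw_distance_bruteforce(a, b, params)
                )

    @given(
        st.lists(st.sampled_from([0.0, 1.0, 2.0]), min_size=1, max_size=6),
        st.lists(st.sampled_from([0.0, 1.0, 2.0]), min_size=1, max_size=6),
        st.integers(min_value=0, max_value=10),
        st.sampled_from(["absolute", "squared"]),
    )
    @settings(deadline=None, max_examples=300, derandomize=True)
    def test_oracle_equivalence_sampled(self, a, b, window, cost):
        params = DTWParams(window=window, local_cost=cost)
        a, b = np.array(a), np.array(b)
        assert dtw_distance(a, b, params) == pytest.approx(
            dtw_distance_bruteforce(a, b, params)
        )

    @given(
        st.lists(st.floats(-5, 5, allow_nan=False), min_size=2, max_size=30),
        st.lists(st.floats(-5, 5, allow_nan=False), min_size=2, max_size=30),
    )
    @settings(deadline=None, max_examples=100, derandomize=True)
    def test_symmetry_and_nonnegativity(self, a, b):
        a, b = np.array(a), np.array(b)
        d = dtw_distance(a, b)
        assert d >= 0
        assert d == pytest.approx(dtw_distance(b, a))

    def test_wider_window_never_increases_distance(self):
        rng = np.random.default_rng(3)
        a, b = rng.normal(size=40), rng.normal(size=40)
        ds = [dtw_distance(a, b, DTWParams(window=w)) for w in (0, 2, 5, 10, 20)]
        assert all(x >= y - 1e-9 for x, y in zip(ds, ds[1:]))


def _labeled_dataset(currents, labels, class_names):
    n, L = np.asarray(currents).shape
    grid = PotentialGrid(n_points=L, boundary_index=L // 2,
                         cathodic_start=0.2, anodic_start=-0.2, step=0.01)
    return ScanDataset(currents, labels, "custom", class_names, grid)


class TestOneNNDTW:
    def test_training_scan_maps_to_own_label(self, tiny_ds):
        model = OneNNDTW().fit(tiny_ds)
        assert model.predict(tiny_ds.subset([0]))[0] == tiny_ds.labels[0]

    def test_tie_breaks_to_earliest_index(self):
        ds = _labeled_dataset(
            [[0.0] * 8, [0.0] * 8, [1.0] * 8], ["a", "b", "b"], ["a", "b"]
        )
        query = ds[0]
        # scans 0 and 1 are identical but carry different labels
        assert knn1_dtw_predict(ds, query) == "a"

    def test_separable_classes_perfect(self):
        # noise-free and narrow concentration spread: nearest-neighbour DTW
        # then sees pure peak-shape differences and classifies perfectly
        # (wide amplitude spread degrades 1NN-DTW — it is not scale invariant)
        spec = vc.generic_library_spec(
            {
                "scheme": "custom",
                "grid": dict(n_points=80, boundary_index=40, cathodic_start=0.40,
                             anodic_start=-0.40, step=0.02),
                "noise_sigma": 0.0,
                "baseline_slope_sigma": 0.0,
                "classes": [
                    {"name": n, "n_samples": 6, "peaks": pk, "oxygen_background": False,
                     "concentration_range": (400.0, 600.0)}
                    for n, pk in [
                        ("A", [[-0.20, "cathodic"]]),
                        ("B", [[0.10, "anodic"]]),
                        ("C", [[0.25, "anodic", 0.05, 0.5]]),
                    ]
                ],
            }
        )
        ds = vc.generate_dataset(spec, seed=11)
        tr, te = vc.stratified_split(ds, vc.SplitPlan(train_fraction=0.5, seed=0), 0)
        model = OneNNDTW().fit(tr)
        assert (model.predict(te) == te.labels).all()

    def test_proba_is_onehot(self, tiny_ds):
        model = OneNNDTW().fit(tiny_ds)
        proba = model.predict_proba(tiny_ds.subset([0, 1]))
        np.testing.assert_allclose(proba.sum(axis=1), 1.0)
        assert set(np.unique(proba)) <= {0.0, 1.0}


class TestProjectionBaselines:
    @pytest.fixture(scope="class")
    def separated(self):
        rng = np.random.default_rng(5)
        a = rng.normal(0.0, 0.1, size=(20, 30))
        b = rng.normal(5.0, 0.1, size=(20, 30))
        ds = _labeled_dataset(np.vstack([a, b]), ["a"] * 20 + ["b"] * 20, ["a", "b"])
        return ds

    @pytest.mark.parametrize("fitter", [fit_pca_svm, fit_lda])
    def test_separable_clouds_perfect(self, separated, fitter):
        tr, te = vc.stratified_split(separated, vc.SplitPlan(train_fraction=0.5, seed=1), 0)
        model = fitter(tr)
        assert (model.predict(te) == te.labels).all()

    def test_probabilities_normalized(self, separated):
        model = fit_pca_svm(separated)
        proba = model.predict_proba(separated)
        np.testing.assert_allclose(proba.sum(axis=1), 1.0, atol=1e-9)

    def test_pca_projection_dimension(self, separated):
        model = fit_pca_svm(separated, ProjectionParams(n_components=3))
        pca = model.pipeline.named_steps["pca"]
        assert pca.transform(separated.currents[:4]).shape[1] == 3

    def test_lda_classifies_all_classes(self, sw11):
        tr, te = vc.stratified_split(sw11, vc.SplitPlan.for_scheme("11-SW", seed=2), 0)
        model = fit_lda(tr)
        proba = model.predict_proba(te)
        assert proba.shape == (len(te), 11)
        np.testing.assert_allclose(proba.sum(axis=1), 1.0, atol=1e-6)
        # 3 discriminant axes only cap the embedding, not the classifier
        assert model.pipeline.named_steps["lda"].n_components == 3

    def test_single_class_rejected(self, tiny_ds):
        sub = tiny_ds.subset(np.flatnonzero(tiny_ds.labels == "A").tolist())
        with pytest.raises(ValueError):
            fit_pca_svm(sub)
        with pytest.raises(ValueError):
            fit_lda(sub)
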