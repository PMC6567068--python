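"""Deep-classifier construction, LR schedule, initialization and training."""

import numpy as np
import pytest

import voltclass as vc
from voltclass.nn.layers import Conv1DSame, softmax, weighted_cross_entropy
from voltclass.nn.models import FCNConfig, LSTMConfig, build_model
from voltclass.nn.training import (
    TrainConfig,
    best_setting,
    desk_config,
    fit_deep,
    lr_schedule_step,
    train,
)
from voltclass.splits import SplitPlan, stratified_split


class TestLRSchedule:
    def test_single_plateau_reduction(self):
        cfg = TrainConfig()
        assert lr_schedule_step(1e-3, 100, cfg) == pytest.approx(7.937e-4, rel=1e-3)

    def test_below_patience_unchanged(self):
        assert lr_schedule_step(1e-3, 50, TrainConfig()) == 1e-3

    def test_floor_after_ten_plateaus(self):
        cfg = TrainConfig()
        lr = 1e-3
        for k in range(1, 11):
            lr = lr_schedule_step(lr, k * cfg.patience, cfg)
        # 1e-3 * 2^(-10/3) < 1e-4, so the floor engages
        assert lr == pytest.approx(1e-4)

    def test_nonpositive_lr_rejected(self):
        with pytest.raises(ValueError):
            lr_schedule_step(0.0, 100, TrainConfig())

    def test_config_validation(self):
        with pytest.raises(ValueError):
            TrainConfig(lr_init=1e-5, lr_final=1e-4)
        with pytest.raises(ValueError):
            TrainConfig(patience=0)


class TestArchitecture:
    def test_fcn_gap_dimension_is_128(self):
        model = build_model("fcn", n_classes=4, length=1002)
        assert model.gap_dim == 128
        assert model.fcn_cfg.filters == (128, 256, 128)
        assert model.fcn_cfg.kernel_sizes == (8, 5, 3)

    @pytest.mark.parametrize("kind", ["lstm", "fcn", "lstm_fcn", "alstm_fcn"])
    def test_probabilities_sum_to_one(self, kind, tiny_ds):
        model = build_model(kind, n_classes=3, length=tiny_ds.n_points,
                            lstm_cfg=LSTMConfig(cells=4))
        model.class_names = tiny_ds.class_names
        proba = model.predict_proba(tiny_ds)
        np.testing.assert_allclose(proba.sum(axis=1), 1.0, atol=1e-6)

    def test_dimension_shuffle_consumes_whole_trace_in_one_step(self):
        model = build_model("lstm", n_classes=3, length=1002, lstm_cfg=LSTMConfig(cells=8))
        lstm = model.rnn_layers[0]
        # the gate kernel maps all 1002 features of the single step at once
        assert lstm.params["W"].shape == (1002, 4 * 8)

    def test_attention_weights_normalized(self, tiny_ds):
        model = build_model("alstm_fcn", n_classes=3, length=tiny_ds.n_points,
                            lstm_cfg=LSTMConfig(cells=4))
        model.class_names = tiny_ds.class_names
        att = model.attention_weights(tiny_ds.subset(range(8)))
        assert att.shape == (8, tiny_ds.n_points)
        assert np.all(att >= 0)
        np.testing.assert_allclose(att.sum(axis=1), 1.0, atol=1e-5)

    def test_unknown_kind_rejected(self):
        with pytest.raises(ValueError):
            build_model("mlp", n_classes=3, length=100)

    def test_trace_shorter_than_kernel_rejected(self):
        with pytest.raises(ValueError):
            build_model("fcn", n_classes=3, length=5)

    def test_he_initialization_variance(self):
        rng = np.random.default_rng(0)
        conv = Conv1DSame(c_in=128, c_out=256, kernel=5, rng=rng)
        fan_in = 5 * 128
        var = conv.params["W"].var()
        assert var == pytest.approx(2.0 / fan_in, rel=0.2)


class TestLossAndSoftmax:
    def test_weighted_equals_unweighted_at_unit_weights(self):
        rng = np.random.default_rng(0)
        logits = rng.normal(size=(6, 3))
        y = rng.integers(0, 3, 6)
        l1, g1 = weighted_cross_entropy(logits, y, np.ones(6))
        p = softmax(logits)
        expected = -np.mean(np.log(p[np.arange(6), y]))
        assert l1 == pytest.approx(expected)
        l2, g2 = weighted_cross_entropy(logits, y, np.full(6, 3.7))
        assert l2 == pytest.approx(l1)
        np.testing.assert_allclose(g1, g2, atol=1e-6)

    def test_softmax_rows_normalized(self):
        z = np.random.default_rng(1).normal(size=(5, 7)) * 30
        np.testing.assert_allclose(softmax(z).sum(axis=1), 1.0, atol=1e-12)


class TestTraining:
    @pytest.fixture(scope="class")
    def split(self, tiny_ds):
        return stratified_split(tiny_ds, SplitPlan(0.7, 1, 0), 0)

    @pytest.mark.parametrize("kind", ["lstm", "fcn", "lstm_fcn", "alstm_fcn"])
    def test_models_learn_separable_classes(self, kind, split):
        tr, te = split
        cfg = TrainConfig(epochs=120, batch_size=8, seed=0, saturation_patience=3)
        model = fit_deep(kind, tr, te, cfg, lstm_cfg=LSTMConfig(cells=8))
        assert model.history.val_accuracy.iloc[-1] >= 0.95

    def test_history_monotone_lr_and_bounded_length(self, split):
        tr, te = split
        cfg = TrainConfig(epochs=25, batch_size=8, seed=1, saturation_patience=0)
        model = fit_deep("fcn", tr, te, cfg)
        h = model.history
        assert len(h) <= 25
        lrs = h.lr.to_numpy()
        assert np.all(np.diff(lrs) <= 1e-12)

    def test_training_determinism(self, split):
        tr, te = split
        cfg = TrainConfig(epochs=5, batch_size=8, seed=42, saturation_patience=0)
        a = fit_deep("fcn", tr, te, cfg)
        b = fit_deep("fcn", tr, te, cfg)
        np.testing.assert_array_equal(a.predict_proba(te), b.predict_proba(te))
        assert a.history.equals(b.history)

    def test_scheme_mismatch_rejected(self, split, sw11):
        tr, _ = split
        model = build_model("fcn", 3, tr.n_points)
        with pytest.raises(ValueError):
            train(model, tr, sw11, TrainConfig(epochs=1))

    def test_save_load_roundtrip(self, split, tmp_path):
        tr, te = split
        cfg = TrainConfig(epochs=3, batch_size=8, seed=7, saturation_patience=0)
        model = fit_deep("lstm_fcn", tr, te, cfg, lstm_cfg=LSTMConfig(cells=4))
        path = tmp_path / "model.npz"
        model.save(path)
        from voltclass.nn.models import DeepClassifier

        back = DeepClassifier.load(path)
        np.testing.assert_allclose(back.predict_proba(te), model.predict_proba(te),
                                   atol=1e-6)
        assert back.class_names == model.class_names


class TestSweep:
    def test_sweep_table_shape_and_best(self, tiny_ds):
        cfg = TrainConfig(epochs=15, batch_size=8, seed=0, saturation_patience=2)
        tbl = vc.sweep("lstm", tiny_ds, cells_grid=(4, 8), n_repeats=2, cfg=cfg)
        assert len(tbl) == 2 * 2  # settings x repeats
        assert set(tbl.parameter) == {"cells"}
        assert best_setting(tbl, "cells") in (4, 8)
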