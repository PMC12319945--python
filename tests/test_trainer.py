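"""Temporal-ensembling targets and the training loops (desk-scale smoke)."""

import numpy as np
import pytest

from bundleseg.augmentation import GeomPolicy, PairPolicy
from bundleseg.network import build_model
from bundleseg.trainer import (
    PredictionHistory,
    TrainConfig,
    TrainSample,
    pretrain,
    te_target,
    train_te,
)


@pytest.fixture()
def te_cfg():
    return TrainConfig(te_history=3, te_threshold=0.5, pretrain_epochs=0)


def _fast_cfg(**over):
    base = dict(
        lr=1e-3,
        batch_size=4,
        pretrain_epochs=2,
        te_epochs=2,
        te_history=2,
        patch_size=64,
        patches_per_section=6,
        seed=7,
        geom_policy=GeomPolicy(translation_px=(-10, 10)),
        pair_policy=PairPolicy(wm_mean_intensity_range=(0.02, 0.6)),
    )
    base.update(over)
    return TrainConfig(**base)


class TestTeTarget:
    def test_mean_of_identical_maps(self, te_cfg):
        h = PredictionHistory(3)
        m = np.full((4, 4), 0.8, dtype=np.float32)
        for _ in range(3):
            h.add("s", m)
        out = te_target(h, "s", 10, None, te_cfg)
        np.testing.assert_array_equal(out, np.ones((4, 4), dtype=np.uint8))

    def test_hand_computed_mean_with_tie_rule(self, te_cfg):
        h = PredictionHistory(3)
        for v in (0.2, 0.6, 0.7):  # mean exactly 0.5 -> label 1 (>= convention)
            h.add("s", np.full((2, 2), v, dtype=np.float32))
        out = te_target(h, "s", 10, None, te_cfg)
        assert (out == 1).all()

    def test_fallback_to_pretrained_prediction(self, te_cfg):
        h = PredictionHistory(3)
        pre = np.array([[0.9, 0.1]], dtype=np.float32)
        out = te_target(h, "s", 0, pre, te_cfg)
        np.testing.assert_array_equal(out, np.array([[1, 0]], dtype=np.uint8))
        h.add("s", np.ones((1, 2), dtype=np.float32))  # still < r maps stored
        out = te_target(h, "s", 1, pre, te_cfg)
        np.testing.assert_array_equal(out, np.array([[1, 0]], dtype=np.uint8))

    def test_missing_pretrain_prediction_raises(self, te_cfg):
        with pytest.raises(ValueError):
            te_target(PredictionHistory(3), "s", 0, None, te_cfg)

    def test_r1_reduces_to_previous_epoch(self):
        cfg = TrainConfig(te_history=1)
        h = PredictionHistory(1)
        h.add("s", np.array([[0.7, 0.2]], dtype=np.float32))
        h.add("s", np.array([[0.1, 0.9]], dtype=np.float32))  # ring keeps only this
        out = te_target(h, "s", 5, None, cfg)
        np.testing.assert_array_equal(out, np.array([[0, 1]], dtype=np.uint8))

    def test_history_ring_never_exceeds_r(self):
        h = PredictionHistory(3)
        for i in range(10):
            h.add("s", np.full((2, 2), i / 10, dtype=np.float32))
        assert h.count("s") == 3

    def test_history_rejects_out_of_range_maps(self):
        with pytest.raises(ValueError):
            PredictionHistory(2).add("s", np.array([1.5]))


class TestTraining:
    def test_pretrain_smoke_and_determinism(self, tiny_stack, tiny_model_cfg):
        labeled = [TrainSample(s.section, s.annotations, None) for s in tiny_stack[:2]]
        cfg = _fast_cfg(pretrain_epochs=2)
        m1 = build_model(tiny_model_cfg, seed=1)
        m1, curve1 = pretrain(m1, labeled, cfg)
        assert len(curve1) == 2 and all(np.isfinite(curve1))
        m2 = build_model(tiny_model_cfg, seed=1)
        m2, curve2 = pretrain(m2, labeled, cfg)
        assert curve1 == curve2

    def test_contrastive_ablation_switch(self, tiny_stack, tiny_model_cfg, monkeypatch):
        """With contrastive weight 0 the contrastive term must never be evaluated."""
        import bundleseg.trainer as trainer_mod

        def boom(*a, **k):  # pragma: no cover - executed only on failure
            raise AssertionError("contrastive loss evaluated despite zero weight")

        monkeypatch.setattr(trainer_mod, "contrastive_loss", boom)
        monkeypatch.setattr(trainer_mod, "contrastive_loss_grad", boom)
        labeled = [TrainSample(s.section, s.annotations, None) for s in tiny_stack[:1]]
        model = build_model(tiny_model_cfg, seed=0)
        cfg = _fast_cfg(pretrain_epochs=1, contrastive_weight=0.0)
        pretrain(model, labeled, cfg)

    def test_empty_labeled_set_rejected(self, tiny_model):
        with pytest.raises(ValueError):
            pretrain(tiny_model, [], _fast_cfg())

    def test_train_te_smoke(self, tiny_stack, tiny_model_cfg):
        labeled = [TrainSample(s.section, s.annotations, None) for s in tiny_stack[:2]]
        unlabeled = [TrainSample(s.section, None, None) for s in tiny_stack[2:]]
        model = build_model(tiny_model_cfg, seed=2)
        cfg = _fast_cfg(pretrain_epochs=1, te_epochs=2)
        model, _ = pretrain(model, labeled, cfg)
        model, logs = train_te(model, labeled, unlabeled, cfg)
        assert len(logs) == 2
        frac = logs["pseudo_label_pos_frac"].to_numpy()
        assert np.isfinite(frac).all()
        assert ((frac >= 0) & (frac <= 1)).all()

    def test_train_te_without_unlabeled_warns(self, tiny_stack, tiny_model_cfg):
        labeled = [TrainSample(s.section, s.annotations, None) for s in tiny_stack[:2]]
        model = build_model(tiny_model_cfg, seed=2)
        cfg = _fast_cfg(te_epochs=1)
        with pytest.warns(UserWarning, match="unlabeled"):
            train_te(model, labeled, [], cfg)

    def test_config_validation(self):
        with pytest.raises(ValueError):
            TrainConfig(te_history=0)
        with pytest.raises(ValueError):
            TrainConfig(early_stop_patience=0)
        with pytest.raises(ValueError):
            TrainConfig(contrastive_weight=-1.0)
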