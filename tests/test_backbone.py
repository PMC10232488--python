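import numpy as np
import pytest

import histotile as ht
from histotile.backbone import (
    BackboneConfig, BackboneTrainConfig, ResidualBlock,
    extract_features_from_arrays, train_arrays,
)


@pytest.fixture(scope="module")
def small_backbone():
    cfg = BackboneConfig(input_size=(32, 32), feature_dim=16)
    return ht.build_backbone(cfg, [f"c{i}" for i in range(4)], seed=7)


class TestForward:
    def test_emits_finite_fixed_length_features(self, small_backbone):
        x = np.random.default_rng(0).random((3, 3, 32, 32)).astype(np.float32)
        feat, logits = small_backbone.forward(x)
        assert feat.shape == (3, 16) and logits.shape == (3, 4)
        assert np.isfinite(feat).all() and np.isfinite(logits).all()

    def test_inference_is_deterministic(self, small_backbone):
        x = np.random.default_rng(1).random((2, 3, 32, 32)).astype(np.float32)
        f1, _ = small_backbone.forward(x)
        f2, _ = small_backbone.forward(x)
        np.testing.assert_array_equal(f1, f2)

    def test_zero_input_gives_bias_only_response(self, small_backbone):
        f1, _ = small_backbone.forward(np.zeros((2, 3, 32, 32), dtype=np.float32))
        f2, _ = small_backbone.forward(
            0.0 * np.random.default_rng(2).random((2, 3, 32, 32)).astype(np.float32))
        np.testing.assert_allclose(f1, f2, atol=1e-6)

    def test_bad_config_rejected_at_build_time(self):
        with pytest.raises(ValueError):
            BackboneConfig(feature_dim=4)
        with pytest.raises(ValueError):
            BackboneConfig(dilation_rates=(2, 2, 3))
        with pytest.raises(NotImplementedError):
            ht.build_backbone(BackboneConfig(use_pretrained_stem=True), ["a", "b"])


class TestResidualBlock:
    def test_zeroed_residual_branch_acts_as_identity(self):
        blk = ResidualBlock(3, 3, rng=np.random.default_rng(0))
        blk.conv2.weight.value[...] = 0.0
        blk.conv2.bias.value[...] = 0.0
        x = np.abs(np.random.default_rng(1).standard_normal((2, 3, 8, 8))
                   ).astype(np.float32)
        out = blk.forward(x, train=False)  # running BN stats are the defaults
        np.testing.assert_allclose(out, x, atol=1e-6)

    def test_shortcut_changes_the_output(self):
        rng = np.random.default_rng(2)
        blk = ResidualBlock(3, 3, rng=rng)
        x = rng.standard_normal((2, 3, 8, 8)).astype(np.float32)
        full = blk.forward(x, train=False)
        # main branch alone (no additive shortcut)
        y = blk.conv1.forward(x)
        y = blk.bn1.forward(y)
        y = blk.relu1.forward(y)
        y = blk.conv2.forward(y)
        y = blk.bn2.forward(y)
        main_only = np.maximum(y, 0.0)
        assert np.abs(full - main_only).max() > 1e-3


class TestTraining:
    def _toy_problem(self, n_per=20):
        spec = ht.SyntheticSpec(n_classes=2, tiles_per_class=n_per + 8,
                                tile_size=(32, 32), noise_sd=6.0, seed=3)
        tiles, labels = ht.generate_arrays(spec)
        x = np.stack([ht.prepare_tile(t, (32, 32)) for t in tiles])
        rng = np.random.default_rng(0)
        idx = rng.permutation(len(x))
        n_tr = 2 * n_per
        return (x[idx[:n_tr]], labels[idx[:n_tr]],
                x[idx[n_tr:]], labels[idx[n_tr:]])

    def test_loss_decreases_and_lr_recorded(self):
        x_tr, y_tr, x_va, y_va = self._toy_problem()
        bb = ht.build_backbone(BackboneConfig(input_size=(32, 32), feature_dim=16),
                               ["0", "1"], seed=1)
        hist = train_arrays(bb, x_tr, y_tr, x_va, y_va,
                            BackboneTrainConfig(max_epochs=6, patience=6, seed=0))
        assert hist["metadata"]["lr"] == 0.002
        assert hist["train_loss"][-1] < hist["train_loss"][0]
        assert len(hist["val_acc"]) <= 6

    def test_zero_epochs_is_a_no_op(self):
        x_tr, y_tr, x_va, y_va = self._toy_problem(n_per=6)
        bb = ht.build_backbone(BackboneConfig(input_size=(32, 32), feature_dim=16),
                               ["0", "1"], seed=1)
        before = bb.state_dict()
        hist = train_arrays(bb, x_tr, y_tr, x_va, y_va,
                            BackboneTrainConfig(max_epochs=0))
        assert hist["train_loss"] == []
        after = bb.state_dict()
        for key in before:
            np.testing.assert_array_equal(before[key], after[key])

    def test_trained_features_separate_classes(self):
        x_tr, y_tr, x_va, y_va = self._toy_problem()
        bb = ht.build_backbone(BackboneConfig(input_size=(32, 32), feature_dim=16),
                               ["0", "1"], seed=2)
        train_arrays(bb, x_tr, y_tr, x_va, y_va,
                     BackboneTrainConfig(max_epochs=8, patience=8, seed=0))
        fm = extract_features_from_arrays(bb, x_va, y_va.astype(str))
        f0 = fm.values[fm.labels == "0"]
        f1 = fm.values[fm.labels == "1"]
        within = np.linalg.norm(f0 - f0.mean(0), axis=1).mean() \
            + np.linalg.norm(f1 - f1.mean(0), axis=1).mean()
        between = np.linalg.norm(f0.mean(0) - f1.mean(0))
        assert between > within / 2


def test_save_load_roundtrip(tmp_path, small_backbone):
    x = np.random.default_rng(5).random((2, 3, 32, 32)).astype(np.float32)
    f1, l1 = small_backbone.forward(x)
    small_backbone.save(tmp_path / "bb.npz")
    loaded = ht.FeatureExtractor.load(tmp_path / "bb.npz")
    f2, l2 = loaded.forward(x)
    np.testing.assert_array_equal(f1, f2)
    np.testing.assert_array_equal(l1, l2)
    assert loaded.class_names == small_backbone.class_names
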