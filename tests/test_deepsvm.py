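import numpy as np
import pytest
from sklearn.svm import SVC

import histotile as ht
from histotile.backbone import FeatureMatrix
from histotile.deepsvm import (
    RbfKernelParams, SvmUnit, decision_scores, load_deepsvm, rbf_gram,
    save_deepsvm,
)


def _blob_features(n_classes=4, n_per=30, d=6, sep=4.0, seed=0):
    rng = np.random.default_rng(seed)
    centers = rng.standard_normal((n_classes, d)) * sep
    xs, ys = [], []
    for c in range(n_classes):
        xs.append(centers[c] + rng.standard_normal((n_per, d)))
        ys.extend([f"k{c}"] * n_per)
    return FeatureMatrix(values=np.vstack(xs), labels=np.array(ys))


class TestRbfKernel:
    def test_self_similarity_is_one(self):
        rng = np.random.default_rng(0)
        for _ in range(5):
            x = rng.standard_normal(4)
            assert ht.rbf_kernel(x, x, RbfKernelParams(c=3.0)) == pytest.approx(1.0)

    def test_worked_value(self):
        k = ht.rbf_kernel(np.array([0.0, 0.0]), np.array([1.0, 1.0]),
                          RbfKernelParams(c=2.0))
        assert k == pytest.approx(np.exp(-1.0), abs=1e-9)

    def test_symmetry_and_range(self):
        rng = np.random.default_rng(1)
        params = RbfKernelParams(c=1.5)
        for _ in range(10):
            x, y = rng.standard_normal((2, 5))
            kxy = ht.rbf_kernel(x, y, params)
            assert kxy == pytest.approx(ht.rbf_kernel(y, x, params))
            assert 0.0 < kxy <= 1.0

    def test_gram_matrices_positive_semidefinite(self):
        rng = np.random.default_rng(2)
        for n in (5, 12, 20):
            x = rng.standard_normal((n, 4))
            gram = rbf_gram(x, x, RbfKernelParams(c=float(4)))
            np.testing.assert_allclose(gram, gram.T, atol=1e-12)
            assert np.linalg.eigvalsh(gram).min() >= -1e-8

    def test_invalid_inputs_rejected(self):
        with pytest.raises(ValueError):
            RbfKernelParams(c=0.0)
        with pytest.raises(ValueError):
            ht.rbf_kernel(np.zeros(3), np.zeros(4), RbfKernelParams(c=1.0))


class TestSvmDecision:
    def test_single_support_vector_at_itself(self):
        sv = np.array([[1.0, -2.0]])
        unit = SvmUnit(support_vectors=sv, dual_coefs=[1.0], bias=0.0,
                       kernel=RbfKernelParams(c=1.0), C=10.0, positive_class="a")
        score, label = ht.svm_decision(unit, sv[0])
        assert score == pytest.approx(1.0)
        assert label == 1

    def test_zero_score_labels_positive(self):
        sv = np.array([[0.0, 0.0]])
        unit = SvmUnit(support_vectors=sv, dual_coefs=[1.0], bias=-1.0,
                       kernel=RbfKernelParams(c=1.0), C=10.0, positive_class="a")
        score, label = ht.svm_decision(unit, sv[0])
        assert score == pytest.approx(0.0)
        assert label == 1

    def test_matches_explicit_sum_oracle(self):
        rng = np.random.default_rng(3)
        sv = rng.standard_normal((3, 2))
        alpha_y = np.array([0.7, -1.2, 0.5])
        b = 0.3
        unit = SvmUnit(support_vectors=sv, dual_coefs=alpha_y, bias=b,
                       kernel=RbfKernelParams(c=2.5), C=10.0, positive_class="a")
        x = rng.standard_normal(2)
        expected = b + sum(
            alpha_y[j] * np.exp(-np.sum((x - sv[j]) ** 2) / 2.5) for j in range(3)
        )
        score, _ = ht.svm_decision(unit, x)
        assert score == pytest.approx(expected, abs=1e-10)

    def test_dimension_mismatch_rejected(self):
        unit = SvmUnit(support_vectors=np.zeros((1, 3)), dual_coefs=[1.0],
                       bias=0.0, kernel=RbfKernelParams(c=1.0), C=1.0,
                       positive_class="a")
        with pytest.raises(ValueError):
            ht.svm_decision(unit, np.zeros(2))


class TestTrainSvmUnit:
    def test_separable_blobs_fit_perfectly(self):
        rng = np.random.default_rng(3)
        x = np.vstack([rng.normal(-2, 0.5, (20, 2)), rng.normal(2, 0.5, (20, 2))])
        t = np.array([-1] * 20 + [1] * 20)
        unit = ht.train_svm_unit(x, t, C=10.0, kernel=RbfKernelParams(c=2.0))
        assert unit.train_accuracy == 1.0

    def test_xor_is_solved_by_the_rbf_kernel(self):
        x = np.array([[0.0, 0.0], [1.0, 1.0], [0.0, 1.0], [1.0, 0.0]])
        t = np.array([1, 1, -1, -1])
        unit = ht.train_svm_unit(x, t, C=10.0, kernel=RbfKernelParams(c=1.0))
        preds = np.sign(decision_scores(unit, x))
        np.testing.assert_array_equal(preds, t)

    def test_duplicated_rows_leave_decision_unchanged(self):
        rng = np.random.default_rng(4)
        x = np.vstack([rng.normal(-1, 0.6, (15, 2)), rng.normal(1, 0.6, (15, 2))])
        t = np.array([-1] * 15 + [1] * 15)
        k = RbfKernelParams(c=2.0)
        u1 = ht.train_svm_unit(x, t, 10.0, k)
        u2 = ht.train_svm_unit(np.vstack([x, x]), np.concatenate([t, t]), 10.0, k)
        grid = np.array(np.meshgrid(np.linspace(-2, 2, 7),
                                    np.linspace(-2, 2, 7))).reshape(2, -1).T
        np.testing.assert_allclose(decision_scores(u1, grid),
                                   decision_scores(u2, grid), atol=1e-6)

    def test_single_class_targets_rejected(self):
        with pytest.raises(ValueError):
            ht.train_svm_unit(np.zeros((4, 2)), np.ones(4), 1.0,
                              RbfKernelParams(c=1.0))


class TestLayerTransform:
    def test_shapes_with_and_without_pass_through(self):
        fm = _blob_features()
        cfg = ht.EnsembleConfig(pass_through=False, max_layers=1)
        model = ht.train_deepsvm(fm, fm, max_layers=1, config=cfg)
        layer = model.output_layer
        out = ht.layer_transform(layer, fm.values, pass_through=False)
        assert out.shape == (len(fm.labels), 4)
        out2 = ht.layer_transform(layer, fm.values, pass_through=True)
        assert out2.shape == (len(fm.labels), 4 + fm.n_features)
        np.testing.assert_array_equal(out2[:, :fm.n_features], fm.values)

    def test_scores_match_unit_by_unit_decision(self):
        fm = _blob_features(n_classes=3, n_per=15)
        model = ht.train_deepsvm(fm, fm, max_layers=1,
                                 config=ht.EnsembleConfig(max_layers=1))
        out = ht.layer_transform(model.output_layer, fm.values)
        for j, unit in enumerate(model.output_layer):
            expected = [ht.svm_decision(unit, row)[0] for row in fm.values[:5]]
            np.testing.assert_allclose(out[:5, j], expected, atol=1e-10)

    def test_empty_layer_rejected(self):
        with pytest.raises(ValueError):
            ht.layer_transform([], np.zeros((2, 3)))


class TestTrainDeepSvm:
    def test_one_layer_equals_flat_one_vs_rest_svm(self):
        train = _blob_features(seed=5)
        probe = _blob_features(seed=6)
        cfg = ht.EnsembleConfig(pass_through=False, bagging=False, max_layers=1)
        model = ht.train_deepsvm(train, probe, max_layers=1, config=cfg)
        assert model.hidden_layers == []
        # independent flat OvR: one sklearn SVC per class, argmax of scores
        classes = sorted(set(train.labels))
        scores = []
        for cls in classes:
            t = np.where(train.labels == cls, 1, -1)
            clf = SVC(C=cfg.C, kernel="rbf", gamma=1.0 / train.n_features)
            clf.fit(train.values, t)
            scores.append(clf.decision_function(probe.values))
        flat_pred = np.asarray(classes, dtype=object)[np.argmax(scores, axis=0)]
        np.testing.assert_array_equal(ht.predict(model, probe.values), flat_pred)

    def test_returned_depth_attains_best_validation_accuracy(self):
        train = _blob_features(sep=1.2, seed=7)
        val = _blob_features(sep=1.2, seed=8)
        model = ht.train_deepsvm(train, val, max_layers=4,
                                 config=ht.EnsembleConfig(max_layers=4,
                                                          patience=2, seed=0))
        accs = model.val_accuracy_per_depth
        assert 1 <= len(accs) <= 4
        assert accs[model.depth - 1] == pytest.approx(max(accs))

    def test_never_materially_worse_than_flat(self):
        train = _blob_features(sep=1.0, seed=9)
        val = _blob_features(sep=1.0, seed=10)
        model = ht.train_deepsvm(train, val, max_layers=3,
                                 config=ht.EnsembleConfig(seed=0))
        flat_acc = model.val_accuracy_per_depth[0]
        assert max(model.val_accuracy_per_depth) >= flat_acc - 0.005

    def test_deterministic_given_seed(self):
        train = _blob_features(sep=1.5, seed=11)
        val = _blob_features(sep=1.5, seed=12)
        cfg = ht.EnsembleConfig(bagging=True, seed=4)
        m1 = ht.train_deepsvm(train, val, max_layers=2, config=cfg)
        m2 = ht.train_deepsvm(train, val, max_layers=2, config=cfg)
        np.testing.assert_array_equal(ht.predict(m1, val.values),
                                      ht.predict(m2, val.values))
        assert m1.val_accuracy_per_depth == m2.val_accuracy_per_depth

    def test_invalid_configurations_rejected(self):
        fm = _blob_features()
        with pytest.raises(ValueError):
            ht.train_deepsvm(fm, fm, max_layers=0)
        single = FeatureMatrix(values=fm.values, labels=np.array(["x"] * len(fm.labels)))
        with pytest.raises(ValueError):
            ht.train_deepsvm(single, single, max_layers=1)


class TestPredict:
    def test_training_set_of_separable_toy_is_reproduced(self):
        fm = _blob_features(sep=5.0, seed=13)
        model = ht.train_deepsvm(fm, fm, max_layers=2,
                                 config=ht.EnsembleConfig(seed=0))
        np.testing.assert_array_equal(ht.predict(model, fm.values), fm.labels)

    def test_single_row_and_row_permutation(self):
        fm = _blob_features(seed=14)
        model = ht.train_deepsvm(fm, fm, max_layers=1,
                                 config=ht.EnsembleConfig(max_layers=1))
        one = ht.predict(model, fm.values[3])
        assert one.shape == (1,)
        perm = np.random.default_rng(0).permutation(len(fm.labels))
        p_full = ht.predict(model, fm.values)
        p_perm = ht.predict(model, fm.values[perm])
        np.testing.assert_array_equal(p_perm, p_full[perm])


def test_save_load_roundtrip(tmp_path):
    train = _blob_features(sep=1.5, seed=15)
    model = ht.train_deepsvm(train, train, max_layers=2,
                             config=ht.EnsembleConfig(seed=1))
    save_deepsvm(model, tmp_path / "m.npz")
    loaded = load_deepsvm(tmp_path / "m.npz")
    np.testing.assert_array_equal(ht.predict(loaded, train.values),
                                  ht.predict(model, train.values))
    assert loaded.val_accuracy_per_depth == model.val_accuracy_per_depth
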