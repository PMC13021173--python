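import numpy as np
import pytest

from acpdiff import SyntheticSpec, generate_peptide_dataset
from acpdiff.classifier import (
    NULL_CONDITION,
    ClassifierConfig,
    ClassifierNetwork,
    TrainedClassifier,
    class_weights,
    evaluate_metrics,
    smote_oversample,
    train_classifier,
    weighted_cross_entropy,
)
from acpdiff.nn import Tensor, sinusoidal_embedding


class TestSmote:
    def test_exact_balance(self, rng):
        X = rng.standard_normal((14, 3))
        y = np.array([0] * 10 + [1] * 4)
        Xb, yb = smote_oversample(X, y, k=3, seed=0)
        _, counts = np.unique(yb, return_counts=True)
        assert np.all(counts == 10)

    def test_originals_preserved_first(self, rng):
        X = rng.standard_normal((12, 4))
        y = np.array([0] * 8 + [1] * 4)
        Xb, yb = smote_oversample(X, y, k=2, seed=1)
        assert np.array_equal(Xb[:12], X)
        assert np.array_equal(yb[:12], y)

    def test_synthetic_points_on_same_class_segments(self, rng):
        X = rng.standard_normal((15, 5))
        y = np.array([0] * 10 + [1] * 5)
        Xb, yb = smote_oversample(X, y, k=3, seed=2)
        members = X[y == 1]
        for row in Xb[15:]:
            # betweenness: the point must lie on a segment between two members
            found = False
            for i in range(len(members)):
                for j in range(len(members)):
                    if i == j:
                        continue
                    d = members[j] - members[i]
                    denom = d @ d
                    u = (row - members[i]) @ d / denom
                    if -1e-9 <= u <= 1 + 1e-9 and np.allclose(members[i] + u * d, row, atol=1e-8):
                        found = True
                        break
                if found:
                    break
            assert found

    def test_determinism(self, rng):
        X = rng.standard_normal((12, 3))
        y = np.array([0] * 8 + [1] * 4)
        a = smote_oversample(X, y, k=2, seed=9)[0]
        b = smote_oversample(X, y, k=2, seed=9)[0]
        assert np.array_equal(a, b)

    def test_singleton_class_rejected(self, rng):
        with pytest.raises(ValueError, match="fewer than 2"):
            smote_oversample(rng.standard_normal((3, 2)), np.array([0, 0, 1]), k=1)

    def test_k_too_large_rejected(self, rng):
        X = rng.standard_normal((7, 2))
        y = np.array([0] * 4 + [1] * 3)
        with pytest.raises(ValueError, match="k=5"):
            smote_oversample(X, y, k=5)


class TestMetrics:
    def test_perfect_predictions(self):
        y = np.array([0, 1, 2, 0, 1, 2])
        probs = np.eye(3)[y] * 0.94 + 0.02
        report = evaluate_metrics(y, probs)
        assert report.accuracy == report.macro_recall == report.macro_f1 == 1.0
        assert report.mean_ovr_auc == 1.0
        assert np.trace(report.confusion) == 6

    def test_hand_computed_three_class_macro_f1(self):
        # truth:      0 0 1 1 2 2   pred: 0 1 1 1 2 0
        y = np.array([0, 0, 1, 1, 2, 2])
        pred = np.array([0, 1, 1, 1, 2, 0])
        probs = np.full((6, 3), 0.05)
        probs[np.arange(6), pred] = 0.9
        # class0: P=1/2 R=1/2 F1=1/2 ; class1: P=2/3 R=1 F1=4/5 ; class2: P=1 R=1/2 F1=2/3
        expected = (0.5 + 0.8 + 2 / 3) / 3
        report = evaluate_metrics(y, probs)
        assert report.macro_f1 == pytest.approx(expected)

    def test_random_scores_auc_near_half(self):
        rng = np.random.default_rng(7)
        y = rng.integers(0, 2, size=2000)
        p1 = rng.uniform(size=2000)
        probs = np.stack([1 - p1, p1], axis=1)
        report = evaluate_metrics(y, probs)
        assert abs(report.mean_ovr_auc - 0.5) < 0.03

    def test_row_sums_validated(self):
        with pytest.raises(ValueError):
            evaluate_metrics(np.array([0, 1]), np.array([[0.9, 0.2], [0.5, 0.5]]))

    def test_absent_class_warns_and_excluded(self):
        y = np.array([0, 0, 1, 1])
        probs = np.full((4, 3), 1 / 3)
        with pytest.warns(UserWarning, match="class 2 absent"):
            evaluate_metrics(y, probs)

    def test_confusion_row_sums_equal_class_counts(self):
        rng = np.random.default_rng(3)
        y = rng.integers(0, 4, size=50)
        probs = rng.dirichlet(np.ones(4), size=50)
        report = evaluate_metrics(y, probs)
        assert np.array_equal(report.confusion.sum(axis=1), np.bincount(y, minlength=4))


class TestNetworkPieces:
    @pytest.fixture
    def net(self, rng):
        return ClassifierNetwork(ClassifierConfig(), rng)

    def test_noise_condition_additivity(self, net, rng):
        x_proj = Tensor(rng.standard_normal((4, 64)))
        labels = np.array([0, 3, 8, 5])
        t = np.array([0.1, 0.5, 0.9, 0.0])
        out = net.noise_condition(x_proj, labels, t).data
        expected = (
            x_proj.data
            + net.condition(labels).data
            + net.time_proj(Tensor(sinusoidal_embedding(t, 64))).data
        )
        assert np.allclose(out, expected)

    def test_null_label_uses_null_embedding(self, net, rng):
        x_proj = Tensor(rng.standard_normal((2, 64)))
        a = net.noise_condition(x_proj, None, 0.0).data
        b = net.noise_condition(x_proj, np.array([NULL_CONDITION] * 2), 0.0).data
        assert np.array_equal(a, b)

    def test_time_proj_zero_init_gives_xproj_plus_cond(self, net, rng):
        # freshly built network: time projection is zero-initialized
        x_proj = Tensor(rng.standard_normal((2, 64)))
        out = net.noise_condition(x_proj, None, 0.7).data
        null = net.condition(np.array([NULL_CONDITION] * 2)).data
        assert np.allclose(out, x_proj.data + null)

    def test_multiscale_residual_degenerates_to_backbone(self, net, rng):
        # weight surgery: all w_i = 0 -> y = F(x)
        net.branch_weights.data[:] = 0.0
        x = Tensor(rng.standard_normal((3, 64)))
        out = net.multiscale_residual(x).data
        backbone = (x + net.backbone_2(net.backbone_1(x).gelu())).data
        assert np.allclose(out, backbone)

    def test_branch_weights_change_output(self, net, rng):
        x = Tensor(rng.standard_normal((3, 64)))
        net.branch_weights.data[:] = 0.0
        base = net.multiscale_residual(x).data
        net.branch_weights.data[:] = 1.0
        assert not np.allclose(net.multiscale_residual(x).data, base)

    def test_predict_proba_rows_sum_to_one(self, net, rng):
        probs = net.predict_proba(rng.standard_normal((5, 200)))
        assert probs.shape == (5, 9)
        assert np.allclose(probs.sum(axis=1), 1.0, atol=1e-6)

    def test_class_weights_mean_one(self):
        y = np.array([0] * 8 + [1] * 2)
        w = class_weights(y, 2, "inverse-frequency")
        assert w.mean() == pytest.approx(1.0)
        assert w[1] > w[0]
        assert np.all(class_weights(y, 2, "uniform") == 1.0)

    def test_weighted_cross_entropy_matches_manual(self, rng):
        logits = Tensor(rng.standard_normal((4, 3)))
        y = np.array([0, 2, 1, 1])
        w = np.array([1.0, 2.0, 0.5])
        loss = float(weighted_cross_entropy(logits, y, w).data)
        z = logits.data - logits.data.max(axis=1, keepdims=True)
        logp = z - np.log(np.exp(z).sum(axis=1, keepdims=True))
        manual = -np.mean(w[y] * logp[np.arange(4), y])
        assert loss == pytest.approx(manual)


def _quick_config(**kw):
    defaults = dict(epochs=3, folds=2, patience=2, seed=5)
    defaults.update(kw)
    return ClassifierConfig(**defaults)


@pytest.fixture(scope="module")
def trained_small():
    """One small imbalanced training run shared by the smoke-level checks."""
    spec = SyntheticSpec(
        class_counts=(100, 24, 48, 48, 48, 48, 48, 48, 48), separability=0.7, seed=11
    )
    records = generate_peptide_dataset(spec)
    model = train_classifier(records, _quick_config())
    return records, model


class TestTraining:
    def test_imbalanced_smoke_minority_recall_positive(self, trained_small):
        records, model = trained_small
        y = np.array([r.label for r in records])
        probs = model.predict(records)
        report = evaluate_metrics(y, probs)
        minority_recall = report.confusion[1, 1] / report.confusion[1].sum()
        assert minority_recall > 0

    def test_predict_shape_and_normalization(self, trained_small):
        records, model = trained_small
        probs = model.predict(records[:5])
        assert probs.shape == (5, 9)
        assert np.allclose(probs.sum(axis=1), 1.0, atol=1e-6)

    def test_determinism_same_seed(self):
        spec = SyntheticSpec(class_counts=(50,) * 9, separability=0.7, seed=2)
        records = generate_peptide_dataset(spec)
        m1 = train_classifier(records, _quick_config())
        m2 = train_classifier(records, _quick_config())
        assert m1.loss_history == m2.loss_history
        assert np.allclose(m1.predict(records[:3]), m2.predict(records[:3]))

    def test_single_class_rejected(self):
        spec = SyntheticSpec(
            class_counts=(250, 2, 2, 2, 2, 2, 2, 2, 2), separability=0.5, seed=0
        )
        records = [r for r in generate_peptide_dataset(spec) if r.label == 0]
        with pytest.raises(ValueError, match="at least 2 classes"):
            train_classifier(records, _quick_config())

    def test_early_stopping_bound(self, trained_small):
        _, model = trained_small
        # training halts within best_epoch + patience + 1 epochs
        assert len(model.loss_history) <= model.config.epochs

    def test_save_load_round_trip(self, trained_small, tmp_path):
        records, model = trained_small
        path = tmp_path / "clf.npz"
        model.save(path)
        back = TrainedClassifier.load(path)
        assert np.allclose(model.predict(records[:4]), back.predict(records[:4]))

    def test_load_rejects_bad_version(self, trained_small, tmp_path):
        records, model = trained_small
        path = tmp_path / "clf.npz"
        model.save(path)
        data = dict(np.load(path))
        data["format_version"] = np.array(99)
        np.savez(path, **data)
        with pytest.raises(ValueError, match="version"):
            TrainedClassifier.load(path)
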