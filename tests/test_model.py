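import numpy as np
import pytest
from hypothesis import given, settings
from hypothesis import strategies as st

from mdfpnet import nn
from mdfpnet.features import BandedSpectrogram, CepstralMatrix, FeatureSet
from mdfpnet.model import (
    BRANCH_ORDER,
    Branch,
    BranchSpec,
    FusionHead,
    TrainConfig,
    build_branch,
    build_cnn1d,
    build_tiny2d,
    concat_branch_outputs,
    cross_entropy,
    fuse_and_predict,
    prepare_branch_input,
    softmax,
    train_branch,
    train_fusion,
)


class TestSoftmax:
    def test_uniform_logits(self):
        np.testing.assert_allclose(softmax(np.zeros(6)), np.full(6, 1 / 6))

    def test_closed_form_single_hot_logit(self):
        y = softmax(np.array([1.0, 0, 0, 0, 0, 0]))
        e = np.e
        np.testing.assert_allclose(y[0], e / (e + 5), rtol=1e-12)
        np.testing.assert_allclose(y[1:], 1 / (e + 5), rtol=1e-12)

    @given(st.lists(st.floats(-50, 50), min_size=2, max_size=10), st.floats(-100, 100))
    @settings(max_examples=50, deadline=None, derandomize=True)
    def test_shift_invariance_and_simplex(self, xs, c):
        x = np.array(xs)
        y = softmax(x)
        assert np.all(y >= 0)
        assert abs(y.sum() - 1.0) < 1e-6
        np.testing.assert_allclose(softmax(x + c), y, atol=1e-12)

    def test_non_finite_rejected(self):
        with pytest.raises(ValueError):
            softmax(np.array([1.0, np.inf]))


class TestCrossEntropy:
    def test_perfect_prediction_zero_loss(self):
        P = np.eye(6)[[0, 3]]
        Y = np.eye(6)[[0, 3]]
        assert cross_entropy(P, Y) == pytest.approx(0.0, abs=1e-9)

    def test_uniform_prediction_is_log6(self):
        P = np.full((4, 6), 1 / 6)
        Y = np.eye(6)[[0, 1, 2, 3]]
        assert cross_entropy(P, Y) == pytest.approx(np.log(6), rel=1e-9)

    def test_two_sample_batch_closed_form(self):
        P = np.array([[0.5, 0.5, 0, 0, 0, 0], [0.25, 0.75, 0, 0, 0, 0]])
        Y = np.eye(6)[[0, 0]]
        expected = -(np.log(0.5) + np.log(0.25)) / 2
        assert cross_entropy(P, Y) == pytest.approx(expected, rel=1e-9)

    def test_non_one_hot_rejected(self):
        P = np.full((1, 3), 1 / 3)
        with pytest.raises(ValueError):
            cross_entropy(P, np.array([[0.5, 0.5, 0.0]]))


class TestCnn1d:
    def test_flatten_width_and_simplex_output(self, rng):
        net = build_cnn1d(128, 6, seed=0)
        x = rng.normal(size=(3, 1, 128)).astype(np.float32)
        probs = net.predict_proba(x)
        assert probs.shape == (3, 6)
        np.testing.assert_allclose(probs.sum(axis=1), 1.0, atol=1e-6)
        flat = [l for l in net.layers if isinstance(l, nn.Flatten)][0]
        assert flat.last_width == 128  # 8 frames x 16 channels

    def test_parameter_count_matches_layer_arithmetic(self):
        net = build_cnn1d(128, 6, seed=0)
        conv1 = 1 * 3 * 16 + 16
        conv_rest = 3 * (16 * 3 * 16 + 16)
        dense1 = 128 * 128 + 128
        dense2 = 128 * 6 + 6
        assert net.n_parameters() == conv1 + conv_rest + dense1 + dense2

    def test_indivisible_input_rejected(self):
        with pytest.raises(ValueError):
            build_cnn1d(100, 6)


class TestBuildBranch:
    def test_tiny2d_contract(self, rng):
        spec = BranchSpec("mel", "tiny2d", (3, 128, 59))
        branch = build_branch(spec, seed=0)
        probs = branch.net.predict_proba(rng.normal(size=(2, 3, 128, 59)).astype(np.float32))
        assert probs.shape == (2, 6)
        np.testing.assert_allclose(probs.sum(axis=1), 1.0, atol=1e-6)

    def test_seed_determinism(self, rng):
        spec = BranchSpec("mfcc", "tiny2d", (3, 32, 59))
        x = rng.normal(size=(2, 3, 32, 59)).astype(np.float32)
        a = build_branch(spec, seed=42).net.predict_proba(x)
        b = build_branch(spec, seed=42).net.predict_proba(x)
        np.testing.assert_array_equal(a, b)

    def test_unknown_backbone_rejected(self):
        with pytest.raises(ValueError, match="unknown backbone"):
            build_branch(BranchSpec("mel", "resnet9000", (3, 32, 32)))
        with pytest.raises(ValueError, match="runtime"):
            build_branch(BranchSpec("mel", "xception", (3, 32, 32)))

    def test_feature_backbone_pairing_enforced(self):
        with pytest.raises(ValueError):
            BranchSpec("mean_mfcc", "tiny2d", (3, 32, 32))
        with pytest.raises(ValueError):
            BranchSpec("mel", "cnn1d", (128,))


class TestGradients:
    @pytest.mark.parametrize("builder", ["cnn1d", "tiny2d"])
    def test_backprop_matches_finite_differences(self, builder, rng):
        # float64 activations keep the finite-difference quotient smooth;
        # pooling/ReLU selections stay fixed for a small enough step
        if builder == "cnn1d":
            net = build_cnn1d(32, 3, seed=1, dropout=0.0)
            x = rng.normal(size=(4, 1, 32))
        else:
            net = build_tiny2d((3, 16, 16), n_classes=3, seed=1, dropout=0.0)
            x = rng.normal(size=(4, 3, 16, 16))
        y = np.array([0, 1, 2, 0])
        _, _, d = nn.softmax_cross_entropy(net.forward(x, train=True), y)
        net.backward(d)
        checks = 0
        for layer in net.layers:
            if "W" not in layer.params:
                continue
            W = layer.params["W"]
            analytic_all = layer.grads["W"].copy()
            for idx in [(0, 0), tuple(m % s for m, s in zip((7, 3), W.shape))]:
                eps = 1e-4
                orig = float(W[idx])
                W[idx] = orig + eps
                l1, _, _ = nn.softmax_cross_entropy(net.forward(x, train=True), y)
                W[idx] = orig - eps
                l2, _, _ = nn.softmax_cross_entropy(net.forward(x, train=True), y)
                W[idx] = orig
                numeric = (l1 - l2) / (2 * eps)
                assert numeric == pytest.approx(analytic_all[idx], rel=1e-3, abs=1e-5)
                checks += 1
        assert checks >= 6


class TestTrainBranch:
    def test_loss_decreases_on_separable_toy(self, rng):
        # two well-separated Gaussian blobs through a 1-D branch
        net = build_cnn1d(32, 2, seed=0, dropout=0.0)
        branch = Branch(BranchSpec("mean_mfcc", "cnn1d", (32,), n_classes=2), net)
        X = np.concatenate(
            [rng.normal(-1, 0.1, size=(30, 1, 32)), rng.normal(1, 0.1, size=(30, 1, 32))]
        ).astype(np.float32)
        y = np.repeat([0, 1], 30)
        history = train_branch(branch, (X, y), TrainConfig(epochs=5, seed=0))
        assert all(b < a for a, b in zip(history, history[1:]))

    def test_zero_learning_rate_freezes_loss(self, rng):
        net = build_cnn1d(32, 2, seed=0, dropout=0.0)
        branch = Branch(BranchSpec("mean_mfcc", "cnn1d", (32,), n_classes=2), net)
        X = rng.normal(size=(16, 1, 32)).astype(np.float32)
        y = rng.integers(0, 2, size=16)
        history = train_branch(branch, (X, y), TrainConfig(lr=0.0, epochs=3, seed=0))
        assert history[0] == pytest.approx(history[-1], rel=1e-6)

    def test_single_batch_overfit(self, rng):
        # pure capacity check, so no dropout regularisation
        net = build_cnn1d(32, 6, seed=0, dropout=0.0)
        branch = Branch(BranchSpec("mean_mfcc", "cnn1d", (32,), n_classes=6), net)
        X = rng.normal(size=(8, 1, 32)).astype(np.float32)
        y = np.arange(8) % 6
        train_branch(branch, (X, y), TrainConfig(epochs=200, seed=0))
        assert (branch.net.predict_proba(X).argmax(axis=1) == y).mean() == 1.0

    def test_out_of_range_labels_rejected(self, rng):
        net = build_cnn1d(32, 2, seed=0)
        branch = Branch(BranchSpec("mean_mfcc", "cnn1d", (32,), n_classes=2), net)
        X = rng.normal(size=(4, 1, 32)).astype(np.float32)
        with pytest.raises(ValueError):
            train_branch(branch, (X, np.array([0, 1, 2, 0])), TrainConfig(epochs=1))


def _toy_feature_set(rng) -> FeatureSet:
    return FeatureSet(
        mel=BandedSpectrogram(rng.normal(size=(59, 128)), "db"),
        mfcc=CepstralMatrix(rng.normal(size=(59, 32))),
        lfcc=CepstralMatrix(rng.normal(size=(59, 32))),
        mean_mfcc=rng.normal(size=128),
    )


def _toy_branches(n_classes=6):
    specs = {
        "mel": BranchSpec("mel", "tiny2d", (3, 128, 59), n_classes),
        "mfcc": BranchSpec("mfcc", "tiny2d", (3, 32, 59), n_classes),
        "lfcc": BranchSpec("lfcc", "tiny2d", (3, 32, 59), n_classes),
        "mean_mfcc": BranchSpec("mean_mfcc", "cnn1d", (128,), n_classes),
    }
    return [build_branch(specs[f], seed=i) for i, f in enumerate(BRANCH_ORDER)]


class TestFusion:
    def test_concatenation_is_24_long(self, rng):
        z = concat_branch_outputs(_toy_branches(), _toy_feature_set(rng))
        assert z.shape == (24,)

    def test_averaging_head_equals_branch_mean(self, rng):
        branches = _toy_branches()
        F = _toy_feature_set(rng)
        z = concat_branch_outputs(branches, F)
        fused = fuse_and_predict(branches, FusionHead.averaging(), F)
        np.testing.assert_allclose(fused, z.reshape(4, 6).mean(axis=0), atol=1e-6)

    def test_output_on_simplex(self, rng):
        fused = fuse_and_predict(_toy_branches(), FusionHead.averaging(), _toy_feature_set(rng))
        assert fused.sum() == pytest.approx(1.0, abs=1e-6)
        assert np.all(fused >= 0)

    def test_wrong_branch_count_rejected(self, rng):
        with pytest.raises(ValueError):
            fuse_and_predict(_toy_branches()[:3], FusionHead.averaging(), _toy_feature_set(rng))


class TestTrainFusion:
    def test_perfect_branches_reach_low_loss(self, rng):
        # branch outputs already one-hot on the true class
        y = rng.integers(0, 6, size=120)
        block = np.eye(6)[y]
        Z = np.tile(block, (1, 4))
        head, history = train_fusion(
            FusionHead.averaging(), (Z, y), TrainConfig(lr=0.1, epochs=50, seed=0)
        )
        probs = head.predict(Z)
        assert nn.softmax_cross_entropy(np.log(np.clip(probs, 1e-12, 1)), y)[0] < 0.05
        assert history[-1] < 0.05

    def test_fusion_beats_uninformative_branches(self, rng):
        # one informative branch among three uniform ones
        y_train = rng.integers(0, 6, size=200)
        y_test = rng.integers(0, 6, size=100)

        def make_z(y):
            informative = 0.7 * np.eye(6)[y] + 0.05
            uniform = np.full((len(y), 6), 1 / 6)
            return np.concatenate([informative, uniform, uniform, uniform], axis=1)

        head, _ = train_fusion(
            FusionHead.averaging(), (make_z(y_train), y_train), TrainConfig(epochs=100, seed=0)
        )
        fused_acc = (head.predict(make_z(y_test)).argmax(axis=1) == y_test).mean()
        best_single = (make_z(y_test)[:, :6].argmax(axis=1) == y_test).mean()
        assert fused_acc >= best_single

    def test_seed_determinism(self, rng):
        y = rng.integers(0, 6, size=60)
        Z = rng.random((60, 24))
        h1, _ = train_fusion(FusionHead.averaging(), (Z, y), TrainConfig(epochs=10, seed=3))
        h2, _ = train_fusion(FusionHead.averaging(), (Z, y), TrainConfig(epochs=10, seed=3))
        np.testing.assert_array_equal(h1.W, h2.W)


class TestPrepareBranchInput:
    def test_shapes_per_branch(self, rng):
        F = _toy_feature_set(rng)
        assert prepare_branch_input(F, BranchSpec("mel", "tiny2d", (3, 128, 59))).shape == (3, 128, 59)
        assert prepare_branch_input(F, BranchSpec("mfcc", "tiny2d", (3, 32, 59))).shape == (3, 32, 59)
        assert prepare_branch_input(F, BranchSpec("mean_mfcc", "cnn1d", (128,))).shape == (1, 128)

    def test_resized_branch_input(self, rng):
        F = _toy_feature_set(rng)
        out = prepare_branch_input(F, BranchSpec("mel", "tiny2d", (3, 128, 345)))
        assert out.shape == (3, 128, 345)
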