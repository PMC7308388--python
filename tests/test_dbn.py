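import math

import numpy as np
import pytest

from numsense.dbn import (
    DbnModel,
    RbmHyper,
    RbmParams,
    ReadoutProtocol,
    _Velocity,
    assert_same_protocol,
    cd1_step,
    curriculum_order,
    encode,
    run_comparison_task,
    train_dbn,
    train_rbm_cd1,
    train_readout,
    train_readout_codes,
    train_readout_online,
)
from numsense.errors import (
    InvalidArgumentError,
    InvalidComparisonError,
)
from numsense.stimulus_space import StimulusPoint
from numsense.trials import TrialPair


def _sigmoid(x):
    return 1.0 / (1.0 + np.exp(-x))


def _toy_model(w1=None, w2=None):
    w1 = np.zeros((4, 3)) if w1 is None else w1
    w2 = np.zeros((3, 2)) if w2 is None else w2
    return DbnModel(
        layers=[
            RbmParams(w1, np.zeros(4), np.zeros(3)),
            RbmParams(w2, np.zeros(3), np.zeros(2)),
        ],
        epochs_trained=0,
        seed=0,
    )


def _pair(n_l, n_r):
    return TrialPair(
        left=StimulusPoint(n_l, 1e4, 1e6), right=StimulusPoint(n_r, 1e4, 1e6)
    )


class TestCd1Oracle:
    def test_single_step_matches_hand_computation(self):
        # 2-visible / 2-hidden toy; the Bernoulli draw is replicated with an
        # identically-seeded generator, everything else is closed form
        W = np.array([[0.1, -0.2], [0.3, 0.05]])
        vb = np.array([0.01, -0.02])
        hb = np.array([0.0, 0.1])
        v0 = np.array([[1.0, 0.0]])
        lr, mom, decay = 0.5, 0.0, 0.0

        h0 = _sigmoid(v0 @ W + hb)
        draws = np.random.default_rng(42).random(h0.shape)
        h0_sample = (draws < h0).astype(float)
        v1 = _sigmoid(h0_sample @ W.T + vb)
        h1 = _sigmoid(v1 @ W + hb)
        expected_W = W + lr * (v0.T @ h0 - v1.T @ h1)
        expected_vb = vb + lr * (v0 - v1).mean(axis=0)
        expected_hb = hb + lr * (h0 - h1).mean(axis=0)
        expected_loss = float(((v0 - v1) ** 2).mean())

        params = RbmParams(W.copy(), vb.copy(), hb.copy())
        loss = cd1_step(
            params,
            v0,
            np.random.default_rng(42),
            learning_rate=lr,
            momentum=mom,
            weight_decay=decay,
            velocity=_Velocity.zeros(params),
        )
        assert np.allclose(params.weights, expected_W, atol=1e-12)
        assert np.allclose(params.visible_bias, expected_vb, atol=1e-12)
        assert np.allclose(params.hidden_bias, expected_hb, atol=1e-12)
        assert loss == pytest.approx(expected_loss, rel=1e-12)

    def test_momentum_and_decay_terms(self):
        W = np.array([[0.2, 0.0], [0.0, -0.1]])
        params = RbmParams(W.copy(), np.zeros(2), np.zeros(2))
        velocity = _Velocity.zeros(params)
        velocity.w = np.full_like(W, 0.04)
        v0 = np.array([[1.0, 1.0]])
        lr, mom, decay = 0.1, 0.9, 0.5

        h0 = _sigmoid(v0 @ W)
        draws = np.random.default_rng(3).random(h0.shape)
        h0_sample = (draws < h0).astype(float)
        v1 = _sigmoid(h0_sample @ W.T)
        h1 = _sigmoid(v1 @ W)
        grad = v0.T @ h0 - v1.T @ h1 - decay * W
        expected_W = W + mom * 0.04 + lr * grad

        cd1_step(
            params, v0, np.random.default_rng(3),
            learning_rate=lr, momentum=mom, weight_decay=decay, velocity=velocity,
        )
        assert np.allclose(params.weights, expected_W, atol=1e-12)


class TestTrainRbm:
    def test_zero_epochs_returns_initialization(self, rng):
        data = rng.random((20, 8))
        init = RbmParams.initialize(8, 4, np.random.default_rng(0))
        ref = init.weights.copy()
        params, losses = train_rbm_cd1(
            data, 4, RbmHyper(), epochs=0, rng=rng, params=init
        )
        assert np.array_equal(params.weights, ref)
        assert losses == []

    def test_learning_reduces_reconstruction_error(self):
        # two 8-pixel prototypes; error after training < untrained baseline
        rng = np.random.default_rng(1)
        protos = np.array([[1, 1, 1, 1, 0, 0, 0, 0], [0, 0, 0, 0, 1, 1, 1, 1]], float)
        data = protos[rng.integers(2, size=500)]
        hyper = RbmHyper(learning_rate=0.2, batch_size=25)

        def recon_error(params, v):
            h = _sigmoid(v @ params.weights + params.hidden_bias)
            hs = (np.random.default_rng(9).random(h.shape) < h).astype(float)
            v1 = _sigmoid(hs @ params.weights.T + params.visible_bias)
            return float(((v - v1) ** 2).mean())

        init = RbmParams.initialize(8, 6, np.random.default_rng(0))
        baseline = recon_error(init, data)
        trained, losses = train_rbm_cd1(
            data, 6, hyper, epochs=20, rng=np.random.default_rng(0)
        )
        assert recon_error(trained, data) < baseline
        assert losses[-1] < losses[0]

    def test_loss_nonincreasing_in_expectation(self):
        # sign test across seeds on held-out toy data
        rng0 = np.random.default_rng(0)
        protos = rng0.integers(2, size=(4, 10)).astype(float)
        improvements = 0
        n_seeds = 8
        for seed in range(n_seeds):
            rng = np.random.default_rng(seed)
            data = protos[rng.integers(4, size=300)]
            _, losses = train_rbm_cd1(
                data, 5, RbmHyper(learning_rate=0.1, batch_size=30),
                epochs=15, rng=rng,
            )
            improvements += losses[-1] < losses[0]
        assert improvements >= 6  # one-sided sign test, p < 0.05 under fair coin

    def test_invalid_data_range_rejected(self, rng):
        with pytest.raises(InvalidArgumentError):
            train_rbm_cd1(rng.random((10, 4)) * 2, 3, RbmHyper(), 1, rng)


class TestTrainDbn:
    def test_checkpoints_young_and_mature(self, rng):
        data = rng.random((60, 16))
        checkpoints = train_dbn(
            data, arch=(8, 4), epochs=5, rng=0, checkpoint_epochs=(1, 5)
        )
        assert sorted(checkpoints) == [1, 5]
        assert checkpoints[1].epochs_trained == 1
        assert checkpoints[5].epochs_trained == 5
        assert checkpoints[1].arch_id == "8x4"

    def test_layer_shapes(self, rng):
        model = train_dbn(rng.random((40, 16)), arch=(8, 4), epochs=1, rng=0)[1]
        assert model.layers[0].weights.shape == (16, 8)
        assert model.layers[1].weights.shape == (8, 4)
        assert model.n_visible == 16
        assert model.code_size == 4

    def test_deterministic_under_seed(self, rng):
        data = rng.random((40, 16))
        a = train_dbn(data, (8, 4), epochs=3, rng=7, checkpoint_epochs=(1,))
        b = train_dbn(data, (8, 4), epochs=3, rng=7, checkpoint_epochs=(1,))
        for e in (1, 3):
            assert np.array_equal(a[e].layers[0].weights, b[e].layers[0].weights)
            assert np.array_equal(a[e].layers[1].weights, b[e].layers[1].weights)

    def test_invalid_arch(self, rng):
        with pytest.raises(InvalidArgumentError):
            train_dbn(rng.random((10, 4)), (0, 2), epochs=1, rng=0)

    def test_mismatched_layer_sizes_rejected(self):
        with pytest.raises(InvalidArgumentError):
            DbnModel(
                layers=[
                    RbmParams(np.zeros((4, 3)), np.zeros(4), np.zeros(3)),
                    RbmParams(np.zeros((5, 2)), np.zeros(5), np.zeros(2)),
                ],
                epochs_trained=0,
                seed=0,
            )


class TestEncode:
    def test_zero_weights_give_half(self):
        model = _toy_model()
        codes = encode(model, np.zeros(4))
        assert np.allclose(codes, 0.5)

    def test_activations_in_open_interval(self, rng):
        model = _toy_model(
            w1=rng.standard_normal((4, 3)), w2=rng.standard_normal((3, 2))
        )
        codes = encode(model, rng.random((10, 4)))
        assert np.all((codes > 0) & (codes < 1))

    def test_deterministic(self, rng):
        model = _toy_model(w1=rng.standard_normal((4, 3)))
        img = rng.random(4)
        assert np.array_equal(encode(model, img), encode(model, img))

    def test_size_mismatch_rejected(self, rng):
        with pytest.raises(InvalidArgumentError):
            encode(_toy_model(), rng.random(5))


class TestReadout:
    def test_zero_iterations_is_chance(self, rng):
        codes = rng.random((50, 6))
        clf = train_readout_codes(
            codes, ["left"] * 25 + ["right"] * 25,
            ReadoutProtocol(iterations=0),
        )
        assert np.all(clf.weights == 0)
        logits = clf.logits(codes)
        assert np.all(logits[:, 0] == logits[:, 1])

    def test_separable_codes_reach_perfect_accuracy(self, rng):
        # codes separated by a hyperplane along the first dimension
        n = 60
        x = np.vstack([rng.random((n, 4)) + [2, 0, 0, 0], rng.random((n, 4))])
        labels = ["left"] * n + ["right"] * n
        clf = train_readout_codes(
            x, labels, ReadoutProtocol(iterations=500, learning_rate=1.0)
        )
        pred = np.argmax(clf.logits(x), axis=1)
        truth = np.array([0] * n + [1] * n)
        assert np.mean(pred == truth) == 1.0

    def test_swap_symmetry(self, rng):
        # swapping left/right codes with swapped labels mirrors the classifier
        h = 3
        left, right = rng.random((40, h)), rng.random((40, h))
        labels = ["left" if i % 2 else "right" for i in range(40)]
        swapped_labels = ["right" if s == "left" else "left" for s in labels]
        proto = ReadoutProtocol(iterations=300, learning_rate=0.8)
        clf = train_readout_codes(np.hstack([left, right]), labels, proto)
        clf_sw = train_readout_codes(np.hstack([right, left]), swapped_labels, proto)
        x = np.hstack([rng.random((10, h)), rng.random((10, h))])
        x_sw = np.hstack([x[:, h:], x[:, :h]])
        assert np.allclose(clf.logits(x), clf_sw.logits(x_sw)[:, ::-1], atol=1e-9)

    def test_dbn_weights_untouched(self, rng):
        model = _toy_model(w1=rng.standard_normal((4, 3)))
        ref = model.layers[0].weights.copy()
        imgs = [(rng.random(4), rng.random(4)) for _ in range(10)]
        train_readout(model, imgs, ["left"] * 5 + ["right"] * 5)
        assert np.array_equal(model.layers[0].weights, ref)

    def test_protocol_identity_check(self):
        a = train_readout_codes(np.ones((4, 2)), ["left"] * 4, ReadoutProtocol())
        b = train_readout_codes(
            np.ones((4, 2)), ["left"] * 4, ReadoutProtocol(iterations=5)
        )
        with pytest.raises(InvalidComparisonError):
            assert_same_protocol(a, b)
        assert_same_protocol(a, a)

    def test_online_single_pass_is_order_sensitive(self, rng):
        model = _toy_model(w1=rng.standard_normal((4, 3)), w2=rng.standard_normal((3, 2)))
        imgs = [(rng.random(4), rng.random(4)) for _ in range(20)]
        labels = ["left" if i % 2 else "right" for i in range(20)]
        clf_fwd = train_readout_online(model, imgs, labels)
        clf_rev = train_readout_online(model, imgs[::-1], labels[::-1])
        assert not np.allclose(clf_fwd.weights, clf_rev.weights)


class TestComparisonTask:
    def test_zero_classifier_is_chance(self, rng):
        model = _toy_model(w1=rng.standard_normal((4, 3)))
        pairs = [_pair(7, 14) if i % 2 else _pair(14, 7) for i in range(400)]
        imgs = [(rng.random(4), rng.random(4)) for _ in pairs]
        clf = train_readout(model, imgs[:10], ["left"] * 10, ReadoutProtocol(iterations=0))
        data = run_comparison_task(model, clf, pairs, imgs, rng=np.random.default_rng(0))
        assert data.accuracy() == pytest.approx(0.5, abs=0.07)

    def test_choices_feed_glm(self, rng):
        from numsense.psychophysics import fit_choice_glm

        model = _toy_model(w1=rng.standard_normal((4, 3)))
        pairs = []
        for i in range(300):
            n_l, n_r = rng.choice([5, 7, 10, 14, 20], size=2, replace=False)
            pairs.append(_pair(int(n_l), int(n_r)))
        imgs = [(rng.random(4), rng.random(4)) for _ in pairs]
        clf = train_readout(model, imgs[:20], ["left"] * 10 + ["right"] * 10)
        data = run_comparison_task(model, clf, pairs, imgs, rng=rng)
        fit = fit_choice_glm(data, gamma_mode=0.01)
        assert fit.n_trials == 300


class TestCurriculumOrder:
    def test_easy_to_hard(self):
        pairs = [_pair(7, 8), _pair(7, 28), _pair(7, 14)]
        order = curriculum_order(pairs, "easy_to_hard")
        assert order[0] == 1  # max |log2 ratio| first
        assert order[-1] == 0

    def test_hard_to_easy_is_reverse(self):
        pairs = [_pair(7, 8), _pair(7, 28), _pair(7, 14), _pair(10, 11)]
        assert curriculum_order(pairs, "hard_to_easy") == list(
            reversed(curriculum_order(pairs, "easy_to_hard"))
        )

    def test_ties_stable_by_pair_id(self):
        pairs = [
            TrialPair(
                left=StimulusPoint(7, 1e4, 1e6),
                right=StimulusPoint(14, 1e4, 1e6),
                pair_id=i,
            )
            for i in range(5)
        ]
        assert curriculum_order(pairs, "easy_to_hard") == [0, 1, 2, 3, 4]

    def test_shuffled_reproducible(self):
        pairs = [_pair(7, 14), _pair(7, 28), _pair(10, 14)]
        a = curriculum_order(pairs, "shuffled", np.random.default_rng(4))
        b = curriculum_order(pairs, "shuffled", np.random.default_rng(4))
        assert a == b

    def test_unknown_mode(self):
        with pytest.raises(InvalidArgumentError):
            curriculum_order([_pair(7, 14)], "alphabetical")
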