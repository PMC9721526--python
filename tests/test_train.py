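"""Tests for the training frameworks: supervised, semi-supervised, post-processing."""

import warnings

import numpy as np
import pytest

from topofit.loss import TopologicalPrior
from topofit.models import build_unet, clone_predictor
from topofit.synthetic import DatasetConfig, make_dataset
from topofit.train import (
    TrainConfig,
    early_stop_index,
    postprocess_adapt,
    soft_dice_loss,
    train_semisupervised,
    train_supervised,
)

RING = TopologicalPrior.from_betti((1, 1))


def ring_prior(_s):
    return RING


@pytest.fixture(scope="module")
def tiny_data():
    cfg = DatasetConfig(n_labelled=4, n_unlabelled=6, n_val=3, n_test=3,
                        shape=(16, 16), m=6, preserve_centre=2, jitter=0.1, seed=21)
    return make_dataset(cfg)


@pytest.fixture(scope="module")
def pretrained(tiny_data):
    labelled, _, val, _ = tiny_data
    net = build_unet(2, depth=2, base_channels=4, seed=2)
    cfg = TrainConfig(lr=1e-3, epochs=60, val_interval=15, patience=4, seed=2)
    net, hist = train_supervised(net, labelled, val, cfg)
    return net, hist


class TestSoftDice:
    def test_perfect_overlap_is_near_zero(self):
        t = np.zeros((8, 8))
        t[2:6, 2:6] = 1.0
        assert soft_dice_loss(t, t) == pytest.approx(0.0, abs=1e-6)

    def test_empty_prediction_on_nonempty_target_is_near_one(self):
        t = np.zeros((8, 8))
        t[2:6, 2:6] = 1.0
        assert soft_dice_loss(np.zeros_like(t), t) == pytest.approx(1.0, abs=1e-6)

    def test_half_intensity_prediction_closed_form(self):
        t = np.zeros((8, 8))
        t[2:6, 2:6] = 1.0
        assert soft_dice_loss(0.5 * t, t) == pytest.approx(1 / 3, abs=1e-5)

    def test_shape_mismatch_rejected(self):
        with pytest.raises(ValueError):
            soft_dice_loss(np.zeros((4, 4)), np.zeros((5, 5)))


class TestEarlyStopping:
    @pytest.mark.parametrize(
        "metrics,patience,expected",
        [
            ([1, 2, 3, 3, 3, 3, 3, 3], 5, 7),      # plateau: 5 bad evals after the best
            ([1, 2, 3, 4, 5], 3, None),            # monotone improvement: never stops
            ([5, 4, 3, 2], 3, 3),
            ([1, 1, 2, 1, 1, 2], 2, 4),            # equal-to-best does not count as improvement
        ],
    )
    def test_stop_index_on_crafted_histories(self, metrics, patience, expected):
        assert early_stop_index(metrics, patience) == expected

    def test_training_respects_patience(self, tiny_data):
        labelled, _, val, _ = tiny_data
        net = build_unet(2, depth=2, base_channels=2, seed=0)
        cfg = TrainConfig(lr=0.0, epochs=100, val_interval=5, patience=3, seed=0)
        _, hist = train_supervised(net, labelled, val, cfg)
        # lr 0 freezes the metric: first eval is best, next 3 trigger the stop
        assert hist["val_epoch"][-1] == 20


class TestSupervised:
    def test_history_and_determinism(self, tiny_data):
        labelled, _, val, _ = tiny_data
        cfg = TrainConfig(lr=1e-3, epochs=10, val_interval=5, patience=5, seed=3)
        n1, h1 = train_supervised(build_unet(2, 2, 2, seed=3), labelled, val, cfg)
        n2, h2 = train_supervised(build_unet(2, 2, 2, seed=3), labelled, val, cfg)
        assert h1["sup_loss"] == h2["sup_loss"]
        assert all(np.array_equal(a, b) for a, b in zip(n1.state_dict(), n2.state_dict()))

    def test_best_checkpoint_is_best_validation(self, pretrained):
        _, hist = pretrained
        assert hist["best_val_metric"] == max(hist["val_metric"])

    def test_training_improves_on_initialisation(self, pretrained):
        _, hist = pretrained
        assert hist["sup_loss"][-1] < hist["sup_loss"][0]

    def test_empty_sets_rejected(self, tiny_data):
        labelled, _, val, _ = tiny_data
        net = build_unet(2, 2, 2, seed=0)
        cfg = TrainConfig(epochs=1)
        with pytest.raises(ValueError):
            train_supervised(net, [], val, cfg)
        with pytest.raises(ValueError):
            train_supervised(net, labelled, [], cfg)


class TestSemiSupervised:
    def test_lam_zero_bitwise_equals_supervised_continuation(self, tiny_data, pretrained):
        labelled, unlabelled, val, _ = tiny_data
        net, _ = pretrained
        cfg = TrainConfig(lam=0.0, lr=3e-4, epochs=6, val_interval=3, patience=99, seed=5)
        a, b = clone_predictor(net), clone_predictor(net)
        a, _ = train_semisupervised(a, labelled, unlabelled, val, ring_prior, cfg)
        b, _ = train_supervised(b, labelled, val, cfg)
        assert all(np.array_equal(x, y) for x, y in zip(a.state_dict(), b.state_dict()))

    def test_topo_stream_changes_weights(self, tiny_data, pretrained):
        labelled, unlabelled, val, _ = tiny_data
        net, _ = pretrained
        base = clone_predictor(net)
        cfg = TrainConfig(lam=0.01, lr=3e-4, epochs=4, val_interval=2, patience=99, seed=5)
        a = clone_predictor(net)
        a, hist = train_semisupervised(a, labelled, unlabelled, val, ring_prior, cfg)
        assert any(t is not None for t in hist["topo_loss"])
        assert not all(
            np.array_equal(x, y) for x, y in zip(a.state_dict(), base.state_dict())
        )

    def test_empty_unlabelled_warns_and_degenerates(self, tiny_data):
        labelled, _, val, _ = tiny_data
        cfg = TrainConfig(lam=0.01, epochs=2, val_interval=1, seed=1)
        with pytest.warns(UserWarning):
            train_semisupervised(build_unet(2, 2, 2, seed=1), labelled, [], val,
                                 ring_prior, cfg)


class TestPostprocessing:
    def test_lam_zero_is_a_no_op(self, tiny_data, pretrained):
        _, _, _, test = tiny_data
        net, _ = pretrained
        anchor = net.predict(test[0].image)
        cfg = TrainConfig(lam=0.0, steps=20, postproc_lr=1e-3, seed=0)
        _, adapted_map, hist = postprocess_adapt(net, test[0].image, RING, cfg)
        assert np.array_equal(adapted_map, anchor)
        assert hist["best_objective"] == 0.0

    def test_original_predictor_untouched(self, tiny_data, pretrained):
        _, _, _, test = tiny_data
        net, _ = pretrained
        before = [v.copy() for v in net.state_dict()]
        out_before = net.predict(test[0].image).copy()
        cfg = TrainConfig(lam=0.01, steps=15, postproc_lr=3e-4, seed=0)
        adapted, _, _ = postprocess_adapt(net, test[0].image, RING, cfg)
        assert all(np.array_equal(a, b) for a, b in zip(net.state_dict(), before))
        assert np.array_equal(net.predict(test[0].image), out_before)
        assert adapted is not net

    def test_returned_weights_achieve_best_objective(self, tiny_data, pretrained):
        _, _, _, test = tiny_data
        net, _ = pretrained
        cfg = TrainConfig(lam=0.01, steps=25, postproc_lr=3e-4, seed=0)
        _, _, hist = postprocess_adapt(net, test[1].image, RING, cfg)
        assert hist["best_objective"] == min(hist["objective"])

    def test_binary_anchor_satisfying_prior_stays_put(self, tiny_data):
        # a predictor whose output already minimises the topological loss
        # has zero gradient from both terms at step 0
        from topofit.loss import topo_loss_on_field
        _, _, _, test = tiny_data
        target = test[0].target
        rep = topo_loss_on_field(target, RING)
        assert rep.total == 0.0
        # clamped descent cannot move a perfect binary anchor
        stepped = np.clip(target - 0.1 * rep.gradient_array(target.shape), 0.0, 1.0)
        assert np.array_equal(stepped, target)
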