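"""Losses, class weights, SegNet construction, unpooling, training contracts."""

import numpy as np
import pytest

from octplaque import nn
from octplaque.nn import TrainConfig
from octplaque.segmenter import (
    SegmenterConfig,
    TverskyTrainLoss,
    WceTrainLoss,
    build_segnet,
    dice_loss,
    median_freq_weights,
    segment_frames,
    train_segmenter,
    tversky_loss,
    wce_loss,
)

TINY_STAGES = [[4], [6]]


# ---------------------------------------------------------------------------
# inverse-median-frequency weights

def test_median_freq_weights_imbalanced():
    """Frequencies 0.9/0.1 → median 0.5 → weights (0.5556, 5.0)."""
    labels = np.zeros((4, 10, 10), dtype=int)
    labels[:, :, :1] = 1  # 10% of each frame positive
    w = median_freq_weights(labels)
    assert w == pytest.approx([0.5 / 0.9, 0.5 / 0.1], abs=1e-4)


def test_median_freq_weights_balanced_and_monotone(rng):
    labels = np.zeros((2, 8, 8), dtype=int)
    labels[:, :4, :] = 1
    assert median_freq_weights(labels) == pytest.approx([1.0, 1.0])
    # rarer class always receives the larger weight
    for frac in (1, 2, 3):
        lab = np.zeros((2, 8, 8), dtype=int)
        lab[:, :frac, :] = 1
        w = median_freq_weights(lab)
        assert w[1] > w[0]


def test_median_freq_weights_absent_class_rejected():
    with pytest.raises(ValueError):
        median_freq_weights(np.zeros((2, 4, 4), dtype=int))


# ---------------------------------------------------------------------------
# loss functions (public, probability-space)

def test_wce_perfect_prediction_is_zero():
    targets = np.array([[0, 1], [1, 0]])
    probs = np.eye(2)[targets]
    assert wce_loss(probs, targets, np.ones(2)) == pytest.approx(0.0, abs=1e-9)


def test_wce_uniform_probs_equals_ln2_per_pixel(rng):
    targets = (rng.random((3, 5, 5)) > 0.5).astype(int)
    probs = np.full(targets.shape + (2,), 0.5)
    assert wce_loss(probs, targets, np.ones(2)) == pytest.approx(np.log(2))


def test_wce_matches_hand_computed_2x2():
    targets = np.array([[0, 1], [1, 0]])
    probs = np.array([[[0.8, 0.2], [0.3, 0.7]], [[0.4, 0.6], [0.9, 0.1]]])
    w = np.array([0.6, 1.4])
    expected = -(
        0.6 * np.log(0.8) + 1.4 * np.log(0.7) + 1.4 * np.log(0.6) + 0.6 * np.log(0.9)
    ) / 4
    assert wce_loss(probs, targets, w) == pytest.approx(expected, abs=1e-10)


@pytest.mark.parametrize("loss_fn", [dice_loss, lambda p, t: tversky_loss(p, t, 0.7, 0.3)])
def test_soft_losses_perfect_and_disjoint(loss_fn):
    targets = np.array([[1, 1], [0, 0]])
    perfect = np.eye(2)[targets]
    disjoint = np.eye(2)[1 - targets]
    assert loss_fn(perfect, targets) == pytest.approx(0.0)
    assert loss_fn(disjoint, targets) == pytest.approx(1.0)


def test_tversky_half_half_equals_dice(rng):
    """α = β = 0.5 reduces Tversky exactly to Dice (soft counts)."""
    for _ in range(50):
        targets = (rng.random((6, 6)) > 0.6).astype(int)
        p1 = rng.random((6, 6))
        probs = np.stack([1 - p1, p1], axis=-1)
        assert tversky_loss(probs, targets, 0.5, 0.5) == pytest.approx(
            dice_loss(probs, targets), abs=1e-12
        )


def test_tversky_invalid_alpha_beta():
    targets = np.array([[1]])
    probs = np.array([[[0.5, 0.5]]])
    with pytest.raises(ValueError):
        tversky_loss(probs, targets, 0.0, 0.5)
    with pytest.raises(ValueError):
        tversky_loss(probs, targets, 0.5, -1.0)


def test_corrupting_perfect_prediction_increases_every_loss(rng):
    targets = (rng.random((8, 8)) > 0.5).astype(int)
    perfect = np.eye(2)[targets].astype(float)
    noisy = 0.7 * perfect + 0.3 * (1 - perfect)
    w = np.ones(2)
    assert wce_loss(noisy, targets, w) > wce_loss(perfect, targets, w)
    assert dice_loss(noisy, targets) > dice_loss(perfect, targets)
    assert tversky_loss(noisy, targets, 0.7, 0.3) > tversky_loss(perfect, targets, 0.7, 0.3)


def test_train_losses_agree_with_public_losses(rng):
    """Gradient-carrying training losses reproduce the probability-space
    definitions when fed matching logits."""
    logits = rng.normal(size=(2, 2, 6, 6))
    targets = (rng.random((2, 6, 6)) > 0.5).astype(int)
    p = nn.softmax(logits, axis=1)
    p_last = np.moveaxis(p, 1, -1)
    w = np.array([0.8, 1.2])
    l_wce, _ = WceTrainLoss(w)(logits, targets)
    assert l_wce == pytest.approx(wce_loss(p_last, targets, w), abs=1e-10)
    l_tv, _ = TverskyTrainLoss(0.7, 0.3, smooth=0.0)(logits, targets)
    assert l_tv == pytest.approx(tversky_loss(p_last, targets, 0.7, 0.3), abs=1e-10)


# ---------------------------------------------------------------------------
# network structure

def test_default_segnet_has_26_convs_5_pools_5_unpools():
    model = build_segnet(SegmenterConfig(seed=0))
    convs = [l for l in model.layers if isinstance(l, nn.Conv2d)]
    pools = [l for l in model.layers if isinstance(l, nn.MaxPoolLast2)]
    unpools = [l for l in model.layers if isinstance(l, nn.MaxUnpoolLast2)]
    assert len(convs) == 27  # 13 encoder + 13 decoder + 1×1 classifier head
    assert sum(1 for c in convs if c.kh == 3) == 26
    assert len(pools) == 5 and len(unpools) == 5
    # decoder stage k consumes indices from encoder stage n+1−k
    assert [u.pool for u in unpools] == pools[::-1]


def test_unpool_restores_maxima_positions(rng):
    """max-unpool(pool(x), indices) leaves each window's maximum at its
    original position and zeros elsewhere."""
    x = rng.normal(size=(2, 3, 8, 10))
    pool = nn.MaxPoolLast2()
    unpool = nn.MaxUnpoolLast2(pool)
    pooled = pool.forward(x)
    restored = unpool.forward(pooled)
    assert restored.shape == x.shape
    for n in range(2):
        for c in range(3):
            for i in range(0, 8, 2):
                for j in range(0, 10, 2):
                    win = x[n, c, i : i + 2, j : j + 2]
                    rwin = restored[n, c, i : i + 2, j : j + 2]
                    k = np.unravel_index(win.argmax(), (2, 2))
                    assert rwin[k] == win[k]
                    assert (rwin.ravel() != 0).sum() <= 1


def test_segment_frames_gating_and_normalization(rng):
    model = build_segnet(SegmenterConfig(encoder_stages=TINY_STAGES, seed=0))
    stack = rng.random((6, 8, 8)).astype(np.float32)
    vol = segment_frames(stack, [(1, 2), (4, 4)], model)
    assert vol.frame_indices.tolist() == [1, 2, 4]
    assert np.allclose(vol.probs.sum(axis=1), 1.0, atol=1e-6)
    assert vol.masks().shape == (3, 8, 8)


def test_train_rejects_frame_without_calcium(rng):
    frames = rng.random((3, 8, 8)).astype(np.float32)
    masks = np.zeros((3, 8, 8), dtype=int)
    masks[0, 2, 2] = 1
    masks[2, 3, 3] = 1
    cfg = SegmenterConfig(encoder_stages=TINY_STAGES, seed=0)
    with pytest.raises(ValueError, match="frame"):
        train_segmenter(frames, masks, frames, masks, cfg,
                        TrainConfig(max_epochs=1, patience=1, seed=0))


def test_training_is_seed_deterministic(rng):
    frames = rng.random((6, 8, 8)).astype(np.float32)
    masks = np.zeros((6, 8, 8), dtype=int)
    masks[:, 2:5, 2:5] = 1
    cfg = SegmenterConfig(encoder_stages=TINY_STAGES, seed=3)
    tcfg = TrainConfig(max_epochs=2, patience=2, seed=3, batch_size=2)
    _, h1 = train_segmenter(frames, masks, frames[:2], masks[:2], cfg, tcfg)
    _, h2 = train_segmenter(frames, masks, frames[:2], masks[:2], cfg, tcfg)
    assert h1["train_loss"][0] == h2["train_loss"][0]
    assert h1["train_loss"] == h2["train_loss"]


def test_training_loss_decreases(rng):
    frames = np.tile(rng.random((1, 8, 8)).astype(np.float32), (8, 1, 1))
    frames[:, 3:6, 3:6] *= 0.2  # dark calcific patch
    masks = np.zeros((8, 8, 8), dtype=int)
    masks[:, 3:6, 3:6] = 1
    cfg = SegmenterConfig(encoder_stages=TINY_STAGES, seed=0)
    tcfg = TrainConfig(max_epochs=8, patience=8, seed=0, batch_size=4)
    _, h = train_segmenter(frames, masks, frames[:2], masks[:2], cfg, tcfg)
    assert h["train_loss"][-1] < h["train_loss"][0]


def test_layerwise_finetune_runs_and_unfreezes_everything(rng):
    frames = rng.random((4, 8, 8)).astype(np.float32)
    masks = np.zeros((4, 8, 8), dtype=int)
    masks[:, 2:5, 2:5] = 1
    cfg = SegmenterConfig(encoder_stages=TINY_STAGES, seed=0)
    tcfg = TrainConfig(max_epochs=2, patience=2, seed=0, batch_size=2)
    model, h = train_segmenter(frames, masks, frames[:1], masks[:1], cfg, tcfg,
                               layerwise=True)
    n_param_layers = sum(1 for l in model.all_layers() if l.params())
    assert len(h["layerwise"]["val_loss"]) == n_param_layers
    assert all(p.trainable for p in model.params())


def test_early_stopping_contract():
    """With a stubbed validation metric that never improves, training halts
    after exactly `patience` non-improving epochs."""
    rng = np.random.default_rng(0)
    model = build_segnet(SegmenterConfig(encoder_stages=[[2]], seed=0))
    X = rng.random((4, 1, 4, 4)).astype(np.float32)
    y = np.zeros((4, 4, 4), dtype=int)
    y[:, 1, 1] = 1
    tcfg = TrainConfig(max_epochs=50, patience=3, seed=0, batch_size=2)
    calls = []

    def stub(model, epoch):
        calls.append(epoch)
        return 1.0  # never improves

    h = nn.fit(model, TverskyTrainLoss(0.5, 0.5), X, y, X, y, tcfg, val_evaluator=stub)
    # epoch 1 sets the best; 3 further non-improving epochs trigger the stop
    assert h["stopped_epoch"] == 4
    assert len(calls) == 4
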