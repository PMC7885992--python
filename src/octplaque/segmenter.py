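"""Step 2: pixel-wise calcium segmentation with a SegNet-style network.

Encoder–decoder semantic segmentation: the encoder is a VGG-16-style
stack of 3×3 convolutions (batch-norm + ReLU) with five 2×2 stride-2
max-pools that record their argmax indices; the decoder mirrors it,
upsampling with max-unpooling driven by the stored indices so that
spatial detail lost in pooling is restored at the exact original
positions, followed by a 1×1 convolution and softmax.  The two-step
design trains this network only on frames known to contain calcium
(Step 1's output), so it never has to learn the appearance variability
of the full pullback.

Three losses over the softmax output are available: weighted
cross-entropy with inverse-median-frequency class weights, soft Dice,
and Tversky (TI = TP / (TP + α·FN + β·FP); α = β = 0.5 recovers Dice).
Defaults α = 0.7, β = 0.3 weigh false negatives more, favoring recall.
"""

from __future__ import annotations

import dataclasses
import json
from dataclasses import dataclass, field
from pathlib import Path

import numpy as np

from . import nn
from .frame_cleanup import LesionIntervals
from .nn import TrainConfig

VGG16_STAGES = [[64, 64], [128, 128], [256, 256, 256], [512, 512, 512], [512, 512, 512]]


@dataclass
class SegmenterConfig:
    encoder_stages: list[list[int]] = field(default_factory=lambda: [list(s) for s in VGG16_STAGES])
    n_classes: int = 2
    loss: str = "tversky"
    tversky_alpha: float = 0.7
    tversky_beta: float = 0.3
    smooth: float = 1.0  # training-time smoothing of soft-count losses
    seed: int = 0

    def __post_init__(self) -> None:
        if self.loss not in ("wce", "dice", "tversky"):
            raise ValueError(f"unknown loss {self.loss!r}")
        if self.tversky_alpha <= 0 or self.tversky_beta <= 0:
            raise ValueError("tversky alpha and beta must be positive")

    def to_dict(self) -> dict:
        return dataclasses.asdict(self)

    @classmethod
    def from_dict(cls, d: dict) -> "SegmenterConfig":
        return cls(**d)


@dataclass
class ProbVolume:
    """Per-pixel class probabilities for the frames Step 1 selected."""

    frame_indices: np.ndarray  # (k,) original frame indices
    probs: np.ndarray  # (k, n_classes, H, W), per-pixel sum = 1

    def masks(self) -> np.ndarray:
        """Binary argmax masks (ties broken to 'other')."""
        return (self.probs[:, 1] > self.probs[:, 0]).astype(np.uint8)


# ---------------------------------------------------------------------------
# class weights and losses (public contracts: probs carry the class axis last)

def median_freq_weights(label_stack: np.ndarray, n_classes: int = 2) -> np.ndarray:
    """Inverse-median-frequency class weights.

    ``freq_c`` is the pixel count of class ``c`` divided by the total
    pixel count of the frames in which ``c`` appears; the weight of
    class ``c`` is ``median(freq) / freq_c``, so rarer classes get
    larger weights.
    """
    labels = np.asarray(label_stack)
    if labels.ndim < 2:
        raise ValueError("expected a stack of label frames")
    frame_pixels = int(np.prod(labels.shape[1:]))
    freqs = np.empty(n_classes)
    for c in range(n_classes):
        present = np.array([(fr == c).any() for fr in labels])
        if not present.any():
            raise ValueError(f"class {c} absent from the label stack")
        count = int((labels[present] == c).sum())
        freqs[c] = count / (present.sum() * frame_pixels)
    return np.median(freqs) / freqs


def _check_probs(probs: np.ndarray, targets: np.ndarray) -> None:
    if probs.shape[:-1] != targets.shape:
        raise ValueError("probs must have shape targets.shape + (n_classes,)")
    if np.any(probs < -1e-9) or np.any(probs > 1 + 1e-9):
        raise ValueError("probabilities must lie in [0, 1]")


def wce_loss(probs: np.ndarray, targets: np.ndarray, weights: np.ndarray,
             eps: float = 1e-12) -> float:
    """Mean over pixels of −w_target · log(p_target)."""
    probs, targets = np.asarray(probs, float), np.asarray(targets, int)
    _check_probs(probs, targets)
    p_t = np.take_along_axis(probs, targets[..., None], axis=-1)[..., 0]
    w = np.asarray(weights, float)[targets]
    return float((-w * np.log(np.clip(p_t, eps, None))).mean())


def tversky_loss(probs: np.ndarray, targets: np.ndarray, alpha: float, beta: float,
                 smooth: float = 0.0) -> float:
    """1 − TP / (TP + α·FN + β·FP) on soft counts of the calcium class."""
    if alpha <= 0 or beta <= 0:
        raise ValueError("alpha and beta must be positive")
    probs, targets = np.asarray(probs, float), np.asarray(targets, int)
    _check_probs(probs, targets)
    p1 = probs[..., 1]
    t = (targets == 1).astype(float)
    tp = float((p1 * t).sum())
    fn = float(((1 - p1) * t).sum())
    fp = float((p1 * (1 - t)).sum())
    denom = tp + alpha * fn + beta * fp + smooth
    if denom == 0.0:
        return 0.0
    return 1.0 - (tp + smooth) / denom


def dice_loss(probs: np.ndarray, targets: np.ndarray, smooth: float = 0.0) -> float:
    """1 − 2|P∩T| / (|P| + |T|) on soft counts."""
    probs, targets = np.asarray(probs, float), np.asarray(targets, int)
    _check_probs(probs, targets)
    p1 = probs[..., 1]
    t = (targets == 1).astype(float)
    inter = float((p1 * t).sum())
    size = float(p1.sum() + t.sum())
    if size + smooth == 0.0:
        return 0.0
    return 1.0 - (2.0 * inter + smooth) / (size + smooth)


# ---------------------------------------------------------------------------
# training-time losses with gradients w.r.t. logits (N, C, H, W)

class WceTrainLoss:
    def __init__(self, weights: np.ndarray):
        self.weights = np.asarray(weights, dtype=np.float64)

    def __call__(self, logits, targets):
        p = nn.softmax(logits, axis=1)
        t = np.asarray(targets, int)
        w = self.weights[t]  # (N, H, W)
        npix = t.size
        p_t = np.take_along_axis(p, t[:, None], axis=1)[:, 0]
        loss = float((-w * np.log(np.clip(p_t, 1e-12, None))).sum() / npix)
        onehot = np.zeros_like(p)
        np.put_along_axis(onehot, t[:, None], 1.0, axis=1)
        grad = (p - onehot) * w[:, None] / npix
        return loss, grad


class TverskyTrainLoss:
    def __init__(self, alpha: float, beta: float, smooth: float = 1.0):
        if alpha <= 0 or beta <= 0:
            raise ValueError("alpha and beta must be positive")
        self.alpha, self.beta, self.smooth = alpha, beta, smooth

    def __call__(self, logits, targets):
        a, b = self.alpha, self.beta
        p = nn.softmax(logits, axis=1)
        p1 = p[:, 1]
        t = (np.asarray(targets, int) == 1).astype(np.float64)
        tp = (p1 * t).sum()
        fn = ((1 - p1) * t).sum()
        fp = (p1 * (1 - t)).sum()
        num = tp + self.smooth
        den = tp + a * fn + b * fp + self.smooth
        loss = float(1.0 - num / den)
        # d(den)/dp1_i = t - a*t + b*(1-t);  d(num)/dp1_i = t
        dTI = (t * den - num * (t - a * t + b * (1 - t))) / den**2
        dL_dp1 = -dTI
        grad = np.empty_like(p)
        grad[:, 1] = dL_dp1 * p1 * (1.0 - p1)
        grad[:, 0] = dL_dp1 * p1 * (0.0 - p[:, 0])
        return loss, grad


def make_train_loss(config: SegmenterConfig, masks: np.ndarray):
    if config.loss == "wce":
        return WceTrainLoss(median_freq_weights(masks, config.n_classes))
    if config.loss == "dice":
        return TverskyTrainLoss(0.5, 0.5, smooth=config.smooth)
    return TverskyTrainLoss(config.tversky_alpha, config.tversky_beta, smooth=config.smooth)


# ---------------------------------------------------------------------------
# network

def build_segnet(config: SegmenterConfig, in_channels: int = 1) -> nn.Sequential:
    """SegNet: mirrored encoder/decoder with index-driven unpooling.

    Decoder stage ``k`` (1-based from the deepest) unpools with the
    indices stored by encoder stage ``n_stages + 1 − k``.
    """
    rng = np.random.default_rng(config.seed)
    stages = config.encoder_stages
    layers: list[nn.Layer] = []
    pools: list[nn.MaxPoolLast2] = []
    cin = in_channels
    for stage in stages:
        for f in stage:
            layers += [nn.Conv2d(cin, f, kernel=3, rng=rng), nn.BatchNorm(f), nn.ReLU()]
            cin = f
        pool = nn.MaxPoolLast2()
        pools.append(pool)
        layers.append(pool)
    for k in range(len(stages) - 1, -1, -1):
        layers.append(nn.MaxUnpoolLast2(pools[k]))
        stage = stages[k]
        out_width = stages[k - 1][-1] if k > 0 else stages[0][0]
        widths = [stage[-1]] * (len(stage) - 1) + [out_width]
        for f in widths:
            layers += [nn.Conv2d(cin, f, kernel=3, rng=rng), nn.BatchNorm(f), nn.ReLU()]
            cin = f
    layers.append(nn.Conv2d(cin, config.n_classes, kernel=1, rng=rng))
    layers[0].skip_input_grad = True  # no gradient needed w.r.t. the image
    return nn.Sequential(layers)


def segment_frames(
    stack: np.ndarray,
    intervals: LesionIntervals,
    model: nn.Sequential,
    batch_size: int = 4,
) -> ProbVolume:
    """Segment only the frames inside the cleaned lesion intervals."""
    stack = np.asarray(stack, dtype=np.float32)
    idx = np.array(
        sorted({f for s, e in intervals for f in range(s, e + 1)}), dtype=int
    )
    if idx.size and (idx.min() < 0 or idx.max() >= stack.shape[0]):
        raise ValueError("lesion interval outside the stack")
    X = stack[idx][:, None]
    probs = np.empty((len(idx), 2, stack.shape[1], stack.shape[2]), dtype=np.float64)
    for i in range(0, len(idx), batch_size):
        logits = model.forward(X[i : i + batch_size], training=False)
        probs[i : i + batch_size] = nn.softmax(logits, axis=1)
    return ProbVolume(frame_indices=idx, probs=probs)


def train_segmenter(
    frames: np.ndarray,
    masks: np.ndarray,
    val_frames: np.ndarray,
    val_masks: np.ndarray,
    config: SegmenterConfig,
    tcfg: TrainConfig,
    require_positive: bool = True,
    layerwise: bool = False,
) -> tuple[nn.Sequential, dict]:
    """Train the segmenter.

    In the two-step regime every training frame must contain calcium
    (``require_positive=True``, the default); a frame with no positive
    pixel is rejected with its index.  ``require_positive=False`` gives
    the one-step regime (train on all frames).  ``layerwise`` enables a
    short fine-tuning sweep that unfreezes layers from the last
    backward after the main fit.
    """
    frames = np.asarray(frames, dtype=np.float32)
    masks = np.asarray(masks, dtype=np.int64)
    if require_positive:
        empty = np.flatnonzero(~masks.any(axis=tuple(range(1, masks.ndim))))
        if empty.size:
            raise ValueError(
                f"two-step training requires calcification in every frame; "
                f"frame(s) {empty.tolist()} have no positive pixel"
            )
    model = build_segnet(config)
    loss = make_train_loss(config, masks)
    X, Xv = frames[:, None], np.asarray(val_frames, np.float32)[:, None]
    yv = np.asarray(val_masks, np.int64)
    history = nn.fit(model, loss, X, masks, Xv, yv, tcfg)
    if layerwise:
        history["layerwise"] = layerwise_finetune(model, loss, X, masks, Xv, yv, tcfg)
    return model, history


def layerwise_finetune(model, loss, X, y, Xv, yv, tcfg: TrainConfig,
                       lr_scale: float = 0.1) -> dict:
    """Freeze everything, then unfreeze one parametric layer at a time
    starting from the last, training one epoch per step at a reduced
    learning rate."""
    param_layers = [l for l in model.all_layers() if l.params()]
    for l in param_layers:
        for p in l.params():
            p.trainable = False
    sub = TrainConfig(
        lr=tcfg.lr * lr_scale, drop_factor=tcfg.drop_factor, drop_period=tcfg.drop_period,
        max_epochs=1, patience=1, batch_size=tcfg.batch_size, seed=tcfg.seed + 17,
    )
    hist = {"val_loss": []}
    for l in reversed(param_layers):
        for p in l.params():
            p.trainable = True
        h = nn.fit(model, loss, X, y, Xv, yv, sub)
        hist["val_loss"].append(h["val_loss"][-1])
    for l in param_layers:
        for p in l.params():
            p.trainable = True
    return hist


def save_segmenter(path, model: nn.Sequential, config: SegmenterConfig) -> None:
    path = Path(path)
    np.savez(path.with_suffix(".npz"), *model.get_state())
    sidecar = {"kind": "segmenter", "config": config.to_dict()}
    path.with_suffix(".json").write_text(json.dumps(sidecar))


def load_segmenter(path) -> tuple[nn.Sequential, SegmenterConfig]:
    path = Path(path)
    sidecar = json.loads(path.with_suffix(".json").read_text())
    config = SegmenterConfig.from_dict(sidecar["config"])
    model = build_segnet(config)
    with np.load(path.with_suffix(".npz")) as data:
        model.set_state([data[f"arr_{i}"] for i in range(len(data.files))])
    return model, config
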