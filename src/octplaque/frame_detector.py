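"""Step 1: per-frame major-calcification detection with a 3-D CNN.

Each frame is classified "calcification" vs "other" from a 5-frame
window centered on it, so the decision can exploit the longitudinal
persistence of calcium.  The default architecture is five 3-D convolutions (kernel 3×5×5 over depth×θ×r, stride 1,
batch-norm + ReLU), five 2×2×1 max-pools (θ and r pooled, depth never),
then two fully connected layers (1024 units + dropout, then a 2-way
softmax).  Filter counts default to (96, 128, 256, 324, 324).  A much smaller filter
list is used for phantom-scale experiments.

θ padding is parametric: the window carries one extra A-line above each
depth slice (the last A-line of the chronologically previous frame) and
one below (the first A-line of the next frame); the first/last frames
reuse their own wrap-around A-lines.  r padding is zero.
"""

from __future__ import annotations

import dataclasses
import json
from dataclasses import dataclass, field
from pathlib import Path

import numpy as np

from . import nn
from .nn import TrainConfig


@dataclass
class DetectorConfig:
    conv_filters: list[int] = field(default_factory=lambda: [96, 128, 256, 324, 324])
    kernel: tuple[int, int, int] = (3, 5, 5)
    fc1_units: int = 1024
    dropout_rate: float = 0.5
    n_classes: int = 2
    seed: int = 0

    def to_dict(self) -> dict:
        return dataclasses.asdict(self)

    @classmethod
    def from_dict(cls, d: dict) -> "DetectorConfig":
        d = dict(d)
        d["kernel"] = tuple(d["kernel"])
        return cls(**d)


@dataclass
class FrameWindow:
    """5-frame block centered on the target frame, with θ padding rows."""

    volume: np.ndarray  # (5, n_alines, n_radial_roi)
    theta_top: np.ndarray  # (5, n_radial_roi): parametric top padding per slice
    theta_bottom: np.ndarray  # (5, n_radial_roi)

    def padded(self) -> np.ndarray:
        """Volume with the parametric θ rows attached: (5, θ+2, r)."""
        return np.concatenate(
            [self.theta_top[:, None, :], self.volume, self.theta_bottom[:, None, :]],
            axis=1,
        )


@dataclass
class FrameLabels:
    labels: np.ndarray  # uint8 (n_frames,), 1 = calcification
    probabilities: np.ndarray  # (n_frames, 2), rows sum to 1


WINDOW_DEPTH = 5


def build_window(stack: np.ndarray, i: int) -> FrameWindow:
    """Build the 5-frame window centered at frame ``i``.

    Edge frames replicate the boundary frame to fill the depth.  The
    parametric θ padding of each depth slice comes from the adjacent
    frames: top = last A-line of the previous frame, bottom = first
    A-line of the next frame; at the pullback ends a frame supplies its
    own last/first A-line.
    """
    stack = np.asarray(stack)
    n = stack.shape[0]
    if n < 1:
        raise ValueError("stack must contain at least one frame")
    if not 0 <= i < n:
        raise IndexError(f"frame index {i} outside [0, {n})")
    half = WINDOW_DEPTH // 2
    js = np.clip(np.arange(i - half, i + half + 1), 0, n - 1)
    volume = stack[js].astype(np.float32)
    top = np.stack([stack[j - 1 if j > 0 else j, -1, :] for j in js]).astype(np.float32)
    bottom = np.stack([stack[j + 1 if j < n - 1 else j, 0, :] for j in js]).astype(np.float32)
    return FrameWindow(volume=volume, theta_top=top, theta_bottom=bottom)


def windows_as_batch(stack: np.ndarray, indices=None) -> np.ndarray:
    """Stack padded windows into a network input (N, 1, 5, θ+2, r)."""
    stack = np.asarray(stack)
    if indices is None:
        indices = range(stack.shape[0])
    return np.stack([build_window(stack, int(i)).padded() for i in indices])[:, None]


def build_detector(config: DetectorConfig, input_hw: tuple[int, int]) -> nn.Sequential:
    """Construct the 3-D CNN for padded windows of shape (5, H, W)."""
    rng = np.random.default_rng(config.seed)
    H, W = input_hw
    layers: list[nn.Layer] = []
    cin = 1
    h, w = H, W
    for f in config.conv_filters:
        layers += [
            nn.Conv3d(cin, f, kernel=config.kernel, rng=rng),
            nn.BatchNorm(f),
            nn.ReLU(),
            nn.MaxPoolLast2(),
        ]
        cin = f
        h, w = h // 2, w // 2
        if h < 1 or w < 1:
            raise ValueError("input too small for the configured pooling depth")
    layers[0].skip_input_grad = True  # no gradient needed w.r.t. the image
    flat = cin * WINDOW_DEPTH * h * w
    layers += [
        nn.Flatten(),
        nn.Linear(flat, config.fc1_units, rng=rng),
        nn.ReLU(),
        nn.Dropout(config.dropout_rate, seed=config.seed + 1),
        nn.Linear(config.fc1_units, config.n_classes, rng=rng),
    ]
    model = nn.Sequential(layers)
    model.input_hw = (H, W)
    return model


def ce_loss(logits: np.ndarray, targets: np.ndarray) -> tuple[float, np.ndarray]:
    """Softmax cross-entropy with gradient w.r.t. the logits."""
    p = nn.softmax(logits, axis=1)
    n = len(targets)
    picked = np.clip(p[np.arange(n), targets], 1e-12, None)
    loss = float(-np.log(picked).mean())
    grad = p.copy()
    grad[np.arange(n), targets] -= 1.0
    return loss, grad / n


def classify_frames(stack: np.ndarray, model: nn.Sequential, batch_size: int = 8) -> FrameLabels:
    """Classify every frame of a preprocessed stack.

    Deterministic in inference mode; the argmax tie is broken toward
    "other" (a frame is positive only if its calcification probability
    strictly exceeds the other-class probability).
    """
    X = windows_as_batch(stack)
    expected = getattr(model, "input_hw", None)
    if expected is not None and tuple(X.shape[-2:]) != tuple(expected):
        raise ValueError(
            f"stack windows have (θ+2, r) = {X.shape[-2:]}, but the model "
            f"expects {tuple(expected)}"
        )
    probs = np.empty((len(X), 2), dtype=np.float64)
    for i in range(0, len(X), batch_size):
        logits = model.forward(X[i : i + batch_size], training=False)
        probs[i : i + batch_size] = nn.softmax(logits, axis=1)
    labels = (probs[:, 1] > probs[:, 0]).astype(np.uint8)
    return FrameLabels(labels=labels, probabilities=probs)


def train_detector(
    train_stacks: list[np.ndarray],
    train_labels: list[np.ndarray],
    val_stacks: list[np.ndarray],
    val_labels: list[np.ndarray],
    config: DetectorConfig,
    tcfg: TrainConfig,
) -> tuple[nn.Sequential, dict]:
    """Train the frame classifier on preprocessed pullback stacks."""
    X = np.concatenate([windows_as_batch(s) for s in train_stacks])
    y = np.concatenate([np.asarray(l, dtype=int) for l in train_labels])
    if len(np.unique(y)) < 2:
        raise ValueError("training labels contain a single class")
    Xv = np.concatenate([windows_as_batch(s) for s in val_stacks])
    yv = np.concatenate([np.asarray(l, dtype=int) for l in val_labels])
    model = build_detector(config, input_hw=X.shape[-2:])
    history = nn.fit(model, ce_loss, X, y, Xv, yv, tcfg)
    return model, history


def save_detector(path, model: nn.Sequential, config: DetectorConfig,
                  input_hw: tuple[int, int]) -> None:
    path = Path(path)
    np.savez(path.with_suffix(".npz"), *model.get_state())
    sidecar = {"kind": "detector", "config": config.to_dict(),
               "input_hw": [int(v) for v in input_hw]}
    path.with_suffix(".json").write_text(json.dumps(sidecar))


def load_detector(path) -> tuple[nn.Sequential, DetectorConfig]:
    path = Path(path)
    sidecar = json.loads(path.with_suffix(".json").read_text())
    config = DetectorConfig.from_dict(sidecar["config"])
    model = build_detector(config, input_hw=tuple(sidecar["input_hw"]))
    with np.load(path.with_suffix(".npz")) as data:
        model.set_state([data[f"arr_{i}"] for i in range(len(data.files))])
    return model, config
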