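"""Polar-domain pre-processing of IVOCT frames.

Per frame, in order: guidewire-shadow detection, lumen-boundary
detection, per-A-line pixel shift so that every A-line starts at its
lumen boundary, crop to a 1 mm (200 px at 5 µm/px) region of interest,
and 7×7 Gaussian despeckling (σ = 1).  The geometric context of each
frame (lumen indices, shift offsets, guidewire interval) is retained so
that segmentation output can be mapped back to raw coordinates.

The lumen detector is a gradient-maximum tracker with a circular
continuity constraint solved by dynamic programming over θ — a simple,
fully self-contained stand-in adequate for phantom data; externally
supplied lumen indices can be passed straight through for real data.
"""

from __future__ import annotations

import dataclasses
import json
from dataclasses import dataclass

import numpy as np
from scipy.ndimage import gaussian_filter, gaussian_filter1d

from .core import PolarFrame, Pullback
from .phantom import catheter_radius_px, guidewire_alines

ROI_DEPTH_PX = 200


@dataclass
class PreprocContext:
    """Invertible geometry of one preprocessed frame."""

    lumen_index: np.ndarray  # (n_alines,) radial index of lumen boundary
    shift_offset: np.ndarray  # (n_alines,) pixels removed before tissue start
    guidewire_interval: tuple[int, int] | None
    roi_depth_px: int = ROI_DEPTH_PX
    n_radial: int = 968

    def to_dict(self) -> dict:
        d = dataclasses.asdict(self)
        d["lumen_index"] = self.lumen_index.tolist()
        d["shift_offset"] = self.shift_offset.tolist()
        return d

    @classmethod
    def from_dict(cls, d: dict) -> "PreprocContext":
        d = dict(d)
        d["lumen_index"] = np.asarray(d["lumen_index"], dtype=int)
        d["shift_offset"] = np.asarray(d["shift_offset"], dtype=int)
        gw = d["guidewire_interval"]
        d["guidewire_interval"] = tuple(gw) if gw is not None else None
        return cls(**d)


def save_contexts(contexts: list[PreprocContext], path) -> None:
    with open(path, "w") as fh:
        json.dump([c.to_dict() for c in contexts], fh)


def load_contexts(path) -> list[PreprocContext]:
    with open(path) as fh:
        return [PreprocContext.from_dict(d) for d in json.load(fh)]


class NoLumenError(RuntimeError):
    """Raised when a frame contains no detectable tissue signal."""


# ---------------------------------------------------------------------------
# guidewire shadow

def detect_guidewire(
    frame: PolarFrame,
    threshold_frac: float = 0.35,
    min_width: int = 3,
    max_width: int | None = None,
    catheter_radius: int | None = None,
) -> tuple[int, int] | None:
    """Locate the guidewire shadow as a circular A-line interval.

    The per-A-line tissue energy (summed intensity beyond the catheter
    radius) is thresholded at ``threshold_frac`` × median; the interval
    is the circular (start, width) pair maximizing the below-threshold
    excess, found by exhaustive dynamic programming over prefix sums.
    Returns an inclusive ``(start, end)`` pair (``end < start`` denotes
    wrap through θ = 0) or ``None`` if no block falls below threshold.
    """
    img = frame.intensity.astype(np.float64)
    n = frame.n_alines
    cat = catheter_radius if catheter_radius is not None else catheter_radius_px(frame.n_radial)
    energy = img[:, cat:].sum(axis=1)
    thr = threshold_frac * np.median(energy)
    score = thr - energy  # positive on shadow A-lines
    if max_width is None:
        max_width = max(min_width, n // 4)

    # max-sum circular interval with width in [min_width, max_width]
    ext = np.concatenate([score, score[: max_width]])
    csum = np.concatenate([[0.0], np.cumsum(ext)])
    best_val, best = -np.inf, None
    for w in range(min_width, max_width + 1):
        sums = csum[w : w + n] - csum[:n]  # start = 0..n-1
        s = int(np.argmax(sums))
        if sums[s] > best_val:
            best_val, best = sums[s], (s, w)
    if best is None or best_val <= 0:
        return None
    start, w = best
    return (start, (start + w - 1) % n)


# ---------------------------------------------------------------------------
# lumen boundary

def detect_lumen(
    frame: PolarFrame,
    guidewire: tuple[int, int] | None = None,
    max_jump: int = 3,
    catheter_radius: int | None = None,
    lumen_index: np.ndarray | None = None,
) -> np.ndarray:
    """Per-A-line radial index of the first tissue pixel.

    Maximizes the summed radial intensity gradient along a θ-circular
    path with ``|index[i] − index[i+1]| ≤ max_jump`` (Viterbi DP).
    Guidewire A-lines carry no boundary information and are filled by
    circular linear interpolation from their neighbors.  Passing
    ``lumen_index`` bypasses detection (external lumen segmentation).
    """
    n_theta, n_r = frame.intensity.shape
    if lumen_index is not None:
        lum = np.asarray(lumen_index, dtype=int)
        if lum.shape != (n_theta,):
            raise ValueError("external lumen_index has wrong shape")
        return lum

    img = frame.intensity.astype(np.float64)
    if img.max() < 1e-9:
        raise NoLumenError("no lumen detectable: frame is dark")
    cat = catheter_radius if catheter_radius is not None else catheter_radius_px(n_r)

    sm = gaussian_filter1d(img, sigma=1.0, axis=1)
    grad = np.zeros_like(sm)
    grad[:, 1:] = sm[:, 1:] - sm[:, :-1]
    # boundary cannot sit inside the catheter dead zone
    grad[:, : cat + 1] = grad.min() - 1.0
    if grad.max() <= 1e-12:
        raise NoLumenError("no lumen detectable: no rising edge found")

    gw = guidewire_alines(guidewire, n_theta) if guidewire is not None else np.array([], int)
    gw_mask = np.zeros(n_theta, dtype=bool)
    gw_mask[gw] = True
    cost = grad.copy()
    cost[gw_mask] = 0.0  # uninformative rows: let continuity carry the path

    # circular Viterbi: start at the strongest non-guidewire A-line
    strength = np.where(gw_mask, -np.inf, grad.max(axis=1))
    anchor = int(np.argmax(strength))
    order = (np.arange(n_theta) + anchor) % n_theta

    win = 2 * max_jump + 1
    dp = cost[order[0]].copy()
    ptr = np.empty((n_theta, n_r), dtype=np.int32)
    pad = np.full(max_jump, -np.inf)
    for step in range(1, n_theta):
        padded = np.concatenate([pad, dp, pad])
        windows = np.lib.stride_tricks.sliding_window_view(padded, win)
        arg = windows.argmax(axis=1)
        prev_best = windows[np.arange(n_r), arg]
        ptr[step] = arg + np.arange(n_r) - max_jump
        dp = cost[order[step]] + prev_best
    path = np.empty(n_theta, dtype=int)
    path[-1] = int(np.argmax(dp))
    for step in range(n_theta - 1, 0, -1):
        path[step - 1] = ptr[step, path[step]]
    lum = np.empty(n_theta, dtype=int)
    lum[order] = path

    # boundary index = first tissue pixel; the gradient peaks at that pixel
    if gw_mask.any() and not gw_mask.all():
        lum = _fill_circular(lum, gw_mask)
    return lum


def _fill_circular(values: np.ndarray, fill_mask: np.ndarray) -> np.ndarray:
    """Circular linear interpolation of masked entries."""
    n = len(values)
    out = values.astype(float).copy()
    good = np.flatnonzero(~fill_mask)
    for i in np.flatnonzero(fill_mask):
        dist_next = (good - i) % n
        dist_prev = (i - good) % n
        nxt = good[np.argmin(dist_next)]
        prv = good[np.argmin(dist_prev)]
        dn = (nxt - i) % n
        dp = (i - prv) % n
        out[i] = (values[prv] * dn + values[nxt] * dp) / (dn + dp)
    return np.rint(out).astype(int)


# ---------------------------------------------------------------------------
# alignment, crop, smoothing

def align_and_crop(
    frame_intensity: np.ndarray,
    ctx: PreprocContext,
) -> np.ndarray:
    """Shift each A-line so its lumen boundary sits at column 0; keep the ROI.

    Output shape is ``(n_alines, roi_depth_px)``; columns beyond the raw
    frame are zero-padded and guidewire A-lines are zeroed.
    """
    if ctx.roi_depth_px <= 0:
        raise ValueError("roi_depth_px must be positive")
    img = np.asarray(frame_intensity)
    n_theta, n_r = img.shape
    roi = ctx.roi_depth_px
    cols = ctx.shift_offset[:, None] + np.arange(roi)[None, :]
    valid = cols < n_r
    out = np.where(valid, img[np.arange(n_theta)[:, None], np.clip(cols, 0, n_r - 1)], 0)
    out = out.astype(img.dtype)
    if ctx.guidewire_interval is not None:
        out[guidewire_alines(ctx.guidewire_interval, n_theta)] = 0.0
    return out


def smooth(frame_intensity: np.ndarray, sigma: float = 1.0, truncate: float = 3.0) -> np.ndarray:
    """7×7 Gaussian despeckling (σ = 1, reflect boundaries)."""
    return gaussian_filter(
        np.asarray(frame_intensity, dtype=np.float32),
        sigma=sigma,
        truncate=truncate,
        mode="reflect",
    )


def preprocess_frame(
    frame: PolarFrame,
    roi_depth_px: int = ROI_DEPTH_PX,
    lumen_index: np.ndarray | None = None,
    catheter_radius: int | None = None,
) -> tuple[np.ndarray, PreprocContext]:
    gw = detect_guidewire(frame, catheter_radius=catheter_radius)
    lum = detect_lumen(
        frame, guidewire=gw, catheter_radius=catheter_radius, lumen_index=lumen_index
    )
    ctx = PreprocContext(
        lumen_index=lum,
        shift_offset=lum.copy(),
        guidewire_interval=gw,
        roi_depth_px=roi_depth_px,
        n_radial=frame.n_radial,
    )
    aligned = align_and_crop(frame.intensity, ctx)
    return smooth(aligned), ctx


def preprocess_pullback(
    pullback: Pullback,
    roi_depth_px: int = ROI_DEPTH_PX,
    lumen_indices: np.ndarray | None = None,
    catheter_radius: int | None = None,
    normalize: bool = True,
) -> tuple[np.ndarray, list[PreprocContext]]:
    """Apply the full per-frame chain to a pullback.

    Returns ``(stack, contexts)`` with ``stack`` of shape
    ``(n_frames, n_alines, roi_depth_px)`` (float32, smoothed) and one
    :class:`PreprocContext` per frame.  With ``normalize`` the stack is
    scaled by its maximum so network inputs are in [0, 1] regardless of
    the acquisition bit depth.
    """
    if len(pullback) == 0:
        raise ValueError("empty pullback")
    out = np.empty((len(pullback), pullback.n_alines, roi_depth_px), dtype=np.float32)
    contexts: list[PreprocContext] = []
    for i, frame in enumerate(pullback.frames):
        try:
            lum = lumen_indices[i] if lumen_indices is not None else None
            aligned, ctx = preprocess_frame(
                frame, roi_depth_px=roi_depth_px, lumen_index=lum,
                catheter_radius=catheter_radius,
            )
        except Exception as exc:
            raise RuntimeError(f"preprocessing failed at frame {i}: {exc}") from exc
        out[i] = aligned
        contexts.append(ctx)
    if normalize and out.max() > 0:
        out /= out.max()
    return out, contexts
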