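"""Missing-frame repair inside lesion intervals.

The segmenter occasionally produces an empty mask on a frame whose
neighbors within the same lesion are clearly calcified.  Because plaque
is spatially continuous along the vessel, such frames are treated as
missing and replaced by shape interpolation of their nearest nonempty
neighbors: per-pixel signed distance transforms of the two neighbor
masks are blended linearly in the frame position and thresholded at
zero, which yields a sharp binary mask that morphs continuously between
the neighbor shapes.
"""

from __future__ import annotations

import numpy as np
from scipy.ndimage import distance_transform_edt

from .frame_cleanup import LesionIntervals


def find_missing(masks: np.ndarray, intervals: LesionIntervals) -> list[int]:
    """Frames strictly inside an interval with an empty mask and nonempty
    neighbors on both sides within the same interval."""
    masks = np.asarray(masks)
    nonempty = masks.any(axis=tuple(range(1, masks.ndim)))
    missing: list[int] = []
    for s, e in intervals:
        for f in range(s + 1, e):
            if nonempty[f]:
                continue
            left = [g for g in range(s, f) if nonempty[g]]
            right = [g for g in range(f + 1, e + 1) if nonempty[g]]
            if left and right:
                missing.append(f)
    return missing


def signed_distance(mask: np.ndarray) -> np.ndarray:
    """Signed Euclidean distance to the mask boundary: negative inside."""
    m = np.asarray(mask).astype(bool)
    if not m.any():
        raise ValueError("mask is empty")
    return distance_transform_edt(~m) - distance_transform_edt(m)


def interpolate_frame(mask_prev: np.ndarray, mask_next: np.ndarray, t: float) -> np.ndarray:
    """Signed-distance morph between two nonempty masks at position t ∈ (0, 1).

    Identical neighbors reproduce themselves exactly for any t.
    """
    if not 0.0 < t < 1.0:
        raise ValueError("t must lie strictly between 0 and 1")
    s = (1.0 - t) * signed_distance(mask_prev) + t * signed_distance(mask_next)
    return (s <= 0).astype(np.uint8)


def fill_missing(masks: np.ndarray, intervals: LesionIntervals) -> tuple[np.ndarray, list[int]]:
    """Replace missing frames by interpolation; frames with nonempty masks
    are never altered.  Returns (repaired masks, replaced frame indices)."""
    masks = np.asarray(masks).astype(np.uint8).copy()
    nonempty = masks.any(axis=tuple(range(1, masks.ndim)))
    replaced: list[int] = []
    for s, e in intervals:
        frames = np.arange(s, e + 1)
        good = frames[nonempty[frames]]
        if good.size < 2:
            continue
        for f in range(s + 1, e):
            if nonempty[f]:
                continue
            left = good[good < f]
            right = good[good > f]
            if left.size == 0 or right.size == 0:
                continue
            a, b = int(left.max()), int(right.min())
            t = (f - a) / (b - a)
            masks[f] = interpolate_frame(masks[a], masks[b], t)
            replaced.append(f)
    return masks, replaced
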