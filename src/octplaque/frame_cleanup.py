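"""1-D morphological cleanup of the per-frame calcification sequence.

The frame classifier occasionally produces isolated positive frames or
single missing frames inside a lesion.  Opening with a flat structuring
element of size 5 removes positive runs shorter than 5 frames; closing
with the same element fills gaps shorter than 5 frames.  The sequence is
treated as zero-padded beyond both ends, so a short run touching the
pullback boundary is also removed.  Maximal runs of the cleaned sequence
are the major calcification lesions.
"""

from __future__ import annotations

import numpy as np
from scipy.ndimage import binary_dilation, binary_erosion

DEFAULT_SE = 5

#: inclusive (start_frame, end_frame) pairs, disjoint and sorted
LesionIntervals = list[tuple[int, int]]


def _check_se(se_size: int) -> None:
    if se_size < 1 or se_size % 2 == 0:
        raise ValueError(f"structuring element size must be odd and >= 1, got {se_size}")


def _padded_op(labels: np.ndarray, se_size: int, first, second) -> np.ndarray:
    x = np.asarray(labels).astype(bool)
    if x.ndim != 1:
        raise ValueError("labels must be a 1-D sequence")
    se = np.ones(se_size, dtype=bool)
    pad = se_size  # zero padding beyond both ends
    xp = np.pad(x, pad)
    return second(first(xp, se), se)[pad:-pad]


def open_1d(labels, se_size: int = DEFAULT_SE) -> np.ndarray:
    """Erosion then dilation: removes positive runs shorter than se_size."""
    _check_se(se_size)
    return _padded_op(labels, se_size, binary_erosion, binary_dilation).astype(np.uint8)


def close_1d(labels, se_size: int = DEFAULT_SE) -> np.ndarray:
    """Dilation then erosion: fills gaps shorter than se_size."""
    _check_se(se_size)
    return _padded_op(labels, se_size, binary_dilation, binary_erosion).astype(np.uint8)


def runs(labels) -> LesionIntervals:
    """Maximal runs of positives as inclusive (start, end) intervals."""
    x = np.asarray(labels).astype(bool).astype(int)
    d = np.diff(np.concatenate([[0], x, [0]]))
    starts = np.flatnonzero(d == 1)
    ends = np.flatnonzero(d == -1) - 1
    return [(int(s), int(e)) for s, e in zip(starts, ends)]


def cleanup(labels, se_size: int = DEFAULT_SE) -> tuple[np.ndarray, LesionIntervals]:
    """Open then close the frame-label sequence; return it with its lesions."""
    x = np.asarray(labels)
    if x.size == 0:
        raise ValueError("empty label sequence")
    cleaned = close_1d(open_1d(x, se_size), se_size)
    return cleaned, runs(cleaned)
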