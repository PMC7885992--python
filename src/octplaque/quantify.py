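"""Evaluation metrics, per-lesion calcium attributes, and the calcium score.

Confusion-matrix metrics: sensitivity = TP/(TP+FN), specificity =
TN/(TN+FP), precision = TP/(TP+FP), F1 = 2TP/(2TP+FP+FN); a metric with
a zero denominator is reported as NaN (undefined), never as 0.

Calcium attributes are measured in the aligned polar domain, where the
lumen boundary sits at radial column 0, so depth is the leading-edge
column × 5 µm and thickness the per-A-line radial extent × 5 µm.  The
arc angle of a frame is the number of A-lines containing calcium times
360°/n_alines (catheter-centric convention).  Lesion length is the
frame count × 0.2 mm frame pitch.  The rule-based calcium score adds 2
if the maximum angle exceeds 180°, 1 if the maximum per-A-line
thickness exceeds 0.5 mm, and 1 if the length exceeds 5 mm — the
IVOCT scoring rule used to predict stent under-expansion risk.
"""

from __future__ import annotations

import math
from dataclasses import dataclass

import numpy as np
import pandas as pd

from .core import FRAME_PITCH_MM, R_PITCH_MM
from .frame_cleanup import LesionIntervals


@dataclass
class ConfusionCounts:
    tp: int
    tn: int
    fp: int
    fn: int
    granularity: str = "pixel"  # or "frame"

    def __post_init__(self) -> None:
        if min(self.tp, self.tn, self.fp, self.fn) < 0:
            raise ValueError("confusion counts must be non-negative")

    @property
    def total(self) -> int:
        return self.tp + self.tn + self.fp + self.fn


def confusion_from_masks(pred, truth, granularity: str = "pixel") -> ConfusionCounts:
    p = np.asarray(pred).astype(bool).ravel()
    t = np.asarray(truth).astype(bool).ravel()
    if p.shape != t.shape:
        raise ValueError("prediction and truth shapes differ")
    return ConfusionCounts(
        tp=int((p & t).sum()),
        tn=int((~p & ~t).sum()),
        fp=int((p & ~t).sum()),
        fn=int((~p & t).sum()),
        granularity=granularity,
    )


def _ratio(num: float, den: float) -> float:
    return num / den if den > 0 else math.nan


def metrics(counts: ConfusionCounts) -> dict[str, float]:
    """Sensitivity, specificity, precision, F1 (NaN when undefined)."""
    return {
        "sensitivity": _ratio(counts.tp, counts.tp + counts.fn),
        "specificity": _ratio(counts.tn, counts.tn + counts.fp),
        "precision": _ratio(counts.tp, counts.tp + counts.fp),
        "f1": _ratio(2 * counts.tp, 2 * counts.tp + counts.fp + counts.fn),
    }


def frame_angle(mask_frame: np.ndarray) -> float:
    """Calcium arc of one aligned polar mask frame, in degrees.

    Counts A-lines containing at least one positive pixel; a
    wrap-around arc is therefore counted once.
    """
    m = np.asarray(mask_frame).astype(bool)
    n_alines = m.shape[0]
    return float(m.any(axis=1).sum()) * 360.0 / n_alines


@dataclass
class LesionAttributes:
    interval: tuple[int, int]
    max_angle_deg: float
    mean_thickness_mm: float
    max_thickness_mm: float
    mean_depth_mm: float
    length_mm: float
    calcium_score: int


def calcium_score(max_angle_deg: float, max_thickness_mm: float, length_mm: float) -> int:
    """0–4 rule-based score: +2 if angle > 180°, +1 if thickness > 0.5 mm,
    +1 if length > 5 mm (strict inequalities)."""
    score = 0
    if max_angle_deg > 180.0:
        score += 2
    if max_thickness_mm > 0.5:
        score += 1
    if length_mm > 5.0:
        score += 1
    return score


def lesion_attributes(
    masks: np.ndarray,
    intervals: LesionIntervals,
    r_pitch_mm: float = R_PITCH_MM,
    frame_pitch_mm: float = FRAME_PITCH_MM,
) -> list[LesionAttributes]:
    """Per-lesion attributes from aligned masks (n_frames, n_alines, roi).

    Thickness and depth are measured per positive A-line (radial extent
    and leading-edge column) and averaged over all positive A-lines of
    all frames in the lesion.
    """
    masks = np.asarray(masks).astype(bool)
    out: list[LesionAttributes] = []
    for s, e in intervals:
        thick_px: list[int] = []
        depth_px: list[int] = []
        max_angle = 0.0
        for f in range(s, e + 1):
            m = masks[f]
            max_angle = max(max_angle, frame_angle(m))
            for aline in np.flatnonzero(m.any(axis=1)):
                cols = np.flatnonzero(m[aline])
                thick_px.append(int(cols[-1] - cols[0] + 1))
                depth_px.append(int(cols[0]))
        if not thick_px:
            raise ValueError(f"lesion [{s}, {e}] has no positive pixels")
        length_mm = (e - s + 1) * frame_pitch_mm
        mean_thick = float(np.mean(thick_px)) * r_pitch_mm
        max_thick = float(np.max(thick_px)) * r_pitch_mm
        mean_depth = float(np.mean(depth_px)) * r_pitch_mm
        out.append(
            LesionAttributes(
                interval=(s, e),
                max_angle_deg=max_angle,
                mean_thickness_mm=mean_thick,
                max_thickness_mm=max_thick,
                mean_depth_mm=mean_depth,
                length_mm=length_mm,
                calcium_score=calcium_score(max_angle, max_thick, length_mm),
            )
        )
    return out


def attributes_table(attrs: list[LesionAttributes]) -> pd.DataFrame:
    """One row per lesion, ready for CSV export."""
    return pd.DataFrame(
        [
            {
                "start_frame": a.interval[0],
                "end_frame": a.interval[1],
                "max_angle_deg": a.max_angle_deg,
                "mean_thickness_mm": a.mean_thickness_mm,
                "max_thickness_mm": a.max_thickness_mm,
                "mean_depth_mm": a.mean_depth_mm,
                "length_mm": a.length_mm,
                "calcium_score": a.calcium_score,
            }
            for a in attrs
        ]
    )


def crossval_split(pullback_ids: list, k: int = 5, seed: int = 0) -> list[dict]:
    """k-fold split by pullback (never by frame).

    The ids are shuffled once and partitioned into k groups; fold i uses
    group i as test, group (i+1) mod k as validation, and the rest for
    training, so each pullback appears in test exactly once.
    """
    ids = list(pullback_ids)
    if len(ids) < k:
        raise ValueError(f"need at least k={k} pullbacks, got {len(ids)}")
    rng = np.random.default_rng(seed)
    perm = [ids[i] for i in rng.permutation(len(ids))]
    groups = [perm[i::k] for i in range(k)]
    folds = []
    for i in range(k):
        test = groups[i]
        val = groups[(i + 1) % k]
        train = [x for j, g in enumerate(groups) if j not in (i, (i + 1) % k) for x in g]
        folds.append({"train": train, "val": val, "test": test})
    return folds
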