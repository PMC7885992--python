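"""End-to-end orchestration of the two-step pipeline.

preprocess → Step 1 (3-D CNN frame detection) → 1-D morphological
cleanup → Step 2 (SegNet segmentation of lesion frames) → CRF
refinement → missing-frame interpolation → geometry restoration →
calcium quantification.  A one-step mode skips Step 1 and segments
every frame, for comparison harnesses.
"""

from __future__ import annotations

import time
from dataclasses import dataclass, field

import numpy as np
import pandas as pd

from .core import Pullback
from .crf import CrfParams, refine_volume
from .frame_cleanup import LesionIntervals, cleanup
from .frame_detector import FrameLabels, classify_frames
from .lesion_post import fill_missing
from .preprocess import ROI_DEPTH_PX, PreprocContext, align_and_crop, preprocess_pullback
from .quantify import attributes_table, confusion_from_masks, lesion_attributes, metrics
from .segmenter import ProbVolume, segment_frames


def restore_geometry(mask_aligned: np.ndarray, ctx: PreprocContext) -> np.ndarray:
    """Inverse of align_and_crop for one frame's mask.

    Each A-line is shifted right by its offset; pixels outside the
    retained ROI are zero.  Output shape is (n_alines, ctx.n_radial).
    """
    mask_aligned = np.asarray(mask_aligned)
    n_theta, roi = mask_aligned.shape
    if roi != ctx.roi_depth_px or len(ctx.shift_offset) != n_theta:
        raise ValueError("context does not match the aligned mask")
    out = np.zeros((n_theta, ctx.n_radial), dtype=mask_aligned.dtype)
    cols = ctx.shift_offset[:, None] + np.arange(roi)[None, :]
    valid = cols < ctx.n_radial
    rows = np.broadcast_to(np.arange(n_theta)[:, None], cols.shape)
    out[rows[valid], cols[valid]] = mask_aligned[valid]
    return out


@dataclass
class PipelineResult:
    frame_labels: FrameLabels | None  # raw Step-1 output (None in one-step mode)
    cleaned_labels: np.ndarray
    intervals: LesionIntervals
    prob_volume: ProbVolume | None
    masks_aligned: np.ndarray  # (n_frames, n_alines, roi)
    masks_raw: np.ndarray  # (n_frames, n_alines, n_radial)
    contexts: list[PreprocContext]
    attributes: pd.DataFrame
    metrics: dict | None
    timings: dict = field(default_factory=dict)
    replaced_frames: list[int] = field(default_factory=list)


def run_pipeline(
    pullback: Pullback,
    detector_model,
    segmenter_model,
    *,
    roi_depth_px: int = ROI_DEPTH_PX,
    crf_params: CrfParams | None = None,
    se_size: int = 5,
    one_step: bool = False,
    truth_masks: np.ndarray | None = None,
    truth_frame_labels: np.ndarray | None = None,
    catheter_radius: int | None = None,
    lumen_indices: np.ndarray | None = None,
) -> PipelineResult:
    """Run the full pipeline on a raw pullback.

    ``truth_masks`` (raw geometry) and ``truth_frame_labels`` enable the
    metrics block.  In one-step mode the detector is skipped and every
    frame is segmented.
    """
    timings: dict[str, float] = {}
    n = len(pullback)

    t0 = time.perf_counter()
    stack, contexts = preprocess_pullback(
        pullback, roi_depth_px=roi_depth_px, catheter_radius=catheter_radius,
        lumen_indices=lumen_indices,
    )
    timings["preprocess"] = time.perf_counter() - t0

    t0 = time.perf_counter()
    if one_step:
        frame_labels = None
        cleaned = np.ones(n, dtype=np.uint8)
        intervals: LesionIntervals = [(0, n - 1)]
    else:
        frame_labels = classify_frames(stack, detector_model)
        cleaned, intervals = cleanup(frame_labels.labels, se_size=se_size)
    timings["detect_frames"] = time.perf_counter() - t0

    masks_full = np.zeros(stack.shape, dtype=np.uint8)
    prob_volume = None
    replaced: list[int] = []
    t0 = time.perf_counter()
    if intervals:
        prob_volume = segment_frames(stack, intervals, segmenter_model)
        _, crf_masks = refine_volume(prob_volume.probs, crf_params)
        masks_full[prob_volume.frame_indices] = crf_masks
        masks_full, replaced = fill_missing(masks_full, intervals)
    timings["segment"] = time.perf_counter() - t0

    t0 = time.perf_counter()
    masks_raw = np.stack(
        [restore_geometry(masks_full[i], contexts[i]) for i in range(n)]
    )
    # quantify only lesions where segmentation actually found calcium
    nonempty_ints = [
        (s, e) for s, e in intervals if masks_full[s : e + 1].any()
    ]
    attrs = lesion_attributes(
        masks_full, nonempty_ints, frame_pitch_mm=pullback.frame_pitch_mm
    ) if nonempty_ints else []
    timings["quantify"] = time.perf_counter() - t0

    report = None
    if truth_masks is not None or truth_frame_labels is not None:
        report = {}
        if truth_frame_labels is not None and not one_step:
            fc = confusion_from_masks(cleaned, truth_frame_labels, granularity="frame")
            report["frame"] = metrics(fc)
        if truth_masks is not None:
            pc = confusion_from_masks(masks_raw, truth_masks, granularity="pixel")
            report["pixel"] = metrics(pc)

    return PipelineResult(
        frame_labels=frame_labels,
        cleaned_labels=cleaned,
        intervals=intervals,
        prob_volume=prob_volume,
        masks_aligned=masks_full,
        masks_raw=masks_raw,
        contexts=contexts,
        attributes=attributes_table(attrs),
        metrics=report,
        timings=timings,
        replaced_frames=replaced,
    )


def align_truth_masks(truth_masks: np.ndarray, contexts: list[PreprocContext]) -> np.ndarray:
    """Map raw-geometry truth masks into the aligned ROI via the contexts."""
    truth_masks = np.asarray(truth_masks)
    return np.stack(
        [
            align_and_crop(truth_masks[i], contexts[i])
            for i in range(truth_masks.shape[0])
        ]
    ).astype(np.uint8)
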