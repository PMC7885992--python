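"""Scaled-down two-step study on synthetic pullbacks.

A desk-scale analogue of the clinical experiment: six phantom pullbacks
(60 frames × 64 A-lines × 64 radial samples, ROI depth 32 px) with
randomly placed calcified lesions at roughly 25% frame prevalence.
Three pullbacks train the networks, one validates, two are held out for
testing.  The detector uses small filter counts ([6, 12]) and the
segmenter two encoder stages ([[8, 8], [16, 16]]); everything else —
the 3×5×5 detector kernel, the 2×2(×1) pooling, the unpooling decoder,
the Tversky loss, the Adam/step-LR/early-stopping schedule — matches
the full-scale configuration.

``run_two_step_study`` trains the two-step system, evaluates frame- and
pixel-level metrics on the held-out pullbacks, and optionally trains
the one-step comparator (SegNet on all frames, no Step 1) on the same
seeds.
"""

from __future__ import annotations

import numpy as np

from .core import Pullback
from .crf import CrfParams
from .frame_detector import DetectorConfig, classify_frames, train_detector
from .nn import TrainConfig
from .phantom import Lesion, PhantomSpec, PhantomTruth, generate_pullback
from .pipeline import align_truth_masks, run_pipeline
from .preprocess import preprocess_pullback
from .quantify import confusion_from_masks, metrics
from .segmenter import SegmenterConfig, train_segmenter

STUDY_N_PULLBACKS = 6
STUDY_N_FRAMES = 60
STUDY_N_ALINES = 64
STUDY_N_RADIAL = 64
STUDY_ROI_DEPTH = 32

DETECTOR_FILTERS = [6, 12]
SEGMENTER_STAGES = [[8, 8], [16, 16]]


def random_study_spec(seed: int, n_frames: int = STUDY_N_FRAMES,
                      n_alines: int = STUDY_N_ALINES,
                      n_radial: int = STUDY_N_RADIAL) -> PhantomSpec:
    """One random phantom spec: 1–2 lesions, ≥8 frames long, ≥8 frames apart."""
    rng = np.random.default_rng(seed)
    n_lesions = int(rng.integers(1, 3))
    lesions: list[Lesion] = []
    cursor = int(rng.integers(2, 10))
    for _ in range(n_lesions):
        length = int(rng.integers(8, 19))
        if cursor + length >= n_frames - 2:
            break
        lesions.append(
            Lesion(
                start_frame=cursor,
                end_frame=cursor + length - 1,
                center_aline=int(rng.integers(0, n_alines)),
                angular_halfwidth_alines=int(rng.integers(6, 13)),
                depth_px=int(rng.integers(2, 7)),
                thickness_px=int(rng.integers(6, 13)),
            )
        )
        cursor += length + int(rng.integers(8, 16))
    return PhantomSpec(
        n_frames=n_frames,
        n_alines=n_alines,
        n_radial=n_radial,
        lesion_list=lesions,
        guidewire_center_aline=int(rng.integers(0, n_alines)),
        guidewire_width_alines=6,
        seed=int(rng.integers(0, 2**31 - 1)),
    )


def study_pullbacks(seed: int, n: int = STUDY_N_PULLBACKS):
    """Generate and preprocess the study pullbacks.

    Returns a list of dicts with keys pullback, truth, stack, contexts,
    aligned_masks.
    """
    ss = np.random.SeedSequence(seed)
    out = []
    for child in ss.spawn(n):
        sub = int(child.generate_state(1)[0] % (2**31))
        spec = random_study_spec(sub)
        pullback, truth = generate_pullback(spec)
        stack, contexts = preprocess_pullback(pullback, roi_depth_px=STUDY_ROI_DEPTH)
        out.append(
            {
                "spec": spec,
                "pullback": pullback,
                "truth": truth,
                "stack": stack,
                "contexts": contexts,
                "aligned_masks": align_truth_masks(truth.masks, contexts),
            }
        )
    return out


#: circular θ rotations applied to the training pullbacks — a rotation of
#: the catheter is physically equivalent, so this is an exact invariance
STUDY_ROLLS = (0, 21, 43)


def _rolled(stack: np.ndarray, shift: int) -> np.ndarray:
    return np.roll(stack, shift, axis=1)


def train_study_models(data, seed: int, loss: str = "tversky",
                       max_epochs: int = 25, one_step: bool = False):
    """Train detector (unless one_step) and segmenter on data[0:3]/data[3].

    Training pullbacks are augmented with circular θ rotations
    (:data:`STUDY_ROLLS`), and the stepped LR schedule is stretched
    (drop every 8 epochs) because a phantom epoch has two orders of
    magnitude fewer minibatch updates than a clinical-scale epoch; with
    the full-scale drop period the optimization would be frozen long
    before convergence.
    """
    tcfg = TrainConfig(drop_period=8, max_epochs=max_epochs, patience=6,
                       batch_size=8, seed=seed)
    train, val = data[:3], data[3]

    detector = None
    det_history = None
    if not one_step:
        dcfg = DetectorConfig(conv_filters=list(DETECTOR_FILTERS), fc1_units=32,
                              dropout_rate=0.25, seed=seed)
        detector, det_history = train_detector(
            [_rolled(d["stack"], r) for r in STUDY_ROLLS for d in train],
            [d["truth"].frame_labels for _ in STUDY_ROLLS for d in train],
            [val["stack"]],
            [val["truth"].frame_labels],
            dcfg,
            tcfg,
        )

    scfg = SegmenterConfig(
        encoder_stages=[list(s) for s in SEGMENTER_STAGES], loss=loss, seed=seed
    )
    if one_step:
        X = np.concatenate(
            [_rolled(d["stack"], r) for r in STUDY_ROLLS for d in train]
        )
        y = np.concatenate(
            [_rolled(d["aligned_masks"], r) for r in STUDY_ROLLS for d in train]
        )
        Xv, yv = val["stack"], val["aligned_masks"]
    else:
        keep = [d["truth"].frame_labels.astype(bool) for d in train]
        X = np.concatenate(
            [_rolled(d["stack"][k], r) for r in STUDY_ROLLS
             for d, k in zip(train, keep)]
        )
        y = np.concatenate(
            [_rolled(d["aligned_masks"][k], r) for r in STUDY_ROLLS
             for d, k in zip(train, keep)]
        )
        vk = val["truth"].frame_labels.astype(bool)
        Xv, yv = val["stack"][vk], val["aligned_masks"][vk]
    segmenter, seg_history = train_segmenter(
        X, y, Xv, yv, scfg, tcfg, require_positive=not one_step
    )
    return {
        "detector": detector,
        "segmenter": segmenter,
        "det_history": det_history,
        "seg_history": seg_history,
    }


def evaluate_study(data, models, one_step: bool = False) -> dict:
    """Held-out evaluation (data[4:]) of frame- and pixel-level metrics."""
    test = data[4:]
    frame_pred, frame_true = [], []
    pixel_pred, pixel_true = [], []
    for d in test:
        result = run_pipeline(
            d["pullback"],
            models["detector"],
            models["segmenter"],
            roi_depth_px=STUDY_ROI_DEPTH,
            crf_params=CrfParams(),
            one_step=one_step,
        )
        frame_pred.append(result.cleaned_labels)
        frame_true.append(d["truth"].frame_labels)
        pixel_pred.append(result.masks_raw)
        pixel_true.append(d["truth"].masks)
    out = {}
    if not one_step:
        fc = confusion_from_masks(
            np.concatenate(frame_pred), np.concatenate(frame_true), "frame"
        )
        out["frame"] = metrics(fc)
    pc = confusion_from_masks(
        np.concatenate(pixel_pred), np.concatenate(pixel_true), "pixel"
    )
    out["pixel"] = metrics(pc)
    return out


def run_two_step_study(seed: int, with_one_step: bool = True,
                       loss: str = "tversky", max_epochs: int = 25) -> dict:
    """Full scaled-down study: train, evaluate, optionally compare modes."""
    data = study_pullbacks(seed)
    models = train_study_models(data, seed, loss=loss, max_epochs=max_epochs)
    results = {"two_step": evaluate_study(data, models)}
    if with_one_step:
        one = train_study_models(data, seed, loss=loss, max_epochs=max_epochs,
                                 one_step=True)
        one["detector"] = None
        results["one_step"] = evaluate_study(data, one, one_step=True)
    results["n_test_frames"] = sum(len(d["pullback"]) for d in data[4:])
    return results
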