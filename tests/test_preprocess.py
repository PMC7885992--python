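"""Guidewire detection, lumen tracking, alignment geometry, despeckling."""

import dataclasses

import numpy as np
import pytest

from octplaque.core import PolarFrame
from octplaque.phantom import Lesion, PhantomSpec, generate_pullback, guidewire_alines
from octplaque.preprocess import (
    NoLumenError,
    PreprocContext,
    align_and_crop,
    detect_guidewire,
    detect_lumen,
    load_contexts,
    preprocess_pullback,
    save_contexts,
    smooth,
)


def synthetic_frame(n_alines=64, n_radial=64, lumen=20, gw=None):
    """Step-edge frame: dark inside `lumen`, bright beyond, optional shadow."""
    img = np.zeros((n_alines, n_radial))
    if np.isscalar(lumen):
        lumen = np.full(n_alines, lumen, dtype=int)
    for a in range(n_alines):
        img[a, lumen[a]:] = 1000.0
    if gw is not None:
        img[guidewire_alines(gw, n_alines), 6:] = 0.0
    return PolarFrame(img)


# ---------------------------------------------------------------------------
# guidewire

def test_guidewire_wedge_found_within_tolerance(small_phantom):
    pb, truth = small_phantom
    interval = detect_guidewire(pb.frames[0])
    assert interval is not None
    s_true, e_true = truth.guidewire_interval
    assert abs(interval[0] - s_true) <= 2
    assert abs(interval[1] - e_true) <= 2


def test_no_shadow_in_uniform_frame():
    frame = PolarFrame(np.full((64, 64), 500.0))
    assert detect_guidewire(frame) is None


def test_wraparound_shadow_single_interval():
    frame = synthetic_frame(gw=(60, 3))
    interval = detect_guidewire(frame)
    assert interval is not None
    start, end = interval
    assert end < start  # wraps through θ = 0
    assert abs(start - 60) <= 2 and abs(end - 3) <= 2


# ---------------------------------------------------------------------------
# lumen

def test_constant_lumen_radius_detected_exactly():
    frame = synthetic_frame(lumen=23)
    assert np.array_equal(detect_lumen(frame), np.full(64, 23))


def test_phantom_lumen_within_two_pixels(small_phantom):
    pb, truth = small_phantom
    for f in (0, 10):
        gw = detect_guidewire(pb.frames[f])
        lum = detect_lumen(pb.frames[f], guidewire=gw)
        non_gw = np.ones(64, dtype=bool)
        non_gw[guidewire_alines(truth.guidewire_interval, 64)] = False
        err = np.abs(lum - truth.lumen_index[f])[non_gw]
        assert (err <= 2).mean() >= 0.95


def test_continuity_constraint_inactive_on_smooth_frames():
    """When the per-A-line gradient argmax is already a smooth path, the
    constrained DP result equals the unconstrained brute force."""
    lum = (24 + 4 * np.sin(2 * np.pi * np.arange(64) / 64)).astype(int)
    frame = synthetic_frame(lumen=lum)
    detected = detect_lumen(frame)
    # brute-force per-A-line gradient argmax (same light radial smoothing)
    from scipy.ndimage import gaussian_filter1d

    sm = gaussian_filter1d(frame.intensity.astype(float), 1.0, axis=1)
    grad = np.zeros_like(sm)
    grad[:, 1:] = sm[:, 1:] - sm[:, :-1]
    grad[:, :5] = -np.inf
    brute = grad.argmax(axis=1)
    assert np.array_equal(detected, brute)


def test_all_dark_frame_raises():
    with pytest.raises(NoLumenError):
        detect_lumen(PolarFrame(np.zeros((32, 32))))


def test_external_lumen_bypass():
    frame = synthetic_frame(lumen=23)
    ext = np.full(64, 11)
    assert np.array_equal(detect_lumen(frame, lumen_index=ext), ext)


# ---------------------------------------------------------------------------
# alignment and crop

def _ctx(lumen, n_radial=968, roi=200, gw=None):
    lumen = np.asarray(lumen, dtype=int)
    return PreprocContext(
        lumen_index=lumen, shift_offset=lumen.copy(), guidewire_interval=gw,
        roi_depth_px=roi, n_radial=n_radial,
    )


def test_full_size_frame_crops_968_to_200(rng):
    img = rng.random((448, 968))
    ctx = _ctx(rng.integers(100, 300, size=448))
    out = align_and_crop(img, ctx)
    assert out.shape == (448, 200)


def test_zero_shift_is_identity_on_roi(rng):
    img = rng.random((64, 300)).astype(np.float32)
    out = align_and_crop(img, _ctx(np.zeros(64), n_radial=300))
    assert np.allclose(out, img[:, :200])


def test_alignment_idempotent_on_aligned_frame(rng):
    img = rng.random((64, 200)).astype(np.float32)
    out = align_and_crop(img, _ctx(np.zeros(64), n_radial=200))
    assert np.allclose(out, img)


def test_shift_inversion_recovers_raw_positions(rng):
    """Every retained pixel maps back to its raw coordinates via the ctx."""
    img = rng.random((32, 400))
    lumen = rng.integers(50, 150, size=32)
    ctx = _ctx(lumen, n_radial=400)
    out = align_and_crop(img, ctx)
    for a in range(32):
        for r in (0, 57, 199):
            raw_col = lumen[a] + r
            if raw_col < 400:
                assert out[a, r] == img[a, raw_col]


def test_invalid_roi_rejected(rng):
    with pytest.raises(ValueError):
        align_and_crop(rng.random((8, 16)), _ctx(np.zeros(8), n_radial=16, roi=0))


# ---------------------------------------------------------------------------
# smoothing

def test_smooth_preserves_constant():
    img = np.full((32, 32), 7.5, dtype=np.float32)
    assert np.allclose(smooth(img), img)


def test_smooth_impulse_is_truncated_gaussian_kernel():
    img = np.zeros((31, 31), dtype=np.float32)
    img[15, 15] = 1.0
    out = smooth(img)
    # separable 7-tap σ=1 kernel, normalized
    x = np.arange(-3, 4)
    k = np.exp(-(x**2) / 2.0)
    k /= k.sum()
    expected = np.outer(k, k)
    assert np.allclose(out[12:19, 12:19], expected, atol=1e-6)
    assert out[15, 15] == pytest.approx(k[3] ** 2, abs=1e-6)
    assert np.allclose(out.sum(), 1.0, atol=1e-6)


def test_smooth_reduces_speckle_variance(small_phantom):
    pb, _ = small_phantom
    img = pb.frames[0].intensity.astype(np.float32)
    assert smooth(img).var() < img.var()


# ---------------------------------------------------------------------------
# pullback-level

def test_preprocess_pullback_shapes_and_contexts(small_phantom):
    pb, _ = small_phantom
    stack, ctxs = preprocess_pullback(pb, roi_depth_px=32)
    assert stack.shape == (len(pb), 64, 32)
    assert len(ctxs) == len(pb)
    assert stack.max() <= 1.0


def test_preprocess_per_frame_independence(small_phantom):
    """Permuting frames permutes the outputs identically."""
    pb, _ = small_phantom
    stack, _ = preprocess_pullback(pb, roi_depth_px=32, normalize=False)
    perm = [5, 0, 3]
    sub = dataclasses.replace(pb, frames=[pb.frames[i] for i in perm])
    stack2, _ = preprocess_pullback(sub, roi_depth_px=32, normalize=False)
    assert np.allclose(stack2, stack[perm])


def test_preprocess_error_names_frame():
    spec = PhantomSpec(n_frames=3, n_alines=64, n_radial=64, seed=1)
    pb, _ = generate_pullback(spec)
    dark = dataclasses.replace(
        pb, frames=pb.frames[:2] + [PolarFrame(np.zeros((64, 64)))]
    )
    with pytest.raises(RuntimeError, match="frame 2"):
        preprocess_pullback(dark, roi_depth_px=32)


def test_roi_crop_loses_exactly_the_deep_mask_fraction():
    """The fraction of truth calcium lost by the ROI crop equals the
    fraction lying deeper than lumen + roi."""
    spec = PhantomSpec(
        n_frames=4, n_alines=64, n_radial=64,
        lesion_list=[Lesion(0, 3, 20, 10, 20, 25)],  # extends past a 32-px ROI
        seed=5,
    )
    pb, truth = generate_pullback(spec)
    from octplaque.pipeline import align_truth_masks

    stack, ctxs = preprocess_pullback(pb, roi_depth_px=32)
    aligned = align_truth_masks(truth.masks, ctxs)
    total = truth.masks.sum()
    deep = 0
    for f in range(4):
        for a in range(64):
            cols = np.flatnonzero(truth.masks[f, a])
            deep += int((cols >= ctxs[f].lumen_index[a] + 32).sum())
    assert total - aligned.sum() == deep


def test_context_json_round_trip(tmp_path, small_phantom):
    pb, _ = small_phantom
    _, ctxs = preprocess_pullback(pb, roi_depth_px=32)
    save_contexts(ctxs, tmp_path / "ctx.json")
    loaded = load_contexts(tmp_path / "ctx.json")
    assert len(loaded) == len(ctxs)
    assert np.array_equal(loaded[0].lumen_index, ctxs[0].lumen_index)
    assert loaded[0].guidewire_interval == ctxs[0].guidewire_interval
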