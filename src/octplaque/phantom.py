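"""Seeded synthetic polar IVOCT pullbacks with pixel-level calcium truth.

The generator emulates the image properties the pipeline exploits, in the
native (θ, r) polar domain:

* a bright lumen border at a per-A-line radius that varies smoothly around
  the vessel and drifts slowly along the pullback;
* tissue backscatter decaying exponentially with depth beyond the lumen;
* multiplicative gamma-distributed speckle;
* a dark wedge of A-lines shadowed by the guidewire;
* calcified lesions rendered as signal-poor regions with a sharply
  delineated (1-px bright) leading edge, persisting over consecutive
  frames — the canonical IVOCT appearance of calcium.

It is deliberately not a physical OCT simulator (no coherent wave model,
no catheter optics); it exists so that every downstream stage is
trainable and testable without external data.  All randomness flows from
``PhantomSpec.seed``; an optional ``speckle_seed`` decouples the noise
realization from the vessel/lesion geometry so that repeat "pullbacks"
of the same lesion can be rendered with independent speckle.
"""

from __future__ import annotations

import dataclasses
import hashlib
import json
from dataclasses import dataclass, field
from pathlib import Path

import numpy as np
from scipy.ndimage import gaussian_filter1d

from .core import FRAME_PITCH_MM, R_PITCH_MM, Pullback, write_stack, read_stack

#: intensity quantization: generated floats in [0, ~1.2] scaled to uint16
INTENSITY_SCALE = 50000.0


@dataclass(frozen=True)
class Lesion:
    """One calcified lesion: a contiguous run of frames with an angular arc.

    ``depth_px`` is the radial offset of the lesion's leading edge from
    the lumen boundary; ``thickness_px`` its radial extent.  The angular
    arc covers ``2 * angular_halfwidth_alines + 1`` A-lines centered on
    ``center_aline`` (circular in θ).
    """

    start_frame: int
    end_frame: int  # inclusive
    center_aline: int
    angular_halfwidth_alines: int
    depth_px: int
    thickness_px: int


@dataclass
class PhantomSpec:
    n_frames: int
    n_alines: int = 448
    n_radial: int = 968
    lesion_list: list[Lesion] = field(default_factory=list)
    guidewire_center_aline: int = 0
    guidewire_width_alines: int = 0
    speckle_scale: float = 0.5
    attenuation_per_px: float = 0.01
    calc_attenuation: float = 0.3
    lumen_radius_frac: float = 0.17
    lumen_amplitude_frac: float = 0.04
    seed: int = 0
    speckle_seed: int | None = None

    def __post_init__(self) -> None:
        self.lesion_list = [
            les if isinstance(les, Lesion) else Lesion(*les) for les in self.lesion_list
        ]
        self.validate()

    def validate(self) -> None:
        if self.n_frames < 1 or self.n_alines < 8 or self.n_radial < 16:
            raise ValueError("phantom dimensions too small")
        if self.speckle_scale <= 0:
            raise ValueError("speckle_scale must be positive")
        if self.attenuation_per_px <= 0:
            raise ValueError("attenuation_per_px must be positive")
        for les in self.lesion_list:
            if not (0 <= les.start_frame <= les.end_frame < self.n_frames):
                raise ValueError(
                    f"lesion frames [{les.start_frame}, {les.end_frame}] outside "
                    f"[0, {self.n_frames})"
                )
            if not (0 <= les.center_aline < self.n_alines):
                raise ValueError(f"lesion center A-line {les.center_aline} out of range")
            arc = 2 * les.angular_halfwidth_alines + 1
            if les.angular_halfwidth_alines < 0 or arc > self.n_alines:
                raise ValueError("lesion angular extent exceeds the frame")
            if les.thickness_px < 1:
                raise ValueError("lesion thickness_px must be >= 1")
            if les.depth_px < 0:
                raise ValueError("lesion depth_px must be >= 0")

    def to_dict(self) -> dict:
        d = dataclasses.asdict(self)
        d["lesion_list"] = [dataclasses.astuple(les) for les in self.lesion_list]
        return d

    @classmethod
    def from_dict(cls, d: dict) -> "PhantomSpec":
        d = dict(d)
        d["lesion_list"] = [Lesion(*les) for les in d.get("lesion_list", [])]
        return cls(**d)


@dataclass
class PhantomTruth:
    """Ground truth accompanying a generated pullback."""

    frame_labels: np.ndarray  # uint8, (n_frames,)
    masks: np.ndarray  # uint8, (n_frames, n_alines, n_radial)
    lumen_index: np.ndarray  # int, (n_frames, n_alines)
    guidewire_interval: tuple[int, int] | None  # inclusive A-line range, circular


def guidewire_alines(interval: tuple[int, int] | None, n_alines: int) -> np.ndarray:
    """A-line indices covered by a circular inclusive interval."""
    if interval is None:
        return np.array([], dtype=int)
    start, end = interval
    if start <= end:
        return np.arange(start, end + 1)
    return np.concatenate([np.arange(start, n_alines), np.arange(0, end + 1)])


def catheter_radius_px(n_radial: int) -> int:
    """Radius of the catheter dead zone: 5% of the radial extent."""
    return max(4, int(round(0.05 * n_radial)))


def _lumen_geometry(spec: PhantomSpec, rng: np.random.Generator) -> np.ndarray:
    """Smooth per-frame per-A-line lumen radius (int indices)."""
    cat = catheter_radius_px(spec.n_radial)
    r0 = spec.lumen_radius_frac * spec.n_radial
    amp = spec.lumen_amplitude_frac * spec.n_radial
    phase0 = rng.uniform(0, 2 * np.pi)
    drift = rng.uniform(-0.08, 0.08)
    theta = 2 * np.pi * np.arange(spec.n_alines) / spec.n_alines
    lumen = np.empty((spec.n_frames, spec.n_alines))
    for f in range(spec.n_frames):
        base = r0 + amp * np.sin(theta + phase0 + drift * f)
        wobble = gaussian_filter1d(
            rng.normal(0.0, 0.6, spec.n_alines), sigma=max(2, spec.n_alines // 32),
            mode="wrap",
        )
        lumen[f] = base + wobble
    lo = cat + 3
    hi = spec.n_radial - 8
    return np.clip(np.rint(lumen), lo, hi).astype(int)


def generate_pullback(spec: PhantomSpec) -> tuple[Pullback, PhantomTruth]:
    """Render a seeded synthetic pullback and its pixel-level truth.

    Deterministic: a fixed spec (including seeds) yields byte-identical
    uint16 intensity stacks and uint8 masks.
    """
    spec.validate()
    geom_rng = np.random.default_rng(spec.seed)
    speckle_seed = (
        spec.speckle_seed
        if spec.speckle_seed is not None
        else int(np.random.SeedSequence(spec.seed).spawn(1)[0].generate_state(1)[0] % (2**31))
    )
    noise_rng = np.random.default_rng(speckle_seed)

    nf, na, nr = spec.n_frames, spec.n_alines, spec.n_radial
    cat = catheter_radius_px(nr)
    lumen = _lumen_geometry(spec, geom_rng)

    if spec.guidewire_width_alines > 0:
        half = spec.guidewire_width_alines // 2
        start = (spec.guidewire_center_aline - half) % na
        end = (start + spec.guidewire_width_alines - 1) % na
        gw_interval: tuple[int, int] | None = (start, end)
        gw = guidewire_alines(gw_interval, na)
    else:
        gw_interval = None
        gw = np.array([], dtype=int)

    r = np.arange(nr)[None, :]  # (1, nr)
    stack = np.empty((nf, na, nr), dtype=np.float64)
    masks = np.zeros((nf, na, nr), dtype=np.uint8)
    shape = 1.0 / spec.speckle_scale**2  # gamma speckle, mean 1, std = speckle_scale

    for f in range(nf):
        lum = lumen[f][:, None]  # (na, 1)
        depth = r - lum
        tissue = depth >= 0
        img = np.full((na, nr), 0.02)
        img += noise_rng.normal(0.0, 0.004, size=(na, nr))
        base = 0.85 * np.exp(-spec.attenuation_per_px * np.clip(depth, 0, None))

        # per-lesion attenuation of the tissue backscatter (signal-poor core)
        atten = np.ones((na, nr))
        edge = np.zeros((na, nr), dtype=bool)
        for les in spec.lesion_list:
            if not (les.start_frame <= f <= les.end_frame):
                continue
            arc = (
                np.arange(les.center_aline - les.angular_halfwidth_alines,
                          les.center_aline + les.angular_halfwidth_alines + 1) % na
            )
            lead = lumen[f][arc] + les.depth_px
            for a, le in zip(arc, lead):
                r0, r1 = le, min(le + les.thickness_px, nr)
                if r0 >= nr:
                    continue
                atten[a, r0:r1] = spec.calc_attenuation
                edge[a, r0] = True
                masks[f, a, r0:r1] = 1

        speckle = noise_rng.gamma(shape, 1.0 / shape, size=(na, nr))
        img = np.where(tissue, base * atten * speckle + 0.01, img)
        # sharply delineated leading edge: 1-px bright border
        img[edge] = 0.95
        # bright lumen border (2 px)
        border = (depth >= 0) & (depth < 2)
        img[border] = 1.0 + noise_rng.normal(0.0, 0.02, size=(na, nr))[border]
        # catheter dead zone
        img[:, :cat] = 0.015

        if gw.size:
            img[gw, cat + 2:] = 0.02 + np.abs(
                noise_rng.normal(0.0, 0.003, size=(gw.size, nr - cat - 2))
            )
            masks[f, gw, :] = 0

        stack[f] = img

    stack = np.clip(stack, 0.0, 1.25)
    stack_u16 = np.rint(stack * INTENSITY_SCALE).astype(np.uint16)
    frame_labels = masks.any(axis=(1, 2)).astype(np.uint8)
    truth = PhantomTruth(
        frame_labels=frame_labels,
        masks=masks,
        lumen_index=lumen,
        guidewire_interval=gw_interval,
    )
    assert np.array_equal(frame_labels, masks.any(axis=(1, 2)).astype(np.uint8))
    pb = Pullback.from_stack(stack_u16, frame_pitch_mm=FRAME_PITCH_MM, r_pitch_mm=R_PITCH_MM)
    return pb, truth


# ---------------------------------------------------------------------------
# fixture I/O

class FixtureIntegrityError(RuntimeError):
    """Raised when a stored fixture fails its checksum."""


def _sha256(path: Path) -> str:
    return hashlib.sha256(path.read_bytes()).hexdigest()


def write_fixture(pullback: Pullback, truth: PhantomTruth, directory,
                  spec: PhantomSpec | None = None) -> Path:
    """Write images + masks as multi-frame TIFF with a JSON manifest.

    Returns the manifest path.  The manifest echoes the generating spec
    (if given), the seed, the truth arrays that are not image-shaped,
    and SHA-256 checksums of both TIFFs.
    """
    directory = Path(directory)
    directory.mkdir(parents=True, exist_ok=True)
    img_path = directory / "images.tif"
    mask_path = directory / "masks.tif"
    write_stack(img_path, pullback.stack().astype(np.uint16))
    write_stack(mask_path, truth.masks.astype(np.uint8))
    manifest = {
        "spec": spec.to_dict() if spec is not None else None,
        "seed": spec.seed if spec is not None else None,
        "frame_pitch_mm": pullback.frame_pitch_mm,
        "r_pitch_mm": pullback.frames[0].r_pitch_mm,
        "frame_labels": truth.frame_labels.tolist(),
        "lumen_index": truth.lumen_index.tolist(),
        "guidewire_interval": truth.guidewire_interval,
        "checksums": {"images.tif": _sha256(img_path), "masks.tif": _sha256(mask_path)},
    }
    manifest_path = directory / "manifest.json"
    manifest_path.write_text(json.dumps(manifest))
    return manifest_path


def read_fixture(directory) -> tuple[Pullback, PhantomTruth, dict]:
    """Load a fixture written by :func:`write_fixture`, verifying checksums."""
    directory = Path(directory)
    manifest = json.loads((directory / "manifest.json").read_text())
    for name, digest in manifest["checksums"].items():
        actual = _sha256(directory / name)
        if actual != digest:
            raise FixtureIntegrityError(
                f"checksum mismatch for {directory / name}: "
                f"expected {digest[:12]}…, got {actual[:12]}…"
            )
    images = read_stack(directory / "images.tif")
    masks = read_stack(directory / "masks.tif")
    gw = manifest["guidewire_interval"]
    truth = PhantomTruth(
        frame_labels=np.asarray(manifest["frame_labels"], dtype=np.uint8),
        masks=masks.astype(np.uint8),
        lumen_index=np.asarray(manifest["lumen_index"], dtype=int),
        guidewire_interval=tuple(gw) if gw is not None else None,
    )
    pb = Pullback.from_stack(
        images,
        frame_pitch_mm=manifest.get("frame_pitch_mm", FRAME_PITCH_MM),
        r_pitch_mm=manifest.get("r_pitch_mm", R_PITCH_MM),
    )
    return pb, truth, manifest
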