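"""Core containers for polar-domain IVOCT data.

A polar frame is the native acquisition geometry of intravascular OCT:
rows are A-lines (the angular coordinate θ) and columns are radial
samples (depth r along each A-line).  A pullback is the ordered stack of
frames acquired while the catheter is withdrawn through the vessel.
"""

from __future__ import annotations

from dataclasses import dataclass, field

import numpy as np
import tifffile

#: radial pixel pitch: 200 px span 1 mm of depth
R_PITCH_MM = 0.005
#: longitudinal frame pitch: 36 mm/s pullback at 180 frames/s
FRAME_PITCH_MM = 0.2


@dataclass
class PolarFrame:
    """One cross-sectional frame in the (θ, r) domain.

    ``intensity`` has shape ``(n_alines, n_radial)``; row ``i`` is the
    A-line acquired at angle ``i * 360 / n_alines`` degrees.
    """

    intensity: np.ndarray
    r_pitch_mm: float = R_PITCH_MM

    def __post_init__(self) -> None:
        self.intensity = np.asarray(self.intensity)
        if self.intensity.ndim != 2:
            raise ValueError("frame intensity must be 2-D (n_alines, n_radial)")
        if np.any(self.intensity < 0):
            raise ValueError("intensities must be non-negative")

    @property
    def n_alines(self) -> int:
        return self.intensity.shape[0]

    @property
    def n_radial(self) -> int:
        return self.intensity.shape[1]


@dataclass
class Pullback:
    """Ordered sequence of polar frames sharing one geometry."""

    frames: list[PolarFrame] = field(default_factory=list)
    frame_pitch_mm: float = FRAME_PITCH_MM

    def __post_init__(self) -> None:
        if self.frame_pitch_mm <= 0:
            raise ValueError("frame_pitch_mm must be positive")
        shapes = {f.intensity.shape for f in self.frames}
        if len(shapes) > 1:
            raise ValueError(f"frames disagree on shape: {sorted(shapes)}")

    def __len__(self) -> int:
        return len(self.frames)

    @property
    def n_alines(self) -> int:
        return self.frames[0].n_alines

    @property
    def n_radial(self) -> int:
        return self.frames[0].n_radial

    def stack(self) -> np.ndarray:
        """Return the pullback as an array (n_frames, n_alines, n_radial)."""
        return np.stack([f.intensity for f in self.frames])

    @classmethod
    def from_stack(
        cls,
        stack: np.ndarray,
        frame_pitch_mm: float = FRAME_PITCH_MM,
        r_pitch_mm: float = R_PITCH_MM,
    ) -> "Pullback":
        stack = np.asarray(stack)
        if stack.ndim != 3:
            raise ValueError("stack must be 3-D (n_frames, n_alines, n_radial)")
        frames = [PolarFrame(fr, r_pitch_mm=r_pitch_mm) for fr in stack]
        return cls(frames=frames, frame_pitch_mm=frame_pitch_mm)


def write_stack(path, stack: np.ndarray) -> None:
    """Write a 3-D array as a multi-frame grayscale TIFF."""
    stack = np.asarray(stack)
    if stack.ndim != 3:
        raise ValueError("expected a 3-D stack")
    tifffile.imwrite(str(path), stack, photometric="minisblack")


def read_stack(path) -> np.ndarray:
    """Read a multi-frame TIFF as a 3-D array (frames first)."""
    arr = tifffile.imread(str(path))
    if arr.ndim == 2:
        arr = arr[None]
    return arr
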