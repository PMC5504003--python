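"""The video-stack container shared by the simulator and the
measurement chain."""

from __future__ import annotations

from dataclasses import dataclass

import numpy as np

__all__ = ["VideoStack"]


@dataclass(frozen=True)
class VideoStack:
    """A grayscale video stack with its acquisition metadata.

    Attributes
    ----------
    frames
        Array of shape ``(n_frames, rows, cols)`` with values in [0, 1].
    fps
        Acquisition rate in frames per second.
    field_deg
        Field size as ``(height_deg, width_deg)``.
    axial_length_mm
        Axial length of the imaged eye, used for angular-to-metric
        conversion downstream.
    """

    frames: np.ndarray
    fps: float
    field_deg: tuple[float, float]
    axial_length_mm: float

    def __post_init__(self) -> None:
        frames = np.asarray(self.frames)
        if frames.ndim != 3 or frames.shape[0] < 2:
            raise ValueError("stack must be 3-D with at least 2 frames")
        if not np.all(np.isfinite(frames)):
            raise ValueError("stack contains non-finite intensities")
        if self.fps <= 0:
            raise ValueError("fps must be positive")
        object.__setattr__(self, "frames", frames)

    @property
    def n_frames(self) -> int:
        return self.frames.shape[0]

    @property
    def frame_shape(self) -> tuple[int, int]:
        return self.frames.shape[1:]

    @property
    def px_per_deg(self) -> float:
        """Sampling density inferred from frame height and field height."""
        return self.frames.shape[1] / self.field_deg[0]

    @property
    def um_per_px(self) -> float:
        """Metric pixel pitch on the retina, micrometres per pixel."""
        from capiflow.velocimetry.scaling import deg_to_mm  # avoid import cycle

        return float(deg_to_mm(1.0 / self.px_per_deg, self.axial_length_mm)) * 1000.0
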