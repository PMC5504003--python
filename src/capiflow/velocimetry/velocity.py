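"""Velocity estimation from fitted band slopes, and the end-to-end
video -> velocity convenience pipeline."""

from __future__ import annotations

from dataclasses import dataclass

import numpy as np

from capiflow.stack import VideoStack
from capiflow.velocimetry.bands import BandTrace, detect_bands
from capiflow.velocimetry.kymograph import Kymograph, build_kymograph
from capiflow.velocimetry.motion import motion_contrast, register_stack
from capiflow.velocimetry.trace import trace_vessel

__all__ = ["VelocityEstimate", "NoMeasurement", "estimate_velocity", "measure_video"]


class NoMeasurement(RuntimeError):
    """Raised when no band could be measured; distinct from zero velocity."""


@dataclass(frozen=True)
class VelocityEstimate:
    """Blood-flow velocity of one video.

    ``velocity_mm_s`` is the unweighted mean of the per-band speeds (the
    reciprocal of each band's slope, scaled by the frame interval);
    ``sd_mm_s`` is their dispersion (NaN for a single band).
    """

    velocity_mm_s: float
    per_band_mm_s: tuple[float, ...]
    sd_mm_s: float
    n_bands: int

    def __post_init__(self) -> None:
        if self.n_bands >= 1 and not self.velocity_mm_s > 0:
            raise ValueError("velocity must be positive when bands exist")

    def to_dict(self) -> dict:
        return {
            "velocity_mm_s": self.velocity_mm_s,
            "per_band_mm_s": list(self.per_band_mm_s),
            "sd_mm_s": self.sd_mm_s,
            "n_bands": self.n_bands,
        }


def estimate_velocity(bands: BandTrace, kymo: Kymograph) -> VelocityEstimate:
    """Convert band slopes to a velocity in mm/s.

    Each band's speed is the reciprocal of its slope (frames per µm)
    divided by the frame interval; the video's velocity is the
    unweighted mean over bands.  Only the magnitude is reported.

    Raises
    ------
    NoMeasurement
        If the trace contains no band.
    """
    if bands.n_bands == 0:
        raise NoMeasurement("no band detected in kymograph")
    slopes = bands.slopes_frames_per_um
    per_band = np.abs(1.0 / (slopes * kymo.dt_s)) / 1000.0  # µm/s -> mm/s
    sd = float(np.std(per_band, ddof=1)) if len(per_band) > 1 else float("nan")
    return VelocityEstimate(
        velocity_mm_s=float(per_band.mean()),
        per_band_mm_s=tuple(float(v) for v in per_band),
        sd_mm_s=sd,
        n_bands=bands.n_bands,
    )


def measure_video(
    stack: VideoStack,
    seed_points: np.ndarray,
    *,
    dx_um: float | None = None,
    register: bool = True,
    detect_kwargs: dict | None = None,
) -> tuple[VelocityEstimate, Kymograph, BandTrace]:
    """Run the full measurement chain on one video.

    Registers the stack, computes the motion-contrast map, traces the
    vessel through ``seed_points``, builds the kymograph and estimates
    the velocity from the detected bands.
    """
    if register:
        frames, _ = register_stack(np.asarray(stack.frames, dtype=float))
        stack = VideoStack(
            frames=frames,
            fps=stack.fps,
            field_deg=stack.field_deg,
            axial_length_mm=stack.axial_length_mm,
        )
    pmap = motion_contrast(stack, register=False)
    path = trace_vessel(pmap, seed_points)
    kymo = build_kymograph(stack, path, dx_um=dx_um)
    bands = detect_bands(kymo, **(detect_kwargs or {}))
    estimate = estimate_velocity(bands, kymo)
    return estimate, kymo, bands
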