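"""Frame registration and motion-contrast perfusion mapping.

Perfused vessels are invisible in a single AOSLO frame focused on the
photoreceptor layer but stand out in a temporal-variation map: moving
blood components modulate the intensity of vessel pixels from frame to
frame while the photoreceptor mosaic stays static.  The motion-contrast
map used here is the per-pixel temporal standard deviation divided by
the temporal mean (plus a small epsilon), computed after rigid
registration, then normalised to [0, 1].
"""

from __future__ import annotations

from dataclasses import dataclass

import numpy as np
from scipy import ndimage
from skimage.registration import phase_cross_correlation

from capiflow.stack import VideoStack

__all__ = ["PerfusionMap", "register_stack", "motion_contrast"]

#: Minimum number of frames for a stable temporal statistic.
MIN_FRAMES = 8

#: Regulariser in the std/mean ratio.
EPSILON = 1e-3


@dataclass(frozen=True)
class PerfusionMap:
    """Motion-contrast image with the metadata needed for tracing.

    ``map`` has the same row/col dimensions as the source frames and is
    normalised to [0, 1]; higher values mean more temporal modulation,
    i.e. perfusion.
    """

    map: np.ndarray
    method: str
    px_per_deg: float
    axial_length_mm: float

    def __post_init__(self) -> None:
        m = np.asarray(self.map, dtype=float)
        if m.ndim != 2:
            raise ValueError("perfusion map must be 2-D")
        if not np.all(np.isfinite(m)):
            raise ValueError("perfusion map contains non-finite values")
        if m.min() < 0:
            raise ValueError("perfusion map must be non-negative")
        object.__setattr__(self, "map", m)

    @property
    def um_per_px(self) -> float:
        from capiflow.velocimetry.scaling import deg_to_mm

        return float(deg_to_mm(1.0 / self.px_per_deg, self.axial_length_mm)) * 1000.0


def register_stack(
    frames: np.ndarray, upsample_factor: int = 10
) -> tuple[np.ndarray, np.ndarray]:
    """Rigidly align every frame to the first by phase correlation.

    Returns the registered stack and the (n_frames, 2) array of applied
    (row, col) shifts.  Only translation is corrected; AOSLO intra-frame
    distortion is out of scope.
    """
    ref = frames[0]
    registered = np.empty_like(frames)
    registered[0] = ref
    shifts = np.zeros((len(frames), 2))
    for i in range(1, len(frames)):
        shift, _, _ = phase_cross_correlation(
            ref, frames[i], upsample_factor=upsample_factor, normalization=None
        )
        shifts[i] = shift
        registered[i] = ndimage.shift(frames[i], shift, order=1, mode="nearest")
    return registered, shifts


def motion_contrast(stack: VideoStack, register: bool = True) -> PerfusionMap:
    """Compute the motion-contrast perfusion map of a video stack.

    Pixels on perfused vessels score higher than static background; a
    temporally constant stack maps to all zeros.

    Raises
    ------
    ValueError
        If the stack has fewer than 8 frames.
    """
    if stack.n_frames < MIN_FRAMES:
        raise ValueError(
            f"motion contrast needs >= {MIN_FRAMES} frames, got {stack.n_frames}"
        )
    frames = np.asarray(stack.frames, dtype=float)
    if register:
        frames, _ = register_stack(frames)
    sd = frames.std(axis=0)
    mean = frames.mean(axis=0)
    contrast = sd / (mean + EPSILON)
    peak = contrast.max()
    if peak > 0:
        contrast = contrast / peak
    return PerfusionMap(
        map=contrast,
        method="temporal_sd_over_mean",
        px_per_deg=stack.px_per_deg,
        axial_length_mm=stack.axial_length_mm,
    )
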