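"""Spatiotemporal (kymograph) image construction.

Row f of the kymograph holds the intensities of frame f interpolated
along the vessel path at uniform metric steps, so moving blood
components trace slanted bands whose slope encodes velocity.
"""

from __future__ import annotations

from dataclasses import dataclass

import numpy as np
from scipy import ndimage

from capiflow.stack import VideoStack
from capiflow.velocimetry.trace import VesselPath

__all__ = ["Kymograph", "build_kymograph"]


@dataclass(frozen=True)
class Kymograph:
    """Spatiotemporal image of one vessel.

    ``image[f, j]`` is the intensity in frame f at arc position
    ``j * dx_um`` along the path; ``dt_s`` is the frame interval.
    """

    image: np.ndarray
    dt_s: float
    dx_um: float

    def __post_init__(self) -> None:
        img = np.asarray(self.image, dtype=float)
        if img.ndim != 2:
            raise ValueError("kymograph must be 2-D")
        if self.dt_s <= 0 or self.dx_um <= 0:
            raise ValueError("dt_s and dx_um must be positive")
        object.__setattr__(self, "image", img)

    @property
    def n_frames(self) -> int:
        return self.image.shape[0]

    @property
    def n_samples(self) -> int:
        return self.image.shape[1]


def build_kymograph(
    stack: VideoStack, path: VesselPath, dx_um: float | None = None
) -> Kymograph:
    """Resample a video stack along a vessel path into a kymograph.

    Parameters
    ----------
    dx_um
        Arc-length sampling step; defaults to the metric pixel pitch of
        the path (one sample per pixel of path length).

    Raises
    ------
    ValueError
        If any path point leaves the frame bounds.
    """
    rows, cols = stack.frame_shape
    pts = path.points
    if (
        pts[:, 0].min() < -0.5
        or pts[:, 0].max() > rows - 0.5
        or pts[:, 1].min() < -0.5
        or pts[:, 1].max() > cols - 0.5
    ):
        raise ValueError("vessel path leaves the frame bounds")

    if dx_um is None:
        dx_um = path.um_per_px
    arc = path.arc_length_um - path.arc_length_um[0]
    n_samples = max(int(np.floor(arc[-1] / dx_um)) + 1, 2)
    arc_uniform = np.arange(n_samples) * dx_um
    coords = np.column_stack(
        [np.interp(arc_uniform, arc, pts[:, j]) for j in range(2)]
    )

    image = np.empty((stack.n_frames, n_samples))
    for f in range(stack.n_frames):
        image[f] = ndimage.map_coordinates(
            stack.frames[f].astype(float), coords.T, order=1, mode="nearest"
        )
    return Kymograph(image=image, dt_s=1.0 / stack.fps, dx_um=float(dx_um))
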