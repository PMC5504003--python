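"""Sub-pixel vessel tracing on a motion-contrast perfusion map."""

from __future__ import annotations

from dataclasses import dataclass

import numpy as np
from scipy import ndimage
from skimage import graph as skgraph

from capiflow.velocimetry.motion import PerfusionMap
from capiflow.velocimetry.scaling import deg_to_mm

__all__ = ["VesselPath", "trace_vessel"]


@dataclass(frozen=True)
class VesselPath:
    """Ordered sub-pixel centreline of one unbranched vessel.

    ``points[0]`` is by convention the upstream end; ``arc_length_um``
    is the cumulative metric length, starting at zero and strictly
    increasing.
    """

    points: np.ndarray        # (n, 2) row/col
    arc_length_um: np.ndarray
    um_per_px: float

    def __post_init__(self) -> None:
        pts = np.asarray(self.points, dtype=float)
        arc = np.asarray(self.arc_length_um, dtype=float)
        if pts.ndim != 2 or pts.shape[0] < 2 or pts.shape[1] != 2:
            raise ValueError("path needs at least 2 (row, col) points")
        if len(arc) != len(pts):
            raise ValueError("arc_length_um must match points")
        if np.any(np.diff(arc) <= 0):
            raise ValueError("arc length must be strictly increasing")
        object.__setattr__(self, "points", pts)
        object.__setattr__(self, "arc_length_um", arc)

    @property
    def length_um(self) -> float:
        return float(self.arc_length_um[-1] - self.arc_length_um[0])

    def reversed(self) -> "VesselPath":
        """Same geometry with the direction convention flipped."""
        arc = self.arc_length_um
        return VesselPath(
            points=self.points[::-1].copy(),
            arc_length_um=(arc[-1] - arc[::-1]).copy(),
            um_per_px=self.um_per_px,
        )


def _refine_normal(
    smoothed: np.ndarray, pts: np.ndarray, half_width: float, step: float = 0.25
) -> np.ndarray:
    """Shift each point to the local ridge centroid along its normal."""
    tangents = np.gradient(pts, axis=0)
    norms = np.linalg.norm(tangents, axis=1, keepdims=True)
    norms[norms == 0] = 1.0
    tangents /= norms
    normals = np.column_stack([-tangents[:, 1], tangents[:, 0]])
    offsets = np.arange(-half_width, half_width + step / 2, step)
    sample_pts = pts[:, None, :] + offsets[None, :, None] * normals[:, None, :]
    vals = ndimage.map_coordinates(
        smoothed, sample_pts.reshape(-1, 2).T, order=1, mode="nearest"
    ).reshape(len(pts), len(offsets))
    vals = vals - vals.min(axis=1, keepdims=True)
    mass = vals.sum(axis=1)
    mass[mass == 0] = 1.0
    shift = (vals * offsets[None, :]).sum(axis=1) / mass
    return pts + shift[:, None] * normals


def trace_vessel(
    pmap: PerfusionMap,
    seed_points: np.ndarray,
    axial_length_mm: float | None = None,
    *,
    seed_threshold: float = 0.2,
    smooth_sigma_px: float = 1.5,
    resample_step_px: float = 1.0,
) -> VesselPath:
    """Trace the vessel ridge through two or more seed points.

    A minimum-cost geodesic through the inverted (smoothed) perfusion
    map connects consecutive seeds; the pixel path is then refined to
    sub-pixel precision by intensity centroids along local normals,
    lightly smoothed, and resampled at a uniform pixel step.  Arc length
    is converted to micrometres with the axial-length-based scaling.

    Raises
    ------
    ValueError
        If fewer than 2 distinct seeds are given, a seed lies outside
        the map, or a seed sits on background (map value below
        ``seed_threshold`` times the map maximum).
    """
    seeds = np.atleast_2d(np.asarray(seed_points, dtype=float))
    if seeds.shape[0] < 2 or seeds.shape[1] != 2:
        raise ValueError("need at least 2 (row, col) seed points")
    if any(
        np.allclose(seeds[i], seeds[i + 1]) for i in range(len(seeds) - 1)
    ):
        raise ValueError("consecutive seed points are identical")

    m = pmap.map
    rows, cols = m.shape
    if np.any(seeds < -0.5) or np.any(seeds[:, 0] > rows - 0.5) or np.any(
        seeds[:, 1] > cols - 0.5
    ):
        raise ValueError("seed point outside the map")

    smoothed = ndimage.gaussian_filter(m, smooth_sigma_px)
    thr = seed_threshold * smoothed.max()
    seed_idx = np.round(seeds).astype(int)
    seed_idx[:, 0] = np.clip(seed_idx[:, 0], 0, rows - 1)
    seed_idx[:, 1] = np.clip(seed_idx[:, 1], 0, cols - 1)
    for r, c in seed_idx:
        if smoothed[r, c] < thr:
            raise ValueError(
                f"seed ({r}, {c}) lies on background "
                f"(map value {smoothed[r, c]:.3g} < threshold {thr:.3g})"
            )

    cost = 1.0 / (smoothed + 1e-3)
    path_px: list[tuple[int, int]] = []
    for a, b in zip(seed_idx[:-1], seed_idx[1:]):
        segment, _ = skgraph.route_through_array(
            cost, tuple(a), tuple(b), fully_connected=True, geometric=True
        )
        if path_px:
            segment = segment[1:]
        path_px.extend(segment)
    pts = np.asarray(path_px, dtype=float)

    pts = _refine_normal(smoothed, pts, half_width=4.0)
    if len(pts) >= 7:
        pts = np.column_stack(
            [ndimage.uniform_filter1d(pts[:, j], size=7, mode="nearest")
             for j in range(2)]
        )

    # Uniform resampling by arc length in pixels.
    seg = np.linalg.norm(np.diff(pts, axis=0), axis=1)
    keep = np.concatenate([[True], seg > 1e-9])
    pts = pts[keep]
    arc_px = np.concatenate(
        [[0.0], np.cumsum(np.linalg.norm(np.diff(pts, axis=0), axis=1))]
    )
    n_samples = max(int(np.floor(arc_px[-1] / resample_step_px)) + 1, 2)
    arc_uniform = np.linspace(0.0, arc_px[-1], n_samples)
    pts = np.column_stack(
        [np.interp(arc_uniform, arc_px, pts[:, j]) for j in range(2)]
    )

    al = pmap.axial_length_mm if axial_length_mm is None else axial_length_mm
    um_per_px = float(deg_to_mm(1.0 / pmap.px_per_deg, al)) * 1000.0
    return VesselPath(
        points=pts,
        arc_length_um=arc_uniform * um_per_px,
        um_per_px=um_per_px,
    )
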