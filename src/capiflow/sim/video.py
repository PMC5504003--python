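"""Synthetic AOSLO capillary-video generator.

Produces multi-frame grayscale stacks of a single unbranched parafoveal
capillary in which bright leukocyte plugs, each trailed by a dark
erythrocyte aggregate, advance along the vessel centreline at a
configurable (optionally pulsatile) velocity over a static
photoreceptor-mosaic background.  Exact per-frame plug positions are
returned as ground truth so the downstream measurement chain can be
validated without real data.

Conventions: pixel coordinates are (row, col), 0-based; intensities are
floats in [0, 1]; arc length runs from the upstream end of the vessel.
"""

from __future__ import annotations

from dataclasses import dataclass

import numpy as np
from scipy import interpolate, ndimage
from scipy.spatial import cKDTree

from capiflow.stack import VideoStack
from capiflow.velocimetry.scaling import deg_to_mm

__all__ = [
    "VideoSimConfig",
    "VideoStack",
    "GroundTruth",
    "default_waypoints",
    "simulate_capillary_video",
]


@dataclass(frozen=True)
class GroundTruth:
    """Exact kinematics of a simulated video.

    ``particle_positions_um[k, f]`` is the arc-length position (µm) of
    the k-th plug front at frame f; positions keep increasing after a
    plug leaves the field so they are monotone in time.
    """

    centreline_px: np.ndarray          # (n_pts, 2) row/col
    arc_length_um: np.ndarray          # (n_pts,) cumulative, starts at 0
    per_frame_velocity_mm_s: np.ndarray
    particle_positions_um: np.ndarray  # (n_particles, n_frames)
    um_per_px: float

    def __post_init__(self) -> None:
        pos = np.asarray(self.particle_positions_um)
        if pos.size and np.any(np.diff(pos, axis=1) < -1e-9):
            raise ValueError("particle positions must be monotone in time")

    @property
    def total_length_um(self) -> float:
        return float(self.arc_length_um[-1])


def default_waypoints(shape: tuple[int, int]) -> np.ndarray:
    """A gently curved left-to-right vessel through the frame centre."""
    rows, cols = shape
    c = np.linspace(0.06 * cols, 0.94 * cols, 7)
    r = rows / 2 + 0.08 * rows * np.sin(np.linspace(0.0, np.pi, 7))
    return np.column_stack([r, c])


@dataclass
class VideoSimConfig:
    """Parameters of the synthetic AOSLO acquisition.

    Defaults follow the clinical protocol: 2-second videos at 64
    frames/s over a 1.4 x 2.8 degree field, sampled so the field is
    roughly 400 x 800 px.
    """

    n_frames: int = 128
    fps: float = 64.0
    field_deg: tuple[float, float] = (1.4, 2.8)
    px_per_deg: float = 285.7
    axial_length_mm: float = 24.0
    vessel_waypoints: np.ndarray | None = None
    true_velocity_mm_s: float = 1.0
    pulsatility: float = 0.0
    cardiac_freq_hz: float = 1.2
    plug_spacing_um: float = 150.0
    plug_len_um: float = 15.0
    tail_len_um: float = 40.0
    vessel_sigma_um: float = 3.0
    plug_amp: float = 0.30
    tail_amp: float = 0.30
    static_vessel_amp: float = 0.04
    cone_spacing_um: float = 7.0
    noise_sd: float = 0.05
    jitter_px_sd: float = 0.3
    seed: int = 0

    @property
    def frame_shape(self) -> tuple[int, int]:
        return (
            int(round(self.field_deg[0] * self.px_per_deg)),
            int(round(self.field_deg[1] * self.px_per_deg)),
        )

    @property
    def um_per_px(self) -> float:
        return float(deg_to_mm(1.0 / self.px_per_deg, self.axial_length_mm)) * 1000.0

    def validate(self) -> None:
        if self.n_frames < 2:
            raise ValueError("n_frames must be >= 2")
        if self.fps <= 0:
            raise ValueError("fps must be positive")
        if self.true_velocity_mm_s <= 0:
            raise ValueError("true_velocity_mm_s must be positive")
        if not (0 <= self.pulsatility < 1):
            raise ValueError("pulsatility must lie in [0, 1)")
        if self.plug_spacing_um <= self.plug_len_um + self.tail_len_um:
            raise ValueError("plug spacing must exceed plug + tail length")
        wp = self.waypoints()
        rows, cols = self.frame_shape
        if np.any(wp[:, 0] < 0) or np.any(wp[:, 0] > rows - 1) or np.any(
            wp[:, 1] < 0
        ) or np.any(wp[:, 1] > cols - 1):
            raise ValueError("vessel waypoints outside frame bounds")
        if len(wp) < 2 or np.allclose(wp.max(axis=0), wp.min(axis=0)):
            raise ValueError("centreline has zero length")

    def waypoints(self) -> np.ndarray:
        if self.vessel_waypoints is None:
            return default_waypoints(self.frame_shape)
        wp = np.atleast_2d(np.asarray(self.vessel_waypoints, dtype=float))
        if wp.shape[0] < 2 or wp.shape[1] != 2:
            raise ValueError("vessel_waypoints must be an (n>=2, 2) array")
        return wp


def _resample_centreline(waypoints: np.ndarray, step_px: float = 0.25) -> np.ndarray:
    """Smooth interpolating curve through the waypoints at ~step_px spacing."""
    deltas = np.linalg.norm(np.diff(waypoints, axis=0), axis=1)
    if np.any(deltas == 0):
        raise ValueError("consecutive waypoints coincide")
    u = np.concatenate([[0.0], np.cumsum(deltas)])
    n_dense = max(int(np.ceil(u[-1] / step_px)), 2)
    u_dense = np.linspace(0.0, u[-1], n_dense)
    k = min(3, len(waypoints) - 1)
    pts = np.column_stack(
        [
            interpolate.make_interp_spline(u, waypoints[:, j], k=k)(u_dense)
            for j in range(2)
        ]
    )
    return pts


def _arc_length(points: np.ndarray) -> np.ndarray:
    seg = np.linalg.norm(np.diff(points, axis=0), axis=1)
    return np.concatenate([[0.0], np.cumsum(seg)])


def _smoothstep(x: np.ndarray) -> np.ndarray:
    t = np.clip(x, 0.0, 1.0)
    return t * t * (3.0 - 2.0 * t)


def _train_profile(
    behind_um: np.ndarray, plug_len: float, tail_len: float,
    plug_amp: float, tail_amp: float, shoulder_um: float = 3.0,
) -> np.ndarray:
    """Intensity modulation at a distance ``behind_um`` behind a plug front.

    Bright plateau over [0, plug_len], dark plateau over
    [plug_len, plug_len + tail_len], smooth shoulders of width
    ``shoulder_um`` between levels.
    """
    x = behind_um
    w = shoulder_um
    rise_in = _smoothstep((x + w / 2) / w)                     # enter plug at front
    fall_plug = _smoothstep((x - plug_len + w / 2) / w)        # plug -> tail
    fall_tail = _smoothstep((x - plug_len - tail_len + w / 2) / w)  # tail -> rest
    plug = rise_in - fall_plug
    tail = fall_plug - fall_tail
    return plug_amp * plug - tail_amp * tail


def _photoreceptor_background(
    shape: tuple[int, int], cone_spacing_px: float, rng: np.random.Generator
) -> np.ndarray:
    """Quasi-regular bright-spot mosaic resembling a cone photoreceptor image."""
    rows, cols = shape
    spots = np.zeros(shape)
    step = max(cone_spacing_px, 2.0)
    r_sites = np.arange(0.0, rows, step)
    c_sites = np.arange(0.0, cols, step)
    rr, cc = np.meshgrid(r_sites, c_sites, indexing="ij")
    rr = rr + rng.normal(0.0, 0.22 * step, rr.shape)
    cc = cc + rng.normal(0.0, 0.22 * step, cc.shape)
    amp = rng.uniform(0.45, 1.0, rr.shape)
    ri = np.clip(np.round(rr).astype(int), 0, rows - 1)
    ci = np.clip(np.round(cc).astype(int), 0, cols - 1)
    np.add.at(spots, (ri.ravel(), ci.ravel()), amp.ravel())
    spots = ndimage.gaussian_filter(spots, sigma=0.35 * step)
    lo, hi = spots.min(), spots.max()
    if hi > lo:
        spots = (spots - lo) / (hi - lo)
    return 0.35 + 0.3 * spots  # mean level ~0.5, moderate contrast


def simulate_capillary_video(cfg: VideoSimConfig) -> tuple[VideoStack, GroundTruth]:
    """Render a synthetic capillary video and its exact kinematics.

    Identical configs (including ``seed``) yield bit-identical output.

    Returns
    -------
    stack, truth
        The video stack and the ground-truth centreline, per-frame
        velocities and plug-front trajectories.
    """
    cfg.validate()
    rng = np.random.default_rng(cfg.seed)
    shape = cfg.frame_shape
    um_per_px = cfg.um_per_px

    centre = _resample_centreline(cfg.waypoints())
    arc_px = _arc_length(centre)
    arc_um = arc_px * um_per_px
    length_um = arc_um[-1]

    # Map every pixel near the vessel to (arc position, perpendicular distance).
    sigma_px = cfg.vessel_sigma_um / um_per_px
    reach = 4.0 * sigma_px
    r0 = max(int(np.floor(centre[:, 0].min() - reach)), 0)
    r1 = min(int(np.ceil(centre[:, 0].max() + reach)) + 1, shape[0])
    c0 = max(int(np.floor(centre[:, 1].min() - reach)), 0)
    c1 = min(int(np.ceil(centre[:, 1].max() + reach)) + 1, shape[1])
    rr, cc = np.meshgrid(np.arange(r0, r1), np.arange(c0, c1), indexing="ij")
    px = np.column_stack([rr.ravel(), cc.ravel()]).astype(float)
    dist_px, idx = cKDTree(centre).query(px, workers=-1)
    near = dist_px <= reach
    strip_rows = rr.ravel()[near]
    strip_cols = cc.ravel()[near]
    strip_arc_um = arc_um[idx[near]]
    strip_gauss = np.exp(-0.5 * (dist_px[near] / sigma_px) ** 2)

    # Per-frame velocity and cumulative displacement of the plug train.
    t = np.arange(cfg.n_frames) / cfg.fps
    v_mm_s = cfg.true_velocity_mm_s * (
        1.0 + cfg.pulsatility * np.sin(2.0 * np.pi * cfg.cardiac_freq_hz * t)
    )
    dt = 1.0 / cfg.fps
    disp_um = np.concatenate([[0.0], np.cumsum(v_mm_s[:-1] * 1000.0 * dt)])

    # Plug fronts tile the vessel at t=0 and keep advancing; enough extra
    # upstream fronts are seeded to cover the total displacement.
    n_extra = int(np.ceil(disp_um[-1] / cfg.plug_spacing_um)) + 1
    n_inside = int(np.floor(length_um / cfg.plug_spacing_um)) + 1
    k = np.arange(n_inside + n_extra)
    fronts0 = length_um - k * cfg.plug_spacing_um  # most downstream first
    positions = fronts0[:, None] + disp_um[None, :]

    background = _photoreceptor_background(
        shape, cfg.cone_spacing_um / um_per_px, rng
    )
    noise_scale = cfg.noise_sd * float(background.mean())

    frames = np.empty((cfg.n_frames,) + shape, dtype=np.float32)
    spacing = cfg.plug_spacing_um
    for f in range(cfg.n_frames):
        # Distance of each strip pixel behind the nearest plug front.
        behind = np.mod(positions[0, f] - strip_arc_um, spacing)
        profile = _train_profile(
            behind, cfg.plug_len_um, cfg.tail_len_um, cfg.plug_amp, cfg.tail_amp
        )
        frame = background.copy()
        frame[strip_rows, strip_cols] += (profile - cfg.static_vessel_amp) * strip_gauss
        if cfg.jitter_px_sd > 0:
            shift = rng.normal(0.0, cfg.jitter_px_sd, size=2)
            frame = ndimage.shift(frame, shift, order=1, mode="nearest")
        if noise_scale > 0:
            frame = frame + rng.normal(0.0, noise_scale, size=shape)
        frames[f] = np.clip(frame, 0.0, 1.0)

    stack = VideoStack(
        frames=frames,
        fps=cfg.fps,
        field_deg=cfg.field_deg,
        axial_length_mm=cfg.axial_length_mm,
    )
    truth = GroundTruth(
        centreline_px=centre,
        arc_length_um=arc_um,
        per_frame_velocity_mm_s=v_mm_s,
        particle_positions_um=positions,
        um_per_px=um_per_px,
    )
    return stack, truth
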