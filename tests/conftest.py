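import numpy as np
import pytest

from capiflow.sim.video import VideoSimConfig, simulate_capillary_video
from capiflow.stack import VideoStack
from capiflow.velocimetry.kymograph import Kymograph
from capiflow.velocimetry.motion import motion_contrast, register_stack
from capiflow.velocimetry.trace import trace_vessel


#: Reduced sampling density used throughout the suite; keeps one video
#: at ~154x308 px so the full chain runs in about a second.
TEST_PX_PER_DEG = 110.0


def small_config(**overrides) -> VideoSimConfig:
    params = dict(px_per_deg=TEST_PX_PER_DEG, true_velocity_mm_s=1.2, seed=7)
    params.update(overrides)
    return VideoSimConfig(**params)


@pytest.fixture(scope="session")
def small_video():
    """One default-noise simulated video shared across the suite."""
    return simulate_capillary_video(small_config())


@pytest.fixture(scope="session")
def registered_products(small_video):
    """Registered stack, perfusion map and traced path for the shared video."""
    stack, truth = small_video
    frames, _ = register_stack(stack.frames.astype(float))
    reg = VideoStack(
        frames=frames,
        fps=stack.fps,
        field_deg=stack.field_deg,
        axial_length_mm=stack.axial_length_mm,
    )
    pmap = motion_contrast(reg, register=False)
    c = truth.centreline_px
    seeds = np.array([c[5], c[len(c) // 2], c[-5]])
    path = trace_vessel(pmap, seeds)
    return reg, truth, pmap, path


def make_band_kymograph(
    advance_um_per_frame: float,
    *,
    n_frames: int = 64,
    n_cols: int = 250,
    dx_um: float = 2.0,
    dt_s: float = 1.0 / 64.0,
    spacing_um: float = 150.0,
    plug_len_um: float = 15.0,
    tail_len_um: float = 40.0,
    start_um: float | None = None,
) -> Kymograph:
    """Noise-free constructed kymograph with a periodic band train.

    Independent of the video simulator: the intensity at arc position s
    and frame f is a piecewise profile of the distance behind the
    nearest plug front, with fronts advancing ``advance_um_per_frame``
    per row.
    """
    s = np.arange(n_cols) * dx_um
    length = n_cols * dx_um
    start = length if start_um is None else start_um
    # Piecewise-linear profile of distance-behind-front with 2 µm
    # shoulders, so edges have sub-pixel positions.
    shoulder = 2.0
    xp = [0.0, shoulder,
          plug_len_um, plug_len_um + shoulder,
          plug_len_um + tail_len_um, plug_len_um + tail_len_um + shoulder,
          spacing_um]
    fp = [0.65, 0.8, 0.8, 0.2, 0.2, 0.5, 0.5]
    img = np.empty((n_frames, n_cols))
    for f in range(n_frames):
        behind = np.mod(start + f * advance_um_per_frame - s, spacing_um)
        img[f] = np.interp(behind, xp, fp)
    return Kymograph(image=img, dt_s=dt_s, dx_um=dx_um)
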