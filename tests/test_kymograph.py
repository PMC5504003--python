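import numpy as np
import pytest

from capiflow.stack import VideoStack
from capiflow.velocimetry.kymograph import Kymograph, build_kymograph
from capiflow.velocimetry.trace import VesselPath


def _stack_from(frames):
    return VideoStack(
        frames=frames, fps=64.0, field_deg=(1.4, 2.8), axial_length_mm=24.0
    )


def _row_path(row, col_start, col_stop, um_per_px=1.0):
    cols = np.arange(col_start, col_stop + 1, dtype=float)
    pts = np.column_stack([np.full_like(cols, float(row)), cols])
    return VesselPath(
        points=pts,
        arc_length_um=(cols - cols[0]) * um_per_px,
        um_per_px=um_per_px,
    )


def test_straight_row_path_is_identity_sampling():
    rng = np.random.default_rng(0)
    frames = rng.random((6, 20, 50))
    path = _row_path(7, 5, 44)
    kymo = build_kymograph(_stack_from(frames), path, dx_um=1.0)
    # dx equals the pixel pitch along the row: row f of the kymograph
    # is exactly row 7, cols 5..44 of frame f.
    assert kymo.image.shape == (6, 40)
    assert np.allclose(kymo.image, frames[:, 7, 5:45], atol=1e-12)


def test_row_count_equals_frame_count(registered_products):
    reg, _, _, path = registered_products
    kymo = build_kymograph(reg, path)
    assert kymo.n_frames == 128
    assert kymo.dt_s == pytest.approx(1.0 / 64.0)


def test_moving_plug_advances_at_v_dt_over_dx():
    # Noise-free simulated video: the brightest kymograph column near a
    # tracked plug front advances v*dt/dx columns per row.
    from conftest import small_config
    from capiflow.sim.video import simulate_capillary_video

    v = 1.0
    cfg = small_config(noise_sd=0.0, jitter_px_sd=0.0, true_velocity_mm_s=v,
                       n_frames=24)
    stack, truth = simulate_capillary_video(cfg)
    pts = truth.centreline_px
    path = VesselPath(
        points=pts, arc_length_um=truth.arc_length_um, um_per_px=truth.um_per_px
    )
    dx = 2.0
    kymo = build_kymograph(stack, path, dx_um=dx)
    step_cols = v * 1000.0 / cfg.fps / dx
    # Track a front that starts upstream so it stays inside the field.
    front0 = truth.particle_positions_um[3, 0]
    for f in range(0, 20, 4):
        expected = (front0 + f * v * 1000.0 / cfg.fps) / dx
        lo = int(expected) - 10
        window = kymo.image[f, lo: int(expected) + 3]
        peak = lo + np.argmax(window)
        # The plug occupies [front - plug_len, front]; its brightest
        # sample lies within that span, just behind the front.
        assert expected - cfg.plug_len_um / dx - 1 <= peak <= expected + 1
    # Consecutive-row cross-correlation of the detrended kymograph
    # should peak at the per-row advance.
    detr = kymo.image - np.median(kymo.image, axis=0, keepdims=True)
    shifts = []
    for f in range(10):
        c = np.correlate(detr[f + 1], detr[f], mode="full")
        shifts.append(np.argmax(c) - (detr.shape[1] - 1))
    assert np.mean(shifts) == pytest.approx(step_cols, abs=0.6)


def test_path_outside_frame_rejected():
    frames = np.zeros((4, 20, 30))
    path = _row_path(25, 0, 10)
    with pytest.raises(ValueError, match="bounds"):
        build_kymograph(_stack_from(frames), path)


def test_invalid_kymograph_construction():
    with pytest.raises(ValueError):
        Kymograph(image=np.zeros((4, 10)), dt_s=0.0, dx_um=1.0)
    with pytest.raises(ValueError):
        Kymograph(image=np.zeros(10), dt_s=1.0, dx_um=1.0)
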