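import numpy as np
import pytest

from capiflow.sim.video import (
    VideoSimConfig,
    default_waypoints,
    simulate_capillary_video,
)

from conftest import small_config


def test_default_protocol_metadata():
    cfg = VideoSimConfig()
    assert cfg.n_frames == 128
    assert cfg.fps == 64.0
    assert cfg.field_deg == (1.4, 2.8)
    rows, cols = cfg.frame_shape
    assert (rows, cols) == (400, 800)  # ~1.4 x 2.8 deg at the default density


def test_stack_shape_and_metadata():
    stack, _ = simulate_capillary_video(small_config(n_frames=16))
    assert stack.n_frames == 16
    assert stack.fps == 64.0
    assert stack.frames.min() >= 0.0 and stack.frames.max() <= 1.0


def test_full_length_default_frame_count(small_video):
    stack, _ = small_video
    assert stack.n_frames == 128  # 2 s at 64 frames/s


def test_noise_free_kinematics_exact():
    v = 1.7
    cfg = small_config(
        noise_sd=0.0, jitter_px_sd=0.0, pulsatility=0.0,
        true_velocity_mm_s=v, n_frames=32,
    )
    _, truth = simulate_capillary_video(cfg)
    step_um = v * 1000.0 / cfg.fps
    diffs = np.diff(truth.particle_positions_um, axis=1)
    assert np.allclose(diffs, step_um, rtol=1e-12, atol=1e-9)
    assert np.allclose(truth.per_frame_velocity_mm_s, v)


def test_pulsatile_velocity_modulates_positions():
    cfg = small_config(pulsatility=0.3, noise_sd=0.0, jitter_px_sd=0.0, n_frames=64)
    _, truth = simulate_capillary_video(cfg)
    diffs = np.diff(truth.particle_positions_um, axis=1)
    assert diffs.std() > 0
    assert np.all(diffs > 0)  # pulsatility < 1 never reverses flow
    mean_v = diffs.mean() * cfg.fps / 1000.0
    assert mean_v == pytest.approx(cfg.true_velocity_mm_s, rel=0.05)


def test_same_seed_bit_identical():
    a, _ = simulate_capillary_video(small_config(n_frames=8, seed=5))
    b, _ = simulate_capillary_video(small_config(n_frames=8, seed=5))
    assert np.array_equal(a.frames, b.frames)


def test_different_seed_differs():
    a, _ = simulate_capillary_video(small_config(n_frames=8, seed=5))
    b, _ = simulate_capillary_video(small_config(n_frames=8, seed=6))
    assert not np.array_equal(a.frames, b.frames)


def test_waypoints_outside_frame_rejected():
    cfg = small_config(vessel_waypoints=np.array([[10.0, -5.0], [50.0, 50.0]]))
    with pytest.raises(ValueError, match="bounds"):
        simulate_capillary_video(cfg)


def test_zero_length_centreline_rejected():
    cfg = small_config(vessel_waypoints=np.array([[40.0, 40.0], [40.0, 40.0]]))
    with pytest.raises(ValueError):
        simulate_capillary_video(cfg)


@pytest.mark.parametrize(
    "bad", [dict(n_frames=1), dict(fps=0.0), dict(true_velocity_mm_s=0.0),
            dict(pulsatility=1.0)]
)
def test_invalid_config_rejected(bad):
    with pytest.raises(ValueError):
        simulate_capillary_video(small_config(**bad))


def test_ground_truth_monotone_positions(small_video):
    _, truth = small_video
    assert np.all(np.diff(truth.particle_positions_um, axis=1) >= 0)


def test_default_waypoints_inside_frame():
    wp = default_waypoints((100, 200))
    assert wp[:, 0].min() >= 0 and wp[:, 0].max() <= 99
    assert wp[:, 1].min() >= 0 and wp[:, 1].max() <= 199


def test_plugs_brighter_and_tails_darker_than_background():
    cfg = small_config(noise_sd=0.0, jitter_px_sd=0.0, n_frames=8)
    stack, truth = simulate_capillary_video(cfg)
    # Sample frame 0 along the centreline; plug regions should be the
    # brightest and tail regions the darkest pixels on the vessel.
    from scipy import ndimage

    vals = ndimage.map_coordinates(
        stack.frames[0].astype(float), truth.centreline_px.T, order=1
    )
    front = truth.particle_positions_um[1, 0]  # a front inside the field
    arc = truth.arc_length_um
    on_plug = (arc < front) & (arc > front - cfg.plug_len_um)
    on_tail = (arc < front - cfg.plug_len_um - 3) & (
        arc > front - cfg.plug_len_um - cfg.tail_len_um + 3
    )
    assert vals[on_plug].mean() > vals.mean() + 0.1
    assert vals[on_tail].mean() < vals.mean() - 0.1
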