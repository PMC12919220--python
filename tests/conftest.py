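"""Shared fixtures: rendered synthetic scenes reused across test modules."""

from dataclasses import replace

import numpy as np
import pytest

from geotax import flytrack, synthgen, vialdetect


def layout_from_ground_truth(gt, frame_size):
    entries = tuple(
        (n, (float(x1), float(y1), float(x2), float(y2)))
        for n, x1, y1, x2, y2 in gt.boxes
    )
    return vialdetect.VialLayout(entries=entries, frame_size=frame_size)


@pytest.fixture(scope="session")
def quarter_scene():
    """A quarter-resolution single-cycle scene with a 900-frame pause."""
    return synthgen.scaled_scene(scale=0.25, n_cycles=1, pause_frames=900, seed=42)


@pytest.fixture(scope="session")
def quarter_recording(quarter_scene):
    """Rendered frames + ground truth: 3 separable flies in each of 12 vials."""
    kin = [
        synthgen.FlyKinematics(vial_num=v, n_flies=3, climb_speed_cm_s=1.0,
                               speed_sd=0.4)
        for v in range(1, 13)
    ]
    frames, gt = synthgen.render_recording(quarter_scene, kin)
    return frames, gt


@pytest.fixture(scope="session")
def trim900(quarter_scene, quarter_recording):
    """One 900-frame trim (the pause phase) with layout and tracker config."""
    frames, gt = quarter_recording
    trim = frames[synthgen.TAP_BURST_FRAMES : synthgen.TAP_BURST_FRAMES + 900]
    layout = layout_from_ground_truth(gt, quarter_scene.image_size)
    config = replace(
        flytrack.TrackerConfig(),
        image_height_px=float(quarter_scene.image_size[1]),
    )
    return trim, layout, config, gt


@pytest.fixture(scope="session")
def trim900_records(trim900):
    trim, layout, config, _ = trim900
    return flytrack.track_trim(trim, layout, config, trim_index=1)


@pytest.fixture(scope="session")
def full_scale_frame():
    """One full-resolution (1280x720) populated holder frame + ground truth."""
    scene = synthgen.scaled_scene(scale=1.0, n_cycles=1, pause_frames=30, seed=7)
    kin = [
        synthgen.FlyKinematics(vial_num=v, n_flies=5, climb_speed_cm_s=1.0,
                               speed_sd=0.3, stall_prob=0.2)
        for v in range(1, 13)
    ]
    frame, gt = synthgen.render_frame(scene, kin, frame_index=20)
    return scene, frame, gt
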