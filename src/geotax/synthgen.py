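"""Synthetic negative-geotaxis recordings with ground truth.

Emulates the assay device's recording protocol: a white-background holder of
12 side-by-side vials filmed at 60 fps and 1280x720; each of four cycles taps
the rack (grounding the flies, seen as a burst of high-motion frames) and
then pauses for 15 seconds while flies climb.  Flies are rendered as dark
filled disks; taps are simulated as a few frames of global frame jitter plus
large random blob displacement, which produces the high-motion spikes the
trial splitter keys on without modelling the lever mechanics.

Every recording comes with ground truth (vial boxes, per-fly trajectories,
tap frame indices) so downstream detection and tracking can be scored
exactly.  Rendering is bit-deterministic for a given (scene, kinematics,
seed): the scene seed fans out into one substream for scene-level noise and
one per fly.

Fly motion model: during a pause each fly climbs at a per-bout speed drawn
from N(climb_speed_cm_s, speed_sd); behavioural state (climbing vs stalled)
is resampled on average twice per second so stalls form realistic bouts
rather than white noise.  Optionally a fly may "slip" — fall instantly back
to the vial bottom and resume climbing at its normal speed — with a fixed
per-frame probability after ``slip_start_s`` seconds into the trial.  Slips
reproduce the phenotype of impaired sustained climbing with intact
instantaneous climbing velocity.
"""

from __future__ import annotations

import json
from dataclasses import dataclass
from pathlib import Path
from typing import Iterator, List, Sequence, Tuple

import numpy as np
import pandas as pd

from geotax import io as gio

Box = Tuple[int, int, int, int]

# Grey levels of the rendered scene (uint8).  Boxes use pixel coordinates,
# origin top-left, y increasing downward, half-open [x1, x2) x [y1, y2).
BACKGROUND_GREY = 255
VIAL_FILL_GREY = 242
VIAL_WALL_GREY = 90
FLY_GREY = 30
WALL_PX = 2

#: expected number of frames per simulated tap burst
TAP_BURST_FRAMES = 5


def default_vial_boxes(
    image_size: Tuple[int, int], n_vials: int
) -> List[Box]:
    """Evenly spaced, non-overlapping vial boxes across the frame width."""
    w, h = image_size
    y1 = round(0.08 * h)
    y2 = round(0.92 * h)
    margin = round(0.04 * w)
    slot = (w - 2 * margin) // n_vials
    gap = max(4, round(0.30 * slot))
    vw = slot - gap
    if vw < 2 * WALL_PX + 2:
        raise ValueError(f"image width {w} too small for {n_vials} vials")
    boxes = []
    for i in range(n_vials):
        x1 = margin + i * slot + gap // 2
        boxes.append((x1, y1, x1 + vw, y2))
    return boxes


@dataclass(frozen=True)
class SceneConfig:
    """Geometry and recording-protocol constants of a synthetic scene."""

    image_size: Tuple[int, int] = (1280, 720)
    n_vials: int = 12
    vial_boxes: Tuple[Box, ...] = ()
    holder_height_cm: float = 17.0
    fps: float = 60.0
    n_cycles: int = 4
    pause_frames: int = 900
    fly_radius_px: int = 5
    noise_sd: float = 2.0
    seed: int = 0
    tap_shift_px: int = 6

    def __post_init__(self) -> None:
        if not self.vial_boxes:
            object.__setattr__(
                self,
                "vial_boxes",
                tuple(default_vial_boxes(self.image_size, self.n_vials)),
            )
        if self.holder_height_cm <= 0:
            raise ValueError("holder_height_cm must be positive")
        if self.fps <= 0:
            raise ValueError("fps must be positive")
        w, h = self.image_size
        boxes = sorted(self.vial_boxes, key=lambda b: b[0])
        for x1, y1, x2, y2 in boxes:
            if not (0 <= x1 < x2 <= w and 0 <= y1 < y2 <= h):
                raise ValueError(f"vial box {(x1, y1, x2, y2)} outside image bounds")
        for (_, _, x2a, _), (x1b, _, _, _) in zip(boxes, boxes[1:]):
            if x1b < x2a:
                raise ValueError("vial boxes overlap")
        object.__setattr__(self, "vial_boxes", tuple(boxes))

    @property
    def n_frames(self) -> int:
        return self.n_cycles * (TAP_BURST_FRAMES + self.pause_frames)

    @property
    def px_per_cm(self) -> float:
        """Vertical image scale: full image height maps to the holder height."""
        return self.image_size[1] / self.holder_height_cm


@dataclass(frozen=True)
class FlyKinematics:
    """Climbing behaviour of the flies in one vial."""

    vial_num: int
    n_flies: int
    climb_speed_cm_s: float = 1.0
    speed_sd: float = 0.0
    stall_prob: float = 0.0
    start_zone: str = "bottom"
    slip_prob: float = 0.0
    slip_start_s: float = 0.0
    slip_onset_spread_s: float = 0.0
    wander_speed_cm_s: float = 0.0
    wander_frac: float = 0.25

    def __post_init__(self) -> None:
        if self.n_flies < 0:
            raise ValueError("n_flies must be >= 0")
        if self.climb_speed_cm_s < 0:
            raise ValueError("climb_speed_cm_s must be >= 0")
        if not 0.0 <= self.stall_prob <= 1.0:
            raise ValueError("stall_prob must be a probability")
        if not 0.0 <= self.slip_prob <= 1.0:
            raise ValueError("slip_prob must be a probability")


@dataclass
class GroundTruth:
    """Exact scene state emitted alongside a rendered recording."""

    boxes: List[Tuple[int, int, int, int, int]]  # (vial_num, x1, y1, x2, y2)
    trajectories: pd.DataFrame  # columns frame, fly_id, vial_num, x, y
    tap_frames: List[int]


def _simulate_trajectories(
    scene: SceneConfig, kinematics: Sequence[FlyKinematics]
) -> tuple[np.ndarray, np.ndarray, np.ndarray, List[int]]:
    """Per-fly per-frame positions.

    Returns (xs, ys) of shape (n_flies_total, n_frames), the vial index of
    each fly, and the tap frame indices (first frame of each burst).
    """
    boxes = {i + 1: b for i, b in enumerate(scene.vial_boxes)}
    for kin in kinematics:
        if kin.vial_num not in boxes:
            raise ValueError(
                f"kinematics references vial {kin.vial_num}, scene has "
                f"vials 1..{len(boxes)}"
            )
    seq = np.random.SeedSequence(scene.seed)
    n_total = sum(k.n_flies for k in kinematics)
    children = seq.spawn(1 + n_total)
    fly_rngs = [np.random.default_rng(c) for c in children[1:]]

    n_frames = scene.n_frames
    xs = np.zeros((n_total, n_frames))
    ys = np.zeros((n_total, n_frames))
    fly_vial = np.zeros(n_total, dtype=int)

    r = scene.fly_radius_px
    px_per_cm = scene.px_per_cm
    dt = 1.0 / scene.fps
    switch_prob = min(1.0, 2.0 * dt)  # behavioural state resampled ~2 Hz

    tap_frames = [
        c * (TAP_BURST_FRAMES + scene.pause_frames) for c in range(scene.n_cycles)
    ]

    fid = 0
    for kin in kinematics:
        x1, y1, x2, y2 = boxes[kin.vial_num]
        top = y1 + r
        bottom = y2 - 1 - r
        if top > bottom:
            top = bottom = (y1 + y2) // 2
        xlo, xhi = x1 + WALL_PX + r, x2 - WALL_PX - r
        if xlo > xhi:
            xlo = xhi = (x1 + x2) / 2
        for i_fly in range(kin.n_flies):
            rng = fly_rngs[fid]
            fly_vial[fid] = kin.vial_num
            # grounded flies spread along the vial bottom: stratified x slots
            # with jitter, and a small vertical pile-up offset
            slot = (xhi - xlo) / max(1, kin.n_flies)
            x0 = xlo + slot * (i_fly + rng.uniform(0.2, 0.8))
            y_jitter = rng.uniform(0.0, min(4.0 * r, bottom - top))
            slip_onset = kin.slip_start_s + (
                rng.uniform(0.0, kin.slip_onset_spread_s)
                if kin.slip_onset_spread_s > 0 else 0.0
            )
            y = float(bottom) - y_jitter
            stalled = False
            at_top = False
            direction = 1.0
            speed = max(0.0, rng.normal(kin.climb_speed_cm_s, kin.speed_sd))
            for f in range(n_frames):
                in_cycle = f % (TAP_BURST_FRAMES + scene.pause_frames)
                if in_cycle < TAP_BURST_FRAMES:
                    # tap burst: rack shaken, fly scattered within the vial
                    xs[fid, f] = rng.uniform(xlo, xhi)
                    ys[fid, f] = rng.uniform(top, bottom)
                    y = float(bottom) - y_jitter  # grounded for the pause
                    at_top = False
                    continue
                t_in_trial = (in_cycle - TAP_BURST_FRAMES) * dt
                if kin.speed_sd > 0 or kin.stall_prob > 0:
                    if rng.uniform() < switch_prob:
                        stalled = rng.uniform() < kin.stall_prob
                        speed = max(
                            0.0, rng.normal(kin.climb_speed_cm_s, kin.speed_sd)
                        )
                        direction = 1.0 if rng.uniform() < 0.5 else -1.0
                if (
                    kin.slip_prob > 0
                    and t_in_trial >= slip_onset
                    and rng.uniform() < kin.slip_prob
                ):
                    y = float(bottom)
                    at_top = False
                elif not stalled:
                    if at_top and kin.wander_speed_cm_s > 0:
                        # flies that reached the top keep walking up and down
                        # within a band below the vial top
                        y += direction * kin.wander_speed_cm_s * px_per_cm * dt
                        band = top + kin.wander_frac * (bottom - top)
                        if y <= top:
                            y, direction = float(top), 1.0
                        elif y >= band:
                            y, direction = float(band), -1.0
                    else:
                        y -= speed * px_per_cm * dt
                        if y <= top:
                            y = float(top)
                            at_top = True
                xs[fid, f] = x0
                ys[fid, f] = y
            fid += 1
    return xs, ys, fly_vial, tap_frames


def _base_scene(scene: SceneConfig) -> np.ndarray:
    w, h = scene.image_size
    img = np.full((h, w), BACKGROUND_GREY, dtype=np.uint8)
    for x1, y1, x2, y2 in scene.vial_boxes:
        img[y1:y2, x1:x2] = VIAL_FILL_GREY
        img[y1:y2, x1 : x1 + WALL_PX] = VIAL_WALL_GREY
        img[y1:y2, x2 - WALL_PX : x2] = VIAL_WALL_GREY
        img[y1 : y1 + WALL_PX, x1:x2] = VIAL_WALL_GREY
        img[y2 - WALL_PX : y2, x1:x2] = VIAL_WALL_GREY
    return img


def _draw_fly(img: np.ndarray, cx: float, cy: float, r: int) -> None:
    h, w = img.shape
    x_lo = max(0, int(np.floor(cx - r)))
    x_hi = min(w, int(np.ceil(cx + r)) + 1)
    y_lo = max(0, int(np.floor(cy - r)))
    y_hi = min(h, int(np.ceil(cy + r)) + 1)
    if x_lo >= x_hi or y_lo >= y_hi:
        return
    yy, xx = np.mgrid[y_lo:y_hi, x_lo:x_hi]
    mask = (xx - cx) ** 2 + (yy - cy) ** 2 <= r * r
    img[y_lo:y_hi, x_lo:x_hi][mask] = FLY_GREY


def iter_frames(
    scene: SceneConfig, kinematics: Sequence[FlyKinematics]
) -> Iterator[np.ndarray]:
    """Lazily yield the rendered greyscale frames of a recording."""
    xs, ys, _, _ = _simulate_trajectories(scene, kinematics)
    base = _base_scene(scene)
    scene_rng = np.random.default_rng(np.random.SeedSequence(scene.seed).spawn(1)[0])
    period = TAP_BURST_FRAMES + scene.pause_frames
    for f in range(scene.n_frames):
        img = base.copy()
        for fid in range(xs.shape[0]):
            _draw_fly(img, xs[fid, f], ys[fid, f], scene.fly_radius_px)
        if f % period < TAP_BURST_FRAMES:
            dx = int(scene_rng.integers(-scene.tap_shift_px, scene.tap_shift_px + 1))
            dy = int(scene_rng.integers(-scene.tap_shift_px, scene.tap_shift_px + 1))
            img = np.roll(np.roll(img, dy, axis=0), dx, axis=1)
        if scene.noise_sd > 0:
            noisy = img.astype(np.float64) + scene_rng.normal(
                0.0, scene.noise_sd, img.shape
            )
            img = np.clip(noisy, 0, 255).astype(np.uint8)
        yield img


def render_recording(
    scene: SceneConfig, kinematics: Sequence[FlyKinematics]
) -> tuple[List[np.ndarray], GroundTruth]:
    """Render a full recording and its ground truth.

    Deterministic for a fixed (scene, kinematics, seed).  For long
    full-resolution recordings prefer :func:`iter_frames` to avoid holding
    every frame in memory.
    """
    xs, ys, fly_vial, tap_frames = _simulate_trajectories(scene, kinematics)
    frames = list(iter_frames(scene, kinematics))
    n_total, n_frames = xs.shape
    traj = pd.DataFrame(
        {
            "frame": np.tile(np.arange(n_frames), n_total),
            "fly_id": np.repeat(np.arange(n_total), n_frames),
            "vial_num": np.repeat(fly_vial, n_frames),
            "x": xs.ravel(),
            "y": ys.ravel(),
        }
    )
    boxes = [
        (i + 1, x1, y1, x2, y2)
        for i, (x1, y1, x2, y2) in enumerate(scene.vial_boxes)
    ]
    return frames, GroundTruth(boxes=boxes, trajectories=traj, tap_frames=tap_frames)


def render_frame(
    scene: SceneConfig, kinematics: Sequence[FlyKinematics], frame_index: int = None
) -> tuple[np.ndarray, GroundTruth]:
    """Render a single (pause-phase) frame; convenient for detector tests."""
    if frame_index is None:
        frame_index = TAP_BURST_FRAMES + scene.pause_frames // 2
    for i, frame in enumerate(iter_frames(scene, kinematics)):
        if i == frame_index:
            xs, ys, fly_vial, tap_frames = _simulate_trajectories(scene, kinematics)
            boxes = [
                (j + 1, x1, y1, x2, y2)
                for j, (x1, y1, x2, y2) in enumerate(scene.vial_boxes)
            ]
            traj = pd.DataFrame(
                {
                    "frame": frame_index,
                    "fly_id": np.arange(xs.shape[0]),
                    "vial_num": fly_vial,
                    "x": xs[:, frame_index],
                    "y": ys[:, frame_index],
                }
            )
            return frame, GroundTruth(boxes, traj, tap_frames)
    raise ValueError(f"frame_index {frame_index} beyond recording length")


def synth_movement_trace(
    n_frames: int,
    tap_frames: Sequence[int],
    tap_height: float = 150_000.0,
    baseline: float = 0.0,
    noise_sd: float = 0.0,
    seed: int = 0,
    fps: float = 60.0,
):
    """Directly synthesize a per-frame motion-energy trace.

    A fixture for the trial splitter that bypasses rendering: the trace is
    ``baseline`` plus non-negative noise, with a 3-frame burst reaching at
    least ``tap_height`` at every entry of ``tap_frames``.
    """
    from geotax.trialsplit import MovementTrace

    if tap_height <= baseline or baseline < 0:
        raise ValueError("require tap_height > baseline >= 0")
    for t in tap_frames:
        if not 0 <= t < n_frames:
            raise ValueError(f"tap frame {t} outside [0, {n_frames})")
    rng = np.random.default_rng(seed)
    values = np.full(n_frames, float(baseline))
    if noise_sd > 0:
        values = np.clip(values + rng.normal(0.0, noise_sd, n_frames), 0.0, None)
    for t in tap_frames:
        if t - 1 >= 0:
            values[t - 1] = max(values[t - 1], 0.6 * tap_height)
        values[t] = tap_height
        if t + 1 < n_frames:
            values[t + 1] = max(values[t + 1], 0.6 * tap_height)
    return MovementTrace(values=values, fps=fps)


def write_coco_annotations(
    records: Sequence[tuple[int, Sequence[tuple[int, int, int, int, int]]]],
    image_size: Tuple[int, int],
    path: str | Path,
    file_template: str = "frame_{:06d}.png",
) -> Path:
    """Write vial ground-truth boxes as COCO-style detection annotations.

    ``records`` is a sequence of (image_id, boxes) where each box is
    (vial_num, x1, y1, x2, y2); bboxes are stored COCO-style as x, y, w, h.
    """
    w, h = image_size
    images, annotations = [], []
    ann_id = 1
    for image_id, boxes in records:
        images.append(
            {
                "id": int(image_id),
                "file_name": file_template.format(image_id),
                "width": w,
                "height": h,
            }
        )
        for _, x1, y1, x2, y2 in boxes:
            annotations.append(
                {
                    "id": ann_id,
                    "image_id": int(image_id),
                    "category_id": 1,
                    "bbox": [int(x1), int(y1), int(x2 - x1), int(y2 - y1)],
                    "area": int((x2 - x1) * (y2 - y1)),
                    "iscrowd": 0,
                }
            )
            ann_id += 1
    doc = {
        "images": images,
        "annotations": annotations,
        "categories": [{"id": 1, "name": "vial"}],
    }
    path = Path(path)
    path.write_text(json.dumps(doc, indent=1))
    return path


def write_experiment_folder(
    path: str | Path,
    scene: SceneConfig,
    kinematics: Sequence[FlyKinematics],
    labels: Sequence[tuple[str, str]],
) -> Path:
    """Materialize one recording subfolder: frames + metadata + ground truth.

    ``labels`` gives one (genotype, sex) pair per kinematics entry; sex must
    be ``M`` or ``F``.  The folder receives a ``frames/`` PNG directory,
    ``geotaxis_metadata.csv`` (columns Vial_Num,Genotype,Gender,N), a
    ground-truth JSON (vial boxes + tap frames) and a trajectory CSV.
    """
    if len(labels) != len(kinematics):
        raise ValueError("need one (genotype, sex) label per kinematics entry")
    path = Path(path)
    path.mkdir(parents=True, exist_ok=True)

    frames, gt = render_recording(scene, kinematics)
    gio.write_frames_dir(frames, path / gio.FRAME_DIR_NAME)

    meta = pd.DataFrame(
        {
            "Vial_Num": [k.vial_num for k in kinematics],
            "Genotype": [g for g, _ in labels],
            "Gender": [s for _, s in labels],
            "N": [k.n_flies for k in kinematics],
        }
    )
    if not set(meta["Gender"]) <= {"M", "F"}:
        raise ValueError("sex labels must be 'M' or 'F'")
    gio.write_metadata(meta, path / gio.METADATA_FILENAME)

    (path / "ground_truth.json").write_text(
        json.dumps(
            {
                "boxes": [list(b) for b in gt.boxes],
                "tap_frames": [int(t) for t in gt.tap_frames],
                "fps": scene.fps,
                "image_size": list(scene.image_size),
                "holder_height_cm": scene.holder_height_cm,
            },
            indent=1,
        )
    )
    gt.trajectories.to_csv(path / "ground_truth_trajectories.csv", index=False)
    return path


def scaled_scene(scale: float = 0.5, **overrides) -> SceneConfig:
    """A SceneConfig at a reduced resolution, keeping the protocol timing.

    Convenience for tests and desk-scale runs: geometry (and the fly radius)
    shrinks with ``scale`` while fps, cycle structure and the physical
    holder height are preserved.
    """
    w, h = (round(1280 * scale), round(720 * scale))
    defaults = dict(
        image_size=(w, h),
        fly_radius_px=max(2, round(5 * scale)),
        tap_shift_px=max(3, round(6 * scale)),
    )
    defaults.update(overrides)
    return SceneConfig(**defaults)
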