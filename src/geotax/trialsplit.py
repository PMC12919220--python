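"""Motion-energy trial segmentation.

A recording holds four tap-and-pause cycles.  Each tap burst shows up as a
spike in per-frame "movement units" — the summed area (px^2) of moving
foreground regions that survive a minimum-area filter.  Trials ("trims") are
the 15-second climbing windows that follow each spike:

* peaks are local maxima of the movement trace above ``peak_height``
  (default 100,000 movement units);
* a trial starts at the first frame after the peak whose motion drops below
  ``inactive_thresh`` (30,000 units), aligning trial time zero with the end
  of tapping;
* the trial ends with the first inactivity run of at least
  ``min_inactive_run`` (270) consecutive sub-threshold frames, capped to
  ``cap_frames`` (900 frames = 15 s at 60 fps).

Foreground is extracted by a per-pixel background model: a running-Gaussian
model (mean/variance tracked with an exponential window, in the
mixture-of-Gaussians family) by default, or simple previous-frame
differencing in pure-array test mode.
"""

from __future__ import annotations

import logging
from dataclasses import dataclass, replace
from pathlib import Path
from typing import Iterable, List, Sequence

import numpy as np
import pandas as pd
from scipy import ndimage, signal

from geotax.io import red_channel, write_frames_dir

logger = logging.getLogger(__name__)

#: reference resolution at which the default area thresholds were set
REFERENCE_IMAGE_SIZE = (1280, 720)


@dataclass(frozen=True)
class MovementTrace:
    """Per-frame scalar motion energy of a recording."""

    values: np.ndarray
    fps: float = 60.0

    def __post_init__(self) -> None:
        values = np.asarray(self.values, dtype=float)
        if values.ndim != 1 or values.size < 1:
            raise ValueError("trace must be a non-empty 1-D array")
        if not np.all(np.isfinite(values)) or np.any(values < 0):
            raise ValueError("trace values must be finite and non-negative")
        object.__setattr__(self, "values", values)

    def __len__(self) -> int:
        return self.values.size

    def to_csv(self, path: str | Path) -> Path:
        df = pd.DataFrame(
            {"frame": np.arange(len(self)), "movement_units": self.values}
        )
        df.to_csv(path, index=False)
        return Path(path)


@dataclass(frozen=True)
class TrimSegment:
    """One trial window, half-open frame range [start_frame, end_frame)."""

    start_frame: int
    end_frame: int
    index: int = 1

    def __post_init__(self) -> None:
        if not 0 <= self.start_frame < self.end_frame:
            raise ValueError(
                f"invalid segment [{self.start_frame}, {self.end_frame})"
            )

    @property
    def n_frames(self) -> int:
        return self.end_frame - self.start_frame


@dataclass(frozen=True)
class SplitterConfig:
    min_contour_area: float = 2000.0
    peak_height: float = 100_000.0
    inactive_thresh: float = 30_000.0
    min_inactive_run: int = 270
    cap_frames: int = 900
    expected_trims: int = 4
    background: str = "gaussian"  # or "framediff"
    history: int = 500
    var_threshold: float = 16.0
    diff_threshold: float = 16.0

    def __post_init__(self) -> None:
        if self.inactive_thresh >= self.peak_height:
            raise ValueError("inactive_thresh must be below peak_height")
        for name in (
            "min_contour_area", "peak_height", "inactive_thresh",
            "min_inactive_run", "cap_frames", "expected_trims",
        ):
            if getattr(self, name) <= 0:
                raise ValueError(f"{name} must be positive")

    def scaled(self, image_size: tuple[int, int]) -> "SplitterConfig":
        """Rescale the area-based thresholds to another frame resolution.

        Movement units are pixel areas, so the defaults (set at 1280x720)
        shrink with the pixel-area ratio; frame-count parameters are
        time-based and stay fixed.
        """
        rw, rh = REFERENCE_IMAGE_SIZE
        ratio = (image_size[0] * image_size[1]) / (rw * rh)
        return replace(
            self,
            min_contour_area=self.min_contour_area * ratio,
            peak_height=self.peak_height * ratio,
            inactive_thresh=self.inactive_thresh * ratio,
        )


class FrameDiffBackground:
    """Previous-frame differencing: foreground where |frame - prev| > thresh."""

    def __init__(self, diff_threshold: float = 16.0) -> None:
        self.diff_threshold = diff_threshold
        self._prev: np.ndarray | None = None

    def apply(self, frame: np.ndarray) -> np.ndarray:
        frame = np.asarray(frame, dtype=np.float64)
        if self._prev is None:
            self._prev = frame
            return np.zeros(frame.shape, dtype=bool)
        if frame.shape != self._prev.shape:
            raise ValueError(
                f"frame shape {frame.shape} != model shape {self._prev.shape}"
            )
        mask = np.abs(frame - self._prev) > self.diff_threshold
        self._prev = frame
        return mask


class RunningGaussianBackground:
    """Per-pixel running Gaussian background model.

    Tracks an exponentially weighted mean and variance per pixel (window
    ``history`` frames); a pixel is foreground when its squared deviation
    from the mean exceeds ``var_threshold`` times the modelled variance.
    Single-component member of the mixture-of-Gaussians family.
    """

    def __init__(
        self,
        history: int = 500,
        var_threshold: float = 16.0,
        initial_var: float = 225.0,
    ) -> None:
        self.alpha = 1.0 / history
        self.var_threshold = var_threshold
        self.initial_var = initial_var
        self._mean: np.ndarray | None = None
        self._var: np.ndarray | None = None

    def apply(self, frame: np.ndarray) -> np.ndarray:
        frame = np.asarray(frame, dtype=np.float64)
        if self._mean is None:
            self._mean = frame.copy()
            self._var = np.full(frame.shape, self.initial_var)
            return np.zeros(frame.shape, dtype=bool)
        if frame.shape != self._mean.shape:
            raise ValueError(
                f"frame shape {frame.shape} != model shape {self._mean.shape}"
            )
        dev2 = (frame - self._mean) ** 2
        mask = dev2 > self.var_threshold * self._var
        a = self.alpha
        self._mean += a * (frame - self._mean)
        self._var += a * (dev2 - self._var)
        np.clip(self._var, 1.0, None, out=self._var)
        return mask


def make_background_model(config: SplitterConfig):
    if config.background == "gaussian":
        return RunningGaussianBackground(config.history, config.var_threshold)
    if config.background == "framediff":
        return FrameDiffBackground(config.diff_threshold)
    raise ValueError(f"unknown background model {config.background!r}")


def frame_motion_energy(frame: np.ndarray, background_model, config: SplitterConfig) -> float:
    """Movement units of one frame: summed area of large moving regions.

    The background model yields a foreground mask; connected regions with
    area >= ``min_contour_area`` px^2 contribute their pixel count.
    """
    mask = background_model.apply(red_channel(np.asarray(frame)))
    if not mask.any():
        return 0.0
    labels, n = ndimage.label(mask)
    if n == 0:
        return 0.0
    areas = np.bincount(labels.ravel())[1:]
    return float(areas[areas >= config.min_contour_area].sum())


def build_movement_trace(
    frames: Iterable[np.ndarray],
    config: SplitterConfig = SplitterConfig(),
    fps: float = 60.0,
) -> MovementTrace:
    """One movement-units value per frame, model updated frame by frame."""
    model = make_background_model(config)
    values = [frame_motion_energy(f, model, config) for f in frames]
    if not values:
        raise ValueError("cannot build a movement trace from zero frames")
    return MovementTrace(values=np.asarray(values), fps=fps)


def _inactive_runs(below: np.ndarray) -> list[tuple[int, int]]:
    """Maximal runs of True as half-open (start, end) pairs."""
    runs = []
    n = below.size
    i = 0
    while i < n:
        if below[i]:
            j = i
            while j < n and below[j]:
                j += 1
            runs.append((i, j))
            i = j
        else:
            i += 1
    return runs


def find_trials(
    trace: MovementTrace, config: SplitterConfig = SplitterConfig()
) -> List[TrimSegment]:
    """Segment a movement trace into climbing trials.

    Returns non-overlapping segments in temporal order.  When more than
    ``expected_trims`` candidates are found, the ones following the highest
    tap peaks are kept; when fewer, what exists is returned with a warning.
    """
    vals = trace.values
    peaks, props = signal.find_peaks(vals, height=config.peak_height)
    below = vals < config.inactive_thresh
    candidates: list[tuple[float, int, int]] = []  # (peak_height, start, end)
    last_end = 0
    for k, p in enumerate(peaks):
        if p < last_end:
            continue  # tap spike swallowed by the previous segment's search
        limit = peaks[k + 1] if k + 1 < len(peaks) else vals.size
        start = p + 1
        while start < limit and not below[start]:
            start += 1
        if start >= limit:
            continue
        local = _inactive_runs(below[start:limit])
        end = None
        for rs, re in local:
            if re - rs >= config.min_inactive_run:
                end = start + re
                break
        if end is None:
            continue
        end = min(end, start + config.cap_frames)
        candidates.append((float(vals[p]), start, end))
        last_end = end

    if len(candidates) > config.expected_trims:
        logger.warning(
            "found %d candidate trials, keeping the %d with highest tap peaks",
            len(candidates), config.expected_trims,
        )
        keep = sorted(candidates, key=lambda c: -c[0])[: config.expected_trims]
        candidates = sorted(keep, key=lambda c: c[1])
    elif len(candidates) < config.expected_trims:
        logger.warning(
            "found only %d of %d expected trials",
            len(candidates), config.expected_trims,
        )
    return [
        TrimSegment(start_frame=int(s), end_frame=int(e), index=i + 1)
        for i, (_, s, e) in enumerate(candidates)
    ]


def cut_segments(
    frames: Sequence[np.ndarray], segments: Sequence[TrimSegment]
) -> List[List[np.ndarray]]:
    """Slice a frame sequence into the trial windows."""
    n = len(frames)
    if not segments:
        logger.warning("no segments to cut")
        return []
    out = []
    for seg in segments:
        if seg.end_frame > n:
            raise ValueError(f"segment {seg} beyond recording length {n}")
        out.append(list(frames[seg.start_frame : seg.end_frame]))
    return out


def cut_segments_to_dirs(
    frames: Sequence[np.ndarray],
    segments: Sequence[TrimSegment],
    out_dir: str | Path,
    recording_name: str,
) -> List[Path]:
    """Write each trial as a frame directory named ``<recording>_trim<k>``."""
    out_dir = Path(out_dir)
    out_dir.mkdir(parents=True, exist_ok=True)
    paths = []
    for trim, seg in zip(cut_segments(frames, segments), segments):
        paths.append(
            write_frames_dir(trim, out_dir / f"{recording_name}_trim{seg.index}")
        )
    return paths


def segments_to_json(segments: Sequence[TrimSegment]) -> list[dict]:
    return [
        {"index": int(s.index), "start_frame": int(s.start_frame),
         "end_frame": int(s.end_frame)}
        for s in segments
    ]
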