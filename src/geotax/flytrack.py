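"""Fly centroid detection, zoning, and per-trial summaries.

Flies are segmented by max-projection background subtraction: the background
of a trim is the per-pixel maximum of every frame's red channel (flies are
dark and transient, so the maximum removes them), and each frame's
normalised deficit against that background is thresholded — separately in
the upper and lower halves of the chamber, which are lit differently — into
a binary mask.  Connected components within an area band become fly
centroids; each centroid is assigned to the vial box containing it and to a
vertical performance zone:

* LP (low performer): bottom ``lp_frac`` of the vial height,
* MP (middle performer): up to ``lp_frac + mp_frac``,
* HP (high performer): the rest.

During the first frames of a trial an "adder" guard suppresses MP/HP counts
within ``adder_px`` of the vial top, ignoring false positives until flies
are fully in view.  Pixel heights convert to centimetres through the chamber
holder height (17 cm over the 720-pixel image height) and frame indices to
seconds through the camera rate (60 fps); summaries are subsampled every 30
frames (2 Hz) over the first 780 frames (13 s) of each trim.
"""

from __future__ import annotations

import logging
from dataclasses import dataclass, field
from pathlib import Path
from typing import Dict, List, Optional, Sequence

import numpy as np
import pandas as pd
from scipy import ndimage

from geotax.io import red_channel
from geotax.vialdetect import VialLayout

logger = logging.getLogger(__name__)

ZONES = ("LP", "MP", "HP")


@dataclass(frozen=True)
class TrackerConfig:
    fps: float = 60.0
    subsample_step: int = 30
    frames_per_trim: int = 780
    thresh_top: float = 0.12
    thresh_bottom: float = 0.18
    min_blob_area: float = 4.0
    max_blob_area: float = 400.0
    zone_fractions: tuple[float, float] = (1.0 / 3.0, 1.0 / 3.0)
    adder_frames: int = 60
    adder_frac: float = 0.10
    adder_px: Optional[float] = None
    holder_height_cm: float = 17.0
    image_height_px: float = 720.0
    min_diff: float = 0.10
    vial_offsets_px: Dict[int, float] = field(default_factory=dict)

    def __post_init__(self) -> None:
        object.__setattr__(
            self, "zone_fractions", tuple(float(f) for f in self.zone_fractions)
        )
        object.__setattr__(
            self,
            "vial_offsets_px",
            {int(k): float(v) for k, v in self.vial_offsets_px.items()},
        )
        lp, mp = self.zone_fractions
        if not (0 < lp and 0 < mp and lp + mp < 1):
            raise ValueError("need 0 < lp_frac and lp_frac + mp_frac < 1")
        if self.frames_per_trim < self.subsample_step:
            raise ValueError("frames_per_trim must be >= subsample_step")
        for name in ("thresh_top", "thresh_bottom"):
            if not 0.0 < getattr(self, name) < 1.0:
                raise ValueError(f"{name} must be in (0, 1)")

    def adder_px_for(self, vial_height_px: float) -> float:
        if self.adder_px is not None:
            return self.adder_px
        return self.adder_frac * vial_height_px


@dataclass(frozen=True)
class CentroidRecord:
    """One detected fly position with vial and zone assignment."""

    trim: int
    frame: int
    vial_num: int
    x: float
    y: float
    zone: str


def pixels_to_cm(
    adj: float, holder_height_cm: float = 17.0, image_height_px: float = 720.0
) -> float:
    """Convert an adjusted vertical pixel displacement to centimetres.

    The chamber holder height (17 cm) maps onto the vertical image
    resolution (720 px), so ``cm = holder_height_cm * adj / image_height_px``.
    """
    adj = np.asarray(adj, dtype=float)
    if np.any(adj < 0):
        raise ValueError("adjusted displacement must be >= 0")
    out = holder_height_cm * adj / image_height_px
    return float(out) if out.ndim == 0 else out


def frame_to_seconds(frame: float, fps: float) -> float:
    """Real time of a frame index: ``t = frame / fps``."""
    if fps <= 0:
        raise ValueError("fps must be positive")
    return frame / fps


def compute_background(frames: Sequence[np.ndarray]) -> np.ndarray:
    """Per-pixel maximum of the red channels, normalised to [0, 1]."""
    it = iter(frames)
    try:
        first = red_channel(np.asarray(next(it))).astype(np.float64)
    except StopIteration:
        raise ValueError("need at least one frame") from None
    background = first
    for f in it:
        red = red_channel(np.asarray(f)).astype(np.float64)
        if red.shape != background.shape:
            raise ValueError(
                f"inconsistent frame sizes: {red.shape} vs {background.shape}"
            )
        background = np.maximum(background, red)
    return background / 255.0


def segment_flies(
    frame: np.ndarray, background: np.ndarray, config: TrackerConfig = TrackerConfig()
) -> List[tuple[float, float]]:
    """Centroids (x, y) of fly-sized dark blobs in one frame.

    The background-minus-frame difference (clipped at zero, normalised by
    its maximum) is binarised with ``thresh_top`` above the image midline
    and ``thresh_bottom`` below; connected components within
    [min_blob_area, max_blob_area] px^2 yield centroids.  A frame whose
    deficit never exceeds ``min_diff`` (no fly present) yields [].
    """
    red = red_channel(np.asarray(frame)).astype(np.float64) / 255.0
    if red.shape != background.shape:
        raise ValueError(f"frame shape {red.shape} != background {background.shape}")
    diff = np.clip(background - red, 0.0, None)
    peak = diff.max()
    if peak < config.min_diff:
        return []
    norm = diff / peak
    mask = np.zeros(norm.shape, dtype=bool)
    mid = norm.shape[0] // 2
    mask[:mid] = norm[:mid] > config.thresh_top
    mask[mid:] = norm[mid:] > config.thresh_bottom
    labels, n = ndimage.label(mask)
    if n == 0:
        return []
    areas = np.bincount(labels.ravel())[1:]
    keep = np.flatnonzero(
        (areas >= config.min_blob_area) & (areas <= config.max_blob_area)
    ) + 1
    centroids = ndimage.center_of_mass(mask, labels, keep)
    return [(float(cx), float(cy)) for cy, cx in centroids]


def assign_vial(
    centroid: tuple[float, float], layout: VialLayout
) -> Optional[int]:
    """Vial number of the box containing a centroid, or None.

    Boxes are half-open, so a point on a shared edge belongs to the box
    whose x1 equals the coordinate; residual overlaps resolve to the box
    with the smallest x1.
    """
    x, y = centroid
    for vial_num, (x1, y1, x2, y2) in layout.entries:  # entries sorted by x1
        if x1 <= x < x2 and y1 <= y < y2:
            return vial_num
    return None


def classify_zone(
    y: float,
    vial_box: tuple[float, float, float, float],
    config: TrackerConfig = TrackerConfig(),
    frame: int = 10**9,
) -> Optional[str]:
    """LP/MP/HP zone of a centroid, or None when the early-frame guard fires.

    Height-from-bottom is measured from the vial's lower edge (image y grows
    downward).  During the first ``adder_frames`` frames, centroids within
    the adder band below the vial top are not counted at all, reproducing
    the delayed MP/HP counting until flies are fully in view.
    """
    x1, y1, x2, y2 = vial_box
    if not y1 <= y < y2:
        raise ValueError(f"y={y} outside vial box {vial_box}")
    height_px = y2 - y1
    if frame < config.adder_frames and y < y1 + config.adder_px_for(height_px):
        return None
    height_from_bottom = y2 - y
    lp, mp = config.zone_fractions
    if height_from_bottom < lp * height_px:
        return "LP"
    if height_from_bottom >= (lp + mp) * height_px:
        return "HP"
    return "MP"


def track_trim(
    frames: Sequence[np.ndarray],
    layout: VialLayout,
    config: TrackerConfig = TrackerConfig(),
    trim_index: int = 1,
    background: np.ndarray | None = None,
) -> List[CentroidRecord]:
    """Detect, assign and zone fly centroids over one trim.

    The background is the max-projection over *all* trim frames; tracking
    then covers the first ``min(frames_per_trim, len(frames))`` frames.
    """
    if len(frames) < 1:
        raise ValueError("trim must contain at least one frame")
    if background is None:
        background = compute_background(frames)
    n = min(config.frames_per_trim, len(frames))
    records: list[CentroidRecord] = []
    n_outside = 0
    for f in range(n):
        for x, y in segment_flies(frames[f], background, config):
            vial = assign_vial((x, y), layout)
            if vial is None:
                n_outside += 1
                continue
            zone = classify_zone(y, layout.box_for(vial), config, frame=f)
            if zone is None:
                continue
            records.append(
                CentroidRecord(trim=trim_index, frame=f, vial_num=vial,
                               x=x, y=y, zone=zone)
            )
    if n_outside:
        logger.info("trim %d: dropped %d centroids outside all vials",
                    trim_index, n_outside)
    return records


def records_to_frame(records: Sequence[CentroidRecord]) -> pd.DataFrame:
    return pd.DataFrame(
        [(r.trim, r.frame, r.vial_num, r.x, r.y, r.zone) for r in records],
        columns=["trim", "frame", "vial_num", "x", "y", "zone"],
    )


@dataclass
class TrimSummary:
    """Subsampled per-vial series for one trim.

    Each attribute is a DataFrame indexed by time in seconds with one column
    per vial number: mean climbing height (cm) and percent occupancy of the
    three zones.  Time points where a vial has no detection are NaN.
    """

    trim: int
    height_cm: pd.DataFrame
    pct_lp: pd.DataFrame
    pct_mp: pd.DataFrame
    pct_hp: pd.DataFrame

    def modality(self, name: str) -> pd.DataFrame:
        return {"position": self.height_cm, "lp": self.pct_lp,
                "mp": self.pct_mp, "hp": self.pct_hp}[name]


def summarize_trim(
    records: Sequence[CentroidRecord],
    layout: VialLayout,
    config: TrackerConfig = TrackerConfig(),
    trim_index: int | None = None,
) -> TrimSummary:
    """Mean height and zone percentages on the 2 Hz subsampled time grid."""
    if trim_index is None:
        trim_index = records[0].trim if records else 1
    sample_frames = range(0, config.frames_per_trim, config.subsample_step)
    times = [frame_to_seconds(f, config.fps) for f in sample_frames]
    vials = layout.vial_nums
    df = records_to_frame(records)
    height = pd.DataFrame(index=pd.Index(times, name="time_s"),
                          columns=vials, dtype=float)
    pcts = {z: height.copy() for z in ZONES}
    for f, t in zip(sample_frames, times):
        at_frame = df[df["frame"] == f] if len(df) else df
        for vial in vials:
            sub = at_frame[at_frame["vial_num"] == vial] if len(at_frame) else at_frame
            if len(sub) == 0:
                continue
            x1, y1, x2, y2 = layout.box_for(vial)
            offset = config.vial_offsets_px.get(vial, 0.0)
            adj = np.clip((y2 - sub["y"].to_numpy()) + offset, 0.0, None)
            height.loc[t, vial] = float(
                np.mean(pixels_to_cm(adj, config.holder_height_cm,
                                     config.image_height_px))
            )
            counts = sub["zone"].value_counts()
            total = float(len(sub))
            for z in ZONES:
                pcts[z].loc[t, vial] = 100.0 * counts.get(z, 0) / total
    if height.isna().any().any():
        n_missing = int(height.isna().sum().sum())
        logger.info("trim %s: %d vial/time cells with no detection",
                    trim_index, n_missing)
    return TrimSummary(trim=trim_index, height_cm=height, pct_lp=pcts["LP"],
                       pct_mp=pcts["MP"], pct_hp=pcts["HP"])


@dataclass
class TrimAggregate:
    """Mean +/- SEM across trims, per modality."""

    mean: Dict[str, pd.DataFrame]
    sem: Dict[str, pd.DataFrame]
    n: Dict[str, pd.DataFrame]


MODALITY_NAMES = ("position", "lp", "mp", "hp")


def aggregate_trims(summaries: Sequence[TrimSummary]) -> TrimAggregate:
    """Mean and standard error over the (typically four) trims.

    SEM uses the n-1 sample standard deviation over the trims that observed
    the vial at that time point; a single observation reports SEM 0 with a
    warning rather than dropping the cell.
    """
    if not summaries:
        raise ValueError("need at least one trim summary")
    mean, sem, n = {}, {}, {}
    for name in MODALITY_NAMES:
        stack = pd.concat(
            [s.modality(name) for s in summaries],
            keys=range(len(summaries)),
        )
        grouped = stack.groupby(level=1, sort=False)
        counts = grouped.count()
        mu = grouped.mean()
        sd = grouped.std(ddof=1)
        se = sd / np.sqrt(counts)
        se = se.where(counts != 1, 0.0)
        if (counts == 1).any().any():
            logger.warning(
                "%s: some vial/time cells aggregate a single trim; SEM "
                "reported as 0", name,
            )
        mean[name], sem[name], n[name] = mu, se, counts
    return TrimAggregate(mean=mean, sem=sem, n=n)


def write_summary_csvs(
    agg: TrimAggregate, out_dir: str | Path
) -> Dict[str, Path]:
    """Write position/lp/mp/hp CSVs: time_s, Vial_<k>, Vial_<k>_sem columns."""
    out_dir = Path(out_dir)
    out_dir.mkdir(parents=True, exist_ok=True)
    paths = {}
    for name in MODALITY_NAMES:
        mu, se = agg.mean[name], agg.sem[name]
        df = pd.DataFrame({"time_s": mu.index})
        for vial in mu.columns:
            df[f"Vial_{vial}"] = mu[vial].to_numpy()
            df[f"Vial_{vial}_sem"] = se[vial].to_numpy()
        path = out_dir / f"{name}.csv"
        df.to_csv(path, index=False)
        paths[name] = path
    return paths


def read_summary_csv(path: str | Path) -> pd.DataFrame:
    """Read a summary CSV back to a time-indexed frame of vial value columns."""
    df = pd.read_csv(path)
    if "time_s" not in df.columns:
        raise ValueError(f"{path}: missing time_s column")
    df = df.set_index("time_s")
    value_cols = [c for c in df.columns
                  if c.startswith("Vial_") and not c.endswith("_sem")]
    return df[value_cols]
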