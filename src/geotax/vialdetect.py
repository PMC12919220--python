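"""Vial localisation, metadata matching, and IoU evaluation.

The deployed assay locates the 12 vials with a learned object detector; this
module exposes that step behind a plain callable interface (any
``frame -> list[Detection]``) and ships a deterministic rule-based backend
that profiles column intensity to find the tall bright vial strips against
the white holder background.  Detections are confidence-filtered
(>= 0.85 by default), sorted left-to-right, matched positionally to the
metadata vial numbers, and written to CSV for the tracking stage.

Coordinate convention: pixel coordinates, origin top-left, y increasing
downward, boxes half-open [x1, x2) x [y1, y2).
"""

from __future__ import annotations

import json
from dataclasses import dataclass, field
from pathlib import Path
from typing import Callable, Iterable, List, Sequence, Tuple

import numpy as np
import pandas as pd

from geotax.io import red_channel

Box = Tuple[float, float, float, float]


class MissingVialsError(ValueError):
    """Metadata lists vials for which no detection survives filtering."""

    def __init__(self, missing: Sequence[int]):
        self.missing = sorted(int(v) for v in missing)
        super().__init__(f"no detection for metadata vials {self.missing}")


@dataclass(frozen=True)
class Detection:
    box: Box
    confidence: float
    label: str = "vial"

    def __post_init__(self) -> None:
        x1, y1, x2, y2 = self.box
        if not (x1 < x2 and y1 < y2):
            raise ValueError(f"degenerate box {self.box}")
        if not 0.0 <= self.confidence <= 1.0:
            raise ValueError("confidence must be in [0, 1]")


@dataclass(frozen=True)
class VialLayout:
    """Ordered vial boxes joined to metadata vial numbers."""

    entries: Tuple[Tuple[int, Box], ...]
    frame_size: Tuple[int, int]

    def __post_init__(self) -> None:
        nums = [n for n, _ in self.entries]
        if len(set(nums)) != len(nums):
            raise ValueError("duplicate vial numbers in layout")
        xs = [b[0] for _, b in self.entries]
        if xs != sorted(xs):
            raise ValueError("layout entries must be sorted by x1")

    def box_for(self, vial_num: int) -> Box:
        for n, b in self.entries:
            if n == vial_num:
                return b
        raise KeyError(vial_num)

    @property
    def vial_nums(self) -> List[int]:
        return [n for n, _ in self.entries]


def iou(box_a: Box, box_b: Box) -> float:
    """Intersection-over-union of two boxes; 0 when disjoint."""
    ax1, ay1, ax2, ay2 = box_a
    bx1, by1, bx2, by2 = box_b
    if ax1 >= ax2 or ay1 >= ay2 or bx1 >= bx2 or by1 >= by2:
        raise ValueError(f"degenerate box: {box_a} / {box_b}")
    iw = min(ax2, bx2) - max(ax1, bx1)
    ih = min(ay2, by2) - max(ay1, by1)
    if iw <= 0 or ih <= 0:
        return 0.0
    inter = iw * ih
    union = (ax2 - ax1) * (ay2 - ay1) + (bx2 - bx1) * (by2 - by1) - inter
    return inter / union


def detect_vials_rule_based(
    frame: np.ndarray,
    darkness_floor: float = 4.0,
    min_width_px: int = 4,
    min_height_px: int = 10,
) -> List[Detection]:
    """Find vials as tall, faintly dark vertical strips on a bright field.

    Column-mean darkness (relative to white, 255) is thresholded at
    ``darkness_floor`` grey levels; each contiguous column run wide enough to
    be a vial becomes a candidate, its vertical extent read off the row-mean
    darkness profile within the strip.  Confidence is the strip's mean
    darkness normalised by the strongest strip, so a uniformly populated
    holder yields near-1.0 confidences and a blank frame yields nothing.
    Deterministic.
    """
    grey = red_channel(np.asarray(frame)).astype(np.float64)
    h, w = grey.shape
    if h < 20 or w < 20:
        raise ValueError(f"frame {w}x{h} too small for vial detection")
    dark = np.clip(255.0 - grey, 0.0, None)
    col_profile = dark.mean(axis=0)

    runs: list[tuple[int, int]] = []
    above = col_profile > darkness_floor
    i = 0
    while i < w:
        if above[i]:
            j = i
            while j < w and above[j]:
                j += 1
            if j - i >= min_width_px:
                runs.append((i, j))
            i = j
        else:
            i += 1

    candidates: list[tuple[Box, float]] = []
    for x1, x2 in runs:
        row_profile = dark[:, x1:x2].mean(axis=1)
        rows = np.flatnonzero(row_profile > darkness_floor)
        if rows.size < min_height_px:
            continue
        y1, y2 = int(rows[0]), int(rows[-1]) + 1
        contrast = float(dark[y1:y2, x1:x2].mean())
        candidates.append(((float(x1), float(y1), float(x2), float(y2)), contrast))
    if not candidates:
        return []
    max_contrast = max(c for _, c in candidates)
    return [
        Detection(box=b, confidence=min(1.0, c / max_contrast))
        for b, c in candidates
    ]


def filter_sort_match(
    detections: Sequence[Detection],
    metadata: pd.DataFrame,
    min_confidence: float = 0.85,
    frame_size: Tuple[int, int] | None = None,
) -> VialLayout:
    """Confidence-filter, sort left-to-right, and join to metadata vials.

    Surviving detections are numbered positionally (leftmost = vial 1) and
    positions whose vial number is absent from the metadata are dropped.
    When exactly as many detections survive as there are metadata rows, the
    left-to-right order is matched directly to the sorted metadata vial
    numbers (so re-matching a layout's own boxes is the identity).  Fewer
    surviving detections than metadata rows is an error naming the missing
    vials.
    """
    required = sorted(int(v) for v in metadata["Vial_Num"])
    kept = sorted(
        (d for d in detections if d.confidence >= min_confidence),
        key=lambda d: d.box[0],
    )
    if len(kept) < len(required):
        raise MissingVialsError(required[len(kept):])
    if len(kept) == len(required):
        entries = tuple((num, d.box) for num, d in zip(required, kept))
    else:
        missing = [v for v in required if v > len(kept)]
        if missing:
            raise MissingVialsError(missing)
        entries = tuple(
            (i + 1, d.box) for i, d in enumerate(kept) if i + 1 in set(required)
        )
    if frame_size is None:
        x2 = max(b[2] for _, b in entries)
        y2 = max(b[3] for _, b in entries)
        frame_size = (int(np.ceil(x2)), int(np.ceil(y2)))
    return VialLayout(entries=entries, frame_size=frame_size)


# ---------------------------------------------------------------------------
# COCO annotations and layout CSV round-trips


@dataclass
class AnnotationSet:
    """Parsed COCO-style vial annotations."""

    images: List[dict] = field(default_factory=list)
    boxes: List[dict] = field(default_factory=list)  # image_id, x, y, w, h, category

    def boxes_for(self, image_id: int) -> List[Box]:
        return [
            (b["x"], b["y"], b["x"] + b["w"], b["y"] + b["h"])
            for b in self.boxes
            if b["image_id"] == image_id
        ]


def read_annotations(path: str | Path) -> AnnotationSet:
    """Read a COCO detection JSON (images/annotations/categories)."""
    path = Path(path)
    try:
        doc = json.loads(path.read_text())
    except json.JSONDecodeError as exc:
        raise ValueError(f"{path}: malformed JSON at char {exc.pos}: {exc.msg}") from exc
    categories = {c["id"]: c["name"] for c in doc.get("categories", [])}
    images = {im["id"]: im for im in doc.get("images", [])}
    out = AnnotationSet(images=list(images.values()))
    for ann in doc.get("annotations", []):
        img = images.get(ann["image_id"])
        if img is None:
            raise ValueError(
                f"{path}: annotation {ann.get('id')} references missing image "
                f"id {ann['image_id']}"
            )
        name = categories.get(ann["category_id"], "?")
        if name != "vial":
            raise ValueError(f"{path}: unexpected category {name!r}")
        x, y, w, h = ann["bbox"]
        if not (0 <= x and 0 <= y and x + w <= img["width"] and y + h <= img["height"]):
            raise ValueError(
                f"{path}: bbox {ann['bbox']} outside image {img['id']} bounds"
            )
        out.boxes.append(
            {"image_id": ann["image_id"], "x": x, "y": y, "w": w, "h": h,
             "category": name}
        )
    return out


LAYOUT_COLUMNS = ["vial_num", "x1", "y1", "x2", "y2"]


def write_layout_csv(layout: VialLayout, path: str | Path) -> Path:
    df = pd.DataFrame(
        [(n, *b) for n, b in layout.entries], columns=LAYOUT_COLUMNS
    )
    df.to_csv(path, index=False)
    return Path(path)


def read_layout_csv(path: str | Path, frame_size: Tuple[int, int] | None = None) -> VialLayout:
    path = Path(path)
    df = pd.read_csv(path)
    if list(df.columns) != LAYOUT_COLUMNS:
        raise ValueError(f"{path}: expected columns {LAYOUT_COLUMNS}")
    entries = tuple(
        (int(r.vial_num), (float(r.x1), float(r.y1), float(r.x2), float(r.y2)))
        for r in df.itertuples()
    )
    if frame_size is None:
        frame_size = (
            int(np.ceil(max(b[2] for _, b in entries))),
            int(np.ceil(max(b[3] for _, b in entries))),
        )
    return VialLayout(entries=entries, frame_size=frame_size)


# ---------------------------------------------------------------------------
# Detector evaluation


@dataclass
class DetectorEvaluation:
    mean_iou: float
    per_frame_mean: List[float]
    all_ious: List[float]


def _greedy_match(dets: Sequence[Box], truths: Sequence[Box]) -> List[float]:
    """IoU per ground-truth box under greedy highest-IoU pairing."""
    pairs = []
    for i, d in enumerate(dets):
        for j, t in enumerate(truths):
            pairs.append((iou(d, t), i, j))
    pairs.sort(key=lambda p: -p[0])
    used_d: set[int] = set()
    used_t: set[int] = set()
    scores = {j: 0.0 for j in range(len(truths))}
    for v, i, j in pairs:
        if i in used_d or j in used_t or v <= 0:
            continue
        scores[j] = v
        used_d.add(i)
        used_t.add(j)
    return [scores[j] for j in range(len(truths))]


def evaluate_detector(
    detector: Callable[[np.ndarray], Sequence[Detection]],
    annotated_frames: Iterable[tuple[np.ndarray, Sequence[Box]]],
) -> DetectorEvaluation:
    """Score a detector against ground-truth boxes.

    Detections are matched to ground truth greedily by highest IoU; every
    unmatched ground-truth box scores 0.  ``mean_iou`` averages over all
    ground-truth boxes of all frames.
    """
    all_ious: list[float] = []
    per_frame = []
    n_frames = 0
    for frame, truths in annotated_frames:
        n_frames += 1
        dets = [d.box for d in detector(frame)]
        scores = _greedy_match(dets, list(truths))
        all_ious.extend(scores)
        per_frame.append(float(np.mean(scores)) if scores else 0.0)
    if n_frames == 0:
        raise ValueError("need at least one annotated frame")
    mean = float(np.mean(all_ious)) if all_ious else 0.0
    return DetectorEvaluation(mean_iou=mean, per_frame_mean=per_frame, all_ious=all_ious)
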