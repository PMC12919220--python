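"""Recording, metadata and frame I/O.

A "recording" is either a video file (MP4/H264, decoded through imageio when
a codec backend is available) or a directory of numbered PNG frames named
``frame_000000.png`` onwards.  Frame directories are the canonical
representation used throughout the test suite because they are codec-free;
both forms are consumed identically downstream.
"""

from __future__ import annotations

import re
import shutil
import subprocess
from pathlib import Path
from typing import Iterable, List, Sequence

import imageio.v3 as iio
import numpy as np
import pandas as pd

METADATA_FILENAME = "geotaxis_metadata.csv"
METADATA_COLUMNS = ["Vial_Num", "Genotype", "Gender", "N"]
FRAME_DIR_NAME = "frames"
_FRAME_RE = re.compile(r"frame_(\d+)\.png$")


class MetadataError(ValueError):
    """Raised when a geotaxis_metadata.csv file violates its schema."""


def red_channel(frame: np.ndarray) -> np.ndarray:
    """Return the red channel of a frame (the frame itself if greyscale)."""
    if frame.ndim == 2:
        return frame
    if frame.ndim == 3:
        return frame[..., 0]
    raise ValueError(f"expected a 2-D or 3-D frame, got shape {frame.shape}")


def read_metadata(path: str | Path) -> pd.DataFrame:
    """Read and validate a per-recording metadata table.

    The file is comma-separated with the exact header
    ``Vial_Num,Genotype,Gender,N``; ``Gender`` must be ``M`` or ``F`` and
    ``Vial_Num``/``N`` integers.
    """
    path = Path(path)
    df = pd.read_csv(path)
    if list(df.columns) != METADATA_COLUMNS:
        raise MetadataError(
            f"{path}: expected columns {METADATA_COLUMNS}, found {list(df.columns)}"
        )
    bad_sex = set(df["Gender"].astype(str)) - {"M", "F"}
    if bad_sex:
        raise MetadataError(f"{path}: Gender values must be M or F, found {bad_sex}")
    try:
        df["Vial_Num"] = df["Vial_Num"].astype(int)
        df["N"] = df["N"].astype(int)
    except (TypeError, ValueError) as exc:
        raise MetadataError(f"{path}: Vial_Num and N must be integers") from exc
    if df["Vial_Num"].duplicated().any():
        raise MetadataError(f"{path}: duplicate Vial_Num entries")
    return df


def write_metadata(df: pd.DataFrame, path: str | Path) -> Path:
    path = Path(path)
    if list(df.columns) != METADATA_COLUMNS:
        raise MetadataError(f"expected columns {METADATA_COLUMNS}")
    df.to_csv(path, index=False)
    return path


def write_frames_dir(frames: Iterable[np.ndarray], directory: str | Path) -> Path:
    """Write frames as ``frame_%06d.png`` under *directory* (created fresh)."""
    directory = Path(directory)
    if directory.exists():
        shutil.rmtree(directory)
    directory.mkdir(parents=True)
    for i, frame in enumerate(frames):
        iio.imwrite(directory / f"frame_{i:06d}.png", np.asarray(frame, dtype=np.uint8))
    return directory


def list_frame_files(directory: str | Path) -> List[Path]:
    directory = Path(directory)
    files = []
    for p in directory.iterdir():
        m = _FRAME_RE.search(p.name)
        if m:
            files.append((int(m.group(1)), p))
    return [p for _, p in sorted(files)]


def read_frames_dir(directory: str | Path) -> List[np.ndarray]:
    files = list_frame_files(directory)
    if not files:
        raise FileNotFoundError(f"no frame_*.png files in {directory}")
    return [iio.imread(p) for p in files]


def find_recording(folder: str | Path) -> Path | None:
    """Locate the recording inside an experiment subfolder.

    Prefers a ``frames/`` directory; falls back to the first MP4/H264 file.
    Returns None when the folder holds neither.
    """
    folder = Path(folder)
    frame_dir = folder / FRAME_DIR_NAME
    if frame_dir.is_dir() and list_frame_files(frame_dir):
        return frame_dir
    for pattern in ("*.mp4", "*.h264"):
        hits = sorted(folder.glob(pattern))
        if hits:
            return hits[0]
    return None


def load_recording(source: str | Path) -> List[np.ndarray]:
    """Load all frames of a recording (frame directory or video file)."""
    source = Path(source)
    if source.is_dir():
        return read_frames_dir(source)
    try:
        return [np.asarray(f) for f in iio.imiter(source)]
    except Exception as exc:  # pragma: no cover - codec-dependent
        raise RuntimeError(
            f"could not decode {source}; no video backend available. "
            "Convert the recording to a frame directory instead."
        ) from exc


def transcode_h264_to_mp4(
    src: str | Path,
    dst: str | Path,
    fps: float = 60.0,
    qscale: int = 0,
) -> Path:
    """Thin ffmpeg wrapper: lossless-quality transcode at an explicit fps.

    The output frame rate is an explicit argument rather than a guessed
    default because H264 elementary streams carry no reliable rate.
    Requires an ``ffmpeg`` binary on PATH.
    """
    if shutil.which("ffmpeg") is None:
        raise RuntimeError("ffmpeg binary not found on PATH; cannot transcode")
    cmd = [
        "ffmpeg", "-y", "-r", str(fps), "-i", str(src),
        "-qscale", str(qscale), "-r", str(fps), str(dst),
    ]
    subprocess.run(cmd, check=True, capture_output=True)
    return Path(dst)


def frames_shape(frames: Sequence[np.ndarray]) -> tuple[int, int]:
    """(width, height) of a frame sequence, validating consistency."""
    shapes = {red_channel(np.asarray(f)).shape for f in frames}
    if len(shapes) != 1:
        raise ValueError(f"inconsistent frame shapes: {shapes}")
    h, w = next(iter(shapes))
    return w, h
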