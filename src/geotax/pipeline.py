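"""End-to-end orchestration over an experiment directory tree.

The experiment root holds one subfolder per recording (frames directory or
video plus ``geotaxis_metadata.csv``).  Each pending folder runs through
motion-energy trial splitting, vial detection, fly tracking and
summarisation; completed folders (all required outputs present and valid)
are skipped, so re-running a finished tree performs no per-folder
recomputation.  After the per-folder loop the experiment-wide aggregation
and, when a statistics spec is configured, the mixed-model comparison
reports are produced.  A manifest records per-folder status, the
configuration hash, and every seed used.
"""

from __future__ import annotations

import dataclasses
import hashlib
import json
import logging
import zlib
from dataclasses import dataclass, field, replace
from pathlib import Path
from typing import Dict, List, Optional, Sequence

import numpy as np
import yaml

from geotax import aggregate as gagg
from geotax import io as gio
from geotax import synthgen
from geotax._version import __version__
from geotax.flytrack import (
    TrackerConfig,
    aggregate_trims,
    read_summary_csv,
    summarize_trim,
    track_trim,
    write_summary_csvs,
)
from geotax.geostats import LMESpec, comparison_report
from geotax.trialsplit import (
    SplitterConfig,
    build_movement_trace,
    cut_segments,
    find_trials,
    segments_to_json,
)
from geotax.vialdetect import (
    detect_vials_rule_based,
    evaluate_detector,
    filter_sort_match,
    read_layout_csv,
    write_layout_csv,
)

logger = logging.getLogger(__name__)

MANIFEST_NAME = "geotax_manifest.json"
STATS_DIR = "Stats"


@dataclass(frozen=True)
class StatsSpec:
    control: str
    comparisons: tuple[str, ...]
    tmax: float = 13.0


@dataclass(frozen=True)
class PipelineConfig:
    seed: int = 0
    tracker: TrackerConfig = field(default_factory=TrackerConfig)
    splitter: SplitterConfig = field(default_factory=SplitterConfig)
    #: rescale area thresholds / image height to the recording's resolution
    auto_scale: bool = True
    min_confidence: float = 0.85
    #: fixed detection frame index within each trim; None = seeded random
    detect_frame: Optional[int] = None
    stats: Optional[StatsSpec] = None
    make_plots: bool = True

    def to_dict(self) -> dict:
        # json round-trip turns tuples into plain lists for YAML/JSON output
        return json.loads(json.dumps(dataclasses.asdict(self)))

    @property
    def config_hash(self) -> str:
        blob = json.dumps(self.to_dict(), sort_keys=True, default=str)
        return hashlib.sha1(blob.encode()).hexdigest()[:12]

    def to_yaml(self, path: str | Path) -> Path:
        Path(path).write_text(yaml.safe_dump(self.to_dict()))
        return Path(path)

    @classmethod
    def from_yaml(cls, path: str | Path) -> "PipelineConfig":
        doc = yaml.safe_load(Path(path).read_text()) or {}
        tracker = TrackerConfig(**doc.pop("tracker", {}))
        splitter = SplitterConfig(**doc.pop("splitter", {}))
        stats_doc = doc.pop("stats", None)
        stats = None
        if stats_doc:
            stats_doc["comparisons"] = tuple(stats_doc.get("comparisons", ()))
            stats = StatsSpec(**stats_doc)
        return cls(tracker=tracker, splitter=splitter, stats=stats, **doc)


def discover_folders(root: str | Path) -> tuple[List[Path], Dict[str, str]]:
    """Experiment subfolders in lexicographic order.

    Returns (valid folders, {folder name: reason} for malformed ones).  A
    valid folder holds a recording (frame directory or video file) and the
    metadata CSV.
    """
    root = Path(root)
    if not root.exists():
        raise FileNotFoundError(root)
    valid, rejected = [], {}
    for sub in sorted(p for p in root.iterdir() if p.is_dir()):
        if sub.name in (STATS_DIR, *gagg.OUTPUT_DIRS.values()):
            continue
        has_meta = (sub / gio.METADATA_FILENAME).exists()
        has_recording = gio.find_recording(sub) is not None
        if has_meta and has_recording:
            valid.append(sub)
        elif has_meta or has_recording:
            missing = "metadata" if not has_meta else "recording"
            rejected[sub.name] = f"missing {missing}"
        # folders with neither are unrelated and silently ignored
    return valid, rejected


def folder_complete(folder: Path) -> bool:
    """True when all required outputs exist and pass schema validation."""
    analysis = folder / gagg.ANALYSIS_DIR
    try:
        for m in gagg.SUMMARY_FILES:
            read_summary_csv(analysis / f"{m}.csv")
        vial_csvs = sorted(analysis.glob("vials_trim*.csv"))
        if not vial_csvs:
            return False
        for p in vial_csvs:
            read_layout_csv(p)
    except (OSError, ValueError):
        return False
    return True


def _folder_seed(config_seed: int, folder_name: str, trim_index: int) -> int:
    return (config_seed * 1_000_003 + zlib.crc32(folder_name.encode())
            + trim_index) % (2**31)


def process_folder(folder: Path, config: PipelineConfig) -> dict:
    """Run conversion-free splitting, detection, tracking and summarisation."""
    folder = Path(folder)
    analysis = folder / gagg.ANALYSIS_DIR
    analysis.mkdir(exist_ok=True)
    meta = gio.read_metadata(folder / gio.METADATA_FILENAME)
    recording = gio.find_recording(folder)
    if recording is None:
        raise FileNotFoundError(f"{folder}: no recording")
    frames = gio.load_recording(recording)
    w, h = gio.frames_shape(frames)

    splitter = config.splitter.scaled((w, h)) if config.auto_scale else config.splitter
    tracker = config.tracker
    if config.auto_scale and tracker.image_height_px != h:
        tracker = replace(tracker, image_height_px=float(h))

    trace = build_movement_trace(frames, splitter, fps=tracker.fps)
    trace.to_csv(analysis / "movement_trace.csv")
    segments = find_trials(trace, splitter)
    (analysis / "segments.json").write_text(
        json.dumps(segments_to_json(segments), indent=1)
    )
    if not segments:
        raise RuntimeError(f"{folder}: no trials found in movement trace")

    trims = cut_segments(frames, segments)
    detect_frames: Dict[int, int] = {}
    summaries = []
    for seg, trim in zip(segments, trims):
        if config.detect_frame is not None:
            idx = min(config.detect_frame, len(trim) - 1)
        else:
            rng = np.random.default_rng(
                _folder_seed(config.seed, folder.name, seg.index)
            )
            idx = int(rng.integers(len(trim)))
        detect_frames[seg.index] = idx
        detections = detect_vials_rule_based(trim[idx])
        layout = filter_sort_match(
            detections, meta, min_confidence=config.min_confidence,
            frame_size=(w, h),
        )
        write_layout_csv(layout, analysis / f"vials_trim{seg.index}.csv")
        records = track_trim(trim, layout, tracker, trim_index=seg.index)
        summaries.append(summarize_trim(records, layout, tracker, seg.index))
    agg = aggregate_trims(summaries)
    write_summary_csvs(agg, analysis)
    if config.make_plots:
        from geotax.plots import plot_trim_aggregate

        plot_trim_aggregate(agg, analysis / "plots")
    return {"detect_frames": detect_frames, "n_trims": len(summaries)}


def run_statistics(
    root: Path, tables: gagg.ExperimentTables, config: PipelineConfig
) -> None:
    stats_dir = Path(root) / STATS_DIR
    stats_dir.mkdir(exist_ok=True)
    spec = LMESpec(
        control=config.stats.control,
        comparisons=config.stats.comparisons,
        tmax=config.stats.tmax,
    )
    for sex in gagg.SEXES:
        sex_tables = {
            m: tables.get(sex, m)
            for m in gagg.MODALITIES
            if not tables.get(sex, m).empty
        }
        if not sex_tables:
            logger.warning("no data for sex %s; statistics skipped", sex)
            continue
        report = comparison_report(spec, sex_tables, sex=sex)
        report.write_csv(stats_dir / f"pvalues_{sex}.csv")
        report.write_json(stats_dir / f"pvalues_{sex}.json")
        if config.make_plots:
            from geotax.plots import plot_comparison_panels

            plot_comparison_panels(report, sex_tables, stats_dir / f"plots_{sex}")


def run_pipeline(
    root: str | Path,
    config: PipelineConfig = PipelineConfig(),
    stats_only: bool = False,
) -> dict:
    """Process every pending folder, then aggregate and run statistics.

    Returns the manifest (also written to ``geotax_manifest.json`` in the
    root).  A stage failure marks its folder failed and the pipeline
    continues.
    """
    root = Path(root)
    folders, rejected = discover_folders(root)
    manifest: dict = {
        "root": str(root),
        "version": __version__,
        "config": config.to_dict(),
        "config_hash": config.config_hash,
        "seed": config.seed,
        "folders": {name: {"status": "failed", "reason": why}
                    for name, why in rejected.items()},
    }
    completed: List[Path] = []
    for folder in folders:
        entry: dict = {"status": "pending"}
        manifest["folders"][folder.name] = entry
        if folder_complete(folder):
            entry["status"] = "complete"
            entry["skipped"] = True
            completed.append(folder)
            continue
        if stats_only:
            entry["status"] = "failed"
            entry["reason"] = "incomplete folder in --stats-only run"
            continue
        try:
            info = process_folder(folder, config)
        except Exception as exc:  # noqa: BLE001 - batch robustness
            logger.exception("folder %s failed", folder.name)
            entry["status"] = "failed"
            entry["reason"] = f"{type(exc).__name__}: {exc}"
            continue
        entry.update(status="complete", skipped=False, **info)
        completed.append(folder)

    if completed:
        tables = gagg.collect_experiment(completed)
        tables.write(root)
        if config.make_plots:
            from geotax.plots import MODALITY_LABELS, plot_genotype_curves

            for (sex, modality), df in tables.tables.items():
                if df.empty:
                    continue
                d = root / gagg.OUTPUT_DIRS[sex]
                plot_genotype_curves(
                    df, d / f"{modality}.png",
                    ylabel=MODALITY_LABELS.get(modality, modality),
                )
        if config.stats is not None:
            run_statistics(root, tables, config)
    (root / MANIFEST_NAME).write_text(json.dumps(manifest, indent=1, default=str))
    return manifest


# ---------------------------------------------------------------------------
# Synthetic experiments and benchmarks


#: behavioural presets.  Both genotypes climb at the same instantaneous
#: speed, wander once they reach the vial top, and occasionally slip back to
#: the bottom with a per-fly endurance onset; the collapse mutant differs
#: only in slipping four times as often, so sustained height gain breaks
#: down mid-assay while instantaneous climbing velocity is unchanged.
CONTROL_KINEMATICS = dict(
    climb_speed_cm_s=3.0, speed_sd=0.8, stall_prob=0.2, wander_speed_cm_s=1.2,
    slip_prob=1.0 / (12.0 * 60.0), slip_start_s=3.0, slip_onset_spread_s=10.0,
)
COLLAPSE_KINEMATICS = dict(
    climb_speed_cm_s=3.0, speed_sd=0.8, stall_prob=0.2, wander_speed_cm_s=1.2,
    slip_prob=1.0 / (3.0 * 60.0), slip_start_s=3.0, slip_onset_spread_s=10.0,
)


def synthesize_experiment(
    root: str | Path,
    n_folders: int = 2,
    scale: float = 0.25,
    seed: int = 0,
    scenario: str = "collapse",
    n_flies: int = 6,
    n_vials: int = 12,
    pause_frames: int = 820,
    n_cycles: int = 4,
    sexes: Sequence[str] = ("M", "F"),
    control_name: str = "w1118",
    mutant_name: str = "clkout",
) -> List[Path]:
    """Write a ready-to-analyse synthetic experiment tree.

    Each recording's vials split evenly between the control genotype and
    either a second identical genotype (``scenario="uniform"``) or the
    mid-assay collapse mutant (``scenario="collapse"``), and between the
    requested sexes.
    """
    root = Path(root)
    root.mkdir(parents=True, exist_ok=True)
    mutant_kin = (
        CONTROL_KINEMATICS if scenario == "uniform" else COLLAPSE_KINEMATICS
    )
    if scenario not in ("uniform", "collapse"):
        raise ValueError(f"unknown scenario {scenario!r}")
    folders = []
    for k in range(n_folders):
        scene = synthgen.scaled_scene(
            scale=scale,
            n_vials=n_vials,
            n_cycles=n_cycles,
            pause_frames=pause_frames,
            seed=seed * 10_007 + k,
        )
        kinematics, labels = [], []
        for v in range(1, n_vials + 1):
            sex = sexes[(v - 1) * len(sexes) // n_vials]
            is_mutant = (v - 1) % 2 == 1
            params = mutant_kin if is_mutant else CONTROL_KINEMATICS
            kinematics.append(
                synthgen.FlyKinematics(vial_num=v, n_flies=n_flies, **params)
            )
            labels.append((mutant_name if is_mutant else control_name, sex))
        folder = root / f"Set{k + 1}_synth"
        synthgen.write_experiment_folder(folder, scene, kinematics, labels)
        folders.append(folder)
    return folders


def detector_benchmark(
    n_frames: int = 50, seed: int = 0, scale: float = 1.0, n_flies: int = 5
):
    """Mean IoU of the rule-based detector over seeded synthetic frames.

    Renders ``n_frames`` independently seeded holder frames with the
    standard fully-populated layout and scores detections against the known
    vial boxes under greedy matching.
    """
    def annotated():
        for k in range(n_frames):
            scene = synthgen.scaled_scene(
                scale=scale, n_cycles=1, pause_frames=30,
                seed=seed * 65_537 + k,
            )
            kin = [
                synthgen.FlyKinematics(vial_num=v, n_flies=n_flies,
                                       climb_speed_cm_s=1.0, speed_sd=0.3,
                                       stall_prob=0.2)
                for v in range(1, scene.n_vials + 1)
            ]
            frame, gt = synthgen.render_frame(scene, kin, frame_index=20)
            yield frame, [(x1, y1, x2, y2) for _, x1, y1, x2, y2 in gt.boxes]

    return evaluate_detector(detect_vials_rule_based, annotated())
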