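"""Experiment-wide aggregation into sex-split, replicate-labelled tables.

Each recording folder contributes one vial per metadata row.  Vials are the
biological replicates: every vial receives a label ``<Genotype>_rep<N>``
where N counts occurrences of that genotype within the same sex across the
whole experiment (folders processed in lexicographic order so labels are
stable).  The result is ten wide tables — {male, female} x {position,
velocity, LP, MP, HP} — with one row per replicate and one column per time
point in seconds; velocity is the numerical gradient of climbing height
against the (possibly non-uniform) time grid, computed per replicate before
any averaging.
"""

from __future__ import annotations

import logging
from dataclasses import dataclass, field
from pathlib import Path
from typing import Dict, List, Sequence, Tuple

import numpy as np
import pandas as pd

from geotax import io as gio
from geotax.flytrack import read_summary_csv

logger = logging.getLogger(__name__)

SEXES = ("M", "F")
MODALITIES = ("position", "velocity", "lp", "mp", "hp")
#: measurement files expected in each folder's analysis directory
SUMMARY_FILES = ("position", "lp", "mp", "hp")
ANALYSIS_DIR = "analysis"
OUTPUT_DIRS = {"M": "Output Males", "F": "Output Females"}


@dataclass
class ExperimentTables:
    """The ten modality tables, keyed by (sex, modality)."""

    tables: Dict[Tuple[str, str], pd.DataFrame] = field(default_factory=dict)
    errors: List[str] = field(default_factory=list)

    def get(self, sex: str, modality: str) -> pd.DataFrame:
        return self.tables[(sex, modality)]

    def write(self, out_root: str | Path) -> Dict[Tuple[str, str], Path]:
        """Write all tables as CSVs under 'Output Males'/'Output Females'."""
        out_root = Path(out_root)
        paths = {}
        for (sex, modality), df in self.tables.items():
            d = out_root / OUTPUT_DIRS[sex]
            d.mkdir(parents=True, exist_ok=True)
            p = d / f"{modality}.csv"
            df.rename_axis("replicate").to_csv(p)
            paths[(sex, modality)] = p
        return paths


def read_modality_table(path: str | Path) -> pd.DataFrame:
    df = pd.read_csv(path, index_col=0)
    df.columns = [float(c) for c in df.columns]
    return df


def replicate_genotype(label: str) -> str:
    """Genotype prefix of a replicate label (text before the final '_rep')."""
    return label.rsplit("_rep", 1)[0]


def velocity_from_position(position: pd.DataFrame) -> pd.DataFrame:
    """Instantaneous climbing speed (cm/s) per replicate.

    Numerical gradient against the actual time grid: central differences at
    interior points, one-sided at the two ends; exact on linear series.
    """
    times = np.asarray([float(c) for c in position.columns])
    if times.size < 2:
        raise ValueError("velocity needs at least 2 time points")
    vel = np.gradient(position.to_numpy(dtype=float), times, axis=1)
    return pd.DataFrame(vel, index=position.index, columns=position.columns)


def collect_experiment(
    folders: Sequence[str | Path],
) -> ExperimentTables:
    """Build the ten sex x modality tables from per-recording summaries.

    Every folder must hold ``geotaxis_metadata.csv`` and an ``analysis``
    directory with the four summary CSVs (position/lp/mp/hp) written by the
    tracking stage.  Folders are processed in lexicographic order; a folder
    with missing files is skipped with an error record, and a metadata vial
    absent from its folder's summaries triggers a warning, not a failure.
    Time grids are merged on the union of exact time values; cells a
    recording did not observe stay NaN.
    """
    folders = sorted(Path(f) for f in folders)
    out = ExperimentTables()
    counters: Dict[Tuple[str, str], int] = {}
    series: Dict[Tuple[str, str], Dict[str, pd.Series]] = {
        (sex, m): {} for sex in SEXES for m in SUMMARY_FILES
    }
    for folder in folders:
        meta_path = folder / gio.METADATA_FILENAME
        analysis = folder / ANALYSIS_DIR
        missing = [
            p.name
            for p in [meta_path, *(analysis / f"{m}.csv" for m in SUMMARY_FILES)]
            if not p.exists()
        ]
        if missing:
            msg = f"{folder}: missing {missing}; folder skipped"
            logger.error(msg)
            out.errors.append(msg)
            continue
        meta = gio.read_metadata(meta_path)
        summaries = {
            m: read_summary_csv(analysis / f"{m}.csv") for m in SUMMARY_FILES
        }
        for row in meta.itertuples():
            sex = str(row.Gender)
            genotype = str(row.Genotype)
            col = f"Vial_{int(row.Vial_Num)}"
            available = all(
                col in s.columns and s[col].notna().any()
                for s in summaries.values()
            )
            if not available:
                logger.warning(
                    "%s: vial %s (%s, %s) absent from summaries; row skipped",
                    folder, row.Vial_Num, genotype, sex,
                )
                continue
            counters[(sex, genotype)] = counters.get((sex, genotype), 0) + 1
            label = f"{genotype}_rep{counters[(sex, genotype)]}"
            for m in SUMMARY_FILES:
                series[(sex, m)][label] = summaries[m][col]
    for sex in SEXES:
        for m in SUMMARY_FILES:
            data = series[(sex, m)]
            if not data:
                logger.warning("no %s replicates for sex %s", m, sex)
                df = pd.DataFrame()
            else:
                df = pd.DataFrame(data).T
                df = df[sorted(df.columns, key=float)]
                df.index.name = "replicate"
            out.tables[(sex, m)] = df
        pos = out.tables[(sex, "position")]
        out.tables[(sex, "velocity")] = (
            velocity_from_position(pos) if pos.shape[1] >= 2 else pd.DataFrame()
        )
    return out


def genotype_curves(table: pd.DataFrame) -> pd.DataFrame:
    """Per-genotype mean, SEM and replicate count at every time point.

    Returns a long frame with columns genotype, time_s, mean, sem, n.
    SEM for a single replicate is reported as 0 and flagged.
    """
    if table.empty:
        raise ValueError("empty modality table")
    rows = []
    groups = table.groupby([replicate_genotype(i) for i in table.index])
    for genotype, sub in groups:
        mu = sub.mean(axis=0)
        n = sub.notna().sum(axis=0)
        sd = sub.std(axis=0, ddof=1)
        sem = (sd / np.sqrt(n)).where(n != 1, 0.0)
        if (n == 1).any():
            logger.warning("genotype %s has single-replicate time points; "
                           "SEM reported as 0", genotype)
        for t in table.columns:
            rows.append((genotype, float(t), mu[t], sem[t], int(n[t])))
    return pd.DataFrame(rows, columns=["genotype", "time_s", "mean", "sem", "n"])
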