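"""Figure output: trajectory bands, HMP bars, and -log10(p) heatmaps."""

from __future__ import annotations

from pathlib import Path
from typing import Dict

import matplotlib

matplotlib.use("Agg")

import matplotlib.pyplot as plt
import numpy as np
import pandas as pd
import seaborn as sns

from geotax.aggregate import MODALITIES, genotype_curves
from geotax.flytrack import MODALITY_NAMES, TrimAggregate

MODALITY_LABELS = {
    "position": "Mean climbing height (cm)",
    "velocity": "Climbing velocity (cm/s)",
    "lp": "Low performers (%)",
    "mp": "Middle performers (%)",
    "hp": "High performers (%)",
}


def plot_trim_aggregate(agg: TrimAggregate, out_dir: str | Path) -> list[Path]:
    """Per-vial mean +/- SEM lines over the trial window, one PNG per modality."""
    out_dir = Path(out_dir)
    out_dir.mkdir(parents=True, exist_ok=True)
    paths = []
    for name in MODALITY_NAMES:
        mu, se = agg.mean[name], agg.sem[name]
        fig, ax = plt.subplots(figsize=(7, 4))
        for vial in mu.columns:
            t = mu.index.to_numpy(dtype=float)
            m = mu[vial].to_numpy(dtype=float)
            s = se[vial].to_numpy(dtype=float)
            ax.plot(t, m, label=f"Vial {vial}", lw=1)
            ax.fill_between(t, m - s, m + s, alpha=0.2)
        ax.set_xlabel("Time (s)")
        ax.set_ylabel(MODALITY_LABELS.get(name, name))
        ax.legend(fontsize=6, ncol=4)
        fig.tight_layout()
        p = out_dir / f"{name}.png"
        fig.savefig(p, dpi=110)
        plt.close(fig)
        paths.append(p)
    return paths


def plot_genotype_curves(
    table: pd.DataFrame, out_path: str | Path, ylabel: str = ""
) -> Path:
    """Genotype mean +/- SEM curves with replicate counts in the legend."""
    curves = genotype_curves(table)
    fig, ax = plt.subplots(figsize=(7, 4))
    for genotype, sub in curves.groupby("genotype"):
        n = int(sub["n"].max())
        ax.plot(sub["time_s"], sub["mean"], label=f"{genotype} (N={n})")
        ax.fill_between(
            sub["time_s"],
            sub["mean"] - sub["sem"],
            sub["mean"] + sub["sem"],
            alpha=0.25,
        )
    ax.set_xlabel("Time (s)")
    ax.set_ylabel(ylabel)
    ax.legend()
    fig.tight_layout()
    fig.savefig(out_path, dpi=110)
    plt.close(fig)
    return Path(out_path)


def plot_comparison_panels(
    report, tables: Dict[str, pd.DataFrame], out_dir: str | Path
) -> list[Path]:
    """Four-panel summary per comparison genotype.

    Panels: position trajectory with SEM bands and reference lines at time
    zero and tmax; bar chart of -log10 HMP for the remaining modalities;
    per-replicate position peaks; heatmap of time-resolved -log10(p) from
    the Mann-Whitney grid.
    """
    from geotax.geostats import peak_metrics
    from geotax.aggregate import replicate_genotype

    out_dir = Path(out_dir)
    out_dir.mkdir(parents=True, exist_ok=True)
    spec = report.spec
    paths = []
    position = tables.get("position")
    for g in spec.comparisons:
        col = f"{spec.control} vs {g}"
        fig, axes = plt.subplots(2, 2, figsize=(11, 7))
        ax = axes[0, 0]
        if position is not None and not position.empty:
            keep = [
                i for i in position.index
                if replicate_genotype(i) in (spec.control, g)
            ]
            curves = genotype_curves(position.loc[keep])
            for genotype, sub in curves.groupby("genotype"):
                ax.plot(sub["time_s"], sub["mean"],
                        label=f"{genotype} (N={int(sub['n'].max())})")
                ax.fill_between(sub["time_s"], sub["mean"] - sub["sem"],
                                sub["mean"] + sub["sem"], alpha=0.25)
            lme_cell = report.cells.loc["position_LME", col]
            ax.set_title(f"Position trajectories, LME {lme_cell}", fontsize=9)
            ax.axvline(0.0, color="grey", ls="--", lw=0.8)
            ax.axvline(spec.tmax, color="grey", ls="--", lw=0.8)
            ax.set_xlabel("Time (s)")
            ax.set_ylabel(MODALITY_LABELS["position"])
            ax.legend(fontsize=8)

        ax = axes[0, 1]
        names, heights = [], []
        for m in MODALITIES:
            p = report.pvalues[col].get(f"{m}_LME")
            if p is not None:
                names.append(m)
                heights.append(-np.log10(max(p, 1e-300)))
        ax.bar(names, heights, color="tab:orange")
        ax.axhline(-np.log10(0.05), color="red", ls="--", lw=0.8)
        ax.set_ylabel("-log10(LME HMP)")
        ax.set_title("Trajectory significance by modality", fontsize=9)

        ax = axes[1, 0]
        if position is not None and not position.empty:
            peaks = peak_metrics(position, tmax=spec.tmax)
            groups = {
                name: peaks[[i for i in peaks.index
                             if replicate_genotype(i) == name]]
                for name in (spec.control, g)
            }
            for i, (name, vals) in enumerate(groups.items()):
                jitter = np.linspace(-0.15, 0.15, len(vals))
                ax.bar([i], [vals.mean()], width=0.6, alpha=0.4)
                ax.plot(np.full(len(vals), i) + jitter, vals.to_numpy(), "ko",
                        ms=3)
            ax.set_xticks([0, 1], [spec.control, g])
            ax.set_ylabel("Peak height (cm)")
            ax.set_title(
                f"Peaks, MWU {report.cells.loc['position_Peak', col]}",
                fontsize=9,
            )

        ax = axes[1, 1]
        grid_rows = []
        for m in MODALITIES:
            grid = report.mwu_grids.get((m, g))
            if grid is not None and not grid.empty:
                grid_rows.append(
                    pd.Series(grid["neglog10p"].to_numpy(),
                              index=grid["time_s"], name=m)
                )
        if grid_rows:
            heat = pd.DataFrame(grid_rows)
            sns.heatmap(heat, ax=ax, cmap="YlOrRd", vmin=0.0, vmax=3.0,
                        cbar_kws={"label": "-log10(p)"})
            ax.set_xlabel("Time (s)")
            ax.set_title("Time-resolved Mann-Whitney divergence", fontsize=9)

        fig.suptitle(f"{spec.control} vs {g} ({report.sex})")
        fig.tight_layout()
        p = out_dir / f"comparison_{spec.control}_vs_{g}.png"
        fig.savefig(p, dpi=110)
        plt.close(fig)
        paths.append(p)
    return paths
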