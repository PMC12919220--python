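"""Genotype x time statistics for geotaxis time series.

For each sex and modality, replicate-level wide tables are melted into a
long table (genotype, replicate, time, measurement, subject) and a linear
mixed-effects model is fitted by REML:

    y_ijt = b0 + b_geno + b_time + b_genoxtime + u_j + u1_j * t + e_ijt

with treatment-coded genotype (control as reference), time entering the
fixed effects as a categorical factor, and a per-subject random intercept
and random slope on numeric time.  Fixed-effect significance comes from
Wald z-tests; the genotype main effect and all genotype x time interaction
p-values of one comparison genotype are combined with the (unweighted)
harmonic mean p-value

    HMP = min(1, r / sum_i 1 / (p_i + eps)),

a conservative combination that remains valid under dependence.  Two
non-parametric complements are provided: a Mann-Whitney U test per time
point (rendered as -log10(p) heatmaps) and a U test on per-replicate peak
values over the trial window.
"""

from __future__ import annotations

import json
import logging
import warnings
from dataclasses import dataclass, field
from pathlib import Path
from typing import Dict, List, Optional, Sequence

import numpy as np
import pandas as pd
from scipy import stats
import statsmodels.formula.api as smf

from geotax.aggregate import MODALITIES, replicate_genotype

logger = logging.getLogger(__name__)


@dataclass(frozen=True)
class LMESpec:
    """Which genotypes to compare, up to which time, for which modality."""

    control: str
    comparisons: tuple[str, ...]
    tmax: float
    modality: str = "position"

    def __post_init__(self) -> None:
        if self.control in self.comparisons:
            raise ValueError("control genotype cannot also be a comparison")
        if self.tmax <= 0:
            raise ValueError("tmax must be positive")
        object.__setattr__(self, "comparisons", tuple(self.comparisons))


def build_long_table(table: pd.DataFrame, spec: LMESpec) -> pd.DataFrame:
    """Melt a wide replicate x time table into the long analysis form.

    Keeps only the control and comparison genotypes and observations with
    time <= tmax.  Columns: Genotype, Replicate, Time, Measurement, Subject
    (= "<genotype>_<replicate id>", which the replicate label already is).
    """
    wanted = {spec.control, *spec.comparisons}
    genotypes = pd.Series(
        [replicate_genotype(i) for i in table.index], index=table.index
    )
    if spec.control not in set(genotypes):
        raise ValueError(f"control genotype {spec.control!r} absent from table")
    sub = table.loc[genotypes.isin(wanted)]
    rows = []
    for label, series in sub.iterrows():
        g = replicate_genotype(label)
        rep = label.rsplit("_rep", 1)[1]
        for t, y in series.items():
            t = float(t)
            if t > spec.tmax or pd.isna(y):
                continue
            rows.append((g, rep, t, float(y), label))
    long = pd.DataFrame(
        rows, columns=["Genotype", "Replicate", "Time", "Measurement", "Subject"]
    )
    if long.empty:
        raise ValueError("no observations at or below tmax")
    return long


def star_annotation(p: float) -> str:
    """Significance stars: *** p<=0.001, ** p<=0.01, * p<=0.05, else NS."""
    if not 0.0 <= p <= 1.0:
        raise ValueError(f"p-value {p} outside [0, 1]")
    if p <= 0.001:
        return "***"
    if p <= 0.01:
        return "**"
    if p <= 0.05:
        return "*"
    return "NS"


def harmonic_mean_p(pvalues: Sequence[float], epsilon: float = 1e-12) -> float:
    """Unweighted harmonic-mean combination of dependent p-values.

    ``min(1, r / sum_i 1/(p_i + epsilon))`` with a tiny epsilon guarding
    p_i = 0.  Equals the common value when all p_i are equal.
    """
    p = np.asarray(list(pvalues), dtype=float)
    if p.size == 0:
        raise ValueError("harmonic_mean_p of an empty list")
    if np.any((p < 0) | (p > 1)) or np.any(~np.isfinite(p)):
        raise ValueError("p-values must lie in [0, 1]")
    return float(min(1.0, p.size / np.sum(1.0 / (p + epsilon))))


@dataclass
class GenotypeComparison:
    """One comparison genotype's terms from a fitted model."""

    genotype: str
    main_p: float
    interaction_ps: Dict[str, float]
    hmp: float
    stars: str


@dataclass
class LMEResult:
    """Fitted fixed effects, variance components, and combined p-values."""

    fixed_effects: pd.DataFrame  # term, estimate, se, p
    cov_re: pd.DataFrame  # random intercept/slope covariance
    resid_var: float
    comparisons: Dict[str, GenotypeComparison]
    converged: bool
    n_obs: int
    n_subjects: int

    def summary(self) -> str:
        lines = [
            f"Linear mixed-effects fit (REML), {self.n_obs} obs, "
            f"{self.n_subjects} subjects; converged={self.converged}",
            f"residual variance {self.resid_var:.4g}; random-effect cov:",
            self.cov_re.to_string(),
            "",
            self.fixed_effects.to_string(index=False),
            "",
        ]
        for comp in self.comparisons.values():
            lines.append(
                f"{comp.genotype}: main p={comp.main_p:.4g}, "
                f"{len(comp.interaction_ps)} interactions, "
                f"HMP={comp.hmp:.4g} ({comp.stars})"
            )
        return "\n".join(lines)


def fit_lme(long: pd.DataFrame, control: str) -> LMEResult:
    """Fit the genotype x categorical-time mixed model by REML.

    Random structure: per-subject intercept and slope on numeric time.
    A singular or non-converged fit is returned flagged rather than raised;
    insufficient replication (fewer than two subjects per genotype or two
    time points) is an error.
    """
    for g, sub in long.groupby("Genotype"):
        if sub["Subject"].nunique() < 2:
            raise ValueError(f"genotype {g} has fewer than 2 subjects")
    if long["Time"].nunique() < 2:
        raise ValueError("need at least 2 time points")
    comparisons = sorted(set(long["Genotype"]) - {control})
    formula = (
        f'Measurement ~ C(Genotype, Treatment(reference="{control}")) * C(Time)'
    )
    model = smf.mixedlm(formula, data=long, groups=long["Subject"],
                        re_formula="~Time")
    converged = True
    with warnings.catch_warnings():
        warnings.simplefilter("ignore")
        try:
            result = model.fit(reml=True)
            converged = bool(getattr(result, "converged", True))
        except np.linalg.LinAlgError:
            logger.warning("singular LME fit; retrying with simplified start")
            result = model.fit(reml=True, method="powell")
            converged = False
    fe_terms = list(result.fe_params.index)
    fixed = pd.DataFrame(
        {
            "term": fe_terms,
            "estimate": result.fe_params.to_numpy(),
            "se": result.bse.loc[fe_terms].to_numpy(),
            "p": result.pvalues.loc[fe_terms].to_numpy(),
        }
    )
    out: Dict[str, GenotypeComparison] = {}
    for g in comparisons:
        marker = f"[T.{g}]"
        main_terms = [t for t in fe_terms if marker in t and ":" not in t]
        inter_terms = [t for t in fe_terms if marker in t and ":" in t]
        if len(main_terms) != 1:
            raise RuntimeError(f"could not locate main effect for {g!r}")
        main_p = float(result.pvalues[main_terms[0]])
        inter = {t: float(result.pvalues[t]) for t in inter_terms}
        ps = [main_p, *inter.values()]
        finite = [p for p in ps if np.isfinite(p)]
        if len(finite) < len(ps):
            logger.warning("%s: %d inestimable Wald p-values dropped from HMP",
                           g, len(ps) - len(finite))
        hmp = harmonic_mean_p(finite)
        out[g] = GenotypeComparison(
            genotype=g, main_p=main_p, interaction_ps=inter,
            hmp=hmp, stars=star_annotation(hmp),
        )
    if not converged:
        logger.warning("LME fit did not fully converge; p-values reported "
                       "from the flagged fit")
    return LMEResult(
        fixed_effects=fixed,
        cov_re=pd.DataFrame(result.cov_re),
        resid_var=float(result.scale),
        comparisons=out,
        converged=converged,
        n_obs=len(long),
        n_subjects=long["Subject"].nunique(),
    )


def simulate_lme_dataset(
    rng: np.random.Generator,
    n_subjects_per_genotype: int = 20,
    n_timepoints: int = 5,
    beta0: float = 1.0,
    genotype_offset: float = 0.0,
    sigma_b: float = 0.5,
    sigma_b1: float = 0.0,
    sigma_e: float = 0.3,
    genotypes: tuple[str, str] = ("ctrl", "mut"),
) -> pd.DataFrame:
    """Draw a long table from the mixed-model equation itself.

    Used for calibration studies: type-I error of the genotype main effect
    under ``genotype_offset=0`` and power under a constant offset.
    """
    times = np.arange(n_timepoints, dtype=float)
    rows = []
    for gi, g in enumerate(genotypes):
        for j in range(n_subjects_per_genotype):
            subject = f"{g}_rep{j + 1}"
            b = rng.normal(0.0, sigma_b)
            b1 = rng.normal(0.0, sigma_b1) if sigma_b1 > 0 else 0.0
            for t in times:
                y = (
                    beta0
                    + (genotype_offset if gi == 1 else 0.0)
                    + b + b1 * t
                    + rng.normal(0.0, sigma_e)
                )
                rows.append((g, str(j + 1), t, y, subject))
    return pd.DataFrame(
        rows, columns=["Genotype", "Replicate", "Time", "Measurement", "Subject"]
    )


# ---------------------------------------------------------------------------
# Mann-Whitney U layer


def mann_whitney_p(a: Sequence[float], b: Sequence[float]) -> float:
    """Two-sided Mann-Whitney U p-value.

    Exact null distribution when the combined sample is small (n <= 20) and
    tie-free, normal approximation with tie correction otherwise.  Two
    groups with all-identical values return p = 1 by convention.
    """
    a = np.asarray(a, dtype=float)
    b = np.asarray(b, dtype=float)
    a = a[np.isfinite(a)]
    b = b[np.isfinite(b)]
    if a.size < 1 or b.size < 1:
        raise ValueError("both groups need at least one observation")
    combined = np.concatenate([a, b])
    if np.all(combined == combined[0]):
        logger.info("all values identical; Mann-Whitney p set to 1")
        return 1.0
    has_ties = np.unique(combined).size < combined.size
    method = "exact" if (combined.size <= 20 and not has_ties) else "asymptotic"
    res = stats.mannwhitneyu(a, b, alternative="two-sided", method=method)
    return float(min(1.0, res.pvalue))


def mwu_timepoints(
    table: pd.DataFrame, control: str, comparison: str,
    tmax: Optional[float] = None,
) -> pd.DataFrame:
    """Per-time-point two-sided U tests between two genotypes.

    Returns a frame with columns time_s, p, neglog10p (the heatmap values).
    """
    genotypes = np.asarray([replicate_genotype(i) for i in table.index])
    rows = []
    for col in table.columns:
        t = float(col)
        if tmax is not None and t > tmax:
            continue
        a = table.loc[genotypes == control, col].dropna()
        b = table.loc[genotypes == comparison, col].dropna()
        if len(a) < 1 or len(b) < 1:
            logger.warning("time %s: a group has no observations; skipped", t)
            continue
        p = mann_whitney_p(a, b)
        rows.append((t, p, -np.log10(p)))
    return pd.DataFrame(rows, columns=["time_s", "p", "neglog10p"])


def peak_metrics(table: pd.DataFrame, tmax: Optional[float] = None) -> pd.Series:
    """Per-replicate maximum over the trial window [0, tmax]."""
    cols = [c for c in table.columns
            if tmax is None or 0.0 <= float(c) <= tmax]
    if not cols:
        raise ValueError("no time points in [0, tmax]")
    return table[cols].max(axis=1)


def mwu_peaks(
    peaks: pd.Series, control: str, comparison: str
) -> float:
    """U test on peak values between two genotypes."""
    genotypes = np.asarray([replicate_genotype(i) for i in peaks.index])
    return mann_whitney_p(
        peaks[genotypes == control], peaks[genotypes == comparison]
    )


# ---------------------------------------------------------------------------
# Comparison report (Table-1-shaped bundle + figures)


@dataclass
class ComparisonReport:
    """All p-values for one sex: 5 modalities x {LME-HMP, Peak-MWU}."""

    spec: LMESpec
    sex: str
    cells: pd.DataFrame  # rows <modality>_LME / <modality>_Peak, cols comparisons
    pvalues: Dict[str, Dict[str, float]]
    lme_results: Dict[tuple[str, str], LMEResult] = field(default_factory=dict)
    mwu_grids: Dict[tuple[str, str], pd.DataFrame] = field(default_factory=dict)
    gaps: List[str] = field(default_factory=list)

    def write_csv(self, path: str | Path) -> Path:
        self.cells.rename_axis("Metrics").to_csv(path)
        return Path(path)

    def write_json(self, path: str | Path) -> Path:
        Path(path).write_text(json.dumps(self.pvalues, indent=1))
        return Path(path)


def comparison_report(
    spec: LMESpec,
    tables: Dict[str, pd.DataFrame],
    sex: str = "M",
) -> ComparisonReport:
    """Pairwise control-vs-comparison statistics across all five modalities.

    For every comparison genotype and every modality present: the LME fitted
    on the control + that genotype (HMP over main effect and interactions)
    and the U test on per-replicate peaks, annotated with stars.  Missing
    modalities leave gaps flagged rather than failing the report.
    """
    row_names = [f"{m}_{kind}" for m in MODALITIES for kind in ("LME", "Peak")]
    col_names = [f"{spec.control} vs {g}" for g in spec.comparisons]
    cells = pd.DataFrame("", index=row_names, columns=col_names)
    pvalues: Dict[str, Dict[str, float]] = {c: {} for c in col_names}
    report = ComparisonReport(spec=spec, sex=sex, cells=cells, pvalues=pvalues)
    for modality in MODALITIES:
        table = tables.get(modality)
        if table is None or table.empty:
            report.gaps.append(modality)
            logger.warning("modality %s missing; report gap", modality)
            continue
        for g, col in zip(spec.comparisons, col_names):
            pair_spec = LMESpec(control=spec.control, comparisons=(g,),
                                tmax=spec.tmax, modality=modality)
            try:
                long = build_long_table(table, pair_spec)
                lme = fit_lme(long, control=spec.control)
                hmp = lme.comparisons[g].hmp
                report.lme_results[(modality, g)] = lme
            except (ValueError, RuntimeError) as exc:
                logger.warning("LME %s/%s failed: %s", modality, g, exc)
                report.gaps.append(f"{modality}_LME:{g}")
                hmp = np.nan
            peaks = peak_metrics(table, tmax=spec.tmax)
            try:
                peak_p = mwu_peaks(peaks, spec.control, g)
            except ValueError as exc:
                logger.warning("peak MWU %s/%s failed: %s", modality, g, exc)
                report.gaps.append(f"{modality}_Peak:{g}")
                peak_p = np.nan
            report.mwu_grids[(modality, g)] = mwu_timepoints(
                table, spec.control, g, tmax=spec.tmax
            )
            for kind, p in (("LME", hmp), ("Peak", peak_p)):
                pvalues[col][f"{modality}_{kind}"] = None if np.isnan(p) else p
                cells.loc[f"{modality}_{kind}", col] = (
                    "NA" if np.isnan(p) else f"{p:.3g} ({star_annotation(p)})"
                )
    return report
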