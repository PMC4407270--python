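"""Direct-repeat recombinant frequency summaries, fold changes and tests.

A fluctuation-style assay: for each strain (genotype x barrier orientation x
reporter position) the frequency of Ade+ recombinants per colony is measured,
split into gene conversions (marker retained) and deletions (marker lost),
in units of 1e-4.  This module computes per-condition means and standard
deviations, fold changes between conditions, deletion percentages, and the
published comparison procedure: Shapiro-Wilk normality per group, a variance
check, then an independent-samples t-test (pooled or Welch).

Fold changes are formatted the way the source tables print them: folds >= 10
to the nearest integer, folds < 10 to one decimal.  The overall recombinant
frequency of a condition is the sum of the conversion and deletion means.

A synthetic per-colony generator (log-normal, moment-matched to a target
mean/SD) stands in for the unpublished raw colony data.
"""

from __future__ import annotations

import math
from dataclasses import dataclass
from importlib import resources

import numpy as np
import pandas as pd
from scipy import stats

__all__ = [
    "FREQUENCY_CLASSES",
    "ConditionSummary",
    "ComparisonResult",
    "packaged_condition_table",
    "summarize",
    "fold_change",
    "format_fold",
    "percent_of_total",
    "compare_conditions",
    "generate_colony_table",
]

FREQUENCY_CLASSES = ("conversion", "deletion")

_CONDITION_KEYS = ["genotype", "orientation", "position"]


@dataclass(frozen=True)
class ConditionSummary:
    """Per-class mean and sample SD (n-1) for one condition."""

    genotype: str
    orientation: str
    position: str
    n: int
    conversion_mean: float
    conversion_sd: float
    deletion_mean: float
    deletion_sd: float

    def mean(self, freq_class: str) -> float:
        if freq_class == "total":
            return self.conversion_mean + self.deletion_mean
        if freq_class not in FREQUENCY_CLASSES:
            raise KeyError(f"unknown frequency class {freq_class!r}")
        return getattr(self, f"{freq_class}_mean")


def packaged_condition_table() -> pd.DataFrame:
    """The packaged published per-condition summary statistics."""
    ref = resources.files("rfbsim.data").joinpath("direct_repeat_frequencies.tsv")
    with resources.as_file(ref) as path:
        return pd.read_csv(path, sep="\t", comment="#")


def condition_summary_from_row(row) -> ConditionSummary:
    return ConditionSummary(
        genotype=row["genotype"], orientation=row["orientation"],
        position=row["position"], n=int(row["n_colonies"]),
        conversion_mean=float(row["conversion_mean"]),
        conversion_sd=float(row["conversion_sd"]),
        deletion_mean=float(row["deletion_mean"]),
        deletion_sd=float(row["deletion_sd"]),
    )


def lookup_condition(table: pd.DataFrame, genotype: str, orientation: str,
                     position: str) -> ConditionSummary:
    sel = table[
        (table["genotype"] == genotype)
        & (table["orientation"] == orientation)
        & (table["position"] == position)
    ]
    if sel.empty:
        raise KeyError(f"condition not found: {(genotype, orientation, position)}")
    return condition_summary_from_row(sel.iloc[0])


def summarize(colonies: pd.DataFrame, genotype: str, orientation: str,
              position: str) -> ConditionSummary:
    """Mean and sample SD of per-colony frequencies for one condition."""
    sel = colonies[
        (colonies["genotype"] == genotype)
        & (colonies["orientation"] == orientation)
        & (colonies["position"] == position)
    ]
    if sel.empty:
        raise KeyError(f"condition not found: {(genotype, orientation, position)}")
    return ConditionSummary(
        genotype=genotype, orientation=orientation, position=position,
        n=len(sel),
        conversion_mean=float(sel["freq_conversion"].mean()),
        conversion_sd=float(sel["freq_conversion"].std(ddof=1)) if len(sel) > 1 else 0.0,
        deletion_mean=float(sel["freq_deletion"].mean()),
        deletion_sd=float(sel["freq_deletion"].std(ddof=1)) if len(sel) > 1 else 0.0,
    )


def format_fold(fold: float) -> str:
    """Printing convention: >= 10 to the nearest integer, < 10 to one decimal."""
    if fold >= 10:
        return f"{math.floor(fold + 0.5):d}-fold"
    return f"{fold:.1f}-fold"


def fold_change(numerator: ConditionSummary, denominator: ConditionSummary,
                freq_class: str) -> tuple[float, str]:
    """Ratio of condition means for a class ('conversion', 'deletion' or
    'total'); returns (raw fold, formatted string)."""
    denom = denominator.mean(freq_class)
    if denom == 0:
        raise ZeroDivisionError("denominator condition has zero mean frequency")
    fold = numerator.mean(freq_class) / denom
    return fold, format_fold(fold)


def percent_of_total(summary: ConditionSummary, freq_class: str) -> int:
    """Percentage of the condition's recombinants in one class, to the
    nearest integer."""
    total = summary.mean("total")
    if total == 0:
        raise ZeroDivisionError("condition has zero total frequency")
    if freq_class not in FREQUENCY_CLASSES:
        raise KeyError(f"unknown frequency class {freq_class!r}")
    return int(math.floor(summary.mean(freq_class) / total * 100 + 0.5))


@dataclass(frozen=True)
class ComparisonResult:
    t_statistic: float
    p_value: float
    test_used: str  # "pooled-t" or "welch-t"
    normality_p_a: float
    normality_p_b: float
    normality_ok: bool
    variance_p: float
    degenerate: bool = False


def compare_conditions(group_a: np.ndarray | pd.Series,
                       group_b: np.ndarray | pd.Series,
                       alpha: float = 0.05) -> ComparisonResult:
    """Two-sided independent-samples t-test with the published gating.

    Shapiro-Wilk per group; Levene's test selects pooled vs Welch t.  Groups
    that fail normality are still compared by t-test but flagged
    (``normality_ok=False``).  Zero variance in both groups with equal means
    is degenerate and reported as p = 1.
    """
    a = np.asarray(group_a, dtype=float)
    b = np.asarray(group_b, dtype=float)
    if len(a) < 3 or len(b) < 3:
        raise ValueError("each group needs n >= 3")

    if a.std() == 0 and b.std() == 0:
        if a.mean() == b.mean():
            return ComparisonResult(0.0, 1.0, "pooled-t", math.nan, math.nan,
                                    False, math.nan, degenerate=True)
        return ComparisonResult(math.inf, 0.0, "pooled-t", math.nan, math.nan,
                                False, math.nan, degenerate=True)

    def _shapiro(x: np.ndarray) -> float:
        if np.ptp(x) == 0:
            return 0.0  # constant group: certainly not normal
        return float(stats.shapiro(x).pvalue)

    pa, pb = _shapiro(a), _shapiro(b)
    normality_ok = pa >= alpha and pb >= alpha
    pvar = float(stats.levene(a, b).pvalue)
    equal_var = pvar >= alpha
    t = stats.ttest_ind(a, b, equal_var=equal_var)
    return ComparisonResult(
        t_statistic=float(t.statistic),
        p_value=float(t.pvalue),
        test_used="pooled-t" if equal_var else "welch-t",
        normality_p_a=pa,
        normality_p_b=pb,
        normality_ok=normality_ok,
        variance_p=pvar,
    )


def _lognormal_params(mean: float, sd: float) -> tuple[float, float]:
    """Moment-match a log-normal to a target mean and SD."""
    if mean < 0 or sd < 0:
        raise ValueError("mean and sd must be >= 0")
    if mean == 0:
        if sd > 0:
            raise ValueError("mean 0 with sd > 0 is infeasible for a log-normal")
        return -math.inf, 0.0
    sigma2 = math.log(1.0 + (sd / mean) ** 2)
    mu = math.log(mean) - sigma2 / 2.0
    return mu, math.sqrt(sigma2)


def generate_colony_table(
    condition_specs: pd.DataFrame,
    seed: int = 0,
    family: str = "lognormal",
) -> pd.DataFrame:
    """Draw synthetic per-colony frequencies for each condition spec row.

    ``condition_specs`` uses the packaged summary-table layout (genotype,
    orientation, position, n_colonies, {class}_mean, {class}_sd).  The
    default family is log-normal matched to each mean/SD: strictly positive
    and right-skewed like fluctuation-assay data.  Reproducible by seed.
    """
    if condition_specs.empty:
        raise ValueError("no condition specs given")
    if family not in ("lognormal", "normal"):
        raise ValueError(f"unknown distribution family {family!r}")
    rng = np.random.default_rng(seed)
    rows = []
    for _, spec in condition_specs.iterrows():
        n = int(spec["n_colonies"])
        if n < 1:
            raise ValueError("n_colonies must be >= 1")
        draws = {}
        for cls in FREQUENCY_CLASSES:
            mean = float(spec[f"{cls}_mean"])
            sd = float(spec[f"{cls}_sd"])
            if family == "lognormal":
                mu, sig = _lognormal_params(mean, sd)
                if math.isinf(mu):
                    draws[cls] = np.zeros(n)
                else:
                    draws[cls] = rng.lognormal(mu, sig, size=n)
            else:
                draws[cls] = np.clip(rng.normal(mean, sd, size=n), 0.0, None)
        for i in range(n):
            rows.append({
                "genotype": spec["genotype"],
                "orientation": spec["orientation"],
                "position": spec["position"],
                "colony_id": f"{spec['genotype']}_{spec['orientation']}_{spec['position']}_{i:03d}",
                "freq_conversion": float(draws["conversion"][i]),
                "freq_deletion": float(draws["deletion"][i]),
            })
    return pd.DataFrame(rows)


# --------------------------------------------------------------------------
# The published fold-change/percentage suite, recomputed from the packaged
# condition means.  Each entry: (label, kind, numerator condition, denominator
# condition (or None), frequency class).

PUBLISHED_COMPARISONS = (
    ("conversion_fold_AO_vs_IO_flanking", "fold",
     ("wild_type", "AO", "flanking"), ("wild_type", "IO", "flanking"), "conversion"),
    ("deletion_fold_AO_vs_IO_flanking", "fold",
     ("wild_type", "AO", "flanking"), ("wild_type", "IO", "flanking"), "deletion"),
    ("total_fold_siteA_AO_vs_IO", "fold",
     ("wild_type", "AO", "siteA"), ("wild_type", "IO", "siteA"), "total"),
    ("total_fold_siteA_vs_flanking_AO", "fold",
     ("wild_type", "AO", "siteA"), ("wild_type", "AO", "flanking"), "total"),
    ("conversion_fold_siteA_AO_vs_IO", "fold",
     ("wild_type", "AO", "siteA"), ("wild_type", "IO", "siteA"), "conversion"),
    ("total_fold_siteB_AO_vs_IO", "fold",
     ("wild_type", "AO", "siteB"), ("wild_type", "IO", "siteB"), "total"),
    ("conversion_fold_siteB_ori1253d_AO_vs_IO", "fold",
     ("ori1253d", "AO", "siteB"), ("ori1253d", "IO", "siteB"), "conversion"),
    ("deletion_fold_siteB_ori1253d_AO_vs_IO", "fold",
     ("ori1253d", "AO", "siteB"), ("ori1253d", "IO", "siteB"), "deletion"),
    ("total_fold_ori1253d_vs_wt_AO_flanking", "fold",
     ("ori1253d", "AO", "flanking"), ("wild_type", "AO", "flanking"), "total"),
    ("total_fold_ori1253d_vs_wt_IO_flanking", "fold",
     ("ori1253d", "IO", "flanking"), ("wild_type", "IO", "flanking"), "total"),
    ("pct_deletions_siteB_AO", "percent",
     ("wild_type", "AO", "siteB"), None, "deletion"),
    ("pct_deletions_siteA_AO", "percent",
     ("wild_type", "AO", "siteA"), None, "deletion"),
)


def published_comparison_suite(table: pd.DataFrame | None = None) -> pd.DataFrame:
    """Recompute every fold change and percentage derivable from the packaged
    condition means, under the documented formatting convention."""
    table = table if table is not None else packaged_condition_table()
    rows = []
    for label, kind, num_key, den_key, cls in PUBLISHED_COMPARISONS:
        num = lookup_condition(table, *num_key)
        if kind == "fold":
            den = lookup_condition(table, *den_key)
            raw, formatted = fold_change(num, den, cls)
            rows.append({"label": label, "kind": kind, "class": cls,
                         "raw": raw, "formatted": formatted})
        else:
            pct = percent_of_total(num, cls)
            rows.append({"label": label, "kind": kind, "class": cls,
                         "raw": pct, "formatted": f"{pct}%"})
    return pd.DataFrame(rows)
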