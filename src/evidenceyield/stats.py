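"""Cohort evidence-yield statistics.

Aggregates per-variant evidence calls into the study's result tables:
per-proband counts by tool x evidence category with cohort summaries
(median/range, mean/sd), unique-variant and gene counts, bootstrap CIs for
proportions, exact two-tailed binomial comparisons of recessive vs dominant
genes with Bonferroni correction, genome-wide fold change, and concordance
against an external classification snapshot.
"""
from __future__ import annotations

from dataclasses import dataclass
from typing import Callable, Iterable, Mapping, Optional, Sequence

import numpy as np
import pandas as pd
from scipy import stats as sps

from .types import ALL_CATEGORIES, ConfigurationError, DataError, DEFAULT_TOOLS

_KEY_COLS = ["chrom", "pos", "ref", "alt"]


def _tools_in(frame: pd.DataFrame) -> list[str]:
    return [c[len("call_"):] for c in frame.columns if c.startswith("call_")]


# ---------------------------------------------------------------------------
# Yield tables


@dataclass
class YieldTable:
    """Per-proband category counts and their cohort summaries."""

    counts: pd.DataFrame   # long: proband_id, tool, category, count (dense)
    summary: pd.DataFrame  # index (tool, category): median, min, max, mean, sd

    def per_proband_totals(self, tool: str) -> pd.Series:
        sub = self.counts[self.counts["tool"] == tool]
        return sub.groupby("proband_id")["count"].sum()

    def to_table1(self) -> pd.DataFrame:
        """Wide 'median (range) / mean (sd)' presentation, one tool pair of columns."""
        cells = {}
        for (tool, cat), row in self.summary.iterrows():
            cells.setdefault(cat, {})[f"{tool} median (range)"] = (
                f"{row['median']:g} ({row['min']:g}-{row['max']:g})"
            )
            cells[cat][f"{tool} mean (sd)"] = f"{row['mean']:.1f} ({row['sd']:.1f})"
        frame = pd.DataFrame.from_dict(cells, orient="index")
        order = [c for c in ALL_CATEGORIES if c in frame.index]
        return frame.loc[order]


def tabulate_yield(observations: pd.DataFrame,
                   tools: Optional[Sequence[str]] = None,
                   categories: Sequence[str] = ALL_CATEGORIES) -> YieldTable:
    """Count calls per proband x tool x category, densely over all categories.

    For each proband and tool the counts over all categories (including
    NoScore) sum to that proband's analyzable-variant total.  Cohort medians
    use midpoint interpolation (the median of {17, 18} is 17.5) and sd is the
    sample standard deviation (n-1).
    """
    tools = list(tools) if tools is not None else _tools_in(observations)
    if observations.empty:
        empty_counts = pd.DataFrame(columns=["proband_id", "tool", "category", "count"])
        empty_summary = pd.DataFrame(
            columns=["median", "min", "max", "mean", "sd"],
            index=pd.MultiIndex.from_arrays([[], []], names=["tool", "category"]),
        )
        return YieldTable(counts=empty_counts, summary=empty_summary)
    dup = observations.duplicated(subset=["proband_id", *_KEY_COLS])
    if dup.any():
        offender = observations.loc[dup.idxmax(), ["proband_id", *_KEY_COLS]]
        raise DataError(f"duplicate (proband, variant) pair: {offender.to_dict()}")
    probands = sorted(observations["proband_id"].unique())
    blocks = []
    for tool in tools:
        col = f"call_{tool}"
        if col not in observations.columns:
            raise ConfigurationError(f"observations lack call column for tool {tool!r}")
        table = (
            observations.groupby(["proband_id", col], observed=False).size()
            .unstack(fill_value=0)
            .reindex(index=probands, fill_value=0)
            .reindex(columns=list(categories), fill_value=0)
        )
        long = table.stack().rename("count").reset_index()
        long.columns = ["proband_id", "category", "count"]
        long.insert(1, "tool", tool)
        blocks.append(long)
    counts = pd.concat(blocks, ignore_index=True)
    grouped = counts.groupby(["tool", "category"])["count"]
    summary = pd.DataFrame({
        "median": grouped.median(),
        "min": grouped.min(),
        "max": grouped.max(),
        "mean": grouped.mean(),
        "sd": grouped.std(ddof=1),
    })
    return YieldTable(counts=counts, summary=summary)


def unique_variant_count(observations: pd.DataFrame,
                         tools: Optional[Sequence[str]] = None) -> pd.DataFrame:
    """Unique variants and distinct genes per (tool, category), deduplicated
    across probands by variant key.  Idempotent under cohort repetition."""
    tools = list(tools) if tools is not None else _tools_in(observations)
    rows = []
    for tool in tools:
        col = f"call_{tool}"
        dedup = observations.drop_duplicates(subset=_KEY_COLS)
        for category, sub in dedup.groupby(col, observed=False):
            rows.append({
                "tool": tool,
                "category": category,
                "n_variants": len(sub),
                "n_genes": sub["gene_symbol"].nunique(),
            })
    return pd.DataFrame(rows, columns=["tool", "category", "n_variants", "n_genes"])


# ---------------------------------------------------------------------------
# Bootstrap


@dataclass(frozen=True)
class ProportionCI:
    proportion: float
    ci_low: float
    ci_high: float
    n: int
    iterations: int
    seed: int
    unit: str

    def __post_init__(self) -> None:
        assert self.ci_low <= self.proportion <= self.ci_high or self.n == 0


def proportion_with_bootstrap(matches: np.ndarray | pd.Series,
                              iterations: int = 1000,
                              seed: int = 0,
                              unit: str = "observation",
                              proband_ids: Optional[Sequence] = None) -> ProportionCI:
    """Point proportion with a percentile bootstrap 95% CI (1,000 iterations).

    ``matches`` is a boolean vector over observations.  The resampling unit is
    either single observations or whole probands (``proband_ids`` then
    required); the CI is the 2.5th/97.5th percentile of the resampled
    proportion.  Fully reproducible given ``seed``.
    """
    if iterations < 1:
        raise ConfigurationError("bootstrap iterations must be >= 1")
    values = np.asarray(matches, dtype=bool)
    n = values.size
    if n == 0:
        raise DataError("cannot bootstrap an empty observation set")
    rng = np.random.default_rng(seed)
    point = values.mean()
    if unit == "observation":
        stats = np.empty(iterations)
        for i in range(iterations):
            idx = rng.integers(0, n, n)
            stats[i] = values[idx].mean()
    elif unit == "proband":
        if proband_ids is None:
            raise ConfigurationError("proband-unit bootstrap requires proband_ids")
        groups = pd.Series(values).groupby(pd.Series(list(proband_ids))).agg(["sum", "size"])
        hits = groups["sum"].to_numpy(float)
        sizes = groups["size"].to_numpy(float)
        k = len(groups)
        stats = np.empty(iterations)
        for i in range(iterations):
            idx = rng.integers(0, k, k)
            stats[i] = hits[idx].sum() / sizes[idx].sum()
    else:
        raise ConfigurationError(f"unknown bootstrap unit {unit!r}")
    lo, hi = np.percentile(stats, [2.5, 97.5])
    return ProportionCI(proportion=float(point), ci_low=float(lo), ci_high=float(hi),
                        n=n, iterations=iterations, seed=seed, unit=unit)


# ---------------------------------------------------------------------------
# AR vs AD comparison


@dataclass(frozen=True)
class MoiComparison:
    tool: str
    k_ar: int
    n: int
    p0: float
    p_value: float
    p_adjusted: float
    method: str = "two-tailed exact binomial, Bonferroni"


def exact_binomial_two_tailed(k: int, n: int, p0: float) -> float:
    """Two-tailed exact binomial p-value by the minimum-likelihood method:
    the sum of probabilities of all outcomes no more probable than ``k``."""
    if n == 0:
        raise DataError("binomial test undefined for n = 0")
    return float(sps.binomtest(k, n, p0, alternative="two-sided").pvalue)


def compare_moi(observations: pd.DataFrame, tool: str,
                strengths: Iterable[str] = ("PP3_Moderate", "PP3_Strong"),
                n_tests: int = 4,
                null: str = "observations",
                gene_counts: Optional[Mapping[str, int]] = None) -> MoiComparison:
    """Are variants at the given strengths enriched in AR-only vs AD-only genes?

    ``k`` = calls at those strengths in AR-only genes, ``n`` = same over
    AR-only + AD-only.  The null proportion ``p0`` is the AR share of ALL
    analyzed observations in AR/AD genes (``null="observations"``), or the AR
    share of gene counts (``null="genes"``, requires ``gene_counts``).
    """
    col = f"call_{tool}"
    in_scope = observations[observations["moi"].isin(["AR_only", "AD_only"])]
    if null == "observations":
        if in_scope.empty:
            raise DataError("no observations in AR-only or AD-only genes")
        p0 = (in_scope["moi"] == "AR_only").mean()
    elif null == "genes":
        if not gene_counts:
            raise ConfigurationError("null='genes' requires gene_counts")
        p0 = gene_counts["AR_only"] / (gene_counts["AR_only"] + gene_counts["AD_only"])
    else:
        raise ConfigurationError(f"unknown null {null!r}")
    hits = in_scope[in_scope[col].isin(list(strengths))]
    k = int((hits["moi"] == "AR_only").sum())
    n = int(len(hits))
    p = exact_binomial_two_tailed(k, n, p0)
    return MoiComparison(tool=tool, k_ar=k, n=n, p0=float(p0), p_value=p,
                         p_adjusted=min(1.0, p * n_tests))


# ---------------------------------------------------------------------------
# Fold change and concordance


def fold_change(count_genomewide: Mapping[str, float],
                count_disease: Mapping[str, float]) -> tuple[dict[str, float], float]:
    """Per-tool genome-wide / disease-gene count ratio and its arithmetic mean."""
    ratios = {}
    for tool, denominator in count_disease.items():
        if denominator == 0:
            raise DataError(f"zero disease-gene count for {tool}; fold change undefined")
        ratios[tool] = count_genomewide[tool] / denominator
    return ratios, float(np.mean(list(ratios.values())))


@dataclass(frozen=True)
class ConcordanceTable:
    n_unique: int
    n_reported: int
    coverage: float
    proportions: Mapping[str, float]  # over reported classes, sums to 1
    counts: Mapping[str, int]


_REPORTING_GROUPS = {"P/LP": "P/LP", "VUS": "VUS/Conflicting",
                     "Conflicting": "VUS/Conflicting", "B/LB": "B/LB"}


def concordance(variant_keys: Iterable[tuple], external: Mapping[tuple, str]) -> ConcordanceTable:
    """Coverage and class proportions of unique variants in an external
    classification table (VUS and Conflicting are reported as one group)."""
    keys = list(dict.fromkeys(variant_keys))
    counts: dict[str, int] = {}
    for key in keys:
        label = external.get(tuple(key))
        if label is None:
            continue
        if label not in _REPORTING_GROUPS:
            raise DataError(f"unknown classification label {label!r}")
        group = _REPORTING_GROUPS[label]
        counts[group] = counts.get(group, 0) + 1
    n_reported = sum(counts.values())
    proportions = {g: c / n_reported for g, c in counts.items()} if n_reported else {}
    return ConcordanceTable(
        n_unique=len(keys),
        n_reported=n_reported,
        coverage=n_reported / len(keys) if keys else 0.0,
        proportions=proportions,
        counts=counts,
    )
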