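"""Model/Results interface over the evidence-yield analysis.

``EvidenceYieldModel`` holds a table of analyzable rare-missense observations
(one row per proband x variant, one ``score_<tool>`` column per predictor)
plus the calibrated threshold tables; ``fit()`` classifies every score,
tabulates per-proband yields, bootstraps the PP3_Strong proportion per tool
and runs the AR-vs-AD enrichment test, returning an
``EvidenceYieldResults`` with a ``summary()`` table.
"""
from __future__ import annotations

from dataclasses import dataclass, field
from typing import Mapping, Optional, Sequence

import pandas as pd

from . import stats
from .calibration import ThresholdTable, attach_calls, load_threshold_tables
from .ingest import (
    AnnotationSpec,
    FilterConfig,
    ScoreTable,
    ingest_cohort,
    load_gene_table,
)
from .types import DEFAULT_TOOLS


class EvidenceYieldModel:
    """Evidence-yield analysis of a cohort of rare missense observations."""

    def __init__(self, observations: pd.DataFrame,
                 thresholds: Optional[Mapping[str, ThresholdTable]] = None,
                 tools: Optional[Sequence[str]] = None):
        self.thresholds = dict(thresholds) if thresholds is not None else load_threshold_tables()
        if tools is not None:
            self.thresholds = {t: self.thresholds[t] for t in tools}
        self.tools = tuple(self.thresholds)
        self.observations = observations
        self.ingest_result = None

    @classmethod
    def from_cohort(cls, vcfs: Mapping[str, str], scores_path: str, genes_path: str,
                    cfg: FilterConfig = FilterConfig(),
                    thresholds: Optional[Mapping[str, ThresholdTable]] = None,
                    tools: Sequence[str] = DEFAULT_TOOLS,
                    annotation_spec: AnnotationSpec = AnnotationSpec()) -> "EvidenceYieldModel":
        """Build the model by ingesting per-proband VCFs plus score/gene tables."""
        score_table = ScoreTable.from_tsv(scores_path, tools=tools)
        gene_table = load_gene_table(genes_path)
        result = ingest_cohort(vcfs, score_table, gene_table, cfg, tools, annotation_spec)
        model = cls(result.observations, thresholds=thresholds, tools=tools)
        model.ingest_result = result
        return model

    def fit(self, bootstrap_iterations: int = 1000, seed: int = 0,
            focus_category: str = "PP3_Strong",
            moi_strengths: Sequence[str] = ("PP3_Moderate", "PP3_Strong"),
            n_tests: Optional[int] = None,
            bootstrap_unit: str = "observation") -> "EvidenceYieldResults":
        calls = attach_calls(self.observations, self.thresholds)
        yield_table = stats.tabulate_yield(calls, self.tools)
        unique = stats.unique_variant_count(calls, self.tools)
        n_tests = n_tests if n_tests is not None else len(self.tools)
        proportions, comparisons = {}, {}
        for tool in self.tools:
            if calls.empty:
                continue
            proportions[tool] = stats.proportion_with_bootstrap(
                (calls[f"call_{tool}"] == focus_category).to_numpy(),
                iterations=bootstrap_iterations, seed=seed, unit=bootstrap_unit,
                proband_ids=calls["proband_id"] if bootstrap_unit == "proband" else None,
            )
            if calls["moi"].isin(["AR_only", "AD_only"]).any():
                comparisons[tool] = stats.compare_moi(
                    calls, tool, strengths=moi_strengths, n_tests=n_tests)
        return EvidenceYieldResults(
            model=self, calls=calls, yield_table=yield_table, unique_counts=unique,
            focus_category=focus_category, proportions=proportions,
            moi_comparisons=comparisons, seed=seed,
        )


@dataclass
class EvidenceYieldResults:
    """Fitted evidence-yield tables, CIs and tests for one cohort run."""

    model: EvidenceYieldModel
    calls: pd.DataFrame
    yield_table: stats.YieldTable
    unique_counts: pd.DataFrame
    focus_category: str
    proportions: Mapping[str, stats.ProportionCI]
    moi_comparisons: Mapping[str, stats.MoiComparison]
    seed: int = 0

    def summary(self) -> str:
        lines = ["Evidence-yield analysis"]
        n_obs = len(self.calls)
        n_probands = self.calls["proband_id"].nunique() if n_obs else 0
        lines.append(f"  probands: {n_probands}   analyzable observations: {n_obs}")
        lines.append("")
        lines.append("Per-proband counts by evidence strength (median (range) / mean (sd)):")
        table1 = self.yield_table.to_table1()
        lines.append(table1.to_string() if not table1.empty else "  (empty cohort)")
        if self.proportions:
            lines.append("")
            lines.append(f"{self.focus_category} proportion of analyzable variants "
                         f"(bootstrap 95% CI, seed {self.seed}):")
            for tool, ci in self.proportions.items():
                lines.append(f"  {tool:14s} {100 * ci.proportion:.2f}% "
                             f"[{100 * ci.ci_low:.3f}, {100 * ci.ci_high:.3f}]")
        if self.moi_comparisons:
            lines.append("")
            lines.append("AR-only vs AD-only enrichment (two-tailed exact binomial, "
                         "Bonferroni-adjusted):")
            for tool, cmp_ in self.moi_comparisons.items():
                lines.append(f"  {tool:14s} k={cmp_.k_ar}/{cmp_.n} null={cmp_.p0:.3f} "
                             f"p={cmp_.p_value:.3g} adj={cmp_.p_adjusted:.3g}")
        return "\n".join(lines)

    def fold_change_vs(self, disease_results: "EvidenceYieldResults",
                       category: Optional[str] = None) -> tuple[dict[str, float], float]:
        """Fold change of summed per-category counts in this (e.g. genome-wide)
        run relative to a disease-gene run."""
        category = category or self.focus_category
        def totals(res: "EvidenceYieldResults") -> dict[str, float]:
            sub = res.yield_table.counts
            sub = sub[sub["category"] == category]
            return sub.groupby("tool")["count"].sum().to_dict()
        return stats.fold_change(totals(self), totals(disease_results))

    def concordance(self, external: Mapping[tuple, str],
                    tool: str, category: Optional[str] = None) -> stats.ConcordanceTable:
        """Concordance of this run's unique variants at a category against an
        external variant -> class table (e.g. a ClinVar snapshot)."""
        category = category or self.focus_category
        sub = self.calls[self.calls[f"call_{tool}"] == category]
        keys = list(sub[["chrom", "pos", "ref", "alt"]].itertuples(index=False, name=None))
        return stats.concordance(keys, external)

    def plot_yield(self, categories: Sequence[str] = ("PP3_Strong", "PP3_Moderate",
                                                      "PP3_Supporting"), ax=None):
        from .plotting import plot_yield_boxes
        return plot_yield_boxes(self.yield_table, categories, ax=ax)
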