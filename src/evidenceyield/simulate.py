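"""Synthetic rare-disease cohorts with the statistical structure the
analysis assumes.

The generator emulates a genome-sequenced cohort after upstream variant
calling: per proband, a negative-binomial number of rare missense candidates
spread over a curated disease-gene set (1,004 AD-only : 1,903 AR-only : 517
other, plus background genes for genome-wide scope), with per-tool predictor
scores drawn from a two-component (deleterious/benign) beta mixture on each
tool's score range, per-tool score missingness, per-population allele
frequencies, and genotype QC fields with an engineered failure fraction.
Fixtures are emitted in the exact formats the ingest module consumes (one
VCF per proband, a score TSV, a gene-list TSV) together with a truth table
recording, per observation, the drawn label, the expected evidence category
per tool, and the expected drop reason in the filter chain.

All randomness flows from one seed through named ``numpy`` SeedSequence
children (gene layout, pool, counts, assignment, QC, extras), so sub-streams
are independently reproducible and identical seeds give byte-identical
fixtures.
"""
from __future__ import annotations

import math
from dataclasses import dataclass, field, replace
from pathlib import Path
from typing import Mapping, Optional, Sequence

import numpy as np
import pandas as pd
from scipy.stats import beta as beta_dist

from .calibration import ThresholdTable, classify_score, load_threshold_tables
from .types import ConfigurationError, DEFAULT_EXCLUDED_POPULATIONS, NO_SCORE

_POPULATIONS = ("afr", "nfe", "eas", "amr", "sas", "fin")  # fin is bottlenecked
_BASES = np.array(list("ACGT"))


@dataclass(frozen=True)
class ToolScoreModel:
    """Two-component score mixture for one predictor.

    Beta shape parameters are on the unit interval and mapped affinely onto
    the tool's score range; ``missingness`` is the probability the tool has
    no score for a variant (precomputed-database coverage gaps).
    """

    deleterious: tuple[float, float]
    benign: tuple[float, float]
    missingness: float = 0.0


# Components fitted once against the per-band evidence fractions implied by
# the study conditions (PP3_Strong mass 0.010-0.013 of analyzed variants,
# BP4 mass 0.53-0.64, indeterminate 0.23-0.25) at marginal deleterious
# weight 0.12; missingness from the per-tool NoScore rates.
DEFAULT_TOOL_MODELS: Mapping[str, ToolScoreModel] = {
    "BayesDel_noAF": ToolScoreModel((12.34, 4.58), (6.60, 7.73), 0.004),
    "MutPred2": ToolScoreModel((8.90, 2.43), (0.90, 2.49), 0.0),
    "REVEL": ToolScoreModel((4.06, 1.54), (0.90, 3.11), 0.136),
    "VEST4": ToolScoreModel((7.18, 1.52), (0.90, 1.75), 0.074),
}


@dataclass(frozen=True)
class GeneratorConfig:
    """Study conditions of the emulated cohort.

    Defaults mirror the analyzed cohort: 300 probands, the curated
    disease-gene census split 1,004/1,903/517 by mode of inheritance, ~75
    rare missense candidates per proband in disease genes (negative binomial,
    size 30), and per-gene-class deleterious fractions whose variant-weighted
    marginal is 0.12 with AR-only genes enriched over AD-only (heterozygous
    deleterious alleles accumulate in recessive genes).
    """

    n_probands: int = 300
    gene_class_counts: Mapping[str, int] = field(
        default_factory=lambda: {"AD_only": 1004, "AR_only": 1903, "other": 517}
    )
    n_background_genes: int = 12142
    scope: str = "disease_genes"  # or "genome_wide"
    mean_variants_per_proband: float = 75.0
    dispersion: float = 30.0  # negative-binomial size parameter
    deleterious_fraction: Mapping[str, float] = field(
        default_factory=lambda: {"AD_only": 0.080, "AR_only": 0.145,
                                 "other": 0.105, "background": 0.050}
    )
    tool_models: Mapping[str, ToolScoreModel] = field(
        default_factory=lambda: dict(DEFAULT_TOOL_MODELS)
    )
    af_novel_fraction: float = 0.55
    af_beta: tuple[float, float] = (0.5, 20.0)
    af_scale: float = 0.05
    pop_multiplier_range: tuple[float, float] = (0.2, 2.5)
    bottleneck_multiplier_range: tuple[float, float] = (0.2, 6.0)
    qc_failure_rates: Mapping[str, float] = field(
        default_factory=lambda: {"genotype_quality": 0.01, "depth": 0.01,
                                 "allele_balance": 0.01}
    )
    nonmissense_fraction: float = 0.05
    hom_alt_fraction: float = 0.05
    shared_pool: bool = True
    pool_factor: float = 2.13  # pool size / expected observation count (~79% unique)

    def __post_init__(self) -> None:
        probs = [self.af_novel_fraction, self.nonmissense_fraction,
                 self.hom_alt_fraction, *self.qc_failure_rates.values(),
                 *self.deleterious_fraction.values()]
        for p in probs:
            if not (0.0 <= p <= 1.0):
                raise ConfigurationError(f"probability outside [0, 1]: {p}")
        if self.scope not in ("disease_genes", "genome_wide"):
            raise ConfigurationError(f"unknown scope {self.scope!r}")

    def gene_frame(self) -> pd.DataFrame:
        """Deterministic gene layout: symbols, classes, loci, transcripts."""
        rows = []
        i = 0
        validity_cycle = ("Definitive", "Strong", "Moderate")
        for moi, count in self.gene_class_counts.items():
            for j in range(count):
                rows.append((f"GENE{i:05d}", validity_cycle[j % 3], moi))
                i += 1
        for _ in range(self.n_background_genes):
            rows.append((f"BKGD{i:05d}", "other_or_absent", "other"))
            i += 1
        frame = pd.DataFrame(rows, columns=["symbol", "validity", "moi"])
        n = len(frame)
        idx = np.arange(n)
        frame["chrom"] = ["chr" + str(1 + (k % 22)) for k in idx]
        frame["start"] = 100_000 + (idx // 22) * 50_000
        frame["transcript"] = [f"ENST{100000 + k:011d}" for k in idx]
        frame["mane_id"] = [f"NM_{100000 + k:09d}.1" for k in idx]
        frame["is_disease"] = frame["validity"].isin(["Definitive", "Strong", "Moderate"])
        return frame

    def marginal_deleterious_fraction(self) -> float:
        """Variant-weighted deleterious fraction under uniform gene sampling."""
        weights = dict(self.gene_class_counts)
        if self.scope == "genome_wide":
            weights["background"] = self.n_background_genes
        total = sum(weights.values())
        return sum(w * self.deleterious_fraction[c] for c, w in weights.items()) / total


def genome_wide_config(**overrides) -> GeneratorConfig:
    """Preset for the genome-wide scope: ~5-fold more genes than the curated
    set, ~5-fold lower deleterious prior in background genes, ~321 rare
    missense candidates per proband."""
    cfg = GeneratorConfig(scope="genome_wide", mean_variants_per_proband=321.0)
    return replace(cfg, **overrides) if overrides else cfg


@dataclass
class Cohort:
    """A generated cohort: gene census, unique-variant pools, observations, truth."""

    cfg: GeneratorConfig
    seed: int
    genes: pd.DataFrame
    pool: pd.DataFrame       # unique missense variants with scores and AFs
    syn_pool: pd.DataFrame   # unique synonymous variants (filter-chain fodder)
    observations: pd.DataFrame  # proband x variant with QC fields
    truth: pd.DataFrame      # per observation: labels, expected calls, expected drop

    def analyzable_observations(self, tools: Optional[Sequence[str]] = None) -> pd.DataFrame:
        """Kept observations in the ingest output schema (no file round trip)."""
        tools = list(tools) if tools is not None else list(self.cfg.tool_models)
        kept = self.truth["expected_drop_reason"].isna().to_numpy()
        obs = self.observations.loc[kept]
        merged = obs.merge(self.pool, on=["chrom", "pos", "ref", "alt"], how="left",
                           suffixes=("", "_pool"))
        out = pd.DataFrame({
            "proband_id": merged["proband_id"],
            "chrom": merged["chrom"],
            "pos": merged["pos"],
            "ref": merged["ref"],
            "alt": merged["alt"],
            "gene_symbol": merged["gene_symbol"],
            "transcript_id": merged["transcript"],
            "consequence": "missense_variant",
            "mane_select": True,
            "validity": merged["validity"],
            "moi": merged["moi"],
            "zygosity": merged["zygosity"],
            "gq": merged["gq"],
            "dp": merged["dp"],
            "ab": merged["ab"],
            "global_af": merged["global_af"],
            "popmax_af": merged["popmax_af"],
        })
        for tool in tools:
            out[f"score_{tool}"] = merged[f"score_{tool}"].to_numpy()
        return out.reset_index(drop=True)


def _draw_pool(cfg: GeneratorConfig, genes: pd.DataFrame, n_pool: int,
               rng: np.random.Generator, missense: bool, pos_offset: int) -> pd.DataFrame:
    """Draw a pool of unique variants over the in-scope genes."""
    in_scope = genes if cfg.scope == "genome_wide" else genes[genes["is_disease"]]
    in_scope = in_scope.reset_index(drop=True)
    gidx = rng.integers(0, len(in_scope), n_pool)
    frame = in_scope.iloc[gidx].reset_index(drop=True)
    # unique positions: consecutive 3-bp-spaced slots within each gene
    slot = pd.Series(gidx).groupby(pd.Series(gidx)).cumcount().to_numpy()
    frame["pos"] = frame["start"] + pos_offset + slot * 3
    ref_i = rng.integers(0, 4, n_pool)
    alt_i = (ref_i + rng.integers(1, 4, n_pool)) % 4
    frame["ref"] = _BASES[ref_i]
    frame["alt"] = _BASES[alt_i]
    cls = np.where(frame["is_disease"], frame["moi"], "background")
    p_del = np.array([cfg.deleterious_fraction[c] for c in cls])
    frame["deleterious"] = rng.random(n_pool) < p_del
    # allele frequencies
    novel = rng.random(n_pool) < cfg.af_novel_fraction
    a, b = cfg.af_beta
    af = np.where(novel, 0.0, rng.beta(a, b, n_pool) * cfg.af_scale)
    frame["global_af"] = af
    lo_m, hi_m = cfg.pop_multiplier_range
    for pop in _POPULATIONS:
        lo, hi = ((lo_m, hi_m) if pop not in DEFAULT_EXCLUDED_POPULATIONS
                  else cfg.bottleneck_multiplier_range)
        frame[f"af_{pop}"] = np.minimum(af * rng.uniform(lo, hi, n_pool), 1.0)
    non_excluded = [p for p in _POPULATIONS if p not in DEFAULT_EXCLUDED_POPULATIONS]
    frame["popmax_af"] = frame[[f"af_{p}" for p in non_excluded]].max(axis=1)
    # predictor scores
    if missense:
        tables = load_threshold_tables()
        for tool, model in cfg.tool_models.items():
            lo_s, hi_s = tables[tool].score_range
            ad, bd = model.deleterious
            ab_, bb = model.benign
            u = np.where(frame["deleterious"],
                         rng.beta(ad, bd, n_pool), rng.beta(ab_, bb, n_pool))
            score = lo_s + (hi_s - lo_s) * u
            miss = rng.random(n_pool) < model.missingness
            frame[f"score_{tool}"] = np.where(miss, np.nan, score)
    frame["gene_symbol"] = frame.pop("symbol")
    return frame.drop(columns=["start", "is_disease"])


def generate_cohort(cfg: GeneratorConfig, seed: int) -> Cohort:
    """Deterministically generate a cohort under the configured conditions."""
    children = np.random.SeedSequence(seed).spawn(5)
    rng_pool, rng_counts, rng_assign, rng_qc, rng_extra = map(np.random.default_rng, children)

    genes = cfg.gene_frame()
    mean, size = cfg.mean_variants_per_proband, cfg.dispersion
    p_nb = size / (size + mean)
    counts = rng_counts.negative_binomial(size, p_nb, cfg.n_probands)
    n_extra = rng_counts.poisson(counts * cfg.nonmissense_fraction)
    total = int(counts.sum())
    total_extra = int(n_extra.sum())

    n_pool = max(total, 1) if not cfg.shared_pool else max(
        int(round(cfg.pool_factor * cfg.n_probands * mean)), 1)
    n_syn_pool = max(total_extra, 1) if not cfg.shared_pool else max(
        int(round(cfg.pool_factor * cfg.n_probands * mean * cfg.nonmissense_fraction)), 1)
    pool = _draw_pool(cfg, genes, n_pool, rng_pool, missense=True, pos_offset=0)
    syn_pool = _draw_pool(cfg, genes, n_syn_pool, rng_pool, missense=False, pos_offset=1)

    proband_ids = [f"PROBAND_{i:04d}" for i in range(cfg.n_probands)]
    rows_p, rows_idx, rows_syn = [], [], []
    cursor = syn_cursor = 0
    for pid, c, e in zip(proband_ids, counts, n_extra):
        if cfg.shared_pool:
            idx = rng_assign.choice(n_pool, size=min(int(c), n_pool), replace=False)
            sidx = rng_assign.choice(n_syn_pool, size=min(int(e), n_syn_pool), replace=False)
        else:
            idx = np.arange(cursor, cursor + int(c)); cursor += int(c)
            sidx = np.arange(syn_cursor, syn_cursor + int(e)); syn_cursor += int(e)
        rows_p += [pid] * (len(idx) + len(sidx))
        rows_idx.append((idx, sidx))
        rows_syn += [False] * len(idx) + [True] * len(sidx)

    midx = np.concatenate([i for i, _ in rows_idx]) if rows_idx else np.array([], dtype=int)
    sidx = np.concatenate([s for _, s in rows_idx]) if rows_idx else np.array([], dtype=int)
    is_syn = np.array(rows_syn, dtype=bool)
    n_obs = len(rows_p)

    source = pd.concat([
        pool.iloc[midx][["chrom", "pos", "ref", "alt", "gene_symbol", "moi",
                         "validity", "global_af", "popmax_af"]],
        syn_pool.iloc[sidx][["chrom", "pos", "ref", "alt", "gene_symbol", "moi",
                             "validity", "global_af", "popmax_af"]],
    ], ignore_index=True) if n_obs else pd.DataFrame(
        columns=["chrom", "pos", "ref", "alt", "gene_symbol", "moi", "validity",
                 "global_af", "popmax_af"])
    # interleave back into per-proband order (missense block then syn block per proband)
    order = []
    m_ptr, s_ptr = 0, len(midx)
    for (idx, sx) in rows_idx:
        order += list(range(m_ptr, m_ptr + len(idx)))
        m_ptr += len(idx)
        order += list(range(s_ptr, s_ptr + len(sx)))
        s_ptr += len(sx)
    source = source.iloc[np.asarray(order, dtype=int)].reset_index(drop=True) if n_obs else source

    # genotype QC fields
    hom = rng_qc.random(n_obs) < cfg.hom_alt_fraction
    rates = cfg.qc_failure_rates
    fail_gq = rng_qc.random(n_obs) < rates.get("genotype_quality", 0.0)
    fail_dp = rng_qc.random(n_obs) < rates.get("depth", 0.0)
    fail_ab = rng_qc.random(n_obs) < rates.get("allele_balance", 0.0)
    gq = np.where(fail_gq, rng_qc.integers(0, 40, n_obs), rng_qc.integers(40, 100, n_obs))
    dp = np.where(fail_dp, rng_qc.integers(3, 10, n_obs), 10 + rng_qc.poisson(25, n_obs))
    ab_target = np.where(hom, rng_qc.uniform(0.9, 1.0, n_obs),
                         np.clip(rng_qc.normal(0.5, 0.06, n_obs), 0.25, 0.75))
    ab_target = np.where(fail_ab, rng_qc.uniform(0.02, 0.18, n_obs), ab_target)
    ad_alt = np.where(fail_ab, np.floor(ab_target * dp), np.round(ab_target * dp))
    ad_alt = np.clip(ad_alt, 0, dp).astype(int)
    ab = np.where(dp > 0, ad_alt / np.maximum(dp, 1), 0.0)

    observations = pd.DataFrame({
        "proband_id": rows_p,
        "chrom": source["chrom"].to_numpy(),
        "pos": source["pos"].to_numpy(),
        "ref": source["ref"].to_numpy(),
        "alt": source["alt"].to_numpy(),
        "is_synonymous": is_syn,
        "zygosity": np.where(hom, "hom_alt", "het"),
        "gq": gq.astype(int),
        "dp": dp.astype(int),
        "ad_alt": ad_alt,
        "ab": ab,
    })

    truth = _truth_table(cfg, observations, source, pool, midx, is_syn, order)
    return Cohort(cfg=cfg, seed=seed, genes=genes, pool=pool, syn_pool=syn_pool,
                  observations=observations, truth=truth)


def _truth_table(cfg: GeneratorConfig, observations: pd.DataFrame, source: pd.DataFrame,
                 pool: pd.DataFrame, midx: np.ndarray, is_syn: np.ndarray,
                 order: list[int]) -> pd.DataFrame:
    """Per observation: labels, expected per-tool categories, expected drop
    reason under the default filter chain (mode=mane_select, max_af=0.01)."""
    tables = load_threshold_tables()
    truth = observations[["proband_id", "chrom", "pos", "ref", "alt"]].copy()
    truth["gene_symbol"] = source["gene_symbol"].to_numpy()
    truth["moi"] = source["moi"].to_numpy()
    truth["validity"] = source["validity"].to_numpy()
    truth["is_synonymous"] = is_syn

    # deleterious label and expected categories come from the missense pool
    n_obs = len(observations)
    deleterious = np.zeros(n_obs, dtype=bool)
    calls = {tool: np.full(n_obs, "", dtype=object) for tool in cfg.tool_models}
    if n_obs:
        inv = np.argsort(np.asarray(order, dtype=int))  # source row -> obs row
        obs_of_concat = inv  # concat index -> observation index
        m_rows = obs_of_concat[: len(midx)]
        deleterious[m_rows] = pool["deleterious"].to_numpy()[midx]
        for tool in cfg.tool_models:
            table = tables[tool]
            scores = pool[f"score_{tool}"].to_numpy()[midx]
            calls[tool][m_rows] = [
                classify_score(None if np.isnan(s) else float(s), table) for s in scores
            ]
    truth["deleterious"] = deleterious
    for tool in cfg.tool_models:
        col = calls[tool]
        col[is_syn] = ""
        truth[f"expected_call_{tool}"] = col

    reason = np.full(n_obs, None, dtype=object)
    gq = observations["gq"].to_numpy()
    dp = observations["dp"].to_numpy()
    ab = observations["ab"].to_numpy()
    gaf = source["global_af"].to_numpy() if n_obs else np.array([])
    pmax = source["popmax_af"].to_numpy() if n_obs else np.array([])
    in_scope = (source["validity"].isin(["Definitive", "Strong", "Moderate"]).to_numpy()
                if n_obs else np.array([], dtype=bool))
    for i in range(n_obs):
        if is_syn[i]:
            reason[i] = "not_missense"
        elif gq[i] < 40:
            reason[i] = "genotype_quality"
        elif dp[i] < 10:
            reason[i] = "depth"
        elif ab[i] < 0.2:
            reason[i] = "allele_balance"
        elif gaf[i] > 0.01 or pmax[i] > 0.01:
            reason[i] = "allele_frequency"
        elif cfg.scope == "disease_genes" and not in_scope[i]:
            reason[i] = "gene_scope"
    truth["expected_drop_reason"] = reason
    return truth


# ---------------------------------------------------------------------------
# Fixture output


def _fmt(x: float) -> str:
    return f"{x:.6g}"


def write_fixtures(cohort: Cohort, out_dir: str | Path) -> dict[str, object]:
    """Emit the cohort in the pipeline's input formats.

    One VCF per proband (GT/GQ/DP/AD; CSQ annotation Consequence|SYMBOL|
    Feature|MANE_SELECT; AF and per-population AF INFO fields), a score TSV
    over the unique missense variants, a gene-list TSV over the curated
    disease genes, and a per-observation truth TSV.
    """
    out = Path(out_dir)
    vcf_dir = out / "vcf"
    vcf_dir.mkdir(parents=True, exist_ok=True)
    cfg = cohort.cfg

    site_info = pd.concat([
        cohort.pool.assign(consequence="missense_variant"),
        cohort.syn_pool.assign(consequence="synonymous_variant"),
    ], ignore_index=True).set_index(["chrom", "pos", "ref", "alt"])

    header_lines = ["##fileformat=VCFv4.2"]
    header_lines += [f"##contig=<ID=chr{i}>" for i in range(1, 23)]
    header_lines += [
        '##INFO=<ID=AF,Number=A,Type=Float,Description="Global allele frequency">',
    ]
    header_lines += [
        f'##INFO=<ID=AF_{pop},Number=A,Type=Float,Description="{pop} allele frequency">'
        for pop in _POPULATIONS
    ]
    header_lines += [
        '##INFO=<ID=CSQ,Number=.,Type=String,Description="Consequence annotations '
        'from Ensembl VEP. Format: Consequence|SYMBOL|Feature|MANE_SELECT">',
        '##FORMAT=<ID=GT,Number=1,Type=String,Description="Genotype">',
        '##FORMAT=<ID=GQ,Number=1,Type=Integer,Description="Genotype quality">',
        '##FORMAT=<ID=DP,Number=1,Type=Integer,Description="Read depth">',
        '##FORMAT=<ID=AD,Number=R,Type=Integer,Description="Allelic depths">',
    ]

    chrom_rank = {f"chr{i}": i for i in range(1, 23)}
    vcf_paths: dict[str, Path] = {}
    for pid, obs in cohort.observations.groupby("proband_id", sort=True):
        obs = obs.sort_values(["chrom", "pos"],
                              key=lambda s: s.map(chrom_rank) if s.name == "chrom" else s)
        lines = list(header_lines)
        lines.append("#CHROM\tPOS\tID\tREF\tALT\tQUAL\tFILTER\tINFO\tFORMAT\t" + pid)
        for row in obs.itertuples(index=False):
            site = site_info.loc[(row.chrom, row.pos, row.ref, row.alt)]
            if isinstance(site, pd.DataFrame):
                site = site.iloc[0]
            info = [f"AF={_fmt(site['global_af'])}"]
            info += [f"AF_{p}={_fmt(site[f'af_{p}'])}" for p in _POPULATIONS]
            csq = f"{site['consequence']}|{site['gene_symbol']}|{site['transcript']}|{site['mane_id']}"
            info.append(f"CSQ={csq}")
            gt = "1/1" if row.zygosity == "hom_alt" else "0/1"
            ad_ref = max(int(row.dp) - int(row.ad_alt), 0)
            sample = f"{gt}:{int(row.gq)}:{int(row.dp)}:{ad_ref},{int(row.ad_alt)}"
            lines.append("\t".join([
                row.chrom, str(int(row.pos)), ".", row.ref, row.alt, "100", "PASS",
                ";".join(info), "GT:GQ:DP:AD", sample,
            ]))
        path = vcf_dir / f"{pid}.vcf"
        path.write_text("\n".join(lines) + "\n")
        vcf_paths[pid] = path

    score_cols = [f"score_{t}" for t in cfg.tool_models]
    scores = cohort.pool[["chrom", "pos", "ref", "alt", "transcript", *score_cols]].copy()
    scores.columns = ["chrom", "pos", "ref", "alt", "transcript", *cfg.tool_models]
    scores_path = out / "scores.tsv"
    scores.to_csv(scores_path, sep="\t", index=False, na_rep=".", float_format="%.6g")

    disease = cohort.genes[cohort.genes["is_disease"]]
    genes_path = out / "genes.tsv"
    disease[["symbol", "validity", "moi"]].to_csv(genes_path, sep="\t", index=False)

    truth_path = out / "truth.tsv"
    cohort.truth.to_csv(truth_path, sep="\t", index=False, na_rep="")

    return {"vcfs": vcf_paths, "scores": scores_path, "genes": genes_path,
            "truth": truth_path}


# ---------------------------------------------------------------------------
# Analytic oracle


def expected_yield(cfg: GeneratorConfig,
                   tables: Optional[Mapping[str, ThresholdTable]] = None) -> pd.DataFrame:
    """Exact per-tool probability mass of each evidence category under the
    configured score mixtures — the analytic expectation for the empirical
    per-category fractions among analyzable variants.

    Masses over all categories including NoScore sum to 1 per tool.
    """
    tables = tables or load_threshold_tables()
    fdel = cfg.marginal_deleterious_fraction()
    rows = []
    for tool, model in cfg.tool_models.items():
        table = tables[tool]
        lo, hi = table.score_range
        ad, bd = model.deleterious
        ab, bb = model.benign

        def cdf(x: float) -> float:
            u = (x - lo) / (hi - lo)
            return (fdel * beta_dist.cdf(u, ad, bd)
                    + (1 - fdel) * beta_dist.cdf(u, ab, bb))

        scored = 1.0 - model.missingness
        intervals = _category_intervals(table)
        for category, (x0, x1) in intervals.items():
            lo_c = cdf(x0) if math.isfinite(x0) else 0.0
            hi_c = cdf(x1) if math.isfinite(x1) else 1.0
            rows.append({"tool": tool, "category": category,
                         "probability": scored * (hi_c - lo_c)})
        rows.append({"tool": tool, "category": NO_SCORE,
                     "probability": model.missingness})
    return pd.DataFrame(rows, columns=["tool", "category", "probability"])


def _category_intervals(table: ThresholdTable) -> dict[str, tuple[float, float]]:
    """Score intervals per reachable category (open/closed endpoints do not
    matter against a continuous mixture)."""
    out: dict[str, tuple[float, float]] = {}
    path = [(s, table.pathogenic[s]) for s in ("Supporting", "Moderate", "Strong", "VeryStrong")
            if s in table.pathogenic]
    for i, (strength, thr) in enumerate(path):
        upper = path[i + 1][1] if i + 1 < len(path) else math.inf
        out[f"PP3_{strength}"] = (thr, upper)
    ben = [(s, table.benign[s]) for s in ("Supporting", "Moderate", "Strong", "VeryStrong")
           if s in table.benign]
    for i, (strength, thr) in enumerate(ben):
        lower = ben[i + 1][1] if i + 1 < len(ben) else -math.inf
        out[f"BP4_{strength}"] = (lower, thr)
    ben_top = ben[0][1] if ben else -math.inf
    out["Indeterminate"] = (ben_top, path[0][1])
    return out
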