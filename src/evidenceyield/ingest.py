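"""Cohort ingest: per-proband VCFs -> filtered rare-missense observations.

The filter chain follows the analysis order: transcript/consequence selection
(MANE Select or most-severe-consequence mode), genotype QC (GQ >= 40,
DP >= 10, allele balance >= 0.2 by default), rarity (global AND popmax allele
frequency <= threshold), then gene scope (curated disease genes or
genome-wide).  Every dropped observation is accounted for by the first
criterion it fails, so input = kept + sum of drops, exactly, per proband.
"""
from __future__ import annotations

import math
from collections import Counter
from dataclasses import dataclass, field, replace
from importlib import resources
from pathlib import Path
from typing import Iterable, Iterator, Mapping, Optional, Sequence

import pandas as pd
import pysam
import yaml

from .types import (
    ConfigurationError,
    ConsequenceAnnotation,
    DataError,
    DEFAULT_EXCLUDED_POPULATIONS,
    DEFAULT_TOOLS,
    DISEASE_VALIDITY,
    FrequencyRecord,
    GeneRecord,
    GenotypeQC,
    VariantKey,
    VariantObservation,
    compute_popmax,
)

__all__ = [
    "AnnotationSpec",
    "FilterConfig",
    "ScoreTable",
    "load_cohort_vcf",
    "apply_genotype_filters",
    "select_missense",
    "apply_af_filter",
    "join_scores",
    "join_genes",
    "load_gene_table",
    "load_external_classifications",
    "ingest_cohort",
    "load_severity_order",
]


@dataclass(frozen=True)
class AnnotationSpec:
    """Location and layout of the VEP-style consequence annotation field."""

    info_field: str = "CSQ"
    consequence_field: str = "Consequence"
    symbol_field: str = "SYMBOL"
    transcript_field: str = "Feature"
    mane_field: str = "MANE_SELECT"
    allele_field: str = "Allele"  # honoured when declared in the header

    def required_fields(self) -> tuple[str, ...]:
        return (self.consequence_field, self.symbol_field,
                self.transcript_field, self.mane_field)


@dataclass(frozen=True)
class FilterConfig:
    """Thresholds and modes of the filter chain (defaults as analyzed)."""

    mode: str = "mane_select"  # or "most_severe"
    max_af: float = 0.01
    scope: str = "disease_genes"  # or "genome_wide"
    gq_min: int = 40
    dp_min: int = 10
    ab_min: float = 0.2
    excluded_populations: frozenset[str] = DEFAULT_EXCLUDED_POPULATIONS
    af_key: str = "AF"
    pop_af_prefix: str = "AF_"

    def __post_init__(self) -> None:
        if self.mode not in ("mane_select", "most_severe"):
            raise ConfigurationError(f"unknown selection mode {self.mode!r}")
        if self.scope not in ("disease_genes", "genome_wide"):
            raise ConfigurationError(f"unknown scope {self.scope!r}")
        if not (0.0 <= self.max_af <= 1.0):
            raise ConfigurationError(f"max_af outside [0, 1]: {self.max_af}")


def load_severity_order(path: Optional[str] = None) -> list[str]:
    """VEP consequence terms, most severe first (packaged default)."""
    if path is None:
        text = resources.files("evidenceyield.data").joinpath("vep_severity.yaml").read_text()
        raw = yaml.safe_load(text)
    else:
        with open(path) as fh:
            raw = yaml.safe_load(fh)
    order = raw.get("severity_order") if raw else None
    if not order:
        raise ConfigurationError("severity config defines no severity_order")
    return list(order)


# ---------------------------------------------------------------------------
# VCF reading


def _annotation_header_fields(header: pysam.VariantHeader, spec: AnnotationSpec) -> list[str]:
    try:
        desc = header.info[spec.info_field].description
    except KeyError:
        raise ConfigurationError(
            f"VCF header lacks INFO field {spec.info_field!r}"
        ) from None
    if "Format:" in desc:
        layout = desc.split("Format:", 1)[1].strip().strip('"')
    else:
        layout = desc
    fields = [f.strip() for f in layout.split("|")]
    missing = [f for f in spec.required_fields() if f not in fields]
    if missing:
        raise ConfigurationError(
            f"annotation field {spec.info_field} lacks sub-fields {missing}; header declares {fields}"
        )
    return fields


def _parse_annotations(raw_entries: Sequence[str], fields: list[str],
                       spec: AnnotationSpec, alt: str) -> list[ConsequenceAnnotation]:
    idx = {name: i for i, name in enumerate(fields)}
    out = []
    for entry in raw_entries:
        parts = entry.split("|")
        if len(parts) < len(fields):
            parts += [""] * (len(fields) - len(parts))
        if spec.allele_field in idx and parts[idx[spec.allele_field]] not in ("", alt):
            continue
        mane = parts[idx[spec.mane_field]]
        out.append(ConsequenceAnnotation(
            transcript_id=parts[idx[spec.transcript_field]],
            gene_symbol=parts[idx[spec.symbol_field]],
            consequence=parts[idx[spec.consequence_field]],
            is_mane_select=mane not in ("", "."),
        ))
    return out


def _is_acgt(allele: str) -> bool:
    return bool(allele) and all(b in "ACGT" for b in allele)


def load_cohort_vcf(path: str, proband_id: str,
                    spec: AnnotationSpec = AnnotationSpec(),
                    cfg: FilterConfig = FilterConfig()) -> Iterator[VariantObservation]:
    """Stream raw observations from one single-sample VCF.

    One observation per called non-reference genotype per alt allele;
    multi-allelic sites are decomposed into per-alt records.  QC subfields
    absent from a record are carried as ``None`` (flagged absent, not zero),
    to be handled by the QC filter.
    """
    try:
        vcf = pysam.VariantFile(path)
    except (OSError, ValueError) as exc:
        raise DataError(f"cannot parse VCF {path}: {exc}") from exc
    fields = _annotation_header_fields(vcf.header, spec)
    samples = list(vcf.header.samples)
    if len(samples) != 1:
        raise DataError(f"{path}: expected a single-sample VCF, found {len(samples)} samples")
    for rec in vcf:
        call = rec.samples[samples[0]]
        gt = tuple(a for a in (call.get("GT") or ()) if a is not None)
        alts = rec.alts or ()
        raw_csq = rec.info.get(spec.info_field, ())
        if isinstance(raw_csq, str):
            raw_csq = (raw_csq,)
        for ai, alt in enumerate(alts, start=1):
            if ai not in gt:
                continue
            if not _is_acgt(rec.ref or "") or not _is_acgt(alt):
                continue  # symbolic/spanning alleles are outside the analyzable set
            zyg = "hom_alt" if gt and all(a == ai for a in gt) else "het"
            gq = call.get("GQ")
            dp = call.get("DP")
            ad = call.get("AD")
            ab = None
            if ad is not None and dp not in (None, 0) and len(ad) > ai and ad[ai] is not None:
                ab = min(ad[ai] / dp, 1.0)
            global_af = 0.0
            af_vals = rec.info.get(cfg.af_key)
            if af_vals is not None:
                af_tuple = af_vals if isinstance(af_vals, tuple) else (af_vals,)
                if len(af_tuple) >= ai and af_tuple[ai - 1] is not None:
                    global_af = float(af_tuple[ai - 1])
            per_pop = {}
            for key in rec.info.keys():
                if key.startswith(cfg.pop_af_prefix) and key != cfg.af_key:
                    vals = rec.info.get(key)
                    vals = vals if isinstance(vals, tuple) else (vals,)
                    if len(vals) >= ai and vals[ai - 1] is not None:
                        per_pop[key[len(cfg.pop_af_prefix):].lower()] = float(vals[ai - 1])
            yield VariantObservation(
                proband_id=proband_id,
                key=VariantKey(chrom=rec.chrom, pos=rec.pos, ref=rec.ref, alt=alt),
                qc=GenotypeQC(genotype_quality=gq, depth=dp, allele_balance=ab, zygosity=zyg),
                freq=FrequencyRecord(global_af=global_af, per_population_af=per_pop),
                annotations=_parse_annotations(raw_csq, fields, spec, alt),
            )


# ---------------------------------------------------------------------------
# Filters


def apply_genotype_filters(obs: VariantObservation,
                           cfg: FilterConfig = FilterConfig()) -> tuple[bool, Optional[str]]:
    """Keep iff GQ, DP and allele balance all meet their (inclusive) bounds.

    Records missing any QC subfield are dropped with reason ``missing_qc``:
    a call that cannot be verified against the bounds cannot satisfy them.
    The drop reason names the first failing criterion.
    """
    qc = obs.qc
    if qc.genotype_quality is None or qc.depth is None or qc.allele_balance is None:
        return False, "missing_qc"
    if qc.genotype_quality < cfg.gq_min:
        return False, "genotype_quality"
    if qc.depth < cfg.dp_min:
        return False, "depth"
    if qc.allele_balance < cfg.ab_min:
        return False, "allele_balance"
    return True, None


def _terms(consequence: str) -> list[str]:
    return [t for t in consequence.split("&") if t]


def select_missense(obs: VariantObservation, mode: str,
                    severity_order: Optional[Sequence[str]] = None
                    ) -> tuple[Optional[VariantObservation], Optional[str]]:
    """Keep the observation iff it is missense under the selection mode.

    ``mane_select``: the annotation on the MANE Select transcript must carry
    ``missense_variant``.  ``most_severe``: ``missense_variant`` must be the
    single most severe consequence over all transcripts; the highest-priority
    missense-bearing transcript (MANE preferred on ties) is selected.
    """
    if not obs.annotations:
        return None, "no_annotation"
    if mode == "mane_select":
        mane = [a for a in obs.annotations if a.is_mane_select]
        if not mane:
            return None, "no_mane_transcript"
        hits = [a for a in mane if "missense_variant" in _terms(a.consequence)]
        if not hits:
            return None, "not_missense"
        return replace(obs, selected_annotation=hits[0]), None
    if mode == "most_severe":
        order = list(severity_order) if severity_order is not None else load_severity_order()
        rank = {term: i for i, term in enumerate(order)}
        fallback = len(order)

        def best_rank(ann: ConsequenceAnnotation) -> int:
            ranks = [rank.get(t, fallback) for t in _terms(ann.consequence)] or [fallback]
            return min(ranks)

        overall = min(best_rank(a) for a in obs.annotations)
        if overall >= fallback or order[overall] != "missense_variant":
            return None, "not_missense"
        hits = [a for a in obs.annotations
                if best_rank(a) == overall and "missense_variant" in _terms(a.consequence)]
        hits.sort(key=lambda a: (not a.is_mane_select,))
        return replace(obs, selected_annotation=hits[0]), None
    raise ConfigurationError(f"unknown selection mode {mode!r}")


def apply_af_filter(obs: VariantObservation, max_af: float,
                    excluded_populations=DEFAULT_EXCLUDED_POPULATIONS
                    ) -> tuple[bool, Optional[str]]:
    """Keep iff both the global AF and the popmax AF are <= ``max_af``.

    Variants absent from the frequency resource carry AF 0 (novel) and are
    always kept.
    """
    popmax = compute_popmax(obs.freq.per_population_af, excluded_populations)
    if obs.freq.global_af > max_af or popmax > max_af:
        return False, "allele_frequency"
    return True, None


# ---------------------------------------------------------------------------
# Table joins


class ScoreTable:
    """Predictor scores keyed by variant (and transcript for per-transcript tools).

    MutPred2, REVEL and VEST4 score transcripts, so their lookups require the
    selected annotation's transcript; BayesDel scores the variant itself and
    is looked up by variant key alone.
    """

    TRANSCRIPT_SPECIFIC = frozenset({"MutPred2", "REVEL", "VEST4"})

    def __init__(self, frame: pd.DataFrame, tools: Sequence[str] = DEFAULT_TOOLS,
                 transcript_specific: Optional[Iterable[str]] = None):
        required = {"chrom", "pos", "ref", "alt", "transcript"}
        missing = required - set(frame.columns)
        if missing:
            raise ConfigurationError(f"score table lacks columns {sorted(missing)}")
        self.tools = tuple(tools)
        self.transcript_specific = frozenset(
            transcript_specific if transcript_specific is not None
            else self.TRANSCRIPT_SPECIFIC & set(tools)
        )
        for tool in self.tools:
            if tool not in frame.columns:
                raise ConfigurationError(f"score table lacks a column for tool {tool!r}")
        self._by_transcript: dict[tuple, dict[str, float]] = {}
        self._by_variant: dict[tuple, dict[str, float]] = {}
        cols = frame[["chrom", "pos", "ref", "alt", "transcript", *self.tools]].itertuples(index=False)
        for row in cols:
            chrom, pos, ref, alt, tx = row[:5]
            vkey = (str(chrom), int(pos), str(ref), str(alt))
            tkey = (*vkey, str(tx))
            for tool, value in zip(self.tools, row[5:]):
                if value is None or (isinstance(value, float) and math.isnan(value)):
                    continue
                value = float(value)
                if tool in self.transcript_specific:
                    slot = self._by_transcript.setdefault(tkey, {})
                    key_desc = tkey
                else:
                    slot = self._by_variant.setdefault(vkey, {})
                    key_desc = vkey
                if tool in slot and slot[tool] != value:
                    raise DataError(
                        f"conflicting {tool} scores for {key_desc}: {slot[tool]} vs {value}"
                    )
                slot[tool] = value

    @classmethod
    def from_tsv(cls, path: str, tools: Sequence[str] = DEFAULT_TOOLS,
                 column_map: Optional[Mapping[str, str]] = None, **kwargs) -> "ScoreTable":
        frame = pd.read_csv(path, sep="\t", dtype={"chrom": str, "ref": str, "alt": str},
                            na_values=["."])
        if column_map:
            frame = frame.rename(columns={v: k for k, v in column_map.items()})
        return cls(frame, tools=tools, **kwargs)

    def lookup(self, key: VariantKey, transcript_id: Optional[str], tool: str) -> Optional[float]:
        vkey = (key.chrom, key.pos, key.ref, key.alt)
        if tool in self.transcript_specific:
            if transcript_id is None:
                return None
            return self._by_transcript.get((*vkey, transcript_id), {}).get(tool)
        return self._by_variant.get(vkey, {}).get(tool)


def join_scores(obs: VariantObservation, score_table: ScoreTable,
                tools: Sequence[str] = DEFAULT_TOOLS) -> VariantObservation:
    """Attach each requested tool's score (or mark it missing).

    Transcript-specific tools are read on the selected annotation's
    transcript only; a score present solely on a non-selected transcript
    stays missing.
    """
    tx = obs.selected_annotation.transcript_id if obs.selected_annotation else None
    scores = {tool: score_table.lookup(obs.key, tx, tool) for tool in tools}
    obs.scores = scores
    return obs


def load_gene_table(path: str) -> dict[str, GeneRecord]:
    frame = pd.read_csv(path, sep="\t", dtype=str)
    missing = {"symbol", "validity", "moi"} - set(frame.columns)
    if missing:
        raise ConfigurationError(f"gene table lacks columns {sorted(missing)}")
    table: dict[str, GeneRecord] = {}
    for row in frame.itertuples(index=False):
        if row.symbol in table:
            raise DataError(f"duplicate gene symbol {row.symbol}")
        table[row.symbol] = GeneRecord(symbol=row.symbol, validity=row.validity, moi=row.moi)
    return table


def join_genes(obs: VariantObservation, gene_table: Mapping[str, GeneRecord],
               scope: str) -> tuple[bool, Optional[str]]:
    """Attach the gene record; under disease-gene scope drop unlisted genes."""
    record = gene_table.get(obs.gene_symbol) if obs.gene_symbol else None
    obs.gene = record
    if scope == "disease_genes":
        if record is None or record.validity not in DISEASE_VALIDITY:
            return False, "gene_scope"
    return True, None


EXTERNAL_CLASSES = ("P/LP", "VUS", "Conflicting", "B/LB")


def load_external_classifications(path: str) -> dict[tuple, str]:
    """Variant -> external assertion class (e.g. a ClinVar snapshot) from TSV."""
    frame = pd.read_csv(path, sep="\t", dtype={"chrom": str, "ref": str, "alt": str})
    missing = {"chrom", "pos", "ref", "alt", "classification"} - set(frame.columns)
    if missing:
        raise ConfigurationError(f"classification table lacks columns {sorted(missing)}")
    out = {}
    for row in frame.itertuples(index=False):
        if row.classification not in EXTERNAL_CLASSES:
            raise DataError(
                f"unknown classification label {row.classification!r}; "
                f"expected one of {EXTERNAL_CLASSES}"
            )
        out[(str(row.chrom), int(row.pos), str(row.ref), str(row.alt))] = row.classification
    return out


# ---------------------------------------------------------------------------
# The chain


@dataclass
class IngestResult:
    """Kept observations (flat table) plus per-proband drop accounting."""

    observations: pd.DataFrame
    drop_counts: pd.DataFrame  # columns: proband_id, reason, count
    raw_counts: dict[str, int] = field(default_factory=dict)

    def kept_per_proband(self) -> pd.Series:
        if self.observations.empty:
            return pd.Series(dtype=int)
        return self.observations.groupby("proband_id").size()


_OBS_COLUMNS = [
    "proband_id", "chrom", "pos", "ref", "alt", "gene_symbol", "transcript_id",
    "consequence", "mane_select", "validity", "moi", "zygosity",
    "gq", "dp", "ab", "global_af", "popmax_af",
]


def _observation_row(obs: VariantObservation, cfg: FilterConfig,
                     tools: Sequence[str]) -> dict:
    ann = obs.selected_annotation
    row = {
        "proband_id": obs.proband_id,
        "chrom": obs.key.chrom,
        "pos": obs.key.pos,
        "ref": obs.key.ref,
        "alt": obs.key.alt,
        "gene_symbol": ann.gene_symbol if ann else None,
        "transcript_id": ann.transcript_id if ann else None,
        "consequence": ann.consequence if ann else None,
        "mane_select": bool(ann.is_mane_select) if ann else False,
        "validity": obs.gene.validity if obs.gene else "other_or_absent",
        "moi": obs.gene.moi if obs.gene else "other",
        "zygosity": obs.qc.zygosity,
        "gq": obs.qc.genotype_quality,
        "dp": obs.qc.depth,
        "ab": obs.qc.allele_balance,
        "global_af": obs.freq.global_af,
        "popmax_af": compute_popmax(obs.freq.per_population_af, cfg.excluded_populations),
    }
    for tool in tools:
        row[f"score_{tool}"] = obs.scores.get(tool)
    return row


def ingest_cohort(vcfs: Mapping[str, str],
                  score_table: Optional[ScoreTable],
                  gene_table: Mapping[str, GeneRecord],
                  cfg: FilterConfig = FilterConfig(),
                  tools: Sequence[str] = DEFAULT_TOOLS,
                  annotation_spec: AnnotationSpec = AnnotationSpec(),
                  severity_order: Optional[Sequence[str]] = None) -> IngestResult:
    """Run the full filter chain over a cohort of ``{proband_id: vcf_path}``.

    Chain order: consequence selection -> genotype QC -> allele frequency ->
    gene scope -> score annotation.  Returns the kept observations as a flat
    table (one ``score_<tool>`` column per tool) and exact per-proband drop
    counts by first failing reason.
    """
    if severity_order is None and cfg.mode == "most_severe":
        severity_order = load_severity_order()
    rows: list[dict] = []
    drops: Counter = Counter()
    raw_counts: dict[str, int] = {}
    for proband_id, path in vcfs.items():
        n_raw = 0
        for obs in load_cohort_vcf(path, proband_id, annotation_spec, cfg):
            n_raw += 1
            selected, reason = select_missense(obs, cfg.mode, severity_order)
            if selected is None:
                drops[(proband_id, reason)] += 1
                continue
            keep, reason = apply_genotype_filters(selected, cfg)
            if not keep:
                drops[(proband_id, reason)] += 1
                continue
            keep, reason = apply_af_filter(selected, cfg.max_af, cfg.excluded_populations)
            if not keep:
                drops[(proband_id, reason)] += 1
                continue
            keep, reason = join_genes(selected, gene_table, cfg.scope)
            if not keep:
                drops[(proband_id, reason)] += 1
                continue
            if score_table is not None:
                join_scores(selected, score_table, tools)
            rows.append(_observation_row(selected, cfg, tools))
        raw_counts[proband_id] = n_raw
    columns = _OBS_COLUMNS + [f"score_{t}" for t in tools]
    observations = pd.DataFrame(rows, columns=columns)
    drop_frame = pd.DataFrame(
        [(p, r, n) for (p, r), n in sorted(drops.items())],
        columns=["proband_id", "reason", "count"],
    )
    return IngestResult(observations=observations, drop_counts=drop_frame, raw_counts=raw_counts)
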