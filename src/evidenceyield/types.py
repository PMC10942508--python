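"""Core domain types shared across the pipeline.

The pipeline's unit of analysis is one proband x variant observation: a
rare missense variant seen in one individual, carrying its genotype QC
fields, allele frequencies, the transcript annotation under which it was
selected, the gene's disease-validity / inheritance classes and the raw
scores of the computational predictors.
"""
from __future__ import annotations

from dataclasses import dataclass, field
from typing import Mapping, Optional

# Ordered evidence scale, strongest pathogenic evidence first.  ``NoScore``
# sits outside the ordering: it marks a variant the predictor did not score.
PATHOGENIC_STRENGTHS = ("VeryStrong", "Strong", "Moderate", "Supporting")
BENIGN_STRENGTHS = ("VeryStrong", "Strong", "Moderate", "Supporting")

EVIDENCE_CATEGORIES = (
    "PP3_VeryStrong",
    "PP3_Strong",
    "PP3_Moderate",
    "PP3_Supporting",
    "Indeterminate",
    "BP4_Supporting",
    "BP4_Moderate",
    "BP4_Strong",
    "BP4_VeryStrong",
)
NO_SCORE = "NoScore"
ALL_CATEGORIES = EVIDENCE_CATEGORIES + (NO_SCORE,)

VALIDITY_CLASSES = ("Definitive", "Strong", "Moderate", "other_or_absent")
DISEASE_VALIDITY = ("Definitive", "Strong", "Moderate")
MOI_CLASSES = ("AD_only", "AR_only", "other")

DEFAULT_TOOLS = ("BayesDel_noAF", "MutPred2", "REVEL", "VEST4")

# Populations conventionally treated as bottlenecked/small and excluded from
# the popmax computation (configurable everywhere it is used).
DEFAULT_EXCLUDED_POPULATIONS = frozenset({"asj", "fin", "ami", "mid", "oth"})


class DataError(ValueError):
    """Input data violates a documented contract (bad AF, conflicting scores...)."""


class ConfigurationError(ValueError):
    """A configuration file or argument is invalid."""


@dataclass(frozen=True)
class VariantKey:
    """Genomic identity of one alt allele (1-based, VCF-style coordinates)."""

    chrom: str
    pos: int
    ref: str
    alt: str

    def __post_init__(self) -> None:
        if self.pos < 1:
            raise DataError(f"position must be >= 1, got {self.pos}")
        for allele in (self.ref, self.alt):
            if not allele or any(b not in "ACGT" for b in allele):
                raise DataError(f"allele must be a non-empty ACGT string, got {allele!r}")
        if self.ref == self.alt:
            raise DataError(f"ref and alt are identical at {self.chrom}:{self.pos}")

    @property
    def is_snv(self) -> bool:
        return len(self.ref) == 1 and len(self.alt) == 1


@dataclass(frozen=True)
class GenotypeQC:
    """Per-call quality fields read from the VCF genotype column.

    ``allele_balance`` is alt-supporting reads over total depth; for hom-alt
    calls it is typically near 1.  Any field may be absent in the input, in
    which case it is ``None`` here and the QC filter drops the record
    (unverifiable calls cannot be shown to meet the bounds).
    """

    genotype_quality: Optional[int]
    depth: Optional[int]
    allele_balance: Optional[float]
    zygosity: str  # "het" or "hom_alt"

    def __post_init__(self) -> None:
        if self.depth is not None and self.depth < 0:
            raise DataError(f"depth must be >= 0, got {self.depth}")
        if self.allele_balance is not None and not (0.0 <= self.allele_balance <= 1.0):
            raise DataError(f"allele balance outside [0, 1]: {self.allele_balance}")
        if self.zygosity not in ("het", "hom_alt"):
            raise DataError(f"unknown zygosity {self.zygosity!r}")


@dataclass(frozen=True)
class FrequencyRecord:
    """Reference-population allele frequencies for one alt allele."""

    global_af: float
    per_population_af: Mapping[str, float] = field(default_factory=dict)

    def __post_init__(self) -> None:
        for label, af in [("global", self.global_af), *self.per_population_af.items()]:
            if not (0.0 <= af <= 1.0):
                raise DataError(f"allele frequency for {label} outside [0, 1]: {af}")

    def popmax(self, excluded_populations=DEFAULT_EXCLUDED_POPULATIONS) -> float:
        return compute_popmax(self.per_population_af, excluded_populations)


def compute_popmax(per_population_af: Mapping[str, float],
                   excluded_populations=DEFAULT_EXCLUDED_POPULATIONS) -> float:
    """Highest AF over non-excluded populations; 0 when none remain.

    Population codes are compared case-insensitively.  An AF outside [0, 1]
    is a data error, never silently clamped.
    """
    excluded = {p.lower() for p in excluded_populations}
    best = 0.0
    for pop, af in per_population_af.items():
        if af is None or pop.lower() in excluded:
            continue
        if not (0.0 <= af <= 1.0):
            raise DataError(f"allele frequency for population {pop} outside [0, 1]: {af}")
        best = max(best, af)
    return best


@dataclass(frozen=True)
class ConsequenceAnnotation:
    """One transcript-level consequence annotation (a variant carries many)."""

    transcript_id: str
    gene_symbol: str
    consequence: str
    is_mane_select: bool


@dataclass(frozen=True)
class GeneRecord:
    symbol: str
    validity: str
    moi: str

    def __post_init__(self) -> None:
        if self.validity not in VALIDITY_CLASSES:
            raise DataError(f"unknown validity class {self.validity!r} for {self.symbol}")
        if self.moi not in MOI_CLASSES:
            raise DataError(f"unknown mode-of-inheritance class {self.moi!r} for {self.symbol}")

    @property
    def is_disease_gene(self) -> bool:
        return self.validity in DISEASE_VALIDITY


@dataclass
class VariantObservation:
    """One proband x variant record flowing through the filter chain."""

    proband_id: str
    key: VariantKey
    qc: GenotypeQC
    freq: FrequencyRecord
    annotations: list[ConsequenceAnnotation] = field(default_factory=list)
    selected_annotation: Optional[ConsequenceAnnotation] = None
    gene: Optional[GeneRecord] = None
    scores: dict[str, Optional[float]] = field(default_factory=dict)

    @property
    def gene_symbol(self) -> Optional[str]:
        if self.selected_annotation is not None:
            return self.selected_annotation.gene_symbol
        return None
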