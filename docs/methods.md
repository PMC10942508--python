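# Methods

## Pipeline model

One observation is a (proband, variant) pair. The ingest chain applies, in
order: consequence selection, genotype QC, rarity, gene scope. Every drop is
attributed to the *first* failing criterion, so per proband the raw record
count equals kept + Σ drops exactly; this bookkeeping identity is asserted
in the tests and surfaced in the run manifest.

**Consequence selection.** `mane_select` keeps a variant iff the annotation
on the MANE Select transcript carries `missense_variant` (ampersand-joined
VEP terms are split). `most_severe` keeps it iff `missense_variant` is the
single most severe term over all transcripts under the packaged VEP
severity ranking (`data/vep_severity.yaml`), selecting the
highest-priority missense-bearing transcript with MANE preferred on ties.
Records with no MANE-flagged annotation drop as `no_mane_transcript` in
MANE mode. Indels survive decomposition but never selection (missense is an
SNV consequence); inputs are assumed normalized upstream and no
left-alignment is attempted.

**Genotype QC.** Inclusive bounds, exactly as printed in the defaults:
GQ ≥ 40, DP ≥ 10, allele balance ≥ 0.2, all configurable. Allele balance is
alt-supporting reads over total depth and its lower bound applies to both
het and hom-alt calls (hemizygous genotypes are treated as hom-alt).
Records missing any QC subfield drop as `missing_qc`: a call that cannot be
verified against the bounds cannot be shown to meet them.

**Rarity.** A variant is kept iff global AF ≤ threshold AND popmax AF ≤
threshold (defaults 0.01; 0.05 as the lenient grid point). Popmax is the
maximum AF over non-bottlenecked populations; the exclusion set defaults to
{ASJ, FIN, AMI, MID, OTH}, the convention of the gnomAD-style frequency
resources the AF fields emulate. Variants absent from the frequency
resource carry AF 0 (novel) and are kept — the standard rare-disease
convention. Frequencies may come from INFO fields (`AF`, `AF_<pop>`) or a
side table.

**Gene scope.** `disease_genes` keeps only genes curated Definitive, Strong
or Moderate; `genome_wide` keeps everything and attaches the gene record
when available. Gene symbols are matched verbatim from the selected
annotation; no alias resolution.

**Score annotation.** MutPred2, REVEL and VEST4 are transcript-specific and
are read on the selected transcript only; BayesDel (no-AF variant) is keyed
by variant alone. Conflicting duplicate scores are a data error, not a
silent overwrite.

## Calibrated interval classification

Each tool's thresholds (`data/thresholds.yaml`) define ordered pathogenic
breakpoints (score ≥ breakpoint ⇒ at least that PP3 strength) and benign
breakpoints (score ≤ breakpoint ⇒ BP4), with an indeterminate gap between
the weakest benign and weakest pathogenic thresholds. Strengths absent from
a tool's map are unreachable — BayesDel and VEST4 cannot emit
BP4_Strong/VeryStrong and MutPred2 cannot emit BP4_VeryStrong, and the test
suite asserts these impossibilities. Numeric values are configuration
transcribed from the published interval calibration and cited per tool in
the YAML; nothing in the code depends on the specific decimals.

Numerical choices: scores are compared at full input precision; a score
equal to a breakpoint takes the *stronger* evidence (≥ pathogenic, ≤
benign), a documented tie-break users can audit; scores outside a tool's
declared range raise rather than clamp.

## Bayesian point combination

Evidence strengths map to points Su/Mo/St/VSt = 1/2/4/8, benign negative,
and the posterior probability of pathogenicity for a total *n* is

    odds(n) = O_PVSt^(n/8) · prior/(1 − prior),   posterior = odds/(1+odds)

with O_PVSt = 350 and prior 0.1 by default (the published framework
constants), and named prior presets 0.045 (disease-associated genes) and
0.01 (genome-wide) for context-specific posteriors. Class bounds partition
the integers: P ≥ 10, LP 6–9, VUS 0–5, LB −6…−1, B ≤ −7. At the minimal
class bounds the defaults give posteriors 99.4% (Pathogenic) and 90.0%
(Likely Pathogenic); a single PP3_Strong (4 points) is a VUS. PP3 and BP4
are mutually exclusive within a profile; no other code-applicability
semantics are enforced — combining-rule caveats (e.g. double-counting of
conservation or frequency signal between PP3 and other codes) are the
curator's responsibility, not the engine's.

## Statistics

* Cohort summaries: medians use midpoint interpolation (the median of an
  even cohort is the mean of the central pair — hence values like 17.5);
  sd is the sample standard deviation (n − 1).
* Bootstrap CIs: percentile 2.5/97.5 of the resampled proportion over 1,000
  replicates by default; the resampling unit defaults to single
  observations (proband-variant pairs), which is the only unit that can
  produce sub-0.01-percentage-point CI widths at ~10⁴–10⁵ observations;
  whole-proband resampling is available. Seeds are mandatory; there is no
  hidden global randomness.
* AR-vs-AD enrichment: exact two-tailed binomial by the minimum-likelihood
  rule (sum of outcome probabilities no larger than the observed one),
  with k = PP3_Moderate+Strong calls in AR-only genes, n = same over
  AR-only ∪ AD-only, and the null p₀ = AR-only share of *all* analyzed
  observations in those genes (a gene-count null, 1,903 : 1,004, is
  available as an option). Bonferroni multiplies by the number of tools
  (default 4). PP3_Supporting can be included via a flag for sensitivity.
* Unique-variant counts deduplicate by variant key across probands and are
  idempotent under cohort repetition. Concordance reports coverage and
  class proportions over reported variants, with VUS and Conflicting
  pooled.

## Synthetic cohorts

The generator's defaults are the study conditions the package analyzes:

* 300 probands; disease-gene census 1,004 AD-only : 1,903 AR-only : 517
  other (validity cycled Definitive/Strong/Moderate), plus 12,142
  background genes for genome-wide scope (~4.5-fold more genes).
* Rare-missense candidates per proband: negative binomial, mean 75
  (disease scope; the analyzable median after engineered drops lands near
  72) or 321 (genome-wide preset), size 30 — chosen to reproduce per-proband
  ranges of roughly 50–190 and 240–850 respectively.
* Scores: per tool a two-component beta mixture on the tool's score range,
  conditioned on a per-variant deleterious/benign label shared across tools
  (inducing realistic positive inter-tool correlation, conditionally
  independent given the label; a correlation knob is out of scope). The
  shipped components were fitted once, by Nelder–Mead on relative band
  error, so that the evidence-band masses match a realistic rare-disease
  profile: PP3_Strong 1.0–1.3% of analyzed variants, PP3_Moderate and
  Supporting ~4–6% each, indeterminate ~23–25%, BP4 ~53–64%. Per-gene-class
  deleterious fractions (AD-only 0.080, AR-only 0.145, other 0.105,
  background 0.050) give a variant-weighted marginal of 0.12 in disease
  genes and build in the AR > AD enrichment; the background value yields a
  genome-wide PP3_Strong fold-increase of ~2.3–2.6× at the default scales.
  These fractions are tuned to the printed proportions of the emulated
  setting, not ground truth about any real cohort.
* Missingness per tool (BayesDel 0.004, MutPred2 0, REVEL 0.136,
  VEST4 0.074) mirrors precomputed-database coverage gaps.
* Allele frequencies: 55% of variants novel (AF 0), the rest
  Beta(0.5, 20)·0.05; per-population AFs are the global AF times
  Uniform(0.2, 2.5) multipliers (bottlenecked FIN up to 6×, exercising the
  popmax exclusion). QC fields fail each bound with probability 0.01 by
  engineering; 5% extra synonymous records exercise consequence selection.
* Variant sharing: by default probands draw without replacement from a
  shared pool sized 2.13× the expected observation count (~79% of
  observations are unique variants, matching heavy-singleton cohorts);
  `shared_pool=False` draws every observation independently, the setting
  used for the parameter-recovery test because it makes the binomial
  standard error exact.
* All randomness descends from one seed through named `SeedSequence`
  children (pool, counts, assignment, QC, extras), so identical seeds give
  byte-identical fixtures.

`expected_yield` integrates the mixture CDF over each category's score
interval — the exact analytic expectation for the empirical per-category
fractions, against which the full pipeline is checked within three binomial
standard errors per tool and category.

What the generator does *not* emulate: linkage and haplotype structure,
pedigrees, sequencing artifacts beyond the QC fields, site-level filters,
genuinely diagnostic variants, or the true joint score distribution of any
real predictor pair. Passing tests therefore demonstrate the pipeline's
correctness and the plausibility of the emulated regime, not properties of
real patient data.

## Problem sizes

The default test and acceptance runs use 12-proband cohorts for unit-level
checks and one 300-proband cohort (~22,000 analyzable observations) for the
end-to-end recovery and monotonicity checks — the full configured cohort
size, which completes in seconds on one CPU.

## Known limitations

* Threshold decimals are transcribed configuration; laboratories should
  verify them against the calibration publication for their tool versions.
* The AR-vs-AD null based on observation shares treats every observation as
  independent; shared variants across probands mildly violate this.
* No compound-het logic, phasing, liftover, or VEP re-implementation;
  annotations are consumed, not computed.
* Concordance consumes a user-supplied snapshot table; there is no live
  ClinVar access.
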