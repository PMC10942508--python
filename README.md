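# evidenceyield

Evidence yield of calibrated PP3/BP4 computational predictions in
rare-disease genome cohorts.

## The problem

The ACMG/AMP sequence-variant classification framework combines weighted
evidence codes into a five-tier verdict (Benign … Pathogenic). Its PP3/BP4
codes cover *in silico* prediction of a missense variant's effect. Interval
calibration of popular metapredictors (BayesDel, MutPred2, REVEL, VEST4)
assigns each score range an evidence strength — Supporting, Moderate or
Strong for pathogenicity (PP3), down to Very Strong for benignity (BP4) —
raising the concern that "Strong" computational evidence might now be handed
to an excessive number of variants per patient.

`evidenceyield` quantifies that concern. From per-proband VCFs it extracts
rare missense variants (MANE Select or most-severe-consequence mode;
genotype quality ≥ 40, depth ≥ 10, allele balance ≥ 0.2; global and popmax
allele frequency ≤ 1% or ≤ 5%), classifies every predictor score against the
calibrated thresholds, and tabulates per-proband counts by evidence strength
— stratified by gene–disease validity (Definitive/Strong/Moderate) and mode
of inheritance (AD-only vs AR-only), with bootstrap confidence intervals,
exact two-tailed binomial enrichment tests (Bonferroni-corrected), unique
variant/gene counts, genome-wide fold changes, and concordance against an
external classification snapshot such as ClinVar.

It also implements the Bayesian point adaptation of the framework that
governs what an evidence profile means downstream: points Su/Mo/St/VSt =
1/2/4/8 (benign negative), posterior odds = 350^(points/8) × prior odds,
class bounds P ≥ 10, LP 6–9, VUS 0–5, LB −6…−1, B ≤ −7. One PP3_Strong line
alone (4 points) therefore leaves a variant a VUS.

Because real patient cohorts cannot be redistributed, the package ships a
first-class synthetic-cohort generator that emulates one: per-proband
rare-missense counts in the tens to hundreds, two-component
(deleterious/benign) score mixtures per tool, per-population allele
frequencies, genotype-QC failures and per-tool score missingness — emitted
as real VCF/TSV inputs with a per-observation truth table.

## Worked example

```python
from dataclasses import replace
from evidenceyield import EvidenceYieldModel
from evidenceyield.simulate import GeneratorConfig, generate_cohort

cohort = generate_cohort(replace(GeneratorConfig(), n_probands=12), 421)
model = EvidenceYieldModel(cohort.analyzable_observations())
print(model.fit(seed=7).summary())
```

```
Evidence-yield analysis
  probands: 12   analyzable observations: 868

Per-proband counts by evidence strength (median (range) / mean (sd)):
               BayesDel_noAF median (range) BayesDel_noAF mean (sd)  ...
PP3_Strong                          1 (0-2)               0.8 (0.7)  ...
PP3_Moderate                      3.5 (1-7)               3.5 (1.9)  ...
Indeterminate                    17 (12-27)              18.1 (4.5)  ...
BP4_Moderate                   28.5 (22-46)              31.1 (8.3)  ...
NoScore                             0 (0-1)               0.2 (0.4)  ...

PP3_Strong proportion of analyzable variants (bootstrap 95% CI, seed 7):
  BayesDel_noAF  1.15% [0.576, 1.959]
  ...
```

Reading: each proband carries a median of one BayesDel PP3_Strong variant
among ~72 analyzable rare missense variants (~1% of them), while most
variants fall in the benign or indeterminate intervals — strong
computational evidence is rare per individual, so calibrated PP3/BP4 use is
unlikely to flood classification with Pathogenic calls (a lone PP3_Strong is
still a VUS):

```
$ evidence-yield combine --codes "PP3:Strong,PM2:Moderate,PS4:Strong" --prior 0.1
points: 10
posterior P(pathogenic): 0.9941
classification: Pathogenic
```

The same pipeline runs on real data from the shell:

```
evidence-yield ingest --vcf-dir vcfs/ --scores dbnsfp_subset.tsv \
    --genes gencc_genes.tsv --mode mane_select --max-af 0.01 \
    --scope disease_genes --out observations.tsv
evidence-yield classify --observations observations.tsv --out calls.tsv
evidence-yield tabulate --calls calls.tsv --out yield.tsv
evidence-yield run --config run.yaml        # all stages + manifest
evidence-yield synth --out fixtures/ --seed 17   # synthetic cohort
```

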