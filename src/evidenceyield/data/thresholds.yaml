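# Calibrated PP3/BP4 evidence-strength breakpoints per computational
# predictor, transcribed from the interval calibration of Pejaver et al.
# (2022), Am J Hum Genet 109:2163-2177.  All four tools score in the
# "higher is more deleterious" direction.  A strength absent from a tool's
# map is unreachable for that tool (the calibration could not support it).
#
# Tie-break convention (documented, auditable): a score equal to a
# breakpoint takes the stronger evidence, i.e. >= for pathogenic
# breakpoints and <= for benign breakpoints.
tools:
  BayesDel_noAF:
    source: "Pejaver et al. 2022, Table 2 (BayesDel without allele frequency)"
    score_range: [-1.3, 0.8]
    pathogenic:
      Supporting: 0.13
      Moderate: 0.27
      Strong: 0.50
    benign:
      Supporting: -0.18
      Moderate: -0.36
  MutPred2:
    source: "Pejaver et al. 2022, Table 2"
    score_range: [0.0, 1.0]
    pathogenic:
      Supporting: 0.737
      Moderate: 0.829
      Strong: 0.932
    benign:
      Supporting: 0.391
      Moderate: 0.197
      Strong: 0.010
  REVEL:
    source: "Pejaver et al. 2022, Table 2"
    score_range: [0.0, 1.0]
    pathogenic:
      Supporting: 0.644
      Moderate: 0.773
      Strong: 0.932
    benign:
      Supporting: 0.290
      Moderate: 0.183
      Strong: 0.016
      VeryStrong: 0.003
  VEST4:
    source: "Pejaver et al. 2022, Table 2"
    score_range: [0.0, 1.0]
    pathogenic:
      Supporting: 0.764
      Moderate: 0.861
      Strong: 0.965
    benign:
      Supporting: 0.449
      Moderate: 0.302
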