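# Informative priors for the MCI analysis.
prevalence: {alpha: 25.422, beta: 281.851}
sensitivity:
  MoCA: {alpha: 824.530, beta: 146.329}
  MMSE: {alpha: 269.497, beta: 110.668}
  ADAS-cog: {alpha: 35.209, beta: 9.552}
specificity:
  MoCA: {alpha: 440.462, beta: 117.819}
  MMSE: {alpha: 469.554, beta: 192.381}
  ADAS-cog: {alpha: 56.016, beta: 11.479}
covariance:
  - pair: [MoCA, MMSE]
    lower: -1.0
    upper: 1.0
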