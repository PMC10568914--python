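# Informative priors for the AD analysis: Beta(alpha, beta) for prevalence
# and per-test sensitivity/specificity, bounded-uniform for the MoCA-MMSE
# conditional-dependence covariances.
prevalence: {alpha: 2.819, beta: 16.021}
sensitivity:
  MoCA: {alpha: 270.154, beta: 20.020}
  MMSE: {alpha: 464.322, beta: 50.770}
  ADAS-cog: {alpha: 125.247, beta: 13.288}
specificity:
  MoCA: {alpha: 192.121, beta: 22.472}
  MMSE: {alpha: 514.797, beta: 69.080}
  ADAS-cog: {alpha: 113.235, beta: 9.448}
covariance:
  - pair: [MoCA, MMSE]
    lower: -1.0
    upper: 1.0
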