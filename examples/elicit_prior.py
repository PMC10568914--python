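"""Turn a literature summary into a Beta prior.

A review reports a test's sensitivity as "most likely 0.90, and we are 95%
sure it exceeds 0.80": the prior mode is 0.90 and the 5th percentile 0.80.
elicit_beta solves for the Beta(alpha, beta) satisfying both.
"""

from blcmdx import beta_summary, elicit_beta

spec = elicit_beta(0.90, bound=0.80, percentile=0.05, central_kind="mode")
s = beta_summary(spec)
print(f"elicited prior: Beta({spec.alpha:.3f}, {spec.beta:.3f})")
print(f"  mode {s.mode:.4f}  mean {s.mean:.4f}  sd {s.variance**0.5:.4f}")
print(f"  5th percentile {float(spec.quantile(0.05)):.4f} (target 0.80)")
# The implied "prior sample size" alpha+beta-2 shows how much data-equivalent
# weight this prior carries in the posterior.
print(f"  effective prior sample size ~ {spec.alpha + spec.beta - 2:.0f}")
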