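"""Fit the latent class model to the packaged AD count table.

Estimates the true AD prevalence and the sensitivity/specificity of MoCA,
MMSE and ADAS-cog without a gold standard, accounting for MoCA-MMSE
conditional dependence. Uses a shortened chain so the example runs in a
few seconds; pass iterations=100_000, burn_in=50_000, thin=10 for the
full protocol.
"""

from blcmdx import (
    MCMCConfig,
    diagnostics,
    load_counts_fixture,
    load_priors_fixture,
    sample_posterior,
    summarize,
)

counts = load_counts_fixture("ad")
priors = load_priors_fixture("ad")
print(f"Observed 8-cell table (n={counts.n}):")
print(counts.to_frame().to_string(index=False))

chains = sample_posterior(
    counts, priors, MCMCConfig(iterations=20_000, burn_in=10_000, thin=4, seed=1)
)
summary = summarize(chains)

# Each row: posterior mean and equal-tailed 95% credible interval.
# "prevalence" is the true (not consensus-diagnosis) AD prevalence; se_*/sp_*
# are the tests' accuracies against the latent disease status.
print(summary.table[["mean", "lower", "upper"]].round(3))
# Youden's J = Se + Sp - 1 per test: 1 = perfect discrimination, 0 = useless.
print(summary.youden["youden"].round(3))
print("converged:", diagnostics(chains).converged)
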