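"""Independent reference implementations used only to check the package.

These deliberately avoid the package's vectorized code paths: cell
probabilities come from explicit per-pattern latent-class enumeration with
a dict-built 2x2 joint for each dependent pair, and Beta log-densities are
hand-coded from lgamma.
"""

from __future__ import annotations

import math

import numpy as np

from blcmdx import AccuracyParams, TestPanel
from blcmdx.model import cov_bounds


def oracle_cell_probs(params: AccuracyParams, panel: TestPanel) -> np.ndarray:
    """Brute-force enumeration: mix over disease status, multiply per-test
    Bernoulli terms, and read dependent-pair cells from the explicit 2x2
    joint built from (margins, covariance)."""
    out = []
    for pattern in panel.patterns():
        total = 0.0
        for diseased in (True, False):
            weight = params.prevalence if diseased else 1.0 - params.prevalence
            margins = params.se if diseased else tuple(1.0 - s for s in params.sp)
            covs = params.cov_d if diseased else params.cov_n
            p = 1.0
            for k in panel.independent_indices:
                p *= margins[k] if pattern[k] == 1 else 1.0 - margins[k]
            for idx, (i, j) in enumerate(panel.dependent_pairs):
                mi, mj, c = margins[i], margins[j], covs[idx]
                joint = {
                    (1, 1): mi * mj + c,
                    (1, 0): mi * (1.0 - mj) - c,
                    (0, 1): (1.0 - mi) * mj - c,
                    (0, 0): (1.0 - mi) * (1.0 - mj) + c,
                }
                p *= joint[(int(pattern[i]), int(pattern[j]))]
            total += weight * p
        out.append(total)
    return np.array(out)


def oracle_log_likelihood(params, counts) -> float:
    probs = oracle_cell_probs(params, counts.panel)
    ll = 0.0
    for c, p in zip(counts.counts, probs):
        if c > 0:
            ll += c * math.log(p)
    return ll


def beta_logpdf(x: float, a: float, b: float) -> float:
    """Hand-coded Beta log-density (lgamma only, no scipy)."""
    return (
        math.lgamma(a + b)
        - math.lgamma(a)
        - math.lgamma(b)
        + (a - 1.0) * math.log(x)
        + (b - 1.0) * math.log(1.0 - x)
    )


def random_valid_params(rng: np.random.Generator, panel: TestPanel) -> AccuracyParams:
    """A parameter draw guaranteed to satisfy all admissibility invariants:
    covariances are placed uniformly inside their bounds."""
    pi = rng.uniform(0.05, 0.95)
    se = tuple(rng.uniform(0.05, 0.95, panel.k))
    sp = tuple(rng.uniform(0.05, 0.95, panel.k))
    cov_d, cov_n = [], []
    for i, j in panel.dependent_pairs:
        lo, hi = cov_bounds(se[i], se[j])
        cov_d.append(rng.uniform(lo, hi))
        lo, hi = cov_bounds(sp[i], sp[j])
        cov_n.append(rng.uniform(lo, hi))
    return AccuracyParams(pi, se, sp, tuple(cov_d), tuple(cov_n))


def exhaustive_best_cutoff(scores, labels, direction):
    """Exhaustive threshold search, coded independently of the package:
    returns the best achievable Youden value over every possible rule."""
    scores = np.asarray(scores, float)
    labels = np.asarray(labels, int)
    distinct = np.unique(scores)
    cuts = [-math.inf, math.inf]
    cuts += list((distinct[:-1] + distinct[1:]) / 2.0)
    best = -math.inf
    for c in cuts:
        if direction == "lower_is_positive":
            pos = scores <= c
        else:
            pos = scores > c
        se = pos[labels == 1].mean()
        sp = (~pos[labels == 0]).mean()
        best = max(best, se + sp - 1.0)
    return best
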