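"""The latent class probability model with pairwise conditional dependence.

Disease status D is an unobserved Bernoulli(pi) class. Given the class,
each test k is positive with probability Se_k (diseased) or 1 - Sp_k
(non-diseased). For a dependent pair (i, j) the within-class joint of the
two binary results is shifted away from independence by an additive
covariance C: among the diseased,

    P(T_i=1, T_j=1 | D=1) = Se_i Se_j + Cd
    P(T_i=1, T_j=0 | D=1) = Se_i (1-Se_j) - Cd
    P(T_i=0, T_j=1 | D=1) = (1-Se_i) Se_j - Cd
    P(T_i=0, T_j=0 | D=1) = (1-Se_i)(1-Se_j) + Cd

and analogously among the non-diseased with margins 1 - Sp and covariance
Cn. Requiring all four joint cells to be non-negative gives the admissible
interval ``cov_bounds``. Cell probabilities for a full result pattern are
the class mixture of products of per-test margins and pair factors; the
observed 2^K table is multinomial in those cells.
"""

from __future__ import annotations

import math
from dataclasses import dataclass, field

import numpy as np

from .panel import CrossClassifiedCounts, TestPanel
from .priors import PriorSet

__all__ = [
    "AccuracyParams",
    "InadmissibleParamsError",
    "cov_bounds",
    "cell_probability",
    "cell_probabilities",
    "log_likelihood",
    "log_posterior",
]


class InadmissibleParamsError(ValueError):
    """Parameters imply a negative cell probability."""


def cov_bounds(p_i: float, p_j: float) -> tuple[float, float]:
    """Admissible interval for the additive covariance of two binary
    results with success margins ``p_i`` and ``p_j``.

    lower = max(-p_i p_j, -(1-p_i)(1-p_j)), upper = min(p_i(1-p_j), (1-p_i)p_j);
    the interval always contains 0, and collapses to {0} for a perfect test.
    """
    if not (0 <= p_i <= 1 and 0 <= p_j <= 1):
        raise ValueError(f"margins must be in [0,1], got ({p_i}, {p_j})")
    lower = max(-p_i * p_j, -(1 - p_i) * (1 - p_j))
    upper = min(p_i * (1 - p_j), (1 - p_i) * p_j)
    return lower, upper


@dataclass(frozen=True)
class AccuracyParams:
    """Latent-class parameter vector for a test panel.

    prevalence
        P(diseased), in [0, 1].
    se, sp
        Per-test sensitivity and specificity, panel order.
    cov_d, cov_n
        Additive covariance per dependent pair among the diseased
        (``cov_d``) and the non-diseased (``cov_n``); empty when the panel
        has no dependent pairs.
    """

    prevalence: float
    se: tuple[float, ...]
    sp: tuple[float, ...]
    cov_d: tuple[float, ...] = ()
    cov_n: tuple[float, ...] = ()

    def __post_init__(self) -> None:
        object.__setattr__(self, "se", tuple(float(x) for x in self.se))
        object.__setattr__(self, "sp", tuple(float(x) for x in self.sp))
        object.__setattr__(self, "cov_d", tuple(float(x) for x in self.cov_d))
        object.__setattr__(self, "cov_n", tuple(float(x) for x in self.cov_n))
        probs = (self.prevalence, *self.se, *self.sp)
        if any(not 0 <= p <= 1 for p in probs):
            raise ValueError(f"probabilities must lie in [0,1]: {probs}")
        if len(self.se) != len(self.sp):
            raise ValueError("se and sp must have the same length")
        if len(self.cov_d) != len(self.cov_n):
            raise ValueError("cov_d and cov_n must have the same length")

    @property
    def k(self) -> int:
        return len(self.se)

    def validate(self, panel: TestPanel) -> None:
        """Check dimensions and covariance admissibility against a panel."""
        if self.k != panel.k:
            raise ValueError(f"params are for K={self.k}, panel has K={panel.k}")
        if len(self.cov_d) != len(panel.dependent_pairs):
            raise ValueError("one covariance per dependent pair required")
        for (i, j), cd, cn in zip(panel.dependent_pairs, self.cov_d, self.cov_n):
            lo, hi = cov_bounds(self.se[i], self.se[j])
            if not lo <= cd <= hi:
                raise InadmissibleParamsError(
                    f"cov_d={cd} outside admissible [{lo:.6g}, {hi:.6g}] "
                    f"for pair ({i},{j})"
                )
            lo, hi = cov_bounds(self.sp[i], self.sp[j])
            if not lo <= cn <= hi:
                raise InadmissibleParamsError(
                    f"cov_n={cn} outside admissible [{lo:.6g}, {hi:.6g}] "
                    f"for pair ({i},{j})"
                )


def _class_cell_probs(
    patterns: np.ndarray,
    margins: np.ndarray,
    pairs: tuple[tuple[int, int], ...],
    covs: tuple[float, ...],
    indep: tuple[int, ...],
) -> np.ndarray:
    """Within-class probabilities of all result patterns.

    ``margins[k]`` is P(test k positive | class); dependent pairs get the
    additive-covariance correction with sign +1 when the pair's results
    agree and -1 when they differ.
    """
    a = np.where(patterns == 1, margins, 1.0 - margins)
    prob = a[:, indep].prod(axis=1) if indep else np.ones(len(patterns))
    for (i, j), c in zip(pairs, covs):
        sign = np.where(patterns[:, i] == patterns[:, j], 1.0, -1.0)
        prob = prob * (a[:, i] * a[:, j] + sign * c)
    return prob


def cell_probabilities(params: AccuracyParams, panel: TestPanel) -> np.ndarray:
    """All 2^K cell probabilities in the panel's canonical pattern order.

    Raises :class:`InadmissibleParamsError`, identifying the offending
    cell, if the parameters imply a negative within-class probability.
    """
    params.validate(panel)
    patterns = panel.patterns()
    indep = panel.independent_indices
    pd_ = _class_cell_probs(
        patterns, np.asarray(params.se), panel.dependent_pairs, params.cov_d, indep
    )
    pn_ = _class_cell_probs(
        patterns,
        1.0 - np.asarray(params.sp),
        panel.dependent_pairs,
        params.cov_n,
        indep,
    )
    tol = 1e-12
    for name, cls in (("diseased", pd_), ("non-diseased", pn_)):
        bad = np.nonzero(cls < -tol)[0]
        if bad.size:
            raise InadmissibleParamsError(
                f"negative {name}-class probability at pattern "
                f"{panel.pattern_label(int(bad[0]))}"
            )
    cells = params.prevalence * np.clip(pd_, 0.0, None) + (
        1.0 - params.prevalence
    ) * np.clip(pn_, 0.0, None)
    return cells


def cell_probability(params: AccuracyParams, panel: TestPanel, pattern) -> float:
    """Probability of one joint result pattern."""
    return float(cell_probabilities(params, panel)[panel.pattern_index(pattern)])


def log_likelihood(params: AccuracyParams, counts: CrossClassifiedCounts) -> float:
    """Multinomial log-likelihood over the 2^K cells, without the
    count-only multinomial coefficient (constant in the parameters).

    Zero-count cells contribute exactly 0; a zero-probability cell with a
    positive count yields -inf.
    """
    cells = cell_probabilities(params, counts.panel)
    c = counts.counts
    nz = c > 0
    if np.any(cells[nz] <= 0):
        return -math.inf
    return float(c[nz] @ np.log(cells[nz]))


def log_posterior(
    params: AccuracyParams, counts: CrossClassifiedCounts, priors: PriorSet
) -> float:
    """Log posterior density (up to the multinomial coefficient).

    Returns -inf outside the admissible covariance region, implementing
    the truncation of the nominal Uniform(-1, 1) covariance priors.
    """
    panel = counts.panel
    if priors.panel != panel:
        raise ValueError("priors and counts refer to different panels")
    try:
        params.validate(panel)
    except InadmissibleParamsError:
        return -math.inf
    lp = priors.prevalence.logpdf(params.prevalence)
    for spec, value in zip(priors.se, params.se):
        lp += spec.logpdf(value)
    for spec, value in zip(priors.sp, params.sp):
        lp += spec.logpdf(value)
    for spec, cd, cn in zip(priors.cov, params.cov_d, params.cov_n):
        lp += spec.logpdf(cd) + spec.logpdf(cn)
    if not math.isfinite(lp):
        return -math.inf
    try:
        ll = log_likelihood(params, counts)
    except InadmissibleParamsError:
        return -math.inf
    return lp + ll
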