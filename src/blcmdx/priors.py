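"""Beta priors for prevalence/sensitivity/specificity and bounded-uniform
covariance priors, with elicitation from a central value plus a percentile.

Informative Beta priors in diagnostic-accuracy work are usually elicited
from a literature point estimate (interpreted as the prior mode or mean)
together with a percentile bound ("we are 95% sure sensitivity exceeds
0.80"). ``elicit_beta`` solves that two-constraint problem numerically.

Covariance terms get a nominal Uniform(-1, 1) prior; its effective support
is truncated at evaluation time to the admissible region where all cell
probabilities stay non-negative (see :mod:`blcmdx.model`), which is what a
rejection-based sampler does implicitly.
"""

from __future__ import annotations

import math
from dataclasses import dataclass
from pathlib import Path
from typing import Callable, Optional

import numpy as np
import yaml
from scipy import optimize, special, stats

from .panel import TestPanel

__all__ = [
    "BetaSpec",
    "UniformSpec",
    "PriorSet",
    "BetaSummary",
    "beta_summary",
    "elicit_beta",
    "load_priors",
    "save_priors",
]


@dataclass(frozen=True)
class BetaSpec:
    """A Beta(alpha, beta) distribution on (0, 1)."""

    alpha: float
    beta: float

    def __post_init__(self) -> None:
        if not (self.alpha > 0 and self.beta > 0):
            raise ValueError(f"Beta parameters must be positive, got {self}")

    @property
    def mean(self) -> float:
        return self.alpha / (self.alpha + self.beta)

    @property
    def variance(self) -> float:
        a, b = self.alpha, self.beta
        return a * b / ((a + b) ** 2 * (a + b + 1))

    @property
    def mode(self) -> Optional[float]:
        """(alpha-1)/(alpha+beta-2), or None when the density has no
        interior mode (alpha <= 1 or beta <= 1)."""
        if self.alpha > 1 and self.beta > 1:
            return (self.alpha - 1) / (self.alpha + self.beta - 2)
        return None

    def quantile(self, p):
        return special.betaincinv(self.alpha, self.beta, p)

    def logpdf(self, x: float) -> float:
        if not 0 < x < 1:
            return -math.inf
        return (
            (self.alpha - 1) * math.log(x)
            + (self.beta - 1) * math.log1p(-x)
            - special.betaln(self.alpha, self.beta)
        )

    def sample(self, rng: np.random.Generator, size=None):
        return rng.beta(self.alpha, self.beta, size=size)


@dataclass(frozen=True)
class BetaSummary:
    mean: float
    variance: float
    mode: Optional[float]
    quantile: Callable


def beta_summary(spec: BetaSpec) -> BetaSummary:
    """Closed-form moments, the mode (None when undefined) and the quantile
    function of a BetaSpec."""
    return BetaSummary(spec.mean, spec.variance, spec.mode, spec.quantile)


@dataclass(frozen=True)
class UniformSpec:
    """Nominal bounded-uniform prior; density is constant on (lower, upper)
    but evaluation is further truncated to the admissible covariance region."""

    lower: float = -1.0
    upper: float = 1.0

    def __post_init__(self) -> None:
        if not self.lower < self.upper:
            raise ValueError(f"need lower < upper, got {self}")

    def logpdf(self, x: float) -> float:
        if self.lower < x < self.upper:
            return -math.log(self.upper - self.lower)
        return -math.inf


class ElicitationError(ValueError):
    """No Beta distribution satisfies the requested constraints."""


def elicit_beta(
    central: float,
    bound: float,
    percentile: float,
    central_kind: str = "mode",
    tol: float = 1e-6,
) -> BetaSpec:
    """Solve for the Beta(alpha, beta) with a given central value and quantile.

    Parameters
    ----------
    central
        The prior mode (default interpretation, the common convention in
        diagnostic-test practice) or mean, in (0, 1).
    bound, percentile
        The ``percentile`` quantile of the solution equals ``bound``; e.g.
        ``bound=0.8, percentile=0.05`` states 95% prior certainty that the
        parameter exceeds 0.8.
    central_kind
        ``"mode"`` or ``"mean"``.

    The family is searched along a one-dimensional concentration axis: for a
    fixed mode m, (alpha, beta) = (1 + m*s, 1 + (1-m)*s); for a fixed mean,
    (m*s, (1-m)*s). The quantile is monotone along s, so a bracketed root
    solve recovers the unique solution when one exists.

    Raises
    ------
    ElicitationError
        If no concentration satisfies the quantile constraint to ``tol``.
    """
    if not 0 < central < 1:
        raise ValueError(f"central value must be in (0,1), got {central}")
    if not 0 < bound < 1:
        raise ValueError(f"bound must be in (0,1), got {bound}")
    if not 0 < percentile < 1:
        raise ValueError(f"percentile must be in (0,1), got {percentile}")
    if central_kind not in ("mode", "mean"):
        raise ValueError(f"central_kind must be 'mode' or 'mean', got {central_kind!r}")
    if bound == central:
        raise ElicitationError("bound must differ from the central value")
    # the quantile approaches `central` only from the correct side
    if (percentile < 0.5) != (bound < central) and central_kind == "mode":
        pass  # feasibility is decided by the bracket scan below

    def make(s: float) -> BetaSpec:
        if central_kind == "mode":
            return BetaSpec(1.0 + central * s, 1.0 + (1.0 - central) * s)
        return BetaSpec(central * s, (1.0 - central) * s)

    def f(log_s: float) -> float:
        return float(make(math.exp(log_s)).quantile(percentile)) - bound

    grid = np.linspace(math.log(1e-4), math.log(1e9), 400)
    vals = np.array([f(g) for g in grid])
    sign_change = np.nonzero(np.diff(np.sign(vals)) != 0)[0]
    if sign_change.size == 0:
        raise ElicitationError(
            f"no Beta with {central_kind} {central} has its {percentile:g} "
            f"quantile at {bound}"
        )
    lo, hi = grid[sign_change[0]], grid[sign_change[0] + 1]
    root = optimize.brentq(f, lo, hi, xtol=1e-13, rtol=8.9e-16)
    spec = make(math.exp(root))
    err = abs(float(spec.quantile(percentile)) - bound)
    if err > tol:
        raise ElicitationError(
            f"solver residual {err:.2e} exceeds tolerance {tol:.0e}"
        )
    return spec


@dataclass(frozen=True)
class PriorSet:
    """Priors for one latent-class analysis, aligned with a TestPanel.

    ``se``/``sp`` hold one BetaSpec per test in panel order; ``cov`` one
    UniformSpec per dependent pair.
    """

    panel: TestPanel
    prevalence: BetaSpec
    se: tuple[BetaSpec, ...]
    sp: tuple[BetaSpec, ...]
    cov: tuple[UniformSpec, ...] = ()

    def __post_init__(self) -> None:
        if len(self.se) != self.panel.k or len(self.sp) != self.panel.k:
            raise ValueError("need one Se and one Sp prior per test")
        cov = tuple(self.cov) or tuple(
            UniformSpec() for _ in self.panel.dependent_pairs
        )
        if len(cov) != len(self.panel.dependent_pairs):
            raise ValueError("need exactly one covariance prior per dependent pair")
        object.__setattr__(self, "se", tuple(self.se))
        object.__setattr__(self, "sp", tuple(self.sp))
        object.__setattr__(self, "cov", cov)


def _spec_to_dict(spec: BetaSpec) -> dict:
    return {"alpha": float(spec.alpha), "beta": float(spec.beta)}


def save_priors(priors: PriorSet, path: str | Path) -> Path:
    path = Path(path)
    doc = {
        "prevalence": _spec_to_dict(priors.prevalence),
        "sensitivity": {
            name: _spec_to_dict(s)
            for name, s in zip(priors.panel.test_names, priors.se)
        },
        "specificity": {
            name: _spec_to_dict(s)
            for name, s in zip(priors.panel.test_names, priors.sp)
        },
        "covariance": [
            {
                "pair": [priors.panel.test_names[i], priors.panel.test_names[j]],
                "lower": u.lower,
                "upper": u.upper,
            }
            for (i, j), u in zip(priors.panel.dependent_pairs, priors.cov)
        ],
    }
    path.write_text(yaml.safe_dump(doc, sort_keys=False))
    return path


def load_priors(path: str | Path, panel: TestPanel) -> PriorSet:
    """Load a prior-configuration YAML file and align it with ``panel``."""
    doc = yaml.safe_load(Path(path).read_text())
    try:
        prevalence = BetaSpec(**doc["prevalence"])
        se = tuple(BetaSpec(**doc["sensitivity"][n]) for n in panel.test_names)
        sp = tuple(BetaSpec(**doc["specificity"][n]) for n in panel.test_names)
    except KeyError as exc:
        raise ValueError(f"prior file is missing an entry for {exc}") from exc
    cov_doc = {
        tuple(sorted(panel.test_names.index(n) for n in item["pair"])): UniformSpec(
            item.get("lower", -1.0), item.get("upper", 1.0)
        )
        for item in doc.get("covariance", [])
    }
    cov = tuple(cov_doc.get(pair, UniformSpec()) for pair in panel.dependent_pairs)
    return PriorSet(panel, prevalence, se, sp, cov)
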