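"""Metropolis-within-Gibbs posterior sampling and convergence diagnostics.

The full conditionals of the dependence model are not conjugate, so each
parameter is updated in turn by a random-walk Metropolis step: probability
parameters (prevalence, Se, Sp) on the logit scale with the appropriate
Jacobian correction, covariance parameters on their natural scale with the
proposal step rescaled to the current admissible interval. Step sizes adapt
toward ~0.44 acceptance (the scalar random-walk optimum) during burn-in
and are frozen afterwards, so the retained draws come from a fixed kernel.
"""

from __future__ import annotations

import math
from dataclasses import dataclass, field, replace

import numpy as np
import pandas as pd
from scipy import special

from .model import AccuracyParams, cov_bounds
from .panel import CrossClassifiedCounts
from .priors import PriorSet

__all__ = [
    "MCMCConfig",
    "PosteriorChains",
    "Diagnostics",
    "sample_posterior",
    "diagnostics",
    "autocorrelation",
    "effective_sample_size",
]

TARGET_ACCEPT = 0.44


@dataclass(frozen=True)
class MCMCConfig:
    """Sampler protocol. The defaults — 100,000 iterations with the first
    50,000 as a burn-in/adaptation phase and every 10th draw retained —
    keep 5,000 draws per chain."""

    iterations: int = 100_000
    burn_in: int = 50_000
    thin: int = 10
    chains: int = 1
    seed: int = 0
    initial_step: float = 0.3
    enforce_se_sp_gt1: bool = False

    def __post_init__(self) -> None:
        if self.iterations <= 0 or self.thin <= 0 or self.chains <= 0:
            raise ValueError("iterations, thin and chains must be positive")
        if not 0 <= self.burn_in < self.iterations:
            raise ValueError("need 0 <= burn_in < iterations")

    @property
    def retained_per_chain(self) -> int:
        return (self.iterations - self.burn_in + self.thin - 1) // self.thin


@dataclass
class PosteriorChains:
    """Retained draws: array of shape (chains, draws, n_params)."""

    panel: "object"
    param_names: list[str]
    draws: np.ndarray = field(repr=False)
    config: MCMCConfig = field(default_factory=MCMCConfig)
    acceptance_rates: np.ndarray | None = field(default=None, repr=False)

    @property
    def n_chains(self) -> int:
        return self.draws.shape[0]

    @property
    def n_draws(self) -> int:
        return self.draws.shape[1]

    def pooled(self) -> np.ndarray:
        """Draws pooled across chains, shape (chains*draws, n_params)."""
        return self.draws.reshape(-1, self.draws.shape[2])

    def to_dataframe(self) -> pd.DataFrame:
        df = pd.DataFrame(self.pooled(), columns=self.param_names)
        df.insert(0, "chain", np.repeat(np.arange(self.n_chains), self.n_draws))
        return df

    def save_draws(self, path) -> None:
        """Plain-text draws table: one column per parameter, one row per
        retained draw."""
        self.to_dataframe().to_csv(path, sep="\t", index=False)

    def params_at(self, chain: int, draw: int) -> AccuracyParams:
        row = self.draws[chain, draw]
        k = self.panel.k
        p = len(self.panel.dependent_pairs)
        return AccuracyParams(
            prevalence=float(row[0]),
            se=tuple(row[1 : 1 + k]),
            sp=tuple(row[1 + k : 1 + 2 * k]),
            cov_d=tuple(row[1 + 2 * k : 1 + 2 * k + p]),
            cov_n=tuple(row[1 + 2 * k + p : 1 + 2 * k + 2 * p]),
        )


def param_names(panel) -> list[str]:
    names = ["prevalence"]
    names += [f"se_{t}" for t in panel.test_names]
    names += [f"sp_{t}" for t in panel.test_names]
    for i, j in panel.dependent_pairs:
        names.append(f"cov_d_{panel.test_names[i]}_{panel.test_names[j]}")
    for i, j in panel.dependent_pairs:
        names.append(f"cov_n_{panel.test_names[i]}_{panel.test_names[j]}")
    return names


def _fast_logpost(counts: CrossClassifiedCounts, priors: PriorSet, enforce: bool):
    """Build a fast log-posterior over the flat state vector.

    Matches :func:`blcmdx.model.log_posterior` (same density, Beta and
    uniform normalizing constants included) but avoids object construction
    inside the sampling loop.
    """
    panel = counts.panel
    k = panel.k
    n_pairs = len(panel.dependent_pairs)
    patterns = panel.patterns().astype(bool)
    indep = list(panel.independent_indices)
    pairs = list(panel.dependent_pairs)
    pair_sign = [
        np.where(patterns[:, i] == patterns[:, j], 1.0, -1.0) for i, j in pairs
    ]
    c = counts.counts.astype(float)
    nz = c > 0
    c_nz = c[nz]

    a = np.array(
        [priors.prevalence.alpha]
        + [s.alpha for s in priors.se]
        + [s.alpha for s in priors.sp]
    )
    b = np.array(
        [priors.prevalence.beta]
        + [s.beta for s in priors.se]
        + [s.beta for s in priors.sp]
    )
    const = -float(special.betaln(a, b).sum())
    const += -sum(math.log(u.upper - u.lower) for u in priors.cov for _ in (0, 1))

    def logpost(state: np.ndarray) -> float:
        theta = state[: 1 + 2 * k]
        if np.any(theta <= 0.0) or np.any(theta >= 1.0):
            return -math.inf
        pi = theta[0]
        se = theta[1 : 1 + k]
        sp = theta[1 + k : 1 + 2 * k]
        if enforce and np.any(se + sp <= 1.0):
            return -math.inf
        cd = state[1 + 2 * k : 1 + 2 * k + n_pairs]
        cn = state[1 + 2 * k + n_pairs :]
        for u, x, y in zip(priors.cov, cd, cn):
            if not (u.lower < x < u.upper and u.lower < y < u.upper):
                return -math.inf

        m_n = 1.0 - sp
        ad = np.where(patterns, se, 1.0 - se)
        an = np.where(patterns, m_n, sp)
        p_d = ad[:, indep].prod(axis=1) if indep else np.ones(len(patterns))
        p_n = an[:, indep].prod(axis=1) if indep else np.ones(len(patterns))
        for idx, (i, j) in enumerate(pairs):
            s = pair_sign[idx]
            p_d = p_d * (ad[:, i] * ad[:, j] + s * cd[idx])
            p_n = p_n * (an[:, i] * an[:, j] + s * cn[idx])
        if np.any(p_d < 0.0) or np.any(p_n < 0.0):
            return -math.inf
        cells = pi * p_d + (1.0 - pi) * p_n
        cells_nz = cells[nz]
        if np.any(cells_nz <= 0.0):
            return -math.inf
        ll = float(c_nz @ np.log(cells_nz))
        lp = float(((a - 1.0) * np.log(theta) + (b - 1.0) * np.log1p(-theta)).sum())
        return ll + lp + const

    return logpost


def _init_state(priors: PriorSet, rng: np.random.Generator, logpost, n_pairs: int):
    for _ in range(200):
        theta = np.concatenate(
            [
                [priors.prevalence.sample(rng)],
                [s.sample(rng) for s in priors.se],
                [s.sample(rng) for s in priors.sp],
            ]
        )
        state = np.concatenate([theta, np.zeros(2 * n_pairs)])
        lp = logpost(state)
        if math.isfinite(lp):
            return state, lp
    raise RuntimeError("could not find an admissible initial point from the priors")


def sample_posterior(
    counts: CrossClassifiedCounts, priors: PriorSet, config: MCMCConfig | None = None
) -> PosteriorChains:
    """Draw from the posterior of the latent class model.

    Deterministic given (counts, priors, config): the same seed reproduces
    the chains bitwise. The first draw of each chain comes from the priors
    (covariances at 0), the burn-in doubles as the step-size adaptation
    phase, and only post-burn-in draws at the thinning stride are kept.
    """
    config = config or MCMCConfig()
    panel = counts.panel
    if priors.panel != panel:
        raise ValueError("priors and counts refer to different panels")
    if counts.n == 0:
        raise ValueError("cannot fit an all-zero count table")

    k = panel.k
    n_pairs = len(panel.dependent_pairs)
    n_prob = 1 + 2 * k
    n_par = n_prob + 2 * n_pairs
    logpost = _fast_logpost(counts, priors, config.enforce_se_sp_gt1)

    se_pairs = [(1 + i, 1 + j) for i, j in panel.dependent_pairs]
    sp_pairs = [(1 + k + i, 1 + k + j) for i, j in panel.dependent_pairs]

    seeds = np.random.SeedSequence(config.seed).spawn(config.chains)
    all_draws = np.empty((config.chains, config.retained_per_chain, n_par))
    accept = np.zeros((config.chains, n_par))

    for chain_idx, ss in enumerate(seeds):
        rng = np.random.default_rng(ss)
        state, lp = _init_state(priors, rng, logpost, n_pairs)
        step = np.full(n_par, config.initial_step)
        n_accept = np.zeros(n_par)
        n_prop = np.zeros(n_par)
        kept = 0

        for it in range(config.iterations):
            adapting = it < config.burn_in
            # probability parameters: random walk on the logit scale
            for p in range(n_prob):
                x = state[p]
                logit = math.log(x / (1.0 - x))
                prop_logit = logit + step[p] * rng.standard_normal()
                y = float(special.expit(prop_logit))
                if not 0.0 < y < 1.0:  # float underflow at extreme logits
                    n_prop[p] += 1
                    continue
                state[p] = y
                lp_prop = logpost(state)
                # Jacobian of the logit transform: d(theta)/d(logit) = theta(1-theta)
                log_ratio = (
                    lp_prop
                    - lp
                    + math.log(y * (1.0 - y))
                    - math.log(x * (1.0 - x))
                )
                accepted = math.log(rng.random()) < log_ratio
                if accepted:
                    lp = lp_prop
                    n_accept[p] += 1
                else:
                    state[p] = x
                n_prop[p] += 1
                if adapting:
                    step[p] *= math.exp(
                        (float(accepted) - TARGET_ACCEPT) / math.sqrt(1.0 + it / 50.0)
                    )
                    step[p] = min(max(step[p], 1e-3), 10.0)
            # covariance parameters: random walk scaled to the admissible width
            for idx in range(2 * n_pairs):
                p = n_prob + idx
                if idx < n_pairs:
                    i, j = se_pairs[idx]
                else:
                    i, j = sp_pairs[idx - n_pairs]
                lo, hi = cov_bounds(state[i], state[j])
                width = max(hi - lo, 1e-12)
                x = state[p]
                state[p] = x + step[p] * width * rng.standard_normal()
                lp_prop = logpost(state)
                accepted = math.log(rng.random()) < lp_prop - lp
                if accepted:
                    lp = lp_prop
                    n_accept[p] += 1
                else:
                    state[p] = x
                n_prop[p] += 1
                if adapting:
                    step[p] *= math.exp(
                        (float(accepted) - TARGET_ACCEPT) / math.sqrt(1.0 + it / 50.0)
                    )
                    step[p] = min(max(step[p], 1e-4), 2.0)
            if it >= config.burn_in and (it - config.burn_in) % config.thin == 0:
                all_draws[chain_idx, kept] = state
                kept += 1
        assert kept == config.retained_per_chain
        accept[chain_idx] = n_accept / np.maximum(n_prop, 1)

    return PosteriorChains(
        panel=panel,
        param_names=param_names(panel),
        draws=all_draws,
        config=config,
        acceptance_rates=accept,
    )


# ---------------------------------------------------------------------------
# diagnostics


def autocorrelation(x: np.ndarray, max_lag: int) -> np.ndarray:
    """Sample autocorrelation function at lags 0..max_lag."""
    x = np.asarray(x, dtype=float)
    n = len(x)
    if max_lag >= n:
        raise ValueError(f"max_lag {max_lag} must be below the chain length {n}")
    x = x - x.mean()
    denom = float(x @ x)
    if denom == 0.0:
        out = np.zeros(max_lag + 1)
        out[0] = 1.0
        return out
    return np.array([float(x[: n - lag] @ x[lag:]) / denom for lag in range(max_lag + 1)])


def effective_sample_size(x: np.ndarray) -> float:
    """ESS via the truncated autocorrelation sum: n / (1 + 2 * sum(rho_k)),
    truncating where consecutive lag-pair sums turn negative (Geyer's
    initial positive sequence)."""
    x = np.asarray(x, dtype=float)
    n = len(x)
    if n < 4:
        return float(n)
    rho = autocorrelation(x, min(n - 1, max(2, n // 2)))
    s = 0.0
    lag = 1
    while lag + 1 < len(rho):
        pair = rho[lag] + rho[lag + 1]
        if pair < 0.0:
            break
        s += pair
        lag += 2
    return float(min(n, n / (1.0 + 2.0 * s)))


def split_rhat(draws: np.ndarray) -> float:
    """Potential scale-reduction on split chains; draws shape (chains, n)."""
    halves = []
    for chain in draws:
        h = len(chain) // 2
        halves.extend([chain[:h], chain[h : 2 * h]])
    arr = np.asarray(halves, dtype=float)
    m, n = arr.shape
    means = arr.mean(axis=1)
    w = arr.var(axis=1, ddof=1).mean()
    b = n * means.var(ddof=1)
    if w == 0.0:
        return 1.0
    return float(math.sqrt((n - 1) / n + b / (w * n)))


@dataclass
class Diagnostics:
    acf: pd.DataFrame
    ess: pd.Series
    trace_summary: pd.DataFrame
    rhat: pd.Series | None
    converged: bool


def diagnostics(
    chains: PosteriorChains,
    max_lag: int = 40,
    ess_threshold: float = 400.0,
    rhat_threshold: float = 1.05,
) -> Diagnostics:
    """Autocorrelation, effective sample size and (for >= 2 chains) the
    split-chain scale-reduction factor, with a documented convergence flag:
    ESS >= ``ess_threshold`` for every parameter and split-Rhat below
    ``rhat_threshold`` when computable."""
    if chains.n_draws == 0:
        raise ValueError("empty chains")
    if max_lag >= chains.n_draws:
        raise ValueError(
            f"max_lag {max_lag} must be below the chain length {chains.n_draws}"
        )
    names = chains.param_names
    acf = pd.DataFrame(
        {
            name: autocorrelation(chains.draws[0, :, p], max_lag)
            for p, name in enumerate(names)
        }
    )
    acf.index.name = "lag"
    ess = pd.Series(
        {
            name: float(
                sum(
                    effective_sample_size(chains.draws[c, :, p])
                    for c in range(chains.n_chains)
                )
            )
            for p, name in enumerate(names)
        }
    )
    pooled = chains.pooled()
    trace = pd.DataFrame(
        {
            "mean": pooled.mean(axis=0),
            "sd": pooled.std(axis=0, ddof=1),
            "first_half_mean": pooled[: len(pooled) // 2].mean(axis=0),
            "second_half_mean": pooled[len(pooled) // 2 :].mean(axis=0),
        },
        index=names,
    )
    rhat = None
    if chains.n_chains >= 2:
        rhat = pd.Series(
            {
                name: split_rhat(chains.draws[:, :, p])
                for p, name in enumerate(names)
            }
        )
    converged = bool((ess >= ess_threshold).all())
    if rhat is not None:
        converged = converged and bool((rhat < rhat_threshold).all())
    return Diagnostics(acf=acf, ess=ess, trace_summary=trace, rhat=rhat, converged=converged)
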