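"""Posterior summaries: means, equal-tailed 95% intervals, Youden indices,
posterior-predictive cell checks and a results report.

"95% interval" throughout means the equal-tailed percentile credible
interval (2.5th and 97.5th percentiles of the pooled draws). Youden's
index for a test is computed from the posterior *means* of its sensitivity
and specificity, J = Se_mean + Sp_mean - 1; the draw-wise version
(posterior distribution of Se + Sp - 1) has the same mean and is reported
alongside with its own interval.
"""

from __future__ import annotations

from dataclasses import dataclass, field

import numpy as np
import pandas as pd

from .mcmc import PosteriorChains, effective_sample_size
from .model import cell_probabilities
from .panel import CrossClassifiedCounts

__all__ = [
    "PosteriorSummary",
    "summarize",
    "youden_index",
    "posterior_predictive_cells",
    "report",
]


def youden_index(se_mean: float, sp_mean: float) -> float:
    """Youden's J = Se + Sp - 1 from posterior mean accuracy estimates."""
    if not (0 <= se_mean <= 1 and 0 <= sp_mean <= 1):
        raise ValueError(f"se and sp must be in [0,1], got ({se_mean}, {sp_mean})")
    return se_mean + sp_mean - 1.0


@dataclass
class PosteriorSummary:
    """Per-parameter posterior table plus per-test Youden indices.

    ``table`` is indexed by parameter name with columns
    mean/median/lower/upper/ess; ``youden`` is indexed by test name and
    holds the point index from posterior means plus the equal-tailed
    interval of the draw-wise Se + Sp - 1.
    """

    table: pd.DataFrame
    youden: pd.DataFrame
    panel: "object" = None
    config: "object" = field(default=None, repr=False)

    def __getitem__(self, parameter: str) -> pd.Series:
        return self.table.loc[parameter]


def summarize(chains: PosteriorChains) -> PosteriorSummary:
    """Pooled posterior means, medians and equal-tailed 95% intervals."""
    if chains.n_draws == 0:
        raise ValueError("empty chains")
    pooled = chains.pooled()
    lower, median, upper = np.percentile(pooled, [2.5, 50.0, 97.5], axis=0)
    ess = [
        sum(
            effective_sample_size(chains.draws[c, :, p])
            for c in range(chains.n_chains)
        )
        for p in range(pooled.shape[1])
    ]
    table = pd.DataFrame(
        {
            "mean": pooled.mean(axis=0),
            "median": median,
            "lower": lower,
            "upper": upper,
            "ess": ess,
        },
        index=pd.Index(chains.param_names, name="parameter"),
    )
    rows = {}
    for t, name in enumerate(chains.panel.test_names):
        se = pooled[:, 1 + t]
        sp = pooled[:, 1 + chains.panel.k + t]
        j_draws = se + sp - 1.0
        rows[name] = {
            "youden": float(se.mean()) + float(sp.mean()) - 1.0,
            "draws_mean": float(j_draws.mean()),
            "draws_lower": float(np.percentile(j_draws, 2.5)),
            "draws_upper": float(np.percentile(j_draws, 97.5)),
        }
    youden = pd.DataFrame(rows).T
    youden.index.name = "test"
    return PosteriorSummary(
        table=table, youden=youden, panel=chains.panel, config=chains.config
    )


def posterior_predictive_cells(
    chains: PosteriorChains, counts: CrossClassifiedCounts
) -> pd.DataFrame:
    """Model-fit check on the 2^K cells.

    For each cell: the posterior mean of the expected count n * P_c and the
    fraction of draws whose expected count exceeds the observed count.
    Tail probabilities near 0 or 1 flag cells the model cannot reproduce.
    """
    panel = counts.panel
    if panel != chains.panel:
        raise ValueError("counts and chains refer to different panels")
    n = counts.n
    expected = np.empty((chains.n_chains * chains.n_draws, panel.n_patterns))
    row = 0
    for c in range(chains.n_chains):
        for d in range(chains.n_draws):
            expected[row] = n * cell_probabilities(chains.params_at(c, d), panel)
            row += 1
    out = pd.DataFrame(
        {
            "pattern": [panel.pattern_label(i) for i in range(panel.n_patterns)],
            "observed": counts.counts,
            "expected": expected.mean(axis=0),
            "tail_prob": (expected > counts.counts[None, :]).mean(axis=0),
        }
    )
    return out


def report(summaries: dict[str, PosteriorSummary]) -> tuple[str, pd.DataFrame]:
    """Human-readable report and a machine-readable results table.

    One row per (analysis, test, parameter) for sensitivity/specificity,
    one prevalence row per analysis, and one Youden row per test per
    analysis; values carried at full precision in the returned DataFrame.
    """
    if not summaries:
        raise ValueError("need at least one summary")
    records = []
    for label, s in summaries.items():
        prev = s.table.loc["prevalence"]
        records.append(
            dict(analysis=label, test="", parameter="prevalence",
                 mean=prev["mean"], lower=prev["lower"], upper=prev["upper"])
        )
        for name in s.panel.test_names:
            for role, key in (("se", f"se_{name}"), ("sp", f"sp_{name}")):
                r = s.table.loc[key]
                records.append(
                    dict(analysis=label, test=name, parameter=role,
                         mean=r["mean"], lower=r["lower"], upper=r["upper"])
                )
        for name in s.panel.test_names:
            y = s.youden.loc[name]
            records.append(
                dict(analysis=label, test=name, parameter="youden",
                     mean=y["youden"], lower=y["draws_lower"], upper=y["draws_upper"])
            )
    table = pd.DataFrame.from_records(records)

    lines = ["# Latent class accuracy results", ""]
    for label, s in summaries.items():
        cfg = s.config
        lines.append(f"## Analysis: {label}")
        if cfg is not None:
            lines.append(
                f"MCMC: {cfg.iterations} iterations, burn-in {cfg.burn_in}, "
                f"thin {cfg.thin}, {cfg.chains} chain(s), seed {cfg.seed}"
            )
        lines.append("")
        prev = s.table.loc["prevalence"]
        lines.append(
            f"True prevalence: {prev['mean']:.3f} "
            f"(95% CI {prev['lower']:.3f}-{prev['upper']:.3f})"
        )
        for name in s.panel.test_names:
            se = s.table.loc[f"se_{name}"]
            sp = s.table.loc[f"sp_{name}"]
            j = s.youden.loc[name, "youden"]
            lines.append(
                f"{name}: Se {se['mean']:.3f} ({se['lower']:.3f}-{se['upper']:.3f}), "
                f"Sp {sp['mean']:.3f} ({sp['lower']:.3f}-{sp['upper']:.3f}), "
                f"Youden {j:.3f}"
            )
        lines.append("")
    return "\n".join(lines), table
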