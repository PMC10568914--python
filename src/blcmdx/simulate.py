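"""Synthetic data with the statistical structure the analysis assumes.

Two generators: cell counts drawn multinomially from the latent-class cell
probabilities (the exact sampling distribution of the observed table), and
a subject-level generator that first draws the latent status, then the
binary results — the dependent pair from its within-class 2x2 joint built
from margins plus the additive covariance, exactly as the probability
model does — and optionally class-conditional continuous scores (normal
components by default, parameterized by per-class location and scale).

``recovery_study`` closes the loop: simulate -> fit -> summarize, reporting
posterior-mean bias and 95%-interval coverage per parameter.
"""

from __future__ import annotations

from dataclasses import dataclass, replace

import numpy as np
import pandas as pd

from .mcmc import MCMCConfig, param_names, sample_posterior
from .model import AccuracyParams, cell_probabilities
from .panel import HIGHER, CrossClassifiedCounts, TestPanel
from .priors import PriorSet
from .summary import summarize

__all__ = [
    "ScoreModel",
    "SimulationScenario",
    "simulate_panel",
    "simulate_subjects",
    "counts_from_subjects",
    "recovery_study",
]


@dataclass(frozen=True)
class ScoreModel:
    """Class-conditional continuous score distribution for one test."""

    loc_diseased: float
    scale_diseased: float
    loc_healthy: float
    scale_healthy: float
    family: str = "normal"

    def __post_init__(self) -> None:
        if self.family != "normal":
            raise ValueError(f"unsupported score family {self.family!r}")
        if self.scale_diseased <= 0 or self.scale_healthy <= 0:
            raise ValueError("scales must be positive")

    def sample(self, rng: np.random.Generator, diseased: np.ndarray) -> np.ndarray:
        loc = np.where(diseased, self.loc_diseased, self.loc_healthy)
        scale = np.where(diseased, self.scale_diseased, self.scale_healthy)
        return rng.normal(loc, scale)


@dataclass(frozen=True)
class SimulationScenario:
    panel: TestPanel
    params: AccuracyParams
    n: int
    seed: int = 0
    score_models: tuple[ScoreModel, ...] = ()

    def __post_init__(self) -> None:
        if self.n < 0:
            raise ValueError("n must be non-negative")
        self.params.validate(self.panel)
        if self.score_models and len(self.score_models) != self.panel.k:
            raise ValueError("need one score model per test when scores are configured")


def simulate_panel(scenario: SimulationScenario) -> CrossClassifiedCounts:
    """Multinomial counts over the 2^K cells; seeded and reproducible."""
    probs = cell_probabilities(scenario.params, scenario.panel)
    rng = np.random.default_rng(scenario.seed)
    counts = rng.multinomial(scenario.n, probs)
    return CrossClassifiedCounts(scenario.panel, counts)


def _pair_joint(m_i: float, m_j: float, cov: float) -> np.ndarray:
    """2x2 joint of two positives-coded results: cells (11, 10, 01, 00)."""
    joint = np.array(
        [
            m_i * m_j + cov,
            m_i * (1 - m_j) - cov,
            (1 - m_i) * m_j - cov,
            (1 - m_i) * (1 - m_j) + cov,
        ]
    )
    return np.clip(joint, 0.0, None)


def simulate_subjects(scenario: SimulationScenario) -> pd.DataFrame:
    """Per-subject latent status, binary results and optional scores.

    Aggregating the binary results reproduces the distribution of
    :func:`simulate_panel` — both factor through the same within-class
    joint construction.
    """
    panel, params = scenario.panel, scenario.params
    rng = np.random.default_rng(scenario.seed)
    n = scenario.n
    diseased = rng.random(n) < params.prevalence
    results = np.zeros((n, panel.k), dtype=np.int8)

    pos_margin = {
        True: np.asarray(params.se),
        False: 1.0 - np.asarray(params.sp),
    }
    for k in panel.independent_indices:
        p = np.where(diseased, pos_margin[True][k], pos_margin[False][k])
        results[:, k] = rng.random(n) < p
    for idx, (i, j) in enumerate(panel.dependent_pairs):
        for is_dis, cov in ((True, params.cov_d[idx]), (False, params.cov_n[idx])):
            mask = diseased == is_dis
            m = pos_margin[is_dis]
            joint = _pair_joint(m[i], m[j], cov)
            joint = joint / joint.sum()
            cells = rng.choice(4, size=int(mask.sum()), p=joint)
            results[mask, i] = cells < 2  # cells 0,1 have test i positive
            results[mask, j] = (cells == 0) | (cells == 2)

    df = pd.DataFrame(results, columns=[f"result_{t}" for t in panel.test_names])
    df.insert(0, "diseased", diseased.astype(int))
    for k, (name, model) in enumerate(zip(panel.test_names, scenario.score_models)):
        df[f"score_{name}"] = model.sample(rng, diseased)
    return df


def counts_from_subjects(df: pd.DataFrame, panel: TestPanel) -> CrossClassifiedCounts:
    """Aggregate a subject table back into the 2^K cell counts."""
    cols = [f"result_{t}" for t in panel.test_names]
    counts = np.zeros(panel.n_patterns, dtype=np.int64)
    for pattern, group in df.groupby(cols, sort=False):
        counts[panel.pattern_index(list(pattern))] = len(group)
    return CrossClassifiedCounts(panel, counts)


def recovery_study(
    scenario: SimulationScenario,
    priors: PriorSet,
    config: MCMCConfig,
    replicates: int,
) -> pd.DataFrame:
    """Simulate-and-refit calibration: per-parameter posterior-mean bias
    and 95%-interval coverage over ``replicates`` independent tables.

    Replicate failures (sampler errors) are recorded in the ``failures``
    attribute of the returned frame, never silently dropped.
    """
    if replicates < 1:
        raise ValueError("need at least one replicate")
    names = param_names(scenario.panel)
    truth = np.concatenate(
        [
            [scenario.params.prevalence],
            scenario.params.se,
            scenario.params.sp,
            scenario.params.cov_d,
            scenario.params.cov_n,
        ]
    )
    means = []
    covered = []
    failures: list[tuple[int, str]] = []
    base = np.random.SeedSequence(scenario.seed)
    data_seeds = base.spawn(replicates)
    for r in range(replicates):
        rep_seed = int(data_seeds[r].generate_state(1)[0] % (2**31))
        rep_scenario = SimulationScenario(
            scenario.panel, scenario.params, scenario.n, seed=rep_seed
        )
        try:
            counts = simulate_panel(rep_scenario)
            chains = sample_posterior(counts, priors, replace(config, seed=rep_seed))
            s = summarize(chains)
        except Exception as exc:  # noqa: BLE001 - recorded, not dropped
            failures.append((r, str(exc)))
            continue
        means.append(s.table["mean"].to_numpy())
        covered.append(
            (s.table["lower"].to_numpy() <= truth)
            & (truth <= s.table["upper"].to_numpy())
        )
    if not means:
        raise RuntimeError(f"all {replicates} replicates failed: {failures}")
    means_arr = np.asarray(means)
    out = pd.DataFrame(
        {
            "truth": truth,
            "mean_estimate": means_arr.mean(axis=0),
            "bias": means_arr.mean(axis=0) - truth,
            "coverage": np.asarray(covered).mean(axis=0),
            "replicates": len(means),
        },
        index=pd.Index(names, name="parameter"),
    )
    out.attrs["failures"] = failures
    return out
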