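"""Youden-optimal dichotomization of continuous test scores.

ROC candidate cutpoints are the midpoints between adjacent distinct
observed scores plus the two extreme rules (everyone positive, everyone
negative). Cutpoints are reported in midpoint form (e.g. 21.5) together
with a rendered decision rule on the observed score grid: "< 22" for
lower-is-positive tests (MoCA/MMSE convention) and ">= 13" for
higher-is-positive tests (ADAS-cog convention). Ties in maximal Youden are
broken toward higher sensitivity, then toward the cutpoint that classifies
more subjects positive — the screening-friendly choice.
"""

from __future__ import annotations

import math
from dataclasses import dataclass
from pathlib import Path

import numpy as np
import pandas as pd

from .panel import HIGHER, LOWER

__all__ = ["ScorePanel", "CutoffResult", "roc_points", "optimal_cutoff", "read_scores"]


@dataclass(frozen=True)
class ScorePanel:
    """Continuous scores for one test with binary reference labels."""

    scores: np.ndarray
    labels: np.ndarray
    direction: str = LOWER

    def __post_init__(self) -> None:
        scores = np.asarray(self.scores, dtype=float)
        labels = np.asarray(self.labels, dtype=int)
        if scores.shape != labels.shape or scores.ndim != 1:
            raise ValueError("scores and labels must be equal-length 1-D arrays")
        if not set(np.unique(labels)) <= {0, 1}:
            raise ValueError("labels must be binary 0/1")
        if labels.min() == labels.max():
            raise ValueError("both classes must be represented")
        if self.direction not in (LOWER, HIGHER):
            raise ValueError(f"unknown direction {self.direction!r}")
        object.__setattr__(self, "scores", scores)
        object.__setattr__(self, "labels", labels)


@dataclass(frozen=True)
class CutoffResult:
    cutpoint: float
    decision_rule: str
    se: float
    sp: float
    youden: float


def _classify(panel: ScorePanel, cutpoint: float) -> np.ndarray:
    if panel.direction == LOWER:
        return panel.scores <= cutpoint
    return panel.scores > cutpoint


def _se_sp(panel: ScorePanel, positive: np.ndarray) -> tuple[float, float]:
    diseased = panel.labels == 1
    se = float(positive[diseased].mean())
    sp = float((~positive[~diseased]).mean())
    return se, sp


def roc_points(panel: ScorePanel) -> pd.DataFrame:
    """One (cutpoint, se, sp) row per candidate rule.

    Midpoints between adjacent distinct scores, plus -inf and +inf for the
    two extreme rules. With all scores identical only the extremes remain.
    """
    distinct = np.unique(panel.scores)
    mids = (distinct[:-1] + distinct[1:]) / 2.0
    cutpoints = np.concatenate([[-math.inf], mids, [math.inf]])
    rows = []
    for c in cutpoints:
        se, sp = _se_sp(panel, _classify(panel, c))
        rows.append((c, se, sp))
    return pd.DataFrame(rows, columns=["cutpoint", "se", "sp"])


def _render_rule(panel: ScorePanel, cutpoint: float) -> str:
    """Inequality on the observed score grid equivalent to the midpoint rule.

    The threshold is the smallest observed score strictly above the
    cutpoint, so integer grids render as "< 22" for cutpoint 21.5 and
    fractional ADAS-style grids as ">= 13" for cutpoint 12.8.
    """
    above = panel.scores[panel.scores > cutpoint]
    if panel.direction == LOWER:
        if above.size == 0:
            return "< inf"  # everyone positive
        t = above.min()
        return f"< {t:g}"
    if above.size == 0:
        return ">= inf"  # nobody positive
    t = above.min()
    return f">= {t:g}"


def optimal_cutoff(panel: ScorePanel) -> CutoffResult:
    """The ROC point maximizing Youden's J = se + sp - 1."""
    points = roc_points(panel)
    j = points["se"] + points["sp"] - 1.0
    best = points[np.isclose(j, j.max())]
    best = best.sort_values("se", ascending=False, kind="stable")
    top_se = best[np.isclose(best["se"], best["se"].iloc[0])]
    # most-positive direction: largest cutpoint when low scores are positive
    if panel.direction == LOWER:
        row = top_se.loc[top_se["cutpoint"].idxmax()]
    else:
        row = top_se.loc[top_se["cutpoint"].idxmin()]
    cut = float(row["cutpoint"])
    return CutoffResult(
        cutpoint=cut,
        decision_rule=_render_rule(panel, cut),
        se=float(row["se"]),
        sp=float(row["sp"]),
        youden=float(row["se"] + row["sp"] - 1.0),
    )


def read_scores(path: str | Path, direction: str = LOWER) -> ScorePanel:
    """Two-column CSV (score, label) -> ScorePanel."""
    df = pd.read_csv(path)
    if not {"score", "label"} <= set(df.columns):
        raise ValueError(f"{path} must have 'score' and 'label' columns")
    return ScorePanel(df["score"].to_numpy(), df["label"].to_numpy(), direction)
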