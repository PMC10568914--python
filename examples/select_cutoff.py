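"""Youden-optimal dichotomization of a continuous cognitive score.

Simulates MoCA-like integer scores for impaired and healthy subjects
(lower score = impairment) and picks the ROC cutpoint maximizing
Se + Sp - 1, reporting both the midpoint cutpoint and the rendered
integer decision rule.
"""

import numpy as np

from blcmdx import ScorePanel, optimal_cutoff, roc_points

rng = np.random.default_rng(0)
impaired = np.clip(np.round(rng.normal(17.1, 4.3, 150)), 0, 30)
healthy = np.clip(np.round(rng.normal(25.9, 2.5, 500)), 0, 30)
panel = ScorePanel(
    scores=np.concatenate([impaired, healthy]),
    labels=np.array([1] * 150 + [0] * 500),
    direction="lower_is_positive",
)

result = optimal_cutoff(panel)
print(f"ROC evaluated {len(roc_points(panel))} candidate rules")
print(f"optimal cutpoint: {result.cutpoint}  ->  positive if score {result.decision_rule}")
print(f"se {result.se:.3f}  sp {result.sp:.3f}  youden {result.youden:.3f}")
# The cutpoint is the midpoint between adjacent observed scores; the rule
# renders it on the integer score grid (e.g. 21.5 -> "< 22").
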