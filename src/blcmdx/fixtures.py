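"""Packaged study inputs: the three-test cognitive screening panel, the
cross-classified result counts of the AD (n = 1289) and MCI (n = 1111)
analyses, and the informative prior sets for each.
"""

from __future__ import annotations

from importlib import resources

from .panel import HIGHER, LOWER, CrossClassifiedCounts, TestPanel, read_counts
from .priors import PriorSet, load_priors

__all__ = ["cognitive_panel", "load_counts_fixture", "load_priors_fixture"]

_COUNT_FILES = {"ad": "table1_ad_counts.csv", "mci": "table2_mci_counts.csv"}
_PRIOR_FILES = {"ad": "priors_ad.yaml", "mci": "priors_mci.yaml"}


def cognitive_panel() -> TestPanel:
    """MoCA, MMSE and ADAS-cog with MoCA-MMSE conditional dependence.

    MoCA and MMSE code impairment as a *low* score, ADAS-cog as a *high*
    score; MoCA and MMSE are modeled as conditionally dependent within each
    latent class.
    """
    return TestPanel(
        test_names=("MoCA", "MMSE", "ADAS-cog"),
        positive_direction=(LOWER, LOWER, HIGHER),
        dependent_pairs=((0, 1),),
    )


def _data_path(filename: str):
    return resources.files("blcmdx.data").joinpath(filename)


def load_counts_fixture(analysis: str) -> CrossClassifiedCounts:
    """The packaged count table for ``"ad"`` or ``"mci"``."""
    key = analysis.lower()
    if key not in _COUNT_FILES:
        raise ValueError(f"unknown analysis {analysis!r}; use 'ad' or 'mci'")
    with resources.as_file(_data_path(_COUNT_FILES[key])) as path:
        return read_counts(path, cognitive_panel())


def load_priors_fixture(analysis: str) -> PriorSet:
    """The packaged informative prior set for ``"ad"`` or ``"mci"``."""
    key = analysis.lower()
    if key not in _PRIOR_FILES:
        raise ValueError(f"unknown analysis {analysis!r}; use 'ad' or 'mci'")
    with resources.as_file(_data_path(_PRIOR_FILES[key])) as path:
        return load_priors(path, cognitive_panel())
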