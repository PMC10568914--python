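"""Posterior summaries, Youden indices, predictive checks, reporting."""

import numpy as np
import pytest

from blcmdx import (
    AccuracyParams,
    BetaSpec,
    MCMCConfig,
    PriorSet,
    SimulationScenario,
    posterior_predictive_cells,
    report,
    sample_posterior,
    simulate_panel,
    summarize,
    youden_index,
)
from blcmdx.mcmc import PosteriorChains, param_names
from blcmdx.panel import CrossClassifiedCounts, TestPanel


def _chains_from_values(panel, values):
    """Wrap a (draws, n_params) array as a single-chain PosteriorChains."""
    arr = np.asarray(values, dtype=float)[None, :, :]
    return PosteriorChains(panel=panel, param_names=param_names(panel), draws=arr)


class TestSummarize:
    def test_constant_chain_degenerates_to_point(self, panel):
        row = np.array([0.2, 0.9, 0.8, 0.7, 0.9, 0.8, 0.7, 0.01, 0.02])
        chains = _chains_from_values(panel, np.tile(row, (50, 1)))
        s = summarize(chains)
        assert s.table.loc["prevalence", "mean"] == pytest.approx(0.2)
        assert s.table.loc["prevalence", "lower"] == s.table.loc["prevalence", "upper"]

    def test_percentiles_match_sort_based_oracle(self, panel):
        seq = np.arange(1, 1001, dtype=float)
        draws = np.tile(seq[:, None], (1, 9))
        s = summarize(_chains_from_values(panel, draws))
        assert s.table.loc["prevalence", "mean"] == pytest.approx(500.5)
        # linear-interpolation percentile rule, checked against numpy on a sorted copy
        expected_lo = np.percentile(np.sort(seq), 2.5)
        expected_hi = np.percentile(np.sort(seq), 97.5)
        assert s.table.loc["prevalence", "lower"] == pytest.approx(expected_lo)
        assert s.table.loc["prevalence", "upper"] == pytest.approx(expected_hi)

    def test_interval_contains_median_everywhere(self, ad_counts, ad_priors):
        chains = sample_posterior(
            ad_counts, ad_priors, MCMCConfig(iterations=4000, burn_in=2000, thin=2, seed=3)
        )
        t = summarize(chains).table
        assert (t["lower"] <= t["median"]).all()
        assert (t["median"] <= t["upper"]).all()

    def test_empty_chains_rejected(self, panel):
        chains = _chains_from_values(panel, np.empty((0, 9)))
        with pytest.raises(ValueError):
            summarize(chains)


class TestYouden:
    def test_perfect_test(self):
        assert youden_index(1.0, 1.0) == pytest.approx(1.0)

    @pytest.mark.parametrize(
        "se,sp,expected",
        [
            # published posterior means -> published Youden values, exactly
            (0.922, 0.907, 0.829),
            (0.912, 0.901, 0.813),
            (0.874, 0.922, 0.796),
            (0.869, 0.835, 0.704),
            (0.845, 0.769, 0.614),
            (0.757, 0.721, 0.478),
        ],
    )
    def test_closed_form_reproduces_published_indices(self, se, sp, expected):
        assert youden_index(se, sp) == pytest.approx(expected, abs=1e-12)

    def test_range_check(self):
        with pytest.raises(ValueError):
            youden_index(1.2, 0.5)


@pytest.fixture(scope="module")
def well_specified(panel, example_params):
    priors = PriorSet(
        panel,
        BetaSpec(2, 2),
        (BetaSpec(4, 2),) * 3,
        (BetaSpec(4, 2),) * 3,
    )
    counts = simulate_panel(SimulationScenario(panel, example_params, 3000, seed=11))
    chains = sample_posterior(
        counts, priors, MCMCConfig(iterations=8000, burn_in=4000, thin=4, seed=11,
                                   enforce_se_sp_gt1=True)
    )
    return chains, counts


class TestPosteriorPredictive:
    def test_expected_counts_sum_to_n_for_every_draw(self, well_specified):
        chains, counts = well_specified
        ppc = posterior_predictive_cells(chains, counts)
        assert ppc["expected"].sum() == pytest.approx(counts.n)

    def test_calibrated_fit_has_no_extreme_cells(self, well_specified):
        chains, counts = well_specified
        ppc = posterior_predictive_cells(chains, counts)
        assert ((ppc["tail_prob"] > 0.01) & (ppc["tail_prob"] < 0.99)).all()

    def test_misspecified_fit_flags_extreme_cells(self, panel):
        """Strongly dependent data forced through an independence model
        leaves cells the posterior cannot reproduce.

        The three-test independence model is nearly saturated (7 free
        parameters for 7 degrees of freedom), so the accuracies are pinned
        at the generating values by sharp priors; the unmodeled dependence
        then has to surface in the cell fit.
        """
        gen = AccuracyParams(0.3, (0.85, 0.85, 0.9), (0.9, 0.9, 0.9), (0.12,), (0.08,))
        counts_dep = simulate_panel(SimulationScenario(panel, gen, 20000, seed=7))
        indep_panel = TestPanel(panel.test_names, panel.positive_direction, ())
        counts = CrossClassifiedCounts(indep_panel, counts_dep.counts)
        priors = PriorSet(
            indep_panel,
            BetaSpec(600, 1400),
            (BetaSpec(1700, 300), BetaSpec(1700, 300), BetaSpec(1800, 200)),
            (BetaSpec(1800, 200),) * 3,
        )
        chains = sample_posterior(
            counts, priors, MCMCConfig(iterations=8000, burn_in=4000, thin=4, seed=7)
        )
        ppc = posterior_predictive_cells(chains, counts)
        assert ((ppc["tail_prob"] <= 0.01) | (ppc["tail_prob"] >= 0.99)).any()


@pytest.fixture(scope="module")
def two_analyses(ad_counts, ad_priors, mci_counts, mci_priors):
    cfg = MCMCConfig(iterations=3000, burn_in=1500, thin=3, seed=2)
    return {
        "AD": summarize(sample_posterior(ad_counts, ad_priors, cfg)),
        "MCI": summarize(sample_posterior(mci_counts, mci_priors, cfg)),
    }


class TestReport:
    def test_row_count_contract(self, two_analyses):
        text, table = report(two_analyses)
        accuracy = table[table["parameter"].isin(["se", "sp", "prevalence"])]
        youden = table[table["parameter"] == "youden"]
        assert len(accuracy) == 14  # 2 analyses x (3 tests x Se/Sp + prevalence)
        assert len(youden) == 6

    def test_values_round_trip_at_full_precision(self, two_analyses, tmp_path):
        import pandas as pd

        _, table = report(two_analyses)
        path = tmp_path / "results.csv"
        table.to_csv(path, index=False)
        again = pd.read_csv(path, float_precision="round_trip").fillna("")
        np.testing.assert_allclose(
            again["mean"].to_numpy(), table["mean"].to_numpy(), rtol=0, atol=0
        )

    def test_report_states_mcmc_settings(self, two_analyses):
        text, _ = report(two_analyses)
        assert "3000 iterations" in text and "burn-in 1500" in text
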