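"""Latent class probability model: bounds, cells, likelihood, posterior."""

import math

import numpy as np
import pytest

from blcmdx import (
    AccuracyParams,
    BetaSpec,
    InadmissibleParamsError,
    PriorSet,
    cell_probabilities,
    cell_probability,
    cov_bounds,
    log_likelihood,
    log_posterior,
)
from blcmdx.panel import CrossClassifiedCounts, TestPanel

from _oracles import (
    beta_logpdf,
    oracle_cell_probs,
    oracle_log_likelihood,
    random_valid_params,
)


class TestCovBounds:
    @pytest.mark.parametrize(
        "pi_pj,expected",
        [
            ((0.5, 0.5), (-0.25, 0.25)),
            ((1.0, 0.7), (0.0, 0.0)),
            ((0.9, 0.8), (-0.02, 0.08)),
        ],
    )
    def test_closed_form_values(self, pi_pj, expected):
        lo, hi = cov_bounds(*pi_pj)
        assert lo == pytest.approx(expected[0], abs=1e-12)
        assert hi == pytest.approx(expected[1], abs=1e-12)

    def test_bounds_straddle_zero_and_match_joint_table_search(self, rng):
        """The interval is exactly the covariance range over all joint 2x2
        tables with the given margins (verified by brute-force grid)."""
        for _ in range(25):
            pi, pj = rng.uniform(0.05, 0.95, 2)
            lo, hi = cov_bounds(pi, pj)
            assert lo <= 0.0 <= hi
            # any p11 in [max(0, pi+pj-1), min(pi,pj)] gives a valid table
            p11_grid = np.linspace(max(0.0, pi + pj - 1.0), min(pi, pj), 500)
            covs = p11_grid - pi * pj
            assert lo == pytest.approx(covs.min(), abs=1e-4)
            assert hi == pytest.approx(covs.max(), abs=1e-4)

    def test_rejects_out_of_range_margins(self):
        with pytest.raises(ValueError):
            cov_bounds(1.2, 0.5)


class TestCellProbabilities:
    def test_degenerate_perfect_tests(self, panel):
        params = AccuracyParams(1.0, (1, 1, 1), (0.5, 0.6, 0.7), (0.0,), (0.0,))
        probs = cell_probabilities(params, panel)
        assert probs[panel.pattern_index((1, 1, 1))] == pytest.approx(1.0)
        assert probs.sum() == pytest.approx(1.0)

    def test_independence_product_value(self, panel):
        params = AccuracyParams(0.5, (0.8, 0.7, 0.9), (0.9, 0.8, 0.95), (0.0,), (0.0,))
        expected = 0.5 * (0.8 * 0.7 * 0.9) + 0.5 * (0.1 * 0.2 * 0.05)
        assert cell_probability(params, panel, (1, 1, 1)) == pytest.approx(expected)
        assert expected == 0.2525

    def test_factorizes_exactly_at_zero_covariance(self, panel, rng):
        for _ in range(50):
            p = random_valid_params(rng, panel)
            p0 = AccuracyParams(p.prevalence, p.se, p.sp, (0.0,), (0.0,))
            probs = cell_probabilities(p0, panel)
            for idx, pattern in enumerate(panel.patterns()):
                d = np.prod([p.se[k] if t else 1 - p.se[k] for k, t in enumerate(pattern)])
                n = np.prod([1 - p.sp[k] if t else p.sp[k] for k, t in enumerate(pattern)])
                assert probs[idx] == pytest.approx(
                    p.prevalence * d + (1 - p.prevalence) * n, abs=1e-14
                )

    def test_normalization_and_oracle_equivalence_bulk(self, panel, rng):
        """10,000 random admissible draws: cells sum to one and match the
        independent brute-force enumeration to 1e-12."""
        for _ in range(10_000):
            params = random_valid_params(rng, panel)
            probs = cell_probabilities(params, panel)
            assert abs(probs.sum() - 1.0) < 1e-12
            assert np.max(np.abs(probs - oracle_cell_probs(params, panel))) < 1e-12

    def test_marginal_consistency_with_and_without_dependence(self, panel, rng):
        """Summing cells with t_k = 1 gives pi*Se_k + (1-pi)*(1-Sp_k); the
        covariance terms cancel in every margin."""
        pats = panel.patterns()
        for _ in range(200):
            p = random_valid_params(rng, panel)
            probs = cell_probabilities(p, panel)
            for k in range(panel.k):
                margin = probs[pats[:, k] == 1].sum()
                expected = p.prevalence * p.se[k] + (1 - p.prevalence) * (1 - p.sp[k])
                assert margin == pytest.approx(expected, abs=1e-12)

    def test_inadmissible_covariance_names_offending_cell(self, panel):
        params = AccuracyParams(0.3, (0.9, 0.8, 0.7), (0.9, 0.9, 0.9), (0.2,), (0.0,))
        with pytest.raises(InadmissibleParamsError, match="admissible"):
            cell_probabilities(params, panel)


class TestLogLikelihood:
    def test_single_cell_case(self):
        p2 = TestPanel(("x", "y"))
        counts = CrossClassifiedCounts(p2, np.array([10, 0, 0, 0]))
        params = AccuracyParams(1.0, (1.0, 0.5), (0.9, 0.9))
        # P(1,1) = 1 * 1 * 0.5 = 0.5, all mass in one cell
        assert log_likelihood(params, counts) == pytest.approx(10 * math.log(0.5))

    def test_zero_count_cells_contribute_nothing(self, panel, rng):
        params = random_valid_params(rng, panel)
        probs = cell_probabilities(params, panel)
        counts = CrossClassifiedCounts(panel, np.array([7, 0, 3, 0, 0, 0, 0, 5]))
        manual = sum(
            c * math.log(p) for c, p in zip(counts.counts, probs) if c > 0
        )
        assert log_likelihood(params, counts) == pytest.approx(manual, abs=1e-12)

    def test_matches_independent_oracle_on_study_data(self, ad_counts, ad_priors):
        params = AccuracyParams(
            ad_priors.prevalence.mean,
            tuple(s.mean for s in ad_priors.se),
            tuple(s.mean for s in ad_priors.sp),
            (0.0,),
            (0.0,),
        )
        ours = log_likelihood(params, ad_counts)
        oracle = oracle_log_likelihood(params, ad_counts)
        assert ours == pytest.approx(oracle, rel=1e-12)


class TestLogPosterior:
    def _flat_priors(self, panel):
        flat = BetaSpec(1, 1)
        return PriorSet(panel, flat, (flat,) * 3, (flat,) * 3)

    def test_flat_prior_identity(self, panel, ad_counts, rng):
        """With Beta(1,1) priors, log-posterior minus log-likelihood is the
        same constant at every admissible parameter point."""
        priors = self._flat_priors(panel)
        diffs = set()
        for _ in range(20):
            p = random_valid_params(rng, panel)
            diffs.add(round(log_posterior(p, ad_counts, priors) - log_likelihood(p, ad_counts), 9))
        assert len(diffs) == 1

    def test_truncation_outside_cov_bounds(self, panel, ad_counts, ad_priors):
        params = AccuracyParams(0.2, (0.9, 0.9, 0.9), (0.9, 0.9, 0.9), (0.5,), (0.0,))
        assert log_posterior(params, ad_counts, ad_priors) == -math.inf

    def test_term_by_term_oracle(self, panel, ad_counts, ad_priors, rng):
        for _ in range(20):
            p = random_valid_params(rng, panel)
            expected = oracle_log_likelihood(p, ad_counts)
            expected += beta_logpdf(
                p.prevalence, ad_priors.prevalence.alpha, ad_priors.prevalence.beta
            )
            for spec, x in zip(ad_priors.se, p.se):
                expected += beta_logpdf(x, spec.alpha, spec.beta)
            for spec, x in zip(ad_priors.sp, p.sp):
                expected += beta_logpdf(x, spec.alpha, spec.beta)
            expected += 2 * math.log(0.5)  # two Uniform(-1,1) covariance terms
            assert log_posterior(p, ad_counts, ad_priors) == pytest.approx(
                expected, rel=1e-10
            )
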