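"""Productivity, occupancy, imputation and pair-estimation checks."""

import numpy as np
import pytest
from scipy.special import expit, logit

from shearwater_census.mcmc import PosteriorSummary
from shearwater_census.records import (ChickStation, HistoricalSummary,
                                       OccupancyRecord, RunConfig)
from shearwater_census.reproduction import (breeding_success,
                                            design_based_pairs,
                                            estimate_chicks, estimate_pairs,
                                            fit_occupancy, fit_productivity,
                                            impute_occupancy)


def _stations(colony, checked, found):
    """Split a (checked, found) total into 5-burrow stations."""
    out, remaining = [], found
    for i in range(checked // 5):
        take = min(5, remaining)
        out.append(ChickStation(colony, "T1", f"S{i}", 5, take))
        remaining -= take
    assert remaining == 0
    return out


class TestProductivity:
    def test_conjugate_posterior_mean(self, fast_config):
        theta = fit_productivity(_stations("CP", 30, 12), fast_config, seed=1)
        s = theta["CP"]
        # Beta(1,1) + 12/30 -> Beta(13, 19), mean 13/32
        n = len(s.draws)
        assert s.mean == pytest.approx(13 / 32, abs=3 * s.psd / np.sqrt(n))

    def test_zero_chicks_boundary(self, fast_config):
        n_checked = 20
        theta = fit_productivity(_stations("CP", n_checked, 0), fast_config, seed=2)
        s = theta["CP"]
        assert s.mean == pytest.approx(1 / (n_checked + 2), rel=0.1)

    def test_unsampled_colony_takes_pooled_mean(self, fast_config):
        stations = _stations("CP", 30, 12) + _stations("MB", 30, 9)
        theta = fit_productivity(stations, fast_config,
                                 colonies=["CP", "MB", "HB"], seed=3)
        np.testing.assert_allclose(
            theta["HB"].draws, (theta["CP"].draws + theta["MB"].draws) / 2)


class TestChicksAndPairs:
    def _totals(self, value, n=5_000):
        return {"CP": PosteriorSummary.point_mass("B[CP]", value, n)}

    def test_certainty_limits(self):
        ones = {"CP": PosteriorSummary.point_mass("t", 1.0, 5_000)}
        zeros = {"CP": PosteriorSummary.point_mass("t", 0.0, 5_000)}
        assert estimate_chicks(self._totals(1_000), ones)["CP"].mean == 1_000.0
        assert estimate_chicks(self._totals(1_000), zeros)["CP"].psd == 0.0
        assert estimate_pairs(self._totals(1_000), ones)["total"].mean == 1_000.0

    def test_binomial_moments(self):
        theta = {"CP": PosteriorSummary.point_mass("t", 0.387, 200_000)}
        chicks = estimate_chicks(self._totals(10_000, 200_000), theta, seed=4)
        s = chicks["CP"]
        var = 10_000 * 0.387 * 0.613
        assert s.mean == pytest.approx(3_870, abs=3 * np.sqrt(var / 200_000) * 100)
        assert s.mean == pytest.approx(3_870, rel=0.01)
        assert s.psd ** 2 == pytest.approx(var, rel=0.05)

    def test_drawwise_bound_by_burrows(self):
        rng = np.random.default_rng(5)
        totals = {"CP": PosteriorSummary.from_draws(
            "B", rng.poisson(500, 10_000).astype(float))}
        rates = {"CP": PosteriorSummary.from_draws("t", rng.uniform(0, 1, 10_000))}
        chicks = estimate_chicks(totals, rates, seed=5)
        assert np.all(chicks["CP"].draws <= totals["CP"].draws)

    def test_mismatched_draws_error(self):
        totals = {"CP": PosteriorSummary.point_mass("B", 100, 1_000)}
        rates = {"CP": PosteriorSummary.point_mass("t", 0.5, 999)}
        with pytest.raises(ValueError, match="mismatched"):
            estimate_chicks(totals, rates)


class TestOccupancy:
    def test_conjugate_posterior(self, fast_config):
        recs = [OccupancyRecord("CP", "2008/9", 100, 67)]
        tau = fit_occupancy(recs, fast_config, seed=6)["CP"]
        assert tau.mean == pytest.approx(68 / 102, abs=0.01)

    def test_strong_literature_prior_dominates_without_data(self, fast_config):
        prior = [HistoricalSummary("NB", "2002/3", "occupancy", 0.5, 0.001)]
        tau = fit_occupancy([], fast_config, priors=prior, seed=7)["NB"]
        assert tau.mean == pytest.approx(0.5, abs=0.01)

    def test_vague_literature_prior_is_negligible(self, fast_config):
        recs = [OccupancyRecord("CP", "2008/9", 100, 67)]
        vague = [HistoricalSummary("CP", "2002/3", "occupancy", 0.67, 10.0)]
        with_prior = fit_occupancy(recs, fast_config, priors=vague, seed=8)["CP"]
        data_only = fit_occupancy(recs, fast_config, seed=8)["CP"]
        assert with_prior.mean == pytest.approx(data_only.mean, abs=0.02)
        assert with_prior.psd == pytest.approx(data_only.psd, abs=0.01)


class TestImputation:
    def test_identity_relationship_recovered(self, fast_config):
        # occupancy ≡ productivity in one season -> slope 1, intercept 0
        rng = np.random.default_rng(9)
        pairs = []
        for _ in range(12):
            p = rng.uniform(0.3, 0.7)
            occ = expit(logit(p) + 0.01 * rng.standard_normal())
            pairs.append((occ, p, "CP", "2008/9"))
        rel = impute_occupancy(pairs, [("CP", "2008/9", 0.5)], fast_config, seed=9)
        assert rel.slope.mean == pytest.approx(1.0, abs=0.1)
        assert rel.intercept.mean == pytest.approx(0.0, abs=0.1)
        assert not rel.year_effects  # single season: no year terms

    def test_noise_free_line_prediction(self, fast_config):
        rng = np.random.default_rng(10)
        a, b = 0.3, 0.8
        pairs = []
        for season in ("2006/7", "2008/9"):
            for _ in range(8):
                p = rng.uniform(0.3, 0.7)
                occ = expit(a + b * logit(p) + 0.005 * rng.standard_normal())
                pairs.append((occ, p, "CP", season))
        rel = impute_occupancy(pairs, [("ALL", "2008/9", 0.45)], fast_config,
                               seed=10)
        pred = rel.predictions[("ALL", "2008/9")]
        line = expit(a + b * logit(0.45))
        mcse = pred.psd / np.sqrt(max(pred.ess or len(pred.draws), 1.0))
        assert pred.mean == pytest.approx(line, abs=max(2 * mcse, 0.02))

    def test_identical_productivities_rejected(self, fast_config):
        pairs = [(0.6, 0.4, "CP", "2008/9")] * 5
        with pytest.raises(ValueError, match="slope unidentifiable"):
            impute_occupancy(pairs, [], fast_config)

    def test_too_few_pairs_rejected(self, fast_config):
        with pytest.raises(ValueError, match="at least 3"):
            impute_occupancy([(0.6, 0.4, "CP", "2008/9")], [], fast_config)


class TestDesignBasedPairs:
    def test_degenerate_inputs(self):
        est, lo, hi = design_based_pairs(1_000, 0.0, 0.5, 0.0)
        assert (est, lo, hi) == (500.0, 500.0, 500.0)
        assert design_based_pairs(1_000, 10.0, 0.0, 0.0)[0] == 0.0

    def test_matches_monte_carlo_product_oracle(self):
        b_mean, b_sd, t_mean, t_sd = 27_323, 2_024, 0.62, 0.04
        est, lo, hi = design_based_pairs(b_mean, b_sd, t_mean, t_sd)
        rng = np.random.default_rng(11)
        prod = rng.normal(b_mean, b_sd, 400_000) * rng.normal(t_mean, t_sd, 400_000)
        assert est == pytest.approx(prod.mean(), rel=0.02)
        mc_half = 1.96 * prod.std()
        assert (hi - lo) / 2 == pytest.approx(mc_half, rel=0.02)


class TestBreedingSuccess:
    @pytest.mark.parametrize("eggs, chicks, late, expected", [
        (100, 69, 0, 0.69),
        (50, 50, 0, 1.0),
        (10, 8, 2, 8 / 12),
    ])
    def test_rate_with_late_found_adjustment(self, eggs, chicks, late, expected):
        bs = breeding_success(eggs, chicks, late)
        assert bs.rate == pytest.approx(expected)
        if expected < 1.0:
            assert bs.posterior.ci95[0] <= expected <= bs.posterior.ci95[1]
        else:  # boundary rate: posterior support cannot include 1 exactly
            assert bs.posterior.ci95[1] > 0.99

    def test_zero_denominator_rejected(self):
        with pytest.raises(ValueError):
            breeding_success(0, 0, 0)

    def test_more_chicks_than_eggs_rejected(self):
        with pytest.raises(ValueError):
            breeding_success(5, 7, 1)


def test_printed_rate_identity(published):
    """Breeding success × occupancy reproduces printed productivity.

    Both factors are printed at 2 dp, so the product can differ from the
    printed productivity by up to one unit in the second decimal.
    """
    for row in published.study_rates.itertuples():
        assert row.breeding_success * row.occupancy == pytest.approx(
            row.productivity, abs=0.01)
    r2008 = published.study_rates.set_index("season").loc["2008/9"]
    assert round(r2008.breeding_success * r2008.occupancy, 2) == 0.46
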