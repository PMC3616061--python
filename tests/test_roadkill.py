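"""Carcass densities, distance-decay GLM, persistence correction, LE."""

import math

import numpy as np
import pandas as pd
import pytest
from hypothesis import given, settings
from hypothesis import strategies as st

from shearwater_census.mcmc import PosteriorSummary
from shearwater_census.records import CarcassTransect, MarkedCarcassStudy, RunConfig
from shearwater_census.roadkill import (background_mortality, carcass_density,
                                        disappearance_rate, expected_snapshot,
                                        fit_carcass_glm, invert_snapshot,
                                        life_expectancy,
                                        mortality_as_survival_delta,
                                        predict_roadside_carcasses,
                                        total_road_mortality)


def _transects(total_count, total_area, n=4, road="road"):
    per = total_count // n
    counts = [per] * n
    counts[0] += total_count - per * n
    return [CarcassTransect(f"t{i}", road, total_area / n, c)
            for i, c in enumerate(counts)]


class TestCarcassDensity:
    def test_roadside_density(self):
        d, se = carcass_density(_transects(10, 800.0))
        assert d == pytest.approx(12.5)

    def test_background_density(self):
        d, se = carcass_density(_transects(2, 4_116.0))
        assert round(d, 2) == 0.49

    def test_zero_carcasses(self):
        d, _ = carcass_density(_transects(0, 500.0))
        assert d == 0.0

    def test_zero_area_rejected(self):
        with pytest.raises(ValueError):
            carcass_density([])


class TestCarcassGlm:
    def _bands(self, counts_by_distance, area=4.0, reps=1):
        rows = []
        for rep in range(reps):
            for d, c in counts_by_distance:
                rows.append({"transect_id": f"t{rep}", "distance_mid_m": d,
                             "area_m2": area, "count": c})
        return pd.DataFrame(rows)

    def test_equal_counts_give_flat_slope(self):
        fit = fit_carcass_glm(self._bands([(1, 3), (3, 3), (5, 3), (7, 3)],
                                          reps=5))
        assert fit.slope == pytest.approx(0.0, abs=1e-6)

    def test_recovers_log_linear_decay(self):
        rng = np.random.default_rng(12)
        rows = []
        for i in range(200):
            d = rng.uniform(0, 9)
            lam = np.exp(1.0 - 0.3 * d)
            rows.append({"transect_id": f"t{i}", "distance_mid_m": d,
                         "area_m2": 1.0, "count": rng.poisson(lam)})
        fit = fit_carcass_glm(pd.DataFrame(rows))
        assert abs(fit.intercept - 1.0) < 2 * fit.intercept_se
        assert abs(fit.slope + 0.3) < 2 * fit.slope_se

    def test_all_zero_counts_flagged_boundary(self):
        fit = fit_carcass_glm(self._bands([(1, 0), (5, 0)], reps=3))
        assert fit.boundary and fit.slope == 0.0
        assert fit.predict_density(3.0) < 1e-10

    def test_single_distance_rejected(self):
        with pytest.raises(ValueError, match="2 distinct"):
            fit_carcass_glm(self._bands([(1, 3)], reps=4))


class TestPredictRoadside:
    def _fit_and_bands(self):
        rng = np.random.default_rng(13)
        rows = []
        for i in range(60):
            for d in (1.0, 3.0, 5.0, 7.0, 9.0):
                lam = 4.0 * np.exp(0.6 - 0.25 * d)
                rows.append({"transect_id": f"t{i}", "distance_mid_m": d,
                             "area_m2": 4.0, "count": rng.poisson(lam)})
        bands = pd.DataFrame(rows)
        return fit_carcass_glm(bands), bands

    def test_in_sample_consistency(self):
        fit, bands = self._fit_and_bands()
        geom = bands[["distance_mid_m", "area_m2"]]
        pred = predict_roadside_carcasses(fit, geom, seed=1)
        assert pred.mean == pytest.approx(bands["count"].sum(), rel=0.05)

    def test_zero_area_and_linearity(self):
        fit, bands = self._fit_and_bands()
        geom = bands[["distance_mid_m", "area_m2"]].copy()
        zero = geom.assign(area_m2=0.0)
        assert predict_roadside_carcasses(fit, zero, seed=1).mean == 0.0
        single = predict_roadside_carcasses(fit, geom, seed=1)
        double = predict_roadside_carcasses(fit, geom.assign(
            area_m2=geom["area_m2"] * 2), seed=1)
        assert double.mean == pytest.approx(2 * single.mean, rel=1e-9)

    def test_extrapolation_warning(self):
        fit, _ = self._fit_and_bands()
        far = pd.DataFrame({"distance_mid_m": [25.0], "area_m2": [10.0]})
        with pytest.warns(UserWarning, match="extrapolation"):
            predict_roadside_carcasses(fit, far, seed=1)


class TestDisappearance:
    def test_no_disappearance_point_estimate(self, tiny_config):
        dr = disappearance_rate(MarkedCarcassStudy(5, 5, 0, 30), tiny_config)
        assert dr.point == 0.0

    def test_defining_identity_holds_exactly(self, tiny_config):
        study = MarkedCarcassStudy(7, 4, 0, 107)
        dr = disappearance_rate(study, tiny_config)
        assert (1 - dr.point) ** 107 == pytest.approx(4 / 7, rel=1e-12)
        assert dr.point == pytest.approx(0.0052, abs=2e-4)

    def test_posterior_matches_grid_oracle(self, fast_config):
        study = MarkedCarcassStudy(7, 4, 0, 107)
        dr = disappearance_rate(study, fast_config, seed=2)
        r = np.linspace(1e-7, 0.2, 400_001)
        s = 107 * np.log1p(-r)
        logp = 4 * s + 3 * np.log1p(-np.exp(s))
        w = np.exp(logp - logp.max())
        w /= w.sum()
        grid_mean = float((r * w).sum())
        cdf = np.cumsum(w)
        assert dr.posterior.mean == pytest.approx(grid_mean, rel=0.05)
        assert dr.posterior.ci95[1] == pytest.approx(
            r[np.searchsorted(cdf, 0.975)], rel=0.1)
        assert dr.posterior.covers(dr.point)

    def test_total_loss_posterior_proper_with_warning(self, tiny_config):
        dr = disappearance_rate(MarkedCarcassStudy(5, 0, 0, 30), tiny_config)
        assert dr.point is None and dr.warnings
        assert 0 < dr.posterior.mean < 1
        assert np.isfinite(dr.posterior.draws).all()


class TestSeasonMortality:
    def test_closed_form_example(self):
        # m = 1, r = 0.5, T = 3: snapshot 1 + 0.5 + 0.25 = 1.75, season 3
        assert expected_snapshot(1.0, 0.5, 3) == pytest.approx(1.75)
        assert invert_snapshot(1.75, 0.5, 3) * 3 == pytest.approx(3.0)

    def test_closed_form_equals_daily_recursion_on_grid(self):
        for m in (0.2, 1.0, 3.0):
            for r in (0.0, 0.01, 0.1, 0.5, 0.9):
                for T in (1, 7, 60, 180):
                    present = 0.0
                    for _ in range(T):
                        present = present * (1 - r) + m
                    assert expected_snapshot(m, r, T) == pytest.approx(
                        present, rel=1e-12)

    def test_no_disappearance_means_m_equals_m_prime(self):
        m_prime = PosteriorSummary.point_mass("M_prime", 42.0, 2_000)
        r = PosteriorSummary.point_mass("r", 0.0, 2_000)
        assert total_road_mortality(m_prime, r, 90).mean == 42.0

    def test_monotone_in_disappearance_rate(self):
        m_prime = PosteriorSummary.point_mass("M_prime", 50.0, 1_000)
        means = [total_road_mortality(
            m_prime, PosteriorSummary.point_mass("r", r, 1_000), 120).mean
            for r in (0.0, 0.002, 0.01, 0.05, 0.2)]
        assert all(a < b for a, b in zip(means, means[1:]))
        assert means[0] == 50.0

    def test_forward_simulation_inversion_recovers_daily_kills(self):
        rng = np.random.default_rng(14)
        m, r, T = 0.8, 0.02, 120
        recovered = []
        for _ in range(100):
            kills = rng.poisson(m, size=T)
            days = np.repeat(np.arange(1, T + 1), kills)
            alive = rng.uniform(size=days.size) < (1 - r) ** (T - days)
            recovered.append(invert_snapshot(float(alive.sum()), r, T))
        se = np.std(recovered) / 10
        assert np.mean(recovered) == pytest.approx(m, abs=3 * se)

    def test_r_one_warns(self):
        m_prime = PosteriorSummary.point_mass("M_prime", 5.0, 100)
        r = PosteriorSummary.point_mass("r", 1.0, 100)
        with pytest.warns(UserWarning, match="last-day"):
            total_road_mortality(m_prime, r, 10)


class TestBackgroundAndLifeExpectancy:
    def test_background_count_from_colony_area(self):
        assert round(background_mortality(0.49, 247_300.0)) == 121
        assert background_mortality(0.0, 247_300.0) == 0.0
        assert background_mortality(1.0, 1_000.0) == 1.0

    def test_life_expectancy_values(self):
        assert round(life_expectancy(0.92)) == 12
        assert round(life_expectancy(0.916), 1) == 11.4
        assert life_expectancy(math.exp(-1)) == pytest.approx(1.0)

    def test_domain_errors(self):
        for phi in (0.0, 1.0, 1.2, -0.1):
            with pytest.raises(ValueError):
                life_expectancy(phi)

    @settings(max_examples=40, deadline=None)
    @given(st.floats(0.02, 0.97), st.floats(0.001, 0.02))
    def test_life_expectancy_strictly_increasing(self, phi, step):
        assert life_expectancy(phi + step) > life_expectancy(phi)

    def test_survival_delta_reduction(self):
        delta = mortality_as_survival_delta(0.004 * 50_000, 50_000,
                                            phi_baseline=0.92)
        assert delta.phi_reduced == pytest.approx(0.916)
        assert delta.le_reduction_pct == pytest.approx(5.0, abs=0.5)
        # definitional identity: the ratio route and the formula route agree
        direct = (1 - delta.le_reduced_years / delta.le_baseline_years) * 100
        assert delta.le_reduction_pct == pytest.approx(direct, abs=1e-12)

    def test_zero_additional_mortality(self):
        delta = mortality_as_survival_delta(0.0, 1_000)
        assert delta.le_reduction_pct == 0.0

    def test_more_deaths_than_adults_rejected(self):
        with pytest.raises(ValueError):
            mortality_as_survival_delta(2_000, 1_000)
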