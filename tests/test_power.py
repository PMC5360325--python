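"""Tests for the Monte Carlo power engine and its analytic oracle."""

import numpy as np
import pytest

from stridepower import (
    DesignSpec,
    VarianceComponents,
    analytic_power_oracle,
    estimate_power,
    min_subjects_for_power,
    power_surface,
    simulate_between_dataset,
    simulate_subject_alpha,
    simulate_within_dataset,
)
from stridepower.exceptions import InvalidInputError, PowerNotAchievableError


def test_within_correlation_from_covariance_matrix():
    """Covariance 0.0072 with variance 0.0081 implies correlation 0.89."""
    assert round(0.0072 / 0.0081, 2) == 0.89


class TestGenerativeModel:
    def test_noise_free_subject_returns_mu(self):
        vc = VarianceComponents(sd_trial=0.0, sd_error=0.0)
        rng = np.random.default_rng(0)
        assert simulate_subject_alpha(0.8, 0.0, vc, 3, rng) == 0.8

    def test_subject_alpha_variance_closed_form(self):
        # subject_effect fixed at 0, so Var = (sd_trial^2 + sd_error^2) / n_trials
        vc = VarianceComponents()
        rng = np.random.default_rng(1)
        draws = np.array(
            [simulate_subject_alpha(0.8, 0.0, vc, 2, rng) for _ in range(30000)]
        )
        expected_sd = np.sqrt((0.16**2 + 0.018**2) / 2)
        assert draws.std(ddof=1) == pytest.approx(expected_sd, rel=0.03)
        assert draws.mean() == pytest.approx(0.8, abs=0.002)

    def test_between_dataset_moments(self):
        spec = DesignSpec(design="between")
        vc = VarianceComponents()
        g1, g2 = simulate_between_dataset(
            spec, vc, 20000, 4, np.random.default_rng(2)
        )
        expected_sd = np.sqrt(0.09**2 + (0.16**2 + 0.018**2) / 4)
        for g, mu in ((g1, 0.8), (g2, 0.70)):
            assert g.mean() == pytest.approx(mu, abs=0.003)
            assert g.std(ddof=1) == pytest.approx(expected_sd, rel=0.02)

    def test_between_dataset_degenerate(self):
        spec = DesignSpec(design="between")
        vc = VarianceComponents(sd_subject=0, sd_trial=0, sd_error=0)
        g1, g2 = simulate_between_dataset(spec, vc, 5, 2, np.random.default_rng(3))
        np.testing.assert_array_equal(g1, 0.8)
        np.testing.assert_array_equal(g2, 0.70)

    def test_within_dataset_subject_correlation(self):
        spec = DesignSpec(design="within")
        vc = VarianceComponents(sd_trial=0.0, sd_error=0.0)
        a, b = simulate_within_dataset(
            spec, vc, 100000, 1, np.random.default_rng(4)
        )
        r = np.corrcoef(a - 0.8, b - 0.70)[0, 1]
        assert r == pytest.approx(0.89, abs=0.004)

    def test_within_perfect_correlation_gives_constant_difference(self):
        spec = DesignSpec(design="within")
        vc = VarianceComponents(
            sd_trial=0.0, sd_error=0.0, within_correlation=1.0
        )
        a, b = simulate_within_dataset(spec, vc, 50, 3, np.random.default_rng(5))
        np.testing.assert_allclose(a - b, 0.10, atol=1e-12)


class TestEstimatePower:
    def test_null_rejection_rate_is_test_level(self):
        vc = VarianceComponents()
        for design in ("between", "within"):
            spec = DesignSpec(design=design, mu1=0.8, mu2=0.8, seed=11)
            p = estimate_power(spec, vc, 20, 2)
            se = np.sqrt(0.05 * 0.95 / spec.n_replicates)
            assert abs(p - 0.05) < 3 * se

    @pytest.mark.parametrize("design", ["between", "within"])
    @pytest.mark.parametrize("n,t", [(5, 1), (12, 4), (25, 2), (40, 8)])
    def test_monte_carlo_matches_analytic_oracle(self, design, n, t):
        spec = DesignSpec(design=design, seed=13)
        vc = VarianceComponents()
        mc = estimate_power(spec, vc, n, t)
        exact = analytic_power_oracle(spec, vc, n, t)
        se = np.sqrt(exact * (1 - exact) / spec.n_replicates)
        assert abs(mc - exact) < 3 * se + 1e-9

    def test_zero_variance_null_warns_and_returns_zero(self):
        spec = DesignSpec(design="within", mu1=0.8, mu2=0.8)
        vc = VarianceComponents(sd_subject=0, sd_trial=0, sd_error=0)
        with pytest.warns(UserWarning):
            assert estimate_power(spec, vc, 10, 1) == 0.0


class TestAnalyticOracle:
    def test_null_power_equals_level_exactly(self):
        spec = DesignSpec(design="within", mu1=0.8, mu2=0.8)
        p = analytic_power_oracle(spec, VarianceComponents(), 10, 2)
        assert p == pytest.approx(0.05, abs=1e-9)

    def test_monotone_in_design_factors(self):
        vc = VarianceComponents()
        w = DesignSpec(design="within")
        powers_n = [analytic_power_oracle(w, vc, n, 2) for n in range(3, 40)]
        assert np.all(np.diff(powers_n) > 0)
        powers_t = [analytic_power_oracle(w, vc, 10, t) for t in (1, 2, 4, 6, 8)]
        assert np.all(np.diff(powers_t) > 0)
        effects = [0.02, 0.05, 0.1, 0.2]
        powers_e = [
            analytic_power_oracle(
                DesignSpec(design="within", mu1=0.7 + e, mu2=0.7), vc, 10, 2
            )
            for e in effects
        ]
        assert np.all(np.diff(powers_e) > 0)

    def test_monotone_in_variance_components(self):
        w = DesignSpec(design="between")
        base = analytic_power_oracle(w, VarianceComponents(), 20, 2)
        for kwargs in (
            {"sd_subject": 0.15},
            {"sd_trial": 0.25},
            {"sd_error": 0.1},
        ):
            worse = analytic_power_oracle(w, VarianceComponents(**kwargs), 20, 2)
            assert worse < base
        within = DesignSpec(design="within")
        low_r = analytic_power_oracle(
            within, VarianceComponents(within_correlation=0.3), 20, 2
        )
        high_r = analytic_power_oracle(
            within, VarianceComponents(within_correlation=0.95), 20, 2
        )
        assert high_r > low_r

    def test_within_dominates_between_pointwise(self):
        # The paired test halves the degrees of freedom, so at very small n
        # and t the dominance holds only up to a sub-millipower margin.
        vc = VarianceComponents()
        for n in (5, 10, 25, 50):
            for t in (1, 2, 4, 8):
                w = analytic_power_oracle(DesignSpec(design="within"), vc, n, t)
                b = analytic_power_oracle(DesignSpec(design="between"), vc, n, t)
                assert w >= b - 1e-3

    def test_high_correlation_many_trials_limit(self):
        vc = VarianceComponents(within_correlation=0.999999)
        spec = DesignSpec(design="within")
        assert analytic_power_oracle(spec, vc, 10, 10**6) > 0.999

    def test_diminishing_returns_from_extra_trials(self):
        vc = VarianceComponents()
        spec = DesignSpec(design="within")
        for n in (8, 12, 16):
            p = {t: analytic_power_oracle(spec, vc, n, t) for t in (2, 4, 6, 8)}
            assert (p[8] - p[6]) < (p[4] - p[2])


class TestSurfaceAndMinN:
    @pytest.fixture(scope="class")
    def surface(self):
        spec = DesignSpec(
            design="within",
            n_subjects_grid=tuple(range(3, 31)),
            trials_grid=(1, 2, 4),
            n_replicates=1000,
            seed=17,
        )
        return power_surface(spec, VarianceComponents())

    def test_surface_reproducible_and_consistent_with_cells(self, surface):
        spec = surface.design
        again = power_surface(spec, surface.variance)
        np.testing.assert_array_equal(surface.power, again.power)
        assert surface.at(12, 4) == estimate_power(spec, surface.variance, 12, 4)

    def test_power_nondecreasing_in_subjects_within_noise(self, surface):
        se = np.sqrt(0.25 / surface.design.n_replicates)
        for j in range(surface.power.shape[1]):
            col = surface.power[:, j]
            assert np.all(np.diff(col) > -2 * 3 * se)

    def test_min_subjects_thresholds(self, surface):
        assert min_subjects_for_power(surface, 1, threshold=0.0) == 3
        with pytest.raises(PowerNotAchievableError):
            min_subjects_for_power(surface, 1, threshold=1.01)
        n80 = min_subjects_for_power(surface, 4, threshold=0.80)
        assert surface.at(n80, 4) >= 0.80

    def test_invalid_trials_column(self, surface):
        with pytest.raises(InvalidInputError):
            min_subjects_for_power(surface, 3)


def test_spec_validation():
    with pytest.raises(InvalidInputError):
        DesignSpec(design="crossover")
    with pytest.raises(InvalidInputError):
        DesignSpec(n_replicates=10)
    with pytest.raises(InvalidInputError):
        VarianceComponents(sd_trial=-0.1)
    with pytest.raises(InvalidInputError):
        VarianceComponents(within_correlation=1.5)
    with pytest.raises(InvalidInputError):
        VarianceComponents.for_strides(120)
    assert VarianceComponents.for_strides(150).sd_trial == 0.12
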