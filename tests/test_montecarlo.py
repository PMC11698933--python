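"""Monte Carlo propagation, percentile summaries and sensitivity analysis."""

import numpy as np
import pytest

import fluorisk as fk
from fluorisk.errors import ConfigurationError, UsageError
from fluorisk.montecarlo import (
    DistributionSpec,
    convergence_check,
    default_specs,
    sample_inputs,
    sensitivity,
    simulate_hq,
)

CHILDREN, TEENAGERS, ADULTS = fk.DEFAULT_COHORTS
D = DistributionSpec


def _point_specs(cohort, C):
    return {
        "C": D.point(C), "IR": D.point(cohort.IR), "EF": D.point(cohort.EF),
        "ED": D.point(cohort.ED), "BW": D.point(cohort.BW), "AT": D.point(cohort.AT),
    }


class TestSampling:
    def test_point_specs_yield_identical_rows(self):
        draws = sample_inputs({"C": D.point(2.3)}, n=50, seed=1)
        assert np.all(draws["C"] == 2.3)

    def test_uniform_mean_matches_closed_form(self):
        n = 20_000
        draws = sample_inputs({"C": D.uniform(0, 1)}, n=n, seed=2)["C"]
        se = np.sqrt(1 / 12 / n)
        assert abs(draws.mean() - 0.5) < 3 * se

    def test_lognormal_median_matches_closed_form(self):
        n = 20_000
        draws = sample_inputs({"C": D.lognormal(0.5, 0.4)}, n=n, seed=3)["C"]
        # median SE for a lognormal: sqrt(pi/(2n)) * sigma * median
        med = np.exp(0.5)
        se = np.sqrt(np.pi / (2 * n)) * 0.4 * med
        assert abs(np.median(draws) - med) < 3 * se

    def test_truncation_honored(self):
        spec = D.truncnorm(78, 20, 60, 96)
        draws = sample_inputs({"BW": spec}, n=5000, seed=4)["BW"]
        assert draws.min() >= 60 and draws.max() <= 96
        ln = D.lognormal(0, 1, low=0.5, high=2.0)
        draws = sample_inputs({"C": ln}, n=5000, seed=4)["C"]
        assert draws.min() >= 0.5 and draws.max() <= 2.0

    def test_unsupported_family_rejected(self):
        with pytest.raises(ConfigurationError, match="family"):
            D("beta", (1, 2))

    def test_invalid_parameterizations_rejected(self):
        with pytest.raises(ConfigurationError):
            D.uniform(2, 1)
        with pytest.raises(ConfigurationError):
            D.triangular(1, 0.5, 2)
        with pytest.raises(ConfigurationError):
            D("point", (1.0, 2.0))
        with pytest.raises(ConfigurationError):
            D.truncnorm(1, 0.1, low=2, high=1)

    def test_draws_independent_of_other_inputs_present(self):
        a = sample_inputs({"C": D.uniform(0, 1)}, n=100, seed=9)["C"]
        b = sample_inputs(
            {"C": D.uniform(0, 1), "BW": D.point(15)}, n=100, seed=9
        )["C"]
        np.testing.assert_array_equal(a, b)


class TestSimulation:
    def test_degenerate_distributions_reproduce_deterministic_hq(self):
        dist = simulate_hq(_point_specs(CHILDREN, 3.80), CHILDREN, n=500, seed=5)
        expected = fk.compute_hq(3.80, CHILDREN)
        assert np.all(dist.hq == expected)
        assert dist.percentiles[95.0] == dist.percentiles[50.0] == expected
        assert fk.round_half_up(expected, 2) == 3.29

    def test_uniform_concentration_p95_closed_form(self):
        a, b, n = 1.0, 3.0, 10_000
        specs = {"C": D.uniform(a, b)}
        dist = simulate_hq(specs, CHILDREN, n=n, seed=6)
        k = CHILDREN.IR / (CHILDREN.BW * CHILDREN.RfD)
        expected = k * (a + 0.95 * (b - a))
        # SE of the empirical 95th percentile of a uniform variate
        se = np.sqrt(0.95 * 0.05 / n) * k * (b - a)
        assert abs(dist.percentiles[95.0] - expected) < 3 * se

    def test_percentiles_monotone_and_hq_nonnegative(self, district_sites):
        specs = default_specs(district_sites, TEENAGERS)
        dist = simulate_hq(specs, TEENAGERS, n=2000, seed=7)
        assert (
            dist.percentiles[5.0] <= dist.percentiles[50.0] <= dist.percentiles[95.0]
        )
        assert (dist.hq >= 0).all()

    def test_seed_determinism_bit_identical(self, district_sites):
        specs = default_specs(district_sites, CHILDREN)
        d1 = simulate_hq(specs, CHILDREN, n=1000, seed=8)
        d2 = simulate_hq(specs, CHILDREN, n=1000, seed=8)
        np.testing.assert_array_equal(d1.hq, d2.hq)
        assert d1.percentiles == d2.percentiles

    def test_scaling_concentration_scales_percentiles(self):
        k = 2.5
        base = {"C": D.triangular(1, 2, 3)}
        scaled = {"C": D.triangular(k, 2 * k, 3 * k)}
        d1 = simulate_hq(base, ADULTS, n=4000, seed=9)
        d2 = simulate_hq(scaled, ADULTS, n=4000, seed=9)
        for q in d1.percentiles:
            assert d2.percentiles[q] == pytest.approx(k * d1.percentiles[q], rel=1e-9)

    def test_missing_concentration_spec_rejected(self):
        with pytest.raises(ConfigurationError, match="C"):
            simulate_hq({"BW": D.point(15)}, CHILDREN, n=10, seed=0)

    def test_p95_ordering_across_cohorts(self, district_sites):
        p95 = {}
        for i, cohort in enumerate(fk.DEFAULT_COHORTS):
            specs = default_specs(district_sites, cohort)
            p95[cohort.name] = simulate_hq(
                specs, cohort, n=5000, seed=10 + i
            ).percentiles[95.0]
        assert p95["children"] > p95["teenagers"] > p95["adults"]


class TestSensitivity:
    def test_single_stochastic_input_gets_full_contribution(self):
        specs = {"C": D.uniform(1, 3)}
        rep = sensitivity(specs, CHILDREN, n=2000, seed=11)
        assert rep.contribution_pct["C"] == pytest.approx(100.0)
        assert rep.contribution_pct["BW"] == 0.0

    def test_contributions_sum_to_100(self, district_sites):
        rep = sensitivity(default_specs(district_sites, ADULTS), ADULTS,
                          n=4000, seed=12)
        assert sum(rep.contribution_pct.values()) == pytest.approx(100.0)

    def test_symmetric_inputs_split_contribution_evenly(self):
        # Var(log C) == Var(log BW) makes the multiplicative model symmetric
        specs = {"C": D.lognormal(0.8, 0.2), "BW": D.lognormal(2.7, 0.2)}
        rep = sensitivity(specs, CHILDREN, n=20_000, seed=13)
        assert rep.contribution_pct["C"] == pytest.approx(50.0, abs=3.0)
        assert rep.contribution_pct["BW"] == pytest.approx(50.0, abs=3.0)

    def test_descending_variance_gives_descending_contribution(self):
        specs = {
            "C": D.lognormal(0.8, 0.4),
            "BW": D.lognormal(2.7, 0.2),
            "IR": D.lognormal(-0.25, 0.1),
        }
        rep = sensitivity(specs, CHILDREN, n=10_000, seed=14)
        assert rep.ordering[:3] == ("C", "BW", "IR")

    def test_default_spec_ordering(self, district_sites):
        rep = sensitivity(default_specs(district_sites, CHILDREN), CHILDREN,
                          n=10_000, seed=15)
        assert rep.ordering[:3] == ("C", "BW", "IR")

    def test_all_point_masses_rejected(self):
        with pytest.raises(UsageError, match="point"):
            sensitivity(_point_specs(CHILDREN, 2.3), CHILDREN, n=100, seed=16)


class TestConvergence:
    def test_degenerate_distribution_has_zero_drift(self):
        dist = simulate_hq(_point_specs(ADULTS, 2.3), ADULTS, n=2000, seed=17)
        rep = convergence_check(dist, block=500)
        assert rep.max_relative_drift == 0.0
        assert not rep.flagged

    def test_uniform_p95_drift_is_small(self):
        dist = simulate_hq({"C": D.uniform(1, 3)}, CHILDREN, n=10_000, seed=18)
        rep = convergence_check(dist, block=1000)
        assert rep.max_relative_drift < 0.02

    def test_too_few_iterations_rejected(self):
        dist = simulate_hq({"C": D.uniform(1, 3)}, CHILDREN, n=100, seed=19)
        with pytest.raises(UsageError):
            convergence_check(dist, block=60)
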