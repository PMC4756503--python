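"""Multiplicative odds, tier classification, and exact score distributions."""

import numpy as np
import pytest

from riskdrift import (
    Locus,
    RiskCategory,
    classify,
    control_dist_at_incidence,
    exact_distribution,
    exact_joint_distribution,
    normalize_odds,
    raw_odds,
    score_cohort,
    simulate_genotypes,
)
from riskdrift.cohort import CohortGenotypes

from helpers import brute_force_distribution, brute_force_joint, make_panel, make_snp


class TestRawOdds:
    def test_no_risk_alleles_give_unit_odds(self):
        panel = make_panel([("a", 0.3, 1.5)])
        geno = CohortGenotypes(matrix=np.zeros((4, 1), dtype=np.int8), snp_ids=("a",))
        assert np.allclose(raw_odds(geno, panel), 1.0)

    def test_homozygote_squares_the_or(self):
        panel = make_panel([("a", 0.3, 2.0)])
        geno = CohortGenotypes(matrix=np.array([[2]], dtype=np.int8), snp_ids=("a",))
        assert raw_odds(geno, panel)[0] == pytest.approx(4.0)

    def test_two_snp_product(self):
        panel = make_panel([("a", 0.3, 1.5), ("b", 0.3, 1.2)])
        geno = CohortGenotypes(matrix=np.array([[1, 2]], dtype=np.int8), snp_ids=("a", "b"))
        assert raw_odds(geno, panel)[0] == pytest.approx(1.5 * 1.44)

    def test_missing_panel_snp_named_in_error(self):
        panel = make_panel([("zz", 0.3, 1.5)])
        geno = CohortGenotypes(matrix=np.zeros((1, 1), dtype=np.int8), snp_ids=("a",))
        with pytest.raises(KeyError, match="zz"):
            raw_odds(geno, panel)


class TestNormalizeOdds:
    def test_constant_vector_maps_to_ones(self):
        assert np.allclose(normalize_odds(np.full(3, 7.0)), 1.0)

    def test_two_point_example(self):
        assert np.allclose(normalize_odds(np.array([1.0, 3.0])), [0.5, 1.5])

    def test_output_mean_is_one(self):
        rng = np.random.default_rng(0)
        odds = rng.lognormal(0.0, 1.0, size=1000)
        assert normalize_odds(odds).mean() == pytest.approx(1.0, abs=1e-12)

    def test_empty_vector_rejected(self):
        with pytest.raises(ValueError, match="empty"):
            normalize_odds(np.array([]))


class TestClassify:
    @pytest.mark.parametrize(
        "value,expected",
        [
            (2.5, RiskCategory.HIGHER),
            (2.0, RiskCategory.AVERAGE),
            (0.5, RiskCategory.AVERAGE),
            (0.4, RiskCategory.LOWER),
            (1.0, RiskCategory.AVERAGE),
        ],
    )
    def test_boundaries_fall_in_average(self, value, expected):
        assert classify(np.array([value]))[0] == expected


class TestExactDistribution:
    def test_null_effect_collapses_to_unit_odds(self):
        panel = make_panel([("a", 0.5, 1.0)])
        dist = exact_distribution(panel)
        assert np.allclose(dist.odds, [1.0])
        assert np.allclose(dist.control_pmf, [1.0])
        assert dist.mu_cases == pytest.approx(dist.mu_controls)

    def test_single_snp_case_reweighting(self):
        # q=0.3, OR=2: control genotype probs (0.49, 0.42, 0.09), raw odds
        # (1, 2, 4), mean 1.69; case probs are odds-weighted
        panel = make_panel([("a", 0.3, 2.0)])
        dist = exact_distribution(panel)
        assert np.allclose(dist.control_pmf, [0.49, 0.42, 0.09])
        assert np.allclose(dist.odds, np.array([1.0, 2.0, 4.0]) / 1.69)
        assert np.allclose(dist.case_pmf, [0.49 / 1.69, 0.84 / 1.69, 0.36 / 1.69])

    def test_two_snp_convolution_matches_brute_force(self):
        specs = [(0.3, 2.0), (0.6, 1.4)]
        panel = make_panel([("a", 0.3, 2.0), ("b", 0.6, 1.4)])
        dist = exact_distribution(panel)
        odds, control, case = brute_force_distribution(specs)
        assert np.allclose(np.sort(dist.odds), odds)
        order = np.argsort(dist.odds)
        assert np.allclose(dist.control_pmf[order], control)
        assert np.allclose(dist.case_pmf[order], case)

    def test_state_cap_enforced(self):
        panel = make_panel([(f"s{i}", 0.3, 1.0 + 0.01 * (i + 1)) for i in range(8)])
        with pytest.raises(ValueError, match="Monte-Carlo"):
            exact_distribution(panel, max_states=100)

    def test_or_one_snp_changes_nothing(self):
        base = make_panel([("a", 0.3, 1.5)])
        extended = make_panel([("a", 0.3, 1.5), ("b", 0.4, 1.0)])
        d1, d2 = exact_distribution(base), exact_distribution(extended)
        assert np.allclose(np.sort(d1.odds), np.sort(d2.odds))
        assert d1.sigma_controls == pytest.approx(d2.sigma_controls)

    def test_non_null_snp_strictly_widens_log_odds(self):
        base = make_panel([("a", 0.3, 1.5)])
        extended = make_panel([("a", 0.3, 1.5), ("b", 0.4, 1.2)])
        assert (
            exact_distribution(extended).sigma_controls
            > exact_distribution(base).sigma_controls
        )

    def test_case_distribution_stochastically_dominates(self):
        panel = make_panel([("a", 0.3, 1.8), ("b", 0.5, 1.3)])
        dist = exact_distribution(panel)
        order = np.argsort(dist.odds)
        control_cdf = np.cumsum(dist.control_pmf[order])
        case_cdf = np.cumsum(dist.case_pmf[order])
        assert np.all(case_cdf <= control_cdf + 1e-12)

    def test_monte_carlo_agrees_with_enumeration(self):
        panel = make_panel([("a", 0.3, 1.6), ("b", 0.5, 1.3), ("c", 0.2, 1.4)])
        dist = exact_distribution(panel)
        exact_props = dist.category_proportions()
        n = 100_000
        loci = [
            Locus(locus_id=s.rsid, chromosome=s.chromosome, snps=(s,))
            for s in panel.snps
        ]
        geno = simulate_genotypes(loci, n=n, seed=9)
        profile = score_cohort(geno, panel)
        mc_props = profile.category_proportions()
        for mc, exact in zip(mc_props, exact_props):
            se = np.sqrt(exact * (1 - exact) / n)
            assert abs(mc - exact) < 3 * se + 1e-9


class TestJointDistribution:
    def test_matches_plain_python_enumeration(self):
        union = [("a", 0.3), ("b", 0.6), ("c", 0.2)]
        specs_a = {"a": 1.6, "b": 1.3}
        specs_b = {"a": 1.5, "b": 1.3, "c": 1.4}
        panel_a = make_panel([("a", 0.3, 1.6), ("b", 0.6, 1.3)])
        panel_b = make_panel([("a", 0.3, 1.5), ("b", 0.6, 1.3), ("c", 0.2, 1.4)])
        oa, ob, p = exact_joint_distribution(panel_a, panel_b)
        ref_a, ref_b, ref_p = brute_force_joint(specs_a, specs_b, union)
        # compare moments of the joint law (support orderings differ)
        for moment in (
            lambda x, y, w: w @ x,
            lambda x, y, w: w @ y,
            lambda x, y, w: w @ (x * y),
            lambda x, y, w: w @ (x**2),
        ):
            assert moment(oa, ob, p) == pytest.approx(moment(ref_a, ref_b, ref_p))

    def test_identical_panels_have_identical_margins(self):
        panel = make_panel([("a", 0.3, 1.6), ("b", 0.6, 1.3)])
        oa, ob, p = exact_joint_distribution(panel, panel)
        assert np.allclose(oa, ob)


class TestIncidenceAdjustment:
    def test_zero_incidence_is_identity(self):
        dist = exact_distribution(make_panel([("a", 0.3, 2.0)]))
        assert control_dist_at_incidence(dist, 0.0) is dist

    def test_infeasible_incidence_rejected(self):
        dist = exact_distribution(make_panel([("a", 0.3, 2.0)]))
        # max normalised odds is 4/1.69 ~ 2.37, so c > 0.42 is impossible
        with pytest.raises(ValueError, match="max"):
            control_dist_at_incidence(dist, 0.45)

    def test_closed_form_single_snp(self):
        dist = exact_distribution(make_panel([("a", 0.3, 2.0)]))
        adjusted = control_dist_at_incidence(dist, 0.10)
        odds = np.array([1.0, 2.0, 4.0]) / 1.69
        base = np.array([0.49, 0.42, 0.09])
        c = 0.10  # normalised odds average 1, so c equals the incidence
        expected = (1 - c * odds) * base
        expected /= expected.sum()
        assert np.allclose(adjusted.control_pmf, expected)

    def test_guardrail_small_shift_at_ten_percent(self):
        panel = make_panel([("a", 0.3, 1.6), ("b", 0.5, 1.3), ("c", 0.2, 1.4)])
        dist = exact_distribution(panel)
        adjusted = control_dist_at_incidence(dist, 0.10)
        base_props = dist.category_proportions()
        adj_props = adjusted.category_proportions()
        assert np.all(np.abs(base_props - adj_props) < 0.02)
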