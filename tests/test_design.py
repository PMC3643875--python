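"""Assignment-correlation calculus and the ignorability decision framework."""

import numpy as np
import pytest
from hypothesis import given, settings
from hypothesis import strategies as st

from clustrial.design import (
    ClusteringSourceSpec,
    DesignError,
    RandomisationScheme,
    VarianceDecomposition,
    analytic_assignment_correlation,
    classify_source,
    empirical_assignment_correlation,
)
from clustrial.io import read_design
from clustrial.simulate import generate_pre_randomised


@pytest.mark.parametrize(
    "scheme, expected",
    [
        (RandomisationScheme("cluster_randomised"), 1.0),
        (RandomisationScheme("crossover_2x2"), -1.0),
        (RandomisationScheme("stratified_permuted_blocks", block_size=4), -1.0 / 3.0),
        (RandomisationScheme("stratified_permuted_blocks", block_size=2), -1.0),
        (RandomisationScheme("simple"), 0.0),
    ],
)
def test_analytic_assignment_correlation(scheme, expected):
    assert analytic_assignment_correlation(scheme) == pytest.approx(expected)


@given(block_size=st.integers(min_value=2, max_value=10_000))
@settings(derandomize=True)
def test_block_correlation_always_in_unit_negative_interval(block_size):
    """-1/(n-1) approaches -1 at n=2 and 0 from below as n grows."""
    rho = analytic_assignment_correlation(
        RandomisationScheme("stratified_permuted_blocks", block_size=block_size)
    )
    assert -1.0 <= rho < 0.0
    if block_size > 2:
        prev = analytic_assignment_correlation(
            RandomisationScheme("stratified_permuted_blocks", block_size=block_size - 1)
        )
        assert prev < rho  # strictly increasing toward 0


@pytest.mark.parametrize("bad", [1, 0, -3])
def test_invalid_block_size_rejected(bad):
    with pytest.raises(DesignError):
        RandomisationScheme("stratified_permuted_blocks", block_size=bad)


def test_block_size_only_for_blocks():
    with pytest.raises(DesignError):
        RandomisationScheme("simple", block_size=4)


class TestEmpiricalCorrelation:
    def test_pure_clusters_give_perfect_concordance(self):
        pairs = [(1, 0)] * 3 + [(2, 1)] * 3
        assert empirical_assignment_correlation(pairs) == pytest.approx(1.0)

    def test_blocks_of_two_enumerated(self):
        # both possible orderings of a block of 2; every within-cluster pair discordant
        pairs = [("a", 0), ("a", 1), ("b", 1), ("b", 0)]
        assert empirical_assignment_correlation(pairs) == pytest.approx(-1.0)

    def test_simple_randomisation_near_zero(self):
        rng = np.random.default_rng(42)
        arms = (rng.random(10_000) < 0.5).astype(int)
        clusters = rng.integers(0, 10, size=10_000)
        rho = empirical_assignment_correlation(zip(clusters, arms))
        assert abs(rho) < 0.03

    def test_matches_analytic_for_each_scheme(self):
        """Empirical pairwise estimator agrees with the closed forms within 3 SE."""
        rng = np.random.default_rng(7)
        # cluster randomised: exact +1
        arms = np.repeat(rng.permutation([0, 1] * 10), 5)
        clusters = np.repeat(np.arange(20), 5)
        assert empirical_assignment_correlation(zip(clusters, arms)) == pytest.approx(1.0)
        # 2x2 crossover: exact -1 (each patient = a cluster of two opposite-arm periods)
        first = rng.integers(0, 2, size=50)
        pairs = [(i, a) for i, f in enumerate(first) for a in (f, 1 - f)]
        assert empirical_assignment_correlation(pairs) == pytest.approx(-1.0)
        # stratified blocks of 4, one block per stratum, 1000 strata pooled:
        # the pairwise estimator's O(1/N) plug-in bias is negligible at this size
        a, c = generate_pre_randomised(1000, 4, 4, seed=99)
        assert empirical_assignment_correlation(zip(c, a)) == pytest.approx(-1.0 / 3.0, abs=0.02)
        # simple randomisation, 100k patients pooled
        r = np.random.default_rng(2024)
        arms = (r.random(100_000) < 0.5).astype(int)
        clusters = r.integers(0, 1000, size=100_000)
        assert empirical_assignment_correlation(zip(clusters, arms)) == pytest.approx(0.0, abs=0.01)

    def test_no_pairs_error(self):
        with pytest.raises(DesignError, match="no pairs"):
            empirical_assignment_correlation([(1, 0), (2, 1)])

    def test_degenerate_arms_error(self):
        with pytest.raises(DesignError, match="degenerate arms"):
            empirical_assignment_correlation([(1, 1), (1, 1), (2, 1)])


class TestClassifySource:
    def test_zero_icc_always_ignorable(self):
        spec = ClusteringSourceSpec(
            "ward", "post_randomisation", icc_assumption="zero", arm_assignment="single_arm"
        )
        v = classify_source(spec)
        assert v.status == "ignorable"
        assert v.se_bias_direction == "none"
        assert v.type1_consequence == "valid"

    def test_unknown_icc_treated_as_nonzero(self):
        spec = ClusteringSourceSpec(
            "class", "post_randomisation", icc_assumption="unknown", arm_assignment="single_arm"
        )
        assert classify_source(spec).status == "non_ignorable"

    @pytest.mark.parametrize("icc", ["nonzero", "unknown"])
    @pytest.mark.parametrize("timing, extra", [
        ("pre_randomisation", {"used_in_randomisation": False}),
        ("pre_randomisation", {"used_in_randomisation": True}),
        ("pre_randomisation", {"used_in_randomisation": True, "balancing": "other"}),
        ("post_randomisation", {"arm_assignment": "equal_probability"}),
        ("post_randomisation", {"arm_assignment": "unequal_probability"}),
        ("post_randomisation", {"arm_assignment": "single_arm"}),
    ])
    def test_lattice_verdicts_follow_the_two_correlation_rule(self, icc, timing, extra):
        """Non-ignorable iff ICC non-zero AND assignment correlation non-zero."""
        spec = ClusteringSourceSpec("src", timing, icc_assumption=icc, **extra)
        v = classify_source(spec)
        corr_zero = (
            extra.get("used_in_randomisation") is False
            or extra.get("arm_assignment") == "equal_probability"
        )
        if corr_zero:
            assert v.status == "ignorable"
            assert (v.se_bias_direction, v.type1_consequence) == ("none", "valid")
            assert v.assignment_correlation_sign == "zero"
        else:
            assert v.status == "non_ignorable"
            if v.assignment_correlation_sign == "positive":
                assert (v.se_bias_direction, v.type1_consequence) == ("downward", "inflated")
            elif v.assignment_correlation_sign == "negative":
                assert (v.se_bias_direction, v.type1_consequence) == ("upward", "conservative")
            else:
                assert extra.get("balancing") == "other"
        # deterministic
        assert classify_source(spec) == v

    def test_faster_case_study_golden(self, fixtures):
        """Centre ignorable; surgeon & surgery type conservative; rehab class inflated."""
        specs = read_design(fixtures["design"])
        verdicts = {s.name: classify_source(s) for s in specs}
        assert verdicts["recruiting centre"].status == "ignorable"
        assert verdicts["surgeon"].status == "non_ignorable"
        assert verdicts["surgeon"].type1_consequence == "conservative"
        assert verdicts["type of surgery"].status == "non_ignorable"
        assert verdicts["type of surgery"].type1_consequence == "conservative"
        assert verdicts["rehabilitation class"].status == "non_ignorable"
        assert verdicts["rehabilitation class"].type1_consequence == "inflated"
        assert sum(v.status == "non_ignorable" for v in verdicts.values()) == 3

    @pytest.mark.parametrize("kwargs", [
        dict(timing="pre_randomisation"),  # missing used_in_randomisation
        dict(timing="post_randomisation"),  # missing arm_assignment
        dict(timing="pre_randomisation", used_in_randomisation=True, arm_assignment="single_arm"),
        dict(timing="post_randomisation", arm_assignment="single_arm", used_in_randomisation=True),
        dict(timing="mid_randomisation", used_in_randomisation=True),
        dict(timing="post_randomisation", arm_assignment="sometimes"),
    ])
    def test_spec_invariants_enforced(self, kwargs):
        with pytest.raises(DesignError):
            ClusteringSourceSpec("bad", **kwargs)


def test_variance_decomposition_total_consistency():
    vd = VarianceDecomposition(v0=0.04, ve=-0.01)
    assert vd.total == pytest.approx(0.03)
    with pytest.raises(DesignError):
        VarianceDecomposition(v0=0.04, ve=-0.01, total=0.05)
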