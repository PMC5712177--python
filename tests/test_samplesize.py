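"""Tests for the analytic sample-size calculations."""

import math

import pytest
from hypothesis import given, settings, strategies as st

from mediansize import (
    ClusterSpec,
    DegenerateDesignError,
    DesignSpec,
    GroupSpec,
    InvalidParameterError,
    LOG_EXPONENTIAL_VARIANCE,
    NoDetectableDifferenceError,
    design_effect,
    inflate_for_clustering,
    n_exponential,
    n_exponential_naive,
    n_from_log_variances,
    n_lognormal,
    n_unequal_allocation,
)

from conftest import TABLE1_REFERENCE, TABLE2_REFERENCE, TABLE3_REFERENCE


class TestPublishedSampleSizes:
    @pytest.mark.parametrize(
        "m1, m2, phi1, phi2, power, n_expected",
        [row[:6] for row in TABLE1_REFERENCE],
    )
    def test_lognormal_rows(self, m1, m2, phi1, phi2, power, n_expected):
        design = DesignSpec(alpha=0.05, power=power)
        result = n_lognormal(GroupSpec(m1, phi1), GroupSpec(m2, phi2), design)
        assert result.n_per_group == n_expected
        assert result.method_tag == "lognormal_eq4"

    @pytest.mark.parametrize(
        "m1, m2, n_expected", [row[:3] for row in TABLE2_REFERENCE]
    )
    def test_exponential_naive_rows(self, m1, m2, n_expected, design_90):
        result = n_exponential_naive(m1, m2, design_90)
        assert result.n_per_group == n_expected
        # the mis-specified log-scale variance is the same constant for
        # every median: log(1/2 + sqrt(1/4 + 1/log^2 2)) ~ 0.7065
        assert result.sigma_sq_1 == pytest.approx(0.7065, abs=5e-5)
        assert result.sigma_sq_2 == pytest.approx(0.7065, abs=5e-5)
        assert "under-sizes" in result.note

    @pytest.mark.parametrize(
        "m1, m2, n_expected", [row[:3] for row in TABLE3_REFERENCE]
    )
    def test_exponential_corrected_rows(self, m1, m2, n_expected, design_90):
        result = n_exponential(m1, m2, design_90)
        assert result.n_per_group == n_expected
        assert result.method_tag == "exponential_eq5"

    def test_exponential_equals_explicit_log_variances(self, design_90):
        """The corrected exponential formula is the generic log-scale
        formula at sigma^2 = pi^2/6 in both groups, exactly."""
        a = n_exponential(80, 70, design_90)
        b = n_from_log_variances(
            LOG_EXPONENTIAL_VARIANCE,
            LOG_EXPONENTIAL_VARIANCE,
            math.log(80) - math.log(70),
            design_90,
        )
        assert a.n_continuous == b.n_continuous
        assert a.n_per_group == b.n_per_group


class TestWorkedExample:
    """SEEG electrode-placement trial: medians 20 vs 16 min, SDs 5, 90%
    power at the 5% level with the rounded quantiles 1.96/1.28."""

    def test_continuous_n(self):
        design = DesignSpec(
            alpha=0.05, power=0.9, z_alpha_half_override=1.96, z_beta_override=1.28
        )
        result = n_lognormal(GroupSpec(20, 5), GroupSpec(16, 5), design)
        assert round(result.n_continuous, 2) == 30.18
        assert result.n_per_group == 31

    def test_pad_option_adds_subjects(self):
        design = DesignSpec(
            alpha=0.05, power=0.9, z_alpha_half_override=1.96, z_beta_override=1.28
        )
        result = n_lognormal(GroupSpec(20, 5), GroupSpec(16, 5), design, pad=1)
        assert result.n_per_group == 32
        assert result.small_sample_pad == 1

    def test_design_effect_and_inflation(self):
        cluster = ClusterSpec(icc=0.2, avg_cluster_size=10)
        assert design_effect(cluster) == pytest.approx(2.8)
        n_units, n_clusters = inflate_for_clustering(32, cluster)
        assert (n_units, n_clusters) == (90, 9)

    def test_exact_quantiles_differ_slightly(self):
        # with full-precision quantiles the continuous n moves a little;
        # the overrides exist to reproduce the rounded-quantile value
        design = DesignSpec(alpha=0.05, power=0.9)
        result = n_lognormal(GroupSpec(20, 5), GroupSpec(16, 5), design)
        assert round(result.n_continuous, 2) == 30.21
        assert result.n_per_group == 31


class TestClustering:
    def test_no_clustering_is_identity(self):
        cluster = ClusterSpec(icc=0.0, avg_cluster_size=10)
        assert design_effect(cluster) == 1.0
        assert inflate_for_clustering(32, cluster) == (32, 4)

    def test_singleton_clusters_are_identity(self):
        cluster = ClusterSpec(icc=0.3, avg_cluster_size=1)
        assert design_effect(cluster) == 1.0
        assert inflate_for_clustering(17, cluster) == (17, 17)

    @pytest.mark.parametrize(
        "icc, size", [(-0.1, 10), (1.0, 10), (0.2, 0.5)]
    )
    def test_invalid_cluster_spec_rejected(self, icc, size):
        with pytest.raises(InvalidParameterError):
            ClusterSpec(icc=icc, avg_cluster_size=size)

    def test_invalid_n_rejected(self):
        with pytest.raises(InvalidParameterError):
            inflate_for_clustering(0, ClusterSpec(icc=0.2, avg_cluster_size=10))


class TestGuards:
    def test_equal_medians_rejected(self, design_90):
        with pytest.raises(NoDetectableDifferenceError, match="medians must differ"):
            n_lognormal(GroupSpec(5, 1), GroupSpec(5, 2), design_90)
        with pytest.raises(NoDetectableDifferenceError):
            n_exponential(5, 5, design_90)

    def test_zero_tau_rejected(self, design_90):
        with pytest.raises(NoDetectableDifferenceError):
            n_from_log_variances(0.5, 0.5, 0.0, design_90)

    def test_doubly_degenerate_rejected(self, design_90):
        with pytest.raises(DegenerateDesignError):
            n_from_log_variances(0.0, 0.0, math.log(2), design_90)
        with pytest.raises(DegenerateDesignError):
            n_lognormal(GroupSpec(1, 0), GroupSpec(2, 0), design_90)

    def test_minimum_two_per_group(self, design_90):
        # huge effect, tiny variance: the formula gives n < 1 but a
        # t-test needs two observations per arm
        result = n_lognormal(GroupSpec(1, 0.01), GroupSpec(100, 0.01), design_90)
        assert result.n_per_group == 2
        assert result.n_per_group == math.ceil(result.n_continuous) + result.small_sample_pad

    def test_invalid_design_rejected(self):
        for kwargs in (
            {"alpha": 0.0},
            {"alpha": 1.0},
            {"power": 0.0},
            {"power": 1.5},
            {"z_alpha_half_override": -1.96},
        ):
            with pytest.raises(InvalidParameterError):
                DesignSpec(**{"alpha": 0.05, "power": 0.9, **kwargs})


class TestUnequalAllocation:
    def test_ratio_one_matches_equal_allocation(self, design_80):
        g1, g2 = GroupSpec(1, 0.5), GroupSpec(1.5, 0.5)
        eq = n_lognormal(g1, g2, design_80)
        un = n_unequal_allocation(g1, g2, design_80, ratio=1.0)
        assert un.n1_continuous == pytest.approx(eq.n_continuous, rel=1e-12)
        assert un.n2_continuous == pytest.approx(eq.n_continuous, rel=1e-12)
        assert un.n1 == un.n2 == 14

    @settings(max_examples=50, deadline=None)
    @given(ratio=st.floats(min_value=0.1, max_value=10))
    def test_continuous_sizes_respect_ratio(self, ratio):
        un = n_unequal_allocation(
            GroupSpec(1, 0.5), GroupSpec(1.5, 0.5), DesignSpec(), ratio=ratio
        )
        assert un.n2_continuous / un.n1_continuous == pytest.approx(ratio, rel=1e-9)

    def test_equal_allocation_minimises_total_for_equal_variances(self, design_90):
        """With sigma1 = sigma2, k = 1 minimises n1 + n2 (brute force)."""
        g1, g2 = GroupSpec(1, 0.5), GroupSpec(2, 1.0)  # equal CV => equal sigma^2
        totals = {
            k: sum(
                n_unequal_allocation(g1, g2, design_90, ratio=k)[2:]
            )
            for k in [0.25, 0.5, 0.75, 1.0, 1.5, 2.0, 4.0]
        }
        assert min(totals, key=totals.get) == 1.0

    def test_invalid_ratio_rejected(self, design_90):
        with pytest.raises(InvalidParameterError):
            n_unequal_allocation(GroupSpec(1, 0.5), GroupSpec(1.5, 0.5), design_90, 0.0)


class TestFormulaProperties:
    @settings(max_examples=100, deadline=None)
    @given(
        m2=st.floats(min_value=0.1, max_value=10).filter(lambda m: abs(m - 1) > 0.05),
        phi1=st.floats(min_value=0.01, max_value=5),
        phi2=st.floats(min_value=0.01, max_value=5),
    )
    def test_symmetric_in_group_order(self, m2, phi1, phi2):
        design = DesignSpec(alpha=0.05, power=0.9)
        a = n_lognormal(GroupSpec(1.0, phi1), GroupSpec(m2, phi2), design)
        b = n_lognormal(GroupSpec(m2, phi2), GroupSpec(1.0, phi1), design)
        assert a.n_continuous == b.n_continuous
        assert a.n_per_group == b.n_per_group

    def test_tau_scaling_homogeneity(self, design_90):
        """Scaling tau by c scales the continuous n by 1/c^2."""
        v = 0.3
        base = n_from_log_variances(v, v, 0.2, design_90)
        scaled = n_from_log_variances(v, v, 0.4, design_90)
        assert scaled.n_continuous == pytest.approx(base.n_continuous / 4, rel=1e-12)

    def test_monotone_in_design_parameters(self):
        g1, g2 = GroupSpec(1, 0.5), GroupSpec(1.25, 0.5)
        n_low = n_lognormal(g1, g2, DesignSpec(alpha=0.05, power=0.8)).n_continuous
        n_high = n_lognormal(g1, g2, DesignSpec(alpha=0.05, power=0.9)).n_continuous
        assert n_high > n_low
        n_strict = n_lognormal(g1, g2, DesignSpec(alpha=0.01, power=0.8)).n_continuous
        assert n_strict > n_low

    def test_monotone_in_raw_sds_and_effect(self, design_90):
        base = n_lognormal(GroupSpec(1, 0.5), GroupSpec(1.25, 0.5), design_90)
        wider = n_lognormal(GroupSpec(1, 0.7), GroupSpec(1.25, 0.5), design_90)
        assert wider.n_continuous > base.n_continuous
        closer = n_lognormal(GroupSpec(1, 0.5), GroupSpec(1.1, 0.5), design_90)
        assert closer.n_continuous > base.n_continuous

    def test_swapping_exponential_medians_preserves_n(self, design_90):
        assert (
            n_exponential(0.1, 0.3, design_90).n_per_group
            == n_exponential(0.3, 0.1, design_90).n_per_group
        )
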