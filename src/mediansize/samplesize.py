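"""Per-group sample sizes for a two-group comparison of medians.

The planned analysis is a two-sample t-test of log-transformed outcomes,
so the classical normal-approximation formula applies on the log scale:

    n = (sigma_1^2 + sigma_2^2) (z_{alpha/2} + z_beta)^2 / tau^2

with tau = log(m1) - log(m2) the log-median difference and sigma_j^2 the
log-scale variances.  For log-normal outcomes sigma_j^2 comes from the
untransformed (median, SD) pair via the closed-form conversion in
:mod:`mediansize.distributions`; for exponential outcomes the correct
log-scale variance is the constant pi^2/6.  A deliberately mis-specified
variant (treating exponential data as log-normal) is provided because it
quantifies how badly the log-normal formula under-sizes in that case.

Cluster designs are handled through the usual design effect
1 + ICC (m - 1) applied to the rounded per-group n.
"""

from __future__ import annotations

import math
from dataclasses import dataclass, field, asdict
from typing import NamedTuple

from scipy.stats import norm

from .distributions import (
    GroupSpec,
    LOG_EXPONENTIAL_VARIANCE,
    log_scale_mean,
    log_scale_variance,
)
from .errors import (
    DegenerateDesignError,
    InvalidParameterError,
    NoDetectableDifferenceError,
)

__all__ = [
    "DesignSpec",
    "SampleSizeResult",
    "ClusterSpec",
    "UnequalAllocation",
    "n_from_log_variances",
    "n_lognormal",
    "n_exponential",
    "n_exponential_naive",
    "design_effect",
    "inflate_for_clustering",
    "n_unequal_allocation",
]

#: Smallest per-group n ever returned: a two-sample t-test needs at least
#: two observations per arm.
MIN_N_PER_GROUP = 2


@dataclass(frozen=True)
class DesignSpec:
    """Significance level, target power and (optional) quantile overrides.

    alpha is the two-sided significance level.  By default the standard
    normal upper quantiles z_{alpha/2} and z_beta are computed in full
    double precision; the overrides substitute externally rounded values
    (e.g. 1.96 and 1.28) verbatim.
    """

    alpha: float = 0.05
    power: float = 0.9
    z_alpha_half_override: float | None = None
    z_beta_override: float | None = None

    def __post_init__(self) -> None:
        if not 0 < self.alpha < 1:
            raise InvalidParameterError(f"alpha must be in (0, 1); got {self.alpha!r}")
        if not 0 < self.power < 1:
            raise InvalidParameterError(f"power must be in (0, 1); got {self.power!r}")
        for name in ("z_alpha_half_override", "z_beta_override"):
            v = getattr(self, name)
            if v is not None and not v > 0:
                raise InvalidParameterError(f"{name} must be positive; got {v!r}")

    @property
    def z_alpha_half(self) -> float:
        """Upper alpha/2 standard-normal quantile (or its override)."""
        if self.z_alpha_half_override is not None:
            return self.z_alpha_half_override
        return float(norm.isf(self.alpha / 2.0))

    @property
    def z_beta(self) -> float:
        """Upper beta standard-normal quantile (or its override)."""
        if self.z_beta_override is not None:
            return self.z_beta_override
        return float(norm.isf(1.0 - self.power))


@dataclass(frozen=True)
class SampleSizeResult:
    """Continuous and rounded per-group n with all intermediate quantities.

    n_per_group = ceil(n_continuous) + small_sample_pad, where
    small_sample_pad is the number of subjects actually added (requested
    padding plus any clamp up to the two-per-arm minimum).
    """

    n_continuous: float
    n_per_group: int
    sigma_sq_1: float
    sigma_sq_2: float
    tau: float
    small_sample_pad: int
    method_tag: str
    note: str = ""

    def to_dict(self) -> dict:
        return asdict(self)


@dataclass(frozen=True)
class ClusterSpec:
    """Intra-class correlation and average cluster size for a clustered design."""

    icc: float
    avg_cluster_size: float

    def __post_init__(self) -> None:
        if not 0 <= self.icc < 1:
            raise InvalidParameterError(f"icc must be in [0, 1); got {self.icc!r}")
        if not self.avg_cluster_size >= 1:
            raise InvalidParameterError(
                f"avg_cluster_size must be >= 1; got {self.avg_cluster_size!r}"
            )


class UnequalAllocation(NamedTuple):
    """Group sizes for allocation ratio k = n2/n1 (continuous and rounded)."""

    n1: int
    n2: int
    n1_continuous: float
    n2_continuous: float


def n_from_log_variances(
    sigma_sq_1: float,
    sigma_sq_2: float,
    tau: float,
    design: DesignSpec,
    pad: int = 0,
    method_tag: str = "explicit_log_variances",
    note: str = "",
) -> SampleSizeResult:
    """Per-group n from log-scale variances and log-median difference tau.

    n_continuous = (sigma_1^2 + sigma_2^2)(z_{alpha/2} + z_beta)^2 / tau^2,
    rounded up to the next integer, plus ``pad`` extra subjects per group
    (advisable for small n, where normal quantiles slightly understate
    the t-test requirement).
    """
    if sigma_sq_1 < 0 or sigma_sq_2 < 0:
        raise InvalidParameterError(
            f"log-scale variances must be non-negative; got {sigma_sq_1!r}, {sigma_sq_2!r}"
        )
    if sigma_sq_1 == 0 and sigma_sq_2 == 0:
        raise DegenerateDesignError(
            "both log-scale variances are zero: outcomes are constant in "
            "both groups and the sample-size formula degenerates"
        )
    if tau == 0:
        raise NoDetectableDifferenceError(
            "medians must differ: the log-median difference tau is zero, "
            "so no finite sample size can detect the (null) difference"
        )
    if pad < 0:
        raise InvalidParameterError(f"pad must be non-negative; got {pad!r}")

    z_sum = design.z_alpha_half + design.z_beta
    n_continuous = (sigma_sq_1 + sigma_sq_2) * z_sum**2 / tau**2
    base = math.ceil(n_continuous)
    n_per_group = max(MIN_N_PER_GROUP, base + pad)
    return SampleSizeResult(
        n_continuous=n_continuous,
        n_per_group=n_per_group,
        sigma_sq_1=sigma_sq_1,
        sigma_sq_2=sigma_sq_2,
        tau=tau,
        small_sample_pad=n_per_group - base,
        method_tag=method_tag,
        note=note,
    )


def n_lognormal(
    group1: GroupSpec, group2: GroupSpec, design: DesignSpec, pad: int = 0
) -> SampleSizeResult:
    """Per-group n for log-normal outcomes specified by median and raw SD.

    Converts each arm's (median, SD) to its log-scale variance, forms
    tau = log(m1) - log(m2), and applies the log-scale formula.
    Symmetric in the two groups.
    """
    if group1.median == group2.median:
        raise NoDetectableDifferenceError(
            "medians must differ: both groups have median "
            f"{group1.median!r}, so tau = 0 and n is infinite"
        )
    tau = log_scale_mean(group1) - log_scale_mean(group2)
    return n_from_log_variances(
        log_scale_variance(group1),
        log_scale_variance(group2),
        tau,
        design,
        pad=pad,
        method_tag="lognormal_eq4",
    )


def n_exponential(
    median1: float, median2: float, design: DesignSpec, pad: int = 0
) -> SampleSizeResult:
    """Per-group n for exponential outcomes, using the correct log-scale
    variance pi^2/6 for both groups."""
    _check_exp_medians(median1, median2)
    return n_from_log_variances(
        LOG_EXPONENTIAL_VARIANCE,
        LOG_EXPONENTIAL_VARIANCE,
        math.log(median1) - math.log(median2),
        design,
        pad=pad,
        method_tag="exponential_eq5",
    )


def n_exponential_naive(
    median1: float, median2: float, design: DesignSpec, pad: int = 0
) -> SampleSizeResult:
    """The log-normal formula mis-applied to exponential outcomes.

    An Exp(rate) outcome with median m has SD m/log(2); feeding that
    (median, SD) pair through the log-normal conversion gives the
    constant log-scale variance log(1/2 + sqrt(1/4 + 1/log^2 2)) ~ 0.7065
    for every median — less than half the true value pi^2/6 ~ 1.645 — so
    the resulting n under-powers the study.  Provided to quantify that
    failure mode, not for design use.
    """
    _check_exp_medians(median1, median2)
    g1 = GroupSpec(median=median1, raw_sd=median1 / math.log(2))
    g2 = GroupSpec(median=median2, raw_sd=median2 / math.log(2))
    result = n_lognormal(g1, g2, design, pad=pad)
    return SampleSizeResult(
        **{
            **result.to_dict(),
            "note": (
                "log-normal formula applied to exponential data: the implied "
                "log-scale variance 0.7065 understates the true pi^2/6, so "
                "this n under-sizes the study"
            ),
        }
    )


def _check_exp_medians(median1: float, median2: float) -> None:
    if not (median1 > 0 and median2 > 0):
        raise InvalidParameterError(
            f"medians must be positive; got {median1!r}, {median2!r}"
        )
    if median1 == median2:
        raise NoDetectableDifferenceError(
            "medians must differ: tau = 0 gives an infinite sample size"
        )


def design_effect(cluster: ClusterSpec) -> float:
    """Variance-inflation factor 1 + ICC (m - 1) for clusters of average size m."""
    return 1.0 + cluster.icc * (cluster.avg_cluster_size - 1.0)


def inflate_for_clustering(
    n_per_group: int, cluster: ClusterSpec
) -> tuple[int, int]:
    """Inflate a per-group n for within-cluster correlation.

    Returns ``(n_units, n_clusters)`` per group: the rounded per-group n
    multiplied by the design effect and re-ceiled, and the number of
    clusters needed to supply that many units at the average cluster
    size.
    """
    if n_per_group < 1:
        raise InvalidParameterError(
            f"n_per_group must be >= 1; got {n_per_group!r}"
        )
    n_units = math.ceil(n_per_group * design_effect(cluster))
    n_clusters = math.ceil(n_units / cluster.avg_cluster_size)
    return n_units, n_clusters


def n_unequal_allocation(
    group1: GroupSpec, group2: GroupSpec, design: DesignSpec, ratio: float
) -> UnequalAllocation:
    """Standard allocation-ratio extension of the log-normal formula.

    For ratio k = n2/n1,

        n1 = (sigma_1^2 + sigma_2^2 / k)(z_{alpha/2} + z_beta)^2 / tau^2,
        n2 = k n1,

    each then rounded up.  ratio = 1 reproduces the equal-allocation
    continuous n in both groups.  This is the usual textbook adjustment,
    provided as a convenience extension of the equal-allocation method.
    """
    if not ratio > 0:
        raise InvalidParameterError(f"ratio must be positive; got {ratio!r}")
    if group1.median == group2.median:
        raise NoDetectableDifferenceError(
            "medians must differ: tau = 0 gives an infinite sample size"
        )
    s1 = log_scale_variance(group1)
    s2 = log_scale_variance(group2)
    if s1 == 0 and s2 == 0:
        raise DegenerateDesignError(
            "both log-scale variances are zero: degenerate design"
        )
    tau = log_scale_mean(group1) - log_scale_mean(group2)
    z_sum = design.z_alpha_half + design.z_beta
    n1_cont = (s1 + s2 / ratio) * z_sum**2 / tau**2
    n2_cont = ratio * n1_cont
    n1 = max(MIN_N_PER_GROUP, math.ceil(n1_cont))
    n2 = max(MIN_N_PER_GROUP, math.ceil(n2_cont))
    return UnequalAllocation(n1=n1, n2=n2, n1_continuous=n1_cont, n2_continuous=n2_cont)
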