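"""Distributional identities for log-normal and exponential outcomes.

A positive outcome T is log-normal when log(T) ~ N(mu, sigma^2).  Two
facts make medians convenient design inputs for such outcomes:

* the population median equals exp(mu), i.e. the geometric mean, so the
  log-scale mean is simply the log of the untransformed median;
* the log-scale variance sigma^2 is recoverable in closed form from the
  median m and the untransformed variance phi^2:

      sigma^2 = log(1/2 + sqrt(1/4 + phi^2 / m^2)).

This module houses those conversions, their inverses (used as round-trip
oracles), and the exponential-distribution facts needed by the
sensitivity analysis: an Exp(lambda) variable has median log(2)/lambda,
standard deviation 1/lambda, and Var[log X] = pi^2/6 regardless of the
rate.
"""

from __future__ import annotations

import math
from dataclasses import dataclass

from .errors import InvalidParameterError

__all__ = [
    "GroupSpec",
    "LogScaleParams",
    "ExponentialSpec",
    "LOG_EXPONENTIAL_VARIANCE",
    "log_scale_mean",
    "log_scale_variance",
    "log_scale_params",
    "raw_variance_from_log",
    "lognormal_mean",
    "exponential_from_median",
    "log_exponential_variance",
]

#: Variance of log(X) for X ~ Exp(lambda), any rate: pi^2 / 6.
LOG_EXPONENTIAL_VARIANCE = math.pi**2 / 6


@dataclass(frozen=True)
class GroupSpec:
    """One arm's outcome summary on the untransformed scale.

    Parameters
    ----------
    median
        Anticipated population median of the outcome, in outcome units
        (e.g. minutes).  Must be strictly positive.
    raw_sd
        Anticipated standard deviation of the *untransformed* outcome,
        same units.  Zero is admitted and denotes a degenerate
        (constant) outcome.
    label
        Optional group name used in error messages and reports.
    """

    median: float
    raw_sd: float
    label: str = ""

    def __post_init__(self) -> None:
        name = f" for group {self.label!r}" if self.label else ""
        if not self.median > 0:
            raise InvalidParameterError(
                f"median must be positive{name}; got {self.median!r} "
                "(the log-scale mean log(median) is undefined otherwise)"
            )
        if self.raw_sd < 0:
            raise InvalidParameterError(
                f"raw_sd must be non-negative{name}; got {self.raw_sd!r}"
            )


@dataclass(frozen=True)
class LogScaleParams:
    """Log-scale mean/variance pair (mu, sigma^2) for one arm.

    exp(mu) is the median of the implied log-normal distribution.
    """

    mu: float
    sigma_sq: float

    def __post_init__(self) -> None:
        if self.sigma_sq < 0:
            raise InvalidParameterError(
                f"sigma_sq must be non-negative; got {self.sigma_sq!r}"
            )


@dataclass(frozen=True)
class ExponentialSpec:
    """Rate/median pair for an Exp(rate) outcome; median * rate = log 2."""

    rate: float
    median: float

    def __post_init__(self) -> None:
        if not self.rate > 0:
            raise InvalidParameterError(f"rate must be positive; got {self.rate!r}")
        if not math.isclose(self.median * self.rate, math.log(2), rel_tol=1e-9):
            raise InvalidParameterError(
                "inconsistent ExponentialSpec: median * rate must equal log(2); "
                f"got {self.median * self.rate!r}"
            )


def log_scale_mean(spec: GroupSpec) -> float:
    """Log-scale mean mu = log(median).

    For a log-normal outcome the population median equals the geometric
    mean exp(mu), so the log-scale mean is the natural log of the
    untransformed median.
    """
    return math.log(spec.median)


def log_scale_variance(spec: GroupSpec) -> float:
    """Log-scale variance implied by an untransformed (median, SD) pair.

    sigma^2 = log(1/2 + sqrt(1/4 + raw_sd^2 / median^2)).  Depends on the
    inputs only through the coefficient of variation raw_sd/median; zero
    iff raw_sd is zero.
    """
    ratio_sq = (spec.raw_sd / spec.median) ** 2
    # log1p of the exact rearrangement r / (1/2 + sqrt(1/4 + r)) avoids
    # cancellation when the coefficient of variation is small
    return math.log1p(ratio_sq / (0.5 + math.sqrt(0.25 + ratio_sq)))


def log_scale_params(spec: GroupSpec) -> LogScaleParams:
    """Both log-scale parameters for one arm."""
    return LogScaleParams(mu=log_scale_mean(spec), sigma_sq=log_scale_variance(spec))


def raw_variance_from_log(params: LogScaleParams) -> float:
    """Untransformed variance of logN(mu, sigma^2): m^2 x (x - 1), x = exp(sigma^2).

    Inverse of :func:`log_scale_variance`; used as the round-trip oracle
    for the median/SD -> log-scale conversion.
    """
    m = math.exp(params.mu)
    # x (x - 1) with x = exp(sigma^2), via expm1 for small variances
    return m * m * math.exp(params.sigma_sq) * math.expm1(params.sigma_sq)


def lognormal_mean(spec: GroupSpec) -> float:
    """Untransformed population mean median * exp(sigma^2 / 2).

    Always >= the median (equality iff raw_sd = 0); the gap explains why
    a t-test of untransformed outcomes can reject even when medians are
    equal but spreads differ.
    """
    return spec.median * math.exp(log_scale_variance(spec) / 2.0)


def exponential_from_median(median: float) -> ExponentialSpec:
    """Exp(rate) spec with the given median: rate = log(2) / median."""
    if not median > 0:
        raise InvalidParameterError(
            f"median must be positive; got {median!r}"
        )
    return ExponentialSpec(rate=math.log(2) / median, median=median)


def log_exponential_variance() -> float:
    """Variance of log X for X exponential: pi^2/6, independent of the rate."""
    return LOG_EXPONENTIAL_VARIANCE
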