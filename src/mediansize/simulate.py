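"""Monte-Carlo power verification for the median-based sample sizes.

For a scenario defined by two groups' (median, raw SD) pairs and a
per-group n, the engine repeatedly draws two samples — from the implied
log-normal distributions, or from exponential distributions matched on
the medians — and applies three two-sided tests:

* a two-sample t-test on log-transformed values (the planned analysis),
* a Mann-Whitney U test on untransformed values,
* a two-sample t-test on untransformed values.

Power is estimated as the rejection proportion over the replicates, with
a binomial Monte-Carlo standard error sqrt(p(1-p)/N).

Reproducibility: every replicate draws from a fresh generator keyed by
(scenario seed, replicate index, group), so a scenario's results are
bit-identical across runs and insensitive to the order in which
replicates are evaluated.

t-test p-values use the pooled-variance (Student) form by default, with
a Welch option.  The Mann-Whitney p-value uses exact enumeration of the
null U distribution when both samples have fewer than 50 observations
(the usual software default for untied data) and the continuity-corrected
normal approximation otherwise; ties have probability zero for these
continuous families.
"""

from __future__ import annotations

import math
from dataclasses import dataclass
from functools import lru_cache

import numpy as np
import pandas as pd
from scipy import stats

from .distributions import GroupSpec, log_scale_mean, log_scale_variance
from .errors import InvalidParameterError
from .samplesize import (
    DesignSpec,
    n_exponential,
    n_exponential_naive,
    n_lognormal,
)

__all__ = [
    "SimulationScenario",
    "PowerEstimates",
    "draw_two_group_sample",
    "run_three_tests",
    "estimate_power",
    "replicate_table",
    "TABLE1_SCENARIOS",
    "EXPONENTIAL_SCENARIOS",
]

FAMILIES = ("lognormal", "exponential")

#: Replicates used in the reference study design.
DEFAULT_N_REPS = 100_000

# Study grid for the log-normal simulations: (m1, m2, phi1, phi2, power),
# twelve scenarios at 80% power and twelve at 90%, all at alpha = 0.05.
TABLE1_SCENARIOS: list[tuple[float, float, float, float, float]] = [
    (1, 1.5, 0.5, 0.5, 0.8),
    (1, 1.25, 0.5, 0.5, 0.8),
    (1, 1.1, 0.5, 0.5, 0.8),
    (1, 0.5, 0.4, 0.4, 0.8),
    (1, 0.7, 0.4, 0.4, 0.8),
    (1, 0.9, 0.4, 0.4, 0.8),
    (1, 0.6, 0.3, 0.3, 0.8),
    (1, 0.7, 0.3, 0.3, 0.8),
    (1, 0.8, 0.3, 0.3, 0.8),
    (1, 0.75, 0.25, 0.25, 0.8),
    (1, 0.88, 0.25, 0.25, 0.8),
    (1, 0.94, 0.25, 0.25, 0.8),
    (1, 1.5, 0.5, 0.7, 0.9),
    (1, 1.25, 0.5, 0.7, 0.9),
    (1, 1.1, 0.5, 0.7, 0.9),
    (1, 0.5, 0.6, 0.4, 0.9),
    (1, 0.7, 0.6, 0.4, 0.9),
    (1, 0.9, 0.6, 0.4, 0.9),
    (1, 0.6, 0.5, 0.3, 0.9),
    (1, 0.7, 0.5, 0.3, 0.9),
    (1, 0.8, 0.5, 0.3, 0.9),
    (1, 0.75, 0.4, 0.25, 0.9),
    (1, 0.88, 0.4, 0.25, 0.9),
    (1, 0.94, 0.4, 0.25, 0.9),
]

# Median pairs for the exponential sensitivity scenarios (90% power); the
# implied raw SD is median/log(2) in each group.
EXPONENTIAL_SCENARIOS: list[tuple[float, float]] = [
    (0.1, 0.3),
    (1, 1.5),
    (10, 7),
    (20, 15),
    (60, 48),
    (80, 70),
]


@dataclass(frozen=True)
class SimulationScenario:
    """One simulation condition: two groups, a per-group n, a family.

    For ``family="exponential"`` the groups' raw SDs are ignored: the
    rates derive from the medians alone (rate = log 2 / median).
    """

    group1: GroupSpec
    group2: GroupSpec
    n_per_group: int
    family: str = "lognormal"
    n_reps: int = DEFAULT_N_REPS
    alpha: float = 0.05
    seed: int = 0

    def __post_init__(self) -> None:
        if self.family not in FAMILIES:
            raise InvalidParameterError(
                f"family must be one of {FAMILIES}; got {self.family!r}"
            )
        if self.n_per_group < 2:
            raise InvalidParameterError(
                f"n_per_group must be >= 2; got {self.n_per_group!r}"
            )
        if self.n_reps < 1:
            raise InvalidParameterError(f"n_reps must be >= 1; got {self.n_reps!r}")
        if not 0 < self.alpha < 1:
            raise InvalidParameterError(f"alpha must be in (0, 1); got {self.alpha!r}")


@dataclass(frozen=True)
class PowerEstimates:
    """Rejection proportions for the three tests, with binomial MC SEs."""

    power_log_t: float
    power_mann_whitney: float
    power_raw_t: float
    n_reps: int
    mc_se_log_t: float
    mc_se_mw: float
    mc_se_raw_t: float

    @classmethod
    def from_counts(cls, counts: np.ndarray, n_reps: int) -> "PowerEstimates":
        p = np.asarray(counts, dtype=float) / n_reps
        se = np.sqrt(p * (1.0 - p) / n_reps)
        return cls(
            power_log_t=float(p[0]),
            power_mann_whitney=float(p[1]),
            power_raw_t=float(p[2]),
            n_reps=n_reps,
            mc_se_log_t=float(se[0]),
            mc_se_mw=float(se[1]),
            mc_se_raw_t=float(se[2]),
        )


def _replicate_rng(seed: int, replicate_index: int, group: int) -> np.random.Generator:
    # Counter-based keying: each (replicate, group) pair owns an
    # independent stream, so results do not depend on evaluation order.
    ss = np.random.SeedSequence(entropy=seed, spawn_key=(replicate_index, group))
    return np.random.default_rng(ss)


def draw_two_group_sample(
    scenario: SimulationScenario, replicate_index: int
) -> tuple[np.ndarray, np.ndarray]:
    """Draw one replicate's two samples (strictly positive values).

    Log-normal draws use each group's implied (mu, sigma^2); exponential
    draws use rate = log(2)/median.  Identical (seed, replicate_index)
    pairs give identical samples.
    """
    n = scenario.n_per_group
    samples = []
    for group_index, group in enumerate((scenario.group1, scenario.group2)):
        rng = _replicate_rng(scenario.seed, replicate_index, group_index)
        if scenario.family == "lognormal":
            mu = log_scale_mean(group)
            sigma = math.sqrt(log_scale_variance(group))
            samples.append(rng.lognormal(mean=mu, sigma=sigma, size=n))
        else:
            samples.append(rng.exponential(scale=group.median / math.log(2), size=n))
    return samples[0], samples[1]


def _student_t_pvalues(x: np.ndarray, y: np.ndarray, welch: bool = False) -> np.ndarray:
    """Two-sided two-sample t-test p-values, rows = replicates.

    Zero-variance guard: if both samples are constant, the p-value is 1
    when the means agree (retain) and 0 when they differ (the statistic
    diverges).
    """
    n1, n2 = x.shape[1], y.shape[1]
    m1, m2 = x.mean(axis=1), y.mean(axis=1)
    v1, v2 = x.var(axis=1, ddof=1), y.var(axis=1, ddof=1)
    if welch:
        se_sq = v1 / n1 + v2 / n2
        with np.errstate(divide="ignore", invalid="ignore"):
            df = se_sq**2 / (v1**2 / (n1**2 * (n1 - 1)) + v2**2 / (n2**2 * (n2 - 1)))
    else:
        sp_sq = ((n1 - 1) * v1 + (n2 - 1) * v2) / (n1 + n2 - 2)
        se_sq = sp_sq * (1.0 / n1 + 1.0 / n2)
        df = np.full_like(se_sq, float(n1 + n2 - 2))
    with np.errstate(divide="ignore", invalid="ignore"):
        t = (m1 - m2) / np.sqrt(se_sq)
    p = np.ones_like(t)
    ok = se_sq > 0
    p[ok] = 2.0 * stats.t.sf(np.abs(t[ok]), df[ok])
    degenerate_diff = ~ok & (m1 != m2)
    p[degenerate_diff] = 0.0
    return p


#: Both-samples-below-this threshold for exact Mann-Whitney enumeration.
MW_EXACT_LIMIT = 50


@lru_cache(maxsize=64)
def _mw_exact_pvalue_table(n1: int, n2: int) -> np.ndarray:
    """Two-sided exact p-value indexed by the integer U statistic.

    The null distribution of U is enumerated with the classical
    recurrence f(u; n1, n2) = f(u - n2; n1 - 1, n2) + f(u; n1, n2 - 1)
    (valid for untied data); the two-sided p-value at u is
    min(1, 2 min(P(U <= u), P(U >= u))).
    """
    # prev[j] holds the count array over u for (i, j); iterate i upward.
    prev = [np.ones(1) for _ in range(n2 + 1)]
    for i in range(1, n1 + 1):
        cur = [np.ones(1)]
        for j in range(1, n2 + 1):
            a = np.zeros(i * j + 1)
            sub = prev[j]
            a[j : j + sub.size] += sub
            a[: cur[j - 1].size] += cur[j - 1]
            cur.append(a)
        prev = cur
    counts = prev[n2]
    cdf = np.cumsum(counts) / counts.sum()
    sf = 1.0 - np.concatenate([[0.0], cdf[:-1]])  # P(U >= u)
    return np.minimum(1.0, 2.0 * np.minimum(cdf, sf))


def _mann_whitney_pvalues(x: np.ndarray, y: np.ndarray) -> np.ndarray:
    """Two-sided Mann-Whitney U p-values, rows = replicates.

    Exact enumeration when both samples are smaller than
    ``MW_EXACT_LIMIT``; continuity-corrected normal approximation (no
    tie correction: the simulated families are continuous) otherwise.
    """
    n1, n2 = x.shape[1], y.shape[1]
    combined = np.concatenate([x, y], axis=1)
    ranks = stats.rankdata(combined, axis=1)
    r1 = ranks[:, :n1].sum(axis=1)
    u1 = r1 - n1 * (n1 + 1) / 2.0
    # Exact enumeration assumes untied data (integer U); midranks from
    # tied values make U half-integer, in which case fall back to the
    # approximation.
    if n1 < MW_EXACT_LIMIT and n2 < MW_EXACT_LIMIT and np.all(u1 == np.floor(u1)):
        table = _mw_exact_pvalue_table(n1, n2)
        return table[u1.astype(np.intp)]
    mu = n1 * n2 / 2.0
    sd = math.sqrt(n1 * n2 * (n1 + n2 + 1) / 12.0)
    z = np.maximum(np.abs(u1 - mu) - 0.5, 0.0) / sd
    return np.minimum(2.0 * stats.norm.sf(z), 1.0)


def _three_test_rejections(
    x: np.ndarray, y: np.ndarray, alpha: float, welch: bool = False
) -> tuple[np.ndarray, np.ndarray, np.ndarray]:
    if np.any(x <= 0) or np.any(y <= 0):
        raise InvalidParameterError(
            "samples must be strictly positive to log-transform"
        )
    reject_log_t = _student_t_pvalues(np.log(x), np.log(y), welch=welch) < alpha
    reject_mw = _mann_whitney_pvalues(x, y) < alpha
    reject_raw_t = _student_t_pvalues(x, y, welch=welch) < alpha
    return reject_log_t, reject_mw, reject_raw_t


def run_three_tests(
    sample1: np.ndarray,
    sample2: np.ndarray,
    alpha: float = 0.05,
    welch: bool = False,
) -> tuple[bool, bool, bool]:
    """Apply the three tests to one pair of samples.

    Returns ``(reject_log_t, reject_mw, reject_raw_t)``: True means the
    null hypothesis is rejected at level ``alpha``.
    """
    x = np.asarray(sample1, dtype=float)
    y = np.asarray(sample2, dtype=float)
    if x.ndim != 1 or y.ndim != 1 or x.size < 2 or y.size < 2:
        raise InvalidParameterError(
            "each sample must be a 1-D vector with at least 2 elements"
        )
    if not 0 < alpha < 1:
        raise InvalidParameterError(f"alpha must be in (0, 1); got {alpha!r}")
    rl, rm, rr = _three_test_rejections(
        x[np.newaxis, :], y[np.newaxis, :], alpha, welch=welch
    )
    return bool(rl[0]), bool(rm[0]), bool(rr[0])


def estimate_power(
    scenario: SimulationScenario,
    welch: bool = False,
    chunk_size: int = 2_000,
) -> PowerEstimates:
    """Rejection proportions for the three tests over the scenario's
    replicates.  Deterministic given the scenario (including its seed);
    replicates are processed in chunks to bound memory."""
    n = scenario.n_per_group
    counts = np.zeros(3)
    for start in range(0, scenario.n_reps, chunk_size):
        stop = min(start + chunk_size, scenario.n_reps)
        x = np.empty((stop - start, n))
        y = np.empty((stop - start, n))
        for i, rep in enumerate(range(start, stop)):
            try:
                x[i], y[i] = draw_two_group_sample(scenario, rep)
            except Exception as exc:  # pragma: no cover - defensive
                raise type(exc)(f"replicate {rep}: {exc}") from exc
        rl, rm, rr = _three_test_rejections(x, y, scenario.alpha, welch=welch)
        counts += (rl.sum(), rm.sum(), rr.sum())
    return PowerEstimates.from_counts(counts, scenario.n_reps)


def _row_seeds(seed: int, n_rows: int) -> list[int]:
    # One sub-seed per table row, derived reproducibly from the master seed.
    state = np.random.SeedSequence(seed).generate_state(n_rows, np.uint32)
    return [int(s) % 2**31 for s in state]


def replicate_table(
    table_id: int, n_reps: int = DEFAULT_N_REPS, seed: int = 0
) -> pd.DataFrame:
    """Re-run one of the three study tables.

    Table 1: log-normal scenarios with n from the median/SD formula.
    Table 2: exponential data, n from the (mis-specified) log-normal
    formula with SD = median/log 2.  Table 3: exponential data, n from
    the corrected formula with log-scale variance pi^2/6.

    The analytic n in each row is computed, not stored; power columns
    are Monte-Carlo estimates with their standard errors.
    """
    if table_id not in (1, 2, 3):
        raise InvalidParameterError(f"table_id must be 1, 2 or 3; got {table_id!r}")
    if n_reps < 1:
        raise InvalidParameterError(f"n_reps must be >= 1; got {n_reps!r}")

    rows = []
    if table_id == 1:
        specs = [
            (m1, m2, p1, p2, power) for (m1, m2, p1, p2, power) in TABLE1_SCENARIOS
        ]
    else:
        specs = [
            (m1, m2, m1 / math.log(2), m2 / math.log(2), 0.9)
            for (m1, m2) in EXPONENTIAL_SCENARIOS
        ]
    seeds = _row_seeds(seed, len(specs))

    for idx, ((m1, m2, p1, p2, power), row_seed) in enumerate(zip(specs, seeds), 1):
        g1 = GroupSpec(median=m1, raw_sd=p1, label="1")
        g2 = GroupSpec(median=m2, raw_sd=p2, label="2")
        design = DesignSpec(alpha=0.05, power=power)
        if table_id == 1:
            result = n_lognormal(g1, g2, design)
            family = "lognormal"
        elif table_id == 2:
            result = n_exponential_naive(m1, m2, design)
            family = "exponential"
        else:
            result = n_exponential(m1, m2, design)
            family = "exponential"
        scenario = SimulationScenario(
            group1=g1,
            group2=g2,
            n_per_group=result.n_per_group,
            family=family,
            n_reps=n_reps,
            alpha=design.alpha,
            seed=row_seed,
        )
        est = estimate_power(scenario)
        rows.append(
            {
                "scenario": idx,
                "m1": m1,
                "m2": m2,
                "phi1": p1,
                "phi2": p2,
                "power_target": power,
                "n": result.n_per_group,
                "power_log_t": est.power_log_t,
                "power_mann_whitney": est.power_mann_whitney,
                "power_raw_t": est.power_raw_t,
                "mc_se_log_t": est.mc_se_log_t,
                "mc_se_mw": est.mc_se_mw,
                "mc_se_raw_t": est.mc_se_raw_t,
                "n_reps": n_reps,
                "seed": row_seed,
            }
        )
    return pd.DataFrame(rows)
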