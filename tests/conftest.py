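"""Shared fixtures and frozen reference values for the test suite.

The reference tables below are the published simulation-study results
this package replicates: each row gives the scenario parameters
(untransformed medians and SDs), the analytic per-group sample size, and
the three Monte-Carlo power estimates reported at N = 100 000
replicates (log-scale t-test, Mann-Whitney U, untransformed t-test).
"""

import math

import pytest

from mediansize import DesignSpec

#: (m1, m2, phi1, phi2, power, n, power_log_t, power_mw, power_raw_t)
TABLE1_REFERENCE = [
    (1, 1.5, 0.5, 0.5, 0.8, 14, 0.781, 0.755, 0.690),
    (1, 1.25, 0.5, 0.5, 0.8, 51, 0.797, 0.776, 0.664),
    (1, 1.1, 0.5, 0.5, 0.8, 303, 0.801, 0.781, 0.639),
    (1, 0.5, 0.4, 0.4, 0.8, 9, 0.788, 0.724, 0.687),
    (1, 0.7, 0.4, 0.4, 0.8, 23, 0.794, 0.772, 0.662),
    (1, 0.9, 0.4, 0.4, 0.8, 204, 0.800, 0.781, 0.669),
    (1, 0.6, 0.3, 0.3, 0.8, 9, 0.791, 0.728, 0.728),
    (1, 0.7, 0.3, 0.3, 0.8, 15, 0.800, 0.762, 0.723),
    (1, 0.8, 0.3, 0.3, 0.8, 32, 0.797, 0.773, 0.713),
    (1, 0.75, 0.25, 0.25, 0.8, 15, 0.784, 0.747, 0.729),
    (1, 0.88, 0.25, 0.25, 0.8, 63, 0.797, 0.776, 0.737),
    (1, 0.94, 0.25, 0.25, 0.8, 250, 0.800, 0.781, 0.741),
    (1, 1.5, 0.5, 0.7, 0.9, 23, 0.888, 0.873, 0.847),
    (1, 1.25, 0.5, 0.7, 0.9, 87, 0.898, 0.883, 0.910),
    (1, 1.1, 0.5, 0.7, 0.9, 530, 0.900, 0.886, 0.992),
    (1, 0.5, 0.6, 0.4, 0.9, 14, 0.890, 0.872, 0.800),
    (1, 0.7, 0.6, 0.4, 0.9, 40, 0.897, 0.882, 0.875),
    (1, 0.9, 0.6, 0.4, 0.9, 383, 0.900, 0.886, 0.993),
    (1, 0.6, 0.5, 0.3, 0.9, 16, 0.896, 0.874, 0.867),
    (1, 0.7, 0.5, 0.3, 0.9, 28, 0.894, 0.877, 0.897),
    (1, 0.8, 0.5, 0.3, 0.9, 65, 0.896, 0.880, 0.946),
    (1, 0.75, 0.4, 0.25, 0.9, 29, 0.892, 0.875, 0.906),
    (1, 0.88, 0.4, 0.25, 0.9, 131, 0.898, 0.882, 0.970),
    (1, 0.94, 0.4, 0.25, 0.9, 537, 0.900, 0.883, 0.998),
]

#: Exponential data sized by the mis-specified log-normal formula
#: (SD = median / log 2): (m1, m2, n, power_log_t, power_mw, power_raw_t).
TABLE2_REFERENCE = [
    (0.1, 0.3, 13, 0.576, 0.600, 0.661),
    (1, 1.5, 91, 0.567, 0.650, 0.769),
    (10, 7, 117, 0.564, 0.649, 0.768),
    (20, 15, 180, 0.565, 0.654, 0.772),
    (60, 48, 299, 0.564, 0.653, 0.775),
    (80, 70, 833, 0.565, 0.654, 0.778),
]

#: Exponential data sized with the corrected log-scale variance pi^2/6.
TABLE3_REFERENCE = [
    (0.1, 0.3, 29, 0.890, 0.933, 0.975),
    (1, 1.5, 211, 0.900, 0.948, 0.985),
    (10, 7, 272, 0.898, 0.947, 0.985),
    (20, 15, 418, 0.900, 0.950, 0.986),
    (60, 48, 695, 0.899, 0.949, 0.985),
    (80, 70, 1939, 0.898, 0.949, 0.985),
]

#: Replicate count behind the reference power estimates.
REFERENCE_N_REPS = 100_000


def power_tolerance(p_ref: float, n_reps: int) -> float:
    """3-SE tolerance for comparing a rejection proportion estimated at
    ``n_reps`` replicates with a reference value itself estimated at
    REFERENCE_N_REPS replicates (both binomial)."""
    var = p_ref * (1 - p_ref) * (1 / n_reps + 1 / REFERENCE_N_REPS)
    return 3 * math.sqrt(var)


@pytest.fixture(scope="session")
def design_90() -> DesignSpec:
    return DesignSpec(alpha=0.05, power=0.9)


@pytest.fixture(scope="session")
def design_80() -> DesignSpec:
    return DesignSpec(alpha=0.05, power=0.8)
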