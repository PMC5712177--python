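# Methods

## Model and assumptions

The outcome T in arm j (j = 1, 2) is assumed log-normal:
log T ~ N(mu_j, sigma_j^2). Two identities drive everything:

* median(T) = exp(mu_j) — the untransformed median coincides with the
  geometric mean, so mu_j = log(m_j) and the log-scale mean difference
  is tau = log(m_1) - log(m_2);
* Var(T) = phi_j^2 determines the log-scale variance through
  sigma_j^2 = log(1/2 + sqrt(1/4 + phi_j^2 / m_j^2)), obtained by
  inverting the log-normal variance formula
  phi^2 = m^2 e^{sigma^2}(e^{sigma^2} - 1).

The planned analysis is a two-sided two-sample t-test of
H0: mu_1 = mu_2 on log-transformed values — equivalently a test of
equal medians on the original scale. The per-group size is the
classical normal-approximation formula
n = (sigma_1^2 + sigma_2^2)(z_{alpha/2} + z_beta)^2 / tau^2.

Assumptions worth stating: groups are independent with equal allocation
(an allocation-ratio variant n_1 = (sigma_1^2 + sigma_2^2/k)(...)/tau^2,
n_2 = k n_1 is provided as a convenience); the test is two-sided; equal
untransformed SDs in the two arms still imply *unequal* log-scale
variances whenever the medians differ, which the formula handles
naturally.

## Parameters

| parameter | meaning | units | default |
|---|---|---|---|
| m1, m2 | untransformed medians | outcome units | required |
| sd1, sd2 | untransformed SDs | outcome units | required (0 admitted: degenerate arm) |
| alpha | two-sided significance level | — | 0.05 |
| power | target power | — | 0.9 |
| z overrides | externally rounded quantiles | — | none (full-precision quantiles) |
| pad | subjects added per group after ceiling | count | 0 |
| icc, cluster size | design effect 1 + ICC(m-1) | — | none |
| n_reps | simulation replicates | count | 100 000 |

Full-precision standard-normal quantiles are the default because the
reference simulation grids are reproduced exactly with them; the
overrides exist for protocols written with the rounded 1.96/1.28, which
is what makes the worked example print 30.18 rather than the 30.21 the
exact quantiles give.

## Rounding and degenerate inputs

The continuous n is rounded **up** per group; `pad` then adds whole
subjects (the normal quantiles slightly understate the t-test
requirement at small n, so one or two extra subjects are advisable
there). The result never drops below 2 per group — a t-test needs two
observations per arm — and when that clamp binds, the recorded pad
reflects the actual addition so n_per_group = ceil(n_continuous) + pad
always holds. Equal medians (tau = 0) and doubly degenerate designs
(both variances zero) are rejected with specific errors. The design
effect multiplies the already-rounded-and-padded per-group n and is
re-ceiled; clusters per group are ceil(units / average cluster size).

## Simulation engine

Each replicate draws n values per arm — logN(log m_j, sigma_j^2) for
the log-normal family, Exp(log 2 / m_j) for the exponential family
(raw SDs are ignored there; the rate is pinned by the median) — and
applies three two-sided tests at level alpha: the t-test on logs, the
Mann-Whitney U test, and the t-test on raw values. Power is the
rejection proportion, reported with the binomial standard error
sqrt(p(1-p)/N).

Numerical/test-method choices:

* **t-test variant:** pooled-variance Student's t by default (the
  classical formula the sample-size calculation derives from), with a
  Welch option; at the tabulated sizes the two are indistinguishable
  relative to Monte-Carlo error.
* **Mann-Whitney p-value:** exact enumeration of the null U
  distribution whenever both samples have fewer than 50 observations —
  the common software default for untied data, and material at small n,
  where the continuity-corrected normal approximation is conservative
  by about 0.01 in power — and the continuity-corrected normal
  approximation otherwise. The exact table comes from the classical
  counting recurrence and is verified against an independent
  implementation in the tests. Ties (probability zero under both
  families) trigger a fallback to the approximation.
* **RNG:** each (replicate, group) pair owns a generator seeded through
  a counter-based key (seed, replicate index, group), so results are
  bit-reproducible and independent of evaluation order or chunking.
  Replicates are processed in chunks of 2000 to bound memory.
* **Degenerate draws:** a zero-SD arm yields constant samples; two
  constant equal samples retain the null by a zero-variance guard,
  constant unequal samples reject.
* **Table replication:** `replicate_table(1|2|3)` re-derives each
  scenario's analytic n from the calculator (never stored) and
  simulates at it — grid 1: log-normal data sized by the median/SD
  formula; grid 2: exponential data sized by the *mis-specified*
  log-normal formula with SD = median/log 2 (its implied log-scale
  variance is the constant ~0.7065, under half the true pi^2/6, so
  power lands near 0.57 instead of 0.9); grid 3: exponential data sized
  with pi^2/6.

## What the generator emulates — and what passing tests do not show

The generator produces exactly the idealised study conditions:
independent, identically distributed log-normal or exponential
outcomes with the specified medians and spreads, no covariates, no
dropout, no measurement error, and no within-cluster correlation (the
cluster adjustment is the analytic design effect only; clustered data
are never simulated). Passing power checks therefore demonstrate that
the formula and the tests behave as claimed *under the assumed
families*; they say nothing about robustness to other skewed
distributions — indeed the exponential grids exist precisely to show
the log-normal formula failing off-family — nor about real-data
complications such as variable cluster sizes or censoring.

## Numerical notes

The variance conversion is computed as
log1p(r / (1/2 + sqrt(1/4 + r))) with r = (sd/median)^2, an exact
rearrangement that avoids cancellation at small coefficients of
variation; its inverse uses expm1. The round-trip
phi^2 -> sigma^2 -> phi^2 is then accurate to 1e-10 relative across
medians 0.01–1000 and SDs 0–100, which the property suite asserts.
Closed-form results are tested at 1e-10–1e-12; Monte-Carlo results at
3 standard errors, combining the uncertainty of both sides when
comparing against reference proportions themselves estimated at
100 000 replicates.

## Problem sizes in the test suite

The suite replicates the full analytic grids (24 + 6 + 6 sample sizes,
closed form) and spot-checks power at a reduced replicate count chosen
to keep the Monte-Carlo tolerance tight but the runtime short: 20 000
replicates for the three acceptance scenarios, 10 000 for additional
grid rows, 1500–5000 for property checks (type-I calibration, raw-t
inflation, Mann-Whitney vs log-t ordering). Full 100 000-replicate
grids remain available through the CLI.

## Known limitations

* Two groups only; no survival/censoring, non-inferiority margins, or
  likelihood-ratio constructions for other families (e.g. Gamma).
* The cluster adjustment assumes a common ICC and average cluster size
  and is not verified by simulation here.
* Off-family behaviour is characterised only for the exponential case;
  for other skewed distributions users should simulate before trusting
  the log-normal formula.
* The exact Mann-Whitney path assumes untied data, appropriate for
  continuous simulation families but not for heavily rounded real data.
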