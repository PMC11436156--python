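# Methods

## The single-interval SCCS reduction

The self-controlled case series (SCCS) design compares each case's event
timing against their own person-time, which removes all fixed confounders.
With one post-vaccination risk interval and a common observation window,
the design reduces to a binomial problem. Each case is observed for `T`
days; days `1..e` form the risk window with relative incidence `rho`
against the remaining `T − e` control days. Conditional on one event per
case, the probability the event lands in the risk window is

    p(rho) = rho * r / (1 + (rho − 1) * r),    r = e / T,

which equals `r` at the null `rho = 1`. A surveillance analysis of `n`
events is therefore a one-sample binomial test of `p = r` against
`p = p(rho)`, and power is governed by the number of observed *events*.

Assumptions inherited from this reduction: every case is vaccinated and
fully observed for the whole window; one event per case; no age or
seasonality trend in baseline incidence; a single risk interval. Partially
observed windows, event-dependent observation, and age-stratified or
semiparametric SCCS variants are out of scope.

## Sample-size engine

`required_events` searches upward from `n = 1` for the smallest event count
whose test attains the target power. The test is upper-tail only at level
`alpha/2`: surveillance flags elevated risk, so the lower half of the
two-sided budget is never spent, which keeps the stated two-sided `alpha`
while maximizing sensitivity to `rho > 1`.

Two conventions enter the calculation, and they are deliberately split:

- **Critical value** (default `tail_method="normal"`): the smallest
  in-risk-window count `c` whose *continuity-corrected normal* upper-tail
  probability under the null is at most `alpha/2`. This is the threshold
  convention of the classical one-proportion sample-size literature, and it
  is the convention under which the two reference designs below give 47 and
  20 events.
- **Attained power**: always the exact binomial upper tail
  `P(X >= c | n, p(rho))`, summed from log-space probability masses — never
  a normal approximation.

A fully exact threshold (`tail_method="exact"`: smallest `c` with exact
`P(X >= c | n, r) <= alpha/2`) is provided for users who want guaranteed
finite-sample size control. The two thresholds occasionally differ by one
count on small designs where the exact tail sits just above `alpha/2`
(e.g. `n = 20`, `r = 28/180`: exact tail at `c = 7` is 0.0264, so the exact
rule takes `c = 8`); under the exact rule the second reference design needs
22 events rather than 20. The default reproduces the published convention;
the exact rule is the conservative alternative. For the default rule the
realized type-I error can exceed `alpha/2` by at most this approximation
gap (0.0264 at its worst across the designs tested), which the Monte Carlo
type-I checks bound explicitly.

Reference designs (two-sided `alpha = 0.05`, power 0.90, 28-day risk window
in 180 days of observation):

- `rho = 3.0` (myocarditis-like): 47 events, critical count 13, attained
  power 0.9033.
- `rho = 5.0` (VITT-like): 20 events, critical count 7, attained power
  0.9178.

Exact-test power is sawtoothed in `n`, so "smallest passing `n`" is the
contract; `strict=True` additionally requires every `n` up to a horizon
(default `5n`) to pass, for users who want a monotone guarantee.
`approx_required_events` offers two asymptotic cross-checks (mixed-variance
Wald and a Kullback–Leibler likelihood-ratio form); both give 44 for the
first design, bracketing the exact 47 from below, and neither is used in
the default path.

## Throughput and days-to-detect

Scenario rows turn populations into detection times:

- **Throughput models.** `anchored`: every jurisdiction achieves the same
  *relative* throughput as an anchor (doses/day scaled by population ratio,
  floored to whole doses) — used for whole-population scenarios anchored to
  Ontario's 50,000 doses/day (≈0.3515% of its population daily). `flat`: a
  fixed fraction of the stratum population per day (the age-restricted
  scenarios use exactly 0.35%/day). `explicit`: a stated doses/day figure,
  for subgroups without packaged census strata (e.g. ~7,500 doses/day among
  women 18–39).
- **Accrual.** Expected events/day is throughput × per-dose risk, kept
  exact as a `fractions.Fraction`; days-to-detect is the exact ceiling of
  `n_required / events_per_day`. Rounding discipline matters: throughputs
  are floored *before* pooling, and day counts always use the unrounded
  rate, never a 2-decimal display value. Human-readable tables round
  events/day to two decimals and print `<0.01` below 0.005; CSVs carry full
  precision.
- **Pooling.** A pool's throughput is the sum of its members' floored
  throughputs (exactly additive in whole doses). National rows support two
  aggregations: `summed` (add all thirteen jurisdictions' floored
  throughputs — requires the census stratum for every jurisdiction, hence
  the packaged territory decomposition) and `direct` (apply the throughput
  model to the printed national count — used for the 18–39 stratum, where
  territory-level age counts are not packaged). For every shipped scenario
  the two modes agree on the resulting day count, and tests assert that
  agreement where both are computable.
- **Averted harm.** Days saved by pooling times the pooled events/day,
  rounded *up* to whole events; deaths apply a case-fatality proportion and
  round *down*. This ceiling/floor pairing is the only one consistent with
  the package's whole-event accounting (an intervention prevents an event
  only once it would actually have accrued; a death count never rounds a
  partial death up). Note the headline depends on which pooled rate prices
  the days saved: 49 days × 0.5564 events/day (six-province pool) averts
  28 events, while the same 49 days × 0.5926 (national rate) would avert
  30; the package computes whichever rate the caller supplies.

## Census registry

The packaged CSV carries 2021 Canadian census populations per jurisdiction:
totals for all ten provinces and three territories, and counts for adults
aged 18–39 where published at the jurisdiction level (provinces and the
national total). The three territory totals (Yukon 40,232; Northwest
Territories 41,070; Nunavut 36,858) are a derived decomposition constrained
to sum to 118,160 — the national total minus the ten provincial totals —
because the summed national throughput is only reproducible with a
per-territory breakdown; day counts are insensitive to the exact split at
these population sizes. Tests assert the decomposition identities from the
packaged data. No sub-provincial geography and no live census retrieval.

## Synthetic case series and Monte Carlo verification

`simulate_dataset` draws each case's event day independently: in the risk
window with probability `rho*e / (rho*e + (T − e))` (algebraically equal to
`p(rho)`), uniformly within whichever segment it lands in. Placing the risk
window at days `1..e` is a labelling convention; only the in/out dichotomy
reaches the statistics. The generator emulates exactly the conditions the
analytic engine assumes — it does not model vaccination-date heterogeneity,
time-varying uptake, age trends, censoring, or multiple events per case, so
agreement between simulation and analytic power validates the engine's
arithmetic, not the design's robustness to those real-world features.

`estimate_relative_incidence` is the conditional ML estimator for the
single-interval SCCS: with `X` of `n` events in the risk window,
`rho_hat = (X/(n−X)) · ((T−e)/e)`, with a Wald interval on the log scale
(variance `1/X + 1/(n−X)`). Degenerate counts (`X = 0` or `X = n`) return
0/inf/nan sentinels rather than raising.

`empirical_power` simulates case series in bulk (default 10,000
replicates), rejects when the in-risk count reaches the engine's critical
value, and always reports the binomial Monte Carlo standard error next to
the estimated proportion. `empirical_type1` is the same machinery with
`rho` forced to 1. All randomness flows through one seeded
`numpy.random.Generator`; the package default seed is 20240914, and
identical inputs reproduce outputs bit-for-bit. At the first reference
design the 10,000-replicate empirical power lands within three Monte Carlo
standard errors of the exact 0.9033.

## Numerical choices and edge cases

- Binomial tails are summed from `scipy.stats.binom.logpmf` via
  `logsumexp`; no closed-form shortcuts.
- Scenario probabilities accept decimal ("0.000015") and ratio
  ("1.5/100000") notation and are normalized to exact fractions; floats
  convert via their shortest decimal representation. Floor (throughput)
  and ceiling (days, averted events) are exact integer arithmetic.
- "Cannot-reject" (no rejection region of size `alpha/2` exists even at
  `c = n`) is a `None` sentinel from `binomial_critical_value`; power is
  reported as 0 with a warning, never an exception.
- `required_events` rejects `rho <= 1` — no finite event count detects a
  non-elevated risk with an upper-tail test.
- The test suite and the shipped scenario configs keep problem sizes at
  desk scale: exact-oracle sweeps to `n = 200`, Monte Carlo studies at
  10,000 replicates, and parameter-recovery studies at 1,000 replicates of
  500 cases, which the full suite completes in a few seconds.

## Known limitations

Constant throughput over time (no uptake decay), identical per-dose risk
across jurisdictions, fully observed windows, and a single risk interval
are all simplifications; each one biases days-to-detect optimistically if
violated. The 18–39 census stratum is not packaged for the territories, so
age-restricted national rows must use the `direct` aggregation. Sample
sizes from the default threshold convention can differ by one or two events
from the fully exact rule on small designs — both are exposed, and the
difference is documented above rather than hidden.
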