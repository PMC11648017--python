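# Methods

## The decision problem

Roughly a fifth to a third of patients with metastatic castration-resistant
prostate cancer (mCRPC) starting a first-line androgen receptor pathway
inhibitor (ARPI; abiraterone acetate or enzalutamide) derive little or no
benefit and progress within six months, but conventional response assessment
(PSA kinetics, imaging under PCWG3 criteria) cannot reliably identify them
before 3–6 months of therapy. Detectable circulating tumor DNA (ctDNA) at
baseline *and* after 4 weeks on treatment identifies most of these
non-durable responders after a single treatment cycle. The model in this
package asks what it is worth, in euros per quality-adjusted life-year
(QALY), to act on that signal: test everyone, switch test-positive patients
to docetaxel at week 4, and let the (predicted durable) remainder continue
ARPI — versus standard of care, in which the first switch happens no earlier
than six months.

## Model structure

A cohort state-transition (Markov) model with seven clinical health states —
first-line ARPI, second-line docetaxel, third-line cabazitaxel,
no-progression-after-docetaxel, no-progression-after-cabazitaxel, best
supportive care (BSC), and death — expanded to 25 Markov states: each
chemotherapy line carries ten tunnel sub-states, one per administered cycle,
because docetaxel and cabazitaxel are given for at most ten cycles and their
costs and time-in-line must be tracked. After ten event-free cycles a
patient moves to the corresponding no-progression state (off drug, still
monitored) until progression, BSC entry, or death. Every alive state has
direct edges to BSC and to death; death is absorbing.

Time runs over a 5-year horizon as one 4-week cycle followed by 3-week
cycles: boundaries at days 0, 28, 49, 70, …, giving 86 full cycles (1813 of
1826.25 days; the final partial cycle is dropped so every cycle is full
length, sacrificing <1% of the horizon). Costs are discounted at 4%/year and
effects at 1.5%/year (Dutch pharmacoeconomic guideline rates), as
`(1+r)^(−t/365.25)` evaluated at cycle start. There is no half-cycle
correction; occupancy is valued at cycle start. This is the simplest
defensible reading of a spreadsheet-style cohort model; the induced bias is
bounded by half a cycle (≤1.5 weeks) of valuation at each transition and is
identical in both arms, so it largely cancels in the increments.

### Survival inputs and transition probabilities

Trial survival enters as medians (exponential approximation; the only
summary universally printed for the cited trials) or as piecewise-constant
hazards for users who digitize curves. Within a cycle, progression, death,
and BSC entry compete as cause-specific constant hazards, converted jointly
by

    Λ = λ_prog + λ_death + λ_bsc,   p_event = 1 − exp(−Λ·Δt),
    p_cause = p_event · λ_cause / Λ,

which is the standard multistate conversion and cannot produce negative
probabilities (unlike subtracting marginal probabilities). PFS events
include deaths, so λ_prog = λ_PFS − λ_OS; inputs with λ_OS > λ_PFS are
rejected (deterministic) or the iteration is skipped with a log entry
(probabilistic draws). Months convert to days at 365.25/12.

Chemotherapy hazards depend on time-in-line (the tunnel index), i.e. the
clock resets on line entry; ARPI and BSC hazards run on calendar time (every
patient enters ARPI at day 0). With exponential inputs all hazards are
constant and the distinction is moot, but it matters for piecewise inputs.

### Strategy arms

Both arms share every parameter, transition row, and cost rule except the
ARPI row of the transition matrix, the durable-responder curves, and the
assay cost (the test suite asserts this by diffing the generated matrix
sequences).

*Standard of care*: the cohort splits 0.5/0.5 (configurable) between
abiraterone and enzalutamide sub-cohorts, each driven by its own trial
PFS/OS. Progression to docetaxel is suppressed — the mass is held in ARPI —
until the first cycle boundary at or after 182.625 days, which on the
28+21k grid is day 196 ("switch after six months at the earliest" on a
discrete grid).

*ctDNA-guided*: identical through the first cycle. At day 28 a fraction
`ctdna_flag_fraction` of ARPI survivors moves to the first docetaxel tunnel
state; the remainder — the predicted durable responders — follows
durable-responder PFS/OS from cycle 2 onward, by default without the
six-month hold (they are known test-negative; a `durable_six_month_hold`
switch restores the hold for sensitivity analysis). Among switchers,
`ctdna_ppv` (base 0.85) are true non-durable responders; false positives
receive the same docetaxel curves — no separate data exist for them — and
the split is carried in the results for reporting only. The assay cost
(3 samples × €350: baseline, week 4, and one germline-control sample) is
charged once to every intervention patient alive at day 28, discounted at
that boundary. Testing precedes the switch decision, so the whole arm pays
it.

The fraction of the intervention cohort that is test-positive is a
first-class parameter (`ctdna_flag_fraction`, default 0.4) because no public
value is printed for it; it must be overridden when better data exist.

### Costs, utilities, adverse events

Per-cycle recurring costs by state: drug and administration (ARPI and the
ten chemotherapy tunnel cycles only — the no-progression states are off
drug), outpatient visits for every on-pathway state, and a BSC per-cycle
cost. One-off costs are charged to the flow entering the triggering state
and discounted at the arrival boundary: expected adverse-event management
cost (Σ p_AE × c_AE over the line's listed grade ≥3 events — charged once on
line entry because severe events cluster early and no duration data exist)
plus a diagnostic work-up on entering each chemotherapy line; the ARPI AE
expectation is charged at day 0. QALYs accrue as occupancy × state utility ×
cycle length, utilities being line-specific EQ-5D-scale values with BSC
lowest.

## Uncertainty

Every probability and utility carries a beta distribution and every cost
and survival median a gamma distribution, parameterized by method of moments
from (mean, SE); SE defaults to 10% of the mean where no better information
exists. A `fixed` kind (or SE = 0) makes any parameter deterministic, so
the degenerate PSA exactly reproduces the deterministic run.

Sampling is inverse-CDF: each parameter consumes exactly one uniform variate
in a fixed traversal order. Consequently two structurally identical
parameter sets sampled from the same seed see identical uniform streams —
common random numbers across arms and across scenario overlays are *exact*,
which keeps the incremental outcomes (ΔC, ΔE) low-variance and makes
one-way-sensitivity differences attributable to the varied scalar alone.
Iteration seeds are spawned as `SeedSequence(seed).spawn(n)`, so iteration
*i* is reproducible from the master seed for any run length > *i*. Draws
that violate a schema invariant (e.g. a sampled PFS median exceeding its OS
median in the tail overlap of the two gammas, ~0.3% of iterations at base
settings) are logged and skipped.

The PSA (base 5000 iterations) reports the mean ICER as the ratio of mean
increments — the ratio-of-means is stable when ΔE crosses zero, unlike the
mean of per-iteration ratios, which is exposed as
`PSAResult.mean_icer_of_ratios` for comparison — plus percentile (order
statistic) 95% intervals, the probability of positive incremental net
monetary benefit (iNMB = WTP·ΔE − ΔC) at the €80,000/QALY threshold, and the
acceptability curve on a €0–200,000 grid in €1,000 steps. The CE plane and
CEAC derive from the same iteration set.

One-way sensitivity endpoints default to full-PSA means with a common seed
(a deterministic mode exists); assigning a scalar to a distributed parameter
rescales its SE to preserve the coefficient of variation. Scenario overlays
are pure (the base set is never mutated) and may be scoped to a single arm;
arm-scoped overlays retain exact common random numbers on all shared
parameters.

## Synthetic parameter sets

The complete input listing of the published analysis (per-line costs,
utilities, AE rates, and the durable-responder survival) is not publicly
printed, so the package ships a synthetic stand-in (`base_like`, also
installed as `data/base_case.yaml`) with the *published anchors fixed* —
assay €350 × 3 samples, predictive value 0.85, ARPI split 0.5/0.5, WTP
€80,000, discounting 4%/1.5% — and everything else at plausible documented
magnitudes: survival medians transcribed from the cited trials
(COU-AA-302, PREVAIL, FIRSTANA, CARD; PROSELICA and an approximate Japanese
real-world series for the scenario overlays) and 2022 Dutch cost
magnitudes. The durable-responder medians (PFS 48, OS 72 months) have no
published anchor at all; they were set so the fixture lies in the regime the
guided strategy is designed around — the durable majority's survival gain
outweighs the switchers' earlier, higher chemotherapy hazard and lower
chemotherapy utilities, giving ΔE > 0 with both cost and QALY increments of
plausible sign. They were *not* fitted to reproduce the published results
table, which the package deliberately refuses to do: with unpublished
inputs, agreement by search would be fabricated. Accordingly the
published-table acceptance comparison measures the distance between the
synthetic inputs and the unpublished ones and is expected to disagree;
the arithmetic identities on the published increments, and every structural
property, hold regardless.

What the fixture does not emulate: correlated uncertainty between
parameters (all draws independent), non-exponential survival shape for the
base case, and any real-world adherence or treatment-intensification
behaviour (the model assumes perfect adherence by design).

Other profiles: `null_effect` is a constructed exact null (durable curves
tied to trial curves, assay cost 0, flag fraction 0, hold in both arms ⇒
both arms structurally identical, ΔC = ΔE = 0 to machine precision — note
that under exact common random numbers every PSA iteration is also exactly
null, so the probability of *strictly positive* iNMB is 0, not ½);
`strong_effect` guarantees ΔE > 0; `stress` exercises piecewise hazards and
edge-of-domain probabilities.

## Validation

An independent individual-level microsimulation draws patient trajectories
through the *same* per-cycle transition matrices and one-off cost rules and
must agree with the cohort engine within 3 Monte Carlo standard errors
(2×10⁵ patients in the acceptance suite). Closed-form oracles cover the
exponential special cases (survival reconstruction to 1e−9, geometric-series
life-years on an absorbing toy chain), quadrature the piecewise hazard
averaging, and brute-force competing-risk simulation the cause-specific
split. Exact algebraic identities — iNMB linear in the assay price with
slope −3 × (discounted day-28 survivor fraction), all results affine in the
ARPI drug split, zero-discount and unit-utility identities — are asserted to
numerical precision.

## Numerical choices and limitations

- Cycle lengths: 28 days then 21 days; cohort evolution in occupancy
  fractions (the nominal 1000-patient cohort only scales reports).
- Transition rows must sum to 1 within 1e−12 and occupancy is checked for
  conservation every cycle.
- BSC entry uses a single global monthly probability (default 0.004/month)
  on every alive state; the published figure shows these edges but no rates.
- Docetaxel/cabazitaxel tunnels are structurally 10 cycles; `max_cycles`
  other than 10 for those lines is rejected rather than silently remapped.
- The exponential-from-median default is a reconstruction, not a published
  method; piecewise hazards are first-class for users with digitized curves.
- FACT-P→EQ-5D mapping, currency inflation, and newer treatment lines
  (PARP inhibitors, radioligand therapy) are out of scope; utilities and
  2022-euro costs enter as config values.
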