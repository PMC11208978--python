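# Methods

## The decision problem

Patients with rheumatoid arthritis (RA) who respond inadequately to
methotrexate can start either a conventional synthetic DMARD (leflunomide)
or, now that cheap biosimilars exist, a biologic DMARD immediately.
`biosimce` implements a lifetime multistate Markov cohort model that compares
three treatment *sequences* from a public-payer perspective:

1. **Leflunomide** → TNFi → non-TNFi bDMARD → JAKi → supportive care
2. **Biosimilar infliximab** → TNFi → non-TNFi → JAKi → supportive care
3. **Biosimilar adalimumab** → TNFi → non-TNFi → JAKi → supportive care

Subsequent lines are *classes*, each a market-share-weighted pool of the
drugs in that class (`pool_by_market_share`).  The cohort enters at age 56
(72.7% female) with baseline HAQ-DI 1.6 and is propagated in 6-month cycles
until age 100.  Costs are 2022 US$; costs and utilities are discounted at
3.5% per year; the willingness-to-pay (WTP) threshold is US $48 555/QALY
(1× 2022 GDP per capita of the modelled health system).

## State space and transitions

The chain runs on *expanded* states so that every history-dependent rule is
Markovian:

- **First line, first cycle.**  The cohort splits by ACR response category,
  derived from the cumulative ACR20/50/70 triple:
  p(<20) = 1 − c20, p(20–50) = c20 − c50, p(50–70) = c50 − c70, p(≥70) = c70.
  ACR20+ responders stay on treatment with a category-specific HAQ-DI
  improvement (−0.16 / −0.45 / −0.70 / −1.02); non-responders switch to the
  next line at cycle end.
- **Maintenance.**  From the second cycle of any line a constant per-cycle
  discontinuation probability routes patients to the next line.  HAQ-DI is
  constant while on treatment.
- **Rebound.**  On leaving a line, HAQ-DI returns to its value at that
  line's entry.  Since the first line is entered at baseline, every
  subsequent line — and supportive care — is entered at baseline HAQ-DI;
  this collapses what would otherwise be a continuous HAQ-DI state into a
  small finite set.
- **Supportive care** is terminal, with HAQ-DI increments −0.04, +0.2, then
  +0.28 per cycle, clamped at the scale ceiling of 3; the tunnel index also
  drives the steroid-injection rule (cost in the first two supportive-care
  cycles only — "every 6 months, up to twice in a lifetime").
- **Mortality.**  Per-cycle background death probability comes from a
  sex-blended life table, q_cycle = 1 − (1 − q_annual)^0.5, multiplied by
  1.33^HAQ-DI and capped at 1.

Within a cycle the event order is **death → accrual → switch**: mortality is
applied at start-of-cycle HAQ-DI, survivors accrue one full cycle of cost
and utility at start-of-cycle HAQ-DI, and switching happens at cycle end.
The order is a definitional choice (the framework we re-implement does not
state one); the microsimulation oracle in the test suite uses the same
convention.  Half-cycle correction is off by default and available as a
flag, implemented as mid-cycle discounting.

Utilities use the linear map **u = 0.74 − 0.17 × HAQ-DI** (QALYs = utility ×
years).  Costs per occupied cycle are drug acquisition (a separate
loading-dose price in a line's first cycle, e.g. infliximab 2792 vs 1654),
expected adverse-event cost (probability × episode cost for pneumonia,
herpes zoster, tuberculosis, hepatitis B), and supportive-care
non-pharmacological care (steroid injections + biweekly physiotherapy),
removable via a flag.  Adverse events affect cost only — no utility
decrement or extra discontinuation — matching how the source framework
describes them.

## Key parameters

| Parameter | Default | Units / notes |
|---|---|---|
| cycle length | 0.5 | years |
| discount rate | 0.035 | per year, scenario 0–0.05 |
| WTP threshold | 48 555 | US$/QALY |
| baseline age / HAQ-DI | 56 / 1.6 | years / scale 0–3 (range 1.2–2.0) |
| mortality hazard ratio | 1.33 | per HAQ-DI point |
| ACR20/50/70, first line | per drug | e.g. leflunomide 62/38/7% |
| discontinuation, first line | 36.5 / 15.4 / 12.9 | %/cycle (leflunomide / infliximab / adalimumab) |
| drug cost per cycle | 124 / 1654 / 940 | US$ (leflunomide / infliximab / adalimumab) |
| supportive-care non-pharma course | 2891 | US$/cycle (steroid 291 + physiotherapy 2600) |

Every uncertain parameter carries a distribution family (Dirichlet for ACR
splits, beta for probabilities, gamma for costs and HAQ-change magnitudes)
and, when no SD is reported, the 25%-of-mean convention.

## Synthetic inputs and what they do (not) show

The published first-line inputs are reproduced exactly; three inputs are not
publicly deposited and are generated by `synthetic_data` with a frozen seed,
tagged `synthetic` in the provenance manifest:

- **Life table** — Gompertz–Makeham hazards per sex (annual q = 1 −
  exp(−(A + B·e^{Cx}))), parameterised for a long-lived urban population:
  life expectancy ~82/77 years at birth (female/male) and ~27 remaining
  years at the cohort entry age of 56.  No infant-mortality hump; irrelevant
  for a cohort entering at 56.
- **Subsequent-line classes** — per-drug costs, discontinuation, adverse
  events and HAQ-DI changes drawn once around plausible anchors and pooled
  by (synthetic) market share.  Per-cycle class costs sit inside the
  originator price band printed for this market (US $3609–$7073 per cycle
  for originator infliximab/adalimumab): in 2022 these classes were
  originator-dominated, and only at that cost scale do the model's lifetime
  totals reach the published order of magnitude (~US $120k vs ~US $150k
  lifetime for the leflunomide sequence).  TNFi efficacy is split into
  TNFi-naive (used after leflunomide) and TNFi-experienced (used after a
  biosimilar TNFi), with the experienced improvement never stronger.
- **Supportive-care costs** — management US $550/cycle plus the
  non-pharmacological course anchored at the printed US $2891.

Because these stand-ins replace real supplementary tables, the bundled
fixture reproduces the published analysis *qualitatively* — both
biosimilar-first sequences dominate leflunomide, the deterministic one-way
excursions all stay below the WTP, and the PSA picks adalimumab-first in
~90% of iterations — but not the printed lifetime totals.  Passing tests
therefore validate the machinery and the direction of every published
claim, not the exact published magnitudes, which depend on data we cannot
redistribute.

## Sensitivity and scenario analyses

**PSA** (`run_psa`): all uncertain parameters drawn jointly and
independently each iteration — no correlation structure is specified by the
source framework.  Beta and gamma are fitted by method of moments (with the
25%-SD rule, gamma shape is exactly 16); negative-mean quantities are
sampled as gamma on the magnitude with sign restored; infeasible beta
moments fall back to a uniform on the declared range with a warning.  The
Dirichlet effective sample size N solves a least-squares fit of
sqrt(s(1−s)/(N+1)) to the reported cumulative-component SDs.  Parameters
shared between strategies (pooled lines, supportive care, episode costs)
receive one draw per iteration.  Substreams are counter-based
(`SeedSequence((seed, iteration))`), so results are independent of
evaluation order.  The CEAC assigns each draw to the strategy with the
highest net monetary benefit (NMB = WTP × QALY − cost); exact ties split
credit equally (measure-zero under continuous draws, relevant only for
degenerate tests).

**DSA** (`tornado_dsa`): one-way excursions over each scalar parameter's
95% CI — the printed range where available, else mean ± 1.96 SD.  ACR
response triples print no range and are varied jointly in the PSA only.
Entries are sorted by ICER bar width per comparison pair; an entry whose
base-case ICER falls outside its [low, high] ICER interval is flagged
non-monotone.

**Scenarios** (`run_scenarios`): alternative linear HAQ→utility mappings
(two bundled alternates, labelled synthetic, coefficients in the config),
horizon 5–40 years, discount 0–5%, baseline age 56 ± 5, a simplified
sequence (first-line failure → supportive care directly), and removal of
non-pharmacological supportive-care costs.  Scenario 0 is always the
untouched base case.

## Numerical choices

- Occupancy conservation (alive + dead = 1) is asserted every cycle at
  1e-8 (hard failure); traces achieve ~1e-15.
- ICERs are reported as the raw ratio even when negative (dominance is
  reported alongside); |ΔQALY| < 1e-12 flags the ICER undefined while the
  NMB comparison still decides cost-effectiveness.
- Report rounding: costs to whole US$, QALYs to 2 d.p., ICERs to whole
  US$/QALY; the unrounded pipeline is kept internally.
- The supportive-care tunnel is enumerated until HAQ-DI reaches 3 (then a
  single absorbing state); with a non-positive late-cycle increment the
  tunnel closes after the steroid window instead.
- Degenerate inputs: zero-width parameter ranges yield zero-width tornado
  bars; a one-hot market share returns the selected drug exactly; shares
  not summing to 1 are renormalised with a warning.

## Problem sizes

The bundled analyses use 88 cycles (age 56→100), PSA with 10 000 iterations
from the command line and 1 000 in the reproduction script and tests (the
CEAC winner probabilities are stable to ~1% at that size), and a
100 000-patient microsimulation as the engine's independent oracle.

## Limitations

- Cohort-level blended-sex mortality; no individual heterogeneity beyond
  the ACR strata, no treatment re-challenge or dose escalation.
- Healthcare-payer perspective only; productivity losses are not modelled.
- The synthetic subsequent-line and life-table values are plausible
  stand-ins, not estimates; absolute outputs from the bundled fixture
  should not be quoted as re-estimates of the published totals.
- "Every other cycle" in the supportive-care trajectory is read as "each
  subsequent cycle"; the leflunomide discontinuation probability is treated
  as per-cycle, as tabulated.
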