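# Methods

This note records the modelling conventions `dmburden` uses, why each was
chosen where a choice was open, and what the tests do and do not establish.

## Model structure

Six conceptual states — incident diabetes (Di), existing prevalent diabetes
(Dep), incident complications (Ci), existing prevalent complications (Cep),
death due to diabetes, death due to other causes — with irreversible
progression and absorbing death states. "Existing prevalent" is the
complement of incident within prevalent: cases already under care at the
index year, which empirically carry different complication and death
hazards than newly diagnosed ones. Incident cases convert to the prevalent
state after five years; the engine implements this with 5-cycle tunnel
states (Di1..Di5, Ci1..Ci5), so the expanded space has 14 states. A
Di→Ci transition always enters Ci1: the complication clock restarts at
complication onset.

Aging: the cohort's integer age advances one year per cycle, and the
probability row in force is the one for the 5-year age group containing the
current age; beyond 85 the 85+ row applies indefinitely. The age trajectory
only moves through group boundaries at cycle boundaries, so no within-cycle
blending is needed.

## Key parameters

| parameter | default | meaning / rationale |
|---|---|---|
| `discount_rate` | 0.05 /year | opportunity-cost discounting of future health years |
| `cycle_length` | 1 year | claims-data resolution and the published convention |
| `horizon` | 100 cycles | upper cap on simulated cycles |
| `max_age` | 100 years | simulation endpoint: valuation stops when the cohort reaches age 100 (set `None` to disable) |
| `tunnel_length` | 5 cycles | incident→prevalent conversion after five years |
| `washout_years` | 3 | claim-free full calendar years required before an index-year diagnosis counts as incident |
| `min_events` | 5 | neighbour-age smoothing threshold for death transitions |
| `duration_days` | 0 | assumed diabetes→complication gap for reverse-diagnosed cases (0/180/365) |
| `start_age_offset` | 1 | entry age = group lower bound + offset |
| `yll_method` | simple | residual life expectancy per death; `annuitized` discounts the lost years from death |
| `discount_timing` | end | accrual discounted at the end-of-cycle boundary; `start` leaves cycle 1 undiscounted |
| disability weights | 0.334 / 0.663 | published severity weights for diabetes without/with complications; interval bounds are user inputs (they collapse to the point when not supplied, since the source interval endpoints are not published) |

## Valuation conventions

Several conventions behind the published per-group results are not stated
in words anywhere; they were fixed by probing the small set of standard
alternatives against the published per-group YLD values and peak locations,
then frozen. The package's defaults are the combination that reproduces
those results; each alternative remains available as a configuration
switch.

- **YLD accrual.** Transitions happen at cycle end. A member who lives
  through cycle k accrues the disability weight of the state occupied
  during cycle k; mass that dies during a cycle accrues nothing for that
  cycle; mass that moves to a complication state accrues the uncomplicated
  weight for its transition cycle. Accrual is discounted at the end-of-cycle
  boundary. No half-cycle correction is applied.
- **Endpoint.** Valuation stops at age 100 (the range of the complete life
  tables this model family is built on), bounded additionally by the
  100-cycle horizon. With an unbounded tail the older female cohorts
  accumulate implausible complication-state years, because the 85+ row's
  death probabilities are applied forever.
- **YLL.** Only diabetes-coded deaths count. Each unit of newly dead mass
  at cycle boundary j is worth the residual life expectancy at its age of
  death (`simple`, default), discounted to cohort entry by (1+r)^-j. The
  annuitized variant ((1-(1+r)^-RLE)/r) is provided but reproduces the
  published YLL peak roughly 40% low, so it is not the default.
- **Starting age.** Entry age defaults to the group's lower bound + 1
  (56 for 55–59). The midpoint (+2) reproduces the published YLD values
  slightly more tightly but misplaces the male complicated-YLD peak in a
  0.8% near-tie between 55–59 and 60–64; +1 is the unique offset consistent
  with both the published values (within 4%) and all published peak
  locations.
- **Per-100,000 denominators.** Per-group figures divide by the population
  implied by the printed incidence (IC/IR×1000, rounded to persons). Sex
  totals are reported both over the summed 30+ derived population and —
  matching how headline national figures are normalised — over an optional
  all-ages population (≈25.6M per sex for Korea 2016).

## Claims derivation

- **Classification.** Incident: first diabetes claim in the index year with
  no diabetes claims in the three preceding full calendar years; the claim
  date is the index date. All other diabetics are existing prevalent cases
  indexed at January 1 (a deliberate convention: their true onset is
  unobservable, which biases their estimated hazards upward). A case whose
  complication history starts with an E-class complication code at or
  before diagnosis is reclassified as prevalent-with-complications, since
  E-class codes denote diabetic complications and imply established
  diabetes.
- **Person-time.** One spell per occupied state, exact day counts divided
  by 365 (not 365.25, matching the source's day arithmetic). Death dates
  are known to the month and resolve to the last day of the month — the
  only convention consistent with the published 578-day worked example
  (complication index June 1, 2014; death December 2015 → December 31).
  All exits from a state share its full person-time at risk (competing-risk
  rates).
- **Pooling and smoothing.** Death-transition estimates pool events and
  person-years across annual complication cohorts before dividing (never
  averaging probabilities), and are then smoothed by merging each age group
  holding fewer than `min_events` events with its adjacent older group
  until every pool reaches the threshold; every member of a merged pool
  reports the pooled estimate. Complication-incidence transitions are left
  unsmoothed.
- **Mortality substitution.** When a general-population mortality table is
  supplied, other-cause death probabilities are floored at the general
  value, and a zero probability for either death cause in the 30–34 group
  is replaced by the general value. The packaged published tables already
  embed this step, so runs on them apply zero substitutions.
- **Complication-timing assumption.** Over-60-class complications diagnosed
  before the diabetes index (pre-existing stroke/IHD histories) have no
  observable diabetes→complication gap. The assumption places their
  complication index `duration_days` after the diabetes index, capped at
  censoring; event counts are invariant and only the Di/Ci person-time
  split moves. This is why the sensitivity analysis barely moves DALYs: on
  a fixed probability table it changes nothing at all, and re-deriving from
  records moves only the 60+ age groups, by a few tens per 100,000 in
  either direction (lengthening the gap shortens complication-state
  person-time, raising complication mortality at old ages). A burden-level
  reattribution of every transition cycle's weight was considered and
  rejected: it would move DALYs by hundreds per 100,000, concentrated in
  the youngest groups — the opposite of the published pattern.

## Synthetic claims

The generator draws competing exponential waiting times per person through
onset → incident diabetes → complication → death, with tunnel conversion to
the prevalent states after five years, on a 13-year observation window
(2004–2016). It reproduces the data artifacts the derivation rules target:
month-coarsened death dates, pre-window diabetes histories with annual
maintenance claims (so washout classification yields both case types),
E-class vs over-60-class complication codes, same-day complications at
diagnosis, and reverse-diagnosed complication claims. Ties between a
complication and a death drawn at the same instant resolve to the
complication first.

Simplifications relative to real claims: hazards are looked up by the
person's age group at state entry and held constant through the spell
(semi-Markov; exact when rates are age-constant); non-diabetic mortality is
not simulated (it only thins denominators); ages are assigned uniformly
within 5-year bands anchored at the default index year so that every
estimation cell is populated there; there is no coding noise, no provider
structure, and no churn in enrollment. Passing recovery tests therefore
establish that the derivation rules are correct under their own stated
assumptions — not that the rules are robust to real-world claims artifacts
beyond those modelled.

The recovery experiment (`recovery_profile`) additionally sets the incident
and prevalent variants of each hazard equal and disables at-diagnosis and
reverse complication cases, so that washout misclassification of recent
onsets (inherent to any washout shorter than the tunnel) cannot bias the
comparison; those rules are exercised by their own targeted tests instead.

## Numerical choices

- Mass conservation is asserted at 1e-12 per cycle inside the engine.
- Probability validation allows exit sums up to 1 + 1e-12 and clips
  negative residuals of at most -1e-12 to zero.
- `p = 1 - exp(-rt)` uses `expm1`/`log1p`; round-tripping through the
  inverse is accurate to ~1e-9 for rates up to 10/year.
- The synthetic life table uses a Gompertz–Makeham force of mortality with
  the level calibrated by Brent root finding so that life expectancy at
  birth is 79.3 (male) / 85.4 (female) years, the approximate Korea-2016
  values; residual expectancies come from trapezoidal integration on a
  monthly grid to age 130. It is a stand-in, labelled synthetic: per-age
  residual expectancies can differ from the official table by a year or
  more, which is the main driver of the remaining gap in the headline DALY
  totals (~5–7% low).
- Life tables are never interpolated: a missing age in 30..130 is an error.

## Known limitations

- One aggregate disability weight per severity level; complication-specific
  weights (retinopathy vs stroke vs neuropathy) are out of scope.
- No age weighting, no treatment effects, no costs.
- The published 95% CI endpoints for the disability weights are not
  reprinted in the source tables, so interval bounds must be supplied by
  the user; defaults collapse to the point estimates.
- Sex totals depend on an external all-ages population figure; per-group
  results do not.
- The claims derivation estimates each transition with a single
  time-constant hazard per cell; duration dependence within a state beyond
  the incident/prevalent split is not modelled.
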