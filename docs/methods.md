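# Methods

## Question and framing

`hbocscreen` implements a decision-analytic cost-effectiveness model
comparing two strategies for a cohort of previously undiagnosed US women of
a single age: population-wide genomic screening for pathogenic variants in
eight hereditary breast and ovarian cancer (HBOC) genes (*BRCA1*, *BRCA2*,
*ATM*, *CHEK2*, *MSH6*, *PALB2*, *RAD51C*, *TP53*) versus the status quo of
family-history-based testing only.  The perspective is the US health care
sector (direct medical costs, 2019 USD); costs and health outcomes are
discounted at 3% per year; cycles are annual; the horizon is lifetime (to
the life table's terminal age, whose death probability is 1).

## Model structure

A decision tree distributes the entering cohort across strata defined by
gene, identification status, and surveillance choice.  In the screening
arm, a fraction 1 − `avoid_screening` participates and is tested
(sensitivity 0.991, specificity 0.999); non-participants and false
negatives can still be identified through the family-history route
(probability 0.174), which is the only identification route in the
comparator arm.  Identified carriers choose intensive surveillance
(mammography + MRI) with probability `mri_uptake` = 0.75, otherwise
mammography only.  The assay cost is charged per participant and the
confirmation cost per positive result, true or false; false positives
return to the noncarrier pathway after confirmation.  Family-history
testing itself is not costed: it is identical in both arms and cancels
from every incremental quantity.  Carriers identified through the
family-history route inside the screening arm are not charged the assay
(they bypass screening).  Learning one's carrier status carries a one-year
disutility of 0.05, applied in the first cycle in both arms.

Each stratum then runs through an annual-cycle Markov cohort model with
states: two precancer monitoring states (with/without MRI); one-year tunnel
states for incident early- and late-stage breast and ovarian cancer and
for each risk-reducing surgery (mastectomy, RRM; salpingo-oophorectomy,
RRSO); after-cancer states by site and stage; after-RRM, after-RRSO and
after-both states; and absorbing death.

### Transition construction

Rows are built to sum to 1 exactly and are verified, never renormalized.
Background death (probability `qx` from the life table) is resolved first;
the competing events among survivors — RRM uptake, RRSO uptake, breast
cancer, ovarian cancer — are decomposed into mutually exclusive first
events on the rate scale: with rates `r_i = -ln(1 - p_i)` and total `R`,
event `i` receives `(1 - qx) * (r_i / R) * (1 - e^{-R})`.  Because events
within a cycle are mutually exclusive by construction, no ordering rule
for same-cycle RRM + RRSO is needed; a woman can still acquire the second
surgery in a later cycle (after-RRM → after-both carries the oophorectomy
cost and disutility on the flow, and symmetrically).

Annual event probabilities come from:

* **Cumulative curves.** Conditional annual probability among the
  event-free: `p(a) = (F(a+1) - F(a)) / (1 - F(a))`.  *BRCA1/2* carriers
  use gene-specific cumulative incidence curves; the other six genes use
  general-population incidence adjusted on the odds scale by the gene's
  odds ratio (exact, not rare-disease approximated, which keeps
  probabilities in [0, 1) even for the ovarian odds ratios above 18);
  gene-cancer pairs without a published odds ratio keep baseline risk.
  Noncarriers use the population curves.
* **Surgical uptake.** Identified carriers only.  *BRCA* carriers follow
  the cumulative uptake curves; non-*BRCA* carriers scale the conditional
  annual uptake on the rate scale by the 0.5 rate ratio.  Women who have
  had cancer, or who are in a surgery-year tunnel, accrue no further
  uptake; the surgery year itself is modeled without competing cancer
  incidence (a one-year deferral, negligible at annual probabilities of a
  few percent).
* **Hazard ratios.** Post-surgical residual risk multiplies the rate:
  `p' = 1 - (1 - p)^HR`.  RRM removes breast cancer risk (HR 0); RRSO
  reduces breast cancer risk (HR 0.63 / 0.36 / 0.36 for BRCA1 / BRCA2 /
  non-BRCA) and ovarian risk (HR 0.31 / 0 / 0).  After both surgeries the
  hazard ratios compose multiplicatively on the rate scale.
* **Cancer mortality.** The published 5-year relative mortality `m5` by
  age band is converted to a constant annual excess death probability
  `1 - (1 - m5)^{1/5}`, added to background `qx` (capped at 1).  Early-stage
  breast cancer multiplies the excess by (1 − 0.943), the early-stage
  mortality risk reduction; the alternative reading (multiplier 0.943
  itself) is selectable via `settings.early_stage_reduction_as_multiplier`.
  The excess persists in after-cancer states by default
  (`settings.excess_mortality_persists`), since the sources give no
  cure-point; the age band follows current age.  The reduction parameter
  is breast-specific; early- and late-stage ovarian cancer therefore share
  one excess mortality, and an ovarian stage shift changes case-stage
  counts but not deaths.

### Stage at diagnosis

The stage split at diagnosis is the single largest input the sources do
not print.  It lives in `settings.stage_policy` as an explicit assumption:
probability of early stage 0.8 under mammography + MRI, 0.5 under
mammography only, 0.5 for unidentified carriers and noncarriers.  The same
split is applied to ovarian cancer for lack of any published
modality-specific ovarian stage data.  These defaults are calibration
hooks, not published values; all headline identities and directional
results here are insensitive to them, but absolute case-stage counts are
not comparable to published stage splits.

### Accrual

End-of-cycle accrual with no half-cycle correction: the cohort occupying a
state at the start of cycle *t* accrues that state's cost and utility at
discount factor `(1 + r)^-(t+1)`; one-time quantities attached to flows
(palliative last-year cancer cost on any cancer-state → death transition,
second-surgery cost/disutility) discount the same way.  Healthy
(monitoring and post-surgical) states have utility 1.0; surgery years
carry their 0.03 disutilities; cancer-year and after-cancer states use the
published utilities.  Mammography is costed in monitoring states for all
women and, with MRI where chosen, continues after RRSO alone; after RRM
no breast surveillance costs accrue.  Life-years count one year per cycle
entered alive (deaths at cycle end), and `LifeTable.life_expectancy` uses
the same convention so the zero-discount, zero-cancer identity holds to
1e-6.  Case counts are undiscounted.

## Cascade testing

Cascade testing attaches to carriers detected by the screening assay
(family-history-identified carriers cascade identically in both arms and
cancel).  Expected surviving relatives per index carrier of age *a*:
mother aged *a* + 27 and sisters aged *a* (one each by default), daughters
aged *a* − 27 (none if *a* < 27), each weighted by life-table survival to
that age; ages below the adult table are treated as certain survival.
Informed (0.70) and tested (0.20) relatives carry the variant with
probability 0.5 and are detected with the assay sensitivity.  Each
detected relative contributes her identified-minus-unidentified outcome
difference at her own age (MRI choice and knowledge disutility included);
relatives younger than the modeled range enter at its lower bound with
discounted deltas shifted back over the waiting years.  Testing costs are
assay per tested relative plus confirmation per positive.  Second-order
cascade (relatives of relatives) and male relatives are out of scope.

## Scenarios

* **No cascade** removes the increment exactly (the combined result minus
  the cascade increment, by construction).
* **Noncarrier harm**: screened noncarriers who receive a negative result
  may relax mammography adherence.  The printed parameterization (a
  "lifetime disutility of 0.03% on 5% of screened noncarriers") is
  ambiguous; a one-time 0.03 QALY loss on 5% of screened noncarriers
  reproduces the published QALY drop (≈142 per 100 000 30-year-olds) and
  is the default, with the lifetime-annual reading available via
  `settings.harm_mode`.  The decrement is participation × (1 − prevalence)
  × 0.05 × 0.03 per woman, subtracted undiscounted from the screening
  arm's QALYs.

## Uncertainty analysis

One-way analysis moves one parameter to each bound (members of the gene
proportion block renormalize the rest of the block) and reports the ICER
at both, sorted by bar width.  The probabilistic analysis samples every
non-fixed parameter:

* **Beta** (proportions, utilities): moment-matched to mean = base and
  sd = (high − low)/3.92, with the variance capped so both shape
  parameters stay ≥ 1 — the cap binds only for near-boundary parameters
  (test sensitivity/specificity), whose printed ±20% ranges are infeasible
  for a beta mean of 0.99+; the mean is preserved exactly in all cases.
* **Normal** (costs): mean = base, sd = (high − low)/3.92, truncated at 0.
* **Log-normal** (odds/hazard ratios, relative mortality): parameterized
  so the sampled 2.5th/97.5th percentiles reproduce the printed 95%
  interval exactly (μ = midpoint of the log interval, σ = log-width/3.92).
  For log-symmetric intervals this coincides with median = base; for the
  strongly asymmetric ovarian odds-ratio intervals (e.g. *TP53*,
  2.56–808.10 around 18.50) no log-normal can match both the base value
  and the interval, and the interval is taken as authoritative.
  Proportion-like draws are clipped below 1.
* **Dirichlet**: the eight gene proportions jointly, with concentration =
  base proportions × 100 (configurable), so draws sum to 1 exactly.
* **Fixed**: hazard ratios printed as exactly 0 and structural rates are
  never sampled.

Each draw re-runs the full pipeline.  Draw *i* uses an independent
substream seeded by (seed, *i*), so results are reproducible, independent
of execution order, and a shorter run is a prefix of a longer one.  95%
credible ranges are 2.5th–97.5th percentiles across draws; the
cost-effectiveness acceptability curve is the fraction of draws with
nonnegative incremental net monetary benefit λ·ΔQALY − ΔCost at each
willingness-to-pay λ, reported at the 50/100/150 k$ thresholds plus a fine
grid.

## Synthetic inputs

The externally sourced inputs — gene-specific cumulative cancer incidence,
cumulative *BRCA* surgical uptake, general-population incidence, and the
background life table — are not available in machine-readable form, so the
package generates structural stand-ins: logistic cumulative curves (zero
at age 20, target level at 80, half-level at a midpoint age) and a
Gompertz–Makeham adult life table (remaining life expectancy ≈ 53 years at
age 30).  Their shapes encode the two features the analysis turns on —
surgical uptake concentrated before age 50 (midpoints 38/44), cancer
incidence concentrated after 50 (midpoints 50–63) — and their lifetime
levels are plausibility-scaled placeholders of the right magnitude for
high-penetrance carriers and the general population.  They are **not**
digitized published curves: passing tests demonstrate internal
correctness, arithmetic identities and directional behaviour (ICER rising
with screening age; cascade removal raising the ICER), not numeric
reproduction of published ICERs, which requires supplying digitized curves
via `hbocscreen.load_curves`.  Real incidence and uptake curves are not
logistic, real life tables are not Gompertz–Makeham, and period-cohort
effects, competing non-cancer morbidity and carrier-specific background
mortality are all absent.

## Numerical choices and problem sizes

Traces run in exact cohort fractions (no Monte Carlo error in the base
case); matrices are built vectorized over ages and verified row-by-row at
1e-9.  Degenerate inputs raise: saturated cumulative curves, probability 1
into rate conversion, row-sum violations, non-conserving traces.  The
engine-oracle check uses a frozen three-state toy chain against a
100 000-path individual microsimulation at 3 Monte Carlo standard errors.
The packaged probabilistic analysis uses 500 draws (the study design this
emulates uses 5000); credible ranges at 500 draws carry sampling noise of
a few percent on the interval endpoints.

## Known limitations

Stage-split inputs are assumptions (above); second primary cancers and
surgery after a cancer diagnosis are not modeled; cancer treatment
pathways are phase-cost aggregates; the harm scenario's two published
summary numbers cannot both be reproduced under any single reading of the
harm parameter (the QALY-drop reading is implemented); and all absolute
results on the packaged synthetic curves are illustrative, not estimates
for any real population.
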