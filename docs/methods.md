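# Methods

`chwplan` models the resource requirements of a ward-based community health
worker (CHW) programme across geographical site classes (peri-urban, rural,
deep-rural), using two South African districts — Sedibeng (Gauteng) and
uMzinyathi (KwaZulu-Natal) — as its bundled reference case. This note
documents the models, the parameters that matter, the synthetic-data design
and its limits, and the numerical conventions.

## Time-use analysis

The unit of analysis is the *activity episode*: one diary row with travel
minutes and activity minutes plus, for home visits, content, condition and
recipient codes. Analyses treat episodes as independent; there is no
adjustment for clustering within CHW or day, and the output metadata should
be read with that in mind.

* **Medians** are reported separately for travel and activity time per
  (district, site class, activity); even-count medians use the midpoint of
  the two central order statistics.
* **Share of time** per broad activity group divides the summed *combined*
  (travel + activity) minutes of the group by the cell total, so travel is
  inside the denominator. Shares within a cell sum to 1.
* **Median contrasts** between site classes use a 0.5-quantile regression
  of minutes on an intercept and a group indicator. For this two-group
  design the least-absolute-deviations solution has the closed form
  `coef = median(B) − median(A)`; the package computes it directly and the
  test suite verifies the identity against an iterative quantile-regression
  fit on odd-count data (where the LAD solution is unique). Inference is a
  seeded nonparametric bootstrap (default 1,000 resamples drawn within each
  group): the p-value is the two-sided percentile p (twice the smaller tail
  mass of the bootstrap coefficient around zero) and the 95% CI is the
  percentile interval, widened to include the point estimate in degenerate
  discrete cases so that `ci_low ≤ estimate ≤ ci_high` always holds.
  The closed form makes each bootstrap replicate a pair of medians, so a
  200-replicate type-I calibration runs in about a second; the calibration
  test requires the null rejection rate at α = 0.05 to lie in [0.02, 0.10].
* **Overall differences** use the Kruskal-Wallis rank test with tie
  correction (implemented via `scipy.stats.kruskal`; the test suite checks
  it against a hand-written rank-formula oracle on exhaustively enumerated
  small datasets). All-tied inputs are defined as H = 0, p = 1.
* **Proportion contrasts** use the two-sided pooled two-proportion z-test
  without continuity correction (`statsmodels` `proportions_ztest`); z²
  equals the 1-df chi-square statistic on the same 2×2 table. When the
  pooled proportion is 0 or 1 the statistic is defined as z = 0, p = 1.
* Significance for report tables is flagged at α = 0.05, as a boolean
  column. No multiple-testing adjustment is applied (the reference analysis
  reports unadjusted per-cell tests).

**Composition conventions.** Content frequencies are per-visit occurrence
rates (fraction of home visits in which a code occurs; codes co-occur, so a
column need not sum to 1). Condition and recipient frequencies count each
recorded code once and normalize over all recorded codes, so those columns
sum to 1. The source tables do not state their denominators — several
printed columns sum to 104–118% — so these conventions are this package's
own, stated in the output metadata, and the recovery tests use them.

## Synthetic diary generator

The generator emulates the study conditions: 111 CHWs in Sedibeng (75
peri-urban / 36 rural) and 110 in uMzinyathi (25 peri-urban / 85
deep-rural), 10 diary days each, and a Poisson number of episodes per
CHW-day (mean 8, truncated at ≥ 1; episode counts are not published, and 8
episodes over a 6–8 hour day is a realistic field workload).

* **Durations** are log-normal, parameterized by the published median
  (median = exp(μ)) and a log-scale dispersion σ (default 0.6). Only
  medians are published and the source notes the data were not normally
  distributed, so a right-skewed positive law is the natural emulation; the
  true dispersion is unrecoverable and the default is arbitrary and
  documented as such. Durations are rounded to whole minutes with a floor
  of 1; σ = 0 degenerates to the median exactly.
* **Activity mix.** With a common σ, the expected duration of an activity
  is proportional to its median, so episode probabilities set to
  `share(a) / (travel_median(a) + activity_median(a))`, normalized, make
  the *expected* share of combined time per activity equal the published
  share column. Rows printed as 0% (< 0.5%) absorb an equal split of the
  column's rounding residue so the non-zero rows hit their printed values
  exactly in expectation. The Sedibeng home-visit share (66% / 57%) spans
  three diary rows (registration, screening, other) and is split evenly
  across them.
* **Visit attributes** are generated for home-visit episodes only: content
  codes as independent Bernoulli occurrences at the printed rates, one
  condition code per episode (printed column renormalized to sum to 1),
  and 1–3 recipients (one guaranteed plus up to two extras at 5% each,
  matching the reported average of 1.1 recipients per visit), drawn
  categorically and de-duplicated.

What passing recovery tests show: the analysis pipeline correctly inverts
this generative model at realistic sample sizes. What they do not show:
robustness to features of real diaries the generator omits — within-CHW
day-to-day correlation, spatial travel structure, missing or misrecorded
entries beyond what the validator rejects, and correlation between an
episode's duration and its content.

## Costing

Ingredient-based costing with two cost categories: set-up items annualized
by straight-line depreciation (`unit_cost × quantity × allocation_share /
life_years`) and recurrent items (life of one year). Allocation shares
attribute shared resources to the programme (35% of health posts, 55% of
professional-nurse time, 50% of the assistant director) as ordinary
ingredient fields, not special cases. Panel subtotals receive a
proportional overhead mark-up (8% in Sedibeng, none in uMzinyathi), so
`total = subtotal × (1 + overhead_rate)` exactly. District metrics combine
all panels: cost per capita (district total / population), cost per CHW
(district total / CHW count) and the PHC share (per-capita cost as a
percent of PHC expenditure per capita: R1,200 Sedibeng, R1,150 uMzinyathi).
USD conversion uses a fixed configurable rate (14.3 ZAR/USD).

A few printed annualized cells differ from unit-cost arithmetic by up to
1.3×10⁻⁴ relative because the source tables round their unit costs.
Ingredients therefore carry the printed annualized value in
`published_annual`; exact reconstructions use `use_published=True`, while
unit-cost-derived lines are validated at a relative tolerance of 2×10⁻⁴.
Display rounding is half-away-from-zero to whole ZAR (percentages to one
decimal); internal arithmetic is unrounded.

Cost-class shares (e.g. training as a percent of expenditure) divide the
class's lines by the panel/district total; overheads carry no class, so all
classes together account for `100/(1 + overhead_rate)` percent. The
published management/supervision shares (28% and 16.7%) and uMzinyathi's
5.8% training share do not reproduce from the printed line items under any
obvious grouping; the package reports its own computed shares (training in
uMzinyathi computes to 4.0%) and does not treat those published shares as
targets.

## Workforce requirements

A workload-indicator calculation per district × site class, per 100,000
total population:

1. Modelled home-visit needs per service type at 70% coverage are inputs
   (the upstream demographic/burden-of-disease needs model is out of
   scope). `derive_visit_needs` back-derives them from per-service hour
   tables (`visits = hours × 60 / minutes_per_visit`) so the bundled
   fixtures are self-contained; coverage is stored on the needs object and
   rescales multiplicatively.
2. `required_hours` converts visits back to hours with the observed median
   combined minutes per visit and sums over services.
3. `available_hours = duty_days × duty_hours × share_home_visits` (200
   days; 6 h/day Sedibeng vs 8 h/day uMzinyathi; home-visit time shares
   66/57/55/49%).
4. `chws_required = total_hours / available_hours × chws_per_visit`, with
   team size 2 in Sedibeng (CHWs pair up for security) and 1 in uMzinyathi.
   Pairing multiplies the requirement; it does not halve available hours.

Rounding ladder: CHW counts are displayed as integers (half away from
zero), but the *relative* requirement between site classes and the
households-per-CHW norm both use the unrounded ratio — the only convention
under which the published +33%/+62% differences and the 169/96 household
norms all reproduce (integer-rounded counts would give +61% for
uMzinyathi). Both values are retained in `WorkforceResult`. The household
norm scales the 250-household peri-urban guideline down by the extra
requirement: `250 × (1 − (ratio − 1))`.

Utilization rates are simple per-capita divisions of facility and
home-visit headcounts; the bundled records are illustrative (chosen to
match the published rounded rates) because the published totals were
computed before rounding and are not recoverable from the printed cells.

## Scenario analysis

The minimum-wage scenario replaces each CHW stipend line with
`12 × new_stipend × quantity` (R3,500/month default) and recomputes the
full summary, so the overhead rate reapplies to the incremented subtotal —
the convention that reproduces the published 25% Sedibeng increase (without
it the figure is 23%). Supervisor stipends below the new wage can be raised
with `raise_supervisors`; that option reproduces uMzinyathi's published
post-increase per-capita R48, while the published 71% uMzinyathi district
increase does not reproduce under any tested convention (CHW-only raise
computes 68.1%, CHW + supervisor 69.7%) and is not treated as a target.

## Pipeline and problem sizes

`run_pipeline` simulates the four study cells, writes the diary file, the
ten report tables, a significance-test table, a manifest (seed, versions,
SHA-256 digests of every report) and a log with per-stage record counts.
Given a seed, all reports are byte-identical across runs. Default problem
sizes are the study's own (221 CHWs × 10 days, ≈ 18,000 episodes; 1,000
bootstrap resamples per contrast), which run end to end in a few seconds.
Recovery tests that assert ratios of heavy-tailed sums (time shares) use a
larger simulated workforce (300 CHWs) purely to keep Monte Carlo error
small relative to the ±2-point tolerance.

## Known limitations

* Episode independence: no CHW- or day-level random effects, so standard
  errors on real (clustered) diary data would be larger than on synthetic.
* The duration dispersion and the episodes-per-day mean are conventions,
  not estimates.
* Costing covers provider-perspective financial costs only: no discounting
  beyond straight-line annualization, no inflation adjustment, no CHW
  out-of-pocket costs.
* The workforce model assumes the current service mix and visit durations;
  it redistributes coverage, it does not re-optimize the package of care.
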