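# chwplan

Planning analytics for community health worker (CHW) programmes: time-use
diary analysis, ingredient-based programme costing, geography-specific
workforce-requirement estimation and stipend scenario analysis. The bundled
reference case is South Africa's ward-based outreach team (WBOT) programme
in two districts — Sedibeng (Gauteng; peri-urban and rural farm sites) and
uMzinyathi (KwaZulu-Natal; peri-urban and deep-rural sites).

## The problem

CHW programmes are planned with flat norms (one CHW per 250 households),
but home visits take longer and CHWs spend a smaller share of their time on
visits in rural and deep-rural areas, so flat norms under-resource exactly
the areas with the worst access. `chwplan` is for health economists and
district planners who need to quantify that gap: how much does the
programme cost, how many CHWs does a geography actually need, and what does
a stipend change do to the budget?

## The models

**Time use.** Activity diaries (one row per episode with travel and
activity minutes) are summarized as medians per activity × site class and
shares of combined time per activity group. Site-class contrasts use a
0.5-quantile regression of minutes on a group indicator — whose coefficient
is the difference of group medians — with a seeded bootstrap for inference,
the Kruskal-Wallis rank test for overall differences, and the pooled
two-proportion z-test for composition frequencies.

**Costing.** Ingredient-based: every line is
`unit_cost × quantity × allocation_share / life_years` (straight-line
annualization of capital; life of 1 year for recurrent items), panels get a
proportional overhead mark-up, and district metrics are cost per capita,
cost per CHW and the share of primary-health-care (PHC) expenditure per
capita.

**Workforce.** A workload-indicator calculation per 100,000 population:
modelled home-visit needs at 70% coverage × median minutes per visit give
required hours; one CHW supplies `duty_days × duty_hours ×
share_of_time_on_home_visits` hours per year; the ratio (times the team
size, where CHWs work in pairs) is the requirement. The requirement ratio
between site classes rescales the 250-household peri-urban norm.

**Scenarios.** Stipend lines are rescaled to a new monthly stipend (the
R3,500 national minimum wage by default), overheads reapply to the new
subtotal, and all expenditure metrics are recomputed.

A synthetic diary generator (log-normal durations centred on the published
medians, activity mix matching the published time shares, categorical visit
attributes) stands in for the original field data, so the entire pipeline
runs and is testable with no external inputs. See `docs/methods.md` for the
full model description and conventions.

## Worked example

```bash
$ chwplan cost --district uMzinyathi --out out/
uMzinyathi: total R14,404,959, R29,948 per CHW, 2.4% of PHC expenditure per capita

$ chwplan workforce --district Sedibeng --out out/
Sedibeng/peri_urban: 168 CHWs per 100,000
Sedibeng/rural: 223 CHWs per 100,000

$ chwplan scenario --district Sedibeng --out out/
Sedibeng: stipend +40%, district expenditure +24.9%, per capita R47 -> R59
```

Reading: the uMzinyathi programme costs about R14.4 million a year
(R29,948 per CHW — 2.4% of the district's PHC spend per person). A fully
peri-urban Sedibeng district would need 168 CHWs per 100,000 people, but a
fully rural one needs 223 — a third more, because rural visits take longer
and a smaller share of CHW time is available for them — so the 250-household
peri-urban norm falls to 169 households per rural CHW. Raising the Sedibeng
stipend from R2,500 to the R3,500 minimum wage (+40%) raises district
expenditure by 25%.

The same calculations are available as a library:

```python
>>> import chwplan as cp
>>> ds = cp.generate_diaries(cp.default_config("uMzinyathi", cp.SiteClass.DEEP_RURAL, seed=1))
>>> t = cp.summarize_times(ds)
>>> t[t.activity_code == "home_visit_other"]
  district site_class    activity_code  median_travel  median_activity  n_episodes
uMzinyathi deep_rural home_visit_other           20.0             60.0        4359
```

— the generator recovers the published deep-rural home-visit medians
(20 min travel, 60 min activity; 50% longer per visit than the 40-minute
peri-urban median). `chwplan report --out DIR --seed N` runs everything end
to end and writes the ten report tables, a significance-test table and a
manifest with file digests; runs are byte-identical given the seed.

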