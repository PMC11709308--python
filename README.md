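# fpscope

Scope-of-practice profiling of family physicians from administrative
fee-for-service billing claims.

Health human resource planning needs to know not just how many family
physicians a region has, but which services each of them actually provides —
clinic medicine only, or also emergency medicine, hospital medicine,
obstetrics, palliative care, and so on. Survey-based estimates suffer from
low response rates and recall bias; billing claims record what physicians
actually did. `fpscope` implements a rule-based claims-classification
pipeline for this problem, built around Ontario's OHIP fee schedule but
re-configurable for other jurisdictions.

## The method

1. **Sentinel-code taxonomy.** Eighteen broad services are each defined by a
   set of fee codes unique to that service — explicit codes (e.g. `H131`,
   `H132`, `H133` for emergency assessments), numeric code ranges
   (`Z491–Z499` for endoscopy), or a suffix rule (any code ending in `B` is
   surgical assisting). Explicit codes and ranges take precedence over
   suffix rules.
2. **Count → threshold → binary.** For physician *i* and service *s*, the
   annual count of qualifying events is
   `c_is = Σ events(claims of i matched to s)`, and the provider indicator is
   `y_is = 1{c_is ≥ t_s}`, with `t_s` the service's annual threshold
   (50 visits for clinic and emergency medicine, 25 for mental health,
   2 deliveries for obstetrics, ...). The threshold screens out one-off
   billings so `y_is` reflects services provided consistently.
3. **Stratification.** Physicians are placed in a 2×2 matrix of geography
   (north = the two former northern LHINs) and rurality (Rurality Index of
   Ontario score ≥ 40 = rural), and binned by career stage (<10, 10–19,
   20–29, >29 years in practice).
4. **Disclosure-safe tables.** Regional provider counts with integer
   percentages; counts of 1–6 are suppressed to `<=6` and affected row
   totals become ranges `[sum + k, sum + 6k]` for `k` suppressed cells.
5. **Service combinations.** Per region, physicians are tallied by their
   *exact* combination of the six most-provided services (standard UpSet
   semantics — exclusive, partitioning the stratum), with career-stage
   composition per combination.

Because the underlying administrative data cannot be redistributed, the
package ships (a) a transcription of the published 2017 Ontario regional
summary as a reference fixture, and (b) a seeded synthetic-cohort generator
whose defaults reproduce that summary's marginal proportions, so the whole
pipeline is testable end to end.

## Worked example

```python
import fpscope as f
from fpscope.stratify import REGION_ORDER

# synthetic cohort: 500 physicians per stratum, reference-derived mixes
cfg = f.default_simulation_config(seed=42,
                                  n_physicians_by_region={r: 500 for r in REGION_ORDER})
cohort = f.simulate_cohort(cfg)

registry = f.default_registry()
profiles, counts = f.build_profiles(cohort.claims, registry,
                                    [p.physician_id for p in cohort.physicians])
strata = f.assign_strata(cohort.physicians)
sexes = {p.physician_id: p.sex for p in cohort.physicians}

table = f.cross_tabulate(profiles, strata, registry, sexes)
safe = f.suppress(table)                       # privacy-masked view
print(safe.to_dataframe("display").head(12).to_string())
print("top-6 services:", f.top_k_services(table, k=6))
print("truth vs pipeline agreement:",
      f.truth_versus_pipeline(cohort.truth, profiles).agreement)
```

prints

```
                   north_rural north_urban south_rural south_urban       total
Total Physicians           500         500         500         500        2000
Total Females        214 (43%)   217 (43%)   215 (43%)   222 (44%)   868 (43%)
<10                  250 (50%)   211 (42%)   236 (47%)   187 (37%)   884 (44%)
10-19                 83 (17%)    90 (18%)    76 (15%)    99 (20%)   348 (17%)
20-29                122 (24%)   108 (22%)   128 (26%)   157 (31%)   515 (26%)
>29                    45 (9%)    91 (18%)    60 (12%)    57 (11%)   253 (13%)
Clinic               451 (90%)   405 (81%)   442 (88%)   440 (88%)  1738 (87%)
Anaesthesia            17 (3%)     46 (9%)     34 (7%)     26 (5%)    123 (6%)
Emergency Medicine   324 (65%)   274 (55%)   318 (64%)   287 (57%)  1203 (60%)
Hospital Medicine    382 (76%)   236 (47%)   311 (62%)    91 (18%)  1020 (51%)
Home Visits            35 (7%)    65 (13%)   142 (28%)    75 (15%)   317 (16%)
Mental Health        206 (41%)   281 (56%)   342 (68%)   327 (65%)  1156 (58%)

top-6 services: ['clinic', 'emergency_medicine', 'mental_health', 'palliative_care', 'hospital_medicine', 'long_term_care']
truth vs pipeline agreement: 1.0
```

Each cell is `providers (percent of stratum physicians)`. The agreement of
1.0 confirms the pipeline recovers exactly the provider flags the generator
planted (the default count model guarantees this separation). The synthetic
top-6 differs from the reference ranking in the last slot because equal-sized
strata overweight the small rural strata relative to the real cohort.

The same pipeline runs from the shell:

```sh
fpscope simulate --seed 42 --out sim/ --n-per-region 500
fpscope profile --registry sim/physicians.csv --claims sim/claims.csv --out report/
fpscope validate-fixture
```

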