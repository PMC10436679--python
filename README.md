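# costkit

Bottom-up activity-based costing of **outpatient treatment for sick young
infants (0–59 days) with possible serious bacterial infection (PSBI) or
fast-breathing pneumonia** in resource-constrained primary care, the setting
in which India's IMNCI guideline allows simplified antibiotic regimens when
hospital referral is not feasible.

It is written for health economists and implementation researchers who hold
a site's raw registers — live births, postnatal home-visit counts, clinical
signs, referral/mobilisation flags, antibiotic courses, a provider-time
survey, salary and price schedules — and want defensible unit costs per
treated infant and per live birth, with the incremental (non-staff) cash
outlay separated out.

## The model

**Classification.** Signs at presentation map to an IMNCI class with the
precedence critical illness ≻ clinical severe infection (CSI) ≻ severe
pneumonia / pneumonia ≻ no sign: fast breathing (RR ≥ 60/min) alone is
pneumonia at 7–59 d and severe pneumonia at < 7 d; stopped feeding well,
T ≥ 38 °C or < 35.5 °C, severe chest indrawing, or movement only when
stimulated is CSI; convulsions, no movement at all, or inability to feed is
critical illness.

**Adherence.** A PSBI course (severe pneumonia/CSI) is *recommended* with
7 d injectable gentamicin + 7 d oral amoxicillin, *acceptable* with 2–6 d
gentamicin and the full amoxicillin course, otherwise *partial*; any other
antibiotic (alone or combined), or non-antibiotics only, is
*non-compliant*. Pneumonia is graded on amoxicillin doses (14 recommended,
10–13 acceptable). Headline unit costs divide by infants on
recommended/acceptable treatment only.

**Staff time.** Providers attend a visit independently, so the expected
time per infant for an activity is Σᵢ coverageᵢ × minutesᵢ over cadres, and
staff cost prices those minutes at per-minute salaries (annual salary /
(240 d × 480 min)). ASHA community health workers are incentive-paid, not
salaried: ₹250 for completing 6–7 postnatal visits, ₹125 for 2–5, ₹100
transport per infant mobilised.

**Commodities.** Gentamicin is priced per administration plus a linked
syringe/needle/spirit/swab set; amoxicillin comes in 60 ml bottles lasting
six days, so bottles = ⌈days/6⌉ (two bottles for the 7-day course).

**Aggregation.** Pre-outpatient (identification, assessment, counselling,
pre-referral dosing, attributed incentive and supply pools) and follow-up
costs are spread per treated infant; outpatient treatment costs are
computed per arm and weighted across PSBI subclasses by treated counts;
operational and administrative (FTE-costed) blocks are spread per live
birth. Totals add the two; incremental cost removes every salary-derived
component. Everything is computed in INR and converted once to US$ (default
₹68.5/US$), rounding half-up at printed precision.

## Worked example

```python
from costkit import cost_site, lucknow_register

report = cost_site(lucknow_register())   # reconstructed study-site register
print(report.treated.psbi, report.treated.pneumonia)  # 208 94
print(report.coverage["visited_pct"])                 # 87.0
t = report.usd_table()
print(t["outpatient_psbi_per_treated"])   # 6.6  US$/treated PSBI infant
print(t["followup_per_treated"])          # 2.5  US$/treated infant
print(t["op_admin_per_live_birth"])       # 1.8  US$/live birth
```

`lucknow_register()` and `palwal_register()` rebuild the two study
site-years from their published tallies (13 895 / 4271 live births, 208 /
67 PSBI-treated infants, …) with *synthetic, calibrated* salary and price
schedules, since the study's own schedules were never published. The
outpatient, follow-up and operational/administrative cells above land on
the published report column; heads that depend on the unpublished
schedules (notably the pre-outpatient block) are computed by the same
rules but are not comparable in absolute terms — `docs/methods.md`
discusses what is and is not reconstructible.

The `examples/` directory holds one short script per capability
(worked time examples, classification, site costing, synthetic-register
parameter recovery, cross-site averages); each prints the numbers it
computes and a line on what they mean. A thin CLI mirrors the pipeline:
`costkit run --register <dir> --out <dir>`, `costkit compare --a <dir> --b
<dir>`, `costkit synth --params params.yaml --seed N --out <dir>`.

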