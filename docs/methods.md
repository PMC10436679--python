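# Methods

## Scope and cost perspective

costkit estimates the *incremental program cost* of delivering outpatient
management of possible serious bacterial infection (PSBI) and
fast-breathing pneumonia to young infants (0–59 days) at primary-care
level, from the provider/program perspective for one site-year. It covers
direct activity costs (staff time, medicines, consumables, community
health worker incentives) and indirect operational costs (administrative
staff time, training, IEC/demand generation). It deliberately excludes
household and societal costs, research costs, health-system capital and
equipment, treatment of minor ailments, and the critical-illness arm
(injectable ampicillin is generally unavailable at primary facilities, so
no categorisable regimen exists to cost). Confidence intervals and
inflation adjustment are out of scope; an inflation factor can be applied
by the caller to any reported figure.

## Model structure

### Classification and adherence

Sign-to-class mapping follows the IMNCI young-infant algorithm with strict
precedence (critical illness ≻ clinical severe infection ≻ severe
pneumonia/pneumonia ≻ no sign). Temperature bounds are ≥ 38.0 °C and
< 35.5 °C exactly — a closed upper and open lower bound — so 35.5–37.99 °C
is unremarkable on the temperature criterion. Signs within a class are
OR-combined.

Adherence grading switches unit between arms deliberately: PSBI courses
are judged on *days* (gentamicin injections are observable facility
events) and pneumonia courses on *doses* (mothers administer at home, and
dose counts are what registers record). Two boundary conventions are
resolved here: courses exceeding the full regimen (amoxicillin > 7 d or
> 14 doses, gentamicin > 7 d) are graded as having met it, keeping the
category partition total over all syntactically valid courses; and any
other antibiotic, even alongside a correct gentamicin + amoxicillin
course, is non-compliant. The half-incentive visit range defaults to 2–5
visits (the stricter of the two readings the program documents admit) and
is configurable to 1–5.

### Staff time

Coverage fractions are treated as *independent attendance probabilities*
per cadre, so expected minutes per infant = Σ coverage × minutes. This is
the only interpretation that reproduces both canonical worked examples
(80 %×10 + 20 %×15 = 11 min; 80 %×5 + 90 %×10 = 13 min) and it is verified
against a Bernoulli attendance simulation in the test suite. Per-minute
salary rates use a 240-day × 480-minute working year (both configurable) —
a standard public-sector assumption; no acceptance-grade figure depends on
it. ASHA time is never salary-costed; her remuneration enters through the
incentive schedule, and a salary entry for ASHA triggers a warning and is
ignored.

Treatment staff cost per treated infant is the per-visit coverage-weighted
cost times visits per course: 7 for the PSBI subclasses (one visit per
daily gentamicin injection of the recommended course) and 1 for pneumonia
(a dispensing visit). Both are configurable in `CostingOptions`.

### Commodities and incentives

The amoxicillin bottle rule ⌈days/6⌉ generalises the stated 0–7-day
behaviour (two bottles for 7 days, one for 1–6) and equals a day-by-day
10 ml/day consumption simulation for all 0–30 days (property-tested). Each
gentamicin administration carries a linked consumable set (syringe,
needle, spirit, cotton swab); oral-only courses therefore have zero
consumable cost. The pre-referral dose is costed as one referral slip, one
gentamicin administration with its consumable set, and one full
amoxicillin bottle — whether a part bottle could serve several pre-referral
doses is unrecorded, so a full bottle is assumed (conservative, flagged in
config by the price structure).

Shared program costs enter through item-keyed attribution fractions
(postnatal incentives 20 %, general consumables 20 %, mother cards 100 %,
annualised HBNC kits/weighing scales 50 %, IEC/job aids 50 %, school
rallies/super-village challenge 100 %, ASHA supervision per diems 10 %).
An unknown key is an error: a missing fraction must never silently default
to full attribution. Only recommended/acceptable courses are costed by
default; partial and non-compliant courses can be priced explicitly for
sensitivity analyses.

### Aggregation and reporting

Pre-outpatient and follow-up pools divide by recommended/acceptable
treated infants of both arms combined (configurable to PSBI-only).
Outpatient PSBI cost is the treated-count-weighted average over severe
pneumonia and clinical severe infection. Operational and administrative
costs divide by live births, since those activities benefit every newborn.
Total per-treated cost = direct per-treated + per-live-birth indirect
block; incremental cost subtracts every salary-derived component
(assessment, counselling, pre-referral, treatment and follow-up staff time
plus administrative staff). Training of trainers is a startup cost,
excluded unless explicitly included.

All arithmetic stays in INR; conversion to US$ happens once at report
time, half-up to 1 decimal for report cells (2 for unit prices), through
the `printed` helper so golden comparisons are made at printed precision,
never on raw floats. A regression test bounds the difference between
convert-then-aggregate and aggregate-then-convert at one unit in the last
printed place per component.

## Study-site registers and calibration

`costkit.sites` rebuilds both site-years deterministically from the
published tallies: every count that the source tables print (live births,
visited infants, complete-visit shares of 39 %/17 %, identified infants,
arm-specific treated and adherence splits, per-activity provider mixes,
minutes and delivery volumes) is reproduced exactly. Where the published
per-activity tallies disagree with the headline counts (mobilisations 685
vs 610 identified in one site; pre-referral doses 32 alongside 108 treated
of 114 PSBI in the other), the per-activity tallies are kept in
`ActivityCoverage.n_units` and drive the cost pools, while infant-level
flags preserve the headline counts for coverage statistics.

Salary and price schedules are **synthetic calibrations** — the study's
supplementary schedules were never published — chosen once so that the
cells of the published cost table that *are* reconstructible land exactly:
outpatient pneumonia 0.9 US$ (0.6 in the other site), outpatient PSBI 6.6,
follow-up 2.5, operational 0.6/1.6, administrative 1.2/2.6, combined
1.8/4.3 per live birth. Two blocks are provably not reconstructible from
printed inputs and are therefore computed but not treated as golden:

* the **pre-outpatient block** — the printed mobilisation volume times the
  ₹100 incentive plus the complete-visit incentive share already exceed
  the published per-treated figure before any staff time is added, so the
  published figure must rest on unpublished denominators;
* the **per-arm staff cells** of the direct-cost table — no single
  non-negative salary vector can satisfy the severe-pneumonia, CSI and
  pneumonia staff cells simultaneously under the printed provider minutes
  and a 7-visit course (shown by interval arithmetic over the rounding
  bands).

Published-figure checks therefore split into: (a) end-to-end pipeline
reproductions on the reconstructed registers (coverage statistics, treated
counts, the calibrated cost cells), and (b) table-arithmetic reproductions
computed through the report operations from printed row values (direct
13.6 = 4.5 + 6.6 + 2.5; total 15.4 = 13.6 + 1.8; staff share 72 %;
cross-site weighted averages 10.1 and 15.8 ≈ 16 US$).

## Synthetic-data generator

`generate_site` emulates the register structure: visit counts from a
free-form distribution conditional on ≥ 1 visit, identification as a
Bernoulli thinning of visited infants, a sign mix over the four classes,
independent mobilisation and referral-acceptance draws (their joint
distribution is unreported, so independence is assumed), per-arm adherence
mixes (acceptable PSBI courses draw gentamicin days uniformly on 2–6,
acceptable pneumonia courses doses on 10–13), and a follow-up count
distribution. Activity tallies are the realised counts, as a real register
would record them. The generator does **not** simulate clinical outcomes,
mortality, seasonality, provider behaviour change, or correlation between
visit intensity and illness — passing parameter-recovery tests therefore
shows the cost arithmetic is right under the stated sampling model, not
that the sampling model captures all features of real registers.

`expected_costs` is the closed-form oracle: exact expectations of every
pool and plug-in ratios (E[numerator]/E[denominator]) for per-treated
lines. In the degenerate limit (all probabilities 0/1, point-mass
distributions) it matches the pipeline exactly; at finite size the
parameter-recovery tests use 20 fixed-seed parameter draws at 6000 live
births and a 3-standard-error band, with the per-line SE approximated by
value × 1.5/√(treated count) — a deliberate overestimate of the
coefficient of variation of a mean of bounded per-infant costs. These
sizes keep the whole recovery suite around a minute on one CPU while
leaving expected treated counts in the hundreds.

## Numerical choices and degenerate inputs

Money amounts are non-negative floats with a currency tag; mixing
currencies or double-converting raises. Rounding is half-up via decimal
arithmetic on the float's shortest representation. Zero denominators are
errors for unit costs (no treated infants, zero live births, zero
trainee-days with nonzero cost) but only warnings for coverage statistics,
which are omitted rather than fabricated. Arms with no treated infants are
skipped and contribute zero lines; an empty register loads and validates
but cannot be costed. Register loading is all-or-nothing and reports every
violation found.

## Known limitations

Beyond the exclusions above: coverage-as-independent-attendance cannot
express deliberate co-attendance or substitution between cadres; follow-up
visits are not differentiated by arm (the sites did not record them so);
commodity wastage, cold chain and stock-outs are not modelled; and the
calibrated site registers inherit every internal inconsistency of their
published source tables, resolved as described rather than hidden.
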