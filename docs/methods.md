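# Methods

This note documents the measurement model the package implements, the
parameters that matter, the design choices made where the procedure was
genuinely open, what the synthetic generator does and does not emulate, and
the known limitations. It states no empirical result that the test suite or
`scripts/acceptance.py` does not itself compute.

## The measurement problem

Administrative claims record drug dispensations with dates, routes and
absolute doses, but not intent. Auditing antiemetic practice therefore
requires three rule systems layered on the raw tables: a definition of the
analyzable first chemotherapy course, a mapping from drugs (and combinations)
to acute emetic-risk categories, and a temporal rule deciding which antiemetic
claims count as *prophylactic* rather than therapeutic. Each layer is a
deterministic, configurable function; the package's output is stratified
proportions with exact binomial confidence intervals, not a fitted model.

## Cohort and course definition

The first course is the earliest chemotherapy claim on/after the diagnosis
date plus every chemotherapy claim in the 8-day window inclusive of the start
(day 1 = start, day 8 = start + 7). Calendar days are used; the claims carry
no times, and the window must contain the day-8 cisplatin of the S-1+CDDP
gastric pattern, which fixes the inclusive convention. Exclusions: any course
claim for interferon-α (used for non-oncologic indications); surgery or
thoracic/abdominal/pericardial drainage dated on any course chemotherapy day
(the drug may have been applied topically); any arterial-route course drug;
haematopoietic stem-cell transplantation within 21 days *after* any course
chemotherapy day, inclusive (conditioning chemotherapy precedes transplant; a
symmetric ±21 d variant is a configuration switch); age at diagnosis <20.
Patients, not courses, are excluded. The flow log conserves counts: registry
input = never-treated + uniquely excluded + final cohort, with every reason
of a multi-reason patient logged.

A course with any intravenous chemotherapy claim belongs to the intravenous
group, otherwise to the oral group. Mixed-route regimens such as S-1+CDDP are
intravenous: their emetogenic driver is the intravenous component. Combined
stage is the pathological stage when a resection occurred and the
pathological stage is known, else the clinical stage.

The adjuvant flag is passed through from the registry when present; a
fallback heuristic (course starting 0–180 days after resection) exists behind
a configuration switch, default off, because the source data never defines
the derivation.

## Risk classification

Rule tables are shipped as versioned CSV data, one file per guideline system
(JSCO 2015 — the default for all headline tabulations — ASCO 2020, NCCN
v2.2020, MASCC/ESMO 2016), with columns
`drug_id,route,tier_bound,bound_op,bound_unit,category,missing_dose_category`.
Only drugs appearing in the published tables are guaranteed; users may extend
the files. Claims carry absolute mg, so dose-tiered rules divide by a fixed
reference body surface area of 1.48 m² (the average Japanese adult). Bound
semantics are read literally from the inequality text: methotrexate >250
mg/m² high, 50–250 closed-interval moderate, <50 low (so exactly 250 and
exactly 50 are moderate); cyclophosphamide >1500 mg/m² high (exactly 1500 is
not); cytarabine >200 (JSCO, NCCN) or >1000 (ASCO, MASCC) moderate. A few
NCCN bounds are absolute mg (doxorubicin ≥60 mg, epirubicin >90 mg) or
carboplatin AUC ≥4; the AUC is unrecoverable from an mg dose without renal
function, so carboplatin under NCCN resolves to moderate with a warning
unless an AUC is supplied (`bound_unit` distinguishes the three scales).

Missing doses are frequent in claims. A dose-tiered drug without a dose
resolves to its documented middle tier (methotrexate, cyclophosphamide and
cytarabine → moderate) with a logged warning — the most common clinical
dosing — and is configurable to `unknown` instead. Blank cells in the
guideline-differences grid (some ASCO/MASCC low-vs-minimal boundaries) are
encoded as `unknown`, never inferred.

A regimen's category is the firing combination override, else the maximum of
its components' single-agent categories under the order high > moderate >
low > minimal, ignoring unclassifiable components (all-unknown regimens are
unknown; `unknown` never wins a maximum). The maximum rule is an assumption —
the source never states the aggregation — but it is the only rule consistent
with the published regimen placements (carboplatin+paclitaxel moderate,
S-1+CDDP high). Combination overrides match by subset, so rituximab + CHOP
still fires the anthracycline+cyclophosphamide rule; specificity is
more-components first, then cancer-restricted before unrestricted, then a
logged lexicographic tie-break. The single-agent overrides (oral etoposide,
nimustine, ranimustine → moderate) are restricted to malignant lymphoma, as
stated. GS (gemcitabine + S-1) is moderate for pancreatic cancer exactly as
printed even though both components alone are low; no generalization to
other cancers is attempted. Supportive steroids (prednisolone inside CHOP)
are steroid-class claims and never enter the chemotherapy component set.

## Prophylaxis attribution

An antiemetic claim counts as prophylactic when (a) dated on the course start
(any route); (b) dated on a later in-window administration day of a component
whose single-agent category is high — the day-8 escalation rule, keyed to the
administration date, not to all later days, and applied for high only (a
configuration tuple can extend it to moderate); or (c) oral and dated in the
30 days before the start, inclusive of day −30. Widening the oral lookback
can only add classes, never remove them. The three classes present (NK1
antagonist, serotonin antagonist, any systemic corticosteroid counted as the
dexamethasone component) collapse to five mutually exclusive, exhaustive
categories. An NK1 antagonist without both partners matches no published
category; it falls through to the category of its serotonin/steroid pair and
is counted in a dedicated audit flag (`nk1_without_partners`) so the
ambiguity stays measurable — consistent with the published five-row
partitions summing slightly below 100%.

## Proportions and intervals

Percentages are computed at full precision and presented rounded half-up to
one decimal. The default 95% interval is the exact Clopper–Pearson interval
(the default of the statistical software named by the source); endpoints are
beta quantiles `B(α/2; k, n−k+1)` and `B(1−α/2; k+1, n−k)`, with closed-form
0 and 1 at the boundaries. The implementation goes through statsmodels; the
test suite checks it against an independent direct beta-quantile computation
to 1e-10 and verifies the exact coverage probability at (n=500, p=0.7) is
≥95% (it is 0.9547 — the exact interval is conservative; the simulated
coverage of 1000 draws is checked against that exact value within Monte
Carlo error, since a raw ≥95% assertion on a finite simulation would fail by
chance about a quarter of the time). Wilson intervals are available by
configuration. Within any stratum the five prophylaxis percentages are
computed on the stratum denominator and sum to 100 up to rounding;
denominators always include the unknown risk category.

## Synthetic generator

`cinv_audit.simulate` emulates the linkage the audit consumes: per patient it
draws a cancer type, a named regimen from that cancer's mixture, demographics
(age ~ N(65.9, 12²) truncated to ≥20; 54.7% male; the published stage
marginals), lays out the regimen's drug claims at its administration-day
offsets (S-1 daily days 1–8 with cisplatin on day 8, three-day etoposide
blocks, and so on), draws one of the five prophylaxis categories from the
regimen's distribution and places the corresponding antiemetic claims on the
attribution-relevant date (the start, or the day-8 cisplatin date for the
escalation regimen; a configurable fraction, default 0.2, uses the oral
30-day lookback instead). Default mixtures are the published cancer-type
marginals and the published within-tier regimen shares renormalized over the
regimens modelled; per-cancer risk-tier shares not printed anywhere were
fixed once at round, clinically plausible values and are documented in the
source. Prophylaxis distributions are the published route × tier rates
renormalized to sum to one (the published rows sum slightly below 100%).

The truth channel records each patient's regimen, risk category, route group
and prophylaxis category *after* accounting for regimen steroids: a CHOP
patient sampled as "none" is truthfully `dex_only`, because day-1
prednisolone is a steroid claim the attribution rules will count. With timing
noise and exclusion injection off, the pipeline output equals the truth
channel exactly, per patient; `timing_noise` displaces each placed antiemetic
outside every attribution window with the given probability, and
`inject_exclusion_noise` adds interferon-α lines, same-day surgery, arterial
routes, day-14 transplants, or under-age registry entries at per-reason
rates (defaults a few per thousand). Nothing in the analysis pipeline reads
the truth channel.

What the generator does **not** emulate: real billing-code vocabularies
(canonical drug names stand in for receipt codes), dose variation and
renal-function-based carboplatin dosing, multi-course trajectories, day-2+
delayed-phase prophylaxis, therapeutic antiemetic use, and correlations
between demographics and regimen choice. Passing recovery tests therefore
demonstrates that the pipeline inverts the generative rules faithfully — not
that it is robust to real-world coding noise, which the source itself lists
as a limitation (intent is unobservable; doses are often missing).

A hand-written 30-patient fixture (every exclusion reason, the day-8
escalation patient, an oral-lookback patient, an NK1-without-partner patient,
a two-course patient and a stage-combination case) ships in
`src/cinv_audit/data/fixtures/` with its hand-enumerated expected outputs and
anchors the golden-file tests.

## Problem sizes and numerical choices

The end-to-end recovery tests run the generator at n = 20,000 (acceptance
tolerance: three binomial standard errors on every category share; exact
per-patient agreement with noise off); the acceptance script uses n = 10,000
for its recovery measurement. Probability vectors are validated to sum to 1
within 1e-9, with float residue absorbed into the largest entry. All
randomness flows from a single integer seed through one numpy generator;
identical seeds give byte-identical datasets and audit outputs. Regimen
component doses are recorded as the maximum observed in the window
(conservative for dose-tiered drugs). Ties between equally specific
combination rules are broken lexicographically and logged.

## Limitations

Olanzapine-era (post-2016) prophylaxis categories, radiotherapy
emetogenicity, patient-level CINV risk factors, therapeutic-vs-prophylactic
intent beyond timing, and full guideline drug catalogues are out of scope.
The guideline tables guarantee only the drugs appearing in the published
tables; anything else classifies as `unknown` and is reported in its own
category rather than dropped.
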