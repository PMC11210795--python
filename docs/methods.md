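# Methods

## Scope and data model

The package operates on a deliberately small, six-domain relational model
(patients, visits, vitals, labs, medication orders, procedures) of the kind
multi-site EHR research networks standardize on.  Value sets are explicit
and closed; `mapped_unit` on a lab record is *defined* as "unit present and
in that lab's allowed set", so unit mapping is a conformance property, not a
conversion service.  Dates are ISO-8601 calendar dates and every day window
is closed on both ends ("within 90 days" means |Δ| ≤ 90).  Written CSVs use
a canonical row order (site, patient, date, domain key), which makes output
byte-reproducible; numeric parsing goes through Python's correctly-rounded
`float()` so a write–load–write cycle is byte-identical.

## eGFR and cohort eligibility

Kidney function uses the bedside Schwartz estimator, eGFR = 0.413 ·
height(cm) / SCr(mg/dL).  It is the standard pediatric estimator when only
creatinine and height are reliably available; a cystatin-C-based estimator
is deliberately excluded because cystatin capture in routine data is too
sparse to anchor eligibility (the serum-cystatin element is instead listed
as "expected sparse" for prioritization).  Each creatinine at ages 1–18
(fractional years, closed window) is paired with the nearest height within
±90 days; an equidistant tie resolves to the earlier height — deterministic
and auditable.

Eligibility is a strictly ordered 11-step sequence (see README).  Decisions
where the sequence is genuinely underspecified:

* the low-eGFR interval is [30, 90): "between 30 and 90" with ≥ 90 defined
  as normal forces the top end open and the bottom end closed;
* "two additional eGFRs at least 90 days apart" is measured first-vs-each-
  additional (both companions ≥ 90 days after the sequence's first eGFR),
  configurable via `gap_days`;
* the cohort entry date (CED) is the date of the *first* eGFR of the
  *earliest* sequence satisfying the low-eGFR steps;
* "prior to entry" for dialysis/transplant exclusion is strictly before the
  CED;
* a normal eGFR on the same calendar day as a qualifying low is not
  "intervening" (only values strictly between the first and last qualifying
  dates disqualify).

The vectorized implementation is pinned, count-for-count and entry-date-for-
entry-date, to an exhaustive brute-force oracle (triple enumeration over all
low-eGFR records) on randomized datasets whose values and spacings
concentrate at the decision boundaries.

## Check catalogs and execution modes

Checks carry the taxonomy axes (category, check type, clinical goal,
data-quality probe, domain(s), variable) and an executor binding.  The two
catalogs are synthesized in code to reproduce the published structural
counts exactly — 79 aggregate-round checks (8/8/8/16/24/8/4/1/1/1 across
domains; 29/14/17/34 across categories) and 65 row-level checks spanning 68
domain assignments with three dual-domain checks (26/5/8/9/27 across
categories).  Category assignments can outnumber checks because one
computation can serve several categories through distinct postprocessing.
Checks aimed at domains outside the simplified model (diagnoses/conditions,
cross-domain fact testing) carry no executor and are skipped with a logged
warning; they exist so the catalog's structure and bookkeeping are faithful.

Executors are per-site aggregations by construction, which is what makes the
distributed mode possible: DQ1 processes each site's records in isolation
and emits aggregates only (no patient identifier appears in any result row),
DQ2 computes from pooled rows.  The only cross-site computation — the
pooled-prevalence floor (0.5 % of patient-years) that drops rare procedure
codes from the utilization matrix — is applied centrally to aggregate rows
in both modes, so mode equivalence is exact and is asserted bitwise in the
tests.  Counting rules: "patients active in a year" (completeness
denominators) means ≥ 1 visit that calendar year; code utilization counts at
most one occurrence of a code per patient per calendar year, making it
invariant to record duplication.

## Detection thresholds

* **Missing years** — a completeness proportion of exactly 0 for a calendar
  year inside the site's active span is missingness of that variable; a
  leading run of zero (or inactive) years is instead a single late-data-
  onset issue (element `cohort_entry`); all-years-zero is total missingness.
* **Spikes** — per-site yearly record counts, leave-one-out z-score with the
  SD floored at 5 % of the leave-one-out mean (a plain SD is degenerate on
  near-constant series); |z| > 2 flags a high/low spike.  Only volume-like
  series (visits, vitals, labs) are scanned; entry-year counts and
  medication/procedure series have strong secular trends by construction
  and would alarm meaninglessly.  A 2-SD rule intrinsically flags a few
  percent of year-points, so modest medium-priority noise on clean data is
  expected and accepted.
* **Cross-site outliers** — Tukey fences (1.5 · IQR, type-7 quartiles) over
  per-site values, requiring ≥ 5 sites, *plus* a practical-significance
  floor: the site must deviate from the cross-site median by more than 20 %.
  Without the floor, tightly clustered homogeneous sites produce fence
  outliers at trivial deviations.  The fence computation itself is pure and
  is property-tested against an independent quantile implementation.
* **Distribution pathologies** — largest exact-value mass fraction > 0.10
  (qualitative-to-quantitative conversion artifacts, defaulted values);
  out-of-range fraction > 0 against per-variable physiologic bounds
  (heights 40–220 cm, urine protein 0–5000 mg/dL, ...; the bounds live in
  config because no authoritative list exists); same-day BP correlation
  below 0.2 is discordant; a majority (> 0.5) of first antihypertensives
  before entry is an event-sequencing anomaly.
* **Conformance** — value-set violations, unit problems, duplicate
  identifiers, and visit-type/in-person inconsistencies are folded into the
  results table as `CONF-*` pseudo-checks so that detection (and therefore
  round comparison) is a pure function of results + configuration.

## Prioritization and themes

The four priority levels are produced by the smallest decision table
consistent with the 13-row published site summary used as a calibration set:
attrition-step anomalies and out-of-range/total-missing eligibility
variables are urgent; interior-year missingness of eligibility or
exposure/outcome variables is high; late onset, clinical-domain count
anomalies, secondary-cohort counts and spikes are medium; expected-sparse
labs, medication count anomalies and demographic distribution shifts are
low.  Printed dq-issue synonyms ("values low", "counts high") normalize into
the closed issue value set before the table applies.  Themes are
many-to-one lookups from (element, dq-issue, tier) to the 11 impact
categories; an issue can carry several.

## Round comparison

The later round re-executes the earlier catalog; an issue is resolved
exactly when the fresh detection pass over the after-results no longer
raises its (site, element, dq-issue) signature.  Resolved issues get status
"improvement"; a metric that improves but still violates its threshold stays
unresolved, with both metrics reported.

## The synthetic network

The generator's defaults are the study conditions: 15 sites × 1000 patients
over 2009–2021, CKD fraction 0.3, baseline eGFR uniform on [30, 90)
declining at −3 ± 1 mL/min/1.73 m² per year with 3-unit measurement noise
(floored at 5 — medians are unaffected by the floor until far beyond the
observed offsets), non-CKD eGFR uniform on [100, 140], blood pressure
bivariate normal (105/65, SD 12/9) at the configured correlation 0.6, about
two visits per patient-year with ±10 % per-site rate jitter and site-specific
dialysis-code preferences for coding heterogeneity.  Heights follow a
piecewise-linear median growth curve (75 cm at age 1 to 170 cm at age 18)
plus patient offsets — ordinal plausibility only.  Serum creatinine is
back-computed from the target eGFR and the same-day emitted height through
the Schwartz relation and kept at full float precision (not rounded to
laboratory display precision), so the analysis-side eGFR equals the
generated truth exactly; this is a deliberate fidelity trade for a sharp
known-truth test surface.  Births span 1992–2008 so every patient is active
across the whole interval, keeping yearly volumes trend-free for the spike
detector.  All values are truncated inside the physiologic bounds, so a
clean network yields zero conformance findings and zero out-of-range
fractions.

Eleven anomaly kinds are injectable with a ground-truth registry recording
each plant's expected (site, element, dq-issue) signature; default
magnitudes are set so detection is unambiguous, and are configurable.  The
anomaly catalog does not attempt clinically realistic comorbidity structure
or real coding vocabularies — only the failure modes the checks exercise.
What passing tests show is therefore that the *machinery* detects these
failure modes at these magnitudes under homogeneous-site conditions; real
networks have heterogeneity that would raise the cross-site noise floor.

## Problem sizes and verification

The test suite and acceptance script use: the default 15 × 1000 network for
recall/specificity (one plant of each kind, fixed seed; recall 11/11 over
the union of both rounds — the aggregate round carries the anthropometrics
density/distribution checks, the row-level round the geographic, timing and
visit-volume checks), 200 randomized ≤ 50-patient boundary-heavy datasets
for oracle equivalence, a 6 × 400 network (≥ 500 cohort members, ≥ 10 000 BP
pairs) for parameter recovery (correlation within ±0.05, decline slope
within ±1), and a 5 × 200 network for bitwise mode-equivalence. Everything
the acceptance script reports is recomputed at run time from these
simulations.

## Known limitations

Demographic realism is minimal; diagnoses and cross-domain checks are
structural placeholders without executors; the issue catalog's resolution
statuses other than open/improvement are annotation vocabulary, not
inference; prioritization is a rule set calibrated to a single published
summary and will not transfer to other studies without re-calibration.
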