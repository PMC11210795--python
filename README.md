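# ssdqa — study-specific data quality assessment for multi-site EHR data

Observational studies that reuse electronic health record (EHR) data from
many institutions inherit every institution's extract-transform-load quirks:
duplicated rows, mislabeled units, defaulted lab values, dropped specialty
mappings, truncated history.  Generic network-level curation catches
structural problems but not *study-specific* ones — whether the data can
actually support a particular cohort definition, exposure, and outcome.
`ssdqa` implements a study-specific data quality assessment framework for a
pediatric chronic kidney disease (CKD) cohort study over a simplified
PCORnet-style common data model: a catalog of taxonomy-annotated checks, two
execution modes (distributed aggregate-only vs centralized row-level), a
detection layer that turns check results into a prioritized, themed issue
catalog, round-over-round improvement tracking, and a synthetic multi-site
EHR generator with ground-truth anomaly plants so the whole stack is
testable without patient data.

It is intended for informaticians and study analysts who want a reusable,
fully scripted version of this workflow — as a Python library first
(`examples/` walks through each capability) with a thin `ssdqa` CLI for the
shell workflow.

## The science in brief

**Kidney function.** Pediatric estimated glomerular filtration rate uses the
bedside Schwartz formula

```
eGFR = k · height(cm) / SCr(mg/dL),   k = 0.413  [mL/min/1.73 m²]
```

with each serum creatinine measured at ages 1–18 paired to the nearest
height within ±90 days (ties to the earlier height).

**Cohort attrition.** Eligibility is an 11-step sequence applied strictly in
order: any encounter in the 2009–2021 interval; an in-person visit; a serum
creatinine; age 1–18 at measurement; a linkable height; one eGFR in
[30, 90); two further low eGFRs each ≥ 90 days after the first; no
intervening normal (≥ 90) eGFR; an in-person nephrology visit; and no
chronic-dialysis or transplant codes before the cohort entry date (the first
eGFR of the earliest qualifying sequence).  Per-site retained counts are
non-increasing by construction and are verified against an exhaustive
brute-force oracle.

**Checks and issues.** Every check carries a Kahn-style category
(completeness, conformance, plausibility, concordance, consistency) plus
check type, clinical goal, and data-quality probe; executors compute
per-site aggregates (completeness trends, BP same-day concordance and
Pearson correlation, unit mapping, patient-year-deduplicated code
utilization, value distributions, medication timing relative to entry,
geocode granularity, attrition).  Detection flags interior missing years,
leave-one-out z-score spikes (|z| > 2, SD floored at 5 % of the mean),
cross-site Tukey-fence outliers (1.5 · IQR, type-7 quartiles), exact-value
mass concentrations, and out-of-range fractions; each issue gets one of four
priorities from a calibrated decision table and one or more impact themes.

## Worked example

```
python examples/02_cohort_attrition.py
```

prints (3 sites × 400 synthetic patients, seed 2):

```
6701 eGFR values computed for 1112 patients

attrition at hs01 (patients retained per step):
  step  0  any encounter in study interval               400
  step  1  any in-person visit                           400
  step  2  serum creatinine present                      397
  step  3  age 1-18 at creatinine measurement            367
  step  4  height within 90 days of creatinine           367
  step  5  one eGFR in [30, 90)                          127
  step  6  two additional low eGFRs >= 90 days after first 91
  step  7  no intervening normal eGFR                     91
  step  8  in-person nephrology visit                     91
  step  9  no dialysis before entry                       91
  step 10  no transplant before entry                     91

cohort: 290 members across 3 sites
fitted eGFR decline from trajectory medians: -2.95 mL/min/1.73m^2 per year
(generator truth: -3.0)
```

The drop at step 5 is the low-eGFR eligibility gate (only CKD-trajectory
patients qualify); the recovered decline slope demonstrates that the
pipeline reconstructs the parameter the generator planted.
`examples/04_inject_and_detect.py` shows the detection side: an
inch-recorded-as-cm height error surfaces as an urgent "outlier values"
issue on the site's tailored summary.

The same workflow from the shell:

```
ssdqa simulate --seed 1 --plants --out data/
ssdqa dq1 --data data/ --out run1/
ssdqa report --run run1/ --round DQ1 --out report/
```

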