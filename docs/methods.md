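# Methods

This note records the model implemented by `d2care`, the conventions that
make its results exactly reproducible, and the boundaries of what the
synthetic generator does and does not emulate.

## 1. Study window and date arithmetic

A reconciliation cycle is parameterized by a `StudyWindow`:

| field | meaning | default (via `from_start`) |
|---|---|---|
| `in_care_start` | start of the in-care lookback | user-supplied |
| `in_care_end` | end of lookback (exclusive) | start + 12 calendar months |
| `ooc_end` | end of the out-of-care window (exclusive) | + 6 calendar months |
| `data_request_date` | date the clinic extract was pulled | + 1 calendar month |

All intervals are **half-open** `[start, end)`: an event exactly on an end
date belongs to the next period. Month arithmetic is calendar-based: adding
*n* months keeps the day-of-month, clipping to the last day of the target
month (Jan 31 + 1 month = Feb 28/29). "At least 6 months apart" means
`add_months(earlier, 6) <= later`. The window validates strict ordering and
requires the lag between `ooc_end` and `data_request_date` to be at least
one calendar month, so the disposition engine always has a lag period in
which a "recent visit" can occur.

The upcoming-visit horizon is `data_request_date + 3 months`.

## 2. In-care definition and box classification

A patient is **in care** if they have ≥1 clinic visit *and* ≥1 viral-load
result in `[in_care_start, in_care_end)`. In-care patients are classified by
presence of visits/VLs in the OOC window `[in_care_end, ooc_end)`:

| box | visit | VL | meaning |
|---|---|---|---|
| A | yes | yes | still in care — excluded from the cycle |
| B | no | yes | labs only (possible silent transfer) |
| C | yes | no | clinic only (labs not reported) |
| D | no | no | potentially lost to follow-up |

Boxes B, C, D form the *potentially out-of-care* cohort. A CD4 result is
surveillance evidence of care contact but does **not** count toward the VL
requirement; cohorts where a patient has CD4 results but no VL are logged as
a data-quality discrepancy and classified by the VL rule as written.

## 3. Case-conference disposition engine

Each potentially-OOC patient receives exactly one disposition. Rules are
evaluated in a fixed order and the first that fires wins; when evidence for
a lower-precedence rule also exists, the conflict is counted and logged but
does not change the outcome.

1. **WELL_PATIENT** — two chronologically *adjacent* VLs, both ≤20
   copies/ml, at least 6 calendar months apart, and **no** detectable VL
   anywhere in `[in_care_start, ooc_end)`. An optional `min_gap_days`
   switch replaces the calendar-month gap with a fixed day count.
2. **RECENT_VISIT** — a clinic visit in the lag period
   `[ooc_end, data_request_date)`.
3. **UPCOMING_VISIT** — a scheduled appointment in
   `[data_request_date, data_request_date + 3 months)`. These patients go on
   a watchlist.
4. **EXTENDED_CARE_FACILITY, INCARCERATED, MOVED_OUT_OF_STATE,
   NOT_OUR_PATIENT, DECEASED, PROVIDER_DISCRETION, OTHER** — driven by
   boolean flags on the patient record and/or case-conference annotation
   rows (`patient_id`, `disposition_code`); unknown codes are a hard error.
5. **RANDOMIZABLE** — no rule fired.

**Watchlist resolution.** After the appointment horizon passes, watchlisted
patients whose appointment outcome is `missed` become randomizable;
`kept` stay non-randomized; `unknown` remain pending. If a patient has
multiple appointments, `missed` outranks `kept` outranks `unknown`, so a
patient is only kept off the eligible list when they verifiably attended.

## 4. Randomization

Eligible patients (`RANDOMIZABLE` plus watchlist additions) are allocated
1:1 to DIS vs SOC with **permuted blocks of size 2 within clinic strata**:
within each clinic, patients are shuffled, paired, and each pair receives a
random permutation of (DIS, SOC); an odd leftover patient gets the first
element of a fresh permutation. Consequences, both tested:

- per-clinic arm imbalance is at most 1, always;
- each patient's marginal probability of DIS is exactly ½ (verified over
  1000 seeds with an exact binomial test at α = 0.001 per patient).

All randomness flows through `numpy.random.default_rng(seed)`; inputs are
sorted by `(clinic_id, patient_id)` first, so the allocation is a pure
function of (eligible set, seed).

## 5. Continuum revision

Given a surveillance continuum (`prevalent` diagnosed, `retained` in care)
and a cycle's non-randomizable fraction `f`:

```
potentially_ooc    = prevalent − retained        (overridable)
additional_in_care = round_half_up(f × potentially_ooc)
revised_retained   = retained + additional_in_care
truly_ooc          = potentially_ooc − additional_in_care
```

so `revised_retained + truly_ooc = prevalent` holds exactly. The additional
in-care cases are attributed to boxes B/C/D by the box shares of the
non-randomized patients; shares must sum to 1 within ±0.005 (published
shares 0.278/0.484/0.239 sum to 1.001), which bounds attribution drift by
`2 + 0.001 × additional_in_care` — a property test enforces this bound.

**Rounding.** All rounding is half-up via `decimal.Decimal`
(never banker's rounding), and percentages of integer counts are computed
with exact `Fraction` arithmetic before rounding, so e.g.
2303/2958 → 77.9 and 884/10617 → 8.3 are reproduced digit-for-digit.

## 6. Flat-file exchange

Extracts are plain CSV with ISO (`%Y-%m-%d`) dates: `patients.csv`,
`clinic_visits.csv`, `appointments.csv`, `surveillance_labs.csv`. The
readers are strict: a missing column is fatal; a malformed row is rejected
with its 1-based row number and a reason; duplicate `(patient_id,
visit_date)` clinic rows are deduplicated with a logged count; negative or
non-numeric lab values are rejected. `join_surveillance` merges the clinic
and surveillance streams losslessly — every input event either lands in the
joined frame or in an exceptions frame naming its source.

## 7. Synthetic cohort generator

`simulate_cohort(CohortConfig)` draws a cohort whose flat files, when run
through the pipeline, reproduce the generator's ground truth **exactly**
(100% box and disposition recovery). Key constructions:

- every patient gets an in-care visit and VL, so the cohort is in care by
  construction; box membership is realized by placing (or withholding)
  OOC-window events;
- well patients get a pair of undetectable VLs ≥6 months apart inside the
  in-care window and no detectable VL anywhere;
- every *non*-well patient whose last in-care VL would be undetectable also
  gets an earlier detectable "breaker" VL, so the well-patient rule cannot
  fire by accident;
- recent visits are placed only in the lag period, appointments only for
  UPCOMING_VISIT patients, and each flag disposition sets exactly one flag,
  so only the intended rule fires.

Default margins emulate a statewide cycle of n = 2958 in-care patients:
box probabilities (0, 763, 1342, 853)/2958; disposition margins with
well 499, recent 946, upcoming 398, randomizable 624 and the residual 491
split evenly across the seven flag dispositions; 23 clinics;
appointment-miss probability 31/241; demographic, CD4 and VL margins
matching the study population. Demographics and labs are drawn
**independently of disposition**, so group comparisons on synthetic data
reflect sampling noise only — the generator emulates marginal structure,
not the real covariate–outcome associations (real cycles found randomized
patients younger, with lower CD4 and more detectable VLs).

Writing a cohort is deterministic: the same `(config, seed)` produces
byte-identical files.

## 8. Reporting

Categorical comparisons use Pearson's chi-square without continuity
correction (`scipy.stats.chi2_contingency(correction=False)`); a
brute-force (O−E)²/E oracle exists only in the tests and agrees to 1e-9.
Continuous comparisons use the pooled two-sample t-test (Welch available by
flag); degenerate zero-variance-identical-mean input yields t = 0, p = 1.
Tables with a zero margin report "not applicable" rather than a spurious
statistic. `flow_accounting` asserts the conservation identities by name
and raises `ConservationError` if any is broken.

## 9. Known limitations and open choices

- **VL-missing patients.** The in-care definition requires a VL, so a
  margin for "VL missing" among in-care patients is contradictory; the
  generator's default for that margin is 0 and the lab margins renormalize.
- **Watchlist denominator.** The appointment-miss probability default
  (31/241) comes from a cycle in which only a subset of the watchlist had
  resolvable outcomes; it is a config knob, not a law.
- **Single cycle.** The pipeline models one reconciliation cycle; repeated
  cycles with carry-over watchlists are out of scope.
- **No record linkage.** Patients are assumed already linked across clinic
  and surveillance streams by `patient_id`; probabilistic matching is out
  of scope.
- **Independence defaults.** Disposition mix is identical across boxes B/C/D
  by default (a per-box override exists), and demographics are independent
  of everything; both are simplifications.
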