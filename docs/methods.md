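# Methods

## Data model and ingestion

FAERS quarterly packages are "$"-delimited ASCII files, one per table (DEMO,
DRUG, REAC, OUTC, THER, INDI), first line a header. The dialect has no
quoting and the delimiter cannot appear inside a field, so rows are split
naively; a row whose field count disagrees with the header is dropped and
counted, never repaired. Only the 2016+ (PRIMARYID-era) layout is supported —
the pre-2014 ISR-era headers are not. Every non-DEMO row must reference a
DEMO PRIMARYID; orphans are counted and dropped. Per-table drop counters are
kept so that `raw rows == kept + dropped` is auditable at every stage.

Dates are stored raw and parsed lazily, because validity requirements differ
per analysis: deduplication needs only an orderable FDA receipt date, whereas
onset analysis demands full day precision. `parse_partial_date` is total:
8 valid digits → day precision, 6 → month, 4 → year, anything else (including
impossible calendar days) → invalid, never an exception.

Deleted-case lists ship inconsistently across quarters, so the reader treats
them as optional (`DELETE*.txt`, one case id per line) and empty when absent.

## Deduplication

A FAERS case accumulates report versions; following the FDA recommendation
exactly one is retained per CASEID: the version with the latest FDA_DT,
ties broken by the numerically higher PRIMARYID. Rows whose FDA_DT cannot be
parsed to at least year precision are dropped and counted. Cases on the
deleted lists are removed after version selection. The operation is
idempotent and invariant to input row order (a stable mergesort on
(caseid, date key, numeric primaryid) precedes the per-case selection), and
the four output counts always sum to the input row count. Deduplication is
keyed on CASEID alone and runs before any filtering.

## Cohort extraction

The analysis cohort is: deduplicated reports, inside the study window
(default 2016-01-01..2021-03-31 on FDA_DT), whose *primary-suspect* (role_cod
PS) drug matches the study lexicon and whose reactions include a target
MedDRA Preferred Term.

* **Drug matching** is exact-token based against an explicit lexicon of
  uppercase generic and trade names (packaged default: ciprofloxacin,
  levofloxacin, moxifloxacin with CIPRO, CILOXAN, LEVAQUIN, QUIXIN, AVELOX,
  MOXEZA, VIGAMOX and salt forms). A verbatim name matches when one of its
  whole-token prefixes equals a lexicon name, so "CIPRO 500MG TABLET" matches
  while "CIPROFIBRATE" never does; substring matching is deliberately
  rejected. The active-ingredient field is consulted when the drug name
  fails. A name reachable from two drug keys is a fatal lexicon error.
* **Event matching** is by PT name equality (case-insensitive); FAERS REAC
  files store names, not codes, so the MedDRA codes (tendonitis 10043255,
  tendon rupture 10043248 in the packaged default) ride along as metadata.
* A report with several matching PS rows, or both target PTs, contributes
  **one** case record (report-level counting); route conflicts between
  matched PS rows resolve by the precedence oral > intravenous > other >
  unknown.
* **Ages** harmonise to years (YR×1, DEC×10, MON÷12, WK÷52.143, DY÷365.25,
  HR÷8766; a bare value with no unit is taken as years); results outside
  [0, 120] become missing. Age bands are <18, 18–65 (inclusive both ends),
  >65, unknown.
* **Routes** classify through a packaged verbatim→class map (oral;
  intravenous incl. drip/bolus/not-otherwise-specified; empty → unknown;
  anything else → other). **Regions** come from a packaged country→continent
  table (ISO-3166 alpha-2 plus common full names); unmapped → Unknown.
* **Indications** of the matched drug class as "infections" (PT contains the
  token "infection" or sits on a packaged infection-PT list), "other", or
  "unknown-indication" ("Product used for unknown indication" or no
  informative PT).
* Therapy start for onset analysis is the earliest valid START_DT of the
  THER row whose dsg_drug_seq equals the matched PS drug's drug_seq.

## Disproportionality statistics

Cells are counted from per-report boolean exposure/event flags over the
deduplicated in-window universe. The implemented forms are the standard
published ones:

* ROR = ad/bc with log-normal 95% CI (z = 1.96).
* PRR = [a/(a+b)]/[c/(c+d)] with the Yates-corrected Pearson χ² (corrected
  deviations floored at zero).
* IC = log₂((a+0.5)/(E+0.5)), E = (a+b)(a+c)/N; IC025 by Norén's
  observed-shrinkage approximation with constants 3.3 and 2.0.
* EBGM = a/E in the shrinkage-free closed form, EBGM05 = EBGM·e^(−1.64·se).
  A full MGPS fit (EM estimation of a two-component gamma mixture prior over
  all drug–event pairs) is intentionally not performed; the variant in use is
  recorded in `metadata.json`. At high counts the closed form and MGPS agree
  closely; at small a it lacks the prior's shrinkage toward 1, which is why
  positivity additionally requires EBGM05 > 2.

Tables with a zero cell return NaN ("undefined") for the statistics whose
preconditions fail — no Haldane 0.5 correction is applied — and undefined
statistics never flag positive. Default criteria: ROR positive iff n ≥ 3 and
CI lower bound > 1; PRR positive iff n ≥ 3, PRR ≥ 2, χ² ≥ 4; IC positive iff
IC025 > 0; EBGM positive iff EBGM05 > 2; combined positive iff any flag.
All thresholds are configurable and echoed into the run metadata.

Stratified screens recompute b, c, d within the stratum: sex and age strata
restrict the whole universe (disproportionality is only meaningful against
the stratum's own background), while a route stratum restricts the *exposure*
flag to reports whose matched PS drug carries that route class, leaving the
background whole.

## Descriptive surfaces

Characteristics tables report counts and percentages (100·count/total,
rounded to 2 decimals) per drug–event group and pooled over drugs; within
each categorical block counts re-sum to the group total. Serious-outcome
proportions divide each outcome code's count by the group total, so a report
carrying several codes contributes to several rows and proportions may sum
past 100%. Mean age uses harmonised ages only, with no imputation. Reporting
year derives from the retained report version's FDA_DT.

Time-to-onset is EVENT_DT − START_DT in calendar days, retained only when
both dates carry day precision and the difference is ≥ 0; same-day onset
counts as 0 (only strictly negative intervals are data errors). Exclusions
are tallied by reason (missing, partial precision, negative) and conserve the
candidate count. Quartiles use the median-of-halves rule — the median of the
lower/upper half, halves excluding the middle element at odd n — which is the
interpolation-free rule that yields half-integer quartiles (e.g. 9.5, 16.5)
on integer day data. Histograms bin left-closed right-open and conserve the
in-range count exactly. The quartile rule is recorded in run metadata.

## Synthetic data generator

The generator emulates the relational structure of a FAERS quarter, not its
content realism: per report one PS drug from a categorical marginal (study
drugs at explicit prevalences, 150 background drugs Zipf-weighted), 0–4
concomitant drugs, target events as independent Bernoulli draws whose rate is
multiplied by a planted λ when the PS drug carries a planted signal, a
Poisson number of Zipf-weighted background PTs, demographics from a
configurable mixture, outcome codes per event class, in-quarter therapy
starts with log-normal onset delays, and configurable fractions of duplicate
versions (same CASEID, later FDA_DT, higher PRIMARYID), deleted cases,
month-truncated/missing dates and negative (data-entry-error) onsets.

Because target events are independent given the PS drug, the 2×2 cell
expectations have the closed form E[a] = N′·p_drug·min(1, λ·p_event) (N′ the
deleted-adjusted universe), used by the calibration tests. Defaults emulate
the reporting structure of the fluoroquinolone tendinopathy setting: six
planted signals with λ between 17 and 93, oral-dominant routes (bias
0.82–0.92), onset medians of 3–18 days, ≈54% female reports, and age bands
concentrated in 18–65. Desk-scale prevalences (study drugs ≈0.4–1% of
reports, target events 0.07–0.1%) keep planted cell counts in the tens at
n = 20,000–40,000 reports; the acceptance script uses 30,000 reports and the
calibration tests 1,500–30,000, sizes chosen so each check runs in seconds.
What the generator does **not** emulate: MedDRA hierarchy structure,
drug-interaction or masking effects, reporter free text, cross-CASEID
(probabilistic) duplicates, and secular reporting trends — so passing tests
demonstrate algorithmic correctness and calibration under the stated
sampling scheme, not performance on real FAERS idiosyncrasies.

## Pipeline and outputs

`run_pipeline` sequences read → dedup → cohort → signal screens (default
strata: sex F/M, age 18–65/>65; route oral/intravenous in a separate table) →
characteristics/outcomes → onset, writes the report CSVs, a flow-count JSON
mirroring the selection flowchart (raw versions, duplicates, deleted,
in-window universe, per-pair cohort sizes), and a metadata JSON recording
every threshold, formula variant and the quartile rule. Outputs are
deterministic given the inputs; every reported number is reproducible by
calling the module operations directly. The CLI exposes `simulate` and
`run`; the individual stages are the library functions themselves.

## Numerical and design choices

* Statistics are computed at full precision and rounded to 2 decimals only in
  output tables.
* Zero-cell handling (NaN, flags false) follows from screening practice:
  high-count signals are the object of interest and corrections would
  manufacture spurious small-n positives.
* Dedup date keys compare at whatever precision the raw FDA_DT offers
  (missing month/day ordered first within the year).
* The 95% CI calibration property (coverage of 1 within 93–97% under
  fixed-margin null tables) is checked by hypergeometric simulation with a
  pinned seed.

## Known limitations

* The closed-form EBGM is not MGPS; at very small expected counts it
  overstates the point estimate relative to a fitted prior.
* PT matching is exact name equality; misspelled reaction terms are missed
  (as they would be in any name-keyed analysis without MedDRA licensing).
* Country mapping covers ISO alpha-2 codes and common full names; rarer
  verbatim country strings fall to Unknown.
* Cross-CASEID duplicates (same patient, different case) are out of scope of
  the FDA rule and are not detected.
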