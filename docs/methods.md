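# Methods

This note records the conventions, parameter choices and numerical decisions
behind `rxstew`, and what the synthetic-data tests do and do not demonstrate.

## Input model

The unit of raw data is one invoice transaction row. Eleven canonical
columns are carried: facility, medication, dose, days_supply,
prescription_number, transaction_date, amount, route, physician, payor, ndc.
Nine are *essential* (dose and NDC are metadata; NDC is never used in
analysis). Header mapping is explicit configuration — source spellings per
canonical column — never inferred from content; two headers in one file
resolving to the same canonical column is an error, and unmapped headers are
reported, not dropped silently. Value coercion (ISO or US date dialect,
chosen per run; currency with `$`/commas/parentheses; integer days supply)
turns failures into missing values, which cleaning step 1 then removes; a
failed parse is never replaced by a default.

Facility names are normalized (uppercase, collapsed whitespace) and passed
through an explicit alias table; unknown names map to themselves, making
consolidation idempotent. Facilities contributing ≤ `min_months` (default
12) distinct months are excluded. The >20% three-month volume screen is
implemented as a sliding window of three consecutive calendar months
comparing first vs last: `|count(last) − count(first)| / count(first)`;
windows starting at a zero count are skipped and reported rather than
divided. Volume flags are advisory — exclusion happens only through the
config `exclusions` list, because deciding whether a volume shift reflects a
closure or a population change requires human review that software cannot
automate.

## Cleaning cascade

Steps run in a fixed order; the ledger records rows removed and remaining at
each step and enforces the telescoping identity `removed + remaining =
previous remaining`.

1. **Incomplete rows.** Any essential field missing. Zero is a value
   (days supply of 0 and amounts of $0 occur in retained data).
2. **Non-pharmaceutical items.** Whole-word keyword match on the uppercased
   name (kits, flushes, dressings, test strips, …). Editable list.
3. **Reimbursements.** `amount < 0`; $0 rows are kept.
4. **De-duplication.** Key = (rx#, medication, transaction date, physician).
   Case One: rows also equal on days supply collapse to the first. Case Two:
   remaining rows in a key group keep the greatest days supply; a tie at the
   maximum keeps the first row in input order (the requirement is
   determinism, not a particular winner). A group containing both phenomena
   contributes to both counts.
5. **Refill consolidation.** One course per (rx#, medication): total days
   supply = Σ days supply (the length of therapy), start date = earliest
   transaction date, descriptive fields from the earliest dispensing. The
   ledger line counts rows-in minus courses-out. One prescription number at
   two facilities is an integrity error.
6. **Non-systemic medications.** Four compiled pattern families on the
   uppercased name: (a) ends with ⟨non-alpha⟩KEYWORD; (b) contains
   ⟨non-alpha⟩KEYWORD⟨non-alpha⟩; (c) starts with KEYWORD⟨non-alpha⟩;
   (d) starts with KEYWORD followed by a blank (solution/injectable leading
   tokens such as LIDOCAINE, NACL, SODIUM CHL, DS). Family (d) is specified
   by its behaviour — `LIDOCAINE HCL 2% JEL` is removed while
   `CREAM OF TARTAR SUPPL` is not — because the requirement is what the
   examples pin down. Patterns compile at load; a bad keyword is a config
   error, never a match-time failure. POSIX classes are rendered as
   `[^A-Z]`-style classes in Python's `re` dialect (names are uppercased
   first).
7. **Insulin and opioids.** Whole-word keyword lists (insulins including
   common analog/brand tokens; opioid generics). These lists are
   package-supplied defaults and explicitly editable — no published roster
   exists for them.

Because steps 6–7 depend only on the medication name, applying them before
or after refill consolidation yields the same final course set; this
commutation is asserted as a property test. A naive quadratic reference
implementation (linear scans per group, no pandas) serves as the oracle for
the whole cascade on fuzzed tables of up to 200 rows.

## Classification and ASI

Courses are labeled antibiotic / anti-hypertensive (beta-blocker, ACE-I,
ARB subclasses only) / other by case-insensitive keyword match against a
bundled lexicon; the longest matching keyword wins, so combination products
(which carry their own keyword, e.g. AMOXICILLIN-CLAVULANATE) never match a
component name first. The bundled lexicon and the antibiotic spectrum index
table are package-supplied, editable stand-ins on the published 1–13 scale
(1 = narrowest, anchored by fidaxomicin; 13 = broadest, anchored by
tigecycline); both files say so in their headers. Antibiotics without a
score are carried as unscored, excluded from ASI averages, and counted in a
coverage report.

## Metrics

**Allocation convention.** Therapy days run consecutively from the day
*after* the transaction date. This exclusive-start rule is the only one
consistent with the canonical worked example (90 days from 2014-12-03 →
28/31/28/3 across Dec–Mar): an inclusive start would give 29 December days.
It is the package's single most consequential convention and is fuzz-tested
against a day-by-day calendar walk for conservation (Σ month allocations =
total days) and the per-month cap (allocation ≤ days in month).

**Rates.** DOT/1000 BDOC = allocated days in the facility-month / bed-days
of care × 1000. Starts/1000 BDOC counts a course once, in the month of its
transaction date. The anti-hypertensive comparator uses the same allocation
machinery. Mean monthly ASI = Σ(ASI × DOT) / Σ DOT over scored antibiotic
courses; undefined (reported missing) when a month has no antibiotic DOT.
The census defines the facility-month grid: covered months with no use are
true zeros; months that receive allocated DOT but lack a census row are
reported with missing rates and `census_available = False` — never silently
zero, so benchmarking stays honest. Bed-size strata are `<100`, `100–150`
(inclusive at both edges), `>150`.

## Validation statistics

Mann–Kendall: S = Σ_{i<j} sign(x_j − x_i); tie-corrected variance
`[n(n−1)(2n+5) − Σ_t t(t−1)(2t+5)]/18`; continuity-corrected
Z = (S∓1)/√Var; two-sided normal p (all-tied series → Z = 0, p = 1; n < 3
is an error). Spearman rho is the Pearson correlation of mid-ranks
(average ranks for ties). Both are implemented in the package and tested
against independent oracles: an all-pairs brute force for S, the
`1 − 6Σd²/(n(n²−1))` closed form on tie-free data, and scipy's
implementation for tied Spearman. Correlation categories: high (rho > 0.7),
moderate (0.5 ≤ rho ≤ 0.7), low otherwise — negative rho is low. Source
comparison restricts to overlapping months (≥ 3 required) and reports the
sign of mean(b − a) to express "consistently greater".

## Synthetic generator

The generator's defaults are the study conditions the tests run under:
8 facilities over 24 months, fleet-mean monthly census 2,700 bed-days (per
facility scaled log-normally, yielding bed counts that populate all three
strata at 75–95% occupancy), antibiotic start rate 4 /1000 BDOC/month (15%
intravenous, dispensed in 2-day aliquots), anti-hypertensive initiation
6 /1000 BDOC/month in 30-day supplies with refill chains of 1–6 dispensings
jittered ±5 days around 30-day intervals (to exercise cross-month
allocation), and junk rates per clean row of 2% incomplete, 10%
non-pharmaceutical, 23% reimbursement, 5% / 1.2% Case One / Case Two
duplicates, 6% non-systemic (cycling through names that exercise every
pattern family), and 8% insulin/opioid — proportions chosen to resemble a
real invoice export in which roughly a third of aggregate rows survive
cleaning. Four header dialects rotate across monthly files (one carries an
unmapped extra column); facility names appear as alias variants with
probability 0.25; one facility's volume halves mid-series to exercise the
>20% screen. Every row is tallied in a `SyntheticTruth` record, so the
cleaning ledger can be compared to planted counts *exactly*, and pipeline
DOT/starts rates to truth rates within 10⁻⁹ (the truth side allocates by an
independent day walk).

The paired dispensing generator writes a superset of the invoice courses
plus extra in-month antibiotic courses sized by `1/skilled_fraction − 1`,
mimicking the fact that dispensing data covers all residents while invoices
cover mainly skilled-nursing care; with `skilled_fraction = 1` the two
sources coincide.

What the generator does **not** emulate: resident-level correlation,
seasonality, dose strength semantics, realistic pricing, mid-course
discontinuation, or route/name inconsistencies beyond its fixed pools.
Passing recovery tests therefore demonstrates that the pipeline's
bookkeeping is exact under the stated phenomena — not that the bundled
keyword lists are complete for any particular pharmacy's catalogue, which
always requires local review.

## Problem sizes in the test suite

The fuzz and recovery suites run at desk scale chosen as a deliberate
trade-off between coverage and turnaround: 15 randomized generator
configurations (plus a 5-facility × 12-month shared fixture) for exact
ledger/truth recovery, 40–60 fuzzed tables of ≤ 200 rows against the
quadratic cleaning oracle, 100–200 cases each for the Mann–Kendall and
Spearman oracles, and 400 random (date, days) pairs for allocation
conservation. All thresholds are exact (integer equality) or 10⁻⁹.

## Known limitations

- Invoice data is a proxy: IV-to-oral switches and early discontinuation
  are invisible, so DOT from days supply over-counts actual administration.
- Classification is name-keyword based; misspelled or novel product names
  fall into "other" (the coverage report surfaces unscored antibiotics).
- The dose column remains free text; no dose-level reconstruction or DDD
  metrics.
- The step-5 ledger line counts collapsed rows (rows-in minus courses-out);
  other tools may count rows lacking a unique prescription number, which
  differs by the number of multi-row courses.
- The interactive-website functionality is covered by static HTML/SVG/CSV
  report output; there is no server component.
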