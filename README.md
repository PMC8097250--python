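# rxstew

Antibiotic-use surveillance metrics from pharmacy invoice data, for nursing
homes and the stewardship teams that support them.

Nursing homes are required to track and report antibiotic use but rarely have
the informatics infrastructure to do it. Pharmacy invoices — billing
transactions from the dispensing pharmacy — are one dataset nearly every
facility already has. `rxstew` turns messy multi-file invoice exports into
standard stewardship metrics:

- **starts/1000 BDOC** — new prescription courses per 1000 bed-days of care
  (frequency of prescribing);
- **DOT/1000 BDOC** — days of therapy per 1000 bed-days (overall rate of
  use), with therapy days distributed across calendar months;
- **LOT** — length of therapy: total days supply of a course, refills
  included;
- **mean ASI** — the DOT-weighted monthly mean antibiotic spectrum index
  (an integer 1–13 scale; higher = broader spectrum).

Getting there requires real data engineering, and that pipeline is the
package: header harmonization across heterogeneous CSV exports, facility-name
consolidation, inclusion screening, a seven-step cleaning cascade with a full
removal ledger, name-based drug classification, and cross-source validation
(Mann–Kendall trend test and Spearman rank correlation against dispensing
data). A seeded synthetic invoice generator with a ground-truth ledger makes
everything testable without any proprietary data.

## The core conventions

**Cleaning cascade** (fixed order, each step logged as rows removed /
remaining): (1) drop rows missing an essential field, (2) drop
non-pharmaceutical items, (3) drop reimbursements (negative amounts; $0 rows
are data), (4) de-duplicate — identical `(rx#, drug, date, physician, days
supply)` rows collapse to one ("Case One"), same key with differing days
supply keeps the greatest ("Case Two"), (5) consolidate rows sharing
`(rx#, drug)` into one course whose summed days supply is the length of
therapy, (6) drop non-systemic products by four name-pattern families
(topicals, drops, inhalers, …), (7) drop insulin and opioids (variable
dose/schedule).

**Cross-month DOT allocation** uses an exclusive-start convention: the first
therapy day is the day *after* the transaction date. A 90-day supply
transacted 2014-12-03 contributes 28 DOT to December 2014 (Dec 4–31), 31 to
January, 28 to February and 3 to March 2015:

```python
>>> import rxstew, datetime as dt
>>> rxstew.allocate_dot(dt.date(2014, 12, 3), 90)
{'2014-12': 28, '2015-01': 31, '2015-02': 28, '2015-03': 3}
```

## Worked example

Generate a messy synthetic dataset (30 monthly invoice files, four header
dialects, aliased facility names, planted junk of every kind), then run the
whole pipeline:

```sh
rxstew simulate --seed 42 --outdir demo --facilities 6 --months 24
cd demo
rxstew run --config config.yml --census census.csv --profiles profiles.csv \
    --outdir out invoices_*.csv
```

which prints the per-stage log

```
23424 rows across 30 files -> demo (7053 planted courses)
{"stage": "ingest", "rows": 23424}
{"stage": "clean", "courses": 7053}
{"stage": "classify", "antibiotic": 1621, "antihypertensive": 2344, "other": 3088}
{"stage": "metrics", "facility_months": 180}
```

`out/ledger.csv` is the removal ledger — 23,424 invoice rows in, 7,053
courses out (30.1% of the aggregate), every step telescoping exactly:

```
 step                 name   rows_removed  rows_remaining  pct_remaining
    1           incomplete            334           23090       0.985741
    2    nonpharmaceutical           1467           21623       0.923113
    3        reimbursement           3512           18111       0.773181
    4           duplicates            938           17173       0.733137
    5 refill_consolidation           8033            9140       0.390198
    6          nonsystemic            913            8227       0.351221
    7       insulin_opioid           1174            7053       0.301101
```

and `out/metrics.csv` holds one row per facility-month, e.g. for
SLEEPYHOLLOW in March 2015 (2,997 bed-days of care): 31.7 antibiotic
DOT/1000 BDOC, 3.7 starts/1000 BDOC, mean ASI 6.77, mean LOT 6.8 days,
bed-size stratum 100–150. The exact cleaning counts here equal the
generator's planted truth — that identity is what the test suite asserts.

`rxstew report --facility SLEEPYHOLLOW ...` renders a static two-panel
benchmarking report (overall DOT/1000 BDOC vs the bed-size stratum median;
per-class rates) with CSV twins of every figure, and
`rxstew validate --a ... --b ...` compares invoice-derived and
dispensing-derived metric series per facility (Spearman rho with
high / moderate / low categories, Mann–Kendall trend).

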