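"""Synthetic pharmacy-invoice generator with a ground-truth ledger.

Emits the messy multi-file inputs the pipeline is built to handle — header
dialects that vary by file, facility-name alias variants, rows missing
essential fields, non-pharmaceutical supply lines, negative reimbursement
rows, the two duplicate cases, refill chains sharing a prescription number,
non-systemic products exercising every name-pattern family, and
insulin/opioid rows — together with a :class:`SyntheticTruth` record of
every planted course and every planted junk row, so cleaning and metric
recovery can be checked exactly.

Everything is driven by one seeded generator: the same seed reproduces the
output byte for byte.
"""

from __future__ import annotations

import datetime as dt
import json
from dataclasses import dataclass, field
from pathlib import Path

import numpy as np
import pandas as pd
import yaml

from .config import CANONICAL_COLUMNS
from .errors import ConfigError
from .classify import load_lexicon

# ---------------------------------------------------------------------------
# Configuration
# ---------------------------------------------------------------------------

@dataclass
class SimConfig:
    """Study conditions for one synthetic dataset.

    Rates are per clean dispensing row (probabilities) or per 1000 BDOC per
    month (start rates).  Defaults emulate the mix observed in real invoice
    exports: ~2% incomplete rows, ~10% supply lines, ~23% reimbursements,
    ~5% exact duplicates, ~1% conflicting-days duplicates, and refill
    chains on maintenance medications.
    """

    n_facilities: int = 8
    start_month: str = "2015-01"
    n_months: int = 24
    census_mean: float = 2700.0       # fleet-mean monthly bed-days of care
    census_sd_frac: float = 0.08
    abx_start_rate: float = 4.0       # antibiotic starts / 1000 BDOC / month
    ahp_start_rate: float = 6.0       # anti-hypertensive courses initiated
    other_start_rate: float = 8.0     # other systemic medications
    iv_abx_fraction: float = 0.15
    ahp_max_refills: int = 5          # chain length 1 .. max_refills + 1
    dup_case1_p: float = 0.05
    dup_case2_p: float = 0.012
    nonpharma_rate: float = 0.10
    reimbursement_rate: float = 0.23
    missing_rate: float = 0.02
    nonsystemic_rate: float = 0.06
    insulin_opioid_rate: float = 0.08
    alias_p: float = 0.25
    volume_shift: bool = True         # halve one facility's volume mid-series
    n_short_facilities: int = 0       # facilities contributing <= 12 months
    seed: int = 0

    def validate(self) -> None:
        probs = {
            "dup_case1_p": self.dup_case1_p, "dup_case2_p": self.dup_case2_p,
            "nonpharma_rate": self.nonpharma_rate,
            "reimbursement_rate": self.reimbursement_rate,
            "missing_rate": self.missing_rate,
            "nonsystemic_rate": self.nonsystemic_rate,
            "insulin_opioid_rate": self.insulin_opioid_rate,
            "alias_p": self.alias_p,
        }
        for name, p in probs.items():
            if not 0.0 <= p <= 1.0:
                raise ConfigError(f"{name} must be in [0, 1], got {p}")
        for name, r in {
            "abx_start_rate": self.abx_start_rate,
            "ahp_start_rate": self.ahp_start_rate,
            "other_start_rate": self.other_start_rate,
        }.items():
            if r < 0:
                raise ConfigError(f"{name} must be >= 0, got {r}")
        if self.n_facilities < 1 or self.n_months < 1:
            raise ConfigError("need at least one facility and one month")
        if self.n_short_facilities >= self.n_facilities:
            raise ConfigError("n_short_facilities must leave at least one full facility")


@dataclass
class SyntheticTruth:
    """Ground truth for one generated dataset."""

    courses: pd.DataFrame            # planted clean courses
    junk_counts: dict[str, int]      # per cleaning-step planted counts
    monthly: pd.DataFrame            # facility, month, bdoc, abx_dot, abx_starts
    aliases: dict[str, str]
    n_rows_total: int
    files: list[str] = field(default_factory=list)

    def to_json(self, path) -> None:
        courses = self.courses.copy()
        courses["start_date"] = courses["start_date"].astype(str)
        payload = {
            "courses": courses.to_dict(orient="records"),
            "junk_counts": self.junk_counts,
            "monthly": self.monthly.to_dict(orient="records"),
            "aliases": self.aliases,
            "n_rows_total": self.n_rows_total,
            "files": self.files,
        }
        Path(path).write_text(json.dumps(payload, indent=1))

    @classmethod
    def from_json(cls, path) -> "SyntheticTruth":
        payload = json.loads(Path(path).read_text())
        courses = pd.DataFrame(payload["courses"])
        if len(courses):
            courses["start_date"] = pd.to_datetime(courses["start_date"])
        return cls(
            courses=courses,
            junk_counts=payload["junk_counts"],
            monthly=pd.DataFrame(payload["monthly"]),
            aliases=payload["aliases"],
            n_rows_total=payload["n_rows_total"],
            files=payload["files"],
        )


# ---------------------------------------------------------------------------
# Name pools
# ---------------------------------------------------------------------------

_FACILITY_BASES = [
    "SLEEPYHOLLOW", "MAPLEWOOD", "OAKDALE MANOR", "RIVERBEND", "WILLOW CREEK",
    "HARBORVIEW", "PINE RIDGE", "CEDARBROOK", "SUNNYVALE", "LAKESIDE COMMONS",
    "BRIARWOOD", "ELM GROVE", "FOXFIELD", "GREENBRIAR", "HILLTOP HOUSE",
    "IVYDALE", "JUNIPER COURT", "KINGSBURY", "LARKSPUR", "MEADOWLANDS",
]

_ALIAS_SUFFIXES = [" CCRC", " LLC", " SNF"]

# interleaved across the four pattern families so every family is exercised
_NONSYSTEMIC_NAMES = [
    "HYDROCORTISONE 2.5% CREAM",            # ends with <non-alpha>KEYWORD
    "PERMETHRIN CREAM 5% 60GM",             # contains <non-alpha>KEYWORD<non-alpha>
    "GELFOAM SIZE 50 SPONGE",               # starts with KEYWORD<non-alpha>
    "LIDOCAINE HCL 2% JEL",                 # starts with KEYWORD<blank>
    "TRIAMCINOLONE 0.1% OINT",
    "CIPROFLOXACIN 0.3% DROP 5ML",
    "WATER INJ BACTERIOSTATIC 30ML",
    "NACL 0.9% IRRIGATION 1000ML",
    "FLUTICASONE 50MCG NASAL",
    "TIMOLOL EYE 0.5% SOLN",
    "SSD 1% CREAM",
    "SODIUM CHL 0.45% 1000ML",
    "ALBUTEROL HFA INHALER",
    "BACITRACIN OINT 1% 30GM",
    "ABH GEL 30ML",
    "DS 50% SOLUTION 500ML",
    "NYSTATIN ORAL RINSE",
    "LACTATED RINGERS",
]

_INSULIN_OPIOID_NAMES = [
    "INSULIN GLARGINE 100U/ML VIAL", "OXYCODONE HCL 5MG TAB",
    "INSULIN LISPRO 100U/ML VIAL", "HYDROCODONE-APAP 5-325MG TAB",
    "NPH INSULIN 100U/ML VIAL", "MORPHINE SULFATE 15MG TAB",
    "INSULIN ASPART 100U/ML VIAL", "TRAMADOL HCL 50MG TAB",
    "METHADONE HCL 10MG TAB", "FENTANYL CITRATE 50MCG/ML INJ",
]

_NONPHARMA_NAMES = [
    "IV START KIT", "NORMAL SALINE FLUSH KIT",
    "STERILE WATER FOR IRRIGATION 500ML", "FOAM DRESSING 4X4",
    "INSULIN SYRINGE 1ML", "BLOOD GLUCOSE TEST STRIP",
    "ALCOHOL PREP PAD", "GAUZE SPONGE 4X4",
]

_PAYORS = ["MEDICARE", "MEDICAID", "PRIVATE", "HOSPICE", "VA", "FACILITY"]
_ORAL_ROUTES = ["PO", "ORAL", "BY MOUTH"]
_IV_ROUTES = ["IV", "INTRAVENOUS", "IVPB"]

# header dialect: canonical column -> source header (None = column absent);
# the fourth dialect carries an extra unmapped column
_DIALECTS: list[dict] = [
    {col: col for col in CANONICAL_COLUMNS},
    {
        "facility": "Facility Name", "medication": "Drug Name", "dose": "Qty",
        "days_supply": "Days Supply", "prescription_number": "Rx",
        "transaction_date": "Transaction Date", "amount": "Amount",
        "route": "Route of Administration", "physician": "Physician",
        "payor": "Payor", "ndc": "NDC",
    },
    {
        "facility": "Facility", "medication": "Medication Name", "dose": "Quantity",
        "days_supply": "Days Dispensed", "prescription_number": "Prescription Number",
        "transaction_date": "Transaction Date", "amount": "Amount",
        "route": "Inventory Category", "physician": "Physician",
        "payor": "Pay Type Description", "ndc": "National Drug Code",
    },
    {
        "facility": "Facility Name", "medication": "Agent", "dose": "Dose",
        "days_supply": "Days of Supply", "prescription_number": "Rx",
        "transaction_date": "Transaction Date", "amount": "Amount",
        "route": "Route of Administration", "physician": "Physician",
        "payor": "Payor", "ndc": "NDC", "_extra": "Batch",
    },
]


def _drug_pools() -> tuple[list[dict], list[str], list[str]]:
    """Systemic name pools from the bundled lexicon: antibiotic entries
    (with class info for the truth record) and anti-hypertensive / other
    invoice-style names."""
    lex = load_lexicon()
    abx, ahp, other = [], [], []
    for entry in lex.entries:
        if entry.category == "antibiotic":
            abx.append(
                {"keyword": entry.keyword, "generic": entry.generic,
                 "class": entry.drug_class}
            )
        elif entry.category == "antihypertensive":
            ahp.append(entry.keyword)
        else:
            other.append(entry.keyword)
    return abx, sorted(ahp), sorted(other)


def _month_sequence(start_month: str, n_months: int) -> list[pd.Period]:
    start = pd.Period(start_month, freq="M")
    return [start + i for i in range(n_months)]


def _daywalk_allocation(start_date: dt.date, total_days: int) -> dict[str, int]:
    """Month allocation by walking calendar days one at a time (first therapy
    day is the day after the transaction date).  Deliberately naive; serves
    as the truth-side counterpart to the metrics module's arithmetic."""
    out: dict[str, int] = {}
    for i in range(1, total_days + 1):
        day = start_date + dt.timedelta(days=i)
        key = f"{day.year:04d}-{day.month:02d}"
        out[key] = out.get(key, 0) + 1
    return out


def _fmt_amount(value: float, styled: bool) -> str:
    if styled:
        sign = "-" if value < 0 else ""
        return f"{sign}${abs(value):,.2f}"
    return f"{value:.2f}"


# ---------------------------------------------------------------------------
# Generator
# ---------------------------------------------------------------------------

def generate(config: SimConfig, outdir: str | Path) -> SyntheticTruth:
    """Write invoice CSV files, census.csv, profiles.csv, config.yml and
    truth.json under ``outdir``; return the in-memory truth record."""
    config.validate()
    outdir = Path(outdir)
    outdir.mkdir(parents=True, exist_ok=True)
    rng = np.random.default_rng(config.seed)
    abx_pool, ahp_pool, other_pool = _drug_pools()

    if config.n_facilities > len(_FACILITY_BASES):
        names = [
            f"{_FACILITY_BASES[i % len(_FACILITY_BASES)]} {i // len(_FACILITY_BASES) + 1}"
            for i in range(config.n_facilities)
        ]
    else:
        names = _FACILITY_BASES[: config.n_facilities]

    aliases: dict[str, str] = {}
    variants: dict[str, list[str]] = {}
    for name in names:
        vs = [name, name.title()]
        for suffix in _ALIAS_SUFFIXES[:2]:
            vs.append(name + suffix)
            aliases[name + suffix] = name
        variants[name] = vs

    months = _month_sequence(config.start_month, config.n_months)
    short_set = set(names[-config.n_short_facilities:]) if config.n_short_facilities else set()
    shift_facility = names[0]  # never in short_set (short facilities come from the tail)

    # facility profiles and census over the active span
    occupancy = {f: float(rng.uniform(0.75, 0.95)) for f in names}
    scale = {f: float(np.exp(rng.normal(0.0, 0.35))) for f in names}
    beds = {
        f: max(30, int(round(config.census_mean * scale[f] / (30.44 * occupancy[f]))))
        for f in names
    }

    def draw_bdoc(facility: str, period: pd.Period) -> int:
        dim = period.days_in_month
        base = beds[facility] * dim * occupancy[facility]
        return max(1, int(round(base * (1.0 + rng.normal(0.0, config.census_sd_frac)))))

    bdoc: dict[tuple[str, str], int] = {}
    for f in names:
        for m in months:
            bdoc[(f, str(m))] = draw_bdoc(f, m)

    rx_counter = 0

    def next_rx(prefix: str = "RX") -> str:
        nonlocal rx_counter
        rx_counter += 1
        return f"{prefix}{rx_counter:07d}"

    def physician() -> str:
        return f"DR{rng.integers(1, 150):04d}"

    def payor() -> str:
        return _PAYORS[rng.integers(0, len(_PAYORS))]

    def ndc() -> str:
        return f"{rng.integers(0, 10**11):011d}" if rng.random() > 0.07 else ""

    def amount() -> float:
        return round(float(rng.uniform(5.0, 400.0)), 2)

    rows_by_month: dict[str, list[dict]] = {str(m): [] for m in months}
    course_records: list[dict] = []
    junk = {k: 0 for k in (
        "incomplete", "nonpharma", "reimbursement", "case1", "case2",
        "refill_rows", "nonsystemic", "insulin_opioid",
    )}
    clean_dispensings: list[dict] = []
    cycle = {"nonsystemic": 0, "insulin_opioid": 0, "nonpharma": 0}

    def make_course(
        facility: str, period: pd.Period, kind: str, single_dispensing: bool = False
    ) -> None:
        # short-history facilities get chain-free courses so their invoice
        # months stay within the short window the screen is meant to catch
        dim = period.days_in_month
        start_day = int(rng.integers(1, dim + 1))
        start = dt.date(period.year, period.month, start_day)
        rx = next_rx()
        doc = physician()
        pay = payor()
        code = ndc()
        if kind == "abx":
            drug = abx_pool[rng.integers(0, len(abx_pool))]
            iv = rng.random() < config.iv_abx_fraction
            if iv:
                route = _IV_ROUTES[rng.integers(0, len(_IV_ROUTES))]
                n_disp = int(rng.integers(2, 5))
                per_disp = [2] * n_disp
                dates = [start + dt.timedelta(days=2 * i) for i in range(n_disp)]
                name = f"{drug['keyword']} {rng.integers(1, 3)}GM INJ"
            else:
                route = _ORAL_ROUTES[rng.integers(0, len(_ORAL_ROUTES))]
                per_disp = [int(rng.choice([5, 7, 10, 14], p=[0.3, 0.4, 0.2, 0.1]))]
                dates = [start]
                name = f"{drug['keyword']} {rng.choice([100, 250, 500, 875])}MG TAB"
            extra = {"category": "antibiotic", "generic": drug["generic"],
                     "class": drug["class"], "route_class": "IV" if iv else "oral"}
        elif kind == "ahp":
            keyword = ahp_pool[rng.integers(0, len(ahp_pool))]
            route = _ORAL_ROUTES[rng.integers(0, len(_ORAL_ROUTES))]
            chain = 1 if single_dispensing else int(rng.integers(1, config.ahp_max_refills + 2))
            per_disp = [30] * chain
            dates = [start]
            for _ in range(chain - 1):
                dates.append(dates[-1] + dt.timedelta(days=int(30 + rng.integers(-5, 6))))
            name = f"{keyword} {rng.choice([5, 10, 25, 50])}MG TAB"
            extra = {"category": "antihypertensive", "generic": keyword,
                     "class": "antihypertensive", "route_class": "oral"}
        else:
            keyword = other_pool[rng.integers(0, len(other_pool))]
            route = _ORAL_ROUTES[rng.integers(0, len(_ORAL_ROUTES))]
            chain = 1 if single_dispensing else int(rng.integers(1, 3))
            days = int(rng.choice([7, 14, 30]))
            per_disp = [days] * chain
            dates = [start]
            for _ in range(chain - 1):
                dates.append(dates[-1] + dt.timedelta(days=int(30 + rng.integers(-5, 6))))
            name = f"{keyword} {rng.choice([10, 20, 40, 500])}MG TAB"
            extra = {"category": "other", "generic": keyword, "class": "",
                     "route_class": "oral"}
        for date, days in zip(dates, per_disp):
            row = {
                "facility": facility, "medication": name,
                "dose": f"{rng.integers(1, 91)} EA", "days_supply": str(days),
                "prescription_number": rx, "transaction_date": date.isoformat(),
                "amount": amount(), "route": route, "physician": doc,
                "payor": pay, "ndc": code,
            }
            clean_dispensings.append(row)
        junk["refill_rows"] += len(dates) - 1
        course_records.append(
            {
                "facility": facility, "medication": name,
                "prescription_number": rx,
                "start_date": min(dates).isoformat(),
                "total_days_supply": int(sum(per_disp)),
                "n_dispensings": len(dates), "route": route, **extra,
            }
        )

    for facility in names:
        active = months if facility not in short_set else months[-10:]
        for period in active:
            mult = 1.0
            if config.volume_shift and facility == shift_facility:
                if months.index(period) >= len(months) // 2:
                    mult = 0.45
            scale_m = bdoc[(facility, str(period))] / 1000.0 * mult
            for kind, rate in (
                ("abx", config.abx_start_rate),
                ("ahp", config.ahp_start_rate),
                ("other", config.other_start_rate),
            ):
                for _ in range(int(rng.poisson(rate * scale_m))):
                    make_course(facility, period, kind,
                                single_dispensing=facility in short_set)

    # junk rows keyed off the clean dispensings
    junk_rows: list[dict] = []
    essential_choices = [
        "facility", "transaction_date", "prescription_number", "medication",
        "days_supply", "amount", "route", "physician", "payor",
    ]
    for row in clean_dispensings:
        if rng.random() < config.dup_case1_p:
            junk_rows.append(dict(row))
            junk["case1"] += 1
        if rng.random() < config.dup_case2_p and int(row["days_supply"]) >= 1:
            copy = dict(row)
            copy["days_supply"] = str(int(rng.integers(0, int(row["days_supply"]))))
            copy["amount"] = amount()
            junk_rows.append(copy)
            junk["case2"] += 1
        if rng.random() < config.nonpharma_rate:
            name = _NONPHARMA_NAMES[cycle["nonpharma"] % len(_NONPHARMA_NAMES)]
            cycle["nonpharma"] += 1
            junk_rows.append(
                {**row, "medication": name, "prescription_number": next_rx("NP"),
                 "days_supply": "1", "route": "SUPPLY", "amount": amount(),
                 "ndc": ""}
            )
            junk["nonpharma"] += 1
        if rng.random() < config.reimbursement_rate:
            junk_rows.append(
                {**row, "prescription_number": next_rx("RB"),
                 "amount": -round(float(rng.uniform(5.0, 300.0)), 2)}
            )
            junk["reimbursement"] += 1
        if rng.random() < config.missing_rate:
            broken = dict(row)
            broken["prescription_number"] = next_rx("MS")
            victim = essential_choices[rng.integers(0, len(essential_choices))]
            if victim == "days_supply":
                broken["days_supply"] = str(rng.choice(["", "abc"]))
            elif victim == "transaction_date":
                broken["transaction_date"] = str(rng.choice(["", "UNKNOWN"]))
            else:
                broken[victim] = ""
            junk_rows.append(broken)
            junk["incomplete"] += 1
        if rng.random() < config.nonsystemic_rate:
            name = _NONSYSTEMIC_NAMES[cycle["nonsystemic"] % len(_NONSYSTEMIC_NAMES)]
            cycle["nonsystemic"] += 1
            junk_rows.append(
                {**row, "medication": name, "prescription_number": next_rx("NS"),
                 "days_supply": str(rng.integers(1, 31)), "route": "TOPICAL",
                 "amount": amount(), "ndc": ndc()}
            )
            junk["nonsystemic"] += 1
        if rng.random() < config.insulin_opioid_rate:
            name = _INSULIN_OPIOID_NAMES[cycle["insulin_opioid"] % len(_INSULIN_OPIOID_NAMES)]
            cycle["insulin_opioid"] += 1
            junk_rows.append(
                {**row, "medication": name, "prescription_number": next_rx("VD"),
                 "days_supply": str(rng.integers(1, 31)), "amount": amount(),
                 "ndc": ndc()}
            )
            junk["insulin_opioid"] += 1

    # bucket every row into the calendar month of its transaction date;
    # refill transactions can fall after the configured span
    def month_key(row: dict) -> str:
        text = row["transaction_date"]
        try:
            date = dt.date.fromisoformat(text)
        except ValueError:
            return str(months[0])
        return f"{date.year:04d}-{date.month:02d}"

    for row in clean_dispensings + junk_rows:
        rows_by_month.setdefault(month_key(row), []).append(row)

    all_months = sorted(rows_by_month)
    courses = pd.DataFrame(course_records)
    if len(courses):
        courses["start_date"] = pd.to_datetime(courses["start_date"])

    # census must cover every month any course allocates therapy days to
    truth_alloc: dict[tuple[str, str], int] = {}
    last_period = months[-1]
    for rec in course_records:
        start = dt.date.fromisoformat(rec["start_date"])
        if rec["category"] != "antibiotic":
            end = start + dt.timedelta(days=rec["total_days_supply"])
            last_period = max(last_period, pd.Period(f"{end.year:04d}-{end.month:02d}", freq="M"))
            continue
        for month, days in _daywalk_allocation(start, rec["total_days_supply"]).items():
            truth_alloc[(rec["facility"], month)] = (
                truth_alloc.get((rec["facility"], month), 0) + days
            )
            last_period = max(last_period, pd.Period(month, freq="M"))
    census_months = _month_sequence(str(months[0]), (last_period - months[0]).n + 1)
    for f in names:
        for m in census_months:
            if (f, str(m)) not in bdoc:
                bdoc[(f, str(m))] = draw_bdoc(f, m)

    starts_truth: dict[tuple[str, str], int] = {}
    for rec in course_records:
        if rec["category"] != "antibiotic":
            continue
        key = (rec["facility"], rec["start_date"][:7])
        starts_truth[key] = starts_truth.get(key, 0) + 1

    monthly = pd.DataFrame(
        [
            {
                "facility": f, "month": str(m), "bdoc": bdoc[(f, str(m))],
                "abx_dot": truth_alloc.get((f, str(m)), 0),
                "abx_starts": starts_truth.get((f, str(m)), 0),
            }
            for f in names
            for m in census_months
        ]
    )

    # ------------------------------------------------------------------
    # serialize
    # ------------------------------------------------------------------
    files: list[str] = []
    for i, month in enumerate(all_months):
        rows = rows_by_month[month]
        if not rows:
            continue
        order = rng.permutation(len(rows))
        dialect = _DIALECTS[i % len(_DIALECTS)]
        styled_amount = i % len(_DIALECTS) == 1
        headers = list(dialect.values())
        lines = [",".join(f'"{h}"' for h in headers)]
        for j in order:
            row = rows[int(j)]
            facility_raw = row["facility"]
            vs = variants.get(facility_raw)
            if vs is not None and rng.random() < config.alias_p:
                facility_raw = vs[int(rng.integers(1, len(vs)))]
            cells = []
            for canonical in dialect:
                if canonical == "_extra":
                    cells.append(f"B{rng.integers(1, 999):03d}")
                    continue
                value = row[canonical]
                if canonical == "facility":
                    value = facility_raw
                elif canonical == "amount" and str(value) != "":
                    value = _fmt_amount(float(value), styled_amount)
                cells.append(str(value))
            lines.append(",".join(f'"{c}"' for c in cells))
        path = outdir / f"invoices_{month}.csv"
        path.write_text("\n".join(lines) + "\n")
        files.append(path.name)

    monthly_out = monthly.rename(columns={})
    monthly_out[["facility", "month", "bdoc"]].to_csv(outdir / "census.csv", index=False)
    pd.DataFrame(
        [
            {"facility": f, "beds": beds[f], "occupancy": round(occupancy[f], 3)}
            for f in names
        ]
    ).to_csv(outdir / "profiles.csv", index=False)

    run_config = {
        "ingest": {
            "date_dialect": "iso",
            "aliases": aliases,
            "min_months": 12,
            "change_threshold": 0.20,
            "exclusions": [],
        }
    }
    (outdir / "config.yml").write_text(yaml.safe_dump(run_config, sort_keys=True))

    truth = SyntheticTruth(
        courses=courses,
        junk_counts=junk,
        monthly=monthly,
        aliases=aliases,
        n_rows_total=len(clean_dispensings) + len(junk_rows),
        files=files,
    )
    truth.to_json(outdir / "truth.json")
    return truth


# ---------------------------------------------------------------------------
# Paired dispensing source
# ---------------------------------------------------------------------------

def generate_paired_dispensing(
    truth: SyntheticTruth,
    path: str | Path,
    skilled_fraction: float = 0.6,
    seed: int = 0,
) -> Path:
    """Write a canonical-format dispensing dataset paired with the invoices.

    Invoice data covers mainly skilled-nursing residents; dispensing data
    covers everyone.  The dispensing set therefore contains every planted
    invoice course plus extra antibiotic courses per facility-month sized so
    dispensing DOT approximates invoice DOT / skilled_fraction, each extra
    course fully contained in its month.  With skilled_fraction = 1 the
    dispensing set equals the invoice courses.
    """
    if not 0.0 < skilled_fraction <= 1.0:
        raise ConfigError("skilled_fraction must be in (0, 1]")
    rng = np.random.default_rng(seed)
    abx_pool, _, _ = _drug_pools()
    rows: list[dict] = []

    def add_row(facility, medication, rx, date, days, route):
        rows.append(
            {
                "facility": facility, "medication": medication, "dose": "",
                "days_supply": str(int(days)), "prescription_number": rx,
                "transaction_date": date.isoformat() if hasattr(date, "isoformat") else str(date)[:10],
                "amount": f"{float(rng.uniform(5.0, 400.0)):.2f}",
                "route": route, "physician": "DR0001", "payor": "MEDICARE",
                "ndc": "",
            }
        )

    for _, course in truth.courses.iterrows():
        add_row(
            course["facility"], course["medication"],
            "D" + str(course["prescription_number"]),
            pd.Timestamp(course["start_date"]).date(),
            int(course["total_days_supply"]), course["route"],
        )

    counter = 0
    if skilled_fraction < 1.0:
        factor = 1.0 / skilled_fraction - 1.0
        for _, rec in truth.monthly.iterrows():
            invoice_dot = int(rec["abx_dot"])
            if invoice_dot <= 0:
                continue
            extra = max(1, int(round(invoice_dot * factor)))
            period = pd.Period(rec["month"], freq="M")
            dim = period.days_in_month
            while extra > 0:
                days = min(5, extra)
                # therapy days t+1 .. t+days must stay inside the month
                start_day = int(rng.integers(1, max(2, dim - days)))
                date = dt.date(period.year, period.month, start_day)
                drug = abx_pool[int(rng.integers(0, len(abx_pool)))]
                counter += 1
                add_row(
                    rec["facility"],
                    f"{drug['keyword']} 500MG TAB",
                    f"XTR{counter:06d}", date, days,
                    "PO",
                )
                extra -= days

    path = Path(path)
    frame = pd.DataFrame(rows, columns=CANONICAL_COLUMNS)
    frame.to_csv(path, index=False)
    return path
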