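"""Seven-step cleaning cascade: invoice rows -> one course per prescription.

Steps run in a fixed order and each reports rows removed to a ledger whose
counts telescope (removed + remaining = previous remaining):

1. drop rows missing any essential field
2. drop non-pharmaceutical items (supplies, flushes, kits)
3. drop reimbursements (negative amounts; $0 rows are retained)
4. de-duplicate: Case One — identical (rx#, drug, date, physician, days
   supply) rows collapse to one; Case Two — same key, differing days supply,
   keep the greatest
5. consolidate refills: rows sharing (rx#, drug) become one course whose
   total days supply is the length of therapy and whose start date is the
   earliest transaction date
6. drop non-systemic medications by name pattern (topicals, drops,
   suppositories, inhaled agents)
7. drop insulin and opioids (variable dose/schedule medications)

Steps 1-4 operate on invoice rows, 6-7 on consolidated courses; the removal
predicates of 6-7 depend only on the medication name, so their position
before or after consolidation cannot change the final course set.
"""

from __future__ import annotations

import re
from dataclasses import dataclass, field
from typing import Mapping, Sequence

import pandas as pd

from .config import (
    DEFAULT_ESSENTIAL_FIELDS,
    DEFAULT_INSULIN_KEYWORDS,
    DEFAULT_NONPHARMA_KEYWORDS,
    DEFAULT_OPIOID_KEYWORDS,
    NONSYSTEMIC_AFFIX_KEYWORDS,
    NONSYSTEMIC_LEADING_KEYWORDS,
    NONSYSTEMIC_PREFIX_KEYWORDS,
)
from .errors import ConfigError, IntegrityError

COURSE_COLUMNS = [
    "facility", "medication", "prescription_number", "start_date",
    "total_days_supply", "route", "physician", "payor", "n_dispensings",
]

STEP_NAMES = [
    "incomplete", "nonpharmaceutical", "reimbursement", "duplicates",
    "refill_consolidation", "nonsystemic", "insulin_opioid",
]

STEP_DESCRIPTIONS = {
    "incomplete": "Removed rows missing data from essential columns",
    "nonpharmaceutical": "Removed rows for non-pharmaceuticals",
    "reimbursement": "Removed rows indicating reimbursements",
    "duplicates": "Removed duplicate rows",
    "refill_consolidation": "Removed rows indicating medication refills",
    "nonsystemic": "Removed rows for non-systemic medications",
    "insulin_opioid": "Removed rows for insulin and opioids",
}


# ---------------------------------------------------------------------------
# Ledger
# ---------------------------------------------------------------------------

@dataclass
class LedgerStep:
    name: str
    description: str
    removed: int
    remaining: int
    pct_remaining: float  # fraction of the aggregate row count


@dataclass
class CleaningLedger:
    """Ordered removal record; mirrors the step/removed/remaining layout."""

    initial: int
    steps: list[LedgerStep] = field(default_factory=list)

    def add(self, name: str, removed: int, remaining: int) -> None:
        previous = self.steps[-1].remaining if self.steps else self.initial
        if removed + remaining != previous:
            raise IntegrityError(
                f"ledger step {name!r}: {removed} removed + {remaining} remaining "
                f"!= {previous} previous"
            )
        pct = remaining / self.initial if self.initial else 0.0
        self.add_raw(LedgerStep(name, STEP_DESCRIPTIONS.get(name, name), removed, remaining, pct))

    def add_raw(self, step: LedgerStep) -> None:
        self.steps.append(step)

    def removed(self, name: str) -> int:
        for step in self.steps:
            if step.name == name:
                return step.removed
        raise KeyError(name)

    def to_frame(self) -> pd.DataFrame:
        rows = [
            {"step": i + 1, "name": s.name, "description": s.description,
             "rows_removed": s.removed, "rows_remaining": s.remaining,
             "pct_remaining": s.pct_remaining}
            for i, s in enumerate(self.steps)
        ]
        return pd.DataFrame(rows)

    def to_dict(self) -> dict:
        return {"initial": self.initial,
                "steps": self.to_frame().to_dict(orient="records")}


# ---------------------------------------------------------------------------
# Steps 1-3: row filters
# ---------------------------------------------------------------------------

def drop_incomplete(
    records: pd.DataFrame, essential: Sequence[str] | None = None
) -> tuple[pd.DataFrame, int]:
    """Keep rows with every essential field present (zero is a value, not missing)."""
    essential = list(essential) if essential is not None else DEFAULT_ESSENTIAL_FIELDS
    mask = records[essential].notna().all(axis=1)
    kept = records[mask]
    return kept, int((~mask).sum())


def _word_pattern(keywords: Sequence[str]) -> re.Pattern | None:
    words = [re.escape(k.upper()) for k in keywords]
    if not words:
        return None
    return re.compile(r"\b(?:" + "|".join(words) + r")\b")


def drop_nonpharmaceutical(
    records: pd.DataFrame, product_keywords: Sequence[str] | None = None
) -> tuple[pd.DataFrame, int]:
    """Remove supply/non-drug lines by whole-word keyword match on the name."""
    keywords = product_keywords if product_keywords is not None else DEFAULT_NONPHARMA_KEYWORDS
    pattern = _word_pattern(keywords)
    if pattern is None:
        return records, 0
    names = records["medication"].fillna("").astype(str).str.upper()
    mask = names.str.contains(pattern, regex=True).astype(bool)
    return records[~mask.to_numpy()], int(mask.sum())


def drop_reimbursements(records: pd.DataFrame) -> tuple[pd.DataFrame, int]:
    """Remove negative-amount rows (payments/credits); $0 rows are kept."""
    mask = records["amount"] < 0
    mask = mask.fillna(False).astype(bool)
    return records[~mask], int(mask.sum())


# ---------------------------------------------------------------------------
# Step 4: de-duplication
# ---------------------------------------------------------------------------

_DEDUP_KEY = ["prescription_number", "medication", "transaction_date", "physician"]


def deduplicate(records: pd.DataFrame) -> tuple[pd.DataFrame, int, int]:
    """Collapse duplicate dispensing rows.

    Case One: rows identical on (rx#, drug, date, physician, days supply)
    collapse to the first.  Case Two: rows sharing the key but differing in
    days supply keep the (first) row with the greatest days supply.  Input
    order is preserved; returns ``(kept, n_case1, n_case2)``.
    """
    n0 = len(records)
    once = records.drop_duplicates(subset=_DEDUP_KEY + ["days_supply"], keep="first")
    case1 = n0 - len(once)
    group_max = once.groupby(_DEDUP_KEY, dropna=False, sort=False)["days_supply"].transform("max")
    at_max = once[once["days_supply"].eq(group_max) | once["days_supply"].isna()]
    kept = at_max.drop_duplicates(subset=_DEDUP_KEY, keep="first")
    case2 = len(once) - len(kept)
    return kept, case1, case2


# ---------------------------------------------------------------------------
# Step 5: refill consolidation
# ---------------------------------------------------------------------------

def consolidate_refills(records: pd.DataFrame) -> pd.DataFrame:
    """One course per (prescription number, medication).

    Total days supply is summed across dispensings (length of therapy);
    the start date is the earliest transaction date; descriptive fields are
    taken from the earliest dispensing.  One prescription number appearing
    at two facilities is a data integrity error, not a consolidation.
    """
    if records.empty:
        return pd.DataFrame(columns=COURSE_COLUMNS)
    ordered = records.sort_values("transaction_date", kind="stable")
    grouped = ordered.groupby(["prescription_number", "medication"], sort=False)
    fac_counts = grouped["facility"].nunique()
    if (fac_counts > 1).any():
        bad = fac_counts[fac_counts > 1].index[0]
        raise IntegrityError(
            f"prescription {bad[0]!r} ({bad[1]!r}) appears at multiple facilities"
        )
    courses = grouped.agg(
        facility=("facility", "first"),
        start_date=("transaction_date", "min"),
        total_days_supply=("days_supply", "sum"),
        route=("route", "first"),
        physician=("physician", "first"),
        payor=("payor", "first"),
        n_dispensings=("days_supply", "size"),
    ).reset_index()
    courses = courses.sort_values(
        ["facility", "start_date", "prescription_number", "medication"],
        kind="stable",
    ).reset_index(drop=True)
    return courses[COURSE_COLUMNS]


# ---------------------------------------------------------------------------
# Steps 6-7: name-pattern removals
# ---------------------------------------------------------------------------

class NonSystemicRules:
    """Compiled name patterns for non-systemic (topical/otic/ophthalmic/
    suppository/inhaled) products, in four families:

    a. name ends with <non-alpha>KEYWORD         (…2.5% CREAM)
    b. name contains <non-alpha>KEYWORD<non-alpha> (… CREAM 5% …)
    c. name starts with KEYWORD<non-alpha>        (GELFOAM …)
    d. name starts with KEYWORD<blank>, optionally followed by a
       percent-bearing token                      (LIDOCAINE HCL 2% JEL)

    Patterns compile at construction; a bad keyword is a config error at
    load time, never a match-time failure.
    """

    def __init__(
        self,
        affix_keywords: Sequence[str] | None = None,
        prefix_keywords: Sequence[str] | None = None,
        leading_keywords: Sequence[str] | None = None,
    ) -> None:
        affix = affix_keywords if affix_keywords is not None else NONSYSTEMIC_AFFIX_KEYWORDS
        prefix = prefix_keywords if prefix_keywords is not None else NONSYSTEMIC_PREFIX_KEYWORDS
        leading = leading_keywords if leading_keywords is not None else NONSYSTEMIC_LEADING_KEYWORDS
        try:
            self.families: list[tuple[str, re.Pattern]] = []
            if affix:
                alts = "|".join(re.escape(k.upper()) for k in affix)
                self.families.append(("a", re.compile(rf"[^A-Z](?:{alts})$")))
                self.families.append(("b", re.compile(rf"[^A-Z](?:{alts})[^A-Z]")))
            if prefix:
                alts = "|".join(re.escape(k.upper()) for k in prefix)
                self.families.append(("c", re.compile(rf"^(?:{alts})[^A-Z]")))
            if leading:
                alts = "|".join(re.escape(k.upper()) for k in leading)
                self.families.append(("d", re.compile(rf"^(?:{alts})[ \t]")))
        except re.error as exc:  # pragma: no cover - defensive
            raise ConfigError(f"non-systemic pattern failed to compile: {exc}") from exc

    def family_of(self, name: str) -> str | None:
        """First matching family label for a medication name, else None."""
        upper = str(name).upper()
        for label, pattern in self.families:
            if pattern.search(upper):
                return label
        return None

    def matches(self, name: str) -> bool:
        return self.family_of(name) is not None


def drop_nonsystemic(
    courses: pd.DataFrame, rules: NonSystemicRules | None = None
) -> tuple[pd.DataFrame, int]:
    """Remove courses whose medication name matches a non-systemic pattern."""
    rules = rules if rules is not None else NonSystemicRules()
    names = courses["medication"].fillna("").astype(str)
    mask = names.map(rules.matches).astype(bool)
    return courses[~mask.to_numpy()], int(mask.sum())


def drop_variable_dose(
    courses: pd.DataFrame,
    insulin_keywords: Sequence[str] | None = None,
    opioid_keywords: Sequence[str] | None = None,
) -> tuple[pd.DataFrame, int]:
    """Remove insulin and opioid courses (no fixed dose or schedule)."""
    insulin = insulin_keywords if insulin_keywords is not None else DEFAULT_INSULIN_KEYWORDS
    opioids = opioid_keywords if opioid_keywords is not None else DEFAULT_OPIOID_KEYWORDS
    pattern = _word_pattern(list(insulin) + list(opioids))
    if pattern is None:
        return courses, 0
    names = courses["medication"].fillna("").astype(str).str.upper()
    mask = names.str.contains(pattern, regex=True).astype(bool)
    return courses[~mask.to_numpy()], int(mask.sum())


# ---------------------------------------------------------------------------
# Step 5-7 driver
# ---------------------------------------------------------------------------

def run_cleaning(
    records: pd.DataFrame, config: Mapping | None = None
) -> tuple[pd.DataFrame, CleaningLedger]:
    """Apply the full cascade in its fixed order; return courses + ledger."""
    from .config import default_config

    cfg = dict(config) if config is not None else default_config()
    cln = cfg["cleaning"]
    ledger = CleaningLedger(initial=len(records))

    kept, removed = drop_incomplete(records, cln.get("essential_fields"))
    ledger.add("incomplete", removed, len(kept))

    kept, removed = drop_nonpharmaceutical(kept, cln.get("nonpharma_keywords"))
    ledger.add("nonpharmaceutical", removed, len(kept))

    kept, removed = drop_reimbursements(kept)
    ledger.add("reimbursement", removed, len(kept))

    kept, case1, case2 = deduplicate(kept)
    ledger.add("duplicates", case1 + case2, len(kept))
    ledger.case1_removed = case1  # type: ignore[attr-defined]
    ledger.case2_removed = case2  # type: ignore[attr-defined]

    courses = consolidate_refills(kept)
    ledger.add("refill_consolidation", len(kept) - len(courses), len(courses))

    ns = cln.get("nonsystemic", {})
    rules = NonSystemicRules(
        ns.get("affix_keywords"), ns.get("prefix_keywords"), ns.get("leading_keywords")
    )
    courses, removed = drop_nonsystemic(courses, rules)
    ledger.add("nonsystemic", removed, len(courses))

    courses, removed = drop_variable_dose(
        courses, cln.get("insulin_keywords"), cln.get("opioid_keywords")
    )
    ledger.add("insulin_opioid", removed, len(courses))

    return courses.reset_index(drop=True), ledger


def write_courses_csv(courses: pd.DataFrame, path) -> None:
    out = courses.copy()
    out["start_date"] = out["start_date"].dt.strftime("%Y-%m-%d")
    out[COURSE_COLUMNS].to_csv(path, index=False)


def read_courses_csv(path) -> pd.DataFrame:
    frame = pd.read_csv(path, dtype=str, keep_default_na=False)
    frame["start_date"] = pd.to_datetime(frame["start_date"], format="%Y-%m-%d")
    frame["total_days_supply"] = pd.to_numeric(frame["total_days_supply"]).astype("Int64")
    frame["n_dispensings"] = pd.to_numeric(frame["n_dispensings"]).astype("Int64")
    extra = [c for c in frame.columns if c not in COURSE_COLUMNS]
    return frame[COURSE_COLUMNS + extra]
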