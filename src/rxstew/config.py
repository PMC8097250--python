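"""Default configuration for the invoice-to-antibiotic-use pipeline.

Every list here is editable through the YAML run configuration; the values
below are the package defaults.  The canonical schema is the eleven-column
invoice layout used throughout: facility, medication, dose, days_supply,
prescription_number, transaction_date, amount, route, physician, payor, ndc.
"""

from __future__ import annotations

import copy
from pathlib import Path
from typing import Any, Mapping

import yaml

from .errors import ConfigError

#: Canonical column order of the harmonized invoice table.
CANONICAL_COLUMNS: list[str] = [
    "facility",
    "medication",
    "dose",
    "days_supply",
    "prescription_number",
    "transaction_date",
    "amount",
    "route",
    "physician",
    "payor",
    "ndc",
]

#: Columns that must be non-missing for a row to survive cleaning step 1.
#: dose and ndc are carried but not essential (NDC is metadata only).
DEFAULT_ESSENTIAL_FIELDS: list[str] = [
    "facility",
    "transaction_date",
    "prescription_number",
    "medication",
    "days_supply",
    "amount",
    "route",
    "physician",
    "payor",
]

#: Accepted source spellings per canonical column.  Matching is
#: case-insensitive on whitespace-collapsed header text; the canonical name
#: itself is always accepted.
DEFAULT_COLUMN_MAP: dict[str, list[str]] = {
    "facility": ["Facility Name", "Facility"],
    "medication": ["Drug Name", "Medication Name", "Agent", "Description"],
    "dose": ["Dose", "Quantity", "Qty"],
    "days_supply": ["Days Supply", "Days of Supply", "Days Dispensed"],
    "prescription_number": ["Prescription Number", "Rx"],
    "transaction_date": ["Transaction Date"],
    "amount": ["Amount"],
    "route": ["Route of Administration", "Inventory Category"],
    "physician": ["Physician"],
    "payor": ["Payor", "Pay Type Description"],
    "ndc": ["NDC", "National Drug Code"],
}

# ---------------------------------------------------------------------------
# Removal keyword tables
# ---------------------------------------------------------------------------

#: Keywords for the two "non-alphabetic neighbour" non-systemic pattern
#: families (name ends with <non-alpha>KEYWORD; name contains
#: <non-alpha>KEYWORD<non-alpha>).
NONSYSTEMIC_AFFIX_KEYWORDS: list[str] = [
    "CREAM", "CRM", "DROP", "EAR", "EYE", "EYEOINT", "FOAM", "GEL",
    "INHALER", "INHAL", "LOTION", "MOUTHWAS", "MOUTHWASH", "NASAL",
    "OINT", "OINTM", "OINTMENT", "OPTH", "OPHTH", "OTIC", "PATCH",
    "RINSE", "SPRAY", "TOPIC", "TOPICAL", "SHAMP", "SHAMPOO",
    "RINGERS", "1:1",
]

#: Keywords for the "starts with KEYWORD<non-alpha>" family.
NONSYSTEMIC_PREFIX_KEYWORDS: list[str] = ["GELFOAM", "WATER INJ", "SSD", "ABH"]

#: Keywords for the "starts with KEYWORD followed by a blank" family
#: (solutions and injectables identified by their leading token).
NONSYSTEMIC_LEADING_KEYWORDS: list[str] = ["DS", "LIDOCAINE", "NACL", "SODIUM CHL"]

#: Non-pharmaceutical invoice lines (supplies, flushes, test materials).
#: Matched as whole words against the uppercased medication string.
DEFAULT_NONPHARMA_KEYWORDS: list[str] = [
    "KIT", "NORMAL SALINE", "STERILE WATER", "DRESSING", "SYRINGE",
    "NEEDLE", "UNDERPAD", "GLUCOSE TEST", "TEST STRIP", "LANCET",
    "ALCOHOL PREP", "GAUZE",
]

#: Insulins (generic + common analog/brand tokens).  Package-supplied default;
#: the source study's list is unpublished.
DEFAULT_INSULIN_KEYWORDS: list[str] = [
    "INSULIN", "GLARGINE", "LISPRO", "ASPART", "DETEMIR", "DEGLUDEC",
    "NPH", "HUMALOG", "NOVOLOG", "LANTUS", "LEVEMIR", "HUMULIN",
    "NOVOLIN", "TRESIBA", "BASAGLAR",
]

#: Opioid generics.  Package-supplied default.
DEFAULT_OPIOID_KEYWORDS: list[str] = [
    "OXYCODONE", "HYDROCODONE", "MORPHINE", "FENTANYL", "HYDROMORPHONE",
    "CODEINE", "TRAMADOL", "METHADONE", "OXYMORPHONE", "BUPRENORPHINE",
    "TAPENTADOL",
]

#: Raw route-of-administration spellings normalized to {oral, IV, IM, other}.
DEFAULT_ROUTE_ALIASES: dict[str, str] = {
    "PO": "oral", "ORAL": "oral", "BY MOUTH": "oral", "P.O.": "oral",
    "IV": "IV", "INTRAVENOUS": "IV", "IVPB": "IV", "IV PUSH": "IV",
    "IM": "IM", "INTRAMUSCULAR": "IM",
    "TOP": "other", "TOPICAL": "other", "EXTERNAL": "other",
    "SUBCUTANEOUS": "other", "SQ": "other", "INHALATION": "other",
}


def default_config() -> dict[str, Any]:
    """Return a deep copy of the full default pipeline configuration."""
    return copy.deepcopy(
        {
            "ingest": {
                "date_dialect": "iso",  # "iso" (YYYY-MM-DD) or "us" (MM/DD/YYYY)
                "column_map": DEFAULT_COLUMN_MAP,
                "aliases": {},  # raw facility spelling -> canonical id
                "min_months": 12,
                "change_threshold": 0.20,
                "exclusions": [],  # facilities removed after human review
            },
            "cleaning": {
                "essential_fields": DEFAULT_ESSENTIAL_FIELDS,
                "nonpharma_keywords": DEFAULT_NONPHARMA_KEYWORDS,
                "nonsystemic": {
                    "affix_keywords": NONSYSTEMIC_AFFIX_KEYWORDS,
                    "prefix_keywords": NONSYSTEMIC_PREFIX_KEYWORDS,
                    "leading_keywords": NONSYSTEMIC_LEADING_KEYWORDS,
                },
                "insulin_keywords": DEFAULT_INSULIN_KEYWORDS,
                "opioid_keywords": DEFAULT_OPIOID_KEYWORDS,
            },
            "classify": {
                "lexicon_path": None,  # None -> bundled data/lexicon.csv
                "asi_path": None,  # None -> bundled data/asi_scores.csv
            },
            "metrics": {
                "route_aliases": DEFAULT_ROUTE_ALIASES,
            },
        }
    )


def _deep_merge(base: dict[str, Any], override: Mapping[str, Any]) -> dict[str, Any]:
    for key, value in override.items():
        if isinstance(value, Mapping) and isinstance(base.get(key), dict):
            base[key] = _deep_merge(base[key], value)
        else:
            base[key] = copy.deepcopy(value)
    return base


def load_config(path: str | Path | None = None) -> dict[str, Any]:
    """Load a YAML run configuration merged over the package defaults.

    ``path=None`` returns the defaults.  Unknown top-level sections are kept
    (forward compatibility); the date dialect is validated here because a
    wrong dialect silently voids every date downstream.
    """
    cfg = default_config()
    if path is not None:
        with open(path, "r", encoding="utf-8") as fh:
            user = yaml.safe_load(fh) or {}
        if not isinstance(user, dict):
            raise ConfigError(f"config root must be a mapping, got {type(user).__name__}")
        cfg = _deep_merge(cfg, user)
    dialect = cfg["ingest"]["date_dialect"]
    if dialect not in ("iso", "us"):
        raise ConfigError(f"date_dialect must be 'iso' or 'us', got {dialect!r}")
    return cfg
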