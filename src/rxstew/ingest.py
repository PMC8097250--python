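"""Read heterogeneous pharmacy invoice exports into one canonical table.

Monthly invoice files from a dispensing pharmacy arrive with varying column
counts and header spellings.  This module maps headers onto the canonical
eleven-column schema, coerces values (dates, currency, integer days supply),
consolidates facility-name variants through an explicit alias table, and
screens facilities for inclusion (short contribution history; abrupt volume
changes over three consecutive months).

Column meaning is never inferred from content: the mapping is explicit
configuration, and unmapped headers are reported rather than dropped
silently.
"""

from __future__ import annotations

import re
from dataclasses import dataclass, field
from pathlib import Path
from typing import Iterable, Mapping, Sequence

import pandas as pd

from .config import CANONICAL_COLUMNS, DEFAULT_COLUMN_MAP, DEFAULT_ESSENTIAL_FIELDS
from .errors import AmbiguousHeaderError, SchemaError

_DATE_FORMATS = {"iso": "%Y-%m-%d", "us": "%m/%d/%Y"}

_WS = re.compile(r"\s+")


def _norm_header(text: str) -> str:
    return _WS.sub(" ", text.strip()).lower()


def normalize_facility(name: str) -> str:
    """Uppercase and collapse internal whitespace (pre-alias normalization)."""
    return _WS.sub(" ", name.strip()).upper()


def build_column_lookup(column_map: Mapping[str, Sequence[str]] | None = None) -> dict[str, str]:
    """Invert a canonical->spellings map to normalized spelling->canonical.

    The canonical names themselves are always accepted.  A spelling assigned
    to two canonical columns is a configuration error.
    """
    column_map = column_map if column_map is not None else DEFAULT_COLUMN_MAP
    lookup: dict[str, str] = {}
    for canonical, spellings in column_map.items():
        for spelling in list(spellings) + [canonical]:
            key = _norm_header(spelling)
            if lookup.get(key, canonical) != canonical:
                raise AmbiguousHeaderError(
                    f"spelling {spelling!r} maps to both "
                    f"{lookup[key]!r} and {canonical!r}"
                )
            lookup[key] = canonical
    return lookup


def harmonize_headers(
    headers: Sequence[str],
    column_map: Mapping[str, Sequence[str]] | None = None,
) -> tuple[dict[str, str], list[str]]:
    """Map one file's headers onto canonical column names.

    Returns ``(mapping, unmapped)`` where *mapping* is source header ->
    canonical name and *unmapped* lists headers with no canonical home.
    Two headers in the same file resolving to one canonical column raise
    :class:`AmbiguousHeaderError` naming both.
    """
    if not headers:
        raise ValueError("headers must be non-empty")
    lookup = build_column_lookup(column_map)
    mapping: dict[str, str] = {}
    claimed: dict[str, str] = {}  # canonical -> source header that claimed it
    unmapped: list[str] = []
    for header in headers:
        canonical = lookup.get(_norm_header(header))
        if canonical is None:
            unmapped.append(header)
            continue
        if canonical in claimed:
            raise AmbiguousHeaderError(
                f"headers {claimed[canonical]!r} and {header!r} both map to "
                f"canonical column {canonical!r}"
            )
        claimed[canonical] = header
        mapping[header] = canonical
    return mapping, unmapped


def _parse_amount(raw: object) -> float | None:
    if raw is None or (isinstance(raw, float) and pd.isna(raw)):
        return None
    text = str(raw).strip()
    if not text:
        return None
    negative = text.startswith("(") and text.endswith(")")
    if negative:
        text = text[1:-1]
    text = text.replace("$", "").replace(",", "").strip()
    try:
        value = float(text)
    except ValueError:
        return None
    return -value if negative else value


def read_invoice_file(
    path: str | Path,
    column_map: Mapping[str, Sequence[str]] | None = None,
    date_dialect: str = "iso",
    essential_fields: Sequence[str] | None = None,
) -> tuple[pd.DataFrame, list[str]]:
    """Read one invoice CSV into the canonical schema.

    Every input row yields exactly one output row.  Values that fail
    coercion (unparsable date, non-numeric days supply or amount) become
    missing — they are removed later by cleaning step 1, never defaulted.
    Returns ``(frame, unmapped_headers)``.
    """
    if date_dialect not in _DATE_FORMATS:
        raise ValueError(f"unknown date dialect {date_dialect!r}")
    essential = list(essential_fields) if essential_fields is not None else DEFAULT_ESSENTIAL_FIELDS
    raw = pd.read_csv(path, dtype=str, keep_default_na=False)
    mapping, unmapped = harmonize_headers(list(raw.columns), column_map)
    if not any(c in essential for c in mapping.values()):
        raise SchemaError(f"{path}: no essential columns could be mapped")
    frame = raw.rename(columns=mapping)
    out = pd.DataFrame(index=frame.index)
    for col in CANONICAL_COLUMNS:
        if col in frame.columns:
            series = frame[col].astype("string").str.strip()
            out[col] = series.mask(series == "", pd.NA)
        else:
            out[col] = pd.Series(pd.NA, index=frame.index, dtype="string")
    out["medication"] = out["medication"].str.upper()
    out["transaction_date"] = pd.to_datetime(
        out["transaction_date"], format=_DATE_FORMATS[date_dialect], errors="coerce"
    )
    out["days_supply"] = pd.to_numeric(out["days_supply"], errors="coerce").astype("Int64")
    # negative days supply is a coercion artifact, not a quantity
    out["days_supply"] = out["days_supply"].mask(out["days_supply"] < 0, pd.NA)
    out["amount"] = out["amount"].map(_parse_amount).astype("Float64")
    return out.reset_index(drop=True), unmapped


def consolidate_facilities(
    names: Iterable[str],
    aliases: Mapping[str, str] | None = None,
) -> dict[str, str]:
    """Map raw facility spellings to canonical facility ids.

    Spellings are normalized (uppercase, collapsed whitespace) and then
    looked up in the alias table (whose keys are normalized the same way);
    unknown names map to their normalized selves, so the operation is
    idempotent and never fails.
    """
    alias_lookup = {normalize_facility(k): v for k, v in (aliases or {}).items()}
    result: dict[str, str] = {}
    for name in names:
        norm = normalize_facility(str(name))
        result[str(name)] = alias_lookup.get(norm, norm)
    return result


@dataclass
class FacilityScreenResult:
    """Inclusion screen for one facility.

    Volume flags are advisory: actual exclusion mirrors the study's human
    review and happens only through the config ``exclusions`` list.
    """

    facility: str
    months_of_data: int
    status: str  # included | excluded_short_history | flagged_volume_change
    flagged_windows: list[tuple[str, float]] = field(default_factory=list)
    skipped_windows: list[str] = field(default_factory=list)  # zero-count window starts


def screen_facilities(
    monthly_counts: Mapping[str, Mapping[str, int]],
    min_months: int = 12,
    change_threshold: float = 0.20,
) -> list[FacilityScreenResult]:
    """Screen facilities on history length and 3-month volume swings.

    A facility contributing ``<= min_months`` distinct months is excluded.
    Otherwise every sliding window of three consecutive calendar months is
    checked: relative change = |count(last) - count(first)| / count(first);
    a window exceeding ``change_threshold`` flags the facility.  Windows
    whose first month has zero rows are skipped and reported, not divided.
    """
    if not 0 < change_threshold <= 1:
        raise ValueError("change_threshold must be in (0, 1]")
    results: list[FacilityScreenResult] = []
    for facility in sorted(monthly_counts):
        counts = monthly_counts[facility]
        months = sorted(pd.Period(m, freq="M") for m in counts)
        n_months = len(months)
        if n_months <= min_months:
            results.append(
                FacilityScreenResult(facility, n_months, "excluded_short_history")
            )
            continue
        flagged: list[tuple[str, float]] = []
        skipped: list[str] = []
        if months:
            full = pd.period_range(months[0], months[-1], freq="M")
            series = [int(counts.get(str(m), 0)) for m in full]
            for i in range(len(full) - 2):
                first, last = series[i], series[i + 2]
                if first == 0:
                    skipped.append(str(full[i]))
                    continue
                change = abs(last - first) / first
                if change > change_threshold:
                    flagged.append((str(full[i]), change))
        status = "flagged_volume_change" if flagged else "included"
        results.append(
            FacilityScreenResult(facility, n_months, status, flagged, skipped)
        )
    return results


def monthly_row_counts(frame: pd.DataFrame) -> dict[str, dict[str, int]]:
    """Rows per facility per transaction month, for the volume screen."""
    dated = frame.dropna(subset=["transaction_date"])
    if dated.empty:
        return {}
    months = dated["transaction_date"].dt.to_period("M").astype(str)
    grouped = dated.groupby(["facility", months], observed=True).size()
    out: dict[str, dict[str, int]] = {}
    for (facility, month), count in grouped.items():
        out.setdefault(str(facility), {})[str(month)] = int(count)
    return out


def ingest_files(
    paths: Sequence[str | Path],
    config: Mapping | None = None,
) -> tuple[pd.DataFrame, dict]:
    """Read, harmonize, and screen a batch of invoice files.

    Returns the canonical invoice table (facility names consolidated,
    config-listed exclusions applied) plus a JSON-serializable ingest
    report: files read, unmapped headers, unaliased facility spellings,
    and screen results.
    """
    from .config import default_config

    cfg = dict(config) if config is not None else default_config()
    ing = cfg["ingest"]
    frames: list[pd.DataFrame] = []
    report: dict = {"files": [], "unmapped_headers": {}, "unaliased_facilities": [],
                    "screen_results": [], "excluded": list(ing.get("exclusions", []))}
    for path in paths:
        frame, unmapped = read_invoice_file(
            path,
            column_map=ing.get("column_map"),
            date_dialect=ing.get("date_dialect", "iso"),
            essential_fields=cfg.get("cleaning", {}).get("essential_fields"),
        )
        report["files"].append({"path": str(path), "rows": int(len(frame))})
        if unmapped:
            report["unmapped_headers"][str(path)] = unmapped
        frames.append(frame)
    table = pd.concat(frames, ignore_index=True) if frames else pd.DataFrame(
        columns=CANONICAL_COLUMNS
    )
    aliases = ing.get("aliases") or {}
    raw_names = [n for n in table["facility"].dropna().unique()] if len(table) else []
    name_map = consolidate_facilities(raw_names, aliases)
    known = {normalize_facility(k) for k in aliases}
    report["unaliased_facilities"] = sorted(
        {v for k, v in name_map.items() if normalize_facility(k) not in known}
    )
    if len(table):
        table["facility"] = table["facility"].map(lambda n: name_map.get(n, n) if pd.notna(n) else n)
    screen = screen_facilities(
        monthly_row_counts(table),
        min_months=int(ing.get("min_months", 12)),
        change_threshold=float(ing.get("change_threshold", 0.20)),
    )
    report["screen_results"] = [
        {
            "facility": r.facility,
            "months_of_data": r.months_of_data,
            "status": r.status,
            "flagged_windows": [[m, c] for m, c in r.flagged_windows],
            "skipped_windows": r.skipped_windows,
        }
        for r in screen
    ]
    short = {r.facility for r in screen if r.status == "excluded_short_history"}
    drop = short | set(ing.get("exclusions", []))
    if drop and len(table):
        table = table[~table["facility"].isin(drop)].reset_index(drop=True)
    report["excluded_short_history"] = sorted(short)
    return table, report


def write_canonical_csv(frame: pd.DataFrame, path: str | Path) -> None:
    """Write the canonical table with fixed column order and ISO dates."""
    out = frame.copy()
    out["transaction_date"] = out["transaction_date"].dt.strftime("%Y-%m-%d")
    out[CANONICAL_COLUMNS].to_csv(path, index=False)


def read_canonical_csv(path: str | Path) -> pd.DataFrame:
    """Read back a canonical table with the pipeline's dtypes."""
    frame = pd.read_csv(path, dtype=str, keep_default_na=False)
    for col in CANONICAL_COLUMNS:
        if col not in frame.columns:
            frame[col] = ""
        series = frame[col].astype("string").str.strip()
        frame[col] = series.mask(series == "", pd.NA)
    frame["transaction_date"] = pd.to_datetime(
        frame["transaction_date"], format="%Y-%m-%d", errors="coerce"
    )
    frame["days_supply"] = pd.to_numeric(frame["days_supply"], errors="coerce").astype("Int64")
    frame["amount"] = pd.to_numeric(frame["amount"], errors="coerce").astype("Float64")
    return frame[CANONICAL_COLUMNS]
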