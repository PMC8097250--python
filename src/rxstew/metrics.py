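"""Facility-month antibiotic-use metrics.

Core quantities, all normalized to bed-days of care (BDOC):

* DOT/1000 BDOC — days of therapy per 1000 bed-days; days supply allocated
  across calendar months with an *exclusive-start* convention: the first
  therapy day is the day AFTER the transaction date.  A 90-day supply with
  transaction date 2014-12-03 therefore contributes 28 days to December 2014
  (Dec 4-31), 31 to January, 28 to February and 3 to March 2015.
* starts/1000 BDOC — each course counts one start in the month containing
  its (transaction) start date.
* LOT — length of therapy: total days supply of a course including refills.
* mean ASI — DOT-weighted mean antibiotic spectrum index per facility-month,
  over scored antibiotic courses; undefined (missing) when a month has no
  antibiotic DOT.

Missing census months propagate as missing rates, never as zero.
"""

from __future__ import annotations

import datetime as dt
from dataclasses import dataclass
from typing import Mapping, Sequence

import numpy as np
import pandas as pd

STRATA = ("<100", "100-150", ">150")


# ---------------------------------------------------------------------------
# Cross-month DOT allocation
# ---------------------------------------------------------------------------

def allocate_dot(start_date: dt.date | pd.Timestamp, total_days: int) -> dict[str, int]:
    """Distribute a course's therapy days over calendar months.

    Therapy days run consecutively from the day after ``start_date``
    (exclusive-start convention).  Returns {"YYYY-MM": days}; values sum to
    ``total_days`` and no month receives more days than it contains.
    """
    total_days = int(total_days)
    if total_days < 1:
        raise ValueError("total_days must be >= 1")
    day = pd.Timestamp(start_date) + pd.Timedelta(days=1)
    allocation: dict[str, int] = {}
    remaining = total_days
    while remaining > 0:
        month_end = day + pd.offsets.MonthEnd(0)
        available = (month_end - day).days + 1
        take = min(remaining, available)
        allocation[day.strftime("%Y-%m")] = take
        remaining -= take
        day = month_end + pd.Timedelta(days=1)
    return allocation


def allocate_courses(courses: pd.DataFrame) -> pd.DataFrame:
    """Long allocation table: one row per (course, month) with its DOT.

    Carries facility plus any classification columns present so callers can
    slice by category, class, route, or ASI without re-joining.
    """
    carry = [c for c in ("category", "class", "subclass", "generic", "asi",
                         "route", "route_class")
             if c in courses.columns]
    rows: list[dict] = []
    for idx, course in courses.iterrows():
        alloc = allocate_dot(course["start_date"], int(course["total_days_supply"]))
        base = {"course_id": idx, "facility": course["facility"]}
        for col in carry:
            base[col] = course[col]
        for month, days in alloc.items():
            rows.append({**base, "month": month, "dot": days})
    if not rows:
        return pd.DataFrame(columns=["course_id", "facility", *carry, "month", "dot"])
    return pd.DataFrame(rows)


# ---------------------------------------------------------------------------
# Census
# ---------------------------------------------------------------------------

def read_census_csv(path) -> pd.DataFrame:
    census = pd.read_csv(path, dtype={"facility": str, "month": str})
    census["bdoc"] = pd.to_numeric(census["bdoc"])
    if (census["bdoc"] <= 0).any():
        raise ValueError("census BDOC must be positive")
    if census.duplicated(subset=["facility", "month"]).any():
        raise ValueError("census has duplicate facility-month rows")
    return census[["facility", "month", "bdoc"]]


def _rate(numerator: pd.Series, bdoc: pd.Series) -> pd.Series:
    return numerator / bdoc * 1000.0


# ---------------------------------------------------------------------------
# Scoped rates
# ---------------------------------------------------------------------------

def dot_rate(
    courses: pd.DataFrame, census: pd.DataFrame, facility: str, month: str
) -> float | None:
    """DOT/1000 BDOC for one facility-month; None when census is missing."""
    row = census[(census["facility"] == facility) & (census["month"] == month)]
    if row.empty:
        return None
    scoped = courses[courses["facility"] == facility]
    total = 0
    for _, course in scoped.iterrows():
        total += allocate_dot(course["start_date"], int(course["total_days_supply"])).get(month, 0)
    return total / float(row["bdoc"].iloc[0]) * 1000.0


def starts_rate(
    courses: pd.DataFrame, census: pd.DataFrame, facility: str, month: str
) -> float | None:
    """Starts/1000 BDOC for one facility-month; None when census is missing."""
    row = census[(census["facility"] == facility) & (census["month"] == month)]
    if row.empty:
        return None
    scoped = courses[courses["facility"] == facility]
    months = pd.to_datetime(scoped["start_date"]).dt.strftime("%Y-%m")
    starts = int((months == month).sum())
    return starts / float(row["bdoc"].iloc[0]) * 1000.0


def mean_monthly_asi(labeled_courses: pd.DataFrame, facility: str, month: str) -> float | None:
    """DOT-weighted mean ASI for one facility-month; None with no scored DOT."""
    abx = labeled_courses[
        (labeled_courses["facility"] == facility)
        & (labeled_courses["category"] == "antibiotic")
        & labeled_courses["asi"].notna()
    ]
    num = den = 0.0
    for _, course in abx.iterrows():
        days = allocate_dot(course["start_date"], int(course["total_days_supply"])).get(month, 0)
        num += float(course["asi"]) * days
        den += days
    return num / den if den > 0 else None


# ---------------------------------------------------------------------------
# Full facility-month metrics table
# ---------------------------------------------------------------------------

def _monthly_sum(alloc: pd.DataFrame, mask: pd.Series | None = None) -> pd.Series:
    scoped = alloc if mask is None else alloc[mask]
    if scoped.empty:
        return pd.Series(dtype=float)
    return scoped.groupby(["facility", "month"])["dot"].sum()


def compute_monthly_metrics(
    labeled_courses: pd.DataFrame,
    census: pd.DataFrame,
    route_aliases: Mapping[str, str] | None = None,
) -> tuple[pd.DataFrame, pd.DataFrame]:
    """Per-facility-month metrics plus a long class-breakdown table.

    The census defines the facility-month grid: covered months with no use
    get zero rates; facility-months that receive allocated DOT but have no
    census row are appended with missing rates and ``census_available`` set
    False (never silently zero).
    """
    from .config import DEFAULT_ROUTE_ALIASES

    aliases = dict(route_aliases) if route_aliases is not None else DEFAULT_ROUTE_ALIASES
    alias_lookup = {str(k).strip().upper(): v for k, v in aliases.items()}

    courses = labeled_courses.copy()
    courses["route_class"] = (
        courses["route"].fillna("").astype(str).str.strip().str.upper()
        .map(alias_lookup).fillna("other")
    )
    alloc = allocate_courses(courses)

    grid = census.set_index(["facility", "month"])[["bdoc"]].copy()

    is_abx = alloc["category"] == "antibiotic" if len(alloc) else pd.Series(dtype=bool)
    abx_dot = _monthly_sum(alloc, is_abx)
    ahp_dot = _monthly_sum(alloc, alloc["category"] == "antihypertensive" if len(alloc) else None)
    all_dot = _monthly_sum(alloc)
    iv_abx_dot = _monthly_sum(alloc, is_abx & (alloc["route_class"] == "IV") if len(alloc) else None)

    scored = alloc[is_abx & alloc["asi"].notna()] if len(alloc) else alloc
    if len(scored):
        weighted = scored.assign(w=scored["asi"].astype(float) * scored["dot"])
        asi_num = weighted.groupby(["facility", "month"])["w"].sum()
        asi_den = weighted.groupby(["facility", "month"])["dot"].sum()
        mean_asi = asi_num / asi_den
    else:
        mean_asi = pd.Series(dtype=float)

    abx_courses = courses[courses["category"] == "antibiotic"].copy()
    if len(abx_courses):
        abx_courses["month"] = pd.to_datetime(abx_courses["start_date"]).dt.strftime("%Y-%m")
        starts = abx_courses.groupby(["facility", "month"]).size()
        lot_mean = abx_courses.groupby(["facility", "month"])["total_days_supply"].mean()
        lot_median = abx_courses.groupby(["facility", "month"])["total_days_supply"].median()
    else:
        starts = lot_mean = lot_median = pd.Series(dtype=float)

    used_index = all_dot.index if len(all_dot) else grid.index[:0]
    full_index = grid.index.union(used_index).union(starts.index if len(starts) else grid.index[:0])
    metrics = pd.DataFrame(index=full_index)
    metrics["bdoc"] = grid["bdoc"]
    metrics["census_available"] = metrics["bdoc"].notna()

    def rate_of(series: pd.Series) -> pd.Series:
        filled = series.reindex(full_index).fillna(0.0)
        return _rate(filled, metrics["bdoc"])

    metrics["dot_per_1000_bdoc"] = rate_of(abx_dot)
    metrics["starts_per_1000_bdoc"] = rate_of(starts.astype(float) if len(starts) else starts)
    metrics["iv_dot_per_1000_bdoc"] = rate_of(iv_abx_dot)
    metrics["all_systemic_dot_per_1000_bdoc"] = rate_of(all_dot)
    metrics["antihypertensive_dot_per_1000_bdoc"] = rate_of(ahp_dot)
    metrics["mean_asi"] = mean_asi.reindex(full_index)
    metrics["lot_mean"] = lot_mean.reindex(full_index)
    metrics["lot_median"] = lot_median.reindex(full_index)
    metrics = metrics.reset_index().rename(columns={"level_0": "facility", "level_1": "month"})
    metrics = metrics.sort_values(["facility", "month"], kind="stable").reset_index(drop=True)

    if len(alloc) and is_abx.any():
        class_dot = (
            alloc[is_abx].groupby(["facility", "month", "class"])["dot"].sum().reset_index()
        )
        class_dot = class_dot.merge(census, on=["facility", "month"], how="left")
        class_dot["dot_per_1000_bdoc"] = _rate(class_dot["dot"], class_dot["bdoc"])
        breakdown = class_dot[["facility", "month", "class", "dot", "dot_per_1000_bdoc"]]
    else:
        breakdown = pd.DataFrame(
            columns=["facility", "month", "class", "dot", "dot_per_1000_bdoc"]
        )
    return metrics, breakdown


def carryover_fraction(courses: pd.DataFrame) -> dict:
    """Share of courses whose therapy days span more than one calendar month."""
    if courses.empty:
        return {"n_courses": 0, "fraction_gt_1_month": None, "fraction_gt_2_months": None}
    spans = [
        len(allocate_dot(c["start_date"], int(c["total_days_supply"])))
        for _, c in courses.iterrows()
    ]
    spans_arr = np.asarray(spans)
    return {
        "n_courses": int(len(spans_arr)),
        "fraction_gt_1_month": float((spans_arr > 1).mean()),
        "fraction_gt_2_months": float((spans_arr > 2).mean()),
    }


# ---------------------------------------------------------------------------
# Bed-size strata
# ---------------------------------------------------------------------------

def bed_stratum(bed_count: int) -> str:
    """<100 | 100-150 (inclusive at both edges) | >150."""
    beds = int(bed_count)
    if beds < 100:
        return "<100"
    if beds <= 150:
        return "100-150"
    return ">150"


def read_profiles_csv(path) -> pd.DataFrame:
    profiles = pd.read_csv(path, dtype={"facility": str})
    profiles["beds"] = pd.to_numeric(profiles["beds"]).astype(int)
    if (profiles["beds"] <= 0).any():
        raise ValueError("bed counts must be positive")
    return profiles


def stratify(metrics: pd.DataFrame, profiles: pd.DataFrame) -> pd.DataFrame:
    """Attach a bed-size ``stratum`` column; unprofiled facilities are
    labeled ``unassigned`` rather than dropped."""
    strata = {
        str(row["facility"]): bed_stratum(row["beds"]) for _, row in profiles.iterrows()
    }
    out = metrics.copy()
    out["stratum"] = out["facility"].map(strata).fillna("unassigned")
    return out
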