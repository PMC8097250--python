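"""Independent reference implementations used as test oracles.

Deliberately naive (quadratic scans, day-by-day walks, closed forms) and
kept structurally unlike the package code they check.
"""

from __future__ import annotations

import datetime as dt

import numpy as np
import pandas as pd


def naive_clean(rows: list[dict], config: dict) -> tuple[list[dict], dict[str, int]]:
    """Brute-force reference for the seven-step cascade on plain dicts.

    Each row is a dict of canonical fields with None for missing; returns
    (courses, per-step removal counts).  Quadratic group scans throughout.
    """
    from rxstew.cleaning import NonSystemicRules
    import re

    cln = config["cleaning"]
    counts: dict[str, int] = {}

    essential = cln["essential_fields"]
    kept = [r for r in rows if all(r.get(f) is not None for f in essential)]
    counts["incomplete"] = len(rows) - len(kept)

    words = [re.escape(k.upper()) for k in cln["nonpharma_keywords"]]
    pattern = re.compile(r"\b(?:" + "|".join(words) + r")\b") if words else None
    if pattern is not None:
        survivors = [r for r in kept
                     if not pattern.search(str(r.get("medication") or "").upper())]
    else:
        survivors = kept
    counts["nonpharmaceutical"] = len(kept) - len(survivors)
    kept = survivors

    survivors = [r for r in kept if not (r.get("amount") is not None and r["amount"] < 0)]
    counts["reimbursement"] = len(kept) - len(survivors)
    kept = survivors

    # de-dup by quadratic scan, preserving first occurrence
    def key(r):
        return (r["prescription_number"], r["medication"], r["transaction_date"], r["physician"])

    seen_exact: set = set()
    once = []
    for r in kept:
        sig = key(r) + (r["days_supply"],)
        if sig in seen_exact:
            continue
        seen_exact.add(sig)
        once.append(r)
    counts["case1"] = len(kept) - len(once)
    survivors = []
    for r in once:
        group = [s for s in once if key(s) == key(r)]
        best = max(g["days_supply"] for g in group)
        firsts = [g for g in group if g["days_supply"] == best]
        if r is firsts[0]:
            survivors.append(r)
    counts["case2"] = len(once) - len(survivors)
    counts["duplicates"] = counts["case1"] + counts["case2"]
    kept = survivors

    # refill consolidation by quadratic scan
    courses = []
    done: set = set()
    for r in kept:
        ckey = (r["prescription_number"], r["medication"])
        if ckey in done:
            continue
        done.add(ckey)
        group = [s for s in kept if (s["prescription_number"], s["medication"]) == ckey]
        earliest = min(group, key=lambda s: s["transaction_date"])
        courses.append(
            {
                "facility": earliest["facility"],
                "medication": r["medication"],
                "prescription_number": r["prescription_number"],
                "start_date": earliest["transaction_date"],
                "total_days_supply": sum(s["days_supply"] for s in group),
                "route": earliest["route"],
                "physician": earliest["physician"],
                "payor": earliest["payor"],
                "n_dispensings": len(group),
            }
        )
    counts["refill_consolidation"] = len(kept) - len(courses)

    ns = cln["nonsystemic"]
    rules = NonSystemicRules(
        ns["affix_keywords"], ns["prefix_keywords"], ns["leading_keywords"]
    )
    survivors = [c for c in courses if not rules.matches(c["medication"])]
    counts["nonsystemic"] = len(courses) - len(survivors)
    courses = survivors

    vd_words = [re.escape(k.upper()) for k in cln["insulin_keywords"] + cln["opioid_keywords"]]
    vd = re.compile(r"\b(?:" + "|".join(vd_words) + r")\b") if vd_words else None
    if vd is not None:
        survivors = [c for c in courses if not vd.search(str(c["medication"]).upper())]
    else:
        survivors = courses
    counts["insulin_opioid"] = len(courses) - len(survivors)
    return survivors, counts


def brute_force_mk_s(values) -> int:
    """All-pairs Mann-Kendall S."""
    s = 0
    n = len(values)
    for i in range(n):
        for j in range(i + 1, n):
            diff = values[j] - values[i]
            s += int(diff > 0) - int(diff < 0)
    return s


def spearman_d2(x, y) -> float:
    """Closed-form rho = 1 - 6*sum(d^2)/(n(n^2-1)); valid only without ties."""
    n = len(x)
    rx = np.argsort(np.argsort(x)) + 1
    ry = np.argsort(np.argsort(y)) + 1
    d2 = float(((rx - ry) ** 2).sum())
    return 1.0 - 6.0 * d2 / (n * (n * n - 1))


def daywalk_allocation(start_date: dt.date, total_days: int) -> dict[str, int]:
    """Month allocation by walking one therapy day at a time (exclusive start)."""
    out: dict[str, int] = {}
    for i in range(1, total_days + 1):
        day = start_date + dt.timedelta(days=i)
        key = f"{day.year:04d}-{day.month:02d}"
        out[key] = out.get(key, 0) + 1
    return out


def frame_to_rows(frame: pd.DataFrame) -> list[dict]:
    """Canonical DataFrame -> plain dicts with None for missing."""
    rows = []
    for _, r in frame.iterrows():
        row = {}
        for col in frame.columns:
            v = r[col]
            row[col] = None if pd.isna(v) else v
        if row.get("days_supply") is not None:
            row["days_supply"] = int(row["days_supply"])
        if row.get("amount") is not None:
            row["amount"] = float(row["amount"])
        rows.append(row)
    return rows
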