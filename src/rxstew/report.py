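"""End-to-end pipeline orchestration and the static benchmarking report.

``run_pipeline`` chains ingest -> clean -> classify -> metrics (and
validate when a second, dispensing-derived source is supplied), persisting
every stage's output and a structured log of row counts.

``render_report`` produces the comparative-feedback report for one facility
against nursing homes in its bed-size stratum: panel (a) overall antibiotic
DOT/1000 BDOC over time, panel (b) per-class rates.  Output is static HTML
plus SVG figures, and every figure has a machine-readable CSV twin written
from exactly the frame that was plotted.
"""

from __future__ import annotations

import json
from dataclasses import dataclass
from pathlib import Path
from typing import Mapping, Sequence

import pandas as pd

from . import cleaning, classify, ingest, metrics, validation
from .config import default_config


@dataclass
class ReportSpec:
    target_facility: str
    period: tuple[str, str] | None = None  # (first month, last month) inclusive
    metrics_included: tuple[str, ...] = ("dot_per_1000_bdoc",)


def run_pipeline(
    invoice_paths: Sequence[str | Path],
    census_path: str | Path,
    profiles_path: str | Path,
    outdir: str | Path,
    config: Mapping | None = None,
    dispensing_path: str | Path | None = None,
) -> dict:
    """Run every stage in order and persist all outputs under ``outdir``.

    Returns a dict with the stage frames and a ``log`` of per-stage counts.
    A stage failure propagates with its own error type; nothing downstream
    runs on partial input.
    """
    cfg = dict(config) if config is not None else default_config()
    outdir = Path(outdir)
    outdir.mkdir(parents=True, exist_ok=True)
    log: list[dict] = []

    canonical, ingest_report = ingest.ingest_files(invoice_paths, cfg)
    ingest.write_canonical_csv(canonical, outdir / "canonical.csv")
    (outdir / "ingest_report.json").write_text(json.dumps(ingest_report, indent=1))
    log.append({"stage": "ingest", "rows": int(len(canonical))})

    courses, ledger = cleaning.run_cleaning(canonical, cfg)
    cleaning.write_courses_csv(courses, outdir / "courses.csv")
    ledger.to_frame().to_csv(outdir / "ledger.csv", index=False)
    (outdir / "ledger.json").write_text(json.dumps(ledger.to_dict(), indent=1))
    log.append({"stage": "clean", "courses": int(len(courses))})

    lexicon = classify.load_lexicon(cfg["classify"].get("lexicon_path"))
    asi_table = classify.load_asi(cfg["classify"].get("asi_path"))
    labeled = classify.classify_courses(courses, lexicon, asi_table)
    cleaning.write_courses_csv(labeled, outdir / "labeled.csv")
    (outdir / "asi_coverage.json").write_text(
        json.dumps(classify.asi_coverage(labeled), indent=1)
    )
    log.append(
        {"stage": "classify",
         "antibiotic": int((labeled["category"] == "antibiotic").sum()),
         "antihypertensive": int((labeled["category"] == "antihypertensive").sum()),
         "other": int((labeled["category"] == "other").sum())}
    )

    census = metrics.read_census_csv(census_path)
    profiles = metrics.read_profiles_csv(profiles_path)
    monthly, breakdown = metrics.compute_monthly_metrics(
        labeled, census, cfg["metrics"].get("route_aliases")
    )
    monthly = metrics.stratify(monthly, profiles)
    monthly.to_csv(outdir / "metrics.csv", index=False)
    breakdown.to_csv(outdir / "class_breakdown.csv", index=False)
    (outdir / "carryover.json").write_text(
        json.dumps(metrics.carryover_fraction(labeled), indent=1)
    )
    log.append({"stage": "metrics", "facility_months": int(len(monthly))})

    result = {
        "canonical": canonical, "ingest_report": ingest_report,
        "courses": courses, "ledger": ledger, "labeled": labeled,
        "metrics": monthly, "class_breakdown": breakdown,
        "census": census, "profiles": profiles, "log": log,
    }

    if dispensing_path is not None:
        disp_canonical = ingest.read_canonical_csv(dispensing_path)
        disp_courses, _ = cleaning.run_cleaning(disp_canonical, cfg)
        disp_labeled = classify.classify_courses(disp_courses, lexicon, asi_table)
        disp_monthly, _ = metrics.compute_monthly_metrics(
            disp_labeled, census, cfg["metrics"].get("route_aliases")
        )
        comparison = validation.compare_all_facilities(monthly, disp_monthly)
        comparison.to_csv(outdir / "comparison.csv", index=False)
        (outdir / "comparison_summary.json").write_text(
            json.dumps(
                {
                    "n_facilities": int(len(comparison)),
                    "categories": comparison["rho_category"].value_counts().to_dict(),
                    "all_positive_difference": bool(
                        (comparison["difference_sign"] > 0).all()
                    ) if len(comparison) else None,
                },
                indent=1,
            )
        )
        result["dispensing_metrics"] = disp_monthly
        result["comparison"] = comparison
        log.append({"stage": "validate", "facilities": int(len(comparison))})

    (outdir / "run_log.json").write_text(json.dumps(log, indent=1))
    return result


# ---------------------------------------------------------------------------
# Benchmarking report
# ---------------------------------------------------------------------------

_HTML_TEMPLATE = """<!DOCTYPE html>
<html>
<head><meta charset="utf-8"><title>Antibiotic use report: {target}</title>
<style>body{{font-family:sans-serif;max-width:60em;margin:2em auto}}</style></head>
<body>
<h1>Antibiotic use report &mdash; {target}</h1>
<p>Bed-size stratum: <b>{stratum}</b>; comparator facilities: {n_comparators}.
{note}</p>
<h2>a. Overall antibiotic use (DOT/1000 BDOC)</h2>
<img src="report_overall.svg" alt="overall antibiotic use"/>
<p>Data table: <a href="report_overall.csv">report_overall.csv</a></p>
<h2>b. Use by antibiotic class (DOT/1000 BDOC)</h2>
<img src="report_classes.svg" alt="use by antibiotic class"/>
<p>Data table: <a href="report_classes.csv">report_classes.csv</a></p>
</body></html>
"""


def render_report(
    monthly: pd.DataFrame,
    breakdown: pd.DataFrame,
    profiles: pd.DataFrame,
    spec: ReportSpec,
    outdir: str | Path,
) -> dict:
    """Render the two-panel benchmarking report; returns written paths.

    The CSV twins are written from the very frames the figures draw, so the
    report numbers cannot drift from the metrics table.
    """
    import matplotlib
    matplotlib.use("Agg")
    import matplotlib.pyplot as plt

    outdir = Path(outdir)
    outdir.mkdir(parents=True, exist_ok=True)
    if spec.target_facility not in set(monthly["facility"]):
        raise ValueError(f"target facility {spec.target_facility!r} not in metrics")

    scoped = monthly.copy()
    classes = breakdown.copy()
    if spec.period is not None:
        lo, hi = spec.period
        scoped = scoped[(scoped["month"] >= lo) & (scoped["month"] <= hi)]
        classes = classes[(classes["month"] >= lo) & (classes["month"] <= hi)]
    if "stratum" not in scoped.columns:
        scoped = metrics.stratify(scoped, profiles)

    stratum = scoped.loc[scoped["facility"] == spec.target_facility, "stratum"].iloc[0]
    peers = scoped[(scoped["stratum"] == stratum) & (scoped["facility"] != spec.target_facility)]
    n_comparators = peers["facility"].nunique()
    note = (
        "<em>Insufficient comparators in this stratum; the report shows the "
        "target facility alone.</em>" if n_comparators == 0 else ""
    )

    target_rows = scoped[scoped["facility"] == spec.target_facility].sort_values("month")
    overall = target_rows[["facility", "month", "dot_per_1000_bdoc"]].copy()
    peer_monthly = (
        peers.groupby("month")["dot_per_1000_bdoc"]
        .median()
        .rename("stratum_median_dot_per_1000_bdoc")
        .reset_index()
    )
    overall = overall.merge(peer_monthly, on="month", how="left")
    overall.to_csv(outdir / "report_overall.csv", index=False)

    fig, ax = plt.subplots(figsize=(8, 4))
    ax.plot(overall["month"], overall["dot_per_1000_bdoc"], marker="o",
            label=spec.target_facility)
    if n_comparators:
        ax.plot(overall["month"], overall["stratum_median_dot_per_1000_bdoc"],
                marker=".", linestyle="--", label=f"stratum {stratum} median")
    ax.set_ylabel("antibiotic DOT/1000 BDOC")
    ax.tick_params(axis="x", rotation=90, labelsize=6)
    ax.legend()
    fig.tight_layout()
    fig.savefig(outdir / "report_overall.svg")
    plt.close(fig)

    facility_classes = (
        classes[classes["facility"] == spec.target_facility]
        .groupby("class")["dot_per_1000_bdoc"].mean().rename("target_rate")
    )
    peer_names = set(peers["facility"])
    peer_classes = (
        classes[classes["facility"].isin(peer_names)]
        .groupby("class")["dot_per_1000_bdoc"].mean().rename("stratum_mean_rate")
    )
    class_table = (
        pd.concat([facility_classes, peer_classes], axis=1)
        .fillna(0.0)
        .sort_values("target_rate", ascending=False)
        .reset_index()
    )
    class_table.to_csv(outdir / "report_classes.csv", index=False)

    fig, ax = plt.subplots(figsize=(8, 4))
    x = range(len(class_table))
    ax.bar([i - 0.2 for i in x], class_table["target_rate"], width=0.4,
           label=spec.target_facility)
    if n_comparators:
        ax.bar([i + 0.2 for i in x], class_table["stratum_mean_rate"], width=0.4,
               label=f"stratum {stratum} mean")
    ax.set_xticks(list(x))
    ax.set_xticklabels(class_table["class"], rotation=45, ha="right", fontsize=7)
    ax.set_ylabel("mean monthly DOT/1000 BDOC")
    ax.legend()
    fig.tight_layout()
    fig.savefig(outdir / "report_classes.svg")
    plt.close(fig)

    html = _HTML_TEMPLATE.format(
        target=spec.target_facility, stratum=stratum,
        n_comparators=n_comparators, note=note,
    )
    (outdir / "report.html").write_text(html)
    return {
        "html": outdir / "report.html",
        "overall_csv": outdir / "report_overall.csv",
        "classes_csv": outdir / "report_classes.csv",
        "overall_table": overall,
        "classes_table": class_table,
        "n_comparators": n_comparators,
    }
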