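"""Cross-month DOT allocation, use rates, ASI aggregation, strata."""

import datetime as dt

import numpy as np
import pandas as pd
import pytest
from hypothesis import given, settings, strategies as st

import rxstew

import _oracles
from conftest import full_row, make_records


class TestAllocateDot:
    def test_ninety_day_course_spanning_four_months(self):
        alloc = rxstew.allocate_dot(dt.date(2014, 12, 3), 90)
        assert alloc == {"2014-12": 28, "2015-01": 31, "2015-02": 28, "2015-03": 3}
        assert sum(alloc.values()) == 90

    def test_single_day_lands_in_month_of_next_day(self):
        assert rxstew.allocate_dot(dt.date(2015, 6, 30), 1) == {"2015-07": 1}
        assert rxstew.allocate_dot(dt.date(2015, 6, 15), 1) == {"2015-06": 1}

    def test_leap_year_february(self):
        assert rxstew.allocate_dot(dt.date(2016, 2, 28), 3) == {"2016-02": 1, "2016-03": 2}

    def test_zero_days_rejected(self):
        with pytest.raises(ValueError):
            rxstew.allocate_dot(dt.date(2015, 1, 1), 0)

    @given(
        offset=st.integers(0, 1500),
        days=st.integers(1, 400),
    )
    @settings(max_examples=400, deadline=None)
    def test_conservation_cap_and_daywalk_agreement(self, offset, days):
        start = dt.date(2014, 1, 1) + dt.timedelta(days=offset)
        alloc = rxstew.allocate_dot(start, days)
        assert sum(alloc.values()) == days
        for month, allocated in alloc.items():
            assert allocated <= pd.Period(month, freq="M").days_in_month
        assert alloc == _oracles.daywalk_allocation(start, days)


def _census(rows):
    return pd.DataFrame(rows, columns=["facility", "month", "bdoc"])


def _courses(rows, lexicon=None, asi=None):
    courses = rxstew.consolidate_refills(make_records(rows))
    return rxstew.classify_courses(courses, lexicon, asi)


class TestScopedRates:
    CENSUS = _census([("MAPLEWOOD", "2014-12", 1000), ("MAPLEWOOD", "2015-01", 3000)])

    def test_dot_rate_arithmetic(self):
        courses = _courses(
            [full_row(transaction_date="2014-12-31", days_supply=150,
                      medication="CIPROFLOXACIN 500MG TAB")]
        )
        # 31 days in January; 150-day course started Dec 31 -> 31 DOT in Jan
        rate = rxstew.dot_rate(courses, self.CENSUS, "MAPLEWOOD", "2015-01")
        assert rate == pytest.approx(31 / 3000 * 1000)

    def test_worked_example_december_rate(self):
        courses = _courses(
            [full_row(transaction_date="2014-12-03", days_supply=90,
                      medication="LISINOPRIL 10MG TAB")]
        )
        assert rxstew.dot_rate(courses, self.CENSUS, "MAPLEWOOD", "2014-12") == pytest.approx(28.0)

    def test_zero_courses_rate_is_zero(self):
        courses = _courses([full_row()]).iloc[:0]
        assert rxstew.dot_rate(courses, self.CENSUS, "MAPLEWOOD", "2014-12") == 0.0

    def test_missing_census_returns_none_not_zero(self):
        courses = _courses([full_row(transaction_date="2014-12-03")])
        assert rxstew.dot_rate(courses, self.CENSUS, "MAPLEWOOD", "2019-01") is None
        assert rxstew.starts_rate(courses, self.CENSUS, "MAPLEWOOD", "2019-01") is None

    def test_starts_rate_counts_start_month_only(self):
        rows = [
            full_row(transaction_date="2014-12-03", days_supply=90,
                     prescription_number=f"R{i}")
            for i in range(6)
        ]
        courses = _courses(rows)
        assert rxstew.starts_rate(courses, self.CENSUS, "MAPLEWOOD", "2014-12") == pytest.approx(6.0)
        # the spanning course never counts as a start in later months
        assert rxstew.starts_rate(courses, self.CENSUS, "MAPLEWOOD", "2015-01") == 0.0


class TestMeanAsi:
    def test_single_drug_mean_equals_its_score(self, asi_table):
        courses = _courses(
            [full_row(medication="AZITHROMYCIN 250MG TAB", transaction_date="2015-01-04")]
        )
        value = rxstew.mean_monthly_asi(courses, "MAPLEWOOD", "2015-01")
        assert value == pytest.approx(asi_table["AZITHROMYCIN"])

    def test_dot_weighted_mean(self):
        # drug A: ASI 2, 10 DOT; drug B: ASI 8, 30 DOT -> (20+240)/40 = 6.5
        rows = [
            full_row(medication="NITROFURANTOIN 100MG TAB", days_supply=10,
                     transaction_date="2015-01-01", prescription_number="RA"),
            full_row(medication="LEVOFLOXACIN 500MG TAB", days_supply=30,
                     transaction_date="2015-01-01", prescription_number="RB"),
        ]
        courses = _courses(rows)
        assert rxstew.mean_monthly_asi(courses, "MAPLEWOOD", "2015-01") == pytest.approx(6.5)

    def test_no_antibiotic_dot_is_undefined(self):
        courses = _courses([full_row(medication="LISINOPRIL 10MG TAB")])
        assert rxstew.mean_monthly_asi(courses, "MAPLEWOOD", "2016-03") is None

    def test_pipeline_monthly_asi_bounded(self, pipeline_result):
        asi = pipeline_result["metrics"]["mean_asi"].dropna()
        assert len(asi) > 0
        assert asi.between(1, 13).all()


class TestMonthlyMetricsTable:
    def test_rate_linearity_in_dot(self):
        rows = [
            full_row(medication="CIPROFLOXACIN 500MG TAB", days_supply=7,
                     transaction_date="2015-01-04", prescription_number="RA"),
            full_row(medication="CEFTRIAXONE 1GM INJ", days_supply=4, route="IV",
                     transaction_date="2015-01-10", prescription_number="RB"),
        ]
        census = _census([("MAPLEWOOD", "2015-01", 2500)])
        single, _ = rxstew.compute_monthly_metrics(_courses(rows), census)
        doubled_rows = [dict(r, days_supply=r["days_supply"] * 2) for r in rows]
        double, _ = rxstew.compute_monthly_metrics(_courses(doubled_rows), census)
        assert double["dot_per_1000_bdoc"].iloc[0] == pytest.approx(
            2 * single["dot_per_1000_bdoc"].iloc[0]
        )

    def test_monthly_rates_cross_check_against_total_dot(self, pipeline_result):
        """Sum over months of rate*BDOC/1000 recovers total allocated DOT."""
        metrics = pipeline_result["metrics"]
        covered = metrics[metrics["census_available"]]
        recovered = (covered["dot_per_1000_bdoc"] * covered["bdoc"] / 1000.0).sum()
        labeled = pipeline_result["labeled"]
        abx = labeled[labeled["category"] == "antibiotic"]
        total = int(abx["total_days_supply"].sum())
        assert recovered == pytest.approx(total, abs=1e-9)

    def test_uncensused_month_marked_unavailable(self):
        rows = [full_row(transaction_date="2015-01-28", days_supply=10,
                         medication="CIPROFLOXACIN 500MG TAB")]
        census = _census([("MAPLEWOOD", "2015-01", 2500)])  # Feb missing
        metrics, _ = rxstew.compute_monthly_metrics(_courses(rows), census)
        feb = metrics[metrics["month"] == "2015-02"].iloc[0]
        assert not feb["census_available"]
        assert pd.isna(feb["dot_per_1000_bdoc"])

    def test_carryover_fraction_of_known_courses(self):
        rows = [
            full_row(transaction_date="2015-01-02", days_supply=5,
                     prescription_number="RA"),  # stays in January
            full_row(transaction_date="2015-01-28", days_supply=10,
                     prescription_number="RB"),  # spans into February
        ]
        out = rxstew.carryover_fraction(_courses(rows))
        assert out["n_courses"] == 2
        assert out["fraction_gt_1_month"] == pytest.approx(0.5)


class TestStratify:
    @pytest.mark.parametrize(
        "beds,stratum",
        [(99, "<100"), (100, "100-150"), (150, "100-150"), (151, ">150")],
    )
    def test_boundaries(self, beds, stratum):
        assert rxstew.bed_stratum(beds) == stratum

    def test_unprofiled_facility_reported_unassigned(self):
        metrics = pd.DataFrame({"facility": ["A", "B"], "month": ["2015-01"] * 2})
        profiles = pd.DataFrame({"facility": ["A"], "beds": [120]})
        out = rxstew.stratify(metrics, profiles)
        assert out.loc[out["facility"] == "A", "stratum"].iloc[0] == "100-150"
        assert out.loc[out["facility"] == "B", "stratum"].iloc[0] == "unassigned"
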