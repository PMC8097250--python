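"""The seven-step cascade: per-step behaviour, ledger bookkeeping, and
equivalence with a brute-force quadratic reference."""

import numpy as np
import pandas as pd
import pytest
from hypothesis import given, settings, strategies as st

import rxstew
from rxstew.cleaning import NonSystemicRules
from rxstew.errors import IntegrityError

import _oracles
from conftest import full_row, make_records


class TestDropIncomplete:
    def test_missing_physician_removed(self):
        records = make_records([full_row(), full_row(physician=None)])
        kept, removed = rxstew.drop_incomplete(records)
        assert removed == 1 and len(kept) == 1

    def test_fully_populated_kept(self):
        kept, removed = rxstew.drop_incomplete(make_records([full_row()]))
        assert removed == 0 and len(kept) == 1

    def test_zero_days_supply_is_a_value_not_missing(self):
        kept, removed = rxstew.drop_incomplete(make_records([full_row(days_supply=0)]))
        assert removed == 0 and len(kept) == 1


class TestDropNonpharmaceutical:
    def test_saline_kit_removed(self):
        records = make_records([full_row(medication="NORMAL SALINE FLUSH KIT")])
        kept, removed = rxstew.drop_nonpharmaceutical(records)
        assert removed == 1 and len(kept) == 0

    def test_antibiotic_kept(self):
        kept, removed = rxstew.drop_nonpharmaceutical(
            make_records([full_row(medication="AMOXICILLIN 500MG CAP")])
        )
        assert removed == 0

    def test_empty_keyword_list_keeps_everything(self):
        records = make_records([full_row(medication="NORMAL SALINE FLUSH KIT")])
        kept, removed = rxstew.drop_nonpharmaceutical(records, [])
        assert removed == 0 and len(kept) == 1


class TestDropReimbursements:
    @pytest.mark.parametrize(
        "amount,kept_expected",
        [(-42.5, 0), (0.0, 1), (15000.08, 1)],
    )
    def test_sign_rule(self, amount, kept_expected):
        kept, removed = rxstew.drop_reimbursements(
            make_records([full_row(amount=amount)])
        )
        assert len(kept) == kept_expected
        assert removed == 1 - kept_expected


class TestDeduplicate:
    def test_case_one_identical_rows_collapse(self):
        records = make_records([full_row(), full_row()])
        kept, case1, case2 = rxstew.deduplicate(records)
        assert (len(kept), case1, case2) == (1, 1, 0)

    def test_case_two_keeps_greatest_days_supply(self):
        records = make_records([full_row(days_supply=7), full_row(days_supply=10)])
        kept, case1, case2 = rxstew.deduplicate(records)
        assert (len(kept), case1, case2) == (1, 0, 1)
        assert kept["days_supply"].iloc[0] == 10

    def test_unique_row_untouched(self):
        records = make_records([full_row()])
        kept, case1, case2 = rxstew.deduplicate(records)
        assert (len(kept), case1, case2) == (1, 0, 0)

    def test_mixed_group_counts_both_cases(self):
        records = make_records(
            [full_row(days_supply=10), full_row(days_supply=10), full_row(days_supply=7)]
        )
        kept, case1, case2 = rxstew.deduplicate(records)
        assert (len(kept), case1, case2) == (1, 1, 1)
        assert kept["days_supply"].iloc[0] == 10

    @given(
        days=st.lists(st.integers(0, 20), min_size=1, max_size=8),
        rxs=st.lists(st.sampled_from(["A", "B", "C"]), min_size=1, max_size=8),
    )
    @settings(max_examples=50, deadline=None)
    def test_idempotent(self, days, rxs):
        n = min(len(days), len(rxs))
        rows = [
            full_row(days_supply=days[i], prescription_number=rxs[i])
            for i in range(n)
        ]
        records = make_records(rows)
        once, c1, c2 = rxstew.deduplicate(records)
        twice, c1b, c2b = rxstew.deduplicate(once)
        pd.testing.assert_frame_equal(once, twice)
        assert (c1b, c2b) == (0, 0)


class TestConsolidateRefills:
    def test_three_monthly_dispensings_sum(self):
        rows = [
            full_row(transaction_date="2015-01-05", days_supply=30),
            full_row(transaction_date="2015-02-04", days_supply=30),
            full_row(transaction_date="2015-03-06", days_supply=30),
        ]
        courses = rxstew.consolidate_refills(make_records(rows))
        assert len(courses) == 1
        course = courses.iloc[0]
        assert course["total_days_supply"] == 90
        assert course["start_date"] == pd.Timestamp("2015-01-05")
        assert course["n_dispensings"] == 3

    def test_single_row_course(self):
        courses = rxstew.consolidate_refills(make_records([full_row(days_supply=14)]))
        assert courses.iloc[0]["total_days_supply"] == 14
        assert courses.iloc[0]["n_dispensings"] == 1

    def test_iv_short_dispensings(self):
        rows = [
            full_row(medication="CEFTRIAXONE 1GM INJ", route="IV",
                     transaction_date=f"2015-01-{5 + 2 * i:02d}", days_supply=2)
            for i in range(3)
        ]
        courses = rxstew.consolidate_refills(make_records(rows))
        assert courses.iloc[0]["total_days_supply"] == 6

    def test_same_rx_two_facilities_is_integrity_error(self):
        rows = [full_row(), full_row(facility="OAKDALE", transaction_date="2015-04-01")]
        with pytest.raises(IntegrityError):
            rxstew.consolidate_refills(make_records(rows))


class TestNonSystemicPatterns:
    RULES = NonSystemicRules()

    @pytest.mark.parametrize(
        "name,family",
        [
            ("HYDROCORTISONE 2.5% CREAM", "a"),
            ("PERMETHRIN CREAM 5% 60GM", "b"),
            ("GELFOAM SIZE 50 SPONGE", "c"),
            ("LIDOCAINE HCL 2% JEL", "d"),
            ("NACL 0.9% IRRIGATION 1000ML", "d"),
            ("LACTATED RINGERS", "a"),
        ],
    )
    def test_printed_examples_removed_by_stated_family(self, name, family):
        assert self.RULES.family_of(name) == family

    @pytest.mark.parametrize(
        "name",
        [
            "CREAM OF TARTAR SUPPL",  # CREAM not preceded by a non-alpha char
            "AMOXICILLIN 500MG CAP",
            "CIPROFLOXACIN 500MG TAB",
            "METOPROLOL 25MG TAB",
            "SULFAMETHOXAZOLE-TRIMETHOPRIM DS TAB",  # DS only leading-anchored
        ],
    )
    def test_systemic_names_retained(self, name):
        assert self.RULES.family_of(name) is None

    def test_lexicon_drug_names_survive_every_removal_predicate(self, lexicon):
        """Planted clean drugs must never collide with a junk pattern."""
        from rxstew.cleaning import drop_nonpharmaceutical, drop_variable_dose

        names = [f"{e.keyword} 500MG TAB" for e in lexicon.entries]
        frame = make_records([full_row(medication=n) for n in names])
        _, removed_np = drop_nonpharmaceutical(frame)
        assert removed_np == 0
        assert not any(self.RULES.matches(n) for n in names)
        courses = rxstew.consolidate_refills(
            make_records(
                [full_row(medication=n, prescription_number=f"R{i}")
                 for i, n in enumerate(names)]
            )
        )
        _, removed_vd = drop_variable_dose(courses)
        assert removed_vd == 0


class TestDropVariableDose:
    @pytest.mark.parametrize(
        "name,removed",
        [
            ("INSULIN GLARGINE 100U/ML", 1),
            ("OXYCODONE HCL 5MG TAB", 1),
            ("METFORMIN 500MG TAB", 0),
        ],
    )
    def test_keyword_rule(self, name, removed):
        courses = rxstew.consolidate_refills(make_records([full_row(medication=name)]))
        _, n = rxstew.drop_variable_dose(courses)
        assert n == removed


class TestRunCleaning:
    def test_empty_input(self, default_cfg):
        records = make_records([full_row()]).iloc[:0]
        courses, ledger = rxstew.run_cleaning(records, default_cfg)
        assert len(courses) == 0
        assert all(step.removed == 0 for step in ledger.steps)

    def test_ledger_telescopes_and_percent_consistent(self, pipeline_result):
        ledger = pipeline_result["ledger"]
        previous = ledger.initial
        for step in ledger.steps:
            assert step.removed + step.remaining == previous
            assert step.pct_remaining == pytest.approx(step.remaining / ledger.initial)
            assert step.remaining <= previous
            previous = step.remaining

    def test_nonsystemic_filter_commutes_with_refill_consolidation(self, small_dataset, default_cfg):
        """Name-based removal before or after consolidation gives the same
        final course set."""
        d = small_dataset["dir"]
        cfg = rxstew.load_config(d / "config.yml")
        cfg["ingest"]["min_months"] = 0
        table, _ = rxstew.ingest_files(sorted(d.glob("invoices_*.csv")), cfg)
        kept, _ = rxstew.drop_incomplete(table)
        kept, _ = rxstew.drop_nonpharmaceutical(kept)
        kept, _ = rxstew.drop_reimbursements(kept)
        kept, _, _ = rxstew.deduplicate(kept)
        rules = NonSystemicRules()

        after = rxstew.consolidate_refills(kept)
        after, _ = rxstew.drop_nonsystemic(after, rules)

        names = kept["medication"].fillna("").astype(str)
        pre_filtered = kept[~names.map(rules.matches)]
        before = rxstew.consolidate_refills(pre_filtered)

        pd.testing.assert_frame_equal(
            after.reset_index(drop=True), before.reset_index(drop=True)
        )

    def test_matches_quadratic_reference_on_random_inputs(self, default_cfg):
        """Pipeline vs naive quadratic oracle, fuzzed small messy tables."""
        rng = np.random.default_rng(11)
        drugs = [
            "AMOXICILLIN 500MG TAB", "CIPROFLOXACIN 250MG TAB",
            "LISINOPRIL 10MG TAB", "HYDROCORTISONE 2.5% CREAM",
            "NORMAL SALINE FLUSH KIT", "OXYCODONE HCL 5MG TAB",
            "LIDOCAINE HCL 2% JEL", "METFORMIN 500MG TAB",
        ]
        for _ in range(60):
            n = int(rng.integers(1, 120))
            rows = []
            for i in range(n):
                row = full_row(
                    medication=str(rng.choice(drugs)),
                    days_supply=int(rng.integers(0, 40)),
                    prescription_number=f"RX{rng.integers(0, max(2, n // 3)):05d}",
                    transaction_date=f"2016-0{rng.integers(1, 5)}-{rng.integers(1, 28):02d}",
                    amount=float(rng.uniform(-50, 200)),
                    physician=f"DR{rng.integers(1, 4)}",
                )
                if rng.random() < 0.1:
                    row[str(rng.choice(["physician", "route", "payor"]))] = None
                rows.append(row)
            records = make_records(rows)
            courses, ledger = rxstew.run_cleaning(records, default_cfg)
            ref_courses, ref_counts = _oracles.naive_clean(
                _oracles.frame_to_rows(records), default_cfg
            )
            for step in (
                "incomplete", "nonpharmaceutical", "reimbursement", "duplicates",
                "refill_consolidation", "nonsystemic", "insulin_opioid",
            ):
                assert ledger.removed(step) == ref_counts[step], step
            got = courses.sort_values(
                ["prescription_number", "medication"]
            ).reset_index(drop=True)
            want = (
                pd.DataFrame(ref_courses, columns=got.columns)
                .sort_values(["prescription_number", "medication"])
                .reset_index(drop=True)
            )
            assert len(got) == len(want)
            assert got["total_days_supply"].tolist() == want["total_days_supply"].tolist()
            assert got["start_date"].tolist() == list(pd.to_datetime(want["start_date"]))
            assert got["n_dispensings"].tolist() == want["n_dispensings"].tolist()
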