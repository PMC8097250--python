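import pathlib

import pandas as pd
import pytest

import rxstew


@pytest.fixture(scope="session")
def default_cfg():
    return rxstew.default_config()


@pytest.fixture(scope="session")
def lexicon():
    return rxstew.load_lexicon()


@pytest.fixture(scope="session")
def asi_table():
    return rxstew.load_asi()


@pytest.fixture(scope="session")
def small_dataset(tmp_path_factory):
    """One generated messy dataset plus its ground truth, shared read-only."""
    outdir = tmp_path_factory.mktemp("simdata")
    config = rxstew.SimConfig(n_facilities=5, n_months=12, seed=20160101)
    truth = rxstew.generate(config, outdir)
    return {"dir": pathlib.Path(outdir), "config": config, "truth": truth}


@pytest.fixture(scope="session")
def pipeline_result(small_dataset, tmp_path_factory):
    """Full pipeline run over the shared dataset."""
    d = small_dataset["dir"]
    cfg = rxstew.load_config(d / "config.yml")
    cfg["ingest"]["min_months"] = 0  # short span: keep every generated facility
    outdir = tmp_path_factory.mktemp("pipeline")
    result = rxstew.run_pipeline(
        sorted(d.glob("invoices_*.csv")), d / "census.csv", d / "profiles.csv",
        outdir, cfg,
    )
    result["outdir"] = outdir
    result["config"] = cfg
    return result


def make_records(rows):
    """Build a canonical-schema DataFrame from compact row dicts."""
    from rxstew.config import CANONICAL_COLUMNS

    frame = pd.DataFrame(rows)
    for col in CANONICAL_COLUMNS:
        if col not in frame.columns:
            frame[col] = pd.NA
    frame["transaction_date"] = pd.to_datetime(frame["transaction_date"])
    frame["days_supply"] = frame["days_supply"].astype("Int64")
    frame["amount"] = frame["amount"].astype("Float64")
    for col in CANONICAL_COLUMNS:
        if col not in ("transaction_date", "days_supply", "amount"):
            frame[col] = frame[col].astype("string")
    return frame[CANONICAL_COLUMNS]


def full_row(**overrides):
    """A complete, clean invoice row; override fields per test."""
    row = {
        "facility": "MAPLEWOOD",
        "medication": "AMOXICILLIN 500MG TAB",
        "dose": "30 EA",
        "days_supply": 10,
        "prescription_number": "RX0000001",
        "transaction_date": "2016-03-05",
        "amount": 42.5,
        "route": "PO",
        "physician": "DR0001",
        "payor": "MEDICARE",
        "ndc": "00000000001",
    }
    row.update(overrides)
    return row
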