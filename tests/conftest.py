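"""Shared fixtures: handcrafted FAERS archives and synthetic cohort frames."""

from __future__ import annotations

from pathlib import Path

import pandas as pd
import pytest

from faersig.case_processing import PSDrugMatch
from faersig.faers_io import REQUIRED_COLUMNS


def write_faers_file(path: Path, table: str, rows: list[dict],
                     header: list[str] | None = None) -> Path:
    """Write rows in the "$" dialect; missing fields become empty strings."""
    cols = header or list(REQUIRED_COLUMNS[table])
    lines = ["$".join(cols)]
    for row in rows:
        lines.append("$".join(str(row.get(c, "")) for c in cols))
    path.write_text("\n".join(lines) + "\n")
    return path


def make_archive(root: Path, label: str = "2016Q1", *,
                 demo: list[dict], drug: list[dict] | None = None,
                 reac: list[dict] | None = None, outc: list[dict] | None = None,
                 ther: list[dict] | None = None, indi: list[dict] | None = None,
                 deleted: list[str] | None = None) -> Path:
    """A minimal but complete quarter directory.

    Non-DEMO tables default to one row referencing the first DEMO report, so
    every mandatory file exists and parses.
    """
    root.mkdir(parents=True, exist_ok=True)
    tag = label[2:]
    first = demo[0]
    ref = {"primaryid": first["primaryid"], "caseid": first["caseid"]}
    defaults = {
        "drug": [{**ref, "drug_seq": "1", "role_cod": "PS",
                  "drugname": "PLACEBO", "prod_ai": "", "route": ""}],
        "reac": [{**ref, "pt": "Headache"}],
        "outc": [{**ref, "outc_cod": "OT"}],
        "ther": [{**ref, "dsg_drug_seq": "1", "start_dt": "", "end_dt": ""}],
        "indi": [{**ref, "indi_drug_seq": "1", "indi_pt": "Pain"}],
    }
    tables = {"demo": demo, "drug": drug, "reac": reac, "outc": outc,
              "ther": ther, "indi": indi}
    for name, rows in tables.items():
        if rows is None:
            rows = defaults[name]
        write_faers_file(root / f"{name.upper()}{tag}.txt", name, rows)
    if deleted:
        (root / f"DELETE{tag}.txt").write_text(
            "caseid\n" + "\n".join(deleted) + "\n")
    return root


def demo_row(primaryid: str, caseid: str, fda_dt: str = "20180301",
             **extra) -> dict:
    row = {"primaryid": primaryid, "caseid": caseid, "fda_dt": fda_dt,
           "event_dt": "", "age": "", "age_cod": "", "sex": "",
           "occp_cod": "", "reporter_country": "US", "occr_country": "US",
           "rept_dt": fda_dt}
    row.update(extra)
    return row


def make_cohort(groups: list[dict]) -> pd.DataFrame:
    """Build a cohort frame from group specs.

    Each spec: ``{"n": 10, "drug": "ciprofloxacin", "event": "tendonitis",
    "sex": "F", "route": "oral", "outcomes": {"DS"}, ...}``; n rows with those
    attributes are emitted with unique case ids.
    """
    records = []
    next_id = 1
    for g in groups:
        for _ in range(g["n"]):
            cid = str(next_id)
            next_id += 1
            drug = g.get("drug", "ciprofloxacin")
            records.append({
                "primaryid": cid + "1",
                "caseid": cid,
                "sex": g.get("sex", "unknown"),
                "age_years": g.get("age_years"),
                "age_group": g.get("age_group", "unknown"),
                "region": g.get("region", "Unknown"),
                "reporter_class": g.get("reporter", "unknown"),
                "ps_drugs": (PSDrugMatch(drug, g.get("route", "unknown"), "1",
                                         g.get("start_dt", "")),),
                "drug_keys": frozenset({drug}),
                "event_keys": frozenset(g.get("events", {g.get("event",
                                                           "tendonitis")})),
                "outcome_codes": frozenset(g.get("outcomes", set())),
                "indication_class": g.get("indication", "unknown-indication"),
                "event_dt": g.get("event_dt", ""),
                "reporting_year": g.get("year", 2018),
            })
    return pd.DataFrame.from_records(records)


@pytest.fixture
def tiny_archive(tmp_path: Path) -> Path:
    """Three reports: a fluoroquinolone tendonitis case, a non-PS case, background."""
    demo = [
        demo_row("1001", "100", "20180301", event_dt="20180110", age="45",
                 age_cod="YR", sex="F", reporter_country="FR"),
        demo_row("2001", "200", "20190501", sex="M"),
        demo_row("3001", "300", "20200101"),
    ]
    drug = [
        {"primaryid": "1001", "caseid": "100", "drug_seq": "1",
         "role_cod": "PS", "drugname": "CIPRO", "prod_ai": "CIPROFLOXACIN",
         "route": "Oral"},
        {"primaryid": "2001", "caseid": "200", "drug_seq": "1",
         "role_cod": "SS", "drugname": "LEVOFLOXACIN", "prod_ai": "",
         "route": ""},
        {"primaryid": "2001", "caseid": "200", "drug_seq": "2",
         "role_cod": "PS", "drugname": "AMOXICILLIN", "prod_ai": "",
         "route": ""},
        {"primaryid": "3001", "caseid": "300", "drug_seq": "1",
         "role_cod": "PS", "drugname": "IBUPROFEN", "prod_ai": "", "route": ""},
    ]
    reac = [
        {"primaryid": "1001", "caseid": "100", "pt": "Tendonitis"},
        {"primaryid": "2001", "caseid": "200", "pt": "Tendon rupture"},
        {"primaryid": "3001", "caseid": "300", "pt": "Headache"},
    ]
    ther = [
        {"primaryid": "1001", "caseid": "100", "dsg_drug_seq": "1",
         "start_dt": "20180105", "end_dt": "20180115"},
    ]
    indi = [
        {"primaryid": "1001", "caseid": "100", "indi_drug_seq": "1",
         "indi_pt": "Urinary tract infection"},
    ]
    outc = [
        {"primaryid": "1001", "caseid": "100", "outc_cod": "DS"},
        {"primaryid": "1001", "caseid": "100", "outc_cod": "HO"},
    ]
    return make_archive(tmp_path / "q", demo=demo, drug=drug, reac=reac,
                        outc=outc, ther=ther, indi=indi)
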