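"""Deduplication rules, lexicon matching, harmonisation, cohort extraction."""

from __future__ import annotations

import datetime as dt

import numpy as np
import pandas as pd
import pytest

from faersig.case_processing import (
    DrugLexicon,
    LexiconError,
    TargetEventSet,
    age_group,
    build_study_data,
    classify_indication,
    classify_route,
    deduplicate,
    extract_cohort,
    harmonize_age,
    map_region,
    match_drug,
)
from faersig.faers_io import read_quarter

from conftest import demo_row, make_archive


def _demo(rows):
    return pd.DataFrame([demo_row(pid, cid, fda) for pid, cid, fda in rows])


class TestDeduplicate:
    def test_latest_fda_dt_wins(self):
        result = deduplicate(_demo([("1001", "100", "20200101"),
                                    ("1002", "100", "20200301")]))
        assert list(result.kept["primaryid"]) == ["1002"]
        assert result.removed_duplicates == 1

    def test_fda_dt_tie_higher_primaryid_wins(self):
        result = deduplicate(_demo([("1002", "100", "20200301"),
                                    ("1003", "100", "20200301")]))
        assert list(result.kept["primaryid"]) == ["1003"]

    def test_distinct_cases_pass_through(self):
        demo = _demo([("1", "100", "20200101"), ("2", "200", "20200101")])
        result = deduplicate(demo)
        assert len(result.kept) == 2
        assert result.removed_duplicates == 0

    def test_deleted_cases_removed_last(self):
        demo = _demo([("1001", "100", "20200101"), ("1002", "100", "20200301"),
                      ("2001", "200", "20200101")])
        result = deduplicate(demo, deleted={"100"})
        assert list(result.kept["caseid"]) == ["200"]
        assert result.removed_deleted == 1
        assert result.removed_duplicates == 1

    def test_unparseable_fda_dt_dropped_and_counted(self):
        demo = _demo([("1", "100", "notadate"), ("2", "200", "20200101")])
        result = deduplicate(demo)
        assert list(result.kept["caseid"]) == ["200"]
        assert result.removed_unparseable == 1

    def test_idempotent(self):
        demo = _demo([("1001", "100", "20200101"), ("1002", "100", "20200301"),
                      ("2001", "200", "20190101"), ("2002", "200", "20190101")])
        once = deduplicate(demo)
        twice = deduplicate(once.kept)
        assert twice.kept.equals(once.kept)
        assert twice.removed_duplicates == 0

    def test_permutation_invariance(self):
        demo = _demo([(f"{c}{v}", str(c), f"2020010{v}")
                      for c in range(100, 120) for v in (1, 2, 3)])
        baseline = deduplicate(demo).kept
        rng = np.random.default_rng(0)
        for _ in range(5):
            shuffled = demo.sample(frac=1, random_state=rng.integers(2**31))
            assert deduplicate(shuffled).kept.equals(baseline)

    def test_conservation(self):
        demo = _demo([("1001", "100", "20200101"), ("1002", "100", "20200301"),
                      ("3", "300", "bad")])
        r = deduplicate(demo, deleted={"999"})
        assert len(r.kept) + r.removed_duplicates + r.removed_deleted \
            + r.removed_unparseable == len(demo)


class TestMatchDrug:
    lexicon = DrugLexicon.default()

    @pytest.mark.parametrize("name, expected", [
        ("CIPRO", "ciprofloxacin"),
        ("cipro", "ciprofloxacin"),
        ("LEVOFLOXACIN.", "levofloxacin"),
        ("CIPRO 500MG TABLET", "ciprofloxacin"),
        ("AVELOX", "moxifloxacin"),
        ("AMOXICILLIN", None),
        ("CIPROFIBRATE", None),        # substring matches must not fire
        ("CIPROFLOXACIN HYDROCHLORIDE", "ciprofloxacin"),
        ("", None),
    ])
    def test_matching(self, name, expected):
        assert match_drug(name, "", self.lexicon) == expected

    def test_prod_ai_fallback(self):
        assert match_drug("ANTIBIOTIC NOS", "MOXIFLOXACIN", self.lexicon) \
            == "moxifloxacin"

    def test_ambiguous_lexicon_is_fatal(self):
        # "ACME" and "ACME FORTE" belong to different keys: the verbatim name
        # "ACME FORTE" token-prefix-matches both.
        lex = DrugLexicon({"d1": frozenset({"ACME"}),
                           "d2": frozenset({"ACME FORTE"})})
        with pytest.raises(LexiconError):
            match_drug("ACME FORTE", "", lex)

    def test_duplicate_name_across_keys_rejected(self):
        with pytest.raises(LexiconError):
            DrugLexicon({"d1": frozenset({"X"}), "d2": frozenset({"X"})})


@pytest.mark.parametrize("route, expected", [
    ("Oral", "oral"),
    ("ORAL", "oral"),
    ("Intravenous drip", "intravenous"),
    ("Intravenous (not otherwise specified)", "intravenous"),
    ("Intravenous bolus", "intravenous"),
    ("Topical", "other"),
    ("", "unknown"),
])
def test_classify_route(route, expected):
    assert classify_route(route) == expected


class TestHarmonizeAge:
    @pytest.mark.parametrize("age, cod, years", [
        (6, "MON", 0.5),
        (65, "YR", 65.0),
        (2, "DEC", 20.0),
        (730.5, "DY", 2.0),
        (8766, "HR", 1.0),
        (52.143, "WK", 1.0),
        (40, "", 40.0),            # missing unit treated as years
        (-5, "YR", None),
        (130, "YR", None),
        ("", "YR", None),
        ("abc", "YR", None),
    ])
    def test_units(self, age, cod, years):
        result = harmonize_age(age, cod)
        if years is None:
            assert result is None
        else:
            assert result == pytest.approx(years, rel=1e-6)

    @pytest.mark.parametrize("years, group", [
        (0.5, "<18"), (17.9, "<18"), (18, "18-65"), (65, "18-65"),
        (65.01, ">65"), (None, "unknown"),
    ])
    def test_age_groups_inclusive_upper_bound(self, years, group):
        assert age_group(years) == group


@pytest.mark.parametrize("country, region", [
    ("FR", "Europe"), ("US", "North America"), ("JP", "Asia"),
    ("AU", "Oceania"), ("BR", "South America"), ("ZA", "Africa"),
    ("", "Unknown"), ("XX", "Unknown"),
])
def test_map_region(country, region):
    assert map_region(country) == region


@pytest.mark.parametrize("pts, expected", [
    (["Urinary tract infection"], "infections"),
    (["Lower respiratory tract infection"], "infections"),
    (["Pneumonia"], "infections"),          # packaged infection list
    (["Hypertension"], "other"),
    (["Product used for unknown indication"], "unknown-indication"),
    ([], "unknown-indication"),
    (["Product used for unknown indication", "Pneumonia"], "infections"),
])
def test_classify_indication(pts, expected):
    assert classify_indication(pts) == expected


class TestExtractCohort:
    def test_ps_match_with_target_pt_enters(self, tiny_archive):
        bundle = read_quarter(tiny_archive, "2016Q1")
        cohort = extract_cohort([bundle])
        assert list(cohort["caseid"]) == ["100"]
        rec = cohort.iloc[0]
        assert rec["event_keys"] == frozenset({"tendonitis"})
        assert rec["drug_keys"] == frozenset({"ciprofloxacin"})
        assert rec["region"] == "Europe"
        assert rec["indication_class"] == "infections"
        assert rec["outcome_codes"] == frozenset({"DS", "HO"})
        # therapy start comes from the THER row of the matched drug_seq
        assert rec["ps_drugs"][0].start_dt == "20180105"
        assert rec["ps_drugs"][0].route_class == "oral"

    def test_non_ps_role_excluded(self, tiny_archive):
        # case 200 has levofloxacin as SS only and must stay out
        bundle = read_quarter(tiny_archive, "2016Q1")
        cohort = extract_cohort([bundle])
        assert "200" not in set(cohort["caseid"])

    def test_both_target_pts_one_record(self, tmp_path):
        root = make_archive(
            tmp_path / "q",
            demo=[demo_row("1", "10", "20180301")],
            drug=[{"primaryid": "1", "caseid": "10", "drug_seq": "1",
                   "role_cod": "PS", "drugname": "LEVAQUIN", "prod_ai": "",
                   "route": ""}],
            reac=[{"primaryid": "1", "caseid": "10", "pt": "Tendonitis"},
                  {"primaryid": "1", "caseid": "10", "pt": "Tendon rupture"}],
        )
        cohort = extract_cohort([read_quarter(root, "2016Q1")])
        assert len(cohort) == 1
        assert cohort.iloc[0]["event_keys"] == frozenset(
            {"tendonitis", "tendon_rupture"})

    def test_caseids_unique(self, tiny_archive):
        cohort = extract_cohort([read_quarter(tiny_archive, "2016Q1")])
        assert cohort["caseid"].is_unique

    def test_window_filter(self, tiny_archive):
        bundle = read_quarter(tiny_archive, "2016Q1")
        window = (dt.date(2018, 1, 1), dt.date(2018, 12, 31))
        cohort = extract_cohort([bundle], window=window)
        assert list(cohort["caseid"]) == ["100"]
        cohort_empty = extract_cohort(
            [bundle], window=(dt.date(2021, 1, 1), dt.date(2021, 3, 31)))
        assert len(cohort_empty) == 0

    def test_lexicon_enlargement_is_monotone(self, tiny_archive):
        """Adding names to the lexicon never shrinks the cohort."""
        bundle = read_quarter(tiny_archive, "2016Q1")
        small = DrugLexicon({"ciprofloxacin": frozenset({"CIPRO"})})
        big = DrugLexicon({"ciprofloxacin": frozenset({"CIPRO"}),
                           "other_drug": frozenset({"IBUPROFEN"})})
        events = TargetEventSet({
            "tendonitis": ("Tendonitis", 10043255),
            "headache": ("Headache", 10019211),
        })
        cohort_small = extract_cohort([bundle], small, events)
        cohort_big = extract_cohort([bundle], big, events)
        assert set(cohort_small["caseid"]) <= set(cohort_big["caseid"])
        assert "300" in set(cohort_big["caseid"])

    def test_dedup_precedes_flagging(self, tmp_path):
        # later report version drops the tendonitis PT; the case must not count
        root = make_archive(
            tmp_path / "q",
            demo=[demo_row("11", "10", "20180101"),
                  demo_row("12", "10", "20180601")],
            drug=[{"primaryid": "11", "caseid": "10", "drug_seq": "1",
                   "role_cod": "PS", "drugname": "CIPRO", "prod_ai": "",
                   "route": ""},
                  {"primaryid": "12", "caseid": "10", "drug_seq": "1",
                   "role_cod": "PS", "drugname": "CIPRO", "prod_ai": "",
                   "route": ""}],
            reac=[{"primaryid": "11", "caseid": "10", "pt": "Tendonitis"},
                  {"primaryid": "12", "caseid": "10", "pt": "Arthralgia"}],
        )
        study = build_study_data([read_quarter(root, "2016Q1")])
        assert len(study.cohort) == 0
        assert study.flow_counts["removed_duplicates"] == 1
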