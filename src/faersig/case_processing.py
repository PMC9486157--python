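"""Deduplication and cohort extraction from parsed FAERS quarters.

A FAERS case (CASEID) typically accumulates several report versions
(PRIMARYID) across quarters.  Following the FDA recommendation, exactly one
version per case is retained: the one with the latest FDA receipt date
(FDA_DT), ties broken by the numerically higher PRIMARYID.  Cases on the
quarterly deleted-case lists are removed afterwards.

The analysis cohort consists of deduplicated reports whose *primary suspect*
(role_cod == "PS") drug matches the study-drug lexicon and whose reactions
include a target MedDRA Preferred Term.  Drug matching is exact-token based
against an explicit lexicon (generic plus trade names); substring matching is
deliberately rejected so that e.g. CIPROFIBRATE never matches CIPRO.
"""

from __future__ import annotations

import datetime as _dt
from dataclasses import dataclass, field
from importlib import resources
from pathlib import Path
from typing import Iterable, Mapping, NamedTuple, Sequence

import numpy as np
import pandas as pd

from .faers_io import QuarterBundle, parse_partial_date

_PUNCT = ".,;:!?/\\"

AGE_UNIT_TO_YEARS: Mapping[str, float] = {
    "YR": 1.0,
    "DEC": 10.0,
    "MON": 1.0 / 12.0,
    "WK": 1.0 / 52.143,
    "DY": 1.0 / 365.25,
    "HR": 1.0 / 8766.0,
}

AGE_GROUPS = ("<18", "18-65", ">65", "unknown")
ROUTE_CLASSES = ("oral", "intravenous", "other", "unknown")
#: precedence when several matched PS rows disagree on route
ROUTE_PRECEDENCE = ("oral", "intravenous", "other", "unknown")
REGIONS = ("Africa", "Asia", "Europe", "North America", "Oceania",
           "South America", "Unknown")
INDICATION_CLASSES = ("infections", "other", "unknown-indication")


class LexiconError(ValueError):
    """A drug name maps to more than one study-drug key."""


def _read_packaged_csv(name: str) -> pd.DataFrame:
    with resources.files("faersig.data").joinpath(name).open("r") as fh:
        return pd.read_csv(fh, dtype=str).fillna("")


@dataclass(frozen=True)
class DrugLexicon:
    """Mapping from study-drug key to its uppercase generic + trade names."""

    entries: Mapping[str, frozenset[str]]

    def __post_init__(self) -> None:
        seen: dict[str, str] = {}
        for key, names in self.entries.items():
            for name in names:
                if name != name.strip().upper():
                    raise LexiconError(f"lexicon name {name!r} not uppercase/trimmed")
                if name in seen and seen[name] != key:
                    raise LexiconError(
                        f"name {name!r} maps to both {seen[name]} and {key}"
                    )
                seen[name] = key

    @property
    def drug_keys(self) -> tuple[str, ...]:
        return tuple(self.entries)

    @classmethod
    def from_frame(cls, frame: pd.DataFrame) -> "DrugLexicon":
        entries = {
            key: frozenset(g["name"].str.strip().str.upper())
            for key, g in frame.groupby("drug_key", sort=True)
        }
        return cls(entries)

    @classmethod
    def from_csv(cls, path: str | Path) -> "DrugLexicon":
        return cls.from_frame(pd.read_csv(path, dtype=str).fillna(""))

    @classmethod
    def default(cls) -> "DrugLexicon":
        """Fluoroquinolone lexicon (ciprofloxacin, levofloxacin, moxifloxacin)."""
        return cls.from_frame(_read_packaged_csv("lexicon.csv"))


@dataclass(frozen=True)
class TargetEventSet:
    """Target adverse events as MedDRA PT name + code per event key."""

    events: Mapping[str, tuple[str, int]]

    @property
    def event_keys(self) -> tuple[str, ...]:
        return tuple(self.events)

    def pt_to_key(self) -> dict[str, str]:
        """Lowercased PT name -> event key (FAERS REAC stores names, not codes)."""
        return {pt.lower(): key for key, (pt, _code) in self.events.items()}

    @classmethod
    def from_csv(cls, path: str | Path) -> "TargetEventSet":
        frame = pd.read_csv(path, dtype=str).fillna("")
        return cls({
            row["event_key"]: (row["pt_name"], int(row["pt_code"]))
            for _, row in frame.iterrows()
        })

    @classmethod
    def default(cls) -> "TargetEventSet":
        """Tendonitis (PT 10043255) and tendon rupture (PT 10043248)."""
        frame = _read_packaged_csv("events.csv")
        return cls({
            row["event_key"]: (row["pt_name"], int(row["pt_code"]))
            for _, row in frame.iterrows()
        })


def _load_route_map() -> dict[str, str]:
    frame = _read_packaged_csv("routes.csv")
    return dict(zip(frame["route"].str.lower(), frame["route_class"]))


def _load_country_map() -> dict[str, str]:
    frame = _read_packaged_csv("countries.csv")
    return dict(zip(frame["country"].str.upper(), frame["region"]))


def _load_infection_pts() -> frozenset[str]:
    frame = _read_packaged_csv("infection_pts.csv")
    return frozenset(frame["indi_pt"].str.lower())


_ROUTE_MAP = _load_route_map()
_COUNTRY_MAP = _load_country_map()
_INFECTION_PTS = _load_infection_pts()


# ---------------------------------------------------------------------------
# deduplication
# ---------------------------------------------------------------------------

@dataclass
class DedupResult:
    """Outcome of FDA-rule deduplication over DEMO rows.

    kept + removed_duplicates + removed_deleted + removed_unparseable equals
    the input row count; exactly one kept row per caseid.
    """

    kept: pd.DataFrame
    removed_duplicates: int
    removed_deleted: int
    removed_unparseable: int


def _date_key(raw: object) -> int:
    """Sortable yyyymmdd integer for a raw FAERS date; -1 if unparseable."""
    p = parse_partial_date(raw)
    if not p.is_valid:
        return -1
    y, m, d = p.sort_key()
    return y * 10000 + m * 100 + d


def deduplicate(demo: pd.DataFrame,
                deleted: Iterable[str] = ()) -> DedupResult:
    """Retain one report version per case: latest FDA_DT, then highest PRIMARYID.

    Rows whose fda_dt cannot be parsed to at least year precision are dropped
    and counted.  Rows whose caseid appears in ``deleted`` are removed last.
    Idempotent and invariant to input row order.
    """
    deleted = set(deleted)
    n_in = len(demo)
    fda_key = demo["fda_dt"].map(_date_key)
    parseable = fda_key >= 0
    removed_unparseable = int((~parseable).sum())
    frame = demo.loc[parseable].copy()
    frame["_fda_key"] = fda_key[parseable]
    frame["_pid_num"] = pd.to_numeric(frame["primaryid"], errors="coerce").fillna(-1)

    # stable canonical order, then keep the last (max) row per caseid
    frame = frame.sort_values(
        ["caseid", "_fda_key", "_pid_num", "primaryid"], kind="mergesort"
    )
    kept = frame.drop_duplicates(subset="caseid", keep="last")
    removed_duplicates = len(frame) - len(kept)

    is_deleted = kept["caseid"].isin(deleted)
    removed_deleted = int(is_deleted.sum())
    kept = (
        kept.loc[~is_deleted]
        .drop(columns=["_fda_key", "_pid_num"])
        .sort_values("caseid", kind="mergesort")
        .reset_index(drop=True)
    )
    assert len(kept) + removed_duplicates + removed_deleted + removed_unparseable == n_in
    return DedupResult(kept, removed_duplicates, removed_deleted, removed_unparseable)


# ---------------------------------------------------------------------------
# field harmonisation
# ---------------------------------------------------------------------------

def match_drug(drugname: str, prod_ai: str, lexicon: DrugLexicon) -> str | None:
    """Match a verbatim FAERS drug name to a study-drug key, or None.

    Matching is case-insensitive on whole-token prefixes of the verbatim name
    after trimming and stripping trailing punctuation, so dose decorations
    ("CIPRO 500MG TAB") match while lexical near-misses ("CIPROFIBRATE") never
    do.  ``prod_ai`` (active ingredient) is consulted when the drug name fails.
    """
    for text in (drugname, prod_ai):
        key = _match_one(text, lexicon)
        if key is not None:
            return key
    return None


def _match_one(text: str, lexicon: DrugLexicon) -> str | None:
    if not text:
        return None
    tokens = [t.strip(_PUNCT) for t in text.strip().upper().split()]
    tokens = [t for t in tokens if t]
    hits: set[str] = set()
    for k in range(1, len(tokens) + 1):
        prefix = " ".join(tokens[:k])
        for key, names in lexicon.entries.items():
            if prefix in names:
                hits.add(key)
    if len(hits) > 1:
        raise LexiconError(f"{text!r} matches several drug keys: {sorted(hits)}")
    return hits.pop() if hits else None


def classify_route(route: str) -> str:
    """Classify a verbatim route string as oral / intravenous / other / unknown."""
    r = (route or "").strip().lower()
    if not r:
        return "unknown"
    return _ROUTE_MAP.get(r, "other")


def harmonize_age(age: object, age_cod: str) -> float | None:
    """Convert a FAERS (age, unit) pair to years; impossible values -> None.

    A missing/unknown unit with a value present is treated as years.  Results
    below 0 or above 120 years are treated as data errors and returned missing.
    """
    try:
        value = float(str(age).strip())
    except (TypeError, ValueError):
        return None
    unit = (age_cod or "").strip().upper()
    factor = AGE_UNIT_TO_YEARS.get(unit, 1.0)
    years = value * factor
    if years < 0 or years > 120:
        return None
    return years


def age_group(age_years: float | None) -> str:
    """Band an age in years as <18, 18-65 (inclusive both ends), >65, unknown."""
    if age_years is None or (isinstance(age_years, float) and np.isnan(age_years)):
        return "unknown"
    if age_years < 18:
        return "<18"
    if age_years <= 65:
        return "18-65"
    return ">65"


def map_region(country: str) -> str:
    """Map a FAERS country string (ISO-like code or name) to a continent."""
    c = (country or "").strip().upper()
    if not c:
        return "Unknown"
    return _COUNTRY_MAP.get(c, "Unknown")


def classify_indication(indi_pts: Sequence[str]) -> str:
    """Class a report's indication PTs for the matched drug.

    "infections" if any PT carries the token "infection" or is on the packaged
    infection-PT list; "unknown-indication" if the only information is
    "Product used for unknown indication" (or nothing); otherwise "other".
    """
    informative = False
    for pt in indi_pts:
        p = (pt or "").strip().lower()
        if not p:
            continue
        if "infection" in p and p != "product used for unknown indication":
            return "infections"
        if p in _INFECTION_PTS:
            return "infections"
        if p != "product used for unknown indication":
            informative = True
    return "other" if informative else "unknown-indication"


# ---------------------------------------------------------------------------
# cohort extraction
# ---------------------------------------------------------------------------

class PSDrugMatch(NamedTuple):
    """One matched primary-suspect drug row within a report."""

    drug_key: str
    route_class: str
    drug_seq: str
    start_dt: str


@dataclass
class StudyData:
    """Deduplicated study universe plus the extracted drug-event cohort.

    ``universe`` has one row per retained report with boolean columns
    ``drug__<key>`` (primary-suspect exposure), ``route__<key>`` (route class
    of the matched PS drug) and ``event__<key>`` (target PT reported).
    ``cohort`` holds the fully joined case records (one row per caseid) for
    reports with at least one matched PS drug and one target event.
    """

    universe: pd.DataFrame
    cohort: pd.DataFrame
    dedup: DedupResult
    flow_counts: dict[str, int] = field(default_factory=dict)


def _concat(bundles: Sequence[QuarterBundle], table: str) -> pd.DataFrame:
    frames = [b.table(table) for b in bundles]
    return pd.concat(frames, ignore_index=True) if frames else pd.DataFrame()


def _in_window(fda_key: pd.Series,
               window: tuple[_dt.date, _dt.date] | None) -> pd.Series:
    if window is None:
        return pd.Series(True, index=fda_key.index)
    lo = window[0].year * 10000 + window[0].month * 100 + window[0].day
    hi = window[1].year * 10000 + window[1].month * 100 + window[1].day
    return (fda_key >= lo) & (fda_key <= hi)


def build_study_data(
    bundles: Sequence[QuarterBundle],
    lexicon: DrugLexicon | None = None,
    events: TargetEventSet | None = None,
    window: tuple[_dt.date, _dt.date] | None = None,
) -> StudyData:
    """Run dedup + window filter + exposure/event flagging + cohort extraction.

    This is the joined path behind :func:`extract_cohort`; it also returns the
    per-report exposure/event flags of the whole deduplicated universe, which
    the disproportionality screen needs as its background.
    """
    lexicon = lexicon or DrugLexicon.default()
    events = events or TargetEventSet.default()

    demo = _concat(bundles, "demo")
    deleted: set[str] = set()
    for b in bundles:
        deleted |= set(b.deleted_caseids)
    n_raw = len(demo)

    dedup = deduplicate(demo, deleted)
    kept = dedup.kept
    fda_key = kept["fda_dt"].map(_date_key)
    kept = kept.loc[_in_window(fda_key, window)].reset_index(drop=True)

    keep_pids = set(kept["primaryid"])
    drug = _concat(bundles, "drug")
    drug = drug.loc[drug["primaryid"].isin(keep_pids)]
    reac = _concat(bundles, "reac")
    reac = reac.loc[reac["primaryid"].isin(keep_pids)]

    # vectorised drug matching over unique verbatim names
    uniq = drug[["drugname", "prod_ai"]].drop_duplicates()
    name_key = {
        (dn, ai): match_drug(dn, ai, lexicon)
        for dn, ai in zip(uniq["drugname"], uniq["prod_ai"])
    }
    drug = drug.copy()
    drug["_match"] = [
        name_key[(dn, ai)] for dn, ai in zip(drug["drugname"], drug["prod_ai"])
    ]
    ps = drug.loc[(drug["role_cod"] == "PS") & drug["_match"].notna()].copy()
    ps["_route_class"] = ps["route"].map(classify_route)

    pt_to_key = events.pt_to_key()
    reac = reac.copy()
    reac["_event"] = reac["pt"].str.strip().str.lower().map(pt_to_key)
    hits = reac.loc[reac["_event"].notna()]

    universe = kept[["primaryid", "caseid", "sex", "age", "age_cod"]].copy()
    universe["age_years"] = [
        harmonize_age(a, c) for a, c in zip(universe["age"], universe["age_cod"])
    ]
    universe["age_group"] = universe["age_years"].map(age_group)
    universe = universe.set_index("primaryid", drop=False)

    for key in lexicon.drug_keys:
        sub = ps.loc[ps["_match"] == key]
        exposed = set(sub["primaryid"])
        universe[f"drug__{key}"] = universe["primaryid"].isin(exposed)
        # one route class per report: precedence oral > intravenous > other > unknown
        route_rank = {c: i for i, c in enumerate(ROUTE_PRECEDENCE)}
        best = (
            sub.assign(_rank=sub["_route_class"].map(route_rank))
            .sort_values(["primaryid", "_rank"], kind="mergesort")
            .drop_duplicates("primaryid", keep="first")
            .set_index("primaryid")["_route_class"]
        )
        universe[f"route__{key}"] = universe["primaryid"].map(best).fillna("")
    for key in events.event_keys:
        with_event = set(hits.loc[hits["_event"] == key, "primaryid"])
        universe[f"event__{key}"] = universe["primaryid"].isin(with_event)

    drug_cols = [f"drug__{k}" for k in lexicon.drug_keys]
    event_cols = [f"event__{k}" for k in events.event_keys]
    in_cohort = universe[drug_cols].any(axis=1) & universe[event_cols].any(axis=1)
    cohort_pids = universe.loc[in_cohort, "primaryid"]

    cohort = _assemble_cohort(
        kept.loc[kept["primaryid"].isin(set(cohort_pids))],
        ps, hits, _concat(bundles, "outc"), _concat(bundles, "ther"),
        _concat(bundles, "indi"), lexicon, events,
    )
    flow = {
        "reports_raw": n_raw,
        "removed_duplicates": dedup.removed_duplicates,
        "removed_deleted": dedup.removed_deleted,
        "removed_unparseable_fda_dt": dedup.removed_unparseable,
        "reports_deduplicated_in_window": len(universe),
        "cohort_reports": len(cohort),
    }
    for key in lexicon.drug_keys:
        for ev in events.event_keys:
            n = int(
                (universe[f"drug__{key}"] & universe[f"event__{ev}"] & in_cohort).sum()
            )
            flow[f"cohort_{key}_{ev}"] = n
    return StudyData(universe=universe.reset_index(drop=True), cohort=cohort,
                     dedup=dedup, flow_counts=flow)


def _assemble_cohort(
    demo: pd.DataFrame,
    ps: pd.DataFrame,
    reac_hits: pd.DataFrame,
    outc: pd.DataFrame,
    ther: pd.DataFrame,
    indi: pd.DataFrame,
    lexicon: DrugLexicon,
    events: TargetEventSet,
) -> pd.DataFrame:
    pids = set(demo["primaryid"])
    ps = ps.loc[ps["primaryid"].isin(pids)]
    reac_hits = reac_hits.loc[reac_hits["primaryid"].isin(pids)]
    outc = outc.loc[outc["primaryid"].isin(pids)] if len(outc) else outc
    ther = ther.loc[ther["primaryid"].isin(pids)] if len(ther) else ther
    indi = indi.loc[indi["primaryid"].isin(pids)] if len(indi) else indi

    # earliest therapy start per (primaryid, drug_seq)
    ther_map: dict[tuple[str, str], str] = {}
    if len(ther):
        t = ther.copy()
        t["_key"] = t["start_dt"].map(_date_key)
        t = t.loc[t["_key"] >= 0].sort_values(
            ["primaryid", "dsg_drug_seq", "_key"], kind="mergesort"
        )
        t = t.drop_duplicates(["primaryid", "dsg_drug_seq"], keep="first")
        ther_map = {
            (pid, seq): dt
            for pid, seq, dt in zip(t["primaryid"], t["dsg_drug_seq"], t["start_dt"])
        }

    events_by_pid: dict[str, frozenset[str]] = {
        pid: frozenset(g["_event"])
        for pid, g in reac_hits.groupby("primaryid", sort=False)
    }
    outc_by_pid: dict[str, frozenset[str]] = (
        {pid: frozenset(g["outc_cod"]) for pid, g in outc.groupby("primaryid", sort=False)}
        if len(outc) else {}
    )
    indi_by_pid_seq: dict[str, dict[str, list[str]]] = {}
    if len(indi):
        for pid, g in indi.groupby("primaryid", sort=False):
            indi_by_pid_seq[pid] = {
                seq: list(sg["indi_pt"]) for seq, sg in g.groupby("indi_drug_seq")
            }

    ps_by_pid = {pid: g for pid, g in ps.groupby("primaryid", sort=False)}

    records: list[dict] = []
    for row in demo.itertuples(index=False):
        pid = row.primaryid
        g = ps_by_pid.get(pid)
        if g is None:
            continue
        matches: list[PSDrugMatch] = []
        indi_pts: list[str] = []
        for seq, key, route in zip(g["drug_seq"], g["_match"], g["_route_class"]):
            start = ther_map.get((pid, seq), "")
            matches.append(PSDrugMatch(key, route, seq, start))
            indi_pts.extend(indi_by_pid_seq.get(pid, {}).get(seq, []))
        matches.sort(key=lambda m: (m.drug_key, m.drug_seq))
        age_years = harmonize_age(row.age, row.age_cod)
        fda = parse_partial_date(row.fda_dt)
        records.append({
            "primaryid": pid,
            "caseid": row.caseid,
            "sex": row.sex if row.sex in ("F", "M") else "unknown",
            "age_years": age_years,
            "age_group": age_group(age_years),
            "region": map_region(row.reporter_country or row.occr_country),
            "reporter_class": row.occp_cod if row.occp_cod else "unknown",
            "ps_drugs": tuple(matches),
            "drug_keys": frozenset(m.drug_key for m in matches),
            "event_keys": events_by_pid.get(pid, frozenset()),
            "outcome_codes": outc_by_pid.get(pid, frozenset()),
            "indication_class": classify_indication(indi_pts),
            "event_dt": row.event_dt,
            "reporting_year": fda.date.year if fda.is_valid else None,
        })
    cohort = pd.DataFrame.from_records(records)
    if len(cohort):
        cohort = cohort.sort_values("caseid", kind="mergesort").reset_index(drop=True)
    return cohort


def extract_cohort(
    bundles: Sequence[QuarterBundle],
    lexicon: DrugLexicon | None = None,
    events: TargetEventSet | None = None,
    window: tuple[_dt.date, _dt.date] | None = None,
) -> pd.DataFrame:
    """Deduplicate and return the drug-event cohort as one row per case.

    A case enters the cohort iff some primary-suspect drug row matches the
    lexicon and some reaction PT equals a target event PT (name equality,
    case-insensitive).  A report carrying both target PTs yields a single row
    with both event keys.
    """
    return build_study_data(bundles, lexicon, events, window).cohort
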