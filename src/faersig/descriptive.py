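"""Descriptive surfaces: clinical characteristics, serious outcomes, onset times.

Time-to-onset is the calendar-day difference between the adverse-event date
(EVENT_DT) and the therapy start date (START_DT) of the matched
primary-suspect drug.  Only pairs where both dates carry full day precision
and the difference is non-negative are retained; same-day onset counts as
0 days.  Exclusions are tallied by reason (missing date, partial precision,
negative interval) so that retained + excluded always equals the input count.

Quartiles use the median-of-halves rule (the median of the lower/upper half
of the sorted values, halves excluding the middle element at odd n), which
yields half-integer quartiles on integer day counts.
"""

from __future__ import annotations

from dataclasses import dataclass
from typing import Mapping, Sequence

import numpy as np
import pandas as pd

from .faers_io import DatePrecision, OUTCOME_CODES, parse_partial_date
from .case_processing import (
    AGE_GROUPS,
    INDICATION_CLASSES,
    REGIONS,
)

ONSET_EXCLUSION_REASONS = ("missing", "partial_precision", "negative")

#: canonical display order of Table-style blocks
SEX_LEVELS = ("F", "M", "unknown")


def percentage(count: int, total: int) -> float:
    """Share of ``count`` in ``total`` as a percentage rounded to 2 decimals."""
    if total == 0:
        return 0.0
    return round(100.0 * count / total, 2)


# ---------------------------------------------------------------------------
# time to onset
# ---------------------------------------------------------------------------

@dataclass(frozen=True)
class OnsetRecord:
    """One valid drug-event onset interval (days, >= 0) for one case."""

    caseid: str
    drug_key: str
    event_key: str
    onset_days: int


def compute_onset(cohort: pd.DataFrame) -> tuple[list[OnsetRecord], dict[str, int]]:
    """Extract valid onset intervals per (case, drug, event) with exclusion tally.

    A candidate is one (report, matched PS drug, target event) triple.  It is
    retained iff the report's EVENT_DT and the drug's START_DT both parse at
    day precision and EVENT_DT >= START_DT.
    """
    records: list[OnsetRecord] = []
    excluded = {reason: 0 for reason in ONSET_EXCLUSION_REASONS}
    for row in cohort.itertuples(index=False):
        event_raw = row.event_dt
        for match in row.ps_drugs:
            for event_key in sorted(row.event_keys):
                start_raw = match.start_dt
                if not event_raw or not start_raw:
                    excluded["missing"] += 1
                    continue
                ev = parse_partial_date(event_raw)
                st = parse_partial_date(start_raw)
                if ev.precision is not DatePrecision.DAY or \
                        st.precision is not DatePrecision.DAY:
                    excluded["partial_precision"] += 1
                    continue
                days = (ev.date - st.date).days
                if days < 0:
                    excluded["negative"] += 1
                    continue
                records.append(OnsetRecord(row.caseid, match.drug_key,
                                           event_key, days))
    return records, excluded


@dataclass(frozen=True)
class OnsetSummary:
    """Quartiles of valid onset intervals for one drug-event pair."""

    drug_key: str
    event_key: str
    n_valid: int
    q1: float
    median: float
    q3: float


def _median(values: np.ndarray) -> float:
    n = len(values)
    mid = n // 2
    if n % 2:
        return float(values[mid])
    return float(values[mid - 1] + values[mid]) / 2.0


def median_of_halves(values: Sequence[float]) -> tuple[float, float, float]:
    """(q1, median, q3) by the median-of-halves rule.

    The lower/upper halves exclude the middle element when n is odd; at n == 1
    all three quartiles coincide with the single value.
    """
    v = np.sort(np.asarray(values, dtype=float))
    n = len(v)
    if n == 0:
        raise ValueError("cannot summarise an empty onset list")
    if n == 1:
        return float(v[0]), float(v[0]), float(v[0])
    med = _median(v)
    half = n // 2
    lower = v[:half]
    upper = v[n - half:]
    return _median(lower), med, _median(upper)


def summarize_onset(onsets: Sequence[OnsetRecord], drug_key: str,
                    event_key: str) -> OnsetSummary:
    """Quartile summary of one drug-event pair's onset intervals."""
    days = [r.onset_days for r in onsets
            if r.drug_key == drug_key and r.event_key == event_key]
    q1, med, q3 = median_of_halves(days)
    return OnsetSummary(drug_key, event_key, len(days), q1, med, q3)


def summarize_onset_all(onsets: Sequence[OnsetRecord]) -> pd.DataFrame:
    """Onset quartiles for every (drug, event) pair present in the records."""
    pairs = sorted({(r.drug_key, r.event_key) for r in onsets})
    rows = [summarize_onset(onsets, d, e) for d, e in pairs]
    return pd.DataFrame(
        [{"drug": s.drug_key, "event": s.event_key, "n_valid": s.n_valid,
          "q1": s.q1, "median": s.median, "q3": s.q3} for s in rows]
    )


def onset_histogram(onsets: Sequence[OnsetRecord],
                    bins: Sequence[float]) -> pd.DataFrame:
    """Left-closed right-open histogram of onset days per (drug, event).

    ``bins`` are strictly increasing edges; a value x falls in bin i iff
    bins[i] <= x < bins[i+1].  Counts over all bins conserve the number of
    in-range records.
    """
    edges = np.asarray(bins, dtype=float)
    if len(edges) < 2 or not np.all(np.diff(edges) > 0):
        raise ValueError("bin edges must be strictly increasing")
    pairs = sorted({(r.drug_key, r.event_key) for r in onsets})
    rows = []
    for drug, event in pairs:
        days = np.array([r.onset_days for r in onsets
                         if r.drug_key == drug and r.event_key == event],
                        dtype=float)
        # strict right-open binning (np.histogram closes the last bin)
        idx = np.searchsorted(edges, days, side="right") - 1
        in_range = (idx >= 0) & (days < edges[-1])
        counts = np.bincount(idx[in_range].astype(int), minlength=len(edges) - 1)
        for i in range(len(edges) - 1):
            rows.append({"drug": drug, "event": event,
                         "bin_lo": edges[i], "bin_hi": edges[i + 1],
                         "count": int(counts[i])})
    return pd.DataFrame(rows,
                        columns=["drug", "event", "bin_lo", "bin_hi", "count"])


# ---------------------------------------------------------------------------
# clinical characteristics and serious outcomes
# ---------------------------------------------------------------------------

def _group_mask(cohort: pd.DataFrame, drug_key: str | None,
                event_key: str) -> pd.Series:
    has_event = cohort["event_keys"].map(lambda s: event_key in s)
    if drug_key is None:
        return has_event
    return has_event & cohort["drug_keys"].map(lambda s: drug_key in s)


def summarize_characteristics(
    cohort: pd.DataFrame,
    drugs: Sequence[str] | None = None,
    events: Sequence[str] | None = None,
) -> pd.DataFrame:
    """Per (drug, event) and pooled counts/percentages of the clinical blocks.

    Blocks: total, sex, age bands (plus mean age over harmonised ages only),
    indication classes, serious outcomes, reporting regions, reporter
    occupations and reporting years.  Within every categorical block the
    counts sum to the group total (outcome counts may exceed it, since one
    report can carry several outcome codes).  The pooled drug group ``all``
    sums the per-drug groups.
    """
    if drugs is None:
        drugs = sorted({d for s in cohort["drug_keys"] for d in s})
    if events is None:
        events = sorted({e for s in cohort["event_keys"] for e in s})
    rows: list[dict] = []
    for event in events:
        group_masks = {drug: _group_mask(cohort, drug, event) for drug in drugs}
        for drug in [*drugs, "all"]:
            if drug == "all":
                # pooled column: a report with two study drugs counts once per drug
                subs = [cohort.loc[group_masks[d]] for d in drugs]
                sub = pd.concat(subs) if subs else cohort.iloc[0:0]
            else:
                sub = cohort.loc[group_masks[drug]]
            total = len(sub)
            rows.append({"drug": drug, "event": event, "block": "total",
                         "level": "n", "count": total,
                         "value": float(total)})
            ages = sub["age_years"].dropna() if total else pd.Series(dtype=float)
            rows.append({"drug": drug, "event": event, "block": "mean_age",
                         "level": "years", "count": int(len(ages)),
                         "value": round(float(ages.mean()), 2) if len(ages) else float("nan")})
            blocks: list[tuple[str, Sequence[str], pd.Series]] = []
            if total:
                blocks = [
                    ("sex", SEX_LEVELS, sub["sex"]),
                    ("age_group", AGE_GROUPS, sub["age_group"]),
                    ("indication", INDICATION_CLASSES, sub["indication_class"]),
                    ("region", REGIONS, sub["region"]),
                    ("reporter", sorted(sub["reporter_class"].unique()),
                     sub["reporter_class"]),
                    ("reporting_year",
                     [str(y) for y in sorted(sub["reporting_year"].dropna().unique())],
                     sub["reporting_year"].map(
                         lambda y: str(y) if pd.notna(y) else "unknown")),
                ]
            for block, levels, series in blocks:
                vc = series.value_counts()
                for level in levels:
                    count = int(vc.get(level, 0))
                    rows.append({"drug": drug, "event": event, "block": block,
                                 "level": str(level), "count": count,
                                 "value": percentage(count, total)})
            # serious outcomes: multi-code, so counted per code
            for code in sorted(OUTCOME_CODES):
                count = int(sub["outcome_codes"].map(lambda s: code in s).sum()) \
                    if total else 0
                rows.append({"drug": drug, "event": event, "block": "outcome",
                             "level": code, "count": count,
                             "value": percentage(count, total)})
    return pd.DataFrame(rows, columns=["drug", "event", "block", "level",
                                       "count", "value"])


def summarize_outcomes(
    cohort: pd.DataFrame,
    drugs: Sequence[str] | None = None,
    events: Sequence[str] | None = None,
) -> pd.DataFrame:
    """Serious-outcome counts and proportions per (drug, event) group.

    A report carrying k outcome codes contributes to k rows; each proportion
    divides by the group's total report count, so proportions across codes may
    sum past 100%.
    """
    if drugs is None:
        drugs = sorted({d for s in cohort["drug_keys"] for d in s})
    if events is None:
        events = sorted({e for s in cohort["event_keys"] for e in s})
    rows = []
    for drug in drugs:
        for event in events:
            sub = cohort.loc[_group_mask(cohort, drug, event)]
            total = len(sub)
            for code in sorted(OUTCOME_CODES):
                count = int(sub["outcome_codes"].map(lambda s: code in s).sum()) \
                    if total else 0
                rows.append({"drug": drug, "event": event, "outc_cod": code,
                             "count": count, "total": total,
                             "proportion_pct": percentage(count, total)})
    return pd.DataFrame(rows)


def route_counts(
    cohort: pd.DataFrame,
    drugs: Sequence[str] | None = None,
    events: Sequence[str] | None = None,
) -> pd.DataFrame:
    """Reports per (drug, event, route class) of the matched PS drug.

    The route class is the matched drug's own; when a report matched the same
    study drug on several PS rows the report-level precedence
    oral > intravenous > other > unknown was already applied upstream.
    """
    if drugs is None:
        drugs = sorted({d for s in cohort["drug_keys"] for d in s})
    if events is None:
        events = sorted({e for s in cohort["event_keys"] for e in s})
    from .case_processing import ROUTE_PRECEDENCE

    rank = {c: i for i, c in enumerate(ROUTE_PRECEDENCE)}
    rows = []
    for drug in drugs:
        for event in events:
            sub = cohort.loc[_group_mask(cohort, drug, event)]
            counts = {c: 0 for c in ROUTE_PRECEDENCE}
            for matches in sub["ps_drugs"]:
                classes = [m.route_class for m in matches if m.drug_key == drug]
                if classes:
                    counts[min(classes, key=rank.get)] += 1
            total = len(sub)
            for cls in ROUTE_PRECEDENCE:
                rows.append({"drug": drug, "event": event, "route": cls,
                             "count": counts[cls],
                             "pct_of_group": percentage(counts[cls], total)})
    return pd.DataFrame(rows)


def concomitant_top(cohort_pids: set[str], drug_table: pd.DataFrame,
                    top: int = 5) -> pd.DataFrame:
    """Most frequent co-reported non-primary-suspect drug names in the cohort."""
    sub = drug_table.loc[
        drug_table["primaryid"].isin(cohort_pids) & (drug_table["role_cod"] != "PS")
    ]
    counts = (
        sub["drugname"].str.strip().str.upper().value_counts().head(top)
    )
    return counts.rename_axis("drugname").reset_index(name="count")
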