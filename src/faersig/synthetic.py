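"""Synthetic FAERS quarters with controlled statistical structure.

The generator emulates the relational shape of a FAERS quarterly package —
reports keyed by PRIMARYID/CASEID with demographic fields, multiple drug rows
with role codes and routes, multiple reaction PTs, outcome codes, therapy
start dates, cross-version duplicates and partial/invalid dates — while the
statistical structure is fully controlled:

* every report draws one primary-suspect drug from a categorical marginal
  (study drugs at explicit prevalences, background drugs Zipf-weighted) and
  0-4 concomitant drugs;
* each target event occurs independently with its base rate, multiplied by a
  planted relative reporting rate ``lam`` when the report's PS drug carries a
  planted signal for that event, so 2x2 cell expectations have a closed form
  (:func:`expected_contingency`);
* background events arrive as a Poisson number of Zipf-weighted PTs;
* a configurable fraction of cases is emitted twice with the FDA-dedup
  resolvable structure (same CASEID, later FDA_DT, higher PRIMARYID), and a
  fraction of cases lands on the deleted-case list;
* therapy starts are uniform in-quarter; event dates are the start plus a
  log-normal delay in days, with configurable fractions of month-truncated,
  missing and negative (data-entry error) event dates to exercise the onset
  exclusion rules.

Identical config + seed give byte-identical output files.  The default
configuration emulates the reporting structure of a fluoroquinolone
tendinopathy study: six planted drug-event signals with tendonitis and
tendon-rupture-like onset profiles, predominantly oral administration, and a
demographic mixture of roughly 54% female reports with most patients aged
18-65.
"""

from __future__ import annotations

import datetime as _dt
from dataclasses import dataclass, field
from pathlib import Path
from typing import Mapping, Sequence

import numpy as np
import pandas as pd

from .faers_io import REQUIRED_COLUMNS, QuarterBundle
from .case_processing import DrugLexicon, TargetEventSet

__all__ = [
    "PlantedSignal", "SynthConfig", "generate_bundle", "generate_quarter",
    "write_bundle_faers", "expected_contingency", "quarter_dates",
]


@dataclass(frozen=True)
class PlantedSignal:
    """A planted drug-event disproportionality signal.

    ``lam`` multiplies the event's base reporting rate for reports whose
    primary-suspect drug is ``drug_key`` (lam >= 1; lam == 1 is a null pair).
    ``route_bias`` is the oral fraction among exposed reports; the onset
    delay for exposed reports with the event is log-normal with the given
    median (days) and log-scale dispersion.
    """

    drug_key: str
    event_key: str
    lam: float = 20.0
    route_bias: float = 0.9
    onset_median_days: float = 5.0
    onset_sigma: float = 1.2

    def __post_init__(self) -> None:
        if self.lam < 1:
            raise ValueError("planted lam must be >= 1")
        if not 0 <= self.route_bias <= 1:
            raise ValueError("route_bias must be in [0, 1]")
        if self.onset_median_days <= 0 or self.onset_sigma <= 0:
            raise ValueError("onset distribution parameters must be positive")


def _default_planted() -> tuple[PlantedSignal, ...]:
    """Six fluoroquinolone-tendinopathy signals with magnitudes and onset
    profiles shaped like the published reporting pattern (strong ciprofloxacin
    tendonitis signal with ~3-day median onset, weaker moxifloxacin signals
    with later onsets)."""
    return (
        PlantedSignal("ciprofloxacin", "tendonitis", 93.0, 0.92, 3.0, 1.3),
        PlantedSignal("ciprofloxacin", "tendon_rupture", 55.0, 0.88, 5.5, 1.3),
        PlantedSignal("levofloxacin", "tendonitis", 88.0, 0.90, 4.0, 1.3),
        PlantedSignal("levofloxacin", "tendon_rupture", 74.0, 0.86, 3.0, 1.3),
        PlantedSignal("moxifloxacin", "tendonitis", 28.0, 0.85, 16.5, 1.3),
        PlantedSignal("moxifloxacin", "tendon_rupture", 17.0, 0.82, 18.0, 1.3),
    )


@dataclass(frozen=True)
class SynthConfig:
    """Configuration of one synthetic quarter.

    Study-drug prevalences and target-event base rates are per-report
    probabilities in the deduplicated universe; background drug/event
    marginals follow a Zipf law.  All rates are in [0, 1].
    """

    n_reports: int = 20_000
    n_background_drugs: int = 150
    n_background_events: int = 300
    drug_zipf: float = 1.4
    event_zipf: float = 1.4
    study_drug_prob: Mapping[str, float] = field(default_factory=lambda: {
        "ciprofloxacin": 0.010, "levofloxacin": 0.009, "moxifloxacin": 0.004,
    })
    target_event_base_rate: Mapping[str, float] = field(default_factory=lambda: {
        "tendonitis": 0.0010, "tendon_rupture": 0.0007,
    })
    planted: tuple[PlantedSignal, ...] = field(default_factory=_default_planted)
    mean_background_events: float = 1.6
    mean_concomitant_drugs: float = 1.2
    duplicate_rate: float = 0.05
    deleted_rate: float = 0.002
    partial_date_rate: float = 0.10
    missing_event_dt_rate: float = 0.30
    missing_start_dt_rate: float = 0.10
    negative_onset_rate: float = 0.02
    missing_age_rate: float = 0.18
    missing_sex_rate: float = 0.08
    missing_route_rate: float = 0.05
    female_share: float = 0.54
    age_band_probs: tuple[float, float, float] = (0.015, 0.72, 0.265)
    country_weights: Mapping[str, float] = field(default_factory=lambda: {
        "US": 0.48, "FR": 0.10, "GB": 0.08, "DE": 0.07, "JP": 0.05,
        "CA": 0.05, "IT": 0.04, "ES": 0.03, "CN": 0.03, "AU": 0.03,
        "BR": 0.02, "ZA": 0.02,
    })
    outcome_probs_target: Mapping[str, float] = field(default_factory=lambda: {
        "DS": 0.45, "HO": 0.20, "OT": 0.55, "LT": 0.02, "DE": 0.005,
        "RI": 0.01, "CA": 0.001,
    })
    outcome_probs_background: Mapping[str, float] = field(default_factory=lambda: {
        "HO": 0.15, "OT": 0.25, "DE": 0.01,
    })
    infection_indication_share: float = 0.75
    unknown_indication_share: float = 0.12
    seed: int = 0

    def __post_init__(self) -> None:
        if self.n_reports < 1:
            raise ValueError("n_reports must be >= 1")
        rates = {
            "duplicate_rate": self.duplicate_rate,
            "deleted_rate": self.deleted_rate,
            "partial_date_rate": self.partial_date_rate,
            "missing_event_dt_rate": self.missing_event_dt_rate,
            "missing_start_dt_rate": self.missing_start_dt_rate,
            "negative_onset_rate": self.negative_onset_rate,
            "missing_age_rate": self.missing_age_rate,
            "missing_sex_rate": self.missing_sex_rate,
            "missing_route_rate": self.missing_route_rate,
            "female_share": self.female_share,
            "infection_indication_share": self.infection_indication_share,
            "unknown_indication_share": self.unknown_indication_share,
        }
        for name, value in rates.items():
            if not 0 <= value <= 1:
                raise ValueError(f"{name} must be in [0, 1], got {value}")
        for key, p in {**self.study_drug_prob,
                       **self.target_event_base_rate}.items():
            if not 0 <= p <= 1:
                raise ValueError(f"probability for {key} out of [0, 1]")
        if sum(self.study_drug_prob.values()) >= 1:
            raise ValueError("study drug probabilities must sum below 1")
        for sig in self.planted:
            if sig.drug_key not in self.study_drug_prob:
                raise ValueError(f"planted drug {sig.drug_key} has no prevalence")
            if sig.event_key not in self.target_event_base_rate:
                raise ValueError(f"planted event {sig.event_key} has no base rate")
            if sig.lam * self.target_event_base_rate[sig.event_key] > 1:
                raise ValueError("lam * base rate exceeds 1")


def quarter_dates(label: str) -> tuple[_dt.date, _dt.date]:
    """First and last calendar day of a quarter tag like ``2016Q1``."""
    year, q = int(label[:4]), int(label[5])
    start = _dt.date(year, 3 * (q - 1) + 1, 1)
    if q == 4:
        end = _dt.date(year, 12, 31)
    else:
        end = _dt.date(year, 3 * q + 1, 1) - _dt.timedelta(days=1)
    return start, end


def _zipf_weights(n: int, s: float) -> np.ndarray:
    ranks = np.arange(1, n + 1, dtype=float)
    w = ranks ** (-s)
    return w / w.sum()


def _fmt(dates: np.ndarray) -> np.ndarray:
    """yyyymmdd strings from datetime64[D]."""
    return (
        pd.Series(dates.astype("datetime64[ns]")).dt.strftime("%Y%m%d").to_numpy()
    )


def generate_bundle(config: SynthConfig, label: str = "2016Q1") -> QuarterBundle:
    """Generate one synthetic quarter in memory (see module docstring).

    Deterministic: the same config and label always return the same bundle.
    """
    rng = np.random.default_rng(config.seed)
    lexicon = DrugLexicon.default()
    events = TargetEventSet.default()
    n = config.n_reports
    q_start, q_end = quarter_dates(label)
    q0 = np.datetime64(q_start.isoformat())
    q_days = (q_end - q_start).days + 1

    study_keys = [k for k in config.study_drug_prob]
    study_p = np.array([config.study_drug_prob[k] for k in study_keys])
    n_drugs = len(study_keys) + config.n_background_drugs
    p_drug = np.empty(n_drugs)
    p_drug[: len(study_keys)] = study_p
    p_drug[len(study_keys):] = (1 - study_p.sum()) * _zipf_weights(
        config.n_background_drugs, config.drug_zipf
    )
    drug_names = [sorted(lexicon.entries[k])[0] for k in study_keys] + [
        f"BACKGROUND DRUG {i:04d}" for i in range(config.n_background_drugs)
    ]
    # a couple of verbatim spellings per study drug to exercise the matcher
    verbatim: dict[int, list[str]] = {}
    for i, key in enumerate(study_keys):
        generic = key.upper()
        trade = [nm for nm in sorted(lexicon.entries[key]) if nm != generic]
        verbatim[i] = [generic, f"{generic} 500MG TABLET"] + trade[:2]

    target_keys = list(config.target_event_base_rate)
    target_pt = {k: events.events[k][0] for k in target_keys
                 if k in events.events}
    lam = np.ones((n_drugs, len(target_keys)))
    sig_by_pair = {}
    for sig in config.planted:
        di = study_keys.index(sig.drug_key)
        ei = target_keys.index(sig.event_key)
        lam[di, ei] = sig.lam
        sig_by_pair[(di, ei)] = sig
    route_bias = {i: 0.85 for i in range(len(study_keys))}
    for sig in config.planted:
        route_bias[study_keys.index(sig.drug_key)] = sig.route_bias

    # ---- per-report draws -------------------------------------------------
    ps_idx = rng.choice(n_drugs, size=n, p=p_drug)
    base = np.array([config.target_event_base_rate[k] for k in target_keys])
    p_event = np.minimum(lam[ps_idx] * base, 1.0)          # (n, n_target)
    target_hit = rng.random((n, len(target_keys))) < p_event

    n_bg_events = rng.poisson(config.mean_background_events, size=n)
    total_bg = int(n_bg_events.sum())
    bg_event_pool = rng.choice(
        config.n_background_events, size=total_bg,
        p=_zipf_weights(config.n_background_events, config.event_zipf),
    )
    bg_offsets = np.concatenate([[0], np.cumsum(n_bg_events)])

    n_con = np.minimum(rng.poisson(config.mean_concomitant_drugs, size=n), 4)
    total_con = int(n_con.sum())
    con_pool = rng.choice(n_drugs, size=total_con, p=p_drug)
    con_offsets = np.concatenate([[0], np.cumsum(n_con)])

    sex_missing = rng.random(n) < config.missing_sex_rate
    sex_female = rng.random(n) < config.female_share
    age_missing = rng.random(n) < config.missing_age_rate
    band = rng.choice(3, size=n, p=np.array(config.age_band_probs)
                      / sum(config.age_band_probs))
    age_years = np.select(
        [band == 0, band == 1, band == 2],
        [rng.integers(2, 18, size=n), rng.integers(18, 66, size=n),
         rng.integers(66, 96, size=n)],
    ).astype(int)
    age_in_months = rng.random(n) < 0.03
    countries = rng.choice(
        list(config.country_weights), size=n,
        p=np.array(list(config.country_weights.values()))
        / sum(config.country_weights.values()),
    )
    occp = rng.choice(["MD", "PH", "HP", "OT", "CN", "LW", ""], size=n,
                      p=[0.12, 0.04, 0.06, 0.14, 0.55, 0.01, 0.08])

    fda_dt = _fmt(q0 + rng.integers(0, q_days, size=n).astype("timedelta64[D]"))
    start_day = rng.integers(0, q_days, size=n)
    start_dates = q0 + start_day.astype("timedelta64[D]")
    start_dt = _fmt(start_dates)

    # onset delay: planted profile when the PS drug + event pair is planted
    delay_median = np.full(n, 10.0)
    delay_sigma = np.full(n, 1.0)
    for (di, ei), sig in sig_by_pair.items():
        mask = (ps_idx == di) & target_hit[:, ei]
        delay_median[mask] = sig.onset_median_days
        delay_sigma[mask] = sig.onset_sigma
    delays = np.round(
        rng.lognormal(np.log(delay_median), delay_sigma)
    ).astype(int)
    negative = rng.random(n) < config.negative_onset_rate
    delays[negative] = -rng.integers(1, 30, size=int(negative.sum()))
    event_dates = start_dates + delays.astype("timedelta64[D]")
    event_dt = _fmt(event_dates)
    truncate = rng.random(n) < config.partial_date_rate
    missing_ev = rng.random(n) < config.missing_event_dt_rate
    missing_start = rng.random(n) < config.missing_start_dt_rate

    is_study = ps_idx < len(study_keys)
    bias = np.array([route_bias.get(i, 0.0) for i in range(len(study_keys))])
    r = rng.random(n)
    oral = np.zeros(n, dtype=bool)
    oral[is_study] = r[is_study] < bias[ps_idx[is_study]]
    iv_pool = ["INTRAVENOUS", "INTRAVENOUS DRIP", "INTRAVENOUS BOLUS"]
    route_draw = rng.choice(iv_pool + ["TOPICAL", "OPHTHALMIC", "UNKNOWN"],
                            size=n, p=[0.35, 0.15, 0.10, 0.15, 0.15, 0.10])
    route_missing = rng.random(n) < config.missing_route_rate
    verbatim_pick = rng.integers(0, 4, size=n)

    dup = rng.random(n) < config.duplicate_rate
    deleted_mask = rng.random(n) < config.deleted_rate
    # the duplicate version carries a strictly later FDA receipt date
    dup_gap = rng.integers(1, 30, size=n)
    dup_fda = pd.Series(
        pd.to_datetime(fda_dt, format="%Y%m%d")
        + pd.to_timedelta(dup_gap, unit="D")
    ).dt.strftime("%Y%m%d").to_numpy()

    outc_codes = sorted(set(config.outcome_probs_target)
                        | set(config.outcome_probs_background))
    p_out_t = np.array([config.outcome_probs_target.get(c, 0.0)
                        for c in outc_codes])
    p_out_b = np.array([config.outcome_probs_background.get(c, 0.0)
                        for c in outc_codes])
    any_target = target_hit.any(axis=1)
    outc_hit = rng.random((n, len(outc_codes))) < np.where(
        any_target[:, None], p_out_t[None, :], p_out_b[None, :]
    )

    infection_pts = ["Urinary tract infection", "Pneumonia", "Sinusitis",
                     "Bronchitis", "Cystitis"]
    other_pts = ["Hypertension", "Pain", "Prophylaxis"]
    indi_class_draw = rng.random(n)
    indi_pick = rng.integers(0, 5, size=n)

    # ---- row assembly -----------------------------------------------------
    demo_rows, drug_rows, reac_rows, outc_rows, ther_rows, indi_rows = \
        [], [], [], [], [], []
    deleted_caseids: set[str] = set()

    for i in range(n):
        caseid = str(90_000_000 + i)
        versions = [(f"{caseid}1", fda_dt[i])]
        if dup[i]:
            versions.append((f"{caseid}2", dup_fda[i]))
        if deleted_mask[i]:
            deleted_caseids.add(caseid)

        ev_raw = "" if missing_ev[i] else (
            event_dt[i][:6] if truncate[i] else event_dt[i]
        )
        st_raw = "" if missing_start[i] else start_dt[i]
        age_val = "" if age_missing[i] else (
            str(age_years[i] * 12) if age_in_months[i] else str(age_years[i])
        )
        age_cod = "" if age_missing[i] else ("MON" if age_in_months[i] else "YR")
        sex = "" if sex_missing[i] else ("F" if sex_female[i] else "M")

        di = ps_idx[i]
        if is_study[i]:
            options = verbatim[di]
            name = options[verbatim_pick[i] % len(options)]
            prod_ai = study_keys[di].upper()
            if oral[i]:
                route = "ORAL"
            elif route_missing[i]:
                route = ""
            else:
                route = route_draw[i]
        else:
            name = drug_names[di]
            prod_ai = ""
            route = "" if route_missing[i] else (
                "ORAL" if r[i] < 0.6 else route_draw[i]
            )

        events_here: list[str] = [
            target_pt[target_keys[ei]]
            for ei in range(len(target_keys)) if target_hit[i, ei]
        ]
        seen_bg = set()
        for j in range(bg_offsets[i], bg_offsets[i + 1]):
            idx = int(bg_event_pool[j])
            if idx not in seen_bg:
                seen_bg.add(idx)
                events_here.append(f"Synthetic PT {idx:04d}")
        if not events_here:
            events_here.append("Synthetic PT 9999")

        if is_study[i]:
            if indi_class_draw[i] < config.infection_indication_share:
                indi_pt = infection_pts[indi_pick[i] % len(infection_pts)]
            elif indi_class_draw[i] < (config.infection_indication_share
                                       + config.unknown_indication_share):
                indi_pt = "Product used for unknown indication"
            else:
                indi_pt = other_pts[indi_pick[i] % len(other_pts)]
        else:
            indi_pt = ""

        for pid, fdt in versions:
            demo_rows.append((pid, caseid, ev_raw, fdt, age_val, age_cod,
                              sex, occp[i], countries[i], countries[i], fdt))
            drug_rows.append((pid, caseid, "1", "PS", name, prod_ai, route))
            seen_con = set()
            seq = 2
            for j in range(con_offsets[i], con_offsets[i + 1]):
                ci = int(con_pool[j])
                if ci == di or ci in seen_con:
                    continue
                seen_con.add(ci)
                drug_rows.append((pid, caseid, str(seq), "C",
                                  drug_names[ci], "", ""))
                seq += 1
            for pt in events_here:
                reac_rows.append((pid, caseid, pt))
            for k, code in enumerate(outc_codes):
                if outc_hit[i, k]:
                    outc_rows.append((pid, caseid, code))
            if st_raw:
                ther_rows.append((pid, caseid, "1", st_raw, ""))
            if indi_pt:
                indi_rows.append((pid, caseid, "1", indi_pt))

    def frame(name: str, rows: list[tuple]) -> pd.DataFrame:
        return pd.DataFrame(rows, columns=list(REQUIRED_COLUMNS[name]),
                            dtype=str)

    return QuarterBundle(
        label=label,
        demo=frame("demo", demo_rows),
        drug=frame("drug", drug_rows),
        reac=frame("reac", reac_rows),
        outc=frame("outc", outc_rows),
        ther=frame("ther", ther_rows),
        indi=frame("indi", indi_rows),
        deleted_caseids=frozenset(deleted_caseids),
    )


def write_bundle_faers(bundle: QuarterBundle, out_dir: str | Path) -> Path:
    """Write a bundle in the "$"-delimited FAERS ASCII dialect.

    File names embed the short quarter tag (DEMO16Q1.txt etc.); the
    deleted-case list, when non-empty, goes to DELETE<tag>.txt.
    """
    out = Path(out_dir)
    out.mkdir(parents=True, exist_ok=True)
    tag = bundle.label[2:].replace("q", "Q")
    for name in REQUIRED_COLUMNS:
        table = bundle.table(name)
        path = out / f"{name.upper()}{tag}.txt"
        with open(path, "w", encoding="utf-8", newline="\n") as fh:
            fh.write("$".join(table.columns) + "\n")
            for row in table.itertuples(index=False):
                fh.write("$".join(row) + "\n")
    if bundle.deleted_caseids:
        with open(out / f"DELETE{tag}.txt", "w", encoding="utf-8",
                  newline="\n") as fh:
            fh.write("caseid\n")
            for cid in sorted(bundle.deleted_caseids):
                fh.write(cid + "\n")
    return out


def generate_quarter(config: SynthConfig, label: str,
                     out_dir: str | Path) -> QuarterBundle:
    """Generate a synthetic quarter and write it as FAERS-dialect files."""
    bundle = generate_bundle(config, label)
    write_bundle_faers(bundle, out_dir)
    return bundle


def expected_contingency(config: SynthConfig, drug_key: str,
                         event_key: str) -> tuple[float, float, float, float]:
    """Closed-form expected 2x2 cells for one study drug-target event pair.

    Expectations are over the *deduplicated* universe: duplicates collapse
    back onto their case, and deleted cases shrink the universe by the
    deletion rate.  With per-report PS probability p_D and event probability
    min(1, lam * p_e) given the PS drug:

        E[a] = N' p_D P(e|D),  E[b] = N' p_D (1 - P(e|D)),
        E[c] = N' sum_{D' != D} p_D' P(e|D'),  E[d] = N' - E[a+b+c].
    """
    if drug_key not in config.study_drug_prob:
        raise ValueError(f"unknown study drug {drug_key}")
    if event_key not in config.target_event_base_rate:
        raise ValueError(f"unknown target event {event_key}")
    n_eff = config.n_reports * (1 - config.deleted_rate)
    base = config.target_event_base_rate[event_key]
    lam_by_drug = {k: 1.0 for k in config.study_drug_prob}
    for sig in config.planted:
        if sig.event_key == event_key:
            lam_by_drug[sig.drug_key] = sig.lam
    p_d = config.study_drug_prob[drug_key]
    p_e_given_d = min(1.0, lam_by_drug[drug_key] * base)
    a = n_eff * p_d * p_e_given_d
    b = n_eff * p_d * (1 - p_e_given_d)
    c = 0.0
    for other, p in config.study_drug_prob.items():
        if other != drug_key:
            c += n_eff * p * min(1.0, lam_by_drug[other] * base)
    p_background = 1 - sum(config.study_drug_prob.values())
    c += n_eff * p_background * base
    d = n_eff - a - b - c
    return a, b, c, d
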