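"""End-to-end orchestration: read -> dedup -> cohort -> signals -> descriptive.

Every number in the report CSVs comes from the underlying module operations;
this module only sequences them and writes artifacts.  Outputs:

* ``table1_characteristics.csv`` — clinical-characteristics blocks
* ``table2_signals.csv`` — unstratified drug-event screen
* ``table3_route_signals.csv`` — oral/intravenous stratified screen
* ``table4_onset.csv`` — onset quartiles per drug-event pair
* ``figure2_histogram.csv`` — onset histogram counts
* ``outcomes.csv`` — serious-outcome proportions
* ``flowchart_counts.json`` — report-flow counts (raw, deduplicated, cohort)
* ``metadata.json`` — thresholds, formula variants, window, versions
"""

from __future__ import annotations

import datetime as _dt
import json
import logging
from dataclasses import dataclass, field
from pathlib import Path
from typing import Mapping, Sequence

import pandas as pd

from . import __version__
from .case_processing import (
    DrugLexicon,
    StudyData,
    TargetEventSet,
    build_study_data,
)
from .descriptive import (
    compute_onset,
    onset_histogram,
    summarize_characteristics,
    summarize_onset_all,
    summarize_outcomes,
)
from .faers_io import QuarterBundle, read_quarter, write_table
from .signal_stats import (
    DEFAULT_CRITERIA,
    METHOD_VARIANTS,
    StratumSpec,
    round_for_report,
    run_signal_screen,
)

logger = logging.getLogger(__name__)

#: default onset histogram edges (days): within a month, then widening spans
DEFAULT_ONSET_BINS = (0, 8, 15, 31, 61, 91, 181, 366, 1096)

DEFAULT_WINDOW = (_dt.date(2016, 1, 1), _dt.date(2021, 3, 31))


@dataclass
class PipelineConfig:
    """Configuration of one full pipeline run.

    ``quarters`` maps quarter labels to archive directories.  The default
    study window covers 2016-01-01 .. 2021-03-31.
    """

    quarters: Mapping[str, str | Path]
    output_dir: str | Path = "faersig_out"
    window: tuple[_dt.date, _dt.date] = DEFAULT_WINDOW
    lexicon_path: str | Path | None = None
    events_path: str | Path | None = None
    criteria: dict = field(default_factory=dict)
    strata: tuple[StratumSpec, ...] = (
        StratumSpec("sex", "F"), StratumSpec("sex", "M"),
        StratumSpec("age_group", "18-65"), StratumSpec("age_group", ">65"),
    )
    route_strata: tuple[StratumSpec, ...] = (
        StratumSpec("route", "oral"), StratumSpec("route", "intravenous"),
    )
    onset_bins: Sequence[float] = DEFAULT_ONSET_BINS

    def __post_init__(self) -> None:
        if self.window[0] >= self.window[1]:
            raise ValueError("window start must precede window end")

    @classmethod
    def from_dict(cls, raw: Mapping) -> "PipelineConfig":
        kwargs = dict(raw)
        if "window" in kwargs:
            lo, hi = kwargs["window"]
            kwargs["window"] = (_dt.date.fromisoformat(str(lo)),
                                _dt.date.fromisoformat(str(hi)))
        for key in ("strata", "route_strata"):
            if key in kwargs:
                kwargs[key] = tuple(
                    StratumSpec(s["axis"], s["level"]) for s in kwargs[key]
                )
        return cls(**kwargs)


@dataclass
class PipelineResult:
    """Artifacts of one pipeline run (frames plus the output directory)."""

    study: StudyData
    signals: pd.DataFrame
    route_signals: pd.DataFrame
    characteristics: pd.DataFrame
    outcomes: pd.DataFrame
    onset_summary: pd.DataFrame
    onset_hist: pd.DataFrame
    flow_counts: dict
    output_dir: Path


def run_pipeline(config: PipelineConfig,
                 bundles: Sequence[QuarterBundle] | None = None) -> PipelineResult:
    """Execute the full pipeline and write all report artifacts.

    ``bundles`` may be supplied directly (e.g. synthetic quarters held in
    memory); otherwise each configured quarter directory is parsed.
    """
    lexicon = (DrugLexicon.from_csv(config.lexicon_path)
               if config.lexicon_path else DrugLexicon.default())
    events = (TargetEventSet.from_csv(config.events_path)
              if config.events_path else TargetEventSet.default())

    if bundles is None:
        bundles = []
        for label, path in config.quarters.items():
            logger.info("reading quarter %s from %s", label, path)
            bundles.append(read_quarter(path, label))

    study = build_study_data(bundles, lexicon, events, config.window)
    drugs = list(lexicon.drug_keys)
    event_keys = list(events.event_keys)

    signals = run_signal_screen(study.universe, drugs, event_keys,
                                config.strata, config.criteria)
    route_signals = run_signal_screen(
        study.universe, drugs, event_keys, config.route_strata, config.criteria
    )
    route_signals = route_signals.loc[
        route_signals["stratum_axis"] == "route"
    ].reset_index(drop=True)

    characteristics = summarize_characteristics(study.cohort, drugs, event_keys) \
        if len(study.cohort) else pd.DataFrame(
            columns=["drug", "event", "block", "level", "count", "value"])
    outcomes = summarize_outcomes(study.cohort, drugs, event_keys) \
        if len(study.cohort) else pd.DataFrame()
    onsets, onset_exclusions = (compute_onset(study.cohort)
                                if len(study.cohort) else ([], {}))
    onset_summary = summarize_onset_all(onsets) if onsets else pd.DataFrame(
        columns=["drug", "event", "n_valid", "q1", "median", "q3"])
    onset_hist = onset_histogram(onsets, config.onset_bins) if onsets else \
        pd.DataFrame(columns=["drug", "event", "bin_lo", "bin_hi", "count"])

    flow = dict(study.flow_counts)
    flow["onset_valid"] = len(onsets)
    flow["onset_excluded"] = dict(onset_exclusions)

    out = Path(config.output_dir)
    out.mkdir(parents=True, exist_ok=True)
    write_table(characteristics, out / "table1_characteristics.csv")
    write_table(round_for_report(signals), out / "table2_signals.csv")
    write_table(round_for_report(route_signals), out / "table3_route_signals.csv")
    write_table(onset_summary, out / "table4_onset.csv")
    write_table(onset_hist, out / "figure2_histogram.csv")
    write_table(outcomes, out / "outcomes.csv")
    (out / "flowchart_counts.json").write_text(
        json.dumps(flow, indent=2, sort_keys=True) + "\n")

    criteria = dict(DEFAULT_CRITERIA)
    criteria.update(config.criteria)
    metadata = {
        "package": "faersig",
        "version": __version__,
        "window": [config.window[0].isoformat(), config.window[1].isoformat()],
        "quarters": sorted(str(k) for k in config.quarters) if config.quarters
        else [b.label for b in bundles],
        "criteria": criteria,
        "method_variants": METHOD_VARIANTS,
        "quartile_rule": "median-of-halves (halves exclude the middle element at odd n)",
        "onset_bins": list(config.onset_bins),
    }
    (out / "metadata.json").write_text(
        json.dumps(metadata, indent=2, sort_keys=True) + "\n")
    return PipelineResult(
        study=study, signals=signals, route_signals=route_signals,
        characteristics=characteristics, outcomes=outcomes,
        onset_summary=onset_summary, onset_hist=onset_hist,
        flow_counts=flow, output_dir=out,
    )
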