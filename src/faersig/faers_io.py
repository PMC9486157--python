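"""Reading and writing FAERS ASCII quarterly packages.

FAERS quarterly packages ship as "$"-delimited text files, one per table
(DEMO, DRUG, REAC, OUTC, THER, INDI), first line a header.  The dialect has
no quoting and the delimiter cannot occur inside a field, so naive splitting
is exact.  Only the post-2014 (PRIMARYID-era) layout is supported.

Dates in FAERS are raw 4/6/8-digit strings with no guarantee of validity;
they are kept verbatim here and parsed lazily with :func:`parse_partial_date`
because different analyses need different precisions (deduplication needs
only FDA_DT ordering, onset analysis needs full day precision).
"""

from __future__ import annotations

import datetime as _dt
import logging
from dataclasses import dataclass, field
from enum import Enum
from pathlib import Path
from typing import Iterable, Mapping, Sequence

import pandas as pd

logger = logging.getLogger(__name__)

DELIMITER = "$"

#: role codes a DRUG row may carry (primary suspect, secondary suspect,
#: concomitant, interacting)
ROLE_CODES = frozenset({"PS", "SS", "C", "I"})

#: the seven FAERS outcome codes (death, life-threatening, hospitalisation,
#: disability, congenital anomaly, required intervention, other serious)
OUTCOME_CODES = frozenset({"DE", "LT", "HO", "DS", "CA", "RI", "OT"})

#: age unit codes accepted in DEMO
AGE_CODES = frozenset({"YR", "MON", "WK", "DY", "HR", "DEC"})

#: columns each table must provide (extra columns in real FAERS headers are
#: tolerated and dropped)
REQUIRED_COLUMNS: Mapping[str, tuple[str, ...]] = {
    "demo": (
        "primaryid", "caseid", "event_dt", "fda_dt", "age", "age_cod",
        "sex", "occp_cod", "reporter_country", "occr_country", "rept_dt",
    ),
    "drug": ("primaryid", "caseid", "drug_seq", "role_cod", "drugname",
             "prod_ai", "route"),
    "reac": ("primaryid", "caseid", "pt"),
    "outc": ("primaryid", "caseid", "outc_cod"),
    "ther": ("primaryid", "caseid", "dsg_drug_seq", "start_dt", "end_dt"),
    "indi": ("primaryid", "caseid", "indi_drug_seq", "indi_pt"),
}

TABLE_NAMES = tuple(REQUIRED_COLUMNS)


class DatePrecision(str, Enum):
    """Precision of a FAERS partial date."""

    DAY = "day"
    MONTH = "month"
    YEAR = "year"
    INVALID = "invalid"


@dataclass(frozen=True)
class PartialDate:
    """A FAERS date parsed to whatever precision the raw string supports.

    ``date`` is the first calendar day consistent with the raw string
    (e.g. ``"201801"`` -> 2018-01-01 at month precision) and is ``None``
    when the string is invalid.
    """

    date: _dt.date | None
    precision: DatePrecision

    @property
    def is_valid(self) -> bool:
        return self.precision is not DatePrecision.INVALID

    def sort_key(self) -> tuple[int, int, int]:
        """Chronological key; invalid dates sort first."""
        if self.date is None:
            return (0, 0, 0)
        return (self.date.year, self.date.month, self.date.day)


def parse_partial_date(raw: object) -> PartialDate:
    """Parse a raw FAERS date string to a calendar date plus precision flag.

    8 valid digits -> day precision, 6 -> month, 4 -> year; anything else
    (empty, non-digit, impossible dates like ``20180230``) -> invalid.
    Total: never raises.
    """
    if raw is None:
        return PartialDate(None, DatePrecision.INVALID)
    s = str(raw).strip()
    if not s.isdigit():
        return PartialDate(None, DatePrecision.INVALID)
    try:
        if len(s) == 8:
            return PartialDate(
                _dt.date(int(s[:4]), int(s[4:6]), int(s[6:8])),
                DatePrecision.DAY,
            )
        if len(s) == 6:
            return PartialDate(
                _dt.date(int(s[:4]), int(s[4:6]), 1), DatePrecision.MONTH
            )
        if len(s) == 4:
            year = int(s)
            if not 1 <= year <= 9999:
                return PartialDate(None, DatePrecision.INVALID)
            return PartialDate(_dt.date(year, 1, 1), DatePrecision.YEAR)
    except ValueError:
        return PartialDate(None, DatePrecision.INVALID)
    return PartialDate(None, DatePrecision.INVALID)


@dataclass
class QuarterBundle:
    """The six parsed tables of one FAERS quarter plus deleted-case ids.

    ``parse_log`` maps ``table -> {"raw_rows": n, "kept": n, "dropped_malformed": n,
    "dropped_invalid": n, "dropped_orphan": n}`` so row-count conservation can
    be audited: raw_rows == kept + all drops for every table.
    """

    label: str
    demo: pd.DataFrame
    drug: pd.DataFrame
    reac: pd.DataFrame
    outc: pd.DataFrame
    ther: pd.DataFrame
    indi: pd.DataFrame
    deleted_caseids: frozenset[str] = frozenset()
    parse_log: dict[str, dict[str, int]] = field(default_factory=dict)

    def table(self, name: str) -> pd.DataFrame:
        return getattr(self, name)

    def equals(self, other: "QuarterBundle") -> bool:
        return (
            self.label == other.label
            and self.deleted_caseids == other.deleted_caseids
            and all(
                self.table(t).reset_index(drop=True).equals(
                    other.table(t).reset_index(drop=True)
                )
                for t in TABLE_NAMES
            )
        )


class FaersIOError(RuntimeError):
    """Fatal problem with a FAERS archive (missing file, no parsable rows)."""


def _read_dollar_file(path: Path) -> tuple[pd.DataFrame, int, int]:
    """Split a "$"-delimited file on the header's field count.

    Returns (frame with lowercase columns, raw data-line count,
    malformed-row count).  Rows whose field count differs from the header
    are dropped and counted, never repaired.
    """
    with open(path, "r", encoding="utf-8", errors="replace") as fh:
        lines = fh.read().splitlines()
    if not lines:
        raise FaersIOError(f"{path}: empty file (no header)")
    header = [c.strip().lower() for c in lines[0].split(DELIMITER)]
    n_fields = len(header)
    rows: list[list[str]] = []
    malformed = 0
    raw = 0
    for line in lines[1:]:
        if line == "":
            continue
        raw += 1
        parts = line.split(DELIMITER)
        if len(parts) != n_fields:
            malformed += 1
            continue
        rows.append([p.strip() for p in parts])
    frame = pd.DataFrame(rows, columns=header, dtype=str)
    return frame, raw, malformed


def _validate_table(name: str, frame: pd.DataFrame) -> tuple[pd.DataFrame, int]:
    """Keep required columns and drop rows violating per-table invariants."""
    required = REQUIRED_COLUMNS[name]
    missing = [c for c in required if c not in frame.columns]
    if missing:
        raise FaersIOError(f"{name.upper()} file lacks required columns: {missing}")
    frame = frame.loc[:, list(required)].fillna("")

    ok = (frame["primaryid"] != "") & (frame["caseid"] != "")
    if name == "demo":
        ok &= frame["age_cod"].isin(AGE_CODES) | (frame["age_cod"] == "")
    elif name == "drug":
        ok &= frame["role_cod"].isin(ROLE_CODES) | (frame["role_cod"] == "")
    elif name == "reac":
        ok &= frame["pt"] != ""
    elif name == "outc":
        ok &= frame["outc_cod"].isin(OUTCOME_CODES)
    elif name == "ther":
        ok &= (frame["dsg_drug_seq"] == "") | frame["dsg_drug_seq"].str.fullmatch(
            r"\d+"
        ).fillna(False)
    dropped = int((~ok).sum())
    return frame.loc[ok].reset_index(drop=True), dropped


def _find_table_file(archive: Path, name: str, label: str) -> Path | None:
    """Locate e.g. DRUG16Q1.txt for table "drug", quarter "2016Q1"."""
    short = label[2:].upper() if len(label) == 6 else label.upper()  # 2016Q1 -> 16Q1
    candidates = sorted(archive.glob("*.txt")) + sorted(archive.glob("*.TXT"))
    for p in candidates:
        stem = p.stem.upper()
        if stem.startswith(name.upper()) and (short in stem or label.upper() in stem):
            return p
    # fall back to name-only match (single-quarter directories)
    for p in candidates:
        if p.stem.upper().startswith(name.upper()):
            return p
    return None


def read_quarter(archive_path: str | Path, label: str) -> QuarterBundle:
    """Parse one FAERS quarterly archive directory into a :class:`QuarterBundle`.

    Parameters
    ----------
    archive_path
        Directory containing the "$"-delimited text files whose names embed
        DEMO/DRUG/REAC/OUTC/THER/INDI and the quarter tag (e.g. DEMO16Q1.txt).
    label
        Quarter tag such as ``"2016Q1"``.

    Raises
    ------
    FaersIOError
        If a mandatory table file is missing or contains zero parsable rows.
    """
    archive = Path(archive_path)
    if not archive.is_dir():
        raise FaersIOError(f"archive path {archive} is not a directory")

    tables: dict[str, pd.DataFrame] = {}
    log: dict[str, dict[str, int]] = {}
    for name in TABLE_NAMES:
        path = _find_table_file(archive, name, label)
        if path is None:
            raise FaersIOError(f"missing mandatory file for table {name.upper()} in {archive}")
        frame, raw, malformed = _read_dollar_file(path)
        frame, invalid = _validate_table(name, frame)
        if raw > 0 and len(frame) == 0:
            raise FaersIOError(f"{path}: zero parsable rows")
        if raw == 0:
            raise FaersIOError(f"{path}: file has no data rows")
        tables[name] = frame
        log[name] = {
            "raw_rows": raw,
            "kept": len(frame),
            "dropped_malformed": malformed,
            "dropped_invalid": invalid,
            "dropped_orphan": 0,
        }
        if malformed or invalid:
            logger.warning(
                "%s: dropped %d malformed and %d invalid rows",
                path.name, malformed, invalid,
            )

    # orphan check: every non-DEMO row must reference a DEMO primaryid
    demo_ids = set(tables["demo"]["primaryid"])
    for name in TABLE_NAMES:
        if name == "demo":
            continue
        frame = tables[name]
        mask = frame["primaryid"].isin(demo_ids)
        orphans = int((~mask).sum())
        if orphans:
            logger.warning("%s: dropped %d orphan rows (primaryid not in DEMO)",
                           name.upper(), orphans)
            tables[name] = frame.loc[mask].reset_index(drop=True)
            log[name]["dropped_orphan"] = orphans
            log[name]["kept"] -= orphans

    deleted = _read_deleted_cases(archive, label)
    return QuarterBundle(label=label, deleted_caseids=deleted, parse_log=log, **tables)


def _read_deleted_cases(archive: Path, label: str) -> frozenset[str]:
    """Deleted-case lists ship inconsistently across quarters; treat as optional."""
    for pattern in ("*DELETE*", "*delete*"):
        for p in sorted(archive.glob(pattern)):
            if not p.is_file():
                continue
            ids: set[str] = set()
            with open(p, "r", encoding="utf-8", errors="replace") as fh:
                for line in fh:
                    token = line.strip().split(DELIMITER)[0].strip()
                    if token.isdigit():
                        ids.add(token)
            return frozenset(ids)
    return frozenset()


def write_table(rows: pd.DataFrame | Iterable, path: str | Path,
                columns: Sequence[str] | None = None) -> Path:
    """Write a table as RFC-4180 CSV (header, UTF-8, deterministic column order).

    ``rows`` may be a DataFrame, an iterable of dataclasses, or an iterable of
    mappings; all must share a schema.
    """
    path = Path(path)
    if isinstance(rows, pd.DataFrame):
        frame = rows
    else:
        records = []
        for r in rows:
            if hasattr(r, "__dataclass_fields__"):
                records.append({k: getattr(r, k) for k in r.__dataclass_fields__})
            else:
                records.append(dict(r))
        frame = pd.DataFrame(records, columns=columns)
        if not records and columns is not None:
            frame = pd.DataFrame(columns=list(columns))
    if columns is not None:
        frame = frame.loc[:, list(columns)]
    path.parent.mkdir(parents=True, exist_ok=True)
    try:
        frame.to_csv(path, index=False, encoding="utf-8", lineterminator="\r\n")
    except OSError as exc:
        raise FaersIOError(f"cannot write {path}: {exc}") from exc
    return path
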