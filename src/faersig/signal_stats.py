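"""Disproportionality statistics on drug-event 2x2 contingency tables.

Against the deduplicated reporting background, each drug-event pair defines

    a = reports with drug and event     b = drug, other events
    c = other drugs, event              d = other drugs, other events

with N = a+b+c+d and expected count E = (a+b)(a+c)/N under independence.
Four classical measures are computed:

* ROR, reporting odds ratio ad/(bc), 95% CI by the log-normal approximation
  exp(ln ROR +/- 1.96 sqrt(1/a+1/b+1/c+1/d)).
* PRR, proportional reporting ratio [a/(a+b)]/[c/(c+d)], with the
  Yates-corrected Pearson chi-squared over the four cells.
* IC, the BCPNN information component log2((a+0.5)/(E+0.5)); its lower
  credibility bound IC025 uses Noren's observed-shrinkage approximation
  IC - 3.3 (a+0.5)^-1/2 - 2.0 (a+0.5)^-3/2.
* EBGM in the shrinkage-free closed form a/E (the MGPS empirical-Bayes prior
  fit over the whole database is out of scope); EBGM05 is the one-sided
  lower 5% bound EBGM exp(-1.64 sqrt(1/a+1/b+1/c+1/d)).

Tables with a zero cell return NaN ("undefined") for the statistics whose
preconditions fail; no continuity correction is applied, and undefined
statistics never flag positive.  All statistics are kept at full precision
internally and only rounded in output tables.
"""

from __future__ import annotations

import math
from dataclasses import asdict, dataclass
from typing import NamedTuple, Sequence

import numpy as np
import pandas as pd

#: default per-algorithm positivity criteria
DEFAULT_CRITERIA = {
    "ror_min_n": 3,       # ROR positive iff n >= 3 and ror_lo95 > 1
    "ror_lo_gt": 1.0,
    "prr_min_n": 3,       # PRR positive iff n >= 3, prr >= 2 and chi2 >= 4
    "prr_ge": 2.0,
    "chi2_ge": 4.0,
    "ic025_gt": 0.0,      # IC positive iff ic025 > 0
    "ebgm05_gt": 2.0,     # EBGM positive iff ebgm05 > 2
}

#: constants of the IC025 approximation
IC025_C1 = 3.3
IC025_C2 = 2.0
Z_TWO_SIDED_95 = 1.96
Z_ONE_SIDED_95 = 1.64

#: identifies the statistic variants in output metadata
METHOD_VARIANTS = {
    "ror": "log-normal 95% CI, z=1.96, no continuity correction",
    "prr": "Yates-corrected Pearson chi-squared",
    "ic": "IC = log2((a+0.5)/(E+0.5)); IC025 by Noren approximation (3.3, 2.0)",
    "ebgm": "closed form a/E without MGPS prior fitting; EBGM05 with z=1.64",
}


@dataclass(frozen=True)
class ContingencyTable:
    """2x2 cells of one drug-event pair against the database background."""

    a: int
    b: int
    c: int
    d: int

    def __post_init__(self) -> None:
        if min(self.a, self.b, self.c, self.d) < 0:
            raise ValueError("contingency cells must be non-negative")

    @property
    def n(self) -> int:
        return self.a + self.b + self.c + self.d

    @property
    def expected(self) -> float:
        """E = (a+b)(a+c)/N, the independence expectation of cell a."""
        if self.n == 0:
            return 0.0
        return (self.a + self.b) * (self.a + self.c) / self.n


class RorResult(NamedTuple):
    ror: float
    lo95: float
    hi95: float


class PrrResult(NamedTuple):
    prr: float
    chi2: float


class IcResult(NamedTuple):
    ic: float
    ic025: float


class EbgmResult(NamedTuple):
    ebgm: float
    ebgm05: float


def _se_log(t: ContingencyTable) -> float:
    return math.sqrt(1 / t.a + 1 / t.b + 1 / t.c + 1 / t.d)


def compute_ror(t: ContingencyTable) -> RorResult:
    """Reporting odds ratio with log-normal 95% CI; NaN on any zero cell."""
    if min(t.a, t.b, t.c, t.d) == 0:
        return RorResult(math.nan, math.nan, math.nan)
    ror = (t.a * t.d) / (t.b * t.c)
    half = Z_TWO_SIDED_95 * _se_log(t)
    return RorResult(ror, ror * math.exp(-half), ror * math.exp(half))


def compute_prr(t: ContingencyTable) -> PrrResult:
    """Proportional reporting ratio and Yates-corrected chi-squared.

    PRR is NaN when c == 0 or when the drug margin is empty; chi2 is NaN when
    any marginal expectation is zero.
    """
    if t.c == 0 or (t.a + t.b) == 0 or (t.c + t.d) == 0:
        return PrrResult(math.nan, _yates_chi2(t))
    prr = (t.a / (t.a + t.b)) / (t.c / (t.c + t.d))
    return PrrResult(prr, _yates_chi2(t))


def _yates_chi2(t: ContingencyTable) -> float:
    n = t.n
    if n == 0:
        return math.nan
    row = (t.a + t.b, t.c + t.d)
    col = (t.a + t.c, t.b + t.d)
    if 0 in row or 0 in col:
        return math.nan
    obs = ((t.a, t.b), (t.c, t.d))
    chi2 = 0.0
    for i in range(2):
        for j in range(2):
            exp = row[i] * col[j] / n
            dev = max(abs(obs[i][j] - exp) - 0.5, 0.0)  # correction floor
            chi2 += dev * dev / exp
    return chi2


def compute_ic(t: ContingencyTable) -> IcResult:
    """BCPNN information component with Noren's IC025 approximation.

    The +0.5 smoothing makes every table admissible (N > 0 required).
    """
    if t.n == 0:
        return IcResult(math.nan, math.nan)
    e = t.expected
    ic = math.log2((t.a + 0.5) / (e + 0.5))
    shrink = IC025_C1 / math.sqrt(t.a + 0.5) + IC025_C2 / (t.a + 0.5) ** 1.5
    return IcResult(ic, ic - shrink)


def compute_ebgm(t: ContingencyTable) -> EbgmResult:
    """Closed-form EBGM = a/E; EBGM05 = EBGM exp(-1.64 se); NaN when undefined.

    EBGM needs a > 0 and E > 0; the lower bound additionally needs all four
    cells positive (its standard error uses every cell).
    """
    e = t.expected
    if t.a == 0 or e == 0:
        return EbgmResult(math.nan, math.nan)
    ebgm = t.a / e
    if min(t.b, t.c, t.d) == 0:
        return EbgmResult(ebgm, math.nan)
    return EbgmResult(ebgm, ebgm * math.exp(-Z_ONE_SIDED_95 * _se_log(t)))


@dataclass
class SignalResult:
    """Four disproportionality statistics with bounds and positivity flags."""

    n_reports: int
    ror: float
    ror_lo95: float
    ror_hi95: float
    prr: float
    chi2: float
    ic: float
    ic025: float
    ebgm: float
    ebgm05: float
    flag_ror: bool = False
    flag_prr: bool = False
    flag_ic: bool = False
    flag_ebgm: bool = False
    flag_any: bool = False


def compute_signals(t: ContingencyTable,
                    criteria: dict | None = None) -> SignalResult:
    """All four statistics for one table, with positivity flags applied."""
    ror = compute_ror(t)
    prr = compute_prr(t)
    ic = compute_ic(t)
    ebgm = compute_ebgm(t)
    result = SignalResult(
        n_reports=t.a,
        ror=ror.ror, ror_lo95=ror.lo95, ror_hi95=ror.hi95,
        prr=prr.prr, chi2=prr.chi2,
        ic=ic.ic, ic025=ic.ic025,
        ebgm=ebgm.ebgm, ebgm05=ebgm.ebgm05,
    )
    return evaluate_criteria(result, t.a, criteria)


def evaluate_criteria(s: SignalResult, n: int,
                      criteria: dict | None = None) -> SignalResult:
    """Apply the per-algorithm signal criteria; any single positive algorithm
    makes the combined flag positive.  Undefined (NaN) statistics never flag."""
    crit = dict(DEFAULT_CRITERIA)
    if criteria:
        crit.update(criteria)

    def ok(x: float) -> bool:
        return isinstance(x, (int, float)) and not math.isnan(x)

    s.flag_ror = bool(n >= crit["ror_min_n"] and ok(s.ror_lo95)
                      and s.ror_lo95 > crit["ror_lo_gt"])
    s.flag_prr = bool(n >= crit["prr_min_n"] and ok(s.prr) and ok(s.chi2)
                      and s.prr >= crit["prr_ge"] and s.chi2 >= crit["chi2_ge"])
    s.flag_ic = bool(ok(s.ic025) and s.ic025 > crit["ic025_gt"])
    s.flag_ebgm = bool(ok(s.ebgm05) and s.ebgm05 > crit["ebgm05_gt"])
    s.flag_any = s.flag_ror or s.flag_prr or s.flag_ic or s.flag_ebgm
    return s


# ---------------------------------------------------------------------------
# screens over the study universe
# ---------------------------------------------------------------------------

@dataclass(frozen=True)
class StratumSpec:
    """A stratification request: an axis (sex/age_group/route/none) + level."""

    axis: str = "none"
    level: str = ""

    _VALUES = {
        "sex": {"F", "M", "unknown"},
        "age_group": {"<18", "18-65", ">65", "unknown"},
        "route": {"oral", "intravenous", "other", "unknown"},
        "none": {""},
    }

    def __post_init__(self) -> None:
        if self.axis not in self._VALUES:
            raise ValueError(f"unknown stratum axis {self.axis!r}")
        if self.level not in self._VALUES[self.axis]:
            raise ValueError(f"level {self.level!r} invalid for axis {self.axis!r}")


def build_contingency(has_drug: Sequence[bool] | pd.Series,
                      has_event: Sequence[bool] | pd.Series) -> ContingencyTable:
    """Count the 2x2 cells from per-report exposure/event flags."""
    drug = np.asarray(has_drug, dtype=bool)
    event = np.asarray(has_event, dtype=bool)
    if drug.shape != event.shape:
        raise ValueError("flag vectors differ in length")
    if drug.size == 0:
        raise ValueError("empty report universe")
    a = int(np.sum(drug & event))
    b = int(np.sum(drug & ~event))
    c = int(np.sum(~drug & event))
    d = int(np.sum(~drug & ~event))
    return ContingencyTable(a, b, c, d)


def run_signal_screen(
    universe: pd.DataFrame,
    drugs: Sequence[str],
    events: Sequence[str],
    strata: Sequence[StratumSpec] = (),
    criteria: dict | None = None,
) -> pd.DataFrame:
    """Screen every (drug, event, stratum) combination over the universe flags.

    ``universe`` is the flag table from
    :func:`faersig.case_processing.build_study_data`: one row per
    deduplicated report with ``drug__<key>``, ``route__<key>``,
    ``event__<key>``, ``sex`` and ``age_group`` columns.

    Sex and age strata restrict the whole background to the stratum; a route
    stratum instead restricts the *exposure* flag to reports whose matched PS
    drug was given by that route (the background stays whole), so cells b, c,
    d are always recomputed within the stratum's own universe.
    """
    specs: list[StratumSpec] = [StratumSpec()] + list(strata)
    rows = []
    for spec in specs:
        if spec.axis in ("sex", "age_group"):
            sub = universe.loc[universe[spec.axis] == spec.level]
        else:
            sub = universe
        for drug in drugs:
            if spec.axis == "route":
                has_drug = sub[f"drug__{drug}"] & (sub[f"route__{drug}"] == spec.level)
            else:
                has_drug = sub[f"drug__{drug}"]
            for event in events:
                row = {
                    "drug": drug,
                    "event": event,
                    "stratum_axis": spec.axis,
                    "stratum_level": spec.level,
                }
                if len(sub) == 0:
                    sig = SignalResult(0, *([math.nan] * 9))
                else:
                    t = build_contingency(has_drug, sub[f"event__{event}"])
                    sig = compute_signals(t, criteria)
                row.update(asdict(sig))
                row["n"] = row.pop("n_reports")
                rows.append(row)
    out = pd.DataFrame(rows)
    cols = ["drug", "event", "stratum_axis", "stratum_level", "n",
            "ror", "ror_lo95", "ror_hi95", "prr", "chi2", "ic", "ic025",
            "ebgm", "ebgm05", "flag_ror", "flag_prr", "flag_ic", "flag_ebgm",
            "flag_any"]
    out = out.loc[:, cols].sort_values(
        ["stratum_axis", "stratum_level", "drug", "event"], kind="mergesort"
    ).reset_index(drop=True)
    return out


def round_for_report(screen: pd.DataFrame, decimals: int = 2) -> pd.DataFrame:
    """Round the statistic columns for presentation (internals stay full precision)."""
    out = screen.copy()
    num = ["ror", "ror_lo95", "ror_hi95", "prr", "chi2", "ic", "ic025",
           "ebgm", "ebgm05"]
    out[num] = out[num].round(decimals)
    return out
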