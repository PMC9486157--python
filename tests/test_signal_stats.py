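"""Disproportionality formulas against an independent brute-force oracle."""

from __future__ import annotations

import itertools
import math

import numpy as np
import pandas as pd
import pytest
from scipy.stats import chi2_contingency

from faersig.signal_stats import (
    ContingencyTable,
    SignalResult,
    StratumSpec,
    build_contingency,
    compute_ebgm,
    compute_ic,
    compute_prr,
    compute_ror,
    compute_signals,
    evaluate_criteria,
    run_signal_screen,
)


# -- independent oracle: the published formulas, written straight down -------

def oracle(a, b, c, d):
    n = a + b + c + d
    e = (a + b) * (a + c) / n
    se = math.sqrt(1 / a + 1 / b + 1 / c + 1 / d)
    ror = (a * d) / (b * c)
    ic = math.log((a + 0.5) / (e + 0.5)) / math.log(2)
    return {
        "ror": ror,
        "ror_lo": ror * math.exp(-1.96 * se),
        "ror_hi": ror * math.exp(1.96 * se),
        "prr": (a / (a + b)) / (c / (c + d)),
        "ic": ic,
        "ic025": ic - 3.3 * (a + 0.5) ** -0.5 - 2.0 * (a + 0.5) ** -1.5,
        "ebgm": a / e,
        "ebgm05": (a / e) * math.exp(-1.64 * se),
    }


GRID = [1, 2, 3, 5, 9, 17, 30]


def test_oracle_equivalence_on_small_table_grid():
    """ror/prr/ic/ebgm match the brute-force formulas to 1e-9 relative."""
    for a, b, c, d in itertools.product(GRID, repeat=4):
        t = ContingencyTable(a, b, c, d)
        exp = oracle(a, b, c, d)
        ror = compute_ror(t)
        assert ror.ror == pytest.approx(exp["ror"], rel=1e-9)
        assert ror.lo95 == pytest.approx(exp["ror_lo"], rel=1e-9)
        assert ror.hi95 == pytest.approx(exp["ror_hi"], rel=1e-9)
        prr = compute_prr(t)
        assert prr.prr == pytest.approx(exp["prr"], rel=1e-9)
        ic = compute_ic(t)
        assert ic.ic == pytest.approx(exp["ic"], rel=1e-9, abs=1e-12)
        assert ic.ic025 == pytest.approx(exp["ic025"], rel=1e-9, abs=1e-12)
        ebgm = compute_ebgm(t)
        assert ebgm.ebgm == pytest.approx(exp["ebgm"], rel=1e-9)
        assert ebgm.ebgm05 == pytest.approx(exp["ebgm05"], rel=1e-9)


def test_yates_chi2_matches_scipy():
    rng = np.random.default_rng(42)
    for _ in range(200):
        a, b, c, d = rng.integers(1, 200, size=4)
        t = ContingencyTable(int(a), int(b), int(c), int(d))
        expected = chi2_contingency([[a, b], [c, d]], correction=True).statistic
        assert compute_prr(t).chi2 == pytest.approx(expected, rel=1e-9, abs=1e-9)


class TestWorkedExamples:
    t = ContingencyTable(10, 90, 100, 9800)

    def test_ror_with_ci(self):
        ror = compute_ror(self.t)
        assert ror.ror == pytest.approx(10.8889, abs=1e-4)
        assert ror.lo95 == pytest.approx(5.5033, abs=1e-3)
        assert ror.hi95 == pytest.approx(21.545, abs=1e-2)

    def test_prr_and_chi2(self):
        prr = compute_prr(self.t)
        assert prr.prr == pytest.approx(9.9, abs=1e-9)
        assert prr.chi2 == pytest.approx(65.514, abs=1e-2)

    def test_ic(self):
        ic = compute_ic(self.t)
        assert ic.ic == pytest.approx(2.7142, abs=1e-3)
        assert ic.ic025 == pytest.approx(1.6371, abs=1e-3)

    def test_ebgm(self):
        ebgm = compute_ebgm(self.t)
        assert ebgm.ebgm == pytest.approx(9.0909, abs=1e-3)
        assert ebgm.ebgm05 == pytest.approx(5.1361, abs=1e-3)


class TestDegenerateAndLimitCases:
    def test_symmetric_table_is_null(self):
        t = ContingencyTable(5, 5, 5, 5)
        assert compute_ror(t).ror == pytest.approx(1.0)
        prr = compute_prr(t)
        assert prr.prr == pytest.approx(1.0)
        assert prr.chi2 == 0.0              # Yates correction floors at 0
        assert compute_ic(t).ic == pytest.approx(0.0, abs=1e-12)
        assert compute_ebgm(t).ebgm == pytest.approx(1.0)

    @pytest.mark.parametrize("cells", [(0, 5, 5, 5), (5, 0, 5, 5),
                                       (5, 5, 0, 5), (5, 5, 5, 0)])
    def test_zero_cells_return_undefined(self, cells):
        t = ContingencyTable(*cells)
        assert math.isnan(compute_ror(t).ror)
        sig = compute_signals(t)
        assert not sig.flag_ror
        assert not sig.flag_any or sig.flag_ic  # IC stays defined by smoothing

    def test_independence_limit_exact(self):
        """Proportional rows: ror = prr = ebgm = 1 and ic = 0 exactly."""
        for a, b, k in [(2, 6, 2), (3, 9, 4), (5, 5, 3)]:
            t = ContingencyTable(a, b, k * a, k * b)  # rows proportional
            assert compute_ror(t).ror == 1.0
            assert compute_prr(t).prr == 1.0
            assert compute_ebgm(t).ebgm == 1.0
            assert compute_ic(t).ic == 0.0          # smoothing cancels at E == a

    def test_sign_property(self):
        """ror > 1 iff prr > 1 iff ad > bc; and then ror > prr."""
        for a, b, c, d in itertools.product([1, 3, 9, 30], repeat=4):
            t = ContingencyTable(a, b, c, d)
            ror = compute_ror(t).ror
            prr = compute_prr(t).prr
            assert (ror > 1) == (a * d > b * c)
            assert (prr > 1) == (a * d > b * c)
            if a * d > b * c:
                assert ror > prr

    def test_monotone_in_a(self):
        b, c, d = 40, 25, 900
        rors = [compute_ror(ContingencyTable(a, b, c, d)).ror
                for a in range(1, 30)]
        ebgms = [compute_ebgm(ContingencyTable(a, b, c, d)).ebgm
                 for a in range(1, 30)]
        assert all(x < y for x, y in zip(rors, rors[1:]))
        assert all(x < y for x, y in zip(ebgms, ebgms[1:]))


class TestCriteria:
    def test_count_gate_blocks_small_n(self):
        t = ContingencyTable(2, 1, 1, 10_000)  # huge ror but n = 2
        sig = compute_signals(t)
        assert not sig.flag_ror
        assert not sig.flag_prr

    def test_independence_all_flags_false(self):
        sig = compute_signals(ContingencyTable(5, 5, 5, 5))
        assert not sig.flag_any

    def test_strong_signal_all_flags_true(self):
        sig = compute_signals(ContingencyTable(100, 100, 100, 99_700))
        assert sig.flag_ror and sig.flag_prr and sig.flag_ic and sig.flag_ebgm
        assert sig.flag_any

    def test_custom_thresholds(self):
        t = ContingencyTable(10, 90, 100, 9800)
        strict = compute_signals(t, criteria={"ebgm05_gt": 100.0})
        assert not strict.flag_ebgm
        assert strict.flag_ror  # other criteria untouched


class TestBuildContingency:
    def test_enumeration(self):
        t = build_contingency([True, True, False, False],
                              [True, False, True, False])
        assert (t.a, t.b, t.c, t.d) == (1, 1, 1, 1)

    def test_no_drug_reports(self):
        t = build_contingency([False, False], [True, False])
        assert t.a == 0 and t.b == 0

    def test_empty_universe_is_error(self):
        with pytest.raises(ValueError, match="empty"):
            build_contingency([], [])

    def test_matches_exhaustive_count_on_random_flags(self):
        rng = np.random.default_rng(3)
        drug = rng.random(10_000) < 0.05
        event = rng.random(10_000) < 0.02
        t = build_contingency(drug, event)
        assert t.a == sum(1 for x, y in zip(drug, event) if x and y)
        assert t.b == sum(1 for x, y in zip(drug, event) if x and not y)
        assert t.c == sum(1 for x, y in zip(drug, event) if not x and y)
        assert t.n == 10_000


def _toy_universe(n=1000, seed=5):
    rng = np.random.default_rng(seed)
    u = pd.DataFrame({
        "sex": rng.choice(["F", "M"], size=n),
        "age_group": rng.choice(["18-65", ">65"], size=n),
    })
    for k in ("ciprofloxacin", "levofloxacin", "moxifloxacin"):
        u[f"drug__{k}"] = rng.random(n) < 0.05
        u[f"route__{k}"] = np.where(u[f"drug__{k}"],
                                    rng.choice(["oral", "intravenous"], size=n),
                                    "")
    for e in ("tendonitis", "tendon_rupture"):
        u[f"event__{e}"] = rng.random(n) < 0.03
    return u


class TestScreen:
    drugs = ["ciprofloxacin", "levofloxacin", "moxifloxacin"]
    events = ["tendonitis", "tendon_rupture"]

    def test_unstratified_shape(self):
        screen = run_signal_screen(_toy_universe(), self.drugs, self.events)
        assert len(screen) == 6
        assert screen["stratum_axis"].eq("none").all()

    def test_route_strata_add_rows(self):
        strata = [StratumSpec("route", "oral"), StratumSpec("route", "intravenous")]
        screen = run_signal_screen(_toy_universe(), self.drugs, self.events, strata)
        assert len(screen) == 18  # 6 unstratified + 12 route rows

    def test_empty_stratum_gives_undefined_row(self):
        u = _toy_universe()
        u["sex"] = "M"  # no female reports at all
        screen = run_signal_screen(u, self.drugs, self.events,
                                   [StratumSpec("sex", "F")])
        female = screen.loc[screen["stratum_level"] == "F"]
        assert len(female) == 6
        assert female["n"].eq(0).all()
        assert not female["flag_any"].any()

    def test_stratified_background_recomputed(self):
        """Sex strata recompute b, c, d inside the stratum's own universe."""
        u = _toy_universe()
        screen = run_signal_screen(u, ["ciprofloxacin"], ["tendonitis"],
                                   [StratumSpec("sex", "F")])
        female = u.loc[u["sex"] == "F"]
        t = build_contingency(female["drug__ciprofloxacin"],
                              female["event__tendonitis"])
        row = screen.loc[screen["stratum_level"] == "F"].iloc[0]
        assert row["n"] == t.a
        if not math.isnan(row["ror"]):
            assert row["ror"] == pytest.approx(compute_ror(t).ror)

    def test_route_stratum_restricts_exposure_not_background(self):
        u = _toy_universe()
        screen = run_signal_screen(u, ["ciprofloxacin"], ["tendonitis"],
                                   [StratumSpec("route", "oral")])
        oral_flag = u["drug__ciprofloxacin"] & (u["route__ciprofloxacin"] == "oral")
        t = build_contingency(oral_flag, u["event__tendonitis"])
        row = screen.loc[screen["stratum_level"] == "oral"].iloc[0]
        assert row["n"] == t.a
        assert t.n == len(u)  # background is the whole universe

    def test_invalid_stratum_rejected(self):
        with pytest.raises(ValueError):
            StratumSpec("sex", "oral")
        with pytest.raises(ValueError):
            StratumSpec("colour", "F")

    def test_deterministic_ordering(self):
        screen1 = run_signal_screen(_toy_universe(), self.drugs, self.events)
        screen2 = run_signal_screen(_toy_universe(), self.drugs, self.events)
        assert screen1.equals(screen2)
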