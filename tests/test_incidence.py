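"""Tests for historical/observed incidence rates and expected counts."""

import numpy as np
import pandas as pd
import pytest

from oebench.fixtures import load_fixture
from oebench.incidence import (
    DesignVariant,
    RateEstimate,
    TimeAtRiskWindow,
    draw_anchor_visits,
    expected_count,
    historical_rates,
    observed_rates,
    person_time_by_stratum,
    totals,
)
from oebench.synthetic import DAYS_PER_YEAR, EventTables

UNADJ = DesignVariant(False, False)
ADJ = DesignVariant(True, False)
ANCH = DesignVariant(False, True)
TAR = TimeAtRiskWindow(1, 28)


class TestTimeAtRiskWindow:
    def test_half_open_bounds(self):
        lo, hi = TAR.bounds(np.array([100]))
        assert lo[0] == 101 and hi[0] == 129  # 28 inclusive days

    @pytest.mark.parametrize("start,end", [(0, 28), (5, 4), (-1, 28)])
    def test_invalid_offsets(self, start, end):
        with pytest.raises(ValueError):
            TimeAtRiskWindow(start, end)


class TestHistoricalRates:
    def test_two_person_half_rate(self):
        tables, exp = load_fixture("two_person_half_rate")
        rates = historical_rates(tables, "nc", TAR, UNADJ, exp["historical_interval"])
        assert len(rates) == 1
        assert rates[0].events == exp["events"]
        assert rates[0].person_time == pytest.approx(exp["person_time_years"])
        assert rates[0].rate == pytest.approx(exp["rate"])

    def test_five_person_strata_match_hand_tally(self):
        tables, exp = load_fixture("five_person_rates")
        rates = historical_rates(tables, "nc", TAR, ADJ, exp["historical_interval"])
        got = {r.stratum: (r.events, r.person_time) for r in rates}
        assert set(got) == set(exp["strata"])
        for stratum, want in exp["strata"].items():
            ev, pt = got[stratum]
            assert ev == want["events"]
            assert pt == pytest.approx(want["person_time_years"])

    def test_marginal_equals_stratum_sum(self):
        tables, exp = load_fixture("five_person_rates")
        marg = historical_rates(tables, "nc", TAR, UNADJ, exp["historical_interval"])
        strat = historical_rates(tables, "nc", TAR, ADJ, exp["historical_interval"])
        assert totals(marg) == totals(strat)  # person-time additivity, exact

    def test_anchored_person_without_visits_contributes_nothing(self):
        tables, exp = load_fixture("two_person_half_rate")
        rates = historical_rates(tables, "nc", TAR, ANCH, exp["historical_interval"])
        assert rates == []  # nobody has a visit -> zero person-time -> non-estimable

    def test_anchored_uses_tar_after_visit(self):
        tables, _ = load_fixture("two_person_half_rate")
        tables.visits = pd.DataFrame({"person_id": [0], "visit_day": [50]})
        # event at day 100 is outside TAR (51..78); person 1 has no visit
        rates = historical_rates(tables, "nc", TAR, ANCH, (0, 365))
        assert totals(rates) == (0, pytest.approx(28 / DAYS_PER_YEAR))

    def test_anchor_draw_deterministic(self):
        tables, _ = load_fixture("five_person_rates")
        tables.visits = pd.DataFrame(
            {"person_id": [0, 0, 0, 2], "visit_day": [10, 20, 30, 40]}
        )
        a1 = draw_anchor_visits(tables, (0, 365), seed=5)
        a2 = draw_anchor_visits(tables, (0, 365), seed=5)
        pd.testing.assert_series_equal(a1, a2)
        assert set(a1.index) == {0, 2}


class TestObservedRates:
    def _hundred_vaccinees(self) -> EventTables:
        t = EventTables.empty()
        n = 100
        t.persons = pd.DataFrame(
            {"person_id": range(n), "sex": ["M"] * n, "birth_day": [-10_000] * n}
        )
        t.observation_periods = pd.DataFrame(
            {"person_id": range(n), "start_day": 0, "end_day": 800}
        )
        t.exposures = pd.DataFrame(
            {"person_id": range(n), "vaccine_id": "v", "exposure_day": 400}
        )
        t.outcomes = pd.DataFrame(
            {"person_id": [0, 1, 2, 3], "outcome_id": "nc", "outcome_day": [405] * 4}
        )
        return t

    def test_rate_arithmetic(self):
        # 100 vaccinees, full 28-day TARs, 4 events -> 4 / (100*28/365.25)
        t = self._hundred_vaccinees()
        rates = observed_rates(t, "v", "nc", TAR, UNADJ, accrual_month=12,
                               surveillance_start=365)
        assert totals(rates) == (4, pytest.approx(100 * 28 / DAYS_PER_YEAR))
        assert rates[0].rate == pytest.approx(4 / (100 * 28 / DAYS_PER_YEAR))

    def test_month_before_first_vaccination_not_estimable(self):
        t = self._hundred_vaccinees()  # vaccinated day 400, month 2
        rates = observed_rates(t, "v", "nc", TAR, UNADJ, 1, surveillance_start=365)
        assert rates == []

    def test_accrual_equals_truncated_data(self):
        # filter-then-compute oracle: accrual at month m == computing on a
        # dataset truncated at the boundary
        t = self._hundred_vaccinees()
        t.exposures["exposure_day"] = np.linspace(370, 700, 100).astype(int)
        rng = np.random.default_rng(0)
        t.outcomes = pd.DataFrame({
            "person_id": rng.integers(0, 100, 60),
            "outcome_id": "nc",
            "outcome_day": rng.integers(370, 760, 60),
        })
        m = 6
        boundary = 365 + 30 * m
        truncated = t.copy()
        truncated.exposures = t.exposures[t.exposures["exposure_day"] < boundary]
        truncated.outcomes = t.outcomes[t.outcomes["outcome_day"] < boundary]
        truncated.observation_periods = t.observation_periods.assign(
            end_day=np.minimum(t.observation_periods["end_day"], boundary)
        )
        got = observed_rates(t, "v", "nc", TAR, ADJ, m, surveillance_start=365)
        want = observed_rates(truncated, "v", "nc", TAR, ADJ, 12, surveillance_start=365)
        assert got == want

    def test_first_event_only(self):
        t = self._hundred_vaccinees()
        # person 0 has 4 events in TAR -> counts once
        t.outcomes = pd.DataFrame(
            {"person_id": [0] * 4, "outcome_id": "nc", "outcome_day": [405, 406, 410, 420]}
        )
        rates = observed_rates(t, "v", "nc", TAR, UNADJ, 12, surveillance_start=365)
        assert totals(rates)[0] == 1

    def test_invalid_month(self):
        t = self._hundred_vaccinees()
        with pytest.raises(ValueError):
            observed_rates(t, "v", "nc", TAR, UNADJ, 0, surveillance_start=365)


class TestExpectedCount:
    def test_two_stratum_arithmetic(self):
        # rates {M:0.1, F:0.3}/py, observed PT {M:10, F:10} py -> E = 4.0
        bg = [RateEstimate("nc", (3, "M"), 1, 10.0), RateEstimate("nc", (3, "F"), 3, 10.0)]
        e = expected_count(bg, {(3, "M"): 10.0, (3, "F"): 10.0})
        assert e == pytest.approx(4.0)

    def test_zero_rates_give_zero_expected(self):
        bg = [RateEstimate("nc", None, 0, 100.0)]
        assert expected_count(bg, {None: 5.0}) == 0.0

    def test_six_stratum_fixture_matches_manual_sum(self):
        _, exp = load_fixture("six_stratum_expected")
        e = expected_count(exp["background"], exp["observed_person_time"])
        assert e == pytest.approx(exp["expected_count"])

    def test_missing_stratum_not_estimable(self):
        bg = [RateEstimate("nc", (0, "M"), 1, 10.0)]
        assert expected_count(bg, {(0, "M"): 1.0, (0, "F"): 1.0}) is None

    def test_no_observed_person_time_not_estimable(self):
        bg = [RateEstimate("nc", None, 1, 10.0)]
        assert expected_count(bg, {None: 0.0}) is None


class TestDesignProperties:
    def test_person_time_additivity_on_simulation(self, nominal_cell):
        tables = nominal_cell["tables"]
        cfg = nominal_cell["config"]
        oid = cfg.outcome_defs[0].outcome_id
        marg = historical_rates(tables, oid, TAR, UNADJ, cfg.historical_window)
        strat = historical_rates(tables, oid, TAR, ADJ, cfg.historical_window)
        ev_m, pt_m = totals(marg)
        ev_s, pt_s = totals(strat)
        assert ev_m == ev_s
        assert pt_m == pytest.approx(pt_s, abs=1e-9)

    def test_anchored_exceeds_unanchored_under_visit_capture(self, visit_capture_cells):
        # directional: anchoring indexes background time right after a visit,
        # where recording is boosted
        tables = visit_capture_cells["tables"]
        cfg = visit_capture_cells["config"]
        higher = 0
        oids = [od.outcome_id for od in cfg.outcome_defs[:30]]
        anchors = draw_anchor_visits(tables, cfg.historical_window, seed=1)
        for oid in oids:
            un = historical_rates(tables, oid, TAR, UNADJ, cfg.historical_window)
            an = historical_rates(tables, oid, TAR, ANCH, cfg.historical_window,
                                  anchors=anchors)
            if an and un and an[0].rate > un[0].rate:
                higher += 1
        assert higher > 0.9 * len(oids)
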