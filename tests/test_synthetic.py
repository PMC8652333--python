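"""Unit and property tests for the synthetic event-table generator."""

import numpy as np
import pytest

from oebench.synthetic import (
    DAYS_PER_YEAR,
    BiasKnobs,
    ConfigError,
    OutcomeDef,
    ScenarioConfig,
    UptakeCurve,
    generate_outcomes,
    generate_population,
    generate_uptake,
    generate_visits,
    simulate_scenario,
)


def _config(**kw) -> ScenarioConfig:
    defaults = dict(n_persons=1000, seed=42, visit_rate=0.0, uptake=UptakeCurve("rapid", 0.0))
    defaults.update(kw)
    cfg = ScenarioConfig(**defaults)
    cfg.validate()
    return cfg


class TestPopulation:
    def test_female_fraction_ccae_like(self):
        # share 51.1% at n=100,000 observed within +-0.005
        cfg = _config(n_persons=100_000, female_fraction=0.511)
        t = generate_population(cfg)
        share = (t.persons["sex"] == "F").mean()
        assert abs(share - 0.511) < 0.005

    def test_empty_population(self):
        t = generate_population(_config(n_persons=0))
        assert len(t.persons) == 0 and len(t.observation_periods) == 0

    def test_observation_covers_both_windows(self):
        cfg = _config(n_persons=50)
        t = generate_population(cfg)
        assert (t.observation_periods["start_day"] == cfg.historical_window[0]).all()
        assert (t.observation_periods["end_day"] == cfg.surveillance_window[1]).all()

    def test_invalid_config_raises(self):
        with pytest.raises(ConfigError):
            ScenarioConfig(n_persons=-1).validate()
        with pytest.raises(ConfigError):
            ScenarioConfig(n_persons=1, historical_window=(0, 400),
                           surveillance_window=(365, 700)).validate()
        with pytest.raises(ConfigError):
            ScenarioConfig(n_persons=1, female_fraction=1.2).validate()


class TestDeterminism:
    def test_identical_seed_identical_tables(self):
        cfg = _config(n_persons=500, visit_rate=2.0, uptake=UptakeCurve("rapid", 0.3),
                      outcome_defs=(OutcomeDef("a", 0.5),))
        assert simulate_scenario(cfg).equals(simulate_scenario(cfg))

    def test_different_seed_different_tables(self):
        cfg1 = _config(n_persons=500, visit_rate=2.0)
        cfg2 = _config(n_persons=500, visit_rate=2.0, seed=43)
        assert not simulate_scenario(cfg1).equals(simulate_scenario(cfg2))

    def test_roundtrip_through_files(self, tmp_path):
        cfg = _config(n_persons=100, visit_rate=2.0, uptake=UptakeCurve("rapid", 0.3),
                      outcome_defs=(OutcomeDef("a", 1.0),))
        t = simulate_scenario(cfg)
        t.write(tmp_path)
        t2 = t.read(tmp_path)
        assert t.equals(t2)


class TestVisits:
    def test_poisson_process_count(self):
        # 3/year x 1,000 persons x 2 years ~ 6,000 +- 3*sqrt(6000)
        cfg = _config(n_persons=1000, visit_rate=3.0,
                      historical_window=(0, 365), surveillance_window=(365, 730))
        t = generate_visits(generate_population(cfg), cfg)
        expected = 3.0 * 1000 * 730 / DAYS_PER_YEAR
        assert abs(len(t.visits) - expected) < 3 * np.sqrt(expected)

    def test_zero_rate_no_visits(self):
        cfg = _config(n_persons=1000, visit_rate=0.0)
        t = generate_visits(generate_population(cfg), cfg)
        assert len(t.visits) == 0

    def test_visits_inside_observation(self):
        cfg = _config(n_persons=200, visit_rate=5.0)
        t = generate_visits(generate_population(cfg), cfg)
        obs = t.observation_periods.set_index("person_id")
        start = obs.loc[t.visits["person_id"], "start_day"].to_numpy()
        end = obs.loc[t.visits["person_id"], "end_day"].to_numpy()
        days = t.visits["visit_day"].to_numpy()
        assert ((days >= start) & (days < end)).all()


class TestUptake:
    def test_rapid_concentration(self):
        cfg = _config(n_persons=10_000, uptake=UptakeCurve("rapid", 0.4))
        t = generate_uptake(generate_population(cfg), cfg)
        assert len(t.exposures) == 4000
        cutoff = cfg.surveillance_window[0] + 60  # end of month 2
        early = (t.exposures["exposure_day"] < cutoff).mean()
        assert early >= 0.8

    def test_slow_spread(self):
        cfg = _config(n_persons=10_000, uptake=UptakeCurve("slow", 0.5))
        t = generate_uptake(generate_population(cfg), cfg)
        month = (t.exposures["exposure_day"] - cfg.surveillance_window[0]) // 30 + 1
        counts = month.value_counts()
        assert set(counts.index) == set(range(1, 13))
        # uniform: each month's share within 3 binomial SE of 1/12
        n = len(t.exposures)
        se = np.sqrt((1 / 12) * (11 / 12) / n)
        assert (abs(counts / n - 1 / 12) < 3 * se + 1 / n).all()

    def test_zero_coverage(self):
        cfg = _config(n_persons=1000, uptake=UptakeCurve("rapid", 0.0))
        t = generate_uptake(generate_population(cfg), cfg)
        assert len(t.exposures) == 0

    def test_one_dose_per_person(self):
        cfg = _config(n_persons=2000, uptake=UptakeCurve("slow", 0.7))
        t = generate_uptake(generate_population(cfg), cfg)
        assert t.exposures["person_id"].is_unique

    def test_age_confounding_shifts_vaccinee_age(self):
        cfg = _config(n_persons=10_000, uptake=UptakeCurve("rapid", 0.3),
                      bias=BiasKnobs(age_confounding_strength=0.5))
        t = generate_uptake(generate_population(cfg), cfg)
        vacc = set(t.exposures["person_id"])
        age = -t.persons["birth_day"] / DAYS_PER_YEAR
        is_vacc = t.persons["person_id"].isin(vacc)
        a, b = age[is_vacc], age[~is_vacc]
        se = np.sqrt(a.var() / len(a) + b.var() / len(b))
        assert a.mean() - b.mean() > 3 * se

    def test_vaccination_day_recorded_as_visit(self):
        cfg = _config(n_persons=500, uptake=UptakeCurve("rapid", 0.5))
        t = generate_uptake(generate_population(cfg), cfg)
        merged = t.exposures.merge(
            t.visits, left_on=["person_id", "exposure_day"],
            right_on=["person_id", "visit_day"],
        )
        assert len(merged) == len(t.exposures)


class TestOutcomes:
    def test_poisson_event_count(self):
        # 0.01/py over ~100,000 person-years -> ~1,000 events +- 3*sqrt(1000)
        cfg = _config(n_persons=50_000, outcome_defs=(OutcomeDef("a", 0.01),))
        t = generate_outcomes(generate_population(cfg), cfg)
        py = 50_000 * 730 / DAYS_PER_YEAR
        expected = 0.01 * py
        assert abs(len(t.outcomes) - expected) < 3 * np.sqrt(expected)

    def test_zero_rate_no_events(self):
        cfg = _config(n_persons=1000, outcome_defs=(OutcomeDef("a", 0.0),))
        t = generate_outcomes(generate_population(cfg), cfg)
        assert len(t.outcomes) == 0

    def test_events_inside_observation(self):
        cfg = _config(n_persons=500, outcome_defs=(OutcomeDef("a", 2.0),))
        t = generate_outcomes(generate_population(cfg), cfg)
        obs = t.observation_periods.set_index("person_id")
        days = t.outcomes["outcome_day"].to_numpy()
        start = obs.loc[t.outcomes["person_id"], "start_day"].to_numpy()
        end = obs.loc[t.outcomes["person_id"], "end_day"].to_numpy()
        assert ((days >= start) & (days < end)).all()

    def test_sex_multiplier(self):
        cfg = _config(n_persons=20_000, female_fraction=0.5,
                      outcome_defs=(OutcomeDef("a", 0.2, sex_multiplier=3.0),))
        t = generate_outcomes(generate_population(cfg), cfg)
        sex = t.persons.set_index("person_id")["sex"]
        n_f = (sex.loc[t.outcomes["person_id"]] == "F").sum()
        n_m = len(t.outcomes) - n_f
        ratio = n_f / n_m
        se = ratio * np.sqrt(1 / n_f + 1 / n_m)
        assert abs(ratio - 3.0) < 3 * se

    def test_visit_capture_boost_rate_ratio(self):
        # empirical rate in (visit, visit+30] windows ~ 2x the rate elsewhere,
        # checked against an independent per-person day classification
        cfg = _config(
            n_persons=8_000, visit_rate=2.0,
            outcome_defs=(OutcomeDef("a", 0.5),),
            bias=BiasKnobs(visit_capture_boost=2.0, visit_capture_days=30),
        )
        t = generate_visits(generate_population(cfg), cfg)
        t = generate_outcomes(t, cfg)
        h0, s1 = cfg.historical_window[0], cfg.surveillance_window[1]
        n_days = s1 - h0
        boosted = {}
        for pid, grp in t.visits.groupby("person_id"):
            mask = np.zeros(n_days, dtype=bool)
            for v in grp["visit_day"]:
                mask[v + 1 - h0 : min(v + 31 - h0, n_days)] = True
            boosted[pid] = mask
        boosted_days = sum(m.sum() for m in boosted.values())
        plain_days = len(t.persons) * n_days - boosted_days
        ev_boosted = sum(
            bool(pid in boosted and boosted[pid][day - h0])
            for pid, day in zip(t.outcomes["person_id"], t.outcomes["outcome_day"])
        )
        ev_plain = len(t.outcomes) - ev_boosted
        ratio = (ev_boosted / boosted_days) / (ev_plain / plain_days)
        se = ratio * np.sqrt(1 / ev_boosted + 1 / ev_plain)
        assert abs(ratio - 2.0) < 3 * se

    def test_window_rate_balance_unbiased(self):
        # neutral knobs, no seasonality/trend: historical and surveillance
        # rates agree within 3 SE for every outcome
        cfg = _config(
            n_persons=20_000,
            outcome_defs=tuple(OutcomeDef(f"o{i}", 0.1) for i in range(5)),
        )
        t = generate_outcomes(generate_population(cfg), cfg)
        h0, h1 = cfg.historical_window
        s0, s1 = cfg.surveillance_window
        for oid, grp in t.outcomes.groupby("outcome_id"):
            d = grp["outcome_day"]
            n_h = ((d >= h0) & (d < h1)).sum()
            n_s = ((d >= s0) & (d < s1)).sum()
            expected_ratio = (h1 - h0) / (s1 - s0)
            ratio = n_h / n_s
            se = ratio * np.sqrt(1 / n_h + 1 / n_s)
            assert abs(ratio - expected_ratio) < 3 * se, oid

    def test_secular_trend_ratio(self):
        # log-linear trend: window totals match the integrated analytic ratio
        slope = 0.5
        cfg = _config(
            n_persons=30_000,
            outcome_defs=(OutcomeDef("a", 0.1, secular_slope=slope),),
        )
        t = generate_outcomes(generate_population(cfg), cfg)
        h0, h1 = cfg.historical_window
        s0, s1 = cfg.surveillance_window
        d = t.outcomes["outcome_day"]
        n_h = ((d >= h0) & (d < h1)).sum()
        n_s = ((d >= s0) & (d < s1)).sum()

        def integral(a, b):
            k = slope / DAYS_PER_YEAR
            return (np.exp(k * b) - np.exp(k * a)) / k

        expected_ratio = integral(h0, h1) / integral(s0, s1)
        ratio = n_h / n_s
        se = ratio * np.sqrt(1 / n_h + 1 / n_s)
        assert abs(ratio - expected_ratio) < 3 * se

    def test_healthy_vaccinee_shift(self):
        cfg = _config(
            n_persons=20_000, uptake=UptakeCurve("rapid", 0.5),
            outcome_defs=(OutcomeDef("a", 0.2),),
            bias=BiasKnobs(healthy_vaccinee_shift=0.5),
        )
        t = generate_uptake(generate_population(cfg), cfg)
        t = generate_outcomes(t, cfg)
        vacc = set(t.exposures["person_id"])
        is_vacc = t.outcomes["person_id"].isin(vacc)
        n_v, n_u = is_vacc.sum(), (~is_vacc).sum()
        # equal group sizes by construction, so the count ratio estimates the shift
        ratio = n_v / n_u
        se = ratio * np.sqrt(1 / n_v + 1 / n_u)
        assert abs(ratio - 0.5) < 3 * se
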