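import numpy as np
import pandas as pd
import pytest

from carecontacts import (
    CohortRule,
    SimulationConfig,
    ValidationError,
    build_denominators,
    eligible_weeks,
    generate_chronic_codes,
    generate_population,
)
from carecontacts.cohort import age_band, eligibility_mask
from carecontacts.weekgrid import week_grid


def sundays(start, end):
    return set(week_grid(start, end))


GRID = week_grid()


class TestRunIn:
    def test_one_year_run_in_delays_entry(self, patient_factory):
        patient = patient_factory(reg_start="2019-06-01")
        rule = CohortRule(condition="depression", min_age_years=11)
        weeks = eligible_weeks(patient, None, rule, GRID)
        # run-in completes 2020-06-01; first grid Sunday on/after is June 7
        assert set(weeks) == sundays("2020-06-07", "2020-07-18")

    def test_no_week_before_registration_plus_one_year(self, patient_factory):
        patient = patient_factory(reg_start="2016-06-15")
        rule = CohortRule(condition="depression")
        weeks = eligible_weeks(patient, None, rule, GRID)
        assert min(weeks) == pd.Timestamp("2017-06-18")


class TestChronicEntry:
    def test_diabetes_entry_on_first_code(
        self, patient_factory, events_factory, codelists
    ):
        patient = patient_factory(reg_start="2015-01-01")
        events = events_factory([("P1", "2018-03-15", "DIABETES_DX")])
        rule = CohortRule(
            condition="diabetic_emergency",
            chronic_mode="from_first_code",
            chronic_codelist="diabetes",
        )
        weeks = eligible_weeks(patient, events, rule, GRID, codelists)
        assert set(weeks) == sundays("2018-03-18", "2020-07-18")

    def test_no_chronic_code_means_never_eligible(
        self, patient_factory, events_factory, codelists
    ):
        patient = patient_factory(reg_start="2015-01-01")
        rule = CohortRule(
            condition="diabetic_emergency",
            chronic_mode="from_first_code",
            chronic_codelist="diabetes",
        )
        weeks = eligible_weeks(
            patient, events_factory([]), rule, GRID, codelists
        )
        assert len(weeks) == 0


class TestAsthmaCurrency:
    RULE = CohortRule(
        condition="asthma_exacerbation",
        chronic_mode="asthma_current",
        chronic_codelist="asthma",
    )

    def test_adult_three_year_window_lapses(
        self, patient_factory, events_factory, codelists
    ):
        patient = patient_factory(birth="1980-07-01", reg_start="2010-01-01")
        events = events_factory([("P1", "2017-02-01", "ASTHMA_DX")])
        weeks = eligible_weeks(patient, events, self.RULE, GRID, codelists)
        # current while week_start < 2017-02-01 + 3 years
        assert set(weeks) == sundays("2017-02-05", "2020-01-26")

    def test_later_code_reopens_eligibility(
        self, patient_factory, events_factory, codelists
    ):
        patient = patient_factory(birth="1980-07-01", reg_start="2010-01-01")
        events = events_factory(
            [("P1", "2017-02-01", "ASTHMA_DX"), ("P1", "2020-03-01", "ASTHMA_DX")]
        )
        weeks = eligible_weeks(patient, events, self.RULE, GRID, codelists)
        expected = sundays("2017-02-05", "2020-01-26") | sundays(
            "2020-03-01", "2020-07-18"
        )
        assert set(weeks) == expected

    def test_child_two_year_window(self, patient_factory, events_factory, codelists):
        patient = patient_factory(birth="2005-07-01", reg_start="2010-01-01")
        events = events_factory([("P1", "2017-02-01", "ASTHMA_DX")])
        weeks = eligible_weeks(patient, events, self.RULE, GRID, codelists)
        # under 11 until 2016-07-01; aged 11 throughout 2017-18; 2-year
        # child window ends before the 18th birthday matters
        assert set(weeks) == sundays("2017-02-05", "2019-01-27")

    def test_copd_reclassification_disqualifies_older_asthma_records(
        self, patient_factory, events_factory, codelists
    ):
        patient = patient_factory(birth="1970-07-01", reg_start="2010-01-01")
        events = events_factory(
            [("P1", "2018-05-01", "ASTHMA_DX"), ("P1", "2019-01-01", "COPD_DX")]
        )
        weeks = eligible_weeks(patient, events, self.RULE, GRID, codelists)
        assert len(weeks) == 0

    def test_copd_code_beyond_two_years_does_not_reclassify(
        self, patient_factory, events_factory, codelists
    ):
        patient = patient_factory(birth="1970-07-01", reg_start="2010-01-01")
        events = events_factory(
            [("P1", "2017-05-01", "ASTHMA_DX"), ("P1", "2019-06-01", "COPD_DX")]
        )
        weeks = eligible_weeks(patient, events, self.RULE, GRID, codelists)
        assert set(weeks) == sundays("2017-05-07", "2020-04-26")

    def test_under_forty_asthma_not_reclassified(
        self, patient_factory, events_factory, codelists
    ):
        patient = patient_factory(birth="1990-07-01", reg_start="2010-01-01")
        events = events_factory(
            [("P1", "2018-05-01", "ASTHMA_DX"), ("P1", "2019-01-01", "COPD_DX")]
        )
        weeks = eligible_weeks(patient, events, self.RULE, GRID, codelists)
        assert len(weeks) > 0


class TestCopdRule:
    def test_requires_both_copd_and_smoking_history(
        self, patient_factory, events_factory, codelists
    ):
        rule = CohortRule(
            condition="copd_exacerbation",
            min_age_years=41,
            chronic_mode="from_first_code",
            chronic_codelist="copd",
            requires_smoking_history=True,
        )
        patient = patient_factory(birth="1960-07-01", reg_start="2010-01-01")
        no_smoking = events_factory([("P1", "2018-01-01", "COPD_DX")])
        assert len(eligible_weeks(patient, no_smoking, rule, GRID, codelists)) == 0
        both = events_factory(
            [("P1", "2018-01-01", "COPD_DX"), ("P1", "2012-05-01", "SMOKING")]
        )
        weeks = eligible_weeks(patient, both, rule, GRID, codelists)
        assert min(weeks) == pd.Timestamp("2018-01-07")


class TestLifeAndDeath:
    def test_no_resurrection_after_death_or_deregistration(self, patient_factory):
        rule = CohortRule(condition="depression")
        dead = patient_factory(reg_start="2010-01-01", death="2019-05-15")
        weeks = eligible_weeks(dead, None, rule, GRID)
        # week starting 2019-05-12 begins before death -> still counted
        assert max(weeks) == pd.Timestamp("2019-05-12")
        gone = patient_factory(reg_start="2010-01-01", reg_end="2019-05-12")
        weeks = eligible_weeks(gone, None, rule, GRID)
        # deregistration exactly on a week start excludes that week
        assert max(weeks) == pd.Timestamp("2019-05-05")

    def test_minimum_age_respected(self, patient_factory):
        rule = CohortRule(condition="stroke", min_age_years=31)
        patient = patient_factory(birth="1988-07-01", reg_start="2010-01-01")
        weeks = eligible_weeks(patient, None, rule, GRID)
        # turns 31 on 2019-07-01 (a Monday); first eligible Sunday July 7
        assert min(weeks) == pd.Timestamp("2019-07-07")


class TestDenominators:
    def test_singleton_patient_yields_unit_series(self, patient_factory, codelists):
        patients = pd.DataFrame([patient_factory(reg_start="2015-01-01")])
        rule = CohortRule(condition="depression")
        out = build_denominators(
            patients, None, rule, GRID, ["sex"], codelists
        )
        overall = out[out["stratifier"] == "overall"]
        assert (overall["count"] == 1).all()
        female = out[(out["stratifier"] == "sex") & (out["stratum"] == "female")]
        assert (female["count"] == 1).all()
        assert set(out[out["stratifier"] == "sex"]["stratum"]) == {"female"}

    def test_unknown_stratifier_rejected(self, patient_factory):
        patients = pd.DataFrame([patient_factory()])
        with pytest.raises(ValidationError, match="deprivation"):
            build_denominators(
                patients, None, CohortRule(condition="x"), GRID, ["deprivation"]
            )

    def test_stratum_counts_partition_overall_on_synthetic_population(
        self, codelists
    ):
        cfg = SimulationConfig(n_patients=1000, seed=21)
        patients = generate_population(cfg)
        events = generate_chronic_codes(patients, cfg)
        rule = CohortRule(condition="depression")
        out = build_denominators(
            patients, events, rule, GRID, ["age_band", "sex", "region"], codelists
        )
        overall = (
            out[out["stratifier"] == "overall"]
            .set_index("week_start")["count"]
            .sort_index()
        )
        assert overall.max() > 0
        for s in ("age_band", "sex", "region"):
            total = (
                out[out["stratifier"] == s]
                .groupby("week_start")["count"]
                .sum()
                .sort_index()
            )
            assert (total == overall).all(), s

    def test_relaxing_chronic_requirement_never_shrinks_denominator(
        self, codelists
    ):
        cfg = SimulationConfig(n_patients=400, seed=22)
        patients = generate_population(cfg)
        events = generate_chronic_codes(patients, cfg)
        strict = CohortRule(
            condition="diabetic_emergency",
            chronic_mode="from_first_code",
            chronic_codelist="diabetes",
        )
        relaxed = CohortRule(condition="diabetic_emergency")
        d_strict = build_denominators(patients, events, strict, GRID, [], codelists)
        d_relaxed = build_denominators(patients, events, relaxed, GRID, [], codelists)
        s = d_strict[d_strict["stratifier"] == "overall"]["count"].to_numpy()
        r = d_relaxed[d_relaxed["stratifier"] == "overall"]["count"].to_numpy()
        assert (r >= s).all()

    def test_age_band_migration_at_birthday_week(self, patient_factory, codelists):
        patients = pd.DataFrame(
            [patient_factory(birth="1999-07-01", reg_start="2005-01-01")]
        )
        rule = CohortRule(condition="depression")
        out = build_denominators(patients, None, rule, GRID, ["age_band"], codelists)
        bands = out[out["stratifier"] == "age_band"]
        young = bands[bands["stratum"] == "11-20"].set_index("week_start")["count"]
        old = bands[bands["stratum"] == "21-30"].set_index("week_start")["count"]
        # 21st birthday 2020-07-01 falls inside the week starting June 28;
        # at that week's start the patient is still 20
        assert young[pd.Timestamp("2020-06-28")] == 1
        assert old[pd.Timestamp("2020-07-05")] == 1
        assert young[pd.Timestamp("2020-07-05")] == 0


def test_age_band_labels():
    assert age_band(11) == "11-20"
    assert age_band(20) == "11-20"
    assert age_band(21) == "21-30"
    assert age_band(95) == "91-100"
    assert age_band(104) == "91-100"


def test_brute_force_recount_matches_vectorised_masks(codelists):
    # independent per-patient/per-week recount on a small population
    cfg = SimulationConfig(n_patients=60, seed=33)
    patients = generate_population(cfg)
    events = generate_chronic_codes(patients, cfg)
    rule = CohortRule(
        condition="diabetic_emergency",
        chronic_mode="from_first_code",
        chronic_codelist="diabetes",
    )
    cal = week_grid()
    out = build_denominators(patients, events, rule, cal, [], codelists)
    overall = out[out["stratifier"] == "overall"].set_index("week_start")["count"]
    dia_codes = codelists["diabetes"].codes
    for w in [cal[0], cal[60], cal[120], cal[-1]]:
        n = 0
        for _, p in patients.iterrows():
            ev = events[events["patient_id"] == p["patient_id"]]
            first_dx = ev.loc[ev["code"].isin(dia_codes), "event_date"].min()
            age = w.year - p["birth_date"].year - (
                (w.month, w.day) < (p["birth_date"].month, p["birth_date"].day)
            )
            ok = (
                age >= 11
                and w >= p["registration_start"] + pd.DateOffset(years=1)
                and (pd.isna(p["registration_end"]) or w < p["registration_end"])
                and (pd.isna(p["death_date"]) or w < p["death_date"])
                and pd.notna(first_dx)
                and w >= first_dx
            )
            n += bool(ok)
        assert overall[w] == n
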