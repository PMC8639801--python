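"""Index-admission selection, planned/unplanned classification and the
(0, 30]-day outcome window."""

import numpy as np
import pandas as pd
import pytest

from readmitwx.cohort import (
    age_band,
    assign_disease_groups,
    assign_season,
    build_cohort,
    classify_planned,
    identify_index_admissions,
    label_outcome,
    load_planned_codes,
    subgroup_membership,
)

from conftest import make_bundle

W0 = pd.Timestamp("2017-01-01")
W1 = pd.Timestamp("2018-12-31")


def visits_df(rows, site="A"):
    return pd.DataFrame(
        rows,
        columns=["visit_id", "person_id", "visit_kind", "admit_date",
                 "discharge_date", "discharged_alive"],
    ).assign(site_id=site).assign(
        admit_date=lambda d: pd.to_datetime(d["admit_date"]),
        discharge_date=lambda d: pd.to_datetime(d["discharge_date"]),
    )


def persons_df(rows):
    return pd.DataFrame(
        rows, columns=["person_id", "gender", "year_of_birth", "location_id"]
    )


@pytest.fixture
def six_visit_bundle():
    """2 under-age, 1 in-hospital death, 3 qualifying."""
    persons = persons_df(
        [
            ("P1", "male", 1940, "L1"),    # 77 in 2017
            ("P2", "female", 1955, "L1"),  # 62: under age
            ("P3", "male", 1945, "L1"),    # 72
        ]
    )
    visits = visits_df(
        [
            ("V1", "P1", "inpatient", "2017-03-01", "2017-03-05", True),   # qualifies
            ("V2", "P2", "inpatient", "2017-04-01", "2017-04-03", True),   # under age
            ("V3", "P2", "emergency", "2018-05-01", "2018-05-01", True),   # still 63
            ("V4", "P3", "inpatient", "2017-06-01", "2017-06-10", False),  # died
            ("V5", "P3", "emergency", "2017-09-01", "2017-09-02", True),   # qualifies
            ("V6", "P1", "inpatient", "2018-02-01", "2018-02-04", True),   # qualifies
        ]
    )
    conditions = pd.DataFrame(
        {"person_id": ["P1"], "icd10_code": ["I50"], "start_date": [pd.Timestamp("2017-03-01")]}
    )
    return make_bundle(persons=persons, visits=visits, conditions=conditions)


def test_six_visit_fixture(six_visit_bundle):
    events = identify_index_admissions(six_visit_bundle, (W0, W1))
    assert sorted(events["visit_id"]) == ["V1", "V5", "V6"]
    assert (events["age_at_index"] >= 65).all()
    v1 = events.set_index("visit_id").loc["V1"]
    assert v1["length_of_stay"] == 4
    assert v1["season"] == "spring"
    assert v1["age_band"] == "70s"


def test_under_age_and_death_excluded(six_visit_bundle):
    events = identify_index_admissions(six_visit_bundle, (W0, W1))
    assert "V2" not in set(events["visit_id"])  # aged 62
    assert "V4" not in set(events["visit_id"])  # not discharged alive


def test_row_order_invariance(six_visit_bundle):
    shuffled = make_bundle(
        persons=six_visit_bundle.persons.sample(frac=1, random_state=1).reset_index(drop=True),
        visits=six_visit_bundle.visits.sample(frac=1, random_state=2).reset_index(drop=True),
        conditions=six_visit_bundle.conditions,
    )
    a = identify_index_admissions(six_visit_bundle, (W0, W1))
    b = identify_index_admissions(shuffled, (W0, W1))
    pd.testing.assert_frame_equal(a, b)


def test_classify_planned():
    lists = load_planned_codes()
    assert classify_planned(["Z511"], lists)          # chemotherapy session
    assert classify_planned(["Z50.1", "I10"], lists)  # rehabilitation
    assert not classify_planned([], lists)            # no diagnosis -> unplanned
    assert not classify_planned(["I50", "J44"], lists)


@pytest.mark.parametrize(
    "date, season",
    [("2017-04-10", "spring"), ("2017-12-31", "winter"), ("2017-06-01", "summer"),
     ("2017-09-30", "fall"), ("2017-02-28", "winter")],
)
def test_assign_season(date, season):
    assert assign_season(date) == season


def test_seasons_partition_year():
    from readmitwx.cohort import _SEASON_OF_MONTH
    counts = pd.Series(_SEASON_OF_MONTH).value_counts()
    assert sorted(counts.index) == ["fall", "spring", "summer", "winter"]
    assert (counts == 3).all()


@pytest.mark.parametrize("age, band", [(65, "60s"), (69, "60s"), (70, "70s"),
                                       (79, "70s"), (85, "80s"), (93, "90s")])
def test_age_bands(age, band):
    assert age_band(age) == band


def outcome_fixture(readmit_rows, readmit_conditions=None):
    """One qualifying index stay (discharge 2017-06-10) plus candidate
    subsequent visits."""
    persons = persons_df([("P1", "male", 1940, "L1")])
    visits = visits_df(
        [("V1", "P1", "inpatient", "2017-06-01", "2017-06-10", True), *readmit_rows]
    )
    conditions = pd.DataFrame(
        {"person_id": ["P1"], "icd10_code": ["I50"], "start_date": [pd.Timestamp("2017-06-01")]}
    )
    if readmit_conditions is not None:
        conditions = pd.concat([conditions, readmit_conditions], ignore_index=True)
    bundle = make_bundle(persons=persons, visits=visits, conditions=conditions)
    events = identify_index_admissions(bundle, (W0, W1))
    return label_outcome(events, bundle).set_index("visit_id").loc["V1"], bundle


def test_unplanned_er_day5_is_outcome():
    row, _ = outcome_fixture([("V2", "P1", "emergency", "2017-06-15", "2017-06-16", True)])
    assert row["outcome"] == 1
    assert row["readmission_date"] == pd.Timestamp("2017-06-15")


def test_day31_not_outcome():
    row, _ = outcome_fixture([("V2", "P1", "emergency", "2017-07-11", "2017-07-12", True)])
    assert row["outcome"] == 0


def test_day30_is_outcome():
    row, _ = outcome_fixture([("V2", "P1", "emergency", "2017-07-10", "2017-07-11", True)])
    assert row["outcome"] == 1


def test_same_day_is_transfer_not_readmission():
    row, _ = outcome_fixture([("V2", "P1", "emergency", "2017-06-10", "2017-06-11", True)])
    assert row["outcome"] == 0


def test_inpatient_route_readmission_not_counted():
    row, _ = outcome_fixture([("V2", "P1", "inpatient", "2017-06-15", "2017-06-20", True)])
    assert row["outcome"] == 0


def test_planned_readmission_not_counted():
    chemo = pd.DataFrame(
        {"person_id": ["P1"], "icd10_code": ["Z511"], "start_date": [pd.Timestamp("2017-06-15")]}
    )
    row, _ = outcome_fixture(
        [("V2", "P1", "emergency", "2017-06-15", "2017-06-16", True)], chemo
    )
    assert row["outcome"] == 0


def test_earliest_readmission_supplies_date():
    row, _ = outcome_fixture(
        [
            ("V2", "P1", "emergency", "2017-06-20", "2017-06-21", True),
            ("V3", "P1", "emergency", "2017-06-12", "2017-06-13", True),
        ]
    )
    assert row["readmission_date"] == pd.Timestamp("2017-06-12")


def test_disease_groups():
    persons = persons_df([("P1", "male", 1940, "L1"), ("P2", "female", 1941, "L1")])
    visits = visits_df(
        [
            ("V1", "P1", "inpatient", "2017-03-01", "2017-03-05", True),
            ("V2", "P2", "inpatient", "2017-04-01", "2017-04-05", True),
        ]
    )
    conditions = pd.DataFrame(
        {
            "person_id": ["P1", "P2"],
            "icd10_code": ["I50", "K35"],
            "start_date": pd.to_datetime(["2017-03-01", "2017-04-01"]),
        }
    )
    bundle = make_bundle(persons=persons, visits=visits, conditions=conditions)
    events = identify_index_admissions(bundle, (W0, W1))
    groups = assign_disease_groups(events, bundle.conditions)
    got = dict(zip(events["visit_id"], groups))
    assert got == {"V1": "I", "V2": "other"}


def test_subgroup_multi_membership():
    persons = persons_df([("P1", "male", 1940, "L1")])
    visits = visits_df([("V1", "P1", "inpatient", "2017-03-01", "2017-03-05", True)])
    conditions = pd.DataFrame(
        {
            "person_id": ["P1", "P1"],
            "icd10_code": ["M16", "J44"],
            "start_date": pd.to_datetime(["2017-03-01", "2017-03-02"]),
        }
    )
    bundle = make_bundle(persons=persons, visits=visits, conditions=conditions)
    events = identify_index_admissions(bundle, (W0, W1))
    members = subgroup_membership(events, bundle.conditions)
    assert set(members["chapter"]) == {"M", "J"}
    # principal diagnosis (first-listed) decides the single-group assignment
    assert assign_disease_groups(events, bundle.conditions).iloc[0] == "M"


def test_planted_outcomes_recovered_exactly(small_study):
    """Every planted readmission is relabelled 1 by the cohort stage and no
    un-planted index event is labelled 1 (the generator spaces a person's
    spontaneous visits beyond the outcome window)."""
    for site in ("internal", "external"):
        bundle = small_study.bundle(site)
        cohort = build_cohort(bundle, window=small_study.config.window)
        truth = small_study.truth[small_study.truth["site_id"] == bundle.site_id]
        merged = cohort.merge(truth[["visit_id", "outcome"]], on="visit_id",
                              suffixes=("", "_truth"), how="inner")
        assert len(merged) == len(truth)
        assert (merged["outcome"] == merged["outcome_truth"]).all()
        # events not in the truth record are the planted readmission visits
        extra = cohort[~cohort["visit_id"].isin(truth["visit_id"])]
        assert (extra["outcome"] == 0).all()
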